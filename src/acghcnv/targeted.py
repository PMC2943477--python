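"""Targeted very-high-density array analysis of candidate CNV regions.

Each candidate region (probe spacing ~214 bp) is segmented by circular
binary segmentation (CBS): recursively find the arc of the circularized
probe series whose mean differs most from its complement, test the split by
permutation, and keep splitting while significant. Segments are then tested
against negative-control regions with a Mann-Whitney U test; a segment is a
CNV only if P < 0.05 *and* its median standardized log2 ratio exceeds twice
the standard deviation of the control-region medians. A region with at
least one CNV segment is copy-number variant; its architecture is
``simple`` (one contiguous CNV) or ``complex`` (CNV segments separated by
normal-copy gaps, or mixed losses and gains).

The module also provides the log2-ratio threshold sweep that relates a
stringency threshold on mean standardized ratios to the false positive rate
and to the fraction of verified calls rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class ControlStats:
    """Summary of the negative-control regions on the targeted array."""

    control_medians: list[float]
    pooled_values: np.ndarray
    sd_of_medians: float

    @classmethod
    def from_regions(cls, control_values: list[np.ndarray], ddof: int = 1) -> "ControlStats":
        """Build from per-control-region standardized ratio vectors.

        ``sd_of_medians`` is the sample s.d. (ddof=1) of the per-region
        medians; at least two control regions are required.
        """
        if len(control_values) < 2:
            raise ValueError("need >=2 control regions for sd_of_medians")
        medians = [float(np.median(np.asarray(v, dtype=float))) for v in control_values]
        pooled = np.concatenate([np.asarray(v, dtype=float) for v in control_values])
        return cls(medians, pooled, float(np.std(medians, ddof=ddof)))


@dataclass
class CbsParams:
    alpha: float = 0.01
    n_perm: int = 1000
    min_probes: int = 10
    seed: int = 0


def _max_arc_stat(x: np.ndarray) -> tuple[float, int, int]:
    """Maximum |t|-like statistic over all arcs of the circularized series.

    For the arc (i, j] (i < j), the statistic compares the arc mean with the
    complement mean, scaled by sqrt(1/k + 1/(n-k)). Returns (stat, i, j).
    """
    n = x.size
    s = np.concatenate([[0.0], np.cumsum(x)])
    total = s[-1]
    i_idx = np.arange(n)
    # matrix of arc sums: sum(i, j] = s[j] - s[i], j in (i, n]
    S = s[None, 1:] - s[:-1, None]  # S[i, j-1] = sum over (i, j]
    k = (np.arange(1, n + 1)[None, :] - i_idx[:, None]).astype(float)
    valid = (k >= 1) & (k <= n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(S / k - (total - S) / (n - k)) / np.sqrt(1.0 / k + 1.0 / (n - k))
    t[~valid] = -np.inf
    flat = int(np.argmax(t))
    i, jm1 = divmod(flat, n)
    return float(t[i, jm1]), i, jm1 + 1


def _split_significant(x: np.ndarray, params: CbsParams, rng: np.random.Generator) -> bool:
    """Permutation test of the best circular split; early-stops once the
    add-one P is guaranteed to exceed alpha."""
    obs, _, _ = _max_arc_stat(x)
    if not np.isfinite(obs):
        return False
    budget = params.n_perm
    stop_at = int(np.ceil(params.alpha * (params.n_perm + 1)))  # exceedances => p > alpha
    exceed = 0
    done = 0
    while done < budget:
        b = min(50, budget - done)
        for _ in range(b):
            stat, _, _ = _max_arc_stat(rng.permutation(x))
            exceed += stat >= obs
        done += b
        if exceed >= stop_at:
            return False
    return (1 + exceed) / (params.n_perm + 1) <= params.alpha


def cbs_segment(values: np.ndarray, params: CbsParams | None = None) -> list[tuple[int, int]]:
    """Circular binary segmentation of an ordered probe series.

    Returns half-open probe-index segments tiling [0, n). Series shorter
    than ``min_probes`` come back as a single segment with a warning.
    Deterministic for a fixed ``params.seed``.
    """
    params = params or CbsParams()
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < params.min_probes:
        log.warning("only %d probes; returning a single segment", n)
        return [(0, n)]
    rng = np.random.default_rng(params.seed)
    segments: list[tuple[int, int]] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        sub = x[lo:hi]
        if hi - lo < 2 or np.allclose(sub, sub[0]) or not _split_significant(sub, params, rng):
            segments.append((lo, hi))
            continue
        _, i, j = _max_arc_stat(sub)
        cuts = sorted({lo, lo + i, lo + j, hi})
        parts = [(a, b) for a, b in zip(cuts, cuts[1:]) if b > a]
        if len(parts) == 1:  # arc spans everything; no real split
            segments.append((lo, hi))
        else:
            stack.extend(parts)
    return sorted(segments)


def test_segment(segment_values: np.ndarray, controls: ControlStats,
                 alpha: float = 0.05, sd_mult: float = 2.0) -> tuple[float, str]:
    """Mann-Whitney test of a segment against pooled control probes.

    Returns (two-sided P, state). The state is non-normal only when P <
    alpha *and* |median| > sd_mult x s.d. of control medians; the sign of
    the median distinguishes loss from gain. The amplitude rule is applied
    symmetrically to losses and gains.
    """
    if controls is None:
        raise ValueError("control statistics are required")
    seg = np.asarray(segment_values, dtype=float)
    if seg.size < 3:
        raise ValueError("segment needs >=3 probes")
    p = float(stats.mannwhitneyu(seg, controls.pooled_values,
                                 alternative="two-sided").pvalue)
    med = float(np.median(seg))
    if p < alpha and abs(med) > sd_mult * controls.sd_of_medians:
        return p, ("loss" if med < 0 else "gain")
    return p, "normal"


@dataclass
class SegmentClassification:
    """Per-region targeted-array result."""

    region_id: str
    strain: str
    segments: pd.DataFrame  # start, end (probe idx), median_ratio, mw_p, state
    region_call: str = field(init=False)  # variant | non-variant
    architecture: str = field(init=False)  # simple | complex | non-variant

    def __post_init__(self) -> None:
        self.region_call = call_region(self.segments)
        self.architecture = classify_architecture(self.segments)


def call_region(segments: pd.DataFrame) -> str:
    """A region is copy-number variant iff >=1 segment is non-normal."""
    return "variant" if (segments["state"] != "normal").any() else "non-variant"


def _coalesce(segments: pd.DataFrame) -> pd.DataFrame:
    """Merge adjacent segments of equal state (probe-index-contiguous)."""
    rows = []
    for seg in segments.sort_values("start").itertuples(index=False):
        if rows and rows[-1]["state"] == seg.state and rows[-1]["end"] == seg.start:
            rows[-1]["end"] = seg.end
        else:
            rows.append({"start": seg.start, "end": seg.end, "state": seg.state})
    return pd.DataFrame(rows)


def classify_architecture(segments: pd.DataFrame) -> str:
    """Label a tested region simple, complex, or non-variant.

    After coalescing adjacent equal-state segments: complex if there are
    >=2 non-normal runs (necessarily separated by normal gaps) or if both
    losses and gains are present; simple if exactly one non-normal run;
    non-variant otherwise.
    """
    runs = _coalesce(segments)
    nn = runs[runs["state"] != "normal"]
    if nn.empty:
        return "non-variant"
    if len(nn) >= 2 or nn["state"].nunique() > 1:
        return "complex"
    return "simple"


def classify_region(
    region_id: str,
    strain: str,
    values: np.ndarray,
    controls: ControlStats,
    cbs: CbsParams | None = None,
    alpha: float = 0.05,
    sd_mult: float = 2.0,
) -> SegmentClassification:
    """Segment, test, and classify one targeted region for one strain.

    Segments with fewer than 3 probes are merged into the nearer (shorter-
    distance, then earlier) neighbor before testing, and logged.
    """
    x = np.asarray(values, dtype=float)
    segs = cbs_segment(x, cbs)
    # fold tiny segments into a neighbor so the rank test is defined
    changed = True
    while changed and len(segs) > 1:
        changed = False
        for k, (a, b) in enumerate(segs):
            if b - a < 3:
                log.info("region %s: merging %d-probe segment into neighbor", region_id, b - a)
                if k == 0:
                    segs[1] = (a, segs[1][1])
                elif k == len(segs) - 1:
                    segs[k - 1] = (segs[k - 1][0], b)
                else:  # nearer = the shorter adjacent segment
                    left, right = segs[k - 1], segs[k + 1]
                    if (left[1] - left[0]) <= (right[1] - right[0]):
                        segs[k - 1] = (left[0], b)
                    else:
                        segs[k + 1] = (a, right[1])
                del segs[k]
                changed = True
                break
    rows = []
    for a, b in segs:
        seg = x[a:b]
        if b - a < 3:  # single tiny region: test undefined, call it normal
            rows.append((a, b, float(np.median(seg)), float("nan"), "normal"))
            continue
        p, state = test_segment(seg, controls, alpha=alpha, sd_mult=sd_mult)
        rows.append((a, b, float(np.median(seg)), p, state))
    frame = pd.DataFrame(rows, columns=["start", "end", "median_ratio", "mw_p", "state"])
    return SegmentClassification(region_id, strain, frame)


def fpr_threshold_sweep(
    calls: pd.DataFrame,
    thresholds: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """FPR versus rejected-verified curve over acceptance thresholds.

    ``calls`` has columns ``mean_std_ratio`` and ``label`` in
    {simple, complex, false_positive}; verified = simple or complex. For
    each threshold t, a call is accepted if its mean standardized ratio is
    <= t. Returns the curve (threshold, n_accepted, fpr, pct_verified_rejected)
    and the least strict threshold achieving FPR 0 (None if none does).
    """
    bad = set(calls["label"]) - {"simple", "complex", "false_positive"}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    if thresholds is None:
        thresholds = np.round(np.arange(-14.0, -1.0 + 1e-9, 0.1), 10)
    means = calls["mean_std_ratio"].to_numpy(dtype=float)
    fp = (calls["label"] == "false_positive").to_numpy()
    verified = ~fp
    n_verified = int(verified.sum())
    rows = []
    zero_fpr: float | None = None
    for t in thresholds:
        acc = means <= t
        n_acc = int(acc.sum())
        fpr = float(100.0 * (acc & fp).sum() / n_acc) if n_acc else float("nan")
        rej = float(100.0 * (verified & ~acc).sum() / n_verified) if n_verified else float("nan")
        rows.append((float(t), n_acc, fpr, rej))
        if n_acc and fpr == 0.0:
            zero_fpr = float(t) if zero_fpr is None else max(zero_fpr, float(t))
    curve = pd.DataFrame(rows, columns=["threshold", "n_accepted", "fpr",
                                        "pct_verified_rejected"])
    return curve, zero_fpr
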