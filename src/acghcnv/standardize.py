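"""SNP-aware processing of probe log2 ratios.

Two-color CGH probes that contain SNPs between the test and reference
genomes hybridize less efficiently in the test channel, depressing their
log2 ratio by roughly -0.5 per SNP — easily mistaken for a deletion signal.
This module quantifies that effect (an ordinary least-squares regression of
log2 ratio on probe SNP count), removes repeat-content probes, and
standardizes ratios within SNP-count groups (0, 1, 2, 3+) so that every
group has median 0 and median absolute deviation 1. The MAD is used
unscaled (no normal-consistency constant).

Probe tables are pandas DataFrames with columns ``chrom, start, end,
probe_id, repeat`` plus per-strain ``snp_count_<strain>`` (int) and
``snp_positions_<strain>`` (tuple of 1-based within-probe offsets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)

#: label used for the pooled "more than two SNPs" group
GROUP_LABELS = ("0", "1", "2", "3+")


@dataclass
class RatioProfile:
    """Per-probe log2 ratios for one (strain, dye) hybridization.

    ``values`` is a float Series indexed by probe_id. ``dye`` is ``"normal"``
    or ``"swap"``; swap profiles are expected to be sign-corrected upstream
    so that a loss is negative in both dyes.
    """

    strain: str
    dye: str
    values: pd.Series
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.dye not in ("normal", "swap"):
            raise ValueError(f"dye must be 'normal' or 'swap', got {self.dye!r}")
        self.values = self.values.astype(float)


@dataclass
class SnpEffectFit:
    """Result of the regression of log2 ratio on probe SNP count."""

    slope: float
    p_value: float
    r_squared: float
    group_medians: dict[str, float]
    stderr: float
    n: int


def filter_repeat_probes(probes: pd.DataFrame) -> pd.DataFrame:
    """Drop probes whose sequence contains repeat elements.

    Returns exactly the rows with ``repeat == False``, order preserved.
    """
    return probes.loc[~probes["repeat"].astype(bool)].copy()


def snp_group(count) -> np.ndarray:
    """Map SNP counts to the groups 0, 1, 2, 3+ (counts >=3 pool into 3+).

    Accepts a scalar or array; returns the group label(s) from
    :data:`GROUP_LABELS`.
    """
    arr = np.minimum(np.asarray(count, dtype=np.int64), 3)
    if np.any(arr < 0):
        raise ValueError("SNP counts must be non-negative")
    out = np.asarray(GROUP_LABELS, dtype=object)[np.atleast_1d(arr)]
    return out if arr.ndim else out[0]


def _aligned(profile: RatioProfile, probes: pd.DataFrame, strain: str):
    col = f"snp_count_{strain}"
    if col not in probes.columns:
        raise KeyError(f"probe table has no SNP annotation for strain {strain!r}")
    idx = probes.set_index("probe_id")
    values = profile.values
    finite = np.isfinite(values.to_numpy())
    if not finite.all():
        log.info("dropping %d non-finite ratios", int((~finite).sum()))
        values = values[finite]
    counts = idx.loc[values.index, col].to_numpy(dtype=np.int64)
    return values, counts, idx


def fit_snp_regression(profile: RatioProfile, probes: pd.DataFrame, strain: str) -> SnpEffectFit:
    """OLS of log2 ratio on SNP count (capped at 3) plus group medians.

    The regressor is the integer count with counts >2 pooled to 3, matching
    the grouping used for standardization. Raises if all probes fall in one
    group (degenerate design).
    """
    values, counts, _ = _aligned(profile, probes, strain)
    x = np.minimum(counts, 3).astype(float)
    if np.unique(x).size < 2:
        raise ValueError("degenerate design: all probes have the same SNP count")
    res = sm.OLS(values.to_numpy(), sm.add_constant(x)).fit()
    groups = snp_group(counts)
    med = {
        g: float(np.median(values.to_numpy()[groups == g])) if np.any(groups == g) else float("nan")
        for g in GROUP_LABELS
    }
    return SnpEffectFit(
        slope=float(res.params[1]),
        p_value=float(res.pvalues[1]),
        r_squared=float(res.rsquared),
        group_medians=med,
        stderr=float(res.bse[1]),
        n=int(res.nobs),
    )


def standardize(profile: RatioProfile, probes: pd.DataFrame, strain: str) -> RatioProfile:
    """Standardize ratios within SNP-count groups: (x - median) / MAD.

    MAD is the plain median absolute deviation (no 1.4826 factor). Groups
    with MAD 0 are centered only, and logged. Returns a new profile with
    ``standardized=True``.
    """
    if profile.standardized:
        raise ValueError("profile is already standardized")
    if len(profile.values) == 0:
        raise ValueError("empty profile")
    values, counts, _ = _aligned(profile, probes, strain)
    groups = snp_group(counts)
    out = values.to_numpy().copy()
    for g in GROUP_LABELS:
        mask = groups == g
        if not np.any(mask):
            continue
        x = out[mask]
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad == 0:
            log.warning("SNP group %s has MAD 0 (%d probes): centered only", g, mask.sum())
            out[mask] = x - med
        else:
            out[mask] = (x - med) / mad
    return RatioProfile(
        strain=profile.strain,
        dye=profile.dye,
        values=pd.Series(out, index=values.index),
        standardized=True,
    )


def fold_position(offset, probe_len) -> np.ndarray:
    """Fold a 1-based within-probe SNP offset into 6 symmetric categories.

    The probe is divided into 11 equal-length segments; segment ``s`` and its
    mirror ``12 - s`` are combined, so category 1 holds the two outermost
    segments and category 6 the central one.
    """
    offset = np.asarray(offset, dtype=np.int64)
    probe_len = np.asarray(probe_len, dtype=np.int64)
    seg = np.floor(11 * (offset - 1) / probe_len).astype(np.int64) + 1
    if np.any((seg < 1) | (seg > 11)):
        raise ValueError("SNP offset outside probe")
    folded = np.minimum(seg, 12 - seg)
    return folded if folded.ndim else folded[()]


def position_profile(profile: RatioProfile, probes: pd.DataFrame, strain: str) -> pd.Series:
    """Median log2 ratio by folded SNP-position category, single-SNP probes only.

    Returns a Series indexed 1..6 (edge to center); categories with no
    probes are NaN. Raises if no single-SNP probes exist for the strain.
    """
    values, counts, idx = _aligned(profile, probes, strain)
    single = counts == 1
    if not np.any(single):
        raise ValueError(f"no single-SNP probes for strain {strain!r}")
    sub = values[single]
    rows = idx.loc[sub.index]
    offsets = np.array([p[0] for p in rows[f"snp_positions_{strain}"]], dtype=np.int64)
    plen = (rows["end"] - rows["start"]).to_numpy(dtype=np.int64)
    cat = fold_position(offsets, plen)
    x = sub.to_numpy()
    return pd.Series(
        [float(np.median(x[cat == c])) if np.any(cat == c) else float("nan") for c in range(1, 7)],
        index=pd.RangeIndex(1, 7, name="folded_category"),
    )
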