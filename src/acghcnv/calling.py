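"""CNV calling from standardized log2-ratio profiles.

Detection follows the Smith-Waterman-style maximal-scoring-segment approach
for aCGH: per-probe ratios are turned into scores against a percentile
threshold of the standardized distribution (10th percentile for losses,
90th for gains), maximal positive-sum segments ("islands") are extracted,
and island significance is assessed against a genome-wide permutation null
of the maximum island score. Calls then pass a probe-density filter and a
dye-swap consensus step: a call is reported only if it is at least
partially replicated in the dye-swap experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .standardize import RatioProfile

log = logging.getLogger(__name__)

CALL_COLUMNS = [
    "strain", "chrom", "start", "end", "state", "n_probes", "score",
    "perm_p", "mean_std_ratio", "median_std_ratio",
]


@dataclass
class CallParams:
    """Calling parameters.

    loss_q / gain_q : percentile thresholds of the standardized ratio
        distribution used to score losses / gains.
    n_perm          : genome-wide permutations for the max-score null.
    genomewide_alpha: family-wise significance level per state.
    min_probes, min_density : probe-density filter (density in probes/kb).
    """

    loss_q: float = 10.0
    gain_q: float = 90.0
    n_perm: int = 1000
    genomewide_alpha: float = 0.05
    min_probes: int = 5
    min_density: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.loss_q < self.gain_q < 100:
            raise ValueError("need 0 < loss_q < gain_q < 100")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")


def score_transform(values: np.ndarray, state: str, threshold_value: float) -> np.ndarray:
    """Per-probe scores, positive where the probe supports the given state.

    Losses score ``t - x`` (positive below the loss threshold), gains score
    ``x - t`` (positive above the gain threshold).
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite ratios in profile")
    if state == "loss":
        return threshold_value - x
    if state == "gain":
        return x - threshold_value
    raise ValueError(f"state must be 'loss' or 'gain', got {state!r}")


def _max_subarray(scores: np.ndarray, lo: int, hi: int):
    """Best-sum subarray of scores[lo:hi); ties broken to the longer, then
    leftmost, segment. Returns (start, end, sum) or None if no positive sum."""
    s = scores[lo:hi]
    prefix = np.concatenate([[0.0], np.cumsum(s)])
    # for each end j (1..n), the best start is the earliest index attaining
    # the running prefix minimum (earliest => longest, then leftmost)
    runmin = np.minimum.accumulate(prefix)
    best_at_end = prefix[1:] - runmin[:-1]
    best = best_at_end.max(initial=-np.inf)
    if best <= 0:
        return None
    # candidate ends achieving the max (floating-point exact ties only)
    ends = np.flatnonzero(best_at_end == best) + 1
    cand = []
    for j in ends:
        i = int(np.argmax(prefix[:j] == runmin[j - 1]))  # earliest attaining min
        cand.append((j - i, -i, i, j))
    _, _, i, j = max(cand)
    return lo + i, lo + j, float(best)


def find_islands(scores: np.ndarray) -> list[tuple[int, int, float]]:
    """Disjoint maximal positive-sum segments of a score vector.

    Recursively extracts the maximum-sum subarray and repeats on the flanks,
    so no island can be extended or merged with a neighbor without lowering
    its score. Returns ``(start, end, score)`` triples in positional order;
    all-negative input yields an empty list.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    out: list[tuple[int, int, float]] = []
    stack = [(0, len(scores))]
    while stack:
        lo, hi = stack.pop()
        if hi <= lo:
            continue
        hit = _max_subarray(scores, lo, hi)
        if hit is None:
            continue
        i, j, sc = hit
        out.append((i, j, sc))
        stack.append((lo, i))
        stack.append((j, hi))
    return sorted(out)


def max_island_scores(score_matrix: np.ndarray) -> np.ndarray:
    """Row-wise maximum island score (0 if a row is all-negative).

    The maximum island score equals the classic maximum subarray sum,
    computed here fully vectorized via prefix sums.
    """
    m = np.atleast_2d(np.asarray(score_matrix, dtype=float))
    prefix = np.concatenate([np.zeros((m.shape[0], 1)), np.cumsum(m, axis=1)], axis=1)
    runmin = np.minimum.accumulate(prefix[:, :-1], axis=1)
    return np.maximum((prefix[:, 1:] - runmin).max(axis=1), 0.0)


def permutation_null(scores: np.ndarray, n_perm: int, seed: int, chunk: int = 64) -> np.ndarray:
    """Null distribution of the genome-wide maximum island score.

    Scores are shuffled genome-wide (a shuffle of the standardized ratios is
    equivalent to a shuffle of their scores, since the threshold is a fixed
    quantile of the same values); for each permutation the maximum island
    score is recorded.
    """
    rng = np.random.default_rng(seed)
    scores = np.asarray(scores, dtype=float)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        # batched permutations via argsort of uniforms
        keys = rng.random((b, scores.size))
        perm = scores[np.argsort(keys, axis=1)]
        out[done:done + b] = max_island_scores(perm)
        done += b
    return out


def permutation_threshold(null_max: np.ndarray, alpha: float) -> float:
    """Score cutoff at genome-wide level alpha (conservative upper quantile)."""
    return float(np.quantile(null_max, 1 - alpha, method="higher"))


def empirical_p(score, null_max: np.ndarray):
    """Add-one empirical P of island score(s) against the max-score null."""
    score = np.atleast_1d(np.asarray(score, dtype=float))
    p = (1 + (null_max[None, :] >= score[:, None]).sum(axis=1)) / (null_max.size + 1)
    return p if p.size > 1 else float(p[0])


def call_state(
    profile: RatioProfile,
    probes: pd.DataFrame,
    params: CallParams,
    state: str,
) -> pd.DataFrame:
    """Call candidate CNVs of one state from a standardized profile.

    Probes are taken in genome order per chromosome; islands are found per
    chromosome, but the permutation null (and hence the significance
    threshold) is genome-wide. Returns calls with ``perm_p <=
    genomewide_alpha`` only, before density filtering and consensus.
    """
    params.validate()
    if not profile.standardized:
        raise ValueError("profile must be standardized before calling")
    idx = probes.set_index("probe_id").loc[profile.values.index]
    if (idx.groupby("chrom", sort=False)["start"].diff().dropna() <= 0).any():
        raise ValueError("probes must be sorted by position within chromosome")
    x = profile.values.to_numpy()
    q = params.loss_q if state == "loss" else params.gain_q
    threshold = float(np.percentile(x, q))
    scores = score_transform(x, state, threshold)
    null = permutation_null(scores, params.n_perm, params.seed)

    chroms = idx["chrom"].to_numpy()
    starts = idx["start"].to_numpy()
    ends = idx["end"].to_numpy()
    rows = []
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        for i, j, sc in find_islands(scores[sel]):
            lo, hi = sel[i], sel[j - 1]
            seg = x[sel[i]:sel[j - 1] + 1]
            p = empirical_p(sc, null)
            if p <= params.genomewide_alpha:
                rows.append((
                    profile.strain, chrom, int(starts[lo]), int(ends[hi]), state,
                    j - i, sc, p, float(seg.mean()), float(np.median(seg)),
                ))
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return calls.sort_values(["chrom", "start"]).reset_index(drop=True)


def density_filter(calls: pd.DataFrame, params: CallParams) -> pd.DataFrame:
    """Remove calls with too few probes or too low probe density."""
    if calls.empty:
        return calls.copy()
    span_kb = (calls["end"] - calls["start"]) / 1000.0
    density = calls["n_probes"] / span_kb
    keep = (calls["n_probes"] >= params.min_probes) & (density >= params.min_density)
    for _, row in calls.loc[~keep].iterrows():
        reason = ("few probes" if row["n_probes"] < params.min_probes else "low density")
        log.info("density filter removed %s:%d-%d (%s)",
                 row["chrom"], row["start"], row["end"], reason)
    return calls.loc[keep].reset_index(drop=True)


def dye_swap_consensus(calls_normal: pd.DataFrame, calls_swap: pd.DataFrame) -> pd.DataFrame:
    """Keep normal-dye calls at least partially replicated in the dye swap.

    A normal-dye call is reported iff it overlaps (>= 1 bp) a swap call of
    the same state; reported coordinates are the normal-dye call's, with the
    best-overlapping swap call's statistics attached as ``*_swap`` columns.
    """
    for df in (calls_normal, calls_swap):
        if not df.empty and df["strain"].nunique() > 1:
            raise ValueError("consensus operates on a single strain")
    if (not calls_normal.empty and not calls_swap.empty
            and calls_normal["strain"].iat[0] != calls_swap["strain"].iat[0]):
        raise ValueError("strain mismatch between normal and swap call sets")
    extra = ["score_swap", "perm_p_swap", "mean_std_ratio_swap", "median_std_ratio_swap"]
    out_rows = []
    for row in calls_normal.itertuples(index=False):
        hits = calls_swap[
            (calls_swap["chrom"] == row.chrom)
            & (calls_swap["state"] == row.state)
            & (calls_swap["start"] < row.end)
            & (row.start < calls_swap["end"])
        ]
        if hits.empty:
            continue
        best = hits.loc[hits["score"].idxmax()]
        out_rows.append(row._asdict() | {
            "score_swap": best["score"], "perm_p_swap": best["perm_p"],
            "mean_std_ratio_swap": best["mean_std_ratio"],
            "median_std_ratio_swap": best["median_std_ratio"],
        })
    return pd.DataFrame(out_rows, columns=CALL_COLUMNS + extra)


def call_cnvs(
    normal: RatioProfile,
    swap: RatioProfile,
    probes: pd.DataFrame,
    params: CallParams,
    states=("loss", "gain"),
) -> pd.DataFrame:
    """Full per-strain calling: both dyes, both states, density filter,
    dye-swap consensus. Returns consensus calls sorted by position."""
    pieces = []
    for state in states:
        cn = density_filter(call_state(normal, probes, params, state), params)
        cs = density_filter(call_state(swap, probes, params, state), params)
        pieces.append(dye_swap_consensus(cn, cs))
    nonempty = [p for p in pieces if not p.empty]
    out = pd.concat(nonempty, ignore_index=True) if nonempty else pieces[0]
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)
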