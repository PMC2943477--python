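"""Feature enrichment in CNV regions under a rotational-permutation null.

CNV regions cluster along the genome, so permuting them to independent
uniform positions destroys spatial structure the null should keep. The
rotational null instead wraps the concatenated genome into a circle and
rotates *all* regions by one shared random offset per replicate: region
sizes, their order, and every inter-region gap are preserved exactly, while
their placement relative to the feature track is randomized. Regions that
straddle a chromosome boundary after unwrapping are split at the boundary,
conserving the total number of region bases.

Enrichment of a feature class (segmental duplications, LINEs, SINEs, LTRs,
...) is quantified as observed / expected percentage of region bases in the
feature union, with the expectation the median over permuted sets, and an
add-one empirical one-sided P in the direction of the observed departure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Genome
from .intervals import CoverageIndex, merge_union

SIZE_CLASSES = ("small", "medium", "large")


def size_classify(length) -> np.ndarray:
    """CNV-region size class: small < 10 kb <= medium <= 100 kb < large."""
    length = np.asarray(length, dtype=np.int64)
    if np.any(length <= 0):
        raise ValueError("region length must be positive")
    out = np.where(length < 10_000, "small",
                   np.where(length <= 100_000, "medium", "large")).astype(object)
    return out if out.ndim else out[()]


@dataclass
class EnrichmentResult:
    feature: str
    size_class: str
    zone: str
    observed_pct: float
    expected_pct: float
    fold_change: float
    p_value: float
    direction: str  # "enrichment" | "depletion"
    n_perm: int
    p_enrichment: float = float("nan")
    p_depletion: float = float("nan")


def rotational_permute(regions: pd.DataFrame, genome: Genome, offset: int) -> pd.DataFrame:
    """Rigidly rotate regions by ``offset`` bases around the circular genome.

    Offset 0 is the identity. Rotated regions that cross a chromosome
    boundary are split; total region bases are conserved exactly.
    """
    total = genome.total_length
    if not regions.empty and (regions["end"] - regions["start"]).max() > total:
        raise ValueError("region longer than the genome")
    if regions.empty:
        return regions.copy()
    a, b = genome.to_absolute(regions["chrom"], regions["start"], regions["end"])
    a = (a + offset) % total
    b = a + (np.asarray(regions["end"]) - np.asarray(regions["start"]))
    # unwrap pieces that run past the end of the circle
    abs_s, abs_e = [], []
    for s, e in zip(a, b):
        if e <= total:
            abs_s.append(s), abs_e.append(e)
        else:
            abs_s.extend([s, 0]), abs_e.extend([total, e - total])
    chrom, start, end, _ = genome.from_absolute(np.asarray(abs_s), np.asarray(abs_e))
    out = pd.DataFrame({"chrom": chrom, "start": start, "end": end})
    order = {n: i for i, n in enumerate(genome.names)}
    return out.sort_values(["chrom", "start"],
                           key=lambda s: s.map(order) if s.name == "chrom" else s
                           ).reset_index(drop=True)


def _zone_intervals(regions: pd.DataFrame, genome: Genome, zone: str,
                    flank_bp: int) -> tuple[np.ndarray, np.ndarray]:
    """Absolute-coordinate union of the requested zone."""
    lengths = genome.lengths
    within_s, within_e = genome.to_absolute(regions["chrom"], regions["start"], regions["end"])
    pieces_s, pieces_e = [], []
    if zone in ("within", "within+flank"):
        pieces_s.append(within_s), pieces_e.append(within_e)
    if zone in ("flank", "within+flank"):
        fs, fe = [], []
        off = genome.offsets()
        for r in regions.itertuples(index=False):
            o, clen = off[r.chrom], lengths[r.chrom]
            left = (max(0, r.start - flank_bp), r.start)
            right = (r.end, min(clen, r.end + flank_bp))
            for s, e in (left, right):
                if e > s:
                    fs.append(o + s), fe.append(o + e)
        pieces_s.append(np.asarray(fs, dtype=np.int64))
        pieces_e.append(np.asarray(fe, dtype=np.int64))
    if zone not in ("within", "flank", "within+flank"):
        raise ValueError(f"bad zone {zone!r}")
    s = np.concatenate(pieces_s) if pieces_s else np.array([], dtype=np.int64)
    e = np.concatenate(pieces_e) if pieces_e else np.array([], dtype=np.int64)
    if zone == "flank":
        # flanks may run into the regions themselves; the flank zone is the
        # flanking sequence only
        region_cov = CoverageIndex(within_s, within_e)
        out_s, out_e = [], []
        ms, me = merge_union(s, e)
        for a, b in zip(ms, me):
            # subtract region-covered parts by walking the region union
            i = np.searchsorted(region_cov._e, a, side="right")
            pos = a
            while pos < b:
                if i < region_cov._s.size and region_cov._s[i] < b:
                    if region_cov._s[i] > pos:
                        out_s.append(pos), out_e.append(region_cov._s[i])
                    pos = region_cov._e[i]
                    i += 1
                else:
                    out_s.append(pos), out_e.append(b)
                    pos = b
        s = np.asarray(out_s, dtype=np.int64)
        e = np.asarray(out_e, dtype=np.int64)
    return merge_union(s, e)


def overlap_pct(regions: pd.DataFrame, features: pd.DataFrame, genome: Genome,
                zone: str = "within", flank_bp: int = 10_000) -> float:
    """Percentage of zone bases covered by the feature-track union.

    Zone ``within`` is the region union itself; ``flank`` the sequence up to
    ``flank_bp`` either side of each breakpoint (excluding region interior);
    ``within+flank`` their union. NaN for an empty zone.
    """
    zs, ze = _zone_intervals(regions, genome, zone, flank_bp)
    zone_len = int(np.sum(ze - zs))
    if zone_len == 0:
        return float("nan")
    fa, fb = genome.to_absolute(features["chrom"], features["start"], features["end"])
    cov = CoverageIndex(fa, fb)
    return 100.0 * float(cov.covered(zs, ze).sum()) / zone_len


def enrichment_test(
    regions: pd.DataFrame,
    features: pd.DataFrame,
    genome: Genome,
    feature_name: str = "feature",
    n_perm: int = 1000,
    seed: int = 0,
    zone: str = "within",
    size_class: str = "all",
    flank_bp: int = 10_000,
) -> EnrichmentResult:
    """Empirical enrichment/depletion test of a feature track in CNV regions.

    The null is ``n_perm`` rotational permutations with shared offsets drawn
    uniformly from the circle; expected = median permuted overlap;
    fold = observed / expected (+inf when expected is 0 and observed > 0).
    The reported P is the smaller one-sided add-one tail with its direction.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if size_class != "all":
        lengths = regions["end"] - regions["start"]
        regions = regions.loc[size_classify(lengths) == size_class].reset_index(drop=True)
    if regions.empty:
        raise ValueError(f"no regions in size class {size_class!r}")
    observed = overlap_pct(regions, features, genome, zone, flank_bp)
    rng = np.random.default_rng(seed)
    offsets = rng.integers(0, genome.total_length, size=n_perm)
    null = np.array([
        overlap_pct(rotational_permute(regions, genome, int(d)), features, genome,
                    zone, flank_bp)
        for d in offsets
    ])
    expected = float(np.median(null))
    if expected > 0:
        fold = observed / expected
    else:
        fold = float("inf") if observed > 0 else float("nan")
    p_enrich = (1 + int((null >= observed).sum())) / (n_perm + 1)
    p_deplete = (1 + int((null <= observed).sum())) / (n_perm + 1)
    if p_enrich <= p_deplete:
        p, direction = p_enrich, "enrichment"
    else:
        p, direction = p_deplete, "depletion"
    return EnrichmentResult(feature_name, size_class, zone, observed, expected,
                            fold, p, direction, n_perm, p_enrich, p_deplete)
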