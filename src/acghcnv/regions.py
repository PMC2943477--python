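"""Cross-strain CNV regions and between-experiment concordance statistics.

Per-strain CNV calls are merged into CNV regions by transitive closure
under >= 1 bp overlap (a chain A-B-C becomes one region); each region
carries a strain-distribution pattern (SDP), a presence bit per strain with
the reference strain fixed at 0. The module also computes size/coverage
summaries, the region-based overlap statistic used to compare two call
sets, pairwise cross-study replication percentages, and false-negative
rates of a lower-density array judged against targeted high-density calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
import pyranges as pr

from .genome import Genome
from .intervals import union_length

log = logging.getLogger(__name__)

STATES = ("loss", "gain")


def _cluster_ids(df: pd.DataFrame) -> np.ndarray:
    """Connected components under strict >=1 bp overlap, per chromosome.

    Returns a cluster id per input row (input order preserved).
    """
    if df.empty:
        return np.array([], dtype=np.int64)
    g = pr.PyRanges(pd.DataFrame({
        "Chromosome": df["chrom"].to_numpy(),
        "Start": df["start"].to_numpy(),
        "End": df["end"].to_numpy(),
        "row": np.arange(len(df)),
    }))
    clustered = g.cluster(slack=-1).df
    out = np.empty(len(df), dtype=np.int64)
    out[clustered["row"].to_numpy()] = clustered["Cluster"].to_numpy()
    return out


def merge_regions(calls: pd.DataFrame, state: str, strain_order=None) -> pd.DataFrame:
    """Merge same-state calls from different strains into CNV regions.

    Returns a frame with columns ``chrom, start, end, state, n_members,
    strains, sdp, n_strains``; the region interval is the union of its
    members, the SDP a '0'/'1' string over ``strain_order`` (pass the full
    strain list including the reference to get a fixed-width SDP).
    """
    if not calls.empty and (calls["state"] != state).any():
        raise ValueError("merge_regions takes calls of a single state; "
                         "use combine_states to mix losses and gains")
    if strain_order is None:
        strain_order = sorted(calls["strain"].unique()) if not calls.empty else []
    if calls.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "state", "n_members",
                                     "strains", "sdp", "n_strains"])
    cid = _cluster_ids(calls)
    rows = []
    for c in pd.unique(cid):
        sub = calls.loc[cid == c]
        strains = sorted(set(sub["strain"]))
        rows.append((
            sub["chrom"].iat[0], int(sub["start"].min()), int(sub["end"].max()),
            state, len(sub), ",".join(strains),
            "".join("1" if s in strains else "0" for s in strain_order),
            len(strains),
        ))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "state", "n_members",
                                      "strains", "sdp", "n_strains"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def combine_states(loss_regions: pd.DataFrame, gain_regions: pd.DataFrame) -> pd.DataFrame:
    """Union-merge loss and gain regions into non-overlapping combined regions.

    Regions containing both a loss and a gain member are flagged ``mixed``.
    """
    for df in (loss_regions, gain_regions):
        if not df.empty and len(np.unique(_cluster_ids(df))) != len(df):
            raise ValueError("input region sets must be internally non-overlapping")
    both = pd.concat([loss_regions.assign(_src="loss"), gain_regions.assign(_src="gain")],
                     ignore_index=True)
    if both.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "mixed", "states"])
    cid = _cluster_ids(both)
    rows = []
    for c in pd.unique(cid):
        sub = both.loc[cid == c]
        states = sorted(set(sub["_src"]))
        rows.append((sub["chrom"].iat[0], int(sub["start"].min()), int(sub["end"].max()),
                     len(states) > 1, ",".join(states)))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "mixed", "states"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def coverage_summary(intervals: pd.DataFrame, genome: Genome, by: str | None = None) -> pd.DataFrame:
    """Count, covered Mb, percent of genome, and median length of intervals.

    ``by`` groups rows (e.g. ``"strain"``); coverage uses the union of
    intervals within each group. Percentages are relative to the genome's
    total length.
    """
    total = genome.total_length
    groups = [("all", intervals)] if by is None else list(intervals.groupby(by))
    rows = []
    for name, sub in groups:
        if sub.empty:
            rows.append((name, 0, 0.0, 0.0, float("nan")))
            continue
        a, b = genome.to_absolute(sub["chrom"], sub["start"], sub["end"])
        cov = union_length(a, b)
        lengths = (sub["end"] - sub["start"]).to_numpy()
        rows.append((name, len(sub), cov / 1e6, 100.0 * cov / total,
                     float(np.median(lengths))))
    return pd.DataFrame(rows, columns=[by or "group", "count", "mb", "pct_genome",
                                       "median_length"])


def overlap_statistic(set_a: pd.DataFrame, set_b: pd.DataFrame) -> float:
    """Region-based overlap between two same-state call sets.

    Calls from the two experiments are grouped per strain into regions by
    >=1 bp overlap; calls seen in only one experiment become singleton
    regions. The statistic is (# regions containing more than one call) /
    (# regions) — 1.0 for identical sets, 0.0 for disjoint ones.
    """
    both = pd.concat([set_a, set_b], ignore_index=True)
    if both.empty:
        return float("nan")
    multi = 0
    total = 0
    for _, sub in both.groupby("strain"):
        cid = _cluster_ids(sub.reset_index(drop=True))
        counts = pd.Series(cid).value_counts()
        total += len(counts)
        multi += int((counts > 1).sum())
    return multi / total


def _round1(x: float) -> float:
    """Round half-up to one decimal (for percentage tables)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def replication_matrix(studies: dict[str, pd.DataFrame], state: str) -> pd.DataFrame:
    """Pairwise cross-study replication percentages for one CNV state.

    ``studies`` maps study name -> call table (columns ``strain, chrom,
    start, end, state`` with states loss/gain/abnormal). Cell (i, j) is the
    percentage of study-i calls of the given state that have >=1 bp overlap
    with a same-strain study-j call of matching state; study-j ``abnormal``
    calls match either state. Each pair is restricted to strains present in
    both studies; pairs with no common strains (or no eligible calls) are NaN.
    """
    names = list(studies)
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for i in names:
        for j in names:
            a, b = studies[i], studies[j]
            common = set(a["strain"]) & set(b["strain"])
            if not common:
                continue
            queries = a[(a["state"] == state) & a["strain"].isin(common)]
            targets = b[b["state"].isin([state, "abnormal"]) & b["strain"].isin(common)]
            if queries.empty:
                continue
            hit = 0
            for row in queries.itertuples(index=False):
                m = targets[
                    (targets["strain"] == row.strain)
                    & (targets["chrom"] == row.chrom)
                    & (targets["start"] < row.end) & (row.start < targets["end"])
                ]
                hit += int(not m.empty)
            mat.loc[i, j] = _round1(100.0 * hit / len(queries))
    return mat


def region_presence_from_calls(regions: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Per (region_id, strain) presence of >=1 bp-overlapping calls.

    ``regions`` needs columns ``region_id, chrom, start, end``; presence is
    evaluated for every strain found in ``calls``.
    """
    strains = sorted(calls["strain"].unique()) if not calls.empty else []
    rows = []
    for r in regions.itertuples(index=False):
        for s in strains:
            sub = calls[
                (calls["strain"] == s) & (calls["chrom"] == r.chrom)
                & (calls["start"] < r.end) & (r.start < calls["end"])
            ]
            rows.append((r.region_id, s, not sub.empty))
    return pd.DataFrame(rows, columns=["region_id", "strain", "variant"])


def false_negative_rate(targeted: pd.DataFrame, array: pd.DataFrame) -> pd.Series:
    """Per-strain false-negative rate of the array, plus the mean.

    Both inputs are presence tables with columns ``region_id, strain,
    variant``; a false negative is a (region, strain) where the targeted
    high-density assay found structural variation but the array did not.
    Strains with no targeted variation get NaN with a warning.
    """
    merged = targeted.merge(array, on=["region_id", "strain"], how="left",
                            suffixes=("_targeted", "_array"))
    merged["variant_array"] = merged["variant_array"].fillna(False)
    rates = {}
    for strain, sub in merged.groupby("strain"):
        pos = sub[sub["variant_targeted"].astype(bool)]
        if pos.empty:
            log.warning("strain %s has no targeted-array variation; FNR undefined", strain)
            rates[strain] = float("nan")
        else:
            rates[strain] = float((~pos["variant_array"].astype(bool)).mean())
    out = pd.Series(rates, name="fnr")
    finite = [v for v in rates.values() if not np.isnan(v)]
    out.loc["mean"] = float(np.mean(finite)) if finite else float("nan")
    return out
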