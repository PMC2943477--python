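"""Synthetic aCGH data with planted copy-number truth.

Forward model of a two-color long-oligonucleotide CGH experiment: a jittered
probe grid (median spacing ~1.1 kb, emulating a 2.1M-probe whole-genome
design), per-strain SNP annotations, repeat-content flags, and per-probe
log2 ratios

    ratio = CNV shift + sum over probe SNPs of effect x position weight
            + repeat bias + Gaussian noise,

with an independent-noise dye-swap replicate sharing the same expectation
(swap profiles are modeled post sign-correction, so a loss is negative in
both dyes). Planted CNVs are either simple (one contiguous loss or gain) or
complex (a parent region of interleaved loss/gain sub-segments separated by
normal-copy gaps), mirroring the architectures that high-density follow-up
arrays reveal in real data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome
from .standardize import RatioProfile, fold_position

#: default position-weight ramp, folded categories 1 (edge) .. 6 (center)
DEFAULT_POSITION_WEIGHTS = (0.6, 0.72, 0.84, 0.96, 1.08, 1.2)


@dataclass
class SimParams:
    """Generator parameters; defaults are the study conditions emulated.

    probe_spacing_bp : target median inter-probe spacing (bp).
    probe_len_bp     : oligo length, 50-75 bp.
    noise_sd         : Gaussian probe noise s.d. (log2 units).
    snp_effect_per_snp : additive log2 depression per within-probe SNP.
    snp_position_weights : multiplier per folded SNP-position category
        (edge -> center); unit weights make the effect purely additive.
    repeat_fraction  : fraction of probes carrying repeat sequence.
    repeat_bias      : extra log2 shift applied to repeat-flagged probes.
    loss_shift / gain_shift : true log2 shift of probes inside a planted
        loss / gain (hemizygous deletion ~ -1.0; single-copy gain ~ +0.58).
    """

    probe_spacing_bp: float = 1136.0
    probe_len_bp: int = 60
    noise_sd: float = 0.4
    snp_effect_per_snp: float = -0.5
    snp_position_weights: tuple = DEFAULT_POSITION_WEIGHTS
    repeat_fraction: float = 0.111
    repeat_bias: float = -0.25
    loss_shift: float = -1.0
    gain_shift: float = 0.585
    seed: int = 0

    def validate(self) -> None:
        if not (50 <= self.probe_len_bp <= 75):
            raise ValueError("probe_len_bp must be in [50, 75]")
        if self.probe_spacing_bp <= self.probe_len_bp:
            raise ValueError("probe spacing must exceed probe length")
        if not 0 <= self.repeat_fraction <= 1:
            raise ValueError("repeat_fraction must be in [0, 1]")
        if len(self.snp_position_weights) != 6:
            raise ValueError("snp_position_weights must have 6 entries")
        numeric = [
            self.probe_spacing_bp, self.noise_sd, self.snp_effect_per_snp,
            self.repeat_fraction, self.repeat_bias, self.loss_shift, self.gain_shift,
            *self.snp_position_weights,
        ]
        if not all(np.isfinite(v) for v in numeric):
            raise ValueError("all numeric parameters must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class TruthCnv:
    """A planted copy-number variant (0-based half-open coordinates)."""

    strain: str
    chrom: str
    start: int
    end: int
    state: str  # "loss" | "gain"
    copy_delta: int
    parent_region_id: str
    architecture: str  # "simple" | "complex"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("start must be < end")
        if self.state not in ("loss", "gain"):
            raise ValueError(f"bad state {self.state!r}")
        if self.architecture not in ("simple", "complex"):
            raise ValueError(f"bad architecture {self.architecture!r}")


def truth_to_frame(truth: list[TruthCnv]) -> pd.DataFrame:
    cols = ["strain", "chrom", "start", "end", "state", "copy_delta",
            "parent_region_id", "architecture"]
    return pd.DataFrame([[getattr(t, c) for c in cols] for t in truth], columns=cols)


def make_probe_grid(genome: Genome, params: SimParams) -> pd.DataFrame:
    """Jittered probe grid over the genome.

    Probes are ``probe_len_bp`` long, non-overlapping, sorted by (chromosome
    order, start), with inter-probe spacing jittered around
    ``probe_spacing_bp`` and a ``repeat_fraction`` share flagged as repeat.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    plen = params.probe_len_bp
    rows = []
    counter = itertools.count()
    for chrom, length in genome.chromosomes:
        if length < plen:
            raise ValueError(f"chromosome {chrom!r} is shorter than one probe")
        pos = int(rng.integers(0, max(1, int(params.probe_spacing_bp))))
        while pos + plen <= length:
            rows.append((chrom, pos, pos + plen, f"p{next(counter):07d}"))
            step = rng.normal(params.probe_spacing_bp, 0.15 * params.probe_spacing_bp)
            pos += max(plen + 1, int(round(step)))
    probes = pd.DataFrame(rows, columns=["chrom", "start", "end", "probe_id"])
    probes["repeat"] = rng.random(len(probes)) < params.repeat_fraction
    return probes


def make_snp_map(
    probes: pd.DataFrame,
    strains,
    snp_rate: float = 0.0033,
    seed: int = 0,
    count_probs=None,
) -> pd.DataFrame:
    """Annotate probes with per-strain SNP counts and within-probe positions.

    By default counts are Poisson(probe length x ``snp_rate``); pass
    ``count_probs`` (probabilities over counts 0..k) to draw counts from an
    explicit distribution instead. Positions are uniform 1-based offsets,
    sorted, without replacement. Returns a copy of the probe table with
    ``snp_count_<strain>`` and ``snp_positions_<strain>`` columns added.
    """
    if snp_rate < 0:
        raise ValueError("snp_rate must be >= 0")
    if isinstance(strains, int):
        strains = [f"strain{i + 1}" for i in range(strains)]
    rng = np.random.default_rng(seed)
    out = probes.copy()
    plen = (out["end"] - out["start"]).to_numpy(dtype=np.int64)
    for strain in strains:
        if count_probs is not None:
            p = np.asarray(count_probs, dtype=float)
            counts = rng.choice(len(p), size=len(out), p=p / p.sum())
        else:
            counts = rng.poisson(plen * snp_rate)
        counts = np.minimum(counts, plen)  # cannot exceed probe length
        positions = [
            tuple(sorted(rng.choice(l, size=c, replace=False) + 1))
            for c, l in zip(counts, plen)
        ]
        out[f"snp_count_{strain}"] = counts.astype(np.int64)
        out[f"snp_positions_{strain}"] = pd.Series(positions, index=out.index, dtype=object)
    return out


def _strain_names(probes: pd.DataFrame) -> list[str]:
    return [c[len("snp_count_"):] for c in probes.columns if c.startswith("snp_count_")]


def _check_conflicts(truth: list[TruthCnv]) -> None:
    by_strain: dict[str, list[TruthCnv]] = {}
    for t in truth:
        by_strain.setdefault(t.strain, []).append(t)
    for strain, items in by_strain.items():
        items = sorted(items, key=lambda t: (t.chrom, t.start))
        max_end: dict[tuple[str, str], int] = {}  # (chrom, state) -> furthest end seen
        for t in items:
            other = "gain" if t.state == "loss" else "loss"
            if t.start < max_end.get((t.chrom, other), -1):
                raise ValueError(
                    f"conflicting truth CNVs overlap on strain {strain} at "
                    f"{t.chrom}:{t.start}-{t.end} ({t.state} vs {other})"
                )
            key = (t.chrom, t.state)
            max_end[key] = max(max_end.get(key, -1), t.end)


def simulate_profiles(
    probes: pd.DataFrame,
    truth: list[TruthCnv],
    params: SimParams,
    seed: int | None = None,
) -> dict[str, tuple[RatioProfile, RatioProfile]]:
    """Simulate (normal, dye-swap) log2-ratio profiles for every annotated strain.

    A probe belongs to a CNV if its midpoint lies inside the truth interval.
    The two dye replicates share the expected signal and differ only by
    independent Gaussian noise.
    """
    params.validate()
    _check_conflicts(truth)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    strains = _strain_names(probes)
    mid = ((probes["start"] + probes["end"]) // 2).to_numpy(dtype=np.int64)
    chroms = probes["chrom"].to_numpy()
    plen = (probes["end"] - probes["start"]).to_numpy(dtype=np.int64)
    weights = np.asarray(params.snp_position_weights, dtype=float)
    repeat = probes["repeat"].to_numpy(dtype=bool)

    out: dict[str, tuple[RatioProfile, RatioProfile]] = {}
    for strain in strains:
        mu = np.zeros(len(probes))
        for t in truth:
            if t.strain != strain:
                continue
            inside = (chroms == t.chrom) & (mid >= t.start) & (mid < t.end)
            shift = params.loss_shift if t.state == "loss" else params.gain_shift
            mu[inside] = shift
        snp_term = np.array([
            sum(params.snp_effect_per_snp * weights[fold_position(p, l) - 1] for p in pos)
            for pos, l in zip(probes[f"snp_positions_{strain}"], plen)
        ])
        mu = mu + snp_term + np.where(repeat, params.repeat_bias, 0.0)
        idx = pd.Index(probes["probe_id"], name="probe_id")
        normal = mu + rng.normal(0.0, params.noise_sd, len(mu))
        swap = mu + rng.normal(0.0, params.noise_sd, len(mu))
        out[strain] = (
            RatioProfile(strain, "normal", pd.Series(normal, index=idx)),
            RatioProfile(strain, "swap", pd.Series(swap, index=idx)),
        )
    return out


def annotate_truth_probes(truth: list[TruthCnv], probes: pd.DataFrame) -> pd.DataFrame:
    """Truth table with per-record probe counts; records no probe midpoint
    falls into are flagged ``unprobed``."""
    frame = truth_to_frame(truth)
    mid = ((probes["start"] + probes["end"]) // 2).to_numpy(dtype=np.int64)
    chroms = probes["chrom"].to_numpy()
    n = [
        int(np.sum((chroms == r.chrom) & (mid >= r.start) & (mid < r.end)))
        for r in frame.itertuples()
    ]
    frame["n_probes"] = n
    frame["unprobed"] = frame["n_probes"] == 0
    return frame


def plant_cnvs(
    genome: Genome,
    strains,
    n_simple: int = 5,
    n_complex: int = 2,
    simple_len=(10_000, 200_000),
    complex_len=(60_000, 300_000),
    seed: int = 0,
) -> list[TruthCnv]:
    """Plant simple and complex CNVs per strain, non-overlapping within strain.

    Simple: one contiguous loss or gain. Complex: a parent region split into
    3-7 sub-segments with at least two non-normal sub-segments and at least
    one normal gap between them (mixed loss/gain allowed).
    """
    if isinstance(strains, int):
        strains = [f"strain{i + 1}" for i in range(strains)]
    rng = np.random.default_rng(seed)
    chrom_arr = genome.chromosomes
    lengths = np.array([l for _, l in chrom_arr], dtype=float)
    truth: list[TruthCnv] = []
    region_counter = itertools.count()

    def place(strain_taken, length):
        """Uniform non-overlapping placement; returns (chrom, start) or None."""
        for _ in range(200):
            ci = rng.choice(len(chrom_arr), p=lengths / lengths.sum())
            cname, clen = chrom_arr[ci]
            if clen <= length:
                continue
            start = int(rng.integers(0, clen - length))
            if all(not (cname == c and start < e and s < start + length)
                   for c, s, e in strain_taken):
                strain_taken.append((cname, start, start + length))
                return cname, start
        raise RuntimeError("could not place CNV; genome too crowded")

    for strain in strains:
        taken: list[tuple[str, int, int]] = []
        for _ in range(n_simple):
            length = int(rng.integers(*simple_len))
            chrom, start = place(taken, length)
            state = "loss" if rng.random() < 0.75 else "gain"
            truth.append(TruthCnv(
                strain, chrom, start, start + length, state,
                -1 if state == "loss" else 1,
                f"region{next(region_counter):04d}", "simple",
            ))
        for _ in range(n_complex):
            length = int(rng.integers(*complex_len))
            chrom, start = place(taken, length)
            rid = f"region{next(region_counter):04d}"
            n_seg = int(rng.integers(3, 8))
            cuts = np.sort(rng.choice(np.arange(1, length), size=n_seg - 1, replace=False))
            bounds = np.concatenate([[0], cuts, [length]])
            # states: >=2 non-normal, >=1 normal gap strictly between them
            while True:
                states = rng.choice(["loss", "gain", "normal"], size=n_seg,
                                    p=[0.4, 0.2, 0.4])
                nn = np.flatnonzero(states != "normal")
                if len(nn) >= 2 and np.any(states[nn[0]:nn[-1] + 1] == "normal"):
                    break
            for k, st in enumerate(states):
                if st == "normal":
                    continue
                truth.append(TruthCnv(
                    strain, chrom, start + int(bounds[k]), start + int(bounds[k + 1]),
                    st, -1 if st == "loss" else 1, rid, "complex",
                ))
    return truth


def make_feature_track(
    genome: Genome,
    n_features: int,
    mean_len: float = 5_000.0,
    seed: int = 0,
    fixed_len: int | None = None,
    non_overlap: bool = False,
) -> pd.DataFrame:
    """Random genomic feature track (stand-in for repeat-class annotations).

    Lengths are exponential with the given mean (or ``fixed_len``); features
    may overlap unless ``non_overlap``. Returns a sorted BED-like frame.
    """
    rng = np.random.default_rng(seed)
    chrom_arr = genome.chromosomes
    lengths = np.array([l for _, l in chrom_arr], dtype=float)
    rows = []
    attempts = 0
    while len(rows) < n_features:
        attempts += 1
        if attempts > 100 * max(n_features, 1):
            raise RuntimeError("could not place features")
        flen = fixed_len if fixed_len is not None else max(1, int(rng.exponential(mean_len)))
        ci = rng.choice(len(chrom_arr), p=lengths / lengths.sum())
        cname, clen = chrom_arr[ci]
        if clen <= flen:
            continue
        start = int(rng.integers(0, clen - flen))
        if non_overlap and any(
            c == cname and start < e and s < start + flen for c, s, e in rows
        ):
            continue
        rows.append((cname, start, start + flen))
    order = {n: i for i, n in enumerate(genome.names)}
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"f{i:05d}" for i in range(len(df))]
    return df.sort_values(
        ["chrom", "start"], key=lambda s: s.map(order) if s.name == "chrom" else s
    ).reset_index(drop=True)
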