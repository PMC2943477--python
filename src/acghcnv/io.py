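"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinates are 0-based half-open (BED convention) everywhere. Profiles
travel as TSV tables (probe_id, chrom, start, end, log2ratio); probe tables
as BED-like TSV with repeat flags and per-strain SNP annotations; calls as
BED6+ with per-dye statistics; study call sets as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import Genome
from .standardize import RatioProfile

STATE_ALIASES = {
    "loss": "loss", "deletion": "loss", "del": "loss",
    "gain": "gain", "duplication": "gain", "dup": "gain", "insertion": "gain",
    "abnormal": "abnormal",
}


def read_chrom_sizes(path) -> Genome:
    """Two-column chrom.sizes file -> Genome, file order preserved."""
    chroms = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
            name, length = parts
            if name in dict(chroms):
                raise ValueError(f"{path}:{ln}: duplicate chromosome {name!r}")
            chroms.append((name, int(length)))
    return Genome(chroms)


def write_chrom_sizes(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_bed(path, genome: Genome | None = None) -> pd.DataFrame:
    """BED3+ -> DataFrame (chrom, start, end, extra columns kept positional).

    Validates half-open sanity (start < end) and, if a genome is given,
    bounds. Malformed lines raise with their line number.
    """
    rows, n_extra = [], 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(
                    f"{path}:{ln}: end <= start ({start}, {end}); "
                    "coordinates must be 0-based half-open"
                )
            if genome is not None:
                lengths = genome.lengths
                if parts[0] not in lengths:
                    raise ValueError(f"{path}:{ln}: unknown chromosome {parts[0]!r}")
                if end > lengths[parts[0]]:
                    raise ValueError(
                        f"{path}:{ln}: interval {parts[0]}:{start}-{end} "
                        "extends past the chromosome end"
                    )
            rows.append([parts[0], start, end, *parts[3:]])
            n_extra = max(n_extra, len(parts) - 3)
    cols = ["chrom", "start", "end"] + [f"col{i + 4}" for i in range(n_extra)]
    return pd.DataFrame(rows, columns=cols[:3 + n_extra])


def write_bed(df: pd.DataFrame, path, columns=None) -> None:
    """Write intervals as BED, sorted by (chrom, start, end), deduplicated."""
    cols = columns or [c for c in df.columns]
    out = df[cols].drop_duplicates().sort_values(["chrom", "start", "end"])
    out.to_csv(path, sep="\t", header=False, index=False)


def write_probes(probes: pd.DataFrame, path) -> None:
    """Probe table as TSV with a header; SNP position tuples serialize as
    comma lists."""
    out = probes.copy()
    for c in out.columns:
        if c.startswith("snp_positions_"):
            out[c] = [",".join(map(str, p)) for p in out[c]]
    out.to_csv(path, sep="\t", index=False)


def read_probes(path) -> pd.DataFrame:
    probes = pd.read_csv(path, sep="\t")
    for c in probes.columns:
        if c.startswith("snp_positions_"):
            probes[c] = [
                tuple(int(v) for v in str(s).split(",")) if pd.notna(s) and str(s) else ()
                for s in probes[c]
            ]
        if c == "repeat":
            probes[c] = probes[c].astype(bool)
    return probes


def write_profile(profile: RatioProfile, probes: pd.DataFrame, path) -> None:
    """Profile TSV: probe_id, chrom, start, end, log2ratio."""
    coords = probes.set_index("probe_id").loc[profile.values.index, ["chrom", "start", "end"]]
    out = coords.assign(log2ratio=profile.values).reset_index()
    out.to_csv(path, sep="\t", index=False)


def read_profile(path, strain: str, dye: str = "normal",
                 standardized: bool = False, sign_flip: bool = False) -> RatioProfile:
    """Read a profile TSV; ``sign_flip`` negates ratios (raw dye-swap data
    where a loss appears positive)."""
    df = pd.read_csv(path, sep="\t")
    values = pd.Series(df["log2ratio"].to_numpy(dtype=float),
                       index=pd.Index(df["probe_id"], name="probe_id"))
    if sign_flip:
        values = -values
    return RatioProfile(strain, dye, values, standardized=standardized)


def write_calls(calls: pd.DataFrame, path) -> None:
    """Calls as BED6+: name=strain:state, score=-log10 perm_p, strand='.',
    then n_probes and per-dye mean/median standardized ratios."""
    if calls.empty:
        Path(path).write_text("")
        return
    extra = [c for c in calls.columns
             if c not in ("strain", "chrom", "start", "end", "state", "perm_p", "score")]
    out = pd.DataFrame({
        "chrom": calls["chrom"],
        "start": calls["start"],
        "end": calls["end"],
        "name": calls["strain"].astype(str) + ":" + calls["state"].astype(str),
        "score": -np.log10(calls["perm_p"].astype(float)).round(4),
        "strand": ".",
    })
    for c in extra:
        out[c] = calls[c]
    out = out.sort_values(["chrom", "start", "end"]).drop_duplicates()
    out.to_csv(path, sep="\t", header=False, index=False)


def read_calls(path) -> pd.DataFrame:
    """Read a BED6+ call file written by :func:`write_calls`."""
    base = ["chrom", "start", "end", "name", "score", "strand"]
    extra = ["n_probes", "island_score", "mean_std_ratio", "median_std_ratio",
             "score_swap", "perm_p_swap", "mean_std_ratio_swap", "median_std_ratio_swap"]
    try:
        df = pd.read_csv(path, sep="\t", header=None)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["strain", "chrom", "start", "end", "state",
                                     "n_probes", "score", "perm_p",
                                     "mean_std_ratio", "median_std_ratio"])
    df.columns = (base + extra)[: df.shape[1]]
    name = df.pop("name").str.split(":", n=1, expand=True)
    df["strain"], df["state"] = name[0], name[1]
    df["perm_p"] = 10.0 ** (-df.pop("score"))
    if "island_score" in df:
        df = df.rename(columns={"island_score": "score"})
    return df


def read_study_table(path) -> pd.DataFrame:
    """Collated published-call CSV -> normalized call table.

    Required columns: study, strain, chrom, start, end, state. States are
    normalized to loss/gain/abnormal via a small alias map; unknown state
    tokens raise.
    """
    df = pd.read_csv(path)
    required = ["study", "strain", "chrom", "start", "end", "state"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing columns {missing}; expected schema: {required}"
        )
    states = df["state"].astype(str).str.strip().str.lower()
    unknown = sorted(set(states) - set(STATE_ALIASES))
    if unknown:
        raise ValueError(f"{path}: unknown state tokens {unknown}; "
                         f"accepted: {sorted(set(STATE_ALIASES))}")
    df = df.copy()
    df["state"] = states.map(STATE_ALIASES)
    return df[required]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
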