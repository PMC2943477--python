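"""End-to-end pipeline: simulate -> standardize -> call -> consensus -> merge.

``pipeline_run`` drives the whole analysis from a configuration mapping and
writes per-stage artifacts plus a machine-readable run manifest (seed,
resolved parameters, and the record counts at every stage) to an output
directory.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import io as aio
from .calling import CallParams, call_cnvs
from .genome import Genome
from .regions import combine_states, coverage_summary, merge_regions
from .simulate import SimParams, make_probe_grid, make_snp_map, plant_cnvs, \
    simulate_profiles, truth_to_frame
from .standardize import filter_repeat_probes, fit_snp_regression, standardize

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "genome": {"chromosomes": [["chr1", 20_000_000], ["chr2", 15_000_000]]},
    "strains": ["strainA", "strainB"],
    "reference_strain": "reference",
    "seed": 0,
    "sim": {},        # SimParams overrides
    "truth": {"n_simple": 4, "n_complex": 1},
    "call": {},       # CallParams overrides
    "snp_rate": 0.0033,
}


def resolve_config(config: dict | None) -> dict:
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    for key in ("sim", "call", "truth"):
        cfg[key] = {**DEFAULT_CONFIG.get(key, {}), **(cfg.get(key) or {})}
    if cfg["reference_strain"] in cfg["strains"]:
        raise ValueError("the reference strain must not appear in the test-strain list")
    return cfg


def pipeline_run(config: dict | None, out_dir) -> dict:
    """Run the full synthetic pipeline; returns the manifest dict.

    Stages: probe grid + SNP map + planted truth -> dye-pair profile
    simulation -> per-experiment SNP standardization -> per-strain CNV
    calling with permutation significance, density filter and dye-swap
    consensus -> cross-strain region merging and state combination.
    """
    cfg = resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    genome = stage("genome", lambda: Genome(cfg["genome"]["chromosomes"]))
    aio.write_chrom_sizes(genome, out / "genome.chrom.sizes")

    sim = SimParams(**cfg["sim"], seed=seed)
    probes = stage("probe_grid", lambda: make_probe_grid(genome, sim))
    probes = stage("snp_map", lambda: make_snp_map(
        probes, cfg["strains"], snp_rate=cfg["snp_rate"], seed=seed + 1))
    truth = stage("truth", lambda: plant_cnvs(
        genome, cfg["strains"], seed=seed + 2, **cfg["truth"]))
    aio.write_probes(probes, out / "probes.tsv")
    truth_to_frame(truth).to_csv(out / "truth.csv", index=False)

    profiles = stage("simulate", lambda: simulate_profiles(probes, truth, sim, seed=seed + 3))

    retained = filter_repeat_probes(probes)
    call_params = CallParams(**cfg["call"], seed=seed + 4)
    counts = {"probes": len(probes), "probes_retained": len(retained)}
    fits = {}
    all_calls = []
    for strain in cfg["strains"]:
        normal, swap = profiles[strain]
        keep = retained["probe_id"]
        normal_raw = type(normal)(normal.strain, normal.dye, normal.values[keep])
        swap_raw = type(swap)(swap.strain, swap.dye, swap.values[keep])
        normal_std = stage(f"standardize:{strain}:normal",
                           lambda p=normal_raw, s=strain: standardize(p, retained, s))
        swap_std = stage(f"standardize:{strain}:swap",
                         lambda p=swap_raw, s=strain: standardize(p, retained, s))
        fit = fit_snp_regression(normal_raw, retained, strain)
        fits[strain] = {"slope": fit.slope, "p_value": fit.p_value,
                        "r_squared": fit.r_squared, "group_medians": fit.group_medians}
        aio.write_profile(normal_std, retained, out / f"profile_{strain}_normal.std.tsv")
        aio.write_profile(swap_std, retained, out / f"profile_{strain}_swap.std.tsv")
        calls = stage(f"call:{strain}", lambda n=normal_std, w=swap_std: call_cnvs(
            n, w, retained, call_params))
        aio.write_calls(calls, out / f"calls_{strain}.bed")
        counts[f"calls_{strain}"] = len(calls)
        all_calls.append(calls)
    aio.write_json(fits, out / "snp_fit_report.json")

    calls = pd.concat(all_calls, ignore_index=True)
    strain_order = [cfg["reference_strain"]] + list(cfg["strains"])
    loss_regions = stage("merge:loss", lambda: merge_regions(
        calls[calls["state"] == "loss"].reset_index(drop=True), "loss", strain_order))
    gain_regions = stage("merge:gain", lambda: merge_regions(
        calls[calls["state"] == "gain"].reset_index(drop=True), "gain", strain_order))
    combined = stage("combine", lambda: combine_states(loss_regions, gain_regions))
    loss_regions.to_csv(out / "regions_loss.tsv", sep="\t", index=False)
    gain_regions.to_csv(out / "regions_gain.tsv", sep="\t", index=False)
    combined.to_csv(out / "regions_combined.tsv", sep="\t", index=False)
    summary = coverage_summary(calls, genome, by="strain")
    summary.to_csv(out / "coverage_summary.tsv", sep="\t", index=False)

    counts.update({
        "consensus_calls": len(calls),
        "loss_regions": len(loss_regions),
        "gain_regions": len(gain_regions),
        "combined_regions": len(combined),
        "mixed_regions": int(combined["mixed"].sum()) if not combined.empty else 0,
    })
    manifest = {
        "seed": seed,
        "strain_order": strain_order,
        "params": {"sim": asdict(sim), "call": asdict(call_params),
                   "truth": cfg["truth"], "snp_rate": cfg["snp_rate"]},
        "counts": counts,
    }
    aio.write_json(manifest, out / "manifest.json")
    return manifest
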