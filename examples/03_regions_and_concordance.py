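"""Merge per-strain CNV calls into regions and compare call sets.

Demonstrates cross-strain region merging with strain-distribution patterns
(SDPs), loss/gain combination with mixed-region flags, per-strain coverage
summaries, the region-based overlap statistic between two experiments, and
pairwise cross-study replication percentages.
"""

import numpy as np
import pandas as pd

from acghcnv import (
    Genome, combine_states, coverage_summary, merge_regions,
    overlap_statistic, replication_matrix,
)

rng = np.random.default_rng(20)
genome = Genome([("chr1", 60_000_000), ("chr2", 40_000_000)])
strains = ["A", "B", "C", "D"]

rows = []
for strain in strains:
    for _ in range(30):
        chrom = "chr1" if rng.random() < 0.6 else "chr2"
        start = int(rng.integers(0, 39_000_000))
        state = "loss" if rng.random() < 0.75 else "gain"
        rows.append((strain, chrom, start, start + int(rng.integers(5000, 400_000)), state))
calls = pd.DataFrame(rows, columns=["strain", "chrom", "start", "end", "state"])

loss = merge_regions(calls[calls.state == "loss"].reset_index(drop=True),
                     "loss", ["ref"] + strains)
gain = merge_regions(calls[calls.state == "gain"].reset_index(drop=True),
                     "gain", ["ref"] + strains)
combined = combine_states(loss, gain)
print(f"{(calls.state == 'loss').sum()} deletion calls -> {len(loss)} regions "
      f"({int((loss.n_strains > 1).sum())} multi-strain)")
print(f"{(calls.state == 'gain').sum()} gain calls -> {len(gain)} regions "
      f"({int((gain.n_strains > 1).sum())} multi-strain)")
print(f"combined: {len(combined)} non-overlapping regions, "
      f"{int(combined.mixed.sum())} containing both deletions and gains")
print("example SDP (ref bit first, one bit per strain):", loss["sdp"].iat[0])

print("\nper-strain deletion coverage:")
print(coverage_summary(calls[calls.state == "loss"], genome, by="strain")
      .round(2).to_string(index=False))

# overlap between an experiment and a noisy replicate of itself
replicate = calls.copy()
replicate["start"] += rng.integers(-20_000, 20_000, len(replicate))
replicate["start"] = replicate["start"].clip(lower=0)
replicate = replicate.sample(frac=0.7, random_state=1)  # replicate misses 30%
stat = overlap_statistic(calls[calls.state == "loss"],
                         replicate[replicate.state == "loss"])
print(f"\noverlap statistic vs a jittered 70% replicate: {stat:.2f} "
      "(1 = every region seen in both, 0 = none shared)")

studies = {
    "full": calls.drop(columns="strain").assign(strain=calls["strain"]),
    "replicate": replicate.drop(columns="strain").assign(strain=replicate["strain"]),
}
mat = replication_matrix(studies, "loss")
print("\npairwise replication (% of row-study deletions overlapped by the "
      "column study, same strain):")
print(mat.to_string())
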