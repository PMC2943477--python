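# Methods

## The measurement model

A two-color aCGH experiment co-hybridizes test and reference genomic DNA
to a tiling array of 50–75-mer oligonucleotides and reports, per probe, the
log2 ratio of test to reference signal: 0 for equal copy number, ≈ −1 for
a hemizygous deletion, ≈ +0.58 (log2 3/2) for a single-copy gain. Two
systematic artifacts sit on top of this: (1) sequence variants between the
test and reference genomes inside a probe weaken test-channel binding —
empirically about −0.5 log2 units per SNP, stronger for SNPs near the probe
center than its ends; (2) repeat-containing probes hybridize promiscuously
and are unusable. The pipeline therefore removes repeat-flagged probes,
then removes the SNP effect by robust within-group standardization, and
only then calls CNVs.

The synthetic generator is the forward version of exactly this model:

```
ratio_i = shift(CNV state at probe i)
        + Σ_{SNPs s in probe i} effect_per_snp × w(position of s)
        + repeat_bias × 1[repeat probe]
        + N(0, noise_sd²)
```

with the dye-swap replicate drawing independent noise on the same
expectation (swap profiles are modeled after sign correction, so a loss is
negative in both dyes). A probe counts as inside a CNV when its midpoint
lies in the truth interval.

### Generator parameters (defaults = emulated study conditions)

| parameter | default | why |
|---|---|---|
| `probe_spacing_bp` | 1136 | median spacing of a repeat-filtered 2.1M whole-genome design; spacing jittered N(μ, 0.15μ) |
| `probe_len_bp` | 60 | mid-range 50–75-mer |
| `noise_sd` | 0.4 | per-probe log2 noise giving the observed weak per-probe signal (R² of the SNP regression ~0.04–0.3 depending on SNP density) |
| `snp_effect_per_snp` | −0.5 | the empirical per-SNP depression |
| `snp_position_weights` | ramp 0.6 → 1.2 | central SNPs disturb duplex formation more; 11 equal probe segments folded into 6 symmetric categories; no published numbers exist, so a monotone ramp averaging ~0.9 is used and is configurable |
| `repeat_fraction` | 0.111 | fraction of probes carrying repeat sequence |
| `repeat_bias` | −0.25 | repeat probes show shifted ratios; magnitude chosen as half a SNP effect, configurable |
| `loss_shift` / `gain_shift` | −1.0 / +0.585 | hemizygous deletion / single-copy gain conventions; the true platform response of a deletion is not published, so −1.0 is a convention |
| `snp_rate` | 0.0033 /bp | ~8.3M SNPs over a ~2.5 Gb genome |

Complex planted CNVs split a parent region into 3–7 sub-segments with at
least two non-normal sub-segments and at least one normal gap strictly
between them, mirroring the interleaved architectures that dense arrays
reveal. `make_snp_map` can draw SNP counts from an explicit distribution
(used by the acceptance script: P(0,1,2,3) = 0.85/0.10/0.03/0.02) instead
of the Poisson(length × rate) default.

**What the generator does not model:** wave artifacts, GC bias,
segmental-duplication cross-hybridization, correlated noise along the
genome, dye-specific (Lowess-type) bias, and reference-assembly errors.
Passing tests therefore demonstrate correctness of the algorithms under
the stated noise model, not robustness to every real-array pathology — in
particular the clean-regime recall/precision of the caller is far better
than on real data, where roughly a third of calls fail molecular
validation because of complex or unmodeled structure.

## Standardization and the SNP regression

Probes are grouped per strain by SNP count 0, 1, 2, 3+ and each group is
transformed to `(x − median) / MAD` with the *unscaled* MAD (no 1.4826
normal-consistency factor) — the plain median absolute deviation is the
definition used. Groups with MAD 0 are centered only and logged. Each
(strain, dye) experiment is standardized independently. Standardization is
a fixed point: re-running it on standardized data returns the values
unchanged. The SNP-effect regression is OLS of log2 ratio on the integer
SNP count capped at 3 (the 3+ group is coded 3, consistent with the
grouping; at realistic SNP densities capping versus not capping moves the
slope by far less than its standard error). Non-finite ratios are dropped with a logged count.

## Calling

With threshold `t` at the 10th (losses) / 90th (gains) percentile of the
standardized distribution, per-probe scores are `t − x` / `x − t`. Islands
are the disjoint maximal positive-sum segments of the score vector,
computed by recursive extraction of the maximum-sum subarray (ties broken
to the longer, then leftmost segment — deterministic output); this
decomposition cannot be extended or merged without losing score, and is
verified in tests against exhaustive enumeration.

Significance is genome-wide: the standardized ratios are shuffled across
all retained probes (a shuffle of ratios is a shuffle of scores, because
the threshold is a fixed quantile of the same multiset), the maximum island
score is recorded per permutation (islands never span chromosome
boundaries), and an island's empirical P is `(1 + #{null ≥ score}) /
(n_perm + 1)`. Defaults: 1000 permutations, α = 0.05 per state. The
genome-wide shuffle (rather than per-chromosome) matches the genome-wide
significance claim being made.

Post-processing: calls need `n_probes ≥ 5` and density ≥ 0.5 probes/kb
(the original density criterion is unpublished; both knobs are exposed and
removals logged), and a normal-dye call is reported only if it overlaps
(≥1 bp) a same-state dye-swap call; the reported coordinates are the
normal-dye call's, with the best-overlapping swap call's statistics
attached.

## Regions and concordance

Merging is transitive closure under strict ≥1 bp overlap (bookended
intervals do not merge), per state; clustering is delegated to pyranges
(`cluster(slack=-1)`). A region's interval is the union of its members and
its SDP is a presence bit per strain with the reference fixed at 0.
Loss and gain region sets are union-merged into non-overlapping combined
regions, flagged mixed when both states contribute. The overlap statistic
groups the two experiments' same-strain calls into regions the same way
and reports multi-member regions / all regions. Replication percentages
restrict each study pair to common strains, demand same-strain ≥1 bp
overlap with matching state, let `abnormal` target calls match either
state, and round half-up to one decimal. The false-negative rate counts
(region × strain) cells where the targeted assay saw variation and the
genome-wide array did not, over cells with targeted variation.

## Rotational permutation and enrichment

Observed CNV regions cluster along the genome; permuting them to
independent uniform positions would destroy that clustering and
overstate significance for any feature that also clusters. The null here
wraps the concatenated genome (karyotype order; configurable) into a
circle and rotates all regions by one shared uniform offset per replicate.
This preserves the number of region bases exactly and the multiset of
circular inter-region gaps; pieces straddling a chromosome boundary after
unwrapping are split rather than discarded, conserving the tested
quantity (base counts; region count can grow by at most the number of
chromosomes). One permutation set (per seed) is reused across features
for efficiency.

The statistic is the percentage of zone bases overlapping the feature
union, where the zone is the region set itself (`within`), the flanking
sequence up to 10 kb from each breakpoint excluding region interiors
(`flank`), or their union. Expected = median over permutations; fold =
observed/expected (+inf when expected is 0 and observed positive);
enrichment and depletion are two one-sided add-one tails and the smaller
is reported with its direction — never 0. Flanks are recomputed for the
split pieces of permuted regions; with ≤ one split per chromosome per
replicate the effect on the null is negligible. Size classes: small
< 10 kb ≤ medium ≤ 100 kb < large.

## Targeted segmentation and classification

Circular binary segmentation: for a probe series, the best arc (i, j] of
the circularized sequence maximizes
`|mean(arc) − mean(complement)| / sqrt(1/k + 1/(n−k))`; the split is kept
if its permutation P (default 1000 shuffles, early-stopped once the
add-one P provably exceeds α) is ≤ α = 0.01, and the parts are split
recursively. Regions with <10 probes return a single segment with a
warning. Enumerating linear arcs covers all circular splits because an
arc and its complement share the statistic. No undo/pruning pass is
applied beyond the significance recursion; adjacent same-state segments
are coalesced at classification time, which makes the architecture label
invariant to redundant splits.

Segments under 3 probes are merged into the nearer (shorter, then earlier)
neighbor and logged, since the rank test is meaningless below that.
Each segment is then Mann-Whitney-tested (two-sided) against the pooled
probes of all control regions — pooling maximizes the null sample — and
called non-normal only when P < 0.05 *and* |median| > 2 × s.d. of the
per-control-region medians (sample s.d., ddof = 1, configurable). The
amplitude rule is applied to |median| so losses and gains face symmetric
thresholds. No multiple-testing correction is applied across segments,
matching the stated per-segment rule; with ~230-probe control regions the
2 × s.d. bar is low, so occasional small spurious segments are expected —
a genuine property of this decision rule, visible in the examples. A
region is variant iff ≥1 segment is non-normal; complex iff ≥2 non-normal
runs remain after coalescing (necessarily separated by normal gaps) or
both losses and gains occur; simple otherwise.

The threshold sweep scans acceptance cutoffs over [−14, −1] in 0.1 steps:
at cutoff `t` a call is accepted when its mean standardized ratio ≤ t; the
curve reports the false positive rate among accepted calls and the
percentage of verified (simple ∪ complex) calls rejected, plus the least
strict cutoff achieving FPR 0 when one exists.

## Numerical and testing choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; identical parameters and seed reproduce outputs bit-exactly.
- Coordinates are 0-based half-open throughout (BED convention).
- Empirical P-values always use the add-one estimator.
- Island and arc ties are broken deterministically (longer, then leftmost).
- Permutation-null quantiles use the conservative `method="higher"`.
- Interval arithmetic (unions, coverage, circular rotation) runs on the
  concatenated integer coordinate with prefix-sum indices; tests verify it
  against bit-array base counting.
- Problem sizes in the heavier test suites — 200 null genomes of 10k
  probes with 200 permutations each for family-wise calibration, 100
  planted replicates for power, 200 replicate datasets for enrichment
  calibration, 30 planted targeted regions for classifier accuracy — were
  chosen to give binomial confidence intervals tight enough for the
  claimed error rates while keeping the default suite quick to run.

## Known limitations

- The caller assumes exchangeable probe noise under the null; spatially
  correlated artifacts (waves) would inflate island scores and are neither
  simulated nor corrected.
- Only autosome-style uniform diploid references are modeled; no sex
  chromosomes, no mosaicism, no segregating within-strain variation.
- The density filter's defaults are plausible conventions, not published
  values; they are logged with every run.
- Merging uses strict ≥1 bp overlap everywhere; reciprocal-overlap
  matching schemes are out of scope.
- Cross-study comparison assumes all call sets share one genome build;
  coordinate lift-over is out of scope.
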