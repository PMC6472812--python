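# Methods

## Problem and scope

Relative RT-qPCR quantification reports a target gene's expression
change against one or more reference genes (RGs) assumed stable across
the experimental conditions. Choosing those references badly is the
dominant avoidable error in qPCR studies, so the field's standard
workflow is: screen candidates that look flat in an orthogonal assay
(here, RNA-Seq differential-expression statistics), calibrate each
assay's amplification efficiency from a dilution series, rank the
candidates with several stability algorithms, reconcile the rankings,
and only then quantify targets. `refstab` implements that workflow
end-to-end, together with a synthetic-data generator that provides
ground truth for every stage.

## Data model

The universal input is a long table of quantification cycles
(sample, gene, replicate, Cq) with per-sample metadata (experiment,
condition ∈ {control, treated}, collection time, tissue) and per-gene
amplification factors `E ∈ (1, 2.5]` (2.0 = perfect doubling; percent
efficiency `e% = (E − 1)·100` appears only at I/O boundaries, because
published assays quote both conventions). Replicates are averaged to a
per-sample mean Cq before any stability statistic; replicate-level
values are kept for QC only. A gene × sample cell backed by fewer than
the requested number of surviving replicates becomes missing and is
propagated as such; pairwise statistics drop incomplete pairs.

Relative quantities are
`Q[g, s] = E_g ^ (minCq_g − meanCq[g, s])`,
calibrated to the per-gene minimum mean Cq so `0 < Q ≤ 1` with the
per-gene maximum exactly 1 (an explicit calibrator sample can replace
the minimum, in which case Q may exceed 1).

## Efficiency calibration

A standard curve regresses mean Cq per dilution level on log10 relative
input (that orientation is what the efficiency formula presumes);
`E = 10^(−1/slope)`. Slopes in `[−3.58, −3.10]` (inclusive, window
configurable) are flagged acceptable, i.e. ~90–110% efficiency.
Reported percent efficiencies are rounded to integers only at output.

## Stability algorithms

**geNorm.** `M_j` = mean over partners k of the SD (n−1 denominator
throughout) across samples of `log2(Q_j/Q_k)`; ranking by stepwise
exclusion of the max-M gene, recomputing M each round, until two genes
remain; those two cannot be separated by the method and are reported as
a tied best pair, ordered by full-set M then gene id. Normalization
factors `NF_n(s)` are geometric means of the top-n genes' Q; the
pairwise variation `V_{n/n+1}` is the SD across samples of
`log2(NF_n/NF_{n+1})`, and the optimal reference count is the smallest
n ≥ 2 with `V ≤ 0.15` (the conventional cut-off; a flag reports when no
n satisfies it). Log base 2 follows the geNorm convention.

**NormFinder.** On natural-log quantities, the per-sample across-gene
mean is removed (sample effect), then per gene × group the model
estimates a group mean, a residual variance, and the inter-group
deviation d. Because the gene-mean subtraction forces a zero sum across
genes, the raw residual variance is biased upward by a share of the
other genes' variation; the corrected variance is
`γ̂² = max(0, s² − mean_genes(s²)/(G−1))` and d is shrunk toward zero by
`t = σ̂_d²/(σ̂_d² + γ̂²/n)` with `σ̂_d² = max(0, Σ_i d_i²/(G−1) −
mean_i(γ̂²_i/n))`. The stability value is
`ρ = mean over groups (|d̂| + √(γ̂²/n))`; lower is more stable. A
single-group design reduces to the SD of the sample-centred
log-quantities. A `plain` mode skips both corrections for oracle
comparison; on well-separated data the two modes rank identically
(asserted in the tests). The default grouping is condition
(control vs treated); grouping by collection time is available, since
published studies rarely state which grouping their NormFinder run
used.

**BestKeeper.** Works on raw per-sample mean Cq. Genes whose Cq sample
SD exceeds 1 cycle are excluded (the original tool's mean-absolute-
deviation-style statistic is also computed and can drive exclusion via
a switch); the BestKeeper index is the per-sample geometric mean Cq of
the retained genes; each retained gene is scored by Pearson r against
the index with a two-sided p from the t approximation (df = n−2, no
multiple-testing correction, matching common BestKeeper practice).
Ranking: significant genes first, by descending r, then ascending SD,
then gene id; zero-variance genes have undefined r and are flagged and
placed last.

## Consensus and subset sweeps

Congruence between two rankings is `100·|top_k(a) ∩ top_k(b)|/k` with
k = 4 by default, on unordered sets (membership, not order). The
factorial sweep enumerates all `2^T − 1` nonempty subsets of collection
times (15 for four times), ordered by size descending then
lexicographically; control samples travel with their matched time. Each
algorithm re-runs per subset; subsets failing an algorithm's
preconditions are recorded as skipped, not fatal. Summaries: per-subset
congruence against the same algorithm's global (all-times) top-k,
unweighted mean congruence per algorithm, and per-gene top-k frequency
over a designated subset family (e.g. the seven early-time subsets).

## Target-gene expression (REST-style)

The expression ratio is
`E_t^(ΔCq_t) / geomean_r(E_r^(ΔCq_r))` with `ΔCq = meanCq_control −
meanCq_treated`. Significance comes from a pairwise fixed-reallocation
randomization test: whole replicates (the joint Cq vector of target and
references, preserving between-gene correlation) are pooled and group
labels reassigned with group sizes fixed; the two-sided p-value counts
reallocations with `|log ratio|` at least the observed one, with the
`(b+1)/(n+1)` correction so p is never 0. Default 2000 iterations,
seed mandatory. Percentile bootstrap (resampling replicates within
groups) gives a 95% interval; calls are `up`/`down` at p < 0.05, else
`ns`.

**Resolution of small designs.** With `n_c` vs `n_t` replicates there
are only `C(n_c+n_t, n_c)` distinct reallocations, and the complete
group swap always reproduces `|log ratio|`; the smallest attainable
two-sided p is therefore `2/C(n_c+n_t, n_c)` — 0.1 at 3v3, 0.029 at
4v4, ~0.0022 at 6v6. A triplicate-vs-triplicate comparison can never
reach p < 0.05, whatever the effect size; this is a property of
permutation tests, not an implementation limit. Calibration studies in
the test suite therefore use 6v6 replicates, where the nominal 5% level
is attainable; a dedicated test asserts the 3v3 granularity fact.

## Synthetic data

`generate_cq_dataset` draws
`Cq = baseline + shift(condition, time) + sample_effect + noise`, with
i.i.d. normal replicate noise on the cycle scale (where replicate SDs
are quoted in practice), deterministic shifts per design cell (so the
ground-truth ordering — ascending injected shift variation, then noise —
is well defined), and an optional per-sample random intercept shared by
all genes. That intercept models template-input variation between cDNA
preparations; it cancels exactly in geNorm's log-ratios and
NormFinder's sample-centring but is the very signal BestKeeper's
index correlation measures, so it defaults to 0 in the raw model and to
0.5 cycles in the benchmark layout.

The ten-gene benchmark (`benchmark_spec`) has baselines spanning
18.1–25.8 cycles (the range seen in real leaf/root candidate panels),
noise SD 0.2 cycles, 4 collection times × control/treated × 3
biological × 3 technical replicates, three zero-shift genes, and seven
shifted genes on a graded ladder (0.5–4 cycles). Shift structure is
deliberate:

* mild shifts (< 2 cycles) are sustained condition responses with signs
  summing to zero across the panel (+0.5, +1, −1.5). If all unstable
  members drifted the same way, the panel consensus would drift with
  them, and consensus-relative metrics (NormFinder's inter-group term,
  BestKeeper's index correlation) by their own definitions could not
  distinguish "stable" from "moving with the crowd" — the ground truth
  would be unidentifiable, which is a real limitation of these methods
  on coherently regulated panels, documented here rather than hidden;
* strong shifts (≥ 2 cycles) are transient responses alternating in
  sign across collection times (zero mean within the treated group),
  mimicking early/late stress kinetics; their Cq SD necessarily exceeds
  1 cycle, so BestKeeper's exclusion rule removes them robustly.

What the generator does **not** emulate: fluorescence-level artefacts
(Cq calling, baseline drift), heteroscedastic noise at high Cq,
amplification-efficiency misestimation, inter-run batch effects, and
biological covariance between genes beyond the shared sample intercept.
Passing recovery benchmarks therefore demonstrates algorithmic
correctness on the stated model, not robustness to those artefacts.

DE-table generation plants reference-like genes (|log2FC| ≤ 1,
p > 0.05 everywhere), target-like genes (one contrast with log2FC > 2,
p < 0.05), and null genes violating both filters (a moderate 1.2–1.9
log2FC contrast with small p).

## Numerical and design choices

* Fold-change screening bound is inclusive (|log2FC| ≤ 1): candidate
  panels in published tables carry cells of exactly ±1.00 among
  accepted references; P-value comparisons are strict. Both
  configurable.
* Randomness: `numpy.random.default_rng` (PCG64) everywhere; identical
  (spec, seed) pairs give byte-identical CSV output.
* Ties: stepwise exclusion breaks exact M ties (tolerance 1e-12) on
  gene id; an all-tied panel is flagged and ordered by gene id.
* Degenerate inputs: zero-variance genes in BestKeeper are flagged with
  undefined r and placed last; zero-variance replicate data in the
  randomization test warns and returns p = 1; genes missing a DE
  contrast are excluded from screening with a warning, never kept
  silently.
* Problem sizes in the test and acceptance suites (100-seed recovery
  runs, 1000-dataset null calibration at 1000 iterations, 6v6
  calibration designs) were chosen as the smallest sizes at which the
  checked proportions are statistically meaningful.

## Known limitations

* geNorm's M rewards co-regulated pairs: two genes regulated in
  lockstep keep near-zero mutual ratios. The benchmark avoids planting
  such pairs; real panels should avoid co-regulated candidates by
  design.
* NormFinder's inter-group term assumes most candidates are unregulated;
  a panel dominated by same-direction regulation shifts its baseline
  (see above).
* BestKeeper's index correlation needs shared sample-level variation to
  carry signal; on perfectly normalized input its ranking is driven by
  noise.
* The REST randomization test is valid but discrete; confidence in
  small designs is bounded by the reallocation count, and the reported
  p never falls below `1/(iterations+1)`.
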