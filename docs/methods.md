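# Methods

## Count model and the per-window exact test

Read counts over non-overlapping genomic windows (1000 bp by default) are
modelled as negative binomial with the mean–dispersion parameterization

    Var(Y) = μ + φ·μ²,

so `φ = 0` is the Poisson limit. The two-group comparison for a window works
on counts rescaled to a common library size — the geometric mean of the
effective library sizes (raw library size × TMM factor) — rounded to the
nearest integer, ties to even (the conditional law below requires integer
sums). Group sums `S_A` (disease, `n_A` samples) and `S_B` (no disease,
`n_B`) are then treated as

    S_g ~ NB(n_g · μ̂,  φ / n_g),   μ̂ = (S_A + S_B) / (n_A + n_B),

which is the exact distribution of a sum of i.i.d. NB variables with common
mean and dispersion. Conditioning on `S = S_A + S_B` gives a discrete law
over the splits `s = 0..S`; the two-sided p-value is the minimum-likelihood
sum: all splits whose conditional probability is no greater than the observed
one (a relative tolerance of 1e-10 absorbs float noise in exact ties; when
every split is included, p is exactly 1). In the Poisson limit the
conditional law reduces to `Binomial(S, n_A/(n_A+n_B))` — e.g. 10 vs 0 with
equal sizes and one sample per group gives p = 2/1024.

The log2 fold change is `log2((S_A/n_A + 0.5) / (S_B/n_B + 0.5))`; the 0.5
pseudo-count per group mean keeps zero-count windows finite.

Windows with mean raw count below `min_mean_count` (default 1.0 read/window)
are not tested: they carry p = 1, are flagged untested, and are excluded from
the multiple-testing correction. Benjamini–Hochberg is applied over tested
windows only (via statsmodels); when DMR-level FDR is wanted it should be
computed as BH over per-DMR minimum p-values and labelled as such — the two
corrections answer different questions.

### Dispersion estimation

The common dispersion is a method-of-moments estimate: per window, from
counts scaled to the common library size, the within-group variance (pooled
across both groups with n−1 denominators) and grand mean `m` give
`φ_w = max(0, (v − m)/m²)`; the common value is the mean-weighted average of
`φ_w` over windows passing the coverage floor. The estimator is deterministic
and recovers simulated values well at the package's reference scale (e.g.
φ = 0.2 estimated within ±0.05 at 10,000 windows, 10 samples/group); the
clipping at zero introduces a small positive bias that is negligible for
φ ≥ 0.05 and keeps Poisson data at φ̂ ≤ 0.01. At least one group needs two or
more replicates, and (by default) at least 50 windows must pass the floor.

### Calibration

On null simulations (no planted effect, φ = 0.1, 8 vs 8 samples) the fraction
of tested windows with p < 0.05 runs at ≈ 0.049 — slightly conservative, as
expected for a discrete exact test.

## Normalization

TMM factors are computed from M-values (log2 ratios of library-size-
normalized counts against a reference sample — the one whose upper-quartile
normalized count is closest to the mean upper quartile), after trimming 30%
of M-values and 5% of A-values from each tail and excluding windows with a
zero count in either sample; factors are normalized to geometric mean 1. The
effective library size is raw library size × factor; `norm: total-count`
fixes all factors at 1. RPKM is `count / (window_kb · library_size/10⁶)`.

## DMR assembly (seed-and-extend)

Windows with `p < seed_threshold` (default 1e-4, strict inequality; ties at
the threshold are excluded) are seeds. Maximal runs of adjacent seed windows
initialize regions; then, iterated to a fixed point, any tested window with
`p < extend_threshold` (default 0.1) whose interval lies within `reach`
(default 1000 bp) of a region edge is absorbed, and regions that touch or
overlap merge. **Reach convention:** a window qualifies when its gap to the
region edge is *strictly less than* `reach` — an adjacent window (gap 0)
extends the region, while a window separated by one full 1000 bp window does
not; an intervening window with p ≥ 0.1 therefore blocks extension. Untested
windows behave as p = 1 and block extension. Extension windows widen the
reported interval but only seed windows count toward
`n_significant_windows`; a DMR with at least two is a "multiple-window" DMR.
Per-DMR summaries report the minimum member p, the member log2 fold change of
largest magnitude with its sign (which also sets the hyper/hypo direction),
summed member CpG counts, and CpG density per 100 bp. A post-assembly audit
(`audit_fixed_point`) verifies no absorbable window remains near any edge;
p-values are two-sided throughout.

## Comparative analysis

Overlap between DMR intervals means ≥ 1 shared bp under half-open semantics;
a minimum reciprocal-overlap fraction is available where a stricter criterion
is wanted (recovery benchmarks use 50%). Venn counts are reported per set —
each DMR is assigned to exactly one region of its own set's partition by
which other sets it overlaps — because sets have different cardinalities and
a shared "element" is an overlap relation, not a merged interval. Extended
overlap compares a strict-threshold set against another comparison's DMRs
assembled at a relaxed threshold (default p < 0.05); the self-comparison is
100% by construction and serves as a contract check. PCA treats samples as
observations and centered (not variance-scaled — RPKM is already
depth-normalized; scaling is available by flag) DMR-window RPKM as features;
component signs are fixed by forcing each component's largest-magnitude
window loading positive, and group separation is summarized by the mean
silhouette of the disease labels on (PC1, PC2).

## Pathology arm

Abnormality density is count per mm² of section area. The disease cutoff per
tissue is the control-group mean plus two sample standard deviations (n−1
denominator — the conventional estimator for a control sample; the summed
density per tissue is used by default, with a per-abnormality-type option). A
tissue is diseased when at least two observers' calls agree (the third
observer is consulted only on disagreement). Disease tables use `+`/`−`/`n/a`
symbols; `n/a` entries are excluded from that pathology's denominator.
`total_disease` counts present flags among the six primary pathologies and
`multiple_disease` is `total ≥ 2`; when the input carries these columns they
are cross-checked against the derivation and a mismatch is a parse error.
Percentages are rounded half-up to whole percent. Group comparisons use the
two-sided Fisher exact test (minimum-likelihood rule, via scipy). Late
puberty, obesity, and tumor flags are ingested as given — their assessment is
qualitative — not computed from densities.

## Synthetic data generator

The generator emulates the statistical structure the analysis consumes, not
the sequencing process: per-sample counts per window are NB with mean
`baseline_mean × L_s × 2^(±effect_log2)` (the effect applied only to disease
samples at planted windows), where `L_s` is a lognormal(0, `libsize_factor_sd`)
depth factor. Planted regions are non-overlapping, grid-aligned,
`dmr_span` windows long, split ~50/50 between methylation gain and loss.
Per-window CpG counts are binomial at `cpg_rate` per 100 bp, and an explicit
sequence consistent with the counts can be generated (CpG dinucleotides occur
exactly where counted, never across a window boundary). One seed drives
deterministic sub-streams for genome, placement, and counts; identical
configurations are bit-identical.

Reference conditions (the package defaults): 2 chromosomes × 10,000 windows
of 1000 bp, 8 disease vs 8 control samples, baseline 50 reads/window,
dispersion 0.1, depth spread 0.1, 20 planted 3-window DMRs at |log2 FC| = 2,
CpG rate 2/100 bp. The source study does not publish per-sample depths or
dispersion estimates, so these are free parameters chosen as typical for
pooled MeDIP-seq at this window size; they are stated here and in the config
echo of every run. What the generator does **not** model: read-level
artifacts (FASTQ, alignment), fragment-size and CpG-affinity bias of MeDIP
enrichment, GC/mappability structure, or correlated biological variation
between neighbouring windows. Passing recovery benchmarks therefore
demonstrates correctness of the statistics and assembly logic under the
stated model, not performance on real libraries, where enrichment bias and
extra-NB variation will reduce power.

## Numerical choices and degenerate inputs

- Equalized counts round ties to even (`numpy.rint`).
- The batch exact test enumerates the conditional law via 1-D log-gamma
  tables indexed by integer counts, in chunks; batch and scalar paths agree
  to ~1e-9 relative.
- Reads are assigned to windows by midpoint under half-open conventions
  (a midpoint exactly on a boundary belongs to the right-hand window);
  malformed intervals (start ≥ end) are input errors, reads on unknown
  chromosomes are counted as skipped.
- Zero-variance PCA input yields all-zero coordinates with zero variance
  explained rather than an error.
- Empty DMR sets propagate as empty results: hyper fraction and overlap
  percentages are reported missing (None), never 0.
- All thresholds are strict inequalities; this is deliberate so that printed
  threshold values never self-include.

## Design decisions

- The per-window statistic is this package's own documented exact NB test;
  numerical agreement with any other implementation of a window-level count
  test is not a contract — distributional calibration (type-I error near
  nominal, oracle equivalence with brute-force enumeration) is.
- Gene association uses a 10 kb distance rule by default (inclusive at the
  boundary); the rule is configurable and echoed in output metadata.
- DMR clusters are ≥ 3 DMRs with consecutive gaps ≤ 2 Mb — an
  operationalization of visual clustering on chromosome plots, and flagged as
  such.
- Library equalization uses the geometric mean of effective sizes so the
  rescaling is symmetric in the samples.

## Limitations

- The common dispersion is a single pooled value; no tagwise or trended
  dispersion, GLM covariates, or paired designs.
- With few replicates per group, window-level FDR over ~20,000 windows is
  weakly powered; reporting both window-level q-values and DMR-level BH on
  minimum p is recommended, and seed-threshold sweeps should accompany any
  fixed-threshold DMR count.
- Venn/overlap results depend on the ≥ 1 bp overlap convention; use the
  reciprocal-fraction option for robustness checks.
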