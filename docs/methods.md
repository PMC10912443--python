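# Methods note

This note records the statistical models implemented in `woundtraj`, the
parameter choices, what the synthetic cohort generator does and does not
emulate, and the numerical conventions that matter for reproducibility.

## Analysis methods

### Normalization

**Size factors (median of ratios).** For counts `k[g,s]`, the reference for
gene `g` is the geometric mean across samples over genes with all-positive
counts; the factor for sample `s` is `exp(median_g(log(k[g,s]) −
log_geomean[g]))`. The median is taken on the log scale, so an even number
of genes interpolates geometrically between the two middle ratios — the
convention of the standard "ratio" estimator (DESeq2), against which the
test-suite cross-checks when `pydeseq2` is installed. Size factors are
identifiable only up to a common scalar; the equivariance property (scaling
one sample by `c` scales its factor by `c` and leaves normalized counts
unchanged) therefore holds after fixing that gauge. Matrices where no gene
is positive everywhere fail loudly unless `positive_only=True`, which
computes each gene's geometric mean over its positive samples and drops
zero entries from the median (a poscounts-style fallback).

**TPM.** `rate[g,s] = k[g,s] / length[g]`, scaled so each column sums to
10⁶. All-zero samples yield all-zero columns with a warning rather than
NaN.

**Down-selection.** Before network construction, genes are kept when every
TPM value is > 0 and the mean TPM is ≥ 1000 (boundary included). This is an
expression filter, not a differential-expression filter.

### Dynamic network analysis (DyNA)

Within each stratum (outcome or colonization, configurable), windows pair
two consecutive observed days (or two adjacent day bins: 3–5, 6, 7, 8–10,
11–12, 13–16, ≥17). In a window with ≥ 3 samples, an edge joins genes `a,b`
when `|Pearson r(a,b)| ≥ 0.99`. Complexity is `2|E|/(n−1)`, with `n` the
full number of genes analyzed — zero-variance genes stay in the node set as
isolated nodes, so complexity is comparable across windows. Windows with
too few samples are reported as missing, not zero.

### Trajectory classification

Per (feature, wound group), Spearman's ρ (average ranks on ties) of the
feature value against days post-injury: **positive** if ρ > 0.1,
**negative** if ρ < −0.1, **flat** otherwise (boundaries inclusive to
flat), undefined when the group has < 3 samples or either variable is
constant. An OLS line on the same points supplies slope and intercept.
Features are summed normalized counts over each of 19 functional
categories, deconvolved cell-type proportions, and the M1/M2 ratio.

### Deconvolution

Each TPM column is renormalized to sum 10⁶ over the genes provided, then
regressed on the cell-type signature matrix (marker-gene TPM profiles) by
non-negative least squares over the shared genes; the coefficients are the
cell fractions directly because both sides are on the same
fraction-of-transcriptome scale. If the fractions sum above 1 they are
projected back to the simplex; `other = 1 − Σ fractions`. A signature with
numerically collinear columns is rejected. The M1/M2 ratio divides the two
macrophage fractions and is reported missing (NaN, with a warning) when the
M2 fraction is below a floor (10⁻⁶ by default) rather than returning
infinities.

### ρ-matrix PCA

The trajectory tables pivot into a feature × 4-group matrix of ρ values;
features lacking a finite ρ in any group are excluded and listed. PCA runs
on the four group observations (features as variables) via SVD after
centering; with 4 observations at most 3 components carry variance.
Variable contributions are `100 · loading² / Σ loading²` per component.
Component signs are fixed by making the largest-|loading| variable
positive, so repeated runs are bit-identical.

### Cross-platform concordance

RNA-seq enters as `log2(TPM + 1)`; qRT-PCR threshold cycles are negated
(lower Ct = more transcript) unless `ct_orientation="raw"`. Both matrices
are median-centered across genes then across samples, and each gene gets a
Spearman ρ across the matched samples. Genes constant on either platform
*before* centering are excluded as undefined (cross-sample centering would
lend them spurious variation). The report includes the mean ρ and the
fraction above a threshold (default 0.5).

## The synthetic cohort generator

Shape: 18 patients, 21 wounds, 64 samples (2–5 per wound on a 2–3-day
cadence within days 3–25), 1500 genes, of which 19 × 20 form the category
blocks and 10 × 50 the cell-type marker blocks. Per sample, the expected
TPM is a mixture of full-transcriptome cell-type profiles (10 immune types
plus "other", each column summing to 10⁶) weighted by proportions that
interpolate linearly in time between group-specific endpoints; category
genes are further multiplied by `exp(slope · (day − midpoint))` with
`slope ∈ {+0.1, 0, −0.1}` per (category, group). Counts are
negative-binomial (gamma–Poisson, `var = μ + 0.05 μ²`) around `μ = depth ·
wound_effect · rate`, with lognormal depth (mean 3·10⁶ reads, log-sd 0.2)
and a lognormal per-wound effect (log-sd 0.1); `depth · wound_effect` is
exported as the true size factor. The paired qRT-PCR panel is
`Ct = 38 − 1.0 · log2(TPM + 1) + N(0, σ)`; `calibrate_ct_noise` bisects σ
until the mean per-gene ρ hits a target (the packaged pipeline default
σ = 0.75 was calibrated to a target mean ρ of 0.5).

Two design decisions deserve a note:

* **Immune totals are held constant over time within each group** (0.35 at
  both endpoints), so the "other" fraction does not drift and category
  trends — expressed mostly by "other" — are not confounded by immune
  drift. What changes over time is the composition (e.g. neutrophils and
  M1 falling while M2, B and NK rise in colonized/healed wounds, and the
  inverse in colonized/failed wounds), which is what deconvolution and the
  M1/M2 ratio are meant to detect.
* **One category per group is left deliberately flat.** At ~16 samples per
  group the Spearman null distribution has sd ≈ 1/√15 ≈ 0.26, so a truly
  flat trajectory lands in |ρ| ≤ 0.1 only ~30% of the time; flatness is
  near-unidentifiable at this cohort size. The trend-recovery benchmark is
  therefore dominated by sign recovery, and the recovery rate is expected
  to sit a few percent below 1 for this structural reason, not because of
  an implementation defect.

The generator emulates: cohort shape and irregular longitudinal sampling,
overdispersed counts with realistic depth variation, mixture-of-cell-types
composition, programmed monotone category trends, and a noisy paired PCR
panel. It does not emulate: patient-level random effects beyond the wound
effect, batch effects, gene–gene correlation beyond co-membership in a
category or marker block, dropout/zero inflation, isoform/length effects
(lengths are uniform 500–5000 bp and time-invariant), censoring by death or
loss to follow-up, or any particular real gene's identity — gene and
category names are labels, not biology.

## Numerical conventions

* All randomness flows from integer seeds through
  `numpy.random.default_rng`; derived seeds are drawn below 2³¹. The
  pipeline derives per-stage streams as `default_rng([seed, stage_index])`.
* Pipeline floats are written with the `%.10g` format; no timestamps or
  absolute paths enter any output, so reruns and stage-at-a-time runs are
  byte-identical. `run_manifest.json` records the package version, the
  SHA-256 of the resolved configuration (output directory excluded — it
  identifies where a run lives, not what it computes) and of every output
  file.
* A failed stage writes a `FAILED` marker file into the run directory and
  re-raises.

## Limitations

Four observations support at most three principal components, so the
ρ-matrix PCA describes separation among these groups; it does not estimate
population structure. The |r| ≥ 0.99 network stringency on 3–10-sample
windows keeps only near-collinear gene pairs, and complexity values are
sensitive to the down-selection that precedes them. Deconvolution assumes
the signature spans the immune content and that markers are not expressed
by the "other" compartment; violations bias fractions upward. All headline
numbers quoted in the README come from `scripts/acceptance.py` and the test
suite on synthetic cohorts — they characterize the implementation, not any
clinical dataset.
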