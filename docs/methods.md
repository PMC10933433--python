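# Methods

## The experimental design being modelled

The pipeline targets iPOND-TMT time-course data: proteins captured on
EdU-labelled DNA in cells treated with DMSO, triptolide (TPL, blocks RNAPII
loading) or DRB (blocks elongation), sampled at three chase points
(Nascent, 1 h, 2 h), in several biological replicates.  Each replicate was
acquired in its own mass-spectrometer run, so replicate and batch are
identified: one TMT channel per (treatment × time × batch) cell.  All
statistics below operate on that design.

## Preprocessing

**QC filter.** Protein groups are kept when they have ≥ `min_razor`
(default 3) unique+razor peptides and are neither reverse-database decoys
nor potential contaminants.  The filter is idempotent and reports a tally
by removal reason.  A reporter intensity of 0 is treated as missing on
read: MaxQuant writes 0 for unquantified channels, and a literal zero would
corrupt the log transform.

**Log + median normalization.** Intensities are log10-transformed and each
sample is shifted so its observed median equals the grand target, defined
as the median of the pre-shift sample medians.  Any common target yields
identical contrasts; the median-of-medians keeps the values on the original
scale.  One consequence worth knowing: shifting a single sample by a
constant leaves the matrix unchanged only when the grand target is
unmoved; in general the whole matrix moves by one common constant, so all
contrasts — the quantities every downstream stage consumes — are exactly
invariant.

**Batch correction.** Per protein, the observed log values are regressed on
batch indicators together with the treatment and time covariates (the
covariate-protected variant is the default; an unprotected variant exists
behind `protect_design=False`).  Protecting the design matters because an
unbalanced missingness pattern would otherwise let real treatment effects
leak into the batch estimate.  The estimated batch effects are re-centred
to mean zero across batches and subtracted, which removes an additive
batch offset exactly under balance and never touches within-batch
contrasts.  Proteins with an entirely missing batch or a collinear
per-protein design pass through unchanged and are reported.  Missing
values are never imputed anywhere in the pipeline.

## Differential abundance

Each protein is fitted on its observed samples with the additive model
`log2 ~ treatment + time_point` (reference levels DMSO and Nascent, no
interaction; log10 input is converted by ×log2 10, so coefficients are
log2 fold changes).  An interaction variant is deliberately out of the
default path: with the planted generative model the factors are additive,
and the main-effect reading of "treatment fold change" is the default
interpretation of contrasts such as TPL-vs-DMSO.

**Variance moderation.** Residual variances s²_g with df_g residual
degrees of freedom are shrunk towards a scaled inverse-χ² prior (d₀, s₀²)
estimated by moment-matching log s²_g: with
e_g = log s²_g − ψ(df_g/2) + log(df_g/2), the model implies
E e = log s₀² + ψ(d₀/2) − log(d₀/2) and Var e = ψ′(d₀/2) + mean ψ′(df_g/2),
solved with a Newton trigamma inverse.  The moderated statistic uses
s̃²_g = (d₀s₀² + df_g s²_g)/(d₀ + df_g) on d₀ + df_g degrees of freedom.
When the observed spread of e is no larger than its sampling component the
prior degenerates to a point mass (d₀ = ∞) at the geometric-mean variance —
chosen so that exactly equal sample variances give s̃²_g ≡ s²_g and the
moderated t collapses to the ordinary t, the natural contract for that
edge.  In the non-degenerate case the estimator agrees with the standard
R implementation of this moment-matching to machine precision (verified in
the test suite by running both routes on the same matrix).

**FDR and calls.** BH adjustment is implemented as the literal step-up
(sort, p·n/i, running minimum from the largest rank, cap at 1), applied
within each contrast.  A protein×contrast is "significant" when
FDR ≤ 0.05 and |log2FC| ≥ 0.5; a stricter FDR < 0.01 preset exists for
nascent-baseline calls.  Note the fold-change gate dominates near the
boundary: an effect of exactly 0.5 log2 units is estimated above the gate
only about half the time, whatever the FDR.

**Heatmap quantities.** Condition-cell means (over observed replicates)
are mean-centred per protein, giving log2 fold changes with respect to the
protein mean; rows are ordered by complete-linkage hierarchical clustering
with Euclidean distance (scipy's deterministic implementation; leaf order
is reproducible for a fixed input order).

## Bootstrap gene-set depletion test

For a set with k quantified members and observed mean log2FC m, draw
B = 100,000 random k-subsets of the full quantified universe (members
included, without replacement; with-replacement draws behind a flag) and
report p = #(null mean < m)/B.  The strict proportion is the default, so
p = 0 is representable; a (count+1)/(B+1) rule is available when a
publishable nonzero p is preferred.  Lower-tail is the default (the
question is depletion); upper and two-sided options exist.  Subsets are
drawn by vectorised rejection sampling (iid indices, redraw rows containing
duplicates — exact uniformity over subsets), falling back to partial
argsort of random keys when k² > n.  Indices depend only on (n, k, seed),
which makes the test monotone under member shifts at a fixed seed.  BH
runs across the set×contrast grid of one panel (stratum); a pooled-grid
flag re-adjusts across strata (replicated chromatin, steady-state
chromatin, whole-cell lysate) instead.  Proteins belonging to several
complexes count in every family containing them.

## TF kinetics

TFs are classified from the Nascent-vs-2h contrast in DMSO: positive
log2FC = enriched on nascent chromatin (transient gain of access).  Five
exhaustive, mutually exclusive categories: |log2FC| < 0.5 is "flat"
regardless of FDR; above the gate, FDR ≤ 0.05 splits significant from
non-significant gain/loss.  Category proportions get Wilson score
intervals (Wald behind a flag); Wilson was chosen for its boundary
behaviour (k = 0 gives a zero lower limit) and nominal coverage at
moderate n, which the suite verifies by simulation.  Flat TFs that are
nevertheless significant in the TPL and/or DRB full-model contrasts are
flagged {TPL_only, DRB_only, both, neither}, optionally cross-annotated
with whole-cell-extract significance.

## Histone PTM relative abundance

Within one sample, the summed area of all modified forms of a histone
peptide is 100% and each form's area is expressed as a percentage of it.
H3 and H3.3 peptides are distinct peptide keys and never pool.  Isobaric
pairs are split beforehand: per distinguishing fragment ion the species-A
share a/(a+b) is computed, shares are averaged over ions, and the parent
area is apportioned by the resulting ratio (conserving the parent area
exactly); pairs without a usable ion stay unsplit and are flagged.
Time-course comparisons use classical paired t-tests pairing by biological
replicate — each time point against the reference time within a treatment
by default, treatments against DMSO at a fixed time as the alternative
orientation.  Comparisons with fewer than two complete pairs or with all
paired differences exactly zero are reported untested rather than given a
fabricated p.

## The synthetic-data generator

What it emulates: log-normal protein baselines (log10 mean 6.0, sd 0.8 —
the typical TMT reporter scale), per-protein residual variances from a
scaled inverse-χ² prior (d₀ = 4, s₀² = 0.04 in log2 units, matching the
moderation model), additive per-batch offsets up to ~0.35 log2 units
(batch effects of the magnitude that motivates correction), planted
additive log2 treatment/time effects on named gene sets, logistic
missingness in true intensity (12% at low abundance falling to 1% at high
— missing-not-at-random, as in real reporter data), decoy and contaminant
rows, and razor-peptide counts with ~8% of proteins under the 3-peptide
cut.  Per-sample loading offsets are exposed (`sample_scale_log2`) rather
than guessing a normalization target.  A truth record stores every planted
delta, the per-protein variances and the noise-free signal matrix.

What it does not emulate: peptide/spectrum-level effects, TMT isotopic
impurity, ratio compression, retention-time drift, or correlated
missingness across channels.  Passing tests therefore demonstrate the
statistical machinery is correct under its stated model, not that the
model captures every artefact of real reporter-ion data.

Default problem sizes used by the test suite and the acceptance script
(3,000 proteins, 3 treatments × 3 time points × 4 batches, B = 100,000
bootstrap iterations; smaller grids for end-to-end determinism checks) are
the package's standard working scale: large enough for stable prior
estimation and calibration statements, small enough to iterate on.

## Numerical and degenerate-input choices

- Zero intensities become missing at parse time; non-positive values at the
  log step raise an error naming protein and sample.
- Proteins with residual df < 1, a rank-deficient design, or fewer than a
  configurable minimum of observations per factor level are excluded from
  fitting and reported, never silently dropped.
- The trigamma inverse uses Newton iteration to 1e-10 relative tolerance.
- p-values are two-sided; d₀ = ∞ uses a 1e12-df t reference
  (indistinguishable from normal).
- Clustering with < 2 rows returns a single-leaf result; equal merge
  heights resolve by scipy's deterministic ordering.
- All randomness flows through numpy Generators; suite-level tests spawn
  per-test streams from one SeedSequence in fixed iteration order, so
  results are reproducible and order-stable.

## Known limitations

- Batch correction is covariate-adjusted least squares; it removes additive
  offsets but not batch-specific variance changes.
- The bootstrap p has resolution 1/B; at B = 100,000 the smallest nonzero
  p is 1e-5 and genuinely extreme depletions report p = 0 under the strict
  rule.
- The five-way TF classification inherits the knife-edge behaviour of the
  0.5 fold-change gate for true effects near 0.5.
- Isobaric splitting averages unweighted ion ratios; a weighted (by ion
  intensity) variant would behave differently for very uneven ions.
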