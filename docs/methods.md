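# Methods

## Model and design

The experiment is a 2 × 2 × 3 factorial with replicates: strain (wild type
vs deletion mutant), memory (naive vs pre-exposed), and heat-shock time
(default 0, 15, 20 min), three biological replicates per cell.  Gene-wise
log2 expression follows a quadratic time polynomial with memory/strain
shifts of every term (12 coefficients; see README).  Memory and strain are
coded 0/1 against the reference (wild type, no-memory), and time enters in
raw minutes without centering — coefficient magnitudes are therefore
per-minute (per-minute²) effects and depend on that scale.  The error is
treated as Gaussian on log2-normalized expression and fitted by ordinary
least squares; per-coefficient t-tests and nested-model F-tests come from
the usual OLS theory.

## Synthetic data generator

`simulate.SimConfig` draws, per gene:

* a baseline log2 mean β0 ~ U(3, 10);
* a profile class over {flat, no_change, dampened, enhanced, reversed}
  (defaults 0.35 / 0.30 / 0.25 / 0.06 / 0.04 — most genes either lack a time
  trend or are unmodulated, and dampening dominates among memory-modulated
  genes, the qualitative structure of repeated-stress experiments);
* a direction (induced/repressed, 50/50) and a linear slope magnitude.
  Genes modulated by any factor draw |βT| = effect_scale · U(1, 2) — the
  strong-responder regime of stress-protein genes (≈ 2–4 log2 units net
  change at 20 min with the default effect_scale 0.2/min).  Unmodulated
  genes draw |βT| = effect_scale · min(Exp(0.35), 3): mostly quiet with a
  visible minority.  Real transcriptomes keep such a quiet majority, and
  scale normalization is only identifiable because of it — a design in which
  every gene moves strongly leaves no anchor for any normalization method;
* interaction slopes realizing the drawn class: dampened βTM = −f·βT with
  f ~ U(0.5, 0.9); enhanced +f·βT, f ~ U(0.5, 1.0); reversed −f·βT,
  f ~ U(1.5, 2.5).  Strain and memory×strain modulations follow the same
  recipes with their own class proportions.  Declared truth classes are then
  computed by applying the classifier's literal rules to the drawn
  coefficients, so truth and rules are consistent by construction;
* quadratic terms tied to the linear ones, βT2 = −c·βT/t_max with c = 0.5:
  every trajectory saturates at the last time point, reproducing the strong
  linear–quadratic coupling of real short time courses.  c = 0 gives purely
  linear profiles.

Counts are negative binomial: μ_gj = s_j · 2^(x_jᵀβ_g), variance
μ + φμ², with φ = 0.1 by default and s_j scaling each sample to a log-normal
library size (mean 5e6, CV 0.2).  As φ → 0 the NB tends to Poisson, not to a
point mass, so even "noise-free" configurations keep counting noise of CV
1/√μ.  The generator does **not** emulate: batch/hidden factors (the data
are generated batch-free, so passing tests say nothing about robustness to
technical structure), gene–gene correlation, length/GC biases, or isoform
structure.

## Normalization

Low-count filtering keeps genes with CPM ≥ 1 (configurable) in at least half
the samples (the quorum fraction is configurable; only the threshold itself
is canonical).  TMM follows the published weighted-trimmed-mean definition —
double trim (30% tails of M, 5% tails of A), inverse asymptotic-variance
weights, zero-count genes excluded, reference chosen by the upper-quartile
rule, factors rescaled to geometric mean 1 — and agrees with Bioconductor
edgeR's `calcNormFactors` to ~1e-4 on test matrices.  Expression is CPM
against the TMM-effective library size, log2 with pseudocount 1.

Two TMM properties surfaced by the simulator are worth knowing.  First, the
depth-dependence of the variance weights means rescaling one sample's counts
shifts its normalized values by a small constant (~0.02 log2) instead of
exactly zero.  Second, under a strong global induction the weighted trimmed
mean under-corrects composition: highly induced, high-count genes enter the
trim window with large weights and drag the factor, leaving a residual
expression drift of a few tenths of a log2 unit between early and late
samples.  This is a property of the estimator (edgeR reproduces it), not of
this implementation; it propagates into the regression as a shared slope
offset and is the main reason deeply dampened genes can be misread as
reversed.  Hidden-batch correction is deliberately out of scope and logged
as such at normalization time.

## Differential expression

The DE probability is the NOISeq idea: per gene, M = log2 ratio and
D = absolute difference of condition means on the linear normalized scale
(pseudocount 0.5), compared against the pooled noise distribution of (|M|, D)
over all within-condition replicate pairs of all genes; prob is the fraction
of noise pairs dominated by the signal pair.  It is deterministic and exact
(no resampling).  The conventional q = 0.8 gates significance.  Fold-change
categories: |FC| > 2 strong, 1.2 < |FC| ≤ 2 slight, otherwise (or when not
significant) unchanged; comparisons are always against time 0 of the same
strain and memory condition, and 5×5 transition tables summarize label flow
between the two later time points.

## Stepwise refinement and significance

Backward elimination removes, one per refit, the least significant removable
term with p > α (default 0.05); a term is removable only while no retained
higher-order term marginalizes it (t²M keeps t, t², M and tM in the model;
the intercept never leaves).  Two calibration facts shape the defaults:

* p-values of terms that *survive* elimination are anti-conservative
  (≈ 12% null retention at α = 0.05 in Gaussian simulations — inherent
  post-selection bias of this classic procedure);
* individually, t and t² are nearly collinear on a 3-point course, so
  single-term full-model t-tests are calibrated but weak.

The pipeline therefore judges factor significance by a nested-model F-test:
full model vs the model without the factor's linear *and* quadratic
time-interaction terms.  The joint test is calibrated (no selection) and
recovers the power the collinearity hides.  The per-term gates ("full",
"final", "retained") remain available as options.  The gene-level time
filter uses the analogous joint F of all eight time terms against the
time-free model, BH-corrected across genes at FDR 0.05, plus at least one
time term retained by stepwise.

## Classification

Factor labels follow the coefficient-sum rules in the README with a
tolerance of 1e-9 on the magnitude comparison; ties inside the tolerance are
no_change.  The sign check precedes the magnitude check (a reversal is also
a magnitude change), and exact cancellation βT + βTM = 0 counts as dampening
— total suppression has no opposite sign.  Quadratic interaction terms never
enter classification, but the refined model is not redefined after excluding
them: coefficients are read off the stepwise-refined fit as-is.  Genes whose
only time terms are quadratic get their direction from the fitted net change
between the first and last time point and `not_applicable` factor labels.
A factor that is not significant (see above) is no_change regardless of
magnitudes.

## Enrichment, proportions, qPCR

Over-representation is the one-sided hypergeometric tail (equivalent to
one-sided Fisher) with BH correction, universe defaulting to all genes that
survive the low-count filter; gene-set members are validated against the
universe and unmatched identifiers are counted per set.  No term-redundancy
reduction is performed.  Subset-vs-background comparisons use a
two-proportion z-test (pooled variance for the test, unpooled normal CI for
the error bars); note the subset is compared against the full background
including itself, as in the figure it reproduces.  qPCR quantification is
2^-ΔΔCt with technical replicates averaged on the Ct scale, an assumed
amplification efficiency of exactly 2, and the calibrator condition at
RQ = 1 per biological replicate by construction; summaries report standard
errors on both the RQ and the ΔΔCt scale.  Paired t-tests handle the
zero-variance degenerate case as t = ±∞, p → 0 with a warning.

## Numerical and engineering choices

OLS uses `numpy.linalg.lstsq` with normal-equation covariance; fits are
cross-checked against statsmodels in the tests.  Rank-deficient designs are
flagged rather than silently pseudo-inverted.  All randomness flows through
one `numpy` Generator seeded from the config, so identical configs reproduce
every output table bitwise.  Default problem sizes in the examples and
reproduction script (1,000–2,000 genes) keep full runs in the tens of
seconds while leaving every per-gene statistic in the regime the defaults
were designed for; the simulator scales to transcriptome size (~6,000 genes)
unchanged.

## Known limitations

* Under the all-responsive simulation regimes used for stress-testing, the
  TMM drift described above plus the finite-replicate noise floor put an
  effective ceiling of roughly 85% on memory-class recovery; the residual
  errors are concentrated in deeply dampened genes (dampening fraction
  > 0.8), whose post-memory slope is statistically indistinguishable from a
  sign flip at three replicates and NB dispersion 0.1.
* The Gaussian OLS treatment of log2-CPM ignores the mean–variance relation
  of counts at low expression; genes passing the CPM filter at the default
  library sizes are in the regime where the biological CV (√φ) dominates.
* The classifier reads only linear-slope coefficients; genes whose
  modulation is purely curvature-shaped are reported but not classified.
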