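# Methods

## Problem and model

The pipeline asks whether a composite promoter-methylation index at *MTHFR*
(mMTHFR) moderates the effect of long-term smoking on DNA methylation at a
panel of smoking-associated CpG loci. Methylation beta values are bounded
fractions with variance shrinking toward the ends of the unit interval, so
per-locus models use beta regression in the mean–precision parameterization:
y ~ Beta(μφ, (1−μ)φ), logit(μ) = x′b, constant φ with log link. Model 1
contains smoking, mMTHFR, sex and age; Model 2 adds smoking × mMTHFR. The
precision is a single constant because only mean-model terms are of
scientific interest; no precision submodel is fitted.

Significant Model 2 interactions are cross-classified by locus direction
(hyper: positive Model 1 smoking coefficient; hypo: negative) against
interaction sign, and consistency is measured by an uncorrected Pearson
chi-square on the 2×2 table. Direction is taken from the analysis sample's
own Model 1 fit rather than an external discovery EWAS, so the
classification is self-contained. Sign-concordant significant loci (hypo
with positive interaction, hyper with negative) define the hypo/hyper
outcome indices: per-sample means of per-probe z-scores (n−1 denominator,
standardized over the full post-QC sample, smokers and non-smokers
together). Index-level OLS models add diet and the five mononuclear-cell
fractions as controls, with classical SEs and t-based two-sided p-values
(the conventional choice when nothing indicates robust variance), and
interactions are explicated as simple slopes at moderator = mean ± 1 SD.

## Estimation details

* **Beta regression.** Starting values: OLS of logit(y) on X for b; a
  delta-method moment estimate for φ (clipped to [1, 1e6]). BFGS with the
  analytic gradient, followed by damped Newton steps on the observed
  information until the gradient max-norm falls below 1e-8 (steps are also
  accepted when they shrink the gradient norm, since near the optimum the
  log-likelihood plateaus at rounding level). A fit is flagged converged
  only if the final gradient max-norm is ≤ 1e-5 and the inverse observed
  information has a positive diagonal. Standard errors come from the
  observed information evaluated by central finite differences of the
  analytic gradient with step 1e-5·max(1, |θj|). During line search the
  objective returns +inf outside |log φ| ≤ 30 or max|η| ≤ 30, which simply
  rejects absurd steps; those bounds are far outside any plausible optimum
  for fractional data.
* **Degenerate loci.** Responses at 0 or 1 are rejected with a pointer to
  the squeeze transform y′ = (y(n−1) + 0.5)/n (n = number of samples), which
  is affine, order-preserving and fixes 0.5. Constant or near-constant loci
  fail convergence; such records are flagged and excluded from
  classification but always counted in scan totals.
* **Deconvolution.** Cell fractions solve min ‖y − Rω‖² s.t. ω ≥ 0,
  Σω ≤ 1. The inequality (not equality) on the sum reflects a
  mononuclear-cell design in which granulocytes are absent from the
  reference, so reference types need not absorb all signal. With K = 5 cell
  types the QP is solved exactly by enumerating the 2^(K+1) active-set
  combinations and checking primal and dual (KKT) feasibility — exact well
  beyond the 1e-8 tolerance, with no iterative solver dependency. All
  reference probes are used; choosing discriminating probes is the
  reference constructor's job.
* **QC conventions.** Samples are removed when their fraction of probes
  with detection p > 0.05 is strictly greater than 1%; probes are removed
  when beadcount < 3 in ≥ 5% of samples or detection p > 0.05 in ≥ 1% of
  samples ("present in x% of samples" reads as attained). All thresholds
  are arguments.
* **Normalization.** Between-sample quantile normalization of beta values,
  stratified by probe design type when the annotation carries one: each
  sample's sorted values are replaced by the across-sample mean of order
  statistics; ties receive the mean of the reference values over the ranks
  they jointly occupy (deterministic, and makes the map idempotent). A
  full intensity-level pipeline (background adjustment of Type I/II
  channels) needs raw intensities this package does not model; the
  operative property — aligned between-sample distributions within design
  strata — is preserved at the beta-value level the pipeline owns. Strata
  with fewer than 2 probes pass through with a warning.
* **Multiple testing.** Bonferroni uses the number of loci scanned as the
  denominator; Benjamini–Hochberg uses the standard step-up adjusted
  values. The chi-square upper tail is computed via the log survival
  function and exponentiated, so p-values at the 1e-44 scale (and far
  beyond) are exact rather than cancelled to zero.

## The synthetic-cohort generator

The generator inverts the analysis model so that every downstream stage has
known ground truth. Defaults are the study conditions: 180 subjects,
smoking prevalence 0.483, age 48.861 (SD 8.586), 37.2% male, moderator–sex
correlation 0.412 (imposed exactly in population via the standardized male
indicator), diet uniform on {1..4}, and Dirichlet cell fractions with means
(CD8T, CD4T, NK, B, Mono) = (0.137, 0.284, 0.071, 0.165, 0.144) and
concentration 50, which gives realistic between-subject variability around
fractions summing to 0.801. The locus panel defaults to 66 hyper + 205 hypo
+ 29 null = 300 loci, mirroring the sign-concordant index sizes at a panel
size that keeps end-to-end runs interactive.

Per locus, the linear predictor contains the class-signed smoking main
effect (default magnitude 0.15 on the logit scale, central to the observed
per-locus coefficient range), an interaction of the opposite sign (default
0.25), small random moderator/sex/age effects, and fraction-weighted
cell-composition offsets (per-type coefficients ~ N(0, 1), centered at the
mean fractions) that make the deconvolution covariates genuinely
confounding at the index level. φ defaults to 50, giving beta-value SDs
near 0.05 at μ = 0.5. Values are drawn Beta(μφ, (1−μ)φ); a noiseless mode
emits μ itself for exactness tests. The seven moderator probes are
logit-linear readouts of the latent moderator with high precision (φ=200)
and low baselines (promoter-island CpGs), so the standardized 7-probe mean
correlates > 0.9 with the latent truth — index validity is a measured
property, not an assumption. Reference marker probes are pure mixtures of
the reference profiles by each sample's true fractions, so noiseless
deconvolution recovers fractions exactly. Consumption is a clipped noisy
monotone map of smoking status into [0, 6], supporting the
consumption-based sensitivity models without simulating longitudinal waves.

What the generator does **not** emulate: batch/plate structure, probe
cross-reactivity and SNP artifacts, realistic genomic annotation,
longitudinal smoking trajectories, or a granulocyte component. Passing
tests therefore demonstrate statistical correctness of the machinery under
the generating model, not robustness to array artifacts. The latent
moderator is standardized rather than matched to any particular observed
index SD, since only its correlation structure matters downstream.

## Problem sizes and numerical tolerances

Oracle tests run at deliberately small sizes: the beta-regression MLE is
checked against an iterative grid-refinement search (final step < 1e-3) on
an n = 20 dataset; deconvolution against a dense step-0.01 simplex grid on
3-type toys (residual within 1e-6); OLS against the normal equations at
1e-10. Calibration checks use 2,000 null loci at n = 180 (type-I error
within 3 binomial SE of 0.05) and 200 replicates at n = 500 (each parameter
within 3 reported SE of truth in ≥ 95% of fits). The end-to-end
sign-pattern check runs the default 180 × 300 cohort. These sizes keep the
whole suite within a couple of minutes while leaving the binomial tolerance
bands meaningful.

## Design choices that were genuinely open

* The interaction classification and outcome indices use the
  sign-concordant subsets per direction class (hypo+, hyper−); an
  all-significant-loci variant would mix antagonistic loci into the index.
* When an index's sign-concordant class is empty the index is reported as
  absent (None) while the other is still built; only both classes empty is
  an error.
* The per-locus models control age and sex only; diet and cell fractions
  enter at the index level. This keeps the per-locus scan identifiable at
  modest n while the index models absorb compositional confounding.
* The broader 24-probe MTHFR moderator definition is supported by passing
  an explicit probe list; the 7-probe first-exon set is the default.
* Bonferroni-restricted index models are the same code path with
  tier="bonferroni"; no separate implementation.
* Report floats are serialized at 6 significant digits (counts exact), so
  byte-identical reports certify determinism without hiding numerical noise.

## Known limitations

Wald inference can be optimistic at very small n or extreme φ; no
likelihood-ratio or bias-corrected alternatives are provided. The
deconvolution active-set enumeration is exponential in the number of cell
types and intended for reference panels of ≲ 10 types. The quantile
normalizer loads each stratum densely; it is sized for locus panels, not
full 485k arrays.
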