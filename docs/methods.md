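# Methods

`mrmediate` implements two-sample, two-step Mendelian randomization (MR)
with a product-of-coefficients mediation decomposition, operating entirely
on GWAS summary statistics.

## Causal model and notation

Genetic variants G serve as instruments under the three instrumental-variable
assumptions: G is associated with the exposure X; G shares no confounder
with the outcome Y; and G affects Y only through X. Two-sample MR estimates
the per-SNP associations (beta_Xj, beta_Yj) in separate GWAS.

The two-step mediation design decomposes the total effect of X on Y through
a mediator M into three coefficients:

- **beta0** — total effect X → Y (univariable MR),
- **beta1** — effect X → M (univariable MR),
- **beta2** — effect M → Y adjusted for X (multivariable MR on the joint
  instrument set).

Indirect effect = beta1·beta2; direct effect = beta0 − beta1·beta2;
proportion mediated P = beta1·beta2 / beta0. The standard error of P is the
first-order delta method for a product over a ratio of *independent*
estimates:

    SE(P) = |P| · sqrt( (se1/beta1)² + (se2/beta2)² + (se0/beta0)² )

with 95% CI P ± 1.96·SE(P). Independence of beta0 and beta2 is an
approximation — both involve the outcome GWAS — and in simulation their
positive error correlation makes the interval mildly conservative (observed
coverage ≈ 0.97 at nominal 0.95). If beta1 = 0, beta2 = 0, or their product
underflows, P is reported as 0 with SE(beta1·beta2)/|beta0| and a
`zero-coefficient` flag; a sign conflict between the indirect and total
effects, or P outside [0, 1], is flagged rather than truncated.

## Instrument selection

Instruments are SNPs with exposure p < 5×10⁻⁸ (strict inequality), pruned
to approximate linkage equilibrium by greedy clumping: repeatedly keep the
most significant remaining SNP and drop SNPs on the same chromosome within
10,000 kb whose r² with it exceeds 0.001 (ties broken by chromosome,
position, then id, for determinism; the window is two-sided on base-pair
distance; SNPs absent from the LD matrix are treated as independent and
logged). Instrument strength is quantified per SNP by

    R²_j = 2·EAF(1−EAF)·beta² / (2·EAF(1−EAF)·beta² + 2·EAF(1−EAF)·N·SE²)

which reduces to beta²/(beta² + N·SE²) — the frequency factor cancels, but
a record without EAF still cannot contribute and is flagged. The set-level
F statistic uses the cumulative R² over the K selected SNPs,
F = R²(N−K−1)/(K(1−R²)); sets with F < 10 are flagged weak rather than
silently discarded (a per-SNP F, the K = 1 form, is also exposed).

## Harmonization

All traits are aligned to the exposure's effect allele. Swapped allele
labels (directly or through the strand complement) negate beta and replace
EAF by 1−EAF. Palindromic variants (A/T, C/G) cannot be resolved from
labels; they are kept only when both frequencies are informative — outside
[limit, 1−limit] with limit 0.42, the common default in two-sample MR
tooling — and the orientation is then inferred from whether the frequencies
sit on the same side of 0.5 (the inferred orientation may itself be a
flip). Ambiguous palindromic SNPs, allele pairs matching on neither strand,
and SNPs absent from any table are dropped with a per-SNP disposition log,
so |kept| + |dropped| always accounts for every input SNP. Harmonization is
idempotent.

## Estimators

All univariable estimators consume the per-SNP Wald ratios
r_j = beta_Yj/beta_Xj with first-order SE sigma_Yj/|beta_Xj| (exposure-side
error deliberately ignored here; RAPS handles it).

- **IVW** (principal method): beta = Σ beta_X beta_Y/sigma_Y² / Σ beta_X²/sigma_Y²,
  i.e. weighted regression through the origin. Default model is
  multiplicative random effects: the fixed-effect SE is inflated by
  sqrt(max(1, Q/(k−1))) with Q Cochran's statistic, never shrinking below
  the fixed-effect SE.
- **MR-Egger**: the same regression with an intercept, inputs oriented so
  beta_X ≥ 0; the slope is the pleiotropy-adjusted effect and the intercept
  estimates average directional pleiotropy. SEs carry the same
  dispersion-floor convention.
- **Weighted median**: the ratio at which cumulative normalized
  inverse-variance weight crosses 0.5, linearly interpolated between
  bracketing SNPs; consistent when ≥ 50% of weight is valid. SE by seeded
  parametric bootstrap (default 1000 resamples of beta_X, beta_Y from their
  stated normal errors).
- **Simple/weighted mode**: argmax of a normal-kernel density of the ratios
  (equal vs inverse-variance weights) on a 4096-point grid, bandwidth =
  factor × 0.9·min(sd, IQR/1.349)·k^(−1/5) over the ratios (modified
  Silverman rule; the IQR term guards against outlier-inflated spread).
  Identical ratios short-circuit to the common value. SE by the same
  bootstrap.
- **RAPS** (simple profile score): beta solves
  Σ (beta_Y − beta·beta_X)(beta_X sigma_Y² + beta·beta_Y sigma_X²)/(sigma_Y² + beta²sigma_X²)² = 0,
  root-bracketed around the IVW estimate (bracket doubling, Brent's
  method); SE is the estimating-equation sandwich with a numerical score
  derivative. The robust-loss and overdispersion variants are reserved
  flags and currently rejected if enabled.

P-values are two-sided normal throughout; CIs are beta ± 1.96·se.

## Sensitivity analyses

- **Cochran's Q** about the fixed-effect IVW estimate with first-order
  ratio weights (df k−1) and **Rucker's Q** about the Egger fit (df k−2);
  the latter never exceeds the former since the origin model is nested.
- **Egger intercept test**: two-sided normal on intercept/SE.
- **MR-PRESSO**: the observed statistic is the sum of squared
  sigma_Y-standardised leave-one-out residuals. The empirical null redraws
  each SNP's effects from N(beta_Xj, sigma_Xj) and
  N(beta_LOO,j·beta_Xj, sigma_Yj) (default 1000 simulations); per-SNP
  outlier p-values are empirical tail probabilities with the
  (r+1)/(n_sim+1) convention, Bonferroni-corrected over SNPs at level 0.05.
  Note the floor p = 1/(n_sim+1) means outliers are only detectable when
  n_sim ≳ k/significance. The distortion test compares the
  outlier-corrected IVW shift against removals of random same-size SNP
  subsets. SNPs are processed in id order internally so results are
  invariant to input row order at a fixed seed.
- **Leave-one-out**: IVW re-estimated excluding each SNP via closed-form
  weighted-sum updates (algebraically identical to refitting), flagging
  exclusions that change the sign or move the estimate by more than
  `loo_flag_multiplier` (default 1.0) full-set SEs.

Multiplicity over mediators uses Benjamini–Hochberg at 0.05, by default per
outcome family (a `bh_scope: global` option pools all pairs).

## Multivariable MR

Outcome betas are regressed on the exposure-beta matrix without intercept,
weights 1/sigma_Y²; under multiplicative random effects SEs scale by
sqrt(max(1, Q/(k−p))). The instrument set is the union of each exposure's
genome-wide-significant, clumped SNPs, harmonized jointly. Near-collinear
designs (condition number > 1e8) raise an error naming the most correlated
pair; an all-zero column (no instrument signal) is reported as coefficient
0 with infinite SE, preserving the nested-model identity with univariable
IVW. An approximate conditional F per exposure is available as a
diagnostic; nothing gates on it.

## Pipeline

`run_two_step` performs, per outcome: instrument selection → harmonization
→ the full estimator suite and diagnostic panel for the total effect; per
mediator: beta1 (univariable), beta2 (MVMR), and the mediation
decomposition; then BH adjustment. When the Egger intercept is significant
at 0.05 (pre-adjustment), an automatic outlier pass runs MR-PRESSO, removes
the detected SNPs, re-estimates IVW and re-tests the intercept; the
post-removal total effect then feeds the mediation stage (`outlier_pass`
can force or suppress this). Stage failures are recorded per trait pair
without aborting the remaining pairs. All randomness (bootstrap, PRESSO)
derives from the single study seed; reports embed a config hash, the seed
and the package version, and identical configs produce byte-identical
reports. `run_reverse_mr` swaps each mediator into the exposure role for a
univariable-only reverse screen with the same report schema.

## Synthetic data

`simulate_mediation_gwas` draws, per SNP, a minor-allele frequency
(uniform on 0.05–0.5) and instrument effects from gamma_min + |N(0, gamma_sd)|
(defaults 0.10 and 0.04), expressed relative to the trait-increasing allele.
Exposure instruments (default 100) affect the mediator as alpha·gamma and the
outcome as direct·gamma + beta2·(mediator effect); mediator-specific
instruments (default 100, zero exposure effect) give the mediator the
independent genetic signal a real mediator GWAS carries — without them the
multivariable design would be exactly collinear and beta2 unidentifiable.
Observed betas add normal noise with SE = 1/sqrt(2·maf(1−maf)·N), the
standard approximation for a standardised continuous trait; a binary
outcome on the log-odds scale is emulated through an effective N. Default
sample sizes (261,932 / 115,006 / 298,957) and effect sizes
(alpha 0.5, beta2 −0.8, direct −0.7, total −1.1) match the scale of large
biobank mediation studies of birth weight and type 2 diabetes. Optional
features: directional or balanced pleiotropy of configurable magnitude on a
configurable fraction of exposure instruments; planted outliers displaced
by a multiple of the outcome SE; a `noise: False` switch that returns the
error-free effects. The effect bound gamma_min is chosen so every planted
instrument passes p < 5×10⁻⁸ at the configured sample sizes, decoupling
selection behaviour from estimator behaviour. `simulate_ld_matrix`
produces block-diagonal r² structure for clumping tests; it is
deterministic unless a jitter is requested.

What the generator does **not** emulate: realistic LD from reference
panels, winner's curse, sample overlap between GWAS, population
stratification, and non-linear or interaction effects. Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated sampling model, not robustness to those phenomena.

## Numerical conventions and edge cases

- Empirical p-values use (r+1)/(n_sim+1); analytic p-values are floored at
  the smallest positive double and capped at 1.
- A single SNP degenerates IVW (and the mode) to the Wald ratio with a
  warning; method minimums are otherwise enforced (Egger/median/mode/RAPS 3,
  PRESSO 4, MVMR p+1).
- Clumping ties on p are broken by (chromosome, position, id).
- Bootstrap and simulation draws use `numpy.random.default_rng` seeded per
  call; defaults are recorded in the output.
- Written summary statistics use repr-precision decimal text, so a
  write/read cycle is bit-exact.

## Known limitations

- **Weak-instrument dilution.** IVW (and MVMR) carry a first-order
  attenuation of relative size ≈ k/(N_x·R²) from exposure-side sampling
  error — about 0.1% at k = 100, N = 10⁵ — visible in large replicate
  studies. RAPS removes it and is the estimator of choice when exposure
  SEs matter.
- **Egger under NOME violation.** With measurement error in beta_X and
  many strong, similar-strength instruments, the Egger intercept inherits
  a regression-dilution bias and its type-I error is inflated; the test is
  calibrated under its stated assumption of negligible exposure-side error
  (verified at the 5% level in simulation).
- The delta-method CI assumes independent beta0, beta1, beta2 (see above).
- Single-mediator decompositions only; interacting mediators are out of
  scope, as is any non-linear dose-response.
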