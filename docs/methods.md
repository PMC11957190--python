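# Methods

## Outcome model

PTSS is modelled as negative binomial (NB2): for outcome y with mean μ and
dispersion θ, Var(y) = μ + μ²/θ; θ → ∞ recovers the Poisson. The NB choice
is made empirically by the `dist_select` stage: Poisson, Gamma, NB and
Weibull are fitted by maximum likelihood and ranked by
BIC = k·ln n − 2·lnL. Poisson and NB have closed-form/profile ML fits
written here (the intercept-only NB mean MLE is the sample mean; θ is
profiled by safeguarded Newton on log θ); Gamma and Weibull MLE are
delegated to `scipy.stats.*.fit(floc=0)`. Gamma and Weibull are
strictly-positive families and refuse zero-valued data; an optional
+0.5 shift flag handles integer outcomes containing zeros (PCL-C sums are
≥ 17 in real data, so this rarely matters). `bootstrap_bic_compare` refits
two families on B resamples of individuals and reports
p = P(BIC_a > BIC_b) with ties counted ½: p near 0.5 means the families
are interchangeable, p near 0 means family a dominates.

## NB regression engine

`fit_nb` maximises the joint NB2 likelihood over (β, θ):

* given θ, Fisher-scoring IRLS for β (weights θμ/(θ+μ), working response
  η + (y−μ)/μ under the log link);
* given β, profile-ML Newton on ξ = log θ with analytic first and second
  derivatives (digamma/trigamma), safeguarded steps clipped to ±2, domain
  [1e-3, 1e6];
* alternation until the relative joint log-likelihood change is < 1e-10 or
  100 outer iterations (non-convergence is flagged, never silent).

θ is capped at 1e6; if the profile score is still positive at the cap
(equi- or under-dispersed data) the fit is flagged as the Poisson limit.
The covariance of β is the inverse observed information at the optimum,
i.e. X'WX with W = (y+θ)θμ/(θ+μ)² for the log link. The log link is the
default: it is canonical for NB GLMs and guarantees positive means. An
identity link is available for the additively specified model; it errors
when the fitted line produces nonpositive means rather than silently
clipping. Engine accuracy is checked two independent ways in the test
suite: against a brute-force BFGS maximiser of a separately written joint
likelihood (1e-5 relative on coefficients) and against statsmodels'
`NegativeBinomial`.

Nested models are compared with a likelihood-ratio chi-square test
(`group_test`). An F test has no exact theory for NB GLMs, so the LRT is
the deliberate stand-in wherever a joint block contribution is assessed.

`fit_nb_l1` maximises lnL − λΣ|β_j| (intercept unpenalised) by cyclic
coordinate descent with soft-thresholding on the IRLS quadratic
approximation, alternating with the same θ profile. No covariance is
reported for penalised fits: Wald inference is invalid after shrinkage.
λ = 0 reproduces the unpenalised fit; the caller supplies the λ grid.

## Screens and multiplicity

For each miRNA the main-effect screen fits
log E[PTSS] = Σᵢ aᵢ·adversityᵢ + b·miRNA and Wald-tests b; the
interaction screen adds c·(adversity_j × miRNA) and tests c, always
retaining all five adversities additively so each test controls for the
remaining exposures. Expression enters as log2(CPM+1) (counts per million,
so library size cancels), after an optional low-expression filter
(default: CPM ≥ 1 in ≥ 50% of samples). The interaction product is formed
after normalisation. The modulation score z = c/SE(c) is invariant to
affine rescaling of either factor, so units of the adversity scale or
expression standardisation do not affect inference.

BH-FDR is applied across the miRNA axis *within* each (adversity,
wave-pair) screen — no cross-adversity pooling — and hits use a strict
q < 0.1. Non-estimable miRNAs (constant expression) and non-converged
fits are excluded from the FDR denominator and reported flagged, so
invalid tests never dilute the adjustment.

## Cross-validation and cross-wave consistency

`kfold_cv_spearman` partitions samples by a seeded permutation cut into k
near-equal contiguous chunks, refits the NB model (including θ) on each
training set, predicts held-out fitted means and reports the mean Spearman
correlation. Spearman is invariant to monotone transforms, so ranking
fitted means under the log link is equivalent to ranking linear
predictors. Folds with constant held-out outcome are recorded as missing
and excluded from the mean with a warning.

`cross_wave_consistency` asks whether discovery-wave hits keep elevated
modulation scores in the validation wave: a one-sided Wilcoxon rank-sum of
hits versus the remaining miRNAs, exact when both groups have ≤ 10 members
and no ties, otherwise the normal approximation with tie correction. An
all-constant score vector returns p = 0.5 (no separation).

## Enrichment

Hits' target genes (score-filtered at ≥ 80, inclusive; duplicate
(miRNA, gene) rows keep the maximum score) are pooled as a set union and
each pathway is tested with the upper-tail hypergeometric probability
P(X ≥ overlap) with N = |universe|, K = |pathway|, n = |targets ∩
universe|. Pathway p-values are BH-adjusted; q < 0.1 flags enrichment. The
gene universe defaults to all score-filtered target genes united with all
pathway genes; it is the dominant analytic degree of freedom, so it is
configurable and always recorded in the run manifest.

## Synthetic cohort generator

The generator emulates the statistical structure the screens assume, at
desk scale:

* **Adversities** (per participant, lifetime profiles): trauma ~ NB(mean
  6.8, θ 3; SD ≈ 4.7), financial ~ Bernoulli(0.625), emotional ~
  Bernoulli(0.316), discrimination ~ truncated normal ≥ 0 (mean 3.4, SD
  0.5), loneliness ~ truncated normal ≥ 0 (mean 1.4, SD 0.5), coupled by a
  Gaussian copula with exchangeable correlation 0.2 (adversities co-occur
  but no joint law is known).
* **Expression**: per-miRNA baseline log2 abundance uniform on [2, 12],
  per-participant biological deviation (SD 0.5 natural-log) shared across
  waves, wave-specific fluctuation (SD 0.25), compositional scaling to
  library sizes log-uniform on [5·10⁵, 2·10⁶], NB counting noise
  (dispersion 20). Library sizes are scaled down from deep-sequencing
  depth to keep simulations fast; relative abundances and stability are
  what matter to the screens. The shared latent makes the median
  per-participant cross-wave Spearman exceed 0.75, matching the stability
  the screens presuppose.
* **Outcome**: log E[PTSS] = intercept + Σ aᵢ·z(advᵢ) + Σ b_m·z(expr_m)
  + Σ c_{m,j}·z(adv_j)·z(expr_m), y ~ NB(μ, θ = 6.5). Effects are in
  log-link units per SD (z-scored adversities, z-scored log2-CPM
  expression); because z-scoring is affine and the screens include all
  main effects, planted interactions lie exactly in the span of the
  screens' raw-scale designs, and modulation scores are unchanged by the
  reparameterisation. The auto-intercept is log(target mean) minus half
  the total effect variance (lognormal moment correction), so the default
  cohort lands near PTSS mean 35; θ = 6.5 moment-matches a PTSS SD of
  ~15 at that mean. The linear predictor is bounded so NB means stay
  below 10⁴ (bounded draws are counted in the ground truth).
* **Defaults**: 600 participants (near the usable study-scale n), 200
  miRNAs, 10 planted modifiers at c = 0.15 per SD cycled across the five
  adversities — modifiers of different exposures, as observed empirically —
  with every realized coefficient, linear predictor and modifier flag
  recorded in `GroundTruth`.
* **Waves**: phenotype rows for waves 2–4; PTSS at waves 2 and 3 is driven
  by wave-2 expression and wave-4 PTSS by wave-4 expression under the same
  effect spec, so the (2→3) and (4→4) screen pairings and the cross-wave
  consistency check all close end-to-end.

The outcome is plain NB, not truncated to the PCL-C range [17, 85]:
truncation would break the NB likelihood the screens assume. Consequently
synthetic PTSS has a heavier right tail than a bounded checklist sum, and
the generator does not emulate item-level response processes, sequencing
reads, or batch structure. Passing tests therefore demonstrate the
statistical machinery under its own assumptions, not robustness to
real-data artefacts.

## Known limitation: concurrent strong modifiers

When several strong interaction effects are present simultaneously, the
per-miRNA screen is misspecified for every *other* miRNA: the omitted
interactions act as a participant-level random adversity slope, i.e.
adversity-dependent overdispersion that the constant-θ NB Wald test cannot
absorb. With 10 concurrent modifiers at c = 0.3 per SD the combined
omitted scale is ~c·√10 ≈ 0.95 per adversity SD versus a residual log-SD
of ~0.43 at θ = 6.5, and null modulation scores inflate from SD 1 to SD
2–4, flooding FDR hit lists (the effect reproduces identically under
statsmodels' NB implementation, so it is a property of the model, not of
this engine). At the default c = 0.15 spread across adversities the
approximation holds and FDR control is approximately maintained. Real hit
lists obtained in cohorts where many strong modifiers coexist should be
interpreted with this in mind; sandwich-type robust errors, which would
mitigate it, are deliberately out of scope. Single-interaction fits are
correctly specified and their Wald intervals achieve nominal coverage
(~95% empirically).

## Numerical and procedural choices

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; pipeline stages derive child seeds from one
  master seed via `SeedSequence`, so a run is reproducible byte for byte
  (timestamps live only in the manifest).
* Tables are written with `%.17g` floats and read with round-trip parsing,
  so write/read cycles are exact.
* Complete-case analysis per fitted model; dropped records are listed with
  reasons in a manifest, never silently discarded. Duplicate biospecimens
  per participant and wave are an error.
* Aggregation conventions: multi-item scales are summed (a mean option
  exists); lifetime trauma is the across-wave sum; lifetime binary
  stressors are any-occurrence indicators.
* Median stratification (for visualising an interaction) labels values
  strictly above the median as high; ties go low.
* BH adjustment is the step-up q_(i) = min_{j≥i}(p_(j)·m/j) capped at 1,
  computed directly and cross-checked against statsmodels in tests.
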