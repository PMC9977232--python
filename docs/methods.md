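# Methods

## The problem

Genetic reference panels — collections of inbred strains sampled from an
outbred population — are used to ask whether the lifespan response to
dietary restriction (DR) is genetically variable. The common analysis
("no pooling") estimates the DR effect in each strain separately and
reads the spread of those estimates as genetic variance. Because every
per-strain estimate also carries sampling error, that spread
systematically overstates the biological among-strain variance,
especially at the small per-strain sample sizes these studies use.
`drpanel` simulates such experiments under a known truth and compares
four estimators of the among-strain variance, so a study can be
designed (strains vs animals-per-strain, power for the variance test)
before any animal is enrolled, and existing `strain,diet,age,event`
tables can be re-analysed with the less biased estimators.

## Generative model

Death times follow a Gompertz hazard, `h(t) = a e^{bt}`, with the
DR effect acting proportionally on the hazard. For animal *i* of
strain *j*:

    h_ij(t) = a e^{bt} · exp( alpha_j + X_i (mu + delta_j) )
    delta_j ~ N(0, sigma_delta²),   alpha_j ~ N(0, sigma_alpha²)

where `X_i` is the diet indicator (0 = ad libitum, 1 = DR), `mu` the
overall log hazard ratio (lnHR) of DR, `delta_j` the strain's deviation
in response, and `alpha_j` an optional strain-level baseline deviation
(off by default: the main model assumes homogeneous survival under AL).
`delta` and `alpha` are drawn independently; no correlation parameter
is offered, the minimal extension being the point of `sigma_alpha`.

The headline summary is the coefficient of genetic variation in
response, `CV_G = sigma_delta / |mu|`, which is unitless and therefore
comparable across the mean-difference and lnHR analysis scales.

Defaults (all in days): `log a = -11.57`, `log b = -4.9` — typical
ad-libitum-fed laboratory rodents, analytic median lifespan ≈ 847 d —
and `mu = -0.5`, a conservative rodent DR effect that moves the median
to ≈ 914 d. Death times are sampled by closed-form inversion of the
survivor function, so sampling is exact and bit-reproducible given a
seed. No censoring is simulated (every record has `event = 1`); the
data model carries the event flag because re-analysis input may be
censored, and the Cox machinery handles censored rows.

`b = 0` is treated as the exponential (constant-hazard) limit rather
than an error, which is convenient for degenerate-input tests.

## The four estimators

All four report: the overall effect, the among-strain SD
`sigma_hat`, `CV_G = sigma_hat / |overall|`, and per-strain effects.

**MD, no pooling.** Per strain: difference in mean age at death
(DR − AL), with the pooled-variance two-sample t test (equivalent to a
per-strain linear model with a diet indicator). `overall` is the
unweighted mean of the per-strain MDs and `sigma_hat` their sample SD.
Per-strain p-values are two-sided and unadjusted — matching the
waterfall-plot convention — with a Holm-adjusted column alongside.
Strains with fewer than two animals in an arm keep their estimate but
are flagged with no test.

**MD, partial pooling.** One linear mixed model
(statsmodels `MixedLM`): `age ~ 1 + diet` with a strain-level random
intercept and random diet slope, independent components (diagonal
covariance). The diet covariate is centred to ±0.5 internally: with
balanced arms this makes the intercept and slope random effects
orthogonal, so each strain's predicted (BLUP) slope is a pure shrinkage
of its raw mean difference toward the pooled MD; the fixed slope
coefficient is unchanged by the recoding. The reported `sigma_hat` is
the REML estimate of the slope SD; the variance test refits the full
and the intercept-only models by ML and refers twice the log-likelihood
difference to chi-square(1) (conservative at the boundary; the 50:50
chi2(0):chi2(1) mixture is available via `boundary_mixture=True`).
Partial pooling intentionally produces no per-strain test.

**lnHR, no pooling.** A Cox proportional-hazards model per strain,
implemented in this package: Newton–Raphson on the log partial
likelihood with Efron tie handling, standard errors from the observed
information, two-sided Wald p-values. Monotone likelihoods (complete
separation of event orderings, common at 2–3 animals per arm) are
detected, capped at |lnHR| = 15 and flagged; flagged strains are
excluded from `overall`/`sigma_hat` with a reported count.

**lnHR, partial pooling.** The mixed-effects Cox (frailty) model with a
Gaussian strain-level random diet slope, also implemented here. For
fixed `sigma²` the penalized log partial likelihood
`l(beta, u) − Σ u_j²/(2 sigma²)` is maximized jointly over
`(beta, u)` by Newton–Raphson with step-halving (tolerance 1e-8 on the
objective, ≤ 50 iterations); the outer problem maximizes the Laplace
approximation to the integrated log likelihood,
`PPL − (q/2) log sigma² − ½ log det K` with `K` the penalized observed
information of `u`, by bounded Brent search on `log sigma²` over
[1e-8, 25] (xatol 1e-6), warm-starting the inner solve. Optima at the
lower bound are reported as `sigma_hat = 0` with all shrunken effects
zero, in which case the fit equals the pooled Cox model exactly. The
variance test is `2·(ILL(sigma_hat²) − l_pooled)` against chi-square(1)
(mixture optional, as above). The random effect enters only on the diet
slope; a strain-level baseline frailty term is not fitted (baseline
heterogeneity in the data is instead part of the simulator via
`sigma_alpha`), a deliberate simplification noted under Limitations.

Because every covariate in these models is a 0/1 product of
indicators, second moments over a risk set equal first moments; the
Hessian exploits that structure, and untied data (the simulated case —
death times are continuous) use a fully vectorised path. A grouped
Efron loop covers tied data such as ages recorded in whole days.

A note on limits: the penalty-free limit (`sigma² → ∞`) of this model
is the *joint* fixed-effects Cox model with one diet dummy per strain
and a shared baseline — not the collection of per-strain Cox fits,
which stratify the baseline. The test suite verifies the limit against
an independent fixed-effects fit.

## Study metrics

* **Bias** — median and IQR of the estimated CV_G over replicate
  simulations, minus the true CV_G. Quartiles use linear interpolation
  (type 7); IQR values depend on this convention.
* **Replicability** — two experiments are simulated per replicate
  sharing one draw of `(delta, alpha)` but with independent death
  times; the Pearson correlation of strain-level estimates between the
  pair (shrunken estimates for partial pooling, i.e. each estimator's
  own strain-level output) is averaged over pairs. Pairs where either
  member has zero variance among estimates (complete shrinkage) leave
  the correlation undefined and are dropped with a reported count —
  scoring them zero would spuriously penalise partial pooling.
* **Power** — the fraction of replicates whose variance LRT p-value is
  below alpha (default 0.05), with a binomial standard error.

## Randomness protocol

A master seed spawns an independent `SeedSequence` child per grid cell,
keyed by the cell's parameters (not its position in the grid), and each
cell spawns one child per replicate; each replicate's pair shares the
strain-effect draw and consumes one stream. Consequences: identical
configurations give bit-identical outputs; increasing the replicate
count leaves earlier replicates unchanged; and reordering or
subsetting the grid does not change any cell's draws.

## Numerical and design choices

* Time unit is days throughout.
* Strain identifiers are integers 1..n in simulation; arbitrary labels
  are accepted in re-analysis input and handled in sorted order.
* Waterfall tables sort by the no-pooling estimate, descending;
  partial-pooling values are reported in the same strain order.
* The mixed-model LRTs default to the plain chi-square(1) reference —
  conservative at the boundary — with the mixture as an explicit
  option, so reported power is if anything understated.
* `run_grid` drops a replicate for an estimator only when the fit
  raises; boundary fits (`sigma_hat = 0`) and optimizer-flagged fits
  are retained as valid outcomes, with cleanly-converged counts
  reported per cell and a flag when more than 20% of fits failed.
* `CV_G` with a zero overall effect is returned as infinity (flagged
  rather than dropped silently); infinite estimates are excluded from
  cell medians.
* Replicated study sizes in this repository's tests and acceptance
  script use 200 replicates per condition, a size at which the binomial
  SE of a power estimate near 0.8 is about 0.028 and CV_G medians are
  stable to a few percent.

## What the simulation does and does not emulate

The generator reproduces the design of real panel studies — dozens of
strains, a handful of animals per strain per diet, both arms per
strain — under exactly Gompertz mortality, perfectly proportional
hazards, normal strain effects and no censoring, attrition, sex
structure, litter/maternal effects, or batch variation. Passing tests
therefore demonstrate properties of the estimators under a correctly
specified model (bias of no pooling, shrinkage of partial pooling,
power of the variance test), not robustness to the many ways real
husbandry data deviate; the re-analysis pipeline applies the same
estimators to real tables but inherits their assumptions.

## Known limitations

* The mixed Cox model fits no baseline frailty term; under strong
  AL-group heterogeneity (`sigma_alpha` large) the shared-baseline
  assumption is mildly violated and the slope variance absorbs part of
  the discrepancy.
* The LMM occasionally reports a non-converged optimizer flag on
  boundary datasets (truth near `sigma = 0` at n = 5); estimates are
  still returned and are retained in studies, flagged.
* Per-strain Cox fits separate frequently at 2–3 animals per arm;
  re-analyses of very small strata should lean on the partial-pooling
  estimators.
* p-values for variance components use asymptotic references; at very
  few strains (< ~10) the LRT calibration is approximate.
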