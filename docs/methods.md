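# Methods

## Model

The hazard of child *j* in cluster *i* of region *q(i)* is
h(t) = δ t^{δ−1} exp(η), with

η = βᵀX_j + (a + w_{q(i)}) Z_{q(i)} + φ_i.

The first column of X is an intercept. The model equation carries no
separate baseline scale (the Weibull baseline δt^{δ−1} is scale-free), so
without an intercept the overall event rate would be forced through the
random effects; the intercept absorbs it and the zero-mean priors on φ and
w keep it identified.

Right-censoring enters through the standard survival likelihood: a death at
t contributes log h(t) − H(t), a child alive at interview contributes −H(t)
with H(t) = t^δ e^η. Deaths recorded as exactly 0 months (survey records
are in whole months) are shifted to 0.25 months so log t is finite; the
count of shifted records is reported. Genuinely positive times are never
floored: flooring creates a point mass that visibly biases δ̂ upward
(measured +0.05 at δ = 0.5 when times below 0.25 months are clamped).

### Spatial components

* **Cluster frailty** φ ~ N(0, σ²R), R_kl = exp(−d_kl ρ), with d the
  great-circle (haversine) distance in km on a mean-radius-6371.0 km
  sphere. The effective range is −log(0.05)/ρ: the distance at which the
  correlation has decayed to 0.05. (Read as a quotient; the product form
  that sometimes appears in print has the wrong units.) One frailty per
  cluster, shared by its children.
* **Spatially varying coefficient** a + w_q, one model per intervention.
  w ~ N(0, σq²(I−γC)⁻¹D) — a proper CAR *covariance* (Cressie form), with
  C_kl = ω_kl/g_k, D = diag(1/g_k); its inverse is the sparse
  (diag(g) − γω)/σq². σq⁻²D⁻¹(I−γC) is symmetric because diag(g)·C = ω.
  γ is admissible on the open interval (1/λ_min, 1/λ_max) of the
  eigenvalues of D^{−1/2}CD^{1/2} (λ_max = 1 since that matrix is similar
  to the row-stochastic C), which contains 0.

### Priors

σ², σq² ~ IG(2.01, 1.01) (mean 1, barely finite variance); δ ~ Exp(0.01);
β, a ~ N(0, 10³); γ uniform over its admissible interval; ρ uniform with
support chosen so the effective range lies between the smallest and largest
nonzero inter-cluster distances (a = −log(0.05)/d_max, b = −log(0.05)/d_min⁺).

### Coverage units

Coverage is stored as a proportion in [0, 1]. The regression covariate Z is
expressed, by default, in units of ten percentage points (Z = proportion/0.1),
so exp(a) is the HRR per 10-point coverage increase; `proportion` and
`percent` units are configuration options, since published hazard-rate
ratios of this kind rarely state their unit and either convention should be
reproducible.

## Screening

Candidate adjustment covariates are screened one at a time with non-spatial
Weibull PH fits (intercept + treatment-coded levels + shape), maximised by
BFGS in (log δ, β) with analytic gradients to a 1e−8 gradient tolerance;
standard errors come from the numerically differentiated observed
information. A covariate enters the spatial model when its smallest
level-wise Wald p-value is strictly below 0.15 — deliberately liberal, a
confounder filter rather than a hypothesis test, so no multiplicity
correction is applied. Wald p-values are the default; reference categories
follow the descriptive-table convention (female, urban, facility birth,
birth order 1–5, youngest mother age group, first birth ≤19, parity 1–5,
educated, richest tercile). Non-converged fits are excluded with a warning
rather than silently included.

## Sampler

Adaptive Metropolis-within-Gibbs over six blocks: δ (random walk on log δ);
(β, a) jointly (multivariate random walk whose proposal covariance is
seeded from the non-spatial MLE's inverse information and then adapted);
w and φ by single-site random walks — a site move shifts η by the same
amount for every child of that region or cluster, so the data term of a
site update is O(1) given per-cluster aggregates; (σ², ρ) and (σq², γ)
jointly, variances and decay on the log scale (with Jacobians). Proposal
scales follow a Robbins–Monro rule towards acceptance 0.44 (scalar sites)
or 0.234 (joint blocks) and freeze after the adaptation window (default:
the burn-in), so the post-adaptation chain is Markov.

Two likelihood-invariant *recentering* moves are interleaved: (a, w) →
(a+s, w−s·1) and (β₀, φ) → (β₀+s, φ−s·1). The global coefficient and the
mean of its random field are confounded in η; without these moves their
split mixes an order of magnitude slower (PSRF ≈ 2–3 instead of ≤ 1.1 on
the recovery runs).

Defaults mirror the full estimation protocol: 2 chains × 300 000 iterations,
burn-in 15 000; thinning 30. Initialisation: δ = 1, β = a = 0, w = φ = 0,
σ² = σq² = 0.5, ρ at the middle of its support, γ = 0; the second chain is
jittered by N(0, 0.1²) on the parameters of active blocks only, so
reduced-model validity runs condition on exactly the documented values.
Convergence is monitored with the original between/within-chain PSRF
(no degrees-of-freedom correction):
PSRF = sqrt(((n−1)/n·W + B/n)/W). Posterior summaries are pooled
post-burn-in medians and equal-tailed 95% intervals (linear-interpolation
percentiles); HRR summaries exponentiate draw-wise, which commutes with
quantiles.

Numerical safeguards: GP covariances carry a relative diagonal jitter
(1e−8·σ²), escalated geometrically if a Cholesky factorisation still fails;
a state outside the prior support scores −∞ rather than raising, so the
sampler never dies mid-run; identical seeds give bit-identical draws.

## Synthetic surveys

The generator draws from the model itself: region adjacency (the bundled
13-region Burkina Faso graph, or a grid-with-diagonal topology for other
Q); clusters uniform in ~0.9°-wide per-region boxes spanning roughly
400 × 400 km, so inter-cluster distances bracket effective ranges of a few
tens of km; children multinomially assigned to clusters; categorical
covariates from the published descriptive marginals with the published
univariable HRRs as true effects; regional coverage from the published
coverage table; w from the CAR, φ from the GP; death times by inverse-CDF
from S(t) = exp(−t^δ e^η); censoring at an age-at-interview uniform on
(0, 60] months (the real censoring-age distribution is unpublished; uniform
is a stand-in, not a claim). Recorded times are floored at 0.01 months only
to satisfy positivity.

Calibration preset (the defaults): δ = 0.5 (infant-concentrated mortality),
a = log 0.9 per ten coverage points (the scale of the published national
HRRs), σ² = 0.15 and effective range 35 km (the scale of the published
spatial-variance and range posteriors), σq² = 0.02 (backed out from the
dispersion of published regional HRRs around their national value,
SD(log HRR_q) ≈ 0.14), γ = 0.5 (moderate positive dependence). The baseline
log-hazard (−4.23) was set once by pilot bisection so that ≈9% of children
die before 60 months, then frozen.

Recovery preset (60 clusters, 4 000 children, covariates sex + residence,
baseline −1.36): the intervention is skilled birth attendance — the widest
regional coverage spread (40–96%), which is what separates a·Z from the
intercept — and the true national effect is strong, a = log 0.6 per ten
points. At this reduced size a weak effect like log 0.9 is not identified:
the posterior SD of a is ≈0.29, dominated by the IG(2.01, 1.01) prior's
pull on σq² (thirteen regions cannot overrule a prior with mean 1), so
interval-coverage checks would pass vacuously and point-recovery checks
could not pass at all. A recovery benchmark needs an effect detectable at
its own sample size.

What the generator does **not** emulate: the two-stage sampling design and
its weights, household clustering below the survey cluster, covariate
dependence (covariates are drawn independently; real wealth, education and
residence are correlated), measurement error in coverage, and the discrete
month-grid of recorded ages. Passing recovery tests therefore show the
estimator is correct under the model's own assumptions — not that the model
is right for any real survey.

## Reporting

National HRR = exp(a) summarised over draws; regional HRR = exp(a + w_q).
"Statistically important": 95% equal-tailed BCI excludes 1. "Protective":
interval entirely below 1 (upper < 1). Per-region counts of protective
interventions use the upper-bound rule; harmful-important entries
(lower > 1) are reported but never counted. Applied to the bundled table of
published regional intervals, this reproduces the reported spread — min 0
(Hauts Bassins), median 3, max 11 (Centre-Est), Sud-Ouest 7. Two printed
rows have upper bounds below 1 without a printed star (Nord ITN use,
Centre-Ouest family planning); they are treated as printing inconsistencies
and counted by the rule. The counting also credits Sahel with nine
protective interventions where the accompanying published narrative says
eight; no counting rule reproduces eight, so the discrepancy is surfaced
rather than resolved.

Under-five mortality is summarised two ways, labelled distinctly: the raw
death fraction (deaths/children), and the Kaplan–Meier 1000·(1 − Ŝ(60))
(`km_5q0`), in which censored children contribute risk time. These differ
by construction — censored children depress the raw fraction — and neither
is the survey-programme synthetic-cohort life-table rate, which is out of
scope.

## Problem sizes and tolerances

Monte-Carlo checks use 20 000 generative draws (covariance agreement within
5% of the local diagonal scale), 1 000 screening replicates at n = 500
(type-I rate 0.15 ± 0.03), and recovery runs of 2 chains × 20 000
iterations (burn-in 2 000, thinning 10) on three seeds — sizes chosen so
the whole validation suite completes in minutes while leaving the
statistical conclusions unambiguous. The likelihood is checked against
adaptive quadrature of the hazard to 1e−6. The prior-only σ² check runs
1.5 million iterations of the (σ², ρ) block with the latent field absent:
IG(2.01, 1.01) has standard deviation 10, so verifying its mean to within
5% needs an effective sample in the hundreds of thousands.

## Known limitations

* One model per intervention — each fit carries its own range and variance
  parameters; no joint model of the sixteen interventions, so regional counts aggregate sixteen separate
  posteriors.
* Coverage is an ecological (region-level) covariate; individual-level
  confounding within regions is absorbed only by X and φ.
* σq² is weakly identified from 13 regions and follows its informative
  prior; regional HRR intervals inherit that width. This is a property of
  the model at Q = 13, not of the sampler.
* The random-walk sampler is correct but not efficient for the full-scale
  survey (541 clusters × 300 000 iterations); the scaled-down protocol is
  the tested configuration.
* The shipped adjacency list is transcribed from the administrative map and
  approximate for short borders; any connected symmetric graph satisfies
  the model contract.
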