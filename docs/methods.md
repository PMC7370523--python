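# Methods

## Model

The package works with random-effects linear models (RELMs) of a
continuous response measured repeatedly before and during treatment:

    Y_{ω,j} = ψ₀ + ψ_cov' x_ω + ψ₁ t_{ω,j} + … + ψ_d t_{ω,j}^d
              + τ_{0,ω} + Σ_{k ∈ random_terms, k≥1} τ_{k,ω} t_{ω,j}^k + ε_{ω,j},

with patient-level binary covariates x_ω, random effects
τ_ω ~ (0, Σ) with unstructured covariance, and i.i.d. homoscedastic
errors ε ~ N(0, σ²_ε).  Baseline rows carry t = 0, so the patient's
pre-treatment level is Λ_ω = ψ₀ + τ_{0,ω} + ψ_cov' x_ω and the
treatment-effect trajectory is the polynomial part,
β_{Q,ω}(t) = Σ_i ψ_i t^i + Σ_{k≥1} τ_{k,ω} t^k.  Two named structures are
used throughout: the random-intercept/random-slope model
(`random_terms=(0,1)`, "Model 1" in the code's scenario tables) and the
model adding a random quadratic slope (`random_terms=(0,1,2)`).

A single error scale is assumed before and after treatment.  Time enters
as raw powers (no orthogonalisation), matching the way these models are
reported clinically; for degrees beyond 2 over wide time ranges the
design can become ill-conditioned, which `fit_relm` surfaces through its
rank check rather than silently reparameterising.

## Estimation

Fitting is delegated to statsmodels `MixedLM` behind the `fit_relm`
surface — it maximises the marginal Gaussian likelihood (V_ω = Z_ω Σ Z_ω'
+ σ²_ε I) by L-BFGS with REML as the default objective and ML selectable;
statsmodels' internal covariance parameterisation keeps Σ̂ positive
semidefinite, and boundary estimates are allowed (tiny negative
eigenvalues from the boundary are clipped to zero).  REML is the default
because it is the convention of the major mixed-model implementations;
the plug-in quantile estimates accept either ML or REML estimates, and
the diagnostic's behaviour is insensitive to the choice at the sample
sizes involved.  Non-convergence is flagged on the returned fit, never
silenced.

Random-effect prediction is implemented in the package directly: the
empirical-Bayes (estimated BLUP) predictor
τ̂_ω = Σ̂ Z_ω' V̂_ω⁻¹ (y_ω − X_ω ψ̂), computed per patient with linear
solves, never explicit inverses.  Tests cross-check it against explicit
matrix algebra on small instances and against statsmodels' own posterior
means.

## Benefits and their theoretical law

With target "Y ≤ y", basal severity is s₀ = 1 − Φ((y − Λ)/σ_ε), treated
severity s₂(t) analogously with Λ + β_Q(t), and the benefit is s₀ − s₂.
For severely ill patients the closed form b ≈ Φ((y − Λ − β_Q(t))/σ_ε) is
used; its error is bounded by 1 − s₀, which the test suite asserts over a
parameter grid.  Patients with EB basal severity below 0.9 trigger a
warning (configurable threshold): the severely-ill form degrades for
them, but they are kept, since partial severity violations are a property
of the sample, not a usage error.

Under random-effect normality the benefit CDF and quantile function are

    F(z) = Φ((Φ⁻¹(z) − μ)/γ),   B(p) = Φ(γ Φ⁻¹(p) + μ),

with plug-ins μ̂ = (y − fitted mean polynomial)/σ̂_ε and
γ̂² = z(t)' Σ̂ z(t) / σ̂²_ε, where z(t) is the random-term basis.  The
quadratic form reduces exactly to the familiar two- and six-term
polynomial expressions for the two named models (property-tested over
random covariance draws).  A degenerate Σ̂ makes the law undefined and
raises.  The covariate-averaged (marginal) law F_m(z) = Σ_g (N_g/N) F(z;
x_g, t) is inverted by Brent's method on [10⁻¹², 1 − 10⁻¹²] with x-tol
10⁻¹⁰; the bracket is guaranteed because F_m is strictly increasing.

### Numerical guards

Benefits and quantile outputs are clipped to [10⁻¹², 1 − 10⁻¹²] and CVM
probability transforms to the same band before squaring: Φ underflows in
double precision around ±8 standard units, and downstream Φ⁻¹ calls must
never receive exact 0 or 1.  The clip bound is far below any discrepancy
scale of interest (the minimum attainable Ω is 1/(12N²)).

## BQQ plots, lineups, CVM

BQQ points pair within-group order statistics of EB benefits with
plug-in quantiles at positions (i − 0.5)/N_g.  The default evaluation
time is the maximum treatment time in the data, the point where the
model's extrapolation burden is smallest and benefits are largest.  Ties
in benefits are broken by patient id in a stable sort — plotting
positions are unaffected; this only pins the point↔patient mapping.
Covariate patterns with a single patient make the diagnostic undefined
(a one-point empirical quantile function); they raise by default or can
be dropped with a warning.

Lineup grids simulate K null datasets from the fitted model — normal
random effects N(0, Σ̂), errors N(0, σ̂²_ε), the *observed* design (same
visit times and covariate group sizes) — and refit each replicate before
computing its panel, so the nulls carry the same estimation noise as the
real-data panel.  Non-convergent refits are resimulated and counted.
The real panel's grid position is caller-specified or drawn from the
lineup RNG.

The per-group Cramér–von Mises discrepancy uses the standard closed form
(verified in tests against brute-force integration of (F_N − F)² dF);
the overall Ω̄ weights groups by size.  Replicate averages Ω̄̄ and the
non-normal/normal ratio R summarise simulation cells, and representative
replicates (Ω̄ closest to Ω̄̄, ties to the lowest index) are the ones
rendered.

## Simulation study

`simulation.py` reproduces a four-scenario validation design.  Shared
conditions: errors N(0, 10); one binary covariate x ~ Bernoulli(0.6);
2 baseline visits at week 0 plus treatment visits at weeks (1, 4) for
n = 4 or (1, 2, 3, 4) for n = 6; benefits evaluated at t = 4 under
target y = 7; fixed effects chosen per scenario — (21, 2, −5, 0.5) for
the bivariate scenarios, (21.4, 1.92, −3.97, 0.35) for the trivariate-t
scenario and (24, 1.92, 0.97, −0.35) for the trivariate mixture — so
that nearly all simulated patients are severely ill
(P(s₀ > 0.9) ≥ 0.95, which the acceptance script re-estimates by Monte
Carlo).

Non-normal random-effect laws and their moment-matched reference
normals N(0, D*):

1. symmetric bivariate mixture ½N(w·m₁, V) + ½N(w·m₂, V), m₁ = (0, −1),
   m₂ = (0, 1), V = [[1, .9], [.9, 1]]; D* = ½m₁*m₁*' + ½m₂*m₂*' + V;
2. asymmetric mixture ¾N((0, −1), V) + ¼N((0, 3), V) with component
   variances σ₁² = σ₂² ∈ {1..5}.  The mixture mean is exactly (0, 0), so
   the second-moment form D* = ¾m₁m₁' + ¼m₂m₂' + V is its covariance;
3. trivariate t_v(0, Γ), v ∈ {3..13}, sampled as Z·√(v/χ²_v) with
   Z ~ N(0, Γ), giving covariance D* = (v/(v−2))Γ (v > 2 enforced);
4. symmetric trivariate mixture with means ±w·(0, −1, 1)/(0, 1, −1) and
   covariance Γ.

Moment matching between each arm is the design's core comparability
construct and is property-tested on 10⁵ draws (with a wide band for the
t at small v, whose sample covariance converges slowly — at v = 3 the
fourth moments are infinite).

Replicate seed management: child generators come from
`SeedSequence(master, spawn_key=(arm, replicate, attempt))`, so arms use
independent streams, any replicate can be regenerated in isolation
(used to re-render representative replicates), and resimulation after a
non-convergent fit or a singleton covariate group advances only the
attempt counter (capped at 50, with counts logged and reported).

The study's published grid uses 500 replicates per cell; that is the
config default, while the acceptance script and test suite run 100
replicates per cell at N = 100, n = 6 — enough to separate R from 1 by a
wide margin for the probed cells (mixture w = 3 and t v = 3) at desk
scale.

## What the generators do and do not emulate

The synthetic trials reproduce the structural features of the motivating
depression study — two pre-treatment measurements, up to four weekly
on-treatment measurements, one binary diagnosis-like covariate, severe
baseline illness — and the exact scenario laws of the validation design.
They do not emulate missing visits, dropout, heteroscedastic or serially
correlated errors, continuous covariates, or measurement floors/ceilings
of bounded clinical scales.  Passing tests therefore demonstrate the
diagnostic's behaviour under the stated sampling models, not robustness
to those real-data complications (the model class itself excludes them
as assumptions).

The real imipramine dataset is not redistributable, so the depression
worked example is exercised structurally on a synthetic lookalike
(37 + 29 patients, 6 visits, random intercept + linear + quadratic
slopes); the published per-patient benefit values are not asserted
anywhere.

## Known limitations

- The diagnostic requires every covariate group to hold at least two
  patients and its sensitivity grows with N_g; with many covariates the
  marginal (covariate-averaged) quantile function is provided as the
  fallback, but its operating characteristics are less studied.
- The severely-ill closed form is the basis of all quantile machinery;
  populations with many non-severe patients fall outside its scope
  (warned, not handled).
- REML/ML fits of the three-random-effect model at n = 6 visits sit near
  the edge of identifiability; boundary covariance estimates occur and
  are accepted, and occasional non-convergent replicates in simulations
  are resimulated rather than imputed.
- The lineup protocol here is visual; no formal lineup p-value machinery
  is included.
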