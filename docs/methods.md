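# Methods

## The model

`istlung` quantifies heterogeneity of specific ventilation and specific
perfusion from Inspired Sinewave Test (IST) observables by simulation-based
optimisation. The chain of ideas:

1. **Forward lung model.** A tidally ventilated lung is discretised into
   `n_alv = 125` alveolar compartments of equal volume `V_A / n_alv`, fed
   through a common series chain of `n_ds = 10` well-mixed dead-space stages
   (total volume `V_D`), with tracer uptake by pulmonary blood flow `Q_P`
   recirculating through five parallel body-tissue compartments. Specific
   ventilation and specific perfusion are distributed over the compartments
   as lognormal quantile midpoints
   `s_i = exp(ln mu + sigma * Phi^-1((i - 0.5)/n))`, normalised to fractions.
   `sigma_V` and `sigma_P` are the heterogeneity indices; `sigma = 0` is a
   perfectly homogeneous lung.

2. **IST recovery.** The inspired N2O fraction is modulated sinusoidally
   (default mean 4%, amplitude 2%) at periods of 180 s and 60 s. For each
   period, a single well-mixed compartment model is least-squares fitted to
   the steady-state end-tidal and per-breath-uptake record, yielding the
   effective lung volume (ELV) and gas-equivalent pulmonary blood flow (Qp)
   at that period. Heterogeneity depresses ELV below the true `V_A`, and
   depresses it more at the shorter period; that frequency dependence is the
   signature the inversion exploits.

3. **Inversion.** The parameter vector
   `theta = (V_A, Q_P, mu_V, sigma_V, mu_P, sigma_P)` is recovered by
   minimising the sum of the four absolute relative observable mismatches

   `f(theta) = |dELV_180|/ELV_180 + |dELV_60|/ELV_60 + |dQp_180|/Qp_180 + |dQp_60|/Qp_60`

   over a bounded box, by Bayesian optimisation (default), bounded
   Nelder–Mead, or random search.

## Breath-resolution update

The simulator advances one breath per step; within-breath gas dynamics are
deliberately out of scope. Per breath, in order:

1. *Inspiration.* The effective alveolar tidal volume `Vx = V_T - V_D` is
   pushed through the dead-space chain (resolved into small aliquots whose
   composed action is precomputed as an exact affine map) and shared among
   compartments in proportion to their ventilation fractions.
2. *Exchange.* Tracer flux to blood for compartment *i* is
   `lam * (Q_P/RR) * pf_i * (F_i - F_ven)` with `lam = 0.47` the N2O
   blood–gas partition coefficient. The flux is evaluated implicitly in the
   end-of-step alveolar fraction: the explicit form overshoots to negative
   fractions when a compartment's perfusion-to-gas-volume ratio is extreme
   (reachable near the `sigma_P = 2` search bound); the implicit form is
   unconditionally stable and remains linear in the state.
3. *Body compartments.* The summed uptake is deposited into the tissue
   compartments in proportion to their flow fractions; the mixed venous
   fraction is the flow-weighted mean of the tissue blood-equilibrium
   fractions. Default tissues are textbook groups (vessel-rich 6 L / 75% of
   flow, muscle 33 L / 18%, fat 14.5 L / 5%, vessel-poor 12 L / 2%, blood
   pool 5 L / 0%), all configurable.
4. *Expiration.* Compartments empty `Vx` back through the chain. The
   end-tidal fraction is the ventilation-weighted mean alveolar fraction;
   the mixed-expired fraction is the volume-weighted mouth output including
   dead-space washout.

Every sub-step is linear in (state, inspired fraction), so each breath is an
exact affine map. Tracer conservation holds to machine precision per breath
(inspired − expired − uptake = change in stored tracer), and the
single-compartment recovery uses a probed copy of the same affine operator,
guaranteeing that the fast fitting path and the reference simulator agree
identically.

With `sigma_V = sigma_P = 0` the 125-compartment lung reproduces the
1-compartment lung to machine precision, which anchors the recovery: the
fitted ELV and Qp of a homogeneous lung equal the true `V_A` and `Q_P`.

## Single-compartment recovery choices

* The one-compartment fit engine includes the same body-recirculation model
  as the full simulator, started tracer-free. Venous N2O builds up on a
  timescale comparable to the forcing periods; a fit engine without
  recirculation misattributes that drift, recovering near-zero Qp and a
  ~35% inflated ELV even for a homogeneous lung.
* The residual combines the end-tidal series with the per-breath uptake
  series (converted to tidal-fraction units so the two channels are
  commensurate without a tuning weight). On the concentration series alone
  the (ELV, Qp) pair is weakly separable — volume damping and uptake damping
  trade off, producing two residual basins. A coarse grid of starts plus a
  closed-form seed precedes the least-squares polish for the same reason.
* Every forcing period is simulated for a common settle time (default 720 s)
  before the final two periods are analysed, so the analysis windows of the
  180 s and 60 s runs see the same venous background. True steady state is
  unreachable on test timescales (slow tissues equilibrate over tens of
  minutes); quasi-steadiness is declared when the fitted end-tidal amplitude
  changes by < 0.5% between consecutive periods, with the run extended up to
  16 periods if needed.
* Dead-space volume is a known input (it is measured by the IST), never
  re-estimated. End-tidal concentrations are the default observable;
  mixed-expired is a switch.

## Identifiability

The four observables constrain four parameter combinations. Under the
quantile-midpoint construction the location parameters `mu_V`, `mu_P` cancel
exactly when the weights are normalised to fractions, so the loss is flat
along those two axes and only `(V_A, Q_P, sigma_V, sigma_P)` are
identifiable. The optimiser still searches the full six-dimensional box (the
anisotropic Matérn kernel learns to ignore the flat axes); recovered `mu`
values are reported but carry no information, and run-to-run repeatability
is assessed on the identifiable four. An optional L2 penalty pulling `mu`
toward 1 (weight 0 by default) is available for users who prefer pinned
values.

## Optimisers

* **Bayesian optimisation** (default, 200-evaluation budget), in two phases
  sharing one evaluation budget.
  *Global phase* (first ~30% of the budget): Gaussian-process surrogates
  with anisotropic Matérn-5/2 kernels on inputs scaled to the unit box. The
  loss is a sum of absolute relative residuals and is kinked at each
  observable's zero crossing, so one GP is fitted per signed residual (each
  residual is a smooth function of the parameters) and the loss posterior at
  a candidate is reassembled from the folded-normal moments of the four
  residual posteriors. A 10-point Latin hypercube seeds the design; each
  iteration maximises expected improvement over a mixed global/local
  candidate set including the surrogate's own plug-in minimiser, refined by
  an L-BFGS polish of the acquisition (surrogate-only, no extra forward
  evaluations).
  *Refinement phase* (remaining budget): damped Gauss–Newton
  (Levenberg–Marquardt) descents on the *true* residual vector with
  forward-difference Jacobians. Convergence is quadratic on the smooth
  least-squares structure, reaching losses near numerical zero that no
  surrogate resolves. The loss surface carries a secondary local minimum (a
  compensation solution with inflated sigma_V and sigma_P), so a descent
  that stalls at a high floor triggers a restart from the surrogate's
  global minimiser away from the basins already visited. Jacobian columns
  that proved negligible (the two flat mu axes) are re-used rather than
  re-probed, and the run stops early once the loss is at numerical zero.
  Objectives that expose only a scalar value (no residual structure) use a
  single GP on the log-warped loss with EI followed by a trust-region
  descent on the surrogate.
* **Nelder–Mead** (400 evaluations): bounded simplex search from the box
  centre plus seeded random restarts (default 3 restarts sharing the
  budget). Forward-model failures enter the simplex as a large finite
  sentinel.
* **Random search** (400 evaluations): uniform sampling of the box.

All three share one evaluation tracker: results are cached on `theta`
quantised at 1e-6, the loss trace records the best value seen after each
evaluation, and a run is *successful* when the final loss is below the
configurable threshold (default 0.05) and the optimum lies strictly inside
the bounds. The reduced test profile uses 60 evaluations (Bayesian) and 120
(others); the verification suite and the acceptance script use 60 for the
repeatability study and 200 for the preset-recovery studies — sizes chosen
so the full verification runs on a single CPU in minutes while leaving the
recovered indices well inside their tolerance bands.

Default search box: `V_A ∈ [0.2, 6] L`, `Q_P ∈ [0.5, 10] L/min`,
`mu ∈ [0.5, 2]`, `sigma ∈ [0.01, 2]`.

## Synthetic patients and cohorts

Verification presets (shared totals `V_A = 2.3 L`, `Q_P = 4.9 L/min`,
`mu = 1`, so they differ only in distribution shape):

| preset    | sigma_V | sigma_P |
|-----------|---------|---------|
| healthy   | 0.3     | 0.5     |
| emphysema | 1.2     | 0.5     |
| embolism  | 0.8     | 1.3     |

Measurement noise is multiplicative Gaussian per observable (observables are
strictly positive scale quantities); the verification studies use noise-free
records so that the loss minimum is exactly zero at the generating
parameters.

The cohort generator emulates a 32-healthy / 72-COPD population: ages
`Normal(53, 22)` (healthy) and `Normal(67, 10)` (COPD), truncated to
[20, 90] years. Healthy indices scatter about the age-normalisation lines
`sigma_V = 0.0043*age + 0.46` and `sigma_P = 0.0045*age + 0.75`; COPD
subjects multiply the age-predicted value by a per-GOLD inflation factor
(1.15, 1.30, 1.45, 1.60 for GOLD 1–4, equal group sizes). The inflation
factors are synthetic calibration constants, not physiological measurements.
Residual scatter (healthy 0.13 / 0.26, COPD 0.15 / 0.21 in index units) is
calibrated so the pooled %-of-age-predicted ventilation index comes out near
100 ± 17 (healthy) and 140 ± 26 (pooled COPD). What the generator does *not*
emulate: measurement error of the IST chain itself, within-subject
repeat variability, comorbidities, smoking exposure, or any bimodal
heterogeneity distribution — so cohort-level classification numbers describe
the generator, not patients, and tests on them validate code paths rather
than clinical performance.

## Cohort analysis

%-of-age-predicted indices are `100 * sigma / (slope*age + intercept)` with
the coefficients above. Healthy-vs-COPD discrimination uses the rank-based
ROC AUC (ties counted half). GOLD grading uses an unpenalised multinomial
logistic regression on the two %-predicted indices, evaluated in-sample
(an optional k-fold switch exists). Group contrasts use the unpaired t test
(two groups) and Kruskal–Wallis (all grades); no multiple-testing correction
is applied.

## Numerical choices and degenerate inputs

* Dead-space aliquot size: at most a quarter of a stage volume (at least 20
  aliquots per push); the composed affine map makes the cost independent of
  the aliquot count.
* A forcing with zero amplitude produces a flat record and raises an
  unidentifiability error in the recovery rather than returning arbitrary
  values; forcing that leaves [0, 1) inspired fractions is rejected.
* `sigma = 0` is handled exactly (uniform weights), and absurd `sigma`
  values that overflow the quantile exponential raise a configuration error.
* Forward-model failures inside an optimisation are mapped to `+inf`
  (Bayesian/random) or a large finite sentinel (Nelder–Mead simplex), never
  exceptions; an all-failure run returns `success = False`.
* Ties in the coarse-start scan of the single-compartment fit are broken by
  start order, making the recovery deterministic.

## Known limitations

* Within-breath dynamics, airway mechanics, O2/CO2 exchange and PEEP effects
  are out of scope.
* Ventilation and perfusion weights are assigned in the same quantile order
  (co-sorted), so compartmental V/Q spread derives from `|sigma_V - sigma_P|`;
  independent or anti-correlated V/Q assignments are not modelled.
* `mu_V`/`mu_P` are structurally unidentifiable (above); models in which
  compartment volumes co-vary with specific ventilation would break that
  degeneracy but are not implemented.
* The body-tissue parameters are textbook constants; the recovered Qp is
  gas-equivalent flow and inherits any mismatch between the assumed and true
  partition coefficients.
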