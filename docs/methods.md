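# Methods

## Model

`dksurv` models the hazard of a subject at time `t`, conditioned on
longitudinal covariates observed up to a final observation time `s` and on
time-fixed covariates `ζ`, as

    h(t | Z_[0,s], ζ) = h0(t) · exp{ Σ_μ ∫_0^m β_μ(t, t', s) z_μ(t') dt' + γ·ζ },
    m = min(s, t).

The two assumptions are proportional hazards (log-hazard linear in the
covariate trajectory) and causality (covariate values after min(s,t) cannot
enter: future values cannot influence the present hazard, and values beyond
`s` were never observed). Note that the kernel mediates *statistical
conditioning*, not necessarily a physical delay mechanism: even when events
are generated by a purely instantaneous covariate effect, conditioning on a
stale measurement induces a decaying dependence on it, so a fitted τ > 0
is expected and τ cannot be read as a biophysical decay constant.

Three kernel families are implemented (see the `kernels` module docstring
for the formulas): families A and B, both satisfying the normalization
∫_0^m β dt' = a (standard-Cox reduction for constant covariates) and the
τ→0 delta limit (instantaneous-Cox reduction), and a `constant` family that
is an instantaneous Cox model on last-carried-forward values — exactly a
standard Cox model when covariates are time-constant. Subjects whose
covariates were observed only at baseline (s = 0) fall outside the
s-conditioned families; for them the association is taken constant
(`a_μ z_μ(0)`, the default) or exponentially decaying
(`a_μ e^{-t/τ_μ} z_μ(0)`, via `baseline_only_rule`).

Trajectories are interpolated by last observation carried forward (LOCF),
closed on the left: an observation exactly at the query time is the carried
value. Under LOCF every kernel integral is a finite sum of per-segment
exponential primitives and is evaluated in closed form.

## Estimation

The baseline hazard is profiled out, leaving the negative log profile
likelihood

    Ω(a, τ, γ) = Σ_{i:event} [ log Σ_{j: T_j ≥ T_i} e^{LP_j(T_i)} − LP_i(T_i) ],

where LP_j(t) is subject j's hazard exponent with conditioning time s_j and
integration limit min(s_j, t). Conventions: the risk set at T_i is closed
(subjects with T_j = T_i belong to it); ties are handled Breslow-style
(shared denominator); the risk-set sum is reduced with log-sum-exp. The
baseline hazard is the generalized Breslow step estimator with mass
d_k / Σ_{j at risk} e^{LP_j(t_k)} at each distinct event time.

Optimization: `(a, γ)` are initialized from a constant-family fit (a convex
Cox-type problem solved by BFGS); τ is optimized on the log scale inside the
box [1e-3, 1e3] × (median follow-up time) by Powell's method, initialized at
the median inter-visit gap. Optional seeded restarts perturb log τ
(sd 1.5 on the log scale) because the τ direction can be nearly flat;
bound hits and non-convergence are reported in the diagnostics rather than
regularized away. Defaults: objective/parameter tolerance 1e-6, 500
iterations per restart, 2 restarts. Parameter uncertainty comes from the
inverse of a central-finite-difference Hessian of Ω at the optimum
(observed information); a singular or indefinite Hessian raises an error
naming the flat directions (e.g. τ under time-constant covariates, where
the objective provably does not depend on it).

Numerical choices: every exponential in the kernel closed forms is written
relative to m or t so its argument is ≤ 0 (no overflow for small τ or large
t); when m/τ < 1e-12 the 0/0-degenerate closed forms are replaced by their
Taylor limit a·z(0); delimited-text input is parsed with round-trip float
precision so writer → reader is bit-exact.

## Prediction

The dynamic predictor at base time `t` truncates the query subject's
trajectory at s* = max{visit ≤ t}, uses s* as the kernel conditioning time,
and sums over training event times in the risk interval:

    π(u | Z_[0,t], t) = exp{ − Σ_{t < T_j ≤ u, events} e^{LP_new(T_j)} / D_j },

with D_j the Breslow denominator. The risk interval is half-open, (t, u]:
conditioning on survival *past* t means an event tied exactly with t must
not contribute, and it makes π(t|t) = 1 exactly; the upper endpoint is
included. This choice matters only under exact ties. For a subject censored
at T_i the conditional survival π(u | Z_[0,t], T_i) starts the risk interval
at T_i instead.

## Prediction error and cross-validation

Accuracy is measured by the censoring-aware expected prediction error
(squared loss by default; absolute loss available). At-risk subjects
(T_i ≥ t, subjects with T_i = t included) contribute exactly one of three
terms: survivors at u (censoring exactly at u counts as a survivor,
following the status indicator I(T_i ≥ u)), observed events before u, and
subjects censored inside [t, u), whose unknown status is replaced by a
mixture weighted with the model's own conditional survival from the
censoring time. Anchor values (squared loss, no censoring in the window):
0.25 when every prediction is 0.5, 0 for perfect and 1 for inverted
predictions.

Cross-validation partitions subjects into k seeded near-equal folds (plain
uniform randomization; optional stratification by event indicator for small
data sets), fits each model recipe per training split, and averages PE
pointwise across folds. Folds without a training event are skipped with a
warning.

## Landmarking comparator

At landmark time v the subjects with T_i > v (strict — an event exactly at
the landmark is excluded, and by construction the landmark baseline uses
only event times > v) are reduced to time-fixed covariates via LOCF at v,
and a standard Cox model is fitted by the same constant-family code path.
The censored-subject conditional is the exact survival ratio, so
π(u|T_i)·π(T_i|t) = π(u|t) holds identically. No administrative horizon
truncation or landmark super-models are implemented.

## Synthetic data generator

The generator draws, per subject: random intercept/slope effects
b ~ N(0, D); a Bernoulli(1/2) fixed covariate; an event time by
inverse-transform sampling of H(t) = h0 e^{γζ} ∫_0^t e^{α A(t')} dt' with
A = m(t) (closed-form inversion) or A = ∫_0^t m (bisection to 1e-10
relative, administrative horizon if H never reaches the target); an
independent exponential censoring time capped by an administrative horizon;
and noisy biomarker observations z_ℓ = m(t_ℓ) + ε_ℓ on a fixed visit
schedule. The final visit is the last schedule time strictly *before* the
observed event time (s_i < T_i), reproducing the observation gap typical of
real follow-up; `observe_until_event=True` instead observes event subjects
up to T_i, as in registries where the marker is recorded at the event.

Defaults (one biomarker, ten study years): n = 500, η0 = 0, η1 = 0.2,
intercept sd 0.7, slope sd 0.2, correlation 0.3, residual sd 0.3, annual
visits at 0..9, administrative censoring at 10, independent censoring rate
0.05/year, h0 = 0.1/year, α = 0.5, γ = 0.5, instantaneous association.
These values are chosen to resemble a standardized log-biomarker in a
PBC-like cohort with a mostly-observed event process (≈ 65–70% events);
they are configurable but the defaults define the package's validation
conditions.

What the generator does *not* emulate: non-linear or spline trajectories,
informative censoring, measurement schedules that depend on disease state,
multivariate random-effect correlation across biomarkers (p > 1 uses
independent blocks), and data generated from the delayed-kernel model
itself (event times would then depend on the observation process, which is
a much harder sampling problem). Passing the recovery tests therefore shows
that the estimator tracks a joint-model association in sign and order of
magnitude under correct proportional hazards — not that τ is consistently
estimated, and not robustness to trajectory mis-specification.

## Validation problem sizes

The test suite checks: closed-form kernel integrals against adaptive
quadrature (100 random trajectories per family, 1e-8); kernel normalization
by quadrature (100 random parameter draws per family, 1e-8); the
instantaneous-Cox limit at τ = 1e-6 (1e-4) and the family-B long-time floor
a/s at t = 1000·s (1e-8); exact agreement of the constant-family pipeline
(objective, estimates, Breslow baseline, survival predictions) with an
independent Cox implementation (lifelines) on a 200-subject time-constant
cohort; sign recovery of (a, γ) on 50 replicates of the default n = 500
scenario and monotonicity of the mean |â| across α ∈ {0.25, 0.5, 1.0}
(20 replicates of n = 300 each, single-start Powell at relaxed tolerance
1e-3/1e-4 — sign and ordering do not require tight convergence); and the
landmarking ratio identity and Cox-oracle agreement (1e-6).

## Known limitations

* τ estimates can be unstable — the objective is often nearly flat in τ —
  and occasionally run to the optimization bounds; this is surfaced in the
  diagnostics, not regularized.
* No measurement-error correction: observed (noisy) covariate values enter
  the hazard directly.
* No interval censoring, left truncation, competing risks, prediction
  intervals (only the parameter covariance is provided), or spline/hard-lag
  kernel shapes.
* LOCF is the only interpolation rule; smoother interpolants would change
  the closed-form integrals.
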