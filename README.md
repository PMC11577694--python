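# dksurv

Dynamic survival prediction with **delayed-association kernels** for
longitudinal covariates.

## The problem

In clinical follow-up studies (liver disease, HIV, transplantation, ...)
biomarkers are measured repeatedly at visits until some subject-specific
final observation time *s*, while the event of interest (death, relapse)
happens at a possibly much later time *T ≥ s*. Clinicians want *dynamic*
predictions: the probability that a patient who is alive at time *t*, with
biomarker history observed up to *t*, survives to a later horizon *u* — a
quantity that can be updated at every new visit. The two standard tools both
compromise: joint models must specify (and can mis-specify) a full
longitudinal model and get computationally heavy with several markers, while
landmarking refits a Cox model on the shrinking at-risk set and uses only the
last observed biomarker value.

`dksurv` takes a third route: condition the hazard *directly* on the observed
covariate history through parametric time-decay kernels,

```
h(t | Z_[0,s]) = h0(t) exp{ Σ_μ ∫_0^min(s,t) β_μ(t,t',s) z_μ(t') dt' + Σ_ν γ_ν ζ_ν }
```

The kernel β_μ(t,t',s) weighs the value of covariate μ at an earlier time t'
in the hazard at t, given covariates observed up to s. Writing
m = min(s,t) and imposing (i) exponential decay with an impact time scale
τ_μ, (ii) exact reduction to the standard Cox model for time-constant
covariates (∫ β = a_μ), and (iii) reduction to the instantaneous Cox model as
τ_μ → 0, leaves two natural one-parameter families:

* **family A** — `β = (a/τ) e^{(t'-m)/τ} / (1 - e^{-m/τ})`; for t > s the
  kernel is independent of t ("irreversible damage": early covariate changes
  are remembered without decay);
* **family B** — `β = (a/τ) e^{-(t-t')/τ} + (a/m)(1 - e^{(m-t)/τ} + e^{-t/τ})`;
  the influence keeps decaying for t > s towards the floor a/s (short-term
  impact with a persistent residual).

Estimation profiles out the baseline hazard exactly as the Cox partial
likelihood does; the baseline then follows from a generalized Breslow
estimator, and dynamic predictions π(u | Z_[0,t], t) are finite sums over the
training event times. The package also provides a censoring-aware expected
prediction error (Brier-type) with k-fold cross-validation, a classical
landmarking comparator, and a joint-model simulator for validation studies.

## Worked example

```python
from dksurv import (SimConfig, simulate_joint_dataset, DelayedKernelModel,
                    FitOptions, prediction_error)

train = simulate_joint_dataset(SimConfig(n=300), seed=1)
test  = simulate_joint_dataset(SimConfig(n=150), seed=2)

res = DelayedKernelModel(train, family="B").fit(FitOptions(seed=0, n_restarts=1))
print(res.summary())
```

```
Delayed-kernel proportional hazards model
  family: B    subjects: 300    events: 220
  Omega (neg. log profile likelihood): 1057.748478
  converged: True

  parameter                 estimate       std err
  a[z1]                     0.600865     0.0811453
  gamma[w1]                 0.450235      0.138001
  tau[z1]                    7.37464       9.19089
```

The generator used α = 0.5 (instantaneous biomarker association) and
γ = 0.5; the fitted amplitude `a` tracks α in sign and size (they are
related, not identical parameters — `a` measures the overall impact of
*conditioning* on the biomarker, and τ absorbs both physical decay and the
information decay of an ageing measurement, which is why its standard error
is wide). Predictions update as follow-up accrues:

```python
subj = test[0]                    # censored at 4.64, biomarkers observed to s = 4
for u in (4.0, 6.0, 8.0):
    print(u, res.predict_survival(subj, u, t=3.0))
#   pi(4.0 | t=3) = 0.8326
#   pi(6.0 | t=3) = 0.5523
#   pi(8.0 | t=3) = 0.3778

prediction_error(res, test, t=3.0, u=6.0)   # censoring-aware Brier score
#   0.2038
```

A prediction error of 0.204 at the three-year window beats the
uninformative-prediction anchor of 0.25 (every subject predicted 0.5).

The same pipeline is scriptable from a shell:

```bash
dksurv simulate --seed 1 --out data/
dksurv fit --data data/long.csv --subjects data/subjects.csv --family B --out fit/
dksurv evaluate --model fit/model.json --data data/long.csv \
    --subjects data/subjects.csv --base-time 3 --u-grid 4,5,6,7,8 --out pe.csv
dksurv cv --data data/long.csv --subjects data/subjects.csv --folds 10 \
    --seed 1 --t-grid 0,1,2,3 --window 2 --landmark --out cv.csv
```

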