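"""Maximum-likelihood fitting of the delayed-kernel hazard model.

The model profiles out the nonparametric baseline hazard exactly as the Cox
partial likelihood does.  Writing ``LP_j(t)`` for subject j's hazard exponent
at time t (fixed-covariate term plus kernel-weighted covariate integrals with
conditioning time ``s_j``), the negative log profile likelihood is

    Omega(a, tau, gamma) = sum_{i: event} log( sum_{j: T_j >= T_i} e^{LP_j(T_i)} )
                           - sum_{i: event} LP_i(T_i)

Minimising Omega gives the ML estimates; the baseline hazard then follows
from the generalized Breslow estimator, with hazard mass
``d_k / sum_{j at risk} e^{LP_j(t_k)}`` at each distinct event time ``t_k``.

The public surface follows the statsmodels convention: build a
:class:`DelayedKernelModel` from a :class:`~dksurv.data.Dataset`, call
``fit()`` and work with the returned :class:`DelayedKernelResults`.
Module-level helpers (:func:`omega_ml`, :func:`fit_dk`,
:func:`breslow_baseline`, :func:`parameter_covariance`) expose the same
operations functionally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from . import _fastpath
from .data import Dataset, SubjectRecord, validate_dataset
from .kernels import (
    CONSTANT,
    CONSTANT_ASSOC,
    KernelSpec,
    MODEL_A,
    MODEL_B,
    batch_weighted_integrals,
    _pack_subject,
)

__all__ = [
    "FitOptions",
    "BaselineHazard",
    "DelayedKernelModel",
    "DelayedKernelResults",
    "omega_ml",
    "fit_dk",
    "breslow_baseline",
    "parameter_covariance",
]


@dataclass
class FitOptions:
    """Optimizer settings for :meth:`DelayedKernelModel.fit`.

    tau is optimized on the log scale inside a box
    ``[tau_bounds_factor[0], tau_bounds_factor[1]] * median follow-up``;
    random restarts perturb log tau (seeded, hence reproducible).
    """

    xtol: float = 1e-6
    ftol: float = 1e-6
    maxiter: int = 500
    n_restarts: int = 2
    seed: int = 0
    tau_bounds_factor: tuple = (1e-3, 1e3)

    def __post_init__(self) -> None:
        if self.xtol <= 0 or self.ftol <= 0:
            raise ValueError("tolerances must be > 0")
        lo, hi = self.tau_bounds_factor
        if not (0 < lo < hi < np.inf):
            raise ValueError("tau bounds must be finite, positive and ordered")


@dataclass
class BaselineHazard:
    """Step cumulative baseline hazard: Breslow mass at each event time."""

    times: np.ndarray
    increments: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.increments = np.asarray(self.increments, dtype=float)
        self._cum = np.cumsum(self.increments)

    def cumulative(self, t) -> np.ndarray:
        """Cumulative hazard H0(t) (events at exactly t included)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        return np.where(idx > 0, self._cum[np.maximum(idx - 1, 0)], 0.0)


class _CohortEvaluator:
    """Padded-array view of a cohort for vectorised linear predictors."""

    def __init__(self, dataset: Dataset):
        subs = dataset.subjects
        N = len(subs)
        p, q = dataset.p, dataset.q
        S = max(max(s.n_obs - 1 for s in subs), 1)
        self.seg_lo = np.zeros((N, S))
        self.seg_hi = np.zeros((N, S))
        self.seg_val = np.zeros((N, p, S))
        self.s = np.zeros(N)
        self.z0 = np.zeros((N, p))
        self.z_last = np.zeros((N, p))
        self.zeta = np.zeros((N, q))
        self.T = np.zeros(N)
        self.delta = np.zeros(N, dtype=int)
        for i, sub in enumerate(subs):
            n = sub.n_obs
            self.seg_lo[i, : n - 1] = sub.obs_times[:-1]
            self.seg_hi[i, : n - 1] = sub.obs_times[1:]
            self.seg_val[i, :, : n - 1] = sub.values[:, :-1]
            self.s[i] = sub.s
            self.z0[i] = sub.values[:, 0]
            self.z_last[i] = sub.values[:, -1]
            self.zeta[i] = sub.fixed
            self.T[i] = sub.event_time
            self.delta[i] = sub.event
        # distinct event times and multiplicities
        ev = self.T[self.delta == 1]
        self.event_times, self.event_counts = np.unique(ev, return_counts=True)
        # index of each event subject's T among the distinct event times
        self._ev_subj = np.flatnonzero(self.delta == 1)
        self._ev_idx = np.searchsorted(self.event_times, self.T[self._ev_subj])

    def linear_predictors(self, spec: KernelSpec, gamma: np.ndarray, times) -> np.ndarray:
        """(K, N) matrix of hazard exponents LP_j(t_k)."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        if spec.p and spec.family != CONSTANT and _fastpath.HAVE_NUMBA:
            lp = _fastpath.lp_matrix(
                spec, times, self.seg_lo, self.seg_hi, self.seg_val,
                self.s, self.z0,
                decaying_rule=spec.baseline_only_rule != CONSTANT_ASSOC,
            )
        elif spec.p:
            integ = batch_weighted_integrals(
                spec, times, self.seg_lo, self.seg_hi, self.seg_val,
                self.s, self.z0, self.z_last,
            )
            lp = integ.sum(axis=2)
        else:
            lp = np.zeros((len(times), len(self.T)))
        if self.zeta.shape[1]:
            lp = lp + (self.zeta @ np.asarray(gamma, dtype=float))[None, :]
        return lp

    def omega(self, spec: KernelSpec, gamma: np.ndarray) -> float:
        if len(self.event_times) == 0:
            raise ValueError("objective undefined: dataset contains no events")
        lp = self.linear_predictors(spec, gamma, self.event_times)  # (K, N)
        if not np.all(np.isfinite(lp)):
            bad = np.argwhere(~np.isfinite(lp))
            raise FloatingPointError(
                f"non-finite hazard exponent for subject index {bad[0][1]}"
            )
        at_risk = self.T[None, :] >= self.event_times[:, None]
        masked = np.where(at_risk, lp, -np.inf)
        lse = logsumexp(masked, axis=1)
        first = float(self.event_counts @ lse)
        second = float(np.sum(lp[self._ev_idx, self._ev_subj]))
        return first - second

    def log_denominators(self, spec: KernelSpec, gamma: np.ndarray) -> np.ndarray:
        """log sum_{j at risk} e^{LP_j} at each distinct event time."""
        lp = self.linear_predictors(spec, gamma, self.event_times)
        at_risk = self.T[None, :] >= self.event_times[:, None]
        return logsumexp(np.where(at_risk, lp, -np.inf), axis=1)


def omega_ml(a, tau, gamma, d: Dataset, family: str,
             baseline_only_rule: str = CONSTANT_ASSOC) -> float:
    """Negative log profile likelihood Omega at the given parameters."""
    spec = KernelSpec(
        family,
        a=np.atleast_1d(np.asarray(a, float)),
        tau=(np.atleast_1d(np.asarray(tau, float)) if family != CONSTANT
             else np.ones(d.p)),
        baseline_only_rule=baseline_only_rule,
    )
    return _CohortEvaluator(d).omega(spec, np.atleast_1d(np.asarray(gamma, float)))


class DelayedKernelModel:
    """Proportional-hazards model with delayed-association kernels.

    Parameters
    ----------
    dataset : Dataset
        Training data (validated on construction).
    family : {"A", "B", "constant"}
        Kernel family.  "constant" reduces to an instantaneous Cox model on
        LOCF covariate values (and exactly to standard Cox for time-constant
        covariates).
    baseline_only_rule : str
        Association rule for subjects observed only at baseline (s = 0).
    """

    def __init__(self, dataset: Dataset, family: str = MODEL_B,
                 baseline_only_rule: str = CONSTANT_ASSOC):
        problems = validate_dataset(dataset)
        if problems:
            raise ValueError("invalid dataset: " + "; ".join(problems))
        if dataset.p == 0 and dataset.q == 0:
            raise ValueError("model needs at least one covariate")
        self.dataset = dataset
        self.family = family
        self.baseline_only_rule = baseline_only_rule
        self._ev = _CohortEvaluator(dataset)
        if len(self._ev.event_times) == 0:
            raise ValueError("objective undefined: dataset contains no events")

    @classmethod
    def from_tables(cls, long_table_path, subject_table_path, family: str = MODEL_B,
                    **kwargs) -> "DelayedKernelModel":
        from .data import read_dataset

        return cls(read_dataset(long_table_path, subject_table_path), family, **kwargs)

    # -- objective ---------------------------------------------------------

    def _spec(self, a, tau) -> KernelSpec:
        return KernelSpec(
            self.family, a=a,
            tau=tau if self.family != CONSTANT else np.ones(self.dataset.p),
            baseline_only_rule=self.baseline_only_rule,
        )

    def omega(self, a, tau, gamma) -> float:
        return self._ev.omega(self._spec(np.atleast_1d(a), np.atleast_1d(tau)),
                              np.atleast_1d(np.asarray(gamma, float)))

    def _unpack(self, x: np.ndarray):
        p, q = self.dataset.p, self.dataset.q
        a = x[:p]
        gamma = x[p:p + q]
        logtau = x[p + q:]
        return a, gamma, logtau

    def _objective(self, x: np.ndarray) -> float:
        a, gamma, logtau = self._unpack(x)
        tau = np.exp(logtau) if len(logtau) else np.ones(self.dataset.p)
        return self._ev.omega(self._spec(a, tau), gamma)

    # -- fitting -----------------------------------------------------------

    def _fit_constant(self, opts: FitOptions):
        """Convex Cox-type fit of (a, gamma) under the constant family."""
        p, q = self.dataset.p, self.dataset.q
        x0 = np.zeros(p + q)

        def f(x):
            spec = self._spec(x[:p], np.ones(p))
            return self._ev.omega(spec, x[p:])

        res = minimize(f, x0, method="BFGS",
                       options={"gtol": min(opts.ftol, 1e-8), "maxiter": opts.maxiter})
        # flat-objective probe: does any coordinate move the objective at all?
        flat = all(
            abs(f(res.x + 0.5 * e) - res.fun) < 1e-10
            for e in np.eye(p + q)
        )
        return res, flat

    def fit(self, opts: FitOptions | None = None) -> "DelayedKernelResults":
        """Maximum-likelihood fit; deterministic for a fixed options seed."""
        opts = opts or FitOptions()
        p, q = self.dataset.p, self.dataset.q
        const_res, flat = self._fit_constant(opts)
        diagnostics = {"flat_objective": flat, "restarts": []}

        if self.family == CONSTANT or p == 0:
            a = const_res.x[:p]
            gamma = const_res.x[p:]
            tau = np.ones(p)
            diagnostics.update(converged=bool(const_res.success), nfev=int(const_res.nfev))
            spec = self._spec(a, tau)
            return DelayedKernelResults(self, spec, gamma, float(const_res.fun),
                                        diagnostics, omega_trace=[float(const_res.fun)])

        # families A/B: Powell over (a, gamma, log tau) with bounded log tau
        med_T = float(np.median(self._ev.T))
        gaps = np.concatenate([np.diff(s.obs_times) for s in self.dataset.subjects])
        gaps = gaps[gaps > 0]
        tau0 = float(np.median(gaps)) if len(gaps) else max(med_T / 4.0, 1e-3)
        lo = np.log(opts.tau_bounds_factor[0] * max(med_T, 1e-12))
        hi = np.log(opts.tau_bounds_factor[1] * max(med_T, 1e-12))
        logtau0 = np.clip(np.log(tau0), lo, hi)

        x0 = np.concatenate([const_res.x[:p], const_res.x[p:], np.full(p, logtau0)])
        bounds = [(None, None)] * (p + q) + [(lo, hi)] * p
        rng = np.random.default_rng(opts.seed)
        starts = [x0]
        for _ in range(opts.n_restarts):
            xr = x0.copy()
            xr[p + q:] = np.clip(xr[p + q:] + rng.normal(0.0, 1.5, size=p), lo, hi)
            starts.append(xr)

        best = None
        trace: list[float] = []

        def recording(x):
            val = self._objective(x)
            if not trace or val < trace[-1]:
                trace.append(val)
            return val

        for k, xs in enumerate(starts):
            res = minimize(
                recording, xs, method="Powell", bounds=bounds,
                options={"xtol": opts.xtol, "ftol": opts.ftol,
                         "maxiter": opts.maxiter},
            )
            diagnostics["restarts"].append(
                {"start": k, "omega": float(res.fun), "converged": bool(res.success),
                 "nfev": int(res.nfev)}
            )
            if best is None or res.fun < best.fun:
                best = res

        a, gamma, logtau = self._unpack(best.x)
        tau = np.exp(logtau)
        at_lo = np.isclose(logtau, lo, atol=1e-6)
        at_hi = np.isclose(logtau, hi, atol=1e-6)
        diagnostics.update(
            converged=any(r["converged"] for r in diagnostics["restarts"]),
            nfev=int(sum(r["nfev"] for r in diagnostics["restarts"])),
            tau_at_lower_bound=at_lo.tolist(),
            tau_at_upper_bound=at_hi.tolist(),
        )
        spec = self._spec(a, tau)
        return DelayedKernelResults(self, spec, gamma, float(best.fun),
                                    diagnostics, omega_trace=trace)


class DelayedKernelResults:
    """Fitted delayed-kernel model: estimates, baseline hazard, predictions."""

    def __init__(self, model: DelayedKernelModel, spec: KernelSpec,
                 gamma: np.ndarray, omega: float, diagnostics: dict,
                 omega_trace=None):
        self.model = model
        self.spec = spec
        self.gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
        self.omega = omega
        self.diagnostics = diagnostics
        self.omega_trace = list(omega_trace or [])
        ev = model._ev
        self._log_denom = ev.log_denominators(spec, self.gamma)
        self._cov = None

    # -- parameter access ---------------------------------------------------

    @property
    def a(self) -> np.ndarray:
        return self.spec.a

    @property
    def tau(self) -> np.ndarray:
        return self.spec.tau

    @property
    def param_names(self) -> list:
        d = self.model.dataset
        names = [f"a[{n}]" for n in d.longitudinal_names]
        names += [f"gamma[{n}]" for n in d.fixed_names]
        if self.model.family != CONSTANT:
            names += [f"tau[{n}]" for n in d.longitudinal_names]
        return names

    @property
    def params(self) -> np.ndarray:
        if self.model.family == CONSTANT:
            return np.concatenate([self.a, self.gamma])
        return np.concatenate([self.a, self.gamma, self.tau])

    # -- baseline hazard -----------------------------------------------------

    def baseline_hazard(self) -> BaselineHazard:
        """Generalized Breslow estimator of the cumulative baseline hazard."""
        ev = self.model._ev
        inc = ev.event_counts * np.exp(-self._log_denom)
        return BaselineHazard(ev.event_times, inc)

    # -- uncertainty ---------------------------------------------------------

    def cov_params(self, rel_step: float = 1e-4) -> np.ndarray:
        """Inverse observed-information covariance of (a, gamma[, tau]).

        The Hessian of Omega is estimated by central finite differences at the
        ML point.  A singular or indefinite Hessian (e.g. tau unidentifiable
        because every trajectory is constant) raises with the flat directions
        named.
        """
        if self._cov is not None:
            return self._cov
        theta = self.params.copy()
        names = self.param_names
        k = len(theta)
        mdl = self.model
        p, q = mdl.dataset.p, mdl.dataset.q

        def f(th):
            a, gamma = th[:p], th[p:p + q]
            tau = th[p + q:] if mdl.family != CONSTANT else np.ones(p)
            if mdl.family != CONSTANT and np.any(tau <= 0):
                return np.inf
            return mdl._ev.omega(mdl._spec(a, tau), gamma)

        h = rel_step * np.maximum(1.0, np.abs(theta))
        H = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                fpp = f(theta + ei + ej)
                fpm = f(theta + ei - ej)
                fmp = f(theta - ei + ej)
                fmm = f(theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        if not np.all(np.isfinite(H)):
            raise np.linalg.LinAlgError("non-finite Hessian of the objective")
        w, V = np.linalg.eigh(H)
        tol = max(abs(w).max(), 1.0) * 1e-10
        if np.any(w <= tol):
            flat = [names[int(np.argmax(np.abs(V[:, i])))]
                    for i in range(k) if w[i] <= tol]
            raise np.linalg.LinAlgError(
                "information matrix is singular/indefinite; flat directions: "
                + ", ".join(sorted(set(flat)))
            )
        self._cov = V @ np.diag(1.0 / w) @ V.T
        self._cov = 0.5 * (self._cov + self._cov.T)
        return self._cov

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params()))

    # -- prediction ----------------------------------------------------------

    def _query_lp(self, subj: SubjectRecord, s_star: float, times: np.ndarray) -> np.ndarray:
        """Hazard exponents of a query subject at training event times."""
        d = self.model.dataset
        if subj.p != d.p:
            raise ValueError("query subject covariate layout does not match model")
        total = np.zeros(len(times))
        for mu in range(d.p):
            packed = _pack_subject(subj.trajectory(mu), s_star)
            sub = KernelSpec(
                self.spec.family,
                a=self.spec.a[mu:mu + 1],
                tau=(self.spec.tau[mu:mu + 1] if self.spec.family != CONSTANT
                     else np.ones(1)),
                baseline_only_rule=self.spec.baseline_only_rule,
            )
            total += batch_weighted_integrals(sub, times, *packed)[:, 0, 0]
        if d.q:
            total += float(self.gamma @ subj.fixed)
        return total

    def _survival_core(self, subj: SubjectRecord, s_star: float,
                       start: float, u: float) -> float:
        ev = self.model._ev
        # risk interval (start, u]: an event tied with the conditioning time
        # does not contribute (we condition on survival past `start`)
        sel = (ev.event_times > start) & (ev.event_times <= u)
        if not np.any(sel):
            return 1.0
        te = ev.event_times[sel]
        lp_new = self._query_lp(subj, s_star, te)
        contrib = ev.event_counts[sel] * np.exp(lp_new - self._log_denom[sel])
        return float(np.exp(-np.sum(contrib)))

    def predict_survival(self, subj: SubjectRecord, u: float,
                         t: float | None = None) -> float:
        """Dynamic survival probability pi(u | Z_[0,t], t).

        With ``t`` omitted the base time is the subject's final observation
        time ``s``.  Covariate integrals are truncated at the last observation
        at or before ``t``; the risk interval is (t, u].
        """
        if t is None:
            t = subj.s
        if u < t:
            raise ValueError(f"horizon u={u} earlier than base time t={t}")
        s_star = float(subj.obs_times[subj.obs_times <= t].max())
        return self._survival_core(subj, s_star, t, u)

    def conditional_survival_from_censoring(self, subj: SubjectRecord,
                                            t: float, u: float) -> float:
        """pi(u | Z_[0,t], T_i) for a subject censored at T_i in [t, u]."""
        if subj.event != 0:
            raise ValueError("defined for censored subjects only (delta = 0)")
        if not (t <= subj.event_time <= u):
            raise ValueError("requires t <= censoring time <= u")
        s_star = float(subj.obs_times[subj.obs_times <= t].max())
        return self._survival_core(subj, s_star, subj.event_time, u)

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        d = self.model.dataset
        lines = [
            "Delayed-kernel proportional hazards model",
            f"  family: {self.model.family}    subjects: {d.n}    "
            f"events: {int(self.model._ev.delta.sum())}",
            f"  Omega (neg. log profile likelihood): {self.omega:.6f}",
            f"  converged: {self.diagnostics.get('converged')}",
            "",
            f"  {'parameter':<20}{'estimate':>14}{'std err':>14}",
        ]
        try:
            se = self.bse
        except np.linalg.LinAlgError:
            se = [float("nan")] * len(self.params)
        for name, val, s in zip(self.param_names, self.params, se):
            lines.append(f"  {name:<20}{val:>14.6g}{s:>14.6g}")
        if self.model.family != CONSTANT:
            if any(self.diagnostics.get("tau_at_lower_bound", [])) or any(
                self.diagnostics.get("tau_at_upper_bound", [])
            ):
                lines.append("  note: tau estimate at optimization bound")
        return "\n".join(lines)

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        d = self.model.dataset
        payload = {
            "family": self.model.family,
            "baseline_only_rule": self.model.baseline_only_rule,
            "a": self.a.tolist(),
            "tau": self.tau.tolist(),
            "gamma": self.gamma.tolist(),
            "omega": self.omega,
            "diagnostics": self.diagnostics,
            "omega_trace": self.omega_trace,
            "training_data": {
                "longitudinal_names": list(d.longitudinal_names),
                "fixed_names": list(d.fixed_names),
                "subjects": [
                    {
                        "id": s.id,
                        "event_time": s.event_time,
                        "event": s.event,
                        "obs_times": s.obs_times.tolist(),
                        "values": s.values.tolist(),
                        "fixed": s.fixed.tolist(),
                    }
                    for s in d.subjects
                ],
            },
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, doc: str) -> "DelayedKernelResults":
        payload = json.loads(doc)
        td = payload["training_data"]
        subjects = [
            SubjectRecord(
                id=s["id"], event_time=s["event_time"], event=s["event"],
                obs_times=np.array(s["obs_times"]), values=np.array(s["values"]),
                fixed=np.array(s["fixed"]),
            )
            for s in td["subjects"]
        ]
        dataset = Dataset(subjects, td["longitudinal_names"], td["fixed_names"])
        model = DelayedKernelModel(dataset, payload["family"],
                                   payload["baseline_only_rule"])
        spec = model._spec(np.array(payload["a"]), np.array(payload["tau"]))
        return cls(model, spec, np.array(payload["gamma"]), payload["omega"],
                   payload["diagnostics"], payload.get("omega_trace"))


def fit_dk(d: Dataset, family: str = MODEL_B,
           opts: FitOptions | None = None,
           baseline_only_rule: str = CONSTANT_ASSOC) -> DelayedKernelResults:
    """Fit the delayed-kernel model to a dataset (functional entry point)."""
    return DelayedKernelModel(d, family, baseline_only_rule).fit(opts)


def breslow_baseline(results: DelayedKernelResults) -> BaselineHazard:
    """Generalized Breslow cumulative baseline hazard of a fitted model."""
    return results.baseline_hazard()


def parameter_covariance(results: DelayedKernelResults) -> np.ndarray:
    """Inverse-information covariance matrix of the fitted parameters."""
    return results.cov_params()
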