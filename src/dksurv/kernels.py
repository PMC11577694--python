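"""Delayed-association kernels and their closed-form LOCF integrals.

The hazard of the delayed-kernel model at time ``t``, conditioned on covariate
trajectories observed up to time ``s``, is

    h(t | Z_[0,s]) = h0(t) * exp{ sum_mu int_0^min(s,t) beta_mu(t,t',s) z_mu(t') dt'
                                  + sum_nu gamma_nu zeta_nu }

The kernel ``beta_mu(t,t',s)`` weights the covariate value at an earlier time
``t'`` in the hazard at ``t``.  Two one-parameter-per-covariate families are
implemented, both built around the time-translation-invariant factor
``exp(-(t-t')/tau)`` and both constrained so that

* a time-constant trajectory reproduces the standard Cox model exactly
  (the kernel integrates to the amplitude ``a_mu`` over [0, min(s,t)]), and
* the limit ``tau -> 0`` reproduces the instantaneous Cox model
  (the kernel tends to ``a_mu * delta(t - t')``).

With ``m = min(s, t)``:

* family A:  beta(t,t',s) = (a/tau) e^{(t'-m)/tau} / (1 - e^{-m/tau}).
  For t > s the kernel no longer depends on t: early covariate changes are
  "remembered" without decay (e.g. irreversible damage).
* family B:  beta(t,t',s) = (a/tau) e^{-(t-t')/tau}
                            + (a/m) (1 - e^{(m-t)/tau} + e^{-t/tau}).
  For t > s the kernel keeps decaying in t, approaching the floor ``a/s``
  as t -> infinity (short-term impact with a persistent residual).

The constant family carries no time scale: its exponent contribution is
simply ``a_mu`` times the carried covariate value at ``min(s,t)``, i.e. an
instantaneous Cox model on LOCF values; it is the natural kernel for
subjects observed only at baseline and the initialisation / Cox-equivalence
work-horse.

Because trajectories are interpolated by LOCF, every integral of the kernel
against a trajectory is a finite sum of exponential primitives over the
inter-visit segments; this module evaluates those sums in closed form, with
all exponents shifted to be non-positive so nothing overflows for small tau
or large t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import SubjectRecord, Trajectory, locf_value

__all__ = [
    "MODEL_A",
    "MODEL_B",
    "CONSTANT",
    "KernelSpec",
    "kernel_value",
    "kernel_b_longtime_limit",
    "weighted_covariate_integral",
    "linear_predictor",
]

MODEL_A = "A"
MODEL_B = "B"
CONSTANT = "constant"
_FAMILIES = (MODEL_A, MODEL_B, CONSTANT)

# constant vs decaying association for subjects observed only at baseline (s=0)
CONSTANT_ASSOC = "constant_assoc"
DECAYING_ASSOC = "decaying_assoc"

# below m/tau ~ this the closed forms degenerate to 0/0; use the Taylor limit
_SMALL_M_OVER_TAU = 1e-12


@dataclass
class KernelSpec:
    """Kernel family plus per-covariate amplitudes ``a`` and time scales ``tau``.

    ``baseline_only_rule`` fixes the association for subjects whose covariates
    were observed only at baseline (s = 0), where the s-conditioned kernels
    are undefined: either a constant association ``a_mu`` (default) or a
    decaying one ``a_mu * exp(-t/tau_mu)``.
    """

    family: str
    a: np.ndarray
    tau: np.ndarray = field(default_factory=lambda: np.zeros(0))
    baseline_only_rule: str = CONSTANT_ASSOC

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        if self.family != CONSTANT:
            if self.tau.shape != self.a.shape:
                raise ValueError("tau must match a in length for families A/B")
            if np.any(self.tau <= 0):
                raise ValueError("impact time scales tau must be > 0")
        if not np.all(np.isfinite(self.a)):
            raise ValueError("amplitudes a must be finite")
        if self.baseline_only_rule not in (CONSTANT_ASSOC, DECAYING_ASSOC):
            raise ValueError(f"unknown baseline_only_rule {self.baseline_only_rule!r}")

    @property
    def p(self) -> int:
        return len(self.a)


def kernel_value(spec: KernelSpec, mu: int, t: float, t_prime: float, s: float) -> float:
    """Pointwise kernel ``beta_mu(t, t', s)`` for families A and B.

    Causality sets the kernel to zero for ``t' > t``.  The constant family has
    no pointwise density (its action is defined through integrals only).
    """
    if spec.family == CONSTANT:
        raise ValueError("the constant family is defined through its integrals only")
    if s <= 0:
        raise ValueError(
            "kernels A/B are undefined for s <= 0; baseline-only subjects follow "
            "the KernelSpec baseline_only_rule"
        )
    if t <= 0:
        raise ValueError("kernel requires t > 0")
    if t_prime > t:
        return 0.0
    a = float(spec.a[mu])
    tau = float(spec.tau[mu])
    m = min(s, t)
    if spec.family == MODEL_A:
        # (a/tau) e^{t'/tau} / (e^{m/tau} - 1), shifted by m so exponents <= 0
        return a / tau * math.exp((t_prime - m) / tau) / (1.0 - math.exp(-m / tau))
    # family B
    decay = a / tau * math.exp(-(t - t_prime) / tau)
    floor = a / m * (1.0 - math.exp((m - t) / tau) + math.exp(-t / tau))
    return decay + floor


def kernel_b_longtime_limit(spec: KernelSpec, mu: int, s: float) -> float:
    """Long-time floor ``a_mu / s`` of the family-B kernel as t -> infinity."""
    if spec.family != MODEL_B:
        raise ValueError("long-time limit a/s applies to family B only")
    if s <= 0:
        raise ValueError("requires s > 0")
    return float(spec.a[mu]) / s


def _segments(traj: Trajectory):
    """LOCF segments (lo, hi, value) covering [0, s]; empty if only one visit."""
    t = traj.obs_times
    return t[:-1], t[1:], traj.values[:-1]


def weighted_covariate_integral(
    spec: KernelSpec, traj: Trajectory, mu: int, t: float, s_eff: float
) -> float:
    """Closed-form ``int_0^min(s_eff,t) beta_mu(t, t', s_eff) z_mu(t') dt'``.

    ``s_eff`` is the conditioning time entering the kernel (the subject's
    final observation time, possibly truncated at a prediction base time).
    For ``s_eff = 0`` the baseline-only rule applies: the integral term is
    replaced by ``a * z(0)`` (constant association) or ``a e^{-t/tau} z(0)``
    (decaying association).
    """
    sub = KernelSpec(
        spec.family,
        a=spec.a[mu : mu + 1],
        tau=spec.tau[mu : mu + 1] if spec.family != CONSTANT else np.ones(1),
        baseline_only_rule=spec.baseline_only_rule,
    )
    out = batch_weighted_integrals(
        sub,
        np.array([t], dtype=float),
        *_pack_subject(traj, s_eff),
    )
    return float(out[0, 0, 0])


def linear_predictor(
    spec: KernelSpec,
    gamma: np.ndarray,
    subj: SubjectRecord,
    t: float,
    s_eff: float | None = None,
) -> float:
    """Exponent of the hazard: fixed-covariate term plus all kernel integrals."""
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    if len(gamma) != subj.q:
        raise ValueError(f"gamma has length {len(gamma)}, expected {subj.q}")
    if subj.p != spec.p:
        raise ValueError("kernel spec covariate count does not match subject")
    if s_eff is None:
        s_eff = subj.s
    total = float(gamma @ subj.fixed) if subj.q else 0.0
    for mu in range(subj.p):
        total += weighted_covariate_integral(spec, subj.trajectory(mu), mu, t, s_eff)
    return total


# ---------------------------------------------------------------------------
# vectorised evaluation over (evaluation times x subjects x visit segments)
# ---------------------------------------------------------------------------


def _pack_subject(traj: Trajectory, s_eff: float):
    """Pack one trajectory (conditioned up to s_eff) into the batch layout."""
    if s_eff < 0:
        raise ValueError("s_eff must be >= 0")
    keep = traj.obs_times <= s_eff
    times = traj.obs_times[keep]
    vals = traj.values[keep]
    if len(times) == 0:
        raise ValueError("trajectory has no observation at or before s_eff")
    if times[-1] < s_eff:  # carry the last value up to the conditioning time
        times = np.append(times, s_eff)
        vals = np.append(vals, vals[-1])
    lo, hi, v = times[:-1], times[1:], vals[:-1]
    S = max(len(lo), 1)
    seg_lo = np.zeros((1, S))
    seg_hi = np.zeros((1, S))
    seg_val = np.zeros((1, 1, S))
    seg_lo[0, : len(lo)] = lo
    seg_hi[0, : len(hi)] = hi
    seg_val[0, 0, : len(v)] = v
    s_arr = np.array([float(s_eff)])
    z0 = np.array([[vals[0]]])
    z_last = np.array([[vals[-1]]])
    return seg_lo, seg_hi, seg_val, s_arr, z0, z_last


def batch_weighted_integrals(
    spec: KernelSpec,
    times: np.ndarray,
    seg_lo: np.ndarray,
    seg_hi: np.ndarray,
    seg_val: np.ndarray,
    s: np.ndarray,
    z0: np.ndarray,
    z_last: np.ndarray,
) -> np.ndarray:
    """Kernel-weighted covariate integrals for every (time, subject) pair.

    Parameters
    ----------
    times : (K,) evaluation times t (must be > 0).
    seg_lo, seg_hi : (N, S) padded LOCF segment bounds per subject
        (padding rows have lo == hi == 0 and value 0).
    seg_val : (N, p, S) covariate value on each segment.
    s : (N,) conditioning time per subject.
    z0 : (N, p) baseline covariate values (used when s == 0 or m/tau ~ 0).
    z_last : (N, p) last carried value at s (used by the constant family).

    Returns
    -------
    (K, N, p) array of integral values.

    Notes
    -----
    Every exponent is written relative to ``m = min(s, t)`` or ``t`` so that
    it is <= 0; the closed forms never evaluate a growing exponential.
    """
    times = np.asarray(times, dtype=float)
    K, N = len(times), len(s)
    p = spec.p
    out = np.empty((K, N, p))

    m = np.minimum(s[None, :], times[:, None])  # (K, N)
    if spec.family == CONSTANT:
        # instantaneous Cox on carried values: a * z(min(s, t)) = a * z(s) since
        # LOCF carries the last value forward; for t < s the carried value at t
        # is still the relevant one -> use last value at or before m.
        for nu in range(N):
            # segments give values on [t_l, t_{l+1}); value at m
            lo = seg_lo[nu]
            hi = seg_hi[nu]
            nseg = int(np.sum(hi > lo))
            knots = np.concatenate([lo[:nseg], [s[nu]]]) if nseg else np.array([0.0])
            idx = np.clip(np.searchsorted(knots, m[:, nu], side="right") - 1, 0, None)
            if nseg:
                vals = np.concatenate(
                    [seg_val[nu, :, :nseg], z_last[nu][:, None]], axis=1
                )  # (p, nseg+1)
            else:
                vals = z0[nu][:, None]
            out[:, nu, :] = vals[:, idx].T
        out *= spec.a[None, None, :]
        return out

    tau = spec.tau  # (p,)
    a = spec.a
    t_col = times[:, None]  # (K, 1)
    for mu in range(p):
        tmu = tau[mu]
        hi_c = np.minimum(seg_hi[None, :, :], m[:, :, None])  # (K, N, S)
        lo_c = np.minimum(seg_lo[None, :, :], m[:, :, None])
        vals = seg_val[None, :, mu, :]  # (1, N, S)
        # degenerate entries (m == 0 or m/tau below the guard) produce inf/nan
        # here and are replaced by the Taylor limit a*z(0) just after
        with np.errstate(divide="ignore", invalid="ignore"):
            if spec.family == MODEL_A:
                diff = np.exp((hi_c - m[:, :, None]) / tmu) - np.exp(
                    (lo_c - m[:, :, None]) / tmu
                )
                denom = -np.expm1(-m / tmu)  # (K, N)
                integ = a[mu] * np.sum(vals * diff, axis=2) / denom
            else:  # MODEL_B
                diff = np.exp((hi_c - t_col[:, :, None]) / tmu) - np.exp(
                    (lo_c - t_col[:, :, None]) / tmu
                )
                term1 = a[mu] * np.sum(vals * diff, axis=2)
                bcoef = (
                    a[mu]
                    / m
                    * (1.0 - np.exp((m - t_col) / tmu) + np.exp(-t_col / tmu))
                )
                term2 = bcoef * np.sum(vals * (hi_c - lo_c), axis=2)
                integ = term1 + term2

        # degenerate conditioning window: m/tau -> 0 collapses both kernels to
        # a delta at 0, i.e. a * z(0); also covers baseline-only subjects under
        # the constant-association rule.
        tiny = m / tmu < _SMALL_M_OVER_TAU
        if np.any(tiny):
            base = np.broadcast_to(a[mu] * z0[None, :, mu], (K, N))
            if spec.baseline_only_rule == DECAYING_ASSOC:
                baseline_subj = s <= 0.0
                dec = base * np.exp(-t_col / tmu)
                base = np.where(baseline_subj[None, :], dec, base)
            integ = np.where(tiny, base, integ)
        out[:, :, mu] = integ
    return out
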