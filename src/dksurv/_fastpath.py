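"""Optional numba-accelerated evaluation of the cohort linear predictors.

Numerically identical to :func:`dksurv.kernels.batch_weighted_integrals`
(same shifted-exponent closed forms, same small-``m/tau`` Taylor guard), but
looping with early exits instead of padded broadcasting.  Falls back cleanly
when numba is unavailable: callers must check :data:`HAVE_NUMBA`.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional speed-up
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # noqa: D103
        def wrap(f):
            return f

        return wrap

_SMALL_M_OVER_TAU = 1e-12
FAMILY_A = 0
FAMILY_B = 1


@njit(cache=True)
def _lp_matrix(times, seg_lo, seg_hi, seg_val, s, z0, a, tau,
               family, decaying_rule):
    K = times.shape[0]
    N = s.shape[0]
    p = a.shape[0]
    S = seg_lo.shape[1]
    out = np.zeros((K, N))
    for j in range(N):
        sj = s[j]
        for k in range(K):
            t = times[k]
            m = sj if sj < t else t
            total = 0.0
            for mu in range(p):
                tmu = tau[mu]
                if m / tmu < _SMALL_M_OVER_TAU:
                    # delta-kernel / baseline-only limit: a * z(0)
                    val = a[mu] * z0[j, mu]
                    if decaying_rule and sj <= 0.0:
                        val *= np.exp(-t / tmu)
                    total += val
                    continue
                acc = 0.0
                wid = 0.0
                if family == FAMILY_A:
                    for l in range(S):
                        lo = seg_lo[j, l]
                        hi = seg_hi[j, l]
                        if hi <= lo or lo >= m:
                            break
                        if hi > m:
                            hi = m
                        acc += seg_val[j, mu, l] * (
                            np.exp((hi - m) / tmu) - np.exp((lo - m) / tmu)
                        )
                    total += a[mu] * acc / (-np.expm1(-m / tmu))
                else:
                    for l in range(S):
                        lo = seg_lo[j, l]
                        hi = seg_hi[j, l]
                        if hi <= lo or lo >= m:
                            break
                        if hi > m:
                            hi = m
                        acc += seg_val[j, mu, l] * (
                            np.exp((hi - t) / tmu) - np.exp((lo - t) / tmu)
                        )
                        wid += seg_val[j, mu, l] * (hi - lo)
                    bcoef = (
                        a[mu] / m
                        * (1.0 - np.exp((m - t) / tmu) + np.exp(-t / tmu))
                    )
                    total += a[mu] * acc + bcoef * wid
            out[k, j] = total
    return out


def lp_matrix(spec, times, seg_lo, seg_hi, seg_val, s, z0, decaying_rule):
    """(K, N) kernel-integral part of the linear predictors (families A/B)."""
    family = FAMILY_A if spec.family == "A" else FAMILY_B
    return _lp_matrix(
        np.ascontiguousarray(times, dtype=np.float64),
        seg_lo, seg_hi, seg_val, s, z0,
        spec.a.astype(np.float64), spec.tau.astype(np.float64),
        family, decaying_rule,
    )
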