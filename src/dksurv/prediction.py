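"""Dynamic survival prediction from a fitted delayed-kernel model.

Thin functional layer over :class:`~dksurv.model.DelayedKernelResults`.  The
predicted survival probability to horizon ``u``, conditional on survival to a
base time ``t`` and covariates observed up to the last visit at or before
``t``, is a product over the training event times in the risk interval:

    pi(u | Z_[0,t], t) = exp{ - sum_{t < T_j <= u, event} e^{LP_new(T_j)} / D_j }

where ``D_j`` is the Breslow risk-set denominator at ``T_j``.  The risk
interval is half-open at the left so that pi(t | ., t) = 1 exactly and an
event tied with the conditioning time does not contribute (we condition on
survival *past* t).
"""

from __future__ import annotations

import pandas as pd

from .data import Dataset, SubjectRecord
from .model import DelayedKernelResults

__all__ = [
    "dynamic_survival",
    "predict_at_base",
    "conditional_survival_from_censoring",
    "predict_table",
]


def dynamic_survival(results: DelayedKernelResults, subj: SubjectRecord, u: float) -> float:
    """pi(u | Z_[0,s], s): survival to u from the subject's last visit s."""
    return results.predict_survival(subj, u)


def predict_at_base(results: DelayedKernelResults, subj: SubjectRecord,
                    t: float, u: float) -> float:
    """pi(u | Z_[0,t], t): survival to u from an arbitrary base time t.

    Covariate integrals are truncated at the last visit at or before t, which
    also becomes the conditioning time of the kernels.
    """
    return results.predict_survival(subj, u, t)


def conditional_survival_from_censoring(results: DelayedKernelResults,
                                        subj: SubjectRecord,
                                        t: float, u: float) -> float:
    """pi(u | Z_[0,t], T_i): survival to u given survival to censoring time."""
    return results.conditional_survival_from_censoring(subj, t, u)


def predict_table(results: DelayedKernelResults, data: Dataset,
                  t: float, u: float) -> pd.DataFrame:
    """Per-subject predictions as a (id, t, u, pi_hat) table."""
    rows = [
        {"id": s.id, "t": t, "u": u,
         "pi_hat": results.predict_survival(s, u, t)}
        for s in data
        if s.event_time >= t
    ]
    return pd.DataFrame(rows, columns=["id", "t", "u", "pi_hat"])
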