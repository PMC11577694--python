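import numpy as np
import pytest
from hypothesis import settings

from dksurv import Dataset, SubjectRecord, SimConfig, simulate_joint_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_subject(sid, T, event, obs_times=(0.0,), values=None, fixed=()):
    obs_times = np.asarray(obs_times, dtype=float)
    if values is None:
        values = np.zeros((1, len(obs_times)))
    return SubjectRecord(id=sid, event_time=T, event=event,
                         obs_times=obs_times, values=values,
                         fixed=np.asarray(fixed, dtype=float))


@pytest.fixture
def toy3():
    """Three subjects, all events at 1, 2, 3, one zero covariate, no fixed."""
    subs = [make_subject(f"s{i}", T, 1) for i, T in enumerate([1.0, 2.0, 3.0])]
    return Dataset(subs, ["z1"], [])


@pytest.fixture(scope="session")
def constant_covariate_data():
    """Simulated cohort whose longitudinal covariate never changes in time."""
    cfg = SimConfig(n=200, eta1=0.0, sigma=0.0, D=((0.49, 0.0), (0.0, 0.0)))
    return simulate_joint_dataset(cfg, 42)


@pytest.fixture(scope="session")
def small_sim_data():
    """Small time-varying cohort for fitted-model behaviour tests."""
    return simulate_joint_dataset(SimConfig(n=120), 11)


def cox_nll_oracle(beta, X, T, delta):
    """Direct Breslow-ties Cox negative log partial likelihood.

    Independent of the package: plain loop over events with explicit
    risk-set sums.
    """
    beta = np.asarray(beta, dtype=float)
    lp = X @ beta
    nll = 0.0
    for i in range(len(T)):
        if delta[i] == 1:
            risk = lp[T >= T[i]]
            nll += np.log(np.sum(np.exp(risk))) - lp[i]
    return nll
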