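import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spmlong as sl

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spec():
    return sl.default_spec()


@pytest.fixture(scope="session")
def truth():
    return sl.default_true_params()


@pytest.fixture(scope="session")
def xmar_small(truth):
    """n=250 cohort with event-driven dropout; shared across read-only tests."""
    data, cohort = sl.simulate_cohort(
        sl.SimConfig(n=250, mechanism="xmar", seed=11), truth)
    return data, cohort


@pytest.fixture(scope="session")
def lmm_fit_small(xmar_small, spec):
    data, _ = xmar_small
    return sl.fit_lmm(data, spec)


@pytest.fixture(scope="session")
def spm_fit_small(xmar_small, spec):
    """Exponential-baseline joint fit with SEs on the n=250 cohort."""
    data, _ = xmar_small
    return sl.fit_spm(data, spec, sl.SPMOptions(baseline="exponential", seed=0))


def tiny_dataset(n_causes=1, with_events=True):
    """Hand-built 3-subject dataset used by exact-value tests."""
    subs = []
    ev = lambda t, s: sl.EventRecord(t, tuple(s)) if with_events else None
    subs.append(sl.SubjectRecord("a", np.array([1.0, 0.5]),
                                 np.array([0.0, 6.0, 20.0]),
                                 np.array([-0.1, -0.4, -1.2]),
                                 ev(25.0, [0] * n_causes)))
    status1 = [0] * n_causes; status1[0] = 1
    subs.append(sl.SubjectRecord("b", np.array([0.0, -0.3]),
                                 np.array([0.0, 6.0]),
                                 np.array([0.2, 0.1]),
                                 ev(9.0, status1)))
    subs.append(sl.SubjectRecord("c", np.array([1.0, 1.2]),
                                 np.array([0.0]),
                                 np.array([-0.8]),
                                 ev(4.0, [0] * n_causes)))
    return sl.PanelDataset(tuple(subs), ("x1", "x2"))


@pytest.fixture
def tiny_data():
    return tiny_dataset()
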