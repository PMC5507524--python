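import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from il6kin.crossval import kfold
from il6kin.presets import PARAMETER_SETS, PROTOCOLS
from il6kin.recovery import recovery_study
from il6kin.synth import DEFAULT_SCHEDULES, generate_series

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def d1_protocol():
    return PROTOCOLS["d1_ostrowski"]


@pytest.fixture(scope="session")
def stage1_params():
    """Cross-validation-winning parameter set, the synthetic ground truth."""
    return PARAMETER_SETS["d1_ostrowski"]


@pytest.fixture(scope="session")
def noiseless_suite(stage1_params):
    """Four exact model series, one per preset protocol, with the standard
    6.9% CV restored as the weighting model."""
    suite = []
    for name in PROTOCOLS:
        s = generate_series(
            PROTOCOLS[name], stage1_params, DEFAULT_SCHEDULES[name], assay_cv=0.0
        )
        suite.append(dataclasses.replace(s, assay_cv=0.069))
    return suite


@pytest.fixture(scope="session")
def noiseless_kfold(noiseless_suite):
    return kfold(noiseless_suite)


@pytest.fixture(scope="session")
def reference_recovery():
    """100 seeded replicates of the generate→fit→summarise study under the
    reference conditions (treadmill-run protocol, 17 samples, 6.9% CV)."""
    return recovery_study(n_replicates=100, seed=1)
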