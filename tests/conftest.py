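import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from isofoodweb import EndmemberSet, IsotopeMeasurement, Role, Tissue

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[
        HealthCheck.too_slow,
        # endmember fixtures are frozen dataclasses, safe to share across examples
        HealthCheck.function_scoped_fixture,
    ],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def em():
    """Mayfly/mussel-style endmembers: 8 per-mil d13c spread, unequal lambdas."""
    return EndmemberSet(
        d13c_littoral=-20.0,
        d13c_pelagic=-28.0,
        d15n_littoral=6.0,
        d15n_pelagic=4.0,
        lambda_littoral=2.25,
        lambda_pelagic=2.0,
        n_littoral=10,
        n_pelagic=10,
    )


@pytest.fixture
def em_equal_lambda():
    return EndmemberSet(
        d13c_littoral=-20.0,
        d13c_pelagic=-28.0,
        d15n_littoral=6.0,
        d15n_pelagic=4.0,
        lambda_littoral=2.0,
        lambda_pelagic=2.0,
    )


def make_measurement(
    sid,
    d13c,
    d15n,
    role=Role.CONSUMER,
    species="perch",
    tissue=Tissue.MUSCLE,
    season="fall",
    stratum="main",
):
    return IsotopeMeasurement(
        specimen_id=sid,
        species=species,
        role=role,
        tissue=tissue,
        season=season,
        stratum=stratum,
        d13c=d13c,
        d15n=d15n,
    )


@pytest.fixture
def baseline_cohort():
    """Two baseline specimens per habitat around the standard endmembers."""
    rng = np.random.default_rng(11)
    out = []
    for i in range(5):
        out.append(
            make_measurement(
                f"lb{i}", -20.0 + rng.normal(0, 0.3), 6.0 + rng.normal(0, 0.3),
                role=Role.LITTORAL_BASELINE, species="mayfly", tissue=Tissue.WHOLE,
            )
        )
        out.append(
            make_measurement(
                f"pb{i}", -28.0 + rng.normal(0, 0.3), 4.0 + rng.normal(0, 0.3),
                role=Role.PELAGIC_BASELINE, species="mussel", tissue=Tissue.WHOLE,
            )
        )
    return out
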