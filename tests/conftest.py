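import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cnsync import ReleaseCurve
from cnsync.kinetics import INTESTINAL_SCHEDULE

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_curve(values, times=(0.0, 20.0, 60.0), *, substrate="diet1",
               nutrient="glucose", replicate=1, phase="intestinal",
               unit="g/kg") -> ReleaseCurve:
    """Single-phase curve helper used across the suite."""
    return ReleaseCurve(
        substrate_id=substrate, nutrient=nutrient, replicate=replicate,
        phases=(phase,) * len(times), times=np.asarray(times, dtype=float),
        cumulative=np.asarray(values, dtype=float), unit=unit,
    )


@pytest.fixture
def simple_curve():
    return make_curve([0.0, 12.0, 30.0])


@pytest.fixture
def full_schedule_curve():
    # saturating shape on the full intestinal sampling schedule
    t = np.array(INTESTINAL_SCHEDULE)
    return make_curve(150.0 * -np.expm1(-0.02 * t), times=t)
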