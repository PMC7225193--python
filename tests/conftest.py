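import numpy as np
import pytest

from rrtpk.core import PKParameters, RRTSettings
from rrtpk.odes import EventKind, EventRecord


@pytest.fixture
def cvvhd() -> RRTSettings:
    """Reference CVVHD circuit: Q_blood 10 L/h, Hct 0.3, Q_dial 3 L/h."""
    return RRTSettings(Q_blood=10.0, Hct=0.3, Q_dial=3.0)


@pytest.fixture
def pip_params() -> PKParameters:
    """Piperacillin-like subject with circuit clearance equal to body clearance."""
    return PKParameters(CL_body=3.0, V_cent=22.0, CL_RRT=3.0)


def dosing_events(sid="1", amount=4000.0, interval=8.0, n_doses=5, duration=0.5,
                  bag_changes=(0.0, 32.0)):
    events = [
        EventRecord(sid, k * interval, EventKind.DOSE, amount=amount, duration=duration)
        for k in range(n_doses)
    ]
    events += [EventRecord(sid, t, EventKind.BAG_CHANGE) for t in bag_changes]
    return events


@pytest.fixture
def pip_events():
    return dosing_events()
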