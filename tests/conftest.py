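import numpy as np
import pytest

import reachtrack as rt


@pytest.fixture(scope="session")
def camera():
    return rt.CameraModel()


@pytest.fixture(scope="session")
def marker():
    return rt.MarkerSpec()


@pytest.fixture(scope="session")
def protocol():
    return rt.Protocol()


@pytest.fixture(scope="session")
def calib(camera, marker):
    """Calibration from a clean rendered frame (shared; it is expensive)."""
    frame = rt.render_frame((376.0, 240.0), camera, marker)
    return rt.calibrate_threshold(frame, marker.circle_radius_px(camera))


@pytest.fixture(scope="session")
def noiseless_sim(protocol, camera):
    """One noiseless trial at the trained speed."""
    return rt.simulate_trial(rt.SubjectParams(speed_mult=1.0),
                             protocol, camera, seed=0)


@pytest.fixture(scope="session")
def noiseless_table(noiseless_sim, protocol):
    records, _ = rt.trial_metrics(noiseless_sim.series, protocol,
                                  participant_id="S001", trial=1, age=70.0)
    return rt.records_to_table(records)
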