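import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from amtc.datamodel import StimulusKind, StimulusSpec, TrialSpikes, UnitRecording

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def am50() -> StimulusSpec:
    """Standard 50-Hz AM condition of the study protocol."""
    return StimulusSpec(
        condition_id="am50", kind=StimulusKind.AM, carrier_hz=11310.0,
        mod_hz=50.0, depth=1.0, duration_ms=500.0, n_trials=15,
        prestim_ms=500.0,
    )


def make_unit(spike_lists, condition_id="am50", unit_id="u0", group="wt",
              bf=None) -> UnitRecording:
    """Build a UnitRecording from a list of per-trial spike-time lists."""
    rec = UnitRecording(unit_id=unit_id, group=group, best_frequency_hz=bf)
    rec.trials[condition_id] = [
        TrialSpikes(unit_id, condition_id, k, np.asarray(t, float))
        for k, t in enumerate(spike_lists)
    ]
    return rec
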