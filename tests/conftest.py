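import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_forcing():
    """One realization of the default 15-component forcing at 1 kHz."""
    from varvent.fot_mechanics import ForcingDesign, design_forcing_signal
    design = ForcingDesign()
    t, x, phases = design_forcing_signal(design, sampling_rate=1000.0, seed=11)
    return design, t, x


@pytest.fixture(scope="session")
def pvv_pattern():
    """A 382-breath pattern built through the full recording pipeline.

    Four 10-minute synthetic recordings (one per 'animal') are pooled, as in
    the plethysmography protocol, then normalized.
    """
    from varvent.breath_pattern import (build_pvv_pattern, detect_breaths,
                                        remove_artifact_segments)
    from varvent.synthetic_data import (BreathingSimParams,
                                        generate_spontaneous_breathing)
    breaths = []
    for seed in range(4):
        params = BreathingSimParams(seed=seed, sampling_rate=250.0)
        rec, _ = generate_spontaneous_breathing(params, duration_s=600.0)
        clean = remove_artifact_segments(rec, detect=True)
        breaths.extend(detect_breaths(clean))
    return build_pvv_pattern(breaths, n_breaths=382)
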