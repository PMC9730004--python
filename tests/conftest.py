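import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import delayrep as dr

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def interval_set():
    return dr.build_interval_set(640.0, 0.15, 3)


@pytest.fixture(scope="session")
def small_exp2_dataset():
    """20 homogeneous-prior observers on the blocked 0.4/2/8 s design."""
    spec = dr.design_presets()["exp2"]
    spec.n_participants = 20
    spec.seed = 11
    pop = dr.PopulationSpec(seed=12)
    data, truth = dr.simulate_dataset(spec)
    return data, truth


@pytest.fixture(scope="session")
def tiny_mixed_dataset():
    """6 observers on the interleaved-retention design (fast fixture)."""
    spec = dr.design_presets()["exp3"]
    spec.n_participants = 6
    spec.seed = 21
    data, truth = dr.simulate_dataset(spec, dr.PopulationSpec(seed=22))
    return data, truth


def make_veridical(n_participants=3, seed=0):
    """Trials where reproduction equals the sample exactly."""
    spec = dr.design_presets()["exp1"]
    spec.n_participants = n_participants
    spec.seed = seed
    data = dr.generate_schedule(spec)
    data["reproduced_ms"] = data["sample_ms"]
    return data
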