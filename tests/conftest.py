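import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cueweight.design import standard_design
from cueweight.observer import belief_trajectories
from cueweight.preprocess import filter_trials
from cueweight.response import ResponseParams
from cueweight.simulate import GroundTruth, simulate_subject

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def exp1_design():
    return standard_design("exp1")


@pytest.fixture(scope="session")
def exp3_design():
    return standard_design("exp3")


@pytest.fixture(scope="session")
def noiseless_params():
    return ResponseParams(2.2, 0.5, 2.0, 0.5, 1e-6)


@pytest.fixture(scope="session")
def study_params():
    return ResponseParams(2.2, 0.5, 2.0, 0.5, 0.2)


def make_labeled_subject(design, w, params, seed=3, **kwargs):
    """Simulate one subject, attach beliefs, apply exclusion."""
    truth = GroundTruth("S00", w, params, **kwargs)
    table = simulate_subject(design, truth, seed=seed)
    return filter_trials(belief_trajectories(table))


@pytest.fixture(scope="session")
def toy_records():
    """Hand-built 10-trial table exercising every exclusion reason.

    1 incorrect, 1 miss, 1 anticipation (90 ms), and 7 correct trials
    of which the 1200 ms one deviates far from the rest.
    """
    rts = [400.0, 410.0, 390.0, 405.0, 395.0, 402.0, 1200.0]
    rows = []
    for i, rt in enumerate(rts):
        rows.append(
            {
                "subject_id": "S00",
                "modality": "visual" if i % 2 == 0 else "tactile",
                "rt_ms": rt,
                "response": "proximal",
                "correct": True,
            }
        )
    rows.append(
        {"subject_id": "S00", "modality": "visual", "rt_ms": 500.0,
         "response": "distal", "correct": False}
    )
    rows.append(
        {"subject_id": "S00", "modality": "tactile", "rt_ms": np.nan,
         "response": "none", "correct": False}
    )
    rows.append(
        {"subject_id": "S00", "modality": "visual", "rt_ms": 90.0,
         "response": "proximal", "correct": True}
    )
    return pd.DataFrame(rows)
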