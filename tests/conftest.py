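import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gaitsym.events import detect_events, segment_steps
from gaitsym.parameters import compute_mfc, compute_step_metrics
from gaitsym.pipeline import PipelineConfig, preprocess_trial
from gaitsym.synthetic import SubjectGaitSpec, simulate_trial

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# generator/pipeline warnings (skipped edge swings) are expected in bulk runs
logging.getLogger("gaitsym").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def synthetic_config() -> PipelineConfig:
    """Pipeline settings for synthetic data: floor at z=0, marker on floor."""
    return PipelineConfig(simulate=True, ground_ref="absolute")


@pytest.fixture(scope="session")
def clean_walk(synthetic_config):
    """One noise-free default subject: trial, truth and all derived stages."""
    trial, truth = simulate_trial(SubjectGaitSpec(), seed=1)
    filtered = preprocess_trial(trial, synthetic_config.filter_spec(trial.fs))
    events = detect_events(filtered, config=synthetic_config.event_config())
    steps = segment_steps(events, trial.fs)
    step_records = compute_step_metrics(filtered, steps)
    swing_records = compute_mfc(filtered, events, ground_ref="absolute")
    return {
        "trial": trial, "truth": truth, "filtered": filtered,
        "events": events, "steps": steps,
        "step_records": step_records, "swing_records": swing_records,
    }


def match_events(detected: np.ndarray, truth_frames: np.ndarray) -> np.ndarray:
    """Signed frame error of the nearest detected event for each truth event."""
    return np.array([detected[np.argmin(np.abs(detected - f))] - f
                     for f in truth_frames])
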