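import logging

import numpy as np
import pytest

from gaitsym.errors import InsufficientEventsError, NoStepsError
from gaitsym.events import GaitEvents, detect_events, segment_steps
from gaitsym.io import MARKERS, TrialTrajectories
from gaitsym.pipeline import preprocess_trial
from gaitsym.synthetic import SubjectGaitSpec, simulate_trial

from conftest import match_events


def test_noise_free_events_within_one_frame(clean_walk):
    truth, events = clean_walk["truth"], clean_walk["events"]
    for foot in "LR":
        for kind, det in (("heel_contact", events.heel_contacts[foot]),
                          ("toe_off", events.toe_offs[foot])):
            errs = match_events(det, truth.interior_events(foot, kind))
            assert np.abs(errs).max() <= 1, (foot, kind)


def test_event_sensitivity_and_precision_on_noisy_trials(synthetic_config):
    """Detection matches truth within 30 ms at >= 0.98 sensitivity/precision
    across marker noise levels 0-2 mm RMS."""
    for noise in (0.0, 0.001, 0.002):
        trial, truth = simulate_trial(
            SubjectGaitSpec(marker_noise_rms=noise), seed=31)
        filtered = preprocess_trial(trial, synthetic_config.filter_spec(100.0))
        events = detect_events(filtered, config=synthetic_config.event_config())
        for foot in "LR":
            for kind, det in (("heel_contact", events.heel_contacts[foot]),
                              ("toe_off", events.toe_offs[foot])):
                tru = truth.interior_events(foot, kind)
                matched_t = sum(np.abs(det - f).min() <= 3 for f in tru)
                matched_d = sum(
                    min(abs(d - f) for f in
                        (truth.heel_contacts if kind == "heel_contact"
                         else truth.toe_offs)[foot]) <= 3
                    for d in det
                )
                assert matched_t / len(tru) >= 0.98, (noise, foot, kind)
                assert matched_d / len(det) >= 0.98, (noise, foot, kind)


def test_stationary_markers_raise(synthetic_config):
    frames = 600
    positions = {m: np.tile([0.1 * i, 0.05, 0.02], (frames, 1))
                 for i, m in enumerate(MARKERS)}
    trial = TrialTrajectories("s", "t", 100.0, positions)
    with pytest.raises(InsufficientEventsError):
        detect_events(trial, config=synthetic_config.event_config())


def test_events_invariant_under_horizontal_translation(clean_walk,
                                                       synthetic_config):
    trial = clean_walk["trial"].copy()
    for m in MARKERS:
        trial.positions[m][:, 0] += 12.0
        trial.positions[m][:, 1] -= 3.0
    filtered = preprocess_trial(trial, synthetic_config.filter_spec(100.0))
    events = detect_events(filtered, config=synthetic_config.event_config())
    ref = clean_walk["events"]
    for foot in "LR":
        np.testing.assert_array_equal(events.heel_contacts[foot],
                                      ref.heel_contacts[foot])
        np.testing.assert_array_equal(events.toe_offs[foot],
                                      ref.toe_offs[foot])


def test_step_segmentation_alternates_and_counts(clean_walk):
    steps = clean_walk["steps"]
    events = clean_walk["events"]
    for a, b in zip(steps[:-1], steps[1:]):
        assert a.leading_foot != b.leading_foot
    n_contacts = sum(len(events.heel_contacts[f]) for f in "LR")
    assert len(steps) <= n_contacts - 1
    # default 36-step subject clears the 30-complete-step-cycles rule
    assert len(steps) >= 30


def test_alternating_toy_events_give_expected_steps():
    ev = GaitEvents(fs=100.0,
                    heel_contacts={"L": np.array([100, 220]),
                                   "R": np.array([160])},
                    toe_offs={"L": np.array([172]), "R": np.array([232])})
    steps = segment_steps(ev, 100.0)
    assert [s.leading_foot for s in steps] == ["R", "L"]
    assert steps[0].trail_heel_contact == 100
    assert steps[0].trail_toe_off == 172
    assert steps[1].trail_toe_off == 232


def test_missed_contact_drops_step_with_warning(caplog):
    ev = GaitEvents(fs=100.0,
                    heel_contacts={"L": np.array([100, 220, 330]),
                                   "R": np.array([275])},
                    toe_offs={"L": np.array([287]), "R": np.array([342])})
    with caplog.at_level(logging.WARNING, logger="gaitsym.events"):
        steps = segment_steps(ev, 100.0)
    assert any("consecutive" in r.message for r in caplog.records)
    assert [s.leading_foot for s in steps] == ["R", "L"]


def test_no_valid_steps_raises():
    ev = GaitEvents(fs=100.0,
                    heel_contacts={"L": np.array([100, 220]),
                                   "R": np.array([], dtype=int)},
                    toe_offs={"L": np.array([], dtype=int),
                              "R": np.array([], dtype=int)})
    with pytest.raises(NoStepsError):
        segment_steps(ev, 100.0)


def test_events_export_table(clean_walk):
    table = clean_walk["events"].to_frame_table()
    assert list(table.columns) == ["foot", "event_type", "frame", "time_s"]
    assert (table["frame"].diff().dropna() >= 0).all()
    assert set(table["event_type"]) == {"heel_contact", "toe_off"}
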