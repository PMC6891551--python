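import numpy as np
import pytest

from gaitsym.errors import SideMissingError
from gaitsym.events import GaitEvents, StepInterval
from gaitsym.io import MARKERS, TrialTrajectories
from gaitsym.parameters import (SwingRecord, compute_mfc, compute_step_metrics,
                                StepRecord, summarize_subject)


def _constant_trial(lhe, rhe, frames=300, fs=100.0):
    positions = {
        "L_HEEL": np.tile(lhe, (frames, 1)).astype(float),
        "R_HEEL": np.tile(rhe, (frames, 1)).astype(float),
        "L_TOE": np.tile(np.add(lhe, [0.15, 0, 0]), (frames, 1)).astype(float),
        "R_TOE": np.tile(np.add(rhe, [0.15, 0, 0]), (frames, 1)).astype(float),
    }
    return TrialTrajectories("s", "t", fs, positions)


def test_step_metrics_hand_computed_displacements():
    # lead (R) heel at (3.200, 0.060, 0.02), trail (L) at (2.540, -0.062, 0.03)
    trial = _constant_trial([2.540, -0.062, 0.03], [3.200, 0.060, 0.02])
    step = StepInterval(leading_foot="R", trail_heel_contact=80,
                        lead_heel_contact=100, trail_toe_off=112)
    (rec,) = compute_step_metrics(trial, [step])
    assert rec.step_length == pytest.approx(0.660, abs=1e-12)
    assert rec.step_width == pytest.approx(0.122, abs=1e-12)
    assert rec.double_support == pytest.approx(0.12, abs=1e-12)


def test_backward_step_dropped_with_warning(caplog):
    trial = _constant_trial([3.200, -0.06, 0.03], [2.540, 0.06, 0.02])
    step = StepInterval("R", 80, 100, 112)  # R heel behind L heel
    with caplog.at_level("WARNING", logger="gaitsym.parameters"):
        records = compute_step_metrics(trial, [step])
    assert records == []
    assert any("nonpositive step length" in r.message for r in caplog.records)


def _swing_trial(toe_z_segment, toe_off=50, fs=100.0):
    frames = toe_off + len(toe_z_segment) + 100
    positions = {m: np.zeros((frames, 3)) for m in MARKERS}
    positions["L_TOE"][toe_off:toe_off + len(toe_z_segment), 2] = toe_z_segment
    trial = TrialTrajectories("s", "t", fs, positions)
    hc = toe_off + len(toe_z_segment) - 1
    events = GaitEvents(fs=fs,
                        heel_contacts={"L": np.array([0, hc]),
                                       "R": np.array([0, hc])},
                        toe_offs={"L": np.array([toe_off]),
                                  "R": np.array([], dtype=int)})
    return trial, events


def brute_force_window_min(toe_z, toe_off, hc, window=(0.2, 0.8)):
    """Independent oracle: scan every sample in the mid-swing window for the
    lowest strict interior local minimum."""
    dur = hc - toe_off
    lo = toe_off + int(np.ceil(window[0] * dur))
    hi = toe_off + int(np.floor(window[1] * dur))
    best = None
    for i in range(lo + 1, hi):
        if toe_z[i] < toe_z[i - 1] and toe_z[i] <= toe_z[i + 1]:
            if best is None or toe_z[i] < toe_z[best]:
                best = i
    return best


def test_mfc_selects_lowest_of_two_window_minima():
    # two local minima: 2.0 cm at 30 % and 1.2 cm at 60 % of a 100-frame swing
    s = np.linspace(0, 1, 101)
    seg = (0.05 * np.exp(-((s - 0.15) / 0.08) ** 2)
           + 0.020 + 0.02 * ((s - 0.30) / 0.2) ** 2)
    seg = np.minimum(seg, 0.012 + 0.05 * ((s - 0.60) / 0.25) ** 2)
    seg[0] = seg[-1] = 0.0
    trial, events = _swing_trial(seg)
    (rec,) = compute_mfc(trial, events, ground_ref="absolute")
    toe_z = trial.marker("L_TOE", 2)
    oracle = brute_force_window_min(toe_z, 50, 50 + len(seg) - 1)
    assert rec.mfc_frame == oracle
    assert rec.mfc == pytest.approx(toe_z[oracle] * 100, abs=1e-9)
    assert rec.mfc == pytest.approx(1.2, abs=0.05)


def test_monotone_swing_yields_no_record(caplog):
    seg = np.linspace(0.05, 0.0, 60)  # toe only descends: no interior minimum
    trial, events = _swing_trial(seg)
    with caplog.at_level("WARNING", logger="gaitsym.parameters"):
        records = compute_mfc(trial, events, ground_ref="absolute")
    assert records == []
    assert any("no interior" in r.message for r in caplog.records)


def test_too_short_swing_skipped(caplog):
    seg = np.array([0.0, 0.01, 0.02, 0.01, 0.02, 0.0])
    trial, events = _swing_trial(seg)
    with caplog.at_level("WARNING", logger="gaitsym.parameters"):
        assert compute_mfc(trial, events, ground_ref="absolute") == []


def test_midstance_reference_absorbs_marker_offset(clean_walk,
                                                   synthetic_config):
    """Raising every toe marker by a constant offset must not change the
    clearance when the mid-stance reference is used."""
    filtered = clean_walk["filtered"].copy()
    base = compute_mfc(filtered, clean_walk["events"],
                       ground_ref="midstance_median")
    lifted = filtered.copy()
    for m in ("L_TOE", "R_TOE"):
        lifted.positions[m][:, 2] += 0.018
    shifted = compute_mfc(lifted, clean_walk["events"],
                          ground_ref="midstance_median")
    assert len(base) == len(shifted)
    for a, b in zip(base, shifted):
        assert b.mfc == pytest.approx(a.mfc, abs=1e-6)


def _records(side_values, foot="R"):
    return [StepRecord(foot, v, 0.12, 0.10) for v in side_values]


def test_summary_hand_computed_mean_and_sample_sd():
    right = _records([0.66, 0.68, 0.64, 0.66], "R")
    left = _records([0.65, 0.65, 0.65, 0.65], "L")
    swings = [SwingRecord("R", 1.5, 10), SwingRecord("L", 1.5, 60),
              SwingRecord("R", 1.7, 110), SwingRecord("L", 1.6, 160)]
    summary = summarize_subject("s", right + left, swings, min_steps=5)
    assert summary.side_mean["R"]["step_length"] == pytest.approx(0.660)
    # sample SD (n-1): sqrt(((0)^2+(.02)^2+(-.02)^2+0)/3) = 0.016330
    assert summary.side_sd["R"]["step_length"] == pytest.approx(0.0163, abs=5e-5)
    assert summary.side_sd["L"]["step_length"] == 0.0
    assert summary.included


def test_pooled_mean_between_side_means(clean_walk):
    summary = summarize_subject("s", clean_walk["step_records"],
                                clean_walk["swing_records"])
    for p in ("step_length", "step_width", "double_support", "mfc"):
        lo = min(summary.side_mean["L"][p], summary.side_mean["R"][p])
        hi = max(summary.side_mean["L"][p], summary.side_mean["R"][p])
        assert lo <= summary.pooled_mean[p] <= hi


def test_below_min_steps_flagged_not_included():
    right = _records([0.66] * 15, "R")
    left = _records([0.66] * 14, "L")
    swings = [SwingRecord("R", 1.5, 1), SwingRecord("L", 1.5, 2)]
    summary = summarize_subject("s", right + left, swings, min_steps=30)
    assert summary.total_steps == 29
    assert not summary.included


def test_missing_side_raises():
    with pytest.raises(SideMissingError):
        summarize_subject("s", _records([0.66, 0.67], "R"),
                          [SwingRecord("R", 1.5, 1), SwingRecord("L", 1.5, 2)])


def test_noise_free_recovery_against_ground_truth(clean_walk):
    """Detected step metrics match the generator's per-step truth within
    5 mm (lengths/widths), 10 ms (double support), 0.05 mm (per-swing MFC
    bias under 0.5 mm)."""
    truth = clean_walk["truth"]
    tsteps = {s.lead_heel_contact: s for s in truth.steps}
    dl, dw, dd = [], [], []
    for iv, rec in zip(clean_walk["steps"], clean_walk["step_records"]):
        t = next((tsteps.get(iv.lead_heel_contact + off)
                  for off in (0, -1, 1, -2, 2)
                  if tsteps.get(iv.lead_heel_contact + off)), None)
        assert t is not None
        dl.append(rec.step_length - t.step_length)
        dw.append(rec.step_width - t.step_width)
        dd.append(rec.double_support - t.double_support)
    assert abs(np.mean(dl)) < 0.005
    assert abs(np.mean(dw)) < 0.005
    assert abs(np.mean(dd)) < 0.010
    dm = []
    for rec in clean_walk["swing_records"]:
        t = min(truth.swings, key=lambda s: abs(s.mfc_frame - rec.mfc_frame))
        if abs(t.mfc_frame - rec.mfc_frame) <= 5:
            dm.append(rec.mfc - t.mfc_m * 100)
    assert abs(np.mean(dm)) < 0.05  # cm
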