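import dataclasses

import numpy as np
import pytest

from gaitsym.errors import SpecError
from gaitsym.parameters import summarize_subject
from gaitsym.symmetry import score_ghq12, si_features
from gaitsym.synthetic import (CohortSpec, ParamCoupling, SideParams,
                               SubjectGaitSpec, simulate_cohort,
                               simulate_trial)


def truth_feature_rows(cohort):
    """SI features and GHQ totals computed from exact ground-truth records."""
    rows = []
    for s in cohort.subjects:
        summary = summarize_subject(s.subject_id, s.truth.step_records(),
                                    s.truth.swing_records())
        row = si_features(summary).as_dict()
        row["ghq_total"] = score_ghq12(s.ghq).total
        rows.append(row)
    return rows


def test_same_seed_gives_bit_identical_trajectories():
    spec = SubjectGaitSpec(marker_noise_rms=0.001)
    t1, g1 = simulate_trial(spec, 5)
    t2, g2 = simulate_trial(spec, 5)
    for m in t1.positions:
        np.testing.assert_array_equal(t1.positions[m], t2.positions[m])
    np.testing.assert_array_equal(g1.heel_contacts["L"], g2.heel_contacts["L"])
    t3, _ = simulate_trial(spec, 6)
    assert not np.array_equal(t3.positions["L_HEEL"], t1.positions["L_HEEL"])


def test_invalid_specs_rejected():
    with pytest.raises(SpecError):
        simulate_trial(SubjectGaitSpec(fs=0.0), 1)
    with pytest.raises(SpecError):
        simulate_trial(SubjectGaitSpec(
            left=SideParams(mfc=0.05)), 1)  # above the early swing peak
    with pytest.raises(SpecError):
        simulate_trial(SubjectGaitSpec(
            right=SideParams(double_support=-0.1)), 1)
    with pytest.raises(SpecError):
        CohortSpec(n_subjects=1).validate()


@pytest.mark.parametrize("seed", [2, 9])
def test_every_swing_has_unique_interior_minimum(seed):
    """The raw rendered toe-height curve has exactly one strict local
    minimum inside 20-80 % of each swing, at the programmed clearance."""
    trial, truth = simulate_trial(SubjectGaitSpec(), seed)
    for s in truth.swings:
        toe_z = trial.marker(f"{s.foot}_TOE", 2)
        dur = s.heel_contact - s.toe_off
        lo = s.toe_off + int(np.ceil(0.2 * dur))
        hi = s.toe_off + int(np.floor(0.8 * dur))
        seg = toe_z[lo:hi + 1]
        minima = np.flatnonzero((seg[1:-1] < seg[:-2])
                                & (seg[1:-1] <= seg[2:])) + 1
        assert len(minima) == 1, (s.foot, s.toe_off)
        assert lo + minima[0] == s.mfc_frame
        assert seg[minima[0]] == pytest.approx(s.mfc_m, abs=1e-9)


def test_ground_truth_step_count_and_ordering():
    trial, truth = simulate_trial(SubjectGaitSpec(n_steps=36), 7)
    assert len(truth.steps) >= 30
    for s in truth.steps:
        assert s.trail_heel_contact < s.lead_heel_contact < s.trail_toe_off
        assert 0 < s.step_length < 1.2
        assert s.double_support > 0
    for foot in "LR":
        assert (np.diff(truth.heel_contacts[foot]) > 0).all()


def test_ghq_totals_match_calibration_target():
    # totals should sit near the calibrated mean 1.563 / SD 2.080
    cohort = simulate_cohort(CohortSpec(n_subjects=1500), 21, render=False)
    totals = np.array([score_ghq12(s.ghq).total for s in cohort.subjects])
    assert totals.min() >= 0 and totals.max() <= 12
    assert totals.mean() == pytest.approx(1.563, abs=0.2)
    assert totals.std(ddof=1) == pytest.approx(2.080, abs=0.25)


def test_null_cohort_si_features_uncorrelated_with_ghq():
    cohort = simulate_cohort(CohortSpec.null(n_subjects=126), 17, render=False)
    rows = truth_feature_rows(cohort)
    ghq = np.array([r["ghq_total"] for r in rows])
    for key in rows[0]:
        if key == "ghq_total":
            continue
        r = np.corrcoef([row[key] for row in rows], ghq)[0, 1]
        assert abs(r) < 0.25, key


def test_stronger_coupling_raises_expected_correlation():
    """Mean SI-GHQ correlation increases monotonically over a 3-point
    coupling grid (20 seeds per grid point), here for step width."""
    grid = (0.0, 0.05, 0.10)
    means = []
    for beta in grid:
        coupling = {
            p: dataclasses.replace(c, beta_mean=beta if p == "step_width"
                                   else 0.0, beta_sd=0.0)
            for p, c in CohortSpec().coupling.items()
        }
        spec = CohortSpec(n_subjects=126, coupling=coupling)
        rs = []
        for seed in range(20):
            cohort = simulate_cohort(spec, 900 + seed, render=False)
            rows = truth_feature_rows(cohort)
            ghq = np.array([r["ghq_total"] for r in rows])
            rs.append(np.corrcoef([r["step_width_si_mean"] for r in rows],
                                  ghq)[0, 1])
        means.append(np.mean(rs))
    assert means[0] < means[1] < means[2]


def test_cohort_latent_drives_ghq_probability():
    cohort = simulate_cohort(CohortSpec(n_subjects=300), 13, render=False)
    rows = truth_feature_rows(cohort)
    ghq = np.array([r["ghq_total"] for r in rows])
    r = np.corrcoef(cohort.latent_scores, ghq)[0, 1]
    assert r > 0.6
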