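"""Synthetic overground-walking cohort generator with exact ground truth.

The generator emulates the cohort protocol the pipeline is built for:
straight overground passes at preferred pace sampled at 100 Hz with
heel/toe markers on both feet, enough step cycles per subject to clear a
30-cycle inclusion rule, and a GHQ-12 questionnaire per subject.  It is
an *event-schedule* simulator, not a musculoskeletal model: per-step
parameters (step time, step length, step width, double support, minimum
foot clearance) are drawn first, the event timeline is quantized to the
frame grid, and marker trajectories are then rendered as monotone cubic
(PCHIP) curves through physiologic control points.  Ground truth —
event frames, per-step parameters, per-swing clearance minima — is
therefore exact by construction.

Cohort structure: a standard-normal latent mental-health burden ``m``
per subject drives (i) the left-right asymmetry of each gait parameter's
mean and stride-to-stride SD through linear couplings, and (ii) the
agree-probability of the 12 GHQ items through a logistic link whose
constants are calibrated so simulated totals have mean ≈ 1.56 and
SD ≈ 2.08.  With all couplings zero the cohort is an exact null for the
association stage.

All randomness flows from one seed: subject streams are spawned from a
``numpy`` ``SeedSequence`` by subject index, so cohorts are bit
reproducible and individual subjects can be re-simulated in isolation.

Toe-swing shape: during each swing the toe height rises to an early-swing
peak, descends to the programmed clearance minimum placed at 55 % of
swing time (snapped to the frame grid), rises to a late-swing peak and
returns to ground at heel contact — the classic double-peak toe
trajectory whose mid-swing local minimum is the MFC.  Near every ground
contact and toe-off the height curve is locally parabolic and symmetric
over ±50 ms, which keeps zero-phase filtering from biasing event timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import SpecError
from .io import MARKERS, GHQResponse, TrialTrajectories
from .parameters import StepRecord, SwingRecord

__all__ = [
    "SideParams", "SubjectGaitSpec", "ParamCoupling", "CohortSpec",
    "TrialGroundTruth", "SyntheticSubject", "SyntheticCohort",
    "simulate_trial", "simulate_cohort",
]

#: GHQ item logistic link, calibrated so totals match mean 1.563 / SD 2.080.
GHQ_INTERCEPT = -2.5372
GHQ_SLOPE = 1.4436

# rendering constants (seconds / meters / m s^-2)
_HEEL_ACCEL = 2.4         # curvature of the heel touchdown parabola
_TOE_ACCEL = 2.3          # curvature of the toe touchdown / toe-off parabolas
_VALLEY_ACCEL = 1.2       # curvature of the mid-swing clearance valley
_LEAD_IN_S = 0.25         # time before the first real heel contact
_TAIL_S = 0.5             # time after the last real heel contact
_N_VIRTUAL = 4            # hidden steps prepended / 2 appended for continuity


@dataclass(frozen=True)
class SideParams:
    """Per-side gait parameter means and stride-to-stride SDs.

    Defaults reproduce a healthy older-adult cohort walking at preferred
    pace: 0.657 m steps 0.121 m apart, 99 ms double support, 1.67 cm
    minimum foot clearance, ~109 steps/min cadence.
    """

    step_length: float = 0.657      # m
    step_width: float = 0.121       # m
    double_support: float = 0.099   # s
    mfc: float = 0.01667            # m
    step_time: float = 0.55         # s
    step_length_sd: float = 0.036
    step_width_sd: float = 0.030
    double_support_sd: float = 0.019
    mfc_sd: float = 0.00447
    step_time_sd: float = 0.02


@dataclass(frozen=True)
class SubjectGaitSpec:
    """One subject's walking blueprint for :func:`simulate_trial`."""

    left: SideParams = SideParams()
    right: SideParams = SideParams()
    fs: float = 100.0
    n_steps: int = 36               # real steps rendered (>= 30-cycle rule)
    marker_noise_rms: float = 0.0   # white noise per coordinate, m
    foot_length: float = 0.15       # toe marker leads heel marker by this, m
    early_swing_peak: float = 0.030  # toe height after toe-off, m
    late_swing_peak: float = 0.030   # toe height before contact, m
    heel_swing_peak: float = 0.13    # heel height in swing, m

    def side(self, s: str) -> SideParams:
        return self.left if s == "L" else self.right

    def validate(self) -> None:
        if self.fs <= 0:
            raise SpecError(f"fs must be positive, got {self.fs}")
        if self.n_steps < 4:
            raise SpecError(f"need at least 4 steps, got {self.n_steps}")
        if self.marker_noise_rms < 0:
            raise SpecError("marker_noise_rms must be nonnegative")
        # the late peak adapts to the drawn clearance (always above it),
        # so only the early-swing peak bounds the programmable MFC
        peak = self.early_swing_peak
        for s in "LR":
            p = self.side(s)
            for name in ("step_length", "step_width", "double_support",
                         "mfc", "step_time"):
                if getattr(p, name) <= 0:
                    raise SpecError(f"{s}.{name} must be positive")
            if p.mfc >= peak - 0.004:
                raise SpecError(
                    f"{s}.mfc={p.mfc} too close to the early swing peak "
                    f"({peak}); no interior minimum guaranteed"
                )


@dataclass(frozen=True)
class ParamCoupling:
    """Latent-score coupling of one parameter's left-right asymmetry.

    Relative mean asymmetry of subject i is
    ``delta_i = base_asym + beta_mean * m_i + N(0, asym_sd)`` with
    ``R = value*(1 + delta/2)``, ``L = value*(1 - delta/2)``; the
    stride-to-stride SD asymmetry follows the same form with the ``sd_``
    fields.  ``beta_* = 0`` gives an exact null.
    """

    base_asym: float
    beta_mean: float = 0.10
    asym_sd: float = 0.04
    base_sd_asym: float = 0.20
    beta_sd: float = 0.40
    sd_asym_sd: float = 0.10


def _default_coupling() -> dict[str, ParamCoupling]:
    # baseline mean asymmetries at the observed cohort scale
    # beta_sd for double support and MFC compensates the stronger
    # measurement attenuation of their SD estimates (timing quantization,
    # clearance extraction error), keeping the realized SD-SI correlations
    # at the same scale as the mean-SI ones
    return {
        "step_length": ParamCoupling(base_asym=0.059),
        "step_width": ParamCoupling(base_asym=0.148),
        "double_support": ParamCoupling(base_asym=0.097, beta_sd=0.52,
                                        base_sd_asym=0.30),
        "mfc": ParamCoupling(base_asym=0.257, beta_sd=0.62,
                             base_sd_asym=0.32),
    }


def _null_coupling() -> dict[str, ParamCoupling]:
    """Baseline asymmetry retained, all latent couplings zero."""
    return {
        p: replace(c, beta_mean=0.0, beta_sd=0.0)
        for p, c in _default_coupling().items()
    }


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level simulation settings (defaults: the study conditions)."""

    n_subjects: int = 126
    base: SubjectGaitSpec = SubjectGaitSpec()
    coupling: dict[str, ParamCoupling] = field(default_factory=_default_coupling)
    between_subject_cv: float = 0.10   # CV of parameter means across subjects
    step_time_between_sd: float = 0.03
    ghq_intercept: float = GHQ_INTERCEPT
    ghq_slope: float = GHQ_SLOPE
    age_mean: float = 66.2
    age_sd: float = 8.38
    prop_male: float = 30 / 126

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise SpecError(f"n_subjects must be >= 2, got {self.n_subjects}")
        for p, c in self.coupling.items():
            if c.beta_mean < 0 or c.beta_sd < 0:
                raise SpecError(f"coupling betas must be >= 0 ({p})")
        self.base.validate()

    @staticmethod
    def null(**kwargs) -> "CohortSpec":
        """A no-coupling cohort (asymmetry present but independent of GHQ)."""
        return CohortSpec(coupling=_null_coupling(), **kwargs)


# ---------------------------------------------------------------------------
# ground truth containers

@dataclass(frozen=True)
class TrueStep:
    leading_foot: str
    trail_heel_contact: int
    lead_heel_contact: int
    trail_toe_off: int
    step_length: float
    step_width: float
    double_support: float


@dataclass(frozen=True)
class TrueSwing:
    foot: str
    toe_off: int
    heel_contact: int
    mfc_frame: int
    mfc_m: float


@dataclass
class TrialGroundTruth:
    """Exact events and parameter values realized in one rendered trial."""

    fs: float
    n_frames: int
    heel_contacts: dict[str, np.ndarray]
    toe_offs: dict[str, np.ndarray]
    steps: list[TrueStep]
    swings: list[TrueSwing]

    def step_records(self) -> list[StepRecord]:
        return [StepRecord(s.leading_foot, s.step_length, s.step_width,
                           s.double_support) for s in self.steps]

    def swing_records(self) -> list[SwingRecord]:
        return [SwingRecord(s.foot, s.mfc_m * 100.0, s.mfc_frame)
                for s in self.swings]

    def interior_events(self, foot: str, kind: str) -> np.ndarray:
        """Events away from the trial edges (first/last of each foot dropped)."""
        arr = self.heel_contacts[foot] if kind == "heel_contact" else self.toe_offs[foot]
        return arr[1:-1]


# ---------------------------------------------------------------------------
# trial simulation

def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _plan(spec: SubjectGaitSpec, rng: np.random.Generator) -> dict:
    """Draw per-step parameters and quantize the event timeline to frames."""
    fs = spec.fs
    n_lead_in, n_tail = _N_VIRTUAL, 2
    m = n_lead_in + spec.n_steps + n_tail
    sides, tau, length, width, ds, mfc = [], [], [], [], [], []
    for k in range(m):
        side = "R" if (k - n_lead_in) % 2 == 0 else "L"
        p = spec.side(side)
        sides.append(side)
        tau.append(float(np.clip(rng.normal(p.step_time, p.step_time_sd), 0.45, 0.85)))
        length.append(float(np.clip(rng.normal(p.step_length, p.step_length_sd), 0.2, 1.2)))
        width.append(float(np.clip(rng.normal(p.step_width, p.step_width_sd), 0.02, 0.35)))
        ds.append(float(np.clip(rng.normal(p.double_support, p.double_support_sd), 0.055, 0.16)))
        hi = spec.early_swing_peak - 0.004
        mfc.append(float(np.clip(rng.normal(p.mfc, p.mfc_sd), 0.004, hi)))

    frames = np.zeros(m, dtype=int)
    for k in range(1, m):
        frames[k] = frames[k - 1] + max(int(round(tau[k] * fs)), int(0.45 * fs))
    frames += int(round(_LEAD_IN_S * fs)) - frames[n_lead_in]
    to_frames = np.zeros(m, dtype=int)  # toe-off of the foot trailing step k
    for k in range(1, m):
        to_frames[k] = frames[k] + max(1, int(round(ds[k] * fs)))
    n_frames = int(frames[n_lead_in + spec.n_steps - 1] + round(_TAIL_S * fs))
    return dict(sides=sides, frames=frames, to_frames=to_frames, length=length,
                width=width, ds=ds, mfc=mfc, n_frames=n_frames,
                first_real=n_lead_in, last_real=n_lead_in + spec.n_steps - 1)


def _positions_at_contacts(plan: dict) -> tuple[np.ndarray, np.ndarray]:
    """Sequential foot placement: lead lands step_length ahead of the trail
    heel and step_width to its lateral side (left feet land in +y)."""
    m = len(plan["sides"])
    x = np.zeros(m)
    y = np.zeros(m)
    for k in range(1, m):
        x[k] = x[k - 1] + plan["length"][k]
        y[k] = y[k - 1] + (plan["width"][k] if plan["sides"][k] == "L"
                           else -plan["width"][k])
    return x, y


class _KnotList:
    """Strictly increasing (time, value) knots on the frame grid."""

    def __init__(self, fs: float):
        self.fs = fs
        self.t: list[float] = []
        self.v: list[float] = []

    def add(self, t: float, v: float) -> None:
        t = round(t * self.fs) / self.fs  # snap to the frame grid
        if self.t and t <= self.t[-1]:
            return
        self.t.append(t)
        self.v.append(v)

    def curve(self) -> PchipInterpolator:
        return PchipInterpolator(np.array(self.t), np.array(self.v))


def _parabola(knots: _KnotList, t0: float, accel: float, base: float = 0.0,
              offsets: tuple[float, ...] = (0.04, 0.02, 0.01)) -> None:
    """Symmetric parabolic valley ``base + accel/2 * (t-t0)^2`` around t0.

    The zero-phase Butterworth kernel has a vanishing second moment, so a
    locally parabolic (symmetric) event neighborhood passes the filter
    with neither value nor timing bias.
    """
    for dt in offsets:
        knots.add(t0 - dt, base + 0.5 * accel * dt * dt)
    knots.add(t0, base)
    for dt in reversed(offsets):
        knots.add(t0 + dt, base + 0.5 * accel * dt * dt)


def _render_foot(spec: SubjectGaitSpec, plan: dict, foot: str,
                 times: np.ndarray) -> dict[str, np.ndarray]:
    fs = spec.fs
    own = [k for k, s in enumerate(plan["sides"]) if s == foot]
    cx, cy = plan["_cx"], plan["_cy"]
    heel_z, toe_z = _KnotList(fs), _KnotList(fs)
    hx, hy = _KnotList(fs), _KnotList(fs)
    t_end = times[-1] + 1.0

    first = own[0]
    hx.add(plan["frames"][first] / fs - 2.0, cx[first])  # pre-trial hold
    hy.add(plan["frames"][first] / fs - 2.0, cy[first])
    heel_z.add(plan["frames"][first] / fs - 2.0, 0.004)
    toe_z.add(plan["frames"][first] / fs - 2.0, 0.0035)

    for k0, k1 in zip(own[:-1], own[1:]):
        c = plan["frames"][k0] / fs
        c2 = plan["frames"][k1] / fs
        to = plan["to_frames"][k0 + 1] / fs  # lifted after the next contact
        st, sw = to - c, c2 - to
        t_mfc = to + 0.55 * sw

        # heel height: wide parabolic touchdown (symmetric over +-90 ms so
        # the filter kernel sees a balanced valley), brief rocker descent to
        # the stance plateau, heel-off rise, swing peak, descent joining the
        # next contact's parabola
        _parabola(heel_z, c, _HEEL_ACCEL, offsets=(0.09, 0.07, 0.05, 0.03, 0.01))
        heel_z.add(c + 0.15, 0.027)
        heel_z.add(c + 0.22, 0.004)
        heel_z.add(to, 0.03)
        heel_z.add(to + 0.35 * sw, spec.heel_swing_peak)
        heel_z.add(c2 - 0.15, 0.027)
        # next loop iteration (or the tail below) adds the c2 parabola

        # toe height: parabolic touchdown, low stance plateau, toe-off with
        # a velocity-symmetric parabola (stance side capped below the rise
        # threshold, swing side extended), early-swing peak, wide parabolic
        # clearance minimum at 55 % swing, late-swing peak, gentle touchdown
        _parabola(toe_z, c, _TOE_ACCEL, offsets=(0.055, 0.03, 0.01))
        toe_z.add(c + 0.5 * st, 0.0035)
        _parabola(toe_z, to, _TOE_ACCEL, offsets=(0.055, 0.03, 0.01))
        toe_z.add(to + 0.07, 0.5 * _TOE_ACCEL * 0.07 ** 2)
        toe_z.add(to + 0.09, 0.5 * _TOE_ACCEL * 0.09 ** 2)
        toe_z.add(to + max(0.18 * sw, 0.105), spec.early_swing_peak)
        # clearance valley: half-width scales with swing; the late peak is
        # placed leaving a ~0.8 m/s touchdown reserve and kept well above
        # the valley edge so short swings retain an interior minimum
        mfc = plan["mfc"][k1]
        t_late = to + min(0.78 * sw, sw - 0.088)
        right_cap = max(t_late - 0.035 - t_mfc, 0.02)
        for f in (0.20, 0.12, 0.05):
            dt = f * sw
            toe_z.add(t_mfc - dt, mfc + 0.5 * _VALLEY_ACCEL * dt * dt)
        toe_z.add(t_mfc, mfc)
        edge = 0.0
        for f in (0.045, 0.11, 0.18):
            dt = min(f * sw, right_cap)
            edge = mfc + 0.5 * _VALLEY_ACCEL * dt * dt
            toe_z.add(t_mfc + dt, edge)
        # low rounded late bump: enough rise to keep the filtered valley an
        # interior minimum without injecting a narrow high spike
        v_late = edge + 0.005
        toe_z.add(t_late - 0.02, v_late - 0.0008)
        toe_z.add(t_late, v_late)
        toe_z.add(t_late + 0.02, v_late - 0.0008)

        # anterior / lateral: hold through stance, monotone advance in
        # swing with gentle symmetric departure and arrival tails
        for knots, coord in ((hx, cx), (hy, cy)):
            p0, p1 = coord[k0], coord[k1]
            step = 1.0 if p1 >= p0 else -1.0
            knots.add(c, p0)
            knots.add(to, p0)
            knots.add(to + 0.04, p0 + step * 0.0004)
            knots.add(to + 0.08, p0 + step * 0.0015)
            knots.add(to + 0.16, p0 + step * 0.006)
            knots.add(c2 - 0.16, p1 - step * 0.006)
            knots.add(c2 - 0.08, p1 - step * 0.0015)
            knots.add(c2 - 0.04, p1 - step * 0.0004)
            knots.add(c2, p1)

    last = own[-1]
    c = plan["frames"][last] / fs
    _parabola(heel_z, c, _HEEL_ACCEL, offsets=(0.09, 0.07, 0.05, 0.03, 0.01))
    heel_z.add(t_end, 0.004)
    _parabola(toe_z, c, _TOE_ACCEL, offsets=(0.055, 0.03, 0.01))
    toe_z.add(t_end, 0.0035)
    hx.add(c, cx[last])
    hx.add(t_end, cx[last])
    hy.add(c, cy[last])
    hy.add(t_end, cy[last])

    x = hx.curve()(times)
    y = hy.curve()(times)
    return {
        f"{foot}_HEEL": np.column_stack([x, y, heel_z.curve()(times)]),
        f"{foot}_TOE": np.column_stack([x + spec.foot_length, y,
                                        toe_z.curve()(times)]),
    }


def _ground_truth(spec: SubjectGaitSpec, plan: dict) -> TrialGroundTruth:
    fs, F = spec.fs, plan["n_frames"]
    first, last = plan["first_real"], plan["last_real"]
    frames, to_frames = plan["frames"], plan["to_frames"]
    sides = plan["sides"]
    hc = {f: [] for f in "LR"}
    to = {f: [] for f in "LR"}
    for k in range(len(sides)):
        if first <= k <= last:
            hc[sides[k]].append(int(frames[k]))
        if k >= 1 and 0 <= to_frames[k] < F:
            trail = "L" if sides[k] == "R" else "R"
            to[trail].append(int(to_frames[k]))
    steps = [
        TrueStep(
            leading_foot=sides[k],
            trail_heel_contact=int(frames[k - 1]),
            lead_heel_contact=int(frames[k]),
            trail_toe_off=int(to_frames[k]),
            step_length=plan["length"][k],
            step_width=plan["width"][k],
            double_support=(to_frames[k] - frames[k]) / fs,
        )
        for k in range(first + 1, last + 1)
    ]
    swings = []
    for k in range(first + 1, last + 1):
        # swing of foot sides[k], ending at its contact frames[k]
        toe_off = to_frames[k - 1]
        if toe_off < 0:
            continue
        sw = (frames[k] - toe_off) / fs
        mfc_frame = int(round(toe_off + 0.55 * sw * fs))
        swings.append(TrueSwing(foot=sides[k], toe_off=int(toe_off),
                                heel_contact=int(frames[k]),
                                mfc_frame=mfc_frame, mfc_m=plan["mfc"][k]))
    return TrialGroundTruth(
        fs=fs, n_frames=F,
        heel_contacts={f: np.array(v, dtype=int) for f, v in hc.items()},
        toe_offs={f: np.array(v, dtype=int) for f, v in to.items()},
        steps=steps, swings=swings,
    )


def simulate_trial(spec: SubjectGaitSpec, seed,
                   subject_id: str = "synthetic", trial_id: str = "t01",
                   render: bool = True
                   ) -> tuple[TrialTrajectories | None, TrialGroundTruth]:
    """Simulate one walking pass; returns trajectories and exact truth.

    ``render=False`` skips trajectory rendering and returns ``(None,
    truth)`` — useful when only ground-truth records are needed.

    Raises
    ------
    SpecError
        If the spec violates its invariants.
    """
    spec.validate()
    rng = _rng_from(seed)
    plan = _plan(spec, rng)
    plan["_cx"], plan["_cy"] = _positions_at_contacts(plan)
    truth = _ground_truth(spec, plan)
    if not render:
        return None, truth
    times = np.arange(plan["n_frames"]) / spec.fs
    positions: dict[str, np.ndarray] = {}
    for foot in "LR":
        positions.update(_render_foot(spec, plan, foot, times))
    if spec.marker_noise_rms > 0:
        for m in MARKERS:
            positions[m] = positions[m] + rng.normal(
                0.0, spec.marker_noise_rms, positions[m].shape
            )
    trial = TrialTrajectories(subject_id=subject_id, trial_id=trial_id,
                              fs=spec.fs, positions=positions)
    return trial, truth


# ---------------------------------------------------------------------------
# cohort simulation

@dataclass
class SyntheticSubject:
    subject_id: str
    latent: float
    age: float
    sex: str
    spec: SubjectGaitSpec
    ghq: GHQResponse
    trial: TrialTrajectories | None
    truth: TrialGroundTruth


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    seed: int
    subjects: list[SyntheticSubject]

    @property
    def latent_scores(self) -> np.ndarray:
        return np.array([s.latent for s in self.subjects])

    @property
    def ghq_responses(self) -> list[GHQResponse]:
        return [s.ghq for s in self.subjects]


def _subject_spec(cohort: CohortSpec, m: float,
                  rng: np.random.Generator) -> SubjectGaitSpec:
    base = cohort.base.left
    cv = cohort.between_subject_cv
    vals: dict[str, dict[str, float]] = {"L": {}, "R": {}}
    for p in ("step_length", "step_width", "double_support", "mfc"):
        c = cohort.coupling[p]
        mean = float(getattr(base, p))
        sd = float(getattr(base, f"{p}_sd"))
        v = max(rng.normal(mean, cv * mean), 0.25 * mean)
        delta = c.base_asym + c.beta_mean * m + rng.normal(0.0, c.asym_sd)
        delta = float(np.clip(delta, -1.2, 1.2))
        gamma = c.base_sd_asym + c.beta_sd * m + rng.normal(0.0, c.sd_asym_sd)
        gamma = float(np.clip(gamma, -1.2, 1.2))
        hi = (cohort.base.early_swing_peak - 0.008) if p == "mfc" else np.inf
        vals["R"][p] = float(np.clip(v * (1 + delta / 2), 0.1 * mean, hi))
        vals["L"][p] = float(np.clip(v * (1 - delta / 2), 0.1 * mean, hi))
        vals["R"][f"{p}_sd"] = max(sd * (1 + gamma / 2), 0.1 * sd)
        vals["L"][f"{p}_sd"] = max(sd * (1 - gamma / 2), 0.1 * sd)
    step_time = float(np.clip(
        rng.normal(base.step_time, cohort.step_time_between_sd), 0.48, 0.75
    ))
    sides = {
        s: SideParams(step_time=step_time, step_time_sd=base.step_time_sd,
                      **vals[s])
        for s in "LR"
    }
    return replace(cohort.base, left=sides["L"], right=sides["R"])


def _ghq_items(p_agree: float, rng: np.random.Generator) -> tuple[int, ...]:
    agree = rng.random(12) < p_agree
    low = rng.integers(0, 2, 12)    # strongly-disagree vs disagree
    high = rng.integers(2, 4, 12)   # agree vs strongly-agree
    return tuple(int(h if a else l) for a, l, h in zip(agree, low, high))


def simulate_cohort(cohort: CohortSpec, seed: int,
                    render: bool = True) -> SyntheticCohort:
    """Simulate a full cohort: one trial + GHQ response per subject.

    Subject ``i`` uses the ``i``-th child stream of ``SeedSequence(seed)``,
    so cohorts are reproducible and subjects independent.
    """
    cohort.validate()
    children = np.random.SeedSequence(seed).spawn(cohort.n_subjects)
    subjects: list[SyntheticSubject] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        m = float(rng.standard_normal())
        spec = _subject_spec(cohort, m, rng)
        sid = f"S{i + 1:03d}"
        trial, truth = simulate_trial(spec, rng, subject_id=sid, render=render)
        p_agree = 1.0 / (1.0 + np.exp(-(cohort.ghq_intercept + cohort.ghq_slope * m)))
        ghq = GHQResponse(subject_id=sid, items=_ghq_items(p_agree, rng))
        age = float(rng.normal(cohort.age_mean, cohort.age_sd))
        sex = "M" if rng.random() < cohort.prop_male else "F"
        subjects.append(SyntheticSubject(
            subject_id=sid, latent=m, age=age, sex=sex, spec=spec,
            ghq=ghq, trial=trial, truth=truth,
        ))
    return SyntheticCohort(spec=cohort, seed=seed, subjects=subjects)
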