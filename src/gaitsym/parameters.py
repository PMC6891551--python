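"""Spatiotemporal gait parameters and per-subject summaries.

Four parameters are extracted per step or swing:

* **step length** (m) — anterior heel-to-heel displacement at the leading
  foot's heel contact;
* **step width** (m) — absolute mediolateral heel-to-heel displacement at
  the same instant (kept nonnegative; crossing steps are rare at
  preferred pace);
* **double support** (s) — leading heel contact to trailing-foot toe-off;
* **minimum foot clearance, MFC** (cm) — lowest toe height above the
  walking surface at the mid-swing local minimum of the toe trajectory,
  a tripping-risk indicator.

Per subject, each parameter is summarized by side-stratified and pooled
mean and stride-to-stride SD (sample SD, n−1), the SD quantifying
intra-subject variability.  Spatial/temporal step parameters are
stratified by the leading foot; MFC by the swinging foot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SideMissingError
from .events import FEET, GaitEvents, StepInterval
from .io import TrialTrajectories

__all__ = ["PARAMETERS", "StepRecord", "SwingRecord", "SubjectGaitSummary",
           "compute_step_metrics", "compute_mfc", "summarize_subject"]

logger = logging.getLogger(__name__)

#: Gait parameters in canonical (report) order.
PARAMETERS = ("step_length", "step_width", "double_support", "mfc")

#: Mid-swing search window for the MFC, as fractions of swing duration.
MFC_WINDOW = (0.2, 0.8)

#: Shortest analyzable swing, in frames.
MIN_SWING_FRAMES = 10

#: Default inclusion threshold: complete step cycles per subject.
DEFAULT_MIN_STEPS = 30


@dataclass(frozen=True)
class StepRecord:
    leading_foot: str
    step_length: float   # m
    step_width: float    # m
    double_support: float  # s


@dataclass(frozen=True)
class SwingRecord:
    foot: str
    mfc: float       # cm above the ground reference
    mfc_frame: int


@dataclass
class SubjectGaitSummary:
    """Side-stratified and pooled mean/SD per gait parameter."""

    subject_id: str
    side_mean: dict[str, dict[str, float]]  # side -> parameter -> mean
    side_sd: dict[str, dict[str, float]]
    pooled_mean: dict[str, float] = field(default_factory=dict)
    pooled_sd: dict[str, float] = field(default_factory=dict)
    n_steps: dict[str, int] = field(default_factory=dict)  # per leading side
    min_steps: int = DEFAULT_MIN_STEPS

    @property
    def total_steps(self) -> int:
        return self.n_steps["L"] + self.n_steps["R"]

    @property
    def included(self) -> bool:
        """Whether the subject meets the minimum step-cycle inclusion rule."""
        return self.total_steps >= self.min_steps


def compute_step_metrics(trial: TrialTrajectories,
                         steps: list[StepInterval]) -> list[StepRecord]:
    """Step length, step width and double-support time for each step.

    Steps with nonpositive length (backward step or a detection fault)
    are dropped with a logged warning.
    """
    records: list[StepRecord] = []
    for s in steps:
        lead = trial.marker(f"{s.leading_foot}_HEEL")
        trail_foot = "L" if s.leading_foot == "R" else "R"
        trail = trial.marker(f"{trail_foot}_HEEL")
        i = s.lead_heel_contact
        length = lead[i, 0] - trail[i, 0]
        if length <= 0:
            logger.warning(
                "nonpositive step length %.3f m at frame %d (%s leading); "
                "record dropped", length, i, s.leading_foot,
            )
            continue
        records.append(StepRecord(
            leading_foot=s.leading_foot,
            step_length=float(length),
            step_width=float(abs(lead[i, 1] - trail[i, 1])),
            double_support=(s.trail_toe_off - s.lead_heel_contact) / trial.fs,
        ))
    return records


def _stance_reference(toe_z: np.ndarray, contacts: np.ndarray,
                      toe_offs: np.ndarray) -> float:
    """Median toe height over the middle thirds of the foot's stances."""
    chunks = []
    for c in contacts:
        later = toe_offs[toe_offs > c]
        if later.size == 0:
            continue
        to = later[0]
        lo = c + (to - c) // 3
        hi = c + 2 * (to - c) // 3
        if hi > lo:
            chunks.append(toe_z[lo:hi])
    if not chunks:
        return float(np.percentile(toe_z, 5))
    return float(np.median(np.concatenate(chunks)))


def compute_mfc(trial: TrialTrajectories, events: GaitEvents,
                ground_ref: str = "midstance_median",
                window: tuple[float, float] = MFC_WINDOW) -> list[SwingRecord]:
    """Minimum foot clearance for every complete swing, in cm.

    The MFC is the lowest interior local minimum of the toe height within
    20–80 % of the swing (toe-off to next same-foot heel contact), minus a
    ground reference:

    * ``"midstance_median"`` (default) — per-foot median toe height over
      mid-stance frames, a foot-flat proxy that absorbs the static marker
      offset of a shoe-mounted marker;
    * ``"absolute"`` — raw toe height, for data whose floor is exactly
      z = 0 and whose toe marker rides at floor level.

    Swings shorter than 10 frames, or with no interior local minimum in
    the window (e.g. monotone toe descent), are skipped with a warning.
    """
    if ground_ref not in ("midstance_median", "absolute"):
        raise ValueError(f"unknown ground_ref {ground_ref!r}")
    records: list[SwingRecord] = []
    for foot in FEET:
        toe_z = trial.marker(f"{foot}_TOE", 2)
        contacts = events.heel_contacts[foot]
        toe_offs = events.toe_offs[foot]
        ref = 0.0
        if ground_ref == "midstance_median":
            ref = _stance_reference(toe_z, contacts, toe_offs)
        for to in toe_offs:
            nxt = contacts[contacts > to]
            if nxt.size == 0:
                continue
            hc = int(nxt[0])
            dur = hc - to
            if dur < MIN_SWING_FRAMES:
                logger.warning("%s swing at frame %d only %d frames; skipped",
                               foot, to, dur)
                continue
            lo = to + int(np.ceil(window[0] * dur))
            hi = to + int(np.floor(window[1] * dur))
            seg = toe_z[lo:hi + 1]
            interior = np.flatnonzero(
                (seg[1:-1] < seg[:-2]) & (seg[1:-1] <= seg[2:])
            ) + 1
            if interior.size == 0:
                logger.warning(
                    "%s swing at frame %d has no interior toe-height minimum "
                    "in the mid-swing window; skipped", foot, to,
                )
                continue
            best = interior[np.argmin(seg[interior])]
            records.append(SwingRecord(
                foot=foot,
                mfc=float((seg[best] - ref) * 100.0),
                mfc_frame=int(lo + best),
            ))
    return records


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def summarize_subject(subject_id: str,
                      step_records: list[StepRecord],
                      swing_records: list[SwingRecord],
                      min_steps: int = DEFAULT_MIN_STEPS) -> SubjectGaitSummary:
    """Side-stratified and pooled mean/SD of all four gait parameters.

    Raises
    ------
    SideMissingError
        If either side has no step or no swing records (downstream SI
        features would be undefined).
    """
    side_mean: dict[str, dict[str, float]] = {s: {} for s in FEET}
    side_sd: dict[str, dict[str, float]] = {s: {} for s in FEET}
    pooled_mean: dict[str, float] = {}
    pooled_sd: dict[str, float] = {}
    n_steps: dict[str, int] = {}

    for side in FEET:
        side_steps = [r for r in step_records if r.leading_foot == side]
        side_swings = [r for r in swing_records if r.foot == side]
        n_steps[side] = len(side_steps)
        if not side_steps or not side_swings:
            raise SideMissingError(
                f"subject {subject_id}: no {'step' if not side_steps else 'swing'}"
                f" records on side {side}"
            )
        for p in ("step_length", "step_width", "double_support"):
            side_mean[side][p], side_sd[side][p] = _mean_sd(
                [getattr(r, p) for r in side_steps]
            )
        side_mean[side]["mfc"], side_sd[side]["mfc"] = _mean_sd(
            [r.mfc for r in side_swings]
        )

    for p in ("step_length", "step_width", "double_support"):
        pooled_mean[p], pooled_sd[p] = _mean_sd(
            [getattr(r, p) for r in step_records]
        )
    pooled_mean["mfc"], pooled_sd["mfc"] = _mean_sd([r.mfc for r in swing_records])

    summary = SubjectGaitSummary(
        subject_id=subject_id, side_mean=side_mean, side_sd=side_sd,
        pooled_mean=pooled_mean, pooled_sd=pooled_sd,
        n_steps=n_steps, min_steps=min_steps,
    )
    if not summary.included:
        logger.warning("subject %s has %d steps (< %d); flagged not-included",
                       subject_id, summary.total_steps, min_steps)
    return summary


def records_to_frame(subject_id: str, trial_id: str,
                     step_records: list[StepRecord],
                     swing_records: list[SwingRecord]) -> pd.DataFrame:
    """Tidy ``subject,trial,foot,parameter,value`` table of all records."""
    rows = []
    for r in step_records:
        for p in ("step_length", "step_width", "double_support"):
            rows.append((subject_id, trial_id, r.leading_foot, p, getattr(r, p)))
    for r in swing_records:
        rows.append((subject_id, trial_id, r.foot, "mfc", r.mfc))
    return pd.DataFrame(rows, columns=["subject", "trial", "foot",
                                       "parameter", "value"])
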