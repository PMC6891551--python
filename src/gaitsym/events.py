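"""Gait event detection from filtered heel/toe kinematics.

Heel contact and toe-off are detected per foot from vertical marker
position and velocity, an overground-friendly scheme that needs no force
plates:

* **heel contact** — local minimum of the filtered heel height whose
  preceding 50 ms of vertical velocity is on average negative (the heel
  is descending into the ground) and whose height lies within 15 mm of
  the trial's 5th-percentile heel height;
* **toe-off** — within each heel-contact-to-heel-contact cycle, the last
  upward zero crossing of the toe vertical velocity before the toe first
  rises 5 mm above its stance-reference height.

A 0.4 s refractory interval between same-type events caps the admissible
cadence at ~150 steps/min, above any plausible preferred-pace walking.
Only complete cycles are kept: a toe-off is reported only when bracketed
by two heel contacts of the same foot, so partial cycles at the trial
edges drop out naturally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import InsufficientEventsError, NoStepsError
from .io import TrialTrajectories
from .preprocess import FilterSpec, derivative, lowpass_filter

__all__ = ["EventConfig", "GaitEvents", "StepInterval", "detect_events",
           "segment_steps"]

logger = logging.getLogger(__name__)

FEET = ("L", "R")


@dataclass(frozen=True)
class EventConfig:
    """Detection thresholds (defaults suit preferred-pace adult walking)."""

    refractory_s: float = 0.4        # min spacing between same-type events
    heel_band_m: float = 0.015       # contact height band above 5th pct heel z
    toe_rise_m: float = 0.005        # swing onset threshold above stance toe z
    pre_contact_window_s: float = 0.05  # descent check before a contact
    apply_filter: bool = True        # low-pass internally before detection


@dataclass
class GaitEvents:
    """Ordered heel-contact and toe-off frame indices per foot."""

    fs: float
    heel_contacts: dict[str, np.ndarray] = field(default_factory=dict)
    toe_offs: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame_table(self) -> pd.DataFrame:
        """Tidy ``foot,event_type,frame,time_s`` table of all events."""
        rows = []
        for foot in FEET:
            for name, frames in (("heel_contact", self.heel_contacts[foot]),
                                 ("toe_off", self.toe_offs[foot])):
                for f in frames:
                    rows.append((foot, name, int(f), f / self.fs))
        df = pd.DataFrame(rows, columns=["foot", "event_type", "frame", "time_s"])
        return df.sort_values(["frame", "foot"], kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class StepInterval:
    """One step: contralateral contact, leading contact, contralateral toe-off."""

    leading_foot: str
    trail_heel_contact: int
    lead_heel_contact: int
    trail_toe_off: int

    def __post_init__(self) -> None:
        if not self.trail_heel_contact < self.lead_heel_contact < self.trail_toe_off:
            raise ValueError(
                "step interval must satisfy trail contact < lead contact < "
                f"trail toe-off, got {self}"
            )


def _detect_heel_contacts(z: np.ndarray, v: np.ndarray, fs: float,
                          cfg: EventConfig) -> np.ndarray:
    dist = max(1, int(round(cfg.refractory_s * fs)))
    minima, _ = find_peaks(-z, distance=dist)
    band = np.percentile(z, 5) + cfg.heel_band_m
    win = max(1, int(round(cfg.pre_contact_window_s * fs)))
    keep = []
    for i in minima:
        # edge guard: boundary filter transients can fake a touchdown, and
        # partial first/last cycles are discarded downstream anyway
        if i < dist or i > z.size - dist:
            continue
        if z[i] > band:
            continue
        if np.mean(v[i - win:i]) < 0:
            keep.append(i)
    return np.asarray(keep, dtype=int)


def _detect_toe_offs(z: np.ndarray, v: np.ndarray, contacts: np.ndarray,
                     cfg: EventConfig) -> np.ndarray:
    upward = np.flatnonzero((v[1:] > 0) & (v[:-1] <= 0)) + 1
    offs = []
    for c0, c1 in zip(contacts[:-1], contacts[1:]):
        # stance toe height referenced per cycle (median over early stance,
        # robust to marker noise); swing onset = first rise above it + 5 mm
        early = z[c0:c0 + max(3, (c1 - c0) // 3)]
        thresh = float(np.median(early)) + cfg.toe_rise_m
        # toe may still be descending at heel contact: wait until it has
        # settled below threshold (stance) before looking for the swing rise
        below = np.flatnonzero(z[c0:c1] <= thresh)
        if below.size == 0:
            continue
        settled = c0 + below[0]
        above = np.flatnonzero(z[settled:c1] > thresh)
        if above.size == 0:
            continue
        rise = settled + above[0]
        cands = upward[(upward > c0) & (upward <= rise)]
        if cands.size:
            offs.append(cands[-1])
    return np.asarray(offs, dtype=int)


def detect_events(trial: TrialTrajectories,
                  spec: FilterSpec | None = None,
                  config: EventConfig | None = None) -> GaitEvents:
    """Detect heel contacts and toe-offs for both feet.

    ``spec`` defaults to the standard 6 Hz zero-phase Butterworth design at
    the trial's sampling rate; set ``config.apply_filter=False`` when the
    trial is already filtered.

    Raises
    ------
    InsufficientEventsError
        If fewer than two heel contacts are found on either foot (including
        the stationary-marker case).
    """
    cfg = config or EventConfig()
    spec = spec or FilterSpec(fs=trial.fs)
    events = GaitEvents(fs=trial.fs)
    for foot in FEET:
        heel_z = trial.marker(f"{foot}_HEEL", 2)
        toe_z = trial.marker(f"{foot}_TOE", 2)
        if cfg.apply_filter:
            heel_z = lowpass_filter(heel_z, spec)
            toe_z = lowpass_filter(toe_z, spec)
        heel_v = derivative(heel_z, trial.fs)
        toe_v = derivative(toe_z, trial.fs)
        contacts = _detect_heel_contacts(heel_z, heel_v, trial.fs, cfg)
        if contacts.size < 2:
            raise InsufficientEventsError(
                f"{foot}: {contacts.size} heel contact(s) detected; "
                "need at least 2 (markers stationary or pass too short?)"
            )
        events.heel_contacts[foot] = contacts
        events.toe_offs[foot] = _detect_toe_offs(toe_z, toe_v, contacts, cfg)
    return events


def segment_steps(events: GaitEvents, fs: float) -> list[StepInterval]:
    """Assemble alternating left/right step intervals from detected events.

    Consecutive same-foot contacts (a missed contralateral detection) are
    not patched: the intervening step is dropped with a logged warning.

    Raises
    ------
    NoStepsError
        If no valid step interval can be formed.
    """
    merged = sorted(
        [(int(f), foot) for foot in FEET for f in events.heel_contacts[foot]]
    )
    steps: list[StepInterval] = []
    for (f_prev, foot_prev), (f_lead, foot_lead) in zip(merged[:-1], merged[1:]):
        if foot_prev == foot_lead:
            logger.warning(
                "consecutive %s heel contacts at frames %d and %d "
                "(missed %s contact?); step skipped",
                foot_prev, f_prev, f_lead, "L" if foot_prev == "R" else "R",
            )
            continue
        trail_offs = events.toe_offs[foot_prev]
        later = trail_offs[trail_offs > f_lead]
        if later.size == 0:
            continue
        trail_to = int(later[0])
        # toe-off must belong to the trailing foot's current stance
        next_trail = events.heel_contacts[foot_prev]
        nxt = next_trail[next_trail > f_prev]
        if nxt.size and trail_to >= nxt[0]:
            continue
        steps.append(StepInterval(leading_foot=foot_lead,
                                  trail_heel_contact=f_prev,
                                  lead_heel_contact=f_lead,
                                  trail_toe_off=trail_to))
    if not steps:
        raise NoStepsError("no valid alternating step interval found")
    return steps
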