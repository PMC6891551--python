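"""Foot-marker trial container and marker/questionnaire file I/O.

Lab-frame convention used throughout the package: ``x`` points along the
direction of travel (anterior), ``y`` to the participant's left, ``z``
vertically up, ground plane nominally at ``z = 0``.  Frame indices are
0-based and intervals half-open.  Trials walked toward −x are rotated
180° about the vertical axis on load so every stored trial progresses
in +x.

Two plain-text marker formats are supported:

* OpenSim-style TRC (tab separated, header with ``DataRate``/``Units``;
  units ``mm`` by convention, converted to meters on load);
* a wide CSV dialect with one metadata line (``# fs=100,units=m``)
  followed by ``frame,L_HEEL_x,L_HEEL_y,L_HEEL_z,...`` columns.

GHQ-12 responses are read from ``subject_id,item01..item12`` CSV with
integer codes 0–3.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, GapTooLongError, MissingMarkerError

__all__ = [
    "MARKERS",
    "TrialTrajectories",
    "GHQResponse",
    "read_marker_table",
    "write_marker_table",
    "read_ghq_csv",
    "write_ghq_csv",
    "validate_trial",
]

#: Required marker names, in canonical column order.
MARKERS = ("L_HEEL", "R_HEEL", "L_TOE", "R_TOE")

#: Longest marker occlusion that is linearly interpolated, in seconds.
MAX_GAP_S = 0.1

#: Shortest accepted walking pass, in seconds.
MIN_DURATION_S = 2.0


@dataclass
class TrialTrajectories:
    """Time-synchronized 3-D positions of the four foot markers, in meters."""

    subject_id: str
    trial_id: str
    fs: float
    positions: dict[str, np.ndarray] = field(repr=False)  # marker -> (frames, 3)

    @property
    def frames(self) -> int:
        return next(iter(self.positions.values())).shape[0]

    @property
    def duration_s(self) -> float:
        return self.frames / self.fs

    def marker(self, name: str, axis: int | None = None) -> np.ndarray:
        pos = self.positions[name]
        return pos if axis is None else pos[:, axis]

    def copy(self) -> "TrialTrajectories":
        return dataclasses.replace(
            self, positions={m: p.copy() for m, p in self.positions.items()}
        )


@dataclass(frozen=True)
class GHQResponse:
    """One subject's GHQ-12 item responses, codes 0–3 per item.

    Codes 0–1 are the "disagree" (healthy) side of each item's 4-point
    scale and 2–3 the "agree" side; item reversal for positively worded
    items is assumed already encoded.
    """

    subject_id: str
    items: tuple[int, ...]


# ---------------------------------------------------------------------------
# helpers

def _fill_gaps(values: np.ndarray, fs: float, marker: str) -> np.ndarray:
    """Linearly interpolate NaN runs up to MAX_GAP_S; longer runs fail."""
    out = values.copy()
    limit = int(round(MAX_GAP_S * fs))
    for axis in range(out.shape[1]):
        col = out[:, axis]
        isnan = ~np.isfinite(col)
        if not isnan.any():
            continue
        # locate runs of consecutive NaN
        edges = np.flatnonzero(np.diff(np.concatenate(([0], isnan.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            if stop - start > limit:
                raise GapTooLongError(
                    f"{marker}: gap of {stop - start} frames at {start}-{stop} "
                    f"exceeds the {limit}-frame interpolation limit"
                )
        good = np.flatnonzero(~isnan)
        if good.size == 0:
            raise GapTooLongError(f"{marker}: no finite samples")
        col[isnan] = np.interp(np.flatnonzero(isnan), good, col[good])
    return out


def _normalize_direction(positions: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Rotate 180° about z when the mean heel trajectory progresses in −x."""
    heel = 0.5 * (positions["L_HEEL"] + positions["R_HEEL"])
    if heel[-1, 0] - heel[0, 0] < 0:
        positions = {
            m: p * np.array([-1.0, -1.0, 1.0]) for m, p in positions.items()
        }
    return positions


def _units_scale(units: str) -> float:
    units = units.strip().lower()
    if units == "mm":
        return 1e-3
    if units == "m":
        return 1.0
    raise FormatError(f"unknown units {units!r} (expected 'mm' or 'm')")


def _finalize(subject_id: str, trial_id: str, fs: float,
              positions: dict[str, np.ndarray]) -> TrialTrajectories:
    for m in MARKERS:
        if m not in positions:
            raise MissingMarkerError(f"marker {m} missing from file")
    positions = {m: _fill_gaps(positions[m], fs, m) for m in MARKERS}
    positions = _normalize_direction(positions)
    trial = TrialTrajectories(subject_id=subject_id, trial_id=trial_id,
                              fs=fs, positions=positions)
    issues = validate_trial(trial)
    if issues:
        raise FormatError("invalid trial: " + "; ".join(issues))
    return trial


# ---------------------------------------------------------------------------
# TRC

def _read_trc(path: Path) -> TrialTrajectories:
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise FormatError(f"{path}: not a TRC file (too short)")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    header = dict(zip(header_keys, header_vals))
    try:
        fs = float(header["DataRate"])
        units = header["Units"]
    except KeyError as exc:
        raise FormatError(f"{path}: TRC header missing {exc}") from exc
    scale = _units_scale(units)
    marker_names = [n for n in lines[3].split("\t")[2:] if n]
    data = []
    for line in lines[5:]:
        if not line.strip():
            continue
        data.append([float(tok) if tok else np.nan for tok in line.split("\t")])
    arr = np.array(data, dtype=float)
    positions: dict[str, np.ndarray] = {}
    for i, name in enumerate(marker_names):
        cols = arr[:, 2 + 3 * i: 5 + 3 * i]
        positions[name] = cols * scale
    return _finalize(path.stem, path.stem, fs, positions)


def _write_trc(trial: TrialTrajectories, path: Path) -> None:
    n = trial.frames
    cols = [np.arange(1, n + 1), np.arange(n) / trial.fs]
    for m in MARKERS:
        cols.extend((trial.positions[m] / 1e-3).T)  # meters -> mm
    rate = f"{trial.fs:.2f}"
    head = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{rate}\t{rate}\t{n}\t{len(MARKERS)}\tmm\t{rate}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(MARKERS) + "\t\t",
        "\t\t" + "\t".join(
            f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(MARKERS))
        ),
        "",
    ]
    with path.open("w") as fh:
        fh.write("\n".join(head) + "\n")
        for row in zip(*cols):
            frame = f"{int(row[0])}\t{row[1]:.5f}"
            rest = "\t".join(f"{v:.8f}" for v in row[2:])
            fh.write(f"{frame}\t{rest}\n")


# ---------------------------------------------------------------------------
# wide CSV

def _read_csv_wide(path: Path) -> TrialTrajectories:
    with path.open() as fh:
        meta_line = fh.readline().strip()
        if meta_line.startswith("#"):
            meta_line = meta_line[1:].strip()
        meta: dict[str, str] = {}
        for tok in meta_line.split(","):
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k.strip()] = v.strip()
        if "fs" not in meta:
            raise FormatError(f"{path}: metadata line must declare fs")
        if "units" not in meta:
            raise FormatError(f"{path}: metadata line must declare units")
        fs = float(meta["fs"])
        scale = _units_scale(meta["units"])
        df = pd.read_csv(fh)
    positions: dict[str, np.ndarray] = {}
    for m in MARKERS:
        names = [f"{m}_{ax}" for ax in "xyz"]
        if not all(c in df.columns for c in names):
            raise MissingMarkerError(f"marker {m} columns missing from {path}")
        positions[m] = df[names].to_numpy(dtype=float) * scale
    return _finalize(meta.get("subject", path.stem), meta.get("trial", path.stem),
                     fs, positions)


def _write_csv_wide(trial: TrialTrajectories, path: Path) -> None:
    data: dict[str, np.ndarray] = {"frame": np.arange(trial.frames)}
    for m in MARKERS:
        for j, ax in enumerate("xyz"):
            data[f"{m}_{ax}"] = trial.positions[m][:, j]
    df = pd.DataFrame(data)
    with path.open("w") as fh:
        fh.write(
            f"# fs={trial.fs:g},units=m,subject={trial.subject_id},"
            f"trial={trial.trial_id}\n"
        )
        df.to_csv(fh, index=False, float_format="%.9f")


# ---------------------------------------------------------------------------
# public API

def read_marker_table(path: str | Path, format: str | None = None) -> TrialTrajectories:
    """Read a four-marker trial from a TRC or wide-CSV file.

    The returned trial is validated, in meters, gap-filled (linear
    interpolation up to 100 ms) and normalized to +x walking direction.

    Raises
    ------
    MissingMarkerError, GapTooLongError, FormatError
    """
    path = Path(path)
    if format is None:
        format = "trc" if path.suffix.lower() == ".trc" else "csv_wide"
    if format == "trc":
        return _read_trc(path)
    if format == "csv_wide":
        return _read_csv_wide(path)
    raise FormatError(f"unknown marker table format {format!r}")


def write_marker_table(trial: TrialTrajectories, path: str | Path,
                       format: str | None = None) -> None:
    """Write a trial so that :func:`read_marker_table` round-trips it."""
    if trial.frames == 0:
        raise ValueError("cannot write a 0-frame trial")
    path = Path(path)
    if format is None:
        format = "trc" if path.suffix.lower() == ".trc" else "csv_wide"
    if format == "trc":
        _write_trc(trial, path)
    elif format == "csv_wide":
        _write_csv_wide(trial, path)
    else:
        raise FormatError(f"unknown marker table format {format!r}")


def validate_trial(trial: TrialTrajectories) -> list[str]:
    """Report every violated trial invariant; empty list means valid."""
    issues: list[str] = []
    if trial.fs <= 0:
        issues.append(f"invalid sampling rate fs={trial.fs}")
    missing = [m for m in MARKERS if m not in trial.positions]
    if missing:
        issues.append("missing markers: " + ", ".join(missing))
        return issues
    lengths = {m: trial.positions[m].shape[0] for m in MARKERS}
    if len(set(lengths.values())) > 1:
        issues.append(f"unequal marker lengths: {lengths}")
        return issues
    limit = int(round(MAX_GAP_S * trial.fs)) if trial.fs > 0 else 0
    for m in MARKERS:
        bad = ~np.isfinite(trial.positions[m]).all(axis=1)
        if bad.any():
            edges = np.flatnonzero(
                np.diff(np.concatenate(([0], bad.view(np.int8), [0])))
            )
            for start, stop in zip(edges[::2], edges[1::2]):
                kind = "gap too long" if stop - start > limit else "unfilled gap"
                issues.append(f"{m}: {kind} ({stop - start} frames at {start}-{stop})")
    if trial.fs > 0 and trial.frames < MIN_DURATION_S * trial.fs:
        issues.append(
            f"trial too short: {trial.frames} frames < "
            f"{MIN_DURATION_S:g} s at fs={trial.fs:g}"
        )
    return issues


# ---------------------------------------------------------------------------
# GHQ-12 CSV

def read_ghq_csv(path: str | Path) -> list[GHQResponse]:
    """Read ``subject_id,item01..item12`` responses with codes 0–3."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    item_cols = [f"item{i:02d}" for i in range(1, 13)]
    missing = [c for c in item_cols if c not in df.columns]
    if missing:
        raise FormatError(f"GHQ CSV missing columns: {', '.join(missing)}")
    return [
        GHQResponse(subject_id=str(row["subject_id"]),
                    items=tuple(int(row[c]) for c in item_cols))
        for _, row in df.iterrows()
    ]


def write_ghq_csv(responses: list[GHQResponse], path: str | Path) -> None:
    rows = [
        {"subject_id": r.subject_id,
         **{f"item{i+1:02d}": v for i, v in enumerate(r.items)}}
        for r in responses
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
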