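"""Zero-phase low-pass filtering and numerical differentiation.

Marker time series are smoothed with a Butterworth low-pass filter applied
forward and backward (zero phase lag, so event timing is preserved), the
standard treatment for optical motion-capture data.  The design cutoff is
6 Hz; the dual pass of an order-2 section gives an effective 4th-order
roll-off with squared magnitude response, i.e. gain 0.5 at the design
cutoff.  Velocities and accelerations are central differences computed on
the filtered signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DerivativeLengthError, FilterLengthError

__all__ = ["FilterSpec", "lowpass_filter", "derivative"]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter design.

    Parameters
    ----------
    cutoff_hz
        Design cutoff frequency in Hz (default 6).
    order
        Effective filter order; must be even and >= 2.  Realized as an
        ``order/2`` Butterworth section run forward and backward.
    fs
        Sampling rate in Hz.
    """

    cutoff_hz: float = 6.0
    order: int = 4
    fs: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.cutoff_hz < self.fs / 2:
            raise ValueError(
                f"cutoff_hz must lie in (0, fs/2); got {self.cutoff_hz} at fs={self.fs}"
            )
        if self.order < 2 or self.order % 2:
            raise ValueError(f"order must be even and >= 2; got {self.order}")


def lowpass_filter(series: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter of a scalar time series.

    The single-pass section has order ``spec.order // 2``; running it
    forward and backward squares the magnitude response (gain 0.5 at the
    design cutoff) and cancels the phase.  Ends are reflect-padded to
    suppress startup transients on short walkway passes.

    Raises
    ------
    FilterLengthError
        If the series is shorter than ``3 * order + 1`` samples.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("lowpass_filter expects a 1-D series")
    min_len = 3 * spec.order + 1
    if x.size < min_len:
        raise FilterLengthError(
            f"series of {x.size} samples shorter than required {min_len}"
        )
    sos = signal.butter(spec.order // 2, spec.cutoff_hz, btype="low",
                        fs=spec.fs, output="sos")
    return signal.sosfiltfilt(sos, x, padtype="even", padlen=3 * spec.order)


def derivative(series: np.ndarray, fs: float, order: int = 1) -> np.ndarray:
    """Finite-difference derivative of a uniformly sampled series.

    Central differences on interior samples, one-sided at the endpoints;
    ``order=1`` gives velocity, ``order=2`` acceleration (the gradient
    applied twice).  Output has the same length as the input with units
    scaled by ``fs`` per differentiation.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("derivative expects a 1-D series")
    if x.size < 3:
        raise DerivativeLengthError(f"need >= 3 samples, got {x.size}")
    if order not in (1, 2):
        raise ValueError("order must be 1 (velocity) or 2 (acceleration)")
    dt = 1.0 / fs
    out = np.gradient(x, dt)
    if order == 2:
        out = np.gradient(out, dt)
    return out
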