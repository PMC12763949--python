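"""Fixed sEMG preprocessing chain: band-pass filter, rectification, RMS envelope.

The chain follows standard amplitude-domain sEMG practice: a 4th-order
Butterworth band-pass (20–450 Hz) removes movement artefact and high-frequency
noise, full-wave rectification folds the signal positive, and a 0.25-s RMS
window reduces the 1024 Hz stream to a 4 Hz activation envelope.  The RMS
windows are non-overlapping: consecutive 0.25-s blocks, which is what produces
the decimated 4 Hz effective rate (overlapping windows would keep the raw
rate).  Filtering is zero-phase (forward–backward) so the envelope stays
time-aligned with the joint-angle signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import ParameterError, TrialDataError

__all__ = ["Envelope", "bandpass", "rectify", "rms_envelope"]


@dataclass
class Envelope:
    """RMS-smoothed activation signal.

    ``values[k]`` is the RMS of the raw-rate samples in the half-open block
    ``[k*w, (k+1)*w)`` where ``w = round(window_s * source_fs_hz)``; sample k
    therefore covers the time span ``[k, k+1) * window_s`` seconds.
    """

    values: np.ndarray
    fs_env_hz: float
    window_s: float
    source_fs_hz: float

    def __len__(self) -> int:
        return len(self.values)

    def time(self) -> np.ndarray:
        """Start time (s) of each envelope block."""
        return np.arange(len(self.values)) * self.window_s


def bandpass(
    emg: np.ndarray,
    fs_hz: float,
    low_hz: float = 20.0,
    high_hz: float = 450.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass.

    ``order`` is the design order passed to the Butterworth prototype (the
    conventional way EMG band-pass filters are quoted); forward–backward
    application squares the magnitude response and cancels the phase.
    Output has the same length as the input.
    """
    x = np.asarray(emg, dtype=float)
    if not 0 < low_hz < high_hz:
        raise ParameterError(f"need 0 < low_hz < high_hz, got {low_hz}, {high_hz}")
    if high_hz >= fs_hz / 2:
        raise ParameterError(
            f"high_hz={high_hz} must be below the Nyquist rate {fs_hz / 2} Hz"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs_hz, output="sos")
    # sosfiltfilt default pad length; signal must exceed it
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(x) <= padlen:
        raise TrialDataError(
            f"signal of {len(x)} samples too short for zero-phase filtering (need > {padlen})"
        )
    return signal.sosfiltfilt(sos, x)


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value; idempotent)."""
    return np.abs(np.asarray(x, dtype=float))


def rms_envelope(x: np.ndarray, fs_hz: float, window_s: float = 0.25) -> Envelope:
    """RMS over consecutive non-overlapping windows of ``window_s`` seconds.

    A trailing partial window is discarded rather than zero-padded, avoiding a
    downward-biased final sample.  For the default 0.25 s at 1024 Hz this maps
    a 60-s trial onto 240 envelope samples at 4 Hz.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise TrialDataError("cannot compute an envelope of an empty signal")
    w = int(round(window_s * fs_hz))
    if w < 1:
        raise ParameterError(f"window_s={window_s} spans less than one sample at {fs_hz} Hz")
    if len(x) < w:
        raise TrialDataError(f"signal of {len(x)} samples shorter than one {w}-sample window")
    n = len(x) // w
    blocks = x[: n * w].reshape(n, w)
    values = np.sqrt(np.mean(blocks**2, axis=1))
    return Envelope(values=values, fs_env_hz=fs_hz / w, window_s=w / fs_hz, source_fs_hz=fs_hz)
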