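"""Baseline-noise correction of the activation envelope.

Resting instrumentation noise puts a nonzero floor under the RMS envelope.  To
keep only genuine muscle activity, a muscle-specific activation threshold is
estimated from the quiet segment before movement starts: locate the minimum
envelope value prior to movement onset, take a 60-point window around that
minimum, and set the threshold to the window mean plus three standard
deviations.  The threshold is subtracted from the whole envelope and only
supra-threshold values are retained; sub-threshold samples are zeroed but kept
on the timeline so that cycle windows stay time-aligned.

Movement onset itself is found from the joint-angle (ROM) signal — the only
kinematic channel recorded — as the first time angular speed exceeds a small
threshold for a sustained interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import OnsetError, ThresholdError
from .preprocess import Envelope

__all__ = [
    "ActivationThreshold",
    "CorrectedEnvelope",
    "detect_movement_onset",
    "estimate_threshold",
    "apply_threshold",
]


@dataclass
class ActivationThreshold:
    """Noise statistics and the resulting activation threshold (µV).

    ``window_bounds`` is the half-open ``[a, b)`` envelope-index range of the
    noise window (at most 60 samples, centred on ``min_index``), and
    ``threshold = noise_mean + k_sd * noise_sd`` with population SD (ddof=0).
    """

    onset_index: int
    min_index: int
    window_bounds: tuple[int, int]
    noise_mean: float
    noise_sd: float
    threshold: float
    k_sd: float = 3.0


@dataclass
class CorrectedEnvelope:
    """Envelope after threshold subtraction.

    ``values[i] = env[i] - threshold`` where ``env[i] > threshold`` and 0
    elsewhere; ``active_mask`` records the comparison.  Carries the envelope
    timing metadata so downstream cycle windows can be mapped to samples.
    """

    values: np.ndarray
    threshold_used: ActivationThreshold
    active_mask: np.ndarray
    fs_env_hz: float
    window_s: float

    def __len__(self) -> int:
        return len(self.values)


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def detect_movement_onset(
    rom: np.ndarray,
    fs_hz: float,
    speed_thresh_deg_s: float = 5.0,
    sustain_s: float = 0.5,
    smooth_s: float = 0.1,
) -> float:
    """Earliest time (s) at which |dROM/dt| exceeds ``speed_thresh_deg_s``
    continuously for at least ``sustain_s``.

    The angular speed is a central difference lightly smoothed over
    ``smooth_s``.  If the movement is already under way at t=0 (no quiescent
    lead-in) the trial start 0.0 is returned with a warning.  A signal whose
    speed never sustains the threshold raises :class:`OnsetError`.
    """
    rom = np.asarray(rom, dtype=float)
    n_sustain = max(1, int(round(sustain_s * fs_hz)))
    if len(rom) < max(3, n_sustain):
        raise OnsetError(f"ROM signal of {len(rom)} samples too short for onset detection")
    speed = np.gradient(rom) * fs_hz
    # smooth the rectified speed: the brief zero crossings at each movement
    # reversal must not break an otherwise sustained suprathreshold run
    speed = _moving_average(np.abs(speed), int(round(smooth_s * fs_hz)))
    above = speed > speed_thresh_deg_s
    if not above.any():
        raise OnsetError("no movement detected (angular speed never exceeds threshold)")
    # run-length scan for the first sustained stretch
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    for s, e in zip(starts, ends):
        if e - s >= n_sustain:
            if s == 0:
                warnings.warn(
                    "movement already under way at trial start; onset set to 0 s",
                    stacklevel=2,
                )
                return 0.0
            return s / fs_hz
    raise OnsetError(
        f"no movement detected (speed never exceeds {speed_thresh_deg_s} deg/s "
        f"for {sustain_s} s)"
    )


def estimate_threshold(
    env: Envelope,
    onset_s: float,
    window_points: int = 60,
    k_sd: float = 3.0,
    clip_to_onset: bool = True,
) -> ActivationThreshold:
    """Mean + ``k_sd``·SD noise threshold from a window around the pre-onset minimum.

    The minimum is the first-occurring argmin of the envelope over
    ``[0, onset)``.  The window spans ``window_points`` envelope samples
    centred on the minimum (half on each side), clipped at the signal bounds
    and — by default — at the movement onset, so the noise statistics are
    taken from resting signal only (``clip_to_onset=False`` restores clipping
    at the signal end alone).  SD is the population SD (ddof=0).
    """
    values = np.asarray(env.values, dtype=float)
    onset_index = int(np.floor(onset_s * env.fs_env_hz))
    if onset_index < 1:
        raise ThresholdError("no pre-onset segment: movement onset at envelope index 0")
    onset_index = min(onset_index, len(values))
    pre = values[:onset_index]
    min_index = int(np.argmin(pre))  # first occurrence on ties
    half = window_points // 2
    limit = onset_index if clip_to_onset else len(values)
    a = max(0, min_index - half)
    b = min(limit, min_index + half)
    window = values[a:b]
    noise_mean = float(np.mean(window))
    noise_sd = float(np.std(window))  # ddof=0
    return ActivationThreshold(
        onset_index=onset_index,
        min_index=min_index,
        window_bounds=(a, b),
        noise_mean=noise_mean,
        noise_sd=noise_sd,
        threshold=noise_mean + k_sd * noise_sd,
        k_sd=k_sd,
    )


def apply_threshold(env: Envelope, thr: ActivationThreshold) -> CorrectedEnvelope:
    """Subtract the threshold and retain only supra-threshold activity.

    Samples at or below the threshold become exactly 0 but stay on the
    timeline (no deletion), keeping cycle windows aligned.
    """
    if not np.isfinite(thr.threshold) or thr.threshold < 0:
        raise ThresholdError(f"invalid threshold {thr.threshold}")
    values = np.asarray(env.values, dtype=float)
    mask = values > thr.threshold
    corrected = np.where(mask, values - thr.threshold, 0.0)
    return CorrectedEnvelope(
        values=corrected,
        threshold_used=thr,
        active_mask=mask,
        fs_env_hz=env.fs_env_hz,
        window_s=env.window_s,
    )
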