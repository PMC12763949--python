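"""Flexion-extension cycle segmentation from the joint-angle signal.

Cycles are anchored at successive peak-flexion maxima of the ROM trace (the
unambiguous extrema of the supported-arm task); cycle *i* is the half-open
time interval between peak *i* and peak *i+1*.  From all detected cycles the
analysis keeps a block of 10 consecutive cycles centred on the middle of the
trial, avoiding transitional effects at the beginning and end of the
recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .exceptions import SegmentationError

__all__ = ["CycleSet", "detect_cycles", "select_central"]


@dataclass
class CycleSet:
    """Ordered, non-overlapping cycle intervals on the trial timeline.

    ``cycles`` holds half-open ``[start_s, end_s)`` intervals; ``selected``
    indexes the chosen consecutive subset (empty until
    :func:`select_central`).
    """

    cycles: list[tuple[float, float]]
    selected: list[int] = field(default_factory=list)
    cadence_bpm: float = 60.0

    def __len__(self) -> int:
        return len(self.cycles)

    @property
    def selected_intervals(self) -> list[tuple[float, float]]:
        return [self.cycles[i] for i in self.selected]

    @property
    def selected_span(self) -> tuple[float, float]:
        """Contiguous time span covered by the selected block."""
        iv = self.selected_intervals
        if not iv:
            raise SegmentationError("no cycles selected")
        return iv[0][0], iv[-1][1]


def detect_cycles(
    rom: np.ndarray,
    fs_hz: float,
    cadence_bpm: float = 60.0,
    min_period_frac: float = 0.5,
    prominence_frac: float = 0.25,
    min_prominence_deg: float = 2.0,
    anchor: str = "peak",
) -> CycleSet:
    """Detect movement cycles by peak-picking the ROM signal.

    Peaks must be separated by at least ``min_period_frac`` of the nominal
    cycle period (60/cadence seconds) and have prominence at least
    ``prominence_frac`` of the ROM amplitude range, which rejects jitter peaks
    at the working cadence.  ``min_prominence_deg`` is an absolute floor on
    that prominence so a quiescent, noise-only angle trace (range well under
    the task's tens of degrees) yields no cycles rather than noise bumps.
    ``anchor="valley"`` segments at full extension instead (same cycles
    shifted by half a phase).
    """
    rom = np.asarray(rom, dtype=float)
    if anchor not in ("peak", "valley"):
        raise SegmentationError(f"unknown cycle anchor {anchor!r}")
    x = rom if anchor == "peak" else -rom
    amp_range = float(np.max(rom) - np.min(rom))
    if amp_range <= 0:
        raise SegmentationError("flat ROM signal: no cycles")
    period_s = 60.0 / cadence_bpm
    distance = max(1, int(round(min_period_frac * period_s * fs_hz)))
    prominence = max(prominence_frac * amp_range, min_prominence_deg)
    peaks, _ = signal.find_peaks(x, distance=distance, prominence=prominence)
    if len(peaks) < 2:
        raise SegmentationError(
            f"found {len(peaks)} qualifying peak(s); at least 2 needed to form a cycle"
        )
    times = peaks / fs_hz
    cycles = [(float(times[i]), float(times[i + 1])) for i in range(len(times) - 1)]
    return CycleSet(cycles=cycles, selected=[], cadence_bpm=cadence_bpm)


def select_central(cs: CycleSet, k: int = 10) -> CycleSet:
    """Select ``k`` consecutive cycles centred on the middle of the trial.

    The block starts at ``floor((n - k) / 2)``; with an even/odd mismatch the
    block sits one cycle earlier rather than later.  Deterministic.
    """
    n = len(cs.cycles)
    if n < k:
        raise SegmentationError(f"only {n} cycles detected, need at least {k}")
    start = (n - k) // 2
    return replace(cs, selected=list(range(start, start + k)))
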