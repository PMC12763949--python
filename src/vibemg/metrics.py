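"""Per-trial RMS over the selected cycles and post/pre ratio assembly.

The per-trial statistic is the RMS of the noise-corrected envelope over the
union of the selected cycle intervals.  By default all on-timeline samples in
that span are pooled — including the zeros produced by thresholding — so the
statistic is a true energy measure over the task window; ``mode="active"``
restricts to supra-threshold samples instead.

Each follow-up trial's RMS is normalized to the same session's baseline by the
post/pre ratio, the unit-free modulation statistic the downstream models run
on.  Because the ratio divides out any multiplicative gain common to a
participant-session (electrode impedance, tissue filtering), no MVC or other
amplitude normalization is applied anywhere.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import MetricError, RatioError
from .activation import CorrectedEnvelope
from .io import FOLLOW_UP_MIN, POST_LABELS
from .segmentation import CycleSet

__all__ = ["total_rms", "compute_ratio", "build_ratio_table", "RATIO_COLUMNS"]

RATIO_COLUMNS = [
    "participant_id",
    "session",
    "trial_label",
    "follow_up_min",
    "pre_rms_uv",
    "post_rms_uv",
    "ratio",
]


def _span_indices(interval: tuple[float, float], window_s: float, n: int) -> np.ndarray:
    """Envelope sample indices whose block start time falls in [start, end)."""
    start_s, end_s = interval
    k0 = int(np.ceil(start_s / window_s - 1e-12))
    k1 = int(np.ceil(end_s / window_s - 1e-12))
    return np.arange(max(0, k0), min(n, k1))


def total_rms(cenv: CorrectedEnvelope, cs: CycleSet, mode: str = "pooled") -> float:
    """RMS (µV) of the corrected envelope over the selected cycle intervals.

    ``mode="pooled"`` (default) pools every envelope sample in the union of
    the selected intervals, thresholded zeros included; ``mode="active"``
    keeps only samples flagged active by the threshold stage.
    """
    if not cs.selected:
        raise MetricError("no cycles selected")
    if mode not in ("pooled", "active"):
        raise MetricError(f"unknown RMS mode {mode!r}")
    idx = np.concatenate(
        [_span_indices(iv, cenv.window_s, len(cenv)) for iv in cs.selected_intervals]
    )
    if idx.size == 0:
        raise MetricError("selected cycle span contains no envelope samples")
    samples = cenv.values[idx]
    if mode == "active":
        samples = samples[cenv.active_mask[idx]]
        if samples.size == 0:
            return 0.0
    return float(np.sqrt(np.mean(samples**2)))


def compute_ratio(pre_rms: float, post_rms: float) -> float:
    """Post/pre RMS ratio; undefined (raises) for a non-positive baseline."""
    if pre_rms <= 0:
        raise RatioError(f"baseline RMS must be positive, got {pre_rms}")
    return post_rms / pre_rms


def build_ratio_table(trial_rms: pd.DataFrame) -> pd.DataFrame:
    """Assemble the long-format ratio table from per-trial RMS values.

    Parameters
    ----------
    trial_rms : DataFrame
        One row per processed trial with columns ``participant_id``,
        ``session``, ``trial_label``, ``rms_uv``.

    Returns
    -------
    DataFrame
        One row per participant × session × post trial (columns
        :data:`RATIO_COLUMNS`).  Missing post trials yield missing rows, not
        zeros; a participant-session without a usable (positive) baseline is
        excluded with a warning.
    """
    required = {"participant_id", "session", "trial_label", "rms_uv"}
    missing = required - set(trial_rms.columns)
    if missing:
        raise MetricError(f"trial RMS table missing column(s) {sorted(missing)}")
    rows = []
    for (pid, session), grp in trial_rms.groupby(["participant_id", "session"], sort=True):
        pre = grp.loc[grp["trial_label"] == "pre", "rms_uv"]
        if pre.empty:
            warnings.warn(f"{pid}/{session}: no baseline trial; excluded", stacklevel=2)
            continue
        pre_rms = float(pre.iloc[0])
        if pre_rms <= 0:
            warnings.warn(
                f"{pid}/{session}: baseline RMS {pre_rms} not positive; "
                "participant-session unusable and excluded",
                stacklevel=2,
            )
            continue
        for label in POST_LABELS:
            post = grp.loc[grp["trial_label"] == label, "rms_uv"]
            if post.empty:
                continue
            post_rms = float(post.iloc[0])
            rows.append(
                {
                    "participant_id": pid,
                    "session": session,
                    "trial_label": label,
                    "follow_up_min": FOLLOW_UP_MIN[label],
                    "pre_rms_uv": pre_rms,
                    "post_rms_uv": post_rms,
                    "ratio": compute_ratio(pre_rms, post_rms),
                }
            )
    return pd.DataFrame(rows, columns=RATIO_COLUMNS)
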