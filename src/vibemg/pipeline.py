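"""End-to-end orchestration: (simulate →) process → model → report.

The pipeline applies the fixed per-trial chain

    band-pass → rectify → RMS envelope → noise threshold → cycle selection →
    total RMS

to every trial of a study, assembles the post/pre ratio table, and fits the
statistical model.  Per-trial failures (flat ROM, no pre-onset segment, too
few cycles, ...) are recorded in a QC log and the run continues over the
remaining trials; the mixed model tolerates the resulting unbalanced table.
Everything is deterministic given the inputs and the config.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activation import apply_threshold, detect_movement_onset, estimate_threshold
from .exceptions import StatsError, VibemgError
from .io import Recording, SessionManifest, iter_session_recordings, load_study
from .metrics import build_ratio_table, total_rms
from .preprocess import bandpass, rectify, rms_envelope
from .segmentation import detect_cycles, select_central
from .simulate import SimConfig, iter_study, simulate_study
from .stats import RmsRatioModel, RmsRatioResults

__all__ = [
    "PipelineConfig",
    "TrialQC",
    "process_recording",
    "run_process",
    "run_stats",
    "run_all",
]

QC_COLUMNS = [
    "participant_id",
    "session",
    "trial_label",
    "status",
    "onset_s",
    "threshold_uv",
    "noise_mean_uv",
    "noise_sd_uv",
    "n_cycles",
    "selected_start",
    "selected_end",
    "rms_uv",
    "message",
]


@dataclass
class PipelineConfig:
    """All stage parameters; defaults reproduce the protocol settings
    (20–450 Hz order-4 band-pass, 0.25-s RMS window, 60-point noise window,
    mean + 3·SD threshold, 10 central cycles, alpha 0.05)."""

    # preprocess
    filter_low_hz: float = 20.0
    filter_high_hz: float = 450.0
    filter_order: int = 4
    window_s: float = 0.25
    # activation
    window_points: int = 60
    k_sd: float = 3.0
    onset_speed_thresh_deg_s: float = 5.0
    onset_sustain_s: float = 0.5
    clip_noise_window_at_onset: bool = True
    # segmentation
    n_cycles: int = 10
    cadence_bpm: float = 60.0
    cycle_anchor: str = "peak"
    peak_prominence_frac: float = 0.25
    min_prominence_deg: float = 2.0
    min_period_frac: float = 0.5
    # metrics
    rms_mode: str = "pooled"
    # stats
    lmm_scale: str = "log"
    alpha: float = 0.05
    alpha_normality: float = 0.05
    # reproducibility / simulation
    seed: int = 0
    sim: SimConfig | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("sim") is not None:
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class TrialQC:
    """Per-trial quality-control record (one row of the QC log)."""

    participant_id: str
    session: str
    trial_label: str
    status: str = "ok"
    onset_s: float = np.nan
    threshold_uv: float = np.nan
    noise_mean_uv: float = np.nan
    noise_sd_uv: float = np.nan
    n_cycles: int = 0
    selected_start: float = np.nan
    selected_end: float = np.nan
    rms_uv: float = np.nan
    message: str = ""


def process_recording(rec: Recording, cfg: PipelineConfig) -> TrialQC:
    """Run the fixed processing chain on one trial.

    Returns a :class:`TrialQC`; any stage failure is captured in
    ``status``/``message`` rather than raised, so batch runs keep going.
    """
    qc = TrialQC(rec.participant_id, rec.session, rec.trial_label)
    try:
        onset_s = detect_movement_onset(
            rec.rom,
            rec.fs_hz,
            speed_thresh_deg_s=cfg.onset_speed_thresh_deg_s,
            sustain_s=cfg.onset_sustain_s,
        )
        qc.onset_s = onset_s
        filtered = bandpass(
            rec.emg, rec.fs_hz, cfg.filter_low_hz, cfg.filter_high_hz, cfg.filter_order
        )
        env = rms_envelope(rectify(filtered), rec.fs_hz, cfg.window_s)
        thr = estimate_threshold(
            env,
            onset_s,
            window_points=cfg.window_points,
            k_sd=cfg.k_sd,
            clip_to_onset=cfg.clip_noise_window_at_onset,
        )
        qc.threshold_uv = thr.threshold
        qc.noise_mean_uv = thr.noise_mean
        qc.noise_sd_uv = thr.noise_sd
        cenv = apply_threshold(env, thr)
        cycles = detect_cycles(
            rec.rom,
            rec.fs_hz,
            cadence_bpm=cfg.cadence_bpm,
            min_period_frac=cfg.min_period_frac,
            prominence_frac=cfg.peak_prominence_frac,
            min_prominence_deg=cfg.min_prominence_deg,
            anchor=cfg.cycle_anchor,
        )
        qc.n_cycles = len(cycles)
        cycles = select_central(cycles, k=cfg.n_cycles)
        qc.selected_start, qc.selected_end = cycles.selected_span
        qc.rms_uv = total_rms(cenv, cycles, mode=cfg.rms_mode)
    except VibemgError as exc:
        qc.status = "failed"
        qc.message = f"{type(exc).__name__}: {exc}"
    return qc


def _iter_recordings(study) -> Iterable[Recording]:
    if isinstance(study, (str, Path)):
        for manifest in load_study(study):
            yield from iter_session_recordings(manifest)
    else:
        for item in study:
            if isinstance(item, SessionManifest):
                yield from iter_session_recordings(item)
            else:
                yield item


def run_process(
    cfg: PipelineConfig, study
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process a whole study into a ratio table plus a per-trial QC log.

    ``study`` may be a study-root directory, an iterable of
    :class:`SessionManifest`, or an iterable of :class:`Recording` (the
    in-memory path used with the simulator).
    """
    qcs = [process_recording(rec, cfg) for rec in _iter_recordings(study)]
    qc_df = pd.DataFrame([asdict(q) for q in qcs], columns=QC_COLUMNS)
    ok = qc_df[qc_df["status"] == "ok"]
    n_failed = len(qc_df) - len(ok)
    if n_failed:
        warnings.warn(f"{n_failed} trial(s) failed QC and were excluded", stacklevel=2)
    trial_rms = ok[["participant_id", "session", "trial_label", "rms_uv"]]
    ratio_df = build_ratio_table(trial_rms)
    return ratio_df, qc_df


def run_stats(
    cfg: PipelineConfig, ratio_df: pd.DataFrame, out_dir: str | Path | None = None
) -> RmsRatioResults:
    """Fit both statistical families on a ratio table; optionally write reports."""
    if ratio_df.empty:
        raise StatsError("empty ratio table: nothing to analyse")
    model = RmsRatioModel(
        ratio_df,
        scale=cfg.lmm_scale,
        alpha=cfg.alpha,
        alpha_normality=cfg.alpha_normality,
    )
    results = model.fit()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.save(out)
        results.plot_boxplots(out / "ratio_boxplots.png")
    return results


def run_all(
    cfg: PipelineConfig,
    out_dir: str | Path,
    study_root: str | Path | None = None,
    write_signals: bool = False,
) -> RmsRatioResults:
    """Full run: simulate (or ingest) → process → stats → report + provenance.

    With no ``study_root`` the study is synthesized from ``cfg.sim`` (by
    default streamed in memory; ``write_signals=True`` additionally writes the
    trial CSV tree under ``out_dir/study``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if study_root is None:
        sim = cfg.sim if cfg.sim is not None else SimConfig(seed=cfg.seed)
        if write_signals:
            study_root = out / "study"
            simulate_study(sim, study_root)
            ratio_df, qc_df = run_process(cfg, study_root)
        else:
            ratio_df, qc_df = run_process(cfg, iter_study(sim))
    else:
        ratio_df, qc_df = run_process(cfg, study_root)
    ratio_df.to_csv(out / "ratios.csv", index=False)
    qc_df.to_csv(out / "qc.csv", index=False)
    results = run_stats(cfg, ratio_df, out)
    provenance = {
        "vibemg_version": __version__,
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": cfg.to_dict(),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2), encoding="utf-8")
    return results
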