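"""Synthetic two-session crossover study generator.

Emulates the study design the analysis assumes: each participant performs, in
each of two sessions (control and fmv), one baseline trial and seven follow-up
trials of 1-minute elbow flexion-extension at 60 bpm, recorded as synchronized
sEMG (µV, 1024 Hz) and elbow angle (degrees).

Signal model per trial:

* **ROM** — a quiescent lead-in at the resting angle, then a sinusoidal
  flexion-extension at the working cadence (half-amplitude 45°, i.e. 90°
  peak-to-peak) plus small low-pass-filtered angle noise.
* **EMG** — band-limited (20–450 Hz shaped) Gaussian carrier noise,
  amplitude-modulated by a raised-cosine burst envelope gated to the
  extension phase of each cycle (the triceps is the elbow extensor), riding
  on additive white instrumentation noise that is present throughout,
  lead-in included.  The burst gain is
  ``burst_amplitude_uv * exp(subject_effect) * exp(trial_noise) * trial_ratio``
  with a log-normal subject effect drawn once per participant (shared by both
  sessions — the within-subject crossover) and log-normal trial-to-trial
  jitter.

``trial_ratio`` is 1 for every baseline trial and follows the configured
``effect_profile`` for follow-up trials, so the post/pre ratio the pipeline
estimates has a known ground truth.  The default fmv profile attenuates
activation to ~0.8–0.86 for the first 20 minutes and relaxes toward 1
afterwards; the control profile is 1 everywhere.

All randomness flows from the single ``seed``: regenerating with the same
config reproduces every sample exactly.  :func:`simulate_ratio_table` is a
fast ratio-level companion generator (no raw signals) for exercising the
statistical layer at many Monte-Carlo replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .io import (
    POST_LABELS,
    SESSIONS,
    TRIAL_LABELS,
    FOLLOW_UP_MIN,
    Recording,
    SessionManifest,
    write_manifest,
    write_trial,
)

__all__ = [
    "POST_MINUTES",
    "SimConfig",
    "default_effect_profile",
    "fmv_table_profile",
    "simulate_rom",
    "simulate_emg",
    "simulate_trial",
    "iter_study",
    "simulate_study",
    "simulate_ratio_table",
]

POST_MINUTES = tuple(FOLLOW_UP_MIN[lab] for lab in POST_LABELS)


def fmv_table_profile() -> dict[int, float]:
    """Default fmv attenuation profile: suppressed ~20 min, then recovery."""
    return {0: 0.84, 5: 0.80, 10: 0.86, 15: 0.84, 20: 0.85, 25: 0.97, 30: 0.93}


def default_effect_profile() -> dict[str, dict[int, float]]:
    return {
        "control": {m: 1.0 for m in POST_MINUTES},
        "fmv": fmv_table_profile(),
    }


@dataclass
class SimConfig:
    """Study-level simulation parameters (defaults are the study conditions)."""

    n_participants: int = 30
    fs_hz: float = 1024.0
    trial_s: float = 60.0
    cadence_bpm: float = 60.0
    rom_amplitude_deg: float = 45.0  # half-amplitude; peak-to-peak 90
    rom_rest_deg: float = 10.0
    rom_noise_deg: float = 0.15
    burst_amplitude_uv: float = 80.0
    burst_duty: float = 0.4
    noise_sd_uv: float = 8.0
    subject_sd_log: float = 0.3
    trial_jitter_log: float = 0.1
    effect_profile: dict[str, dict[int, float]] = field(default_factory=default_effect_profile)
    lead_in_s: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burst_amplitude_uv < 0 or self.noise_sd_uv < 0:
            raise ValueError("amplitudes must be non-negative")
        for session in SESSIONS:
            prof = self.effect_profile.get(session, {})
            missing = [m for m in POST_MINUTES if m not in prof]
            if missing:
                raise ValueError(f"effect_profile[{session!r}] missing minute(s) {missing}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "effect_profile" in d and d["effect_profile"] is not None:
            d["effect_profile"] = {
                s: {int(k): float(v) for k, v in prof.items()}
                for s, prof in d["effect_profile"].items()
            }
        return cls(**d)


def _movement_phase(cfg: SimConfig) -> np.ndarray:
    n_mov = int(round(cfg.trial_s * cfg.fs_hz))
    t = np.arange(n_mov) / cfg.fs_hz
    return 2 * np.pi * (cfg.cadence_bpm / 60.0) * t


def simulate_rom(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Joint-angle trace: lead-in at rest, then sinusoidal cycling plus noise."""
    n_lead = int(round(cfg.lead_in_s * cfg.fs_hz))
    phase = _movement_phase(cfg)
    movement = cfg.rom_rest_deg + cfg.rom_amplitude_deg * (1.0 - np.cos(phase))
    rom = np.concatenate([np.full(n_lead, cfg.rom_rest_deg), movement])
    if cfg.rom_noise_deg > 0:
        white = rng.standard_normal(len(rom))
        sos = signal.butter(2, 3.0, btype="low", fs=cfg.fs_hz, output="sos")
        colored = signal.sosfilt(sos, white)
        sd = np.std(colored)
        if sd > 0:
            rom = rom + colored * (cfg.rom_noise_deg / sd)
    return rom


def _burst_gate(cfg: SimConfig, n_total: int) -> np.ndarray:
    """Raised-cosine burst envelope centred on mid-extension of each cycle."""
    n_lead = n_total - int(round(cfg.trial_s * cfg.fs_hz))
    phase = _movement_phase(cfg)
    # flexion peak at phase pi; extension (angle decreasing) on (pi, 2*pi)
    u = np.mod(phase - 1.5 * np.pi + np.pi, 2 * np.pi) - np.pi
    half_width = np.pi * cfg.burst_duty
    gate = np.where(
        np.abs(u) < half_width, np.cos(np.pi * u / (2 * half_width)) ** 2, 0.0
    )
    return np.concatenate([np.zeros(n_lead), gate])


def simulate_emg(
    rom: np.ndarray,
    cfg: SimConfig,
    subject_effect: float = 0.0,
    trial_log_noise: float = 0.0,
    trial_ratio: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Burst-modulated band-limited EMG matching a simulated ROM trace."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = len(rom)
    gate = _burst_gate(cfg, n)
    gain = (
        cfg.burst_amplitude_uv
        * np.exp(subject_effect + trial_log_noise)
        * trial_ratio
    )
    sos = signal.butter(4, [20.0, 450.0], btype="bandpass", fs=cfg.fs_hz, output="sos")
    carrier = signal.sosfilt(sos, rng.standard_normal(n))
    sd = np.std(carrier)
    if sd > 0:
        carrier /= sd
    white = rng.normal(0.0, cfg.noise_sd_uv, n) if cfg.noise_sd_uv > 0 else 0.0
    return gain * gate * carrier + white


def simulate_trial(
    cfg: SimConfig,
    participant_id: str,
    session: str,
    trial_label: str,
    subject_effect: float,
    trial_ratio: float,
    rng: np.random.Generator,
) -> Recording:
    rom = simulate_rom(cfg, rng)
    trial_log_noise = rng.normal(0.0, cfg.trial_jitter_log) if cfg.trial_jitter_log > 0 else 0.0
    emg = simulate_emg(rom, cfg, subject_effect, trial_log_noise, trial_ratio, rng)
    return Recording(
        participant_id=participant_id,
        session=session,
        trial_label=trial_label,
        fs_hz=cfg.fs_hz,
        emg=emg,
        rom=rom,
    )


def iter_study(cfg: SimConfig):
    """Yield every trial Recording of the study in a fixed deterministic order.

    Order: participant-major, then session (control, fmv), then protocol
    trial order.  A single generator seeded from ``cfg.seed`` drives every
    draw, so the stream is fully reproducible.
    """
    rng = np.random.default_rng(cfg.seed)
    for p in range(cfg.n_participants):
        pid = f"P{p + 1:02d}"
        subject_effect = (
            rng.normal(0.0, cfg.subject_sd_log) if cfg.subject_sd_log > 0 else 0.0
        )
        for session in SESSIONS:
            for label in TRIAL_LABELS:
                ratio = (
                    1.0
                    if label == "pre"
                    else cfg.effect_profile[session][FOLLOW_UP_MIN[label]]
                )
                yield simulate_trial(cfg, pid, session, label, subject_effect, ratio, rng)


def simulate_study(cfg: SimConfig, out_dir: str | Path) -> list[Path]:
    """Write the full study tree (trial CSVs + session manifests) to disk.

    Returns the manifest paths.  Byte-identical across runs with the same
    config and seed.
    """
    out = Path(out_dir)
    manifest_paths: list[Path] = []
    current: SessionManifest | None = None
    for rec in iter_study(cfg):
        sess_dir = out / rec.participant_id / rec.session
        if (
            current is None
            or current.participant_id != rec.participant_id
            or current.session != rec.session
        ):
            if current is not None:
                path = (out / current.participant_id / current.session) / "manifest.yaml"
                write_manifest(current, path)
                manifest_paths.append(path)
            sess_dir.mkdir(parents=True, exist_ok=True)
            current = SessionManifest(
                participant_id=rec.participant_id,
                session=rec.session,
                metadata={"generator": "vibemg.simulate", "seed": cfg.seed},
            )
        fname = f"{rec.trial_label}.csv"
        write_trial(rec, sess_dir / fname)
        current.trials.append((rec.trial_label, fname))
    if current is not None:
        path = (out / current.participant_id / current.session) / "manifest.yaml"
        write_manifest(current, path)
        manifest_paths.append(path)
    return manifest_paths


def simulate_ratio_table(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    resid_sd_log: float = 0.2,
) -> pd.DataFrame:
    """Draw a ratio table directly, without synthesizing raw signals.

    Generative model on the log scale:
    ``log ratio_{i,s,t} = log r_{s,t} + b_i + e_{i,s,t}`` with a per-participant
    intercept ``b_i ~ N(0, subject_sd_log)`` shared across sessions and
    residual ``e ~ N(0, resid_sd_log)``.  With the defaults the ratio
    dispersion is ~0.3, matching the magnitudes the full recordings cannot
    produce cheaply at many replicates.  Intended for Monte-Carlo studies of
    the statistical layer; the signal-level generator remains the end-to-end
    reference.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rows = []
    for p in range(cfg.n_participants):
        pid = f"P{p + 1:02d}"
        b = rng.normal(0.0, cfg.subject_sd_log) if cfg.subject_sd_log > 0 else 0.0
        for session in SESSIONS:
            for label in POST_LABELS:
                minute = FOLLOW_UP_MIN[label]
                true_r = cfg.effect_profile[session][minute]
                e = rng.normal(0.0, resid_sd_log) if resid_sd_log > 0 else 0.0
                rows.append(
                    {
                        "participant_id": pid,
                        "session": session,
                        "trial_label": label,
                        "follow_up_min": minute,
                        "pre_rms_uv": 1.0,
                        "post_rms_uv": float(true_r * np.exp(b + e)),
                        "ratio": float(true_r * np.exp(b + e)),
                    }
                )
    return pd.DataFrame(rows)
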