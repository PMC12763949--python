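"""Trial and study I/O.

A *trial* is one synchronized recording of raw surface EMG (µV) and elbow
joint angle / range of motion (degrees), stored as a plain CSV with header
``time_s, emg_uV, rom_deg`` (comma separator, '.' decimal, UTF-8).  A *session*
(control or fmv) groups one baseline ``pre`` trial and seven ``post`` trials
taken every 5 minutes over a 30-minute follow-up; a YAML manifest per session
maps trial labels to relative file paths.  Study layout on disk::

    study_root/<participant_id>/<session>/manifest.yaml
    study_root/<participant_id>/<session>/<trial>.csv

Exports from acquisition systems with different column names can be ingested
by passing ``column_map`` to :func:`read_trial` (e.g. ``{"rom": "rom_deg"}``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ManifestError, TrialDataError, TrialFormatError

__all__ = [
    "SESSIONS",
    "TRIAL_LABELS",
    "POST_LABELS",
    "FOLLOW_UP_MIN",
    "Recording",
    "SessionManifest",
    "read_trial",
    "write_trial",
    "read_manifest",
    "write_manifest",
    "load_study",
    "iter_session_recordings",
]

SESSIONS = ("control", "fmv")

#: Trial labels in protocol order: baseline, then follow-ups every 5 min.
TRIAL_LABELS = ("pre", "post", "post5", "post10", "post15", "post20", "post25", "post30")
POST_LABELS = TRIAL_LABELS[1:]

#: Follow-up time in minutes after the intervention window.  The baseline is
#: recorded before the 5-minute intervention/rest period and is assigned the
#: nominal offset -5.
FOLLOW_UP_MIN = {
    "pre": -5,
    "post": 0,
    "post5": 5,
    "post10": 10,
    "post15": 15,
    "post20": 20,
    "post25": 25,
    "post30": 30,
}

REQUIRED_COLUMNS = ("time_s", "emg_uV", "rom_deg")

#: Hard lower bound on trial duration: the pre-movement noise window plus a
#: handful of movement cycles cannot fit in less.
MIN_TRIAL_S = 10.0
NOMINAL_TRIAL_S = 60.0


@dataclass
class Recording:
    """One trial's synchronized sEMG and joint-angle streams.

    Parameters
    ----------
    participant_id : str
        Opaque participant identifier.
    session : str
        ``"control"`` or ``"fmv"``.
    trial_label : str
        One of :data:`TRIAL_LABELS`.
    fs_hz : float
        Sampling rate of both streams, Hz.
    emg : ndarray
        Raw sEMG samples, µV.
    rom : ndarray
        Elbow joint angle, degrees, on the same timeline as ``emg``.
    """

    participant_id: str
    session: str
    trial_label: str
    fs_hz: float
    emg: np.ndarray
    rom: np.ndarray
    duration_tol_s: float = 5.0

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        self.rom = np.asarray(self.rom, dtype=float)
        if self.session not in SESSIONS:
            raise TrialDataError(f"unknown session {self.session!r}")
        if self.trial_label not in TRIAL_LABELS:
            raise TrialDataError(f"unknown trial label {self.trial_label!r}")
        if self.fs_hz <= 0:
            raise TrialDataError(f"fs_hz must be positive, got {self.fs_hz}")
        if self.emg.ndim != 1 or self.rom.ndim != 1:
            raise TrialDataError("emg and rom must be 1-D sample streams")
        if len(self.emg) != len(self.rom):
            raise TrialDataError(
                f"emg and rom must share a timeline: {len(self.emg)} vs {len(self.rom)} samples"
            )
        if len(self.emg) == 0:
            raise TrialDataError("empty trial rejected")
        if not np.all(np.isfinite(self.emg)):
            i = int(np.flatnonzero(~np.isfinite(self.emg))[0])
            raise TrialDataError(f"emg contains non-finite value at sample {i}")
        if self.duration_s < MIN_TRIAL_S:
            raise TrialDataError(
                f"trial duration {self.duration_s:.2f} s below hard minimum {MIN_TRIAL_S} s"
            )
        if abs(self.duration_s - NOMINAL_TRIAL_S) > self.duration_tol_s:
            warnings.warn(
                f"trial {self.participant_id}/{self.session}/{self.trial_label}: "
                f"duration {self.duration_s:.1f} s deviates from nominal {NOMINAL_TRIAL_S:.0f} s",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return len(self.emg)

    @property
    def duration_s(self) -> float:
        return len(self.emg) / self.fs_hz

    @property
    def follow_up_min(self) -> int:
        return FOLLOW_UP_MIN[self.trial_label]

    def time(self) -> np.ndarray:
        """Sample times in seconds from trial start (0-based)."""
        return np.arange(self.n_samples) / self.fs_hz


@dataclass
class SessionManifest:
    """Ordered listing of one participant-session's trial files."""

    participant_id: str
    session: str
    trials: list[tuple[str, str]] = field(default_factory=list)  # (label, relative path)
    metadata: dict = field(default_factory=dict)
    root: Path | None = None  # directory the relative paths resolve against

    def validate(self) -> None:
        labels = [lab for lab, _ in self.trials]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ManifestError(
                f"{self.participant_id}/{self.session}: duplicate trial label(s) {dup}"
            )
        unknown = [l for l in labels if l not in TRIAL_LABELS]
        if unknown:
            raise ManifestError(f"{self.participant_id}/{self.session}: unknown label(s) {unknown}")
        if labels.count("pre") != 1:
            raise ManifestError(
                f"{self.participant_id}/{self.session}: exactly one 'pre' trial required"
            )
        posts = [l for l in labels if l != "pre"]
        if posts != sorted(posts, key=FOLLOW_UP_MIN.get):
            raise ManifestError(
                f"{self.participant_id}/{self.session}: post trials not in follow-up order"
            )
        missing = [l for l in TRIAL_LABELS if l not in labels]
        if missing:
            warnings.warn(
                f"{self.participant_id}/{self.session}: missing trial(s) {missing}; "
                "analysis proceeds on the unbalanced data",
                stacklevel=2,
            )

    def path_for(self, label: str) -> Path:
        for lab, rel in self.trials:
            if lab == label:
                base = self.root if self.root is not None else Path(".")
                return base / rel
        raise KeyError(label)


def _infer_fs(time_s: np.ndarray) -> float:
    dt = np.diff(time_s)
    if np.any(dt <= 0):
        i = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise TrialDataError(f"time_s not strictly increasing at row {i}")
    return float(np.round(1.0 / np.median(dt)))


def read_trial(
    path: str | Path,
    participant_id: str = "unknown",
    session: str = "control",
    trial_label: str = "pre",
    fs_hz: float | None = None,
    column_map: dict[str, str] | None = None,
) -> Recording:
    """Read one trial CSV into a :class:`Recording`.

    The sampling rate is inferred from the reciprocal of the median time step,
    rounded to the nearest integer Hz, unless ``fs_hz`` overrides it.
    ``column_map`` renames foreign column headers onto the required
    ``time_s, emg_uV, rom_deg`` before validation (converter hook for
    third-party exports).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise TrialFormatError(f"{path}: missing required column {col!r}")
    time_s = df["time_s"].to_numpy(dtype=float)
    emg = df["emg_uV"].to_numpy(dtype=float)
    if np.any(np.isnan(emg)):
        i = int(np.flatnonzero(np.isnan(emg))[0])
        raise TrialDataError(f"{path}: NaN in emg_uV, first at data row {i}")
    if fs_hz is None:
        fs_hz = _infer_fs(time_s)
    else:
        _infer_fs(time_s)  # still enforce monotonic time
    return Recording(
        participant_id=participant_id,
        session=session,
        trial_label=trial_label,
        fs_hz=fs_hz,
        emg=emg,
        rom=df["rom_deg"].to_numpy(dtype=float),
    )


def write_trial(rec: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` to the neutral CSV dialect.

    Values are printed with 12 significant digits, so a read-back agrees with
    the original well within 1e-9 relative error.
    """
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": rec.time(), "emg_uV": rec.emg, "rom_deg": rec.rom}
    )
    try:
        df.to_csv(path, index=False, float_format="%.12g")
    except OSError as exc:
        raise OSError(f"cannot write trial file {path}: {exc}") from exc


class _StrictLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys (duplicate trial labels)."""


def _no_duplicates(loader: _StrictLoader, node: yaml.MappingNode):  # pragma: no cover - thin
    seen = set()
    for key_node, _ in node.value:
        key = loader.construct_object(key_node, deep=True)
        if key in seen:
            raise ManifestError(f"duplicate key {key!r} in manifest mapping")
        seen.add(key)
    return loader.construct_mapping(node, deep=True)


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _no_duplicates
)


def write_manifest(manifest: SessionManifest, path: str | Path) -> None:
    doc = {
        "participant_id": manifest.participant_id,
        "session": manifest.session,
        "trials": {lab: rel for lab, rel in manifest.trials},
        "metadata": manifest.metadata,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def read_manifest(path: str | Path) -> SessionManifest:
    path = Path(path)
    doc = yaml.load(path.read_text(encoding="utf-8"), Loader=_StrictLoader)
    if not isinstance(doc, dict) or "trials" not in doc:
        raise ManifestError(f"{path}: not a session manifest")
    trials = list(doc["trials"].items())
    # present trials in protocol order regardless of file order
    trials.sort(key=lambda t: FOLLOW_UP_MIN.get(t[0], 99))
    m = SessionManifest(
        participant_id=str(doc.get("participant_id", path.parent.parent.name)),
        session=str(doc.get("session", path.parent.name)),
        trials=trials,
        metadata=doc.get("metadata") or {},
        root=path.parent,
    )
    m.validate()
    return m


def load_study(root: str | Path) -> list[SessionManifest]:
    """Load every session manifest under ``root`` (see module docstring layout).

    Participants with missing trials are retained with a warning — the
    downstream mixed model tolerates unbalanced data.  An empty directory
    yields an empty list with a warning.
    """
    root = Path(root)
    manifests = [read_manifest(p) for p in sorted(root.glob("*/*/manifest.yaml"))]
    if not manifests:
        warnings.warn(f"no session manifests found under {root}", stacklevel=2)
    return manifests


def iter_session_recordings(manifest: SessionManifest):
    """Yield the manifest's trials as :class:`Recording` objects, in order."""
    for label, _rel in manifest.trials:
        yield read_trial(
            manifest.path_for(label),
            participant_id=manifest.participant_id,
            session=manifest.session,
            trial_label=label,
        )
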