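"""File formats, manifests and run configuration.

Formats are deliberately plain: WAV for audio, delimited text (CSV) for
envelopes, EEG matrices, keyword/response event tables, manifests and result
tables, JSON for configuration and run metadata.  Envelope/EEG CSVs carry a
one-line ``key=value`` header with the sampling rate and trial id; matrices
are stored samples-in-rows, channels-in-columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .dsp import EEGRecord, Envelope, MODEL_RATE_HZ
from .inference import KeywordInterval, make_windows
from .simulate import ConditionSpec, EEGSimSpec, SimConfig, SimulatedSubject

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["trial_id", "window_index", "stream", "onset_s", "offset_s", "response"]
MANIFEST_COLUMNS = [
    "subject", "condition", "trial_id",
    "target_envelope_path", "masker_envelope_path", "eeg_path", "events_path", "seed",
]

__all__ = [
    "read_wav",
    "write_wav",
    "write_envelope_csv",
    "read_envelope_csv",
    "write_eeg_csv",
    "read_eeg_csv",
    "write_events_csv",
    "read_events_csv",
    "windows_from_events",
    "write_decoder_csv",
    "read_decoder_csv",
    "load_manifest",
    "write_dataset",
    "load_dataset",
    "RunConfig",
    "write_run_metadata",
]


# ---------------------------------------------------------------------------
# WAV


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a mono WAV file (PCM 16/24/32-bit or float) as float in [-1, 1]."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(rate)


def write_wav(path, samples: np.ndarray, rate_hz: float) -> None:
    """Write a mono float32 WAV file."""
    wavfile.write(path, int(round(rate_hz)), np.asarray(samples, dtype=np.float32))


# ---------------------------------------------------------------------------
# headers for delimited signal files


def _write_header_csv(path, arr2d: np.ndarray, rate_hz: float, trial_id: str | None) -> None:
    header = f"rate_hz={rate_hz},trial_id={trial_id if trial_id is not None else ''}"
    np.savetxt(path, arr2d, delimiter=",", header=header, comments="# ")


def _read_header_csv(path) -> tuple[np.ndarray, float, str | None]:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise ValueError(f"{path}: missing rate_hz/trial_id header line")
    fields = dict(kv.split("=", 1) for kv in first.lstrip("# ").strip().split(","))
    data = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    trial_id = fields.get("trial_id") or None
    return data, float(fields["rate_hz"]), trial_id


def write_envelope_csv(path, env: Envelope) -> None:
    _write_header_csv(path, env.samples[:, None], env.rate_hz, env.trial_id)


def read_envelope_csv(path) -> Envelope:
    data, rate, trial_id = _read_header_csv(path)
    return Envelope(data[:, 0], rate, trial_id=trial_id)


def write_eeg_csv(path, eeg: EEGRecord, trial_id: str | None = None) -> None:
    # stored samples-in-rows, channels-in-columns
    _write_header_csv(path, eeg.data.T, eeg.rate_hz, trial_id)


def read_eeg_csv(path) -> EEGRecord:
    data, rate, _ = _read_header_csv(path)
    return EEGRecord(data.T, rate)


# ---------------------------------------------------------------------------
# events (keyword windows + responses)


def write_events_csv(path, trial_id: str, windows) -> None:
    rows = []
    for w in windows:
        for kw in (w.target_kw, w.masker_kw):
            rows.append(
                {
                    "trial_id": trial_id,
                    "window_index": w.index,
                    "stream": kw.stream,
                    "onset_s": kw.onset_s,
                    "offset_s": kw.offset_s,
                    "response": w.response,
                }
            )
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing event columns {sorted(missing)}")
    return df


def windows_from_events(df: pd.DataFrame, trial_id: str | None = None):
    """Rebuild ResponseWindows from an event table (one trial)."""
    if trial_id is not None:
        df = df[df.trial_id == trial_id]
    target_kws, masker_kws, responses = [], [], []
    for idx in sorted(df.window_index.unique()):
        grp = df[df.window_index == idx]
        t = grp[grp.stream == "target"].iloc[0]
        m = grp[grp.stream == "masker"].iloc[0]
        target_kws.append(KeywordInterval(t.onset_s, t.offset_s, "target"))
        masker_kws.append(KeywordInterval(m.onset_s, m.offset_s, "masker"))
        responses.append(t.response)
    return make_windows(target_kws, masker_kws, responses)


# ---------------------------------------------------------------------------
# decoder serialization


def write_decoder_csv(path, decoder) -> None:
    header = (
        f"n_channels={decoder.n_channels},n_lags={decoder.spec.n_lags},"
        f"lambda={decoder.ridge_lambda},rate_hz={decoder.spec.rate_hz},"
        f"min_lag_ms={decoder.spec.min_lag_ms},max_lag_ms={decoder.spec.max_lag_ms}"
    )
    np.savetxt(path, decoder.as_channel_lag(), delimiter=",", header=header, comments="# ")


def read_decoder_csv(path):
    from .decoding import Decoder, LagSpec

    with open(path) as fh:
        first = fh.readline()
    fields = dict(kv.split("=", 1) for kv in first.lstrip("# ").strip().split(","))
    W = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    spec = LagSpec(
        float(fields["min_lag_ms"]), float(fields["max_lag_ms"]), float(fields["rate_hz"])
    )
    return Decoder(W.ravel(), int(fields["n_channels"]), spec, float(fields["lambda"]))


# ---------------------------------------------------------------------------
# manifests and datasets


def load_manifest(path) -> pd.DataFrame:
    """Validated dataset manifest; referenced files must exist."""
    df = pd.read_csv(path)
    missing_cols = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing manifest columns {sorted(missing_cols)}")
    if df.trial_id.duplicated().any():
        dupes = df.trial_id[df.trial_id.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate trial_id values {dupes}")
    base = Path(path).parent
    offenders = []
    path_cols = ["target_envelope_path", "masker_envelope_path", "eeg_path", "events_path"]
    for row_number, row in enumerate(df.itertuples(), start=2):
        for col in path_cols:
            p = base / getattr(row, col)
            if not p.exists():
                offenders.append(f"row {row_number}: missing {p}")
    if offenders:
        raise FileNotFoundError("; ".join(offenders))
    return df


def write_dataset(dataset: Sequence[SimulatedSubject], out_dir) -> Path:
    """Write envelopes/EEG/events per trial plus a manifest CSV; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for subject in dataset:
        sdir = out / subject.subject_id
        sdir.mkdir(exist_ok=True)
        for t in subject.trials:
            stem = t.trial_id
            write_envelope_csv(sdir / f"{stem}_target.csv", t.envelope_target)
            write_envelope_csv(sdir / f"{stem}_masker.csv", t.envelope_masker)
            write_eeg_csv(sdir / f"{stem}_eeg.csv", t.eeg, trial_id=stem)
            write_events_csv(sdir / f"{stem}_events.csv", stem, t.windows)
            rows.append(
                {
                    "subject": subject.subject_id,
                    "condition": t.condition,
                    "trial_id": stem,
                    "target_envelope_path": f"{subject.subject_id}/{stem}_target.csv",
                    "masker_envelope_path": f"{subject.subject_id}/{stem}_masker.csv",
                    "eeg_path": f"{subject.subject_id}/{stem}_eeg.csv",
                    "events_path": f"{subject.subject_id}/{stem}_events.csv",
                    "seed": subject.seed_entropy,
                }
            )
    manifest_path = out / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest_path, index=False)
    return manifest_path


def load_dataset(manifest_path) -> list[SimulatedSubject]:
    """Rebuild SimulatedSubjects (without latent trajectories) from a manifest."""
    from .decoding import TrialRecord

    df = load_manifest(manifest_path)
    base = Path(manifest_path).parent
    subjects: dict[str, SimulatedSubject] = {}
    for row in df.itertuples():
        events = read_events_csv(base / row.events_path)
        trial = TrialRecord(
            eeg=read_eeg_csv(base / row.eeg_path),
            envelope_target=read_envelope_csv(base / row.target_envelope_path),
            envelope_masker=read_envelope_csv(base / row.masker_envelope_path),
            condition=row.condition,
            trial_id=row.trial_id,
            windows=windows_from_events(events, row.trial_id),
        )
        subjects.setdefault(
            row.subject, SimulatedSubject(row.subject, [], seed_entropy=int(row.seed))
        ).trials.append(trial)
    return list(subjects.values())


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Single source of truth for an end-to-end pipeline run."""

    out_dir: str = "results"
    master_seed: int = 0
    n_subjects: int = 4
    n_trials_per_condition: int = 8
    conditions: tuple[ConditionSpec, ...] = field(
        default_factory=lambda: SimConfig().conditions
    )
    n_channels: int = 31
    snr: float = 0.05
    ridge_lambda: float = 10.0**0.5
    scope: str = "target_windows"
    filler: str = "mixture"
    switch_duration_s: float = 2.0
    grid_scopes: tuple[str, ...] = ("segments", "target_windows")
    grid_fillers: tuple[str, ...] = ("mixture", "target", "masker", "noise", "other_speech")
    grid_speeds: tuple[float, ...] = (1.0, 2.0, 3.0)
    run_grid: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "conditions" in raw:
            raw["conditions"] = tuple(ConditionSpec(**c) for c in raw["conditions"])
        for key in ("grid_scopes", "grid_fillers", "grid_speeds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_subjects=self.n_subjects,
            n_trials_per_condition=self.n_trials_per_condition,
            conditions=self.conditions,
            eeg=EEGSimSpec(n_channels=self.n_channels, snr=self.snr),
            master_seed=self.master_seed,
        )

    def to_jsonable(self) -> dict:
        return json.loads(json.dumps(asdict(self)))


def write_run_metadata(out_dir, config: RunConfig, extra: dict | None = None) -> Path:
    """Echo every parameter and seed of a run into a metadata JSON."""
    import platform

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": config.to_jsonable(),
        "python": platform.python_version(),
    }
    if extra:
        meta.update(extra)
    path = out / "run_metadata.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path
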