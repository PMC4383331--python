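"""Recording container and on-disk formats.

A :class:`Recording` holds one subject's continuous multi-channel EEG in μV,
its event table (stimulus onsets, stimulus codes, button-press onsets) and
optional clinical metadata.  The native *fixture* format is a little-endian
32-bit float channel × sample matrix plus a JSON sidecar and a TSV event
table; it round-trips bit-exactly.  EDF/BDF files can be read through
:mod:`mne` when it is installed; there is no EDF/BDF writer.

All electrode selection throughout the package is by channel *label*, never
by row index, so channel order is an implementation detail that the formats
nevertheless preserve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "SeverityRecord",
    "FormatError",
    "make_event_table",
    "validate_event_table",
    "read_recording",
    "write_recording",
    "read_metadata_table",
    "write_metadata_table",
]

#: Recognised EOG channel labels (vertical / horizontal electro-oculogram).
EOG_LABELS = ("EOGv", "EOGh")

EVENT_COLUMNS = ("onset_sample", "code", "response_sample")


class FormatError(ValueError):
    """A file or in-memory structure violates the format contract."""


@dataclass
class SeverityRecord:
    """Clinical covariates recorded for patients.

    hospitalizations
        Number of documented hospitalizations (≥ 1 for patients).
    dose_load
        Dose-wise medication load, arbitrary units.
    saps, sans
        Counts of positive / negative symptoms.
    """

    hospitalizations: int
    dose_load: float
    saps: int
    sans: int

    def __post_init__(self) -> None:
        if min(self.hospitalizations, self.dose_load, self.saps, self.sans) < 0:
            raise FormatError("severity covariates must be non-negative")


def make_event_table(onsets, codes, responses=None) -> pd.DataFrame:
    """Build a validated event table.

    Parameters
    ----------
    onsets : sequence of int
        Stimulus onset samples, strictly increasing.
    codes : sequence of str
        Stimulus codes; the predictive-sequence epochs carry code ``"P"``.
    responses : sequence of int or None, optional
        Button-press samples; ``None``/NaN marks an absent press.
    """
    onsets = np.asarray(onsets, dtype=np.int64)
    if responses is None:
        responses = [None] * len(onsets)
    table = pd.DataFrame(
        {
            "onset_sample": onsets,
            "code": [str(c) for c in codes],
            "response_sample": pd.array(
                [None if r is None or (isinstance(r, float) and np.isnan(r)) else int(r) for r in responses],
                dtype="Int64",
            ),
        }
    )
    validate_event_table(table)
    return table


def validate_event_table(events: pd.DataFrame, n_samples: int | None = None) -> None:
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise FormatError(f"event table missing columns: {sorted(missing)}")
    onsets = events["onset_sample"].to_numpy()
    if len(onsets) and np.any(np.diff(onsets) <= 0):
        raise FormatError("event onsets must be strictly increasing")
    resp = events["response_sample"]
    present = resp.notna()
    if present.any():
        bad = resp[present].to_numpy(dtype=np.int64) <= events.loc[present, "onset_sample"].to_numpy()
        if bad.any():
            raise FormatError("response_sample must follow its onset_sample")
    if n_samples is not None and len(onsets):
        if onsets.min() < 0 or onsets.max() >= n_samples:
            raise FormatError(
                f"event onset outside signal range [0, {n_samples}): field onset_sample"
            )


@dataclass
class Recording:
    """One subject's continuous EEG with events and metadata.

    ``signal`` is channels × samples in μV (rows follow ``channel_labels``).
    ``scale_to_uv`` restores physical μV after energy normalization:
    ``signal * scale_to_uv`` is always in μV.
    """

    subject_id: str
    group: str  # healthy | patient | unknown
    channel_labels: list[str]
    fs: float
    signal: np.ndarray
    events: pd.DataFrame
    metadata: SeverityRecord | None = None
    scale_to_uv: float = 1.0
    artifact_truth: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channel_labels):
            raise FormatError(
                f"signal has {self.signal.shape[0] if self.signal.ndim == 2 else '?'} rows "
                f"but {len(self.channel_labels)} channel labels: field signal"
            )
        if self.fs <= 0:
            raise FormatError("fs must be positive")
        if self.group not in ("healthy", "patient", "unknown"):
            raise FormatError(f"unknown group {self.group!r}")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise FormatError("duplicate channel labels")
        validate_event_table(self.events, n_samples=self.signal.shape[1])

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def eeg_labels(self) -> list[str]:
        return [c for c in self.channel_labels if c not in EOG_LABELS]

    @property
    def eog_labels(self) -> list[str]:
        return [c for c in self.channel_labels if c in EOG_LABELS]

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.signal[self.channel_labels.index(label)]
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def copy_with(self, **kw) -> "Recording":
        if "signal" not in kw:
            kw["signal"] = self.signal.copy()
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# fixture format
# ---------------------------------------------------------------------------

def _fixture_paths(path: Path):
    base = path.with_suffix("") if path.suffix == ".f32" else path
    return base.with_suffix(".f32"), base.with_suffix(".json"), Path(str(base) + ".events.tsv")


def write_recording(rec: Recording, path, format: str = "fixture") -> None:
    """Write a recording.

    Only the ``fixture`` format is writable: ``<base>.f32`` raw little-endian
    float32 (channels × samples), ``<base>.json`` sidecar and
    ``<base>.events.tsv``.  The signal is stored as float32, so the round trip
    is bit-exact for float32 signals (everything the simulator emits) and
    float32-quantized otherwise.
    """
    if format != "fixture":
        raise FormatError(f"writing format {format!r} is not supported (fixture only)")
    sig_path, json_path, events_path = _fixture_paths(Path(path))
    sig = np.ascontiguousarray(rec.signal, dtype="<f4")
    sig.tofile(sig_path)
    scale = rec.scale_to_uv
    if isinstance(scale, np.ndarray):  # per-channel normalization
        scale = np.asarray(scale).ravel().tolist()
    sidecar = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "channel_labels": list(rec.channel_labels),
        "fs": rec.fs,
        "n_samples": rec.n_samples,
        "scale_to_uv": scale,
        "metadata": None
        if rec.metadata is None
        else {
            "hospitalizations": int(rec.metadata.hospitalizations),
            "dose_load": float(rec.metadata.dose_load),
            "saps": int(rec.metadata.saps),
            "sans": int(rec.metadata.sans),
        },
        "artifact_truth": None
        if rec.artifact_truth is None
        else rec.artifact_truth.to_dict(orient="list"),
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    ev = rec.events.copy()
    ev["response_sample"] = ev["response_sample"].astype("Int64")
    ev.to_csv(events_path, sep="\t", index=False, na_rep="NA")


def read_recording(path, format: str = "fixture") -> Recording:
    """Read a recording from disk.

    ``format`` is one of ``fixture``, ``edf``, ``bdf``.  EDF/BDF reading uses
    :mod:`mne` and looks for a ``<base>.events.tsv`` companion for the event
    table (EDF annotations carry no response samples).
    """
    path = Path(path)
    if format == "fixture":
        return _read_fixture(path)
    if format in ("edf", "bdf"):
        return _read_edf_like(path, format)
    raise FormatError(f"unknown format {format!r}")


def _read_fixture(path: Path) -> Recording:
    sig_path, json_path, events_path = _fixture_paths(path)
    for p in (sig_path, json_path, events_path):
        if not p.exists():
            raise FormatError(f"fixture component missing: {p}")
    meta = json.loads(json_path.read_text())
    labels = meta["channel_labels"]
    raw = np.fromfile(sig_path, dtype="<f4")
    n_ch, n_samp = len(labels), int(meta["n_samples"])
    if raw.size != n_ch * n_samp:
        raise FormatError(
            f"{sig_path}: expected {n_ch}×{n_samp} samples, found {raw.size}: field signal"
        )
    events = pd.read_csv(
        events_path, sep="\t", dtype={"onset_sample": np.int64, "code": str}, na_values=["NA"]
    )
    events["response_sample"] = pd.array(
        [None if pd.isna(v) else int(v) for v in events["response_sample"]], dtype="Int64"
    )
    sev = meta.get("metadata")
    truth = meta.get("artifact_truth")
    scale = meta.get("scale_to_uv", 1.0)
    if isinstance(scale, list):
        scale = np.asarray(scale).reshape(-1, 1)
    return Recording(
        subject_id=meta["subject_id"],
        group=meta["group"],
        channel_labels=labels,
        fs=float(meta["fs"]),
        signal=raw.reshape(n_ch, n_samp),
        events=events,
        metadata=None if sev is None else SeverityRecord(**sev),
        scale_to_uv=scale if isinstance(scale, np.ndarray) else float(scale),
        artifact_truth=None if truth is None else pd.DataFrame(truth),
    )


def _read_edf_like(path: Path, format: str) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an optional extra
        raise FormatError("reading EDF/BDF requires the 'mne' package") from exc
    reader = mne.io.read_raw_edf if format == "edf" else mne.io.read_raw_bdf
    raw = reader(path, preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # mne is in volts
    events_path = Path(str(path.with_suffix("")) + ".events.tsv")
    if events_path.exists():
        events = pd.read_csv(events_path, sep="\t", na_values=["NA"])
        events["response_sample"] = pd.array(
            [None if pd.isna(v) else int(v) for v in events["response_sample"]], dtype="Int64"
        )
    else:
        events = make_event_table([], [])
    return Recording(
        subject_id=path.stem,
        group="unknown",
        channel_labels=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        signal=signal,
        events=events,
    )


# ---------------------------------------------------------------------------
# subject metadata tables
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ("subject_id", "group", "hospitalizations", "dose_load", "saps", "sans")


def write_metadata_table(recordings: list[Recording], path) -> None:
    rows = []
    for rec in recordings:
        m = rec.metadata
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "hospitalizations": None if m is None else m.hospitalizations,
                "dose_load": None if m is None else m.dose_load,
                "saps": None if m is None else m.saps,
                "sans": None if m is None else m.sans,
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_metadata_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(METADATA_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"metadata table missing columns: {sorted(missing)}")
    return table
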