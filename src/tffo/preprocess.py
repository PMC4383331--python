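"""Raw-data preprocessing: filtering, normalization, blink removal, epoching.

Pipeline order for a recording: band-pass filter and energy-normalize,
remove ocular components with ICA, then cut stimulus-locked epochs and
apply the exclusion rules.  Every excluded event is logged with exactly one
reason, assigned by first match in the fixed precedence
``miss → saccade → amplitude`` (boundary events that cannot be cut get
reason ``other``), and exclusion is per-event: an event rejected on one
channel is dropped from all channels.

Conventions, stated once and used everywhere: sample indexing is 0-based;
user-facing times are ms relative to stimulus onset; ms→sample conversion
rounds half to even; epochs cover [-200, +1000] ms and their length is
⌊1.2·fs⌋ samples (614 at 512 Hz).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .io import EOG_LABELS, Recording

__all__ = ["EpochSet", "bandpass_normalize", "remove_blinks", "epoch_and_exclude"]

EXCLUSION_REASONS = ("miss", "saccade", "amplitude", "other")


class ConfigurationError(ValueError):
    pass


def _ms_to_samples(ms: float, fs: float) -> int:
    # round-half-to-even on sample boundaries
    return int(np.rint(ms * fs / 1e3))


@dataclass
class EpochSet:
    """One subject's surviving stimulus-locked epochs plus the audit log.

    ``data`` is (n surviving events × n channels × n samples); rows of the
    event axis follow trial order and ``event_indices`` gives each row's
    ordinal among the selected stimulus code's events.  ``exclusion_log``
    has one row per excluded event: (subject, event_index, reason).
    """

    subject_id: str
    group: str
    channel_labels: list[str]
    fs: float
    data: np.ndarray
    event_indices: list[int]
    exclusion_log: pd.DataFrame
    t0_offset_ms: float = 200.0
    metadata: object = None
    extras: dict = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.data.shape[2]) / self.fs * 1e3 - self.t0_offset_ms

    def channel_data(self, label: str) -> np.ndarray:
        try:
            row = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epoch set") from None
        return self.data[:, row, :]


def bandpass_normalize(
    rec: Recording, low: float = 0.1, high: float = 30.0, per_channel: bool = False
) -> Recording:
    """Zero-phase band-pass then total-energy normalization.

    A 4th-order Butterworth band-pass is applied forward-backward per
    channel; the recording is then scaled so the total energy Σx² over all
    channels and samples is 1 (``per_channel=True`` instead normalizes each
    channel, discarding the inter-channel amplitude topography).  The
    returned recording's ``scale_to_uv`` restores the filtered signal to
    physical μV, which is what the 75 μV exclusion rule operates on.
    """
    if not 0 < low < high < rec.fs / 2:
        raise ConfigurationError(
            f"band [{low}, {high}] Hz outside (0, Nyquist={rec.fs / 2}) Hz"
        )
    sos = butter(4, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sosfiltfilt(sos, np.asarray(rec.signal, dtype=np.float64), axis=1)
    if per_channel:
        energy = np.sum(filtered**2, axis=1, keepdims=True)
        if np.any(energy == 0):
            raise ValueError("cannot normalize: a channel has zero energy")
        scale = 1.0 / np.sqrt(energy)
    else:
        energy = float(np.sum(filtered**2))
        if energy == 0:
            raise ValueError("cannot normalize an all-zero recording")
        scale = 1.0 / math.sqrt(energy)
    return rec.copy_with(signal=filtered * scale, scale_to_uv=1.0 / scale)


def remove_blinks(
    rec: Recording,
    eog_labels: tuple = EOG_LABELS,
    threshold: float = 0.7,
    seed: int = 0,
    max_iter: int = 1000,
):
    """ICA-based removal of ocular components.

    The EEG channels (EOG excluded) are decomposed into as many independent
    components as channels; every component whose absolute Pearson
    correlation with any EOG channel exceeds ``threshold`` is zeroed and the
    signal reconstructed.  Returns ``(recording, report)`` where the report
    lists each component's strongest EOG correlation and whether it was
    removed.  If nothing crosses the threshold the signal is returned
    unchanged (exact identity).
    """
    missing = [lab for lab in eog_labels if lab not in rec.channel_labels]
    if missing or len(eog_labels) < 2:
        raise ConfigurationError(f"need >= 2 EOG channels; missing {missing}")
    if rec.n_samples < 30 * rec.fs:
        raise ConfigurationError("blink removal needs >= 30 s of signal")
    eeg_rows = [i for i, c in enumerate(rec.channel_labels) if c not in eog_labels]
    eog = np.stack([rec.channel(lab) for lab in eog_labels]).astype(np.float64)
    x = np.asarray(rec.signal[eeg_rows], dtype=np.float64).T  # samples × channels

    ica = FastICA(
        n_components=len(eeg_rows), random_state=seed, max_iter=max_iter, whiten="unit-variance"
    )
    with warnings.catch_warnings():
        # EOG identification tolerates an unconverged unmixing matrix
        warnings.simplefilter("ignore", ConvergenceWarning)
        sources = ica.fit_transform(x)

    def _corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        return 0.0 if denom == 0 else float(np.dot(a, b) / denom)

    rows = []
    removed = []
    for comp in range(sources.shape[1]):
        corrs = {lab: _corr(sources[:, comp], eog[j]) for j, lab in enumerate(eog_labels)}
        best = max(corrs, key=lambda lab: abs(corrs[lab]))
        hit = abs(corrs[best]) > threshold
        if hit:
            removed.append(comp)
        rows.append(
            {"component": comp, "eog_label": best, "correlation": corrs[best], "removed": hit}
        )
    report = pd.DataFrame(rows, columns=["component", "eog_label", "correlation", "removed"])
    if not removed:
        return rec.copy_with(), report
    sources[:, removed] = 0.0
    cleaned = ica.inverse_transform(sources).T
    signal = np.array(rec.signal, dtype=np.float64)
    signal[eeg_rows] = cleaned
    return rec.copy_with(signal=signal), report


def _detect_saccade(eog_h: np.ndarray, fs: float, threshold_uv: float) -> bool:
    """Step detector: max difference of medians of 100 ms flanks around a split."""
    w = _ms_to_samples(100.0, fs)
    n = eog_h.size
    if n < 2 * w:
        return False
    stride = max(1, w // 10)
    for split in range(w, n - w + 1, stride):
        left = np.median(eog_h[split - w : split])
        right = np.median(eog_h[split : split + w])
        if abs(right - left) > threshold_uv:
            return True
    return False


def epoch_and_exclude(
    rec: Recording,
    stim_code: str = "P",
    amp_limit_uv: float = 75.0,
    rt_window_ms: tuple = (150.0, 1150.0),
    saccade_threshold_uv: float = 40.0,
    pre_ms: float = 200.0,
    epoch_s: float = 1.2,
) -> EpochSet:
    """Cut [-200, +1000] ms epochs at every ``stim_code`` event and exclude.

    An event is excluded — from all channels — when, in precedence order:
    ``other``  the epoch would extend past a recording edge;
    ``miss``   no button press within ``rt_window_ms`` post-onset;
    ``saccade`` a step-like horizontal-EOG deflection exceeds the threshold;
    ``amplitude`` any EEG channel exceeds ``amp_limit_uv`` (physical μV,
    restored via ``scale_to_uv``) anywhere in the epoch.
    """
    events = rec.events[rec.events["code"] == stim_code].reset_index(drop=True)
    if events.empty:
        raise ConfigurationError(f"no events with code {stim_code!r}")
    fs = rec.fs
    pre = _ms_to_samples(pre_ms, fs)
    total = int(math.floor(epoch_s * fs))
    eeg_rows = [i for i, c in enumerate(rec.channel_labels) if c not in EOG_LABELS]
    eog_h_row = (
        rec.channel_labels.index("EOGh") if "EOGh" in rec.channel_labels else None
    )
    sig_uv = np.asarray(rec.signal) * rec.scale_to_uv

    kept, kept_idx, log_rows = [], [], []

    def _log(idx, reason):
        log_rows.append({"subject": rec.subject_id, "event_index": idx, "reason": reason})

    rt_lo, rt_hi = (_ms_to_samples(m, fs) for m in rt_window_ms)
    for idx, ev in events.iterrows():
        onset = int(ev["onset_sample"])
        lo, hi = onset - pre, onset - pre + total
        if lo < 0 or hi > rec.n_samples:
            _log(idx, "other")
            continue
        resp = ev["response_sample"]
        if pd.isna(resp) or not (onset + rt_lo <= int(resp) <= onset + rt_hi):
            _log(idx, "miss")
            continue
        if eog_h_row is not None and _detect_saccade(
            sig_uv[eog_h_row, lo:hi], fs, saccade_threshold_uv
        ):
            _log(idx, "saccade")
            continue
        if np.any(np.abs(sig_uv[eeg_rows, lo:hi]) > amp_limit_uv):
            _log(idx, "amplitude")
            continue
        kept.append(rec.signal[:, lo:hi])
        kept_idx.append(idx)

    data = (
        np.stack(kept)
        if kept
        else np.empty((0, len(rec.channel_labels), total), dtype=rec.signal.dtype)
    )
    return EpochSet(
        subject_id=rec.subject_id,
        group=rec.group,
        channel_labels=list(rec.channel_labels),
        fs=fs,
        data=np.asarray(data, dtype=np.float64),
        event_indices=kept_idx,
        exclusion_log=pd.DataFrame(log_rows, columns=["subject", "event_index", "reason"]),
        t0_offset_ms=pre_ms,
        metadata=rec.metadata,
    )
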