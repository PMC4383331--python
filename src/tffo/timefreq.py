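"""Discrete Stockwell transform and windowed time-frequency features.

The Stockwell transform (S-transform) is a time-frequency representation
with a Gaussian analysis window whose width scales inversely with frequency,
and with phase referenced to t = 0 — a phase-corrected relative of the
continuous wavelet transform.  Two kernel variants are implemented:

``"plain"``
    window  w(t) = exp(-π t² f²) — a unit-height Gaussian; voices grow in
    amplitude as 1/f because the window area is 1/f.
``"classic"``
    window  w(t) = |f|/√(2π) · exp(-t² f² / 2) — the unit-area Gaussian of
    the original S-transform, which preserves amplitude across voices.

Classification is invariant to a global amplitude factor but not to window
width, so both variants are kept; ``classic`` is the default because its
unit-area window makes tone energy localize at the tone's own voice.

The discrete transform treats the frame as one period (circular convolution
per voice), the standard convention for FFT-based S-transforms; the voice at
frequency zero is the signal mean.  By default the transform is applied to
the analytic representation of the real frame (negative frequencies zeroed,
positive doubled): near the Nyquist voice the two spectral images of a real
tone otherwise interfere and smear energy across neighbouring voices, while
the analytic convention keeps each tone's magnitude localized at its own
voice.  ``analytic=False`` restores the plain two-sided convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "STFeatureMap",
    "WindowSpec",
    "FeatureMatrix",
    "stockwell",
    "enumerate_windows",
    "extract_features",
]

KERNELS = ("classic", "plain")


class DataError(ValueError):
    """Input data violates an operation's precondition."""


@dataclass
class WindowSpec:
    """A rectangular region of the time-frequency plane.

    ``t_start``/``t_end`` are ms relative to stimulus onset (the [a, b]
    interval); ``f_low``/``f_high`` are Hz (the analysed band).
    """

    t_start: float
    t_end: float
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(f"empty time window [{self.t_start}, {self.t_end}]")
        if not self.f_low < self.f_high:
            raise ValueError(f"empty frequency band [{self.f_low}, {self.f_high}]")

    def as_tuple(self):
        return (self.t_start, self.t_end, self.f_low, self.f_high)

    def __str__(self) -> str:
        return f"[{self.t_start:g},{self.t_end:g}]ms×[{self.f_low:g},{self.f_high:g}]Hz"


@dataclass
class STFeatureMap:
    """Magnitude of the S-transform: time bins × frequency voices.

    ``time_axis`` is in ms relative to stimulus onset, ``freq_axis`` in Hz
    (uniform voices spaced fs/N).  The complex transform is retained in
    ``_complex`` for phase-aware diagnostics.
    """

    magnitudes: np.ndarray
    time_axis: np.ndarray
    freq_axis: np.ndarray
    _complex: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes)
        if self.magnitudes.shape != (len(self.time_axis), len(self.freq_axis)):
            raise ValueError("magnitude shape inconsistent with axes")

    def window(self, spec: WindowSpec) -> np.ndarray:
        """Return the sub-matrix of magnitudes inside ``spec`` (inclusive)."""
        tmask = (self.time_axis >= spec.t_start) & (self.time_axis <= spec.t_end)
        fmask = (self.freq_axis >= spec.f_low) & (self.freq_axis <= spec.f_high)
        if not tmask.any() or not fmask.any():
            raise ValueError(f"window {spec} selects no bins")
        return self.magnitudes[np.ix_(tmask, fmask)]


def _time_window(voice: int, n: int, kernel: str) -> np.ndarray:
    """Sampled analysis window for a voice, circularly wrapped to length n."""
    lag = np.arange(n, dtype=float)
    lag[lag > n / 2] -= n
    f = voice / n  # cycles per sample
    if kernel == "plain":
        return np.exp(-np.pi * (lag * f) ** 2)
    if kernel == "classic":
        return (f / np.sqrt(2 * np.pi)) * np.exp(-0.5 * (lag * f) ** 2)
    raise ValueError(f"unknown kernel {kernel!r}; choose from {KERNELS}")


def stockwell(
    x,
    fs: float,
    *,
    t0_offset_ms: float = 0.0,
    fmax: float | None = None,
    kernel: str = "classic",
    analytic: bool = True,
) -> STFeatureMap:
    """Discrete S-transform of a real frame.

    Parameters
    ----------
    x : 1-D array, length ≥ 8
        Signal frame (μV).
    fs : float
        Sampling rate in Hz.
    t0_offset_ms : float
        Time (ms) of stimulus onset within the frame; the returned
        ``time_axis`` is shifted so that onset is at 0 ms.
    fmax : float, optional
        Highest voice to compute (Hz).  Defaults to Nyquist (all voices
        0..N/2).  Restricting voices only drops columns; it never changes
        the values of the remaining ones.
    kernel : {"classic", "plain"}
        Analysis-window variant, see module docstring.
    analytic : bool
        Transform the analytic (one-sided spectrum) representation of the
        frame rather than the raw real frame (default True).

    Returns
    -------
    STFeatureMap with shape (N time bins, n_voices).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise DataError("stockwell needs a 1-D frame of length >= 8")
    if not np.all(np.isfinite(x)):
        raise DataError("stockwell input contains NaN/Inf")
    n = x.size
    n_half = n // 2
    voices = np.arange(n_half + 1)
    if fmax is not None:
        voices = voices[voices * fs / n <= fmax + 1e-9]
    out = np.empty((n, len(voices)), dtype=complex)
    spectrum = np.fft.fft(x)
    if analytic:
        one_sided = np.zeros_like(spectrum)
        one_sided[0] = spectrum[0]
        one_sided[1:(n + 1) // 2] = 2.0 * spectrum[1:(n + 1) // 2]
        if n % 2 == 0:
            one_sided[n // 2] = spectrum[n // 2]
        spectrum = one_sided
    idx = np.arange(n)
    for col, v in enumerate(voices):
        if v == 0:
            out[:, col] = x.mean()
            continue
        # circular convolution of x·e^{-i2πvk/N} with the voice window,
        # done in the spectral domain: shift the spectrum by v voices and
        # multiply by the window's DFT.
        g_hat = np.fft.fft(_time_window(v, n, kernel))
        out[:, col] = np.fft.ifft(spectrum[(idx + v) % n] * g_hat)
    time_axis = np.arange(n) / fs * 1e3 - t0_offset_ms
    freq_axis = voices * fs / n
    return STFeatureMap(
        magnitudes=np.abs(out), time_axis=time_axis, freq_axis=freq_axis, _complex=out
    )


# ---------------------------------------------------------------------------
# window/band enumeration
# ---------------------------------------------------------------------------

def _slide(lo: float, hi: float, width: float, step: float) -> list[tuple[float, float]]:
    out = []
    start = lo
    while start + width <= hi + 1e-9:
        out.append((start, start + width))
        start += step
    return out


def enumerate_windows(
    t_range=(0.0, 1000.0),
    time_grids=((100.0, 25.0), (500.0, 50.0)),
    f_range=(0.0, 30.0),
    freq_grids=((5.0, 1.0), (10.0, 2.0)),
) -> list[WindowSpec]:
    """Full cross product of sliding time windows × sliding frequency bands.

    Each (width, step) pair is kept together — by default 100 ms windows
    slide by 25 ms and 500 ms windows by 50 ms over the post-stimulus
    interval, while 5 Hz bands slide by 1 Hz and 10 Hz bands by 2 Hz up to
    30 Hz.  Ordering is deterministic: time-major, then frequency.
    """
    t_lo, t_hi = t_range
    f_lo, f_hi = f_range
    t_windows: list[tuple[float, float]] = []
    for width, step in time_grids:
        if width > t_hi - t_lo:
            raise ValueError(f"time width {width} exceeds span {t_hi - t_lo}")
        t_windows.extend(_slide(t_lo, t_hi, width, step))
    f_bands: list[tuple[float, float]] = []
    for width, step in freq_grids:
        if width > f_hi - f_lo:
            raise ValueError(f"band width {width} exceeds span {f_hi - f_lo}")
        f_bands.extend(_slide(f_lo, f_hi, width, step))
    return [
        WindowSpec(ts, te, fl, fh) for (ts, te) in t_windows for (fl, fh) in f_bands
    ]


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Per-subject flattened S-transform features for one grid coordinate.

    ``values`` is a DataFrame (rows = subjects, columns = flattened window
    bins, time-major); ``labels`` maps subject → group; ``skipped`` lists
    subjects with too few surviving epochs.
    """

    values: pd.DataFrame
    labels: pd.Series
    provenance: dict
    skipped: list[str] = field(default_factory=list)

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)


def average_epochs(epoch_set, electrode: str, n_events: int) -> np.ndarray:
    """Mean of the first ``n_events`` surviving epochs (trial order) on one channel."""
    data = epoch_set.channel_data(electrode)
    if data.shape[0] < n_events:
        raise DataError(
            f"subject {epoch_set.subject_id}: {data.shape[0]} surviving epochs < {n_events}"
        )
    return data[:n_events].mean(axis=0)


def extract_features(
    epoch_sets,
    labels,
    spec: WindowSpec,
    electrode: str,
    n_events: int,
    mode: str = "average-then-transform",
    kernel: str = "classic",
) -> FeatureMatrix:
    """S-transform features for every subject at one grid coordinate.

    Uses exactly the first ``n_events`` surviving epochs per subject (trial
    order, first-anchored).  Default mode averages those epochs, transforms
    the average and restricts the magnitude map to ``spec``;
    ``transform-then-average`` instead transforms each epoch and averages
    the magnitude maps (kept for sensitivity analysis).  Subjects with too
    few surviving epochs are skipped and listed in ``skipped``.
    """
    if mode not in ("average-then-transform", "transform-then-average"):
        raise ValueError(f"unknown feature mode {mode!r}")
    rows, index, skipped = [], [], []
    for es in epoch_sets:
        data = es.channel_data(electrode)
        if data.shape[0] < n_events:
            skipped.append(es.subject_id)
            continue
        if mode == "average-then-transform":
            frame = data[:n_events].mean(axis=0)
            st = stockwell(
                frame, es.fs, t0_offset_ms=es.t0_offset_ms, fmax=spec.f_high, kernel=kernel
            )
            win = st.window(spec)
        else:
            win = None
            for ep in data[:n_events]:
                st = stockwell(
                    ep, es.fs, t0_offset_ms=es.t0_offset_ms, fmax=spec.f_high, kernel=kernel
                )
                w = st.window(spec)
                win = w if win is None else win + w
            win = win / n_events
        rows.append(win.ravel())
        index.append(es.subject_id)
    if not rows:
        raise DataError("no subject has enough surviving epochs")
    values = pd.DataFrame(np.vstack(rows), index=index)
    lab = pd.Series(labels).reindex(index)
    return FeatureMatrix(
        values=values,
        labels=lab,
        provenance={
            "electrode": electrode,
            "window": spec.as_tuple(),
            "n_events": n_events,
            "mode": mode,
            "kernel": kernel,
        },
        skipped=skipped,
    )
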