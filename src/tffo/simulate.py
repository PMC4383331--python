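"""Synthetic two-population ERP cohort generator.

Emulates the statistical structure the discrimination pipeline assumes: two
groups of subjects performing a visual oddball-like task in which blocks of
78 triangle stimuli (150 ms duration, 1 s inter-stimulus interval) contain
three-triangle predictive sequences; the epochs time-locked to the final
stimulus of a predictive sequence (code ``"P"``) are the analysed events.

Signal model, per subject:

* background noise — an independent 1/f (power-law) Gaussian process per
  channel plus a shared, spatially common component (a cheap stand-in for
  volume conduction) plus a white floor;
* evoked responses — damped Gabor bursts (carrier at the effect-band
  center, Gaussian envelope spanning each effect window) added to every EEG
  channel at every "P" event, with amplitude decaying exponentially over
  the P-event index (habituation);
* group difference — on the effect channels only, patients' bursts are
  attenuated by ``effect_size`` (patient/healthy amplitude ratio) and
  latency-shifted/jittered; both modulations scale with ``1 − effect_size``
  (and with each patient's latent severity when a severity model is given),
  so ``effect_size = 1`` is an exact null by construction;
* artifacts — blinks (low-frequency, high-amplitude, strongest on the EOG
  and frontal channels), horizontal-EOG saccade steps, epochs exceeding
  75 μV, and "miss" epochs whose button press is deleted, each drawn
  per-epoch with configurable probabilities and reported in a ground-truth
  table.

Two EOG channels (``EOGv``, ``EOGh``) are always appended to the montage.
All randomness flows from one seed through ``numpy.random.SeedSequence``;
identical (spec, seed) gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EOG_LABELS, Recording, SeverityRecord, make_event_table

__all__ = [
    "MONTAGE_64",
    "ArtifactRates",
    "NoiseModel",
    "CohortSpec",
    "SeverityModel",
    "generate_cohort",
    "generate_recording",
    "inject_artifacts",
]

#: 64-channel 10-20/10-10 montage (Biosemi layout order).
MONTAGE_64 = [
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz", "Fpz",
    "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8", "FC6",
    "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4",
    "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class ArtifactRates:
    """Per-epoch contamination probabilities."""

    blink: float = 0.0
    saccade: float = 0.0
    miss: float = 0.0
    large_amplitude: float = 0.0

    def validate(self) -> None:
        for name in ("blink", "saccade", "miss", "large_amplitude"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"artifact_rates.{name}={v} not in [0, 1]")


@dataclass
class NoiseModel:
    """Background model: 1/f^exponent process + white floor (μV RMS)."""

    exponent: float = 1.5
    pink_uv: float = 10.0
    white_uv: float = 1.0
    shared_fraction: float = 0.3  # variance fraction of the common component
    eog_shared_fraction: float = 0.1

    def validate(self) -> None:
        if self.exponent < 0 or self.pink_uv < 0 or self.white_uv < 0:
            raise ConfigurationError("noise_model parameters must be non-negative")
        if not 0 <= self.shared_fraction < 1 or not 0 <= self.eog_shared_fraction < 1:
            raise ConfigurationError("noise_model shared fractions must be in [0, 1)")


@dataclass
class CohortSpec:
    """Study conditions of a simulated cohort.

    Defaults reproduce the emulated protocol: 25 subjects per group, the
    64-channel 10-20 montage at 512 Hz, blocks of 78 stimuli of 150 ms at
    1 s ISI with predictive ("P") sequences, group differences confined to
    frontal-central channels in the 15–20 Hz band near 200–300 ms and
    900–950 ms post-stimulus, and habituation with a ~3-trial decay so only
    early trials carry strong responses.
    """

    n_per_group: int = 25
    channel_labels: tuple = tuple(MONTAGE_64)
    fs: float = 512.0
    n_stimuli_per_block: int = 78
    stimulus_duration_ms: float = 150.0
    isi_ms: float = 1000.0
    effect_channels: tuple = ("F2", "FC3")
    effect_band: tuple = (15.0, 20.0)
    effect_windows: tuple = ((200.0, 300.0), (900.0, 950.0))
    effect_size: float = 0.5
    habituation_tau: float = 3.0  # trials; math.inf disables habituation
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    # evoked-response shape
    burst_amplitude_uv: float = 20.0
    burst_sigma_ms: float = 40.0  # Gaussian envelope sd; ~4 Hz spectral sd
    latency_jitter_ms: float = 5.0  # common trial-to-trial jitter (both groups)
    patient_latency_shift_ms: float = 30.0  # at full effect (ratio → 0)
    patient_extra_jitter_ms: float = 10.0  # at full effect, added in quadrature
    # behaviour
    rt_mean_ms: float = 400.0
    rt_sd_ms: float = 80.0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def soa_ms(self) -> float:
        """Stimulus-onset asynchrony: ISI counted offset-to-onset."""
        return self.isi_ms + self.stimulus_duration_ms

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("invariant violated: n_per_group >= 2")
        if self.fs <= 2 * self.effect_band[1]:
            raise ConfigurationError(
                f"invariant violated: fs > 2 × effect_band.high ({self.fs} <= {2 * self.effect_band[1]})"
            )
        if not self.effect_band[0] < self.effect_band[1]:
            raise ConfigurationError("invariant violated: effect_band low < high")
        for lo, hi in self.effect_windows:
            if not (0 <= lo < hi <= self.soa_ms):
                raise ConfigurationError(
                    f"invariant violated: effect_window [{lo}, {hi}] outside [0, isi + stimulus_duration]"
                )
        missing = set(self.effect_channels) - set(self.channel_labels)
        if missing:
            raise ConfigurationError(
                f"invariant violated: effect_channels not in montage: {sorted(missing)}"
            )
        if self.effect_size < 0:
            raise ConfigurationError("invariant violated: effect_size >= 0")
        if self.habituation_tau <= 0:
            raise ConfigurationError("invariant violated: habituation_tau > 0")
        self.artifact_rates.validate()
        self.noise_model.validate()

    @property
    def all_labels(self) -> list[str]:
        return list(self.channel_labels) + list(EOG_LABELS)


class SeverityModel:
    """Latent-severity plumbing for patients.

    Each patient draws a latent severity s ∈ [0, 1]; ``severity_link`` (a
    monotone non-decreasing map of [0, 1] onto [0, 1], identity by default)
    converts it into the weight that scales the group effect, and the
    clinical covariates are monotone-in-s random draws: hospitalizations
    1 + Poisson(λ·s), symptom counts Binomial with success probability s,
    dose uniform-jittered around s·range.
    """

    def __init__(
        self,
        hospitalization_lambda: float = 4.0,
        dose_range=(1.0, 10.0),
        saps_range=(0, 20),
        sans_range=(0, 20),
        severity_link=None,
    ) -> None:
        self.hospitalization_lambda = hospitalization_lambda
        self.dose_range = dose_range
        self.saps_range = saps_range
        self.sans_range = sans_range
        self.severity_link = severity_link if severity_link is not None else (lambda s: s)
        self.validate()

    def validate(self) -> None:
        if self.hospitalization_lambda < 0:
            raise ConfigurationError("invariant violated: hospitalization_lambda >= 0")
        grid = np.linspace(0, 1, 101)
        vals = np.array([self.severity_link(g) for g in grid], dtype=float)
        if np.any(np.diff(vals) < -1e-12):
            raise ConfigurationError("invariant violated: severity_link must be monotone non-decreasing")

    def draw(self, rng: np.random.Generator) -> tuple[float, SeverityRecord]:
        s = rng.uniform(0.05, 1.0)
        hosp = 1 + rng.poisson(self.hospitalization_lambda * s)
        saps = int(rng.binomial(self.saps_range[1] - self.saps_range[0], s)) + self.saps_range[0]
        sans = int(rng.binomial(self.sans_range[1] - self.sans_range[0], s)) + self.sans_range[0]
        lo, hi = self.dose_range
        dose = float(np.clip(lo + s * (hi - lo) + rng.normal(0, 0.1 * (hi - lo)), lo, hi))
        return s, SeverityRecord(hospitalizations=int(hosp), dose_load=dose, saps=saps, sans=sans)


# ---------------------------------------------------------------------------
# signal building blocks
# ---------------------------------------------------------------------------

def _colored_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """Unit-variance Gaussian noise with power spectrum ∝ f^(-exponent)."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaped = np.maximum(freqs, 0.1) ** (-exponent / 2.0)  # clamp below 0.1 Hz
    shaped[0] = 0.0  # no DC
    x = np.fft.irfft(spectrum * shaped, n=n)
    return x / x.std()


def _background(rng, n_ch_eeg: int, n: int, fs: float, nm: NoiseModel) -> np.ndarray:
    """Background for EEG + 2 EOG channels (EOG rows last)."""
    shared = _colored_noise(rng, n, fs, nm.exponent)
    out = np.empty((n_ch_eeg + 2, n))
    for c in range(n_ch_eeg + 2):
        frac = nm.shared_fraction if c < n_ch_eeg else nm.eog_shared_fraction
        pink = _colored_noise(rng, n, fs, nm.exponent)
        mix = math.sqrt(1 - frac) * pink + math.sqrt(frac) * shared
        out[c] = nm.pink_uv * mix + nm.white_uv * rng.standard_normal(n)
    return out


def _gabor(t_ms: np.ndarray, center_ms: float, sigma_ms: float, f_hz: float) -> np.ndarray:
    dt = t_ms - center_ms
    return np.exp(-0.5 * (dt / sigma_ms) ** 2) * np.cos(2 * np.pi * f_hz * dt / 1e3)


def _add_burst(signal_row, fs, onset_sample, center_ms, sigma_ms, f_hz, amplitude):
    half_ms = 4 * sigma_ms
    lo = onset_sample + int(np.rint((center_ms - half_ms) * fs / 1e3))
    hi = onset_sample + int(np.rint((center_ms + half_ms) * fs / 1e3))
    lo, hi = max(lo, 0), min(hi, signal_row.size)
    if lo >= hi:
        return
    t_ms = (np.arange(lo, hi) - onset_sample) / fs * 1e3
    signal_row[lo:hi] += amplitude * _gabor(t_ms, center_ms, sigma_ms, f_hz)


def _stimulus_sequence(n_stimuli: int) -> list[str]:
    """Alternating standard / predictive triples; deterministic P positions.

    Every second triple is the predictive left-up-right sequence whose final
    stimulus carries code "P"; remaining stimuli are standards ("S").  With
    78 stimuli this yields 13 P events.
    """
    codes = []
    for triple in range(math.ceil(n_stimuli / 3)):
        if triple % 2 == 1:
            codes.extend(["L", "U", "P"])
        else:
            codes.extend(["S", "S", "S"])
    return codes[:n_stimuli]


def expected_burst_amplitudes(spec: CohortSpec, n_events: int) -> np.ndarray:
    """Habituation-scaled healthy burst amplitudes for the first P events."""
    i = np.arange(n_events)
    return spec.burst_amplitude_uv * np.exp(-i / spec.habituation_tau)


# ---------------------------------------------------------------------------
# recording generation
# ---------------------------------------------------------------------------

def generate_recording(
    spec: CohortSpec,
    subject_id: str,
    group: str,
    seed_seq: np.random.SeedSequence,
    severity_weight: float = 1.0,
    metadata: SeverityRecord | None = None,
) -> Recording:
    """One subject's continuous recording (no artifacts; float32 μV)."""
    rng = np.random.default_rng(seed_seq)
    fs = spec.fs
    soa = int(np.rint(spec.soa_ms * fs / 1e3))
    lead = int(np.rint(2.0 * fs))
    n_samples = lead + spec.n_stimuli_per_block * soa + lead
    labels = spec.all_labels
    n_eeg = len(spec.channel_labels)
    signal = _background(rng, n_eeg, n_samples, fs, spec.noise_model)

    codes = _stimulus_sequence(spec.n_stimuli_per_block)
    onsets = lead + np.arange(spec.n_stimuli_per_block) * soa
    rts = np.clip(rng.normal(spec.rt_mean_ms, spec.rt_sd_ms, len(onsets)), 200.0, 900.0)
    responses = onsets + np.rint(rts * fs / 1e3).astype(int)

    # group modulation: both aspects scale with (1 - amplitude ratio)
    if group == "patient":
        ratio = 1.0 - (1.0 - spec.effect_size) * severity_weight
    else:
        ratio = 1.0
    shift_ms = spec.patient_latency_shift_ms * (1.0 - ratio)
    extra_jitter_ms = spec.patient_extra_jitter_ms * (1.0 - ratio)

    f_center = 0.5 * (spec.effect_band[0] + spec.effect_band[1])
    effect_rows = [labels.index(c) for c in spec.effect_channels]
    p_events = [i for i, c in enumerate(codes) if c == "P"]
    for p_ordinal, stim_idx in enumerate(p_events):
        hab = math.exp(-p_ordinal / spec.habituation_tau)
        for w_lo, w_hi in spec.effect_windows:
            center = 0.5 * (w_lo + w_hi)
            sigma = spec.burst_sigma_ms
            base_jitter = rng.normal(0.0, spec.latency_jitter_ms) if spec.latency_jitter_ms else 0.0
            eff_jitter = rng.normal(0.0, extra_jitter_ms) if extra_jitter_ms else 0.0
            for row in range(n_eeg):
                if row in effect_rows:
                    amp = spec.burst_amplitude_uv * hab * ratio
                    c_ms = center + base_jitter + shift_ms + eff_jitter
                else:
                    amp = spec.burst_amplitude_uv * hab
                    c_ms = center + base_jitter
                _add_burst(signal[row], fs, onsets[stim_idx], c_ms, sigma, f_center, amp)

    events = make_event_table(onsets, codes, responses)
    return Recording(
        subject_id=subject_id,
        group=group,
        channel_labels=labels,
        fs=fs,
        signal=signal.astype(np.float32),
        events=events,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

def _frontal_weight(label: str) -> float:
    if label.startswith(("Fp", "AF")):
        return 0.5
    if label.startswith(("FC", "FT")):
        return 0.15
    if label.startswith("F"):
        return 0.3
    if label.startswith(("C", "T")):
        return 0.08
    return 0.03


def inject_artifacts(rec: Recording, rates: ArtifactRates, seed: int):
    """Contaminate "P" epochs; returns (new recording, ground-truth table).

    Artifact types are drawn independently per epoch, so one epoch may carry
    several truth rows.  Blinks are 300 ms raised-cosine deflections (200 μV
    on EOGv, scaled down over frontal→posterior EEG channels); saccades are
    smoothed 60 μV steps on EOGh; large-amplitude events are 120 μV Gaussian
    bumps on one random EEG channel; a miss deletes the button press.
    """
    rates.validate()
    rng = np.random.default_rng(seed)
    out = rec.copy_with(events=rec.events.copy())
    fs = rec.fs
    pre = int(np.rint(0.2 * fs))
    total = int(math.floor(1.2 * fs))
    sig = out.signal.astype(np.float64)
    labels = rec.channel_labels
    eog_v = labels.index("EOGv") if "EOGv" in labels else None
    eog_h = labels.index("EOGh") if "EOGh" in labels else None
    eeg_rows = [i for i, c in enumerate(labels) if c not in EOG_LABELS]

    truth_rows = []
    p_mask = out.events["code"] == "P"
    for p_ordinal, (tbl_idx, ev) in enumerate(out.events[p_mask].iterrows()):
        onset = int(ev["onset_sample"])
        e_lo = onset - pre
        kinds = []
        if rng.random() < rates.miss:
            kinds.append("miss")
        if rng.random() < rates.saccade:
            kinds.append("saccade")
        if rng.random() < rates.blink:
            kinds.append("blink")
        if rng.random() < rates.large_amplitude:
            kinds.append("large_amplitude")
        for kind in kinds:
            if kind == "miss":
                out.events.loc[tbl_idx, "response_sample"] = pd.NA
            elif kind == "saccade" and eog_h is not None:
                t0 = e_lo + pre + int(rng.uniform(0.1, 0.7) * fs)
                ramp = int(np.rint(0.02 * fs))
                length = int(np.rint(0.6 * fs))
                step = np.full(length, 60.0 * rng.choice([-1.0, 1.0]))
                step[:ramp] *= np.linspace(0, 1, ramp)
                step[-ramp:] *= np.linspace(1, 0, ramp)
                hi = min(t0 + length, sig.shape[1])
                sig[eog_h, t0:hi] += step[: hi - t0]
            elif kind == "blink":
                t0 = e_lo + int(rng.uniform(0.05, 0.85) * total)
                length = int(np.rint(0.3 * fs))
                bump = 200.0 * np.hanning(length)
                hi = min(t0 + length, sig.shape[1])
                if eog_v is not None:
                    sig[eog_v, t0:hi] += bump[: hi - t0]
                for row in eeg_rows:
                    sig[row, t0:hi] += _frontal_weight(labels[row]) * bump[: hi - t0]
            elif kind == "large_amplitude":
                row = int(rng.choice(eeg_rows))
                t0 = e_lo + int(rng.uniform(0.1, 0.8) * total)
                length = int(np.rint(0.25 * fs))
                hi = min(t0 + length, sig.shape[1])
                sig[row, t0:hi] += 120.0 * np.hanning(length)[: hi - t0]
            truth_rows.append(
                {"event_index": p_ordinal, "onset_sample": onset, "kind": kind}
            )
    out.signal = sig.astype(rec.signal.dtype)
    truth = pd.DataFrame(truth_rows, columns=["event_index", "onset_sample", "kind"])
    out.artifact_truth = truth
    return out, truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec, severity: SeverityModel | None = None) -> list[Recording]:
    """Generate 2 × n_per_group recordings (healthy first, then patients).

    Patient evoked bursts on the effect channels are attenuated and
    latency-jittered according to ``effect_size`` scaled by each patient's
    latent severity (weight 1 for every patient when ``severity`` is None);
    habituation attenuates bursts over the P-event index; artifacts are
    injected at the configured rates with per-subject ground-truth tables
    attached as ``Recording.artifact_truth``.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    n = spec.n_per_group
    subject_seqs = root.spawn(2 * n)
    sev_rng = np.random.default_rng(root.spawn(1)[0])
    artifact_seeds = np.random.default_rng(root.spawn(1)[0]).integers(0, 2**31 - 1, 2 * n)

    recordings = []
    any_rate = (
        spec.artifact_rates.blink
        or spec.artifact_rates.saccade
        or spec.artifact_rates.miss
        or spec.artifact_rates.large_amplitude
    )
    for i in range(2 * n):
        if i < n:
            sid, group, weight, meta = f"h{i:02d}", "healthy", 1.0, None
        else:
            sid, group = f"p{i - n:02d}", "patient"
            if severity is not None:
                s, meta = severity.draw(sev_rng)
                weight = float(severity.severity_link(s))
            else:
                weight, meta = 1.0, None
        rec = generate_recording(spec, sid, group, subject_seqs[i], weight, meta)
        if any_rate:
            rec, _ = inject_artifacts(rec, spec.artifact_rates, int(artifact_seeds[i]))
        recordings.append(rec)
    return recordings
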