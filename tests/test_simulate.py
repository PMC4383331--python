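"""Synthetic-cohort generator contracts: determinism, spectrum, injected effect."""

import math

import numpy as np
import pytest
from scipy.signal import welch
from scipy.stats import ttest_ind

from tffo import (
    ArtifactRates,
    CohortSpec,
    NoiseModel,
    SeverityModel,
    WindowSpec,
    bandpass_normalize,
    epoch_and_exclude,
    generate_cohort,
    inject_artifacts,
    stockwell,
)
from tffo.simulate import ConfigurationError

LABELS3 = ("F2", "FC3", "Pz")


def test_bit_identical_under_fixed_seed():
    spec = dict(n_per_group=2, channel_labels=LABELS3, n_stimuli_per_block=12, seed=7)
    a = generate_cohort(CohortSpec(**spec))
    b = generate_cohort(CohortSpec(**spec))
    for ra, rb in zip(a, b):
        assert ra.signal.tobytes() == rb.signal.tobytes()
        assert ra.events.equals(rb.events)


@pytest.mark.parametrize(
    "bad",
    [
        dict(n_per_group=1),
        dict(fs=30.0),  # <= 2 × band high
        dict(effect_windows=((200.0, 1400.0),)),  # beyond isi + duration
        dict(artifact_rates=ArtifactRates(blink=1.5)),
        dict(effect_channels=("Nope",)),
        dict(habituation_tau=0.0),
    ],
)
def test_invalid_spec_names_violated_invariant(bad):
    with pytest.raises(ConfigurationError):
        CohortSpec(channel_labels=LABELS3, **bad)


def test_null_effect_size_yields_uniform_group_test_pvalues():
    """effect_size=1 injects no group difference: band-power t-test p ≈ U(0,1)."""
    from scipy.stats import kstest

    pvals = []
    for seed in range(12):
        spec = CohortSpec(
            n_per_group=4, channel_labels=LABELS3, seed=500 + seed,
            effect_windows=((200.0, 300.0),), effect_size=1.0,
        )
        powers, groups = [], []
        for rec in generate_cohort(spec):
            es = epoch_and_exclude(bandpass_normalize(rec))
            w = WindowSpec(200, 300, 15, 20)
            frame = es.channel_data("F2")[:8].mean(axis=0)
            st = stockwell(frame, es.fs, t0_offset_ms=200.0, fmax=30)
            powers.append(float((st.window(w) ** 2).sum()))
            groups.append(rec.group)
        powers = np.array(powers)
        groups = np.array(groups)
        pvals.append(ttest_ind(powers[groups == "healthy"], powers[groups == "patient"]).pvalue)
    assert kstest(pvals, "uniform").pvalue > 0.005


@pytest.fixture(scope="module")
def long_cohort():
    """3+3 subjects, 101 "P" events each, pure amplitude effect (ratio 0.4)."""
    spec = CohortSpec(
        n_per_group=3, channel_labels=("F2", "FC3", "Pz", "Cz", "Oz"), seed=21,
        n_stimuli_per_block=606, effect_size=0.4, habituation_tau=math.inf,
        effect_windows=((200.0, 300.0),), latency_jitter_ms=0.0,
        patient_latency_shift_ms=0.0, patient_extra_jitter_ms=0.0,
    )
    recs = generate_cohort(spec)
    sets = [epoch_and_exclude(bandpass_normalize(r)) for r in recs]
    return recs, sets


class TestInjectedEffect:
    def test_magnitude_ratio_matches_injected_amplitude_ratio(self, long_cohort):
        """Mean in-window magnitude ratio equals the 0.4 amplitude ratio ±10%.

        Oracle: with no jitter, shift or habituation the averaged epoch is
        burst + O(noise/√101), and the S-transform is linear, so the
        patient/healthy magnitude ratio equals the injected amplitude ratio.
        """
        recs, sets = long_cohort
        w = WindowSpec(200, 300, 15, 20)
        vals = {"healthy": [], "patient": []}
        for rec, es in zip(recs, sets):
            frame = es.channel_data("F2").mean(axis=0)
            st = stockwell(frame, es.fs, t0_offset_ms=200.0, fmax=30)
            vals[rec.group].append(float(st.window(w).mean()))
        ratio = np.mean(vals["patient"]) / np.mean(vals["healthy"])
        assert ratio == pytest.approx(0.4, rel=0.10)

    def test_effect_confined_to_channel_band_window(self, long_cohort):
        """Group band power off-channel, off-band, off-window differs < 5%.

        Per-epoch 2–12 Hz power in [400, 1000] ms on the non-effect
        channels, pooled over ~300 epochs per group.
        """
        from scipy.signal import butter, sosfiltfilt

        recs, sets = long_cohort
        powers = {"healthy": [], "patient": []}
        for rec, es in zip(recs, sets):
            tmask = (es.times_ms >= 400) & (es.times_ms <= 1000)
            sos = butter(4, [2.0, 12.0], btype="bandpass", fs=es.fs, output="sos")
            for ch in ("Pz", "Cz", "Oz"):
                banded = sosfiltfilt(sos, es.channel_data(ch), axis=1)
                powers[rec.group].extend(np.mean(banded[:, tmask] ** 2, axis=1))
        rel = abs(np.mean(powers["patient"]) / np.mean(powers["healthy"]) - 1)
        assert rel < 0.05


def test_spectral_contract_loglog_slope():
    """Null, burst-free signal follows the configured 1/f^1.5 spectrum."""
    spec = CohortSpec(
        n_per_group=2, channel_labels=LABELS3, seed=9, effect_size=1.0,
        burst_amplitude_uv=0.0, noise_model=NoiseModel(exponent=1.5, white_uv=0.0),
    )
    rec = generate_cohort(spec)[0]  # ~94 s of signal
    f, p = welch(np.asarray(rec.signal[:3], dtype=float), fs=rec.fs, nperseg=4096)
    band = (f >= 1) & (f <= 30)
    slope = np.polyfit(np.log(f[band]), np.log(p[:, band].mean(axis=0)), 1)[0]
    assert slope == pytest.approx(-1.5, rel=0.20)


def test_habituation_decay_constant_recovered():
    """Matched-filter burst amplitudes decay with the configured tau ± 25%."""
    tau = 4.0
    spec = CohortSpec(
        n_per_group=2, channel_labels=LABELS3, seed=11, habituation_tau=tau,
        noise_model=NoiseModel(pink_uv=2.0, white_uv=0.2),
        latency_jitter_ms=0.0, effect_windows=((200.0, 300.0),),
    )
    rec = generate_cohort(spec)[0]
    es = epoch_and_exclude(bandpass_normalize(rec))
    t = es.times_ms
    template = np.exp(-0.5 * ((t - 250) / 40.0) ** 2) * np.cos(2 * np.pi * 17.5 * (t - 250) / 1e3)
    amps = es.channel_data("Pz") @ template / (template @ template)
    fitted_tau = -1.0 / np.polyfit(np.arange(10), np.log(amps[:10]), 1)[0]
    assert fitted_tau == pytest.approx(tau, rel=0.25)


class TestInjectArtifacts:
    def recording(self, seed=5):
        return generate_cohort(
            CohortSpec(n_per_group=2, channel_labels=LABELS3, seed=seed)
        )[0]

    def test_zero_rates_identity(self):
        rec = self.recording()
        out, truth = inject_artifacts(rec, ArtifactRates(), seed=0)
        np.testing.assert_array_equal(out.signal, rec.signal)
        assert truth.empty

    def test_rate_one_large_amplitude_saturates(self):
        rec = self.recording()
        n_p = int((rec.events["code"] == "P").sum())
        _, truth = inject_artifacts(rec, ArtifactRates(large_amplitude=1.0), seed=0)
        listed = truth[truth["kind"] == "large_amplitude"]["event_index"]
        assert sorted(listed) == list(range(n_p))

    def test_miss_count_matches_removed_presses(self):
        rec = self.recording()
        out, truth = inject_artifacts(rec, ArtifactRates(miss=0.3), seed=42)
        p_before = rec.events[rec.events["code"] == "P"]["response_sample"]
        p_after = out.events[out.events["code"] == "P"]["response_sample"]
        removed = int(p_before.notna().sum() - p_after.notna().sum())
        assert removed == len(truth[truth["kind"] == "miss"])
        assert removed > 0  # the draw at this seed contains misses


def test_severity_model_monotone_link_required():
    with pytest.raises(ConfigurationError, match="monotone"):
        SeverityModel(severity_link=lambda s: -s)


def test_patient_covariates_track_latent_severity():
    """More severe patients have (stochastically) more hospitalizations."""
    model = SeverityModel()
    rng = np.random.default_rng(0)
    draws = [model.draw(rng) for _ in range(300)]
    s = np.array([d[0] for d in draws])
    hosp = np.array([d[1].hospitalizations for d in draws])
    assert hosp.min() >= 1
    assert np.corrcoef(s, hosp)[0, 1] > 0.5
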