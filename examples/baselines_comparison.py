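"""Compare the time-frequency classifier with the latency baselines.

The cohort's group difference is purely spectral (an amplitude-attenuated
beta burst, no latency shift), so methods that summarize each subject by
the *location* of their energy peak — 2-means on mean peak-energy latency
(PE-Latency) and KNN on peak-latency histograms in the P300 window
(P300-RF-Latency) — should do clearly worse than the Stockwell-feature
classifier run on the same epochs.
"""

from tffo import (
    CohortSpec,
    WindowSpec,
    bandpass_normalize,
    epoch_and_exclude,
    extract_features,
    generate_cohort,
    loo_cv,
    p300_rf_latency_classify,
    pe_latency_classify,
)

spec = CohortSpec(
    n_per_group=20,
    channel_labels=("F2", "FC3", "Pz"),
    effect_windows=((200.0, 300.0),),
    effect_size=0.3,
    burst_amplitude_uv=12.0,
    patient_latency_shift_ms=0.0,
    patient_extra_jitter_ms=0.0,
    seed=2,
)
sets, labels = [], {}
for rec in generate_cohort(spec):
    sets.append(epoch_and_exclude(bandpass_normalize(rec)))
    labels[rec.subject_id] = rec.group

features = extract_features(
    sets, labels, WindowSpec(200, 300, 15, 20), electrode="F2", n_events=8
)
tffo_cv = loo_cv(features, k=3)
pe_cv = pe_latency_classify(sets, labels, electrode="F2", seed=0)
rf_cv = p300_rf_latency_classify(sets, labels, electrode="F2", k=3)

print(f"{'method':<18}{'accuracy':>9}{'specificity':>13}{'sensitivity':>13}")
for name, cv in (
    ("TFFO", tffo_cv),
    ("PE-Latency", pe_cv),
    ("P300-RF-Latency", rf_cv),
):
    print(f"{name:<18}{cv.accuracy:>9.3f}{cv.specificity:>13.3f}{cv.sensitivity:>13.3f}")
print("\nhigher TFFO accuracy shows the discriminative information is spectral,")
print("not a latency difference the baselines could also exploit")
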