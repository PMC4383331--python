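"""Generate a small synthetic EEG cohort and write it to disk.

Two groups of subjects perform the triangle task (78 stimuli, 150 ms
duration, 1 s ISI, predictive "P" sequences); patients carry an attenuated,
latency-jittered beta burst on the frontal-central effect channels.  The
printed counts describe the protocol; the files are the fixture format the
rest of the pipeline reads.
"""

from pathlib import Path

from tffo import ArtifactRates, CohortSpec, SeverityModel, generate_cohort
from tffo.io import write_metadata_table, write_recording

out = Path("scratch/example_cohort")
out.mkdir(parents=True, exist_ok=True)

spec = CohortSpec(
    n_per_group=4,
    channel_labels=("F2", "FC3", "AFz", "Cz", "Pz"),
    effect_windows=((200.0, 300.0),),
    effect_size=0.4,
    artifact_rates=ArtifactRates(blink=0.05, miss=0.1),
    seed=7,
)
recordings = generate_cohort(spec, severity=SeverityModel())

for rec in recordings:
    write_recording(rec, out / rec.subject_id)
write_metadata_table(recordings, out / "metadata.tsv")

rec = recordings[0]
n_p = int((rec.events["code"] == "P").sum())
print(f"wrote {len(recordings)} recordings to {out}")
print(f"channels: {rec.channel_labels}")
print(f"samples per recording: {rec.n_samples} at {rec.fs:g} Hz "
      f"({rec.n_samples / rec.fs:.1f} s)")
print(f'"P" (predictive-sequence) events per block: {n_p}')
patient = next(r for r in recordings if r.group == "patient")
m = patient.metadata
print(f"example patient metadata: hospitalizations={m.hospitalizations}, "
      f"dose={m.dose_load:.1f}, SAPS={m.saps}, SANS={m.sans}")
# Each P event should trigger an evoked beta burst; patients' bursts on the
# effect channels are scaled toward effect_size × the healthy amplitude.
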