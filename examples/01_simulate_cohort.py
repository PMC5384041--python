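"""Simulate a small synthetic polysomnography cohort on disk.

Writes one EDF (EEG_F, EEG_P, EMG1, EMG2 at 512 Hz) and one 4-s-epoch
hypnogram TSV per subject, plus a YAML manifest.  The mutant ("KI") group
carries a NREM delta/theta amplitude deficit (x0.7), the kind of spectral
genotype effect the analysis pipeline is built to detect.
"""

import tempfile
from pathlib import Path

import sleepspectra as ss

cfg = ss.SimConfig(duration_h=1.0, n_per_group=2, seed=7)
base = ss.default_spectral_model()
ki_effect = ss.GenotypeEffect({("NR", (1.0, 4.0)): 0.7,
                               ("NR", (5.0, 8.0)): 0.7})
models = {"WT": (base, ss.GenotypeEffect()), "KI": (base, ki_effect)}

with tempfile.TemporaryDirectory() as tmp:
    manifest_path = ss.generate_cohort(cfg, tmp, models=models)
    manifest = ss.read_manifest(manifest_path)
    print(f"cohort seed {manifest['seed']}, "
          f"{len(manifest['subjects'])} subjects:")
    for subj in manifest["subjects"]:
        edf_mb = (Path(tmp) / subj["edf"]).stat().st_size / 1e6
        print(f"  {subj['id']} ({subj['genotype']}): {subj['edf']} "
              f"({edf_mb:.1f} MB), {len(subj['artifact_epochs'])} "
              "artifact-contaminated epochs")

# Each subject gets an independent hypnogram (phase-dependent Markov chain)
# and waveforms whose per-state spectra follow the oscillator model; the
# artifact epochs listed are ground truth for testing the rejection rule.
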