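import numpy as np
import pytest

import sleepspectra as ss

# a compact cohort for end-to-end tests: 24 h (one full light-dark day) at a
# reduced 128-Hz rate so EDF files and FFTs stay small; bins 1-56 Hz remain
# below the 64-Hz Nyquist
COHORT_FS = 128.0
COHORT_HOURS = 24.0


@pytest.fixture(scope="session")
def disk_cohort(tmp_path_factory):
    """2+2-subject cohort on disk with a mild NREM delta/theta deficit in
    the KI group; returns (manifest_path, sim_config)."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = ss.SimConfig(sampling_rate_hz=COHORT_FS, duration_h=COHORT_HOURS,
                       n_per_group=2, seed=42)
    base = ss.default_spectral_model()
    effect = ss.GenotypeEffect({("NR", (1.0, 4.0)): 0.7,
                                ("NR", (5.0, 8.0)): 0.7})
    models = {"WT": (base, ss.GenotypeEffect()), "KI": (base, effect)}
    manifest = ss.generate_cohort(cfg, out, models=models)
    return manifest, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def default_model():
    return ss.default_spectral_model()


@pytest.fixture()
def no_effect():
    return ss.GenotypeEffect()
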