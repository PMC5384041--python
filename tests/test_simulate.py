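"""Synthetic-data generator: hypnogram chains, oscillator spectra,
genotype effects, artifacts, cohort output."""

import numpy as np
import pytest

import sleepspectra as ss


def _identity_transitions():
    eye = np.eye(3)
    return ss.TransitionModel(light=eye, dark=eye, initial_state="W")


class TestHypnogram:
    def test_absorbing_chain_stays_in_initial_state(self, rng):
        cfg = ss.SimConfig(duration_h=1.0, seed=0)
        hyp = ss.generate_hypnogram(cfg, _identity_transitions(), rng)
        assert (hyp.states == "W").all()

    def test_default_config_epoch_count(self, rng):
        cfg = ss.SimConfig(seed=0)  # 48 h, 4-s epochs
        hyp = ss.generate_hypnogram(cfg, ss.default_transitions(), rng)
        assert hyp.n_epochs == 43_200

    def test_determinism(self):
        cfg = ss.SimConfig(duration_h=2.0, seed=5)
        tm = ss.default_transitions()
        h1 = ss.generate_hypnogram(cfg, tm, np.random.default_rng(9))
        h2 = ss.generate_hypnogram(cfg, tm, np.random.default_rng(9))
        assert (h1.states == h2.states).all()

    def test_invalid_transition_row_is_named(self):
        mat = np.eye(3)
        mat[1, 1] = 0.5  # row NR sums to 0.5
        with pytest.raises(ValueError, match="row 1"):
            ss.TransitionModel(light=mat, dark=np.eye(3))

    def test_empirical_proportions_match_stationary_distribution(self, rng):
        # reversible chain built by detailed balance around pi = (.35,.55,.10)
        p_nw = 0.35 * 0.050 / 0.55
        mat = np.array([
            [0.948, 0.050, 0.002],
            [p_nw, 1.0 - p_nw - 0.010, 0.010],
            [0.007, 0.055, 0.938],
        ])
        tm = ss.TransitionModel(light=mat, dark=mat)
        # oracle: stationary distribution by eigen-decomposition
        vals, vecs = np.linalg.eig(mat.T)
        pi = np.real(vecs[:, np.argmax(np.real(vals))])
        pi = pi / pi.sum()
        assert pi == pytest.approx([0.35, 0.55, 0.10], abs=1e-12)
        cfg = ss.SimConfig(duration_h=24.0, seed=0)
        hyp = ss.generate_hypnogram(cfg, tm, rng)
        assert hyp.n_epochs >= 10_000
        for state, target in zip(("W", "NR", "R"), pi):
            assert np.mean(hyp.states == state) == pytest.approx(target, abs=0.03)


class TestEpochSignal:
    def test_zero_amplitudes_give_zero_signal(self, rng):
        model = ss.StateSpectralModel(
            oscillators={s: (ss.Oscillator(2.0, 1.0, 0.0),) for s in ("W", "NR", "R")},
            noise_amp={s: 0.0 for s in ("W", "NR", "R")},
            emg_amp={s: 0.0 for s in ("W", "NR", "R")},
        )
        x = ss.generate_epoch_signal("NR", model, ss.GenotypeEffect(), 2048, 512.0, rng)
        assert np.all(x == 0)

    def test_unknown_state_rejected(self, default_model, no_effect, rng):
        with pytest.raises(ValueError, match="unknown state"):
            ss.generate_epoch_signal("N2", default_model, no_effect, 2048, 512.0, rng)

    def test_single_delta_oscillator_concentrates_power(self, rng):
        model = ss.StateSpectralModel(
            oscillators={"W": (), "R": (),
                         "NR": (ss.Oscillator(2.0, 0.5, 30.0),)},
            noise_amp={"W": 0.0, "NR": 0.0, "R": 0.0},
            emg_amp={"W": 0.0, "NR": 0.0, "R": 0.0},
        )
        x = np.concatenate([
            ss.generate_epoch_signal("NR", model, ss.GenotypeEffect(), 2048, 512.0, rng)
            for _ in range(20)
        ])
        spec = ss.epoch_power_spectrum(x, 512.0, 4.0)
        total = spec.power.sum()
        delta = spec.power[:, :4].sum()
        assert delta / total >= 0.90

    def test_genotype_multiplier_scales_power_quadratically(self, rng):
        """A 0.8 amplitude multiplier on (NREM, delta) scales the mean delta
        power by 0.8^2 (Monte-Carlo over 1000 epochs, 5% tolerance)."""
        model = ss.StateSpectralModel(
            oscillators={"W": (), "R": (),
                         "NR": (ss.Oscillator(2.0, 1.0, 30.0),)},
            noise_amp={"W": 0.0, "NR": 0.0, "R": 0.0},
            emg_amp={"W": 0.0, "NR": 0.0, "R": 0.0},
        )
        n_epochs = 1000
        effect = ss.GenotypeEffect({("NR", (1.0, 4.0)): 0.8})
        states = np.repeat("NR", n_epochs)
        base = ss.sample_epoch_spectra(states, model, ss.GenotypeEffect(),
                                       512.0, 4.0, np.random.default_rng(1))
        mod = ss.sample_epoch_spectra(states, model, effect,
                                      512.0, 4.0, np.random.default_rng(2))
        assert mod[:, :4].sum(axis=1).mean() / base[:, :4].sum(axis=1).mean() \
            == pytest.approx(0.8 ** 2, rel=0.05)
        # ... and exactly in expectation
        exp_base = ss.expected_bin_power("NR", model, ss.GenotypeEffect(),
                                         512.0, 4.0).sum()
        exp_mod = ss.expected_bin_power("NR", model, effect, 512.0, 4.0).sum()
        assert exp_mod / exp_base == pytest.approx(0.8 ** 2, abs=1e-12)

    def test_time_domain_spectra_match_analytic_bin_power(self, default_model,
                                                          no_effect, rng):
        """The waveform path and the analytic expectation (used by the fast
        sampler) agree on where the power sits."""
        states = np.repeat("NR", 400)
        hyp = ss.Hypnogram(states=states, epoch_s=4.0)
        cfg = ss.SimConfig(duration_h=400 * 4 / 3600.0, seed=0)
        rec = ss.generate_recording(hyp, default_model, no_effect, cfg, rng)
        spec = ss.epoch_power_spectrum(ss.derive_bipolar(rec), 512.0, 4.0)
        expected = ss.expected_bin_power("NR", default_model, no_effect, 512.0, 4.0)
        observed = spec.power.mean(axis=0)
        heavy = expected > 0.02 * expected.max()
        ratio = observed[heavy] / expected[heavy]
        assert np.all((ratio > 0.8) & (ratio < 1.25))


class TestArtifacts:
    def test_rate_zero_is_noop(self, default_model, no_effect, rng):
        cfg = ss.SimConfig(duration_h=0.05, seed=0, epoch_s=4.0,
                           sampling_rate_hz=128.0)
        hyp = ss.generate_hypnogram(cfg, ss.default_transitions(), rng)
        rec = ss.generate_recording(hyp, default_model, no_effect, cfg, rng)
        out, log = ss.inject_artifacts(rec, ss.ArtifactModel(rate_per_h=0.0), rng)
        assert log == []
        for name in rec.channels:
            assert np.array_equal(out.channels[name], rec.channels[name])

    def test_poisson_count_within_3_sigma(self, rng):
        # 48 h at rate 2/h -> Poisson(96); content-free carrier signal
        fs = 16.0
        n = int(48 * 3600 * fs)
        rec = ss.Recording(channels={"EEG_F": np.zeros(n), "EEG_P": np.zeros(n)},
                           sampling_rate_hz=fs)
        _, log = ss.inject_artifacts(rec, ss.ArtifactModel(rate_per_h=2.0), rng)
        assert abs(len(log) - 96) <= 3 * np.sqrt(96)

    def test_artifact_epoch_exceeds_rejection_threshold(self, default_model,
                                                        no_effect):
        rng = np.random.default_rng(3)
        cfg = ss.SimConfig(duration_h=0.1, seed=3)
        hyp = ss.generate_hypnogram(cfg, ss.default_transitions(), rng)
        rec = ss.generate_recording(hyp, default_model, no_effect, cfg, rng)
        rec, log = ss.inject_artifacts(
            rec, ss.ArtifactModel(rate_per_h=15.0, amplitude=30.0), rng)
        assert log, "expected at least one artifact at this rate"
        spec = ss.normalize(ss.epoch_power_spectrum(ss.derive_bipolar(rec),
                                                    512.0, 4.0))
        assert spec.power[log].max() > 300.0


class TestCohort:
    def test_minimal_cohort_files(self, tmp_path):
        cfg = ss.SimConfig(duration_h=0.1, n_per_group=1, seed=1,
                           sampling_rate_hz=128.0)
        manifest_path = ss.generate_cohort(cfg, tmp_path)
        manifest = ss.read_manifest(manifest_path)
        assert len(manifest["subjects"]) == 2
        assert len(list(tmp_path.glob("*.edf"))) == 2
        assert len(list(tmp_path.glob("*_hypnogram.tsv"))) == 2

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = ss.SimConfig(duration_h=0.1, n_per_group=1, seed=7,
                           sampling_rate_hz=128.0)
        ss.generate_cohort(cfg, tmp_path / "a")
        ss.generate_cohort(cfg, tmp_path / "b")
        for name in ("WT01_hypnogram.tsv", "KI01_hypnogram.tsv", "WT01.edf"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_default_cohort_all_states_in_every_3h_bin(self):
        """Scored hypnograms of the default 7+7 / 48-h design must expose
        every state in every 3-h ZT bin (so no empty time-course cells)."""
        cfg = ss.SimConfig(seed=11)
        tm = ss.default_transitions()
        ss_root = np.random.SeedSequence(cfg.seed)
        per_bin = int(3 * 3600 / cfg.epoch_s)
        for child in ss_root.spawn(14):
            rng = np.random.Generator(np.random.PCG64(child))
            hyp = ss.generate_hypnogram(cfg, tm, rng)
            bins = hyp.states.reshape(-1, per_bin)
            for b in range(bins.shape[0]):
                present = set(bins[b])
                assert present == {"W", "NR", "R"}, f"bin {b} has {present}"
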