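"""Synthetic two-genotype mouse polysomnography cohorts.

Emulates the statistical structure of a chronic EEG/EMG sleep study:
48-h recordings sampled at 512 Hz under a 12:12 light-dark cycle, scored
in 4-s epochs into wake (W), NREM (NR) and REM (R) sleep.  Vigilance
states follow a phase-dependent first-order Markov chain; within each
state the EEG is a sum of band-limited stochastic oscillators (second-
order resonators driven by white noise) plus broadband noise, so that
per-band power is analytically predictable.  A multiplicative genotype
effect rescales the amplitude of oscillators falling in chosen bands,
and sporadic high-amplitude transients emulate recording artifacts.

Two generation paths are provided and cross-checked against each other:

* the time-domain path (:func:`generate_recording`, :func:`generate_cohort`)
  synthesises actual 512-Hz waveforms and writes EDF files;
* the spectral path (:func:`sample_epoch_spectra`) draws per-epoch 1-Hz-bin
  periodogram powers directly from the distribution the oscillator model
  implies (Gamma with shape = Fourier components per bin), which makes
  cohort-scale Monte-Carlo studies of the downstream statistics feasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

STATES = ("W", "NR", "R")
_STATE_INDEX = {s: i for i, s in enumerate(STATES)}


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation parameters.

    Defaults reproduce the study conditions: 512 Hz sampling, 4-s scoring
    epochs, 48-h continuous recordings aligned to lights-on, and seven
    animals per genotype.
    """

    sampling_rate_hz: float = 512.0
    epoch_s: float = 4.0
    duration_h: float = 48.0
    lights_on_offset_h: float = 0.0
    n_per_group: int = 7
    seed: int = 0
    # between-animal variability: log-normal sigma applied per subject and
    # per oscillator amplitude (~15% CV in band power)
    subject_amp_sigma: float = 0.075

    def __post_init__(self) -> None:
        ns = self.epoch_s * self.sampling_rate_hz
        if ns <= 0 or abs(ns - round(ns)) > 1e-9:
            raise ValueError(
                f"epoch_s x sampling_rate_hz must be a positive integer, got {ns}"
            )
        total_s = self.duration_h * 3600.0
        if total_s <= 0 or abs(total_s / self.epoch_s - round(total_s / self.epoch_s)) > 1e-9:
            raise ValueError(
                "duration_h x 3600 must be an integer multiple of epoch_s "
                f"(got duration {self.duration_h} h, epoch {self.epoch_s} s)"
            )
        if not 0 <= self.lights_on_offset_h < 24:
            raise ValueError("lights_on_offset_h must lie in [0, 24)")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.epoch_s * self.sampling_rate_hz))

    @property
    def n_epochs(self) -> int:
        return int(round(self.duration_h * 3600.0 / self.epoch_s))


@dataclass(frozen=True)
class Oscillator:
    """A band-limited EEG rhythm: resonator at ``f0`` Hz with half-power
    bandwidth ``bw`` Hz and RMS amplitude ``amp`` microvolt."""

    f0: float
    bw: float
    amp: float

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("oscillator center frequency must be positive")
        if self.bw <= 0:
            raise ValueError("oscillator bandwidth must be positive")
        if self.amp < 0:
            raise ValueError("oscillator amplitude must be >= 0")


@dataclass(frozen=True)
class StateSpectralModel:
    """Per-state EEG composition and EMG tone.

    ``oscillators`` maps state -> tuple of :class:`Oscillator`; ``noise_amp``
    is broadband (white) EEG noise RMS per state; ``emg_amp`` the EMG RMS per
    state (wake > NREM > REM, REM near-atonic).
    """

    oscillators: dict[str, tuple[Oscillator, ...]]
    noise_amp: dict[str, float]
    emg_amp: dict[str, float]

    def __post_init__(self) -> None:
        for st in STATES:
            if st not in self.oscillators or st not in self.noise_amp:
                raise ValueError(f"state {st!r} missing from spectral model")
            if self.noise_amp[st] < 0 or self.emg_amp.get(st, 0.0) < 0:
                raise ValueError("amplitudes must be >= 0")

    def for_state(self, state: str) -> tuple[tuple[Oscillator, ...], float]:
        if state not in _STATE_INDEX:
            raise ValueError(f"unknown state label {state!r}")
        return self.oscillators[state], self.noise_amp[state]


def default_spectral_model() -> StateSpectralModel:
    """Plausible mouse cortical EEG: irregular theta-dominated wake,
    high-amplitude delta NREM with a sigma (spindle) component, and regular
    low-amplitude theta REM.  Amplitudes are on the order of the ~100 uV
    scale typical of rodent cortical screw electrodes."""
    return StateSpectralModel(
        oscillators={
            "W": (Oscillator(7.0, 2.5, 20.0), Oscillator(20.0, 8.0, 9.0)),
            "NR": (Oscillator(2.0, 1.6, 45.0), Oscillator(6.0, 2.0, 12.0),
                   Oscillator(12.0, 2.0, 10.0)),
            "R": (Oscillator(7.5, 1.5, 30.0),),
        },
        noise_amp={"W": 14.0, "NR": 12.0, "R": 8.0},
        emg_amp={"W": 30.0, "NR": 8.0, "R": 1.5},
    )


@dataclass(frozen=True)
class GenotypeEffect:
    """Multiplicative genotype effect on oscillator amplitudes.

    ``multipliers`` maps ``(state, (lo_hz, hi_hz))`` to a positive factor;
    every oscillator of that state whose center frequency lies in
    ``[lo_hz, hi_hz]`` has its amplitude multiplied, so band *power* scales
    with the square of the factor.  Broadband noise is unaffected.
    """

    multipliers: dict[tuple[str, tuple[float, float]], float] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for (state, (lo, hi)), m in self.multipliers.items():
            if state not in _STATE_INDEX:
                raise ValueError(f"unknown state label {state!r}")
            if not (0 < lo <= hi):
                raise ValueError(f"invalid band range ({lo}, {hi})")
            if m <= 0:
                raise ValueError("multipliers must be > 0")

    def amplitude_factor(self, state: str, f0: float) -> float:
        factor = 1.0
        for (st, (lo, hi)), m in self.multipliers.items():
            if st == state and lo <= f0 <= hi:
                factor *= m
        return factor


@dataclass(frozen=True)
class TransitionModel:
    """Per-epoch vigilance-state transitions, one row-stochastic 3x3 matrix
    for each lighting phase, in state order (W, NR, R)."""

    light: np.ndarray
    dark: np.ndarray
    initial_state: str = "W"

    def __post_init__(self) -> None:
        for name, mat in (("light", self.light), ("dark", self.dark)):
            mat = np.asarray(mat, dtype=float)
            object.__setattr__(self, name, mat)
            if mat.shape != (3, 3):
                raise ValueError(f"{name} matrix must be 3x3")
            if np.any(mat < 0) or np.any(mat > 1):
                raise ValueError(f"{name} matrix entries must lie in [0, 1]")
            bad = np.nonzero(np.abs(mat.sum(axis=1) - 1.0) > 1e-12)[0]
            if bad.size:
                raise ValueError(
                    f"{name} matrix row {bad[0]} (state {STATES[bad[0]]}) "
                    f"sums to {mat[bad[0]].sum()!r}, expected 1"
                )
        if self.initial_state not in _STATE_INDEX:
            raise ValueError(f"unknown initial state {self.initial_state!r}")


def default_transitions() -> TransitionModel:
    """Nocturnal-rodent sleep structure: sleep-dominated light phase
    (roughly 35% W / 55% NR / 10% R at stationarity) and wake-dominated
    dark phase (roughly 65% W / 30% NR / 5% R), with bout lengths of
    minutes for W/NR and about a minute for REM."""
    light = np.array([
        [0.950, 0.050, 0.000],
        [0.028, 0.955, 0.017],
        [0.090, 0.010, 0.900],
    ])
    dark = np.array([
        [0.978, 0.022, 0.000],
        [0.050, 0.940, 0.010],
        [0.100, 0.020, 0.880],
    ])
    return TransitionModel(light=light, dark=dark, initial_state="W")


@dataclass(frozen=True)
class ArtifactModel:
    """Sporadic high-amplitude transients (movement/chewing noise).

    Each transient is a Hann-windowed oscillation at a random frequency in
    ``freq_range`` (slow, movement-like by default), scaled to ``amplitude``
    times the RMS of the epoch it starts in, so its power is concentrated in
    one or two 1-Hz bins the way recording noise bursts are.  The default
    rate contaminates roughly 2% of 4-s epochs, the rejection fraction
    typically reported for chronic mouse EEG.
    """

    rate_per_h: float = 19.0
    amplitude: float = 30.0   # multiple of the affected epoch's RMS
    duration_s: float = 1.0
    freq_range: tuple[float, float] = (1.5, 4.0)

    def __post_init__(self) -> None:
        if self.rate_per_h < 0:
            raise ValueError("artifact rate must be >= 0")
        if self.amplitude < 0:
            raise ValueError("artifact amplitude must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("artifact duration must be positive")
        lo, hi = self.freq_range
        if not 0 < lo <= hi:
            raise ValueError("invalid artifact frequency range")


# ---------------------------------------------------------------------------
# hypnogram generation
# ---------------------------------------------------------------------------

def generate_hypnogram(sim_config: SimConfig, transitions: TransitionModel,
                       rng: np.random.Generator):
    """Simulate a scored hypnogram from the phase-dependent Markov chain.

    Returns a :class:`sleepspectra.io.Hypnogram` with one label per epoch.
    """
    from .io import Hypnogram

    n = sim_config.n_epochs
    epochs_per_h = int(round(3600.0 / sim_config.epoch_s))
    # lighting phase of each epoch (ZT hour 0-11 light, 12-23 dark)
    zt_h = ((np.arange(n) / epochs_per_h) - sim_config.lights_on_offset_h) % 24.0
    is_light = zt_h < 12.0

    cum = {
        True: np.cumsum(transitions.light, axis=1),
        False: np.cumsum(transitions.dark, axis=1),
    }
    u = rng.random(n)
    states = np.empty(n, dtype=np.int8)
    cur = _STATE_INDEX[transitions.initial_state]
    for i in range(n):
        row = cum[bool(is_light[i])][cur]
        cur = int(np.searchsorted(row, u[i], side="right"))
        cur = min(cur, 2)
        states[i] = cur
    labels = np.array(STATES, dtype="<U2")[states]
    return Hypnogram(states=labels, epoch_s=sim_config.epoch_s)


def _simulate_chains(n_epochs: int, n_chains: int, transitions: TransitionModel,
                     is_light: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorised Markov simulation of many chains at once (epochs x chains)."""
    cum_l = np.cumsum(transitions.light, axis=1)
    cum_d = np.cumsum(transitions.dark, axis=1)
    out = np.empty((n_epochs, n_chains), dtype=np.int8)
    cur = np.full(n_chains, _STATE_INDEX[transitions.initial_state], dtype=np.int8)
    u = rng.random((n_epochs, n_chains))
    for i in range(n_epochs):
        cum = cum_l if is_light[i] else cum_d
        rows = cum[cur]                      # (chains, 3)
        nxt = (u[i][:, None] > rows).sum(axis=1)
        cur = np.minimum(nxt, 2).astype(np.int8)
        out[i] = cur
    return out


# ---------------------------------------------------------------------------
# oscillator realisation and its spectral footprint
# ---------------------------------------------------------------------------

def _resonator(osc: Oscillator, fs: float):
    """Second-order IIR peak filter realising the oscillator, plus the
    white-noise variance gain of the filter (sum of squared impulse
    response), used to scale output RMS exactly."""
    if osc.f0 >= fs / 2:
        raise ValueError(
            f"oscillator center {osc.f0} Hz is at or above Nyquist ({fs / 2} Hz)"
        )
    q = max(osc.f0 / osc.bw, 0.2)
    b, a = sps.iirpeak(osc.f0, q, fs=fs)
    # impulse-response energy; resonator time constant ~ fs/(pi*bw)
    n_ir = int(min(max(20 * fs / (np.pi * osc.bw), 256), 1 << 18))
    h = sps.lfilter(b, a, np.r_[1.0, np.zeros(n_ir - 1)])
    gain = float(np.sum(h * h))
    return b, a, gain


def _one_sided_weights(n: int) -> np.ndarray:
    """Doubling weights of the one-sided periodogram on the rfft grid."""
    w = np.full(n // 2 + 1, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    return w


def expected_component_power(state: str, model: StateSpectralModel,
                             effect: GenotypeEffect, n_samples: int,
                             fs: float) -> np.ndarray:
    """Expected one-sided periodogram power (uV^2) of each rfft component
    for one epoch of the given state: oscillator RMS^2 distributed over the
    grid proportionally to the resonator's squared frequency response, plus
    flat broadband noise.  Sums to the epoch's expected mean-square value."""
    oscillators, noise = model.for_state(state)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    w = _one_sided_weights(n_samples)
    total = np.zeros_like(freqs)
    for osc in oscillators:
        amp = osc.amp * effect.amplitude_factor(state, osc.f0)
        if amp == 0:
            continue
        b, a, _ = _resonator(osc, fs)
        _, h = sps.freqz(b, a, worN=freqs, fs=fs)
        shape = w * np.abs(h) ** 2
        total += amp ** 2 * shape / shape.sum()
    if noise > 0:
        total += noise ** 2 * w / w.sum()
    return total


def expected_bin_power(state: str, model: StateSpectralModel,
                       effect: GenotypeEffect, fs: float, epoch_s: float,
                       n_bins: int = 56) -> np.ndarray:
    """Expected per-epoch power (uV^2) in 1-Hz bins 1..n_bins, bin f
    aggregating rfft components in (f-1, f] Hz."""
    n = int(round(epoch_s * fs))
    comp = expected_component_power(state, model, effect, n, fs)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    out = np.empty(n_bins)
    for f in range(1, n_bins + 1):
        sel = (freqs > f - 1) & (freqs <= f)
        out[f - 1] = comp[sel].sum()
    return out


def generate_epoch_signal(state: str, model: StateSpectralModel,
                          effect: GenotypeEffect, n_samples: int, fs: float,
                          rng: np.random.Generator) -> np.ndarray:
    """One epoch of single-channel EEG for the given state (uV)."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    oscillators, noise = model.for_state(state)
    x = np.zeros(n_samples)
    for osc in oscillators:
        amp = osc.amp * effect.amplitude_factor(state, osc.f0)
        if amp == 0:
            continue
        b, a, gain = _resonator(osc, fs)
        white = rng.standard_normal(n_samples)
        x += sps.lfilter(b, a, white) * (amp / np.sqrt(gain))
    if noise > 0:
        x += noise * rng.standard_normal(n_samples)
    return x


def _crossfaded_signal(states: np.ndarray, model: StateSpectralModel,
                       effect: GenotypeEffect, n_per_epoch: int, fs: float,
                       rng: np.random.Generator,
                       crossfade_s: float = 0.25) -> np.ndarray:
    """Concatenate per-epoch segments with an equal-power cosine crossfade
    so epoch boundaries do not inject broadband leakage."""
    nc = int(round(crossfade_s * fs))
    nc = min(nc, n_per_epoch)
    n_ep = len(states)
    out = np.empty(n_ep * n_per_epoch)
    theta = 0.5 * np.pi * np.arange(1, nc + 1) / (nc + 1)
    w_in, w_out = np.sin(theta), np.cos(theta)
    prev_tail = None
    for i, st in enumerate(states):
        seg = generate_epoch_signal(str(st), model, effect,
                                    n_per_epoch + nc, fs, rng)
        if prev_tail is not None and nc > 0:
            seg[:nc] = seg[:nc] * w_in + prev_tail * w_out
        out[i * n_per_epoch:(i + 1) * n_per_epoch] = seg[:n_per_epoch]
        prev_tail = seg[n_per_epoch:] if nc > 0 else None
    return out


def generate_recording(hypnogram, model: StateSpectralModel,
                       effect: GenotypeEffect, sim_config: SimConfig,
                       rng: np.random.Generator,
                       common_mode_amp: float = 10.0):
    """Synthesise a four-channel recording matching a hypnogram.

    The state-dependent EEG signal appears as the *difference* of the two
    referential channels (EEG_F - EEG_P); a shared common-mode noise
    component on both channels cancels under bipolar derivation.  EMG
    channels carry state-dependent muscle tone.
    """
    from .io import Recording

    fs = sim_config.sampling_rate_hz
    npe = sim_config.samples_per_epoch
    states = hypnogram.states
    eeg = _crossfaded_signal(states, model, effect, npe, fs, rng)
    n = eeg.size
    common = common_mode_amp * rng.standard_normal(n)
    emg = np.empty(n)
    amps = np.array([model.emg_amp[s] for s in states])
    emg = (np.repeat(amps, npe) * rng.standard_normal(n))
    channels = {
        "EEG_F": 0.5 * eeg + common,
        "EEG_P": -0.5 * eeg + common,
        "EMG1": emg,
        "EMG2": emg + 0.2 * np.abs(emg).mean() * rng.standard_normal(n),
    }
    return Recording(channels=channels, sampling_rate_hz=fs,
                     lights_on_offset_h=sim_config.lights_on_offset_h)


def inject_artifacts(recording, model: ArtifactModel,
                     rng: np.random.Generator, epoch_s: float = 4.0):
    """Add Poisson-placed high-amplitude transients to both EEG channels.

    The copy on the parietal channel is delayed by a random 10-40 ms jitter
    and halved, so the transient survives channel subtraction.  Transients
    shorter than an epoch are placed wholly inside one epoch (their windowed
    tails carry no energy across boundaries anyway); longer ones are placed
    freely.  Returns the new recording and the sorted list of epoch indices
    overlapping an artifact.
    """
    from .io import Recording

    fs = recording.sampling_rate_hz
    n = recording.n_samples
    duration_h = n / fs / 3600.0
    expected = model.rate_per_h * duration_h
    k = int(rng.poisson(expected)) if expected > 0 else 0
    f = recording.channels["EEG_F"].copy()
    p = recording.channels["EEG_P"].copy()
    npe = int(round(epoch_s * fs))
    n_art = int(round(model.duration_s * fs))
    affected: set[int] = set()
    max_jitter = int(0.040 * fs)
    if k > 0:
        n_epochs_total = n // npe
        if n_art + max_jitter <= npe:
            eps = rng.integers(0, n_epochs_total, size=k)
            offs = rng.integers(0, npe - n_art - max_jitter + 1, size=k)
            starts = np.sort(eps * npe + offs)
        else:
            starts = np.sort(rng.integers(0, max(n - n_art, 1), size=k))
        bipolar = f - p
        win = np.hanning(n_art)
        t = np.arange(n_art) / fs
        for s0 in starts:
            ep = int(s0 // npe)
            seg = bipolar[ep * npe:(ep + 1) * npe]
            rms = float(np.sqrt(np.mean(seg ** 2))) or 1.0
            f_art = rng.uniform(*model.freq_range)
            phase = rng.uniform(0, 2 * np.pi)
            burst = (model.amplitude * rms * np.sqrt(2.0) * win
                     * np.sin(2 * np.pi * f_art * t + phase))
            end = min(s0 + n_art, n)
            f[s0:end] += burst[: end - s0]
            jitter = int(rng.integers(int(0.010 * fs), max_jitter + 1))
            s1 = min(s0 + jitter, n)
            end1 = min(s1 + n_art, n)
            p[s1:end1] += 0.5 * burst[: end1 - s1]
            last_ep = min(int((end1 - 1) // npe), n // npe - 1)
            affected.update(range(ep, last_ep + 1))
    channels = dict(recording.channels)
    channels["EEG_F"] = f
    channels["EEG_P"] = p
    out = Recording(channels=channels,
                    sampling_rate_hz=recording.sampling_rate_hz,
                    lights_on_offset_h=recording.lights_on_offset_h)
    return out, sorted(affected)


# ---------------------------------------------------------------------------
# fast spectral path
# ---------------------------------------------------------------------------

def sample_epoch_spectra(states: np.ndarray, model: StateSpectralModel,
                         effect: GenotypeEffect, fs: float, epoch_s: float,
                         rng: np.random.Generator,
                         n_bins: int = 56) -> np.ndarray:
    """Draw per-epoch 1-Hz-bin powers directly from the periodogram
    distribution of the oscillator model.

    For Gaussian stationary signals the one-sided periodogram power of each
    Fourier component is exponential with mean equal to the component's
    expected power; a 1-Hz bin summing ``k`` components is approximated as
    Gamma(k, bin_mean / k) (exact when the spectrum is flat within the bin).
    Returns an (n_epochs, n_bins) array in uV^2, statistically matched to
    :func:`generate_epoch_signal` + the per-epoch FFT without synthesising
    any waveform.
    """
    n = int(round(epoch_s * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    k_per_bin = np.array([
        int(np.sum((freqs > f - 1) & (freqs <= f))) for f in range(1, n_bins + 1)
    ])
    means = {
        st: expected_bin_power(st, model, effect, fs, epoch_s, n_bins)
        for st in STATES
    }
    states = np.asarray(states)
    out = np.empty((states.size, n_bins))
    for st in STATES:
        sel = states == st
        m = int(sel.sum())
        if m == 0:
            continue
        g = rng.standard_gamma(k_per_bin[0], size=(m, n_bins)) \
            if np.all(k_per_bin == k_per_bin[0]) else \
            np.stack([rng.standard_gamma(k, size=m) for k in k_per_bin], axis=1)
        out[sel] = g * (means[st] / k_per_bin)
    return out


def subject_model(model: StateSpectralModel, sigma: float,
                  rng: np.random.Generator) -> StateSpectralModel:
    """Between-animal variability: jitter each oscillator amplitude by an
    independent log-normal factor (median 1, log-sd ``sigma``)."""
    if sigma == 0:
        return model
    oscillators = {}
    for st in STATES:
        oscillators[st] = tuple(
            replace(o, amp=o.amp * float(np.exp(sigma * rng.standard_normal())))
            for o in model.oscillators[st]
        )
    noise = {st: a * float(np.exp(sigma * rng.standard_normal()))
             for st, a in model.noise_amp.items()}
    return StateSpectralModel(oscillators=oscillators, noise_amp=noise,
                              emg_amp=dict(model.emg_amp))


# ---------------------------------------------------------------------------
# cohort generation (on disk)
# ---------------------------------------------------------------------------

def generate_cohort(sim_config: SimConfig, out_dir,
                    models: dict[str, tuple[StateSpectralModel, GenotypeEffect]] | None = None,
                    transitions: TransitionModel | None = None,
                    artifact_model: ArtifactModel | None = None,
                    genotypes: tuple[str, str] = ("WT", "KI")):
    """Write a full synthetic cohort: one EDF and one hypnogram TSV per
    subject plus a YAML manifest recording genotypes, seeds and paths.

    ``models`` maps genotype label to (spectral model, genotype effect);
    by default both genotypes share :func:`default_spectral_model` with no
    effect.  Deterministic given ``sim_config.seed``.
    """
    from pathlib import Path

    from .io import write_edf, write_hypnogram, write_manifest

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if models is None:
        base = default_spectral_model()
        models = {g: (base, GenotypeEffect()) for g in genotypes}
    if transitions is None:
        transitions = default_transitions()
    if artifact_model is None:
        artifact_model = ArtifactModel()

    ss = np.random.SeedSequence(sim_config.seed)
    subjects = []
    subject_seeds = ss.spawn(len(genotypes) * sim_config.n_per_group)
    idx = 0
    for genotype in genotypes:
        model, effect = models[genotype]
        for j in range(sim_config.n_per_group):
            sid = f"{genotype}{j + 1:02d}"
            rng = np.random.Generator(np.random.PCG64(subject_seeds[idx]))
            idx += 1
            subj_model = subject_model(model, sim_config.subject_amp_sigma, rng)
            hyp = generate_hypnogram(sim_config, transitions, rng)
            rec = generate_recording(hyp, subj_model, effect, sim_config, rng)
            rec, art_epochs = inject_artifacts(rec, artifact_model, rng,
                                               epoch_s=sim_config.epoch_s)
            edf_path = out / f"{sid}.edf"
            hyp_path = out / f"{sid}_hypnogram.tsv"
            write_edf(edf_path, rec)
            write_hypnogram(hyp_path, hyp)
            subjects.append({
                "id": sid,
                "genotype": genotype,
                "edf": edf_path.name,
                "hypnogram": hyp_path.name,
                "artifact_epochs": [int(e) for e in art_epochs],
            })
    manifest = {
        "seed": sim_config.seed,
        "sampling_rate_hz": sim_config.sampling_rate_hz,
        "epoch_s": sim_config.epoch_s,
        "duration_h": sim_config.duration_h,
        "lights_on_offset_h": sim_config.lights_on_offset_h,
        "subjects": subjects,
    }
    manifest_path = out / "manifest.yaml"
    write_manifest(manifest_path, manifest)
    return manifest_path
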