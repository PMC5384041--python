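"""Per-epoch EEG power spectra with cohort normalization and
amplitude-threshold artifact rejection.

The analysis signal is the bipolar derivation (frontal minus parietal),
zero-phase filtered (0.55-Hz high-pass + mains notch), cut into scoring
epochs and Fourier-transformed.  One-sided periodogram power is aggregated
into 1-Hz bins: bin ``f`` collects FFT components with frequency in
``(f-1, f]`` Hz, so bins 1..56 partition (0, 56] Hz exactly.  Powers are
then expressed as a percentage of the mean total (1-56 Hz) power across
retained epochs, and epochs with any bin above a threshold (default 300%)
are discarded in repeated normalize-reject passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import FilterSpec, Recording


@dataclass
class EpochSpectra:
    """Epochs x 1-Hz-bin power matrix with a retained-epoch mask.

    ``power`` is uV^2 while ``normalized`` is False, percent of the mean
    total power of retained epochs afterwards.  ``norm_constant`` keeps the
    uV^2 mean total power the current percent scale refers to.
    """

    power: np.ndarray
    bins: np.ndarray = field(default_factory=lambda: np.arange(1, 57))
    retained: np.ndarray | None = None
    normalized: bool = False
    norm_constant: float | None = None

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.ndim != 2:
            raise ValueError("power must be an (epochs x bins) matrix")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if self.retained is None:
            self.retained = np.ones(self.power.shape[0], dtype=bool)
        self.retained = np.asarray(self.retained, dtype=bool)
        if self.retained.shape != (self.power.shape[0],):
            raise ValueError("retained mask length must equal epoch count")

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]

    def copy(self) -> "EpochSpectra":
        return EpochSpectra(power=self.power.copy(), bins=self.bins.copy(),
                            retained=self.retained.copy(),
                            normalized=self.normalized,
                            norm_constant=self.norm_constant)


def derive_bipolar(recording: Recording, frontal: str = "EEG_F",
                   parietal: str = "EEG_P") -> np.ndarray:
    """Frontal minus parietal referential channels; common-mode content
    (shared reference activity, cable noise) cancels."""
    for name in (frontal, parietal):
        if name not in recording.channels:
            raise KeyError(
                f"channel {name!r} not in recording "
                f"(has {list(recording.channels)})"
            )
    return recording.channels[frontal] - recording.channels[parietal]


def apply_filters(x: np.ndarray, fs: float,
                  spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase high-pass + mains notch; output has the input's length."""
    spec = spec or FilterSpec()
    spec.validate(fs)
    x = np.asarray(x, dtype=float)
    if x.size <= 3 * max(spec.order, 2):
        raise ValueError("signal too short for the configured filter order")
    sos = sps.butter(spec.order, spec.highpass_hz, btype="highpass",
                     fs=fs, output="sos")
    # pad by several high-pass time constants so edge transients decay
    # inside the padding, not in the returned signal
    padlen = int(min(x.size - 1, 6 * fs / spec.highpass_hz))
    y = sps.sosfiltfilt(sos, x, padlen=padlen)
    b, a = sps.iirnotch(spec.notch_hz, spec.notch_q, fs=fs)
    return sps.filtfilt(b, a, y, padlen=min(x.size - 1, padlen))


def epoch_power_spectrum(x: np.ndarray, fs: float, epoch_s: float = 4.0,
                         total_range: tuple[int, int] = (1, 56),
                         window: str = "rectangular") -> EpochSpectra:
    """Per-epoch one-sided periodogram power in 1-Hz bins (uV^2).

    The per-component power is normalised so that the sum over all FFT
    components equals the epoch's mean-square value (Parseval); the optional
    Hann window is power-compensated.
    """
    x = np.asarray(x, dtype=float)
    n = int(round(epoch_s * fs))
    if n <= 0:
        raise ValueError("epoch length must be positive")
    rem = x.size % n
    if rem:
        raise ValueError(
            f"signal length {x.size} is not an integer number of {epoch_s}-s "
            f"epochs at {fs} Hz ({rem} samples left over)"
        )
    epochs = x.reshape(-1, n)
    if window == "hann":
        w = np.hanning(n)
        epochs = epochs * (w / np.sqrt(np.mean(w ** 2)))
    elif window != "rectangular":
        raise ValueError(f"unknown FFT window {window!r}")
    spec = np.fft.rfft(epochs, axis=1)
    comp = np.abs(spec) ** 2 / n ** 2
    comp *= 2.0
    comp[:, 0] /= 2.0
    if n % 2 == 0:
        comp[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    lo, hi = total_range
    power = np.empty((epochs.shape[0], hi - lo + 1))
    for j, f in enumerate(range(lo, hi + 1)):
        sel = (freqs > f - 1) & (freqs <= f)
        power[:, j] = comp[:, sel].sum(axis=1)
    return EpochSpectra(power=power, bins=np.arange(lo, hi + 1))


def normalize(spectra: EpochSpectra) -> EpochSpectra:
    """Express every bin as a percentage of the mean total power over
    retained epochs; all epochs (retained or not) are rescaled."""
    out = spectra.copy()
    if not out.retained.any():
        raise ValueError("cannot normalize: no retained epochs")
    totals = out.power[out.retained].sum(axis=1)
    mean_total = float(totals.mean())
    if mean_total <= 0:
        raise ValueError("cannot normalize: mean total power is zero")
    out.power = out.power * (100.0 / mean_total)
    if out.normalized and out.norm_constant is not None:
        # re-normalization: keep the constant on the original uV^2 scale
        out.norm_constant = out.norm_constant * mean_total / 100.0
    else:
        out.norm_constant = mean_total
    out.normalized = True
    return out


def reject_artifacts(spectra: EpochSpectra, threshold_percent: float = 300.0,
                     passes: int = 2) -> tuple[EpochSpectra, pd.DataFrame]:
    """Iterative normalize-then-threshold artifact rejection.

    Each pass normalizes over the currently retained epochs and drops every
    retained epoch having any 1-Hz bin above ``threshold_percent``.  After
    the final pass the spectra are re-normalized over the surviving set, so
    downstream percent values refer to the analyzed epochs.  Returns the
    cleaned spectra and a per-pass report (epochs before, removed, fraction).
    """
    if threshold_percent <= 0:
        raise ValueError("threshold must be > 0")
    if passes < 1:
        raise ValueError("passes must be >= 1")
    out = spectra.copy()
    rows = []
    for p in range(1, passes + 1):
        out = normalize(out)
        before = int(out.retained.sum())
        exceed = (out.power > threshold_percent).any(axis=1) & out.retained
        out.retained = out.retained & ~exceed
        if not out.retained.any():
            raise ValueError(
                f"rejection pass {p} removed all epochs "
                f"(threshold {threshold_percent}%)"
            )
        removed = int(exceed.sum())
        rows.append({"pass": p, "epochs_before": before,
                     "epochs_removed": removed,
                     "fraction_removed": removed / before})
    out = normalize(out)
    report = pd.DataFrame(rows)
    report.attrs["overall_fraction_removed"] = (
        1.0 - out.retained.sum() / spectra.retained.sum()
    )
    return out, report
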