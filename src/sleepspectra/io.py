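"""File formats and run configuration.

Signals travel as EDF (European Data Format): reading goes through MNE,
writing through a minimal plain-EDF emitter (16-bit samples, one-second
data records).  Hypnograms are two-column TSV files (epoch index, state
label in {W, NR, R}); cohort manifests and run configuration are YAML.

All signal values are microvolt and all powers uV^2 throughout the
package.  Zeitgeber convention: ZT0 = lights-on; light phase ZT [0, 12),
dark phase ZT [12, 24).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger("sleepspectra")

VALID_STATES = ("W", "NR", "R")
DEFAULT_BANDS: dict[str, tuple[int, int]] = {
    "delta": (1, 4),
    "theta": (5, 8),
    "alpha": (9, 12),
    "sigma": (13, 15),
    "beta": (15, 30),   # 15-Hz overlap with sigma kept as printed band limits
}
# alternative non-overlapping preset
BANDS_NO_OVERLAP: dict[str, tuple[int, int]] = {**DEFAULT_BANDS, "beta": (16, 30)}


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Multichannel signal in uV with lights-on alignment metadata."""

    channels: dict[str, np.ndarray]
    sampling_rate_hz: float
    lights_on_offset_h: float = 0.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("recording must contain at least one channel")
        lengths = {name: len(x) for name, x in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channels have unequal lengths: {lengths}")
        if not 0 <= self.lights_on_offset_h < 24:
            raise ValueError("lights_on_offset_h must lie in [0, 24)")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_h(self) -> float:
        return self.n_samples / self.sampling_rate_hz / 3600.0


@dataclass
class Hypnogram:
    """Scored vigilance states, one label per fixed-length epoch."""

    states: np.ndarray
    epoch_s: float = 4.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="<U2")
        if self.states.size == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = ~np.isin(self.states, VALID_STATES)
        if bad.any():
            i = int(np.nonzero(bad)[0][0])
            raise FormatError(
                f"unknown state label {self.states[i]!r} at epoch {i}; "
                f"expected one of {VALID_STATES}"
            )
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")

    @property
    def n_epochs(self) -> int:
        return int(self.states.size)

    @property
    def duration_h(self) -> float:
        return self.n_epochs * self.epoch_s / 3600.0


@dataclass(frozen=True)
class FilterSpec:
    """Noise-reduction filtering applied before the FFT: zero-phase
    Butterworth high-pass (removes DC and electrode drift) plus a mains
    notch."""

    highpass_hz: float = 0.55
    order: int = 4
    notch_hz: float = 60.0
    notch_q: float = 30.0

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not 0 < self.highpass_hz < nyq:
            raise ValueError(
                f"high-pass cutoff {self.highpass_hz} Hz outside (0, {nyq})"
            )
        if not 0 < self.notch_hz < nyq:
            raise ValueError(f"notch {self.notch_hz} Hz outside (0, {nyq})")


@dataclass
class RunConfig:
    """Validated analysis parameters with study defaults."""

    bands: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    rejection_threshold_percent: float = 300.0
    rejection_passes: int = 2
    time_bin_h: float = 3.0
    total_power_range: tuple[int, int] = (1, 56)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    fft_window: str = "rectangular"
    alpha: float = 0.05
    epoch_s: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo_t, hi_t = self.total_power_range
        if not (1 <= lo_t <= hi_t):
            raise ValueError(f"invalid total power range {self.total_power_range}")
        for name, (lo, hi) in self.bands.items():
            if not (lo_t <= lo <= hi <= hi_t):
                raise ValueError(
                    f"band {name!r} ({lo}-{hi} Hz) outside total power range "
                    f"{lo_t}-{hi_t} Hz"
                )
        if self.rejection_threshold_percent <= 0:
            raise ValueError("rejection threshold must be > 0")
        if self.rejection_passes < 1:
            raise ValueError("rejection passes must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.time_bin_h <= 0 or abs(24.0 / self.time_bin_h - round(24.0 / self.time_bin_h)) > 1e-9:
            raise ValueError("time_bin_h must divide 24 h")


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, applying defaults for absent keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"config {path} must be a mapping")
    kwargs = {}
    if "bands" in raw:
        kwargs["bands"] = {
            str(k): (int(v[0]), int(v[1])) for k, v in raw.pop("bands").items()
        }
    if "filter" in raw:
        kwargs["filter_spec"] = FilterSpec(**raw.pop("filter"))
    known = {"rejection_threshold_percent", "rejection_passes", "time_bin_h",
             "alpha", "seed", "fft_window", "epoch_s"}
    if "total_power_range" in raw:
        v = raw.pop("total_power_range")
        kwargs["total_power_range"] = (int(v[0]), int(v[1]))
    for k in list(raw):
        if k in known:
            kwargs[k] = raw.pop(k)
    if raw:
        raise FormatError(f"unknown config keys: {sorted(raw)}")
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # shorten numeric fields without breaking the fixed layout
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, recording: Recording) -> None:
    """Write a plain EDF file (16-bit, 1-s data records).

    Physical range is set per channel to the observed amplitude extreme, so
    quantisation error is at most range/65534.  The recording must span an
    integer number of seconds at an integer sampling rate.
    """
    fs = recording.sampling_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n = recording.n_samples
    if n % fs != 0:
        raise ValueError(
            f"recording length {n} is not an integer number of seconds at {fs} Hz"
        )
    n_records = n // fs
    names = list(recording.channels)
    ns = len(names)

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("X X X X", 80)                 # local patient id
    header += _edf_field("Startdate 01-JAN-2001 X X X", 80)
    header += _edf_field("01.01.01", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (ns + 1), 8)
    header += _edf_field("", 44)
    header += _edf_field(n_records, 8)
    header += _edf_field(1, 8)                          # record duration (s)
    header += _edf_field(ns, 4)

    phys_max = []
    for name in names:
        x = recording.channels[name]
        pm = float(np.max(np.abs(x)))
        pm = max(pm, 1e-3)
        phys_max.append(pm)

    def per_channel(fmt) -> bytes:
        return b"".join(fmt(i) for i in range(ns))

    header += per_channel(lambda i: _edf_field(names[i], 16))
    header += per_channel(lambda i: _edf_field("", 80))
    header += per_channel(lambda i: _edf_field("uV", 8))
    header += per_channel(lambda i: _edf_field(f"{-phys_max[i]:.6g}"[:8], 8))
    header += per_channel(lambda i: _edf_field(f"{phys_max[i]:.6g}"[:8], 8))
    header += per_channel(lambda i: _edf_field(-32767, 8))
    header += per_channel(lambda i: _edf_field(32767, 8))
    header += per_channel(lambda i: _edf_field("", 80))
    header += per_channel(lambda i: _edf_field(fs, 8))
    header += per_channel(lambda i: _edf_field("", 32))
    assert len(header) == 256 * (ns + 1)

    # the stated physical max must match what we wrote (parsed back), so
    # digitise against the parsed value to keep the round trip exact
    parsed_pm = [float(f"{pm:.6g}"[:8]) for pm in phys_max]
    digital = np.empty((ns, n), dtype="<i2")
    for i, name in enumerate(names):
        x = np.clip(recording.channels[name], -parsed_pm[i], parsed_pm[i])
        digital[i] = np.round(x / parsed_pm[i] * 32767).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        # records: for each second, each channel's fs samples in sequence
        blocks = digital.reshape(ns, n_records, fs).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(blocks).tobytes())


def read_recording(path, lights_on_offset_h: float = 0.0,
                   min_eeg_channels: int = 2) -> Recording:
    """Load an EDF recording via MNE and return signals in uV."""
    import mne

    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such EDF file: {p}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(p, preload=True, verbose="error")
    eeg = [ch for ch in raw.ch_names if ch.upper().startswith("EEG")]
    if len(eeg) < min_eeg_channels:
        raise FormatError(
            f"{p.name}: expected >= {min_eeg_channels} EEG channels, found "
            f"{eeg or 'none'} among {raw.ch_names}"
        )
    data = raw.get_data(units="uV")
    channels = {name: np.asarray(data[i], dtype=float)
                for i, name in enumerate(raw.ch_names)}
    logger.info("read %s: %d channels x %d samples at %g Hz", p.name,
                len(channels), data.shape[1], raw.info["sfreq"])
    return Recording(channels=channels, sampling_rate_hz=float(raw.info["sfreq"]),
                     lights_on_offset_h=lights_on_offset_h)


# ---------------------------------------------------------------------------
# hypnograms
# ---------------------------------------------------------------------------

def write_hypnogram(path, hypnogram: Hypnogram) -> None:
    """Two-column TSV: 0-based epoch index, state label."""
    with open(path, "w") as fh:
        for i, st in enumerate(hypnogram.states):
            fh.write(f"{i}\t{st}\n")


def read_hypnogram(path, epoch_s: float = 4.0) -> Hypnogram:
    """Read a two-column TSV hypnogram with contiguous 0-based indices."""
    p = Path(path)
    states = []
    with open(p) as fh:
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{p.name}:{lineno + 1}: expected 2 columns")
            idx_s, label = parts
            try:
                idx = int(idx_s)
            except ValueError as exc:
                raise FormatError(
                    f"{p.name}:{lineno + 1}: non-integer epoch index {idx_s!r}"
                ) from exc
            if idx != len(states):
                raise FormatError(
                    f"{p.name}: epoch index {idx} at line {lineno + 1}; expected "
                    f"{len(states)} (indices must be contiguous and 0-based)"
                )
            if label not in VALID_STATES:
                raise FormatError(
                    f"{p.name}: unknown state label {label!r} at epoch {idx}"
                )
            states.append(label)
    if not states:
        raise FormatError(f"{p.name}: empty hypnogram")
    return Hypnogram(states=np.array(states, dtype="<U2"), epoch_s=epoch_s)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_manifest(path) -> dict:
    manifest = yaml.safe_load(Path(path).read_text())
    if not isinstance(manifest, dict) or "subjects" not in manifest:
        raise FormatError(f"manifest {path} must be a mapping with 'subjects'")
    return manifest
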