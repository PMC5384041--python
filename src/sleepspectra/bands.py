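"""Band powers, per-state spectral profiles and 3-h band time courses.

Operates on normalized :class:`~sleepspectra.spectral.EpochSpectra` aligned
epoch-for-epoch with a hypnogram.  Bands are inclusive 1-Hz-bin ranges; the
default set keeps the printed sigma (13-15 Hz) / beta (15-30 Hz) overlap at
15 Hz (bands are descriptive summaries, not a partition).  Empty cells are
reported as missing (NaN), never as zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .architecture import _epoch_zt_hours
from .io import DEFAULT_BANDS, Hypnogram, VALID_STATES
from .spectral import EpochSpectra


def validate_bands(bands: dict[str, tuple[int, int]],
                   bin_range: tuple[int, int] = (1, 56)) -> None:
    lo_t, hi_t = bin_range
    for name, (lo, hi) in bands.items():
        if not (lo_t <= lo <= hi <= hi_t):
            raise ValueError(
                f"band {name!r} ({lo}-{hi} Hz) references bins outside "
                f"{lo_t}-{hi_t} Hz"
            )


def band_powers(spectra: EpochSpectra,
                bands: dict[str, tuple[int, int]] | None = None) -> pd.DataFrame:
    """Per-epoch band power: the sum of a band's 1-Hz bins, retained epochs
    only.  Index = original epoch indices of retained epochs."""
    bands = bands or DEFAULT_BANDS
    if not spectra.normalized:
        raise ValueError("band_powers expects normalized spectra")
    validate_bands(bands, (int(spectra.bins[0]), int(spectra.bins[-1])))
    idx = np.nonzero(spectra.retained)[0]
    data = {}
    for name, (lo, hi) in bands.items():
        cols = (spectra.bins >= lo) & (spectra.bins <= hi)
        data[name] = spectra.power[idx][:, cols].sum(axis=1)
    return pd.DataFrame(data, index=pd.Index(idx, name="epoch"))


def state_spectral_profile(spectra: EpochSpectra, hypnogram: Hypnogram,
                           state: str) -> tuple[np.ndarray, int]:
    """Mean normalized power per 1-Hz bin over retained epochs of one state.

    Returns the profile (NaN-filled if the state never occurs among retained
    epochs) and the number of epochs averaged.
    """
    if state not in VALID_STATES:
        raise ValueError(f"unknown state {state!r}")
    if hypnogram.n_epochs != spectra.n_epochs:
        raise ValueError(
            f"hypnogram has {hypnogram.n_epochs} epochs but spectra have "
            f"{spectra.n_epochs}"
        )
    sel = spectra.retained & (hypnogram.states == state)
    n = int(sel.sum())
    if n == 0:
        return np.full(spectra.power.shape[1], np.nan), 0
    return spectra.power[sel].mean(axis=0), n


def band_timecourse(band_table: pd.DataFrame, hypnogram: Hypnogram,
                    lights_on_offset_h: float = 0.0,
                    bin_width_h: float = 3.0) -> pd.DataFrame:
    """Mean band power per (state, band, ZT bin), per day then averaged.

    ``band_table`` is the per-epoch output of :func:`band_powers` (indexed
    by epoch).  The hypnogram must cover an integer number of days after
    ZT0 alignment.  Returns a long-format frame with columns state, band,
    zt_bin (left edge, h) and value; cells with no retained epochs on any
    day are NaN.
    """
    if bin_width_h <= 0 or abs(24.0 / bin_width_h - round(24.0 / bin_width_h)) > 1e-9:
        raise ValueError("bin_width_h must divide 24 h")
    epoch_s = hypnogram.epoch_s
    zt = _epoch_zt_hours(hypnogram.n_epochs, epoch_s, lights_on_offset_h)
    t_h = np.arange(hypnogram.n_epochs) * epoch_s / 3600.0
    covered_h = hypnogram.n_epochs * epoch_s / 3600.0 - lights_on_offset_h
    if covered_h <= 0 or abs(covered_h / 24.0 - round(covered_h / 24.0)) > 1e-9:
        raise ValueError(
            f"hypnogram covers {covered_h:g} h after alignment; integer days required"
        )
    day = np.floor((t_h - lights_on_offset_h) / 24.0).astype(int)
    n_bins = int(round(24.0 / bin_width_h))
    zt_bin = np.minimum((zt / bin_width_h).astype(int), n_bins - 1)

    idx = band_table.index.to_numpy()
    keep = day[idx] >= 0          # epochs before first lights-on are dropped
    tbl = band_table.iloc[keep]
    meta = pd.DataFrame({
        "state": hypnogram.states[idx[keep]],
        "zt_bin": zt_bin[idx[keep]] * bin_width_h,
        "day": day[idx[keep]],
    }, index=tbl.index)
    long = tbl.join(meta).melt(
        id_vars=["state", "zt_bin", "day"], var_name="band", value_name="value")
    per_day = long.groupby(["state", "band", "zt_bin", "day"])["value"].mean()
    averaged = per_day.groupby(["state", "band", "zt_bin"]).mean()
    full = pd.MultiIndex.from_product(
        [list(VALID_STATES), list(band_table.columns),
         [b * bin_width_h for b in range(n_bins)]],
        names=["state", "band", "zt_bin"])
    out = averaged.reindex(full).reset_index()
    return out


def within_state_normalize(timecourse: pd.DataFrame) -> pd.DataFrame:
    """Express each (state, band) time course as percent of its own 24-h
    mean, per subject: cell / mean(all that state-band's cells) x 100.

    Requires complete cells (no NaN) for every (state, band) present; the
    mean of the normalized cells is exactly 100.
    """
    out = timecourse.copy()
    group_cols = [c for c in ("subject", "state", "band") if c in out.columns]

    def _norm(g: pd.DataFrame) -> pd.DataFrame:
        if g["value"].isna().all():
            return g          # state absent entirely: nothing to normalize
        if g["value"].isna().any():
            key = tuple(g.iloc[0][group_cols])
            raise ValueError(f"missing cells in time course for {key}")
        m = g["value"].mean()
        if m == 0:
            key = tuple(g.iloc[0][group_cols])
            raise ValueError(f"zero 24-h mean for {key}")
        g = g.copy()
        g["value"] = 100.0 * g["value"] / m
        return g

    pieces = [
        _norm(g) for _, g in out.groupby(group_cols, sort=False)
    ]
    return pd.concat(pieces).sort_index()
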