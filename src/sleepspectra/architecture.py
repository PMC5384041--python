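"""Sleep architecture from scored hypnograms.

Phase proportions, hourly time-of-day profiles, and episode (bout)
statistics, with day-level averaging: each metric is computed per 24-h day
aligned to lights-on (ZT0) and then averaged across days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Hypnogram, VALID_STATES

PHASES = ("light", "dark")


@dataclass(frozen=True)
class Episode:
    """A maximal run of consecutive epochs in one state."""

    state: str
    start: int          # epoch index within the hypnogram passed in
    length: int         # epochs
    phase: str          # lighting phase at onset ("light" or "dark")


def _epoch_zt_hours(n_epochs: int, epoch_s: float,
                    lights_on_offset_h: float) -> np.ndarray:
    """Zeitgeber time (h) of each epoch's start."""
    t_h = np.arange(n_epochs) * epoch_s / 3600.0
    return (t_h - lights_on_offset_h) % 24.0


def split_days(hypnogram: Hypnogram, lights_on_offset_h: float = 0.0) -> list[Hypnogram]:
    """Split into per-24-h segments, each starting at ZT0.

    Epochs recorded before the first lights-on are discarded; the remainder
    must cover an integer number of days.
    """
    epochs_per_day = int(round(24.0 * 3600.0 / hypnogram.epoch_s))
    skip = 0
    if lights_on_offset_h > 0:
        skip = int(round(lights_on_offset_h * 3600.0 / hypnogram.epoch_s))
    states = hypnogram.states[skip:]
    if states.size == 0 or states.size % epochs_per_day != 0:
        covered_h = states.size * hypnogram.epoch_s / 3600.0
        raise ValueError(
            f"hypnogram covers {covered_h:g} h after ZT0 alignment; an integer "
            "number of 24-h days is required"
        )
    n_days = states.size // epochs_per_day
    return [
        Hypnogram(states=states[d * epochs_per_day:(d + 1) * epochs_per_day],
                  epoch_s=hypnogram.epoch_s)
        for d in range(n_days)
    ]


def state_proportions(day: Hypnogram, phase: str) -> dict[str, float]:
    """Fraction of the 12-h phase spent in each state (sums to 1)."""
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}, got {phase!r}")
    half = day.n_epochs // 2
    seg = day.states[:half] if phase == "light" else day.states[half:]
    return {s: float(np.mean(seg == s)) for s in VALID_STATES}


def hourly_profile(day: Hypnogram) -> pd.DataFrame:
    """24 x 3 table: fraction of each ZT hour spent in each state."""
    per_h = int(round(3600.0 / day.epoch_s))
    rows = []
    for h in range(24):
        seg = day.states[h * per_h:(h + 1) * per_h]
        rows.append([float(np.mean(seg == s)) for s in VALID_STATES])
    return pd.DataFrame(rows, columns=list(VALID_STATES),
                        index=pd.Index(range(24), name="zt_hour"))


def segment_episodes(hypnogram: Hypnogram,
                     lights_on_offset_h: float = 0.0) -> list[Episode]:
    """Partition the hypnogram into maximal same-state runs.

    An episode's phase is the lighting phase of its first epoch; episodes
    spanning the light/dark boundary belong wholly to their onset phase.
    """
    states = hypnogram.states
    change = np.nonzero(states[1:] != states[:-1])[0] + 1
    starts = np.r_[0, change]
    ends = np.r_[change, states.size]
    zt = _epoch_zt_hours(states.size, hypnogram.epoch_s, lights_on_offset_h)
    return [
        Episode(state=str(states[s]), start=int(s), length=int(e - s),
                phase="light" if zt[s] < 12.0 else "dark")
        for s, e in zip(starts, ends)
    ]


def episode_stats(episodes: list[Episode], epoch_s: float,
                  min_epochs: int = 1) -> pd.DataFrame:
    """Episode count and mean duration (s) per state per onset phase.

    Episodes shorter than ``min_epochs`` are excluded (default keeps all).
    States absent in a phase get count 0 and NaN duration.
    """
    rows = []
    for phase in PHASES:
        for state in VALID_STATES:
            lengths = [e.length for e in episodes
                       if e.state == state and e.phase == phase
                       and e.length >= min_epochs]
            rows.append({
                "phase": phase,
                "state": state,
                "count": len(lengths),
                "mean_duration_s": float(np.mean(lengths)) * epoch_s
                if lengths else np.nan,
            })
    return pd.DataFrame(rows).set_index(["phase", "state"])


def architecture_summary(hypnogram: Hypnogram,
                         lights_on_offset_h: float = 0.0) -> dict:
    """Per-subject architecture metrics, computed per day then averaged.

    Returns ``proportions`` (phase x state fractions), ``hourly`` (24 x 3
    fractions) and ``episodes`` (count and mean duration per phase x state).
    """
    days = split_days(hypnogram, lights_on_offset_h)
    prop_frames, hourly_frames, episode_frames = [], [], []
    for day in days:
        prop_frames.append(pd.DataFrame(
            {ph: state_proportions(day, ph) for ph in PHASES}
        ).T.rename_axis("phase"))
        hourly_frames.append(hourly_profile(day))
        eps = segment_episodes(day, lights_on_offset_h=0.0)
        episode_frames.append(episode_stats(eps, day.epoch_s))
    proportions = sum(prop_frames) / len(prop_frames)
    hourly = sum(hourly_frames) / len(hourly_frames)
    episodes = pd.concat(episode_frames).groupby(level=["phase", "state"]).mean()
    return {"proportions": proportions, "hourly": hourly, "episodes": episodes}
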