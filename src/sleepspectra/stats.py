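"""Two-group statistics: pooled-variance t-tests, split-plot repeated-
measures ANOVA, and Bonferroni-corrected post-hoc tests.

The split-plot (mixed) design has one between-subject factor (genotype,
``g`` groups) and one within-subject factor (frequency bin or time bin,
``w`` levels) with subjects nested in groups.  The between effect is tested
against the subjects-within-groups mean square; the within effect and the
interaction against the residual (subject x level) mean square:

    between     df = (g - 1, N - g)
    within      df = (w - 1, (N - g)(w - 1))
    interaction df = ((g - 1)(w - 1), (N - g)(w - 1))

No sphericity correction is applied by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats


def students_t(group_a, group_b) -> tuple[float, int, float]:
    """Two-sided pooled-variance (equal-variance) Student's t-test.

    Returns (t, df, p) with df = n_a + n_b - 2.  If the pooled variance is
    zero: identical means give (0, df, 1); different means are an error.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must contain finite values only")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t = diff / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    p = 2.0 * sstats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


@dataclass
class AnovaTable:
    """F, df and p per effect of a split-plot design."""

    effects: dict[str, dict] = field(default_factory=dict)
    group_sizes: dict[str, int] = field(default_factory=dict)
    n_within: int = 0

    def __getitem__(self, effect: str) -> dict:
        return self.effects[effect]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.effects).T.rename_axis("effect")


def mixed_anova(data, groups, within_name: str = "within",
                between_name: str = "genotype") -> AnovaTable:
    """Split-plot ANOVA on an (N subjects x w levels) response matrix.

    ``groups`` assigns each row to a between-subject group; data must be
    complete (no NaN).  With a single within level the design degenerates to
    a one-way ANOVA on the column (a warning is issued and only the between
    effect is reported).
    """
    y = np.asarray(data, dtype=float)
    groups = np.asarray(groups)
    if y.ndim != 2 or y.shape[0] != groups.size:
        raise ValueError("data must be (subjects x within levels) matching groups")
    if np.isnan(y).any():
        missing = [(int(i), int(j)) for i, j in zip(*np.nonzero(np.isnan(y)))]
        raise ValueError(f"missing cells (subject, level): {missing[:10]}")
    labels, ginv = np.unique(groups, return_inverse=True)
    g = labels.size
    n_j = np.bincount(ginv)
    if np.any(n_j < 2):
        raise ValueError("each group needs at least 2 subjects")
    N, w = y.shape

    table = AnovaTable(group_sizes={str(l): int(n) for l, n in zip(labels, n_j)},
                       n_within=w)
    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([subj_means[ginv == j].mean() for j in range(g)])

    ss_between = w * float(np.sum(n_j * (group_means - grand) ** 2))
    ss_subj = w * float(np.sum((subj_means - group_means[ginv]) ** 2))
    df_b, df_subj = g - 1, N - g
    f_b = (ss_between / df_b) / (ss_subj / df_subj)
    table.effects[between_name] = {
        "F": float(f_b), "df1": df_b, "df2": df_subj,
        "p": float(sstats.f.sf(f_b, df_b, df_subj)),
        "SS": ss_between, "SS_error": ss_subj,
    }
    if w == 1:
        warnings.warn("single within level: reporting one-way ANOVA on the "
                      "column; within/interaction effects are undefined")
        return table

    level_means = y.mean(axis=0)
    cell_means = np.stack([y[ginv == j].mean(axis=0) for j in range(g)])
    ss_within_factor = N * float(np.sum((level_means - grand) ** 2))
    ss_inter = float(np.sum(
        n_j[:, None] * (cell_means - group_means[:, None]
                        - level_means[None, :] + grand) ** 2))
    ss_total = float(np.sum((y - grand) ** 2))
    ss_resid = ss_total - ss_between - ss_subj - ss_within_factor - ss_inter
    df_w = w - 1
    df_resid = (N - g) * (w - 1)
    f_w = (ss_within_factor / df_w) / (ss_resid / df_resid)
    f_i = (ss_inter / (df_b * df_w)) / (ss_resid / df_resid)
    table.effects[within_name] = {
        "F": float(f_w), "df1": df_w, "df2": df_resid,
        "p": float(sstats.f.sf(f_w, df_w, df_resid)),
        "SS": ss_within_factor, "SS_error": ss_resid,
    }
    table.effects["interaction"] = {
        "F": float(f_i), "df1": df_b * df_w, "df2": df_resid,
        "p": float(sstats.f.sf(f_i, df_b * df_w, df_resid)),
        "SS": ss_inter, "SS_error": ss_resid,
    }
    return table


def bonferroni_posthoc(data, groups, alpha: float = 0.05,
                       m: int | None = None,
                       level_names=None) -> pd.DataFrame:
    """Per-within-level two-group t-tests with Bonferroni adjustment.

    ``m`` is the number of comparisons charged (defaults to the number of
    within levels); adjusted p = min(1, m x raw p); a level is flagged when
    the adjusted p is below ``alpha``.
    """
    y = np.asarray(data, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("post-hoc t-tests require exactly 2 groups")
    w = y.shape[1]
    m = w if m is None else m
    if m < 1:
        raise ValueError("m must be >= 1")
    if level_names is None:
        level_names = list(range(w))
    rows = []
    a_sel, b_sel = groups == labels[0], groups == labels[1]
    for k in range(w):
        t, df, p = students_t(y[a_sel, k], y[b_sel, k])
        p_adj = min(1.0, m * p)
        rows.append({"level": level_names[k], "t": t, "df": df, "p_raw": p,
                     "p_bonferroni": p_adj, "significant": p_adj < alpha})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Monte-Carlo validation of the ANOVA under the generator's null
# ---------------------------------------------------------------------------

def type_i_error_sim(n_reps: int = 1000, alpha: float = 0.05, seed: int = 0,
                     n_per_group: int = 4, duration_h: float = 6.0,
                     band: tuple[int, int] = (1, 4), state: str = "NR",
                     bin_width_h: float = 3.0) -> float:
    """Empirical type-I error of the between-genotype split-plot F test.

    Simulates cohorts with *equal* genotype models (null), runs the spectral
    pipeline on fast-path sampled epoch spectra (normalize, two-pass 300%
    rejection, band extraction, ZT time bins), and returns the fraction of
    replicates whose between-genotype p-value falls below ``alpha``.
    Deterministic given ``seed``.
    """
    from . import simulate as sim
    from .spectral import EpochSpectra, reject_artifacts

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg = sim.SimConfig(duration_h=duration_h, n_per_group=n_per_group,
                        seed=seed)
    model = sim.default_spectral_model()
    effect = sim.GenotypeEffect()
    transitions = sim.default_transitions()
    n_subj = 2 * n_per_group
    n_ep = cfg.n_epochs
    epochs_per_h = int(round(3600.0 / cfg.epoch_s))
    is_light = (((np.arange(n_ep) / epochs_per_h)
                 - cfg.lights_on_offset_h) % 24.0) < 12.0
    rng = np.random.Generator(np.random.PCG64(seed))
    # all hypnograms for all replicates in one vectorised pass
    chains = sim._simulate_chains(n_ep, n_reps * n_subj, transitions,
                                  is_light, rng)
    state_labels = np.array(sim.STATES, dtype="<U2")
    zt_bin = np.minimum(
        ((np.arange(n_ep) / epochs_per_h) % 24.0 / bin_width_h).astype(int),
        int(round(24.0 / bin_width_h)) - 1)
    n_bins_seen = np.unique(zt_bin[:n_ep]).size
    lo, hi = band
    groups = np.array(["WT"] * n_per_group + ["KI"] * n_per_group)

    hits = 0
    for r in range(n_reps):
        cells = np.empty((n_subj, n_bins_seen))
        for s in range(n_subj):
            states = state_labels[chains[:, r * n_subj + s]]
            subj = sim.subject_model(model, cfg.subject_amp_sigma, rng)
            pw = sim.sample_epoch_spectra(states, subj, effect,
                                          cfg.sampling_rate_hz, cfg.epoch_s, rng)
            spec = EpochSpectra(power=pw)
            spec, _ = reject_artifacts(spec, 300.0, 2)
            sel_cols = (spec.bins >= lo) & (spec.bins <= hi)
            bandpow = spec.power[:, sel_cols].sum(axis=1)
            in_state = (states == state) & spec.retained
            for b in range(n_bins_seen):
                m = in_state & (zt_bin == b)
                cells[s, b] = bandpow[m].mean() if m.any() else np.nan
        if np.isnan(cells).any():
            continue   # a state missing from a bin: replicate not analysable
        tbl = mixed_anova(cells, groups, within_name="time")
        if tbl["genotype"]["p"] < alpha:
            hits += 1
    return hits / n_reps
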