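# Methods

## Scope and data model

The package analyses scored rodent polysomnography: a multichannel
`Recording` (μV, with its sampling rate and the lights-on offset that
anchors zeitgeber time ZT0) and a `Hypnogram` (one label in {W, NR, R} per
4-s epoch). All powers are μV² before normalization and percent afterwards.
ZT convention: ZT0 = lights-on, light phase ZT [0, 12), dark ZT [12, 24).
Sleep scoring itself is out of scope — hypnograms are inputs.

## Spectral chain

**Bipolar derivation.** Frontal minus parietal referential channels.
Common-mode activity (shared reference signal, cable pickup) cancels
exactly; independent components' variances add.

**Filtering.** Zero-phase (forward-backward) 4th-order Butterworth
high-pass at 0.55 Hz plus a 60-Hz notch (Q = 30). Acquisition-software
filter settings of the form "HFF 0.55 Hz / band stop 0.45 Hz / band stop
60 Hz" are not mutually consistent under the usual hardware conventions; we
read them as intent — remove DC/drift and mains — and a 0.55-Hz high-pass
subsumes any 0.45-Hz stop. Forward-backward filtering is padded by six
high-pass time constants so that edge transients decay inside the padding;
with scipy's default short padding a pure 10-Hz tone acquires ~30% edge
error from the low cutoff.

**Per-epoch FFT.** Rectangular window by default (a Hann option, power
compensated, is available via `fft_window`). One-sided periodogram power is
normalized so the sum over all components equals the epoch's mean square
(Parseval). The 1-Hz bin *f* aggregates components in (*f*−1, *f*] Hz; with
4-s epochs the grid step is 0.25 Hz, so bins 1–56 tile (0, 56] Hz exactly
with four components each. Epoch *i* covers samples
[*i*·fs·epoch_s, (*i*+1)·fs·epoch_s), sample-aligned with the hypnogram.

**Normalization.** Each bin becomes a percentage of the mean total
(1–56 Hz) power over *retained* epochs; all epochs are rescaled, only
retained ones enter the mean. The mean of retained totals is exactly 100
afterwards, normalization is idempotent, and the whole chain is invariant
to rescaling the raw signal (gain calibration cannot change results).

**Artifact rejection.** Per pass: normalize, then drop every retained epoch
with any 1-Hz bin above the threshold (default 300%, 2 passes); after the
final pass the spectra are re-normalized over the survivors so downstream
percent values refer to the analysed epoch set. Both passes read "any
frequency band" as "any 1-Hz bin". Retained sets are nested across passes
and monotone in the threshold. Pooling is per subject across the full
recording, all states together. A threshold of 300% cannot empty the set
when epochs are homogeneous (a bin can exceed 3× the mean total only if
epochs differ), but the degenerate all-removed case raises an error.

## Architecture metrics

Days are split at ZT0 (epochs before the first lights-on are dropped; an
integer day count is required) and every metric is computed per day, then
averaged — so a hypnogram of two identical days reproduces the single-day
values exactly. Phase proportions are fractions of the 12-h half-days;
hourly profiles are 24 × 3 fractions. Episodes are maximal same-state runs;
an episode belongs wholly to the phase of its onset epoch (keeps counts
integral; the common convention in rodent sleep work). No minimum episode
duration and no smoothing of brief arousals by default; `episode_stats`
takes an optional minimum length that excludes shorter bouts from counts
and durations. States absent from a phase are reported with count 0 and
missing (NaN) duration, never zero.

## Band summaries

Default bands: delta 1–4, theta 5–8, alpha 9–12, sigma 13–15, beta
15–30 Hz. The sigma/beta overlap at bin 15 is kept as printed — bands are
descriptive summaries, not a partition; `BANDS_NO_OVERLAP` provides beta
16–30. Band power is the sum of the constituent normalized bins over
retained epochs. State spectral profiles are means over retained epochs of
one state (with the epoch count reported; an absent state yields NaN, not
zero). Band time courses average per (state, band, 3-h ZT bin) per day,
then across days; empty cells are NaN and propagate as missing. The
within-state normalization re-expresses each (subject, state, band) series
as percent of its own 24-h mean (exactly 100 on average); it requires
complete cells and a nonzero mean.

## Statistics

Two-group contrasts use the pooled-variance Student's *t* (two-sided,
df = n₁+n₂−2). "Repeated-measures two-way ANOVA" on (genotype × frequency)
or (genotype × time) is realized as a split-plot design — genotype between
subjects, the repeated factor within, subjects nested in groups — which is
the only standard reading for cohorts of n per genotype measured at every
level. The between effect is tested against subjects-within-groups, the
within and interaction effects against the subject × level residual; no
sphericity correction by default (none is conventional in this literature;
the F statistics match `pingouin.mixed_anova` to 1e-8 in tests). Unequal
group sizes are handled with group-size-weighted marginal means (exact
partition for balanced designs). Post-hoc per-level comparisons are
Bonferroni-corrected with m defaulting to the number of within levels (56
for full spectra) — the most conservative choice. p-values come from the F
and t distributions (scipy's regularized-incomplete-beta implementations).

## Synthetic-data generator

The generator defines the study conditions: 512 Hz sampling, 4-s epochs,
48-h recordings aligned to a 12:12 light-dark cycle, seven subjects per
genotype. What it emulates, and how:

* **Hypnograms** — first-order Markov chains with separate light- and
  dark-phase transition matrices (per 4-s epoch). Defaults give a nocturnal
  pattern (roughly 45/48/8% W/NR/R in the light phase and 72/25/3% in the
  dark in long runs) with wake/NREM bouts of minutes and REM bouts of
  ~40–60 s.
* **EEG** — per state, a sum of band-limited oscillators realized as
  second-order resonators (`iirpeak`) driven by white noise, scaled by the
  filter's impulse-response energy so the output RMS is exact, plus
  broadband noise. Defaults (μV RMS): wake theta 7 Hz/20 + beta 20 Hz/9 +
  noise 14; NREM delta 2 Hz/45 + theta 6 Hz/12 + sigma 12 Hz/10 + noise 12;
  REM theta 7.5 Hz/30 + noise 8 — high-amplitude delta-dominated NREM and
  regular low-amplitude theta REM on the ~100 μV scale of rodent cortical
  electrodes. Published traces fix only these qualitative features, not
  amplitudes; the defaults are plausibility choices. Epochs are generated
  independently and joined with a 0.25-s equal-power crossfade so boundary
  discontinuities do not leak broadband power into low bins. The
  state-dependent signal appears as the difference of the two referential
  channels; a shared common-mode noise term cancels under subtraction.
* **Genotype effects** — multiplicative factors on the amplitude of
  oscillators whose center frequency falls in a chosen (state, band);
  band power scales with the square. Broadband noise is unaffected.
* **Between-animal variability** — each subject jitters every oscillator
  amplitude by an independent log-normal factor (log-sd 0.075, ~15% CV in
  band power). This was set so that a ×0.7 amplitude deficit produces
  between-group F statistics of order 10–30 at n = 7+7, the magnitude such
  studies report; it is the one free realism parameter.
* **Artifacts** — Poisson-placed Hann-windowed slow oscillations (1.5–4 Hz)
  at 30× the epoch RMS, 1 s long, added to both EEG channels with a 10–40 ms
  jittered, halved copy on the parietal channel so bipolar subtraction does
  not cancel them. Broadband bursts would spread over all 56 bins and evade
  a per-bin threshold; real movement artifacts are slow high-amplitude
  deflections, which is what the 300% rule is meant to catch. The default
  rate (19/h) contaminates ~2% of epochs, the rejection fraction typically
  reported for chronic mouse EEG. Transients shorter than an epoch are
  placed wholly within one epoch.
* **EMG** — state-dependent white noise (wake 30, NREM 8, REM 1.5 μV RMS,
  i.e. REM atonia). It is written to the EDFs for completeness but consumed
  by no analysis stage, since scoring is out of scope.

Everything is deterministic given the seed (per-subject seeds are spawned
from the cohort seed), hypnograms bit-for-bit and signals
sample-for-sample.

**Fast spectral path.** For Monte-Carlo studies of the statistics the
generator can skip waveforms: for a Gaussian stationary signal the
one-sided periodogram power of each Fourier component is exponentially
distributed around the model PSD, so a 1-Hz bin (4 components) is drawn as
Gamma(4, mean/4), with the bin means computed from the resonators' squared
frequency responses. This treats the PSD as flat within each bin and
ignores resonator start-up transients and crossfade effects; tests verify
the time-domain path's mean bin powers match the analytic means within
~20% on all bins carrying appreciable power. Cohort-level calibration uses
this path; the full waveform path is exercised end to end (EDF on disk →
statistics) on smaller problems.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: circadian drift beyond the two-phase chain,
state-transition spectral dynamics (e.g. pre-REM theta/delta mixtures),
cross-frequency coupling, 1/f background slopes, electrode impedance drift,
and scorer disagreement. Results on synthetic cohorts validate the
*pipeline's arithmetic and statistical calibration*, not any biological
claim.

## File formats

EDF for signals: reading via MNE; writing via a built-in plain-EDF emitter
(16-bit, 1-s records, per-channel physical range set to the observed
extreme, so quantization error is ≤ range/65534; integer sampling rates and
whole seconds required). Hypnograms are two-column TSV (0-based contiguous
epoch index, label); manifests and run configs are YAML. Config defaults:
bands as above, threshold 300%, 2 passes, 3-h bins, total range 1–56 Hz,
α = 0.05.

## Problem sizes

The test suite and the acceptance script run on scaled-down problems chosen
to preserve the estimands: end-to-end disk cohorts use 2+2 subjects and
24-h recordings at 128 Hz (bins 1–56 Hz stay below the 64-Hz Nyquist; one
full light-dark day exercises the day/ZT logic); type-I calibration uses
1000 cohorts of 4+4 subjects with 6-h recordings on the fast path; effect
recovery uses 20 cohorts of 7+7 subjects with 24-h fast-path recordings,
with the demonstration deficit at amplitude ×0.7 on NREM delta and theta
(≈ 35–45% reduction in normalized power after renormalization — the damping
occurs because delta dominates NREM total power, so suppressing it lowers
the denominator too).

## Known limitations

* The split-plot ANOVA assumes compound symmetry; no Greenhouse–Geisser
  correction is applied by default (matching field practice), though the
  within/interaction tests are anti-conservative under sphericity
  violations.
* Normalized (relative) power couples bands: a true deficit in one band
  raises every other band's share, so single-band interpretations of
  flagged bins need care (see `examples/04`).
* The EDF writer emits plain EDF only (no EDF+ annotations); hypnograms
  travel as sidecar TSVs.
* Rejection pools epochs per subject across the whole recording; per-day
  pooling is not currently configurable.
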