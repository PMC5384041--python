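"""Two-genotype comparison: split-plot ANOVA and Bonferroni post-hoc tests.

Simulates a 7+7 cohort through the generator's fast spectral path (per-epoch
bin powers drawn from the oscillator model's periodogram distribution, no
waveforms) with a NREM delta/theta amplitude deficit (x0.7) in the mutants,
then runs the two headline analyses: per-state 56-bin spectral profiles with a
genotype x frequency split-plot ANOVA and per-bin Bonferroni t-tests, and
3-h band time courses with a genotype x time ANOVA.
"""

import numpy as np

import sleepspectra as ss

res = ss.effect_recovery_sim(n_seeds=1, seed=0, delta_theta_multiplier=0.7,
                             n_per_group=7, duration_h=24.0)
row = res.iloc[0]

print("NREM band time course, genotype effect (split-plot ANOVA, df=(1,12)):")
print(f"  delta: p = {row['nrem_delta_genotype_p']:.2e}")
print(f"  theta: p = {row['nrem_theta_genotype_p']:.2e}")
print(f"NREM profile genotype x frequency interaction: "
      f"p = {row['profile_interaction_p']:.2e}")
print(f"Bonferroni-flagged 1-Hz bins (m = 56): {row['flagged_bins']}")

# With this effect size the genotype term should be strongly significant for
# both bands and the flagged bins should cover the low-frequency (delta/
# theta) range; flags above ~15 Hz can appear too, because normalized power
# is relative — suppressing delta raises every other band's share.

# Under the null the same machinery stays quiet:
null = ss.effect_recovery_sim(n_seeds=1, seed=1, delta_theta_multiplier=1.0,
                              n_per_group=7, duration_h=24.0)
print(f"\nno-effect cohort: NREM delta genotype p = "
      f"{null.iloc[0]['nrem_delta_genotype_p']:.3f}, flagged bins: "
      f"{null.iloc[0]['flagged_bins']}")
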