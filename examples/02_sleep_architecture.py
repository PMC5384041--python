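"""Sleep architecture from a scored hypnogram.

Simulates a 48-h hypnogram (12:12 light-dark) and reports the quantities a
sleep study tabulates: time in each vigilance state per phase, and episode
(bout) counts and mean durations — each computed per 24-h day aligned to
lights-on, then averaged across the two days.
"""

import numpy as np

import sleepspectra as ss

cfg = ss.SimConfig(duration_h=48.0, seed=3)
rng = np.random.default_rng(cfg.seed)
hyp = ss.generate_hypnogram(cfg, ss.default_transitions(), rng)

summary = ss.architecture_summary(hyp, lights_on_offset_h=0.0)

print(f"hypnogram: {hyp.n_epochs} epochs of {hyp.epoch_s:g} s")
print("\ntime in state (fraction of the 12-h phase, 2-day average):")
print(summary["proportions"].round(3))
print("\nepisodes per phase (count and mean bout duration, 2-day average):")
print(summary["episodes"].round(1))

# A nocturnal pattern should appear: more NREM/REM sleep in the light phase,
# more wake in the dark phase; mean NREM bouts of a few minutes.
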