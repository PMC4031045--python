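"""Generate one session of the conditioning task and summarize its structure.

Builds a 60-fractal schedule with truncated-Poisson presentation counts
(mean 4, every fractal shown at least 3 times) and interleaved observation
screens, then prints what a subject would experience.
"""

import numpy as np

from optiprior import TaskConfig, generate_schedule, summarize_decisions

rng = np.random.default_rng(0)
config = TaskConfig()  # 60 fractals, mean 4 presentations, interleaved groups of 5
schedule = generate_schedule(config, rng)
schedule.validate()

summaries = summarize_decisions(schedule)
counts = [s.n_shown for s in summaries]
rates = [s.n_rewards / s.n_shown for s in summaries]

print(f"events in session:        {len(schedule.events)}")
print(f"decision screens:         {len(summaries)}")
print(f"observations per fractal: min {min(counts)}, mean {np.mean(counts):.2f}")
print(f"mean observed reward rate: {np.mean(rates):.3f}")
print(f"example decision: fractal {summaries[0].fractal_id} seen "
      f"{summaries[0].n_shown}x ({summaries[0].n_rewards} rewarded) "
      f"vs square at b={summaries[0].square_prob:.1f}")
# The observed rate hovers near 0.5 because the hidden per-fractal reward
# probabilities are uniform on [0, 1]; each decision pits that sparse
# experience against an explicitly stated square probability.
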