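"""When does it pay a microbe to manipulate its host?

Two strains compete for host-derived resources on the [0,1] behavior
segment: an affecting strain at coordinate 0 (it secretes reward/aversion
feedback proportional to its abundance, and pays a growth cost for it) and
a silent competitor at coordinate 1.  The host performs a Laplace random
walk.  We compare a cost below the maximal resource advantage (0.1) with a
cost above it.
"""

import numpy as np

from gutloop import SimConfig, run_two_strain

N_SEEDS = 30

for cost in (0.05, 0.12):
    cfg = SimConfig(sigma=1e-3, s=0.1, cost=cost, mean_effect=10.0,
                    total_steps_two_strain=100_000)
    finals = [
        run_two_strain(cfg, np.random.default_rng(np.random.SeedSequence([1, k])))[1]
        for k in range(N_SEEDS)
    ]
    mean = np.mean(finals)
    print(f"cost={cost:.2f}: mean final proportion of the affecting strain "
          f"over {N_SEEDS} walks = {mean:.3f}")

print()
print("A mean above 0.5 means manipulation is selectively favored: the")
print("extra resources gained by dragging the host toward the strain's")
print("niche outweigh the production cost.  Above cost 0.1 (the largest")
print("possible growth advantage) the affecting strain always loses.")
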