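"""Community cohesion and the negative:positive stability ratio.

Cohesion weighs each taxon's null-corrected average correlation with the
rest of the community (its connectedness) by its abundance.  The absolute
ratio of negative to positive cohesion indexes stability: values below 1
mean facilitation/synchrony dominates (positive feedback, less stable),
values above 1 mean competition dominates.
"""

import numpy as np

from coalmix import cohesion_pipeline
from coalmix.simulate import simulate_correlated_community

# identical base communities; the competitive variant additionally couples
# its ten most abundant taxa into anti-phase pairs (shared-resource see-saw).
# pooling several seeds smooths the single-community noise of the metric.
for name, n_pairs in (("no planted coupling", 0), ("with competition", 5)):
    stabilities = []
    for seed in range(8):
        cm = simulate_correlated_community(
            250, 40, seed=seed,
            negative_pairs=[(2 * i, 2 * i + 1) for i in range(n_pairs)],
            negative_loading=3.0,
        )
        res = cohesion_pipeline(cm, n_iter=100, seed=seed)
        stabilities += res.stability.dropna().tolist()
    med = float(np.median(stabilities))
    print(f"{name:>20}: median stability ratio |neg:pos| = {med:.3f}")

print("\nPlanting competitive (anti-phase) pairs raises negative cohesion and")
print("pushes the stability ratio above the uncoupled community's —")
print("competition-dominated communities score as more stable.")
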