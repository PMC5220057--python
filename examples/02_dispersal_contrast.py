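"""Chemotaxis vs passive dispersal in a structured environment.

In spatially structured habitats, cells that sense and swim toward
resource particles encounter them orders of magnitude more often than
passive drifters, at twice the energetic cost of undirected swimming.
Three paired runs (identical configurations except the dispersal mode)
make the contrast visible.
"""

import numpy as np

from seedbanksim import build_model, run_model

totals = {"chemotaxis": [], "passive": []}
for seed in (1, 2, 3):
    for mode in totals:
        params, traits, regime, rng = build_model(
            seed, regime=f"consumer_resource,monoculture_labile,{mode},structured")
        res = run_model(params, traits, regime, rng, burnin_cap=600,
                        production_steps=800, cadence=10)
        total = sum(r.encounters_per_step * 10 for r in res.records)
        totals[mode].append(total)
        print(f"seed {seed} {mode:10s}: {total:8.0f} encounters over the recorded window")

ratio = np.mean(totals["chemotaxis"]) / max(np.mean(totals["passive"]), 1.0)
print(f"\nchemotaxis / passive encounter ratio: {ratio:.0f}x")
# A ratio far above 1 reproduces the qualitative benefit of chemotaxis
# where resources are aggregated rather than well mixed.
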