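"""Monolayer drug response at a reduced scale.

Grows a plated population from a single cell to 300 cells, then applies
the ATR inhibitor at three concentrations (10 replicates each) and follows
the culture for 48 h.  Prints the late-time γH2AX-positive fraction (cells
sitting in the damaged-S pool) and the final cell count: damage rises and
growth stalls as the dose increases.
"""

import numpy as np

from atrabm import (DoseDescriptor, ModelParams, SimulationConfig,
                    run_experiment)

params = ModelParams()
print(f"{'dose':>8} {'gammaH2AX % (last 12 h)':>24} {'final cells':>12}")
for c_uM in (0.0, 1.0, 10.0):
    config = SimulationConfig.monolayer(
        lattice_size=50, treatment_trigger_count=300, follow_up_time=48.0,
        dose=DoseDescriptor(mode="monolayer_step", concentration=c_uM),
        n_replicates=10, seed=1)
    result = run_experiment(config, params)
    gamma = result.mean["gammaH2AX_pct"].to_numpy()[-12:].mean()
    cells = result.mean["count_total"].to_numpy()[-1]
    print(f"{config.dose.label:>8} {gamma:24.1f} {cells:12.0f}")
print("\nDamage saturates near the fraction of cells routed through the\n"
      "damaged-S branch; counts include persistent dead cells, so the\n"
      "curve flattens rather than declines.")
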