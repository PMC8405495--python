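"""Root-mean-square comparison of a simulation against a reference table.

Runs a quick monolayer experiment and scores its mean damage curve against
the packaged SYNTHETIC stand-in fixture (see src/atrabm/data/README.md —
those numbers are not measurements, so the RMSE here only demonstrates the
machinery).  Swap in your own CSV with measured means to score real data.
"""

import os

import atrabm
from atrabm import (DoseDescriptor, ModelParams, SimulationConfig,
                    load_fixture, rmse_against_fixture, run_experiment)

fixture_path = os.path.join(os.path.dirname(atrabm.__file__), "data",
                            "synthetic_invitro_monolayer.csv")
fixture = load_fixture(fixture_path)
print(f"reference: {fixture_path}")
print(f"doses in table: {fixture.doses}")

params = ModelParams()
dose_label = "1 uM"
config = SimulationConfig.monolayer(
    lattice_size=60, treatment_trigger_count=500, follow_up_time=72.0,
    dose=DoseDescriptor(mode="monolayer_step", concentration=1.0),
    n_replicates=10, seed=2)
result = run_experiment(config, params)

err = rmse_against_fixture(result, fixture, dose_label, "gammaH2AX_pct")
print(f"\ndamage RMSE vs synthetic reference at {dose_label}: "
      f"{err:.2f} percent units")
print("(computed over the reference time points, simulation means "
      "interpolated)")
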