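"""Dose–effect of ATR inhibition on DNA-damage repair.

Evaluates the sigmoid Emax model (EC50 = 1 µM, Hill exponent 2) across
concentrations and prints the drug effect E(C) and the resulting
probability that a replication-stress-damaged cell repairs instead of
being sentenced to die.  E rises from 0 to Emax; the repair probability
falls from 1 (certain repair without drug) to 1 - Emax.
"""

from atrabm import ModelParams, emax_effect, repair_probability

params = ModelParams()
print(f"EC50 = {params.ec50} uM, gamma = {params.gamma}, Emax = {params.emax}")
print(f"{'C [uM]':>8} {'effect E':>10} {'P(repair)':>10}")
for c in (0.0, 0.1, 0.3, 1.0, 3.0, 10.0, 100.0):
    e = emax_effect(c, params.ec50, params.gamma, params.emax)
    print(f"{c:8.1f} {e:10.4f} {repair_probability(c, params):10.4f}")
print("\nAt C = EC50 the effect is half-maximal, so half of all damaged\n"
      "cells fail repair; far above EC50 repair is fully inhibited.")
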