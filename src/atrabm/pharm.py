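"""Pharmacodynamics: dose fields and the sigmoid Emax repair-inhibition model.

The ATR inhibitor blocks the repair transition out of the damaged-S state.
The drug effect at concentration C is the Hill/Emax form

    E(C) = Emax * C**gamma / (EC50**gamma + C**gamma)

and the probability that a damaged cell repairs (instead of being sentenced
to die) is ``1 - E(C)``.  With Emax = 1, C = 0 always repairs and C -> inf
never does.
"""

from __future__ import annotations

import numpy as np

from .params import DoseDescriptor, ModelParams


def monolayer_concentration(dose: DoseDescriptor, t: float, t0: float) -> float:
    """Homogeneous well-plate concentration [µM]: 0 before treatment time
    ``t0``, the applied concentration at and after it, with no decay."""
    if dose.mode != "monolayer_step":
        raise ValueError("monolayer_concentration needs a monolayer_step dose")
    return dose.concentration if t >= t0 else 0.0


def emax_effect(c, ec50: float, gamma: float, emax: float):
    """Sigmoid Emax drug effect in [0, emax]; accepts scalars or arrays."""
    if ec50 <= 0 or gamma <= 0:
        raise ValueError("ec50 and gamma must be positive")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("drug concentration must be non-negative")
    cg = np.power(c, gamma)
    out = emax * cg / (ec50 ** gamma + cg)
    return float(out) if out.ndim == 0 else out


def repair_probability(c, params: ModelParams):
    """Probability that a damaged-S cell repairs at local concentration ``c``."""
    return 1.0 - emax_effect(c, params.ec50, params.gamma, params.emax)
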