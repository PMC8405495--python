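"""Per-agent cell-cycle state machine with a DNA-damage branch.

Every agent carries an individual doubling time tau_i ~ Normal(mu, sigma)
(redrawn if non-positive) and a phase clock.  A phase completes once the
clock has accumulated the phase's share of tau_i:

    G1:   G1DF * theta_g1 * tau   (G1DF >= 1 elongates G1 under hypoxia;
                                   implemented by accumulating dt / G1DF)
    D-S:  theta_ds * tau          (replication-stress damaged S entry)
    S:    theta_s * tau
    G2/M: theta_g2m * tau         (ends in mitosis: a daughter is produced)

At G1 exit a uniform draw routes the agent into the damaged-S state with
probability pi_ds, else into S.  Leaving D-S, the agent repairs into S with
probability 1 - E(C) (Emax model, local drug concentration C); on failure it
is sentenced to die: it stays on the lattice, gamma-H2AX positive, until the
lethal delay T_{L->D} = tau_i has elapsed.  An agent in G1 with no free
space within its placement neighbourhood exits to quiescence (G0) and
resumes G1 — clock preserved — when space reappears.
"""

from __future__ import annotations

import enum
from typing import Optional

import numpy as np

from .params import ModelParams
from .pharm import repair_probability


class State(enum.IntEnum):
    G1 = 0
    S = 1
    DS = 2        # replication-stress damaged S; gamma-H2AX positive
    G2M = 3
    G0 = 4        # quiescent (no space); re-enters G1 without clock reset
    LETHAL = 5    # failed repair, awaiting death; still gamma-H2AX positive
    DEAD = 6


#: states that accumulate cycle-clock time
CYCLING_STATES = (State.G1, State.S, State.DS, State.G2M)
#: states whose occupants count as DNA-damaged (gamma-H2AX positive)
DAMAGED_STATES = (State.DS, State.LETHAL)
#: states that consume oxygen / block space as living matter
VIABLE_STATES = (State.G1, State.S, State.DS, State.G2M, State.G0, State.LETHAL)


def sample_doubling_time(mu: float, sigma: float, rng: np.random.Generator,
                         size: Optional[int] = None):
    """Draw individual doubling times from Normal(mu, sigma), redrawing any
    non-positive values (with mu=24 h, sigma=0.5 h rejection is ~0)."""
    if mu <= 0 or sigma < 0:
        raise ValueError("mu must be positive and sigma non-negative")
    if sigma == 0:
        return mu if size is None else np.full(size, mu)
    n = 1 if size is None else size
    draws = rng.normal(mu, sigma, n)
    bad = draws <= 0
    while np.any(bad):
        draws[bad] = rng.normal(mu, sigma, int(bad.sum()))
        bad = draws <= 0
    return float(draws[0]) if size is None else draws


def g1_delay_factor(oxygen_pct, a1: float = 0.9209, a2: float = 0.8200,
                    a3: float = -0.2389):
    """Hypoxic G1 elongation factor as a function of scaled oxygen [%].

    Piecewise: 2 below 1% oxygen, a1 + a2/(a3 + K) on [1%, 10.5%], and 1 in
    normoxia.  The fitted coefficients make the pieces meet to within 2e-3.
    """
    k = np.asarray(oxygen_pct, dtype=float)
    mid = a1 + a2 / (a3 + np.where((k >= 1.0) & (k <= 10.5), k, 1.0))
    out = np.where(k < 1.0, 2.0, np.where(k <= 10.5, mid, 1.0))
    return float(out) if out.ndim == 0 else out


def phase_duration(state: State, tau: float, oxygen_pct: float,
                   params: ModelParams, mode: str = "monolayer",
                   via_ds: bool = False) -> float:
    """Nominal residence time of ``state`` for an agent with doubling time
    ``tau`` at the given local oxygen (monolayer mode is always normoxic).

    The damaged-S detour is part of the S share of the cycle: a cell that
    repaired out of D-S spends the remaining (theta_s - theta_ds) * tau in
    S, so every surviving cycle lasts tau in total.
    """
    if state == State.G1:
        g1df = 1.0 if mode == "monolayer" else g1_delay_factor(
            oxygen_pct, params.g1df_a1, params.g1df_a2, params.g1df_a3)
        return g1df * params.theta_g1 * tau
    if state == State.S:
        frac = params.theta_s - (params.theta_ds if via_ds else 0.0)
        return frac * tau
    if state == State.DS:
        return params.theta_ds * tau
    if state == State.G2M:
        return params.theta_g2m * tau
    raise ValueError(f"state {state!r} has no phase duration")


class Population:
    """Struct-of-arrays agent registry (grow-only storage; dead spheroid
    agents stay in the registry with ``on_lattice`` False)."""

    def __init__(self, capacity: int = 256):
        self._n = 0
        self.row = np.zeros(capacity, dtype=np.int32)
        self.col = np.zeros(capacity, dtype=np.int32)
        self.state = np.zeros(capacity, dtype=np.int8)
        self.tau = np.zeros(capacity, dtype=np.float64)
        self.clock = np.zeros(capacity, dtype=np.float64)
        self.death_clock = np.zeros(capacity, dtype=np.float64)
        self.on_lattice = np.zeros(capacity, dtype=bool)
        self.via_ds = np.zeros(capacity, dtype=bool)   # routed through D-S this cycle

    def __len__(self) -> int:
        return self._n

    def _grow(self) -> None:
        cap = self.row.size * 2
        for name in ("row", "col", "state", "tau", "clock", "death_clock",
                     "on_lattice", "via_ds"):
            arr = getattr(self, name)
            new = np.zeros(cap, dtype=arr.dtype)
            new[: self._n] = arr[: self._n]
            setattr(self, name, new)

    def add(self, r: int, c: int, tau: float, state: State = State.G1,
            clock: float = 0.0) -> int:
        if self._n == self.row.size:
            self._grow()
        i = self._n
        self.row[i], self.col[i] = r, c
        self.state[i] = state
        self.tau[i] = tau
        self.clock[i] = clock
        self.death_clock[i] = 0.0
        self.on_lattice[i] = True
        self.via_ds[i] = False
        self._n += 1
        return i

    # views over the live prefix -------------------------------------------
    def view(self, name: str) -> np.ndarray:
        return getattr(self, name)[: self._n]

    def counts_by_state(self) -> dict[str, int]:
        s = self.state[: self._n]
        n = {st.name: int(np.sum(s == st)) for st in State}
        return n

    def phase_thresholds(self, params: ModelParams) -> np.ndarray:
        """Per-agent completion threshold of the current phase (G1 uses the
        unscaled theta_g1 * tau; hypoxia slows the clock, not the bar)."""
        theta = np.array([params.theta_g1, params.theta_s, params.theta_ds,
                          params.theta_g2m, np.inf, np.inf, np.inf])
        s = self.state[: self._n]
        thr = self.tau[: self._n] * theta[s]
        # D-S time counts within the S share: a repaired cell spends the
        # remaining (theta_s - theta_ds) * tau in S, keeping the cycle at tau
        after_ds = (s == State.S) & self.via_ds[: self._n]
        if after_ds.any():
            thr[after_ds] -= params.theta_ds * self.tau[: self._n][after_ds]
        return thr


def handle_completion(pop: Population, i: int, params: ModelParams,
                      local_drug: float, rng: np.random.Generator) -> str:
    """Resolve the transition of agent ``i`` whose current phase has just
    completed.  Returns the event name; ``"divide"`` is signalled for the
    engine to attempt daughter placement (G2/M completion).

    The clock overshoot beyond the phase threshold is carried into the next
    phase so that long-run phase bookkeeping stays exact to within one dt.
    """
    s = State(pop.state[i])
    thr = phase_duration(s, pop.tau[i], 100.0, params,
                         via_ds=bool(pop.via_ds[i])) if s != State.G1 \
        else params.theta_g1 * pop.tau[i]
    over = max(pop.clock[i] - thr, 0.0)
    if s == State.G1:
        if rng.random() < params.pi_ds:
            pop.state[i] = State.DS
            pop.via_ds[i] = True
            pop.clock[i] = over
            return "entered_ds"
        pop.state[i] = State.S
        pop.via_ds[i] = False
        pop.clock[i] = over
        return "entered_s"
    if s == State.DS:
        if attempt_repair(local_drug, params, rng):
            pop.state[i] = State.S
            pop.clock[i] = over
            return "repaired"
        pop.state[i] = State.LETHAL
        pop.clock[i] = 0.0
        pop.death_clock[i] = over
        return "lethal"
    if s == State.S:
        pop.state[i] = State.G2M
        pop.clock[i] = over
        return "entered_g2m"
    if s == State.G2M:
        return "divide"    # engine places the daughter and resets the parent
    raise ValueError(f"agent {i} in state {s!r} cannot complete a phase")


def attempt_repair(local_drug: float, params: ModelParams,
                   rng: np.random.Generator) -> bool:
    """Bernoulli repair decision at damaged-S exit, probability 1 - E(C)."""
    return rng.random() < repair_probability(local_drug, params)
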