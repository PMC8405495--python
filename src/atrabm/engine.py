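"""Simulation orchestration: the coupled agent/field time loop.

A replicate starts from one agent in the centre of the lattice (or, for
scaled studies, a pre-grown disc), grows the population, and starts
treatment when the trigger fires — a population count in monolayer mode, an
extrapolated spheroid volume in spheroid mode.  Treatment time T0 anchors
the readout grid: observables are recorded every ``output_interval`` hours
of post-treatment time.

Monolayer mode has no field dynamics: oxygen is plentiful and the applied
drug concentration appears everywhere at T0 and never decays.  Spheroid
mode couples the agents to a quasi-steady oxygen field (re-solved on the
current colony geometry every ``field_update_interval``) and to a transient
drug field integrated explicitly through every agent step, fed daily at
boundary sites and eliminated with a 6 h half-life.

Agents update on a fixed step dt (default 0.1 h, resolving the shortest
phase, theta_ds * tau ≈ 0.72 h); phase completions are processed in a
random order each step to avoid lattice-scan anisotropy.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np

from . import fields as flds
from .cellcycle import (Population, State, VIABLE_STATES, handle_completion,
                        sample_doubling_time, g1_delay_factor)
from .lattice import (EMPTY, Lattice, boundary_mask, place_daughter,
                      remove_dead, space_map)
from .params import ModelParams, SimulationConfig
from .pharm import monolayer_concentration
from .readouts import (ExperimentResult, ReadoutSeries, gammaH2AX_fraction,
                       spheroid_volume, state_counts)

logger = logging.getLogger(__name__)

_SECONDS_PER_HOUR = 3600.0


class LatticeOverflowError(RuntimeError):
    """No free site anywhere for a mandatory monolayer placement."""


class _FieldState:
    """Spheroid-only transport state, cached against lattice occupancy."""

    def __init__(self, config: SimulationConfig, params: ModelParams):
        size = config.lattice_size
        self.dx = config.lattice_spacing_cm
        self.d_o2 = params.d_oxygen * _SECONDS_PER_HOUR          # cm²/h
        self.d_drug = flds.drug_diffusivity(self.d_o2)
        self.r_k = params.r_k * _SECONDS_PER_HOUR                # a.u./h
        self.phi_k = params.phi_k * _SECONDS_PER_HOUR            # 1/h
        self.eta = params.eta_drug                               # 1/h
        self.slow = params.intracellular_slowdown
        self.drug_slow = params.slowdown_applies_to_drug
        self.oxygen = np.ones((size, size))
        self.oxygen_pct = np.full((size, size), params.h)
        self.drug = np.zeros((size, size))
        self._geom_version = -1
        self.supply_mask = np.ones((size, size), np.uint8)
        self.cell_mask = np.zeros((size, size), bool)
        self.occ_mask = np.zeros((size, size), bool)

    def refresh_geometry(self, lat: Lattice, pop: Population) -> None:
        if self._geom_version == lat.version:
            return
        ids = lat.occupancy
        occ = ids != EMPTY
        viable = np.zeros_like(occ)
        if occ.any():
            viable[occ] = np.isin(pop.state[ids[occ]], VIABLE_STATES)
        self.occ_mask = occ
        self.cell_mask = viable
        self.supply_mask = boundary_mask(lat)
        self._geom_version = lat.version

    def update_oxygen(self, params: ModelParams) -> None:
        d = flds.cell_diffusivity(self.d_o2, self.occ_mask, self.slow)
        # between updates the colony changes by a handful of sites, so a
        # warm-started solve at modest tolerance tracks the scaled field
        # to well below the 10% hypoxia classification margin
        self.oxygen = flds.steady_state_oxygen(
            d, self.supply_mask, self.cell_mask, self.dx,
            self.r_k, self.phi_k, x0=self.oxygen, rtol=1e-5)
        self.oxygen_pct = flds.scale_oxygen(self.oxygen, params.h)

    def integrate_drug(self, lat: Lattice, amplitude: float, dt: float) -> None:
        slow = self.slow if self.drug_slow else 1.0
        d = flds.cell_diffusivity(self.d_drug, self.occ_mask, slow)
        f = flds.ScalarField(self.drug, d, self.dx, species="drug")
        flds.drug_step(f, lat, amplitude, self.eta, dt,
                       supply_mask=self.supply_mask)
        self.drug = f.values


def _seed_population(config: SimulationConfig, params: ModelParams,
                     lat: Lattice, pop: Population,
                     rng: np.random.Generator) -> None:
    r0, c0 = lat.centre
    radius = config.initial_colony_radius
    if radius <= 0:
        i = pop.add(r0, c0, sample_doubling_time(params.mu, params.sigma, rng))
        lat.place(i, r0, c0)
        return
    # pre-grown disc for scaled studies, seeded in the colony's own
    # attractor state: enclosed agents quiescent (G0, holding a G1 clock),
    # agents with reachable free space at random cycle positions
    rr, cc = np.ogrid[:lat.size, :lat.size]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
    for r, c in zip(*np.nonzero(inside)):
        tau = sample_doubling_time(params.mu, params.sigma, rng)
        i = pop.add(int(r), int(c), tau, State.G0, 0.0)
        lat.place(i, int(r), int(c))
    smap = space_map(lat, config.nu or 3)
    for i in range(len(pop)):
        tau = pop.tau[i]
        if smap[pop.row[i], pop.col[i]]:
            u = rng.random() * tau
            if u < params.theta_g1 * tau:
                st, clk = State.G1, u
            elif u < (params.theta_g1 + params.theta_s) * tau:
                st, clk = State.S, u - params.theta_g1 * tau
            else:
                st, clk = State.G2M, u - (params.theta_g1 + params.theta_s) * tau
        else:
            st, clk = State.G0, rng.random() * params.theta_g1 * tau
        pop.state[i] = st
        pop.clock[i] = clk


def run_replicate(config: SimulationConfig, params: ModelParams,
                  seed: Optional[int] = None,
                  observer=None) -> ReadoutSeries:
    """Run one stochastic replicate; deterministic given (config, params,
    seed).  Returns readouts on the post-treatment time grid.

    ``observer(rel_time, lattice, pop, field_state)``, when given, is called
    at every readout time — for spatial diagnostics or VTK snapshots.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mode = config.mode
    lat = Lattice(config.lattice_size, config.lattice_spacing_cm, mode)
    pop = Population()
    _seed_population(config, params, lat, pop, rng)

    fs = _FieldState(config, params) if mode == "spheroid" else None
    dose = config.dose
    dt = config.dt
    t = 0.0
    t0: Optional[float] = None
    next_output = 0.0
    next_field = 0.0
    include_dead = config.count_dead_in_readouts

    rec_t: list[float] = []
    rec_gamma: list[float] = []
    rec_counts: dict[str, list[int]] = {k: [] for k in
                                        ("G1", "S", "D-S", "G2M", "G0",
                                         "dead", "total")}
    rec_vol: list[float] = []

    def record(rel_time: float) -> None:
        rec_t.append(rel_time)
        rec_gamma.append(gammaH2AX_fraction(
            pop, include_dead=config.gammaH2AX_include_dead))
        for k, v in state_counts(pop, include_dead=include_dead).items():
            rec_counts[k].append(v)
        if mode == "spheroid":
            rec_vol.append(spheroid_volume(lat))
        if observer is not None:
            observer(rel_time, lat, pop, fs)

    while True:
        # treatment trigger
        if t0 is None:
            if mode == "monolayer":
                # nothing is ever removed from a monolayer lattice
                triggered = len(pop) >= config.treatment_trigger_count
            else:
                triggered = spheroid_volume(lat) >= \
                    config.treatment_trigger_volume_cm3
            if triggered:
                t0 = t
                logger.debug("treatment trigger at t=%.1f h (pop=%d)",
                             t, len(pop))
            elif t >= config.max_pre_treatment_time:
                raise RuntimeError(
                    f"treatment trigger not reached within "
                    f"{config.max_pre_treatment_time} h")
        # readouts + termination on the post-treatment grid
        if t0 is not None:
            rel = t - t0
            while next_output <= rel + 1e-9:
                record(next_output)
                next_output += config.output_interval
            if rel >= config.follow_up_time - 1e-9:
                break

        # fields (spheroid only)
        drug_now: float | np.ndarray = 0.0
        if fs is not None:
            fs.refresh_geometry(lat, pop)
            if t + 1e-9 >= next_field:
                fs.update_oxygen(params)
                next_field = t + config.field_update_interval
            if t0 is not None and dose.mode == "spheroid_daily":
                amp = dose.amplitude if dose.supply_active(t - t0) else 0.0
                if amp > 0.0 or fs.drug.max() > 0.0:
                    fs.integrate_drug(lat, amp, dt)
            drug_now = fs.drug
        elif t0 is not None:
            drug_now = monolayer_concentration(dose, t, t0)

        _advance_agents(config, params, lat, pop, fs, drug_now, dt, rng)
        remove_dead(lat, pop, t)
        t += dt

    counts = {k: np.asarray(v, dtype=np.int64) for k, v in rec_counts.items()}
    return ReadoutSeries(
        times=np.asarray(rec_t), gammaH2AX_pct=np.asarray(rec_gamma),
        counts_by_state=counts,
        volume_cm3=np.asarray(rec_vol) if mode == "spheroid" else None,
        t0=t0, dose_label=dose.label, seed=seed)


def _advance_agents(config: SimulationConfig, params: ModelParams,
                    lat: Lattice, pop: Population, fs: Optional[_FieldState],
                    drug_now, dt: float, rng: np.random.Generator) -> None:
    """One vectorised agent step plus sequential transition handling."""
    n = len(pop)
    s = pop.state[:n]
    row = pop.row[:n]
    col = pop.col[:n]
    G1, G0 = int(State.G1), int(State.G0)

    # quiescence bookkeeping: G1 agents need free space within the placement
    # neighbourhood to keep cycling; G0 agents resume when space reappears
    smap = None
    if config.nu is not None:
        smap = space_map(lat, config.nu)
        has_space = smap[row, col]
        s[(s == G1) & ~has_space] = G0
        s[(s == G0) & has_space] = G1
    elif lat.n_occupied >= lat.size * lat.size:
        s[s == G1] = G0          # unbounded order, lattice saturated
    else:
        s[s == G0] = G1

    # clock accumulation (G1 slowed by the hypoxic delay factor)
    g1 = np.flatnonzero(s == G1)
    if fs is not None and g1.size:
        k_here = fs.oxygen_pct[row[g1], col[g1]]
        g1df = g1_delay_factor(k_here, params.g1df_a1, params.g1df_a2,
                               params.g1df_a3)
        pop.clock[g1] += dt / g1df
    else:
        pop.clock[g1] += dt
    other = (s == int(State.S)) | (s == int(State.DS)) | (s == int(State.G2M))
    pop.clock[:n][other] += dt
    lethal = s == int(State.LETHAL)
    if lethal.any():
        pop.death_clock[:n][lethal] += dt

    # phase completions, in random order (lattice contention fairness);
    # non-cycling states carry an infinite threshold
    thr = pop.phase_thresholds(params)
    done = np.flatnonzero(pop.clock[:n] >= thr)
    if done.size == 0:
        return
    scalar_drug = np.isscalar(drug_now) or np.ndim(drug_now) == 0
    G2M = int(State.G2M)
    for i in rng.permutation(done):
        if pop.state[i] == G2M:
            # space map is a superset of every placement ring: a False
            # entry means the scan cannot succeed, so defer cheaply
            if smap is not None and not smap[pop.row[i], pop.col[i]]:
                continue
            site = place_daughter((int(pop.row[i]), int(pop.col[i])), lat,
                                  config.nu, rng)
            if site is None:
                if config.nu is None:
                    # unbounded order: failure means the whole lattice is
                    # full and a mandatory monolayer placement is impossible
                    raise LatticeOverflowError(
                        "no free lattice site for a mandatory daughter "
                        "placement")
                continue   # defer division; re-attempt next step
            over = max(pop.clock[i] - thr[i], 0.0)
            pop.state[i] = State.G1
            pop.clock[i] = over
            pop.via_ds[i] = False
            tau_d = sample_doubling_time(params.mu, params.sigma, rng)
            j = pop.add(site[0], site[1], tau_d)
            lat.place(j, *site)
        else:
            c_loc = float(drug_now) if scalar_drug else \
                float(drug_now[pop.row[i], pop.col[i]])
            handle_completion(pop, i, params, c_loc, rng)


def run_experiment(config: SimulationConfig, params: ModelParams,
                   progress: bool = False) -> ExperimentResult:
    """Run ``config.n_replicates`` replicates (seeds ``seed + i``) and
    aggregate per-time-point means and standard deviations."""
    runs = []
    for i in range(config.n_replicates):
        rep_seed = config.seed + i
        runs.append(run_replicate(config, params, seed=rep_seed))
        if progress:
            logger.info("replicate %d/%d done (seed %d)", i + 1,
                        config.n_replicates, rep_seed)
    return ExperimentResult.from_replicates(runs)
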