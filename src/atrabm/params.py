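"""Calibrated model constants and per-run simulation configuration.

All durations are in hours, lengths in cm, concentrations in µM and
diffusivities in cm² s⁻¹ unless a field name says otherwise.  The defaults
are the in vitro-calibrated values for LoVo (human colon carcinoma) cells
treated with the ATR inhibitor AZD6738: mean doubling time 24 h (s.d. 0.5 h),
replication-stress entry probability 0.75, damaged-S residence fraction 0.03,
Emax dose response with EC50 = 1 µM and Hill exponent 2, and a lethal delay
equal to the agent's own doubling time.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import yaml

#: molecular weights (g/mol) used to relate drug and oxygen diffusivity
MW_O2 = 31.998
MW_AZD = 412.512

#: oxygen percentage at or below which a cell counts as hypoxic
HYPOXIA_THRESHOLD_PCT = 10.0


@dataclass
class ModelParams:
    """All calibrated constants of the cell-cycle / transport / drug model."""

    # cell cycle
    mu: float = 24.0              #: mean individual doubling time [h]
    sigma: float = 0.5            #: s.d. of the doubling time [h]
    pi_ds: float = 0.75           #: probability of entering the damaged-S state at G1 exit
    theta_g1: float = 11.0 / 24.0  #: fraction of tau spent in G1
    theta_s: float = 8.0 / 24.0    #: fraction of tau spent in S
    theta_g2m: float = 5.0 / 24.0  #: fraction of tau spent in G2/M
    theta_ds: float = 0.03         #: fraction of tau spent in damaged S (additional to S)

    # drug response (sigmoid Emax)
    ec50: float = 1.0             #: half-maximal concentration [µM]
    gamma: float = 2.0            #: Hill exponent
    emax: float = 1.0             #: maximal effect; 1 = complete repair inhibition

    # oxygen transport
    d_oxygen: float = 2.5e-5      #: oxygen diffusivity [cm²/s]
    intracellular_slowdown: float = 1.5   #: divide D by this where a cell sits
    r_k: float = 1.0e-2           #: oxygen supply coefficient [a.u./s] on boundary sites
    phi_k: float = 3.0e-3         #: oxygen consumption rate by viable cells [1/s]
    h: float = 100.0              #: oxygen rescaling factor (max site maps to h %)
    hypoxia_threshold: float = HYPOXIA_THRESHOLD_PCT

    # G1 delay factor coefficients (hypoxic G1 elongation)
    g1df_a1: float = 0.9209
    g1df_a2: float = 0.8200
    g1df_a3: float = -0.2389

    # drug transport
    drug_half_life: float = 6.0   #: in vivo elimination half-life [h]
    slowdown_applies_to_drug: bool = True  #: apply the 1.5 intracellular factor to drug too

    def __post_init__(self) -> None:
        if not math.isclose(self.theta_g1 + self.theta_s + self.theta_g2m, 1.0,
                            rel_tol=0, abs_tol=1e-9):
            raise ValueError("theta_g1 + theta_s + theta_g2m must equal 1 "
                             "(damaged-S time is additional)")
        if not 0.0 <= self.pi_ds <= 1.0:
            raise ValueError("pi_ds must lie in [0, 1]")
        if self.ec50 <= 0 or self.gamma <= 0:
            raise ValueError("ec50 and gamma must be positive")
        if not 0.0 < self.emax <= 1.0:
            raise ValueError("emax must lie in (0, 1]")
        if self.mu <= 0 or self.sigma < 0:
            raise ValueError("mu must be positive and sigma non-negative")
        for name in ("d_oxygen", "r_k", "phi_k", "h", "drug_half_life",
                     "intracellular_slowdown"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def d_drug(self) -> float:
        """Drug diffusivity [cm²/s], scaled from oxygen by molecular weight."""
        return self.d_oxygen * math.sqrt(MW_O2 / MW_AZD)

    @property
    def eta_drug(self) -> float:
        """First-order drug elimination rate [1/h]."""
        return math.log(2.0) / self.drug_half_life

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class DoseDescriptor:
    """How the drug reaches the system.

    ``monolayer_step``: the applied concentration ``concentration`` (µM)
    appears everywhere, instantaneously, at treatment time T0 and never
    decays (well-plate solvent exposure).

    ``spheroid_daily``: a supply term feeds lattice sites outside the tumour
    for ``window_h`` hours once per ``interval_h``, ``n_doses`` times,
    starting at T0; the amplitude (µM/h) is ``dose_mg_per_kg *
    supply_coeff``, the single linear bioavailability knob mapping an oral
    mg/kg dose label onto the lattice.
    """

    mode: str = "monolayer_step"            # monolayer_step | spheroid_daily
    concentration: float = 0.0              #: applied concentration C [µM] (monolayer)
    dose_mg_per_kg: float = 0.0             #: dose label, e.g. 25 or 50 (spheroid)
    supply_coeff: float = 0.4               #: µM/h of supply per mg/kg during the window
    window_h: float = 1.0                   #: daily administration window [h]
    n_doses: int = 14                       #: number of daily doses
    interval_h: float = 24.0                #: dosing interval [h]

    def __post_init__(self) -> None:
        if self.mode not in ("monolayer_step", "spheroid_daily"):
            raise ValueError(f"unknown dose mode {self.mode!r}")
        if self.concentration < 0 or self.dose_mg_per_kg < 0:
            raise ValueError("dose must be non-negative")
        if self.n_doses < 0:
            raise ValueError("n_doses must be >= 0")

    @property
    def amplitude(self) -> float:
        """Supply amplitude [µM/h] during an administration window."""
        return self.dose_mg_per_kg * self.supply_coeff

    @property
    def label(self) -> str:
        if self.mode == "monolayer_step":
            return f"{self.concentration:g} uM"
        return f"{self.dose_mg_per_kg:g} mg/kg"

    def supply_active(self, t_since_t0: float) -> bool:
        """True while a dose window is open at time ``t_since_t0`` [h] >= 0."""
        if self.mode != "spheroid_daily" or self.amplitude == 0 or t_since_t0 < 0:
            return False
        k = int(t_since_t0 // self.interval_h)
        return k < self.n_doses and (t_since_t0 - k * self.interval_h) < self.window_h


@dataclass
class SimulationConfig:
    """Geometry, discretisation, trigger and replication settings for a run."""

    mode: str = "monolayer"                 # monolayer | spheroid
    lattice_size: int = 100                 #: L (square lattice, L x L sites)
    lattice_spacing_cm: Optional[float] = None  #: dx [cm]; spheroid default 40 µm
    dt: float = 0.1                         #: agent time step [h]
    follow_up_time: float = 72.0            #: simulated time after treatment starts [h]
    treatment_trigger_count: int = 1000     #: monolayer: treat at this population
    treatment_trigger_volume_cm3: float = 0.25  #: spheroid: treat at this volume
    max_pre_treatment_time: float = 2400.0  #: abort guard for the growth phase [h]
    dose: DoseDescriptor = field(default_factory=DoseDescriptor)
    n_replicates: int = 100
    seed: int = 0
    output_interval: float = 1.0            #: readout cadence [h]
    nu: Optional[int] = None                #: max daughter-placement order; None = unbounded
    field_update_interval: float = 0.1      #: oxygen re-solve cadence [h] (spheroid)
    initial_colony_radius: int = 0          #: >0: start from a pre-grown disc (scaled studies)
    count_dead_in_readouts: bool = True     #: monolayer: dead cells in cell counts
    gammaH2AX_include_dead: bool = False    #: dead corpses in the γH2AX denominator
    quiescence_union_shapes: bool = True    #: G0 space scan over Moore∪von Neumann orders

    def __post_init__(self) -> None:
        if self.mode not in ("monolayer", "spheroid"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.lattice_size <= 0 or self.dt <= 0:
            raise ValueError("lattice_size and dt must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.mode == "spheroid":
            if self.lattice_spacing_cm is None:
                self.lattice_spacing_cm = 40e-4  # 40 µm
            if self.lattice_spacing_cm <= 0:
                raise ValueError("spheroid mode needs a physical lattice spacing")
            if self.nu is None:
                self.nu = 3
        else:
            # monolayer: spacing is one cell diameter and carries no dynamics;
            # field PDEs are not run in this mode.
            self.nu = self.nu  # None = unbounded

    @classmethod
    def monolayer(cls, **kw) -> "SimulationConfig":
        kw.setdefault("mode", "monolayer")
        kw.setdefault("lattice_size", 100)
        kw.setdefault("output_interval", 1.0)
        return cls(**kw)

    @classmethod
    def spheroid(cls, **kw) -> "SimulationConfig":
        kw.setdefault("mode", "spheroid")
        kw.setdefault("lattice_size", 1000)
        kw.setdefault("output_interval", 6.0)
        kw.setdefault("follow_up_time", 14 * 24.0)
        return cls(**kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str) -> tuple[SimulationConfig, ModelParams]:
    """Read a YAML config with optional ``simulation``/``params``/``dose`` maps."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    dose = DoseDescriptor(**raw.get("dose", {}))
    sim_kw = dict(raw.get("simulation", {}))
    sim_kw["dose"] = dose
    config = SimulationConfig(**sim_kw)
    params = ModelParams(**raw.get("params", {}))
    return config, params


def dump_config(config: SimulationConfig, params: ModelParams, path: str) -> None:
    doc = {
        "simulation": {k: v for k, v in config.to_dict().items() if k != "dose"},
        "dose": config.dose.__dict__.copy(),
        "params": params.to_dict(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
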