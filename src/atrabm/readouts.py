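"""Model readouts and file I/O.

The two observables the model is judged on are the percentage of
DNA-damaged (gamma-H2AX positive) cells — occupants of the damaged-S pool,
including repair-failed cells awaiting death — and the size of the system:
total cell count in monolayer mode, extrapolated spheroid volume in
spheroid mode.  The simulated 2-D cell disc is extrapolated to a sphere of
equal cross-section radius: r = sqrt(A / pi), V = 4/3 pi r^3.

Time series are written as long-format CSV (time, dose, replicate, metric,
value).  Experimental reference tables ("fixtures") are CSVs with columns
source, dose, time_h, metric, mean, dispersion and are validated on load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cellcycle import DAMAGED_STATES, Population, State
from .lattice import Lattice

#: state labels reported in counts_by_state (damaged pool under "D-S")
COUNT_COLUMNS = ("G1", "S", "D-S", "G2M", "G0", "dead", "total")


def gammaH2AX_fraction(pop: Population, include_dead: bool = True,
                       on_lattice_only: bool = True) -> float:
    """Percentage of gamma-H2AX positive agents.

    Numerator: agents in the damaged-S pool (D-S plus repair-failed agents
    awaiting death).  Denominator: agents still on the lattice; monolayer
    dead cells are never removed and are counted unless ``include_dead`` is
    False.  Returns NaN for an empty population.
    """
    s = pop.view("state")
    on = pop.view("on_lattice") if on_lattice_only else np.ones(len(pop), bool)
    denom_mask = on.copy()
    if not include_dead:
        denom_mask &= s != State.DEAD
    denom = int(denom_mask.sum())
    if denom == 0:
        return float("nan")
    damaged = int(np.sum(np.isin(s, DAMAGED_STATES) & on))
    return 100.0 * damaged / denom


def state_counts(pop: Population, include_dead: bool = True) -> dict[str, int]:
    """Counts per reported state; the "D-S" column is the damaged pool."""
    s = pop.view("state")
    on = pop.view("on_lattice")
    c = {
        "G1": int(np.sum((s == State.G1) & on)),
        "S": int(np.sum((s == State.S) & on)),
        "D-S": int(np.sum(np.isin(s, DAMAGED_STATES) & on)),
        "G2M": int(np.sum((s == State.G2M) & on)),
        "G0": int(np.sum((s == State.G0) & on)),
        "dead": int(np.sum((s == State.DEAD) & on)) if include_dead else 0,
    }
    c["total"] = sum(c.values())
    return c


def spheroid_volume(lat: Lattice) -> float:
    """Disc-to-spheroid extrapolated volume [cm³] from occupied sites."""
    if lat.spacing_cm is None:
        raise ValueError("spheroid volume needs a physical lattice spacing")
    area = lat.n_occupied * lat.spacing_cm ** 2
    r = math.sqrt(area / math.pi)
    return 4.0 / 3.0 * math.pi * r ** 3


def rmse(sim: np.ndarray, data: np.ndarray) -> float:
    """Root-mean-square error between aligned series."""
    sim = np.asarray(sim, dtype=float)
    data = np.asarray(data, dtype=float)
    if sim.shape != data.shape or sim.size == 0:
        raise ValueError("series must be non-empty and equally long")
    return float(np.sqrt(np.mean((sim - data) ** 2)))


@dataclass
class ReadoutSeries:
    """Per-replicate time series; times are hours since treatment start."""

    times: np.ndarray
    gammaH2AX_pct: np.ndarray
    counts_by_state: dict[str, np.ndarray]
    volume_cm3: Optional[np.ndarray] = None
    t0: float = 0.0                      #: treatment time on the absolute clock [h]
    dose_label: str = ""
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        n = len(self.times)
        for k, v in self.counts_by_state.items():
            if len(v) != n:
                raise ValueError(f"counts series {k!r} length mismatch")
        tot = sum(np.asarray(self.counts_by_state[k]) for k in
                  ("G1", "S", "D-S", "G2M", "G0", "dead"))
        if not np.array_equal(tot, np.asarray(self.counts_by_state["total"])):
            raise ValueError("counts_by_state does not sum to total")
        g = np.asarray(self.gammaH2AX_pct)
        if np.nanmin(g, initial=0) < 0 or np.nanmax(g, initial=0) > 100:
            raise ValueError("gammaH2AX_pct outside [0, 100]")

    def to_frame(self, replicate: int = 0) -> pd.DataFrame:
        rows = {"time": self.times, "dose": self.dose_label,
                "replicate": replicate,
                "gammaH2AX_pct": self.gammaH2AX_pct}
        for k, v in self.counts_by_state.items():
            rows[f"count_{k}"] = v
        if self.volume_cm3 is not None:
            rows["volume_cm3"] = self.volume_cm3
        wide = pd.DataFrame(rows)
        return wide.melt(id_vars=["time", "dose", "replicate"],
                         var_name="metric", value_name="value")


@dataclass
class ExperimentResult:
    """Replicate-aggregated means and standard deviations on a common
    post-treatment time grid."""

    times: np.ndarray
    mean: pd.DataFrame       # columns = metrics, index = times
    sd: pd.DataFrame
    replicates: list[ReadoutSeries] = field(default_factory=list)
    dose_label: str = ""

    @classmethod
    def from_replicates(cls, runs: list[ReadoutSeries]) -> "ExperimentResult":
        frames = [r.to_frame(i) for i, r in enumerate(runs)]
        tidy = pd.concat(frames, ignore_index=True)
        g = tidy.groupby(["time", "metric"])["value"]
        mean = g.mean().unstack("metric")
        sd = g.std(ddof=1).unstack("metric").fillna(0.0)
        return cls(times=mean.index.to_numpy(), mean=mean, sd=sd,
                   replicates=runs, dose_label=runs[0].dose_label)

    def to_frame(self) -> pd.DataFrame:
        out = []
        for stat, df in (("mean", self.mean), ("sd", self.sd)):
            t = df.reset_index().melt(id_vars="time", var_name="metric",
                                      value_name="value")
            t["stat"] = stat
            t["dose"] = self.dose_label
            out.append(t)
        return pd.concat(out, ignore_index=True)


def write_timeseries(obj, path: str) -> None:
    """Write a ReadoutSeries, ExperimentResult or tidy DataFrame as CSV."""
    if isinstance(obj, ReadoutSeries):
        df = obj.to_frame()
    elif isinstance(obj, ExperimentResult):
        df = obj.to_frame()
    else:
        df = pd.DataFrame(obj)
    df.to_csv(path, index=False)


# -- fixtures ---------------------------------------------------------------

FIXTURE_COLUMNS = ("source", "dose", "time_h", "metric", "mean", "dispersion")


@dataclass
class FixtureTable:
    """Reference measurements to compare simulations against."""

    table: pd.DataFrame
    source: str = ""

    @property
    def doses(self) -> list[str]:
        return sorted(self.table["dose"].unique())

    def series(self, dose: str, metric: str) -> pd.DataFrame:
        sub = self.table[(self.table["dose"] == dose) &
                         (self.table["metric"] == metric)]
        return sub.sort_values("time_h")


def load_fixture(path: str) -> FixtureTable:
    """Load and validate a fixture CSV (strictly increasing times per dose
    and metric, non-negative dispersion, all required columns present)."""
    df = pd.read_csv(path)
    missing = [c for c in FIXTURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fixture {path!r} is missing columns: {missing}")
    if (df["dispersion"] < 0).any():
        bad = df.index[df["dispersion"] < 0][0]
        raise ValueError(f"fixture {path!r}: negative dispersion at data row "
                         f"{bad + 1}")
    for (dose, metric), sub in df.groupby(["dose", "metric"]):
        t = sub["time_h"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"fixture {path!r}: times not strictly increasing for "
                f"dose={dose!r}, metric={metric!r}")
    src = df["source"].iloc[0] if len(df) else ""
    return FixtureTable(table=df, source=src)


def rmse_against_fixture(result: ExperimentResult, fixture: FixtureTable,
                         dose: str, metric: str,
                         sim_metric: Optional[str] = None) -> float:
    """RMSE between the replicate-mean simulation curve (interpolated onto
    the fixture's time points) and the fixture means."""
    ref = fixture.series(dose, metric)
    if ref.empty:
        raise ValueError(f"fixture has no rows for dose={dose!r}, "
                         f"metric={metric!r}")
    sim_metric = sim_metric or metric
    if sim_metric not in result.mean.columns:
        raise ValueError(f"simulation lacks metric {sim_metric!r}")
    sim = np.interp(ref["time_h"].to_numpy(), result.times,
                    result.mean[sim_metric].to_numpy())
    return rmse(sim, ref["mean"].to_numpy())
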