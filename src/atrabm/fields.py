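"""Oxygen and drug transport on the lattice.

Both species obey reaction–diffusion equations with spatially varying
diffusivity (divided by an intracellular slowdown factor of 1.5 where an
agent sits), zero-flux boundaries and explicit finite-difference updates in
conservative flux form with harmonic-mean interface diffusivities:

    oxygen:  dK/dt = div(D_K grad K) + r_K * m(x,t) - phi_K * K * cell(x,t)
    drug:    dC/dt = div(D_C grad C) + p(x,t)       - eta * C

m is the supply mask (empty sites not enclosed by the colony), cell marks
viable agents, p feeds boundary sites during daily administration windows,
and eta = ln 2 / half-life is first-order elimination.  Oxygen equilibrates
orders of magnitude faster than the cells evolve, so the engine treats it as
quasi-steady: the steady state of the same discretisation is obtained
directly with a preconditioned conjugate-gradient solve, warm-started from
the previous field.  Scaled oxygen is expressed in percent of the current
global maximum so that the hypoxia threshold (10%) is a relative one.

Units are caller-consistent: the engine works in cm and hours; the tests
often use dx = 1, D = 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.sparse import csr_matrix, diags
from scipy.sparse.linalg import cg, spsolve

from . import _kernels
from .lattice import Lattice, boundary_mask
from .params import MW_AZD, MW_O2, ModelParams


@dataclass
class ScalarField:
    """A concentration grid with site-dependent diffusivity."""

    values: np.ndarray          #: concentration (oxygen a.u. or drug µM)
    diffusivity: np.ndarray     #: per-site D, same units as dx²/time
    dx: float                   #: lattice spacing
    species: str = "oxygen"     # oxygen | drug

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.diffusivity = np.asarray(self.diffusivity, dtype=float)
        if self.values.shape != self.diffusivity.shape:
            raise ValueError("values and diffusivity shapes differ")
        if np.any(self.diffusivity <= 0):
            raise ValueError("diffusivity must be positive everywhere")
        if np.any(self.values < 0):
            raise ValueError("concentrations must be non-negative")

    def total_mass(self) -> float:
        return float(self.values.sum()) * self.dx ** 2


def uniform_field(size: int, dx: float, d: float, value: float = 0.0,
                  species: str = "oxygen") -> ScalarField:
    return ScalarField(np.full((size, size), float(value)),
                       np.full((size, size), float(d)), dx, species)


def interface_weights(diffusivity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Harmonic-mean diffusivities on x- and y-interfaces (conservative and
    the standard choice for discontinuous coefficients)."""
    d = diffusivity
    wx = 2.0 * d[:, :-1] * d[:, 1:] / (d[:, :-1] + d[:, 1:])
    wy = 2.0 * d[:-1, :] * d[1:, :] / (d[:-1, :] + d[1:, :])
    return wx, wy


def stability_limit(diffusivity: np.ndarray, dx: float) -> float:
    """Largest admissible explicit time step, dx² / (4 max D)."""
    return dx * dx / (4.0 * float(diffusivity.max()))


def fd_step(f: ScalarField, source: np.ndarray, sink_rate: np.ndarray,
            dt: float, use_kernel: bool = False) -> ScalarField:
    """Advance the field by ``dt`` (internally sub-stepped to stability).

    ``source`` adds concentration per unit time; ``sink_rate`` removes
    ``sink_rate * value``.  Pure numpy by default; ``use_kernel`` switches
    to the compiled loop when ``sink_rate`` is spatially uniform.
    """
    bound = stability_limit(f.diffusivity, f.dx)
    nsub = max(1, int(math.ceil(dt / (0.9 * bound))))
    dts = dt / nsub
    inv_dx2 = 1.0 / (f.dx * f.dx)
    wx, wy = interface_weights(f.diffusivity)
    src = np.broadcast_to(np.asarray(source, dtype=float), f.values.shape)
    snk = np.broadcast_to(np.asarray(sink_rate, dtype=float), f.values.shape)

    if use_kernel and np.ptp(snk) == 0:
        v = _kernels.diffuse_react(np.ascontiguousarray(f.values),
                                   np.ascontiguousarray(wx),
                                   np.ascontiguousarray(wy),
                                   np.ascontiguousarray(src),
                                   float(snk.flat[0]), inv_dx2, dts, nsub)
    else:
        v = f.values.copy()
        with np.errstate(invalid="ignore", over="ignore"):   # caught below
            for _ in range(nsub):
                div = np.zeros_like(v)
                fx = wx * (v[:, 1:] - v[:, :-1])
                fy = wy * (v[1:, :] - v[:-1, :])
                div[:, :-1] += fx
                div[:, 1:] -= fx
                div[:-1, :] += fy
                div[1:, :] -= fy
                v = v + dts * (div * inv_dx2 + src - snk * v)
    if not np.all(np.isfinite(v)):
        raise FloatingPointError(f"{f.species} field became non-finite")
    tol = 1e-9 * max(float(np.abs(v).max()), 1.0)
    if v.min() < -tol:
        raise FloatingPointError(
            f"{f.species} field went negative beyond solver tolerance "
            f"(min {v.min():.3e})")
    np.clip(v, 0.0, None, out=v)
    f.values = v
    return f


# -- oxygen ----------------------------------------------------------------

def cell_diffusivity(base_d: float, occupied: np.ndarray,
                     slowdown: float) -> np.ndarray:
    """Per-site diffusivity: ``base_d`` outside the colony, divided by the
    intracellular slowdown factor where an agent sits."""
    d = np.full(occupied.shape, base_d, dtype=float)
    d[occupied] = base_d / slowdown
    return d


def oxygen_step(f: ScalarField, lat: Lattice, cell_mask: np.ndarray,
                params: ModelParams, dt: float,
                time_unit_s: float = 1.0) -> ScalarField:
    """One transient step of the oxygen equation: supply r_K on the boundary
    mask, consumption phi_K on viable-cell sites.  ``time_unit_s`` converts
    the per-second coefficients to the caller's time unit (3600 for hours)."""
    m = boundary_mask(lat).astype(float)
    src = params.r_k * time_unit_s * m
    snk = params.phi_k * time_unit_s * cell_mask.astype(float)
    return fd_step(f, src, snk, dt)


def steady_state_oxygen(diffusivity: np.ndarray, supply_mask: np.ndarray,
                        cell_mask: np.ndarray, dx: float, r_k: float,
                        phi_k: float, x0: np.ndarray | None = None,
                        rtol: float = 1e-8) -> np.ndarray:
    """Steady state of the oxygen equation on the same flux-form stencil.

    Solves  -div(D grad K) + phi_k*cell*K = r_k*m  with zero-flux boundaries
    by preconditioned CG (the operator is symmetric positive definite as
    soon as any viable cell consumes).  With no consumers the steady state
    is unbounded; a uniform field is returned instead, which the percent
    rescaling maps to uniform normoxia.
    """
    H, W = diffusivity.shape
    n_cells = int(np.count_nonzero(cell_mask))
    if n_cells == 0:
        return np.ones((H, W))
    wx, wy = interface_weights(diffusivity)
    inv_dx2 = 1.0 / (dx * dx)
    N = H * W
    idx = np.arange(N).reshape(H, W)

    rows, cols, vals = [], [], []
    diag = phi_k * cell_mask.astype(float).ravel()

    def add_edges(w, ia, ib):
        wv = w.ravel() * inv_dx2
        a, b = ia.ravel(), ib.ravel()
        rows.extend((a, b, a, b))
        cols.extend((b, a, a, b))
        vals.extend((-wv, -wv, wv, wv))

    add_edges(wx, idx[:, :-1], idx[:, 1:])
    add_edges(wy, idx[:-1, :], idx[1:, :])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    A = csr_matrix((vals, (rows, cols)), shape=(N, N))
    A = A + diags(diag)
    b = (r_k * supply_mask.astype(float)).ravel()

    M = diags(1.0 / A.diagonal())
    guess = None if x0 is None else x0.ravel()
    sol, info = cg(A, b, x0=guess, rtol=rtol, atol=0.0, maxiter=20 * N, M=M)
    if info != 0:
        sol = spsolve(A.tocsc(), b)
    return np.clip(sol.reshape(H, W), 0.0, None)


def scale_oxygen(values: np.ndarray, h: float = 100.0) -> np.ndarray:
    """Percent-scale oxygen: K_hat = K / max(K) * h, recomputed per call."""
    vmax = float(values.max())
    if vmax <= 0:
        warnings.warn("all-zero oxygen field; scaled oxygen set to 0",
                      RuntimeWarning, stacklevel=2)
        return np.zeros_like(values)
    return values / vmax * h


# -- drug ------------------------------------------------------------------

def drug_diffusivity(d_oxygen: float) -> float:
    """Drug diffusivity from the oxygen one via the inverse square-root
    molecular-weight rule: D_drug / D_O2 = sqrt(MW_O2 / MW_drug) ≈ 0.27851."""
    if d_oxygen <= 0:
        raise ValueError("d_oxygen must be positive")
    return d_oxygen * math.sqrt(MW_O2 / MW_AZD)


def decay_constant(half_life: float) -> float:
    """First-order elimination rate ln 2 / t_half."""
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    return math.log(2.0) / half_life


def drug_step(f: ScalarField, lat: Lattice, supply_amplitude: float,
              eta: float, dt: float,
              supply_mask: np.ndarray | None = None) -> ScalarField:
    """Advance the drug field by ``dt``: supply on boundary-mask sites at
    ``supply_amplitude`` (0 outside administration windows), uniform
    first-order decay ``eta``.  Uses the compiled kernel."""
    if supply_mask is None:
        supply_mask = boundary_mask(lat)
    src = supply_amplitude * supply_mask.astype(float)
    return fd_step(f, src, np.full_like(f.values, eta), dt, use_kernel=True)
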