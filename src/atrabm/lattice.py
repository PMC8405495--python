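"""Square-lattice spatial bookkeeping for the agent population.

Each lattice point holds at most one agent.  Daughter placement alternates
stochastically between Moore (8-connected, Chebyshev rings) and von Neumann
(4-connected, Manhattan rings) neighbourhoods, scanning outward from order 1
and filling the first ring with a free site; this produces approximately
circular colonies.  The boundary mask m(x, t) marks the sites from which
oxygen (and, in dosing windows, drug) is supplied: empty sites that are not
completely surrounded by agents, with the off-lattice side counting as empty.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage

EMPTY = -1

_MOORE = "moore"
_VON_NEUMANN = "von_neumann"

# 3x3 kernel counting first-order Moore neighbours (centre excluded)
_NEIGH_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)


class Lattice:
    """Occupancy grid.  ``occupancy[r, c]`` is an agent id or ``EMPTY``."""

    def __init__(self, size: int, spacing_cm: Optional[float] = None,
                 mode: str = "monolayer"):
        if size <= 0:
            raise ValueError("size must be positive")
        self.size = int(size)
        self.spacing_cm = spacing_cm
        self.mode = mode
        self.occupancy = np.full((size, size), EMPTY, dtype=np.int64)
        self.n_occupied = 0
        self.version = 0   # bumped on every occupancy change (cache key)

    # -- basic occupancy ----------------------------------------------------
    def in_bounds(self, r: int, c: int) -> bool:
        return 0 <= r < self.size and 0 <= c < self.size

    def is_free(self, r: int, c: int) -> bool:
        return self.occupancy[r, c] == EMPTY

    def place(self, agent_id: int, r: int, c: int) -> None:
        if not self.in_bounds(r, c):
            raise ValueError(f"site ({r}, {c}) is off-lattice")
        if self.occupancy[r, c] != EMPTY:
            raise ValueError(f"site ({r}, {c}) already occupied")
        self.occupancy[r, c] = agent_id
        self.n_occupied += 1
        self.version += 1

    def free_site(self, r: int, c: int) -> None:
        if self.occupancy[r, c] == EMPTY:
            raise ValueError(f"site ({r}, {c}) already empty")
        self.occupancy[r, c] = EMPTY
        self.n_occupied -= 1
        self.version += 1

    @property
    def centre(self) -> tuple[int, int]:
        return self.size // 2, self.size // 2


def neighbourhood_sites(center: tuple[int, int], order: int, shape: str,
                        size: int) -> list[tuple[int, int]]:
    """Sites of the order-``order`` ring around ``center``, clipped at edges.

    Moore rings are Chebyshev-distance shells (8k sites in the interior),
    von Neumann rings Manhattan-distance shells (4k sites).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    r0, c0 = center
    if not (0 <= r0 < size and 0 <= c0 < size):
        raise ValueError("center is off-lattice")
    k = order
    sites: list[tuple[int, int]] = []
    if shape == _MOORE:
        for dc in range(-k, k + 1):          # top and bottom edges of the shell
            sites.append((r0 - k, c0 + dc))
            sites.append((r0 + k, c0 + dc))
        for dr in range(-k + 1, k):          # left/right edges, corners done
            sites.append((r0 + dr, c0 - k))
            sites.append((r0 + dr, c0 + k))
    elif shape == _VON_NEUMANN:
        for dr in range(-k, k + 1):
            rest = k - abs(dr)
            if rest == 0:
                sites.append((r0 + dr, c0))
            else:
                sites.append((r0 + dr, c0 - rest))
                sites.append((r0 + dr, c0 + rest))
    else:
        raise ValueError(f"unknown neighbourhood shape {shape!r}")
    return [(r, c) for r, c in sites if 0 <= r < size and 0 <= c < size]


def place_daughter(parent: tuple[int, int], lattice: Lattice,
                   max_order: Optional[int], rng: np.random.Generator
                   ) -> Optional[tuple[int, int]]:
    """Pick the site for a newborn daughter of the agent at ``parent``.

    A fair coin chooses Moore vs von Neumann for this division, then rings
    of increasing order are scanned; the first ring containing free sites
    donates one uniformly at random.  ``max_order=None`` means unbounded
    (clipped only by the lattice edge).  Returns ``None`` when every
    admissible ring is full.
    """
    shape = _MOORE if rng.random() < 0.5 else _VON_NEUMANN
    # largest ring that can still intersect the lattice
    hard_cap = (lattice.size - 1) if shape == _MOORE else 2 * (lattice.size - 1)
    top = hard_cap if max_order is None else min(max_order, hard_cap)
    occ = lattice.occupancy
    for k in range(1, top + 1):
        ring = neighbourhood_sites(parent, k, shape, lattice.size)
        free = [s for s in ring if occ[s] == EMPTY]
        if free:
            return free[rng.integers(len(free))]
    return None


def space_available(site: tuple[int, int], lattice: Lattice,
                    max_order: int) -> bool:
    """True iff any site within the union of order 1..``max_order`` Moore and
    von Neumann neighbourhoods of ``site`` is empty.

    The union over orders 1..k of both ring families is the Chebyshev ball of
    radius k (minus the centre), so a clipped square window suffices.
    """
    r, c = site
    k = max_order
    sub = lattice.occupancy[max(0, r - k): r + k + 1, max(0, c - k): c + k + 1]
    # centre is occupied by the querying agent, so counting it is harmless
    return bool(np.any(sub == EMPTY))


def space_map(lattice: Lattice, max_order: int) -> np.ndarray:
    """Boolean grid: site has >=1 empty site within Chebyshev radius
    ``max_order``.  Off-lattice never counts as available space."""
    empty = (lattice.occupancy == EMPTY).astype(np.uint8)
    return ndimage.maximum_filter(empty, size=2 * max_order + 1,
                                  mode="constant", cval=0).astype(bool)


def boundary_mask(lattice: Lattice) -> np.ndarray:
    """Supply mask m(x, t): 1 at empty sites not completely surrounded by
    agents (first-order Moore adjacency; the off-lattice side counts as
    empty), 0 elsewhere."""
    empty = (lattice.occupancy == EMPTY).astype(float)
    neigh = ndimage.convolve(empty, _NEIGH_KERNEL, mode="constant", cval=1.0)
    return ((empty > 0) & (neigh > 0.5)).astype(np.uint8)


def remove_dead(lattice: Lattice, pop, now: float) -> int:
    """Declare dead every repair-failed agent whose lethal delay has elapsed.

    In spheroid mode the agent's site is freed (in vivo-like clearance of
    cell corpses); in monolayer mode the dead cell keeps occupying its site
    for the rest of the run.  Returns the number of newly dead agents.
    """
    from .cellcycle import State  # local import avoids a cycle

    n = len(pop)
    lethal = pop.state[:n] == int(State.LETHAL)
    if not lethal.any():
        return 0
    idx = np.flatnonzero(lethal & (pop.death_clock[:n] >= pop.tau[:n]))
    for i in idx:
        pop.state[i] = State.DEAD
        if lattice.mode == "spheroid":
            lattice.free_site(pop.row[i], pop.col[i])
            pop.on_lattice[i] = False
    return int(idx.size)
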