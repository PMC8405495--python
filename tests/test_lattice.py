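"""Spatial bookkeeping: neighbourhood rings, daughter placement, quiescence
space checks, the supply boundary mask, and dead-agent removal."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atrabm.cellcycle import Population, State
from atrabm.lattice import (EMPTY, Lattice, boundary_mask,
                            neighbourhood_sites, place_daughter, remove_dead,
                            space_available, space_map)


def brute_force_ring(center, order, shape, size):
    """Independent oracle: enumerate all lattice sites at the exact
    Chebyshev (Moore) or Manhattan (von Neumann) distance."""
    r0, c0 = center
    out = set()
    for r in range(size):
        for c in range(size):
            d = (max(abs(r - r0), abs(c - c0)) if shape == "moore"
                 else abs(r - r0) + abs(c - c0))
            if d == order:
                out.add((r, c))
    return out


class TestNeighbourhoodSites:
    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_interior_ring_sizes(self, order):
        moore = neighbourhood_sites((10, 10), order, "moore", 21)
        vn = neighbourhood_sites((10, 10), order, "von_neumann", 21)
        assert len(moore) == 8 * order
        assert len(vn) == 4 * order

    def test_corner_clipping(self):
        assert len(neighbourhood_sites((0, 0), 1, "moore", 9)) == 3

    @pytest.mark.parametrize("center", [(0, 0), (0, 4), (3, 3), (8, 8), (8, 1)])
    @pytest.mark.parametrize("order", [1, 2, 3])
    @pytest.mark.parametrize("shape", ["moore", "von_neumann"])
    def test_matches_brute_force_enumeration(self, center, order, shape):
        got = set(neighbourhood_sites(center, order, shape, 9))
        assert got == brute_force_ring(center, order, shape, 9)

    def test_rejects_off_lattice_center(self):
        with pytest.raises(ValueError):
            neighbourhood_sites((9, 0), 1, "moore", 9)
        with pytest.raises(ValueError):
            neighbourhood_sites((0, 0), 0, "moore", 9)


def _occupy(lat, sites):
    for k, (r, c) in enumerate(sites):
        lat.place(1000 + k, r, c)


class TestPlaceDaughter:
    def test_lone_parent_gets_first_order_site(self, rng):
        lat = Lattice(11)
        lat.place(0, 5, 5)
        for _ in range(20):
            site = place_daughter((5, 5), lat, None, rng)
            assert max(abs(site[0] - 5), abs(site[1] - 5)) == 1

    def test_saturated_neighbourhood_blocks_division(self, rng):
        lat = Lattice(11)
        lat.place(0, 5, 5)
        full = {s for k in (1, 2, 3)
                for s in brute_force_ring((5, 5), k, "moore", 11)}
        _occupy(lat, sorted(full))
        assert place_daughter((5, 5), lat, 3, rng) is None

    def test_single_gap_at_order_three_found_with_certainty(self, rng):
        lat = Lattice(11)
        lat.place(0, 5, 5)
        full = {s for k in (1, 2, 3)
                for s in brute_force_ring((5, 5), k, "moore", 11)}
        full.discard((5, 8))    # Chebyshev and Manhattan distance 3
        _occupy(lat, sorted(full))
        for _ in range(20):
            assert place_daughter((5, 5), lat, 3, rng) == (5, 8)

    def test_lower_orders_prioritised(self, rng):
        # orders 1-2 of both shapes full except (4, 4): a Moore draw finds
        # it at order 1, a von Neumann draw at order 2 — never the open
        # order-3 ring
        lat = Lattice(11)
        lat.place(0, 5, 5)
        full = {s for k in (1, 2)
                for s in brute_force_ring((5, 5), k, "moore", 11)}
        full.discard((4, 4))
        _occupy(lat, sorted(full))
        for _ in range(20):
            assert place_daughter((5, 5), lat, 3, rng) == (4, 4)

    @given(seed=st.integers(0, 200))
    @settings(deadline=None, max_examples=60)
    def test_never_returns_occupied_or_off_lattice(self, seed):
        r = np.random.default_rng(seed)
        lat = Lattice(7)
        sites = [(i, j) for i in range(7) for j in range(7)]
        r.shuffle(sites)
        k = int(r.integers(1, 48))
        for aid, s in enumerate(sites[:k]):
            lat.place(aid, *s)
        parent = sites[int(r.integers(0, k))]
        site = place_daughter(parent, lat, None, r)
        if site is None:
            assert lat.n_occupied == 49
        else:
            assert 0 <= site[0] < 7 and 0 <= site[1] < 7
            assert lat.occupancy[site] == EMPTY


class TestSpaceAvailable:
    def test_isolated_agent(self):
        lat = Lattice(11)
        lat.place(0, 5, 5)
        assert space_available((5, 5), lat, 3)

    def test_fully_enclosed_through_order_three(self):
        lat = Lattice(11)
        lat.place(0, 5, 5)
        full = {s for k in (1, 2, 3)
                for s in brute_force_ring((5, 5), k, "moore", 11)}
        _occupy(lat, sorted(full))
        assert not space_available((5, 5), lat, 3)

    def test_single_gap_at_order_two_is_enough(self):
        lat = Lattice(11)
        lat.place(0, 5, 5)
        full = {s for k in (1, 2, 3)
                for s in brute_force_ring((5, 5), k, "moore", 11)}
        full.discard((5, 7))
        _occupy(lat, sorted(full))
        assert space_available((5, 5), lat, 3)

    def test_freed_site_restores_space(self):
        """The quiescence re-entry path: freeing a neighbouring site flips
        the space query back to True."""
        lat = Lattice(11)
        lat.place(0, 5, 5)
        full = sorted({s for k in (1, 2, 3)
                       for s in brute_force_ring((5, 5), k, "moore", 11)})
        _occupy(lat, full)
        assert not space_available((5, 5), lat, 3)
        lat.free_site(5, 6)
        assert space_available((5, 5), lat, 3)

    def test_space_map_agrees_with_pointwise_query(self):
        r = np.random.default_rng(7)
        lat = Lattice(15)
        for aid, (i, j) in enumerate([(int(r.integers(15)), int(r.integers(15)))
                                      for _ in range(60)]):
            if lat.occupancy[i, j] == EMPTY:
                lat.place(aid, i, j)
        smap = space_map(lat, 3)
        occupied = list(zip(*np.nonzero(lat.occupancy != EMPTY)))
        for site in occupied:
            assert smap[site] == space_available(site, lat, 3)


class TestBoundaryMask:
    def test_empty_lattice_supplies_everywhere(self):
        assert boundary_mask(Lattice(9)).all()

    def test_full_lattice_supplies_nowhere(self):
        lat = Lattice(5)
        for aid, (i, j) in enumerate([(i, j) for i in range(5)
                                      for j in range(5)]):
            lat.place(aid, i, j)
        assert not boundary_mask(lat).any()

    def test_solid_block_masks_only_itself(self):
        # 5x5 agent block centred on 9x9: every empty site keeps an empty
        # Moore neighbour, so m=0 exactly on the block
        lat = Lattice(9)
        block = [(i, j) for i in range(2, 7) for j in range(2, 7)]
        _occupy(lat, block)
        m = boundary_mask(lat)
        assert m.sum() == 81 - 25
        for (i, j) in block:
            assert m[i, j] == 0

    def test_enclosed_hole_is_not_supplied(self):
        # a single empty site completely surrounded by agents is interior:
        # oxygen is supplied only from outside the colony boundary
        lat = Lattice(9)
        block = [(i, j) for i in range(2, 7) for j in range(2, 7)
                 if (i, j) != (4, 4)]
        _occupy(lat, block)
        m = boundary_mask(lat)
        assert m[4, 4] == 0

    def test_lattice_edge_counts_as_empty_side(self):
        # an empty corner site walled in by agents still touches the
        # off-lattice side, which counts as empty
        lat = Lattice(9)
        _occupy(lat, [(0, 1), (1, 0), (1, 1)])
        assert boundary_mask(lat)[0, 0] == 1


class TestRemoveDead:
    def _pending_agent(self, mode):
        lat = Lattice(9, spacing_cm=40e-4 if mode == "spheroid" else None,
                      mode=mode)
        pop = Population()
        i = pop.add(4, 4, 24.0, State.LETHAL)
        lat.place(i, 4, 4)
        return lat, pop

    def test_spheroid_clearance_frees_the_site(self):
        lat, pop = self._pending_agent("spheroid")
        pop.death_clock[0] = 24.0
        assert remove_dead(lat, pop, now=0.0) == 1
        assert pop.state[0] == State.DEAD
        assert lat.occupancy[4, 4] == EMPTY
        assert not pop.on_lattice[0]

    def test_monolayer_corpse_keeps_its_site(self):
        lat, pop = self._pending_agent("monolayer")
        pop.death_clock[0] = 24.0
        assert remove_dead(lat, pop, now=0.0) == 1
        assert pop.state[0] == State.DEAD
        assert lat.occupancy[4, 4] != EMPTY
        assert pop.on_lattice[0]

    def test_lethal_delay_not_yet_elapsed(self):
        lat, pop = self._pending_agent("spheroid")
        pop.death_clock[0] = 23.9
        assert remove_dead(lat, pop, now=0.0) == 0
        assert pop.state[0] == State.LETHAL
        assert lat.occupancy[4, 4] != EMPTY


class TestOccupancyConsistency:
    def test_place_and_free_roundtrip(self):
        lat = Lattice(5)
        lat.place(0, 2, 2)
        assert lat.n_occupied == 1
        with pytest.raises(ValueError):
            lat.place(1, 2, 2)      # one agent per site
        lat.free_site(2, 2)
        assert lat.n_occupied == 0
        with pytest.raises(ValueError):
            lat.free_site(2, 2)
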