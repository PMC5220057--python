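"""Engine: encounter detection, dispersal energetics, step scheduling,
determinism and exact energy bookkeeping."""

import numpy as np
import pytest
from scipy import stats

import seedbanksim as sbs
from seedbanksim.engine import PROCESS_BLOCKS, detect_encounters, apply_dispersal_cost
from seedbanksim.params import ModelParams, sample_species_traits
from seedbanksim.population import Community
from seedbanksim.regimes import Dispersal, parse_regime
from seedbanksim.resources import ParticlePool, ResourceParticle

from conftest import brute_force_encounters, make_state


def _random_scene(rng, n_cells=100, n_parts=100, n_types=3, span=30_000.0):
    """Random community + particle pool with contact-scale particle sizes."""
    traits = sample_species_traits(rng, 12, parse_regime(
        "consumer_resource,polyculture_labile,passive,well_mixed"))
    comm = Community()
    comm.add_arrays(rng.integers(0, 12, n_cells), rng.uniform(0.1, 1.0, n_cells),
                    np.ones(n_cells, dtype=bool), rng.uniform(0, span, (n_cells, 3)),
                    np.tile([1.0, 0, 0], (n_cells, 1)), np.zeros(n_cells, dtype=np.int64))
    pool = ParticlePool()
    pool.add([ResourceParticle(id=pool.claim_id(), rtype=int(rng.integers(n_types)),
                               content=float(rng.uniform(1.0, 10_000.0)),
                               position=rng.uniform(0, span, 3))
              for _ in range(n_parts)])
    return comm, traits, pool


class TestEncounterDetection:
    def test_contact_requires_overlapping_spheres(self, rng):
        comm, _, pool = _random_scene(rng, n_cells=0, n_parts=0)
        # monoculture traits so every species consumes type 0
        traits = sample_species_traits(rng, 12, parse_regime(0))
        # one cell of radius ~0.31 um, one particle of radius 2000 um
        comm.add_arrays([0], [0.125], [True], [[0.0, 0.0, 0.0]],
                        [[1.0, 0.0, 0.0]], [0])
        content = 1000.0 * (4000.0 / 4000.0) ** 3  # diameter 4000, radius 2000
        pool.add([ResourceParticle(id=0, rtype=0, content=content,
                                   position=np.array([2000.0, 0.0, 0.0]))])
        assert detect_encounters(comm, traits, pool) == [(0, 0)]
        pool.pos[0, 0] = 2100.0  # beyond the summed radii: no contact
        assert detect_encounters(comm, traits, pool) == []

    def test_dormant_cells_register_no_encounters(self, rng):
        comm, traits, pool = _random_scene(rng)
        comm.active[:] = False
        assert detect_encounters(comm, traits, pool) == []

    def test_matches_all_pairs_oracle_on_random_scenes(self, rng):
        for _ in range(5):
            comm, traits, pool = _random_scene(rng)
            got = sorted(detect_encounters(comm, traits, pool))
            want = sorted(brute_force_encounters(comm, traits, pool))
            assert got == want

    def test_kdtree_path_matches_oracle(self, rng):
        # force the tree-pruned branch with a larger scene
        comm, traits, pool = _random_scene(rng, n_cells=600, n_parts=500)
        assert comm.n * pool.n > 200_000
        got = sorted(detect_encounters(comm, traits, pool))
        want = sorted(brute_force_encounters(comm, traits, pool))
        assert got == want


class TestDispersalCost:
    def test_passive_is_free(self):
        assert apply_dispersal_cost(0.8, 5000.0, Dispersal.PASSIVE, 0.01, 43_200.0) == 0.0

    def test_chemotaxis_costs_twice_run_and_tumble(self):
        rt = apply_dispersal_cost(0.8, 5000.0, Dispersal.RUN_TUMBLE, 0.01, 43_200.0)
        cx = apply_dispersal_cost(0.8, 5000.0, Dispersal.CHEMOTAXIS, 0.01, 43_200.0)
        assert cx == pytest.approx(2.0 * rt)
        assert rt == pytest.approx(0.01 * (5000.0 / 43_200.0) * 0.8)

    def test_zero_distance_costs_nothing_and_negative_rejected(self):
        assert apply_dispersal_cost(0.8, 0.0, Dispersal.CHEMOTAXIS, 0.01, 43_200.0) == 0.0
        with pytest.raises(ValueError):
            apply_dispersal_cost(0.8, -1.0, Dispersal.RUN_TUMBLE, 0.01, 43_200.0)


class TestStep:
    def test_empty_closed_state_only_advances_the_clock(self):
        state = make_state(seed=3, supply_rate=0.0, immigration_rate=0.0)
        state.community.remove(np.arange(state.community.n))
        before = state.step_index
        sbs.step(state)
        assert state.step_index == before + 1
        assert state.community.n == 0 and state.particles.n == 0
        assert state.tallies["births"] == 0 and state.tallies["encounters"] == 0

    def test_identical_seeds_give_identical_trajectories(self):
        a = make_state(seed=11, regime="scavenging,lock_and_key,chemotaxis,structured")
        b = make_state(seed=11, regime="scavenging,lock_and_key,chemotaxis,structured")
        for _ in range(120):
            sbs.step(a)
            sbs.step(b)
        np.testing.assert_array_equal(a.community.ids, b.community.ids)
        np.testing.assert_array_equal(a.community.quota, b.community.quota)
        np.testing.assert_array_equal(a.community.pos, b.community.pos)
        np.testing.assert_array_equal(a.particles.ids, b.particles.ids)
        np.testing.assert_array_equal(a.particles.content, b.particles.content)
        assert a.tallies == b.tallies and a.ledger == b.ledger

    def test_process_order_is_shuffled_uniformly(self):
        # an empty closed state makes steps cheap; the shuffle is still drawn
        state = make_state(seed=5, supply_rate=0.0, immigration_rate=0.0)
        state.community.remove(np.arange(state.community.n))
        firsts = []
        for _ in range(3000):
            sbs.step(state)
            firsts.append(state.last_block_order[0])
        counts = [firsts.count(b) for b in PROCESS_BLOCKS]
        assert stats.chisquare(counts).pvalue > 0.01

    @pytest.mark.parametrize("regime", [
        "consumer_resource,monoculture_labile,run_tumble,well_mixed",
        "crossfeed_twoway,lock_and_key,chemotaxis,structured",
        "scavenging,polyculture_labile,passive,structured",
    ])
    def test_energy_ledgers_balance_over_a_run(self, regime):
        state = make_state(seed=2, regime=regime)
        for _ in range(250):
            sbs.step(state)
        dq, dc = sbs.ledger_imbalance(state)
        assert dq <= 1e-9 * max(1.0, state.community.total_quota)
        assert dc <= 1e-9 * max(1.0, state.particles.total_content)

    def test_closed_system_energy_is_non_increasing(self):
        # no supply, no immigration, no metabolite by-products
        state = make_state(seed=9, regime="scavenging,monoculture_labile,run_tumble,well_mixed",
                           supply_rate=0.0, immigration_rate=0.0)
        kappa = state.params.mass_to_quota
        energy = state.community.total_quota + kappa * state.particles.total_content
        for _ in range(200):
            sbs.step(state)
            now = state.community.total_quota + kappa * state.particles.total_content
            assert now <= energy + 1e-9
            energy = now
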