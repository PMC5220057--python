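"""Cell physiology: geometry, founding, immigration, consumption, fission,
maintenance, death and dormancy."""

import numpy as np
import pytest

from seedbanksim.params import ModelParams, sample_species_traits
from seedbanksim.population import (
    Individual,
    check_death,
    consume,
    diameter_from_quota,
    dormancy_transition,
    immigrate,
    initialize_community,
    maintenance_step,
    reproduce,
    sample_logseries_species,
)
from seedbanksim.regimes import parse_regime
from seedbanksim.resources import ResourceParticle


def _individual(quota=0.5, active=True, species=0):
    return Individual(id=0, species=species, quota=quota, active=active,
                      position=np.zeros(3), heading=np.array([1.0, 0.0, 0.0]))


class TestCellGeometry:
    @pytest.mark.parametrize("quota,expected", [
        (1.0, 1.25),      # full quota = maximum diameter
        (0.5, 0.992),     # the printed "1 um" at the immigrant lower bound
        (0.125, 0.625),   # (1/8)^(1/3) = 1/2
    ])
    def test_cube_root_law(self, quota, expected):
        assert diameter_from_quota(quota) == pytest.approx(expected, abs=5e-4)

    def test_rejects_non_positive_quota(self):
        with pytest.raises(ValueError):
            diameter_from_quota(0.0)


class TestFounding:
    def test_community_starts_with_100_individuals(self, rng):
        params = ModelParams()
        traits = sample_species_traits(rng, 50, parse_regime(0))
        comm = initialize_community(params, traits, rng)
        assert comm.n == 100
        assert comm.active.all()
        assert comm.quota.min() >= 0.5 and comm.quota.max() <= 1.0
        assert comm.pos.min() >= 0 and comm.pos.max() <= params.domain_length
        assert len(set(comm.ids.tolist())) == 100

    def test_log_series_founders_favour_low_species_indices(self, rng):
        draws = sample_logseries_species(rng, 0.99, 100, 20_000)
        assert draws.min() >= 0 and draws.max() < 100
        counts = np.bincount(draws, minlength=100)
        # log-series pmf declines in the species index
        assert counts[0] > counts[9] > counts[49]


class TestImmigration:
    def test_zero_rate_never_adds(self, rng):
        params = ModelParams(immigration_rate=0.0)
        traits = sample_species_traits(rng, 10, parse_regime(0))
        assert all(immigrate(rng, params, traits, 0) is None for _ in range(300))

    def test_arrival_frequency_and_quota_range(self):
        rng = np.random.default_rng(42)
        params = ModelParams(immigration_rate=0.05)
        traits = sample_species_traits(rng, 10, parse_regime(0))
        n = 10_000
        arrivals = [ind for _ in range(n)
                    if (ind := immigrate(rng, params, traits, 0)) is not None]
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(len(arrivals) / n - 0.05) < 3 * se
        quotas = np.array([a.quota for a in arrivals])
        assert quotas.min() >= 0.5 and quotas.max() <= 1.0
        assert all(a.active for a in arrivals)


class TestConsumption:
    def _particle(self, content):
        return ResourceParticle(id=0, rtype=0, content=content, position=np.zeros(3))

    def test_fills_quota_and_drains_particle(self):
        ind = _individual(quota=0.5)
        part = self._particle(1000.0)
        delta = consume(ind, part, kappa=0.001)
        assert delta == pytest.approx(0.5)
        assert ind.quota == pytest.approx(1.0)
        assert part.content == pytest.approx(500.0)

    def test_satiated_cell_leaves_particle_untouched(self):
        ind = _individual(quota=1.0)
        part = self._particle(1000.0)
        assert consume(ind, part, kappa=0.001) == 0.0
        assert part.content == 1000.0

    def test_dormant_cell_does_not_consume(self):
        ind = _individual(quota=0.2, active=False)
        part = self._particle(1000.0)
        assert consume(ind, part, kappa=0.001) == 0.0
        assert ind.quota == 0.2 and part.content == 1000.0

    def test_species_rate_scales_the_bite(self):
        ind = _individual(quota=0.0 + 1e-12)
        part = self._particle(1000.0)
        delta = consume(ind, part, kappa=0.001, rate=0.25)
        assert delta == pytest.approx(0.25)
        assert part.content == pytest.approx(750.0)

    def test_exchange_conserves_energy_exactly(self, rng):
        for _ in range(100):
            q0 = float(rng.uniform(0.01, 1.0))
            c0 = float(rng.uniform(1.0, 10_000.0))
            ind = _individual(quota=q0)
            part = self._particle(c0)
            delta = consume(ind, part, kappa=0.001, rate=float(rng.uniform(0.1, 1.0)))
            assert (ind.quota - q0) == pytest.approx(delta, abs=1e-15)
            assert 0.001 * (c0 - part.content) == pytest.approx(delta, rel=1e-12)


class TestReproduction:
    def test_forced_fission_halves_quota_after_growth_cost(self):
        ind = _individual(quota=1.0)
        rng = np.random.default_rng(0)  # first uniform < 1 == p, so success
        daughter = reproduce(ind, growth_rate=1.0, c_g=0.1, rng=rng,
                             daughter_id=99, step=5)
        assert daughter is not None
        assert ind.quota == pytest.approx(0.45)
        assert daughter.quota == pytest.approx(0.45)
        assert daughter.species == ind.species
        np.testing.assert_array_equal(daughter.position, ind.position)
        assert daughter.birth_step == 5

    def test_probability_is_growth_rate_times_quota(self, rng):
        # empirical fission frequency over many trials matches g*Q
        g, q, n = 0.6, 0.5, 8000
        hits = sum(reproduce(_individual(quota=q), g, 0.1, rng, 1, 0) is not None
                   for _ in range(n))
        se = np.sqrt(g * q * (1 - g * q) / n)
        assert abs(hits / n - g * q) < 3 * se

    def test_starved_and_dormant_cells_do_not_divide(self, rng):
        # p = g*Q -> 0 as Q -> 0, so a vanishing quota never divides in practice
        assert all(reproduce(_individual(quota=1e-12), 1.0, 0.1, rng, 1, 0) is None
                   for _ in range(200))
        assert reproduce(_individual(active=False), 1.0, 0.1, rng, 1, 0) is None


class TestMaintenanceDeathDormancy:
    def test_active_pays_full_maintenance(self):
        ind = _individual(quota=0.5)
        maintenance_step(ind, 0.01, 50.0)
        assert ind.quota == pytest.approx(0.49)

    def test_dormant_pays_reduced_maintenance(self):
        ind = _individual(quota=0.5, active=False)
        maintenance_step(ind, 0.01, 100.0)
        assert ind.quota == pytest.approx(0.4999)

    @pytest.mark.parametrize("quota,m,alive", [
        (0.0005, 0.001, False),   # below maintenance: dead
        (0.001, 0.001, True),     # boundary is strict: alive
        (0.5, 0.001, True),
    ])
    def test_death_rule_is_strict_inequality(self, quota, m, alive):
        assert check_death(_individual(quota=quota), m) is alive

    def test_dormant_cells_die_by_the_same_rule(self):
        assert not check_death(_individual(quota=0.0005, active=False), 0.001)

    def test_depletion_triggers_dormancy(self, rng):
        ind = _individual(quota=0.4)
        dormancy_transition(ind, maintenance=0.01, theta_d=50.0,
                            resuscitation_prob=0.0, rng=rng)
        assert not ind.active  # 0.4 <= 50 * 0.01

    def test_rich_cells_stay_active_and_zero_rho_never_wakes(self, rng):
        rich = _individual(quota=0.9)
        dormancy_transition(rich, 0.01, 50.0, 0.0, rng)
        assert rich.active
        dormant = _individual(quota=0.4, active=False)
        for _ in range(300):
            dormancy_transition(dormant, 0.01, 50.0, 0.0, rng)
        assert not dormant.active

    def test_resuscitation_frequency_is_binomial(self, rng):
        n, rho = 10_000, 0.005
        wakes = 0
        for _ in range(n):
            ind = _individual(quota=0.4, active=False)
            dormancy_transition(ind, 0.01, 50.0, rho, rng)
            wakes += ind.active
        se = np.sqrt(rho * (1 - rho) / n)
        assert abs(wakes / n - rho) < 3 * se
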