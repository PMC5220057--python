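"""One simulation step: randomized process scheduling and encounter dynamics.

Each step executes nine life-history/environment process blocks in a freshly
shuffled order (random ordering prevents artifacts that a fixed schedule
would impose): resource supply, immigration, spatial mixing, active
dispersal with its energetic cost, encounter → breakdown → consumption
(with metabolite by-products and recalcitrance handling costs), clonal
reproduction, maintenance, death (with necromass under scavenging), and
dormancy transitions.

The engine keeps exact energy ledgers.  Quota changes only through
consumption (+), maintenance (−), growth cost (−), dispersal cost (−),
handling cost (−), immigration (+), and removal at death; particle content
changes only through supply (+), necromass and metabolite creation (+),
consumption (−), sub-floor crumb loss (−) and the particle-count cap (−).
Both ledgers balance to floating-point precision over arbitrary runs and are
audited in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .params import ModelParams, SpeciesTraits, ensure_rng
from .population import Community, immigrate, initialize_community
from .regimes import ComplexityRegime, Dispersal, Mixing, ResourceComplexity, Trophic
from .resources import (
    ORIGIN_FRAGMENT,
    ParticlePool,
    ResourceParticle,
    spawn_metabolite,
    spawn_necromass,
    split_particle,
    supply_step,
)
from .space import random_unit_vectors, reflect, relocate_well_mixed, run_tumble_step

#: The process blocks whose execution order is shuffled every step.
PROCESS_BLOCKS = (
    "supply",
    "immigration",
    "mixing",
    "dispersal",
    "encounter",
    "reproduction",
    "maintenance",
    "death",
    "dormancy",
)

_TALLY_KEYS = ("births", "deaths", "immigrations", "encounters", "consumptions",
               "supplied_particles", "breakdown_attempts", "breakdown_failures")

_LEDGER_KEYS = (
    "quota_in_init", "quota_in_immigration", "quota_in_consumption",
    "quota_out_maintenance", "quota_out_growth", "quota_out_dispersal",
    "quota_out_handling", "quota_out_death",
    "content_in_supply", "content_in_necromass", "content_in_metabolite",
    "content_out_consumed", "content_out_floor", "content_out_cap",
)


@dataclass
class ModelState:
    """Full mutable state of one model realization."""

    params: ModelParams
    traits: SpeciesTraits
    regime: ComplexityRegime
    community: Community
    particles: ParticlePool
    rng: np.random.Generator
    step_index: int = 0
    tallies: dict = field(default_factory=lambda: {k: 0 for k in _TALLY_KEYS})
    ledger: dict = field(default_factory=lambda: {k: 0.0 for k in _LEDGER_KEYS})
    last_block_order: tuple = ()

    @property
    def supplied_types(self) -> list[int]:
        return list(range(self.traits.n_supplied))


def init_state(params: ModelParams, traits: SpeciesTraits, regime: ComplexityRegime,
               seed) -> ModelState:
    """Build a founded model state (100 individuals, empty particle pool)."""
    rng = ensure_rng(seed)
    community = initialize_community(params, traits, rng)
    state = ModelState(
        params=params, traits=traits, regime=regime,
        community=community, particles=ParticlePool(), rng=rng,
    )
    state.ledger["quota_in_init"] = community.total_quota
    return state


# ---------------------------------------------------------------------------
# encounter detection


def detect_encounters(community: Community, traits: SpeciesTraits,
                      pool: ParticlePool, active_only: bool = True) -> list[tuple[int, int]]:
    """Contacts between cells and consumable resource particles.

    A contact exists when the centre distance is at most the sum of the two
    sphere radii and the particle's type is consumable by the cell's
    species.  Each individual is paired with at most its nearest contacting
    particle, ties broken by the lowest particle ID.  An encounter is a
    contact by a metabolically active cell, so dormant cells are excluded
    by default.  Returns ``(individual_id, particle_id)`` pairs; the result
    is exactly equivalent to a brute-force all-pairs scan.
    """
    if community.n == 0 or pool.n == 0:
        return []
    idx = np.where(community.active)[0] if active_only else np.arange(community.n)
    if idx.size == 0:
        return []
    cell_pos = community.pos[idx]
    cell_r = community.radii()[idx]
    part_r = pool.radii()
    consumable = traits.consumable[community.species[idx]][:, pool.rtype]  # (n_cells, n_parts)

    pairs: list[tuple[int, int]] = []
    if idx.size * pool.n <= 200_000:
        diff = cell_pos[:, None, :] - pool.pos[None, :, :]
        dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        contact = (dist <= cell_r[:, None] + part_r[None, :]) & consumable
        rows = np.where(contact.any(axis=1))[0]
        for r in rows:
            d = np.where(contact[r], dist[r], np.inf)
            j = int(np.argmin(d))  # first minimum = lowest ID (insertion order)
            pairs.append((int(community.ids[idx[r]]), int(pool.ids[j])))
        return pairs

    # large problems: KD-tree candidate pruning with identical contract
    tree = cKDTree(pool.pos)
    query_r = float(cell_r.max() + part_r.max())
    neighborhoods = tree.query_ball_point(cell_pos, query_r)
    for r, cand in enumerate(neighborhoods):
        if not cand:
            continue
        cand = np.sort(np.asarray(cand, dtype=np.int64))
        ok = consumable[r, cand]
        cand = cand[ok]
        if cand.size == 0:
            continue
        d = np.linalg.norm(pool.pos[cand] - cell_pos[r], axis=1)
        hit = d <= cell_r[r] + part_r[cand]
        if not hit.any():
            continue
        dh = np.where(hit, d, np.inf)
        j = int(cand[np.argmin(dh)])
        pairs.append((int(community.ids[idx[r]]), int(pool.ids[j])))
    return pairs


def apply_dispersal_cost(quota: float, distance: float, mode: Dispersal, c_d: float,
                         L: float, chemotaxis_multiplier: float = 2.0) -> float:
    """Energetic deduction for one movement: mult · c_d · (distance/L) · Q.

    Passive dispersal (and dormant cells) cost nothing; run-and-tumble has
    multiplier 1; chemotaxis, which requires sense perception, costs twice
    as much per distance travelled.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    mult = {Dispersal.PASSIVE: 0.0, Dispersal.RUN_TUMBLE: 1.0,
            Dispersal.CHEMOTAXIS: chemotaxis_multiplier}[mode]
    return mult * c_d * (distance / L) * max(quota, 0.0)


# ---------------------------------------------------------------------------
# process blocks


def _block_supply(state: ModelState) -> None:
    p = supply_step(
        state.rng, state.params, state.supplied_types,
        recalcitrant=state.regime.is_lock_and_key,
        next_id=state.particles.claim_id(), L=state.params.domain_length,
    )
    if p is not None:
        state.particles.add([p])
        state.tallies["supplied_particles"] += 1
        state.ledger["content_in_supply"] += p.content
    # note: the claimed ID is simply skipped on the non-supplying branch


def _block_immigration(state: ModelState) -> None:
    ind = immigrate(state.rng, state.params, state.traits, state.step_index,
                    L=state.params.domain_length)
    if ind is not None:
        state.community.add_arrays([ind.species], [ind.quota], [True],
                                   ind.position[None, :], ind.heading[None, :],
                                   [state.step_index])
        state.tallies["immigrations"] += 1
        state.ledger["quota_in_immigration"] += ind.quota


def _block_mixing(state: ModelState) -> None:
    L = state.params.domain_length
    comm, pool = state.community, state.particles
    if state.regime.mixing is Mixing.WELL_MIXED:
        if comm.n:
            comm.pos = relocate_well_mixed(state.rng, comm.n, L)
        if pool.n:
            pool.pos = relocate_well_mixed(state.rng, pool.n, L)
        return
    # structured: particles jiggle by Brownian motion; so do cells without
    # active dispersal (dormant cells always; all cells under passive mode)
    sigma = state.params.brownian_sigma
    if pool.n:
        pool.pos = reflect(pool.pos + state.rng.normal(0.0, 1.0, pool.pos.shape) * sigma, L)
    if comm.n:
        if state.regime.dispersal is Dispersal.PASSIVE:
            mask = np.ones(comm.n, dtype=bool)
        else:
            mask = ~comm.active
        k = int(mask.sum())
        if k:
            comm.pos[mask] = reflect(
                comm.pos[mask] + state.rng.normal(0.0, 1.0, (k, 3)) * sigma, L)


def _nearest_consumable_bulk(state: ModelState, idx: np.ndarray):
    """Vectorized nearest consumable particle for the individuals in ``idx``.

    Returns (target pool index or -1, centre distance) arrays.  Exact
    distance ties are resolved arbitrarily here (they occur with probability
    zero for continuous positions); the scalar API in ``space`` implements
    the lowest-ID tie-break and is the reference for constructed ties.
    """
    pool, traits, comm = state.particles, state.traits, state.community
    best_d = np.full(idx.size, np.inf)
    best_j = np.full(idx.size, -1, dtype=np.int64)
    species = comm.species[idx]
    for t in np.unique(pool.rtype):
        eaters = np.where(traits.consumable[species, t])[0]
        if eaters.size == 0:
            continue
        pj = np.where(pool.rtype == t)[0]
        if pj.size == 0:
            continue
        if pj.size <= 16 or eaters.size * pj.size <= 20_000:
            diff = comm.pos[idx[eaters]][:, None, :] - pool.pos[pj][None, :, :]
            dd = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
            jj = np.argmin(dd, axis=1)
            d = dd[np.arange(eaters.size), jj]
        else:
            tree = cKDTree(pool.pos[pj])
            d, jj = tree.query(comm.pos[idx[eaters]])
        better = d < best_d[eaters]
        best_d[eaters[better]] = d[better]
        best_j[eaters[better]] = pj[jj[better]]
    return best_j, best_d


def _block_dispersal(state: ModelState) -> None:
    mode = state.regime.dispersal
    if mode is Dispersal.PASSIVE:
        return
    comm, traits, params = state.community, state.traits, state.params
    idx = np.where(comm.active)[0]
    if idx.size == 0:
        return
    L = params.domain_length
    step_len = traits.dispersal_frac[comm.species[idx]] * L

    if mode is Dispersal.RUN_TUMBLE:
        new_pos, new_head = run_tumble_step(comm.pos[idx], comm.heading[idx],
                                            step_len, state.rng, L)
        comm.pos[idx] = new_pos
        comm.heading[idx] = new_head
        travelled = step_len
    else:  # chemotaxis
        target_j, dist = _nearest_consumable_bulk(state, idx)
        travelled = np.zeros(idx.size)
        have = target_j >= 0
        if have.any():
            hi = np.where(have)[0]
            pr = state.particles.radii()[target_j[hi]]
            cr = comm.radii()[idx[hi]]
            to_contact = np.maximum(dist[hi] - pr - cr, 0.0)
            travel = np.minimum(step_len[hi], to_contact)
            delta = state.particles.pos[target_j[hi]] - comm.pos[idx[hi]]
            norm = np.linalg.norm(delta, axis=1)
            nz = norm > 0
            move = np.zeros_like(delta)
            move[nz] = delta[nz] / norm[nz, None] * travel[nz, None]
            comm.pos[idx[hi]] += move
            travelled[hi] = travel
        if (~have).any():
            lo = np.where(~have)[0]
            new_pos, new_head = run_tumble_step(comm.pos[idx[lo]], comm.heading[idx[lo]],
                                                step_len[lo], state.rng, L)
            comm.pos[idx[lo]] = new_pos
            comm.heading[idx[lo]] = new_head
            travelled[lo] = step_len[lo]

    mult = 1.0 if mode is Dispersal.RUN_TUMBLE else params.chemotaxis_cost_multiplier
    cost = mult * params.dispersal_cost_coeff * (travelled / L) * np.clip(comm.quota[idx], 0.0, None)
    comm.quota[idx] -= cost
    state.ledger["quota_out_dispersal"] += float(np.sum(cost))


def _block_encounter(state: ModelState) -> None:
    comm, pool, traits, params = state.community, state.particles, state.traits, state.params
    pairs = detect_encounters(comm, traits, pool)
    state.tallies["encounters"] += len(pairs)
    if not pairs:
        return
    state.rng.shuffle(pairs)

    id_to_ind = {int(i): k for k, i in enumerate(comm.ids)}
    id_to_part = {int(i): k for k, i in enumerate(pool.ids)}
    removed: set[int] = set()
    removed_idx: list[int] = []
    children: list[ResourceParticle] = []
    crossfeed = state.regime.is_crossfeed
    structured = state.regime.mixing is Mixing.STRUCTURED
    kappa = params.mass_to_quota
    floor = params.content_floor

    for iid, pid in pairs:
        if pid in removed:
            continue  # the particle fragmented or vanished earlier this step
        i = id_to_ind[iid]
        j = id_to_part[pid]
        sp = int(comm.species[i])

        if pool.recalcitrant[j]:
            # lock-and-key: invest time and energy regardless of the outcome
            handling = params.growth_cost_coeff * max(float(comm.quota[i]), 0.0)
            comm.quota[i] -= handling
            state.ledger["quota_out_handling"] += handling
            state.tallies["breakdown_attempts"] += 1
            if state.rng.random() >= traits.lock_key_prob[pool.rtype[j]]:
                state.tallies["breakdown_failures"] += 1
                continue

        rate = float(traits.consumption_rate[sp])
        headroom = 1.0 - float(comm.quota[i])
        delta = min(rate * kappa * float(pool.content[j]), headroom)
        if delta <= 0.0:
            continue  # satiated: contact counts as an encounter, nothing moves
        comm.quota[i] += delta
        pool.content[j] -= delta / kappa
        state.ledger["quota_in_consumption"] += delta
        state.ledger["content_out_consumed"] += delta / kappa
        state.tallies["consumptions"] += 1

        if crossfeed and traits.metabolite_target[sp] >= 0:
            met = spawn_metabolite(comm.pos[i], delta, params.crossfeed_yield, kappa,
                                   floor, traits.metabolite_type(sp), pool.claim_id())
            if met is not None:
                children.append(met)
                state.ledger["content_in_metabolite"] += met.content

        remainder = float(pool.content[j])
        if remainder <= floor:
            state.ledger["content_out_floor"] += remainder
            removed.add(pid)
            removed_idx.append(j)
            continue
        # the remaining portion is randomly broken in two parts
        parent = pool.get(j)
        ids = (pool.claim_id(), pool.claim_id())
        c1, c2 = split_particle(parent, state.rng, structured=structured,
                                jitter=params.fragment_jitter, ids=ids,
                                L=params.domain_length)
        for child in (c1, c2):
            if child.content <= floor:
                state.ledger["content_out_floor"] += child.content
            else:
                children.append(child)
        removed.add(pid)
        removed_idx.append(j)

    pool.remove(removed_idx)
    pool.add(children)


def _block_reproduction(state: ModelState) -> None:
    comm, traits, params = state.community, state.traits, state.params
    idx = np.where(comm.active & (comm.quota > 0))[0]
    if idx.size == 0:
        return
    g = traits.growth_rate[comm.species[idx]]
    p = np.clip(g * comm.quota[idx], 0.0, 1.0)
    success = state.rng.random(idx.size) < p
    if not success.any():
        return
    si = idx[success]
    gs = g[success]
    cost = params.growth_cost_coeff * gs * comm.quota[si]
    half = (comm.quota[si] - cost) / 2.0
    comm.quota[si] = half
    state.ledger["quota_out_growth"] += float(np.sum(cost))
    k = si.size
    comm.add_arrays(comm.species[si], half, np.ones(k, dtype=bool),
                    comm.pos[si].copy(), random_unit_vectors(state.rng, k),
                    np.full(k, state.step_index, dtype=np.int64))
    state.tallies["births"] += k


def _block_maintenance(state: ModelState) -> None:
    comm, traits = state.community, state.traits
    if comm.n == 0:
        return
    m = traits.maintenance[comm.species]
    f = traits.maintenance_reduction[comm.species]
    ded = np.where(comm.active, m, m / f)
    comm.quota -= ded
    state.ledger["quota_out_maintenance"] += float(np.sum(ded))


def _block_death(state: ModelState) -> None:
    comm, traits, params = state.community, state.traits, state.params
    if comm.n == 0:
        return
    dead = comm.quota < traits.maintenance[comm.species]
    if not dead.any():
        return
    di = np.where(dead)[0]
    if state.regime.trophic is Trophic.SCAVENGING:
        necro = []
        for i in di:
            p = spawn_necromass(comm.pos[i], float(comm.quota[i]), params.necromass_value,
                                params.mass_to_quota, params.content_floor,
                                state.traits.necromass_type, state.particles.claim_id())
            if p is not None:
                necro.append(p)
                state.ledger["content_in_necromass"] += p.content
        state.particles.add(necro)
    state.ledger["quota_out_death"] += float(np.sum(comm.quota[di]))
    comm.remove(di)
    state.tallies["deaths"] += di.size


def _block_dormancy(state: ModelState) -> None:
    comm, traits, params = state.community, state.traits, state.params
    if comm.n == 0:
        return
    m = traits.maintenance[comm.species]
    rho = traits.resuscitation_prob[comm.species]
    was_active = comm.active.copy()
    go_dormant = was_active & (comm.quota <= params.dormancy_threshold_coeff * m)
    wake = (~was_active) & (state.rng.random(comm.n) < rho)
    comm.active[go_dormant] = False
    comm.active[wake] = True


_BLOCK_FUNCS = {
    "supply": _block_supply,
    "immigration": _block_immigration,
    "mixing": _block_mixing,
    "dispersal": _block_dispersal,
    "encounter": _block_encounter,
    "reproduction": _block_reproduction,
    "maintenance": _block_maintenance,
    "death": _block_death,
    "dormancy": _block_dormancy,
}


def _enforce_particle_cap(state: ModelState) -> None:
    pool, cap = state.particles, state.params.max_particles
    if pool.n <= cap:
        return
    order = np.argsort(pool.content, kind="stable")
    drop = order[: pool.n - cap]
    state.ledger["content_out_cap"] += float(np.sum(pool.content[drop]))
    pool.remove(drop)


def step(state: ModelState) -> ModelState:
    """Advance the model by one time step (1200 simulated seconds).

    The process blocks run in a freshly shuffled order; within blocks,
    individuals are treated in random or order-independent fashion (the
    consumption loop shuffles its contact pairs; purely per-individual
    updates commute).  Raises ``RuntimeError`` if an internal invariant
    (positive particle content, finite quotas) is violated.
    """
    order = state.rng.permutation(len(PROCESS_BLOCKS))
    names = tuple(PROCESS_BLOCKS[i] for i in order)
    for name in names:
        _BLOCK_FUNCS[name](state)
    _enforce_particle_cap(state)
    state.last_block_order = names
    state.step_index += 1

    if state.particles.n and not np.all(state.particles.content > 0):
        raise RuntimeError("internal consistency failure: non-positive particle content")
    if state.community.n and not np.all(np.isfinite(state.community.quota)):
        raise RuntimeError("internal consistency failure: non-finite cell quota")
    return state


def ledger_imbalance(state: ModelState) -> tuple[float, float]:
    """Absolute quota- and content-ledger imbalances (should be ≈ 0).

    quota:   Σ Q  =  init + immigration + consumption − maintenance − growth
                     − dispersal − handling − death
    content: Σ c  =  supply + necromass + metabolite − consumed − floor − cap
    """
    led = state.ledger
    expected_quota = (led["quota_in_init"] + led["quota_in_immigration"]
                      + led["quota_in_consumption"] - led["quota_out_maintenance"]
                      - led["quota_out_growth"] - led["quota_out_dispersal"]
                      - led["quota_out_handling"] - led["quota_out_death"])
    expected_content = (led["content_in_supply"] + led["content_in_necromass"]
                        + led["content_in_metabolite"] - led["content_out_consumed"]
                        - led["content_out_floor"] - led["content_out_cap"])
    return (abs(state.community.total_quota - expected_quota),
            abs(state.particles.total_content - expected_content))
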