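"""Individual cells and their physiology.

A cell's state is its species, its relative quota Q ∈ (0, 1] (endogenous
resource as a fraction of the species maximum), an activity flag (active or
dormant), a 3-D position and a movement heading.  Quota buys everything:
maintenance each step, the cost of growth at fission, the cost of active
dispersal, and the handling cost of recalcitrant resources.  Cells die when
their quota falls below their species' maintenance cost, go dormant when
energetically depleted, and resuscitate at random.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .params import (
    DOMAIN_LENGTH_UM,
    QUOTA_MAX_DIAMETER_UM,
    ModelParams,
    SpeciesTraits,
)
from .space import random_unit_vectors


@dataclass
class Individual:
    """One cell."""

    id: int
    species: int
    quota: float              # relative cell quota in (0, 1]
    active: bool
    position: np.ndarray      # (3,) μm
    heading: np.ndarray       # unit 3-vector
    birth_step: int = 0

    @property
    def diameter(self) -> float:
        return float(diameter_from_quota(self.quota))

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


def diameter_from_quota(quota):
    """Cell diameter (μm) from relative quota.

    Quota is proportional to cell volume, so d = 1.25 · Q^(1/3) μm: a full
    quota gives the 1.25 μm maximum and the immigrant range [0.5, 1.0] maps
    to diameters of about 1 to 1.25 μm.
    """
    arr = np.asarray(quota, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("quota must be > 0")
    d = QUOTA_MAX_DIAMETER_UM * np.cbrt(arr)
    if np.isscalar(quota) or arr.ndim == 0:
        return float(d)
    return d


def sample_logseries_species(rng: np.random.Generator, alpha: float, n_species: int,
                             size: int) -> np.ndarray:
    """Species indices drawn from a log-series(α) truncated to the pool size.

    The log-series assigns species k (1-based) probability ∝ α^k / k, the
    classic metacommunity abundance model; draws beyond the pool are
    rejected and redrawn.
    """
    out = np.empty(size, dtype=np.int64)
    filled = 0
    while filled < size:
        draws = stats.logser.rvs(alpha, size=size - filled, random_state=rng)
        draws = np.atleast_1d(draws)
        ok = draws <= n_species
        k = int(ok.sum())
        out[filled:filled + k] = draws[ok] - 1  # to 0-based species indices
        filled += k
    return out


class Community:
    """Array-backed collection of individuals with unique, increasing IDs."""

    __slots__ = ("ids", "species", "quota", "active", "pos", "heading", "birth_step", "next_id")

    def __init__(self):
        self.ids = np.empty(0, dtype=np.int64)
        self.species = np.empty(0, dtype=np.int64)
        self.quota = np.empty(0, dtype=float)
        self.active = np.empty(0, dtype=bool)
        self.pos = np.empty((0, 3), dtype=float)
        self.heading = np.empty((0, 3), dtype=float)
        self.birth_step = np.empty(0, dtype=np.int64)
        self.next_id = 0

    @property
    def n(self) -> int:
        return int(self.ids.shape[0])

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    @property
    def total_quota(self) -> float:
        return float(self.quota.sum())

    def radii(self) -> np.ndarray:
        if self.n == 0:
            return np.empty(0)
        return QUOTA_MAX_DIAMETER_UM * np.cbrt(np.clip(self.quota, 0.0, None)) / 2.0

    def claim_id(self) -> int:
        iid = self.next_id
        self.next_id += 1
        return iid

    def add_arrays(self, species, quota, active, pos, heading, birth_step) -> np.ndarray:
        """Append a batch of individuals; returns the new IDs."""
        k = len(species)
        new_ids = np.arange(self.next_id, self.next_id + k, dtype=np.int64)
        self.next_id += k
        self.ids = np.concatenate([self.ids, new_ids])
        self.species = np.concatenate([self.species, np.asarray(species, dtype=np.int64)])
        self.quota = np.concatenate([self.quota, np.asarray(quota, dtype=float)])
        self.active = np.concatenate([self.active, np.asarray(active, dtype=bool)])
        self.pos = np.concatenate([self.pos, np.asarray(pos, dtype=float).reshape(k, 3)])
        self.heading = np.concatenate([self.heading, np.asarray(heading, dtype=float).reshape(k, 3)])
        self.birth_step = np.concatenate([self.birth_step, np.asarray(birth_step, dtype=np.int64)])
        return new_ids

    def remove(self, indices) -> None:
        if len(indices) == 0:
            return
        keep = np.ones(self.n, dtype=bool)
        keep[np.asarray(indices, dtype=np.int64)] = False
        self.ids = self.ids[keep]
        self.species = self.species[keep]
        self.quota = self.quota[keep]
        self.active = self.active[keep]
        self.pos = self.pos[keep]
        self.heading = self.heading[keep]
        self.birth_step = self.birth_step[keep]

    def get(self, index: int) -> Individual:
        return Individual(
            id=int(self.ids[index]), species=int(self.species[index]),
            quota=float(self.quota[index]), active=bool(self.active[index]),
            position=self.pos[index].copy(), heading=self.heading[index].copy(),
            birth_step=int(self.birth_step[index]),
        )

    def as_list(self) -> list[Individual]:
        return [self.get(i) for i in range(self.n)]


def initialize_community(params: ModelParams, traits: SpeciesTraits,
                         rng: np.random.Generator, n_individuals: int = 100,
                         L: float = DOMAIN_LENGTH_UM) -> Community:
    """Found a community of (by default) 100 active individuals.

    Species identities come from a log-series(α) truncated to the species
    pool; quotas are uniform in [0.5, 1.0] (the immigrant range); positions
    are uniform in the domain.
    """
    comm = Community()
    species = sample_logseries_species(rng, params.logseries_alpha, traits.n_species,
                                       n_individuals)
    quota = rng.uniform(0.5, 1.0, size=n_individuals)
    pos = rng.uniform(0.0, L, size=(n_individuals, 3))
    heading = random_unit_vectors(rng, n_individuals)
    comm.add_arrays(species, quota, np.ones(n_individuals, dtype=bool), pos, heading,
                    np.zeros(n_individuals, dtype=np.int64))
    return comm


def immigrate(rng: np.random.Generator, params: ModelParams, traits: SpeciesTraits,
              step: int, L: float = DOMAIN_LENGTH_UM) -> Optional[Individual]:
    """With probability ``immigration_rate``, one propagule enters.

    Immigrant species are uniform over the pool (unlike the log-series
    founders), the quota uniform in [0.5, 1.0], the position uniform
    anywhere in the domain.  The caller assigns the unique ID.
    """
    if rng.random() >= params.immigration_rate:
        return None
    return Individual(
        id=-1,  # assigned by the community on insertion
        species=int(rng.integers(traits.n_species)),
        quota=float(rng.uniform(0.5, 1.0)),
        active=True,
        position=rng.uniform(0.0, L, size=3),
        heading=random_unit_vectors(rng),
        birth_step=step,
    )


def consume(individual: Individual, particle, kappa: float, rate: float = 1.0) -> float:
    """Transfer resource from a contacted particle into the cell quota.

    The quota gain is δ = min(rate · κ · content, 1 − Q): the bite is capped
    both by the particle's content (scaled by the species consumption rate)
    and by quota headroom (satiation).  The particle loses exactly δ/κ mass
    units, so κ·Δcontent = δ and the exchange conserves energy.  Dormant
    individuals do not consume (δ = 0, particle untouched).  The caller is
    responsible for splitting or discarding the remainder.
    """
    if not individual.active:
        return 0.0
    headroom = 1.0 - individual.quota
    delta = min(rate * kappa * particle.content, headroom)
    if delta <= 0.0:
        return 0.0
    individual.quota += delta
    particle.content -= delta / kappa
    return delta


def reproduce(individual: Individual, growth_rate: float, c_g: float,
              rng: np.random.Generator, daughter_id: int,
              step: int) -> Optional[Individual]:
    """Clonal binary fission without mutation.

    Reproduction succeeds with probability p = g_s · Q (the quota ratio
    scaled by the species growth rate, so p ∈ [0, 1]).  On success a growth
    cost c_g·g_s·Q is paid — larger cells pay more to double — and the
    remaining quota is halved between mother and daughter.  The daughter
    inherits the mother's species and coordinates.
    """
    if not individual.active:
        return None
    p = max(growth_rate * individual.quota, 0.0)
    if rng.random() >= p:
        return None
    remaining = individual.quota - c_g * growth_rate * individual.quota
    half = remaining / 2.0
    individual.quota = half
    return Individual(
        id=daughter_id, species=individual.species, quota=half, active=True,
        position=individual.position.copy(),
        heading=random_unit_vectors(rng),
        birth_step=step,
    )


def maintenance_step(individual: Individual, maintenance: float,
                     maintenance_reduction: float) -> None:
    """Deduct basal metabolic cost: m_s while active, m_s/f_s while dormant."""
    if individual.active:
        individual.quota -= maintenance
    else:
        individual.quota -= maintenance / maintenance_reduction


def check_death(individual: Individual, maintenance: float) -> bool:
    """Alive iff Q >= m_s (strict inequality kills), in any activity state."""
    return not individual.quota < maintenance


def dormancy_transition(individual: Individual, maintenance: float, theta_d: float,
                        resuscitation_prob: float, rng: np.random.Generator) -> None:
    """Energetic-depletion dormancy entry and stochastic resuscitation.

    Active cells go dormant deterministically once Q ≤ θ_d·m_s; dormant
    cells resuscitate with per-step probability ρ_s.
    """
    if individual.active:
        if individual.quota <= theta_d * maintenance:
            individual.active = False
    else:
        if rng.random() < resuscitation_prob:
            individual.active = True
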