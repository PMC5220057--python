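"""Resource particles: supply, geometry, fragmentation and by-products.

Particles carry a scalar resource ``content`` in mass units; their physical
diameter follows from content by sphere-volume scaling anchored at
4000 μm for content 1000 (so the supplied range 1000-10,000 spans diameters
4000-8600 μm).  Consumption bites content off a particle and splits the
remainder randomly in two, which is the only fragmentation process; crumbs
below a configurable content floor are lost from the system.  Scavenging
and cross-feeding produce necromass and metabolite particles as labile
by-products.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import DOMAIN_LENGTH_UM, REF_CONTENT, REF_DIAMETER_UM, ModelParams
from .space import reflect

ORIGIN_SUPPLIED = 0
ORIGIN_FRAGMENT = 1
ORIGIN_NECROMASS = 2
ORIGIN_METABOLITE = 3


@dataclass
class ResourceParticle:
    """One resource particle."""

    id: int
    rtype: int
    content: float            # mass units, > 0
    position: np.ndarray      # (3,) μm
    recalcitrant: bool = False
    origin: int = ORIGIN_SUPPLIED

    @property
    def diameter(self) -> float:
        return float(diameter_from_content(self.content))

    @property
    def radius(self) -> float:
        return float(radius_from_content(self.content))


def diameter_from_content(content):
    """Particle diameter (μm) from resource content (mass units).

    d = 4000 · (content / 1000)^(1/3); strictly increasing, so content 8000
    doubles the diameter of content 1000 and content 10,000 gives ≈ 8617.7 μm.
    """
    arr = np.asarray(content, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("particle content must be > 0")
    d = REF_DIAMETER_UM * np.cbrt(arr / REF_CONTENT)
    if np.isscalar(content) or arr.ndim == 0:
        return float(d)
    return d


def radius_from_content(content):
    d = diameter_from_content(content)
    return d / 2.0 if np.isscalar(d) else d / 2.0


def supply_step(rng: np.random.Generator, params: ModelParams, supplied_types,
                recalcitrant: bool, next_id: int,
                L: float = DOMAIN_LENGTH_UM) -> Optional[ResourceParticle]:
    """With probability ``params.supply_rate``, create one entering particle.

    The type is uniform over the regime's supplied types, the content uniform
    in [content_min, content_max], the position uniform in the domain; the
    recalcitrant flag marks lock-and-key models.  Returns None on the
    non-supplying branch.
    """
    if rng.random() >= params.supply_rate:
        return None
    supplied_types = list(supplied_types)
    rtype = int(supplied_types[rng.integers(len(supplied_types))])
    content = float(rng.uniform(params.content_min, params.content_max))
    position = rng.uniform(0.0, L, size=3)
    return ResourceParticle(
        id=next_id, rtype=rtype, content=content, position=position,
        recalcitrant=recalcitrant, origin=ORIGIN_SUPPLIED,
    )


def split_particle(particle: ResourceParticle, rng: np.random.Generator,
                   structured: bool, jitter: float, ids: tuple[int, int],
                   L: float = DOMAIN_LENGTH_UM) -> tuple[ResourceParticle, ResourceParticle]:
    """Randomly break a particle in two parts that conserve content exactly.

    A uniform fraction u splits the content into u·c and (1-u)·c.  Children
    inherit the type and recalcitrance of the parent.  In structured
    environments both children land within ``jitter`` of the parent per axis
    (fragments aggregate); in well-mixed environments the placement is moot
    because every position is re-randomized at the next mixing update, so the
    children simply keep the parent position.
    """
    u = float(rng.uniform())
    first = u * particle.content
    contents = (first, particle.content - first)  # conserves content exactly
    children = []
    for pid, c in zip(ids, contents):
        if structured:
            pos = reflect(particle.position + rng.uniform(-jitter, jitter, size=3), L)
        else:
            pos = particle.position.copy()
        children.append(
            ResourceParticle(
                id=pid, rtype=particle.rtype, content=c, position=pos,
                recalcitrant=particle.recalcitrant, origin=ORIGIN_FRAGMENT,
            )
        )
    return children[0], children[1]


def attempt_breakdown(rng: np.random.Generator, recalcitrant: bool,
                      lock_key_prob: float) -> bool:
    """Whether an individual in contact succeeds in breaking down a particle.

    Labile particles are assimilated immediately (always succeeds, no cost).
    Recalcitrant lock-and-key particles succeed with their type's breakdown
    probability; the handling cost is charged by the engine regardless of
    the outcome.
    """
    if not recalcitrant:
        return True
    return bool(rng.random() < lock_key_prob)


def spawn_necromass(position: np.ndarray, quota_dead: float, nu: float, kappa: float,
                    content_floor: float, necromass_type: int,
                    next_id: int) -> Optional[ResourceParticle]:
    """Labile necromass particle left by a dead cell under scavenging.

    The nutritional worth ν (1-100) is read as a percent yield of the dead
    cell's quota, so content = (ν/100)·Q_dead/κ; nothing is created below
    the content floor.  Outside scavenging regimes dead cells are simply
    lost and this function is never invoked.
    """
    content = (nu / 100.0) * max(quota_dead, 0.0) / kappa
    if content <= content_floor:
        return None
    return ResourceParticle(
        id=next_id, rtype=necromass_type, content=content,
        position=np.asarray(position, dtype=float).copy(),
        recalcitrant=False, origin=ORIGIN_NECROMASS,
    )


def spawn_metabolite(position: np.ndarray, delta_consumed: float, beta: float,
                     kappa: float, content_floor: float, metabolite_type: int,
                     next_id: int) -> Optional[ResourceParticle]:
    """Labile metabolite by-product of a consumption event (cross-feeding).

    content = β · δ_consumed / κ at the producer's position; None below the
    content floor (or for β = 0).
    """
    content = beta * delta_consumed / kappa
    if content <= content_floor:
        return None
    return ResourceParticle(
        id=next_id, rtype=metabolite_type, content=content,
        position=np.asarray(position, dtype=float).copy(),
        recalcitrant=False, origin=ORIGIN_METABOLITE,
    )


class ParticlePool:
    """Array-backed collection of resource particles.

    Columns are kept in insertion order with strictly increasing IDs, so the
    first index found by an argmin over distances is also the lowest-ID
    tie-break required of encounter detection.
    """

    __slots__ = ("ids", "rtype", "content", "pos", "recalcitrant", "origin", "next_id")

    def __init__(self):
        self.ids = np.empty(0, dtype=np.int64)
        self.rtype = np.empty(0, dtype=np.int64)
        self.content = np.empty(0, dtype=float)
        self.pos = np.empty((0, 3), dtype=float)
        self.recalcitrant = np.empty(0, dtype=bool)
        self.origin = np.empty(0, dtype=np.int64)
        self.next_id = 0

    @property
    def n(self) -> int:
        return int(self.ids.shape[0])

    @property
    def total_content(self) -> float:
        return float(self.content.sum())

    def radii(self) -> np.ndarray:
        if self.n == 0:
            return np.empty(0)
        return REF_DIAMETER_UM * np.cbrt(self.content / REF_CONTENT) / 2.0

    def claim_id(self) -> int:
        pid = self.next_id
        self.next_id += 1
        return pid

    def add(self, particles) -> None:
        """Append particle dataclasses (IDs must already be claimed/increasing)."""
        particles = list(particles)
        if not particles:
            return
        self.ids = np.concatenate([self.ids, [p.id for p in particles]])
        self.rtype = np.concatenate([self.rtype, [p.rtype for p in particles]])
        self.content = np.concatenate([self.content, [p.content for p in particles]])
        self.pos = np.concatenate([self.pos, np.array([p.position for p in particles], dtype=float)])
        self.recalcitrant = np.concatenate([self.recalcitrant, [p.recalcitrant for p in particles]])
        self.origin = np.concatenate([self.origin, [p.origin for p in particles]])

    def remove(self, indices) -> None:
        if len(indices) == 0:
            return
        keep = np.ones(self.n, dtype=bool)
        keep[np.asarray(indices, dtype=np.int64)] = False
        self.ids = self.ids[keep]
        self.rtype = self.rtype[keep]
        self.content = self.content[keep]
        self.pos = self.pos[keep]
        self.recalcitrant = self.recalcitrant[keep]
        self.origin = self.origin[keep]

    def get(self, index: int) -> ResourceParticle:
        return ResourceParticle(
            id=int(self.ids[index]), rtype=int(self.rtype[index]),
            content=float(self.content[index]), position=self.pos[index].copy(),
            recalcitrant=bool(self.recalcitrant[index]), origin=int(self.origin[index]),
        )

    def as_list(self) -> list[ResourceParticle]:
        return [self.get(i) for i in range(self.n)]
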