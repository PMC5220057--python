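"""Domain geometry and dispersal kinematics.

The habitat is a cube of side L = 43,200 μm with reflecting boundaries
(individuals "hit the edge and turn"; a periodic wrap would make edges
undetectable).  Three movement primitives cover the dispersal modes:
uniform relocation (well-mixed environments), Brownian steps (structured
environments and passive entities), and straight-line motion for
run-and-tumble and chemotaxis.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

from .params import DOMAIN_LENGTH_UM


def reflect(coordinate, L: float = DOMAIN_LENGTH_UM):
    """Mirror-reflect a coordinate (scalar or array) into [0, L].

    Reflection is applied about whichever boundary is violated, repeatedly
    if the excursion exceeds L, via the standard triangle-wave fold with
    period 2L.  Non-finite inputs are rejected.
    """
    arr = np.asarray(coordinate, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("coordinates must be finite")
    folded = np.mod(arr, 2.0 * L)
    folded = np.where(folded > L, 2.0 * L - folded, folded)
    if np.isscalar(coordinate) or arr.ndim == 0:
        return float(folded)
    return folded


def random_unit_vectors(rng: np.random.Generator, n: Optional[int] = None) -> np.ndarray:
    """Isotropic random 3-D unit vector(s): one (3,) vector if n is None."""
    size = (3,) if n is None else (n, 3)
    v = rng.normal(size=size)
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    # a zero draw has probability zero; guard anyway
    norm = np.where(norm == 0, 1.0, norm)
    return v / norm


def relocate_well_mixed(rng: np.random.Generator, n: int, L: float = DOMAIN_LENGTH_UM) -> np.ndarray:
    """Uniform independent positions in [0, L]^3 for n entities.

    Applied to every organism and resource particle each step under
    well-mixed conditions, making successive positions uncorrelated.
    """
    return rng.uniform(0.0, L, size=(n, 3))


def brownian_step(pos: np.ndarray, sigma: float, rng: np.random.Generator,
                  L: float = DOMAIN_LENGTH_UM) -> np.ndarray:
    """Displace position(s) by zero-mean Gaussian noise of SD ``sigma`` per
    axis, then reflect into the domain.  ``sigma`` = 0 leaves positions
    unchanged (the rng is still advanced for reproducibility of call
    sequences)."""
    if sigma < 0:
        raise ValueError(f"brownian sigma must be >= 0, got {sigma}")
    pos = np.asarray(pos, dtype=float)
    noise = rng.normal(0.0, 1.0, size=pos.shape) * sigma
    return reflect(pos + noise, L)


def run_tumble_step(pos: np.ndarray, heading: np.ndarray, step_length,
                    rng: np.random.Generator, L: float = DOMAIN_LENGTH_UM):
    """Advance along the current heading; tumble on boundary contact.

    Straight-line motion by ``step_length`` along ``heading``.  Rows whose
    raw trajectory leaves the domain are mirror-reflected back inside and
    receive a fresh uniform random heading ("turned and moved in a new,
    randomly chosen direction").  Interior moves keep their heading, so the
    walk is ballistic between wall contacts.

    Accepts a single position (shape (3,)) or a batch (n, 3); returns
    ``(new_pos, new_heading)`` of matching shape.
    """
    pos = np.asarray(pos, dtype=float)
    heading = np.asarray(heading, dtype=float)
    single = pos.ndim == 1
    p = pos[None, :] if single else pos
    h = heading[None, :] if single else heading
    step = np.broadcast_to(np.asarray(step_length, dtype=float), (p.shape[0],))

    raw = p + h * step[:, None]
    hit = np.any((raw < 0.0) | (raw > L), axis=1)
    new_pos = reflect(raw, L)
    new_heading = h.copy()
    n_hit = int(hit.sum())
    if n_hit:
        new_heading[hit] = random_unit_vectors(rng, n_hit)
    if single:
        return new_pos[0], new_heading[0]
    return new_pos, new_heading


def chemotaxis_move(pos: np.ndarray, target_pos: np.ndarray, target_radius: float,
                    step_length: float, cell_radius: float = 0.0) -> tuple[np.ndarray, float]:
    """Move straight toward a target particle centre, stopping at contact.

    Travels ``min(step_length, distance_to_contact)`` where the distance to
    contact is the centre separation minus the two radii (never negative).
    Returns the new position and the distance actually travelled (used for
    the energetic cost of directed movement).
    """
    pos = np.asarray(pos, dtype=float)
    target_pos = np.asarray(target_pos, dtype=float)
    delta = target_pos - pos
    dist = float(np.linalg.norm(delta))
    if dist == 0.0:
        return pos.copy(), 0.0
    to_contact = max(dist - target_radius - cell_radius, 0.0)
    travel = min(float(step_length), to_contact)
    return pos + delta / dist * travel, travel


def nearest_consumable(pos: np.ndarray, particles: Iterable, consumable_types) -> Optional[int]:
    """ID of the nearest particle whose type the individual can consume.

    Linear scan over ``particles`` (objects with ``id``, ``rtype`` and
    ``position`` attributes); ties in centre distance are broken by the
    lowest particle ID.  Returns None when no consumable particle exists.
    """
    pos = np.asarray(pos, dtype=float)
    types = set(consumable_types)
    best_id: Optional[int] = None
    best_key: Optional[tuple[float, int]] = None
    for part in particles:
        if part.rtype not in types:
            continue
        d = float(np.linalg.norm(np.asarray(part.position, dtype=float) - pos))
        key = (d, int(part.id))
        if best_key is None or key < best_key:
            best_key = key
            best_id = int(part.id)
    return best_id


def chemotaxis_step(pos, heading, particles, consumable_types, step_length,
                    rng: np.random.Generator, L: float = DOMAIN_LENGTH_UM,
                    cell_radius: float = 0.0):
    """Chemotactic movement with run-and-tumble fallback.

    Senses the nearest consumable particle (unlimited sensing range; the
    energetic penalty is the offsetting cost) and moves straight toward its
    centre.  With no consumable particle present this behaves exactly like
    :func:`run_tumble_step` under the same rng state.

    Returns ``(new_pos, new_heading, distance_moved)``.
    """
    particles = list(particles)
    target_id = nearest_consumable(pos, particles, consumable_types)
    if target_id is None:
        new_pos, new_heading = run_tumble_step(pos, heading, step_length, rng, L)
        return new_pos, new_heading, float(step_length)
    target = next(p for p in particles if p.id == target_id)
    from .resources import radius_from_content  # local import avoids a cycle

    new_pos, travel = chemotaxis_move(
        pos, target.position, radius_from_content(target.content), step_length, cell_radius
    )
    return new_pos, np.asarray(heading, dtype=float).copy(), travel
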