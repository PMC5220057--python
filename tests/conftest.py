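"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import seedbanksim as sbs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_state(seed=7, regime="consumer_resource,monoculture_labile,run_tumble,well_mixed",
               **param_overrides):
    """Small fully-sampled model state for engine-level tests."""
    params, traits, reg, gen = sbs.build_model(seed, regime=regime,
                                               param_overrides=param_overrides or None)
    return sbs.init_state(params, traits, reg, gen)


def brute_force_encounters(community, traits, pool, active_only=True):
    """All-pairs reference for encounter detection.

    Scans every (cell, particle) pair, keeps consumable contacts, and pairs
    each cell with its nearest contacting particle (lowest particle ID on
    ties).  Intentionally independent of the engine implementation.
    """
    pairs = []
    cells = community.as_list()
    parts = pool.as_list()
    for ind in cells:
        if active_only and not ind.active:
            continue
        best = None  # (distance, particle_id)
        r_cell = 1.25 * max(ind.quota, 0.0) ** (1.0 / 3.0) / 2.0
        for part in parts:
            if not traits.consumable[ind.species, part.rtype]:
                continue
            d = float(np.linalg.norm(ind.position - part.position))
            r_part = 4000.0 * (part.content / 1000.0) ** (1.0 / 3.0) / 2.0
            if d <= r_cell + r_part:
                key = (d, part.id)
                if best is None or key < best:
                    best = key
        if best is not None:
            pairs.append((ind.id, best[1]))
    return pairs
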