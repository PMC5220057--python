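"""Model parameters and species traits.

Environment-level constants and ranges follow the published parameter table;
species-level vital rates are drawn uniformly within their printed ranges.
A handful of closure constants (marked "not printed" below) are required to
make the model concrete; their defaults are documented in ``docs/methods.md``
and all are configurable.

Units
-----
Lengths are micrometres (μm), time is one model step (1200 simulated
seconds, the minimum doubling time), cell quota is a fraction of the species
maximum in (0, 1], and resource content is in the dimensionless "mass units"
of the supplied particle sizes (1000-10,000 at entry).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .regimes import ComplexityRegime, ResourceComplexity, Trophic

# ---------------------------------------------------------------------------
# space-time equivalency: the fastest cells swim 36 μm/s and nothing doubles
# faster than once per 1200 s, so one step of maximal dispersal spans the
# whole domain side.
MAX_DISPERSAL_UM_PER_S = 36.0
SECONDS_PER_STEP = 1200.0
DOMAIN_LENGTH_UM = MAX_DISPERSAL_UM_PER_S * SECONDS_PER_STEP  # 43,200 μm

# particle geometry anchor: content 1000 maps to a 4000 μm diameter and
# volume scales linearly with content (cube-root diameter scaling).
REF_CONTENT = 1000.0
REF_DIAMETER_UM = 4000.0

# cell geometry anchor: a full quota (1.0) maps to a 1.25 μm diameter.
QUOTA_MAX_DIAMETER_UM = 1.25

CHEMOTAXIS_COST_MULTIPLIER = 2.0  # "twice as energetically costly"

#: Uniform sampling ranges for the randomized parameterization.
PARAM_RANGES: dict[str, tuple[float, float]] = {
    "supply_rate": (0.1, 1.0),
    "resource_diversity": (1, 10),
    "necromass_value": (1.0, 100.0),
    "immigration_rate": (0.01, 0.1),
    "logseries_alpha": (0.95, 0.99),
}

TRAIT_RANGES: dict[str, tuple[float, float]] = {
    "maintenance": (0.001, 0.01),
    "dispersal_frac": (0.01, 1.0),
    "growth_rate": (0.1, 1.0),
    "resuscitation_prob": (0.001, 0.01),
    "maintenance_reduction": (10.0, 100.0),
    "consumption_rate": (0.1, 1.0),
    "lock_key_prob": (0.01, 1.0),
}


def ensure_rng(seed) -> np.random.Generator:
    """Accept an int seed, a Generator, or None and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class ModelParams:
    """All environment-level constants of one model realization.

    The first block is sampled per model; the second block holds fixed
    physical constants; the third holds closure constants that the source
    material leaves unspecified (defaults chosen once, see methods note).
    """

    # --- sampled per model -------------------------------------------------
    supply_rate: float = 0.5            # P(resource particle enters) per step
    resource_diversity: int = 3         # number of resource types in the pool
    necromass_value: float = 50.0       # nutritional worth of necromass, % of quota
    immigration_rate: float = 0.05      # P(individual enters) per step
    logseries_alpha: float = 0.97       # log-series parameter for initial SAD

    # --- fixed physical constants -----------------------------------------
    content_min: float = 1000.0         # supplied particle content, mass units
    content_max: float = 10000.0
    domain_length: float = DOMAIN_LENGTH_UM
    seconds_per_step: float = SECONDS_PER_STEP
    species_pool_size: int = 100
    quota_max_diameter: float = QUOTA_MAX_DIAMETER_UM
    chemotaxis_cost_multiplier: float = CHEMOTAXIS_COST_MULTIPLIER

    # --- closure constants (not printed in the source material) -----------
    mass_to_quota: float = 0.001        # κ: quota units gained per mass unit
    growth_cost_coeff: float = 0.1      # c_g: growth cost = c_g·g_s·Q at fission
    dispersal_cost_coeff: float = 0.01  # c_d: cost = mult·c_d·(dist/L)·Q
    crossfeed_yield: float = 0.1        # β: metabolite mass per mass consumed
    dormancy_threshold_coeff: float = 50.0  # θ_d: dormant when Q ≤ θ_d·m_s
    brownian_sigma: float = 10.0        # σ_B: per-axis Brownian SD, μm/step
    fragment_jitter: float = 100.0      # ε: fragment placement jitter, μm
    content_floor: float = 1e-3         # crumbs below this content are lost
    max_particles: int = 10000          # particle-count cap (remove smallest)

    rng_seed: Optional[int] = None

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


def sample_params(seed) -> ModelParams:
    """Draw one randomized environment-level parameterization.

    Every ranged field is uniform within its printed range; the same seed
    always yields the identical :class:`ModelParams`.
    """
    rng = ensure_rng(seed)
    lo, hi = PARAM_RANGES["resource_diversity"]
    return ModelParams(
        supply_rate=rng.uniform(*PARAM_RANGES["supply_rate"]),
        resource_diversity=int(rng.integers(int(lo), int(hi) + 1)),
        necromass_value=rng.uniform(*PARAM_RANGES["necromass_value"]),
        immigration_rate=rng.uniform(*PARAM_RANGES["immigration_rate"]),
        logseries_alpha=rng.uniform(*PARAM_RANGES["logseries_alpha"]),
        rng_seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


@dataclass
class SpeciesTraits:
    """Per-species vital rates and resource-use structure for S species.

    Resource types are small integers.  Types ``0 .. n_supplied-1`` are the
    externally supplied types; type ``n_supplied`` is the universal necromass
    type (relevant under scavenging); type ``n_supplied + 1 + s`` is the
    metabolite produced by species ``s`` (relevant under cross-feeding).
    ``consumable[s, t]`` says whether species ``s`` can consume type ``t``.
    """

    maintenance: np.ndarray           # m_s, quota units per step
    dispersal_frac: np.ndarray        # δ_s, fraction of L per step
    growth_rate: np.ndarray           # g_s, probability scale
    resuscitation_prob: np.ndarray    # ρ_s, per step
    maintenance_reduction: np.ndarray  # f_s ≥ 1, divisor while dormant
    consumption_rate: np.ndarray      # r_s, fraction of the maximal bite
    consumable: np.ndarray            # (S, n_types) bool
    metabolite_target: np.ndarray     # (S,) species index fed by s, or -1
    n_supplied: int                   # number of externally supplied types
    lock_base: Optional[str]          # "mono"/"poly" under lock-and-key, else None
    lock_key_prob: np.ndarray         # (n_supplied,) breakdown probability

    @property
    def n_species(self) -> int:
        return int(self.maintenance.shape[0])

    @property
    def n_types(self) -> int:
        return int(self.consumable.shape[1])

    @property
    def necromass_type(self) -> int:
        return self.n_supplied

    def metabolite_type(self, species: int) -> int:
        return self.n_supplied + 1 + int(species)

    def copy(self) -> "SpeciesTraits":
        return SpeciesTraits(
            maintenance=self.maintenance.copy(),
            dispersal_frac=self.dispersal_frac.copy(),
            growth_rate=self.growth_rate.copy(),
            resuscitation_prob=self.resuscitation_prob.copy(),
            maintenance_reduction=self.maintenance_reduction.copy(),
            consumption_rate=self.consumption_rate.copy(),
            consumable=self.consumable.copy(),
            metabolite_target=self.metabolite_target.copy(),
            n_supplied=self.n_supplied,
            lock_base=self.lock_base,
            lock_key_prob=self.lock_key_prob.copy(),
        )


def _crossfeed_targets(rng: np.random.Generator, S: int, mutual: bool) -> np.ndarray:
    """Assign each species the species its metabolite feeds.

    One-way cross-feeding avoids reciprocal pairs where possible; two-way
    cross-feeding builds a random matching of mutual pairs (an odd species
    out receives a one-way target).
    """
    target = np.full(S, -1, dtype=np.int64)
    if S == 1:
        return target
    if mutual:
        perm = rng.permutation(S)
        for k in range(0, S - 1, 2):
            a, b = int(perm[k]), int(perm[k + 1])
            target[a], target[b] = b, a
        if S % 2 == 1:
            leftover = int(perm[-1])
            target[leftover] = int(perm[0])
        return target
    for s in range(S):
        options = [t for t in range(S) if t != s and target[t] != s]
        if not options:  # unavoidable reciprocity (e.g. S == 2)
            options = [t for t in range(S) if t != s]
        target[s] = int(rng.choice(options))
    return target


def sample_species_traits(seed, S: int, regime: ComplexityRegime) -> SpeciesTraits:
    """Draw vital rates and resource-use structure for a pool of S species.

    Raises ``ValueError`` for S < 1.  Under polyculture each species
    specializes on one of the three supplied types; under monoculture all
    species consume the single type.  Lock-and-key models randomize whether
    the underlying supply is mono- or polyculture.
    """
    if S < 1:
        raise ValueError(f"species pool size must be >= 1, got {S}")
    rng = ensure_rng(seed)

    draws = {
        name: rng.uniform(*TRAIT_RANGES[name], size=S)
        for name in (
            "maintenance",
            "dispersal_frac",
            "growth_rate",
            "resuscitation_prob",
            "maintenance_reduction",
            "consumption_rate",
        )
    }

    lock_base: Optional[str] = None
    if regime.resource is ResourceComplexity.LOCK_AND_KEY:
        lock_base = "mono" if rng.random() < 0.5 else "poly"
        n_supplied = 1 if lock_base == "mono" else 3
    elif regime.resource is ResourceComplexity.MONOCULTURE_LABILE:
        n_supplied = 1
    else:
        n_supplied = 3

    n_types = n_supplied + 1 + S  # supplied + necromass + one metabolite per species
    consumable = np.zeros((S, n_types), dtype=bool)
    if n_supplied == 1:
        consumable[:, 0] = True
    else:
        specialist = rng.integers(0, n_supplied, size=S)
        consumable[np.arange(S), specialist] = True

    if regime.trophic is Trophic.SCAVENGING:
        consumable[:, n_supplied] = True  # necromass is universally consumable

    metabolite_target = np.full(S, -1, dtype=np.int64)
    if regime.is_crossfeed:
        metabolite_target = _crossfeed_targets(
            rng, S, mutual=regime.trophic is Trophic.CROSSFEED_TWOWAY
        )
        for s in range(S):
            t = metabolite_target[s]
            if t >= 0:
                consumable[t, n_supplied + 1 + s] = True

    if regime.resource is ResourceComplexity.LOCK_AND_KEY:
        lock_key_prob = rng.uniform(*TRAIT_RANGES["lock_key_prob"], size=n_supplied)
    else:
        lock_key_prob = np.ones(n_supplied)

    return SpeciesTraits(
        consumable=consumable,
        metabolite_target=metabolite_target,
        n_supplied=n_supplied,
        lock_base=lock_base,
        lock_key_prob=lock_key_prob,
        **draws,
    )
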