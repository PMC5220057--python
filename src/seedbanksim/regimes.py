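"""Factorial complexity regimes: trophic x resource x dispersal x mixing.

A simulated community lives in one of 72 ecological settings obtained by
crossing four levels of trophic complexity (plain consumer-resource,
scavenging of necromass, one-way cross-feeding, reciprocal cross-feeding),
three levels of resource complexity (a single labile resource type, three
labile types each usable only by specialists, or recalcitrant "lock-and-key"
resources), three modes of individual dispersal (passive, run-and-tumble,
chemotaxis) and two spatial mixing conditions (well mixed vs. structured).
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass
from enum import Enum


class Trophic(str, Enum):
    """Trophic complexity level of a model community."""

    CONSUMER_RESOURCE = "consumer_resource"
    SCAVENGING = "scavenging"
    CROSSFEED_ONEWAY = "crossfeed_oneway"
    CROSSFEED_TWOWAY = "crossfeed_twoway"


class ResourceComplexity(str, Enum):
    """How resources are supplied and how hard they are to break down."""

    MONOCULTURE_LABILE = "monoculture_labile"
    POLYCULTURE_LABILE = "polyculture_labile"
    LOCK_AND_KEY = "lock_and_key"


class Dispersal(str, Enum):
    """Mode of active dispersal available to individuals."""

    PASSIVE = "passive"
    RUN_TUMBLE = "run_tumble"
    CHEMOTAXIS = "chemotaxis"


class Mixing(str, Enum):
    """Spatial mixing of the environment between time steps."""

    WELL_MIXED = "well_mixed"
    STRUCTURED = "structured"


@dataclass(frozen=True)
class ComplexityRegime:
    """One of the 72 factorial combinations of ecological complexity."""

    trophic: Trophic
    resource: ResourceComplexity
    dispersal: Dispersal
    mixing: Mixing

    @property
    def is_crossfeed(self) -> bool:
        return self.trophic in (Trophic.CROSSFEED_ONEWAY, Trophic.CROSSFEED_TWOWAY)

    @property
    def is_lock_and_key(self) -> bool:
        return self.resource is ResourceComplexity.LOCK_AND_KEY

    def replace(self, **kwargs) -> "ComplexityRegime":
        return dataclasses.replace(self, **kwargs)

    def __str__(self) -> str:
        return ",".join(
            (self.trophic.value, self.resource.value, self.dispersal.value, self.mixing.value)
        )


def enumerate_regimes() -> tuple[ComplexityRegime, ...]:
    """Return all 72 complexity regimes in a fixed, trophic-major order.

    The order is the lexicographic product of the enum declaration orders,
    with trophic level varying slowest and mixing fastest.  The first element
    is (consumer_resource, monoculture_labile, passive, well_mixed).
    """
    return tuple(
        ComplexityRegime(t, r, d, m)
        for t, r, d, m in itertools.product(Trophic, ResourceComplexity, Dispersal, Mixing)
    )


def regime_index(regime: ComplexityRegime) -> int:
    """Position of ``regime`` in :func:`enumerate_regimes` (0-71)."""
    return enumerate_regimes().index(regime)


def parse_regime(spec: "int | str | ComplexityRegime") -> ComplexityRegime:
    """Resolve a regime from an index 0-71, a comma-separated token string,
    or an existing :class:`ComplexityRegime` (returned unchanged).

    Token strings name the four axes in any order is *not* supported; the
    expected form is ``"trophic,resource,dispersal,mixing"`` using the enum
    values, e.g. ``"scavenging,lock_and_key,chemotaxis,structured"``.
    """
    if isinstance(spec, ComplexityRegime):
        return spec
    if isinstance(spec, int) or (isinstance(spec, str) and spec.strip().isdigit()):
        idx = int(spec)
        regimes = enumerate_regimes()
        if not 0 <= idx < len(regimes):
            raise ValueError(f"regime index must be in [0, {len(regimes) - 1}], got {idx}")
        return regimes[idx]
    if isinstance(spec, str):
        tokens = [tok.strip() for tok in spec.split(",")]
        if len(tokens) != 4:
            raise ValueError(
                "expected four comma-separated tokens (trophic,resource,dispersal,mixing); "
                f"got {spec!r}"
            )
        return ComplexityRegime(
            Trophic(tokens[0]),
            ResourceComplexity(tokens[1]),
            Dispersal(tokens[2]),
            Mixing(tokens[3]),
        )
    raise TypeError(f"cannot parse regime from {type(spec).__name__}")
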