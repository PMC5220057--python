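"""Community and resource statistics per sampled time point.

A :class:`MetricsRecord` summarizes one sampling instant: abundances,
percent dormancy (the relative seed-bank size), interval-averaged
productivity and encounter rate, the standing resource pool, mean cell and
particle diameters, and the species abundance distribution (SAD).  The
module also provides the Fisher log-series goodness-of-fit used to judge
whether emergent SADs look like real microbial communities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .engine import ModelState
from .params import QUOTA_MAX_DIAMETER_UM
from .resources import diameter_from_content

#: Fixed column order of the CSV serialization.
CSV_COLUMNS = (
    "step", "N", "N_active", "pct_dormant", "productivity", "immigrations",
    "encounters_per_step", "R_total", "n_particles", "mean_particle_diam",
    "mean_cell_diam", "sad",
)


@dataclass
class MetricsRecord:
    """One sampled time point of a model run."""

    step: int
    N: int
    N_active: int
    pct_dormant: float            # % of N; NaN when N == 0
    productivity: float           # births per step over the interval
    immigrations: int             # arrivals over the interval
    encounters_per_step: float    # mean contacts per step over the interval
    R_total: float                # summed particle content, mass units
    n_particles: int
    mean_particle_diam: float     # μm; NaN when no particles
    mean_cell_diam: float         # μm; NaN when no cells
    sad: dict = field(default_factory=dict)  # species index -> abundance

    def to_row(self) -> dict:
        row = {k: getattr(self, k) for k in CSV_COLUMNS if k != "sad"}
        row["sad"] = json.dumps({int(k): int(v) for k, v in self.sad.items()})
        return row


def record_metrics(state: ModelState, steps_since_last: int,
                   interval_tallies: Optional[dict] = None) -> MetricsRecord:
    """Summarize the current state into one record.

    ``interval_tallies`` holds the births/immigrations/encounters counted
    since the previous record (defaults to the state's cumulative tallies);
    rate-like fields are averaged over ``steps_since_last``.
    """
    if steps_since_last < 1:
        raise ValueError("steps_since_last must be >= 1")
    t = interval_tallies if interval_tallies is not None else state.tallies
    comm, pool = state.community, state.particles
    n = comm.n
    n_active = comm.n_active

    species, counts = np.unique(comm.species, return_counts=True) if n else ((), ())
    sad = {int(s): int(c) for s, c in zip(species, counts)}

    if n:
        mean_cell = float(np.mean(QUOTA_MAX_DIAMETER_UM
                                  * np.cbrt(np.clip(comm.quota, 0.0, None))))
        pct_dormant = 100.0 * (n - n_active) / n
    else:
        mean_cell = float("nan")
        pct_dormant = float("nan")
    mean_part = float(np.mean(diameter_from_content(pool.content))) if pool.n else float("nan")

    return MetricsRecord(
        step=state.step_index,
        N=n,
        N_active=n_active,
        pct_dormant=pct_dormant,
        productivity=t.get("births", 0) / steps_since_last,
        immigrations=int(t.get("immigrations", 0)),
        encounters_per_step=t.get("encounters", 0) / steps_since_last,
        R_total=pool.total_content,
        n_particles=pool.n,
        mean_particle_diam=mean_part,
        mean_cell_diam=mean_cell,
        sad=sad,
    )


def records_to_frame(records) -> pd.DataFrame:
    """Tidy DataFrame (one CSV-ready row per record, fixed column order)."""
    return pd.DataFrame([r.to_row() for r in records], columns=list(CSV_COLUMNS))


# ---------------------------------------------------------------------------
# Fisher log-series fit


def solve_logseries_x(S: int, N: int) -> float:
    """Solve the Fisher log-series parameter x from richness S and size N.

    Fisher's relations give S = -a·ln(1-x) and N = a·x/(1-x) for the same
    a ("Fisher's alpha"), hence S/N = -(1-x)·ln(1-x)/x, solved by bisection
    on x ∈ (0, 1).
    """
    if not 0 < S <= N:
        raise ValueError("need 0 < S <= N")
    if S == N:  # every species a singleton: x -> 0 limit
        return 1e-12

    def f(x):
        return S / N + (1.0 - x) * np.log(1.0 - x) / x

    return float(optimize.brentq(f, 1e-12, 1.0 - 1e-12, xtol=1e-14))


def logseries_rank_abundance(S: int, N: int, alpha: Optional[float] = None) -> np.ndarray:
    """Expected rank-abundance vector (descending) of a log-series community.

    With ``alpha`` given, that value is used as the log-series parameter x;
    otherwise x is solved from the observed S and N via Fisher's relations.
    Ranks are mapped to the quantiles of the log-series distribution
    (rank k of S at quantile (k - 1/2)/S), the standard construction for
    comparing an observed SAD against the model's expectation.
    """
    x = float(alpha) if alpha is not None else solve_logseries_x(S, N)
    q = (np.arange(1, S + 1) - 0.5) / S  # ascending quantiles
    pred = _logser_ppf(q, x)
    return np.sort(pred)[::-1]


def _logser_ppf(q: np.ndarray, x: float) -> np.ndarray:
    """Quantiles of the log-series pmf p(k) ∝ x^k / k, k = 1, 2, ...

    Direct inversion of the cumulative pmf, accumulated in growing chunks
    until the largest requested quantile is covered (the generic discrete
    inversion machinery is unreliable far out in this distribution's tail).
    """
    qmax = float(np.max(q))
    norm = -np.log1p(-x)
    cdf = np.empty(0)
    k_hi = 0
    while (cdf.size == 0 or cdf[-1] < qmax) and k_hi < 10_000_000:
        k_new = np.arange(k_hi + 1, max(2 * k_hi, 1024) + 1, dtype=float)
        with np.errstate(over="ignore"):
            pmf = np.exp(k_new * np.log(x) - np.log(k_new)) / norm
        prev = cdf[-1] if cdf.size else 0.0
        cdf = np.concatenate([cdf, prev + np.cumsum(pmf)])
        k_hi = int(k_new[-1])
    return np.searchsorted(cdf, q) + 1.0


def logseries_r2(sad, alpha: Optional[float] = None) -> float:
    """Modified r² of a log-series fit to a species abundance distribution.

    Observed abundances (any mapping or sequence of positive counts, at
    least two species) are rank-matched against the expected log-series
    rank-abundance vector and compared on log abundances:

        r² = 1 − Σ(log o − log p)² / Σ(log o − mean log o)²

    The statistic can be negative for poor fits and is 1 for a perfect one.
    """
    if hasattr(sad, "values") and not isinstance(sad, np.ndarray):
        values = list(sad.values()) if isinstance(sad, dict) else list(sad.values)
    else:
        values = list(sad)
    obs = np.sort(np.asarray(values, dtype=float))[::-1]
    obs = obs[obs > 0]
    S = obs.size
    if S < 2:
        raise ValueError("log-series fit is undefined for fewer than two species")
    N = int(round(obs.sum()))
    pred = logseries_rank_abundance(S, N, alpha)
    lo, lp = np.log(obs), np.log(np.clip(pred, 1e-300, None))
    sse = float(np.sum((lo - lp) ** 2))
    sst = float(np.sum((lo - lo.mean()) ** 2))
    if sst == 0.0:
        return 1.0 if sse == 0.0 else -np.inf
    return 1.0 - sse / sst
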