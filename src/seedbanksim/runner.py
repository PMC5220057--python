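"""Run workflow: burn-in to mean reversion, sampled production runs,
ensembles, and dormancy scenario presets.

A model is first iterated until its total abundance fluctuates around a
stable mean (the burn-in, which is discarded), then run for a production
phase of 2000 further steps with a metrics record taken every 10th step.
One generation is one time step: the step length is the minimum doubling
time, so the fastest species doubles at most once per step.  Ensembles are
mutually independent seeded runs summarized into a tidy table; sweeps of
many thousands of models are replaced by desk-scale ensembles of tens of
runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import ModelState, init_state, step
from .metrics import MetricsRecord, record_metrics, records_to_frame
from .params import ModelParams, SpeciesTraits, ensure_rng, sample_params, sample_species_traits
from .regimes import ComplexityRegime, enumerate_regimes, parse_regime, regime_index

TERMINAL_COMPLETED = "completed"
TERMINAL_EXTINCT = "extinct"
TERMINAL_BURNIN_CAP = "burnin_cap_reached"

#: Dormancy scenario presets: a strong capacity for dormancy (cheap dormant
#: maintenance, rare random resuscitation) vs. a weak one.
_PRESETS = {
    "strong_dormancy": {"maintenance_reduction": 100.0, "resuscitation_prob": 0.001},
    "weak_dormancy": {"maintenance_reduction": 10.0, "resuscitation_prob": 0.1},
}


def scenario_presets(name: str) -> dict:
    """Trait overrides for the named dormancy scenario.

    ``strong_dormancy`` sets the dormant maintenance divisor to 100 and the
    resuscitation probability to 0.001 for every species; ``weak_dormancy``
    sets 10 and 0.1.  All other sampled parameters are untouched.  The weak
    preset's resuscitation probability deliberately sits outside the usual
    sampled range — that is the point of the scenario.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    return dict(_PRESETS[name])


def apply_preset(traits: SpeciesTraits, overrides: dict) -> SpeciesTraits:
    """Return a copy of ``traits`` with uniform per-species overrides applied."""
    out = traits.copy()
    for key, value in overrides.items():
        arr = getattr(out, key)
        if not isinstance(arr, np.ndarray):
            raise KeyError(f"{key!r} is not a per-species trait array")
        arr[:] = value
    return out


def detect_mean_reversion(n_series: Sequence[float], window: int = 100,
                          tol: float = 0.1, min_steps: int = 500) -> bool:
    """Has a total-abundance series settled into fluctuation around a mean?

    Convergence requires at least ``min_steps`` observations and compares
    the means of the two most recent non-overlapping windows of length
    ``window``: converged when they differ by at most ``tol`` times the
    pooled standard deviation of the two windows.  A constant series
    converges (0 ≤ 0); a trending series keeps its window means separated
    by ≈ window·slope, far above the dispersion, and never converges.
    """
    if window < 10:
        raise ValueError("window must be >= 10")
    arr = np.asarray(n_series, dtype=float)
    if arr.size < max(2 * window, min_steps):
        return False
    recent = arr[-2 * window:]
    m1 = recent[:window].mean()
    m2 = recent[window:].mean()
    pooled_sd = recent.std()
    return bool(abs(m1 - m2) <= tol * pooled_sd)


@dataclass
class RunResult:
    """Outcome of one simulated model."""

    params: ModelParams
    regime: ComplexityRegime
    burn_in_steps: int
    records: list[MetricsRecord]
    terminal_status: str
    extinction_step: Optional[int] = None
    seed: Optional[int] = None

    @property
    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def build_model(seed, regime=None, param_overrides: Optional[dict] = None,
                preset: Optional[str] = None,
                species_pool_size: Optional[int] = None):
    """Sample a full model configuration from one seed.

    Returns ``(params, traits, regime, run_seed)``.  When ``regime`` is None
    one of the 72 combinations is chosen at random; otherwise any form
    accepted by :func:`seedbanksim.regimes.parse_regime` works.  Parameter
    overrides are applied after sampling; a dormancy preset (by name)
    overrides the corresponding traits for every species.
    """
    rng = ensure_rng(seed)
    if regime is None:
        regimes = enumerate_regimes()
        regime = regimes[int(rng.integers(len(regimes)))]
    else:
        regime = parse_regime(regime)
    params = sample_params(rng)
    if param_overrides:
        params = params.replace(**param_overrides)
    if isinstance(seed, (int, np.integer)):
        params = params.replace(rng_seed=int(seed))
    pool_size = species_pool_size or params.species_pool_size
    traits = sample_species_traits(rng, pool_size, regime)
    if preset:
        traits = apply_preset(traits, scenario_presets(preset))
    return params, traits, regime, rng


def run_model(params: ModelParams, traits: SpeciesTraits, regime: ComplexityRegime,
              seed, burnin_cap: int = 10000, production_steps: int = 2000,
              cadence: int = 10, burnin_window: int = 100, burnin_tol: float = 0.1,
              burnin_min_steps: int = 500) -> RunResult:
    """Burn in to mean reversion, then run the sampled production phase.

    The model steps until :func:`detect_mean_reversion` fires on the total
    abundance series (or ``burnin_cap`` steps elapse, which flags — but does
    not discard — the run).  The production phase runs ``production_steps``
    further steps, taking a metrics record every ``cadence`` steps, so a
    completed default run carries 200 records at steps burn_in + 10k.
    A community that reaches N = 0 with no immigration terminates early as
    extinct, keeping its truncated records.
    """
    state = init_state(params, traits, regime, seed)
    run_seed = int(seed) if isinstance(seed, (int, np.integer)) else None
    n_series: list[int] = []

    def extinct() -> bool:
        return state.community.n == 0 and params.immigration_rate == 0

    # ---- burn-in ----------------------------------------------------------
    status = TERMINAL_BURNIN_CAP
    while state.step_index < burnin_cap:
        step(state)
        n_series.append(state.community.n)
        if extinct():
            return RunResult(params, regime, state.step_index, [], TERMINAL_EXTINCT,
                             extinction_step=state.step_index, seed=run_seed)
        if len(n_series) >= burnin_min_steps and detect_mean_reversion(
                n_series, window=burnin_window, tol=burnin_tol,
                min_steps=burnin_min_steps):
            status = TERMINAL_COMPLETED
            break
    burn_in = state.step_index

    # ---- production -------------------------------------------------------
    records: list[MetricsRecord] = []
    snapshot = dict(state.tallies)
    for k in range(1, production_steps + 1):
        step(state)
        if extinct():
            return RunResult(params, regime, burn_in, records, TERMINAL_EXTINCT,
                             extinction_step=state.step_index, seed=run_seed)
        if k % cadence == 0:
            interval = {key: state.tallies[key] - snapshot[key] for key in state.tallies}
            records.append(record_metrics(state, cadence, interval))
            snapshot = dict(state.tallies)
    return RunResult(params, regime, burn_in, records, status, seed=run_seed)


@dataclass
class EnsembleSpec:
    """A batch of independent seeded runs.

    ``regimes`` may be None (a random regime per run), a single regime spec,
    a list the length of ``seeds``, or the string ``"factorial"`` for one
    run per complexity combination (seeds are then cycled over the 72).
    """

    seeds: Sequence[int]
    regimes: object = None
    preset: Optional[str] = None
    param_overrides: Optional[dict] = None
    burnin_cap: int = 10000
    production_steps: int = 2000
    cadence: int = 10
    species_pool_size: Optional[int] = None

    def resolved(self) -> list[tuple[int, object]]:
        seeds = list(self.seeds)
        if len(set(seeds)) != len(seeds):
            raise ValueError("ensemble seeds must be distinct")
        if self.regimes == "factorial":
            regs = list(enumerate_regimes())
            if len(seeds) != len(regs):
                seeds = [int(s) for s in np.resize(seeds, len(regs))]
            return list(zip(seeds, regs))
        if self.regimes is None or isinstance(self.regimes, (int, str)) or hasattr(
                self.regimes, "trophic"):
            return [(s, self.regimes) for s in seeds]
        regs = list(self.regimes)
        if len(regs) != len(seeds):
            raise ValueError("regime list length must match seeds")
        return list(zip(seeds, regs))


_SUMMARY_FIELDS = ("N", "N_active", "pct_dormant", "productivity",
                   "encounters_per_step", "R_total", "n_particles",
                   "mean_particle_diam", "mean_cell_diam")


def summarize_run(result: RunResult) -> dict:
    """Per-run means of every recorded metric plus run bookkeeping."""
    row = {
        "seed": result.seed,
        "regime": str(result.regime),
        "regime_index": regime_index(result.regime),
        "status": result.terminal_status,
        "burn_in_steps": result.burn_in_steps,
        "n_records": len(result.records),
        "extinct": result.terminal_status == TERMINAL_EXTINCT,
    }
    if result.records:
        frame = result.frame
        for name in _SUMMARY_FIELDS:
            row[f"mean_{name}"] = float(np.nanmean(frame[name].to_numpy(dtype=float)))
        enc = frame["encounters_per_step"].to_numpy(dtype=float)
        mean_enc = float(np.nanmean(enc))
        row["cv_encounters"] = float(np.nanstd(enc) / mean_enc) if mean_enc > 0 else float("nan")
    else:
        for name in _SUMMARY_FIELDS:
            row[f"mean_{name}"] = float("nan")
        row["cv_encounters"] = float("nan")
    return row


def run_ensemble(spec: EnsembleSpec):
    """Run all configurations in ``spec``; returns (results, summary frame).

    Runs are mutually independent (each seeds its own generator), so the
    summary is invariant to execution order; rows are indexed by seed order
    as given.
    """
    results = []
    for seed, regime in spec.resolved():
        params, traits, regime_r, rng = build_model(
            int(seed), regime=regime, param_overrides=spec.param_overrides,
            preset=spec.preset, species_pool_size=spec.species_pool_size)
        res = run_model(params, traits, regime_r, rng, burnin_cap=spec.burnin_cap,
                        production_steps=spec.production_steps, cadence=spec.cadence)
        res.seed = int(seed)
        results.append(res)
    summary = pd.DataFrame([summarize_run(r) for r in results])
    return results, summary
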