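# Methods

`seedbanksim` is a stochastic, spatially explicit, individual-based model
(IBM) of heterotrophic microbial communities in which dormancy — and hence a
seed bank — emerges from the microscale economics of finding food.  This
note records the model, its assumptions, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## The model

**Space and time.** The habitat is a cube of side L = 43,200 μm with
reflecting boundaries.  One time step represents 1200 s (20 min), chosen as
the minimum doubling time of a fast bacterium; with a maximal swimming speed
of 36 μm/s this sets a space–time equivalency in which the fastest species
can either double once or cross the domain once per step.  All positions are
3-D points; cells and resource particles are spheres.

**Individuals.** A cell carries a relative quota Q ∈ (0, 1] — its endogenous
resource store as a fraction of the species maximum.  Quota is proportional
to cell volume, so diameter d = 1.25·Q^(1/3) μm: immigrants arrive with
Q ~ U(0.5, 1.0), i.e. diameters of about 1–1.25 μm.  Each species has
uniformly sampled vital rates: maintenance m ∈ [0.001, 0.01] quota/step,
dispersal reach δ ∈ [0.01, 1] of L per step, growth rate g ∈ [0.1, 1],
resuscitation probability ρ ∈ [0.001, 0.01]/step, dormant maintenance
divisor f ∈ [10, 100], and a consumption rate r ∈ [0.1, 1] (the fraction of
the encounter-limited maximal bite; see *Consumption*).

**Resources.** Particles enter with probability `supply_rate` ∈ [0.1, 1] per
step, carrying content c ~ U(1000, 10,000) mass units at a uniform random
position.  Diameter follows sphere-volume scaling anchored at 4000 μm for
content 1000 (so supplied particles span 4000–8600 μm).  One mass unit is
worth κ = 0.001 quota units, i.e. a species' full quota equals 1000 mass
units, matching the convention that cell quota and particle size share a
scale.

**Life history per step.** Nine process blocks run in a freshly shuffled
order each step (shuffling prevents scheduling artifacts): supply,
immigration, mixing, dispersal, encounter/consumption, reproduction,
maintenance, death, dormancy transitions.

- *Encounter and consumption.* An encounter is physical contact (centre
  distance ≤ sum of radii) between an active cell and a particle of a type
  its species can consume; each cell is served by at most its nearest
  contacting particle per step.  A bite transfers
  δ = min(r·κ·c, 1 − Q) quota (satiation-capped); the remainder of the
  particle is split in two at a uniform random fraction.  In structured
  environments fragments land within ε = 100 μm of the parent, so breakdown
  products aggregate.  Fragments whose content falls below the floor
  (10⁻³ mass units, a 40 μm sphere) are lost as unusable crumbs.
- *Recalcitrance.* Under lock-and-key resource complexity every supplied
  particle requires a successful Bernoulli trial (type-specific probability
  ∈ [0.01, 1]) before any consumption, and the attempt itself costs
  c_g·Q whether or not it succeeds.
- *Reproduction.* Binary fission without mutation, with probability g·Q.
  A growth cost c_g·g·Q (c_g = 0.1) is paid, and the remaining quota is
  halved between mother and daughter at the mother's coordinates.
- *Maintenance, death.* Active cells pay m per step, dormant cells m/f.
  A cell whose quota falls below m dies, active or dormant.  Under
  scavenging, a dead cell leaves a labile, universally consumable necromass
  particle of content (ν/100)·Q_dead/κ with ν ∈ [1, 100]; ν is read as a
  percent yield so death never amplifies energy.
- *Dormancy.* Entry is deterministic on energetic depletion: an active
  cell with Q ≤ θ_d·m (θ_d = 50) goes dormant.  Exit is stochastic with
  probability ρ per step.  Dormant cells do not consume, grow, or actively
  disperse, and register no encounters.
- *Dispersal and its cost.* Passive cells move only with the environment:
  uniform relocation each step when well mixed, Brownian jiggle
  (σ_B = 10 μm/step) when structured.  Run-and-tumble cells travel δ·L
  along a straight line and tumble to a fresh random heading on hitting a
  boundary.  Chemotactic cells sense the nearest consumable particle
  (unlimited range — the offsetting control is energetic) and move straight
  toward contact.  Movement costs mult·c_d·(distance/L)·Q with c_d = 0.01
  and mult = 0 (passive), 1 (run-and-tumble), 2 (chemotaxis).
- *Cross-feeding.* Each species is randomly wired at model birth to produce
  a metabolite consumable by one other species (one-way: reciprocal pairs
  avoided; two-way: a random matching of mutual pairs).  A consumption of δ
  spawns a metabolite particle of content β·δ/κ (β = 0.1) at the producer's
  position.

**Complexity regimes.** The factorial crossing of 4 trophic levels
(consumer-resource, scavenging, one-way cross-feeding, two-way
cross-feeding) × 3 resource levels (labile monoculture, labile three-type
polyculture with specialist consumers, lock-and-key) × 3 dispersal modes ×
2 mixing conditions yields 72 regimes.  Lock-and-key models randomize
whether their underlying supply is mono- or polyculture.

**Workflow.** A model is founded with 100 active individuals whose species
come from a log-series(α) metacommunity (α ∈ [0.95, 0.99]) truncated to the
pool of S = 100 species; later immigrants are uniform over the pool, as is
standard for propagule rain.  The run burns in until the total-abundance
series reaches mean reversion — the means of the two most recent
non-overlapping 100-step windows within 0.1 pooled SD of each other, after
at least 500 steps, capped at a configurable number of steps (capped runs
are flagged, not discarded) — then runs a 2000-step production phase
recording every 10th step.  One generation ≡ one step, since the step is
defined as the minimum doubling time.

## Closure constants

The following constants are required by the implementation but are not fixed
by the source model description; each default was chosen once on physical
grounds and is configurable through `ModelParams`.

| constant | default | rationale |
|---|---|---|
| κ (quota per mass unit) | 0.001 | full quota ≡ 1000 mass units, aligning the cell and particle scales |
| c_g (growth cost coefficient) | 0.1 | fission costs ≤ 10% of quota; modest but non-trivial |
| c_d (dispersal cost coefficient) | 0.01 | a full-domain swim costs 1% (run-tumble) or 2% (chemotaxis) of quota, comparable to a few steps of maintenance |
| θ_d (dormancy threshold, × m) | 50 | cells bail into dormancy at ~5–50% quota, well above the death line |
| σ_B (Brownian SD) | 10 μm/step | sub-cell-scale jiggle: structured habitats stay structured |
| ε (fragment jitter) | 100 μm | fragments aggregate near their parent |
| β (cross-feeding yield) | 0.1 | by-products carry 10% of consumed energy; no amplification |
| content floor | 10⁻³ mass units | crumbs below a 40 μm sphere are unusable; bounds fragment dust |
| particle cap | 10,000 | explicit version of the model's stated bound on particle numbers; smallest particles are discarded first, ledger-accounted |

The species consumption rate r ∈ [0.1, 1] deserves a note: species-specific
consumption rates are part of the model narrative but carry no printed
range.  A fractional bite is what drives the observed cascade of particle
fragmentation — with r ≡ 1 every particle smaller than a cell's headroom is
swallowed whole on first contact and mid-sized fragments never form.

## Numerical choices

- All randomness flows from one `numpy` PCG64 generator per model; identical
  seeds give bitwise-identical trajectories.
- Exact energy bookkeeping: cumulative ledgers record every quota and
  content flow (supply, consumption, maintenance, growth, dispersal,
  handling, death, necromass, metabolites, crumb loss, cap removal).  The
  invariant |Σ state − Σ ledger| ≤ 10⁻⁹ × total is asserted in tests over
  multi-hundred-step runs of heterogeneous regimes.
- Encounter detection is exactly equivalent to the brute-force all-pairs
  scan (tested against an independent oracle); a k-d tree prunes candidates
  on large scenes without changing the contract.  Distance ties break to the
  lowest particle ID (relevant only for constructed inputs).
- Consumption pairs are processed in shuffled order; a particle that
  fragments mid-block is not served twice.
- Cells whose quota is driven below zero within a step are carried (the
  ledger stays exact) and removed at the next death check; geometry clips
  negative quotas to zero.
- The log-series rank-abundance expectation inverts the cumulative pmf
  directly in growing chunks, because generic discrete-quantile inversion is
  unreliable deep in the distribution's tail.  When no parameter is given,
  x is solved from (S, N) via Fisher's relations by bisection.
- Cross-feeding adds β·δ of energy per consumption (a by-product, not a
  transfer), so the closed-system monotonicity property (total quota +
  κ·content non-increasing without supply or immigration) holds in
  non-cross-feeding regimes and is tested there.

## What the experiments show — and what they do not

The synthetic experiments reproduce the *study conditions* of the original
ensemble at desk scale: tens of seeded runs of some hundreds to thousands
of steps instead of >10,000 models.  Problem sizes used by the acceptance
script: a 20-run mixed-regime ensemble (burn-in capped at 400 steps, 800
production steps, records every 10th) for the emergent size statistics, and
10 paired structured runs (burn-in capped at 500 steps, 1000 production
steps) for the chemotaxis/passive encounter contrast.  The test suite uses
similarly scaled designs, including 7 matched seeds per dormancy preset
under total resource cut-off for the extinction contrast.

Qualitative contrasts (chemotaxis ≫ passive encounters in structured
habitats; fewer extinctions under strong dormancy; encounter rate
anti-correlated with seed-bank size; lock-and-key stabilizing encounter time
series) are properties of the mechanism and survive scaling well.
Quantitative emergent statistics are scale-sensitive; in particular the mean
particle diameter is dominated by freshly supplied particles (4000–8600 μm)
in low-encounter regimes, because at the printed domain side of 43,200 μm
supplied particles are enormous relative to the habitat.  The printed domain
volume (8·10⁴ cm³) corresponds to a side of 432,000 μm — ten times the
printed side length — and in that larger, sparser world unconsumed supply
would weigh far less in the particle-size distribution.  We use the printed
side length as authoritative and report the statistic honestly as measured.

The generator emulates randomized parameterization, not any real community:
no evolution or mutation (reproduction is clonal), no explicit enzymes,
diffusion fields or chemoattractant gradients, no predation or parasitism,
no hydrodynamics.  Passing tests therefore demonstrate internal consistency
and the stated emergent contrasts under the model's assumptions — not
predictions for any particular natural system.

## Known limitations

- Single-service consumption (one bite per cell per step) is a scheduling
  choice; a config switch for multi-service would change encounter-rate
  scaling at high particle densities.
- Chemotaxis pays its doubled cost even when falling back to run-and-tumble
  (no consumable particle anywhere): sensing is modeled as always-on.
- The particle cap is a hard bound; in extremely productive well-mixed runs
  it discards the smallest crumbs slightly earlier than the floor would.
- Burn-in detection watches total abundance only; a run can pass mean
  reversion while its resource pool is still drifting.
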