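# Methods

## Model

The system is a population of `C` identical, well-mixed compartments
(modeling water-in-oil droplets), each holding integer copy numbers of
replicator species. Species are *hosts* — RNAs encoding their own
replicase, the only class that can drive replication — or *parasites*,
which are copied by host replicase but encode none. Within a compartment
the copy numbers follow the coupled logistic equations

    dH_i/dt = H_i (Σ_j k_ji^H H_j) (1 − (ΣH + ΣP)/N)
    dP_h/dt = P_h (Σ_j k_jh^P H_j) (1 − (ΣH + ΣP)/N)

There is no degradation term (negligible in the experimental system the
model mirrors), no resource accounting, and no sequence-level fidelity
model; compartments interact only through the fusion–division step.

One round of the serial cycle applies, in order: replication in every
compartment; culling (retain `⌊C·S⌋` uniformly chosen compartments,
replace the rest with empty ones — the total compartment count is
invariant); and `A` fusion–division events (pool two distinct uniformly
chosen compartments, split each species' pooled count Binomial(n, 1/2)
between the daughters — exactly conservative). A multi-round run records
global per-species totals every round; a species is **sustained** when its
final global total strictly exceeds `C`, evaluated after the complete
final round.

### Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `C` | compartments | 3000 | experimental droplet count scaled down |
| `S` | culling rate | 0.25 | `⌊C·S⌋ = 750` compartments survive per round |
| `A` | fusion–division events/round | 5000 | scales ∝ C (rounded down to a multiple of 500: C=10000 → 16500) to keep events per compartment constant |
| `N` | carrying capacity (copies) | 100 | shared by all compartments |
| `T` | replication-step horizon (model time) | 1.0 | see below |
| rounds | serial-cycle length | 100 (screens), 1000 (evolution) | |
| `k^H` | host replication coefficients | grid {1.7, 2.0, 2.3, 2.6} (+0.2, 4.1 extremes) | spans the experimentally estimated 2.0–2.3 |
| `k^P` | parasite replication coefficients | grid up to 20.0; 7.0 is the experimental value | |

**Initial condition.** Every compartment starts with equal founder shares,
`⌊N/n⌋` copies each for `n` founders (50/50 for two, 33 each for three) —
the integer split closest to filling each compartment to capacity.

**Horizon T.** The replication-step duration is not an observable of the
model; we integrate to `T = 1` by default. Because growth saturates at
capacity (the logistic factor → 0), endpoints are T-insensitive for the
screen coefficients: for k ≥ 1.7 the difference between `T = 1` and
`T = 10` endpoints is below 1e−9 copies. The insensitivity genuinely fails
for weak replicators (k ≈ 0.2) with small inocula — a compartment seeded
with 5 copies reaches ~40 copies by `T = 1` but capacity by `T = 10` — so
sustained counts in the extreme-value corner of the screens depend on this
choice. Both regimes are pinned by tests.

## Numerics

* **Integrator.** Cash–Karp embedded Runge–Kutta 5(4) with standard step
  control, `rtol = 1e-6`, `atol = 1e-9`, compiled with numba (the screens
  integrate ~3000 compartments × 100 rounds × 100 runs per grid cell; a
  Python-level adaptive solver per compartment is not feasible at that
  volume). The dynamics are smooth and non-stiff at the coefficient
  magnitudes used (k ≤ 20, N = 100). Single-species compartments below
  capacity use the closed-form solution of the separable scalar ODE
  (`ln(y/(N−y))/N − 1/y = const + k t`, inverted by safeguarded Newton).
  Tests check both paths against a fixed-step RK4 oracle at `dt = 1e-5`
  and against an independent adaptive solver to < 1e-4 relative error.
* **Endpoint memoization.** Within a run the coefficient matrix and the
  dynamics parameters are fixed, and compartment states are small integer
  vectors (counts stay below ~2N + 1 because growth saturates at N and
  fusion pools at most two compartments). ODE endpoints are therefore
  cached per integer initial state — exact reuse, not approximation — and
  the cache is discarded whenever the matrix changes (species turnover in
  evolutionary runs).
* **Discretization.** The ODE produces real endpoints but culling and
  binomial fusion need integers. Default is stochastic rounding (floor
  plus Bernoulli on the fractional part), unbiased in expectation;
  deterministic nearest-rounding is available for reproducible unit
  checks. Counts never go below 0; a species absent from a compartment
  stays absent (no spontaneous generation), and endpoints above capacity
  (possible after fusion) decay toward N.
* **Randomness.** Each run draws from one seeded numpy Generator. Culling,
  rounding, initial conditions and mutation use the Generator directly;
  the compiled fusion–division chain uses numba's internal stream,
  reseeded from the Generator every round. Sweep and batch workers derive
  per-(cell, run) seeds from `SeedSequence(master, cell, run)`, so
  execution order and parallelism never change results; identical seeds
  reproduce runs bit-for-bit.

## Sustainability screens

`topology_spec`/`build_grid` enumerate the published grid layouts (HH:
{1.7, 2.0, 2.3, 2.6}⁴ = 256 cells; HP: 6 host × 9 parasite values; HPP:
two independent parasite axes; HHP: host grid with fixed parasite
coefficients 7.0/7.0, 7.0/0.1 or 7.0/1.0; HHH: two fixed sustainable
host-pair conditions × gridded third-host coefficients). Default
`n_runs = 100` per cell matches the main screens; supplementary-scale
grids use 10. HH cells on the diagonal (`k11 = k22`, `k12 = k21`) are
computed but flagged: there the two hosts are one species relabelled. For
the same reason the HPP exclusion check ("the weaker parasite is
competitively excluded") samples cells with distinct parasite
coefficients — with identical coefficients the two parasites drift
neutrally as one species and can both stay above the sustainability line.

The three-inequality HHP heuristic (`check_hhp_condition`) orients Host 1
as the parasite-susceptible host (`k11P ≥ k21P`) and then requires strict
asymmetric resistance (`k11P > k21P`), a resistant host that replicates
the susceptible one more than itself (`k21H > k22H`), and a susceptible
host receiving at least as much replication as the resistant one
(`k11H + k21H ≥ k12H + k22H`). Orientation makes the verdict invariant
under host relabeling (property-tested).

## Evolutionary simulation

A mutation step runs immediately before replication whenever one or two
species are alive (the species cap of three bounds computational cost; no
coefficient trade-off structure is modeled). For each (parent species,
compartment), an appearance test fires with probability
`min(1, r × rate)`, where `r` is the parent's replication count in that
compartment during the *previous* round's replication step (counted
before culling; round 1 has no mutation). Rates: host→host 0.02 per
replication (≈ 9.1e-6 errors/nt × 2000 nt), host→parasite 0.001,
parasite→parasite 0.002 (parasites are ~10× shorter). New-host
coefficients are drawn uniformly from [1, 3] and new-parasite coefficients
from [0, 10]; a new host's replicase-side coefficients onto existing
templates are drawn at creation by template class (the matrix must be
complete; this is one defensible reading, isolated in
`_draw_coefficients`).

Two points in the appearance bookkeeping were genuinely open and are
policy-switchable (`EvolutionConfig`):

* **Copies per appearance.** A new species enters with exactly one copy in
  one compartment drawn uniformly among the firing compartments
  (`multi_copy_appearance=False`, default). At the cycle's steady state
  occupied compartments regrow by tens of copies per round, so the
  per-compartment probability saturates and thousands of compartments
  fire; granting each firing a copy would make every newcomer start with
  thousands of copies and establish instantly, erasing the drift-dominated
  establishment dynamics the model is about.
* **Class order.** At most one new host type and one new parasite type
  appear per round; by default both classes may appear in the same round
  (`appearance_order="both"`), letting the species count transiently reach
  cap + 1 until a newcomer dies out. Host-first priority starves parasite
  invasions from two-species states (measured: ~30× fewer parasite than
  host events) and distorts the network statistics toward host-only
  topologies; `host_first`, `parasite_first` and `random` remain available.

Every round the species with global totals strictly above 1000 copies
form the classified network (labels H, HP, HH, HHP, HPP, HHH by member
roles). Maintained networks are maximal runs of an identical above-
threshold species-id set lasting strictly more than 100 rounds; each
records the classified composition of the round immediately preceding its
interval (its *predecessor* — implemented as the prior classified
composition, not necessarily itself maintained). Global extinction (all
totals zero) is absorbing and ends the run.

## Coefficient estimation

Fold values are common logs of 0→1 h concentration ratios,
`v = log10(c₁/c₀)` (unit-free, scale-invariant). Self coefficients are the
self-assay folds (`k_ii = v_iii`); cross coefficients normalize away the
competition between the two templates sharing a tube,
`k_ij = k_ii · v_ijj / v_iji`, taking the fold-value ratio of competing
RNAs as the ratio of their replication coefficients (the assay's modeling
assumption, taken as given). Replicate measurements are averaged with
first-order error propagation; full precision is kept (tables round to one
decimal only at presentation). A zero competitor fold leaves the cross
coefficient undefined (reported missing); negative folds propagate with a
warning. Hosts are the species that served as replicase source (RNA I);
templates never used as RNA I are parasites.

## Synthetic data

`make_fixture` generates the package's test inputs: coefficient matrices
within the model's ranges, fold tables built by inverting the estimator
(recovery is exact by construction — the fixture validates the inversion
algebra, not measurement noise), equal-length sequence pairs with a
planted Hamming distance, and HHP parameter tables with an exact
condition-pass count (rejection-sampled against the checker). These are
synthetic stand-ins: they exercise the code paths at realistic scales but
say nothing about assay noise, qPCR calibration, alignment or any other
property of real measured data.

## Scaled-down statistics and what they show

The published batch scale (1000 evolutionary runs × 1000 rounds × 3000
compartments; 100-run sweeps over hundreds of cells) is cluster-scale.
The test suite and `scripts/acceptance.py` run 30–80-run evolutionary
batches and sampled grid cells (sizes recorded per result), which resolve
modal structure (which network is most often maintained, which composition
precedes it, the direction of the compartment-number effect) but estimate
fractions with ±0.05–0.1 standard errors.

A known quantitative limitation: the appearance bookkeeping above
reproduces the qualitative transition structure (HHP the dominant
maintained three-member network, mostly preceded by HP, extinction
increasing as compartments decrease) but yields lower absolute extinction
fractions (~0.5/0.35/0.0 at C = 1000/3000/5000 in batches of 20–40) than
the published 0.936/0.796/0.470. The appearance probability
`min(1, r × rate)` saturates in essentially every occupied compartment at
any sustainable steady state (75% culling forces ~4× regrowth per round),
so new-species attempts occur nearly every open round and a parasite-
stricken system is usually rescued by a new host before dying. A much
lower effective appearance flux would lengthen the lone-host phase and
raise extinction, but no reading of the stated per-replication rates
produces one; the rates are kept at their stated values rather than tuned.
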