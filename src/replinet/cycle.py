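"""The serial replication cycle: replication -> culling -> fusion-division.

One round applies the within-compartment replication dynamics to every
compartment, randomly retains floor(C*S) compartments (replacing the rest
with empty ones), and then performs A fusion-division events, each pooling
two random compartments and redistributing every species binomially between
the two daughters.  A multi-round run records per-species global totals each
round; a species is "sustained" when its final global total exceeds the
compartment count C.

Randomness: each run draws from a single seeded numpy Generator.  Culling,
stochastic rounding and initial conditions consume the Generator directly;
the fusion-division loop runs in a compiled kernel whose internal stream is
reseeded from the Generator at every round, so identical seeds reproduce
runs bit-for-bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from numba import njit

from .core import (
    CoefficientMatrix,
    CompartmentState,
    ConfigurationError,
    DynamicsConfig,
    ReplicationNumericsError,
    Species,
    discretize_counts,
    make_endpoint_cache,
    _integrate_all,
)

__all__ = [
    "CycleConfig",
    "PopulationState",
    "RunOutcome",
    "cull",
    "fuse_divide_once",
    "run_round",
    "is_sustained",
    "run_simulation",
]

_SEED_MOD = 2**31 - 1


@dataclass
class CycleConfig:
    """Fixed machinery of the serial replication cycle.

    Defaults follow the compartmentalized serial-transfer setup the model
    emulates: C = 3000 compartments, culling rate S = 0.25 (750 retained per
    round), A = 5000 fusion-division events per round, carrying capacity
    N = 100, 100 rounds.
    """

    compartments: int = 3000
    culling_rate: float = 0.25
    fusion_frequency: int = 5000
    rounds: int = 100
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.compartments < 1:
            raise ConfigurationError("compartments must be positive")
        if not 0.0 <= self.culling_rate <= 1.0:
            raise ConfigurationError("culling_rate must lie in [0, 1]")
        if self.fusion_frequency < 0:
            raise ConfigurationError("fusion_frequency must be non-negative")
        if self.rounds < 1:
            raise ConfigurationError("rounds must be positive")

    @property
    def n_retained(self) -> int:
        """C_S = floor(C * S), the number of compartments kept by culling."""
        return math.floor(self.compartments * self.culling_rate)


class PopulationState:
    """Counts of every species in every compartment at one point in a cycle.

    Backed by a (C, S) integer array; the compartment count C is invariant
    across all cycle steps.
    """

    def __init__(
        self,
        counts: np.ndarray,
        species: Sequence[Species],
        round_index: int = 0,
    ) -> None:
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[1] != len(species):
            raise ConfigurationError(
                "counts must be a (compartments, species) array"
            )
        if np.any(counts < 0):
            raise ConfigurationError("copy numbers must be non-negative")
        self.counts = counts
        self.species: Tuple[Species, ...] = tuple(species)
        self.round_index = int(round_index)

    # -- construction ------------------------------------------------------
    @classmethod
    def initial_fill(
        cls,
        species: Sequence[Species],
        compartments: int,
        carrying_capacity: int,
    ) -> "PopulationState":
        """Fill every compartment with equal founder shares up to capacity.

        With n founders each receives floor(N / n) copies, the integer
        split closest to filling the compartment to its carrying capacity.
        """
        if not species:
            raise ConfigurationError("at least one founding species required")
        per = carrying_capacity // len(species)
        counts = np.full((compartments, len(species)), per, dtype=np.int64)
        return cls(counts, species, round_index=0)

    # -- views -------------------------------------------------------------
    @property
    def n_compartments(self) -> int:
        return self.counts.shape[0]

    @property
    def ids(self) -> Tuple[str, ...]:
        return tuple(sp.id for sp in self.species)

    def totals(self) -> Dict[str, int]:
        """Per-species global totals (sums over compartments)."""
        sums = self.counts.sum(axis=0)
        return {sp.id: int(n) for sp, n in zip(self.species, sums)}

    def compartment(self, index: int) -> CompartmentState:
        return CompartmentState(
            {
                sp.id: int(n)
                for sp, n in zip(self.species, self.counts[index])
                if n > 0
            }
        )

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.counts.copy(), self.species, self.round_index
        )


@dataclass
class RunOutcome:
    """Result of a multi-round run.

    ``trajectory`` holds per-round global totals with shape
    (rounds + 1, species); row 0 is the initial condition.
    """

    species: Tuple[Species, ...]
    survivor_state: Dict[str, bool]
    trajectory: np.ndarray
    sustained_all: bool

    def trajectory_frame(self) -> pd.DataFrame:
        """Tidy (round, species_id, role, global_total) table."""
        rows = []
        for rnd in range(self.trajectory.shape[0]):
            for j, sp in enumerate(self.species):
                rows.append(
                    (rnd, sp.id, sp.role, int(self.trajectory[rnd, j]))
                )
        return pd.DataFrame(
            rows, columns=["round", "species_id", "role", "global_total"]
        )

    def to_json(self, path=None) -> str:
        payload = {
            "species": [
                {"id": sp.id, "role": sp.role, "birth_round": sp.birth_round}
                for sp in self.species
            ],
            "survivor_state": self.survivor_state,
            "sustained_all": self.sustained_all,
            "final_totals": {
                sp.id: int(self.trajectory[-1, j])
                for j, sp in enumerate(self.species)
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# Cycle steps
# ---------------------------------------------------------------------------

def replicate_population(
    pop: PopulationState,
    matrix: CoefficientMatrix,
    cfg: CycleConfig,
    rng: np.random.Generator,
    cache=None,
) -> Tuple[PopulationState, np.ndarray]:
    """Replication step for every compartment.

    Returns the post-replication population and the per-compartment,
    per-species replication counts max(new - old, 0) consumed by the
    evolutionary mutation step.  ``cache`` memoizes ODE endpoints for
    repeated integer compartment states of this (matrix, dynamics) pair.
    """
    if pop.ids != matrix.ids:
        raise ConfigurationError(
            "population species do not match coefficient matrix"
        )
    dyn = cfg.dynamics
    old = pop.counts
    cont = old.astype(np.float64)
    bad = _integrate_all(
        cont,
        np.ascontiguousarray(matrix.k),
        float(dyn.carrying_capacity),
        float(dyn.horizon),
        float(dyn.rel_tol),
        float(dyn.abs_tol),
        cache if cache is not None else make_endpoint_cache(),
    )
    if bad >= 0:
        raise ReplicationNumericsError(
            f"non-finite replication output in compartment {bad} "
            f"(initial counts {old[bad].tolist()})"
        )
    new = discretize_counts(cont, dyn.rounding_mode, rng)
    new[old == 0] = 0
    replicated = np.maximum(new - old, 0)
    return (
        PopulationState(new, pop.species, pop.round_index),
        replicated,
    )


def cull(
    pop: PopulationState, cfg: CycleConfig, rng: np.random.Generator
) -> PopulationState:
    """Randomly retain floor(C*S) compartments; empty the rest.

    The compartment count stays fixed: culled compartments are replaced by
    empty ones, modeling dilution with fresh droplets.
    """
    c = pop.n_compartments
    keep = cfg.n_retained
    counts = pop.counts.copy()
    if keep < c:
        retained = rng.choice(c, size=keep, replace=False)
        mask = np.ones(c, dtype=bool)
        mask[retained] = False
        counts[mask] = 0
    return PopulationState(counts, pop.species, pop.round_index)


@njit(cache=True)
def _fuse_divide_kernel(counts, n_events):
    """Repeat the fuse-then-binomially-divide event ``n_events`` times.

    Each event pools two distinct random compartments and splits every
    species' pooled count x ~ Binomial(n, 1/2) / n - x between them, which
    conserves global totals exactly.  Uses numba's internal np.random
    stream (seed it with _seed_fusion_stream before calling).
    """
    c, s = counts.shape
    for _ in range(n_events):
        a = np.random.randint(0, c)
        b = np.random.randint(0, c - 1)
        if b >= a:
            b += 1
        for i in range(s):
            n = counts[a, i] + counts[b, i]
            if n > 0:
                x = np.random.binomial(n, 0.5)
                counts[a, i] = x
                counts[b, i] = n - x


@njit(cache=True)
def _seed_fusion_stream(seed):
    np.random.seed(seed)


def fuse_divide_once(
    pop: PopulationState, rng: np.random.Generator
) -> PopulationState:
    """One fusion-division event: pool two random compartments, resplit.

    Per species the pooled count n is redistributed as x ~ Binomial(n, 1/2)
    to one daughter and n - x to the other; totals are conserved exactly.
    """
    c = pop.n_compartments
    if c < 2:
        raise ConfigurationError("fusion-division requires at least 2 compartments")
    a, b = rng.choice(c, size=2, replace=False)
    counts = pop.counts.copy()
    pooled = counts[a] + counts[b]
    x = rng.binomial(pooled, 0.5)
    counts[a] = x
    counts[b] = pooled - x
    return PopulationState(counts, pop.species, pop.round_index)


def fuse_divide_many(
    pop: PopulationState, n_events: int, rng: np.random.Generator
) -> PopulationState:
    """Apply ``n_events`` sequential fusion-division events (compiled path).

    Pairs are drawn independently for each event (with replacement across
    events, without replacement within a pair).
    """
    if pop.n_compartments < 2:
        raise ConfigurationError("fusion-division requires at least 2 compartments")
    counts = pop.counts.copy()
    _seed_fusion_stream(int(rng.integers(_SEED_MOD)))
    _fuse_divide_kernel(counts, int(n_events))
    return PopulationState(counts, pop.species, pop.round_index)


def run_round(
    pop: PopulationState,
    matrix: CoefficientMatrix,
    cfg: CycleConfig,
    rng: np.random.Generator,
    cache=None,
) -> Tuple[PopulationState, np.ndarray]:
    """One serial-cycle round: replication, culling, A fusion-divisions.

    Returns the end-of-round population and the pre-culling replication
    counts (per compartment, per species).
    """
    pop, replicated = replicate_population(pop, matrix, cfg, rng, cache=cache)
    pop = cull(pop, cfg, rng)
    if cfg.fusion_frequency > 0:
        pop = fuse_divide_many(pop, cfg.fusion_frequency, rng)
    pop.round_index += 1
    return pop, replicated


def is_sustained(pop: PopulationState, species_id: str, cfg: CycleConfig) -> bool:
    """A species is sustained when its global total strictly exceeds C."""
    return pop.totals()[species_id] > cfg.compartments


def run_simulation(
    matrix: CoefficientMatrix,
    founders: Sequence[Species] | None = None,
    cfg: CycleConfig | None = None,
    rng: np.random.Generator | None = None,
) -> RunOutcome:
    """Run the full serial replication cycle and report sustainability.

    Every compartment starts with equal founder shares summing to at most
    the carrying capacity.  The run executes ``cfg.rounds`` rounds; an
    all-empty population is absorbing, so the run ends early once every
    species has died out globally.
    """
    cfg = cfg or CycleConfig()
    founders = tuple(founders) if founders is not None else matrix.species
    if not founders:
        raise ConfigurationError("founders must be non-empty")
    if tuple(sp.id for sp in founders) != matrix.ids:
        raise ConfigurationError("founders must match the coefficient matrix")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    pop = PopulationState.initial_fill(
        founders, cfg.compartments, cfg.dynamics.carrying_capacity
    )
    cache = make_endpoint_cache()
    traj = np.zeros((cfg.rounds + 1, len(founders)), dtype=np.int64)
    traj[0] = pop.counts.sum(axis=0)
    for rnd in range(1, cfg.rounds + 1):
        pop, _ = run_round(pop, matrix, cfg, rng, cache=cache)
        traj[rnd] = pop.counts.sum(axis=0)
        if traj[rnd].sum() == 0:  # extinction is absorbing
            break
    survivor = {
        sp.id: bool(traj[-1, j] > cfg.compartments)
        for j, sp in enumerate(founders)
    }
    return RunOutcome(
        species=tuple(founders),
        survivor_state=survivor,
        trajectory=traj,
        sustained_all=all(survivor.values()),
    )
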