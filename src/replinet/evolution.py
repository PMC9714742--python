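"""Evolutionary transition simulation: stochastic appearance of replicators.

Starting from a single self-replicating host, a mutation step runs
immediately before each round's replication step.  New species appear per
(parent species, compartment) with probability min(1, r * rate), where r is
that parent's replication count in that compartment during the previous
round's replication step:

* host -> new host at 0.02 per replication (per-nucleotide replication
  error rate ~9.1e-6 times a ~2000 nt host genome);
* host -> new parasite at 0.001;
* parasite -> new parasite at 0.002 (parasites are ~10x shorter, hence the
  higher per-replication rate than host -> parasite).

New hosts draw replication coefficients uniformly from [1, 3], new
parasites from [0, 10].  To bound the computational cost the species count
is capped at three: the mutation step only runs while one or two species
are alive.  At most one new host type and one new parasite type appear
per round; by default both classes may appear in the same round (so the
count can transiently exceed the cap by one until a newcomer dies out).
A new species enters with exactly one copy in one compartment (drawn
uniformly among the compartments whose appearance test fired), so
establishment is a rare event governed by drift through culling and
fusion-division.  Each round the set of species whose global
total exceeds 1000
copies defines the classified network (H, HP, HHP, ...); a network
maintained for more than 100 consecutive rounds is recorded together with
the composition that immediately preceded it.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    HOST,
    PARASITE,
    CoefficientMatrix,
    ConfigurationError,
    Species,
    SpeciesRegistry,
    make_endpoint_cache,
)
from .cycle import (
    CycleConfig,
    PopulationState,
    cull,
    fuse_divide_many,
    replicate_population,
)

__all__ = [
    "EvolutionConfig",
    "AppearanceEvent",
    "MaintainedNetwork",
    "EvolutionLog",
    "mutation_step",
    "classify_network",
    "composition_label",
    "run_evolution",
    "run_evolution_batch",
    "predecessor_analysis",
    "mutation_rate_from_error_rate",
]

_SEED_MOD = 2**31 - 1


def mutation_rate_from_error_rate(
    per_nucleotide_rate: float, genome_length: int
) -> float:
    """Expected mutations per replication event of one genome.

    E.g. the Qbeta replicase error rate ~9.1e-6 per nucleotide on a
    ~2000 nt host RNA gives ~0.02 mutations per replication, the default
    host -> host appearance rate.
    """
    return per_nucleotide_rate * genome_length


@dataclass
class EvolutionConfig:
    """Rates and bookkeeping thresholds of the evolutionary simulation."""

    host_from_host_rate: float = 0.02
    parasite_from_host_rate: float = 0.001
    parasite_from_parasite_rate: float = 0.002
    host_coeff_range: Tuple[float, float] = (1.0, 3.0)
    parasite_coeff_range: Tuple[float, float] = (0.0, 10.0)
    species_cap: int = 3
    classification_threshold: int = 1000
    maintenance_window: int = 100
    founder_coefficient: float = 2.0
    rounds: int = 1000
    #: if True, every firing compartment receives one copy of the (single)
    #: new species instead of one uniformly chosen compartment.  With
    #: saturating appearance probabilities this makes new species enter
    #: with thousands of copies and establish immediately; kept only as an
    #: alternative reading of the appearance rule.
    multi_copy_appearance: bool = False
    #: how to resolve a round in which both a new host and a new parasite
    #: fire: 'both' admits both (the species count may transiently reach
    #: cap + 1 until newcomers die out or displace), 'host_first' and
    #: 'parasite_first' give the named class priority for the last free
    #: slot, 'random' breaks the tie with a fair coin.
    appearance_order: str = "both"

    _ORDERS = ("both", "host_first", "parasite_first", "random")

    def __post_init__(self) -> None:
        for rate in (
            self.host_from_host_rate,
            self.parasite_from_host_rate,
            self.parasite_from_parasite_rate,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError("appearance rates must lie in [0, 1]")
        for lo, hi in (self.host_coeff_range, self.parasite_coeff_range):
            if lo > hi or lo < 0:
                raise ConfigurationError("coefficient ranges must be ordered and >= 0")
        if self.species_cap < 1:
            raise ConfigurationError("species_cap must be >= 1")
        if self.rounds < 1:
            raise ConfigurationError("rounds must be positive")
        if self.appearance_order not in self._ORDERS:
            raise ConfigurationError(
                f"appearance_order must be one of {self._ORDERS}"
            )


@dataclass(frozen=True)
class AppearanceEvent:
    round_index: int
    parent_role: str
    species_id: str
    role: str
    compartments: Tuple[int, ...]
    coefficients: Dict[str, float]


@dataclass(frozen=True)
class MaintainedNetwork:
    """A classified composition persisting > maintenance_window rounds."""

    composition: frozenset
    label: str
    start: int
    end: int
    predecessor_label: str
    coefficients: Dict[Tuple[str, str], float]
    roles: Dict[str, str]

    @property
    def duration(self) -> int:
        return self.end - self.start + 1


@dataclass
class EvolutionLog:
    """Per-round records and derived statistics of one evolutionary run."""

    seed: int | None
    registry: SpeciesRegistry
    totals: List[Dict[str, int]]
    appearances: List[AppearanceEvent]
    timeline: List[frozenset]
    labels: List[str]
    maintained: List[MaintainedNetwork]
    extinct: bool
    extinction_round: int | None

    def totals_frame(self) -> pd.DataFrame:
        rows = []
        for rnd, totals in enumerate(self.totals):
            for sid, n in totals.items():
                rows.append((rnd, sid, self.registry[sid].role, n))
        return pd.DataFrame(
            rows, columns=["round", "species_id", "role", "global_total"]
        )

    def to_json(self, path=None) -> str:
        payload = {
            "seed": self.seed,
            "extinct": self.extinct,
            "extinction_round": self.extinction_round,
            "species": [
                {"id": sp.id, "role": sp.role, "birth_round": sp.birth_round}
                for sp in self.registry
            ],
            "appearances": [
                {
                    "round": ev.round_index,
                    "parent_role": ev.parent_role,
                    "species_id": ev.species_id,
                    "role": ev.role,
                    "compartments": list(ev.compartments),
                    "coefficients": ev.coefficients,
                }
                for ev in self.appearances
            ],
            "maintained": [
                {
                    "composition": sorted(net.composition),
                    "label": net.label,
                    "start": net.start,
                    "end": net.end,
                    "predecessor": net.predecessor_label,
                }
                for net in self.maintained
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def composition_label(roles: Iterable[str]) -> str:
    """Canonical topology label (e.g. HHP) from member roles; '' if empty."""
    roles = list(roles)
    return "H" * roles.count(HOST) + "P" * roles.count(PARASITE)


def classify_network(
    pop: PopulationState, cfg: EvolutionConfig | None = None
) -> Tuple[frozenset, str]:
    """Species with global totals strictly above the classification threshold.

    Returns (id set, topology label); the label is '' when no species
    clears the threshold.
    """
    threshold = (cfg or EvolutionConfig()).classification_threshold
    totals = pop.totals()
    members = frozenset(sid for sid, n in totals.items() if n > threshold)
    label = composition_label(
        pop.species[pop.ids.index(sid)].role for sid in members
    )
    return members, label


# ---------------------------------------------------------------------------
# Mutation step
# ---------------------------------------------------------------------------

def _draw_coefficients(
    new_sp: Species,
    existing: Sequence[Species],
    cfg: EvolutionConfig,
    rng: np.random.Generator,
) -> Dict[Tuple[str, str], float]:
    """Coefficients involving a newly appeared species.

    Template-side draws follow the template's class: k_j,new from [1, 3]
    for a new host and [0, 10] for a new parasite, for every replicase
    host j (including the new host itself).  A new host additionally draws
    its replicase-side coefficients onto the existing templates, again by
    template class.
    """
    lo_h, hi_h = cfg.host_coeff_range
    lo_p, hi_p = cfg.parasite_coeff_range
    coeffs: Dict[Tuple[str, str], float] = {}
    hosts = [sp for sp in existing if sp.role == HOST]
    if new_sp.role == HOST:
        for rep in hosts + [new_sp]:
            coeffs[(rep.id, new_sp.id)] = rng.uniform(lo_h, hi_h)
        for tpl in existing:
            lo, hi = (lo_h, hi_h) if tpl.role == HOST else (lo_p, hi_p)
            coeffs[(new_sp.id, tpl.id)] = rng.uniform(lo, hi)
    else:
        for rep in hosts:
            coeffs[(rep.id, new_sp.id)] = rng.uniform(lo_p, hi_p)
    return coeffs


def _append_species(
    pop: PopulationState,
    matrix: CoefficientMatrix,
    new_sp: Species,
    coeffs: Mapping[Tuple[str, str], float],
    compartments: Sequence[int],
) -> Tuple[PopulationState, CoefficientMatrix]:
    """Widen population and matrix by one species, one copy per firing."""
    counts = np.hstack(
        [pop.counts, np.zeros((pop.n_compartments, 1), dtype=np.int64)]
    )
    for c in compartments:
        counts[c, -1] += 1
    species = pop.species + (new_sp,)
    n = len(species)
    k = np.zeros((n, n))
    k[: n - 1, : n - 1] = matrix.k
    new_matrix = CoefficientMatrix(species, k=k)
    for (rep, tpl), value in coeffs.items():
        new_matrix.set(rep, tpl, value)
    return (
        PopulationState(counts, species, pop.round_index),
        new_matrix,
    )


def mutation_step(
    pop: PopulationState,
    matrix: CoefficientMatrix,
    prev_replications: Mapping[str, np.ndarray] | None,
    cfg: EvolutionConfig,
    rng: np.random.Generator,
    round_index: int = 0,
    id_counter: Dict[str, int] | None = None,
) -> Tuple[PopulationState, CoefficientMatrix, List[AppearanceEvent]]:
    """Stochastic appearance of new replicator species before replication.

    ``prev_replications`` maps parent species id to its per-compartment
    replication counts from the previous round's replication step (None or
    missing ids mean no replication, hence no appearances -- in particular
    round 1 has no mutation).  Skipped entirely unless the current species
    count is one or two.  The appearance test fires per (parent,
    compartment) with probability min(1, count * rate).  Per product class
    at most one new species appears per round; it receives exactly one
    copy in one compartment drawn uniformly among the firing compartments
    (all firing compartments receive a copy only under
    ``cfg.multi_copy_appearance``).  ``cfg.appearance_order`` resolves
    rounds in which both classes fire: by default both species are
    admitted; the priority policies give one class the last free slot.
    """
    n_live = len(pop.species)
    if n_live >= cfg.species_cap or not prev_replications:
        return pop, matrix, []

    rate_of = {
        (HOST, HOST): cfg.host_from_host_rate,
        (HOST, PARASITE): cfg.parasite_from_host_rate,
        (PARASITE, PARASITE): cfg.parasite_from_parasite_rate,
    }
    # per product class, the union of firing compartments over all parents
    firings: Dict[str, List[Tuple[int, str]]] = {HOST: [], PARASITE: []}
    for parent in pop.species:
        reps = prev_replications.get(parent.id)
        if reps is None:
            continue
        reps = np.asarray(reps)
        for product in (HOST, PARASITE):
            rate = rate_of.get((parent.role, product))
            if rate is None or rate == 0.0:
                continue
            p = np.minimum(reps * rate, 1.0)
            nz = np.nonzero(p)[0]
            if nz.size == 0:
                continue
            fired = nz[rng.random(nz.size) < p[nz]]
            firings[product].extend((int(c), parent.role) for c in fired)

    events: List[AppearanceEvent] = []
    order = cfg.appearance_order
    if order == "both":
        classes = (HOST, PARASITE)
        slots = 2  # both classes admitted; the count may transiently
        # exceed the cap by one until a newcomer dies out
    else:
        classes = (PARASITE, HOST) if order == "parasite_first" else (HOST, PARASITE)
        if order == "random" and rng.random() < 0.5:
            classes = (PARASITE, HOST)
        slots = cfg.species_cap - n_live
    if id_counter is None:
        id_counter = {HOST: sum(sp.role == HOST for sp in pop.species),
                      PARASITE: sum(sp.role == PARASITE for sp in pop.species)}
    for product in classes:
        fired = firings[product]
        if not fired or slots <= 0:
            continue
        if cfg.multi_copy_appearance:
            comps = [c for c, _ in fired]
            parent_role = fired[0][1]
        else:
            comp, parent_role = fired[int(rng.integers(len(fired)))]
            comps = [comp]
        id_counter[product] = id_counter.get(product, 0) + 1
        prefix = "H" if product == HOST else "P"
        new_sp = Species(
            f"{prefix}{id_counter[product]}", product, birth_round=round_index
        )
        coeffs = _draw_coefficients(new_sp, pop.species, cfg, rng)
        pop, matrix = _append_species(pop, matrix, new_sp, coeffs, comps)
        events.append(
            AppearanceEvent(
                round_index=round_index,
                parent_role=parent_role,
                species_id=new_sp.id,
                role=product,
                compartments=tuple(sorted(comps)),
                coefficients={f"{r}->{t}": v for (r, t), v in coeffs.items()},
            )
        )
        slots -= 1
    return pop, matrix, events


def _drop_extinct(
    pop: PopulationState, matrix: CoefficientMatrix
) -> Tuple[PopulationState, CoefficientMatrix, bool]:
    """Remove species with zero global total, freeing slots for new ones."""
    sums = pop.counts.sum(axis=0)
    alive = sums > 0
    if alive.all():
        return pop, matrix, False
    species = tuple(sp for sp, ok in zip(pop.species, alive) if ok)
    idx = np.nonzero(alive)[0]
    new_pop = PopulationState(
        pop.counts[:, idx], species, pop.round_index
    )
    new_matrix = CoefficientMatrix(species, k=matrix.k[np.ix_(idx, idx)])
    return new_pop, new_matrix, True


def _extract_maintained(
    timeline: Sequence[frozenset],
    labels: Sequence[str],
    registry: SpeciesRegistry,
    matrices: Mapping[frozenset, Dict[Tuple[str, str], float]],
    window: int,
) -> List[MaintainedNetwork]:
    """Maximal runs of identical non-empty compositions longer than window.

    The predecessor is the classified composition of the round immediately
    before the interval ('' when the interval starts the run or follows an
    unclassified round).
    """
    maintained: List[MaintainedNetwork] = []
    start = 0
    for i in range(1, len(timeline) + 1):
        if i < len(timeline) and timeline[i] == timeline[start]:
            continue
        comp = timeline[start]
        length = i - start
        if comp and length > window:
            maintained.append(
                MaintainedNetwork(
                    composition=comp,
                    label=labels[start],
                    start=start,
                    end=i - 1,
                    predecessor_label=labels[start - 1] if start > 0 else "",
                    coefficients=matrices.get(comp, {}),
                    roles={sid: registry[sid].role for sid in comp},
                )
            )
        start = i
    return maintained


def run_evolution(
    cfg: EvolutionConfig | None = None,
    cycle_cfg: CycleConfig | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> EvolutionLog:
    """One evolutionary run: mutation -> replication -> culling -> fusion.

    Starts from a single host self-replicating with the founder
    coefficient in every compartment and executes ``cfg.rounds`` rounds.
    Every round is classified by the >threshold species set; maintained
    networks, their predecessors and global extinction are extracted at
    the end.  Global extinction is absorbing and ends the round loop.
    """
    cfg = cfg or EvolutionConfig()
    cycle_cfg = cycle_cfg or CycleConfig()
    if rng is None:
        rng = np.random.default_rng(seed)

    founder = Species("H1", HOST, birth_round=0)
    registry = SpeciesRegistry([founder])
    matrix = CoefficientMatrix(
        [founder], coeffs={("H1", "H1"): cfg.founder_coefficient}
    )
    pop = PopulationState.initial_fill(
        [founder], cycle_cfg.compartments, cycle_cfg.dynamics.carrying_capacity
    )

    id_counter = {HOST: 1, PARASITE: 0}
    prev_replications: Dict[str, np.ndarray] | None = None
    cache = make_endpoint_cache()

    totals_log: List[Dict[str, int]] = [pop.totals()]
    timeline: List[frozenset] = []
    labels: List[str] = []
    appearances: List[AppearanceEvent] = []
    comp_matrices: Dict[frozenset, Dict[Tuple[str, str], float]] = {}
    extinct = False
    extinction_round: int | None = None

    for rnd in range(1, cfg.rounds + 1):
        pop, matrix, events = mutation_step(
            pop, matrix, prev_replications, cfg, rng,
            round_index=rnd, id_counter=id_counter,
        )
        if events:
            for ev in events:
                registry.add(
                    Species(ev.species_id, ev.role, birth_round=rnd)
                )
            appearances.extend(events)
            cache = make_endpoint_cache()  # matrix changed

        pop, replicated = replicate_population(
            pop, matrix, cycle_cfg, rng, cache=cache
        )
        prev_replications = {
            sp.id: replicated[:, j] for j, sp in enumerate(pop.species)
        }
        pop = cull(pop, cycle_cfg, rng)
        if cycle_cfg.fusion_frequency > 0:
            pop = fuse_divide_many(pop, cycle_cfg.fusion_frequency, rng)
        pop.round_index = rnd

        totals_log.append(pop.totals())
        comp, label = classify_network(pop, cfg)
        timeline.append(comp)
        labels.append(label)
        if comp and comp not in comp_matrices:
            comp_matrices[comp] = {
                (rep.id, tpl.id): matrix.get(rep.id, tpl.id)
                for rep in matrix.species
                for tpl in matrix.species
                if {rep.id, tpl.id} <= comp
            }

        pop, matrix, dropped = _drop_extinct(pop, matrix)
        if dropped:
            cache = make_endpoint_cache()
            prev_replications = {
                sid: arr
                for sid, arr in prev_replications.items()
                if sid in pop.ids
            }
        if len(pop.species) == 0:
            extinct = True
            extinction_round = rnd
            break

    if extinct:  # pad the remaining rounds: empty system stays empty
        missing = cfg.rounds - len(timeline)
        timeline.extend([frozenset()] * missing)
        labels.extend([""] * missing)
        totals_log.extend([{}] * missing)

    maintained = _extract_maintained(
        timeline, labels, registry, comp_matrices, cfg.maintenance_window
    )
    return EvolutionLog(
        seed=seed,
        registry=registry,
        totals=totals_log,
        appearances=appearances,
        timeline=timeline,
        labels=labels,
        maintained=maintained,
        extinct=extinct,
        extinction_round=extinction_round,
    )


def run_evolution_batch(
    n_runs: int,
    cfg: EvolutionConfig | None = None,
    cycle_cfg: CycleConfig | None = None,
    master_seed: int = 0,
    progress: bool = False,
) -> List[EvolutionLog]:
    """Independent evolutionary runs with seeds derived from a master seed."""
    runs = range(n_runs)
    if progress:
        from tqdm import tqdm

        runs = tqdm(runs, desc="evolution")
    logs = []
    for i in runs:
        ss = np.random.SeedSequence([int(master_seed), int(i)])
        seed = int(ss.generate_state(1)[0] % _SEED_MOD)
        logs.append(run_evolution(cfg, cycle_cfg, seed=seed))
    return logs


def maintained_counts(logs: Iterable[EvolutionLog]) -> Counter:
    """Runs in which each topology label was maintained at least once."""
    tally: Counter = Counter()
    for log in logs:
        for label in {net.label for net in log.maintained}:
            tally[label] += 1
    return tally


def extinction_fraction(logs: Sequence[EvolutionLog]) -> float:
    return sum(log.extinct for log in logs) / len(logs)


def predecessor_analysis(
    logs: Iterable[EvolutionLog], target_label: str = "HHP"
) -> Counter:
    """Predecessor-composition counts for maintained networks of one label.

    For every maintained network matching ``target_label``, counts the
    topology label of the classified network immediately preceding its
    interval ('none' when nothing preceded it).
    """
    tally: Counter = Counter()
    for log in logs:
        for net in log.maintained:
            if net.label == target_label:
                tally[net.predecessor_label or "none"] += 1
    return tally
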