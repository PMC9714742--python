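"""Sustainability screens over replication-coefficient grids.

Enumerates coefficient grids for the network topologies reachable with up
to three members (H, HH, HP, HPP, HHP, HHH), runs repeated serial-cycle
simulations per grid cell, and tallies runs by final survivor state.  The
full-network tally per cell is the heatmap value of the published screens;
partial-survivor states are tallied alongside.

Cells are independent work units: per-run seeds derive deterministically
from (master seed, cell index, run index), so execution order and
parallelism never change results.
"""

from __future__ import annotations

import itertools
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    HOST,
    PARASITE,
    CoefficientMatrix,
    ConfigurationError,
    Species,
)
from .cycle import CycleConfig, run_simulation

__all__ = [
    "COEFF_VALUES_MAIN",
    "COEFF_VALUES_EXTREME",
    "PARASITE_COEFF_VALUES",
    "TopologySpec",
    "SweepResult",
    "topology_spec",
    "build_grid",
    "run_sweep",
    "check_hhp_condition",
    "scaled_fusion_frequency",
]

#: Host coefficient values of the main screens; spans the experimentally
#: estimated range (2.0-2.3) plus one smaller and one larger value.
COEFF_VALUES_MAIN: Tuple[float, ...] = (1.7, 2.0, 2.3, 2.6)
#: Extreme host values probed in the supplementary screens.
COEFF_VALUES_EXTREME: Tuple[float, ...] = (0.2, 4.1)
#: Parasite coefficient axis: host values plus the experimental parasite
#: value (7.0) and larger ones.
PARASITE_COEFF_VALUES: Tuple[float, ...] = (
    0.2, 1.7, 2.0, 2.3, 2.6, 4.1, 7.0, 10.0, 20.0,
)

_SLOT_RE = re.compile(r"^k(\d)(\d)([HP])$")


def _parse_slot(slot: str) -> Tuple[int, int, str]:
    """'kjiX' -> (replicase host index j, template index i, class X)."""
    m = _SLOT_RE.match(slot)
    if not m:
        raise ConfigurationError(f"malformed coefficient slot {slot!r}")
    return int(m.group(1)), int(m.group(2)), m.group(3)


@dataclass
class TopologySpec:
    """A gridded screen over one network topology.

    ``free`` maps coefficient slots (e.g. ``'k21H'``) to the value list
    gridded over; ``fixed`` maps the remaining slots to constants.  Slots
    are named k<j><i><class>: replicase host j, template i, class H (host
    template) or P (parasite template).
    """

    name: str
    hosts: int
    parasites: int
    free: Dict[str, Tuple[float, ...]]
    fixed: Dict[str, float] = field(default_factory=dict)
    n_runs: int = 100

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ConfigurationError("n_runs must be >= 1")
        slots = set(self.free) | set(self.fixed)
        if set(self.free) & set(self.fixed):
            raise ConfigurationError("a slot cannot be both free and fixed")
        for slot in slots:
            j, i, cls = _parse_slot(slot)
            if not 1 <= j <= self.hosts:
                raise ConfigurationError(f"slot {slot}: no host {j}")
            bound = self.hosts if cls == "H" else self.parasites
            if not 1 <= i <= bound:
                raise ConfigurationError(f"slot {slot}: no template {i}")
        expected = self.hosts * self.hosts + self.hosts * self.parasites
        if len(slots) != expected:
            raise ConfigurationError(
                f"{self.name}: {len(slots)} slots given, topology needs {expected}"
            )
        if any(len(v) == 0 for v in self.free.values()):
            raise ConfigurationError("empty grid axis")

    @property
    def species(self) -> Tuple[Species, ...]:
        return tuple(
            [Species(f"H{i}", HOST) for i in range(1, self.hosts + 1)]
            + [Species(f"P{h}", PARASITE) for h in range(1, self.parasites + 1)]
        )

    @property
    def n_cells(self) -> int:
        return int(np.prod([len(v) for v in self.free.values()])) if self.free else 1


def topology_spec(name: str, n_runs: int | None = None, **overrides) -> TopologySpec:
    """Built-in grid definitions for the published screens.

    Names: ``h``, ``hh``, ``hp``, ``hpp``, ``hhp_sym``, ``hhp_asym``,
    ``hhh_cond1``, ``hhh_cond2``.  Keyword overrides replace individual
    free axes (pass a tuple) or fixed slots (pass a float), e.g.
    ``topology_spec('hhp_asym', k21P=1.0)`` for the intermediate-resistance
    variant.
    """
    key = name.lower()
    host_axis = COEFF_VALUES_MAIN
    host_axis_ext = tuple(sorted(COEFF_VALUES_MAIN + COEFF_VALUES_EXTREME))
    if key == "h":
        spec = TopologySpec("h", 1, 0, free={"k11H": host_axis_ext})
    elif key == "hh":
        spec = TopologySpec(
            "hh", 2, 0,
            free={s: host_axis for s in ("k11H", "k12H", "k21H", "k22H")},
        )
    elif key == "hp":
        spec = TopologySpec(
            "hp", 1, 1,
            free={"k11H": host_axis_ext, "k11P": PARASITE_COEFF_VALUES},
        )
    elif key == "hpp":
        spec = TopologySpec(
            "hpp", 1, 2,
            free={
                "k11H": host_axis_ext,
                "k11P": PARASITE_COEFF_VALUES,
                "k12P": PARASITE_COEFF_VALUES,
            },
        )
    elif key in ("hhp_sym", "hhp_asym"):
        spec = TopologySpec(
            key, 2, 1,
            free={s: host_axis for s in ("k11H", "k12H", "k21H", "k22H")},
            fixed={"k11P": 7.0, "k21P": 7.0 if key == "hhp_sym" else 0.1},
        )
    elif key in ("hhh_cond1", "hhh_cond2"):
        # host-pair values fixed at one sustainable HH cell:
        # condition 1 = low self- and high cross-replication,
        # condition 2 = balanced replication.
        pair = (
            {"k11H": 1.7, "k21H": 2.6, "k12H": 2.0, "k22H": 1.7}
            if key == "hhh_cond1"
            else {"k11H": 2.0, "k21H": 1.7, "k12H": 2.0, "k22H": 1.7}
        )
        spec = TopologySpec(
            key, 3, 0,
            free={
                "k31H": host_axis,
                "k32H": host_axis,
                "k13H": host_axis,
                "k23H": host_axis,
                "k33H": (1.7, 2.6),
            },
            fixed=pair,
        )
    else:
        raise ConfigurationError(f"unknown topology {name!r}")
    for slot, value in overrides.items():
        if slot in spec.free and isinstance(value, (tuple, list)):
            spec.free[slot] = tuple(value)
        elif slot in spec.fixed or slot in spec.free:
            spec.free.pop(slot, None)
            spec.fixed[slot] = float(value)
        else:
            raise ConfigurationError(f"unknown slot {slot!r} for {name}")
    if n_runs is not None:
        spec.n_runs = n_runs
    return spec


def _matrix_for(spec: TopologySpec, assignment: Mapping[str, float]) -> CoefficientMatrix:
    species = spec.species
    coeffs = {}
    for slot, value in {**spec.fixed, **assignment}.items():
        j, i, cls = _parse_slot(slot)
        template = f"H{i}" if cls == "H" else f"P{i}"
        coeffs[(f"H{j}", template)] = float(value)
    return CoefficientMatrix(species, coeffs=coeffs)


def build_grid(
    spec: TopologySpec,
) -> List[Tuple[Dict[str, float], CoefficientMatrix]]:
    """Cartesian product of the free axes, merged with the fixed slots.

    Returns (cell assignment, coefficient matrix) pairs in a deterministic
    order (itertools.product over sorted slot names).
    """
    slots = sorted(spec.free)
    cells = []
    for values in itertools.product(*(spec.free[s] for s in slots)):
        assignment = dict(zip(slots, values))
        cells.append((assignment, _matrix_for(spec, assignment)))
    if not cells:
        raise ConfigurationError(f"{spec.name}: empty grid")
    return cells


def _cell_is_diagonal(spec: TopologySpec, assignment: Mapping[str, float]) -> bool:
    """HH cells where Hosts 1 and 2 are identical (k11=k22 and k12=k21).

    On this diagonal the two hosts are the same species relabelled; the
    published screen omits these cells.
    """
    if spec.hosts != 2 or spec.parasites != 0:
        return False
    a = {**spec.fixed, **assignment}
    return a["k11H"] == a["k22H"] and a["k12H"] == a["k21H"]


@dataclass
class SweepResult:
    """Per-cell tallies of runs by final survivor state."""

    spec_name: str
    free_slots: Tuple[str, ...]
    cells: List[Dict[str, float]]
    tallies: List[Counter]
    n_runs: int
    diagonal: List[bool]
    species_ids: Tuple[str, ...]

    def sustained_counts(self) -> np.ndarray:
        """Per cell, the number of runs in which every species is sustained."""
        full = tuple(sorted(self.species_ids))
        return np.array([t.get(full, 0) for t in self.tallies], dtype=np.int64)

    def to_long_frame(self) -> pd.DataFrame:
        """One row per (cell, survivor state) with its run count."""
        rows = []
        for idx, (cell, tally) in enumerate(zip(self.cells, self.tallies)):
            for state, count in sorted(tally.items()):
                row = dict(cell)
                row["cell_index"] = idx
                row["survivors"] = "+".join(state) if state else "extinct"
                row["runs"] = count
                row["diagonal"] = self.diagonal[idx]
                rows.append(row)
        return pd.DataFrame(rows)

    def heatmap(self, x_slot: str, y_slot: str) -> pd.DataFrame:
        """Wide all-sustained-count table over two free slots.

        Remaining free slots must be single-valued across the grid.
        """
        counts = self.sustained_counts()
        df = pd.DataFrame(self.cells)
        df["sustained"] = counts
        others = [s for s in self.free_slots if s not in (x_slot, y_slot)]
        for s in others:
            if df[s].nunique() > 1:
                raise ConfigurationError(
                    f"slot {s} varies; fix it before projecting to a heatmap"
                )
        return df.pivot_table(
            index=y_slot, columns=x_slot, values="sustained", aggfunc="sum"
        )


def _survivor_state(outcome) -> Tuple[str, ...]:
    return tuple(sorted(sid for sid, ok in outcome.survivor_state.items() if ok))


def _run_seed(master_seed: int, cell_index: int, run_index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(cell_index), int(run_index)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_cell(
    spec: TopologySpec,
    cell_index: int,
    assignment: Mapping[str, float],
    matrix: CoefficientMatrix,
    cfg: CycleConfig,
    master_seed: int,
) -> Counter:
    """All runs of one grid cell; independent of every other cell."""
    tally: Counter = Counter()
    for run_index in range(spec.n_runs):
        seed = _run_seed(master_seed, cell_index, run_index)
        outcome = run_simulation(
            matrix, cfg=cfg, rng=np.random.default_rng(seed)
        )
        tally[_survivor_state(outcome)] += 1
    return tally


def run_sweep(
    spec: TopologySpec,
    cfg: CycleConfig | None = None,
    master_seed: int = 0,
    n_jobs: int = 1,
    progress: bool = False,
) -> SweepResult:
    """Run ``spec.n_runs`` independent simulations for every grid cell.

    Tallies runs by the set of sustained species; the all-sustained count
    per cell is the published heatmap value, the partial states the
    supplementary tallies.
    """
    cfg = cfg or CycleConfig()
    grid = build_grid(spec)
    iterator = enumerate(grid)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(list(iterator), desc=f"sweep {spec.name}")

    def _one(idx, assignment, matrix):
        return run_cell(spec, idx, assignment, matrix, cfg, master_seed)

    if n_jobs != 1:
        from joblib import Parallel, delayed

        tallies = Parallel(n_jobs=n_jobs)(
            delayed(_one)(idx, a, m) for idx, (a, m) in iterator
        )
    else:
        tallies = [_one(idx, a, m) for idx, (a, m) in iterator]

    return SweepResult(
        spec_name=spec.name,
        free_slots=tuple(sorted(spec.free)),
        cells=[a for a, _ in grid],
        tallies=list(tallies),
        n_runs=spec.n_runs,
        diagonal=[_cell_is_diagonal(spec, a) for a, _ in grid],
        species_ids=tuple(sp.id for sp in spec.species),
    )


def check_hhp_condition(matrix: CoefficientMatrix) -> bool:
    """Three-inequality sustainability heuristic for an HHP network.

    With Host 1 the parasite-susceptible host and Host 2 the resistant one
    (hosts are oriented so that k11P >= k21P), the network is flagged
    sustainable-like when all of the following hold:

    1. asymmetric parasite resistance: k11P > k21P (strict);
    2. the resistant host replicates the susceptible one more than itself:
       k21H > k22H;
    3. the susceptible host receives at least as much replication as the
       resistant one: k11H + k21H >= k12H + k22H.
    """
    hosts = [sp for sp in matrix.species if sp.role == HOST]
    parasites = [sp for sp in matrix.species if sp.role == PARASITE]
    if len(hosts) != 2 or len(parasites) != 1:
        raise ConfigurationError(
            "HHP condition requires exactly two hosts and one parasite"
        )
    p = parasites[0].id
    h1, h2 = hosts[0].id, hosts[1].id
    if matrix.get(h1, p) < matrix.get(h2, p):
        h1, h2 = h2, h1  # orient: Host 1 = parasite-susceptible
    k11p, k21p = matrix.get(h1, p), matrix.get(h2, p)
    k11, k21 = matrix.get(h1, h1), matrix.get(h2, h1)
    k12, k22 = matrix.get(h1, h2), matrix.get(h2, h2)
    return (k11p > k21p) and (k21 > k22) and (k11 + k21 >= k12 + k22)


def check_hhp_condition_row(row: Mapping[str, float]) -> bool:
    """The HHP condition on a flat slot->value mapping (one table row)."""
    species = (
        Species("H1", HOST), Species("H2", HOST), Species("P1", PARASITE),
    )
    coeffs = {}
    for slot in ("k11H", "k12H", "k21H", "k22H", "k11P", "k21P"):
        j, i, cls = _parse_slot(slot)
        coeffs[(f"H{j}", f"H{i}" if cls == "H" else f"P{i}")] = float(row[slot])
    return check_hhp_condition(CoefficientMatrix(species, coeffs=coeffs))


def scaled_fusion_frequency(
    compartments: int, base_compartments: int = 3000, base_frequency: int = 5000
) -> int:
    """Fusion-division frequency scaled proportionally to compartment count.

    Keeps the average number of fusion-division events per compartment
    constant, rounding down to a multiple of 500 (3000 -> 5000,
    10000 -> 16500).
    """
    if compartments < 1:
        raise ConfigurationError("compartments must be positive")
    raw = base_frequency * compartments / base_compartments
    return int(math.floor(raw / 500.0) * 500)
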