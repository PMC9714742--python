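"""Configuration files, run manifests, fixture generation and serialization.

Configs are YAML with optional sections ``cycle``, ``dynamics`` and
``evolution``; absent keys fall back to the model's standard conditions
(C = 3000 compartments, culling rate S = 0.25, fusion-division frequency
A = 5000, carrying capacity N = 100).  When ``cycle.compartments`` is
changed without an explicit ``fusion_frequency``, A is rescaled
proportionally so the average number of fusion-division events per
compartment stays constant.

A RunManifest snapshots the configuration, the master seed and derived
per-task seeds, so a manifest plus the package version determines every
output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd
import yaml

try:
    from importlib.metadata import version as _pkg_version

    _version = _pkg_version("replinet")
except Exception:  # pragma: no cover - not installed
    _version = "unknown"

from .core import (
    HOST,
    PARASITE,
    CoefficientMatrix,
    ConfigurationError,
    DynamicsConfig,
    Species,
)
from .cycle import CycleConfig
from .estimation import FoldTable
from .evolution import EvolutionConfig
from .sweep import SweepResult, check_hhp_condition_row, scaled_fusion_frequency

__all__ = [
    "RunManifest",
    "load_config",
    "make_fixture",
    "write_sweep_csv",
    "write_hhp_parameter_csv",
]

_NUCLEOTIDES = "ACGU"


# ---------------------------------------------------------------------------
# Config loading
# ---------------------------------------------------------------------------

def _build_section(cls, data: Mapping, name: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigurationError(
            f"unknown keys in section {name!r}: {sorted(unknown)}"
        )
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> Dict[str, object]:
    """Load and validate a YAML run configuration.

    Returns a dict with a ``cycle`` CycleConfig (dynamics filled in) and,
    when the file has an ``evolution`` section, an ``evolution``
    EvolutionConfig.  Validation errors name the offending fields.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    known = {"cycle", "dynamics", "evolution"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")

    dyn = _build_section(DynamicsConfig, raw.get("dynamics", {}), "dynamics")
    cycle_raw = dict(raw.get("cycle", {}))
    if "compartments" in cycle_raw and "fusion_frequency" not in cycle_raw:
        cycle_raw["fusion_frequency"] = scaled_fusion_frequency(
            int(cycle_raw["compartments"])
        )
    cycle = _build_section(CycleConfig, {**cycle_raw, "dynamics": dyn}, "cycle")

    out: Dict[str, object] = {"cycle": cycle}
    if "evolution" in raw:
        out["evolution"] = _build_section(
            EvolutionConfig, raw["evolution"], "evolution"
        )
    return out


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Snapshot that, with the code version, pins down a run's outputs."""

    command: str
    master_seed: int
    config: Dict[str, object] = field(default_factory=dict)
    derived_seeds: Dict[str, int] = field(default_factory=dict)
    outputs: List[str] = field(default_factory=list)
    version: str = _version

    def derive_seed(self, task: str) -> int:
        """Deterministic per-task seed recorded in the manifest."""
        ss = np.random.SeedSequence(
            [self.master_seed, abs(hash(task)) % (2**31)]
        )
        seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        self.derived_seeds[task] = seed
        return seed

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        payload["config"] = _jsonable(self.config)
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

def write_sweep_csv(result: SweepResult, out_dir) -> List[Path]:
    """Long-format tally CSV plus, when 2D, a wide heatmap CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    long_path = out_dir / f"sweep_{result.spec_name}_long.csv"
    result.to_long_frame().to_csv(long_path, index=False)
    paths.append(long_path)
    if len(result.free_slots) == 2:
        x, y = result.free_slots
        heat_path = out_dir / f"sweep_{result.spec_name}_heatmap.csv"
        result.heatmap(x, y).to_csv(heat_path)
        paths.append(heat_path)
    return paths


def write_hhp_parameter_csv(logs, path) -> pd.DataFrame:
    """Coefficient sets of maintained HHP networks, one row per network.

    Columns follow the flat slot layout (k11H ... k21P) with Host 1 the
    parasite-susceptible host, plus the three-inequality condition flag.
    """
    rows = []
    for run_index, log in enumerate(logs):
        for net in log.maintained:
            if net.label != "HHP":
                continue
            hosts = sorted(s for s in net.composition if net.roles[s] == HOST)
            (par,) = [s for s in net.composition if net.roles[s] == PARASITE]
            h1, h2 = hosts
            if net.coefficients[(h1, par)] < net.coefficients[(h2, par)]:
                h1, h2 = h2, h1
            row = {
                "run": run_index,
                "start_round": net.start,
                "k11H": net.coefficients[(h1, h1)],
                "k21H": net.coefficients[(h2, h1)],
                "k12H": net.coefficients[(h1, h2)],
                "k22H": net.coefficients[(h2, h2)],
                "k11P": net.coefficients[(h1, par)],
                "k21P": net.coefficients[(h2, par)],
            }
            row["condition"] = check_hhp_condition_row(row)
            rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=[
            "run", "start_round",
            "k11H", "k21H", "k12H", "k22H", "k11P", "k21P", "condition",
        ],
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# Fixture generation (synthetic inputs with known ground truth)
# ---------------------------------------------------------------------------

def _random_matrix(rng: np.random.Generator, n_hosts=2, n_parasites=1) -> CoefficientMatrix:
    species = [Species(f"H{i+1}", HOST) for i in range(n_hosts)] + [
        Species(f"P{h+1}", PARASITE) for h in range(n_parasites)
    ]
    matrix = CoefficientMatrix(species)
    for rep in species:
        if rep.role != HOST:
            continue
        for tpl in species:
            lo, hi = (1.0, 3.0) if tpl.role == HOST else (0.0, 10.0)
            matrix.set(rep.id, tpl.id, float(rng.uniform(lo, hi)))
    return matrix


def _fold_table_for(matrix: CoefficientMatrix, rng: np.random.Generator) -> FoldTable:
    """Fold table that the estimator inverts exactly back to ``matrix``.

    Self folds equal k_ii; cross assays draw an arbitrary competitor fold
    v[i][j][i] and set v[i][j][j] = k_ij * v[i][j][i] / k_ii.
    """
    table = FoldTable()
    hosts = [sp.id for sp in matrix.species if sp.role == HOST]
    for i in hosts:
        k_ii = matrix.get(i, i)
        table.add(i, i, i, k_ii)
        for sp in matrix.species:
            j = sp.id
            if j == i:
                continue
            v_iji = float(rng.uniform(0.5, 1.0)) * max(k_ii, 1e-6)
            v_ijj = matrix.get(i, j) * v_iji / k_ii
            table.add(i, j, i, v_iji)
            table.add(i, j, j, v_ijj)
    return table


def _sequence_pair(
    rng: np.random.Generator, length=200, distance=7
) -> Tuple[str, str]:
    if distance > length:
        raise ConfigurationError("distance cannot exceed length")
    seq = "".join(rng.choice(list(_NUCLEOTIDES), size=length))
    positions = rng.choice(length, size=distance, replace=False)
    other = list(seq)
    for pos in positions:
        other[pos] = rng.choice([b for b in _NUCLEOTIDES if b != seq[pos]])
    return seq, "".join(other)


def _s1data_like(
    rng: np.random.Generator, n_rows=218, n_pass=148
) -> pd.DataFrame:
    """Synthetic HHP coefficient table with an exact condition-pass count.

    Mimics the shape of the maintained-HHP parameter export: host
    coefficients in [1, 3], parasite coefficients in [0, 10], with exactly
    ``n_pass`` rows satisfying the three-inequality HHP condition
    (rejection-sampled against the checker itself).
    """
    rows = []
    want = [True] * n_pass + [False] * (n_rows - n_pass)
    rng.shuffle(want)
    for target in want:
        while True:
            row = {
                "k11H": rng.uniform(1, 3),
                "k21H": rng.uniform(1, 3),
                "k12H": rng.uniform(1, 3),
                "k22H": rng.uniform(1, 3),
                "k11P": rng.uniform(0, 10),
                "k21P": rng.uniform(0, 10),
            }
            if check_hhp_condition_row(row) == target:
                rows.append(row)
                break
    return pd.DataFrame(rows)


def make_fixture(
    kind: str,
    rng: np.random.Generator,
    out_dir=None,
    **kwargs,
) -> Dict[str, object]:
    """Generate small synthetic inputs with known ground truth.

    Kinds: ``coefficient_matrix`` (random matrix within the model's
    coefficient ranges), ``fold_table`` (assay table built by inverting
    the estimator, so recovery is exact), ``sequence_pair`` (equal-length
    sequences at a prescribed Hamming distance, default 7) and
    ``s1data_like`` (HHP coefficient table with an exact condition-pass
    count, default 148 of 218).  All outputs are synthetic stand-ins
    constructed by this package, not measured data.  When ``out_dir`` is
    given, files are written and their paths returned alongside the
    objects.
    """
    out: Dict[str, object] = {}
    if kind == "coefficient_matrix":
        matrix = _random_matrix(rng, **kwargs)
        out["matrix"] = matrix
        if out_dir is not None:
            path = Path(out_dir) / "synthetic_coefficients.csv"
            matrix.to_csv(path)
            out["path"] = path
    elif kind == "fold_table":
        matrix = kwargs.pop("matrix", None) or _random_matrix(rng, **kwargs)
        table = _fold_table_for(matrix, rng)
        out["matrix"] = matrix
        out["fold_table"] = table
        if out_dir is not None:
            path = Path(out_dir) / "synthetic_folds.csv"
            table.to_csv(path)
            out["path"] = path
    elif kind == "sequence_pair":
        seq_a, seq_b = _sequence_pair(rng, **kwargs)
        out["sequences"] = (seq_a, seq_b)
        if out_dir is not None:
            path = Path(out_dir) / "synthetic_pair.fasta"
            with open(path, "w") as fh:
                fh.write(f">synthetic_host_1\n{seq_a}\n>synthetic_host_2\n{seq_b}\n")
            out["path"] = path
    elif kind == "s1data_like":
        df = _s1data_like(rng, **kwargs)
        out["frame"] = df
        if out_dir is not None:
            path = Path(out_dir) / "synthetic_hhp_parameters.csv"
            df.to_csv(path, index=False)
            out["path"] = path
    else:
        raise ConfigurationError(f"unknown fixture kind {kind!r}")
    return out


# ---------------------------------------------------------------------------
# Plot helpers (optional conveniences; not used by the batch pipelines)
# ---------------------------------------------------------------------------

def plot_heatmap(result: SweepResult, x_slot: str, y_slot: str, ax=None):
    """All-sustained-count heatmap of a 2D sweep."""
    import matplotlib.pyplot as plt

    grid = result.heatmap(x_slot, y_slot)
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(grid.to_numpy(), origin="lower", aspect="auto")
    ax.set_xticks(range(grid.shape[1]), [str(v) for v in grid.columns])
    ax.set_yticks(range(grid.shape[0]), [str(v) for v in grid.index])
    ax.set_xlabel(x_slot)
    ax.set_ylabel(y_slot)
    ax.figure.colorbar(im, ax=ax, label="runs with all species sustained")
    return ax


def plot_trajectory(frame: pd.DataFrame, ax=None):
    """Per-species global totals against rounds (tidy trajectory frame)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for sid, sub in frame.groupby("species_id"):
        ax.plot(sub["round"], sub["global_total"], label=sid)
    ax.set_xlabel("round")
    ax.set_ylabel("global copy number")
    ax.set_yscale("symlog")
    ax.legend()
    return ax
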