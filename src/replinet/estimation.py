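"""Replication-coefficient estimation from two-step assay fold values.

The assay translates replicase from one RNA (RNA I) and then lets it
replicate RNA I together with a second template (RNA II).  The measured
quantity is the fold value

    v[i][j][h] = log10(concentration of h at 1 h / concentration at 0 h)

for the reaction with replicase source i, added template j, measured
species h (h is i or j).  Self-replication coefficients are read off
directly (k_ii = v[i][i][i]); cross coefficients are normalized by the
competition between the two templates present in the same tube:

    k_ij = k_ii * v[i][j][j] / v[i][j][i]

assuming the fold-value ratio of the competing RNAs equals the ratio of
their replication coefficients.  A Hamming-distance helper characterizes
the representative sequences the assay species derive from.
"""

from __future__ import annotations

import math
import warnings
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
)

__all__ = [
    "MeasurementError",
    "FoldTable",
    "EstimationResult",
    "fold_value",
    "estimate_coefficients",
    "hamming_distance",
]


class MeasurementError(ValueError):
    """Raised for physically impossible assay inputs."""


def fold_value(conc_start: float, conc_end: float) -> float:
    """Common-log fold value of a 0 -> 1 h concentration change.

    Both concentrations must be positive (same units; the ratio is
    unit-free).
    """
    if conc_start <= 0 or conc_end <= 0:
        raise MeasurementError(
            f"concentrations must be positive, got ({conc_start}, {conc_end})"
        )
    return math.log10(conc_end / conc_start)


@dataclass
class FoldTable:
    """Replicate-aware fold values keyed by (RNA I, RNA II, measured).

    ``values`` holds one or more replicate fold values per key; the
    estimator uses replicate means and reports standard deviations.
    """

    values: Dict[Tuple[str, str, str], List[float]] = field(default_factory=dict)

    def add(self, rna_i: str, rna_ii: str, measured: str, fold: float) -> None:
        if measured not in (rna_i, rna_ii):
            raise MeasurementError(
                f"measured species {measured!r} is neither RNA I nor RNA II"
            )
        self.values.setdefault((rna_i, rna_ii, measured), []).append(float(fold))

    def mean(self, rna_i: str, rna_ii: str, measured: str) -> float:
        return float(np.mean(self.values[(rna_i, rna_ii, measured)]))

    def std(self, rna_i: str, rna_ii: str, measured: str) -> float:
        reps = self.values[(rna_i, rna_ii, measured)]
        return float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0

    def __contains__(self, key: Tuple[str, str, str]) -> bool:
        return key in self.values

    @property
    def rna_i_species(self) -> Tuple[str, ...]:
        """Species that served as replicase source (hosts by definition)."""
        seen: Dict[str, None] = {}
        for (i, _, _) in self.values:
            seen.setdefault(i)
        return tuple(seen)

    @property
    def template_species(self) -> Tuple[str, ...]:
        seen: Dict[str, None] = {}
        for (i, j, _) in self.values:
            seen.setdefault(i)
            seen.setdefault(j)
        return tuple(seen)

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "FoldTable":
        """Load an assay CSV with columns
        (rna_I, rna_II, measured, replicate, conc_0h, conc_1h) or
        (rna_I, rna_II, measured, replicate, fold)."""
        df = pd.read_csv(path)
        required = {"rna_I", "rna_II", "measured"}
        if not required <= set(df.columns):
            raise MeasurementError(
                f"fold CSV needs columns {sorted(required)}, got {list(df.columns)}"
            )
        table = cls()
        for _, row in df.iterrows():
            if "fold" in df.columns:
                f = float(row["fold"])
            else:
                f = fold_value(float(row["conc_0h"]), float(row["conc_1h"]))
            table.add(str(row["rna_I"]), str(row["rna_II"]), str(row["measured"]), f)
        return table

    def to_csv(self, path) -> None:
        rows = [
            {
                "rna_I": i,
                "rna_II": j,
                "measured": h,
                "replicate": r + 1,
                "fold": f,
            }
            for (i, j, h), reps in sorted(self.values.items())
            for r, f in enumerate(reps)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class EstimationResult:
    """Estimated coefficients with replicate spread and missing entries."""

    coefficients: Dict[Tuple[str, str], float]
    std: Dict[Tuple[str, str], float]
    missing: List[Tuple[str, str]]
    hosts: Tuple[str, ...]
    parasites: Tuple[str, ...]

    def to_matrix(self) -> CoefficientMatrix:
        """Full CoefficientMatrix; entries never measured default to 0.

        Raises if any measured cross-assay was undefined (zero competitor
        fold), since that leaves a genuinely unknown coefficient.
        """
        if self.missing:
            raise MeasurementError(
                f"undefined coefficients for pairs {self.missing}"
            )
        species = [Species(h, HOST) for h in self.hosts] + [
            Species(p, PARASITE) for p in self.parasites
        ]
        matrix = CoefficientMatrix(species)
        for (rep, tpl), value in self.coefficients.items():
            matrix.set(rep, tpl, max(value, 0.0))  # negatives clamp to 0
        return matrix


def estimate_coefficients(folds: FoldTable) -> EstimationResult:
    """Estimate the replication-coefficient matrix from a fold table.

    Species that appear as RNA I are hosts (they produced active
    replicase); templates never used as RNA I are parasites.  Full
    precision is kept; presentation rounding is the caller's concern.
    Negative mean folds (net degradation in the assay) propagate with a
    warning; a zero competitor fold leaves the cross coefficient
    undefined and is reported as missing.
    """
    hosts = folds.rna_i_species
    if not hosts:
        raise MeasurementError("fold table contains no RNA I assays")
    parasites = tuple(s for s in folds.template_species if s not in hosts)
    coeffs: Dict[Tuple[str, str], float] = {}
    stds: Dict[Tuple[str, str], float] = {}
    missing: List[Tuple[str, str]] = []

    for i in hosts:
        if (i, i, i) not in folds:
            raise MeasurementError(f"missing self-assay for host {i!r}")
        k_ii = folds.mean(i, i, i)
        if k_ii < 0:
            warnings.warn(
                f"negative self fold for {i!r}; coefficient propagated as-is",
                stacklevel=2,
            )
        coeffs[(i, i)] = k_ii
        stds[(i, i)] = folds.std(i, i, i)
        for j in folds.template_species:
            if j == i:
                continue
            if (i, j, j) not in folds or (i, j, i) not in folds:
                continue
            v_jj = folds.mean(i, j, j)
            v_ji = folds.mean(i, j, i)
            if v_ji == 0.0:
                missing.append((i, j))
                continue
            k_ij = k_ii * v_jj / v_ji
            if k_ij < 0:
                warnings.warn(
                    f"negative fold ratio for ({i!r}, {j!r}); "
                    "coefficient propagated as-is",
                    stacklevel=2,
                )
            coeffs[(i, j)] = k_ij
            # first-order error propagation over the three replicate means
            rel = 0.0
            for key, mean in (((i, i, i), k_ii), ((i, j, j), v_jj), ((i, j, i), v_ji)):
                if mean != 0:
                    rel += (folds.std(*key) / mean) ** 2
            stds[(i, j)] = abs(k_ij) * math.sqrt(rel)
    return EstimationResult(
        coefficients=coeffs,
        std=stds,
        missing=missing,
        hosts=hosts,
        parasites=parasites,
    )


def hamming_distance(seq_a: str, seq_b: str) -> int:
    """Number of mismatched positions between equal-length sequences.

    Sequences must be pre-aligned and equal in length; comparisons across
    indels are out of scope (align first, or compare the indel-free
    segments).
    """
    a = str(seq_a).upper()
    b = str(seq_b).upper()
    if len(a) != len(b):
        raise ConfigurationError(
            f"sequences differ in length ({len(a)} vs {len(b)}); "
            "hamming_distance is alignment-free and needs equal lengths"
        )
    return sum(x != y for x, y in zip(a, b))
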