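"""Species bookkeeping, replication coefficients, and within-compartment dynamics.

A compartment is a well-mixed droplet holding integer copy numbers of host
and parasitic replicators.  Hosts encode their own replicase and can copy any
template; parasites are copied by host replicase but provide none.  Inside a
compartment the copy numbers follow coupled logistic equations

    dH_i/dt = H_i (sum_j k_ji^H H_j) (1 - (sum H + sum P) / N)
    dP_h/dt = P_h (sum_j k_jh^P H_j) (1 - (sum H + sum P) / N)

where ``k_ji`` is the coefficient with which replicase from host *j* copies
template *i* and *N* is the shared carrying capacity.  There is no
degradation term; an empty compartment stays empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from numba import njit

HOST = "host"
PARASITE = "parasite"

__all__ = [
    "HOST",
    "PARASITE",
    "Species",
    "SpeciesRegistry",
    "CoefficientMatrix",
    "CompartmentState",
    "DynamicsConfig",
    "ConfigurationError",
    "ReplicationNumericsError",
    "replicate_compartment",
    "integrate_compartments",
    "discretize_counts",
    "make_endpoint_cache",
]


class ConfigurationError(ValueError):
    """Raised for invalid species sets, coefficients or cycle parameters."""


class ReplicationNumericsError(RuntimeError):
    """Raised when the replication ODE produces non-finite output."""


# ---------------------------------------------------------------------------
# Species and coefficient bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Species:
    """A replicator species: a host (replicase-encoding) or a parasite.

    ``birth_round`` is 0 for founders and the appearance round for species
    created during an evolutionary run.
    """

    id: str
    role: str
    birth_round: int = 0

    def __post_init__(self) -> None:
        if self.role not in (HOST, PARASITE):
            raise ConfigurationError(
                f"species role must be '{HOST}' or '{PARASITE}', got {self.role!r}"
            )
        if self.birth_round < 0:
            raise ConfigurationError("birth_round must be non-negative")

    @property
    def is_host(self) -> bool:
        return self.role == HOST


class SpeciesRegistry:
    """Ordered set of species with unique ids."""

    def __init__(self, species: Iterable[Species] = ()) -> None:
        self._species: Dict[str, Species] = {}
        for sp in species:
            self.add(sp)

    def add(self, sp: Species) -> Species:
        if sp.id in self._species:
            raise ConfigurationError(f"duplicate species id {sp.id!r}")
        self._species[sp.id] = sp
        return sp

    def __contains__(self, sid: str) -> bool:
        return sid in self._species

    def __getitem__(self, sid: str) -> Species:
        return self._species[sid]

    def __iter__(self) -> Iterator[Species]:
        return iter(self._species.values())

    def __len__(self) -> int:
        return len(self._species)

    @property
    def ids(self) -> Tuple[str, ...]:
        return tuple(self._species)

    @property
    def hosts(self) -> Tuple[Species, ...]:
        return tuple(sp for sp in self if sp.role == HOST)

    @property
    def parasites(self) -> Tuple[Species, ...]:
        return tuple(sp for sp in self if sp.role == PARASITE)


class CoefficientMatrix:
    """Replication coefficients k[replicase j, template i] for a species set.

    Rows index the replicase provider, columns the template, mirroring the
    published table of estimated coefficients.  Parasites cannot provide
    replicase, so their rows are identically zero; all entries are >= 0.
    """

    def __init__(
        self,
        species: Sequence[Species],
        coeffs: Mapping[Tuple[str, str], float] | None = None,
        k: np.ndarray | None = None,
    ) -> None:
        self.species: Tuple[Species, ...] = tuple(species)
        ids = [sp.id for sp in self.species]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate species ids in coefficient matrix")
        self._index = {sid: i for i, sid in enumerate(ids)}
        n = len(self.species)
        if k is not None:
            arr = np.asarray(k, dtype=np.float64)
            if arr.shape != (n, n):
                raise ConfigurationError(f"coefficient array must be {n}x{n}")
            self.k = arr.copy()
        else:
            self.k = np.zeros((n, n), dtype=np.float64)
        if coeffs:
            for (rep, tpl), value in coeffs.items():
                self.set(rep, tpl, value)
        self.validate()

    # -- access ------------------------------------------------------------
    @property
    def ids(self) -> Tuple[str, ...]:
        return tuple(sp.id for sp in self.species)

    def index(self, sid: str) -> int:
        try:
            return self._index[sid]
        except KeyError:
            raise ConfigurationError(f"unknown species {sid!r}") from None

    def get(self, replicase: str, template: str) -> float:
        return float(self.k[self.index(replicase), self.index(template)])

    def set(self, replicase: str, template: str, value: float) -> None:
        j, i = self.index(replicase), self.index(template)
        if value < 0:
            raise ConfigurationError(
                f"coefficient k[{replicase},{template}] must be >= 0, got {value}"
            )
        if self.species[j].role == PARASITE and value != 0.0:
            raise ConfigurationError(
                f"parasite {replicase!r} cannot act as replicase"
            )
        self.k[j, i] = value

    def validate(self) -> None:
        if np.any(self.k < 0):
            raise ConfigurationError("replication coefficients must be >= 0")
        for j, sp in enumerate(self.species):
            if sp.role == PARASITE and np.any(self.k[j] != 0.0):
                raise ConfigurationError(
                    f"parasite {sp.id!r} has non-zero replicase coefficients"
                )

    @property
    def host_coeffs(self) -> Dict[Tuple[str, str], float]:
        """(replicase host, template host) -> k_ji^H."""
        return {
            (rj.id, ti.id): float(self.k[self.index(rj.id), self.index(ti.id)])
            for rj in self.species
            if rj.role == HOST
            for ti in self.species
            if ti.role == HOST
        }

    @property
    def parasite_coeffs(self) -> Dict[Tuple[str, str], float]:
        """(replicase host, template parasite) -> k_jh^P."""
        return {
            (rj.id, th.id): float(self.k[self.index(rj.id), self.index(th.id)])
            for rj in self.species
            if rj.role == HOST
            for th in self.species
            if th.role == PARASITE
        }

    # -- serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Rows = replicase species, columns = template species."""
        return pd.DataFrame(self.k, index=list(self.ids), columns=list(self.ids))

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.insert(0, "role", [sp.role for sp in self.species])
        df.to_csv(path, index_label="replicase")

    @classmethod
    def from_csv(cls, path) -> "CoefficientMatrix":
        df = pd.read_csv(path, index_col="replicase")
        roles = df.pop("role")
        species = [Species(str(sid), str(roles[sid])) for sid in df.index]
        if list(df.columns) != [sp.id for sp in species]:
            raise ConfigurationError("coefficient CSV rows and columns disagree")
        return cls(species, k=df.to_numpy(dtype=np.float64))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoefficientMatrix):
            return NotImplemented
        return (
            self.ids == other.ids
            and tuple(sp.role for sp in self.species)
            == tuple(sp.role for sp in other.species)
            and np.array_equal(self.k, other.k)
        )

    def __repr__(self) -> str:
        return f"CoefficientMatrix({list(self.ids)!r})"


# ---------------------------------------------------------------------------
# Compartment state and dynamics configuration
# ---------------------------------------------------------------------------

@dataclass
class CompartmentState:
    """Integer copy numbers of every species in one compartment."""

    counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, n in self.counts.items():
            if n < 0 or int(n) != n:
                raise ConfigurationError(
                    f"count for {sid!r} must be a non-negative integer, got {n}"
                )
            self.counts[sid] = int(n)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def is_empty(self) -> bool:
        return self.total == 0


@dataclass
class DynamicsConfig:
    """Parameters of the within-compartment replication step.

    carrying_capacity
        N, the copy-number ceiling shared by all compartments (default 100).
    horizon
        Integration time T of the replication step, model-time units.  The
        dynamics saturate at capacity, so the final composition is
        insensitive to T beyond saturation; default 1.0.
    rel_tol, abs_tol
        Adaptive solver tolerances.
    rounding_mode
        'stochastic' (floor plus Bernoulli on the fractional part; unbiased)
        or 'nearest' (deterministic, for reproducible unit checks).
    """

    carrying_capacity: int = 100
    horizon: float = 1.0
    rel_tol: float = 1e-6
    abs_tol: float = 1e-9
    rounding_mode: str = "stochastic"

    def __post_init__(self) -> None:
        if self.carrying_capacity <= 0:
            raise ConfigurationError("carrying_capacity must be positive")
        if self.horizon <= 0:
            raise ConfigurationError("horizon must be positive")
        if self.rounding_mode not in ("stochastic", "nearest"):
            raise ConfigurationError(
                f"unknown rounding_mode {self.rounding_mode!r}"
            )


# ---------------------------------------------------------------------------
# Numerical kernels (numba)
# ---------------------------------------------------------------------------
# Cash-Karp embedded Runge-Kutta 5(4) with standard step control.  The ODE is
# smooth and non-stiff at the coefficient magnitudes used here (k <= ~20,
# N = 100), and the state dimension is tiny (<= 3 in practice), so an explicit
# adaptive method is adequate and fast.  Compartments holding a single
# species below capacity are solved in closed form instead: the scalar ODE
# dy/dt = k y^2 (1 - y/N) separates to (1/N) ln(y/(N-y)) - 1/y = const + k t,
# inverted by a bisection-safeguarded Newton iteration.

_MAX_STEPS = 1_000_000


@njit(cache=True, fastmath=True)
def _deriv(y, k, n_cap, out):
    s = y.shape[0]
    tot = 0.0
    for i in range(s):
        tot += y[i]
    fac = 1.0 - tot / n_cap
    for i in range(s):
        lam = 0.0
        for j in range(s):
            lam += k[j, i] * y[j]
        out[i] = y[i] * lam * fac


@njit(cache=True, fastmath=True)
def _single_species_endpoint(y0, kk, n_cap, horizon):
    """Closed-form endpoint for one species with 0 < y0 < N and k > 0.

    Solves F(y) = F(y0) + k t for F(y) = ln(y/(N-y))/N - 1/y, the
    antiderivative of 1/(y^2 (1 - y/N)).  F is strictly increasing on
    (0, N), so the root is unique; Newton from y0 with bisection safeguard.
    """
    target = math.log(y0 / (n_cap - y0)) / n_cap - 1.0 / y0 + kk * horizon
    lo = y0
    hi = n_cap
    y = y0
    for _ in range(200):
        f = math.log(y / (n_cap - y)) / n_cap - 1.0 / y - target
        if f > 0.0:
            hi = y
        else:
            lo = y
        fp = 1.0 / (y * y * (1.0 - y / n_cap))
        step = f / fp
        ynew = y - step
        if not (lo < ynew < hi):
            ynew = 0.5 * (lo + hi)
        if abs(ynew - y) < 1e-12 * n_cap:
            y = ynew
            break
        y = ynew
    return y


@njit(cache=True, fastmath=True)
def _integrate_one(y, k, n_cap, horizon, rtol, atol, scratch):
    """Integrate one compartment in place; returns 0 on success, 1 on failure."""
    s = y.shape[0]
    k1 = scratch[0]
    k2 = scratch[1]
    k3 = scratch[2]
    k4 = scratch[3]
    k5 = scratch[4]
    k6 = scratch[5]
    ytmp = scratch[6]
    y5 = scratch[7]

    _deriv(y, k, n_cap, k1)
    allzero = True
    for i in range(s):
        if k1[i] != 0.0:
            allzero = False
            break
    if allzero:  # fixed point: empty, host-free, or exactly at capacity
        return 0

    dmax = 0.0
    ymax = 0.0
    for i in range(s):
        if abs(k1[i]) > dmax:
            dmax = abs(k1[i])
        if y[i] > ymax:
            ymax = y[i]
    t = 0.0
    dt = 0.05 * (ymax + 1.0) / dmax
    if dt > horizon:
        dt = horizon
    steps = 0
    while t < horizon:
        if steps > _MAX_STEPS:
            return 1
        steps += 1
        if t + dt > horizon:
            dt = horizon - t

        # Cash-Karp stages (k1 already holds f(y))
        for i in range(s):
            ytmp[i] = y[i] + dt * (0.2 * k1[i])
        _deriv(ytmp, k, n_cap, k2)
        for i in range(s):
            ytmp[i] = y[i] + dt * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
        _deriv(ytmp, k, n_cap, k3)
        for i in range(s):
            ytmp[i] = y[i] + dt * (0.3 * k1[i] - 0.9 * k2[i] + 1.2 * k3[i])
        _deriv(ytmp, k, n_cap, k4)
        for i in range(s):
            ytmp[i] = y[i] + dt * (
                -11.0 / 54.0 * k1[i]
                + 2.5 * k2[i]
                - 70.0 / 27.0 * k3[i]
                + 35.0 / 27.0 * k4[i]
            )
        _deriv(ytmp, k, n_cap, k5)
        for i in range(s):
            ytmp[i] = y[i] + dt * (
                1631.0 / 55296.0 * k1[i]
                + 175.0 / 512.0 * k2[i]
                + 575.0 / 13824.0 * k3[i]
                + 44275.0 / 110592.0 * k4[i]
                + 253.0 / 4096.0 * k5[i]
            )
        _deriv(ytmp, k, n_cap, k6)

        err = 0.0
        for i in range(s):
            y5[i] = y[i] + dt * (
                37.0 / 378.0 * k1[i]
                + 250.0 / 621.0 * k3[i]
                + 125.0 / 594.0 * k4[i]
                + 512.0 / 1771.0 * k6[i]
            )
            y4 = y[i] + dt * (
                2825.0 / 27648.0 * k1[i]
                + 18575.0 / 48384.0 * k3[i]
                + 13525.0 / 55296.0 * k4[i]
                + 277.0 / 14336.0 * k5[i]
                + 0.25 * k6[i]
            )
            ay = abs(y[i])
            ay5 = abs(y5[i])
            sc = atol + rtol * (ay if ay > ay5 else ay5)
            e = abs(y5[i] - y4) / sc
            if e > err:
                err = e
        if not math.isfinite(err):
            return 1

        if err <= 1.0:
            t += dt
            for i in range(s):
                y[i] = y5[i]
                if not math.isfinite(y[i]):
                    return 1
                if y[i] < 0.0:  # exact solution is non-negative; clip noise
                    y[i] = 0.0
            _deriv(y, k, n_cap, k1)
            fac = 5.0 if err == 0.0 else 0.9 * err ** -0.2
            if fac > 5.0:
                fac = 5.0
            dt *= fac
        else:
            fac = 0.9 * err ** -0.2
            if fac < 0.2:
                fac = 0.2
            dt *= fac
    return 0


@njit(inline="always", fastmath=True)
def _d3(y0, y1, y2, kk, n_cap):
    fac = 1.0 - (y0 + y1 + y2) / n_cap
    d0 = y0 * (kk[0, 0] * y0 + kk[1, 0] * y1 + kk[2, 0] * y2) * fac
    d1 = y1 * (kk[0, 1] * y0 + kk[1, 1] * y1 + kk[2, 1] * y2) * fac
    d2 = y2 * (kk[0, 2] * y0 + kk[1, 2] * y1 + kk[2, 2] * y2) * fac
    return d0, d1, d2


@njit(cache=True, fastmath=True)
def _integrate_one3(y, kk, n_cap, horizon, rtol, atol):
    """Unrolled Cash-Karp 5(4) for up to three species (registers only)."""
    y0 = y[0]
    y1 = y[1]
    y2 = y[2]
    a0, a1, a2 = _d3(y0, y1, y2, kk, n_cap)
    if a0 == 0.0 and a1 == 0.0 and a2 == 0.0:
        return 0
    dmax = max(abs(a0), abs(a1), abs(a2))
    ymax = max(y0, y1, y2)
    dt = 0.05 * (ymax + 1.0) / dmax
    if dt > horizon:
        dt = horizon
    t = 0.0
    steps = 0
    while t < horizon:
        if steps > _MAX_STEPS:
            return 1
        steps += 1
        if t + dt > horizon:
            dt = horizon - t

        b0, b1, b2 = _d3(
            y0 + dt * 0.2 * a0, y1 + dt * 0.2 * a1, y2 + dt * 0.2 * a2,
            kk, n_cap,
        )
        c0, c1, c2 = _d3(
            y0 + dt * (0.075 * a0 + 0.225 * b0),
            y1 + dt * (0.075 * a1 + 0.225 * b1),
            y2 + dt * (0.075 * a2 + 0.225 * b2),
            kk, n_cap,
        )
        d0, d1, d2 = _d3(
            y0 + dt * (0.3 * a0 - 0.9 * b0 + 1.2 * c0),
            y1 + dt * (0.3 * a1 - 0.9 * b1 + 1.2 * c1),
            y2 + dt * (0.3 * a2 - 0.9 * b2 + 1.2 * c2),
            kk, n_cap,
        )
        e0, e1, e2 = _d3(
            y0 + dt * (-11.0 / 54.0 * a0 + 2.5 * b0 - 70.0 / 27.0 * c0 + 35.0 / 27.0 * d0),
            y1 + dt * (-11.0 / 54.0 * a1 + 2.5 * b1 - 70.0 / 27.0 * c1 + 35.0 / 27.0 * d1),
            y2 + dt * (-11.0 / 54.0 * a2 + 2.5 * b2 - 70.0 / 27.0 * c2 + 35.0 / 27.0 * d2),
            kk, n_cap,
        )
        f0, f1, f2 = _d3(
            y0 + dt * (1631.0 / 55296.0 * a0 + 175.0 / 512.0 * b0 + 575.0 / 13824.0 * c0
                       + 44275.0 / 110592.0 * d0 + 253.0 / 4096.0 * e0),
            y1 + dt * (1631.0 / 55296.0 * a1 + 175.0 / 512.0 * b1 + 575.0 / 13824.0 * c1
                       + 44275.0 / 110592.0 * d1 + 253.0 / 4096.0 * e1),
            y2 + dt * (1631.0 / 55296.0 * a2 + 175.0 / 512.0 * b2 + 575.0 / 13824.0 * c2
                       + 44275.0 / 110592.0 * d2 + 253.0 / 4096.0 * e2),
            kk, n_cap,
        )

        z0 = y0 + dt * (37.0 / 378.0 * a0 + 250.0 / 621.0 * c0 + 125.0 / 594.0 * d0 + 512.0 / 1771.0 * f0)
        z1 = y1 + dt * (37.0 / 378.0 * a1 + 250.0 / 621.0 * c1 + 125.0 / 594.0 * d1 + 512.0 / 1771.0 * f1)
        z2 = y2 + dt * (37.0 / 378.0 * a2 + 250.0 / 621.0 * c2 + 125.0 / 594.0 * d2 + 512.0 / 1771.0 * f2)
        w0 = y0 + dt * (2825.0 / 27648.0 * a0 + 18575.0 / 48384.0 * c0 + 13525.0 / 55296.0 * d0
                        + 277.0 / 14336.0 * e0 + 0.25 * f0)
        w1 = y1 + dt * (2825.0 / 27648.0 * a1 + 18575.0 / 48384.0 * c1 + 13525.0 / 55296.0 * d1
                        + 277.0 / 14336.0 * e1 + 0.25 * f1)
        w2 = y2 + dt * (2825.0 / 27648.0 * a2 + 18575.0 / 48384.0 * c2 + 13525.0 / 55296.0 * d2
                        + 277.0 / 14336.0 * e2 + 0.25 * f2)

        sc0 = atol + rtol * max(abs(y0), abs(z0))
        sc1 = atol + rtol * max(abs(y1), abs(z1))
        sc2 = atol + rtol * max(abs(y2), abs(z2))
        err = max(abs(z0 - w0) / sc0, abs(z1 - w1) / sc1, abs(z2 - w2) / sc2)
        if not math.isfinite(err):
            return 1

        if err <= 1.0:
            t += dt
            y0 = z0 if z0 > 0.0 else 0.0
            y1 = z1 if z1 > 0.0 else 0.0
            y2 = z2 if z2 > 0.0 else 0.0
            if not (math.isfinite(y0) and math.isfinite(y1) and math.isfinite(y2)):
                return 1
            a0, a1, a2 = _d3(y0, y1, y2, kk, n_cap)
            fac = 5.0 if err == 0.0 else 0.9 * err ** -0.2
            if fac > 5.0:
                fac = 5.0
            dt *= fac
        else:
            fac = 0.9 * err ** -0.2
            if fac < 0.2:
                fac = 0.2
            dt *= fac
    y[0] = y0
    y[1] = y1
    y[2] = y2
    return 0


# Memoization of ODE endpoints: within one replication step (and across
# rounds of one run) the coefficient matrix and dynamics parameters are
# fixed, and compartment states are small integer vectors (counts stay below
# ~2N + 1 because growth saturates at N and fusion pools at most two
# compartments).  Endpoints for repeated integer initial states are
# therefore reused exactly -- a lookup, not an approximation.

_CACHE_BASE = 2048  # per-species count bound for cache keys


def make_endpoint_cache():
    """Fresh endpoint-memoization dict for one (matrix, dynamics) pair."""
    from numba.core import types
    from numba.typed import Dict

    return Dict.empty(types.int64, types.UniTuple(types.float64, 3))


@njit(cache=True)
def _integrate_all(yc, k, n_cap, horizon, rtol, atol, cache):
    """Integrate every compartment of a float (C, S) array in place.

    Returns the index of the first compartment with non-finite output,
    or -1 on success.  ``cache`` memoizes endpoints by integer initial
    state; it must belong to this (k, dynamics) pair.
    """
    n_comp, s = yc.shape
    small = s <= 3
    kk = np.zeros((3, 3))
    if small:
        for j in range(s):
            for i in range(s):
                kk[j, i] = k[j, i]
    scratch = np.empty((8, s))
    ybuf = np.zeros(3)
    for c in range(n_comp):
        tot = 0.0
        nz = -1
        n_nz = 0
        for i in range(s):
            if yc[c, i] > 0.0:
                nz = i
                n_nz += 1
                tot += yc[c, i]
        if n_nz == 0:
            continue
        if small:
            key = np.int64(0)
            cacheable = True
            for i in range(3):
                v = yc[c, i] if i < s else 0.0
                ybuf[i] = v
                iv = np.int64(v)
                if iv != v or iv >= _CACHE_BASE:
                    cacheable = False
                key = key * _CACHE_BASE + iv
            if cacheable and key in cache:
                hit = cache[key]
                for i in range(s):
                    yc[c, i] = hit[i]
                continue
            if n_nz == 1 and tot < n_cap and k[nz, nz] > 0.0:
                ybuf[nz] = _single_species_endpoint(
                    tot, k[nz, nz], n_cap, horizon
                )
            elif _integrate_one3(ybuf, kk, n_cap, horizon, rtol, atol) != 0:
                return c
            if cacheable:
                cache[key] = (ybuf[0], ybuf[1], ybuf[2])
            for i in range(s):
                yc[c, i] = ybuf[i]
        else:
            if n_nz == 1 and tot < n_cap and k[nz, nz] > 0.0:
                yc[c, nz] = _single_species_endpoint(
                    tot, k[nz, nz], n_cap, horizon
                )
                continue
            if _integrate_one(yc[c], k, n_cap, horizon, rtol, atol, scratch) != 0:
                return c
    return -1


# ---------------------------------------------------------------------------
# Python-facing operations
# ---------------------------------------------------------------------------

def integrate_compartments(
    counts: np.ndarray,
    k: np.ndarray,
    cfg: DynamicsConfig,
    cache=None,
) -> np.ndarray:
    """Continuous ODE solution after the replication step for a (C, S) batch.

    ``counts`` are integer initial conditions; the returned array is the
    un-rounded continuous endpoint at t = horizon.  ``cache`` (from
    :func:`make_endpoint_cache`) memoizes endpoints for repeated integer
    states; it must be dedicated to this (k, cfg) pair.
    """
    yc = counts.astype(np.float64)
    bad = _integrate_all(
        yc,
        np.ascontiguousarray(k, dtype=np.float64),
        float(cfg.carrying_capacity),
        float(cfg.horizon),
        float(cfg.rel_tol),
        float(cfg.abs_tol),
        cache if cache is not None else make_endpoint_cache(),
    )
    if bad >= 0:
        raise ReplicationNumericsError(
            f"non-finite replication output in compartment {bad} "
            f"(initial counts {counts[bad].tolist()})"
        )
    return yc


def discretize_counts(
    continuous: np.ndarray, mode: str, rng: np.random.Generator | None
) -> np.ndarray:
    """Convert continuous ODE output back to non-negative integer counts.

    'stochastic': floor plus a Bernoulli draw on the fractional part, which
    is unbiased in expectation.  'nearest': deterministic half-away rounding.
    """
    y = np.maximum(continuous, 0.0)
    if mode == "nearest":
        return np.rint(y).astype(np.int64)
    if rng is None:
        raise ConfigurationError("stochastic rounding requires an rng")
    lo = np.floor(y)
    frac = y - lo
    return (lo + (rng.random(y.shape) < frac)).astype(np.int64)


def replicate_compartment(
    state: CompartmentState,
    matrix: CoefficientMatrix,
    cfg: DynamicsConfig,
    rng: np.random.Generator | None = None,
) -> Tuple[CompartmentState, Dict[str, int]]:
    """Run the replication step for a single compartment.

    Integrates the coupled logistic equations over [0, horizon] from the
    integer initial condition, then discretizes per ``cfg.rounding_mode``.
    Returns the new state and, per species, the replication count
    max(new - old, 0).  Species absent from the compartment stay absent.
    """
    for sid in state.counts:
        if sid not in matrix.ids:
            raise ConfigurationError(
                f"species {sid!r} in compartment not covered by coefficient matrix"
            )
    old = np.array(
        [state.counts.get(sid, 0) for sid in matrix.ids], dtype=np.int64
    )
    cont = integrate_compartments(old[None, :], matrix.k, cfg)[0]
    cont[old == 0] = 0.0
    new = discretize_counts(cont, cfg.rounding_mode, rng)
    new_state = CompartmentState(
        {sid: int(n) for sid, n in zip(matrix.ids, new)}
    )
    replicated = {
        sid: int(max(n - o, 0)) for sid, n, o in zip(matrix.ids, new, old)
    }
    return new_state, replicated
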