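"""Configuration statistics for multilevel exponential random graph models.

A MERGM over the free layers (collaboration ``A``, actions ``X``) given the
exogenous CLD ``B`` and attributes ``Y`` has probability

    P(A = a, X = x | B = b, Y = y) = exp( sum_Q theta_Q z_Q(a, x, b, y) ) / kappa

where each ``z_Q`` counts (or geometrically smooths the counts of) a small
subgraph configuration.  This module defines the 23-effect catalogue used in
community steering-committee / causal-loop-diagram studies, grouped by level:

* within the directed collaboration network ``A``: Density, Reciprocity,
  In2Star, alternating in-/out-stars (AinS, AoutS), in/out-degree
  correlation (AinAoutS), alternating transitive and cyclic triangles
  (ATT, ACT), and categorical homophily (Edu_Match, Org_Match);
* within the bipartite action network ``X``: DensityX, alternating stars on
  the member side (ASA) and the variable side (ASB), and alternating
  two-paths between members sharing action targets (ACA);
* interactions: activity correlation ATXAX (level AX); CLD-degree /
  action-degree products In2StarBX, Out2StarBX, the cross-level triangle
  TXBX and reciprocated-path L3XBXreciprocity (level BX); and the
  cross-level three-paths and four-cycles L3AXBin, C4AXBentrainment,
  C4AXBexchange, C4AXBreciprocity (level AXB).

Counting conventions are over ordered node tuples with no symmetry division,
fixed so that each pictured minimal configuration counts exactly 1; TXBX
counts each *directed* CLD arc once, so a reciprocated CLD dyad under one
member contributes 2.  Alternating statistics use a damping parameter
``lambda > 1`` (default 2, the PNet/MPNet convention).

Besides closed-form evaluation the module provides exact change statistics
(the difference in every ``z_Q`` caused by toggling one ``A`` or ``X`` tie,
computed locally — the quantity that drives Metropolis acceptance) and an
independent brute-force oracle that re-counts every configuration by
exhaustive enumeration, used to validate the closed forms on small networks.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .netdata import MISSING, MultilevelNetwork

# ----------------------------------------------------------------------
# Specs and catalogue
# ----------------------------------------------------------------------

LEVELS = ("A", "X", "AX", "BX", "AXB")


@dataclass(frozen=True)
class ConfigurationSpec:
    """One named z_Q statistic with its smoothing and attribute binding."""

    name: str
    lam: float = 2.0
    attribute: str | None = None

    def __post_init__(self) -> None:
        if self.name not in CATALOGUE:
            raise KeyError(f"unknown configuration {self.name!r}; known: {sorted(CATALOGUE)}")
        meta = CATALOGUE[self.name]
        if meta.uses_lambda and not self.lam > 1:
            raise ValueError(f"{self.name}: smoothing lambda must exceed 1, got {self.lam}")
        if meta.needs_attribute and not self.attribute:
            raise ValueError(f"{self.name} requires an attribute name")

    @property
    def level(self) -> str:
        return CATALOGUE[self.name].level

    @property
    def label(self) -> str:
        return f"{self.name}[{self.attribute}]" if self.attribute else self.name


@dataclass(frozen=True)
class _Meta:
    level: str
    uses_lambda: bool = False
    needs_attribute: bool = False


CATALOGUE: dict[str, _Meta] = {
    # -- within A ------------------------------------------------------
    "Density": _Meta("A"),
    "Reciprocity": _Meta("A"),
    "In2Star": _Meta("A"),
    "AinS": _Meta("A", uses_lambda=True),
    "AoutS": _Meta("A", uses_lambda=True),
    "AinAoutS": _Meta("A", uses_lambda=True),
    "ATT": _Meta("A", uses_lambda=True),
    "ACT": _Meta("A", uses_lambda=True),
    "Edu_Match": _Meta("A", needs_attribute=True),
    "Org_Match": _Meta("A", needs_attribute=True),
    # -- within X ------------------------------------------------------
    "DensityX": _Meta("X"),
    "ASA": _Meta("X", uses_lambda=True),
    "ASB": _Meta("X", uses_lambda=True),
    "ACA": _Meta("X", uses_lambda=True),
    "ACA_variable": _Meta("X", uses_lambda=True),  # variable-anchored variant
    # -- interactions --------------------------------------------------
    "ATXAX": _Meta("AX", uses_lambda=True),
    "In2StarBX": _Meta("BX"),
    "Out2StarBX": _Meta("BX"),
    "TXBX": _Meta("BX"),
    "L3XBXreciprocity": _Meta("BX"),
    "L3AXBin": _Meta("AXB"),
    "C4AXBentrainment": _Meta("AXB"),
    "C4AXBexchange": _Meta("AXB"),
    "C4AXBreciprocity": _Meta("AXB"),
}

#: The 23 effects of the published catalogue (ACA_variable is an extra
#: variant kept for the anchoring ambiguity; it is not part of the 23).
CATALOGUE_23 = tuple(n for n in CATALOGUE if n != "ACA_variable")


def catalogue_json() -> str:
    """Export the statistic catalogue (name, level, lambda usage) as JSON."""
    return json.dumps(
        [
            {"name": n, "level": m.level, "uses_lambda": m.uses_lambda, "needs_attribute": m.needs_attribute}
            for n, m in CATALOGUE.items()
        ],
        indent=2,
    )


def default_specs(names: Iterable[str], lam: float = 2.0) -> list[ConfigurationSpec]:
    """Build specs for effect names, binding the conventional attributes."""
    attr = {"Edu_Match": "education", "Org_Match": "organisation"}
    return [ConfigurationSpec(n, lam=lam, attribute=attr.get(n)) for n in names]


# ----------------------------------------------------------------------
# Mutable network state with degree caches (shared with the sampler)
# ----------------------------------------------------------------------


class NetworkState:
    """Matrices of one multilevel network plus the degree caches the local
    change-statistic formulas consume.  ``B`` and attribute-derived arrays
    are exogenous and read-only; ``toggle_A``/``toggle_X`` flip one tie and
    update the caches incrementally."""

    __slots__ = ("A", "X", "B", "din_A", "dout_A", "dX_a", "dX_v",
                 "din_B", "dout_B", "M_B", "_match")

    def __init__(self, mnet: MultilevelNetwork):
        self.A = mnet.A.astype(np.int8).copy()
        self.X = mnet.X.astype(np.int8).copy()
        self.B = mnet.B.astype(np.int8)
        self.din_A = self.A.sum(axis=0, dtype=np.int64)
        self.dout_A = self.A.sum(axis=1, dtype=np.int64)
        self.dX_a = self.X.sum(axis=1, dtype=np.int64)
        self.dX_v = self.X.sum(axis=0, dtype=np.int64)
        self.din_B = self.B.sum(axis=0, dtype=np.int64)
        self.dout_B = self.B.sum(axis=1, dtype=np.int64)
        self.M_B = (self.B * self.B.T).astype(np.int8)
        self._match: dict[str, np.ndarray] = {}
        for col in mnet.Y.columns:
            y = mnet.Y[col].to_numpy(dtype=object)
            m = (y[:, None] == y[None, :]) & (y != MISSING)[:, None]
            self._match[col] = m.astype(np.int8)

    def match_matrix(self, attribute: str) -> np.ndarray:
        try:
            return self._match[attribute]
        except KeyError:
            raise KeyError(f"attribute {attribute!r} not present in the network's table") from None

    def toggle_A(self, i: int, j: int) -> None:
        new = 1 - self.A[i, j]
        self.A[i, j] = new
        d = 1 if new else -1
        self.dout_A[i] += d
        self.din_A[j] += d

    def toggle_X(self, i: int, v: int) -> None:
        new = 1 - self.X[i, v]
        self.X[i, v] = new
        d = 1 if new else -1
        self.dX_a[i] += d
        self.dX_v[v] += d


# ----------------------------------------------------------------------
# Closed-form values and local change statistics
# ----------------------------------------------------------------------

def _gw(deg: np.ndarray, lam: float) -> np.ndarray:
    # geometrically weighted star contribution per node:
    # lam^2 [ (1 - 1/lam)^d - 1 + d/lam ]
    q = 1.0 - 1.0 / lam
    return lam * lam * (q ** deg - 1.0 + deg / lam)


def _sat(deg: np.ndarray, lam: float) -> np.ndarray:
    # saturating activity: 1 - (1 - 1/lam)^d
    return 1.0 - (1.0 - 1.0 / lam) ** deg


class _Stat:
    """Evaluator for one configuration statistic.

    ``value`` computes z from scratch; ``delta_A``/``delta_X`` return the
    change in z caused by *adding* the given tie to a state in which it is
    absent.  Statistics blind to a layer inherit the zero default.
    """

    def __init__(self, spec: ConfigurationSpec):
        self.spec = spec
        self.lam = spec.lam
        self.q = 1.0 - 1.0 / spec.lam

    def value(self, st: NetworkState) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def delta_A(self, st: NetworkState, i: int, j: int) -> float:
        return 0.0

    def delta_X(self, st: NetworkState, i: int, v: int) -> float:
        return 0.0


class _Density(_Stat):
    def value(self, st):
        return float(st.A.sum())

    def delta_A(self, st, i, j):
        return 1.0


class _Reciprocity(_Stat):
    def value(self, st):
        return float((st.A * st.A.T).sum()) / 2.0

    def delta_A(self, st, i, j):
        return float(st.A[j, i])


class _In2Star(_Stat):
    def value(self, st):
        d = st.din_A
        return float((d * (d - 1) // 2).sum())

    def delta_A(self, st, i, j):
        return float(st.din_A[j])


class _AinS(_Stat):
    def value(self, st):
        return float(_gw(st.din_A, self.lam).sum())

    def delta_A(self, st, i, j):
        return self.lam * (1.0 - self.q ** st.din_A[j])


class _AoutS(_Stat):
    def value(self, st):
        return float(_gw(st.dout_A, self.lam).sum())

    def delta_A(self, st, i, j):
        return self.lam * (1.0 - self.q ** st.dout_A[i])


class _AinAoutS(_Stat):
    def value(self, st):
        return float(self.lam ** 2 * (_sat(st.din_A, self.lam) * _sat(st.dout_A, self.lam)).sum())

    def delta_A(self, st, i, j):
        lam, q = self.lam, self.q
        di = lam * q ** st.dout_A[i] * (1.0 - q ** st.din_A[i])
        dj = lam * q ** st.din_A[j] * (1.0 - q ** st.dout_A[j])
        return di + dj


class _ATT(_Stat):
    def value(self, st):
        A = st.A
        P = (A.astype(np.int64) @ A.astype(np.int64))
        return float(self.lam * (A * (1.0 - self.q ** P)).sum())

    def delta_A(self, st, i, j):
        A, q = st.A, self.q
        Ai, Aj = A[i, :].astype(np.int64), A[j, :].astype(np.int64)
        coli, colj = A[:, i].astype(np.int64), A[:, j].astype(np.int64)
        p_ij = int(Ai @ colj)
        out = self.lam * (1.0 - q ** p_ij)
        # existing ties i->k gaining the two-path i->j->k
        mask1 = Ai * Aj
        if mask1.any():
            p_ik = Ai @ A  # two-path counts for all targets k
            out += float((mask1 * q ** p_ik).sum())
        # existing ties k->j gaining the two-path k->i->j
        mask2 = colj * coli
        if mask2.any():
            p_kj = A.astype(np.int64) @ colj
            out += float((mask2 * q ** p_kj).sum())
        return out


class _ACT(_Stat):
    def value(self, st):
        A = st.A
        C = (A.astype(np.int64) @ A.astype(np.int64)).T
        return float(self.lam * (A * (1.0 - self.q ** C)).sum())

    def delta_A(self, st, i, j):
        A, q = st.A, self.q
        Ai, Aj = A[i, :].astype(np.int64), A[j, :].astype(np.int64)
        coli, colj = A[:, i].astype(np.int64), A[:, j].astype(np.int64)
        c_ij = int(Aj @ coli)  # cyclic paths j -> k -> i closing the new arc
        out = self.lam * (1.0 - q ** c_ij)
        mask = Aj * coli  # nodes x with j -> x and x -> i
        if mask.any():
            c_xi = Ai @ A       # c for ties x->i: paths i -> k -> x
            c_jx = A.astype(np.int64) @ colj  # c for ties j->x: paths x -> k -> j
            out += float((mask * (q ** c_xi + q ** c_jx)).sum())
        return out


class _Match(_Stat):
    def value(self, st):
        m = st.match_matrix(self.spec.attribute)
        return float((st.A * m).sum())

    def delta_A(self, st, i, j):
        return float(st.match_matrix(self.spec.attribute)[i, j])


class _DensityX(_Stat):
    def value(self, st):
        return float(st.X.sum())

    def delta_X(self, st, i, v):
        return 1.0


class _ASA(_Stat):
    def value(self, st):
        return float(_gw(st.dX_a, self.lam).sum())

    def delta_X(self, st, i, v):
        return self.lam * (1.0 - self.q ** st.dX_a[i])


class _ASB(_Stat):
    def value(self, st):
        return float(_gw(st.dX_v, self.lam).sum())

    def delta_X(self, st, i, v):
        return self.lam * (1.0 - self.q ** st.dX_v[v])


class _ACA(_Stat):
    """Alternating two-paths anchored on member pairs sharing action targets."""

    def value(self, st):
        X = st.X.astype(np.int64)
        S = X @ X.T
        iu = np.triu_indices(S.shape[0], k=1)
        return float(self.lam * (1.0 - self.q ** S[iu]).sum())

    def delta_X(self, st, i, v):
        X = st.X
        others = X[:, v].astype(bool).copy()
        others[i] = False
        if not others.any():
            return 0.0
        s = X.astype(np.int64) @ X[i, :].astype(np.int64)
        return float((self.q ** s[others]).sum())


class _ACAVariable(_Stat):
    """Variable-anchored variant: alternating counts of members shared by
    pairs of CLD variables."""

    def value(self, st):
        X = st.X.astype(np.int64)
        S = X.T @ X
        iu = np.triu_indices(S.shape[0], k=1)
        return float(self.lam * (1.0 - self.q ** S[iu]).sum())

    def delta_X(self, st, i, v):
        X = st.X
        others = X[i, :].astype(bool).copy()
        others[v] = False
        if not others.any():
            return 0.0
        s = X.T.astype(np.int64) @ X[:, v].astype(np.int64)
        return float((self.q ** s[others]).sum())


class _ATXAX(_Stat):
    def value(self, st):
        return float(self.lam ** 2 * (_sat(st.dout_A, self.lam) * _sat(st.dX_a, self.lam)).sum())

    def delta_A(self, st, i, j):
        return self.lam * self.q ** st.dout_A[i] * (1.0 - self.q ** st.dX_a[i])

    def delta_X(self, st, i, v):
        return self.lam * self.q ** st.dX_a[i] * (1.0 - self.q ** st.dout_A[i])


class _In2StarBX(_Stat):
    def value(self, st):
        return float((st.din_B * st.dX_v).sum())

    def delta_X(self, st, i, v):
        return float(st.din_B[v])


class _Out2StarBX(_Stat):
    def value(self, st):
        return float((st.dout_B * st.dX_v).sum())

    def delta_X(self, st, i, v):
        return float(st.dout_B[v])


class _TXBX(_Stat):
    def value(self, st):
        X = st.X.astype(np.int64)
        return float(((X @ st.B.astype(np.int64)) * X).sum())

    def delta_X(self, st, i, v):
        return float(st.X[i, :].astype(np.int64) @ (st.B[:, v] + st.B[v, :]).astype(np.int64))


class _L3XBXreciprocity(_Stat):
    def value(self, st):
        X, M = st.X.astype(np.int64), st.M_B.astype(np.int64)
        t = st.dX_v
        return float(t @ M @ t - ((X @ M) * X).sum())

    def delta_X(self, st, i, v):
        col = st.X.astype(np.int64) @ st.M_B[:, v].astype(np.int64)
        return float(2 * (col.sum() - col[i]))


class _L3AXBin(_Stat):
    def value(self, st):
        return float(st.din_A @ st.X.astype(np.int64) @ st.din_B)

    def delta_A(self, st, i, j):
        return float(st.X[j, :].astype(np.int64) @ st.din_B)

    def delta_X(self, st, i, v):
        return float(st.din_A[i] * st.din_B[v])


class _C4Entrainment(_Stat):
    def value(self, st):
        X, B = st.X.astype(np.int64), st.B.astype(np.int64)
        return float((st.A * (X @ B @ X.T)).sum())

    def delta_A(self, st, i, j):
        X, B = st.X.astype(np.int64), st.B.astype(np.int64)
        return float(X[i, :] @ B @ X[j, :])

    def delta_X(self, st, a, w):
        A = st.A.astype(np.int64)
        X, B = st.X.astype(np.int64), st.B.astype(np.int64)
        t1 = A[a, :] @ (X @ B[w, :])   # new tie is the source-side action
        t2 = A[:, a] @ (X @ B[:, w])   # new tie is the target-side action
        return float(t1 + t2)


class _C4Exchange(_Stat):
    def value(self, st):
        X, B = st.X.astype(np.int64), st.B.astype(np.int64)
        return float((st.A * (X @ B.T @ X.T)).sum())

    def delta_A(self, st, i, j):
        X, B = st.X.astype(np.int64), st.B.astype(np.int64)
        return float(X[j, :] @ B @ X[i, :])

    def delta_X(self, st, a, w):
        A = st.A.astype(np.int64)
        X, B = st.X.astype(np.int64), st.B.astype(np.int64)
        t1 = A[a, :] @ (X @ B[:, w])
        t2 = A[:, a] @ (X @ B[w, :])
        return float(t1 + t2)


class _C4Reciprocity(_Stat):
    def value(self, st):
        R = (st.A * st.A.T).astype(np.int64)
        X, M = st.X.astype(np.int64), st.M_B.astype(np.int64)
        return float((R * (X @ M @ X.T)).sum())

    def delta_A(self, st, i, j):
        if not st.A[j, i]:
            return 0.0
        X, M = st.X.astype(np.int64), st.M_B.astype(np.int64)
        return float(2 * (X[i, :] @ M @ X[j, :]))

    def delta_X(self, st, a, w):
        R = (st.A[a, :] * st.A[:, a]).astype(np.int64)
        X, M = st.X.astype(np.int64), st.M_B.astype(np.int64)
        return float(2 * (R @ (X @ M[:, w])))


_STAT_CLASSES: dict[str, type[_Stat]] = {
    "Density": _Density,
    "Reciprocity": _Reciprocity,
    "In2Star": _In2Star,
    "AinS": _AinS,
    "AoutS": _AoutS,
    "AinAoutS": _AinAoutS,
    "ATT": _ATT,
    "ACT": _ACT,
    "Edu_Match": _Match,
    "Org_Match": _Match,
    "DensityX": _DensityX,
    "ASA": _ASA,
    "ASB": _ASB,
    "ACA": _ACA,
    "ACA_variable": _ACAVariable,
    "ATXAX": _ATXAX,
    "In2StarBX": _In2StarBX,
    "Out2StarBX": _Out2StarBX,
    "TXBX": _TXBX,
    "L3XBXreciprocity": _L3XBXreciprocity,
    "L3AXBin": _L3AXBin,
    "C4AXBentrainment": _C4Entrainment,
    "C4AXBexchange": _C4Exchange,
    "C4AXBreciprocity": _C4Reciprocity,
}


def build_evaluators(specs: Sequence[ConfigurationSpec]) -> list[_Stat]:
    return [_STAT_CLASSES[s.name](s) for s in specs]


# ----------------------------------------------------------------------
# Public evaluation API
# ----------------------------------------------------------------------

@dataclass
class StatisticsVector:
    """Ordered (label -> value) evaluation of a spec list on one network."""

    specs: tuple[ConfigurationSpec, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.specs = tuple(self.specs)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.specs),):
            raise ValueError("one value per spec required")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite statistic value")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.specs)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, map(float, self.values)))

    def __getitem__(self, label: str) -> float:
        return self.as_dict()[label]


def _level_dispatch(spec: ConfigurationSpec, expected: str | tuple[str, ...]) -> None:
    levels = (expected,) if isinstance(expected, str) else expected
    if spec.level not in levels:
        raise ValueError(f"{spec.name} is level {spec.level}, expected one of {levels}")


def z_within_A(mnet: MultilevelNetwork, spec: ConfigurationSpec) -> float:
    """Evaluate one collaboration-level (A) statistic."""
    _level_dispatch(spec, "A")
    return _STAT_CLASSES[spec.name](spec).value(NetworkState(mnet))


def z_bipartite_X(mnet: MultilevelNetwork, spec: ConfigurationSpec) -> float:
    """Evaluate one action-level (X) statistic."""
    _level_dispatch(spec, "X")
    return _STAT_CLASSES[spec.name](spec).value(NetworkState(mnet))


def z_interaction(mnet: MultilevelNetwork, spec: ConfigurationSpec) -> float:
    """Evaluate one interaction (AX / BX / AXB) statistic."""
    _level_dispatch(spec, ("AX", "BX", "AXB"))
    return _STAT_CLASSES[spec.name](spec).value(NetworkState(mnet))


def evaluate_statistics(mnet: MultilevelNetwork, specs: Sequence[ConfigurationSpec]) -> StatisticsVector:
    """Evaluate an ordered list of configuration statistics on one network."""
    if not specs:
        raise ValueError("spec list must be non-empty")
    st = NetworkState(mnet)
    values = np.array([ev.value(st) for ev in build_evaluators(specs)])
    return StatisticsVector(tuple(specs), values)


def change_statistics(
    mnet: MultilevelNetwork,
    tie: tuple[str, int, int],
    specs: Sequence[ConfigurationSpec],
) -> np.ndarray:
    """Change vector Δz = z(tie present) − z(tie absent) for one free tie.

    ``tie`` is ``(layer, i, j)`` with layer ``"A"`` (j an actor index) or
    ``"X"`` (j a variable index).  The CLD layer is exogenous and cannot be
    toggled.
    """
    layer, i, j = tie
    if layer == "B":
        raise ValueError("layer B is exogenous; its ties cannot be toggled")
    if layer not in ("A", "X"):
        raise ValueError(f"unknown layer {layer!r}")
    st = NetworkState(mnet)
    if layer == "A":
        if not (0 <= i < st.A.shape[0] and 0 <= j < st.A.shape[0] and i != j):
            raise ValueError(f"invalid A tie ({i}, {j})")
        was = st.A[i, j]
        if was:
            st.toggle_A(i, j)
        out = np.array([ev.delta_A(st, i, j) for ev in build_evaluators(specs)])
        if was:
            st.toggle_A(i, j)
    else:
        if not (0 <= i < st.X.shape[0] and 0 <= j < st.X.shape[1]):
            raise ValueError(f"invalid X tie ({i}, {j})")
        was = st.X[i, j]
        if was:
            st.toggle_X(i, j)
        out = np.array([ev.delta_X(st, i, j) for ev in build_evaluators(specs)])
        if was:
            st.toggle_X(i, j)
    return out


# ----------------------------------------------------------------------
# Brute-force oracle
# ----------------------------------------------------------------------

def _alt_star(degrees: Iterable[int], lam: float) -> float:
    # alternating k-star series: sum_{k>=2} (-1)^k S_k / lam^(k-2),
    # S_k = number of k-in(out)-stars = sum_nodes C(d, k)
    total = 0.0
    for d in degrees:
        for k in range(2, int(d) + 1):
            total += (-1) ** k * math.comb(int(d), k) * lam ** (2 - k)
    return total


def _alt_sat(d: int, lam: float) -> float:
    # series form of 1 - (1 - 1/lam)^d = sum_{k>=1} (-1)^(k+1) C(d,k) / lam^k
    return sum((-1) ** (k + 1) * math.comb(d, k) * lam ** (-k) for k in range(1, d + 1))


def _alt_path(count: int, lam: float) -> float:
    # series form of lam (1 - (1-1/lam)^p) = sum_{k>=1} (-1)^(k+1) C(p,k) lam^(1-k)
    return sum((-1) ** (k + 1) * math.comb(count, k) * lam ** (1 - k) for k in range(1, count + 1))


def brute_force_count(mnet: MultilevelNetwork, spec: ConfigurationSpec) -> float:
    """Count a configuration statistic by exhaustive enumeration.

    Deliberately naive (explicit loops over ordered node tuples; alternating
    statistics as alternating sums over raw k-configuration counts) so it can
    serve as an independent oracle for the closed forms.  Limited to
    networks with at most 8 actors and 8 variables.
    """
    if mnet.n_actors > 8 or mnet.n_variables > 8:
        raise ValueError("brute-force oracle limited to n_A <= 8 and n_B <= 8")
    # plain int arrays: the naive sums below must not inherit narrow dtypes
    A = mnet.A.astype(np.int64)
    B = mnet.B.astype(np.int64)
    X = mnet.X.astype(np.int64)
    nA, nB = mnet.n_actors, mnet.n_variables
    lam = spec.lam
    actors = range(nA)
    variables = range(nB)
    name = spec.name

    if name == "Density":
        return float(sum(A[i, j] for i in actors for j in actors if i != j))
    if name == "Reciprocity":
        return float(sum(A[i, j] * A[j, i] for i in actors for j in actors if i < j))
    if name == "In2Star":
        return float(sum(
            A[i, j] * A[k, j]
            for j in actors for i, k in itertools.combinations(actors, 2)
            if i != j and k != j
        ))
    if name == "AinS":
        return _alt_star((sum(A[i, j] for i in actors) for j in actors), lam)
    if name == "AoutS":
        return _alt_star((sum(A[i, j] for j in actors) for i in actors), lam)
    if name == "AinAoutS":
        out = 0.0
        for i in actors:
            din = sum(A[k, i] for k in actors)
            dout = sum(A[i, k] for k in actors)
            out += lam ** 2 * _alt_sat(din, lam) * _alt_sat(dout, lam)
        return out
    if name == "ATT":
        out = 0.0
        for i in actors:
            for j in actors:
                if i != j and A[i, j]:
                    paths = sum(A[i, k] * A[k, j] for k in actors if k not in (i, j))
                    out += _alt_path(paths, lam)
        return out
    if name == "ACT":
        out = 0.0
        for i in actors:
            for j in actors:
                if i != j and A[i, j]:
                    cycles = sum(A[j, k] * A[k, i] for k in actors if k not in (i, j))
                    out += _alt_path(cycles, lam)
        return out
    if name in ("Edu_Match", "Org_Match"):
        y = mnet.attribute(spec.attribute)
        return float(sum(
            A[i, j]
            for i in actors for j in actors
            if i != j and y[i] != MISSING and y[i] == y[j]
        ))
    if name == "DensityX":
        return float(sum(X[i, v] for i in actors for v in variables))
    if name == "ASA":
        return _alt_star((sum(X[i, v] for v in variables) for i in actors), lam)
    if name == "ASB":
        return _alt_star((sum(X[i, v] for i in actors) for v in variables), lam)
    if name == "ACA":
        out = 0.0
        for i, j in itertools.combinations(actors, 2):
            shared = sum(X[i, v] * X[j, v] for v in variables)
            out += _alt_path(shared, lam)
        return out
    if name == "ACA_variable":
        out = 0.0
        for u, v in itertools.combinations(variables, 2):
            shared = sum(X[i, u] * X[i, v] for i in actors)
            out += _alt_path(shared, lam)
        return out
    if name == "ATXAX":
        out = 0.0
        for i in actors:
            dout = sum(A[i, k] for k in actors)
            dx = sum(X[i, v] for v in variables)
            out += lam ** 2 * _alt_sat(dout, lam) * _alt_sat(dx, lam)
        return out
    if name == "In2StarBX":
        return float(sum(
            B[u, v] * X[i, v]
            for v in variables for u in variables for i in actors
            if u != v
        ))
    if name == "Out2StarBX":
        return float(sum(
            B[v, u] * X[i, v]
            for v in variables for u in variables for i in actors
            if u != v
        ))
    if name == "TXBX":
        return float(sum(
            X[i, u] * X[i, v] * B[u, v]
            for i in actors for u in variables for v in variables
            if u != v
        ))
    if name == "L3XBXreciprocity":
        return float(sum(
            X[i, u] * X[j, v] * B[u, v] * B[v, u]
            for i in actors for j in actors if i != j
            for u in variables for v in variables if u != v
        ))
    if name == "L3AXBin":
        return float(sum(
            A[k, i] * X[i, v] * B[w, v]
            for i in actors for k in actors if k != i
            for v in variables for w in variables if w != v
        ))
    if name == "C4AXBentrainment":
        return float(sum(
            A[i, j] * X[i, u] * X[j, v] * B[u, v]
            for i in actors for j in actors if i != j
            for u in variables for v in variables if u != v
        ))
    if name == "C4AXBexchange":
        return float(sum(
            A[i, j] * X[i, u] * X[j, v] * B[v, u]
            for i in actors for j in actors if i != j
            for u in variables for v in variables if u != v
        ))
    if name == "C4AXBreciprocity":
        return float(sum(
            A[i, j] * A[j, i] * X[i, u] * X[j, v] * B[u, v] * B[v, u]
            for i in actors for j in actors if i != j
            for u in variables for v in variables if u != v
        ))
    raise KeyError(f"unknown configuration {name!r}")
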