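"""Data model and I/O for multilevel collaboration/CLD networks.

The object of study is a three-layer construct observed in community-based
systems interventions:

* ``A`` — a binary *directed* collaboration network among steering-committee
  members (``A[i, j] = 1`` iff member *i* nominated member *j*);
* ``B`` — a binary *directed* network over causal-loop-diagram (CLD)
  variables (``B[u, v] = 1`` iff driver *u* has a direct causal effect on
  driver *v*); ``B`` is exogenous: models condition on it and never alter it;
* ``X`` — a binary bipartite "action" incidence between members and CLD
  variables (``X[i, v] = 1`` iff member *i* reports working on driver *v*);
  a single undirected tie variable per member–variable pair;
* ``Y`` — categorical member attributes (organisation type, education
  level, gender).

Edge lists are carried as tab-separated records ``layer<TAB>source<TAB>target``
with layer tags ``A``, ``B`` or ``X``; attributes travel as a CSV with an
``id`` column.  Node indexing is positional (0-based) internally; files use
opaque string identifiers only.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mergm")

LAYERS = ("A", "B", "X")

#: Declared category code lists for the member attribute table.
ORGANISATION_TYPES = (
    "local government",
    "education",
    "health service",
    "primary care partnership",
    "primary health network",
    "other",
)
EDUCATION_LEVELS = (
    "less than year 12",
    "year 12 or equivalent",
    "diploma or advanced diploma",
    "bachelor's degree",
    "graduate certificate or graduate diploma",
    "master's degree",
)
GENDERS = ("female", "male", "other")

ATTRIBUTE_CODES: Mapping[str, tuple[str, ...]] = {
    "organisation": ORGANISATION_TYPES,
    "education": EDUCATION_LEVELS,
    "gender": GENDERS,
}

MISSING = ""  # canonical missing-value marker in attribute columns


class ValidationError(ValueError):
    """Raised when an input file or constructed network violates an invariant."""


def _unique(ids: Sequence[str], what: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if list(ids).count(i) > 1})
        raise ValidationError(f"duplicate {what} identifiers: {dupes}")
    return ids


@dataclass(frozen=True)
class MultilevelNetwork:
    """Bundle of the three network layers plus member attributes.

    Attributes
    ----------
    actors
        Ordered member identifiers (rows/columns of ``A``, rows of ``X``).
    variables
        Ordered CLD variable identifiers (rows/columns of ``B``, columns of
        ``X``).
    A, B, X
        Binary adjacency / incidence matrices (``int8``).
    Y
        Attribute table indexed by actor id; missing values are empty strings.
    """

    actors: tuple[str, ...]
    variables: tuple[str, ...]
    A: np.ndarray
    B: np.ndarray
    X: np.ndarray
    Y: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        object.__setattr__(self, "actors", _unique(self.actors, "actor"))
        object.__setattr__(self, "variables", _unique(self.variables, "variable"))
        n_a, n_b = len(self.actors), len(self.variables)
        if n_a < 2:
            raise ValidationError(f"need at least 2 actors, got {n_a}")
        if n_b < 1:
            raise ValidationError("need at least 1 CLD variable")
        for name, mat, shape in (
            ("A", self.A, (n_a, n_a)),
            ("B", self.B, (n_b, n_b)),
            ("X", self.X, (n_a, n_b)),
        ):
            arr = np.asarray(mat, dtype=np.int8)
            if arr.shape != shape:
                raise ValidationError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.isin(arr, (0, 1)).all():
                raise ValidationError(f"{name} must be binary")
            object.__setattr__(self, name, arr)
        for name in ("A", "B"):
            mat = getattr(self, name)
            if np.diagonal(mat).any():
                raise ValidationError(f"{name} has self-loops on its diagonal")
        y = self.Y
        if y is None or len(y) == 0:
            y = pd.DataFrame(index=pd.Index(self.actors, name="id"))
        else:
            y = y.copy()
            if "id" in y.columns:
                y = y.set_index("id")
            y.index = y.index.astype(str)
            missing = [a for a in self.actors if a not in y.index]
            if missing:
                raise ValidationError(f"attribute table lacks records for actors {missing}")
            extra = [i for i in y.index if i not in self.actors]
            if extra:
                raise ValidationError(f"attribute records for unknown actors {extra}")
            y = y.loc[list(self.actors)]
            y = y.fillna(MISSING).astype(str)
        object.__setattr__(self, "Y", y)

    # -- convenience ---------------------------------------------------
    @property
    def n_actors(self) -> int:
        return len(self.actors)

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def actor_index(self, actor_id: str) -> int:
        return self.actors.index(actor_id)

    def variable_index(self, variable_id: str) -> int:
        return self.variables.index(variable_id)

    def attribute(self, name: str) -> np.ndarray:
        """Per-actor values of one attribute column (empty string = missing)."""
        if name not in self.Y.columns:
            raise KeyError(f"unknown attribute {name!r}; have {list(self.Y.columns)}")
        return self.Y[name].to_numpy(dtype=object)

    def with_layers(self, A: np.ndarray | None = None, X: np.ndarray | None = None) -> "MultilevelNetwork":
        """Copy with replaced free layers (B and Y are exogenous, never replaced)."""
        return replace(self, A=self.A if A is None else A, X=self.X if X is None else X)

    def equal_layers(self, other: "MultilevelNetwork") -> bool:
        return (
            self.actors == other.actors
            and self.variables == other.variables
            and np.array_equal(self.A, other.A)
            and np.array_equal(self.B, other.B)
            and np.array_equal(self.X, other.X)
            and self.Y.equals(other.Y)
        )


# ----------------------------------------------------------------------
# Reading and writing
# ----------------------------------------------------------------------

def _read_edge_records(path: Path) -> list[tuple[str, str, str, int]]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if [p.strip().lower() for p in parts[:3]] == ["layer", "source", "target"]:
                continue  # optional header
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: expected 'layer<TAB>source<TAB>target', got {line!r}")
            layer, src, tgt = (p.strip() for p in parts[:3])
            if layer not in LAYERS:
                raise ValidationError(f"{path}:{lineno}: unknown layer tag {layer!r}")
            records.append((layer, src, tgt, lineno))
    return records


def read_multilevel(
    edge_paths: str | Path | Iterable[str | Path],
    attributes: str | Path | pd.DataFrame | None = None,
    actors: Sequence[str] | None = None,
    variables: Sequence[str] | None = None,
) -> MultilevelNetwork:
    """Read a :class:`MultilevelNetwork` from layered edge-list files.

    Each record routes to layer ``A`` (member -> member), ``B`` (variable ->
    variable) or ``X`` (member -> variable).  The actor registry comes from
    ``actors`` or, failing that, the attribute table; the variable registry
    from ``variables`` or, failing that, the union of identifiers seen in
    ``B``/``X`` records.  Endpoints not in an explicitly given registry raise
    a :class:`ValidationError` naming the offending record; duplicate records
    are accepted idempotently with a logged warning.

    An optional fourth column on ``B`` records (causal polarity ``+``/``-``)
    is read and collapsed to a plain binary tie.
    """
    if isinstance(variables, (str, Path)):
        variables = [
            ln.strip() for ln in Path(variables).read_text().splitlines() if ln.strip()
        ]
    if isinstance(edge_paths, (str, Path)):
        edge_paths = [edge_paths]
    paths = [Path(p) for p in edge_paths]
    records: list[tuple[str, str, str, str]] = []
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)
        records.extend((layer, s, t, f"{p}:{ln}") for layer, s, t, ln in _read_edge_records(p))

    y = None
    if attributes is not None:
        y = attributes if isinstance(attributes, pd.DataFrame) else pd.read_csv(attributes, dtype=str)

    actors_fixed = actors is not None
    if actors is None:
        if y is not None:
            actors = list(y["id"] if "id" in y.columns else y.index)
            actors_fixed = True
        else:
            seen: dict[str, None] = {}
            for layer, s, t, _ in records:
                if layer == "A":
                    seen.setdefault(s)
                    seen.setdefault(t)
                elif layer == "X":
                    seen.setdefault(s)
            actors = list(seen)
    variables_fixed = variables is not None
    if variables is None:
        seen = {}
        for layer, s, t, _ in records:
            if layer == "B":
                seen.setdefault(s)
                seen.setdefault(t)
            elif layer == "X":
                seen.setdefault(t)
        variables = list(seen)

    a_idx = {a: i for i, a in enumerate(map(str, actors))}
    v_idx = {v: i for i, v in enumerate(map(str, variables))}
    A = np.zeros((len(a_idx), len(a_idx)), dtype=np.int8)
    B = np.zeros((len(v_idx), len(v_idx)), dtype=np.int8)
    X = np.zeros((len(a_idx), len(v_idx)), dtype=np.int8)

    unknown: list[str] = []
    for layer, s, t, where in records:
        if layer in ("A", "B") and s == t:
            raise ValidationError(f"{where}: self-loop ({s} -> {t}) in layer {layer}")
        if layer == "A":
            reg_s, reg_t = a_idx, a_idx
            mat = A
        elif layer == "B":
            reg_s, reg_t = v_idx, v_idx
            mat = B
        else:
            reg_s, reg_t = a_idx, v_idx
            mat = X
        bad = [e for e, reg in ((s, reg_s), (t, reg_t)) if e not in reg]
        if bad:
            unknown.append(f"{where}: layer {layer} record ({s}, {t}) references unknown id(s) {bad}")
            continue
        i, j = reg_s[s], reg_t[t]
        if mat[i, j]:
            logger.warning("duplicate edge record at %s: layer %s (%s, %s)", where, layer, s, t)
        mat[i, j] = 1

    if unknown and (actors_fixed or variables_fixed):
        raise ValidationError("unknown endpoint identifiers:\n" + "\n".join(unknown))

    return MultilevelNetwork(tuple(map(str, actors)), tuple(map(str, variables)), A, B, X, y)


def write_multilevel(
    mnet: MultilevelNetwork,
    edge_path: str | Path,
    attr_path: str | Path | None = None,
    variables_path: str | Path | None = None,
) -> None:
    """Write a network as one layered TSV edge list (plus optional attribute
    CSV and variable-registry file, one id per line, which preserves
    variables that appear in no edge).

    ``read_multilevel`` on the written files reproduces the matrices and
    attributes exactly (the round-trip property the tests assert).
    """
    if variables_path is not None:
        Path(variables_path).write_text("\n".join(mnet.variables) + "\n")
    lines = ["layer\tsource\ttarget"]
    for i, j in zip(*np.nonzero(mnet.A)):
        lines.append(f"A\t{mnet.actors[i]}\t{mnet.actors[j]}")
    for u, v in zip(*np.nonzero(mnet.B)):
        lines.append(f"B\t{mnet.variables[u]}\t{mnet.variables[v]}")
    for i, v in zip(*np.nonzero(mnet.X)):
        lines.append(f"X\t{mnet.actors[i]}\t{mnet.variables[v]}")
    Path(edge_path).write_text("\n".join(lines) + "\n")
    if attr_path is not None:
        mnet.Y.rename_axis("id").reset_index().to_csv(attr_path, index=False)


def read_adjacency(path: str | Path) -> np.ndarray:
    """Read a small whitespace-delimited 0/1 adjacency matrix (test fixtures)."""
    return np.loadtxt(path, dtype=np.int8)


# ----------------------------------------------------------------------
# Transformations and summaries
# ----------------------------------------------------------------------

def restrict_to_respondents(mnet: MultilevelNetwork, respondents: Iterable[str]) -> MultilevelNetwork:
    """Restrict the free layers to survey respondents.

    Collaboration rows *and* columns and action rows are kept for respondents
    only — nominations of non-respondents are discarded, matching the
    convention that the modelled collaboration network contains respondents
    alone.  ``B`` is untouched.  Idempotent.
    """
    resp = [str(r) for r in respondents]
    if not resp:
        raise ValidationError("empty respondent set")
    unknown = [r for r in resp if r not in mnet.actors]
    if unknown:
        raise ValidationError(f"unknown respondent ids {unknown}")
    keep = [i for i, a in enumerate(mnet.actors) if a in set(resp)]
    actors = tuple(mnet.actors[i] for i in keep)
    return MultilevelNetwork(
        actors,
        mnet.variables,
        mnet.A[np.ix_(keep, keep)],
        mnet.B,
        mnet.X[keep, :],
        mnet.Y.loc[list(actors)] if len(mnet.Y.columns) else None,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def descriptive_summary(mnet: MultilevelNetwork, invited: int) -> dict:
    """Descriptive statistics of one community's multilevel network.

    Returns the survey response rate (as a rounded percentage), the mean and
    range of collaboration out-degree, the mean and range of the number of
    actions per member, the CLD size, and per-category attribute counts with
    percentages rounded half-up to integers.
    """
    if invited == 0:
        raise ValidationError("invited count must be positive")
    if invited < mnet.n_actors:
        raise ValidationError(f"invited ({invited}) < respondents ({mnet.n_actors})")
    out_deg = mnet.A.sum(axis=1)
    actions = mnet.X.sum(axis=1)
    summary = {
        "n_respondents": mnet.n_actors,
        "n_invited": int(invited),
        "response_rate_pct": _round_half_up(100.0 * mnet.n_actors / invited),
        "out_degree": {
            "mean": float(out_deg.mean()),
            "min": int(out_deg.min()),
            "max": int(out_deg.max()),
        },
        "actions_per_member": {
            "mean": float(actions.mean()),
            "min": int(actions.min()),
            "max": int(actions.max()),
        },
        "n_cld_variables": mnet.n_variables,
        "attributes": {},
    }
    for col in mnet.Y.columns:
        vals = mnet.Y[col]
        counts = vals[vals != MISSING].value_counts()
        summary["attributes"][col] = {
            str(cat): {"n": int(n), "pct": _round_half_up(100.0 * n / mnet.n_actors)}
            for cat, n in counts.items()
        }
    return summary


def summary_to_json(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
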