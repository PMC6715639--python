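"""Metropolis tie-toggle MCMC for multilevel ERGMs.

The sampler walks the joint space of the free layers (collaboration ``A``
and actions ``X``) conditional on the fixed CLD ``B`` and attributes ``Y``.
Each update proposes one tie variable — an ordered actor pair in ``A`` or an
actor–variable pair in ``X`` — and toggles it with the Metropolis
probability ``min(1, exp(theta . dz))`` where ``dz`` is the vector of local
change statistics.  By default every free tie variable is proposed with
equal probability, i.e. the A-versus-X proposal mix equals the proportion
of A tie variables among all free ties.

The running statistic vector is maintained incrementally from the accepted
change statistics and re-synchronised against a full evaluation at a long
fixed period to rule out floating-point drift.

``exact_enumeration_moments`` sums the Boltzmann weights over *every* graph
state of a tiny tie universe, giving the normalising constant and exact
expected statistics — the oracle the sampler is validated against.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .configs import (
    ConfigurationSpec,
    NetworkState,
    StatisticsVector,
    build_evaluators,
    evaluate_statistics,
)
from .netdata import MultilevelNetwork

_BUFFER = 8192
_RESYNC_PERIOD = 1_000_000


@dataclass(frozen=True)
class ModelSpec:
    """A MERGM: configuration statistics plus one parameter per statistic."""

    specs: tuple[ConfigurationSpec, ...]
    theta: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "specs", tuple(self.specs))
        theta = np.asarray(self.theta, dtype=float)
        if theta.shape != (len(self.specs),):
            raise ValueError("theta must hold one value per configuration spec")
        if not np.isfinite(theta).all():
            raise ValueError("theta must be finite")
        object.__setattr__(self, "theta", theta)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.specs)

    def with_theta(self, theta: np.ndarray) -> "ModelSpec":
        return ModelSpec(self.specs, np.asarray(theta, dtype=float))


@dataclass(frozen=True)
class MCMCSettings:
    """Tuning of the Metropolis chain.

    ``mix`` is the probability of proposing an A-tie toggle; ``None`` selects
    the uniform-over-tie-variables default.  ``burn_in`` updates are discarded
    before the first recorded sample and ``interval`` updates separate
    successive samples.
    """

    burn_in: int = 100_000
    interval: int = 10_000
    mix: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.interval < 1:
            raise ValueError("interval must be >= 1")
        if self.mix is not None and not (0.0 <= self.mix <= 1.0):
            raise ValueError("mix must lie in [0, 1]")


@dataclass
class SampleBatch:
    """Statistics (and optionally networks) recorded at the thinning interval."""

    labels: tuple[str, ...]
    stats: np.ndarray  # (n_samples, n_stats)
    networks: list[MultilevelNetwork] | None = None
    acceptance_rate: float = float("nan")

    def mean(self) -> np.ndarray:
        return self.stats.mean(axis=0)

    def sd(self) -> np.ndarray:
        return self.stats.std(axis=0, ddof=1)

    def cov(self) -> np.ndarray:
        return np.cov(self.stats, rowvar=False, ddof=1).reshape(len(self.labels), len(self.labels))

    def to_tsv(self, path: str | Path) -> None:
        header = "\t".join(self.labels)
        np.savetxt(path, self.stats, delimiter="\t", header=header, comments="")


def propose_toggle(
    mnet: MultilevelNetwork, settings: MCMCSettings, rng: np.random.Generator
) -> tuple[str, int, int]:
    """Draw one candidate tie: an ordered A pair or an X actor–variable pair."""
    n_a, n_b = mnet.n_actors, mnet.n_variables
    n_pairs_a = n_a * (n_a - 1)
    n_pairs_x = n_a * n_b
    mix = settings.mix if settings.mix is not None else n_pairs_a / (n_pairs_a + n_pairs_x)
    if rng.random() < mix:
        r = int(rng.integers(n_pairs_a))
        i, j = divmod(r, n_a - 1)
        if j >= i:
            j += 1
        return ("A", i, j)
    r = int(rng.integers(n_pairs_x))
    return ("X", r // n_b, r % n_b)


class MetropolisSampler:
    """Single Metropolis chain over (A, X) at fixed theta.

    Keeps the current network state, its statistic vector, and buffered
    random draws.  ``theta`` may be reassigned between runs (used by the
    stochastic-approximation estimator, which interleaves short runs with
    parameter updates on one continuing chain).
    """

    def __init__(self, start: MultilevelNetwork, model: ModelSpec, settings: MCMCSettings,
                 rng: np.random.Generator | None = None):
        self.mnet = start
        self.model = model
        self.settings = settings
        self.rng = rng if rng is not None else np.random.default_rng(settings.seed)
        self.state = NetworkState(start)
        self.evals = build_evaluators(model.specs)
        self.theta = [float(t) for t in model.theta]
        self.z = [ev.value(self.state) for ev in self.evals]
        n_a, n_b = start.n_actors, start.n_variables
        self._n_a, self._n_b = n_a, n_b
        self._n_pairs_a = n_a * (n_a - 1)
        self._n_pairs_x = n_a * n_b
        mix = settings.mix
        if mix is None:
            mix = self._n_pairs_a / (self._n_pairs_a + self._n_pairs_x)
        self._mix = mix
        self._steps = 0
        self._accepted = 0
        self._buf_pos = _BUFFER
        self._since_resync = 0

    # -- internals -----------------------------------------------------
    def _refill(self) -> None:
        self._u_layer = self.rng.random(_BUFFER)
        self._u_accept = self.rng.random(_BUFFER)
        if self._n_pairs_a:
            self._idx_a = self.rng.integers(0, self._n_pairs_a, size=_BUFFER)
        if self._n_pairs_x:
            self._idx_x = self.rng.integers(0, self._n_pairs_x, size=_BUFFER)
        self._buf_pos = 0

    def set_theta(self, theta: Sequence[float]) -> None:
        if len(theta) != len(self.theta):
            raise ValueError("theta length mismatch")
        self.theta = [float(t) for t in theta]

    def resync(self) -> None:
        """Recompute the running statistic vector from scratch."""
        self.z = [ev.value(self.state) for ev in self.evals]
        self._since_resync = 0

    def step(self) -> bool:
        """One Metropolis update; returns True if the toggle was accepted."""
        if self._buf_pos >= _BUFFER:
            self._refill()
        pos = self._buf_pos
        self._buf_pos += 1
        st = self.state
        if self._u_layer[pos] < self._mix:
            r = int(self._idx_a[pos])
            i, j = divmod(r, self._n_a - 1)
            if j >= i:
                j += 1
            present = st.A[i, j]
            if present:
                st.toggle_A(i, j)
            deltas = [ev.delta_A(st, i, j) for ev in self.evals]
            toggle = st.toggle_A
        else:
            r = int(self._idx_x[pos])
            i, j = r // self._n_b, r % self._n_b
            present = st.X[i, j]
            if present:
                st.toggle_X(i, j)
            deltas = [ev.delta_X(st, i, j) for ev in self.evals]
            toggle = st.toggle_X
        logr = 0.0
        for t, d in zip(self.theta, deltas):
            logr += t * d
        if not math.isfinite(logr):
            raise FloatingPointError(
                f"non-finite change-statistic dot product at tie ({i}, {j})"
            )
        if present:
            logr = -logr
        accept = logr >= 0.0 or self._u_accept[pos] < math.exp(logr)
        # state currently has the tie absent; restore or commit
        if accept:
            if not present:
                toggle(i, j)
                for k, d in enumerate(deltas):
                    self.z[k] += d
            else:
                for k, d in enumerate(deltas):
                    self.z[k] -= d
            self._accepted += 1
        elif present:
            toggle(i, j)
        self._steps += 1
        self._since_resync += 1
        if self._since_resync >= _RESYNC_PERIOD:
            self.resync()
        return accept

    def run(self, n_steps: int) -> None:
        for _ in range(n_steps):
            self.step()

    @property
    def acceptance_rate(self) -> float:
        return self._accepted / self._steps if self._steps else float("nan")

    def current_network(self) -> MultilevelNetwork:
        return self.mnet.with_layers(A=self.state.A.copy(), X=self.state.X.copy())

    def current_stats(self) -> np.ndarray:
        return np.array(self.z, dtype=float)

    def sample(self, n_samples: int, interval: int, keep_networks: bool = False) -> SampleBatch:
        stats = np.empty((n_samples, len(self.evals)))
        networks = [] if keep_networks else None
        for s in range(n_samples):
            self.run(interval)
            stats[s] = self.z
            if keep_networks:
                networks.append(self.current_network())
        return SampleBatch(self.model.labels, stats, networks, self.acceptance_rate)


def mcmc_sample(
    start: MultilevelNetwork,
    model: ModelSpec,
    settings: MCMCSettings,
    n_samples: int,
    keep_networks: bool = False,
    rng: np.random.Generator | None = None,
) -> SampleBatch:
    """Draw ``n_samples`` statistic vectors from the MERGM at ``model.theta``.

    Runs ``settings.burn_in`` updates, then records every
    ``settings.interval`` updates.  Deterministic given
    ``settings.seed`` (or an explicit ``rng``).
    """
    sampler = MetropolisSampler(start, model, settings, rng=rng)
    sampler.run(settings.burn_in)
    return sampler.sample(n_samples, settings.interval, keep_networks)


def empty_start(mnet: MultilevelNetwork) -> MultilevelNetwork:
    """The network with the same B/Y but empty free layers (simulation start)."""
    return mnet.with_layers(A=np.zeros_like(mnet.A), X=np.zeros_like(mnet.X))


def proposal_mix(specs: Sequence[ConfigurationSpec], n_a: int, n_b: int) -> float:
    """A-toggle probability that proposes each *modelled* tie variable uniformly.

    A layer no statistic touches is held at its start state (probability 0
    or 1), conditioning the model on it.
    """
    a_free = any(s.level in ("A", "AX", "AXB") for s in specs)
    x_free = any(s.level in ("X", "AX", "BX", "AXB") for s in specs)
    if not (a_free or x_free):
        raise ValueError("model touches neither free layer")
    if not x_free:
        return 1.0
    if not a_free:
        return 0.0
    n_pairs_a = n_a * (n_a - 1)
    return n_pairs_a / (n_pairs_a + n_a * n_b)


# ----------------------------------------------------------------------
# Exact enumeration oracle
# ----------------------------------------------------------------------

def exact_enumeration_moments(
    model: ModelSpec,
    n_A: int,
    n_B: int,
    B: np.ndarray | None = None,
    Y=None,
    actors: Sequence[str] | None = None,
    variables: Sequence[str] | None = None,
) -> tuple[StatisticsVector, float]:
    """Exact E[z] and normalising constant kappa by summing the whole graph space.

    Enumerates every assignment of the ``n_A (n_A - 1) + n_A n_B`` free tie
    variables (bounded at 20, i.e. about a million states), weights each
    state by ``exp(theta . z)`` and returns the expected statistics vector
    together with kappa.  Intractable beyond toy sizes by design — this is
    the independent gold standard for the Metropolis sampler.
    """
    free_a = [(i, j) for i in range(n_A) for j in range(n_A) if i != j]
    n_free = len(free_a) + n_A * n_B
    if n_free > 20:
        raise ValueError(f"{n_free} free tie variables exceeds the enumeration bound of 20")
    if B is None:
        B = np.zeros((n_B, n_B), dtype=np.int8)
    template = MultilevelNetwork(
        tuple(actors) if actors else tuple(f"m{i}" for i in range(n_A)),
        tuple(variables) if variables else tuple(f"v{i}" for i in range(n_B)),
        np.zeros((n_A, n_A), dtype=np.int8),
        B,
        np.zeros((n_A, n_B), dtype=np.int8),
        Y,
    )
    theta = model.theta
    log_weights = []
    zs = []
    free_x = list(itertools.product(range(n_A), range(n_B)))
    for bits in itertools.product((0, 1), repeat=n_free):
        A = np.zeros((n_A, n_A), dtype=np.int8)
        X = np.zeros((n_A, n_B), dtype=np.int8)
        for (i, j), b in zip(free_a, bits[: len(free_a)]):
            A[i, j] = b
        for (i, v), b in zip(free_x, bits[len(free_a):]):
            X[i, v] = b
        z = evaluate_statistics(template.with_layers(A=A, X=X), list(model.specs)).values
        zs.append(z)
        log_weights.append(float(theta @ z))
    log_w = np.array(log_weights)
    m = log_w.max()
    w = np.exp(log_w - m)
    kappa = float(w.sum() * math.exp(m))
    expect = (np.asarray(zs) * w[:, None]).sum(axis=0) / w.sum()
    return StatisticsVector(model.specs, expect), kappa
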