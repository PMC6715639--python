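"""Simulation-based goodness of fit for fitted MERGMs.

Networks are simulated from the fitted model and every statistic of
interest — the fitted effects plus an auxiliary battery the model was *not*
asked to reproduce — is compared with its observed value through the GOF
t-ratio ``(observed - simulated mean) / simulated SD``.  Fitted effects
should sit essentially at their observed values (|t| < 0.1, the convergence
check); auxiliary effects are adequately reproduced when |t| < 2.

The default auxiliary battery is the full configuration catalogue plus the
in/out-degree standard deviations and the global clustering coefficient of
the collaboration network, operationalising "a parsimonious model that
adequately reproduces the overall multilevel structure".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import networkx as nx
import numpy as np

from .configs import CATALOGUE_23, ConfigurationSpec, default_specs, evaluate_statistics
from .estimator import FitResult
from .netdata import MultilevelNetwork
from .sampler import MCMCSettings, mcmc_sample, proposal_mix

FITTED_THRESHOLD = 0.1
AUXILIARY_THRESHOLD = 2.0


def _degree_sd(axis: int) -> Callable[[MultilevelNetwork], float]:
    def stat(mnet: MultilevelNetwork) -> float:
        return float(mnet.A.sum(axis=axis).std())
    return stat


def _global_clustering(mnet: MultilevelNetwork) -> float:
    g = nx.from_numpy_array(mnet.A, create_using=nx.DiGraph)
    return float(nx.transitivity(g.to_undirected()))


#: name -> scalar graph functionals appended to the auxiliary battery
EXTRA_AUXILIARY: dict[str, Callable[[MultilevelNetwork], float]] = {
    "A_in_degree_sd": _degree_sd(axis=0),
    "A_out_degree_sd": _degree_sd(axis=1),
    "A_global_clustering": _global_clustering,
}


@dataclass
class GofReport:
    """Observed value, simulated mean/SD, t-ratio and adequacy per statistic."""

    labels: tuple[str, ...]
    fitted: tuple[bool, ...]            # True for effects in the fitted model
    observed: np.ndarray
    sim_mean: np.ndarray
    sim_sd: np.ndarray

    @property
    def tratios(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (self.observed - self.sim_mean) / self.sim_sd
        t = np.where((self.sim_sd == 0) & (self.observed == self.sim_mean), 0.0, t)
        t = np.where((self.sim_sd == 0) & (self.observed != self.sim_mean), np.inf, t)
        return t

    @property
    def adequate(self) -> np.ndarray:
        thresh = np.where(self.fitted, FITTED_THRESHOLD, AUXILIARY_THRESHOLD)
        return np.abs(self.tratios) < thresh

    def all_fitted_adequate(self) -> bool:
        return bool(np.all(self.adequate[np.array(self.fitted)]))

    def all_adequate(self) -> bool:
        return bool(np.all(self.adequate))

    def to_records(self) -> list[dict]:
        return [
            {
                "statistic": lab,
                "in_model": bool(f),
                "observed": float(o),
                "sim_mean": float(m),
                "sim_sd": float(s),
                "t_ratio": float(t),
                "adequate": bool(a),
            }
            for lab, f, o, m, s, t, a in zip(
                self.labels, self.fitted, self.observed, self.sim_mean,
                self.sim_sd, self.tratios, self.adequate,
            )
        ]

    def to_tsv(self, path: str | Path) -> None:
        lines = ["statistic\tin_model\tobserved\tsim_mean\tsim_sd\tt_ratio\tadequate"]
        for r in self.to_records():
            lines.append(
                "\t".join([
                    r["statistic"], str(int(r["in_model"])), f"{r['observed']:.4f}",
                    f"{r['sim_mean']:.4f}", f"{r['sim_sd']:.4f}", f"{r['t_ratio']:.4f}",
                    str(int(r["adequate"])),
                ])
            )
        Path(path).write_text("\n".join(lines) + "\n")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_records(), indent=2) + "\n")


def default_auxiliary(fitted_specs: Sequence[ConfigurationSpec]) -> list[ConfigurationSpec]:
    """The full 23-effect catalogue minus the effects already in the model."""
    have = {s.label for s in fitted_specs}
    return [s for s in default_specs(CATALOGUE_23) if s.label not in have]


def run_gof(
    mnet: MultilevelNetwork,
    fit: FitResult,
    auxiliary: Sequence[ConfigurationSpec] | None = None,
    n_graphs: int = 5000,
    total_updates: int = 50_000_000,
    extra: dict[str, Callable[[MultilevelNetwork], float]] | None = None,
    seed: int | None = None,
) -> GofReport:
    """Goodness-of-fit test by simulating ``n_graphs`` networks at theta-hat.

    The chain starts at the observed network and advances
    ``total_updates / n_graphs`` Metropolis updates between retained graphs
    (defaults: 5000 graphs from 50 million updates).  ``auxiliary`` defaults
    to the catalogue battery; ``extra`` maps names to arbitrary scalar graph
    functionals (degree SDs and clustering by default).
    """
    if n_graphs < 2:
        raise ValueError("need at least 2 simulated graphs")
    if auxiliary is None:
        auxiliary = default_auxiliary(fit.specs)
    if extra is None:
        extra = EXTRA_AUXILIARY
    interval = max(1, total_updates // n_graphs)
    mix = proposal_mix(fit.specs, mnet.n_actors, mnet.n_variables)
    settings = MCMCSettings(burn_in=interval, interval=interval, mix=mix, seed=seed)
    batch = mcmc_sample(mnet, fit.model(), settings, n_graphs, keep_networks=True)

    all_specs = list(fit.specs) + list(auxiliary)
    labels = [s.label for s in all_specs] + list(extra)
    fitted_mask = [True] * len(fit.specs) + [False] * (len(auxiliary) + len(extra))

    observed = np.concatenate([
        evaluate_statistics(mnet, all_specs).values,
        [fn(mnet) for fn in extra.values()],
    ])
    sims = np.empty((n_graphs, len(labels)))
    for g, net in enumerate(batch.networks):
        sims[g, : len(all_specs)] = evaluate_statistics(net, all_specs).values
        for e, fn in enumerate(extra.values()):
            sims[g, len(all_specs) + e] = fn(net)

    return GofReport(
        tuple(labels),
        tuple(fitted_mask),
        observed,
        sims.mean(axis=0),
        sims.std(axis=0, ddof=1),
    )
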