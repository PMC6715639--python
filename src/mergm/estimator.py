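"""Stochastic-approximation maximum-likelihood estimation for MERGMs.

The MLE solves the moment equation E_theta[z] = z_obs.  Following the
classic three-phase Robbins–Monro schedule used by PNet-family software:

* **Phase 1** simulates at the initial parameters and estimates the
  statistic covariance ``D``, whose diagonal scales the updates;
* **Phase 2** iterates ``theta <- theta - a * diag(D)^-1 (z_sim - z_obs)``
  on a continuing chain, over subphases with geometrically shrinking gain;
* **Phase 3** draws a long sample at the final parameters to compute the
  convergence t-ratio ``t_Q = (mean z_sim,Q - z_obs,Q) / sd(z_sim,Q)`` per
  effect and standard errors from the inverse of the simulated statistic
  covariance (the Fisher information of an exponential family).

A parameter is flagged significant when its estimate exceeds twice its
standard error in absolute value.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .configs import ConfigurationSpec, StatisticsVector, evaluate_statistics
from .netdata import MultilevelNetwork
from .sampler import MCMCSettings, MetropolisSampler, ModelSpec, proposal_mix


class DegenerateModelError(RuntimeError):
    """Simulation collapsed onto empty or complete graphs for a whole phase."""


class SingularCovarianceError(RuntimeError):
    """The simulated statistic covariance is (numerically) singular."""


@dataclass(frozen=True)
class EstimationSettings:
    """Robbins–Monro schedule.  ``steps_per_iter`` (chain updates between
    successive simulated networks) defaults to the number of free tie
    variables, i.e. one expected sweep over the tie universe."""

    phase1_samples: int = 500
    subphases: int = 5
    iters_per_subphase: int = 200
    gain: float = 0.1
    phase3_samples: int = 1000
    steps_per_iter: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("phase1_samples", "subphases", "iters_per_subphase", "phase3_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.gain <= 1.0):
            raise ValueError("gain must lie in (0, 1]")


@dataclass
class FitResult:
    """Per-effect estimates, standard errors, convergence t-ratios and
    significance flags, plus the phase-3 statistic covariance."""

    specs: tuple[ConfigurationSpec, ...]
    theta: np.ndarray
    stderr: np.ndarray
    tratios: np.ndarray
    observed: StatisticsVector
    covariance: np.ndarray

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.specs)

    @property
    def estimable(self) -> np.ndarray:
        return np.isfinite(self.stderr)

    @property
    def significant(self) -> np.ndarray:
        return np.array([
            classify_significance(t, se) if np.isfinite(se) else False
            for t, se in zip(self.theta, self.stderr)
        ])

    def model(self) -> ModelSpec:
        return ModelSpec(self.specs, self.theta)

    def to_records(self) -> list[dict]:
        return [
            {
                "effect": lab,
                "estimate": float(t),
                "stderr": float(se) if np.isfinite(se) else None,
                "t_ratio": float(tr),
                "significant": bool(sig),
                "estimable": bool(est),
            }
            for lab, t, se, tr, sig, est in zip(
                self.labels, self.theta, self.stderr, self.tratios,
                self.significant, self.estimable,
            )
        ]

    def to_tsv(self, path: str | Path) -> None:
        lines = ["effect\testimate\tstderr\tsig\tconv_t"]
        for r in self.to_records():
            star = "*" if r["significant"] else ""
            se = f"{r['stderr']:.3f}" if r["stderr"] is not None else "inestimable"
            lines.append(
                f"{r['effect']}\t{r['estimate']:.3f}\t{se}\t{star}\t{r['t_ratio']:.3f}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_records(), indent=2) + "\n")


def classify_significance(estimate: float, stderr: float) -> bool:
    """Significance rule: |estimate / stderr| strictly greater than 2."""
    if not stderr > 0:
        raise ValueError(f"standard error must be positive, got {stderr}")
    return abs(estimate / stderr) > 2.0


def check_convergence(fit: FitResult, threshold: float = 0.1) -> tuple[bool, dict[str, float]]:
    """True iff every modeled effect's |convergence t-ratio| is below threshold."""
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    report = dict(zip(fit.labels, map(float, fit.tratios)))
    return all(abs(t) < threshold for t in fit.tratios), report


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return math.log(p / (1 - p))


def initial_theta(mnet: MultilevelNetwork, specs: Sequence[ConfigurationSpec]) -> np.ndarray:
    """Density effects start at the logit of the observed layer density;
    every other effect starts at zero."""
    n_a, n_b = mnet.n_actors, mnet.n_variables
    theta = np.zeros(len(specs))
    for k, spec in enumerate(specs):
        if spec.name == "Density":
            theta[k] = _logit(mnet.A.sum() / (n_a * (n_a - 1)))
        elif spec.name == "DensityX":
            theta[k] = _logit(mnet.X.sum() / (n_a * n_b))
    return theta


def _check_not_degenerate(stats: np.ndarray, labels, layer_max: dict[str, int]) -> None:
    # all-empty or all-full across an entire phase signals degeneracy;
    # detect via a density-style statistic when one is present
    for k, lab in enumerate(labels):
        if lab in layer_max:
            col = stats[:, k]
            if np.all(col == 0) or np.all(col >= layer_max[lab]):
                raise DegenerateModelError(
                    f"near-degenerate model: {lab} stuck at {col[0]} across a whole phase"
                )


def fit(
    mnet: MultilevelNetwork,
    specs: Sequence[ConfigurationSpec],
    settings: EstimationSettings = EstimationSettings(),
    theta0: np.ndarray | None = None,
) -> FitResult:
    """Robbins–Monro MCMC maximum-likelihood fit of a MERGM.

    Deterministic given ``settings.seed``.  Raises
    :class:`DegenerateModelError` when the simulation collapses and
    :class:`SingularCovarianceError` (naming the collinear statistics) when
    the phase-3 covariance cannot be inverted.
    """
    specs = list(specs)
    z_obs_vec = evaluate_statistics(mnet, specs)
    z_obs = z_obs_vec.values
    if not np.isfinite(z_obs).all():
        raise ValueError("observed statistics must be finite")

    n_a, n_b = mnet.n_actors, mnet.n_variables
    n_free_a = n_a * (n_a - 1)
    n_free_x = n_a * n_b
    mix = proposal_mix(specs, n_a, n_b)
    n_free = (n_free_a if mix > 0 else 0) + (n_free_x if mix < 1 else 0)
    layer_max = {"Density": n_free_a, "DensityX": n_free_x}
    sweep = settings.steps_per_iter if settings.steps_per_iter is not None else n_free

    theta = initial_theta(mnet, specs) if theta0 is None else np.asarray(theta0, dtype=float).copy()
    rng = np.random.default_rng(settings.seed)
    model = ModelSpec(tuple(specs), theta)
    chain_settings = MCMCSettings(burn_in=0, interval=sweep, mix=mix)
    sampler = MetropolisSampler(mnet, model, chain_settings, rng=rng)

    # ---- Phase 1: covariance scaling at theta0 ----------------------
    sampler.run(10 * sweep)
    batch = sampler.sample(settings.phase1_samples, sweep)
    _check_not_degenerate(batch.stats, model.labels, layer_max)
    d_diag = batch.stats.var(axis=0, ddof=1)
    # an effect whose statistic is constant at the observed zero cannot move
    # the likelihood: freeze it at zero and report it as inestimable
    estimable = d_diag > 0
    bad = [
        lab for lab, v, obs in zip(model.labels, d_diag, z_obs)
        if v <= 0 and obs != batch.stats[0, model.labels.index(lab)]
    ]
    if bad:
        raise SingularCovarianceError(
            f"statistics with zero simulated variance but unmatched observed value: {bad}"
        )
    d_safe = np.where(estimable, d_diag, np.inf)

    # ---- Phase 2: stochastic approximation ---------------------------
    # the final estimate is the Polyak average of the last-subphase iterates,
    # which removes most of the residual stochastic-approximation noise
    for sub in range(settings.subphases):
        a = settings.gain / (2 ** sub)
        last = sub == settings.subphases - 1
        if last:
            theta_sum = np.zeros_like(theta)
        for _ in range(settings.iters_per_subphase):
            sampler.run(sweep)
            z_sim = sampler.current_stats()
            theta = theta - a * (z_sim - z_obs) / d_safe
            sampler.set_theta(theta)
            if last:
                theta_sum += theta
        if last:
            theta = theta_sum / settings.iters_per_subphase
            sampler.set_theta(theta)

    # ---- Phase 3a: Newton polish of the moment equation --------------
    # E[z](theta) has gradient Cov(z), so a Newton-Raphson step on the
    # simulated mean removes most of the residual phase-2 noise; two
    # passes have independent Monte-Carlo noise, so their average roughly
    # halves the variance of the polished estimate
    idx = np.flatnonzero(estimable)
    polished = []
    for _ in range(2):
        sampler.run(10 * sweep)
        batch3a = sampler.sample((3 * settings.phase3_samples) // 2, 2 * sweep)
        _check_not_degenerate(batch3a.stats, model.labels, layer_max)
        cov_a = batch3a.cov()[np.ix_(idx, idx)]
        resid = (batch3a.mean() - z_obs)[idx]
        try:
            step = np.linalg.solve(cov_a, resid)
        except np.linalg.LinAlgError:
            break  # singular here is diagnosed on the final sample below
        norm = np.abs(step).max()
        if norm > 0.5:  # keep the polish local; a huge step means no polish
            step *= 0.5 / norm
        theta[idx] = theta[idx] - step
        polished.append(theta.copy())
        sampler.set_theta(theta)
    if len(polished) > 1:
        theta = np.mean(polished, axis=0)
        sampler.set_theta(theta)

    # ---- Phase 3b: convergence diagnostics and standard errors ------
    # thinned at two sweeps per sample to keep autocorrelation low
    sampler.run(10 * sweep)
    batch3 = sampler.sample(settings.phase3_samples, 2 * sweep)
    _check_not_degenerate(batch3.stats, model.labels, layer_max)
    mean3 = batch3.mean()
    sd3 = batch3.sd()
    with np.errstate(invalid="ignore"):
        tratios = np.where(
            sd3 > 0,
            (mean3 - z_obs) / np.where(sd3 > 0, sd3, 1.0),
            np.where(mean3 == z_obs, 0.0, np.inf),
        )
    cov = batch3.cov()
    sub_cov = cov[np.ix_(idx, idx)]
    try:
        inv = np.linalg.inv(sub_cov)
    except np.linalg.LinAlgError:
        corr = sub_cov / np.sqrt(np.outer(np.diag(sub_cov), np.diag(sub_cov)))
        pairs = [
            (model.labels[idx[i]], model.labels[idx[j]])
            for i in range(len(idx))
            for j in range(i + 1, len(idx))
            if abs(corr[i, j]) > 0.999
        ]
        raise SingularCovarianceError(
            f"singular statistic covariance; collinear statistics: {pairs}"
        ) from None
    diag_inv = np.diag(inv)
    if (diag_inv <= 0).any():
        raise SingularCovarianceError("inverse covariance has non-positive diagonal")
    stderr = np.full(len(specs), np.nan)
    stderr[idx] = np.sqrt(diag_inv)

    return FitResult(tuple(specs), theta, stderr, tratios, z_obs_vec, cov)
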