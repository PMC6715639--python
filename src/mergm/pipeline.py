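"""End-to-end study orchestration and command-line interface.

``run_study`` reproduces the workflow of a multilevel community study:
read (or synthesise) a multilevel network, print descriptives, fit the
community's MERGM, star the significant effects, test goodness of fit, and
write every result as both human-readable tables and machine-readable JSON.
The two bundled model presets carry exactly the effects the respective
published community models include.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import click
import numpy as np
import yaml

from . import synthgen
from .configs import ConfigurationSpec, default_specs
from .estimator import EstimationSettings, FitResult, check_convergence, fit
from .gof import GofReport, run_gof
from .netdata import descriptive_summary, read_multilevel, write_multilevel
from .sampler import MCMCSettings, ModelSpec, mcmc_sample
from .synthgen import CommunityProfile, community_1_profile, community_2_profile, generate_community

logger = logging.getLogger("mergm")

#: Effects of the two community model presets.
COMMUNITY_1_EFFECTS: tuple[str, ...] = (
    "Density", "Reciprocity", "In2Star", "AinS", "AoutS", "AinAoutS", "ATT",
    "Edu_Match", "Org_Match",
    "DensityX", "ASA", "ASB",
    "TXBX",
    "L3AXBin", "C4AXBentrainment", "C4AXBexchange", "C4AXBreciprocity",
)
COMMUNITY_2_EFFECTS: tuple[str, ...] = (
    "Density", "Reciprocity", "In2Star", "AinS", "AoutS", "AinAoutS", "ATT", "ACT",
    "Edu_Match", "Org_Match",
    "DensityX", "ASA", "ACA",
    "ATXAX", "In2StarBX", "Out2StarBX", "TXBX", "L3XBXreciprocity",
    "C4AXBentrainment",
)
PRESETS: Mapping[str, tuple[str, ...]] = {
    "community1": COMMUNITY_1_EFFECTS,
    "community2": COMMUNITY_2_EFFECTS,
}


@dataclass
class RunConfig:
    """One study run: data source, model effects, tuning, output location.

    Exactly one of ``edge_paths`` (with ``attribute_path``) or ``profile``
    must be set.
    """

    edge_paths: tuple[str, ...] | None = None
    attribute_path: str | None = None
    profile: CommunityProfile | None = None
    invited: int | None = None
    effects: tuple[str, ...] = COMMUNITY_1_EFFECTS
    lam: float = 2.0
    estimation: EstimationSettings = field(default_factory=EstimationSettings)
    gof_graphs: int = 500
    gof_updates: int = 2_000_000
    outdir: str = "mergm_results"
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if (self.edge_paths is None) == (self.profile is None):
            raise ValueError("set exactly one of edge_paths or profile")
        for name in self.effects:
            ConfigurationSpec(name, lam=self.lam,
                              attribute="education" if "Match" in name else None)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "profile" in raw and raw["profile"] is not None:
            prof = raw["profile"]
            raw["profile"] = (
                community_1_profile() if prof == "community1"
                else community_2_profile() if prof == "community2"
                else CommunityProfile(**prof)
            )
        if "estimation" in raw:
            raw["estimation"] = EstimationSettings(**raw["estimation"])
        if "edge_paths" in raw and raw["edge_paths"] is not None:
            raw["edge_paths"] = tuple(raw["edge_paths"])
        if "effects" in raw:
            raw["effects"] = tuple(raw["effects"])
        return cls(**raw)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Emits descriptives, the estimates table with significance stars, the GOF
    table, a machine-readable ``results.json``, and a log of seeds and
    settings under ``config.outdir``.  The returned dict carries the same
    content plus the fitted :class:`FitResult` and :class:`GofReport`.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.verbosity)
    try:
        logger.info("run configuration: seed=%d effects=%s", config.seed, list(config.effects))
        if config.profile is not None:
            profile = synthgen.CommunityProfile(
                **{**asdict(config.profile), "seed": config.seed}
            ) if config.profile.seed != config.seed else config.profile
            logger.info("generating synthetic community: %s", profile)
            mnet = generate_community(profile)
            invited = config.invited if config.invited is not None else profile.invited
            write_multilevel(mnet, outdir / "network.tsv", outdir / "attributes.csv")
        else:
            logger.info("reading networks from %s", list(config.edge_paths))
            mnet = read_multilevel(list(config.edge_paths), config.attribute_path)
            invited = config.invited if config.invited is not None else mnet.n_actors

        descriptives = descriptive_summary(mnet, invited)
        _json_dump(descriptives, outdir / "descriptives.json")

        attr = {"Edu_Match": "education", "Org_Match": "organisation"}
        specs = [
            ConfigurationSpec(n, lam=config.lam, attribute=attr.get(n))
            for n in config.effects
        ]
        est_settings = EstimationSettings(
            **{**asdict(config.estimation), "seed": config.seed + 1}
        )
        logger.info("fitting %d effects with settings %s", len(specs), est_settings)
        result = fit(mnet, specs, est_settings)
        converged, conv_report = check_convergence(result)
        logger.info("converged=%s t-ratios=%s", converged, conv_report)
        result.to_tsv(outdir / "estimates.tsv")

        gof = run_gof(
            mnet, result,
            n_graphs=config.gof_graphs, total_updates=config.gof_updates,
            seed=config.seed + 2,
        )
        gof.to_tsv(outdir / "gof.tsv")

        bundle = {
            "seed": config.seed,
            "descriptives": descriptives,
            "estimates": result.to_records(),
            "converged": converged,
            "convergence_t_ratios": conv_report,
            "gof": gof.to_records(),
        }
        _json_dump(bundle, outdir / "results.json")
        bundle["fit"] = result
        bundle["gof_report"] = gof
        bundle["network"] = mnet
        return bundle
    finally:
        logger.removeHandler(handler)
        handler.close()


# ----------------------------------------------------------------------
# CLI
# ----------------------------------------------------------------------

@click.group()
def cli() -> None:
    """Multilevel ERGM analysis of collaboration networks over causal loop diagrams."""


def _load_config(config_path, seed, outdir) -> RunConfig:
    cfg = RunConfig.from_yaml(config_path)
    if seed is not None:
        cfg.seed = seed
    if outdir is not None:
        cfg.outdir = outdir
    return cfg


@cli.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True),
              help="YAML run configuration.")
@click.option("--seed", type=int, default=None)
@click.option("--outdir", type=click.Path(), default=None)
def report(config_path, seed, outdir) -> None:
    """Full pipeline: descriptives, fit, significance, GOF, JSON bundle."""
    bundle = run_study(_load_config(config_path, seed, outdir))
    click.echo(json.dumps({k: bundle[k] for k in ("converged",)}, indent=2))
    if not bundle["converged"]:
        sys.exit(1)


@cli.command(name="fit")
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--seed", type=int, default=None)
@click.option("--outdir", type=click.Path(), default=None)
def fit_cmd(config_path, seed, outdir) -> None:
    """Estimate the MERGM only (no GOF)."""
    cfg = _load_config(config_path, seed, outdir)
    cfg.gof_graphs = 2  # minimal; full GOF via `report`
    bundle = run_study(cfg)
    if not bundle["converged"]:
        sys.exit(1)


@cli.command()
@click.option("--community", type=click.Choice(["community1", "community2"]),
              default="community1")
@click.option("--seed", type=int, default=0)
@click.option("--outdir", type=click.Path(), default="synth_data")
def synth(community, seed, outdir) -> None:
    """Generate a synthetic community and write its edge list and attributes."""
    profile = (community_1_profile(seed) if community == "community1"
               else community_2_profile(seed))
    mnet = generate_community(profile)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_multilevel(mnet, out / "network.tsv", out / "attributes.csv")
    summary = descriptive_summary(mnet, profile.invited)
    _json_dump(summary, out / "descriptives.json")
    click.echo(f"wrote {out}/network.tsv ({mnet.n_actors} actors, {mnet.n_variables} variables)")


@cli.command()
@click.option("--edges", multiple=True, required=True, type=click.Path(exists=True))
@click.option("--attributes", type=click.Path(exists=True), default=None)
@click.option("--effects", default="community1",
              help="Preset name or comma-separated effect names.")
@click.option("--theta", required=True, help="Comma-separated parameter values.")
@click.option("--n-samples", type=int, default=100)
@click.option("--interval", type=int, default=10_000)
@click.option("--burn-in", type=int, default=100_000)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), default="samples.tsv")
def simulate(edges, attributes, effects, theta, n_samples, interval, burn_in, seed, out) -> None:
    """Simulate statistic vectors from a MERGM at fixed parameters."""
    mnet = read_multilevel(list(edges), attributes)
    names = PRESETS.get(effects, tuple(e.strip() for e in effects.split(",")))
    specs = default_specs(names)
    theta_vec = np.array([float(t) for t in theta.split(",")])
    model = ModelSpec(tuple(specs), theta_vec)
    batch = mcmc_sample(mnet, model,
                        MCMCSettings(burn_in=burn_in, interval=interval, seed=seed),
                        n_samples)
    batch.to_tsv(out)
    click.echo(f"wrote {n_samples} sampled statistic vectors to {out}")


@cli.command(name="gof")
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--seed", type=int, default=None)
@click.option("--outdir", type=click.Path(), default=None)
def gof_cmd(config_path, seed, outdir) -> None:
    """Fit, then run the simulation-based goodness-of-fit battery."""
    bundle = run_study(_load_config(config_path, seed, outdir))
    bad = [r["statistic"] for r in bundle["gof"] if not r["adequate"]]
    click.echo("all statistics adequate" if not bad else f"inadequate: {bad}")
    if not bundle["converged"]:
        sys.exit(1)


if __name__ == "__main__":  # pragma: no cover
    cli()
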