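"""End-to-end orchestration: build -> tolerances -> nulls -> bleaching ->
robustness -> comparisons, with one master seed and a reproducible manifest.

The master seed spawns one independent substream per (stage, scope, model)
via numpy SeedSequence, so adding a stage or scope never perturbs the
streams of the others, and re-running a config reproduces every output
bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .bleaching import BleachingConfig, resistance_ensemble
from .environment import MIN_LINKS_FOR_REPORTING, load_default_environment, read_environment_csv
from .network import build_network, filter_records, read_records, subset_network, summarize, write_edge_list
from .robustness import RemovalModel, robustness_ensemble
from .stats import compare_ensembles
from .tolerance import SymbiontClassModel, Taxonomy, ToleranceTables

__all__ = ["RunConfig", "run_pipeline"]

DEFAULT_REMOVAL_MODELS = (
    "random_links",
    "bleaching",
    "susceptible_links:averaged",
    "susceptible_links:host",
    "susceptible_links:symbiont",
    "random_nodes",
    "susceptible_nodes",
)
NULL_KINDS = ("shuffled_tolerance", "random_tolerance", "rbdc", "rbndc")


@dataclass
class RunConfig:
    edges: str
    host_tolerance: str
    symbiont_tolerance: str
    environment: str | None = None  # None = packaged default subregions
    taxonomy: str | None = None
    class_model: str | None = None
    scopes: list = field(default_factory=list)  # [] = global + all reportable scopes
    t_delta: float = 3.0
    replicates: int = 100
    n_perm: int = 9999
    alpha: float = 0.05
    min_links: int = MIN_LINKS_FOR_REPORTING
    removal_models: list = field(default_factory=lambda: list(DEFAULT_REMOVAL_MODELS))
    nulls: list = field(default_factory=lambda: list(NULL_KINDS))
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def validate_paths(self) -> None:
        for p in (self.edges, self.host_tolerance, self.symbiont_tolerance,
                  self.environment, self.taxonomy, self.class_model):
            if p is not None and not pathlib.Path(p).exists():
                raise FileNotFoundError(p)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(master: int, *labels) -> int:
    """Stable derived seed: independent of execution order, below 2**31."""
    digest = hashlib.sha256(("/".join(map(str, labels)) + f"#{master}").encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _reportable_scopes(net, env, min_links) -> list[str]:
    scopes = []
    for region in env.regions:
        if subset_network(net, region).number_of_edges() >= min_links:
            scopes.append(region)
    for sub in env.subregions:
        if subset_network(net, sub).number_of_edges() >= min_links:
            scopes.append(sub)
    return scopes


def run_pipeline(config: RunConfig) -> dict:
    """Execute all requested stages; returns (and writes) the run manifest."""
    config.validate_paths()
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    env = (read_environment_csv(config.environment) if config.environment
           else load_default_environment())
    records = filter_records(read_records(config.edges))
    net = build_network(records, env)
    tables = ToleranceTables.from_csv(
        config.host_tolerance,
        config.symbiont_tolerance,
        class_model=(SymbiontClassModel.from_yaml(config.class_model)
                     if config.class_model else None),
    )
    taxonomy = Taxonomy()
    if config.taxonomy:
        import pandas as pd

        taxonomy = Taxonomy.from_frame(pd.read_csv(config.taxonomy))

    scopes = list(config.scopes) or (
        ["global"] + _reportable_scopes(net, env, config.min_links)
    )
    cfg = BleachingConfig(t_delta=config.t_delta, replicates=config.replicates)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            k: {"path": p, "sha256": _sha256(p)}
            for k, p in {
                "edges": config.edges,
                "host_tolerance": config.host_tolerance,
                "symbiont_tolerance": config.symbiont_tolerance,
                "environment": config.environment,
                "taxonomy": config.taxonomy,
            }.items()
            if p is not None
        },
        "scopes": scopes,
        "stages": {},
        "errors": {},
    }

    results: dict = {}
    for scope in scopes:
        sub = net if scope == "global" else subset_network(net, scope)
        entry: dict = {"summary": summarize(sub).to_dict()}
        try:
            res = resistance_ensemble(
                sub, tables, cfg, seed=_stage_seed(config.seed, "resistance", scope),
                taxonomy=taxonomy,
            )
            entry["resistance"] = {"natural": res.to_dict()}
            for kind in config.nulls:
                entry["resistance"][kind] = resistance_ensemble(
                    sub, tables, cfg,
                    seed=_stage_seed(config.seed, "resistance", scope, kind),
                    taxonomy=taxonomy, null=kind,
                ).to_dict()
            entry["resistance_comparison"] = compare_ensembles(
                {k: v["values"] for k, v in entry["resistance"].items()},
                alpha=config.alpha, n_perm=config.n_perm,
                seed=_stage_seed(config.seed, "compare-resistance", scope),
            ).to_dict()
            entry["r50"] = {}
            for label in config.removal_models:
                model = RemovalModel.parse(label)
                entry["r50"][label] = robustness_ensemble(
                    sub, model, tables, cfg,
                    seed=_stage_seed(config.seed, "robustness", scope, label),
                    taxonomy=taxonomy,
                ).to_dict()
            entry["r50_comparison"] = compare_ensembles(
                {k: v["values"] for k, v in entry["r50"].items()},
                alpha=config.alpha, n_perm=config.n_perm,
                seed=_stage_seed(config.seed, "compare-r50", scope),
            ).to_dict()
        except Exception as exc:  # record partial completion, keep going
            manifest["errors"][scope] = f"{type(exc).__name__}: {exc}"
        results[scope] = entry

    write_edge_list(net, outdir / "network_edges.csv")
    results_path = outdir / "results.json"
    with open(results_path, "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True)
    manifest["stages"]["results"] = {
        "path": str(results_path), "sha256": _sha256(results_path)
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
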