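"""Removal models, removal trajectories, and the R50 robustness metric.

Robustness treats an attack as a stepped perturbation: entities (links or
nodes) are deleted one at a time in a model-specific order, and after every
deletion we count how many of the original nodes still remain. A node remains
only while it keeps at least one link, so secondary extinctions (a node
stranded by losing its last link) count as losses for both attack classes.
R50 is the fraction of the attacked entity class that must be removed before
no more than half of the original nodes remain.

Five removal models: random links, links in bleaching-threshold order (low W
first), links in order of susceptible tolerance (averaged / host-only /
symbiont-only), random nodes, and nodes in ascending tolerance (hosts and
symbionts pooled). Ties are broken by a fresh uniform shuffle per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .bleaching import (
    BleachingConfig,
    ResistanceResult,
    assign_link_weights,
    simulate_bleaching,
    _apply_null,
    _replicate_rngs,
)
from .network import HOST, host_nodes
from .tolerance import ToleranceTables, Taxonomy, assign_tolerances

__all__ = [
    "RemovalModel",
    "RemovalTrajectory",
    "R50Result",
    "removal_order",
    "removal_trajectory",
    "r50",
    "robustness_ensemble",
    "family_susceptibility",
]

LINK_KINDS = ("random_links", "bleaching", "susceptible_links")
NODE_KINDS = ("random_nodes", "susceptible_nodes")
SUSCEPTIBLE_MODES = ("averaged", "host", "symbiont")


@dataclass(frozen=True)
class RemovalModel:
    """One of the five attack orderings.

    ``mode`` applies only to susceptible_links and selects the link tolerance:
    the holobiont average of the two endpoints, or the host's or symbiont's
    tolerance alone. ``node_class`` optionally restricts node attacks to one
    node class (default: hosts and symbionts pooled).
    """

    kind: str
    mode: str | None = None
    node_class: str | None = None

    def __post_init__(self):
        if self.kind not in LINK_KINDS + NODE_KINDS:
            raise ValueError(f"unknown removal model kind {self.kind!r}")
        if self.kind == "susceptible_links":
            if self.mode not in SUSCEPTIBLE_MODES:
                raise ValueError(
                    f"susceptible_links needs mode in {SUSCEPTIBLE_MODES}, got {self.mode!r}"
                )
        elif self.mode is not None:
            raise ValueError(f"mode is only valid for susceptible_links, not {self.kind}")

    @property
    def removes_links(self) -> bool:
        return self.kind in LINK_KINDS

    @classmethod
    def parse(cls, text: str) -> "RemovalModel":
        """Parse CLI-style labels like 'susceptible-links:host'."""
        kind, _, mode = text.replace("-", "_").partition(":")
        return cls(kind, mode or None)


def _shuffled_sort(items, keys, rng: np.random.Generator):
    """Ascending sort by key with uniform random tie-breaking."""
    jitter = rng.random(len(items))
    idx = np.lexsort((jitter, np.asarray(keys, dtype=float)))
    return [items[i] for i in idx]


def removal_order(net: nx.Graph, model: RemovalModel, rng: np.random.Generator,
                  t_delta: float = 3.0) -> list:
    """The full, ordered list of links or nodes this model attacks."""
    if model.removes_links:
        links = sorted(net.edges())
        if model.kind == "random_links":
            return [links[i] for i in rng.permutation(len(links))]
        if model.kind == "bleaching":
            if not all("tolerance" in net.nodes[n] for n in net.nodes):
                raise ValueError("bleaching removal requires tolerances on all nodes")
            assign_link_weights(net, t_delta)
            return _shuffled_sort(links, [net.edges[e]["W"] for e in links], rng)
        keys = []
        for u, v in links:
            h, s = (u, v) if net.nodes[u]["kind"] == HOST else (v, u)
            th, ts = net.nodes[h]["tolerance"], net.nodes[s]["tolerance"]
            keys.append({"averaged": (th + ts) / 2, "host": th, "symbiont": ts}[model.mode])
        return _shuffled_sort(links, keys, rng)

    nodes = sorted(net.nodes())
    if model.node_class is not None:
        nodes = [n for n in nodes if net.nodes[n]["kind"] == model.node_class]
    if model.kind == "random_nodes":
        return [nodes[i] for i in rng.permutation(len(nodes))]
    return _shuffled_sort(nodes, [net.nodes[n]["tolerance"] for n in nodes], rng)


@dataclass
class RemovalTrajectory:
    """Original-node survival after each primary removal.

    ``remaining_counts[k]`` is the number of original nodes still holding at
    least one link after the first k removals; ``remaining_counts[0]`` is the
    initial state. Denominators are the ORIGINAL node and entity counts.
    """

    entity: str  # "links" or "nodes"
    n_original_nodes: int
    n_entities: int
    remaining_counts: np.ndarray = field(repr=False)

    @property
    def fractions_removed(self) -> np.ndarray:
        if self.n_entities == 0:
            return np.array([0.0])
        return np.arange(len(self.remaining_counts)) / self.n_entities

    @property
    def fractions_remaining(self) -> np.ndarray:
        return self.remaining_counts / self.n_original_nodes


def removal_trajectory(net: nx.Graph, order: list, entity: str | None = None) -> RemovalTrajectory:
    """Delete entities one at a time and track surviving original nodes."""
    if entity is None:
        entity = "links" if order and isinstance(order[0], tuple) else "nodes"
    degree = dict(net.degree())
    for e in order:
        for x in (e if entity == "links" else (e,)):
            if x not in degree:
                raise KeyError(f"removal order references unknown node {x!r}")
    n0 = net.number_of_nodes()
    remaining = sum(1 for d in degree.values() if d > 0)
    counts = [remaining]
    if entity == "links":
        for u, v in order:
            for x in (u, v):
                degree[x] -= 1
                if degree[x] == 0:
                    remaining -= 1
            counts.append(remaining)
    else:
        removed = set()
        adj = {n: set(net.neighbors(n)) for n in net.nodes}
        for n in order:
            if degree[n] > 0:
                remaining -= 1  # the primary removal itself
            removed.add(n)
            for nb in adj[n]:
                if nb in removed:
                    continue
                degree[nb] -= 1
                if degree[nb] == 0:
                    remaining -= 1
            degree[n] = 0
            counts.append(remaining)
    n_entities = net.number_of_edges() if entity == "links" else n0
    return RemovalTrajectory(entity, n0, n_entities, np.asarray(counts))


def r50(trajectory: RemovalTrajectory) -> float:
    """Smallest fraction removed at which <= 50% of original nodes remain."""
    n = trajectory.n_original_nodes
    # survival requires strictly more than half the original nodes
    hits = np.nonzero(2 * trajectory.remaining_counts <= n)[0]
    if len(hits) == 0:
        raise ValueError("trajectory never reaches 50% of nodes remaining")
    return float(hits[0] / trajectory.n_entities)


class R50Result(ResistanceResult):
    """Per-replicate R50 values with ensemble mean and sd."""


def robustness_ensemble(
    net: nx.Graph,
    model: RemovalModel,
    tables: ToleranceTables,
    cfg: BleachingConfig = BleachingConfig(),
    seed: int = 0,
    taxonomy: Taxonomy | None = None,
    null: str | None = None,
) -> R50Result:
    """Per-replicate tolerance redraw -> removal order -> trajectory -> R50.

    ``null`` optionally re-applies a null construction each replicate,
    as in :func:`coralnet.bleaching.resistance_ensemble`.
    """
    rngs = _replicate_rngs(seed, cfg.replicates + 1)
    frozen = None
    if cfg.host_impute_once:
        frozen = assign_tolerances(net, tables, taxonomy, rngs[-1])
    values, n_failed = [], 0
    for rng in rngs[: cfg.replicates]:
        assign_tolerances(net, tables, taxonomy, rng, frozen_host_imputes=frozen)
        sim_net = _apply_null(net, null, rng)
        order = removal_order(sim_net, model, rng, cfg.t_delta)
        traj = removal_trajectory(sim_net, order)
        try:
            values.append(r50(traj))
        except ValueError:
            n_failed += 1
    return R50Result(np.asarray(values), n_failed=n_failed)


@dataclass
class FamilySusceptibility:
    """Host nodes always among the first ``n_first`` bleached, summarized."""

    hosts: list
    by_family: dict
    by_subregion: dict
    n_first: int


def family_susceptibility(
    net: nx.Graph,
    tables: ToleranceTables,
    cfg: BleachingConfig = BleachingConfig(),
    seed: int = 0,
    taxonomy: Taxonomy | None = None,
    n_first: int = 100,
) -> FamilySusceptibility:
    """Which host families always bleach early.

    Runs the bleaching model per replicate, takes each replicate's first
    ``n_first`` bleached host nodes (isolation-event order, shuffled within
    ties), and intersects those sets across replicates; the surviving hosts
    are counted per family and per subregion.
    """
    n_hosts = len(host_nodes(net))
    if n_hosts < n_first:
        warnings.warn(
            f"network has {n_hosts} hosts < n_first={n_first}; using all hosts"
        )
        n_first = n_hosts
    rngs = _replicate_rngs(seed, cfg.replicates + 1)
    frozen = None
    if cfg.host_impute_once:
        frozen = assign_tolerances(net, tables, taxonomy, rngs[-1])
    always: set | None = None
    for rng in rngs[: cfg.replicates]:
        assign_tolerances(net, tables, taxonomy, rng, frozen_host_imputes=frozen)
        curve = simulate_bleaching(net, cfg.t_delta, rng=rng)
        first = set(curve.first_bleached[:n_first])
        always = first if always is None else (always & first)
    hosts = sorted(always or set())
    by_family: dict = {}
    by_subregion: dict = {}
    for h in hosts:
        d = net.nodes[h]
        by_family[d.get("family", "unknown")] = by_family.get(d.get("family", "unknown"), 0) + 1
        by_subregion[d["subregion"]] = by_subregion.get(d["subregion"], 0) + 1
    return FamilySusceptibility(hosts, by_family, by_subregion, n_first)
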