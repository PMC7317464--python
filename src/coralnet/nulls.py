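"""Null networks: physiological and structural controls.

Four constructions, each answering one question about what drives resistance:

* shuffled tolerance — permute tolerances within each node class (structure
  untouched): do the specific taxon-tolerance assignments matter?
* random tolerance — replace every tolerance with Uniform(0,1) (structure
  untouched): does the natural tolerance distribution matter?
* RBDC — rewire links with bipartite double-edge swaps so every node keeps
  its exact degree, then shuffle tolerances: do the specific association
  patterns matter?
* RBNDC — replace the wiring with a uniform random bipartite graph with the
  same host count, symbiont count, and link count, then shuffle tolerances:
  does the degree distribution itself matter?

Host nodes always keep their subregion, and hence their T_MMM baseline, so
the bleaching model stays well defined on every null.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np

from .network import HOST, host_nodes, symbiont_nodes

__all__ = ["shuffled_tolerance", "random_tolerance", "rbdc", "rbndc", "make_null"]


def _permute_within_class(net: nx.Graph, nodes: list, rng, with_replacement: bool):
    vals = [net.nodes[n]["tolerance"] for n in nodes]
    if with_replacement:
        new = [vals[i] for i in rng.integers(0, len(vals), len(vals))]
    else:
        new = [vals[i] for i in rng.permutation(len(vals))]
    for n, v in zip(nodes, new):
        net.nodes[n]["tolerance"] = v
        net.nodes[n]["tol_source"] = "shuffled"


def shuffled_tolerance(net: nx.Graph, rng: np.random.Generator,
                       with_replacement: bool = False) -> nx.Graph:
    """Permute host tolerances among hosts and symbiont tolerances among
    symbionts; by default a permutation, preserving each multiset exactly.
    Structure is untouched. Returns a copy."""
    out = net.copy()
    _permute_within_class(out, sorted(host_nodes(out)), rng, with_replacement)
    _permute_within_class(out, sorted(symbiont_nodes(out)), rng, with_replacement)
    return out


def random_tolerance(net: nx.Graph, rng: np.random.Generator) -> nx.Graph:
    """Every node tolerance ~ Uniform(0, 1) independently; structure untouched."""
    out = net.copy()
    for n in sorted(out.nodes):
        out.nodes[n]["tolerance"] = float(rng.uniform())
        out.nodes[n]["tol_source"] = "random-uniform"
    return out


def rbdc(net: nx.Graph, rng: np.random.Generator, n_swaps: int | None = None) -> nx.Graph:
    """Degree-conserving rewiring by bipartite double-edge swaps.

    Picks two links (h1-s1, h2-s2) and swaps partners to (h1-s2, h2-s1)
    whenever that creates no duplicate link; every node's degree is exactly
    preserved and the graph stays simple and bipartite. Default swap budget
    is 10x the link count. Tolerances are then shuffled within classes.
    Warns and returns the (tolerance-shuffled) input when the network is too
    constrained to swap.
    """
    out = net.copy()
    edges = [tuple(_host_first(out, u, v)) for u, v in out.edges()]
    edges.sort()
    L = len(edges)
    if n_swaps is None:
        n_swaps = 10 * L
    edge_set = set(edges)
    done = 0
    if L >= 2:
        for _ in range(n_swaps):
            i, j = rng.integers(0, L, 2)
            if i == j:
                continue
            (h1, s1), (h2, s2) = edges[i], edges[j]
            if s1 == s2 or h1 == h2:
                continue
            if (h1, s2) in edge_set or (h2, s1) in edge_set:
                continue
            edge_set.discard((h1, s1))
            edge_set.discard((h2, s2))
            edge_set.add((h1, s2))
            edge_set.add((h2, s1))
            edges[i], edges[j] = (h1, s2), (h2, s1)
            done += 1
    if done == 0 and L >= 2:
        warnings.warn("network too constrained to rewire; structure unchanged")
    out.remove_edges_from(list(out.edges()))
    out.add_edges_from(sorted(edge_set))
    return shuffled_tolerance(out, rng)


def rbndc(net: nx.Graph, rng: np.random.Generator) -> nx.Graph:
    """Uniform random bipartite wiring with (N_host, N_symbiont, L) preserved.

    L distinct host-symbiont pairs are placed uniformly at random; host nodes
    keep their subregion identity so T_MMM remains defined. Tolerances are
    then shuffled within classes.
    """
    hosts = sorted(host_nodes(net))
    syms = sorted(symbiont_nodes(net))
    L = net.number_of_edges()
    n_possible = len(hosts) * len(syms)
    if L > n_possible:
        raise ValueError(f"cannot place {L} links among {n_possible} possible pairs")
    flat = rng.choice(n_possible, size=L, replace=False)
    out = net.copy()
    out.remove_edges_from(list(out.edges()))
    out.add_edges_from(
        sorted((hosts[k // len(syms)], syms[k % len(syms)]) for k in flat)
    )
    return shuffled_tolerance(out, rng)


def _host_first(net, u, v):
    return (u, v) if net.nodes[u]["kind"] == HOST else (v, u)


def make_null(net: nx.Graph, kind: str, rng: np.random.Generator, **kw) -> nx.Graph:
    """Dispatch by kind: shuffled_tolerance | random_tolerance | rbdc | rbndc."""
    funcs = {
        "shuffled_tolerance": shuffled_tolerance,
        "random_tolerance": random_tolerance,
        "rbdc": rbdc,
        "rbndc": rbndc,
    }
    if kind not in funcs:
        raise ValueError(f"unknown null kind {kind!r}")
    return funcs[kind](net, rng, **kw)
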