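"""Build and summarize the bipartite coral-symbiont association network.

Hosts are geographically distinct: the node identity is the (species,
subregion) pair, so a species sampled in three subregions contributes three
host nodes. Symbiont ITS2 types are global: one node per type regardless of
where it was sampled. Each curated association record becomes one undirected
link. The network may be disconnected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .environment import SubregionEnvironment, EnvironmentLookupError

__all__ = [
    "AssociationRecord",
    "FilterRules",
    "NetworkSummary",
    "read_records",
    "filter_records",
    "build_network",
    "subset_network",
    "summarize",
    "host_nodes",
    "symbiont_nodes",
    "write_edge_list",
    "read_edge_list",
    "write_graphml",
]

HOST = "host"
SYMBIONT = "symbiont"

_REQUIRED_COLUMNS = ("host_species", "subregion", "region", "symbiont_type")
_OPTIONAL_COLUMNS = ("host_family", "symbiont_genus", "in_situ", "scleractinian")
_UNKNOWN_TOKENS = {"", "na", "n/a", "nan", "none", "unknown", "?"}


class SchemaError(ValueError):
    """An input table is missing a required column."""


def _norm(s) -> str:
    """Trim and collapse internal whitespace; case is preserved."""
    if s is None or (isinstance(s, float) and pd.isna(s)):
        return ""
    return " ".join(str(s).split())


def _norm_or_unknown(s) -> str:
    out = _norm(s)
    return out if out.lower() not in _UNKNOWN_TOKENS else "unknown"


def _as_flag(v, default: bool = True) -> bool:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return default
    if isinstance(v, (bool, int)):
        return bool(v)
    return _norm(v).lower() in {"1", "true", "yes", "y", "t"}


@dataclass(frozen=True)
class AssociationRecord:
    """One curated coral-symbiont association observation."""

    host_species: str
    subregion: str
    region: str
    symbiont_type: str
    host_family: str = "unknown"
    symbiont_genus: str = "unknown"
    in_situ: bool = True
    scleractinian: bool = True

    def key(self) -> tuple[str, str, str]:
        """Identity triple for geographic deduplication."""
        return (self.host_species, self.subregion, self.symbiont_type)


@dataclass(frozen=True)
class FilterRules:
    """Which curation flags to enforce when filtering raw records."""

    require_scleractinian: bool = True
    require_in_situ: bool = True
    require_known_subregion: bool = True
    deduplicate: bool = True


def read_records(path_or_df) -> list[AssociationRecord]:
    """Read association records from a delimited table.

    Required columns: host_species, subregion, region, symbiont_type.
    Optional: host_family, symbiont_genus, in_situ, scleractinian.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(path_or_df, sep=None, engine="python")
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"association table missing required column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            AssociationRecord(
                host_species=_norm(d["host_species"]),
                subregion=_norm_or_unknown(d["subregion"]),
                region=_norm_or_unknown(d["region"]),
                symbiont_type=_norm(d["symbiont_type"]),
                host_family=_norm_or_unknown(d.get("host_family")),
                symbiont_genus=_norm_or_unknown(d.get("symbiont_genus")),
                in_situ=_as_flag(d.get("in_situ")),
                scleractinian=_as_flag(d.get("scleractinian")),
            )
        )
    return records


def filter_records(
    records: Iterable[AssociationRecord], rules: FilterRules = FilterRules()
) -> list[AssociationRecord]:
    """Apply curation filters and geographic deduplication, order-stable.

    Records are kept only if they pass the enforced flags; duplicates on the
    (host_species, subregion, symbiont_type) triple are collapsed to the first
    occurrence, so each surviving record is a geographically unique
    association. Idempotent.
    """
    seen: set[tuple[str, str, str]] = set()
    out: list[AssociationRecord] = []
    for rec in records:
        if not rec.host_species or not rec.symbiont_type:
            continue
        if rules.require_scleractinian and not rec.scleractinian:
            continue
        if rules.require_in_situ and not rec.in_situ:
            continue
        if rules.require_known_subregion and rec.subregion.lower() in _UNKNOWN_TOKENS | {"unknown"}:
            continue
        if rules.deduplicate:
            if rec.key() in seen:
                continue
            seen.add(rec.key())
        out.append(rec)
    return out


def host_id(species: str, subregion: str) -> str:
    return f"{species} [{subregion}]"


def build_network(
    records: Sequence[AssociationRecord], env: SubregionEnvironment
) -> nx.Graph:
    """Construct the bipartite network: one link per filtered record.

    Host node identity is the (species, subregion) pair; every host node
    carries its subregion's T_MMM baseline. Raises EnvironmentLookupError if
    a record's subregion has no environment entry.
    """
    net = nx.Graph()
    net.graph["environment"] = env
    hosts, syms, links = {}, {}, []
    for rec in records:
        if rec.subregion not in env:
            raise EnvironmentLookupError(
                f"subregion {rec.subregion!r} absent from environment table"
            )
        h = host_id(rec.host_species, rec.subregion)
        hosts.setdefault(
            h,
            dict(
                kind=HOST,
                species=rec.host_species,
                subregion=rec.subregion,
                region=env.region_of(rec.subregion),
                t_mmm=env.t_mmm(rec.subregion),
                family=rec.host_family,
            ),
        )
        s = rec.symbiont_type
        syms.setdefault(s, dict(kind=SYMBIONT, genus=rec.symbiont_genus))
        if syms[s]["genus"] == "unknown" and rec.symbiont_genus != "unknown":
            syms[s]["genus"] = rec.symbiont_genus
        links.append((h, s))
    # deterministic lexicographic node order so seeded runs are reproducible
    for h in sorted(hosts):
        net.add_node(h, bipartite=0, **hosts[h])
    for s in sorted(syms):
        net.add_node(s, bipartite=1, **syms[s])
    net.add_edges_from(sorted(set(links)))
    return net


def host_nodes(net: nx.Graph) -> list[str]:
    return [n for n, d in net.nodes(data=True) if d["kind"] == HOST]


def symbiont_nodes(net: nx.Graph) -> list[str]:
    return [n for n, d in net.nodes(data=True) if d["kind"] == SYMBIONT]


def subset_network(net: nx.Graph, scope: str) -> nx.Graph:
    """Restrict to one region or subregion.

    Host nodes are kept if they fall inside the scope; symbiont nodes are kept
    only if they retain at least one link in scope. An unknown scope label
    raises EnvironmentLookupError; an in-scope but empty result is legitimate.
    """
    env: SubregionEnvironment = net.graph["environment"]
    if scope in env.regions:
        subregions = set(env.subregions_of(scope))
    elif scope in env:
        subregions = {scope}
    else:
        raise EnvironmentLookupError(f"unknown region/subregion: {scope!r}")
    keep_hosts = {
        n for n, d in net.nodes(data=True)
        if d["kind"] == HOST and d["subregion"] in subregions
    }
    sub = nx.Graph()
    sub.graph["environment"] = env
    sub.graph["scope"] = scope
    for h in sorted(keep_hosts):
        sub.add_node(h, **net.nodes[h])
    keep_syms = sorted({s for h in keep_hosts for s in net.neighbors(h)})
    for s in keep_syms:
        sub.add_node(s, **net.nodes[s])
    sub.add_edges_from(
        (h, s) for h in keep_hosts for s in net.neighbors(h)
    )
    return sub


@dataclass
class NetworkSummary:
    """Counts, mean degree, both connectance variants, degree sequences.

    Two connectance conventions are reported with provenance labels:
    ``connectance_caption`` is L/(hosts x symbionts), the textbook bipartite
    fill; ``connectance_printed`` is L/N^2, which reproduces the values
    printed for the real networks. Neither is used in any downstream metric.
    """

    n: int
    n_host: int
    n_symbiont: int
    n_species: int
    n_links: int
    mean_degree: float | None
    connectance_caption: float | None
    connectance_printed: float | None
    degree_sequence: dict = field(repr=False, default_factory=dict)
    connectance_defined: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(net: nx.Graph) -> NetworkSummary:
    hosts = host_nodes(net)
    syms = symbiont_nodes(net)
    n_h, n_s = len(hosts), len(syms)
    n = n_h + n_s
    links = net.number_of_edges()
    species = {net.nodes[h]["species"] for h in hosts}
    degs = dict(net.degree())
    seq = {
        "host": sorted((degs[h] for h in hosts), reverse=True),
        "symbiont": sorted((degs[s] for s in syms), reverse=True),
        "combined": sorted(degs.values(), reverse=True),
    }
    defined = n_h > 0 and n_s > 0
    return NetworkSummary(
        n=n,
        n_host=n_h,
        n_symbiont=n_s,
        n_species=len(species),
        n_links=links,
        mean_degree=(2 * links / n) if n else None,
        connectance_caption=(links / (n_h * n_s)) if defined else None,
        connectance_printed=(links / n**2) if n else None,
        degree_sequence=seq,
        connectance_defined=defined,
    )


def write_edge_list(net: nx.Graph, path) -> pd.DataFrame:
    """Export one row per link with host/symbiont attributes; round-trips."""
    rows = []
    for u, v in sorted(net.edges()):
        if net.nodes[u]["kind"] != HOST:
            u, v = v, u
        du, dv = net.nodes[u], net.nodes[v]
        rows.append(
            dict(
                host_id=u,
                symbiont_id=v,
                host_species=du["species"],
                subregion=du["subregion"],
                region=du["region"],
                symbiont_type=v,
                host_family=du.get("family", "unknown"),
                symbiont_genus=dv.get("genus", "unknown"),
            )
        )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def read_edge_list(path_or_df, env: SubregionEnvironment) -> nx.Graph:
    """Rebuild a network from its exported edge list (identity round-trip)."""
    return build_network(read_records(path_or_df), env)


def write_graphml(net: nx.Graph, path) -> None:
    g = nx.Graph()
    g.add_nodes_from(
        (n, {k: v for k, v in d.items() if isinstance(v, (str, int, float, bool))})
        for n, d in net.nodes(data=True)
    )
    g.add_edges_from(net.edges())
    nx.write_graphml(g, path)
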