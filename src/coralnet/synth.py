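"""Synthetic association networks with the structure the analysis assumes.

The generator emulates the statistical shape of the curated global
coral-symbiont network: a sparse bipartite graph whose symbiont degrees
follow a truncated power law (a few generalist hubs, many specialists),
hosts with low degree, hosts partitioned into subregions that carry real
T_MMM baselines, host tolerances derived from a BRI-like distribution, and
symbiont tolerances from a high/medium/low class mixture. A configurable
fraction of taxa is withheld from the tolerance source tables to exercise
the imputation paths.

Everything derives deterministically from the spec's seed, and the bundle
retains the ground truth of every draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .degree_fit import sample_truncated_power_law
from .environment import SubregionEnvironment, load_default_environment
from .network import AssociationRecord, build_network
from .tolerance import SymbiontClassModel, Taxonomy, ToleranceTables

__all__ = [
    "GeneratorSpec",
    "SyntheticBundle",
    "generate_network",
    "generate_tolerances",
    "global_like_spec",
    "single_subregion_preset",
]

# host-node counts per subregion in the real global network (sums to 685)
_GLOBAL_HOST_COUNTS = {
    "Great Barrier Reef": 157, "Central Pacific": 30, "Japan": 58,
    "Eastern Pacific": 14, "Western Pacific": 16, "American Samoa": 2,
    "Phuket": 140, "Western Indian": 109, "Western Australia": 20,
    "Western Caribbean": 52, "Eastern Caribbean": 40, "Central Caribbean": 31,
    "Florida": 15, "Gulf of Mexico": 1,
}

_GENERA = ("Cladocopium", "Symbiodinium", "Durusdinium", "Breviolum")
_GENUS_PROBS = (0.60, 0.15, 0.15, 0.10)


class GenerationError(RuntimeError):
    """The requested degree sequence could not be realized."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic network draw."""

    n_hosts: int = 685
    n_symbionts: int = 250
    n_links: int = 1697
    n_species: int | None = 362
    # symbiont degree model: truncated power law with planted generalist hubs
    degree_exponent: float = 2.0
    degree_cutoff: float = 0.005  # exponential decay rate lambda
    n_hubs: int = 3
    hub_min_degree: int = 140
    # host-side heterogeneity (lognormal propensity sd; larger = more skew)
    host_skew: float = 0.7
    # tolerance models
    bri_mean: float = 45.0
    bri_sd: float = 20.0
    bri_species_sd: float = 5.0
    host_unlisted_fraction: float = 0.2
    symbiont_unlisted_fraction: float = 0.2
    class_model: SymbiontClassModel = field(default_factory=SymbiontClassModel)
    # geography: None = packaged default subregions with real host proportions
    subregion_hosts: dict | None = None
    n_families: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_links > self.n_hosts * self.n_symbionts:
            raise ValueError("n_links exceeds the number of possible host-symbiont pairs")
        if self.n_links < max(self.n_hosts, self.n_symbionts):
            raise ValueError("n_links too small for every node to have degree >= 1")


def global_like_spec(seed: int = 0) -> GeneratorSpec:
    """Preset matching the real global network's printed marginals."""
    return GeneratorSpec(seed=seed)


@dataclass
class SyntheticBundle:
    """A mutually consistent set of inputs plus generation ground truth."""

    records: list
    env: SubregionEnvironment
    tables: ToleranceTables
    taxonomy: Taxonomy
    ground_truth: dict = field(repr=False, default_factory=dict)

    def network(self):
        return build_network(self.records, self.env)

    def write(self, outdir) -> dict:
        """Write the CSV dialects the network builder reads; returns paths."""
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "edges": outdir / "edges.csv",
            "environment": outdir / "environment.csv",
            "host_tolerance": outdir / "host_tolerance.csv",
            "symbiont_tolerance": outdir / "symbiont_tolerance.csv",
            "taxonomy": outdir / "taxonomy.csv",
        }
        pd.DataFrame([vars(r) for r in self.records]).to_csv(paths["edges"], index=False)
        self.env.table.to_csv(paths["environment"], index=False)
        self.tables.host.to_csv(paths["host_tolerance"], index=False)
        self.tables.symbiont.to_csv(paths["symbiont_tolerance"], index=False)
        pd.DataFrame(
            {"species": list(self.taxonomy.family_of),
             "family": list(self.taxonomy.family_of.values())}
        ).to_csv(paths["taxonomy"], index=False)
        return {k: str(v) for k, v in paths.items()}


def _symbiont_degrees(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    """Truncated-power-law degrees with planted hubs, summing to n_links."""
    n_plain = spec.n_symbionts - spec.n_hubs
    hub_cap = min(spec.n_hosts, spec.hub_min_degree + 60)
    for _ in range(200):
        hubs = rng.integers(spec.hub_min_degree, hub_cap + 1, spec.n_hubs)
        plain = sample_truncated_power_law(
            n_plain, spec.degree_exponent, spec.degree_cutoff, rng,
            k_min=1, k_max=max(2, spec.hub_min_degree - 1),
        )
        degrees = np.concatenate([hubs, plain]).astype(int)
        deficit = spec.n_links - int(degrees.sum())
        # nudge non-hub degrees within bounds to hit the link count exactly
        for _ in range(50_000):
            if deficit == 0:
                break
            i = spec.n_hubs + int(rng.integers(n_plain))
            step = 1 if deficit > 0 else -1
            if 1 <= degrees[i] + step <= spec.hub_min_degree - 1:
                degrees[i] += step
                deficit -= step
        if deficit == 0:
            return degrees
    raise GenerationError("could not realize a symbiont degree sequence summing to n_links")


def _host_quota(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    """Target host degrees: >=1 each, extras spread by lognormal propensity."""
    extra = spec.n_links - spec.n_hosts
    w = rng.lognormal(0.0, spec.host_skew, spec.n_hosts)
    return 1 + rng.multinomial(extra, w / w.sum())


def _wire(spec: GeneratorSpec, sym_deg: np.ndarray, host_quota: np.ndarray,
          rng: np.random.Generator) -> list[tuple[int, int]]:
    """Configuration-style wiring: exact symbiont degrees, no duplicate links.

    Symbionts are processed hub-first; each picks its hosts without
    replacement with probability proportional to the hosts' remaining stub
    quota (plus a small floor so the wiring always completes).
    """
    stubs = host_quota.astype(float).copy()
    edges: list[tuple[int, int]] = []
    order = np.argsort(-sym_deg)
    for s in order:
        d = int(sym_deg[s])
        w = np.maximum(stubs, 0.0) + 1e-3
        hosts = rng.choice(spec.n_hosts, size=d, replace=False, p=w / w.sum())
        for h in hosts:
            edges.append((int(h), int(s)))
            stubs[h] -= 1
    # repair pass: every host must keep degree >= 1, so steal a link from a
    # high-degree host for any host the weighted draw left unlinked
    host_deg = np.zeros(spec.n_hosts, dtype=int)
    for h, _ in edges:
        host_deg[h] += 1
    linked_syms = {}
    for h, s in edges:
        linked_syms.setdefault(h, set()).add(s)
    for h0 in np.nonzero(host_deg == 0)[0]:
        for attempt in range(10_000):
            i = int(rng.integers(len(edges)))
            h, s = edges[i]
            if host_deg[h] >= 2 and s not in linked_syms.get(h0, set()):
                edges[i] = (int(h0), s)
                host_deg[h] -= 1
                host_deg[h0] += 1
                linked_syms[h].discard(s)
                linked_syms.setdefault(h0, set()).add(s)
                break
        else:
            raise GenerationError("could not connect every host")
    return edges


def _subregion_partition(spec: GeneratorSpec, env: SubregionEnvironment,
                         rng: np.random.Generator) -> list[str]:
    counts = spec.subregion_hosts
    if counts is None:
        # scale the real per-subregion host proportions to n_hosts
        total = sum(_GLOBAL_HOST_COUNTS.values())
        raw = {k: v * spec.n_hosts / total for k, v in _GLOBAL_HOST_COUNTS.items()}
        counts = {k: int(np.floor(v)) for k, v in raw.items()}
        leftovers = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
        i = 0
        while sum(counts.values()) < spec.n_hosts:
            counts[leftovers[i % len(leftovers)]] += 1
            i += 1
    labels = [s for s, c in counts.items() for _ in range(c)]
    if len(labels) != spec.n_hosts:
        raise GenerationError("subregion host counts do not sum to n_hosts")
    for s in counts:
        if s not in env:
            raise GenerationError(f"subregion {s!r} not in environment")
    return labels


def _species_assignment(spec: GeneratorSpec, subregions: list[str],
                        rng: np.random.Generator) -> list[str]:
    """Give each host a species, unique within its subregion; species may
    recur across subregions so geographic host nodes outnumber species."""
    n_species = spec.n_species or max(2, int(0.53 * spec.n_hosts))
    pool = [f"Synthcora sp{n:04d}" for n in range(n_species)]
    # widespread species are more likely to be picked in several subregions
    w = rng.lognormal(0.0, 1.0, n_species)
    out = [""] * spec.n_hosts
    by_sub: dict[str, list[int]] = {}
    for i, s in enumerate(subregions):
        by_sub.setdefault(s, []).append(i)
    for s, idxs in by_sub.items():
        if len(idxs) > n_species:
            raise GenerationError(f"subregion {s} needs more species than exist")
        chosen = rng.choice(n_species, size=len(idxs), replace=False, p=w / w.sum())
        for i, sp in zip(idxs, chosen):
            out[i] = pool[sp]
    return out


def generate_tolerances(spec: GeneratorSpec, species: list[str],
                        symbionts: list[str], genera: list[str],
                        rng: np.random.Generator):
    """Draw ground-truth BRI/rank values and build the source tables.

    The configured unlisted fraction of taxa is withheld from the tables so
    downstream tolerance assignment must impute them.
    """
    uniq_species = sorted(set(species))
    bri = np.clip(rng.normal(spec.bri_mean, spec.bri_sd, len(uniq_species)), 0, 100)
    listed_h = rng.random(len(uniq_species)) >= spec.host_unlisted_fraction
    host_df = pd.DataFrame(
        {
            "species": [s for s, keep in zip(uniq_species, listed_h) if keep],
            "bri_mean": [round(float(b), 3) for b, keep in zip(bri, listed_h) if keep],
            "bri_sd": spec.bri_species_sd,
        }
    )
    ranks = [spec.class_model.draw_rank(g, rng) for g in genera]
    listed_s = rng.random(len(symbionts)) >= spec.symbiont_unlisted_fraction
    sym_df = pd.DataFrame(
        {
            "its2_type": [t for t, keep in zip(symbionts, listed_s) if keep],
            "genus": [g for g, keep in zip(genera, listed_s) if keep],
            "rank_score": [round(float(r), 3) for r, keep in zip(ranks, listed_s) if keep],
        }
    )
    tables = ToleranceTables(host=host_df, symbiont=sym_df, class_model=spec.class_model)
    truth = {
        "bri": dict(zip(uniq_species, bri.tolist())),
        "rank": dict(zip(symbionts, [float(r) for r in ranks])),
        "host_listed": dict(zip(uniq_species, listed_h.tolist())),
        "symbiont_listed": dict(zip(symbionts, listed_s.tolist())),
    }
    return tables, truth


def generate_network(spec: GeneratorSpec,
                     env: SubregionEnvironment | None = None) -> SyntheticBundle:
    """Generate a full synthetic bundle from the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    env = env or load_default_environment()

    sym_deg = _symbiont_degrees(spec, rng)
    host_quota = _host_quota(spec, rng)
    edges = _wire(spec, sym_deg, host_quota, rng)

    subregions = _subregion_partition(spec, env, rng)
    species = _species_assignment(spec, subregions, rng)
    families = [f"Synthfam{n:02d}" for n in range(spec.n_families)]
    fam_of = {
        sp: families[int(rng.integers(spec.n_families))] for sp in sorted(set(species))
    }
    symbionts = [f"S{n + 1}" for n in range(spec.n_symbionts)]
    genera = [
        _GENERA[i]
        for i in rng.choice(len(_GENERA), size=spec.n_symbionts, p=_GENUS_PROBS)
    ]
    for k in range(spec.n_hubs):  # real hubs are Cladocopium generalists
        genera[k] = "Cladocopium"

    records = [
        AssociationRecord(
            host_species=species[h],
            subregion=subregions[h],
            region=env.region_of(subregions[h]),
            symbiont_type=symbionts[s],
            host_family=fam_of[species[h]],
            symbiont_genus=genera[s],
        )
        for h, s in sorted(edges)
    ]
    tables, tol_truth = generate_tolerances(spec, species, symbionts, genera, rng)
    return SyntheticBundle(
        records=records,
        env=env,
        tables=tables,
        taxonomy=Taxonomy(fam_of),
        ground_truth={
            "spec": spec,
            "symbiont_degrees": sym_deg.tolist(),
            "host_degree_quota": host_quota.tolist(),
            **tol_truth,
        },
    )


def single_subregion_preset(
    t_mmm: float = 28.68,
    n_hosts: int = 60,
    n_symbionts: int = 25,
    n_links: int = 150,
    seed: int = 0,
    **overrides,
) -> SyntheticBundle:
    """One-subregion bundle: every link threshold lies in [T_MMM, T_MMM + T_delta],
    so resistance is bounded by 1. Useful for oracle and bound tests."""
    env = SubregionEnvironment(
        pd.DataFrame(
            {"subregion": ["Single"], "region": ["SingleRegion"], "t_mmm_2005_c": [t_mmm]}
        )
    )
    kwargs = dict(
        n_hosts=n_hosts,
        n_symbionts=n_symbionts,
        n_links=n_links,
        n_species=n_hosts,  # species unique within a subregion, only one here
        n_hubs=min(2, n_symbionts - 1),
        hub_min_degree=max(3, min(n_hosts // 2, 10)),
        subregion_hosts={"Single": n_hosts},
        seed=seed,
    )
    kwargs.update(overrides)
    spec = GeneratorSpec(**kwargs)
    return generate_network(spec, env=env)
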