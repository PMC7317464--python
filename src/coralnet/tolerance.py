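"""Thermal tolerance assignment for host and symbiont nodes.

Hosts: a taxon-level Bleaching Resistance Index (BRI, percent bleached tissue
expected under heat stress, 0-100) is mapped to a tolerance tau_host = 1 -
BRI/100, so fully susceptible species sit at 0 and fully resistant at 1.
Species missing from the source table get a BRI drawn from a Normal whose
mean and sd come from the closest listed relative group (congeners, then
confamilials, then a global fallback), clamped to [0, 100].

Symbionts: a thermal-tolerance rank score (0-100, ordinal) is compressed by a
square-root transform, tau_symbiont = sqrt(rank)/10. ITS2 types missing from
the source table draw a rank from a high/medium/low tolerance-class mixture
with genus-specific mixing proportions; these draws are taken fresh for every
simulation replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .network import HOST, host_nodes, symbiont_nodes

__all__ = [
    "NodeTolerance",
    "ToleranceTables",
    "SymbiontClassModel",
    "Taxonomy",
    "host_tolerance_from_bri",
    "symbiont_tolerance_from_rank",
    "impute_host_tolerance",
    "impute_symbiont_tolerance",
    "assign_tolerances",
]

MEASURED = "measured"
IMPUTED_RELATIVE = "imputed-relative"
IMPUTED_CLASS = "imputed-class"


class ToleranceDomainError(ValueError):
    """A BRI or rank score falls outside [0, 100]."""


class ImputationError(LookupError):
    """No relative available to impute from and fallback is disabled."""


@dataclass(frozen=True)
class NodeTolerance:
    value: float
    source: str

    def __post_init__(self):
        if not (0.0 <= self.value <= 1.0):
            raise ToleranceDomainError(f"tolerance {self.value} outside [0, 1]")


def host_tolerance_from_bri(bri: float) -> NodeTolerance:
    """tau_host = 1 - BRI/100 (higher BRI means more bleaching, lower tolerance)."""
    if not (0.0 <= bri <= 100.0):
        raise ToleranceDomainError(f"BRI {bri} outside [0, 100]")
    return NodeTolerance(1.0 - bri / 100.0, MEASURED)


def symbiont_tolerance_from_rank(rank: float) -> NodeTolerance:
    """tau_symbiont = sqrt(rank)/10; the square root narrows ordinal rank gaps."""
    if not (0.0 <= rank <= 100.0):
        raise ToleranceDomainError(f"rank score {rank} outside [0, 100]")
    return NodeTolerance(math.sqrt(rank) / 10.0, MEASURED)


# default mixing proportions of the three tolerance classes by symbiont genus;
# Durusdinium is the stress-tolerant genus, Breviolum/Cladocopium skew lower
_DEFAULT_PROPORTIONS = {
    "Durusdinium": {"high": 0.70, "medium": 0.25, "low": 0.05},
    "Symbiodinium": {"high": 0.45, "medium": 0.35, "low": 0.20},
    "Cladocopium": {"high": 0.20, "medium": 0.50, "low": 0.30},
    "Breviolum": {"high": 0.10, "medium": 0.40, "low": 0.50},
}
_DEFAULT_CLASS_DISTS = {
    "high": {"mean": 75.0, "sd": 10.0},
    "medium": {"mean": 45.0, "sd": 10.0},
    "low": {"mean": 15.0, "sd": 10.0},
}


@dataclass
class SymbiontClassModel:
    """High/medium/low rank-score mixture used to impute unlisted symbionts.

    Each class is a truncated normal on [0, 100]; genus-level mixing
    proportions say how likely an unlisted type in that genus is to belong to
    each class. Unknown genera use the pooled (average) proportions.
    """

    proportions: dict = field(default_factory=lambda: {g: dict(p) for g, p in _DEFAULT_PROPORTIONS.items()})
    class_dists: dict = field(default_factory=lambda: {c: dict(d) for c, d in _DEFAULT_CLASS_DISTS.items()})

    def __post_init__(self):
        if not self.class_dists:
            raise ValueError("class model has no tolerance-class distributions")
        for genus, props in self.proportions.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mixing proportions for {genus} sum to {total}, not 1")

    def pooled_proportions(self) -> dict:
        classes = list(self.class_dists)
        pooled = {c: 0.0 for c in classes}
        for props in self.proportions.values():
            for c in classes:
                pooled[c] += props.get(c, 0.0)
        n = len(self.proportions) or 1
        return {c: v / n for c, v in pooled.items()}

    def draw_rank(self, genus: str, rng: np.random.Generator) -> float:
        props = self.proportions.get(genus) or self.pooled_proportions()
        classes = sorted(props)
        p = np.array([props[c] for c in classes])
        cls = classes[rng.choice(len(classes), p=p / p.sum())]
        d = self.class_dists[cls]
        a, b = (0.0 - d["mean"]) / d["sd"], (100.0 - d["mean"]) / d["sd"]
        return float(truncnorm.rvs(a, b, loc=d["mean"], scale=d["sd"], random_state=rng))

    @classmethod
    def from_yaml(cls, path) -> "SymbiontClassModel":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            proportions=cfg.get("proportions", {g: dict(p) for g, p in _DEFAULT_PROPORTIONS.items()}),
            class_dists=cfg.get("class_dists", {c: dict(d) for c, d in _DEFAULT_CLASS_DISTS.items()}),
        )


@dataclass
class Taxonomy:
    """species -> family map; genus is taken from the binomial's first word."""

    family_of: dict = field(default_factory=dict)

    @staticmethod
    def genus_of(species: str) -> str:
        return species.split()[0] if species.split() else "unknown"

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Taxonomy":
        return cls(dict(zip(df["species"], df["family"])))


@dataclass
class ToleranceTables:
    """Measured source tables plus the imputation model.

    host: DataFrame with species, bri_mean, bri_sd.
    symbiont: DataFrame with its2_type, genus, rank_score.
    """

    host: pd.DataFrame
    symbiont: pd.DataFrame
    class_model: SymbiontClassModel = field(default_factory=SymbiontClassModel)

    def __post_init__(self):
        for col in ("species", "bri_mean", "bri_sd"):
            if col not in self.host.columns:
                raise ValueError(f"host tolerance table missing column {col!r}")
        for col in ("its2_type", "rank_score"):
            if col not in self.symbiont.columns:
                raise ValueError(f"symbiont tolerance table missing column {col!r}")
        bad = self.host[(self.host.bri_mean < 0) | (self.host.bri_mean > 100)]
        if len(bad):
            raise ToleranceDomainError(f"BRI means outside [0,100]: {list(bad.species)}")
        bad = self.symbiont[(self.symbiont.rank_score < 0) | (self.symbiont.rank_score > 100)]
        if len(bad):
            raise ToleranceDomainError(f"rank scores outside [0,100]: {list(bad.its2_type)}")
        self._host_idx = self.host.set_index("species")
        self._sym_idx = self.symbiont.set_index("its2_type")

    @classmethod
    def from_csv(cls, host_path, symbiont_path, class_model=None) -> "ToleranceTables":
        return cls(
            host=pd.read_csv(host_path),
            symbiont=pd.read_csv(symbiont_path),
            class_model=class_model or SymbiontClassModel(),
        )

    def host_entry(self, species: str):
        if species in self._host_idx.index:
            row = self._host_idx.loc[species]
            return float(row["bri_mean"]), float(row["bri_sd"])
        return None

    def symbiont_rank(self, its2: str):
        if its2 in self._sym_idx.index:
            return float(self._sym_idx.loc[its2, "rank_score"])
        return None


def _relative_group(species: str, tables: ToleranceTables, taxonomy: Taxonomy):
    """(mean, sd) pooled over the closest listed relatives, or None."""
    listed = tables.host
    genus = Taxonomy.genus_of(species)
    congeners = listed[listed["species"].map(Taxonomy.genus_of) == genus]
    if len(congeners):
        return float(congeners["bri_mean"].mean()), float(congeners["bri_sd"].mean())
    family = taxonomy.family_of.get(species)
    if family is not None:
        fam = listed[listed["species"].map(taxonomy.family_of.get) == family]
        if len(fam):
            return float(fam["bri_mean"].mean()), float(fam["bri_sd"].mean())
    return None


def impute_host_tolerance(
    species: str,
    tables: ToleranceTables,
    taxonomy: Taxonomy,
    rng: np.random.Generator,
    allow_global_fallback: bool = True,
) -> NodeTolerance:
    """Draw BRI ~ Normal(relative mean, relative sd), clamp to [0,100], transform."""
    group = _relative_group(species, tables, taxonomy)
    if group is None:
        if not allow_global_fallback:
            raise ImputationError(f"no listed relative for host species {species!r}")
        if len(tables.host):
            group = float(tables.host["bri_mean"].mean()), float(tables.host["bri_sd"].mean())
        else:
            # no listed host at all: fall back to a vague mid-scale BRI prior
            group = (50.0, 20.0)
    mean, sd = group
    bri = mean if sd == 0 else float(rng.normal(mean, sd))
    bri = min(100.0, max(0.0, bri))
    return NodeTolerance(host_tolerance_from_bri(bri).value, IMPUTED_RELATIVE)


def impute_symbiont_tolerance(
    its2: str,
    genus: str,
    tables: ToleranceTables,
    rng: np.random.Generator,
) -> NodeTolerance:
    """Class draw per genus proportions, then rank draw, then transform."""
    rank = tables.class_model.draw_rank(genus, rng)
    return NodeTolerance(symbiont_tolerance_from_rank(rank).value, IMPUTED_CLASS)


def assign_tolerances(
    net,
    tables: ToleranceTables,
    taxonomy: Taxonomy | None = None,
    rng: np.random.Generator | None = None,
    frozen_host_imputes: dict | None = None,
) -> dict:
    """Set ``tolerance``/``tol_source`` attributes on every node of ``net``.

    Measured values are deterministic; imputed values use ``rng`` and should
    be redrawn per simulation replicate. Pass ``frozen_host_imputes`` (the
    returned dict from a previous call) to hold imputed host draws fixed
    across replicates. Returns the imputed host draws of this call.
    """
    taxonomy = taxonomy or Taxonomy()
    rng = rng if rng is not None else np.random.default_rng()
    frozen_host_imputes = frozen_host_imputes or {}
    host_draws: dict = {}
    for h in host_nodes(net):
        species = net.nodes[h]["species"]
        entry = tables.host_entry(species)
        if entry is not None:
            tol = host_tolerance_from_bri(entry[0])
        elif h in frozen_host_imputes:
            tol = frozen_host_imputes[h]
        else:
            tol = impute_host_tolerance(species, tables, taxonomy, rng)
            host_draws[h] = tol
        net.nodes[h]["tolerance"] = tol.value
        net.nodes[h]["tol_source"] = tol.source
    for s in symbiont_nodes(net):
        rank = tables.symbiont_rank(s)
        if rank is not None:
            tol = symbiont_tolerance_from_rank(rank)
        else:
            tol = impute_symbiont_tolerance(s, net.nodes[s].get("genus", "unknown"), tables, rng)
        net.nodes[s]["tolerance"] = tol.value
        net.nodes[s]["tol_source"] = tol.source
    return {**frozen_host_imputes, **host_draws}
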