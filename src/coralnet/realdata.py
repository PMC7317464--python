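"""Loader for the curated real association data set, when available.

The curated GeoSymbio-derived association table and the host/symbiont
tolerance source tables are distributed separately from this package. To run
the real-data analyses, place them under ``data/real/`` in the working tree
(or pass an explicit directory):

    data/real/associations.csv        host_species, subregion, region,
                                      symbiont_type [, host_family,
                                      symbiont_genus, in_situ, scleractinian]
    data/real/host_tolerance.csv      species, bri_mean, bri_sd
    data/real/symbiont_tolerance.csv  its2_type, genus, rank_score
    data/real/taxonomy.csv            species, family          (optional)

The packaged subregion environment table is used unless ``environment.csv``
is also present.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass

import pandas as pd

from .environment import load_default_environment, read_environment_csv
from .network import build_network, filter_records, read_records
from .tolerance import Taxonomy, ToleranceTables

__all__ = ["RealDataset", "load_real_dataset", "DEFAULT_REAL_DATA_DIR"]

DEFAULT_REAL_DATA_DIR = pathlib.Path("data") / "real"


class RealDataUnavailable(FileNotFoundError):
    """The separately distributed real data files were not found."""


@dataclass
class RealDataset:
    records: list
    env: object
    tables: ToleranceTables
    taxonomy: Taxonomy

    def network(self):
        return build_network(self.records, self.env)


def load_real_dataset(root=None) -> RealDataset:
    root = pathlib.Path(root) if root is not None else DEFAULT_REAL_DATA_DIR
    assoc = root / "associations.csv"
    host_tol = root / "host_tolerance.csv"
    sym_tol = root / "symbiont_tolerance.csv"
    missing = [str(p) for p in (assoc, host_tol, sym_tol) if not p.exists()]
    if missing:
        raise RealDataUnavailable(
            "real data files not found: " + ", ".join(missing)
            + f" (see coralnet.realdata docstring for the expected layout under {root})"
        )
    env_path = root / "environment.csv"
    env = read_environment_csv(env_path) if env_path.exists() else load_default_environment()
    taxonomy = Taxonomy()
    tax_path = root / "taxonomy.csv"
    if tax_path.exists():
        taxonomy = Taxonomy.from_frame(pd.read_csv(tax_path))
    return RealDataset(
        records=filter_records(read_records(assoc)),
        env=env,
        tables=ToleranceTables.from_csv(host_tol, sym_tol),
        taxonomy=taxonomy,
    )
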