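import numpy as np
import pandas as pd
import pytest

import coralnet as cn
from coralnet.environment import SubregionEnvironment


@pytest.fixture(scope="session")
def toy_env():
    return SubregionEnvironment(
        pd.DataFrame(
            {
                "subregion": ["North Reef", "South Reef", "Far Reef"],
                "region": ["Toy Ocean", "Toy Ocean", "Other Ocean"],
                "t_mmm_2005_c": [28.0, 29.0, 30.0],
            }
        )
    )


def make_records(rows):
    """rows: (species, subregion, symbiont[, genus])"""
    out = []
    for row in rows:
        sp, sub, sym = row[:3]
        genus = row[3] if len(row) > 3 else "Cladocopium"
        out.append(
            cn.AssociationRecord(
                host_species=sp,
                subregion=sub,
                region="Toy Ocean",
                symbiont_type=sym,
                host_family="Toyfam",
                symbiont_genus=genus,
            )
        )
    return out


@pytest.fixture(scope="session")
def toy_net(toy_env):
    """Small fixed network: 4 hosts over 2 subregions, 3 symbionts, 6 links."""
    records = make_records(
        [
            ("Acropora alpha", "North Reef", "C1"),
            ("Acropora alpha", "South Reef", "C1"),
            ("Acropora beta", "North Reef", "C1"),
            ("Acropora beta", "North Reef", "D1", "Durusdinium"),
            ("Porites gamma", "South Reef", "B1", "Breviolum"),
            ("Porites gamma", "South Reef", "C1"),
        ]
    )
    return cn.build_network(records, toy_env)


def star_network(toy_env, n_leaves=10, subregion="North Reef"):
    records = make_records(
        [(f"Coral sp{i:02d}", subregion, "HUB") for i in range(n_leaves)]
    )
    return cn.build_network(records, toy_env)


def set_tolerances(net, host_tol=None, sym_tol=None, default=0.5):
    """Directly attach tolerance attributes (bypassing source tables)."""
    host_tol = host_tol or {}
    sym_tol = sym_tol or {}
    for n, d in net.nodes(data=True):
        table = host_tol if d["kind"] == "host" else sym_tol
        d["tolerance"] = table.get(n, default)
        d["tol_source"] = "measured"
    return net


@pytest.fixture(scope="session")
def small_bundle():
    return cn.single_subregion_preset(n_hosts=40, n_symbionts=15, n_links=90, seed=11)


@pytest.fixture(scope="session")
def global_like_bundle():
    return cn.generate_network(cn.global_like_spec(seed=1))
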