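import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import coralnet as cn
from coralnet.tolerance import (
    IMPUTED_CLASS,
    IMPUTED_RELATIVE,
    MEASURED,
    ImputationError,
    ToleranceDomainError,
    impute_host_tolerance,
    impute_symbiont_tolerance,
)


@pytest.fixture(scope="module")
def tables():
    return cn.ToleranceTables(
        host=pd.DataFrame(
            {
                "species": ["Acropora alpha", "Acropora beta", "Porites gamma"],
                "bri_mean": [40.0, 40.0, 70.0],
                "bri_sd": [10.0, 10.0, 0.0],
            }
        ),
        symbiont=pd.DataFrame(
            {
                "its2_type": ["C1", "D1"],
                "genus": ["Cladocopium", "Durusdinium"],
                "rank_score": [25.0, 81.0],
            }
        ),
    )


class TestTransforms:
    @pytest.mark.parametrize("bri,expected", [(100.0, 0.0), (0.0, 1.0), (37.5, 0.625)])
    def test_host_bri_transform(self, bri, expected):
        tol = cn.host_tolerance_from_bri(bri)
        assert tol.value == pytest.approx(expected)
        assert tol.source == MEASURED

    @pytest.mark.parametrize("rank,expected", [(100.0, 1.0), (0.0, 0.0), (25.0, 0.5)])
    def test_symbiont_rank_transform(self, rank, expected):
        tol = cn.symbiont_tolerance_from_rank(rank)
        assert tol.value == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [-0.1, 100.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ToleranceDomainError):
            cn.host_tolerance_from_bri(bad)
        with pytest.raises(ToleranceDomainError):
            cn.symbiont_tolerance_from_rank(bad)

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=50, derandomize=True)
    def test_transforms_monotone_and_bounded(self, x, y):
        lo, hi = sorted([x, y])
        # higher BRI -> lower host tolerance; higher rank -> higher symbiont tolerance
        assert cn.host_tolerance_from_bri(hi).value <= cn.host_tolerance_from_bri(lo).value
        assert (cn.symbiont_tolerance_from_rank(hi).value
                >= cn.symbiont_tolerance_from_rank(lo).value)
        for v in (cn.host_tolerance_from_bri(x).value,
                  cn.symbiont_tolerance_from_rank(x).value):
            assert 0.0 <= v <= 1.0


class TestHostImputation:
    def test_zero_sd_relative_is_deterministic(self, tables):
        rng = np.random.default_rng(0)
        tol = impute_host_tolerance("Porites unlisted", tables, cn.Taxonomy(), rng)
        assert tol.value == pytest.approx(1 - 70.0 / 100)
        assert tol.source == IMPUTED_RELATIVE

    def test_congener_normal_draw_mean(self, tables):
        # congeners listed with (mean 40, sd 10) -> tolerance mean 1 - 0.40 = 0.60
        rng = np.random.default_rng(42)
        draws = [
            impute_host_tolerance("Acropora unlisted", tables, cn.Taxonomy(), rng).value
            for _ in range(10_000)
        ]
        assert np.mean(draws) == pytest.approx(0.60, abs=0.01)
        assert all(0.0 <= v <= 1.0 for v in draws)

    def test_negative_draws_clamped_to_full_tolerance(self):
        tables = cn.ToleranceTables(
            host=pd.DataFrame({"species": ["Acropora a"], "bri_mean": [1.0],
                               "bri_sd": [50.0]}),
            symbiont=pd.DataFrame({"its2_type": ["C1"], "genus": ["Cladocopium"],
                                   "rank_score": [50.0]}),
        )
        rng = np.random.default_rng(3)
        draws = [impute_host_tolerance("Acropora b", tables, cn.Taxonomy(), rng).value
                 for _ in range(200)]
        assert max(draws) == 1.0  # BRI clamped at 0
        assert all(v <= 1.0 for v in draws)

    def test_confamilial_used_when_no_congener(self, tables):
        taxonomy = cn.Taxonomy({"Porites gamma": "Poritidae", "Goniopora x": "Poritidae"})
        rng = np.random.default_rng(0)
        tol = impute_host_tolerance("Goniopora x", tables, taxonomy, rng)
        assert tol.value == pytest.approx(0.30)  # Porites gamma: mean 70, sd 0

    def test_no_relative_and_fallback_disabled_raises(self, tables):
        with pytest.raises(ImputationError, match="Unknownus"):
            impute_host_tolerance("Unknownus x", tables, cn.Taxonomy(),
                                  np.random.default_rng(0), allow_global_fallback=False)


class TestSymbiontImputation:
    def test_point_mass_class_always_same_value(self, tables):
        model = cn.SymbiontClassModel(
            proportions={"Durusdinium": {"high": 1.0}},
            class_dists={"high": {"mean": 81.0, "sd": 1e-12}},
        )
        t = cn.ToleranceTables(host=tables.host, symbiont=tables.symbiont,
                               class_model=model)
        rng = np.random.default_rng(5)
        for _ in range(10):
            tol = impute_symbiont_tolerance("D-new", "Durusdinium", t, rng)
            assert tol.value == pytest.approx(0.9, abs=1e-6)
            assert tol.source == IMPUTED_CLASS

    def test_class_frequencies_match_proportions(self):
        # separate the classes so each draw is attributable, then count
        model = cn.SymbiontClassModel(
            proportions={"Cladocopium": {"high": 0.5, "medium": 0.3, "low": 0.2}},
            class_dists={
                "high": {"mean": 90.0, "sd": 1e-9},
                "medium": {"mean": 50.0, "sd": 1e-9},
                "low": {"mean": 10.0, "sd": 1e-9},
            },
        )
        rng = np.random.default_rng(6)
        draws = np.array([model.draw_rank("Cladocopium", rng) for _ in range(10_000)])
        freqs = {
            "high": np.mean(draws > 80),
            "medium": np.mean((draws > 30) & (draws < 70)),
            "low": np.mean(draws < 30),
        }
        for cls, p in [("high", 0.5), ("medium", 0.3), ("low", 0.2)]:
            assert freqs[cls] == pytest.approx(p, abs=0.02)

    def test_unknown_genus_uses_pooled_proportions(self):
        model = cn.SymbiontClassModel()
        pooled = model.pooled_proportions()
        assert sum(pooled.values()) == pytest.approx(1.0)
        rng = np.random.default_rng(1)
        assert 0 <= model.draw_rank("Nonexistium", rng) <= 100

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            cn.SymbiontClassModel(proportions={"X": {"high": 0.5, "low": 0.4}})
        with pytest.raises(ValueError):
            cn.SymbiontClassModel(class_dists={})


class TestAssignTolerances:
    def test_measured_constant_imputed_varies_across_replicates(self, toy_net, tables):
        net = toy_net.copy()
        vals = []
        for seed in (1, 2):
            cn.assign_tolerances(net, tables, rng=np.random.default_rng(seed))
            vals.append({n: net.nodes[n]["tolerance"] for n in net.nodes})
            sources = {n: net.nodes[n]["tol_source"] for n in net.nodes}
        measured = [n for n, s in sources.items() if s == MEASURED]
        imputed = [n for n, s in sources.items() if s != MEASURED]
        assert measured and imputed
        for n in measured:
            assert vals[0][n] == vals[1][n]
        assert any(vals[0][n] != vals[1][n] for n in imputed)

    def test_frozen_host_imputes_reused(self, toy_env, tables):
        from conftest import make_records

        net = cn.build_network(
            make_records([("Montipora zeta", "North Reef", "C1")]), toy_env
        )
        draws = cn.assign_tolerances(net, tables, rng=np.random.default_rng(1))
        v1 = net.nodes["Montipora zeta [North Reef]"]["tolerance"]
        cn.assign_tolerances(net, tables, rng=np.random.default_rng(99),
                             frozen_host_imputes=draws)
        assert net.nodes["Montipora zeta [North Reef]"]["tolerance"] == v1

    def test_all_tolerances_in_unit_interval(self, global_like_bundle):
        net = global_like_bundle.network()
        cn.assign_tolerances(net, global_like_bundle.tables,
                             taxonomy=global_like_bundle.taxonomy,
                             rng=np.random.default_rng(0))
        assert all(0.0 <= net.nodes[n]["tolerance"] <= 1.0 for n in net.nodes)
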