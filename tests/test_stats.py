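"""Contingency tables, odds ratios, Fisher's exact test, and shade DE."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from pseudoshade.counting import ECRegistry, EquivalenceClass, make_cell_ec_matrix
from pseudoshade.ornament import ShadeRegistry
from pseudoshade.simulate import preset_null
from pseudoshade.stats import (
    ContingencyTable,
    build_table,
    filter_ecs,
    fisher_exact,
    haldane_anscombe_or,
    odds_ratio,
    read_t2g,
    results_frame,
    shade_de,
)

from .conftest import fisher_bruteforce


class TestOddsRatio:
    @pytest.mark.parametrize(
        "table,expected",
        [((2, 2, 2, 2), 1.0), ((2, 1, 1, 2), 4.0), ((5, 0, 0, 5), math.inf),
         ((0, 5, 5, 0), 0.0)],
    )
    def test_examples(self, table, expected):
        assert odds_ratio(ContingencyTable(*table)) == expected

    def test_double_zero_is_undefined_sentinel(self):
        assert math.isnan(odds_ratio(ContingencyTable(0, 0, 3, 0)))

    def test_reciprocal_identity(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 20, 4))
            fwd = odds_ratio(ContingencyTable(a, b, c, d))
            rev = odds_ratio(ContingencyTable(b, a, d, c))
            assert fwd * rev == pytest.approx(1.0)

    def test_haldane_anscombe_is_finite_on_boundaries(self):
        assert math.isfinite(haldane_anscombe_or(ContingencyTable(5, 0, 0, 5)))


class TestFisherExact:
    def test_most_probable_table_gives_p_one(self):
        assert fisher_exact(ContingencyTable(2, 2, 2, 2)) == 1.0

    def test_extreme_table_enumerates_to_2_over_252(self):
        assert fisher_exact(ContingencyTable(5, 0, 0, 5)) == pytest.approx(2 / 252)

    def test_empty_table(self):
        assert fisher_exact(ContingencyTable(0, 0, 0, 0)) == 1.0

    def test_matches_bruteforce_oracle_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, 4))
            got = fisher_exact(ContingencyTable(a, b, c, d))
            assert got == pytest.approx(fisher_bruteforce(a, b, c, d), rel=1e-12)

    def test_matches_scipy_independent_implementation(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, 4))
            _, p_scipy = scipy.stats.fisher_exact([[a, b], [c, d]])
            assert fisher_exact(ContingencyTable(a, b, c, d)) == pytest.approx(
                p_scipy, rel=1e-6, abs=1e-12
            )


def _presence_matrix(cells):
    """cells: {barcode: list of ec_ids present (count 1 each)}."""
    registry = ECRegistry()
    shade_reg = ShadeRegistry()
    shade = shade_reg.new_shade(0, "t0", "c0")
    # EC 0: shade-containing for gene of t0; EC 1: regular EC of that gene
    registry.get_id(EquivalenceClass(frozenset({0}), frozenset({shade})))
    registry.get_id(EquivalenceClass(frozenset({0}), frozenset()))
    triples = {
        (bc, f"u{ec}", ec) for bc, ecs in cells.items() for ec in ecs
    }
    matrix = make_cell_ec_matrix(triples, registry, ["t0"])
    return matrix, shade_reg


class TestBuildTable:
    def test_constructed_extreme(self):
        cells = {f"in{i}": [0] for i in range(5)}
        cells.update({f"out{i}": [1] for i in range(5)})
        matrix, _ = _presence_matrix(cells)
        cluster = {f"in{i}" for i in range(5)}
        t = build_table(matrix, 0, cluster, gene_ecs=[1])
        assert t == ContingencyTable(5, 0, 0, 5)

    def test_uniform_presence(self):
        cells = {f"in{i}": [0, 1] for i in range(2)}
        cells.update({f"out{i}": [0, 1] for i in range(2)})
        matrix, _ = _presence_matrix(cells)
        t = build_table(matrix, 0, {"in0", "in1"}, gene_ecs=[1])
        assert t == ContingencyTable(2, 2, 2, 2)

    def test_cell_counts_once_even_with_many_gene_ecs(self):
        registry = ECRegistry()
        shade_reg = ShadeRegistry()
        shade = shade_reg.new_shade(0, "t0", "c0")
        registry.get_id(EquivalenceClass(frozenset({0}), frozenset({shade})))
        registry.get_id(EquivalenceClass(frozenset({0}), frozenset()))
        registry.get_id(EquivalenceClass(frozenset({0}), frozenset({shade, shade + "x"})))
        shade_reg.parent[shade + "x"] = 0
        triples = {("bc0", "u1", 1), ("bc0", "u2", 2), ("bc1", "u3", 1)}
        matrix = make_cell_ec_matrix(triples, registry, ["t0"])
        t = build_table(matrix, 0, {"bc0"}, gene_ecs=[1])
        assert (t.c, t.d) == (1, 1)

    def test_empty_cluster_rejected(self):
        matrix, _ = _presence_matrix({"bc0": [0]})
        with pytest.raises(ValueError):
            build_table(matrix, 0, set(), gene_ecs=[1])


def _de_fixture(rng, n_cells=60, planted=True):
    """Two genes; gene0 has a shade EC concentrated in cluster c0 when
    ``planted``; presence of regular ECs everywhere."""
    registry = ECRegistry()
    shade_reg = ShadeRegistry()
    s0 = shade_reg.new_shade(0, "t0", "c0")
    ec_shade = registry.get_id(EquivalenceClass(frozenset({0}), frozenset({s0})))
    ec_reg0 = registry.get_id(EquivalenceClass(frozenset({0}), frozenset()))
    ec_reg1 = registry.get_id(EquivalenceClass(frozenset({1}), frozenset()))
    barcodes = [f"bc{i:03d}" for i in range(n_cells)]
    clusters = {bc: "c0" if i < n_cells // 2 else "c1" for i, bc in enumerate(barcodes)}
    triples = set()
    for i, bc in enumerate(barcodes):
        triples.add((bc, "u0", ec_reg0))
        triples.add((bc, "u1", ec_reg1))
        if planted:
            if clusters[bc] == "c0" and i % 2 == 0:
                triples.add((bc, "u2", ec_shade))
        else:
            if i % 4 == 0:
                triples.add((bc, "u2", ec_shade))
    matrix = make_cell_ec_matrix(triples, registry, ["t0", "t1"])
    t2g = pd.DataFrame(
        {"target": ["t0", "t1"], "gene": ["gene0", "gene1"],
         "biotype": ["protein_coding"] * 2}
    )
    return matrix, shade_reg, t2g, clusters, ec_shade


class TestFilterEcs:
    def _base(self, presence_cells=12):
        registry = ECRegistry()
        shade_reg = ShadeRegistry()
        s0 = shade_reg.new_shade(0, "t0", "c0")
        ec_ids = {
            "shaded": registry.get_id(
                EquivalenceClass(frozenset({0}), frozenset({s0}))
            ),
            "regular": registry.get_id(
                EquivalenceClass(frozenset({0}), frozenset())
            ),
            "multigene": registry.get_id(
                EquivalenceClass(frozenset({0, 1}), frozenset({s0}))
            ),
            "pseudo": registry.get_id(
                EquivalenceClass(frozenset({2}), frozenset({s0}))
            ),
            "unannotated": registry.get_id(
                EquivalenceClass(frozenset({3}), frozenset({s0}))
            ),
        }
        triples = set()
        for name, ec in ec_ids.items():
            n = presence_cells if name != "regular" else 12
            for i in range(n):
                triples.add((f"bc{i:02d}", f"u{ec}", ec))
        matrix = make_cell_ec_matrix(
            triples, registry, ["t0", "t1", "t2", "t3"]
        )
        t2g = pd.DataFrame(
            {
                "target": ["t0", "t1", "t2", "t3"],
                "gene": ["gene0", "gene1", "gene2", None],
                "biotype": ["protein_coding", "protein_coding",
                            "processed_pseudogene", "protein_coding"],
            }
        )
        return matrix, shade_reg, t2g, ec_ids

    def test_keeps_only_single_annotated_gene_shade_ecs(self):
        matrix, shade_reg, t2g, ec_ids = self._base()
        kept = filter_ecs(matrix, shade_reg, t2g, min_cells=10)
        assert kept == [ec_ids["shaded"]]

    def test_min_cells_threshold(self):
        matrix, shade_reg, t2g, ec_ids = self._base(presence_cells=9)
        assert filter_ecs(matrix, shade_reg, t2g, min_cells=10) == []
        assert ec_ids["shaded"] in filter_ecs(matrix, shade_reg, t2g, min_cells=9)

    def test_missing_target_rejected_by_name(self):
        matrix, shade_reg, t2g, _ = self._base()
        with pytest.raises(KeyError, match="t3"):
            filter_ecs(matrix, shade_reg, t2g[t2g["target"] != "t3"], min_cells=10)


class TestShadeDe:
    def test_planted_shade_is_top_hit_with_or_above_one(self, rng):
        matrix, shade_reg, t2g, clusters, ec_shade = _de_fixture(rng)
        results = shade_de(matrix, shade_reg, t2g, clusters, min_cells=10)
        top = results[0]
        assert (top.ec_id, top.cluster) == (ec_shade, "c0")
        assert top.odds_ratio > 1
        assert top.p_adj < 0.05

    def test_uniform_shade_is_null(self, rng):
        matrix, shade_reg, t2g, clusters, ec_shade = _de_fixture(rng, planted=False)
        results = shade_de(matrix, shade_reg, t2g, clusters, min_cells=10)
        for r in results:
            assert r.p_adj > 0.5
            assert 0.2 < r.odds_ratio < 5

    def test_single_cluster_gives_sentinel_odds_ratios(self, rng):
        matrix, shade_reg, t2g, clusters, _ = _de_fixture(rng)
        one_cluster = {bc: "all" for bc in clusters}
        results = shade_de(matrix, shade_reg, t2g, one_cluster, min_cells=10)
        for r in results:
            assert r.table.b == 0 and r.table.d == 0
            assert math.isnan(r.odds_ratio) or math.isinf(r.odds_ratio)

    def test_bh_adjustment_properties(self, rng):
        matrix, shade_reg, t2g, clusters = preset_null(17, n_ecs=40, n_cells=80)
        results = shade_de(matrix, shade_reg, t2g, clusters, min_cells=5)
        by_p = sorted(results, key=lambda r: r.p)
        for r in results:
            assert r.p_adj >= r.p - 1e-12
            assert 0 <= r.p_adj <= 1
        adj = [r.p_adj for r in by_p]
        assert adj == sorted(adj)  # monotone in p

    def test_single_test_p_adj_equals_p(self, rng):
        matrix, shade_reg, t2g, clusters, _ = _de_fixture(rng)
        c0_only = {bc: "c0" for bc in clusters}
        results = shade_de(matrix, shade_reg, t2g, c0_only, min_cells=10)
        assert len(results) == 1
        assert results[0].p_adj == pytest.approx(results[0].p)

    def test_no_testable_ecs_returns_empty(self, rng):
        matrix, shade_reg, t2g, clusters, _ = _de_fixture(rng)
        results = shade_de(matrix, shade_reg, t2g, clusters, min_cells=1000)
        assert results == []

    def test_results_frame_is_volcano_ready(self, rng):
        matrix, shade_reg, t2g, clusters, _ = _de_fixture(rng)
        frame = results_frame(shade_de(matrix, shade_reg, t2g, clusters, min_cells=10))
        assert list(frame.columns) == [
            "ec_id", "gene", "cluster", "a", "b", "c", "d",
            "odds_ratio", "p", "p_adj",
        ]
        assert len(frame) == 2  # one testable EC x two clusters


def test_read_t2g_roundtrip(tmp_path):
    path = tmp_path / "t2g.tsv"
    path.write_text("t0\tgene0\tprotein_coding\nt1\tgene1\tlncRNA\n")
    t2g = read_t2g(path)
    assert list(t2g["target"]) == ["t0", "t1"]
    assert list(t2g.columns) == ["target", "gene", "biotype"]
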