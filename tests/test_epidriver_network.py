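import networkx as nx
import numpy as np
import pandas as pd
import pytest

import epiorigin as eo
from epiorigin.differential import log2_cpm
from epiorigin.epidriver_network import (
    CoexpressionModules,
    _rank_auc,
    build_coexpression_modules,
    build_directed_net,
    call_epidrivers,
    overlap_significance,
    score_a_formula,
    score_importance,
)
from epiorigin.omics_io import CountMatrix, EdgeList, ReactionTable, ValidationError

import _brute
from conftest import make_samples


def _reactions(rows):
    return ReactionTable(pd.DataFrame(
        [(e, frozenset(s), frozenset(p)) for e, s, p in rows],
        columns=["enzyme_gene", "substrates", "products"],
        index=pd.Index([f"r{i}" for i in range(len(rows))], name="reaction_id")))


def _counts_from_log(log_expr, genes):
    arr = np.round(np.power(2.0, log_expr)).astype(np.int64)
    samples = [f"s{i:02d}" for i in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))


class TestDirectedNet:
    def test_product_feeds_substrate(self):
        net = build_directed_net(_reactions([
            ("A", ["m1"], ["m2"]), ("B", ["m2"], ["m3"])]))
        assert set(net.edges) == {("A", "B")}

    def test_disjoint_metabolites_no_edges(self):
        net = build_directed_net(_reactions([
            ("A", ["m1"], ["m2"]), ("B", ["m3"], ["m4"])]))
        assert net.number_of_edges() == 0

    def test_ppi_weight_cutoff_and_both_directions(self):
        edges = EdgeList(pd.DataFrame({
            "gene_a": ["A", "A"], "gene_b": ["B", "C"], "weight": [0.7, 0.3]}))
        net = build_directed_net(edges)
        assert set(net.edges) == {("A", "B"), ("B", "A")}

    def test_no_self_edge_even_when_enzyme_recycles(self):
        net = build_directed_net(_reactions([("A", ["m1"], ["m2"]),
                                             ("A", ["m2"], ["m3"])]))
        assert ("A", "A") not in net.edges


class TestScoreFormula:
    def test_printed_formula_value(self):
        # |0.8 - 0.5| * log2((4/8) / (100/1000)) = 0.3 * log2(5)
        assert score_a_formula(0.8, 4, 8, 100, 1000) == pytest.approx(
            0.3 * np.log2(5.0), abs=1e-12)

    def test_annihilation_cases(self):
        assert score_a_formula(0.5, 3, 9, 10, 100) == 0.0
        assert score_a_formula(0.8, 10, 100, 100, 1000) == pytest.approx(0.0)
        assert score_a_formula(0.9, 0, 5, 10, 100) == -np.inf

    def test_rank_auc_ties_counted_half(self):
        assert _rank_auc(np.array([1.0, 1.0]), np.array([1.0, 0.0])) == pytest.approx(0.75)


def _random_instance(rng, n_genes):
    genes = [f"g{i}" for i in range(n_genes)]
    expr = rng.normal(size=(n_genes, 12))
    counts = _counts_from_log(np.clip(expr + 8, 1, 16), genes)
    samples = make_samples(["tumor"] * 8 + ["normal"] * 4)
    net = nx.DiGraph()
    net.add_nodes_from(genes)
    for _ in range(n_genes * 2):
        a, b = rng.choice(n_genes, 2, replace=False)
        net.add_edge(genes[a], genes[b])
    module_genes = set(rng.choice(genes, size=max(2, n_genes // 2), replace=False))
    network_genes = set(genes)
    modules = CoexpressionModules(
        gene_to_module={g: (1 if g in module_genes else 0) for g in genes},
        modules={1: module_genes}, tumor_specific={1},
        tau=0.6, min_module_size=2, network_genes=network_genes)
    return counts, samples, net, modules


def test_score_importance_matches_brute_force_oracle():
    rng = np.random.default_rng(100)
    for _ in range(10):
        n_genes = int(rng.integers(6, 21))
        counts, samples, net, modules = _random_instance(rng, n_genes)
        scored = score_importance(net, modules, counts, samples).set_index("gene")
        tumor = list(samples.tumor_samples())
        expr = log2_cpm(counts)[tumor]
        expr_rows = {g: expr.loc[g].to_numpy() for g in expr.index}
        succ = {g: sorted(net.successors(g)) for g in net.nodes}
        ts = modules.tumor_specific_genes
        for gene in net.nodes:
            ref = _brute.score_a(succ, gene, expr_rows, modules.network_genes, ts)
            if ref is None:
                assert gene not in scored.index or not succ[gene]
                continue
            row = scored.loc[gene]
            assert row["auc"] == pytest.approx(ref["auc"], abs=1e-12)
            if np.isinf(ref["score"]):
                assert np.isneginf(row["score_a"])
            else:
                assert row["score_a"] == pytest.approx(ref["score"], abs=1e-12)


class TestCoexpressionModules:
    def _block_counts(self, shift_block=None, seed=0, n_noise=6):
        rng = np.random.default_rng(seed)
        n_t, n_n = 16, 16
        f1, f2 = rng.normal(size=n_t), rng.normal(size=n_t)
        rows, genes = [], []
        for i in range(12):
            t = 8 + 1.5 * f1 + rng.normal(0, 0.25, n_t)
            n = 8 + rng.normal(0, 0.25, n_n)
            if shift_block == 1:
                t = t + 2.0
            rows.append(np.r_[t, n]); genes.append(f"a{i}")
        for i in range(12):
            t = 8 + 1.5 * f2 + rng.normal(0, 0.25, n_t)
            n = 8 + rng.normal(0, 0.25, n_n)
            rows.append(np.r_[t, n]); genes.append(f"b{i}")
        for i in range(n_noise):  # heavy ballast keeps CPM composition stable
            rows.append(np.r_[np.full(n_t + n_n, 14.0) + rng.normal(0, 0.5, n_t + n_n)])
            genes.append(f"z{i}")
        counts = _counts_from_log(np.array(rows), genes)
        samples = make_samples(["tumor"] * n_t + ["normal"] * n_n)
        return counts, samples

    def test_two_planted_blocks_are_recovered(self):
        counts, samples = self._block_counts()
        mods = build_coexpression_modules(counts, samples, min_size=10)
        blocks = [m for m in mods.modules.values() if len(m & {f"a{i}" for i in range(12)}) >= 10
                  or len(m & {f"b{i}" for i in range(12)}) >= 10]
        assert len(blocks) >= 2
        for m in mods.modules.values():  # no module mixes the two blocks
            assert not (m & {f"a{i}" for i in range(12)} and m & {f"b{i}" for i in range(12)})

    def test_only_shifted_block_is_tumor_specific(self):
        counts, samples = self._block_counts(shift_block=1)
        mods = build_coexpression_modules(counts, samples, min_size=10)
        ts = mods.tumor_specific_genes
        assert {f"a{i}" for i in range(12)} <= ts
        assert not ({f"b{i}" for i in range(12)} & ts)

    def test_independent_noise_yields_no_modules(self):
        rng = np.random.default_rng(4)
        counts = _counts_from_log(rng.normal(8, 1, size=(50, 24)),
                                  [f"g{i}" for i in range(50)])
        samples = make_samples(["tumor"] * 12 + ["normal"] * 12)
        mods = build_coexpression_modules(counts, samples, min_size=10)
        assert mods.modules == {}

    def test_constant_gene_is_excluded_with_count(self):
        counts, samples = self._block_counts()
        vals = counts.values.copy()
        vals.iloc[0] = 0  # zero everywhere: constant (zero) on the log-CPM scale
        mods = build_coexpression_modules(CountMatrix(vals), samples, min_size=10)
        assert mods.n_dropped_constant >= 1


class TestEpidriverCalls:
    def _de(self, genes, sig):
        return pd.DataFrame({"gene_id": genes, "log2fc": 3.0, "p": 0.001,
                             "q": 0.001, "significant": [g in sig for g in genes]})

    def _scores(self, genes, key):
        return pd.DataFrame({"gene": genes, "auc": 0.8, "c_in": 1, "c_all": 1,
                             "n_in": 1, "n_all": 2, "score_a": 0.3,
                             "key_gene": [g in key for g in genes]})

    def test_union_over_networks(self):
        genes = ["g1", "g2", "g3"]
        calls = call_epidrivers(self._de(genes, {"g1", "g2"}),
                                self._scores(genes, {"g1"}),
                                self._scores(genes, {"g3"}),
                                {"g1": True, "g2": True, "g3": True})
        out = calls.set_index("gene")["epi_driver"]
        assert bool(out["g1"]) and not bool(out["g2"]) and not bool(out["g3"])

    def test_key_without_de_is_not_driver(self):
        genes = ["g1"]
        calls = call_epidrivers(self._de(genes, set()),
                                self._scores(genes, {"g1"}),
                                self._scores(genes, {"g1"}), {"g1": True})
        assert not calls["epi_driver"].any()

    def test_empty_de_yields_no_drivers(self):
        calls = call_epidrivers(pd.DataFrame(columns=["gene_id", "significant"]),
                                None, None, {})
        assert len(calls) == 0 or not calls["epi_driver"].any()

    def test_monotone_in_inputs(self):
        genes = ["g1", "g2"]
        base = call_epidrivers(self._de(genes, {"g1"}), self._scores(genes, {"g1"}),
                               None, {"g1": True})
        grown = call_epidrivers(self._de(genes, {"g1", "g2"}), self._scores(genes, {"g1", "g2"}),
                                None, {"g1": True, "g2": True})
        before = set(base.loc[base["epi_driver"], "gene"])
        after = set(grown.loc[grown["epi_driver"], "gene"])
        assert before <= after


class TestOverlap:
    def test_full_overlap_hypergeometric_tail(self):
        u = {f"x{i}" for i in range(10)}
        a = set(list(u)[:5])
        out = overlap_significance(a, a, u)
        assert out["overlap"] == 5
        assert out["p"] == pytest.approx(1 / 252, rel=1e-9)

    def test_disjoint_sets_enrichment_p_is_one(self):
        u = [f"x{i}" for i in range(10)]
        out = overlap_significance(set(u[:5]), set(u[5:]), set(u))
        assert out["overlap"] == 0 and out["p"] == pytest.approx(1.0)

    def test_empty_set(self):
        u = {"a", "b", "c"}
        out = overlap_significance(set(), {"a"}, u)
        assert out["overlap"] == 0 and out["p"] == pytest.approx(1.0)
        with pytest.raises(ValidationError):
            overlap_significance({"a"}, {"b"}, set())
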