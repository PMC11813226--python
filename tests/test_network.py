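"""Co-expression network, Leiden modules, eigengenes, cross-tissue pairs."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from crossnet import (
    CoexprNetwork, build_network, cross_tissue_module_correlation,
    detect_modules, eigengene, filter_low_expression, module_deg_enrichment,
    module_patterns, simulate_module_matrix,
)
from crossnet.de import DEGSets


def adjusted_rand_index(a, b):
    n = len(a)
    pairs = lambda x: sum(v * (v - 1) // 2 for v in Counter(x).values())
    sij = sum(v * (v - 1) // 2 for v in Counter(zip(a, b)).values())
    sa, sb = pairs(a), pairs(b)
    expected = sa * sb / (n * (n - 1) // 2)
    return (sij - expected) / ((sa + sb) / 2 - expected)


def clique_network(sizes, tissue="T"):
    """Disjoint cliques with rho 0.9 as a ready-made CoexprNetwork."""
    nodes, rows, start = [], [], 0
    for s in sizes:
        members = [f"g{start + i:04d}" for i in range(s)]
        nodes += members
        rows += [
            {"gene_i": a, "gene_j": b, "rho": 0.9, "p": 1e-8, "q": 1e-6}
            for i, a in enumerate(members) for b in members[i + 1:]
        ]
        start += s
    return CoexprNetwork(nodes=nodes, edges=pd.DataFrame(rows), tissue=tissue)


class TestFilter:
    def test_zero_and_boundary_genes(self):
        mat = pd.DataFrame({"s1": [0.0, 1.0, 5.0], "s2": [0.0, 1.0, 0.1]},
                           index=list("abc"))
        kept = filter_low_expression(mat, threshold=1.0)
        assert list(kept) == ["b", "c"]  # mean TPM exactly 1 is retained

    def test_matches_mean_threshold_oracle(self, rng):
        mat = pd.DataFrame(rng.random(size=(100, 6)) * 3)
        kept = filter_low_expression(mat, 1.0)
        expected = mat.index[mat.to_numpy().mean(axis=1) >= 1.0]
        assert list(kept) == list(expected)

    def test_all_filtered_errors(self):
        with pytest.raises(ValueError):
            filter_low_expression(pd.DataFrame({"s": [0.1, 0.2]}), 1.0)


class TestBuildNetwork:
    def test_perfect_pair_among_noise(self, rng):
        x = rng.normal(size=(30, 20))
        x[1] = x[0]  # duplicated profile
        net = build_network(pd.DataFrame(x), tissue="T")
        top = net.edges.iloc[0]
        assert {top.gene_i, top.gene_j} == {0, 1} and top.rho == pytest.approx(1.0)

    def test_null_matrix_retains_nothing(self, rng):
        net = build_network(pd.DataFrame(rng.normal(size=(60, 10))), tissue="T")
        assert net.n_candidate_edges <= 3
        assert len(net.edges) <= 3

    def test_rank_invariance_and_sample_order(self, rng):
        expr, _ = simulate_module_matrix(2, 20, 30, 0.85, seed=4)
        net = build_network(expr, tissue="T")
        monotone = np.exp(expr)  # strictly increasing transform
        net2 = build_network(monotone, tissue="T")
        perm = rng.permutation(expr.shape[1])
        net3 = build_network(expr.iloc[:, perm], tissue="T")
        for other in (net2, net3):
            pd.testing.assert_frame_equal(
                net.edges[["gene_i", "gene_j"]], other.edges[["gene_i", "gene_j"]]
            )
            np.testing.assert_allclose(net.edges["rho"], other.edges["rho"], atol=1e-12)

    def test_planted_modules_dominate_edges(self):
        expr, labels = simulate_module_matrix(3, 40, 40, 0.9, n_noise_genes=80, seed=7)
        net = build_network(expr, tissue="T")
        lab = dict(zip(expr.index, labels))
        intra = np.mean(
            [lab[a] == lab[b] != -1 for a, b in zip(net.edges.gene_i, net.edges.gene_j)]
        )
        assert intra >= 0.90

    def test_candidate_basis_keeps_decile_of_candidates(self):
        expr, _ = simulate_module_matrix(3, 30, 40, 0.9, seed=3)
        net = build_network(expr, tissue="T", top_frac_basis="candidates")
        assert len(net.edges) == int(0.10 * net.n_candidate_edges)

    def test_constant_gene_pairs_excluded(self, rng):
        x = rng.normal(size=(10, 12))
        x[0] = 5.0
        net = build_network(pd.DataFrame(x), tissue="T")
        assert net.n_constant_pairs_excluded == 9
        assert not ((net.edges.gene_i == 0) | (net.edges.gene_j == 0)).any()

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError):
            build_network(pd.DataFrame(rng.normal(size=(5, 3))))


class TestDetectModules:
    def test_two_disjoint_cliques(self):
        mods = detect_modules(clique_network([40, 40]), min_size=30, seed=0)
        assert sorted(len(m.genes) for m in mods.modules) == [40, 40]
        assert mods.modules[0].id == "T.M0"
        assert not mods.unassigned

    def test_small_cliques_discarded(self):
        mods = detect_modules(clique_network([10, 10]), min_size=30, seed=0)
        assert mods.modules == []
        assert len(mods.unassigned) == 20

    def test_empty_network(self):
        net = CoexprNetwork(nodes=["a", "b"], edges=pd.DataFrame(
            columns=["gene_i", "gene_j", "rho", "p", "q"]), tissue="T")
        mods = detect_modules(net)
        assert mods.modules == [] and mods.unassigned == {"a", "b"}

    def test_planted_partition_graph_recovery(self, rng):
        """3 x 50 planted-partition graph (p_in=0.3, p_out=0.01): ARI >= 0.9."""
        aris = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            rows, labels = [], {}
            for m in range(3):
                for i in range(50):
                    labels[f"g{m * 50 + i:04d}"] = m
            genes = sorted(labels)
            for i, a in enumerate(genes):
                for b in genes[i + 1:]:
                    p = 0.3 if labels[a] == labels[b] else 0.01
                    if r.random() < p:
                        rows.append({"gene_i": a, "gene_j": b, "rho": 0.5,
                                     "p": 1e-6, "q": 1e-4})
            net = CoexprNetwork(nodes=genes, edges=pd.DataFrame(rows), tissue="T")
            mods = detect_modules(net, min_size=30, seed=seed)
            assignment = {g: m.id for m in mods.modules for g in m.genes}
            common = sorted(assignment)
            aris.append(adjusted_rand_index(
                [labels[g] for g in common], [assignment[g] for g in common]))
        assert min(aris) >= 0.9

    def test_partition_covers_all_nodes(self):
        expr, _ = simulate_module_matrix(3, 40, 40, 0.9, n_noise_genes=60, seed=1)
        net = build_network(expr, tissue="T")
        mods = detect_modules(net, expr=expr, min_size=30, seed=1)
        total = sum(len(m.genes) for m in mods.modules) + len(mods.unassigned)
        assert total == len(net.nodes)
        all_genes = set().union(*(m.genes for m in mods.modules)) | mods.unassigned
        assert all_genes == set(net.nodes)

    def test_membership_stable_across_seeds(self):
        expr, _ = simulate_module_matrix(3, 40, 40, 0.9, seed=5)
        net = build_network(expr, tissue="T")
        runs = []
        for seed in (1, 2, 3):
            mods = detect_modules(net, min_size=30, seed=seed)
            runs.append({g: m.id for m in mods.modules for g in m.genes})
        common = set(runs[0]) & set(runs[1]) & set(runs[2])
        for other in runs[1:]:
            ari = adjusted_rand_index(
                [runs[0][g] for g in sorted(common)], [other[g] for g in sorted(common)]
            )
            assert ari >= 0.95


class TestEigengene:
    def test_identical_profiles(self, rng):
        profile = rng.normal(size=10)
        sub = pd.DataFrame(np.tile(profile, (5, 1)))
        eig, ve = eigengene(sub)
        assert ve == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(eig, z / np.linalg.norm(z), atol=1e-8)

    def test_sign_convention_survives_negation(self, rng):
        sub = pd.DataFrame(rng.normal(size=(8, 12)) + rng.normal(size=12))
        eig1, _ = eigengene(sub)
        eig2, _ = eigengene(-sub)
        # orientation is tied to the (re-standardized) mean profile, which
        # flips under negation, so the eigengene flips consistently
        corr = np.corrcoef(eig1, eig2)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-8)
        mean1 = ((sub - sub.mean(axis=1).to_numpy()[:, None])
                 .div(sub.std(axis=1), axis=0).mean(axis=0))
        assert np.dot(eig1, mean1) >= 0

    def test_matches_full_decomposition(self, rng):
        sub = pd.DataFrame(rng.normal(size=(20, 15)))
        eig, ve = eigengene(sub)
        z = ((sub.T - sub.mean(axis=1)) / sub.std(axis=1)).T.to_numpy()
        w, v = np.linalg.eigh(z.T @ z)
        assert ve == pytest.approx(w[-1] / w.sum(), rel=1e-9)
        top = v[:, -1]
        assert abs(np.dot(top, eig)) == pytest.approx(1.0, abs=1e-9)

    def test_constant_module_errors(self):
        with pytest.raises(ValueError):
            eigengene(pd.DataFrame(np.ones((4, 6))))

    def test_unit_norm(self, rng):
        eig, _ = eigengene(pd.DataFrame(rng.normal(size=(6, 9))))
        assert np.linalg.norm(eig) == pytest.approx(1.0)


class TestModuleDEGEnrichment:
    def make_mods(self, genesets, tissue="T"):
        from crossnet.network import Module, ModuleSet
        ms = ModuleSet(tissue=tissue)
        for i, genes in enumerate(genesets):
            ms.modules.append(Module(id=f"{tissue}.M{i}", genes=set(genes)))
        return ms

    def test_exact_copy_minimal_p(self):
        genes = {f"g{i}" for i in range(40)}
        mods = self.make_mods([genes])
        degs = {"suc": DEGSets(up=genes, down=set(), alpha=0.01, background_n=500)}
        table = module_deg_enrichment(mods, degs, 500)
        up = table[table.direction == "up"].iloc[0]
        assert up.k == 40 and up.p < 1e-50

    def test_disjoint_module_p_one(self):
        mods = self.make_mods([{f"g{i}" for i in range(30)}])
        degs = {"suc": DEGSets(up={f"h{i}" for i in range(30)}, down=set(),
                               alpha=0.01, background_n=500)}
        table = module_deg_enrichment(mods, degs, 500)
        assert (table[table.direction == "up"]["p"] == 1.0).all()

    def test_dual_pattern_flagged(self):
        genes = {f"g{i}" for i in range(50)}
        mods = self.make_mods([genes])
        degs = {
            "sucrose_vs_control": DEGSets(up=genes, down=set(), alpha=0.01,
                                          background_n=1000),
            "D1_vs_sucrose": DEGSets(up=set(), down=set(list(genes)[:40]), alpha=0.01,
                                     background_n=1000),
        }
        table = module_deg_enrichment(mods, degs, 1000)
        patterns = module_patterns(table, "sucrose_vs_control", "D1_vs_sucrose")
        assert patterns["T.M0"] == "sucrose-up/treatment-down"


class TestCrossTissueModules:
    def eig_mods(self, eigs, tissue):
        from crossnet.network import Module, ModuleSet
        ms = ModuleSet(tissue=tissue)
        for i, e in enumerate(eigs):
            ms.modules.append(Module(
                id=f"{tissue}.M{i}", genes={f"{tissue}{i}g{j}" for j in range(30)},
                eigengene=pd.Series(e, index=[f"{tissue}_s{j}" for j in range(len(e))]),
            ))
        return ms

    def animals(self, tissue, n):
        return pd.Series([f"r{j}" for j in range(n)],
                         index=[f"{tissue}_s{j}" for j in range(n)])

    def test_duplicated_eigengene_r_one(self, rng):
        e = rng.normal(size=20)
        ma = self.eig_mods([e], "A")
        mb = self.eig_mods([e], "B")
        cc = cross_tissue_module_correlation(ma, mb, self.animals("A", 20),
                                             self.animals("B", 20))
        assert cc.pairs.iloc[0]["R"] == pytest.approx(1.0)
        assert cc.pairs.iloc[0]["significant"]

    def test_same_tissue_rejected(self, rng):
        ma = self.eig_mods([rng.normal(size=10)], "A")
        with pytest.raises(ValueError):
            cross_tissue_module_correlation(ma, ma, self.animals("A", 10),
                                            self.animals("A", 10))

    def test_no_shared_animals_errors(self, rng):
        ma = self.eig_mods([rng.normal(size=10)], "A")
        mb = self.eig_mods([rng.normal(size=10)], "B")
        other = pd.Series([f"q{j}" for j in range(10)],
                          index=[f"B_s{j}" for j in range(10)])
        with pytest.raises(ValueError, match="shared animals"):
            cross_tissue_module_correlation(ma, mb, self.animals("A", 10), other)

    def test_independent_tissues_null_calibration(self, rng):
        """20 independent module pairs: ~5% pass raw p<0.05, ~none pass BH."""
        raw = bh = 0
        for rep in range(25):
            r = np.random.default_rng(rep)
            ma = self.eig_mods([r.normal(size=40) for _ in range(4)], "A")
            mb = self.eig_mods([r.normal(size=40) for _ in range(5)], "B")
            cc = cross_tissue_module_correlation(ma, mb, self.animals("A", 40),
                                                 self.animals("B", 40))
            raw += (cc.pairs["p"] < 0.05).sum()
            bh += cc.pairs["significant"].sum()
        n_tests = 25 * 20
        assert raw / n_tests == pytest.approx(0.05, abs=0.03)
        assert bh / n_tests < 0.01
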