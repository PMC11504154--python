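import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpdicho import (ExpressionMatrix, GeneSet, RankedList,
                     core_gene_compilation, core_overlap_comparison,
                     enrichment_score, gsea_phenotype, rank_by_signal_to_noise)
from mpdicho.gsea_lite import EnrichmentResult, shared_core
from mpdicho.io_formats import ValidationError


def es_oracle(gene_ids, scores, members, weight):
    """Independent plain-Python running-sum enumeration of the weighted KS ES."""
    hits = [g in members for g in gene_ids]
    n, n_hit = len(gene_ids), sum(hits)
    denom = sum(abs(s) ** weight for s, h in zip(scores, hits) if h)
    run, best = 0.0, 0.0
    trace = []
    for s, h in zip(scores, hits):
        if h:
            run += (abs(s) ** weight / denom) if denom > 0 else 1.0 / n_hit
        else:
            run -= 1.0 / (n - n_hit)
        trace.append(run)
        if abs(run) > abs(best):
            best = run
    return best, trace


def random_instance(rng):
    n = int(rng.integers(5, 31))
    genes = [f"G{i:02d}" for i in range(n)]
    scores = np.sort(rng.normal(size=n))[::-1]
    k = int(rng.integers(1, n))
    members = set(rng.choice(genes, size=k, replace=False))
    return genes, scores, members


class TestEnrichmentScore:
    def test_single_gene_first_weight_zero(self):
        rl = RankedList(np.array(["A", "B", "C"], dtype=object),
                        np.array([2.0, 1.0, 0.5]))
        res = enrichment_score(rl, GeneSet("S", ("A",)), weight=0.0)
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge == ("A",)

    def test_single_gene_last_weight_zero(self):
        rl = RankedList(np.array(["A", "B", "C"], dtype=object),
                        np.array([2.0, 1.0, 0.5]))
        res = enrichment_score(rl, GeneSet("S", ("C",)), weight=0.0)
        assert res.es == pytest.approx(-1.0)
        assert res.peak_index == 1  # just before the hit at the end
        assert res.leading_edge == ("C",)

    def test_no_overlap_and_full_cover_rejected(self):
        rl = RankedList(np.array(["A", "B"], dtype=object), np.array([1.0, 0.0]))
        with pytest.raises(ValidationError, match="no overlap"):
            enrichment_score(rl, GeneSet("S", ("X",)))
        with pytest.raises(ValidationError, match="whole"):
            enrichment_score(rl, GeneSet("S", ("A", "B")))

    def test_running_sum_terminates_at_zero(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            genes, scores, members = random_instance(rng)
            rl = RankedList(np.array(genes, dtype=object), scores)
            res = enrichment_score(rl, GeneSet("S", tuple(sorted(members))))
            assert res.running_sum[-1] == pytest.approx(0.0, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 10**6), st.sampled_from([0.0, 0.5, 1.0, 2.0]))
    def test_matches_brute_force_oracle(self, seed, weight):
        """Exhaustive running-sum enumeration agrees on random instances."""
        rng = np.random.default_rng(seed)
        genes, scores, members = random_instance(rng)
        rl = RankedList(np.array(genes, dtype=object), scores)
        res = enrichment_score(rl, GeneSet("S", tuple(sorted(members))), weight)
        expected, trace = es_oracle(genes, scores, members, weight)
        assert res.es == pytest.approx(expected, abs=1e-9)
        np.testing.assert_allclose(res.running_sum, trace, atol=1e-9)

    def test_matches_gseapy_prerank_es(self):
        """Independent cross-check of the weighted KS statistic."""
        import pandas as pd
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(20)]
        scores = np.sort(rng.normal(size=20))[::-1]
        members = (genes[1], genes[4], genes[7], genes[15])
        ref = gseapy.prerank(rnk=pd.DataFrame({"gene": genes, "score": scores}),
                             gene_sets={"S1": list(members)}, permutation_num=10,
                             min_size=2, max_size=50, weight=1.0, seed=1,
                             outdir=None, no_plot=True)
        rl = RankedList(np.array(genes, dtype=object), scores)
        ours = enrichment_score(rl, GeneSet("S1", members)).es
        assert ours == pytest.approx(float(ref.res2d["ES"].iloc[0]), abs=1e-9)


class TestSignalToNoiseRanking:
    @staticmethod
    def _matrix():
        # gene up in class A with low noise ranks first
        values = np.array([
            [5.0, 5.1, 4.9, 1.0, 1.1, 0.9],   # up in A
            [1.0, 1.2, 0.8, 1.1, 0.9, 1.0],   # flat
            [0.5, 0.4, 0.6, 3.0, 3.1, 2.9],   # up in B
        ])
        return ExpressionMatrix(["UP_A", "FLAT", "UP_B"],
                                [f"s{i}" for i in range(6)], values)

    def test_strong_class_marker_ranks_first(self):
        labels = ["A"] * 3 + ["B"] * 3
        ranked = rank_by_signal_to_noise(self._matrix(), labels)
        assert ranked.gene_ids[0] == "UP_A"
        assert ranked.gene_ids[-1] == "UP_B"

    def test_label_swap_negates_scores(self):
        labels = ["A"] * 3 + ["B"] * 3
        fwd = rank_by_signal_to_noise(self._matrix(), labels, classes=("A", "B"))
        rev = rank_by_signal_to_noise(self._matrix(), labels, classes=("B", "A"))
        fwd_map = dict(zip(fwd.gene_ids, fwd.scores))
        rev_map = dict(zip(rev.gene_ids, rev.scores))
        for g in fwd_map:
            assert fwd_map[g] == pytest.approx(-rev_map[g], abs=1e-12)

    def test_hand_computed_scores(self):
        # 2 genes, hand-set means/sds; sd floored at max(0.2|mu|, 0.2)
        values = np.array([[2.0, 2.0, 2.0, 0.0, 0.0, 0.0],
                           [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]])
        mat = ExpressionMatrix(["g1", "g2"], [f"s{i}" for i in range(6)], values)
        ranked = rank_by_signal_to_noise(mat, ["A"] * 3 + ["B"] * 3)
        scores = dict(zip(ranked.gene_ids, ranked.scores))
        # g1: (2-0)/(0.4+0.2) with sd floors 0.2*2 and 0.2
        assert scores["g1"] == pytest.approx(2.0 / 0.6, abs=1e-9)
        # g2: (1-4)/(1+1), sds are 1 > floors
        assert scores["g2"] == pytest.approx(-1.5, abs=1e-9)

    def test_small_class_rejected(self):
        with pytest.raises(ValidationError, match=">= 3"):
            rank_by_signal_to_noise(self._matrix(), ["A"] * 2 + ["B"] * 4)


class TestGseaPhenotype:
    @staticmethod
    def _planted(seed=0, n_samples=100):
        rng = np.random.default_rng(seed)
        n_genes = 210
        genes = [f"G{i:03d}" for i in range(n_genes)]
        values = rng.uniform(0, 1, size=(n_genes, n_samples))
        labels = ["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2)
        # plant: first 10 genes up in class A, clearly beyond the split noise
        values[:10, :n_samples // 2] += 0.5
        mat = ExpressionMatrix(genes, [f"s{i}" for i in range(n_samples)], values)
        planted = GeneSet("PLANTED", tuple(genes[:10]))
        decoy = GeneSet("DECOY", tuple(genes[100:110]))
        return mat, labels, [planted, decoy]

    def test_planted_signal_detected(self):
        mat, labels, sets = self._planted()
        results = gsea_phenotype(mat, labels, sets, n_perm=200, seed=1)
        planted = next(r for r in results if r.set_name == "PLANTED")
        assert planted.es > 0 and planted.nes > 0
        assert planted.p_nominal <= 1 / 200
        assert set(planted.leading_edge) <= set(sets[0].genes)

    def test_same_seed_reproduces_bitwise(self):
        mat, labels, sets = self._planted()
        a = gsea_phenotype(mat, labels, sets, n_perm=120, seed=7)
        b = gsea_phenotype(mat, labels, sets, n_perm=120, seed=7)
        assert a == b

    def test_too_few_permutations_rejected(self):
        mat, labels, sets = self._planted()
        with pytest.raises(ValidationError, match="n_perm"):
            gsea_phenotype(mat, labels, sets, n_perm=50, seed=1)


class TestCoreGenes:
    @staticmethod
    def _res(name, es, p, q, edge):
        return EnrichmentResult(set_name=name, es=es, nes=es, p_nominal=p,
                                fdr_q=q, leading_edge=edge, n_perm=100,
                                size=len(edge))

    def test_no_passing_sets(self):
        results = [self._res("A", 0.5, 0.5, 0.9, ("x",))]
        genes, total = core_gene_compilation(results)
        assert genes == [] and total == 0

    def test_union_counts_shared_gene_once(self):
        results = [self._res("A", 0.5, 0.01, 0.1, ("x", "y")),
                   self._res("B", 0.6, 0.01, 0.1, ("y", "z"))]
        genes, total = core_gene_compilation(results)
        assert genes == ["x", "y", "z"] and total == 3

    def test_direction_filter(self):
        results = [self._res("A", 0.5, 0.01, 0.1, ("x",)),
                   self._res("B", -0.6, 0.01, 0.1, ("y",))]
        assert core_gene_compilation(results, direction="pos")[0] == ["x"]
        assert core_gene_compilation(results, direction="neg")[0] == ["y"]

    def test_overlap_comparison_reproduces_z(self):
        res = core_overlap_comparison(113, 1721, 386, 1490)
        assert res.z == pytest.approx(15.086, abs=5e-4)
        same = core_overlap_comparison(("a", "b"), 10, ("c", "d"), 10)
        assert same.z == pytest.approx(0.0)

    def test_shared_core_counts(self):
        k, n = shared_core(["a", "b", "c"], ["b", "c", "d"])
        assert (k, n) == (2, 4)
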