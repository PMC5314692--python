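"""Sampling enrichment, AUC, functional similarity, bias sets, enrichment."""

import math
import random

import numpy as np
import pytest
from scipy import stats

from ppikit.core import (
    GoldStandardSet,
    InputError,
    NegativeSet,
    ScoredInteraction,
    canonical_pair,
)
from ppikit.ontology import AnnotationCorpus, gene_pair_gosim
from ppikit import quality as qe

K = canonical_pair


def _keys(pairs):
    return {K(a, b) for a, b in pairs}


class TestMpeDistribution:
    def test_saturation_when_db_subset_of_gold(self):
        db = _keys([(f"A{i}", f"B{i}") for i in range(20)])
        gold = GoldStandardSet(frozenset(db))
        dist = qe.mpe_distribution(db, gold, sample_size=5, n_samples=50, seed=0)
        assert (dist.overlaps == 5).all()

    def test_zero_when_disjoint(self):
        db = _keys([(f"A{i}", f"B{i}") for i in range(20)])
        gold = GoldStandardSet(frozenset(_keys([("X", "Y")])))
        dist = qe.mpe_distribution(db, gold, sample_size=5, n_samples=50, seed=0)
        assert (dist.overlaps == 0).all() and dist.mean == 0.0

    def test_mean_near_hypergeometric_expectation(self):
        db = _keys([(f"A{i}", f"B{i}") for i in range(200)])
        gold_pairs = frozenset(sorted(db)[:40])
        dist = qe.mpe_distribution(db, GoldStandardSet(gold_pairs), 50, 500, seed=0)
        expectation = 50 * 40 / 200  # = 10
        var = 50 * 0.2 * 0.8 * (150 / 199)
        se = math.sqrt(var / 500)
        assert abs(dist.mean - expectation) < 3 * se

    def test_oversized_sample_rejected(self):
        db = _keys([("A", "B")])
        with pytest.raises(InputError):
            qe.mpe_distribution(db, GoldStandardSet(frozenset()), 2, 10, seed=0)

    def test_reproducible_under_seed(self):
        db = _keys([(f"A{i}", f"B{i}") for i in range(50)])
        gold = GoldStandardSet(frozenset(sorted(db)[:10]))
        a = qe.mpe_distribution(db, gold, 10, 100, seed=42)
        b = qe.mpe_distribution(db, gold, 10, 100, seed=42)
        assert (a.overlaps == b.overlaps).all()


class TestNormalizedSampleSize:
    @pytest.mark.parametrize(
        "base,ratio,expected", [(10_000, 4.85, 48_500), (1000, 1.0, 1000), (1000, 0.5, 500)]
    )
    def test_examples(self, base, ratio, expected):
        assert qe.normalized_sample_size(base, ratio) == expected

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(InputError):
            qe.normalized_sample_size(1000, 0.0)


class TestFalsePositiveRatio:
    def test_no_overlap(self):
        rep = qe.false_positive_ratio(_keys([("A", "B")]), NegativeSet(frozenset()))
        assert rep.overlap == 0 and rep.ratio == 0.0

    def test_toy_counts(self):
        db = _keys([(f"A{i}", f"B{i}") for i in range(10)])
        negs = NegativeSet(frozenset(sorted(db)[:2] + [K("X", "Y")]))
        rep = qe.false_positive_ratio(db, negs)
        assert rep.overlap == 2 and rep.db_size == 10 and rep.ratio == pytest.approx(0.2)

    def test_empty_db_rejected(self):
        with pytest.raises(InputError):
            qe.false_positive_ratio(set(), NegativeSet(frozenset()))


def _scored(items):
    return [
        ScoredInteraction(K(a, b), 0.0, p, p, 1, frozenset({"s"})) for (a, b), p in items
    ]


def brute_force_auc(pos_scores, neg_scores):
    total = 0.0
    for p in pos_scores:
        for n in neg_scores:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos_scores) * len(neg_scores))


class TestScoreAuc:
    def test_perfect_separation(self):
        scored = _scored([(("A", "B"), 0.9), (("C", "D"), 0.8), (("E", "F"), 0.1)])
        gold = GoldStandardSet(frozenset({K("A", "B"), K("C", "D")}))
        negs = NegativeSet(frozenset({K("E", "F")}))
        assert qe.score_auc(scored, gold, negs) == 1.0

    def test_pure_ties_give_half(self):
        scored = _scored([(("A", "B"), 0.5), (("C", "D"), 0.5)])
        gold = GoldStandardSet(frozenset({K("A", "B")}))
        negs = NegativeSet(frozenset({K("C", "D")}))
        assert qe.score_auc(scored, gold, negs) == 0.5

    def test_four_pair_enumeration(self):
        scored = _scored(
            [(("A", "B"), 0.9), (("C", "D"), 0.4), (("E", "F"), 0.5), (("G", "H"), 0.1)]
        )
        gold = GoldStandardSet(frozenset({K("A", "B"), K("C", "D")}))
        negs = NegativeSet(frozenset({K("E", "F"), K("G", "H")}))
        assert qe.score_auc(scored, gold, negs) == pytest.approx(0.75)

    def test_matches_bruteforce_on_random_instances(self):
        rng = random.Random(3)
        for _ in range(30):
            n_pos, n_neg = rng.randint(1, 100), rng.randint(1, 100)
            pos = [round(rng.random(), 2) for _ in range(n_pos)]
            neg = [round(rng.random(), 2) for _ in range(n_neg)]
            items = [((f"P{i}", f"Q{i}"), p) for i, p in enumerate(pos + neg)]
            scored = _scored(items)
            gold = GoldStandardSet(frozenset(si.key for si in scored[:n_pos]))
            negs = NegativeSet(frozenset(si.key for si in scored[n_pos:]))
            assert qe.score_auc(scored, gold, negs) == pytest.approx(
                brute_force_auc(pos, neg), abs=1e-12
            )

    def test_empty_class_rejected(self):
        scored = _scored([(("A", "B"), 0.9)])
        gold = GoldStandardSet(frozenset({K("A", "B")}))
        with pytest.raises(InputError):
            qe.score_auc(scored, gold, NegativeSet(frozenset()))


class TestGoSim:
    def test_self_similarity_is_one(self, tiny_corpus):
        assert gene_pair_gosim("g1", "g1", tiny_corpus, "BP") == pytest.approx(1.0)

    def test_root_only_gene_has_zero_self_similarity(self, tiny_corpus):
        assert gene_pair_gosim("g5", "g5", tiny_corpus, "BP") == 0.0

    def test_hand_computed_lin_value(self, tiny_corpus):
        # IC: A = -ln(3/5), A1 = -ln(2/5), A2 = -ln(1/5); MICA(A1, A2) = A
        expected = 2 * -math.log(0.6) / (-math.log(0.4) - math.log(0.2))
        assert gene_pair_gosim("g1", "g2", tiny_corpus, "BP") == pytest.approx(expected)

    def test_only_shared_root_gives_zero(self, tiny_corpus):
        assert gene_pair_gosim("g1", "g3", tiny_corpus, "BP") == 0.0

    def test_unannotated_gene_is_undefined(self, tiny_corpus):
        assert gene_pair_gosim("g1", "nope", tiny_corpus) is None

    def test_symmetric_and_bounded(self, tiny_corpus):
        genes = ["g1", "g2", "g3", "g4", "g5"]
        for a in genes:
            for b in genes:
                s = gene_pair_gosim(a, b, tiny_corpus, "BP")
                assert s == pytest.approx(gene_pair_gosim(b, a, tiny_corpus, "BP"))
                assert 0.0 <= s <= 1.0

    def test_matches_bruteforce_term_pair_oracle(self, tiny_corpus):
        """Independent oracle: recompute closure, IC, Lin and BMA from the
        raw fixture definition with plain loops."""
        parents = {"A": "root", "B": "root", "A1": "A", "A2": "A", "B1": "B", "root": None}
        direct = {"g1": {"A1"}, "g2": {"A2"}, "g3": {"B1"}, "g4": {"A1"}, "g5": {"root"}}

        def anc(t):
            out = set()
            while t is not None:
                out.add(t)
                t = parents[t]
            return out

        counts = {}
        for terms in direct.values():
            covered = set().union(*(anc(t) for t in terms))
            for t in covered:
                counts[t] = counts.get(t, 0) + 1
        ic = {t: -math.log(c / len(direct)) for t, c in counts.items()}

        def lin(a, b):
            common = anc(a) & anc(b)
            denom = ic[a] + ic[b]
            if denom <= 0:
                return 0.0
            return 2 * max(ic[t] for t in common) / denom

        def bma(g1, g2):
            t1, t2 = direct[g1], direct[g2]
            row = sum(max(lin(a, b) for b in t2) for a in t1)
            col = sum(max(lin(a, b) for a in t1) for b in t2)
            return (row + col) / (len(t1) + len(t2))

        for a in direct:
            for b in direct:
                assert gene_pair_gosim(a, b, tiny_corpus, "BP") == pytest.approx(bma(a, b))

    def test_cross_namespace_mean(self):
        dag = [("b1", "broot", "BP"), ("m1", "mroot", "MF"), ("b2", "broot", "BP")]
        gaf = [("g1", "b1"), ("g1", "m1"), ("g2", "b1"), ("g2", "m1"), ("g3", "b2")]
        corpus = AnnotationCorpus.build(gaf, dag)
        bp = corpus.gene_similarity("g1", "g2", "BP")
        mf = corpus.gene_similarity("g1", "g2", "MF")
        assert gene_pair_gosim("g1", "g2", corpus) == pytest.approx((bp + mf) / 2)
        # g3 has BP only: cross-namespace score falls back to the BP score
        assert gene_pair_gosim("g1", "g3", corpus) == corpus.gene_similarity("g1", "g3", "BP")


class TestTierGoSimTest:
    def _fixture(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i:03d}" for i in range(60)]
        leaves = [f"L{i}" for i in range(12)]
        dag = [(leaf, "root", "BP") for leaf in leaves]
        assign = {g: leaves[int(rng.integers(0, len(leaves)))] for g in genes}
        gaf = [(g, assign[g]) for g in genes]
        corpus = AnnotationCorpus.build(gaf, dag)
        # 5-star pairs share a leaf term; 1-star pairs are random
        same = [g for g in genes if assign[g] == assign[genes[0]]]
        high = []
        for i, g in enumerate(genes):
            partner = next((h for h in genes[i + 1:] if assign[h] == assign[g]), None)
            if partner:
                high.append(
                    ScoredInteraction(K(g, partner), 0.0, 0.95, 0.95, 5, frozenset({"s"}))
                )
        low = [
            ScoredInteraction(
                K(genes[int(rng.integers(0, 60))], genes[int(rng.integers(0, 60))]),
                0.0, 0.1, 0.1, 1, frozenset({"s"}),
            )
            for _ in range(80)
        ]
        low = [si for si in low if not si.key.is_self]
        assert len(same) >= 2 and len(high) >= 30
        return corpus, high + low

    def test_constructed_separation_is_significant(self):
        corpus, scored = self._fixture()
        report = qe.tier_gosim_test(scored, corpus, tiers=(1, 5), n_per_tier=30, seed=1)
        assert report.tests[5][1] < 0.01
        assert report.mean(5) > float(report.baseline.mean())

    def test_random_tier_is_not_separated(self):
        corpus, scored = self._fixture()
        report = qe.tier_gosim_test(scored, corpus, tiers=(1,), n_per_tier=30, seed=1)
        # 1-star pairs are drawn like the baseline: no real difference
        assert report.tests[1][1] > 0.05

    def test_undersized_tier_skipped_with_warning(self):
        corpus, scored = self._fixture()
        with pytest.warns(UserWarning, match="tier 3"):
            report = qe.tier_gosim_test(scored, corpus, tiers=(3, 5), n_per_tier=30, seed=1)
        assert report.skipped == [3] and 5 in report.tier_samples


class TestBiasSets:
    def test_absent_proteins(self):
        db = _keys([("P1", "P2"), ("P3", "P4")])
        ref = ["P1", "P2", "P3", "P4", "P5", "P6"]
        assert qe.absent_protein_set(db, ref) == {"P5", "P6"}
        assert qe.absent_protein_set(db, ["P1", "P2"]) == set()
        assert qe.absent_protein_set(set(), ref) == set(ref)

    def test_missing_overlap(self):
        gold = GoldStandardSet(frozenset(_keys([("A", "B"), ("C", "D")])))
        assert qe.missing_overlap_set(_keys([("A", "B"), ("C", "D")]), gold) == set()
        assert qe.missing_overlap_set(_keys([("X", "Y")]), gold) == {"A", "B", "C", "D"}
        assert qe.missing_overlap_set(_keys([("A", "B")]), gold) == {"C", "D"}

    def test_hub_set_star_graph(self):
        db = _keys([("HUB", f"L{i}") for i in range(5)])
        assert qe.hub_set(db, k=1) == ["HUB"]

    def test_hub_set_larger_k_returns_all_with_warning(self):
        db = _keys([("A", "B")])
        with pytest.warns(UserWarning):
            assert qe.hub_set(db, k=10) == ["A", "B"]

    def test_hub_set_known_degrees_and_tie_break(self):
        db = _keys([("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("X", "Y")])
        # degrees: A=3, B=2, C=2, D=1, X=1, Y=1; ties lexicographic
        assert qe.hub_set(db, k=6) == ["A", "B", "C", "D", "X", "Y"]


class TestEnrichment:
    def _corpus(self):
        dag = [("t", "root", "BP"), ("u", "root", "BP")]
        genes = [f"g{i:02d}" for i in range(20)]
        gaf = [(g, "t") for g in genes[:4]] + [(g, "u") for g in genes[4:]]
        return AnnotationCorpus.build(gaf, dag), genes

    def test_exact_hypergeometric_tail(self):
        corpus, genes = self._corpus()
        gene_set = genes[:3] + genes[4:6]  # 3 of the 4 t-genes, 5 total
        df = qe.enrichment(gene_set, genes, corpus).set_index("term")
        expected = (
            math.comb(4, 3) * math.comb(16, 2) + math.comb(4, 4) * math.comb(16, 1)
        ) / math.comb(20, 5)
        assert df.loc["t", "p_value"] == pytest.approx(expected)
        assert df.loc["t", "set_count"] == 3 and df.loc["t", "background_count"] == 4

    def test_whole_background_term_has_p_one(self):
        corpus, genes = self._corpus()
        df = qe.enrichment(genes[:5], genes, corpus).set_index("term")
        assert df.loc["root", "p_value"] == pytest.approx(1.0)

    def test_set_equals_background_all_p_one(self):
        corpus, genes = self._corpus()
        df = qe.enrichment(genes, genes, corpus)
        assert np.allclose(df["p_value"], 1.0)

    def test_adjusted_p_at_least_raw(self):
        corpus, genes = self._corpus()
        df = qe.enrichment(genes[:3], genes, corpus)
        assert (df["adjusted_p"] >= df["p_value"] - 1e-15).all()

    def test_matches_combinatorial_oracle_on_small_backgrounds(self):
        rng = random.Random(7)
        corpus, genes = self._corpus()
        for _ in range(10):
            n = rng.randint(2, 8)
            gene_set = rng.sample(genes, n)
            df = qe.enrichment(gene_set, genes, corpus).set_index("term")
            for term, bg_count in [("t", 4), ("u", 16)]:
                k = df.loc[term, "set_count"]
                tail = sum(
                    math.comb(bg_count, i) * math.comb(20 - bg_count, n - i)
                    for i in range(k, min(bg_count, n) + 1)
                ) / math.comb(20, n)
                assert df.loc[term, "p_value"] == pytest.approx(tail)

    def test_empty_set_rejected_and_subset_enforced(self):
        corpus, genes = self._corpus()
        with pytest.raises(InputError):
            qe.enrichment([], genes, corpus)
        with pytest.raises(InputError):
            qe.enrichment(["zzz"], genes, corpus)
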