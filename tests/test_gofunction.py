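"""Ontology parsing, information content and the functional score."""

import numpy as np
import pytest

from synscreen.errors import (MissingAnnotationError, OntologyError,
                              UndefinedScoreError)
from synscreen.gofunction import (GOAnnotationCorpus, OntologyDAG,
                                  parse_obo, s_function)
from synscreen.tnetwork import TargetSet

from oracles import brute_lin, walk_ancestors


def write_obo(tmp_path, body: str):
    f = tmp_path / "toy.obo"
    f.write_text("format-version: 1.2\nontology: toy\n\n" + body)
    return f


class TestParseObo:
    def test_two_term_is_a(self, tmp_path):
        f = write_obo(tmp_path,
                      "[Term]\nid: T:1\nname: a\n\n"
                      "[Term]\nid: T:2\nname: b\nis_a: T:1\n")
        dag = parse_obo(f)
        assert dag.parents["T:2"] == {"T:1"}
        assert dag.parents["T:1"] == set()

    def test_obsolete_flagged(self, tmp_path):
        f = write_obo(tmp_path,
                      "[Term]\nid: T:1\nname: a\n\n"
                      "[Term]\nid: T:2\nname: dead\nis_obsolete: true\n")
        dag = parse_obo(f)
        assert dag.obsolete == {"T:2"}

    def test_cycle_is_error(self, tmp_path):
        f = write_obo(tmp_path,
                      "[Term]\nid: T:1\nname: a\nis_a: T:2\n\n"
                      "[Term]\nid: T:2\nname: b\nis_a: T:1\n")
        with pytest.raises(OntologyError):
            parse_obo(f)

    def test_dangling_is_a_dropped_with_warning(self, tmp_path):
        f = write_obo(tmp_path,
                      "[Term]\nid: T:1\nname: a\nis_a: T:404\n")
        with pytest.warns(UserWarning, match="undefined"):
            dag = parse_obo(f)
        assert dag.parents["T:1"] == set()


@pytest.fixture
def gold_corpus(gold_bundle):
    """Toy corpus with p = {root: 1, mid: 1/2, X: 1/4, Y: 1/8}."""
    return GOAnnotationCorpus.from_files(gold_bundle.obo,
                                         gold_bundle.annotations)


ROOT, MID, X, Y = "TOY:0000001", "TOY:0000002", "TOY:0000003", "TOY:0000004"


class TestTermProbability:
    def test_root_probability_one(self, gold_corpus):
        assert gold_corpus.term_probability(ROOT) == 1.0

    def test_cumulative_division(self, gold_corpus):
        assert gold_corpus.term_probability(MID) == 0.5
        assert gold_corpus.term_probability(X) == 0.25
        assert gold_corpus.term_probability(Y) == 0.125

    def test_unannotated_term_rejected(self, gold_corpus):
        with pytest.raises(MissingAnnotationError):
            gold_corpus.term_probability("T:404")

    def test_parent_frequency_dominates_child(self, gold_corpus):
        for child, parent in [(MID, ROOT), (X, MID), (Y, MID)]:
            assert gold_corpus.freq[parent] >= gold_corpus.freq[child]


class TestTermSimilarity:
    def test_identity_is_one(self, gold_corpus):
        assert gold_corpus.term_similarity(Y, Y) == 1.0

    def test_siblings_through_mica(self, gold_corpus):
        # 2 log2(1/2) / (log2(1/4) + log2(1/8)) = -2 / -5
        assert gold_corpus.term_similarity(X, Y) == pytest.approx(0.4)

    def test_symmetric(self, gold_corpus):
        assert gold_corpus.term_similarity(X, Y) == \
            gold_corpus.term_similarity(Y, X)

    def test_root_only_ancestor_gives_zero(self, tmp_path):
        # two leaves whose only shared ancestor has p = 1
        obo = write_obo(tmp_path,
                        "[Term]\nid: R\nname: r\n\n"
                        "[Term]\nid: L1\nname: x\nis_a: R\n\n"
                        "[Term]\nid: L2\nname: y\nis_a: R\n")
        ann = tmp_path / "ann.tsv"
        ann.write_text("g1\tL1\ng2\tL1\ng3\tL2\n")
        corpus = GOAnnotationCorpus.from_files(obo, ann)
        assert corpus.term_similarity("L1", "L2") == 0.0

    def test_literal_max_rule_degenerates_to_zero(self, gold_corpus):
        # the max-p common ancestor of distinct terms is the root
        assert gold_corpus.term_similarity(X, Y, "literal_max") == 0.0

    def test_matches_exhaustive_ancestor_oracle(self, gold_corpus):
        dag = gold_corpus.dag
        p = {t: gold_corpus.term_probability(t) for t in dag.terms}
        for t1 in dag.terms:
            for t2 in dag.terms:
                ours = gold_corpus.term_similarity(t1, t2)
                brute = brute_lin(dag.parents, p, t1, t2)
                assert ours == pytest.approx(brute, abs=1e-12)

    def test_mica_never_increases_toward_root(self, gold_corpus):
        # scoring X,Y through mid (p=1/2) beats scoring through root (p=1)
        sim_mica = gold_corpus.term_similarity(X, Y, "mica")
        sim_root = gold_corpus.term_similarity(X, Y, "literal_max")
        assert sim_mica >= sim_root


class TestGenePairSimilarity:
    def test_identical_single_annotations(self, gold_corpus):
        # genes B and F6 both annotate to X
        assert gold_corpus.gene_pair_similarity("B", "F6") == 1.0

    def test_single_cross_pair(self, gold_corpus):
        assert gold_corpus.gene_pair_similarity("B", "D") == \
            pytest.approx(0.4)

    def test_unannotated_gene_scores_zero_with_warning(self, gold_corpus):
        with pytest.warns(UserWarning, match="unannotated"):
            assert gold_corpus.gene_pair_similarity("B", "GHOST") == 0.0

    def test_aggregation_rules_ordering(self, tmp_path):
        obo = write_obo(tmp_path,
                        "[Term]\nid: R\nname: r\n\n"
                        "[Term]\nid: A\nname: a\nis_a: R\n\n"
                        "[Term]\nid: B\nname: b\nis_a: A\n\n"
                        "[Term]\nid: C\nname: c\nis_a: A\n")
        ann = tmp_path / "ann.tsv"
        ann.write_text("g1\tB\ng1\tC\ng2\tB\nf1\tR\nf2\tR\nf3\tA\n")
        corpus = GOAnnotationCorpus.from_files(obo, ann)
        mx = corpus.gene_pair_similarity("g1", "g2", "max")
        bma = corpus.gene_pair_similarity("g1", "g2", "bma")
        avg = corpus.gene_pair_similarity("g1", "g2", "avg")
        assert mx == 1.0  # shared term B
        assert mx >= bma >= avg > 0.0


class TestSFunction:
    def test_identical_single_annotation_is_one(self, gold_corpus):
        s = s_function(TargetSet("a", ("B",)), TargetSet("b", ("F6",)),
                       gold_corpus)
        assert s == pytest.approx(1.0)

    def test_single_pair_value(self, gold_corpus):
        s = s_function(TargetSet("a", ("B",)), TargetSet("b", ("D",)),
                       gold_corpus)
        assert s == pytest.approx(0.4)

    def test_unannotated_targets_score_zero(self, gold_corpus):
        with pytest.warns(UserWarning):
            s = s_function(TargetSet("a", ("GHOST1",)),
                           TargetSet("b", ("GHOST2",)), gold_corpus)
        assert s == 0.0

    def test_empty_set_rejected(self, gold_corpus):
        with pytest.raises(UndefinedScoreError):
            s_function(TargetSet("a", ()), TargetSet("b", ("B",)),
                       gold_corpus)

    def test_symmetry_and_bounds_random_sets(self, gold_corpus):
        rng = np.random.default_rng(3)
        genes = ["B", "D", "F1", "F5", "F6"]
        for _ in range(25):
            tk = TargetSet("a", tuple(
                rng.choice(genes, size=rng.integers(1, 4), replace=False)))
            th = TargetSet("b", tuple(
                rng.choice(genes, size=rng.integers(1, 4), replace=False)))
            ab = s_function(tk, th, gold_corpus)
            ba = s_function(th, tk, gold_corpus)
            assert ab == pytest.approx(ba, abs=1e-12)
            assert 0.0 <= ab <= 1.0

    def test_ordered_pair_denominator(self, gold_corpus):
        # m=2, n=1: S = 2 * (sim(B,D) + sim(F6,D)) / (3*2)
        s = s_function(TargetSet("a", ("B", "F6")),
                       TargetSet("b", ("D",)), gold_corpus)
        assert s == pytest.approx(2 * (0.4 + 0.4) / 6)


def test_corpus_restriction_recomputes_frequencies(gold_corpus):
    sub = gold_corpus.restricted_to({"B", "D"})
    # only B->X and D->Y remain; cumulative root freq is 2
    assert sub.freq["TOY:0000001"] == 2
    assert sub.term_probability(X) == pytest.approx(0.5)
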