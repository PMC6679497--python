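"""Score assembly, normalization, diagonal ranking and the screen object."""

import math

import numpy as np
import pandas as pd
import pytest

from synscreen import fixtures
from synscreen.chem import PharmacophoreSiteSet, preprocess_smiles
from synscreen.config import RunConfig
from synscreen.errors import DomainError
from synscreen.gofunction import GOAnnotationCorpus
from synscreen.network import compute_centralities
from synscreen.ranking import (DrugRecord, SynergyScreen, assemble_scores,
                               normalize_and_rank, read_ranked_table,
                               read_target_table, write_ranked_table)
from synscreen.tnetwork import TargetSet


@pytest.fixture
def gold_corpus(gold_bundle):
    return GOAnnotationCorpus.from_files(gold_bundle.obo,
                                         gold_bundle.annotations)


def drug(drug_id, targets, smiles=None, sites=None):
    return DrugRecord(drug_id, TargetSet(drug_id, tuple(targets)),
                      preprocess_smiles(smiles, drug_id) if smiles else None,
                      sites)


class TestAssembleScores:
    def test_identical_candidate_hits_identity_bounds(self, path_net,
                                                      gold_corpus):
        cs = compute_centralities(path_net)
        sites = PharmacophoreSiteSet("x", (("A", 0.0, 0.0, 0.0),))
        ref = drug("REF", ["B"], "CCCCC", sites)
        twin = drug("TWIN", ["B"], "CCCCC", sites)
        raw = assemble_scores(ref, [twin], path_net, cs, gold_corpus)
        row = raw.iloc[0]
        assert row["s_tnetwork"] == pytest.approx(2.0)
        assert row["s_function"] == pytest.approx(1.0)  # both annotate X
        assert row["s_similarity"] == pytest.approx(2.0)

    def test_candidate_without_targets_downgraded(self, path_net,
                                                  gold_corpus):
        cs = compute_centralities(path_net)
        ref = drug("REF", ["B"], "CCCCC")
        bad = drug("BAD", [], "CCCC")
        with pytest.warns(UserWarning):
            raw = assemble_scores(ref, [bad], path_net, cs, gold_corpus)
        assert raw.iloc[0]["s_tnetwork"] == 0.0
        assert raw.iloc[0]["s_2d"] > 0.0  # other axes survive

    def test_empty_candidate_list_rejected(self, path_net, gold_corpus):
        cs = compute_centralities(path_net)
        with pytest.raises(DomainError):
            assemble_scores(drug("REF", ["B"]), [], path_net, cs,
                            gold_corpus)

    def test_order_preserved_pre_ranking(self, path_net, gold_corpus):
        cs = compute_centralities(path_net)
        ref = drug("REF", ["B"], "CCCCC")
        with pytest.warns(UserWarning):  # missing 3D data
            raw = assemble_scores(
                ref, [drug("C1", ["D"], "CCCC"), drug("C2", ["C"], "CCO")],
                path_net, cs, gold_corpus)
        assert list(raw["drug_id"]) == ["C1", "C2"]

    def test_missing_3d_skip_axis_policy(self, path_net, gold_corpus):
        cs = compute_centralities(path_net)
        cfg = RunConfig(missing_3d="skip_axis")
        ref = drug("REF", ["B"], "CCCCC")
        raw = assemble_scores(ref, [drug("C1", ["D"], "CCCC")], path_net,
                              cs, gold_corpus, cfg)
        assert math.isnan(raw.iloc[0]["s_3d"])
        assert raw.iloc[0]["s_similarity"] == pytest.approx(2.0 / 3.0)


def raw_frame(rows):
    df = pd.DataFrame(rows, columns=["drug_id", "s_tnetwork", "s_function",
                                     "s_similarity"])
    df["s_2d"] = df["s_similarity"] / 2
    df["s_3d"] = df["s_similarity"] / 2
    return df


class TestNormalizeAndRank:
    def test_minmax_arithmetic(self):
        df = raw_frame([("a", 0.2, 0.0, 0.0), ("b", 1.0, 0.5, 1.0),
                        ("c", 2.0, 1.0, 2.0)])
        ranked = normalize_and_rank(df)
        x = ranked.set_index("drug_id")["norm_x"]
        assert x["a"] == 0.0
        assert x["b"] == pytest.approx(4.0 / 9.0)
        assert x["c"] == 1.0

    def test_unit_triple_total_and_rank(self):
        df = raw_frame([("lo", 0.0, 0.0, 0.0), ("hi", 1.0, 1.0, 1.0)])
        ranked = normalize_and_rank(df).set_index("drug_id")
        assert ranked.at["hi", "total"] == pytest.approx(math.sqrt(3.0))
        assert ranked.at["lo", "total"] == 0.0
        assert ranked.at["hi", "rank"] == 1

    def test_constant_axis_is_neutral(self):
        df = raw_frame([("a", 1.0, 0.3, 0.1), ("b", 1.0, 0.9, 0.7)])
        ranked = normalize_and_rank(df)
        assert (ranked["norm_x"] == 0.5).all()

    def test_ranks_are_gapless_permutation(self):
        rng = np.random.default_rng(23)
        rows = [(f"d{i}", *rng.uniform(0, 2, 3)) for i in range(15)]
        ranked = normalize_and_rank(raw_frame(rows))
        assert sorted(ranked["rank"]) == list(range(1, 16))

    def test_ties_break_lexicographically(self):
        df = raw_frame([("zeta", 1.0, 1.0, 1.0), ("alpha", 1.0, 1.0, 1.0)])
        ranked = normalize_and_rank(df)
        assert list(ranked["drug_id"]) == ["alpha", "zeta"]

    def test_affine_rescaling_of_axis_preserves_ranking(self):
        rng = np.random.default_rng(31)
        rows = [(f"d{i}", *rng.uniform(0, 2, 3)) for i in range(10)]
        base = normalize_and_rank(raw_frame(rows))
        scaled_rows = [(d, 3.0 * x + 5.0, y, z) for d, x, y, z in rows]
        scaled = normalize_and_rank(raw_frame(scaled_rows))
        assert list(base["drug_id"]) == list(scaled["drug_id"])
        assert np.allclose(base["total"], scaled["total"], atol=1e-12)

    def test_total_rules_agree_on_order(self):
        rng = np.random.default_rng(37)
        rows = [(f"d{i}", *rng.uniform(0, 2, 3)) for i in range(8)]
        diag = normalize_and_rank(raw_frame(rows), "diagonal")
        tot = normalize_and_rank(raw_frame(rows), "sum")
        assert list(diag["drug_id"]) == list(tot["drug_id"])

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            normalize_and_rank(raw_frame([]))


class TestScreenEndToEnd:
    def test_gold_screen_reproduces_manifest(self, gold_bundle):
        screen = SynergyScreen.from_files(
            gold_bundle.network, gold_bundle.disease_genes,
            gold_bundle.targets, gold_bundle.smiles, gold_bundle.sites,
            gold_bundle.obo, gold_bundle.annotations, reference_id="REF")
        res = screen.fit()
        row = res.table.set_index("drug_id").loc["CAND"]
        expected = gold_bundle.manifest_data["expected"]
        for key in ("s_tnetwork", "s_function", "s_2d", "s_3d",
                    "s_similarity"):
            assert row[key] == pytest.approx(expected[key], abs=1e-5)

    def test_deterministic_output(self, gold_bundle, tmp_path):
        def run():
            return SynergyScreen.from_files(
                gold_bundle.network, gold_bundle.disease_genes,
                gold_bundle.targets, gold_bundle.smiles, gold_bundle.sites,
                gold_bundle.obo, gold_bundle.annotations,
                reference_id="REF").fit()
        t1, t2 = run().table, run().table
        pd.testing.assert_frame_equal(t1, t2)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_ranked_table(t1, p1)
        write_ranked_table(t2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_summary_names_reference_and_winner(self, gold_bundle):
        res = SynergyScreen.from_files(
            gold_bundle.network, gold_bundle.disease_genes,
            gold_bundle.targets, gold_bundle.smiles, gold_bundle.sites,
            gold_bundle.obo, gold_bundle.annotations,
            reference_id="REF").fit()
        text = res.summary()
        assert "REF" in text and "CAND" in text
        assert res.top == "CAND"
        assert res.rank_of("CAND") == 1

    def test_unknown_reference_rejected(self, gold_bundle):
        with pytest.raises(DomainError):
            SynergyScreen.from_files(
                gold_bundle.network, gold_bundle.disease_genes,
                gold_bundle.targets, reference_id="NOPE")

    def test_planted_synergist_wins_single_seed(self, tmp_path):
        bundle = fixtures.gen_fixture_bundle(tmp_path / "fx", seed=1234,
                                             planted_synergist=True)
        res = SynergyScreen.from_files(
            bundle.network, bundle.disease_genes, bundle.targets,
            bundle.smiles, bundle.sites, bundle.obo, bundle.annotations,
            reference_id="LEF").fit()
        assert res.rank_of("PLANTED") == 1

    def test_background_scoring_graph_runs(self, gold_bundle):
        cfg = RunConfig(scoring_graph="background")
        res = SynergyScreen.from_files(
            gold_bundle.network, gold_bundle.disease_genes,
            gold_bundle.targets, gold_bundle.smiles, gold_bundle.sites,
            gold_bundle.obo, gold_bundle.annotations,
            reference_id="REF", config=cfg).fit()
        # gold disease genes cover the whole path, so scores coincide
        assert res.table.iloc[0]["s_tnetwork"] == pytest.approx(
            2.0 * math.exp(-2.0), abs=1e-10)


def test_target_table_reader(tmp_path):
    f = tmp_path / "targets.tsv"
    f.write_text("# comment\ndrug_id\ttarget_id\nd1\tA\nd1\tB\nd2\tC\n")
    targets = read_target_table(f)
    assert targets["d1"].targets == ("A", "B")
    assert targets["d2"].size == 1


def test_ranked_table_round_trip(tmp_path):
    df = raw_frame([("a", 0.2, 0.1, 0.5), ("b", 1.2, 0.8, 1.5)])
    ranked = normalize_and_rank(df)
    out = tmp_path / "ranked.tsv"
    write_ranked_table(ranked, out)
    back = read_ranked_table(out)
    assert list(back.columns) == list(ranked.columns)
    assert np.allclose(back["total"], ranked["total"], atol=1e-5)


def test_write_empty_table_rejected(tmp_path):
    with pytest.raises(DomainError):
        write_ranked_table(pd.DataFrame(), tmp_path / "x.tsv")
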