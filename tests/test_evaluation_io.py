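"""ROC/AUC evaluation and the plain-text readers/writers."""
import numpy as np
import pytest

from coca import (
    ExpressionMatrix,
    InputError,
    LabeledRanking,
    auc,
    evaluate_ranking,
    roc_curve,
)
from coca.io import (
    load_expression,
    load_geneset,
    load_gmt,
    load_ranking,
    write_expression,
    write_manifest,
    write_ranking,
)


def brute_force_auc(scores, labels):
    """All-pairs Mann-Whitney probability with ties counting one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def _ranking(scores, labels):
    ids = np.array([f"g{i}" for i in range(len(scores))])
    pos = {f"g{i}" for i, l in enumerate(labels) if l == 1}
    return LabeledRanking(ids, np.asarray(scores, float), pos)


class TestRoc:
    def test_hand_enumerated_four_gene_curve(self):
        # ranks: P, N, P, N
        r = _ranking([4.0, 3.0, 2.0, 1.0], [1, 0, 1, 0])
        assert roc_curve(r) == [(0, 0), (0, 0.5), (0.5, 0.5), (0.5, 1.0), (1.0, 1.0)]
        assert auc(r) == pytest.approx(0.75)

    def test_perfect_separation(self):
        r = _ranking([3.0, 2.0, 1.0, 0.5], [1, 1, 0, 0])
        assert (0.0, 1.0) in roc_curve(r)
        assert auc(r) == 1.0

    def test_all_tied_scores_give_diagonal(self):
        r = _ranking([1.0, 1.0, 1.0, 1.0], [1, 0, 1, 0])
        pts = roc_curve(r)
        assert pts[0] == (0, 0) and pts[-1] == (1.0, 1.0)
        assert auc(r) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(InputError, match="positive and one negative"):
            auc(_ranking([2.0, 1.0], [1, 1]))

    def test_curve_monotone_nondecreasing(self, rng):
        for _ in range(20):
            n = rng.integers(5, 40)
            scores = np.sort(rng.normal(size=n))[::-1]
            labels = rng.integers(0, 2, size=n)
            if labels.all() or not labels.any():
                continue
            pts = np.array(roc_curve(_ranking(scores, labels)))
            assert np.all(np.diff(pts[:, 0]) >= 0)
            assert np.all(np.diff(pts[:, 1]) >= 0)

    def test_auc_equals_brute_force_mann_whitney(self, rng):
        for _ in range(25):
            n = int(rng.integers(8, 200))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            scores = np.sort(scores)[::-1]
            labels = rng.integers(0, 2, size=n)
            if labels.all() or not labels.any():
                continue
            r = _ranking(scores, labels)
            assert auc(r) == pytest.approx(brute_force_auc(scores, labels), rel=1e-12)

    def test_validation(self):
        with pytest.raises(InputError, match="non-increasing"):
            _ranking([1.0, 2.0], [1, 0])
        with pytest.raises(InputError, match="not present"):
            LabeledRanking(np.array(["a", "b"]), np.array([2.0, 1.0]), {"zzz"})

    def test_exclusion_of_knowledge_genes(self):
        ids = ["k1", "p1", "n1", "p2", "n2"]
        scores = [5.0, 4.0, 3.0, 2.0, 1.0]
        # with k1 kept it counts as a top-scoring negative: 3 of 6 pairs
        val_all, _ = evaluate_ranking(ids, scores, {"p1", "p2"})
        assert val_all == pytest.approx(0.5)
        val_ex, _ = evaluate_ranking(ids, scores, {"p1", "p2"}, exclude={"k1"})
        assert val_ex == pytest.approx(0.75)
        # excluding a positive changes the score set
        val_ex2, _ = evaluate_ranking(ids, scores, {"p1", "p2"}, exclude={"p1"})
        assert val_ex2 == pytest.approx(1 / 3)


class TestExpressionIo:
    def test_tsv_round_trip_full_precision(self, tmp_path, rng):
        em = ExpressionMatrix(
            rng.standard_normal((5, 3)), [f"g{i}" for i in range(5)], ["a", "b", "c"]
        )
        path = tmp_path / "expr.tsv"
        write_expression(em, path)
        back = load_expression(path)
        np.testing.assert_array_equal(back.values, em.values)
        assert back.gene_ids.tolist() == em.gene_ids.tolist()
        assert back.sample_ids.tolist() == em.sample_ids.tolist()

    def test_gct_equals_equivalent_tsv(self, tmp_path, rng):
        em = ExpressionMatrix(
            rng.standard_normal((4, 3)), list("wxyz"), ["s1", "s2", "s3"]
        )
        tsv, gct = tmp_path / "e.tsv", tmp_path / "e.gct"
        write_expression(em, tsv, dialect="tsv")
        write_expression(em, gct, dialect="gct")
        a, b = load_expression(tsv), load_expression(gct)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.gene_ids.tolist() == b.gene_ids.tolist()

    def test_csv_dialect_detected_by_extension(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("gene_id,s1,s2\ng1,1.5,2\ng2,0,1\n")
        em = load_expression(path)
        assert em.values[0, 0] == 1.5

    def test_duplicate_gene_ids_listed(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene_id\ts1\ts2\ng1\t1\t2\ng1\t3\t4\ng2\t0\t0\n")
        with pytest.raises(InputError, match="g1"):
            load_expression(path)

    def test_ragged_row_reported_with_line(self, tmp_path):
        path = tmp_path / "ragged.tsv"
        path.write_text("gene_id\ts1\ts2\ng1\t1\t2\ng2\t1\t2\t3\t4\n")
        with pytest.raises(InputError, match="line|malformed"):
            load_expression(path)

    def test_missing_values_rejected(self, tmp_path):
        path = tmp_path / "na.tsv"
        path.write_text("gene_id\ts1\ts2\ng1\t1\t\ng2\t3\t4\n")
        with pytest.raises(InputError, match="issing"):
            load_expression(path)


class TestGeneSetIo:
    def test_plain_list_with_comments(self, tmp_path):
        path = tmp_path / "set.txt"
        path.write_text("# cycle genes\ng1\ng2\n\ng3\n")
        assert load_geneset(path) == {"g1", "g2", "g3"}

    def test_gmt_record(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("set1\tdesc\tg1\tg2\nset2\tdesc\tg3\n")
        assert load_gmt(path) == {"set1": {"g1", "g2"}, "set2": {"g3"}}
        assert load_geneset(path) == {"g1", "g2"}
        assert load_geneset(path, name="set2") == {"g3"}
        with pytest.raises(InputError, match="set9"):
            load_geneset(path, name="set9")

    def test_malformed_gmt_line(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_name\tdesc\n")
        with pytest.raises(InputError, match="line 1"):
            load_gmt(path)


class TestRankingIo:
    def test_round_trip_exact(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {
                "rank": [1, 2],
                "gene_id": ["gA", "gB"],
                "participation_bagged": [1.23456789012345, -0.5],
                "abs_participation": [1.23456789012345, 0.5],
                "participation_sd": [0.1, 0.2],
                "method": ["coca", "coca"],
            }
        )
        path = tmp_path / "ranking.tsv"
        write_ranking(df, path)
        back = load_ranking(path)
        pd.testing.assert_frame_equal(back, df)

    def test_manifest_contains_seed_and_hash(self, tmp_path):
        import json

        path = tmp_path / "manifest.json"
        write_manifest(path, seed=42, config={"n_boot": 5})
        data = json.loads(path.read_text())
        assert data["seed"] == 42
        assert len(data["config_sha256"]) == 64
        assert "coca" in data["versions"]
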