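import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cccbench import (
    LRResult,
    PerturbationSpec,
    average_jaccard,
    build_report,
    evaluate_noise,
    evaluate_replicates,
    jaccard,
    jaccard_top_k,
    pairwise_method_agreement,
    rank_methods,
    summary_table,
)
from cccbench.robustness import read_records, records_to_frame


def _result(selected, method="m", dataset_id="d", scores=None):
    selected = set(selected)
    scores = scores or {p: 1.0 for p in selected}
    return LRResult(method=method, dataset_id=dataset_id, scores=scores, selected=selected)


def _brute_force_jaccard(a, b):
    """Independent oracle: explicit membership bitsets over the union."""
    universe = sorted(set(a) | set(b))
    if not universe:
        return 1.0
    bits_a = [x in a for x in universe]
    bits_b = [x in b for x in universe]
    inter = sum(1 for p, q in zip(bits_a, bits_b) if p and q)
    union = sum(1 for p, q in zip(bits_a, bits_b) if p or q)
    return inter / union


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"x", "y"}, {"y", "z"}, 1 / 3),
            ({"x"}, {"x"}, 1.0),
            ({"x"}, {"y"}, 0.0),
            (set(), set(), 1.0),
            (set(), {"x"}, 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)

    def test_matches_brute_force_on_random_set_systems(self):
        rng = np.random.default_rng(0)
        universe = list(range(12))
        for _ in range(10):
            a = {x for x in universe if rng.random() < 0.4}
            b = {x for x in universe if rng.random() < 0.4}
            assert jaccard(a, b) == pytest.approx(_brute_force_jaccard(a, b))

    @given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)))
    @settings(deadline=None, max_examples=100)
    def test_symmetric_bounded_and_equality(self, a, b):
        j = jaccard(a, b)
        assert 0.0 <= j <= 1.0
        assert j == jaccard(b, a)
        assert (j == 1.0) == (a == b)


class TestTopK:
    def test_identical_results_any_k(self):
        r = _result({("a", "b")}, scores={("a", "b"): 2.0, ("c", "d"): 1.0})
        assert jaccard_top_k(r, r, 1) == 1.0
        assert jaccard_top_k(r, r, 30) == 1.0

    def test_k_larger_than_maps_equals_full_jaccard(self):
        ra = _result(set(), scores={("a", "b"): 1.0, ("c", "d"): 2.0})
        rb = _result(set(), scores={("c", "d"): 5.0, ("e", "f"): 1.0})
        assert jaccard_top_k(ra, rb, 99) == pytest.approx(
            jaccard({("a", "b"), ("c", "d")}, {("c", "d"), ("e", "f")})
        )

    def test_reversed_scores_disjoint_halves(self):
        pairs = [(f"L{i:02d}", f"R{i:02d}") for i in range(60)]
        fwd = {p: float(i) for i, p in enumerate(pairs)}
        rev = {p: float(-i) for i, p in enumerate(pairs)}
        ra = _result(set(), scores=fwd)
        rb = _result(set(), scores=rev)
        assert jaccard_top_k(ra, rb, 30) == 0.0


class TestEvaluate:
    def test_three_replicates_give_three_records(self):
        group = {0.9: [_result({("a", "b")}, dataset_id=f"r{i}") for i in range(3)]}
        records = evaluate_replicates(group)
        assert len(records) == 3  # C(3,2)
        assert all(r.jaccard == 1.0 for r in records)

    def test_small_group_skipped_with_warning(self, caplog):
        records = evaluate_replicates({0.9: [_result({("a", "b")})]})
        assert records == []
        assert "skipped" in caplog.text

    def test_mixed_methods_rejected(self):
        group = {0.9: [_result(set(), method="m1"), _result(set(), method="m2")]}
        with pytest.raises(ValueError, match="mix"):
            evaluate_replicates(group)

    def test_noise_records(self):
        orig = _result({("a", "b"), ("c", "d")})
        specs = [
            PerturbationSpec("dropout", 0.1, i, seed=i) for i in range(1, 4)
        ]
        noised = [(s, _result({("a", "b"), ("c", "d")})) for s in specs]
        records = evaluate_noise(orig, noised)
        assert len(records) == 3
        assert all(r.jaccard == 1.0 and r.kind == "dropout" for r in records)

    def test_noise_method_mismatch(self):
        orig = _result(set(), method="m1")
        spec = PerturbationSpec("dropout", 0.1, 1, seed=0)
        with pytest.raises(ValueError, match="mismatch"):
            evaluate_noise(orig, [(spec, _result(set(), method="m2"))])

    def test_both_empty_counts_as_consistent(self):
        orig = _result(set())
        spec = PerturbationSpec("dropout", 0.1, 1, seed=0)
        (rec,) = evaluate_noise(orig, [(spec, _result(set()))])
        assert rec.jaccard == 1.0


def _records_frame(rows):
    return pd.DataFrame(
        rows, columns=["method", "kind", "proportion", "dataset_id", "pair_id", "jaccard"]
    )


class TestAveraging:
    def test_per_proportion_mean(self):
        df = _records_frame(
            [("m", "dropout", 0.1, "d", f"p{i}", j) for i, j in enumerate([1.0, 0.5, 0.0])]
        )
        out = average_jaccard(df, level="per_proportion")
        assert out["mean_jaccard"].tolist() == [0.5]

    def test_overall_is_unweighted_mean_of_proportion_means(self):
        rows = []
        for p, j in [(0.05, 0.9), (0.10, 0.8), (0.15, 0.7)]:
            rows.append(("m", "dropout", p, "d", "x", j))
            rows.append(("m", "dropout", p, "d", "y", j))
        out = average_jaccard(_records_frame(rows), level="overall")
        assert out["overall_jaccard"].iloc[0] == pytest.approx(0.8)

    def test_single_proportion_overall_equals_its_mean(self):
        df = _records_frame([("m", "dropout", 0.1, "d", "x", 0.6)])
        out = average_jaccard(df, level="overall")
        assert out["overall_jaccard"].iloc[0] == pytest.approx(0.6)

    def test_overall_between_min_and_max_proportion_means(self):
        rng = np.random.default_rng(1)
        rows = [
            ("m", "dropout", p, "d", f"x{i}", float(rng.random()))
            for p in (0.05, 0.1, 0.15)
            for i in range(5)
        ]
        df = _records_frame(rows)
        per = average_jaccard(df, level="per_proportion")["mean_jaccard"]
        ov = average_jaccard(df, level="overall")["overall_jaccard"].iloc[0]
        assert per.min() <= ov <= per.max()

    def test_summary_ov_is_row_mean(self):
        rows = [
            ("m", "dropout", p, "d", "x", j)
            for p, j in [(0.05, 0.9), (0.10, 0.8), (0.15, 0.7)]
        ]
        table = summary_table(_records_frame(rows), "dropout")
        assert table.loc["m", "OV"] == pytest.approx(
            table.loc["m", ["5%", "10%", "15%"]].mean()
        )

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            average_jaccard(_records_frame([]))


class TestRanking:
    def _overall(self, values):
        rows = []
        for method, kinds in values.items():
            for kind, v in kinds.items():
                rows.append({"method": method, "kind": kind, "overall_jaccard": v})
        return pd.DataFrame(rows)

    def test_two_methods_all_kinds(self):
        df = self._overall({
            "a": {"dropout": 0.9, "gaussian": 0.9},
            "b": {"dropout": 0.8, "gaussian": 0.8},
        })
        ranks = rank_methods(df)
        assert ranks.loc["a", "overall_rank"] == 1.0
        assert ranks.loc["b", "overall_rank"] == 2.0

    def test_best_and_worst_average_to_middle(self):
        df = self._overall({
            "a": {"k1": 0.9, "k2": 0.1},
            "b": {"k1": 0.5, "k2": 0.5},
            "c": {"k1": 0.1, "k2": 0.9},
        })
        ranks = rank_methods(df)
        assert ranks.loc["a", "overall_rank"] == 2.0  # rank 1 and rank 3

    def test_midrank_on_ties(self):
        df = self._overall({"a": {"k1": 0.7}, "b": {"k1": 0.7}, "c": {"k1": 0.1}})
        ranks = rank_methods(df)
        assert ranks.loc["a", "k1"] == 1.5 and ranks.loc["b", "k1"] == 1.5

    def test_single_method_rejected(self):
        with pytest.raises(ValueError):
            rank_methods(self._overall({"a": {"k1": 0.5}}))

    def test_ranks_are_permutation_with_ties(self):
        rng = np.random.default_rng(2)
        df = self._overall({
            f"m{i}": {k: float(rng.random()) for k in ("k1", "k2", "k3")}
            for i in range(5)
        })
        ranks = rank_methods(df)
        for kind in ("k1", "k2", "k3"):
            assert ranks[kind].sum() == pytest.approx(15.0)  # 1+2+3+4+5
        assert ranks["overall_rank"].between(1, 5).all()
        assert ranks["overall_rank"].is_monotonic_increasing


class TestAgreement:
    def test_identical_selections(self):
        res = [_result({("a", "b")}, method=m) for m in ("m1", "m2")]
        mat, mean = pairwise_method_agreement(res)
        assert mat.loc["m1", "m2"] == 1.0

    def test_symmetric_unit_diagonal(self):
        res = [
            _result({("a", "b")}, method="m1"),
            _result({("a", "b"), ("c", "d")}, method="m2"),
            _result({("e", "f")}, method="m3"),
        ]
        mat, mean = pairwise_method_agreement(res)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
        assert np.allclose(np.diag(mat.to_numpy()), 1.0)

    def test_mean_excludes_diagonal(self):
        # pairwise jaccards for m1: 0.2 with m2, 0.4 with m3 -> mean 0.3
        def s(*names):
            return {(n, "x") for n in names}

        r1 = _result(s("a", "b", "c"), method="m1")
        r2 = _result(s("c", "d", "e"), method="m2")
        r3 = _result(s("a", "b", "d", "e"), method="m3")
        mat, mean = pairwise_method_agreement([r1, r2, r3])
        assert mat.loc["m1", "m2"] == pytest.approx(0.2)
        assert mat.loc["m1", "m3"] == pytest.approx(0.4)
        assert mean["m1"] == pytest.approx(0.3)

    def test_single_method_rejected(self):
        with pytest.raises(ValueError):
            pairwise_method_agreement([_result(set())])


class TestReport:
    def _records(self):
        rows = []
        for m in ("m1", "m2"):
            for p in (0.05, 0.1):
                for i in range(3):
                    rows.append((m, "dropout", p, "d", f"rep{i}", (i + 1) / 4))
            rows.append((m, "biological_replicate", np.nan, "d", "r1|vs|r2", 0.5))
        return _records_frame(rows)

    def test_rerun_byte_identical(self, tmp_path):
        df = self._records()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        build_report(df, d1)
        build_report(df, d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_regenerated_from_records_file(self, tmp_path):
        df = self._records()
        d1 = tmp_path / "a"
        build_report(df, d1)
        d2 = tmp_path / "b"
        build_report(read_records(d1 / "records.tsv"), d2)
        assert (d1 / "summary_dropout.tsv").read_bytes() == (d2 / "summary_dropout.tsv").read_bytes()
        assert (d1 / "ranking.tsv").read_bytes() == (d2 / "ranking.tsv").read_bytes()

    def test_ov_column_in_files(self, tmp_path):
        build_report(self._records(), tmp_path / "r")
        table = pd.read_csv(tmp_path / "r" / "summary_dropout.tsv", sep="\t", index_col=0)
        np.testing.assert_allclose(
            table["OV"], table[["5%", "10%"]].mean(axis=1), rtol=1e-4
        )
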