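"""Statistical layer: rank correlation and its exact small-n p-values,
Bonferroni thresholds, filtered correlation screens, Welch t-tests,
generation trends and dispersion, and the PCA/k-means embedding."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from clonoscope.lineage import CellRecord, LineageForest
from clonoscope.measure import FeatureTable
from clonoscope.stats import (
    auto_k,
    binary_ttests,
    bonferroni_threshold,
    correlation_matrix,
    generation_area_trend,
    generation_dispersion,
    pca_embed,
    spearman,
)


class TestSpearman:
    def test_monotone_sequences(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [10, 20, 30, 40, 50])[0] == pytest.approx(1.0)
        assert spearman(x, [50, 40, 30, 20, 10])[0] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # ranks differ by d = (0, -1, 1, -1, 1); 1 - 6*4/(5*24) = 0.8
        r, _ = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert r == pytest.approx(0.8)

    def test_matches_library_coefficient_with_ties(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 5, size=40).astype(float)
        y = x + rng.integers(0, 3, size=40)
        r, p = spearman(x, y)
        r_ref, p_ref = sps.spearmanr(x, y)
        assert r == pytest.approx(r_ref)
        assert p == pytest.approx(p_ref, rel=1e-6)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_p_matches_enumeration_oracle(self, n):
        """For n <= 7 without ties the p-value equals the naive exhaustive
        permutation tail probability."""
        rng = np.random.default_rng(n)
        x = rng.permutation(n).astype(float)
        y = rng.permutation(n).astype(float)
        r_obs, p = spearman(x, y)
        rx = sps.rankdata(x)
        count = 0
        total = 0
        for perm in itertools.permutations(sps.rankdata(y)):
            rho = np.corrcoef(rx, perm)[0, 1]
            total += 1
            if abs(rho) >= abs(r_obs) - 1e-12:
                count += 1
        assert p == pytest.approx(count / total)

    def test_constant_input_undefined(self):
        r, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(r) and math.isnan(p)

    def test_too_few_pairs_raise(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


class TestSpearmanProperties:
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=4, max_size=12
        ),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_symmetric(self, xs, rnd):
        ys = list(xs)
        rnd.shuffle(ys)
        if len(set(xs)) < 2 or len(set(ys)) < 2:
            return
        r_xy, p_xy = spearman(xs, ys)
        r_yx, p_yx = spearman(ys, xs)
        assert -1.0 <= r_xy <= 1.0
        assert 0.0 <= p_xy <= 1.0
        assert r_xy == pytest.approx(r_yx)
        assert p_xy == pytest.approx(p_yx)


class TestBonferroni:
    def test_threshold_for_276_pairwise_comparisons(self):
        th = bonferroni_threshold(0.05, 276)
        assert th == pytest.approx(1.8116e-4, rel=1e-3)
        assert float(f"{th:.1e}") == 1.8e-4  # 1.8e-4 at two significant figures

    def test_threshold_for_105_pairwise_comparisons(self):
        th = bonferroni_threshold(0.05, 105)
        assert th == pytest.approx(4.76e-4, rel=1e-2)
        assert round(th, 4) == 0.0005  # the printed one-significant-figure value

    def test_single_comparison_uncorrected(self):
        assert bonferroni_threshold(0.05, 1) == 0.05


def _table(df, mask=None):
    mask = mask if mask is not None else pd.DataFrame(
        True, index=df.index, columns=df.columns
    )
    return FeatureTable(data=df, mask=mask)


class TestCorrelationMatrix:
    def test_pair_count_for_24_properties(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(30, 24)),
                          columns=[f"p{i}" for i in range(24)])
        rep = correlation_matrix(_table(df))
        assert rep.m == 276  # C(24, 2)
        assert rep.bonferroni_p == pytest.approx(0.05 / 276)

    def test_masked_property_reports_zero_n(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        mask = pd.DataFrame(True, index=df.index, columns=df.columns)
        mask["c"] = False
        rep = correlation_matrix(_table(df, mask))
        row = rep.pairs.set_index(["property_a", "property_b"]).loc[("a", "c")]
        assert row["n_used"] == 0
        assert row["highlight"] == "none"
        assert np.isnan(row["r_s"])

    def test_duplicated_column_perfectly_correlated(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=25)
        df = pd.DataFrame({"a": v, "b": v, "c": rng.normal(size=25)})
        rep = correlation_matrix(_table(df))
        row = rep.pairs.set_index(["property_a", "property_b"]).loc[("a", "b")]
        assert row["r_s"] == pytest.approx(1.0)
        assert row["highlight"] == "pass_both"

    def test_symmetric_and_order_invariant(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        rep1 = correlation_matrix(_table(df))
        rep2 = correlation_matrix(_table(df[list("dcba")]))
        m1 = rep1.matrix()
        m2 = rep2.matrix().loc[m1.index, m1.columns]
        assert np.allclose(m1.to_numpy(), m1.to_numpy().T, equal_nan=True)
        assert np.allclose(m1.to_numpy(), m2.to_numpy(), equal_nan=True)

    def test_r_critical_gates_pass_both(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0, 1, 40)
        df = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.35, 40)})
        rep_lo = correlation_matrix(_table(df), r_critical=0.99)
        assert (rep_lo.pairs["highlight"] != "pass_both").all()


class TestBinaryTTests:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=40)
        df = pd.DataFrame({"prop": np.concatenate([v, v])})
        grouping = pd.Series([True] * 40 + [False] * 40)
        rep = binary_ttests(_table(df), grouping)
        assert rep.loc[0, "p_value"] > 0.9
        assert not rep.loc[0, "significant"]

    def test_separated_groups_match_welch_closed_form(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)
        df = pd.DataFrame({"prop": np.concatenate([a, b])})
        grouping = pd.Series([True] * 50 + [False] * 50)
        rep = binary_ttests(_table(df), grouping)
        # closed-form Welch statistic
        se = math.sqrt(a.var(ddof=1) / 50 + b.var(ddof=1) / 50)
        t_expected = (a.mean() - b.mean()) / se
        assert rep.loc[0, "t"] == pytest.approx(t_expected)
        assert rep.loc[0, "significant"]

    def test_per_filter_threshold(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(30, 4)),
                          columns=["p1", "p2", "p3", "q1"])
        grouping = pd.Series(
            [True] * 15 + [False] * 15, index=df.index
        )
        filters = {"p1": "parent", "p2": "parent", "p3": "parent",
                   "q1": "all"}
        rep = binary_ttests(_table(df), grouping, filters=filters)
        by_prop = rep.set_index("property")
        # three parent-derived properties share a 0.05/3 threshold
        assert by_prop.loc["p1", "threshold"] == pytest.approx(0.05 / 3)
        assert by_prop.loc["q1", "threshold"] == pytest.approx(0.05)


class TestTrendsAndDispersion:
    def _table_for_trend(self, areas_by_gen):
        rows = []
        for gen, area in areas_by_gen:
            rows.append({"generation": gen, "avg_area_first_0.83d_um2": area,
                         "colony_id": "f1"})
        df = pd.DataFrame(rows, index=[f"c{i}" for i in range(len(rows))])
        return _table(df)

    def test_halving_areas_give_perfect_negative_trend(self):
        t = self._table_for_trend(
            [(g, 1000.0 / 2**g) for g in (1, 2, 2, 3, 3, 4)]
        )
        (res,) = generation_area_trend(t)
        assert res.r_s == pytest.approx(-1.0)
        assert not res.degenerate

    def test_constant_areas_flagged_degenerate(self):
        t = self._table_for_trend([(g, 500.0) for g in (1, 2, 3, 4)])
        (res,) = generation_area_trend(t)
        assert res.degenerate
        assert res.r_s == 0.0 and res.p_value == 1.0

    def test_generation_dispersion(self):
        recs = {}
        for i, gen in enumerate([4, 4, 5, 5]):
            cid = f"c{i}"
            recs[cid] = CellRecord(
                cell_id=cid, parent_id=None, twin_id=None, generation=gen,
                birth_frame=0, last_frame=100, divided=False,
            )
        f = LineageForest(records=recs, roots=list(recs))
        disp = generation_dispersion(f, 50, membership={c: "col" for c in recs})
        assert disp["col"] == pytest.approx(0.5773502, abs=1e-6)  # sample SD

    def test_uniform_generation_colony_zero_dispersion(self):
        recs = {
            "a": CellRecord("a", None, None, 3, 0, 100, False),
            "b": CellRecord("b", None, None, 3, 0, 100, False),
        }
        f = LineageForest(records=recs, roots=["a", "b"])
        disp = generation_dispersion(f, 50, membership={"a": "x", "b": "x"})
        assert disp["x"] == 0.0

    def test_empty_colony_omitted(self):
        recs = {"a": CellRecord("a", None, None, 1, 0, 10, False)}
        f = LineageForest(records=recs, roots=["a"])
        assert generation_dispersion(f, 50) == {}


class TestEmbedding:
    def test_auto_k_reading(self):
        # sqrt(N / 2) for the pooled 1384-cell dataset
        assert auto_k(1384) == 26
        assert auto_k(8) == 2

    def test_single_varying_column_dominates_pc1(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "a": rng.normal(0, 1, 50),
            "b": rng.normal(0, 0.01, 50),
            "c": rng.normal(0, 0.01, 50),
        })
        # z-scoring equalises variances, so craft correlated noise instead:
        df["b"] = df["a"] * 0.9 + rng.normal(0, 0.1, 50)
        emb = pca_embed(df, k=2)
        pc1 = emb.loadings["PC1"].abs()
        assert pc1["a"] > pc1["c"]

    def test_duplicate_rows_identical_scores(self):
        rng = np.random.default_rng(1)
        base = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        dup = pd.concat([base, base.iloc[:5]], ignore_index=True)
        emb = pca_embed(dup, k=3)
        for i in range(5):
            assert np.allclose(emb.scores.iloc[i], emb.scores.iloc[20 + i])

    def test_explained_variance_sums_to_column_count(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(60, 5)),
                          columns=[f"p{i}" for i in range(5)])
        emb = pca_embed(df, k=2)
        assert emb.explained_variance.sum() == pytest.approx(5.0, abs=1e-9)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        emb = pca_embed(df, k=2)
        s = emb.scores.to_numpy()
        gram = s.T @ s
        off = gram - np.diag(np.diag(gram))
        assert np.allclose(off, 0.0, atol=1e-8)

    def test_masked_rows_dropped(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        mask = pd.DataFrame(True, index=df.index, columns=df.columns)
        mask.iloc[0, 0] = False
        emb = pca_embed(_table(df, mask))
        assert len(emb.scores) == 29
        assert 0 not in emb.scores.index
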