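import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coac.decomposition import compute_svd
from coac.features import (
    SubnetworkEigensystem,
    f_score,
    feature_matrix,
    feature_value,
    label_drug_response,
    rank_by_group_difference,
    select_features,
    stratify_samples,
    subnetwork_eigensystem,
)
from coac.matrix import ExpressionMatrix
from coac.mining import AssociationRule, Subnetwork, build_subnetwork


def subnetwork_over(genes):
    genes = tuple(genes)
    n = len(genes)
    return Subnetwork(
        rule=AssociationRule(genes=genes, components=(0,)),
        giant_genes=genes,
        edges=[],
        correlations=np.ones((n, n)),
        avg_correlation=1.0,
        avg_component_ratio=1.0,
    )


class TestEigensystem:
    def test_perfectly_correlated_pair(self):
        base = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        values = np.column_stack([base, 2 * base + 1])
        m = ExpressionMatrix(values, ["a", "b"], [f"c{i}" for i in range(5)])
        e = subnetwork_eigensystem(subnetwork_over(["a", "b"]), m, v=2)
        np.testing.assert_allclose(e.eigenvalues, [2.0, 0.0], atol=1e-10)
        np.testing.assert_allclose(e.eigenvectors[:, 0], [1 / np.sqrt(2)] * 2)

    def test_uncorrelated_genes_identity_spectrum(self):
        # orthogonal contrast design: exact zero pairwise correlations
        values = 2.0 + np.array(
            [[1, 1, 1], [-1, 1, -1], [1, -1, -1], [-1, -1, 1]], dtype=float
        )
        m = ExpressionMatrix(values, ["a", "b", "c"], [f"c{i}" for i in range(4)])
        e = subnetwork_eigensystem(subnetwork_over(["a", "b", "c"]), m, v=3)
        np.testing.assert_allclose(e.eigenvalues, [1.0, 1.0, 1.0], atol=1e-10)

    def test_matches_dense_eigh_oracle_up_to_sign(self):
        rng = np.random.default_rng(0)
        values = rng.random((30, 4)) * 3
        m = ExpressionMatrix(values, list("abcd"), [f"c{i}" for i in range(30)])
        e = subnetwork_eigensystem(subnetwork_over("abcd"), m, v=4)
        corr = np.corrcoef(values, rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        np.testing.assert_allclose(e.eigenvalues, evals[::-1], atol=1e-10)
        for t in range(4):
            ref = evecs[:, ::-1][:, t]
            got = e.eigenvectors[:, t]
            assert min(np.abs(got - ref).max(), np.abs(got + ref).max()) < 1e-8

    def test_trace_equals_gene_count(self):
        rng = np.random.default_rng(1)
        values = rng.random((25, 5))
        m = ExpressionMatrix(values, list("abcde"), [f"c{i}" for i in range(25)])
        e = subnetwork_eigensystem(subnetwork_over("abcde"), m, v=5)
        assert e.eigenvalues.sum() == pytest.approx(5.0)

    def test_sign_convention(self):
        rng = np.random.default_rng(2)
        values = rng.random((20, 3))
        m = ExpressionMatrix(values, list("abc"), [f"c{i}" for i in range(20)])
        e = subnetwork_eigensystem(subnetwork_over("abc"), m, v=3)
        for t in range(e.v):
            col = e.eigenvectors[:, t]
            assert col[np.argmax(np.abs(col))] > 0

    def test_constant_gene_named_in_error(self):
        values = np.column_stack([np.ones(6), np.arange(6, dtype=float)])
        m = ExpressionMatrix(values, ["flat", "ok"], [f"c{i}" for i in range(6)])
        with pytest.raises(ValueError, match="flat"):
            subnetwork_eigensystem(subnetwork_over(["flat", "ok"]), m)


def toy_eigensystem(sigma=(2.0, 1.0)):
    f1 = np.array([1.0, 0.0, 0.0])
    f2 = np.array([0.0, 1.0, 0.0])
    return SubnetworkEigensystem(
        gene_ids=("a", "b", "c"),
        eigenvalues=np.array(sigma),
        eigenvectors=np.column_stack([f1, f2]),
    )


class TestFeatureValue:
    def test_parallel_to_leading_eigenvector_is_one(self):
        e = toy_eigensystem()
        single = SubnetworkEigensystem(
            e.gene_ids, e.eigenvalues[:1], e.eigenvectors[:, :1]
        )
        assert feature_value(np.array([5.0, 0.0, 0.0]), single) == pytest.approx(1.0)

    def test_orthogonal_to_all_retained_is_zero(self):
        e = toy_eigensystem()
        assert feature_value(np.array([0.0, 0.0, 7.0]), e) == pytest.approx(0.0)

    def test_attenuation_coefficient(self):
        # S = F2, sigma = (2, 1): 0 + (1/2) * 1 = 0.5
        e = toy_eigensystem(sigma=(2.0, 1.0))
        assert feature_value(np.array([0.0, 1.0, 0.0]), e) == pytest.approx(0.5)

    def test_invariant_to_positive_rescaling(self):
        e = toy_eigensystem()
        rng = np.random.default_rng(5)
        S = rng.random(3)
        assert feature_value(10 * S, e) == pytest.approx(
            feature_value(S, e), abs=1e-10
        )

    def test_single_eigenvector_bounded(self):
        e = toy_eigensystem()
        single = SubnetworkEigensystem(
            e.gene_ids, e.eigenvalues[:1], e.eigenvectors[:, :1]
        )
        rng = np.random.default_rng(6)
        for _ in range(20):
            v = feature_value(rng.standard_normal(3), single)
            assert -1.0 - 1e-12 <= v <= 1.0 + 1e-12

    def test_zero_vector_scores_zero(self):
        assert feature_value(np.zeros(3), toy_eigensystem()) == 0.0

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="length"):
            feature_value(np.ones(4), toy_eigensystem())


class TestFeatureMatrix:
    def test_single_cell_single_subnetwork_composition(self):
        e = toy_eigensystem()
        m = ExpressionMatrix(np.array([[1.0, 2.0, 3.0]]), ["a", "b", "c"], ["cell"])
        fm = feature_matrix(m, [e])
        assert fm.shape == (1, 1)
        assert fm.iloc[0, 0] == pytest.approx(feature_value(np.array([1.0, 2.0, 3.0]), e))

    def test_row_scale_invariance(self):
        e = toy_eigensystem()
        rng = np.random.default_rng(3)
        v = rng.random((2, 3))
        v[1] = 10 * v[0]
        m = ExpressionMatrix(v, ["a", "b", "c"], ["c1", "c2"])
        fm = feature_matrix(m, [e])
        assert fm.iloc[0, 0] == pytest.approx(fm.iloc[1, 0], abs=1e-10)

    def test_matches_per_entry_oracle(self):
        rng = np.random.default_rng(4)
        m = ExpressionMatrix(rng.random((3, 3)), ["a", "b", "c"], ["c1", "c2", "c3"])
        e1, e2 = toy_eigensystem(), toy_eigensystem(sigma=(3.0, 0.5))
        e1.name, e2.name = "s1", "s2"
        fm = feature_matrix(m, [e1, e2])
        for ci, cell in enumerate(m.cell_ids):
            for e in (e1, e2):
                assert fm.loc[cell, e.name] == pytest.approx(
                    feature_value(m.dense()[ci], e), abs=1e-12
                )

    def test_empty_eigensystem_list_is_error(self, toy_dense):
        with pytest.raises(ValueError):
            feature_matrix(toy_dense, [])

    def test_missing_genes_skip_with_warning(self):
        e = toy_eigensystem()
        m = ExpressionMatrix(np.ones((2, 2)), ["a", "b"], ["c1", "c2"])
        with pytest.raises(ValueError, match="skipped"):
            with pytest.warns(UserWarning):
                feature_matrix(m, [e])


class TestFScore:
    def labels(self, n_a, n_b):
        return {f"a{i}": "g1" for i in range(n_a)} | {
            f"b{i}": "g2" for i in range(n_b)
        }

    def series(self, a_vals, b_vals):
        idx = [f"a{i}" for i in range(len(a_vals))] + [
            f"b{i}" for i in range(len(b_vals))
        ]
        return pd.Series(list(a_vals) + list(b_vals), index=idx)

    def test_identical_group_means_score_zero(self):
        s = self.series([0.0, 1.0], [1.0, 0.0])
        assert f_score(s, self.labels(2, 2), mode="anova") == pytest.approx(0.0)
        assert f_score(s, self.labels(2, 2), mode="ratio") == pytest.approx(0.0)

    def test_ratio_mode_hand_computation(self):
        # A={0,0}, B={1,1}: between-group var 0.25, merged var 0.25 -> 1.0
        s = self.series([0.0, 0.0], [1.0, 1.0])
        assert f_score(s, self.labels(2, 2), mode="ratio") == pytest.approx(1.0)

    def test_anova_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1, 35)
        s = self.series(a, b)
        expected = stats.f_oneway(a, b).statistic
        assert f_score(s, self.labels(40, 35), mode="anova") == pytest.approx(expected)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        shift=st.floats(-50, 50, allow_nan=False),
        scale=st.floats(0.01, 50, allow_nan=False),
        mode=st.sampled_from(["anova", "ratio", "var_diff"]),
    )
    def test_shift_and_scale_invariance(self, shift, scale, mode):
        rng = np.random.default_rng(1)
        s = self.series(rng.normal(0, 1, 10), rng.normal(1, 2, 12))
        base = f_score(s, self.labels(10, 12), mode=mode)
        moved = f_score(s * scale + shift, self.labels(10, 12), mode=mode)
        assert moved == pytest.approx(base, rel=1e-6, abs=1e-9)

    def test_empty_group_is_error(self):
        s = pd.Series([1.0, 2.0], index=["a0", "a1"])
        with pytest.raises(ValueError):
            f_score(s, {"a0": "g1", "a1": "g1", "zz": "g2"})

    def test_constant_feature_is_error(self):
        s = self.series([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="variance"):
            f_score(s, self.labels(2, 2))


class TestSelectFeatures:
    def make_fm(self):
        rng = np.random.default_rng(2)
        idx = [f"a{i}" for i in range(30)] + [f"b{i}" for i in range(30)]
        labels = {i: ("g1" if i.startswith("a") else "g2") for i in idx}
        fm = pd.DataFrame(
            {
                "strong": np.r_[rng.normal(0, 0.2, 30), rng.normal(3, 0.2, 30)],
                "weak": np.r_[rng.normal(0, 1, 30), rng.normal(0.1, 1, 30)],
                "null": rng.normal(0, 1, 60),
            },
            index=idx,
        )
        return fm, labels

    def test_threshold_and_order(self):
        fm, labels = self.make_fm()
        scores = select_features(fm, labels, threshold=2.4)
        assert scores[0].feature == "strong" and scores[0].kept
        per_feature = {s.feature: s for s in scores}
        for col in fm.columns:
            assert per_feature[col].f_score == pytest.approx(
                f_score(fm[col], labels)
            )
            assert per_feature[col].kept == (per_feature[col].f_score > 2.4)

    def test_zero_threshold_keeps_positive_scores(self):
        fm, labels = self.make_fm()
        scores = select_features(fm, labels, threshold=0.0)
        for s in scores:
            assert s.kept == (s.f_score > 0)


class TestRankByGroupDifference:
    def test_null_feature_ranks_last_and_dominant_first(self):
        idx = [f"a{i}" for i in range(20)] + [f"b{i}" for i in range(20)]
        labels = {i: ("g1" if i.startswith("a") else "g2") for i in idx}
        rng = np.random.default_rng(3)
        common = rng.normal(0, 1, 40)
        fm = pd.DataFrame(
            {
                "dominant": np.r_[rng.normal(0, 0.5, 20), rng.normal(10, 4, 20)],
                "mid": np.r_[rng.normal(0, 1, 20), rng.normal(1, 2, 20)],
                "flat": common,
            },
            index=idx,
        )
        order = rank_by_group_difference(fm, labels)
        assert order[0] == "dominant" and order[-1] == "flat"

    def test_matches_rank_product_oracle(self):
        idx = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        labels = {i: ("g1" if i.startswith("a") else "g2") for i in idx}
        rng = np.random.default_rng(4)
        fm = pd.DataFrame(
            {f"f{i}": rng.normal(i * 0.3, 1 + 0.2 * i, 20) for i in range(4)},
            index=idx,
        )
        order = rank_by_group_difference(fm, labels, combine="product")
        dm, dv = {}, {}
        for c in fm.columns:
            a = fm[c][:10].to_numpy()
            b = fm[c][10:].to_numpy()
            dm[c] = abs(a.mean() - b.mean())
            dv[c] = abs(a.var() - b.var())
        mr = pd.Series(dm).rank(ascending=False, method="min")
        vr = pd.Series(dv).rank(ascending=False, method="min")
        expected = sorted(fm.columns, key=lambda c: (mr[c] * vr[c], c))
        assert order == expected


class TestStratify:
    def test_small_example(self):
        vals = pd.Series([3.0, 1.0, 2.0], index=["a", "b", "c"])
        top, bottom = stratify_samples(vals, k=1)
        assert top == ["a"] and bottom == ["b"]

    def test_default_groups_disjoint(self):
        rng = np.random.default_rng(5)
        vals = pd.Series(rng.random(458), index=[f"p{i:03d}" for i in range(458)])
        top, bottom = stratify_samples(vals, k=32)
        assert len(top) == len(bottom) == 32
        assert not set(top) & set(bottom)

    def test_ties_broken_by_id_stable(self):
        vals = pd.Series([1.0, 1.0, 1.0, 0.0], index=["d", "b", "a", "z"])
        top, bottom = stratify_samples(vals, k=2)
        assert top == ["a", "b"]  # ties by id
        assert bottom == ["d", "z"]

    def test_too_large_k_is_error(self):
        with pytest.raises(ValueError):
            stratify_samples(pd.Series([1.0, 2.0, 3.0], index=list("abc")), k=2)


class TestDrugResponse:
    def test_boundary_and_elementwise(self):
        s = pd.Series([12.0, 10.0, 1.0, 50.0, 9.9], index=list("abcde"))
        labels = label_drug_response(s)
        assert labels["a"] == "resistant"  # 12 > 10
        assert labels["b"] == "sensitive"  # exactly 10 is not "higher than"
        assert list(labels[["c", "d", "e"]]) == ["sensitive", "resistant", "sensitive"]

    def test_nonpositive_is_error(self):
        with pytest.raises(ValueError):
            label_drug_response(pd.Series([5.0, 0.0], index=["a", "b"]))
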