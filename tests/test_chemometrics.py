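"""PCA / PLS-DA / OPLS-DA, VIP, critical-r rules, RPT, ANOVA battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.linalg import subspace_angles

from helpers import null_scaled
from nmrpath import chemometrics as chem
from nmrpath.errors import ArgumentError, InsufficientDataError, RankError


def _two_class(n_per=20, p=10, seed=0, separation=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per, p))
    y = np.array([-1.0] * n_per + [1.0] * n_per)
    X[:, 0] += separation * y
    return chem.autoscale(X), y


class TestAutoscale:
    def test_constant_column_dropped_with_warning(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.warns(UserWarning):
            Xs = chem.autoscale(X, columns=["a", "b"])
        assert Xs.dropped == ["b"] and Xs.columns == ["a"]

    def test_simple_column_hand_value(self):
        Xs = chem.autoscale(np.array([[1.0, 0.0], [2.0, 1.0], [3.0, -1.0]]))
        assert np.allclose(Xs.X[:, 0], [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        Xs = chem.autoscale(rng.normal(size=(10, 4)))
        again = chem.autoscale(Xs.X)
        assert np.allclose(again.X, Xs.X, atol=1e-12)

    def test_means_zero_sds_one(self):
        rng = np.random.default_rng(2)
        Xs = chem.autoscale(rng.normal(size=(12, 6)) * 7 + 3)
        assert np.abs(Xs.X.mean(axis=0)).max() < 1e-9
        assert np.abs(Xs.X.std(axis=0, ddof=1) - 1).max() < 1e-9

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            chem.autoscale(np.ones((2, 3)))


class TestPca:
    def test_rank_one_matrix_explained_by_first_component(self):
        a = np.array([1.0, -2.0, 0.5, 3.0, -1.0])
        b = np.array([0.5, 1.0, -2.0, 0.3])
        Xs = chem.autoscale(np.outer(a, b))
        model = chem.pca(Xs, n_comp=1, cv_folds=3)
        assert model.r2x[0] == pytest.approx(1.0, abs=1e-9)

    def test_loadings_match_eigendecomposition(self):
        rng = np.random.default_rng(6)
        Xs = chem.autoscale(rng.normal(size=(6, 4)))
        model = chem.pca(Xs, n_comp=2, cv_folds=3)
        _, _, vt = np.linalg.svd(Xs.X, full_matrices=False)
        angle = subspace_angles(model.loadings, vt[:2].T).max()
        assert angle < 1e-6

    def test_sign_flipped_data_negates_scores(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 5))
        Xs = chem.autoscale(X)
        neg = chem.ScaledMatrix(
            X=-Xs.X, mean=Xs.mean, sd=Xs.sd, columns=Xs.columns, dropped=[]
        )
        m1 = chem.pca(Xs, n_comp=2, cv_folds=4)
        m2 = chem.pca(neg, n_comp=2, cv_folds=4)
        assert np.allclose(m1.loadings, m2.loadings, atol=1e-8)
        assert np.allclose(m1.scores, -m2.scores, atol=1e-8)

    def test_excess_components_rejected(self):
        Xs = chem.autoscale(np.random.default_rng(0).normal(size=(4, 3)))
        with pytest.raises(RankError):
            chem.pca(Xs, n_comp=4)


class TestPlsda:
    def test_separable_data_validates(self):
        Xs, y = _two_class(n_per=20, p=10, seed=3, separation=10.0)
        model = chem.plsda(Xs, y, n_comp=2)
        assert model.r2y > 0.9
        rpt = chem.permutation_test(Xs, y, n_perm=100, seed=3)
        assert rpt.q2_original > 0.9
        assert rpt.valid

    def test_null_data_fails_validation(self):
        Xs, y = _two_class(n_per=20, p=10, seed=4, separation=0.0)
        rpt = chem.permutation_test(Xs, y, n_perm=200, seed=4)
        assert not rpt.valid

    def test_identity_permutation_reproduces_original_statistics(self):
        Xs, y = _two_class(seed=5, separation=1.0)
        model = chem.plsda(Xs, y)
        r2, q2 = chem.plsda_quiet(Xs, y, n_comp=2, cv_folds=7, seed=0)
        assert model.r2y == pytest.approx(r2)
        assert model.q2 == pytest.approx(q2)

    def test_single_class_rejected(self):
        Xs, _ = _two_class(seed=6)
        with pytest.raises(ArgumentError):
            chem.plsda(Xs, np.ones(Xs.ns))

    def test_vip_mean_square_is_one(self):
        Xs, y = _two_class(seed=8, separation=1.5)
        model = chem.plsda(Xs, y, n_comp=2)
        assert np.mean(model.vip**2) == pytest.approx(1.0, abs=1e-10)


class TestOplsda:
    def test_zero_orthogonal_components_reduce_to_pls(self):
        Xs, y = _two_class(seed=9, separation=1.0)
        opls = chem.oplsda(Xs, y, n_ortho=0)
        pls = chem.plsda(Xs, y, n_comp=1)
        assert np.allclose(opls.tp, pls.scores[:, 0], atol=1e-10)

    def test_orthogonal_filter_beats_pca_on_structured_confound(self):
        rng = np.random.default_rng(10)
        n = 60
        y = np.array([-1.0] * 30 + [1.0] * 30)
        z = rng.normal(size=n)  # large y-orthogonal structure
        X = np.column_stack(
            [y + 0.3 * rng.normal(size=n) for _ in range(5)]
            + [3.0 * z + 0.3 * rng.normal(size=n) for _ in range(5)]
        )
        Xs = chem.autoscale(X)
        opls = chem.oplsda(Xs, y, n_ortho=1)
        pca_model = chem.pca(Xs, n_comp=1, cv_folds=5)
        corr_opls = abs(np.corrcoef(opls.tp, y)[0, 1])
        corr_pca = abs(np.corrcoef(pca_model.scores[:, 0], y)[0, 1])
        assert abs(opls.to[:, 0] @ y) < 1e-8 * np.linalg.norm(opls.to[:, 0]) * np.linalg.norm(y)
        assert corr_opls > corr_pca

    def test_identical_copies_have_unit_vip(self):
        rng = np.random.default_rng(11)
        col = rng.normal(size=20)
        X = np.tile(col[:, None], (1, 6))
        y = np.array([-1.0] * 10 + [1.0] * 10)
        Xs = chem.autoscale(X)
        model = chem.oplsda(Xs, y, n_ortho=0)
        assert np.allclose(model.vip, 1.0, atol=1e-10)

    def test_contracts_hold_across_random_fits(self):
        for seed in range(5):
            Xs, y = _two_class(n_per=12, p=8, seed=100 + seed, separation=0.8)
            m = chem.oplsda(Xs, y, n_ortho=1)
            assert np.mean(m.vip**2) == pytest.approx(1.0, abs=1e-8)
            assert abs(m.tp @ m.to[:, 0]) < 1e-8 * np.linalg.norm(m.tp) * np.linalg.norm(m.to[:, 0])
            assert abs(m.to[:, 0] @ y) < 1e-8 * np.linalg.norm(m.to[:, 0]) * np.linalg.norm(y)


class TestCriticalR:
    @pytest.mark.parametrize(
        "n1,n2,alpha,expected",
        [
            (11, 32, 0.01, 0.389),
            (15, 32, 0.01, 0.372),
            (11, 32, 0.05, 0.301),
            (15, 32, 0.05, 0.288),
        ],
    )
    def test_study_critical_values(self, n1, n2, alpha, expected):
        assert chem.critical_r(n1, n2, alpha) == expected

    def test_limit_alpha_to_one_drives_r_to_zero(self):
        assert chem.critical_r(11, 32, 0.999, decimals=None) < 0.01

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        df=st.integers(min_value=3, max_value=200),
        alpha=st.floats(min_value=0.001, max_value=0.2),
    )
    def test_strictly_decreasing_in_df_and_alpha(self, df, alpha):
        r = chem.critical_r(2, df, alpha, decimals=None)
        assert chem.critical_r(2, df + 1, alpha, decimals=None) < r
        assert chem.critical_r(2, df, alpha * 1.5, decimals=None) < r

    def test_tiny_df_rejected(self):
        with pytest.raises(ArgumentError):
            chem.critical_r(2, 2, 0.05)


def _fake_opls(vip, r, n1=11, n2=32):
    k = len(vip)
    return chem.OplsModel(
        tp=np.zeros(n1 + n2),
        pp=np.zeros(k),
        w=np.zeros(k),
        to=np.zeros((n1 + n2, 1)),
        po=np.zeros((k, 1)),
        wo=np.zeros((k, 1)),
        r2y=0.5,
        vip=np.asarray(vip, dtype=float),
        loading_r=np.asarray(r, dtype=float),
        y=np.array([-1.0] * n2 + [1.0] * n1),
        n1=n2,
        n2=n1,
        columns=[f"v{i}" for i in range(k)],
    )


class TestSelectDifferential:
    def test_threshold_labels_at_df_41(self):
        model = _fake_opls(vip=[1.5, 0.9, 1.2, 1.1], r=[0.40, 0.95, 0.35, -0.20])
        table = chem.select_differential(model)
        assert list(table["label"]) == ["very_significant", "NS", "significant", "NS"]
        assert list(table["direction"][:2]) == ["up", "up"]
        assert table["direction"][3] == "down"

    def test_vip_gate_blocks_high_correlation(self):
        model = _fake_opls(vip=[0.9], r=[0.95])
        assert chem.select_differential(model)["label"][0] == "NS"


class TestLinearBoundary:
    def test_separated_clouds_classify_perfectly(self):
        rng = np.random.default_rng(12)
        a = rng.normal((3.0, 0.0), 0.2, size=(25, 2))
        b = rng.normal((-3.0, 0.0), 0.2, size=(25, 2))
        scores = np.vstack([a, b])
        labels = np.array(["x"] * 25 + ["y"] * 25)
        res = chem.linear_boundary(scores, labels)
        assert res.misclassified == 0

    def test_identical_distributions_near_chance(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=(200, 2))
        labels = np.array(["x", "y"] * 100)
        res = chem.linear_boundary(scores, labels)
        assert res.misclassified > 50  # >25% wrong, near the 50% chance level

    def test_label_swap_flips_orientation_only(self):
        rng = np.random.default_rng(14)
        scores = np.vstack(
            [rng.normal((1, 0), 1.0, (30, 2)), rng.normal((-1, 0), 1.0, (30, 2))]
        )
        labels = np.array(["x"] * 30 + ["y"] * 30)
        swapped = np.where(labels == "x", "y", "x")
        r1 = chem.linear_boundary(scores, labels)
        r2 = chem.linear_boundary(scores, swapped)
        assert np.allclose(r1.coef, -r2.coef, rtol=1e-8)
        assert r1.misclassified == r2.misclassified


class TestUnivariate:
    def test_hand_computed_anova(self):
        table = pd.DataFrame(
            {"group": ["a", "a", "a", "b", "b", "b"], "m": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]}
        )
        res = chem.anova_tukey(table)
        assert res.table.loc[0, "F"] == pytest.approx(13.5)
        assert res.table.loc[0, "p"] == pytest.approx(sps.f.sf(13.5, 1, 4), abs=1e-6)

    def test_tukey_adjusted_p_not_below_pairwise_t(self):
        rng = np.random.default_rng(15)
        table = pd.DataFrame(
            {
                "group": np.repeat(["a", "b", "c"], 10),
                "m": np.concatenate(
                    [rng.normal(0, 1, 10), rng.normal(0.5, 1, 10), rng.normal(1.0, 1, 10)]
                ),
            }
        )
        res = chem.anova_tukey(table)
        for _, row in res.tukey["m"].iterrows():
            g1, g2 = row["group1"], row["group2"]
            x1 = table.loc[table["group"] == g1, "m"]
            x2 = table.loc[table["group"] == g2, "m"]
            _, p_raw = sps.ttest_ind(x1, x2)
            assert row["p_adj"] >= p_raw - 1e-12

    def test_null_f_statistics_stay_small_on_average(self):
        rng = np.random.default_rng(16)
        fs = []
        for _ in range(30):
            table = pd.DataFrame(
                {"group": np.repeat(["a", "b", "c"], 8), "m": rng.normal(size=24)}
            )
            fs.append(chem.anova_tukey(table).table.loc[0, "F"])
        # F(2, 21) has mean df2/(df2-2) = 21/19
        assert np.mean(fs) < 2.5

    def test_group_with_one_member_rejected(self):
        table = pd.DataFrame({"group": ["a", "a", "b"], "m": [1.0, 2.0, 3.0]})
        with pytest.raises(ArgumentError):
            chem.anova_tukey(table)

    def test_zscore_rows_standardized(self):
        rng = np.random.default_rng(17)
        table = pd.DataFrame(
            {"group": ["a"] * 5 + ["b"] * 5, "m1": rng.normal(3, 2, 10), "m2": rng.normal(-1, 5, 10)}
        )
        z = chem.zscore_matrix(table)
        assert z.shape == (2, 10)
        assert np.abs(z.mean(axis=1)).max() < 1e-9
        assert np.abs(z.std(axis=1, ddof=1) - 1).max() < 1e-9


def test_null_opls_keeps_false_positive_labels_rare():
    """Sanity check of the labeling rule under the null at study dimensionality."""
    Xs, y = null_scaled(seed=0, ns=43, nv=150)
    model = chem.oplsda(Xs, y, n_ortho=1)
    table = chem.select_differential(model)
    assert (table["label"] == "very_significant").mean() < 0.1
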