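"""O2PLS-DA, cross-validation, CV-ANOVA, S-plots, univariates, ddCt, PCA."""

import numpy as np
import pandas as pd
import pytest

from lipidims import chemometrics as chem


def random_matrix(rng, n=20, p=30):
    return pd.DataFrame(rng.normal(size=(n, p)),
                        columns=[f"v{i}" for i in range(p)])


class TestNormalizeTagPool:
    def test_two_tag_proportions(self):
        X = pd.DataFrame({"TAG(50:1)": [300.0], "TAG(52:2)": [100.0]},
                         index=["s1"])
        out = chem.normalize_tag_pool(X, ["TAG(50:1)", "TAG(52:2)"])
        assert out.loc["s1"].tolist() == pytest.approx([0.75, 0.25])

    def test_scale_invariance_and_unit_sum(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.uniform(1, 100, size=(5, 4)),
                         columns=list("abcd"))
        out = chem.normalize_tag_pool(X, list("abcd"))
        out10 = chem.normalize_tag_pool(X * 10, list("abcd"))
        pd.testing.assert_frame_equal(out, out10)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_total_names_sample(self):
        X = pd.DataFrame({"a": [0.0], "b": [0.0]}, index=["bad_sample"])
        with pytest.raises(ValueError, match="bad_sample"):
            chem.normalize_tag_pool(X, ["a", "b"])


class TestO2plsda:
    def test_separated_classes_q2_matches_independent_cv_oracle(
            self, two_class_fixture):
        # a 5-sigma shift on 3 of 50 variables separates the classes; the
        # cross-validated Q2 must agree with an independent sklearn-PLS CV
        # loop using the same fold assignment
        from sklearn.cross_decomposition import PLSRegression

        X, y = two_class_fixture
        model = chem.fit_o2plsda(X, y, n_orth=0)
        assert model.q2 > 40.0
        assert model.r2y > model.q2

        Xv, yv = X.to_numpy(float), y.to_numpy(float)
        rng = np.random.default_rng(0)
        order = rng.permutation(len(yv))
        assign = np.empty(len(yv), int)
        assign[order] = np.arange(len(yv)) % 7
        pred = np.empty(len(yv))
        for k in range(7):
            te, tr = assign == k, assign != k
            m = PLSRegression(n_components=1).fit(Xv[tr], yv[tr])
            pred[te] = m.predict(Xv[te]).ravel()
        q2_ref = 100 * (1 - ((yv - pred) ** 2).sum()
                        / ((yv - yv.mean()) ** 2).sum())
        assert model.q2 == pytest.approx(q2_ref, abs=1e-6)

    def test_reduces_to_pls_at_zero_orth(self, two_class_fixture):
        # independent single-component PLS (NIPALS, sklearn) must give the
        # same predictive scores up to sign
        from sklearn.cross_decomposition import PLSRegression

        X, y = two_class_fixture
        model = chem.fit_o2plsda(X, y, n_orth=0)
        Xs, _, _ = chem.scale_matrix(X.to_numpy(float), "uv")
        pls = PLSRegression(n_components=1, scale=False).fit(Xs, y - y.mean())
        t_ref = pls.x_scores_[:, 0]
        sign = np.sign(t_ref @ model.t)
        np.testing.assert_allclose(model.t, sign * t_ref, atol=1e-8)

    def test_orthogonal_scores_perpendicular(self, two_class_fixture):
        X, y = two_class_fixture
        model = chem.fit_o2plsda(X, y, n_orth=2)
        for k in range(model.t_orth.shape[1]):
            dot = model.t @ model.t_orth[:, k]
            norm = np.linalg.norm(model.t) * np.linalg.norm(model.t_orth[:, k])
            assert abs(dot) / norm <= 1e-8

    def test_permuted_labels_give_negative_q2(self):
        # null data: no label assignment should cross-validate
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(40, 50)),
                         columns=[f"v{i}" for i in range(50)])
        y = np.repeat([0, 1], 20)
        neg = sum(
            chem.cross_validated_q2(X, pd.Series(rng.permutation(y)),
                                    seed=rep) <= 0
            for rep in range(10))
        assert neg >= 9

    def test_single_class_rejected(self):
        X = random_matrix(np.random.default_rng(1), n=10)
        with pytest.raises(ValueError):
            chem.fit_o2plsda(X, np.zeros(10))

    def test_excessive_orth_rejected(self):
        X = random_matrix(np.random.default_rng(1), n=8, p=4)
        with pytest.raises(ValueError):
            chem.fit_o2plsda(X, np.repeat([0, 1], 4), n_orth=5)


class TestPredictY:
    def test_training_scores_near_labels(self, two_class_fixture):
        X, y = two_class_fixture
        model = chem.fit_o2plsda(X, y, n_orth=0)
        pred = chem.predict_y(model, X)
        assert pred[y == 1].mean() > 0.9
        assert pred[y == 0].mean() < 0.1

    def test_mean_sample_scores_at_half(self, two_class_fixture):
        X, y = two_class_fixture  # balanced classes: y_mean = 0.5
        model = chem.fit_o2plsda(X, y, n_orth=1)
        mean_sample = pd.DataFrame([X.mean()], index=["m"])
        assert chem.predict_y(model, mean_sample)["m"] == pytest.approx(0.5,
                                                                        abs=1e-8)

    def test_variable_mismatch_rejected(self, two_class_fixture):
        X, y = two_class_fixture
        model = chem.fit_o2plsda(X, y)
        with pytest.raises(ValueError):
            chem.predict_y(model, X.iloc[:, :10])


class TestQ2:
    def test_noiseless_linear_relation(self):
        # y is an exact linear function of the lone predictor: the
        # cross-validated fit is essentially perfect
        n = 20
        y = np.repeat([0.0, 1.0], n // 2)
        X = pd.DataFrame({"signal": y})
        assert chem.cross_validated_q2(X, y) > 99.0

    def test_null_data_nonpositive(self):
        rng = np.random.default_rng(4)
        X = random_matrix(rng, n=24, p=40)
        y = np.repeat([0, 1], 12)
        assert chem.cross_validated_q2(X, y, seed=1) <= 0.0

    def test_q2_below_r2y_on_random_inputs(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = random_matrix(rng, n=16, p=12)
            y = np.repeat([0, 1], 8)
            m = chem.fit_o2plsda(X, y, n_orth=seed % 3)
            assert m.q2 <= m.r2y


class TestCvAnova:
    def test_separated_fixture_significant(self, two_class_fixture):
        X, y = two_class_fixture
        model = chem.fit_o2plsda(X, y, n_orth=0)
        assert chem.cv_anova(model) < 0.001
        assert model.cv_anova_p == pytest.approx(chem.cv_anova(model))

    def test_null_fixture_rarely_significant(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = random_matrix(rng, n=20, p=30)
            y = np.repeat([0, 1], 10)
            model = chem.fit_o2plsda(X, y, cv_seed=seed)
            hits += model.cv_anova_p <= 0.05
        assert hits <= 1

    def test_p_decreases_with_effect_size(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(20, 30))
        y = np.repeat([0, 1], 10)
        ps = []
        for delta in (2.0, 3.0, 4.0):
            X = base.copy()
            X[y == 1, :3] += delta
            model = chem.fit_o2plsda(
                pd.DataFrame(X, columns=[f"v{i}" for i in range(30)]), y)
            ps.append(model.cv_anova_p)
        assert ps[0] > ps[1] > ps[2]


class TestSPlot:
    def test_planted_variables_at_extreme_ranks(self, two_class_fixture):
        X, y = two_class_fixture
        model = chem.fit_o2plsda(X, y, n_orth=0)
        sp = chem.s_plot(model, X)
        top3 = set(sp.sort_values("rank").index[:3])
        assert top3 == {"v0", "v1", "v2"}

    def test_correlations_bounded(self, two_class_fixture):
        X, y = two_class_fixture
        sp = chem.s_plot(chem.fit_o2plsda(X, y), X)
        assert sp["p_corr"].abs().max() <= 1.0 + 1e-12

    def test_zero_variance_variable_missing_corr(self, two_class_fixture):
        X, y = two_class_fixture
        X = X.copy()
        X["flat"] = 1.0
        model = chem.fit_o2plsda(X, y)
        sp = chem.s_plot(model, X)
        assert np.isnan(sp.loc["flat", "p_corr"])


class TestUnivariate:
    def test_identical_groups_no_rejections(self):
        rng = np.random.default_rng(0)
        block = rng.normal(size=(4, 6))
        X = pd.DataFrame(np.vstack([block, block]),
                         columns=[f"v{i}" for i in range(6)])
        groups = pd.Series(["a"] * 4 + ["b"] * 4)
        X.index = groups.index
        res = chem.ttest_bonferroni(X, groups, ("a", "b"))
        np.testing.assert_allclose(res["p"], 1.0)
        assert not res["significant"].any()

    def test_glucose_summary_statistics(self):
        # fasting glucose: controls 4.5 +/- 0.5 mmol/l (n=27) vs
        # lipodystrophy 6.4 +/- 2.7 mmol/l (n=14)
        t_student, p_student = chem.ttest_from_summary(
            4.5, 0.5, 27, 6.4, 2.7, 14, equal_var=True)
        assert p_student < 0.01
        t_welch, p_welch = chem.ttest_from_summary(4.5, 0.5, 27, 6.4, 2.7, 14)
        assert p_welch < 0.05
        assert abs(t_welch) < abs(t_student)  # Welch is the cautious variant

    def test_familywise_error_controlled_under_global_null(self):
        rng = np.random.default_rng(11)
        alpha, reps, rejections = 0.05, 40, 0
        for _ in range(reps):
            X = pd.DataFrame(rng.normal(size=(20, 50)))
            X.columns = [f"v{i}" for i in range(50)]
            groups = pd.Series(["a"] * 10 + ["b"] * 10, index=X.index)
            res = chem.ttest_bonferroni(X, groups, ("a", "b"), alpha=alpha)
            rejections += res["significant"].any()
        assert rejections / reps <= alpha

    def test_small_group_rejected(self):
        X = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        groups = pd.Series(["a", "a", "b"])
        with pytest.raises(ValueError):
            chem.ttest_bonferroni(X, groups, ("a", "b"))


class TestFoldChanges:
    def test_equal_means_unit_fold(self):
        X = pd.DataFrame({"v": [2.0, 2.0, 2.0, 2.0]})
        groups = pd.Series(["a", "a", "b", "b"])
        res = chem.fold_changes(X, groups, ("a", "b"))
        assert res.loc["v", "fold_change"] == pytest.approx(1.0)
        assert res.loc["v", "log2_fc"] == pytest.approx(0.0)

    def test_reciprocal_symmetry(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.uniform(1, 10, size=(8, 3)), columns=list("xyz"))
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=X.index)
        ab = chem.fold_changes(X, groups, ("a", "b"))["fold_change"]
        ba = chem.fold_changes(X, groups, ("b", "a"))["fold_change"]
        np.testing.assert_allclose(ab * ba, 1.0)

    def test_zero_denominator_rejected(self):
        X = pd.DataFrame({"v": [1.0, 1.0, 0.0, 0.0]})
        groups = pd.Series(["a", "a", "b", "b"])
        with pytest.raises(ValueError):
            chem.fold_changes(X, groups, ("a", "b"))


class TestDeltaDeltaCt:
    @staticmethod
    def _table(planted):
        rows = []
        for group in ("wt", "ob"):
            for i in range(3):
                sid = f"{group}{i}"
                rows.append({"sample_id": sid, "group": group,
                             "gene": "18S", "ct": 11.0})
                for gene in ("FASN", "ACACA"):
                    shift = planted if group == "ob" else 0.0
                    rows.append({"sample_id": sid, "group": group,
                                 "gene": gene, "ct": 24.0 + shift})
        return pd.DataFrame(rows)

    def test_flat_table_gives_unit_expression(self):
        res = chem.delta_delta_ct(self._table(0.0), "18S", "wt")
        np.testing.assert_allclose(res["relative_expression"], 1.0)

    def test_planted_minus_two_ddct_gives_fourfold(self):
        res = chem.delta_delta_ct(self._table(-2.0), "18S", "wt")
        ob = res[res["group"] == "ob"]
        np.testing.assert_allclose(ob["relative_expression"], 4.0)
        np.testing.assert_allclose(ob["ddct"], -2.0)

    def test_missing_reference_gene_rejected(self):
        tab = self._table(0.0)
        tab = tab[tab["gene"] != "18S"]
        with pytest.raises(ValueError):
            chem.delta_delta_ct(tab, "18S", "wt")


class TestPca:
    def test_rank_one_matrix_single_component(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([0.5, -1.0, 2.0])
        X = pd.DataFrame(np.outer(u, v))
        _, _, ev = chem.pca(X, n_components=2)
        assert ev[0] == pytest.approx(100.0, abs=1e-8)

    def test_explained_variance_properties(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(12, 6)))
        _, _, ev = chem.pca(X, n_components=4)
        assert ev.sum() <= 100.0 + 1e-9
        assert np.all(np.diff(ev) <= 1e-9)

    def test_scores_match_covariance_eigendecomposition(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(5, 4)))
        scores, loadings, ev = chem.pca(X, n_components=3)
        Xc = X - X.mean()
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (len(X) - 1))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for k in range(3):
            ref = Xc.to_numpy() @ evecs[:, k]
            sign = np.sign(ref @ scores.iloc[:, k])
            np.testing.assert_allclose(scores.iloc[:, k], sign * ref, atol=1e-8)
        np.testing.assert_allclose(
            ev[:3], 100 * evals[:3] / evals.sum(), atol=1e-8)
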