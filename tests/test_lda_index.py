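import itertools

import numpy as np
import pytest

from mirindex import lda_index, performance


def _two_clusters(rng, n_per=10, k=2, gap=8.0, sd=0.3):
    X0 = rng.normal(0, sd, (n_per, k))
    X1 = rng.normal(gap, sd, (n_per, k))
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(n_per, bool), np.ones(n_per, bool)]
    return X, y


class TestFisherFit:
    def test_one_dimensional_closed_form(self):
        # class means 10 and 12, pooled variance exactly 1:
        # w = (mu1 - mu0) / sigma^2 = 2, boundary at the midpoint 11
        X = np.array([[9.0], [10.0], [11.0], [11.0], [12.0], [13.0]])
        y = np.array([False, False, False, True, True, True])
        m = lda_index.fit_fisher_lda(X, y)
        assert m.coefficients[0] == pytest.approx(2.0)
        assert m.intercept == pytest.approx(-22.0)
        assert 10.0 * m.coefficients[0] + m.intercept < 0  # class-0 side
        assert 12.0 * m.coefficients[0] + m.intercept > 0  # class-1 side
        score_mid = 11.0 * m.coefficients[0] + m.intercept
        assert score_mid == pytest.approx(0.0, abs=1e-12)

    def test_identical_class_means_give_zero_direction(self, rng):
        base = rng.normal(size=(10, 3))
        X = np.vstack([base, base])  # same points, so identical means
        y = np.r_[np.zeros(10, bool), np.ones(10, bool)]
        m = lda_index.fit_fisher_lda(X, y)
        assert np.all(np.abs(m.coefficients) < 1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_direct_linear_solve(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(25, 3))
        y = np.zeros(25, bool)
        y[rng.permutation(25)[:12]] = True
        X[y] += rng.normal(0.5, 0.3, 3)
        m = lda_index.fit_fisher_lda(X, y)
        mu1, mu0 = X[y].mean(0), X[~y].mean(0)
        S = (
            (X[y] - mu1).T @ (X[y] - mu1) + (X[~y] - mu0).T @ (X[~y] - mu0)
        ) / (25 - 2)
        w = np.linalg.solve(S, mu1 - mu0)
        np.testing.assert_allclose(m.coefficients, w, rtol=1e-8)
        assert m.intercept == pytest.approx(-w @ (mu0 + mu1) / 2, rel=1e-8)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            lda_index.fit_fisher_lda(np.zeros((3, 1)), [True, False, False])

    def test_singular_covariance_needs_ridge(self):
        X = np.ones((8, 2))
        X[4:, 0] = 2.0
        X[:, 1] = X[:, 0]  # perfectly collinear
        y = np.r_[np.zeros(4, bool), np.ones(4, bool)]
        with pytest.raises(np.linalg.LinAlgError):
            lda_index.fit_fisher_lda(X, y, ridge=None)
        m = lda_index.fit_fisher_lda(X, y, ridge="auto")
        assert np.all(np.isfinite(m.coefficients))

    def test_affine_equivariance(self, rng):
        X, y = _two_clusters(rng, n_per=12, gap=2.0, sd=1.0)
        m1 = lda_index.fit_fisher_lda(X, y)
        shifted = X.copy()
        shifted[:, 0] += 100.0
        m2 = lda_index.fit_fisher_lda(shifted, y)
        np.testing.assert_allclose(m2.coefficients, m1.coefficients, rtol=1e-9)
        s1, _ = lda_index.score_samples(m1, X)
        s2, _ = lda_index.score_samples(m2, shifted)
        np.testing.assert_allclose(s1, s2, atol=1e-8)


class TestLoocv:
    def test_separable_clusters_are_perfect(self, rng):
        X, y = _two_clusters(rng, n_per=10)
        res = lda_index.loocv_classify(X, y)
        assert res.accuracy == 1.0

    def test_matches_independent_refit_loop(self, rng):
        n = 8
        X = rng.normal(size=(n, 2))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=bool)
        X[y] += 0.8
        res = lda_index.loocv_classify(X, y)
        # independent oracle: textbook LDA refit per left-out sample
        for j in range(n):
            keep = np.ones(n, bool)
            keep[j] = False
            Xk, yk = X[keep], y[keep]
            mu1, mu0 = Xk[yk].mean(0), Xk[~yk].mean(0)
            S = (
                (Xk[yk] - mu1).T @ (Xk[yk] - mu1)
                + (Xk[~yk] - mu0).T @ (Xk[~yk] - mu0)
            ) / (n - 1 - 2)
            w = np.linalg.solve(S, mu1 - mu0)
            score = X[j] @ w - w @ (mu0 + mu1) / 2
            assert score == pytest.approx(res.scores[j], rel=1e-9, abs=1e-9)

    def test_fast_kernel_agrees_with_refit_loop(self, rng):
        for _ in range(5):
            n = 30
            X = rng.normal(size=(n, 4))
            y = np.zeros(n, bool)
            y[rng.permutation(n)[:14]] = True
            X[y, :2] += 0.7
            res = lda_index.loocv_classify(X, y)
            acc, sens, spec, _ = lda_index.loocv_subset_stats(X, y, range(4))
            assert acc == pytest.approx(res.accuracy, abs=1e-12)
            assert sens == pytest.approx(res.sensitivity, abs=1e-12)
            assert spec == pytest.approx(res.specificity, abs=1e-12)

    def test_null_data_accuracy_near_chance(self):
        rng = np.random.default_rng(31)
        accs = []
        for _ in range(100):
            X = rng.normal(size=(50, 3))
            y = np.zeros(50, bool)
            y[rng.permutation(50)[:25]] = True
            acc, _, _, _ = lda_index.loocv_subset_stats(X, y, range(3))
            accs.append(acc)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            lda_index.loocv_classify(np.zeros((3, 1)), [True, True, False])


class TestSearch:
    def test_exhaustive_beam_matches_pair_enumeration(self, rng):
        n, p = 30, 6
        X = rng.normal(size=(n, p))
        y = np.zeros(n, bool)
        y[:14] = True
        X[y, 0] += 1.2
        X[y, 3] += 0.8
        ids = [f"miR-{i}" for i in range(p)]
        table = lda_index.search_best_combinations(
            X, y, ids, max_size=2, beam_width=np.inf
        )
        # independent oracle: explicit-refit LOOCV over all 15 pairs
        best = None
        for pair in itertools.combinations(range(p), 2):
            res = lda_index.loocv_classify(X[:, pair], y)
            model = lda_index.fit_fisher_lda(X[:, pair], y)
            scores, _ = lda_index.score_samples(model, X[:, pair])
            auc, _, _ = performance.roc_auc(scores, y)
            key = (-res.accuracy, -auc, tuple(sorted(ids[i] for i in pair)))
            if best is None or key < best:
                best = key
        assert table.row(2).mirna_ids == best[2]
        assert table.row(2).loocv_accuracy == pytest.approx(-best[0], abs=1e-12)

    def test_deterministic_given_inputs(self, rng):
        X = rng.normal(size=(40, 10))
        y = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        ids = [f"miR-{i}" for i in range(10)]
        t1 = lda_index.search_best_combinations(X, y, ids, max_size=3, beam_width=4)
        t2 = lda_index.search_best_combinations(X, y, ids, max_size=3, beam_width=4)
        for r1, r2 in zip(t1.rows, t2.rows):
            assert r1.mirna_ids == r2.mirna_ids
            assert r1.loocv_accuracy == r2.loocv_accuracy
            np.testing.assert_array_equal(r1.model.coefficients, r2.model.coefficients)

    def test_size_one_winner_near_chance_on_null_data(self):
        # a small candidate pool: the winner's LOOCV accuracy carries a
        # selection-bias optimism that grows with the number of candidates
        rng = np.random.default_rng(17)
        winners = []
        for _ in range(40):
            X = rng.normal(size=(60, 3))
            y = np.zeros(60, bool)
            y[:30] = True
            t = lda_index.search_best_combinations(
                X, y, [f"m{i}" for i in range(3)], max_size=1
            )
            winners.append(t.rows[0].loocv_accuracy)
        assert np.mean(winners) == pytest.approx(0.5, abs=0.1)

    def test_oversized_request_truncates_with_warning(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        with pytest.warns(UserWarning, match="truncat"):
            t = lda_index.search_best_combinations(
                X, y, ["a", "b", "c"], max_size=9, beam_width=np.inf
            )
        assert max(r.size for r in t.rows) == 3


class TestSizeSelection:
    def _table(self, pvalues):
        rows = []
        for i, p in enumerate([None] + list(pvalues)):
            rows.append(
                lda_index.CandidateRow(
                    size=i + 1,
                    mirna_ids=tuple(f"m{j}" for j in range(i + 1)),
                    model=None,
                    loocv_accuracy=0.9,
                    loocv_sensitivity=0.9,
                    loocv_specificity=0.9,
                    apparent_auc=0.95,
                    p_vs_previous=p,
                )
            )
        return lda_index.CandidateTable(rows)

    def test_growth_stops_at_last_significant_improvement(self):
        # the printed pattern: .006 (2 vs 1), .01 (3 vs 2), .15 (4 vs 3) -> size 3
        table = self._table([0.006, 0.01, 0.15, 0.83])
        assert lda_index.select_final_size(table, alpha=0.05) == 3

    def test_no_significant_improvement_keeps_single_mirna(self):
        assert lda_index.select_final_size(self._table([0.2, 0.5])) == 1

    def test_monotone_significance_reaches_max_size(self):
        assert lda_index.select_final_size(self._table([0.01, 0.01, 0.01])) == 4


class TestYoudenCalibration:
    def test_worked_example_recentres_scores(self):
        # raw scores (0.1, 0.2, 0.8, 0.9): optimal threshold 0.5, J = 1
        model = lda_index.LinearIndexModel(["m"], np.array([1.0]), intercept=0.0)
        X = np.array([[0.1], [0.2], [0.8], [0.9]])
        y = np.array([False, False, True, True])
        out = lda_index.calibrate_cutoff_youden(model, X, y)
        scores, calls = lda_index.score_samples(out, X)
        np.testing.assert_allclose(scores, [-0.4, -0.3, 0.3, 0.4])
        np.testing.assert_array_equal(calls, y)
        assert out.cutoff == 0.0

    def test_idempotent(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.r_[np.ones(15, bool), np.zeros(15, bool)]
        X[y] += 1.0
        model = lda_index.fit_fisher_lda(X, y)
        once = lda_index.calibrate_cutoff_youden(model, X, y)
        twice = lda_index.calibrate_cutoff_youden(once, X, y)
        assert abs(twice.intercept - once.intercept) < 1e-12

    def test_attains_exhaustive_maximum(self, rng):
        for _ in range(10):
            X = rng.normal(size=(25, 1))
            y = rng.random(25) < 0.5
            y[0], y[1] = True, False
            model = lda_index.LinearIndexModel(["m"], np.array([1.0]), intercept=0.0)
            out = lda_index.calibrate_cutoff_youden(model, X, y)
            scores, _ = lda_index.score_samples(out, X)
            j_at_zero = performance.youden_statistic(scores, y, 0.0)
            grid = np.concatenate([scores, [scores.min() - 1, scores.max() + 1]])
            j_best = max(performance.youden_statistic(scores, y, t) for t in grid)
            assert j_at_zero == pytest.approx(j_best, abs=1e-12)

    def test_degenerate_scores_warn(self):
        model = lda_index.LinearIndexModel(["m"], np.array([0.0]), intercept=1.0)
        with pytest.warns(UserWarning, match="degenerate"):
            out = lda_index.calibrate_cutoff_youden(
                model, np.zeros((4, 1)), [True, False, True, False]
            )
        assert out.intercept == model.intercept


class TestScoring:
    def test_published_index_worked_example(self):
        model = lda_index.published_glioma_index()
        sample = {"miR-4763-3p": 12.0, "miR-1915-3p": 12.0, "miR-3679-5p": 10.0}
        score, call = lda_index.score_index(model, sample)
        assert score == pytest.approx(5.47373, abs=1e-9)
        assert call

    def test_zero_score_is_positive_boundary(self):
        model = lda_index.LinearIndexModel(["a", "b"], np.zeros(2), intercept=0.0)
        score, call = lda_index.score_index(model, {"a": 3.0, "b": -1.0})
        assert score == 0.0
        assert call  # ties go to the sensitive side

    def test_linearity_in_each_feature(self, rng):
        model = lda_index.LinearIndexModel(
            ["a", "b", "c"], rng.normal(size=3), intercept=rng.normal()
        )
        base = {"a": 1.0, "b": 2.0, "c": 3.0}
        s0, _ = lda_index.score_index(model, base)
        for i, name in enumerate(model.mirna_ids):
            bumped = dict(base)
            bumped[name] += 0.7
            s1, _ = lda_index.score_index(model, bumped)
            assert s1 - s0 == pytest.approx(0.7 * model.coefficients[i], abs=1e-9)

    def test_missing_feature_named_in_error(self):
        model = lda_index.published_glioma_index()
        with pytest.raises(KeyError, match="miR-3679-5p"):
            lda_index.score_index(model, {"miR-4763-3p": 1.0, "miR-1915-3p": 2.0})
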