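import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from sibmicro import (mds_components, lda_fit, lda_posterior,
                      cv_sibling_score, auc_vs_components, loess,
                      score_gap_curve, auc_mann_whitney)
from sibmicro.sibship import SiblingExposure, SiblingStatus


def euclid_dm(points, ids=None):
    d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(d, ids=ids)


class TestMDS:
    def test_euclidean_isometry(self, rng):
        pts = rng.normal(size=(12, 2))
        comp = mds_components(euclid_dm(pts), k=2).to_numpy()
        d2 = np.sqrt(((comp[:, None] - comp[None]) ** 2).sum(-1))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        np.testing.assert_allclose(d2, d, atol=1e-8)

    def test_k_bounds(self, rng):
        dm = euclid_dm(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            mds_components(dm, k=0)
        with pytest.raises(ValueError):
            mds_components(dm, k=5)

    def test_fewer_positive_axes_warns(self, rng):
        pts = np.linspace(0, 1, 6)[:, None]
        with pytest.warns(UserWarning, match="positive axes"):
            comp = mds_components(euclid_dm(pts), k=4)
        assert comp.shape[1] < 4

    def test_nmds_available(self, rng):
        dm = euclid_dm(rng.normal(size=(15, 3)))
        comp = mds_components(dm, k=2, method="nmds", seed=0)
        assert comp.shape == (15, 2)


class TestLDA:
    def test_symmetric_midpoint_posterior_half(self):
        rng = np.random.default_rng(0)
        x0 = rng.normal(-2, 1, 500)
        x1 = rng.normal(2, 1, 500)
        # force exact sample moments
        x0 = (x0 - x0.mean()) / x0.std(ddof=0) - 2
        x1 = (x1 - x1.mean()) / x1.std(ddof=0) + 2
        X = np.r_[x0, x1][:, None]
        y = np.r_[np.zeros(500), np.ones(500)]
        m = lda_fit(X, y)
        assert lda_posterior(m, [[0.0]])[0] == pytest.approx(0.5, abs=1e-6)
        # 1-D closed form: posterior at mu1 = logistic(w * 2) with w = 4/sigma2
        assert lda_posterior(m, [[2.0]])[0] == pytest.approx(
            1 / (1 + np.exp(-8)), abs=1e-3)

    def test_matches_sklearn_posteriors(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        # sklearn pools with denominator n, we use n - 2: agreement is O(1/n)
        X = rng.normal(size=(400, 4))
        y = (rng.random(400) < 0.5).astype(int)
        X[y == 1] += 0.8
        mine = lda_posterior(lda_fit(X, y), X)
        ref = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        np.testing.assert_allclose(mine, ref.predict_proba(X)[:, 1],
                                   atol=5e-3)

    def test_shuffled_labels_posterior_near_prior(self, rng):
        X = rng.normal(size=(1000, 3))
        y = (rng.random(1000) < 0.3).astype(int)
        post = lda_posterior(lda_fit(X, y), X)
        assert post.mean() == pytest.approx(0.3, abs=0.05)
        assert auc_mann_whitney(y, post) == pytest.approx(0.5, abs=0.08)

    def test_singular_covariance_uses_ridge(self, rng):
        X = np.repeat(rng.normal(size=(40, 1)), 3, axis=1)  # rank 1
        y = np.r_[np.zeros(20), np.ones(20)]
        m = lda_fit(X, y)
        assert m.ridge_used
        assert np.all(np.isfinite(m.w))


class TestCVScore:
    @staticmethod
    def separable(rng, n=120, gap=4.0):
        y = (rng.random(n) < 0.5).astype(int)
        pts = rng.normal(size=(n, 3))
        pts[:, 0] += gap * y
        return euclid_dm(pts), y

    def test_same_seed_identical_scores(self, rng):
        dm, y = self.separable(rng)
        a = cv_sibling_score(dm, y, k=3, folds=5, seed=42)
        b = cv_sibling_score(dm, y, k=3, folds=5, seed=42)
        pd.testing.assert_frame_equal(a.scores, b.scores)
        assert a.cv_auc == b.cv_auc

    def test_separable_data_high_auc(self, rng):
        dm, y = self.separable(rng, gap=5.0)
        res = cv_sibling_score(dm, y, k=3, folds=5, seed=0)
        assert res.cv_auc > 0.95
        assert res.scores["score"].between(0, 1).all()

    def test_each_sample_scored_out_of_fold(self, rng):
        dm, y = self.separable(rng)
        res = cv_sibling_score(dm, y, k=3, folds=5, seed=1)
        assert (res.scores["fold"] >= 0).all()
        assert res.scores["score"].notna().all()

    def test_label_poisoning_leaves_own_score_unchanged(self, rng):
        dm, y = self.separable(rng, n=60)
        fold = np.tile(np.arange(5), 12)
        a = cv_sibling_score(dm, y, k=3, seed=0, fold_assignment=fold)
        y2 = y.copy()
        y2[7] = 1 - y2[7]
        b = cv_sibling_score(dm, y2, k=3, seed=0, fold_assignment=fold)
        assert a.scores["score"].iloc[7] == pytest.approx(
            b.scores["score"].iloc[7], abs=1e-12)

    def test_strict_mode_runs_and_scores_in_range(self, rng):
        dm, y = self.separable(rng, n=80)
        res = cv_sibling_score(dm, y, k=3, folds=4, seed=0, strict=True)
        assert res.scores["score"].between(0, 1).all()
        assert res.cv_auc > 0.8


class TestAUCCurves:
    def test_signal_on_first_axis_plateaus(self, rng):
        n = 100
        y = (rng.random(n) < 0.5).astype(int)
        pts = rng.normal(size=(n, 5)) * 0.3
        pts[:, 0] = y * 4 + rng.normal(size=n) * 0.3
        dm = euclid_dm(pts)
        curve = auc_vs_components({"euclid": dm}, y, k_range=[1, 2, 4, 8],
                                  folds=5, seed=0)
        aucs = curve.set_index("k")["cv_auc"]
        assert aucs[1] > 0.9
        assert abs(aucs[8] - aucs[1]) < 0.08

    def test_null_labels_flat_at_half(self, rng):
        n = 80
        dm = euclid_dm(rng.normal(size=(n, 5)))
        y = (rng.random(n) < 0.5).astype(int)
        curve = auc_vs_components({"e": dm}, y, k_range=[1, 3, 5],
                                  folds=5, seed=0)
        assert np.allclose(curve["cv_auc"], 0.5, atol=0.18)

    def test_oversized_k_truncated_with_warning(self, rng):
        dm = euclid_dm(rng.normal(size=(20, 3)))
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        with pytest.warns(UserWarning, match="truncated"):
            curve = auc_vs_components({"e": dm}, y, k_range=[2, 50],
                                      folds=4, seed=0)
        assert curve["k"].max() == 2


class TestLoess:
    def test_constant_signal_fits_constant(self, rng):
        x = rng.uniform(0, 10, 50)
        fit = loess(x, np.full(50, 0.4))
        np.testing.assert_allclose(fit["fitted"], 0.4, atol=1e-9)

    def test_recovers_smooth_quadratic(self, rng):
        x = np.linspace(0, 5, 120)
        y = 0.2 * x ** 2 - x + 3 + rng.normal(0, 0.05, 120)
        fit = loess(x, y, span=0.5)
        truth = 0.2 * fit["x"] ** 2 - fit["x"] + 3
        assert np.abs(fit["fitted"] - truth).mean() < 0.05

    def test_invalid_span(self):
        with pytest.raises(ValueError):
            loess([1, 2, 3, 4], [1, 2, 3, 4], span=0.0)


def exposures_for(gaps):
    out = []
    for i, g in enumerate(gaps):
        has = g is not None
        out.append(SiblingExposure(
            child_id=f"c{i}", status=SiblingStatus.older_only if has
            else SiblingStatus.none, n_older=1 if has else 0, n_younger=0,
            gap_closest_older=g, gap_category=None, n_older_category=None,
            sex_closest_older=None, burden=0.0))
    return out


class TestScoreGapCurve:
    def test_constant_scores_constant_curve(self, rng):
        gaps = list(rng.uniform(0.8, 9, 30)) + [None] * 10
        exp = exposures_for(gaps)
        scores = pd.Series(0.6, index=[e.child_id for e in exp])
        curve = score_gap_curve(scores, exp)
        np.testing.assert_allclose(curve.curve["fitted"], 0.6, atol=1e-9)
        assert curve.reference_mean == pytest.approx(0.6)

    def test_needs_enough_children(self):
        exp = exposures_for([2.0] * 5)
        scores = pd.Series(0.5, index=[e.child_id for e in exp])
        with pytest.raises(ValueError):
            score_gap_curve(scores, exp)

    def test_sigmoid_shape_recovered_from_noisy_scores(self, rng):
        gaps = rng.uniform(0.8, 10, 300)
        e = 1 / (1 + np.exp((gaps - 5.0)))
        scores = np.clip(0.35 + 0.4 * e + rng.normal(0, 0.08, 300), 0, 1)
        exp = exposures_for(list(gaps))
        s = pd.Series(scores, index=[x.child_id for x in exp])
        curve = score_gap_curve(s, exp)
        assert curve.fitted_at(2.0) > curve.fitted_at(8.0) + 0.2
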