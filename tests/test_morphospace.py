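import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from lycaeides.errors import DegenerateInputError, InvalidInputError
from lycaeides.morphospace import (
    BivariateFit,
    TrialTable,
    direction_sign_test,
    fit_bivariate,
    kl_divergence,
    kl_permutation_test,
    pca_scores,
    procrustes_fit,
)


def _rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestProcrustes:
    def test_similarity_transform_is_removed(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(10, 2))
        copy = 2.5 * base @ _rot(0.7).T + np.array([3.0, -1.0])
        aligned = procrustes_fit([base, copy])
        assert np.allclose(aligned[0], aligned[1], atol=1e-8)

    def test_outputs_centered_and_unit_size(self):
        rng = np.random.default_rng(1)
        aligned = procrustes_fit([rng.normal(size=(8, 2)) for _ in range(4)])
        for cfg in aligned:
            assert np.allclose(cfg.mean(axis=0), 0.0, atol=1e-10)
            assert np.sqrt((cfg**2).sum()) == pytest.approx(1.0, abs=1e-10)

    def test_two_config_rotation_matches_svd_solution(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(7, 2))
        b = rng.normal(size=(7, 2))
        aligned = procrustes_fit([a, b])
        # independent closed form: optimal orthogonal map between the
        # pre-processed configurations via SVD of the cross-product
        def prep(x):
            x = x - x.mean(axis=0)
            return x / np.sqrt((x**2).sum())
        A, B = prep(a), prep(b)
        # align B onto A
        U, _, Vt = np.linalg.svd(B.T @ A)
        R = U @ Vt
        d1 = ((aligned[0] - aligned[1]) ** 2).sum()
        d2 = ((A - B @ R) ** 2).sum()
        assert d1 == pytest.approx(d2, rel=1e-6)

    def test_missing_characters_rejected(self):
        a = np.zeros((5, 2))
        b = a.copy()
        b[2, 0] = np.nan
        with pytest.raises(InvalidInputError, match="drop"):
            procrustes_fit([a + np.arange(10).reshape(5, 2), b])

    def test_fewer_than_two_configs_rejected(self):
        with pytest.raises(InvalidInputError):
            procrustes_fit([np.zeros((5, 2))])


class TestPCA:
    def test_collinear_points_put_all_variance_on_pc1(self):
        t = np.linspace(0, 1, 9)
        X = np.column_stack([t, 2 * t])
        res = pca_scores(X, n_components=1)
        assert res.proportion[0] == pytest.approx(1.0)

    def test_scores_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 6)) @ rng.normal(size=(6, 6))
        res = pca_scores(X)
        C = np.cov(X, rowvar=False)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        Xc = X - X.mean(axis=0)
        for k in range(res.scores.shape[1]):
            v = evecs[:, k]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            assert np.allclose(res.scores[:, k], Xc @ v, atol=1e-8)
            assert res.proportion[k] == pytest.approx(evals[k] / evals.sum(), abs=1e-10)

    def test_variance_proportions_sum_to_one_at_full_rank(self):
        rng = np.random.default_rng(6)
        res = pca_scores(rng.normal(size=(20, 4)))
        assert res.proportion.sum() == pytest.approx(1.0, abs=1e-10)

    def test_constant_matrix_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pca_scores(np.ones((5, 3)))


class TestBivariateFit:
    def test_mean_is_centroid_for_unit_weights(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        fit = fit_bivariate(pts)
        assert np.allclose(fit.mean, pts.mean(axis=0))

    def test_doubling_multiplicities_changes_nothing(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(6, 2))
        w = np.array([1.0, 2, 1, 3, 1, 2])
        f1 = fit_bivariate(pts, w)
        f2 = fit_bivariate(pts, 2 * w)
        assert np.allclose(f1.mean, f2.mean)
        assert np.allclose(f1.cov, f2.cov)

    def test_cov_matches_direct_summation_oracle(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1], [2, 2], [1, 3]])
        w = np.array([1.0, 2, 1, 1, 3])
        fit = fit_bivariate(pts, w)
        mu = np.zeros(2)
        for p, wi in zip(pts, w):
            mu += wi * p
        mu /= w.sum()
        cov = np.zeros((2, 2))
        for p, wi in zip(pts, w):
            cov += wi * np.outer(p - mu, p - mu)
        cov /= w.sum()
        assert np.allclose(fit.mean, mu, atol=1e-12)
        assert np.allclose(fit.cov, cov, atol=1e-12)

    def test_fewer_than_three_distinct_points_degenerate(self):
        with pytest.raises(DegenerateInputError):
            fit_bivariate(np.array([[0.0, 0], [1, 1], [0, 0]]))


class TestKLDivergence:
    def test_identical_fits_give_zero(self):
        f = BivariateFit(mean=[0.3, -0.2], cov=[[2.0, 0.5], [0.5, 1.0]], n_obs=10)
        assert kl_divergence(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_unit_covariances_mean_shift(self):
        a = BivariateFit(mean=[1.0, 0.0], cov=np.eye(2), n_obs=5)
        p = BivariateFit(mean=[0.0, 0.0], cov=np.eye(2), n_obs=5)
        assert kl_divergence(a, p) == pytest.approx(0.5)

    def test_matches_monte_carlo_integration_oracle(self):
        a = BivariateFit(mean=[1.0, 0.0], cov=np.diag([2.0, 1.0]), n_obs=5)
        p = BivariateFit(mean=[0.0, 0.0], cov=np.eye(2), n_obs=5)
        rng = np.random.default_rng(11)
        x = rng.multivariate_normal(a.mean, a.cov, size=1_000_000)
        mc = np.mean(
            multivariate_normal.logpdf(x, a.mean, a.cov)
            - multivariate_normal.logpdf(x, p.mean, p.cov)
        )
        assert kl_divergence(a, p) == pytest.approx(mc, rel=0.01)

    def test_invariant_under_common_affine_map(self):
        rng = np.random.default_rng(12)
        A = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        shift = rng.normal(size=2)
        fa = BivariateFit(mean=[0.5, 0.1], cov=[[1.5, 0.3], [0.3, 0.8]], n_obs=9)
        fp = BivariateFit(mean=[0.0, 0.0], cov=[[1.0, -0.2], [-0.2, 2.0]], n_obs=9)
        fa2 = BivariateFit(mean=A @ fa.mean + shift, cov=A @ fa.cov @ A.T, n_obs=9)
        fp2 = BivariateFit(mean=A @ fp.mean + shift, cov=A @ fp.cov @ A.T, n_obs=9)
        assert kl_divergence(fa2, fp2) == pytest.approx(kl_divergence(fa, fp), rel=1e-9)


class TestKLPermutationTest:
    @staticmethod
    def _two_trial_fixture():
        scores = {
            "A": (0.0, 0.0), "B": (1.0, 0.2), "C": (0.1, 1.0),
            "D": (2.0, 1.5), "E": (-1.0, 0.5), "F": (0.5, -1.0),
        }
        trials = TrialTable(
            trial_ids=["t1", "t2"],
            presented=[("A", "B", "C"), ("D", "E", "F")],
            approaches=[["B"], ["E"]],
        )
        return trials, scores

    def test_exhaustive_mode_matches_nine_outcome_enumeration(self):
        trials, scores = self._two_trial_fixture()
        res = kl_permutation_test(trials, scores, exhaustive=True)
        assert res.mode == "exhaustive"
        assert res.n_reps == 9
        # independent enumeration: mean-shift statistic against the
        # presented fit (2-point approached sets are covariance-degenerate)
        pres = np.array([scores[m] for t in trials.presented for m in t])
        mu_p = pres.mean(axis=0)
        dp = pres - mu_p
        cov_p = dp.T @ dp / len(pres)
        inv_p = np.linalg.inv(cov_p)
        stats = []
        for b1, b2 in itertools.product(range(3), repeat=2):
            pts = np.array([scores[trials.presented[0][b1]],
                            scores[trials.presented[1][b2]]])
            d = mu_p - pts.mean(axis=0)
            stats.append(0.5 * d @ inv_p @ d)
        stats = np.sort(stats)
        assert np.allclose(np.sort(res.null_samples), stats, atol=1e-12)
        assert res.p_value == pytest.approx(np.mean(stats >= res.d_kl - 1e-12))

    def test_sampled_p_converges_to_enumeration(self):
        trials, scores = self._two_trial_fixture()
        exact = kl_permutation_test(trials, scores, exhaustive=True)
        sampled = kl_permutation_test(trials, scores, n_reps=4000, seed=5)
        assert sampled.p_value == pytest.approx(exact.p_value, abs=0.03)

    def test_strong_preference_detected(self):
        rng = np.random.default_rng(21)
        ids = [f"m{i}" for i in range(15)]
        pts = rng.normal(size=(15, 2))
        scores = dict(zip(ids, map(tuple, pts)))
        pc1 = {m: scores[m][0] for m in ids}
        trial_ids, presented, approaches = [], [], []
        for t in range(50):
            pick = rng.choice(15, size=3, replace=False)
            pres = tuple(ids[i] for i in pick)
            best = max(pres, key=lambda m: pc1[m])  # always the extreme model
            trial_ids.append(str(t))
            presented.append(pres)
            approaches.append([best])
        trials = TrialTable(trial_ids, presented, approaches)
        res = kl_permutation_test(trials, scores, n_reps=500, seed=2)
        assert res.p_value <= 0.05

    def test_unscored_model_rejected(self):
        trials, scores = self._two_trial_fixture()
        del scores["F"]
        with pytest.raises(InvalidInputError, match="unscored"):
            kl_permutation_test(trials, scores, n_reps=10, seed=0)


class TestDirectionSignTest:
    @pytest.mark.parametrize(
        "agree,total,expected",
        [(6, 6, 0.015625), (0, 1, 1.0), (5, 6, 7 / 64)],
    )
    def test_exact_binomial_tail(self, agree, total, expected):
        assert direction_sign_test(agree, total) == pytest.approx(expected, abs=1e-12)

    def test_zero_trials_rejected(self):
        with pytest.raises(InvalidInputError):
            direction_sign_test(0, 0)
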