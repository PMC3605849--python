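"""Wing-pattern morphospace analysis.

Tools for the model-presentation mate-preference assay: generalized
Procrustes superimposition of wing-character centroids, PCA of character
areas or aligned positions, bivariate-normal fits of the morphospace
occupied by presented versus approached wing models, the closed-form
Gaussian Kullback-Leibler divergence between those fits, and a
trial-resampling permutation null for it. A one-tailed binomial sign test
covers the across-population direction-of-shift comparison.

The KL direction is the approached distribution relative to the presented
one (presented = reference measure); it is recorded in results and
configurable. Each approach event is one observation; each model contributes
one presented observation per trial in which it appears.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.stats import binom

from .errors import DegenerateInputError, InvalidInputError

__all__ = [
    "TrialTable",
    "BivariateFit",
    "KLResult",
    "PCAResult",
    "procrustes_fit",
    "pca_scores",
    "fit_bivariate",
    "kl_divergence",
    "kl_permutation_test",
    "direction_sign_test",
]


@dataclass
class TrialTable:
    """Presentation trials: three distinct wing models shown, a multiset of
    approach events among them."""

    trial_ids: list
    presented: list[tuple]  # 3 distinct model ids per trial
    approaches: list[list]  # model ids approached in each trial

    def __post_init__(self) -> None:
        if not (len(self.trial_ids) == len(self.presented) == len(self.approaches)):
            raise InvalidInputError("trial table columns have unequal lengths")
        for t, pres, app in zip(self.trial_ids, self.presented, self.approaches):
            if len(pres) != 3 or len(set(pres)) != 3:
                raise InvalidInputError(f"trial {t!r}: need 3 distinct presented models")
            if any(a not in pres for a in app):
                raise InvalidInputError(f"trial {t!r}: approach to a model not presented")

    @property
    def n_trials(self) -> int:
        return len(self.trial_ids)


@dataclass
class BivariateFit:
    """Frequency-weighted ML bivariate-normal fit of morphospace scores."""

    mean: np.ndarray  # (2,)
    cov: np.ndarray  # (2, 2) symmetric positive definite
    n_obs: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mean.shape != (2,) or self.cov.shape != (2, 2):
            raise InvalidInputError("BivariateFit is strictly two-dimensional")
        if not np.allclose(self.cov, self.cov.T, atol=1e-12):
            raise InvalidInputError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.cov) <= 0):
            raise DegenerateInputError("covariance must be positive definite")


@dataclass
class KLResult:
    d_kl: float
    null_samples: np.ndarray
    p_value: float
    n_reps: int
    mode: str  # "sampled" | "exhaustive"
    direction: str = "approached_vs_presented"
    seed: int | None = None


@dataclass
class PCAResult:
    scores: np.ndarray  # (n_obs, n_components)
    proportion: np.ndarray  # variance proportions per component
    components: np.ndarray  # (n_components, n_vars) loadings
    mean: np.ndarray = field(default=None)


def procrustes_fit(configs: list[np.ndarray], tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Generalized Procrustes superimposition of landmark configurations.

    Each configuration is translated to zero centroid, scaled to unit
    centroid size, and iteratively rotated to the evolving mean shape until
    the mean shape changes by less than ``tol``. Characters missing in any
    configuration must be dropped from all configurations beforehand.

    Returns the aligned coordinates, shape (n_configs, n_landmarks, 2).
    """
    if len(configs) < 2:
        raise InvalidInputError("need at least two configurations")
    arrs = [np.asarray(c, dtype=float) for c in configs]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs) or shape[1] != 2:
        raise InvalidInputError("configurations must share one (n_landmarks, 2) shape")
    if any(np.any(~np.isfinite(a)) for a in arrs):
        raise InvalidInputError(
            "missing characters detected; drop them from all configurations "
            "before the Procrustes fit"
        )
    X = np.stack(arrs)
    X -= X.mean(axis=1, keepdims=True)
    size = np.sqrt((X**2).sum(axis=(1, 2), keepdims=True))
    if np.any(size == 0):
        raise InvalidInputError("a configuration has zero centroid size")
    X /= size

    mean = X[0].copy()
    for _ in range(max_iter):
        for i in range(X.shape[0]):
            R, _ = orthogonal_procrustes(X[i], mean)
            X[i] = X[i] @ R
        new_mean = X.mean(axis=0)
        new_mean /= np.sqrt((new_mean**2).sum())
        if np.sqrt(((new_mean - mean) ** 2).sum()) < tol:
            mean = new_mean
            break
        mean = new_mean
    return X


def pca_scores(features: np.ndarray, n_components: int | None = None,
               correlation: bool = False) -> PCAResult:
    """Principal components of an observation-by-variable matrix.

    Covariance-based by default (the wing-character areas share units);
    ``correlation=True`` standardizes columns first. Components are ordered
    by decreasing variance, and each component's sign is fixed so its
    largest-magnitude loading is positive.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise InvalidInputError("need >= 2 observations and >= 1 variable")
    mean = X.mean(axis=0)
    Xc = X - mean
    if correlation:
        sd = Xc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise DegenerateInputError("constant column under correlation PCA")
        Xc = Xc / sd
    total_var = np.sum(Xc.var(axis=0, ddof=1))
    if total_var == 0:
        raise DegenerateInputError("constant feature matrix")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12))
    k = rank if n_components is None else int(n_components)
    if k < 1 or k > rank:
        raise InvalidInputError(f"n_components must lie in [1, rank={rank}]")
    # sign convention: largest-magnitude loading positive
    for c in range(k):
        idx = np.argmax(np.abs(Vt[c]))
        if Vt[c, idx] < 0:
            Vt[c] = -Vt[c]
            U[:, c] = -U[:, c]
    var = S**2 / (X.shape[0] - 1)
    return PCAResult(
        scores=U[:, :k] * S[:k],
        proportion=var[:k] / total_var,
        components=Vt[:k],
        mean=mean,
    )


def fit_bivariate(points: np.ndarray, weights: np.ndarray | None = None) -> BivariateFit:
    """Weighted maximum-likelihood bivariate-normal fit.

    ``weights`` are observation multiplicities; the covariance divides by the
    total weight (ML, not the unbiased n-1 form), so the fitted object is a
    probability model. Requires >= 3 distinct points.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    w = np.ones(len(pts)) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (len(pts),) or np.any(w < 0) or w.sum() <= 0:
        raise InvalidInputError("weights must be non-negative with positive sum")
    if len(np.unique(pts[w > 0], axis=0)) < 3:
        raise DegenerateInputError("need >= 3 distinct points for a full-rank covariance")
    wt = w / w.sum()
    mean = wt @ pts
    d = pts - mean
    cov = (d * wt[:, None]).T @ d
    if np.any(np.linalg.eigvalsh(cov) <= 1e-300):
        raise DegenerateInputError("singular covariance (collinear points)")
    return BivariateFit(mean=mean, cov=cov, n_obs=int(round(w.sum())))


def kl_divergence(fit_a: BivariateFit, fit_p: BivariateFit) -> float:
    """Closed-form Gaussian KL divergence of the approached distribution
    relative to the presented one:

        D_KL = 1/2 [ tr(S_p^-1 S_a) + (m_p - m_a)' S_p^-1 (m_p - m_a)
                     - 2 + ln(det S_p / det S_a) ]
    """
    return _kl_gauss(fit_a.mean, fit_a.cov, fit_p.mean, fit_p.cov)


def _kl_gauss(mu_a, cov_a, mu_p, cov_p) -> float:
    sign_p, logdet_p = np.linalg.slogdet(cov_p)
    sign_a, logdet_a = np.linalg.slogdet(cov_a)
    if sign_p <= 0 or sign_a <= 0:
        raise InvalidInputError("covariances must be positive definite")
    inv_p = np.linalg.inv(cov_p)
    diff = mu_p - mu_a
    val = 0.5 * (np.trace(inv_p @ cov_a) + diff @ inv_p @ diff - 2.0 + logdet_p - logdet_a)
    return float(max(val, 0.0))


def _kl_statistic(app_pts, app_w, fit_p: BivariateFit) -> float:
    """Test statistic for the permutation null.

    Ordinarily the full Gaussian KL of the approached fit against the
    presented fit. When the approached covariance is singular (fewer than 3
    distinct points, or collinear), the statistic degrades to its mean-shift
    term with the approached covariance replaced by the presented one
    (0.5 * dmu' S_p^-1 dmu) — applied identically to observed data and null
    replicates so the test remains exact.
    """
    wt = app_w / app_w.sum()
    mean = wt @ app_pts
    d = app_pts - mean
    cov = (d * wt[:, None]).T @ d
    eig = np.linalg.eigvalsh(cov)
    if eig[0] <= 1e-12 * max(eig[-1], 1.0):
        diff = fit_p.mean - mean
        inv_p = np.linalg.inv(fit_p.cov)
        return float(max(0.5 * diff @ inv_p @ diff, 0.0))
    return _kl_gauss(mean, cov, fit_p.mean, fit_p.cov)


def _collapse(points_list: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(points_list, dtype=float).reshape(-1, 2)
    uniq, inv, cnt = np.unique(pts, axis=0, return_inverse=True, return_counts=True)
    return uniq, cnt.astype(float)


def kl_permutation_test(
    trials: TrialTable,
    scores: dict,
    n_reps: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
) -> KLResult:
    """Trial-resampling permutation test for morphospace preference.

    The observed statistic is the Gaussian KL divergence between the
    approached and presented morphospace fits. The null replaces each
    trial's approaches with an equal number of uniform draws from that
    trial's three presented models; ``exhaustive=True`` enumerates every
    possible assignment instead (only feasible for small designs). Sampled
    p-values use the add-one rule p = (1 + #{null >= obs}) / (1 + n_reps);
    exhaustive p-values are exact outcome fractions.
    """
    if trials.n_trials < 1:
        raise InvalidInputError("no trials")
    if not exhaustive and n_reps < 1:
        raise InvalidInputError("n_reps must be >= 1")
    missing = {m for pres in trials.presented for m in pres if m not in scores}
    if missing:
        raise InvalidInputError(f"unscored models: {sorted(missing)}")

    pres_pts = np.array(
        [scores[m] for pres in trials.presented for m in pres], dtype=float
    )
    app_ids = [a for app in trials.approaches for a in app]
    if not app_ids:
        raise DegenerateInputError("no approach events")
    app_pts = np.array([scores[m] for m in app_ids], dtype=float)

    u_pres, w_pres = _collapse(pres_pts)
    fit_p = fit_bivariate(u_pres, w_pres)
    observed = _kl_statistic(app_pts, np.ones(len(app_pts)), fit_p)

    trial_opts = [np.array([scores[m] for m in pres]) for pres in trials.presented]
    n_app = [len(app) for app in trials.approaches]

    if exhaustive:
        per_trial = [
            list(itertools.product(range(3), repeat=k)) for k in n_app
        ]
        total = int(np.prod([len(c) for c in per_trial]))
        if total > 200_000:
            raise InvalidInputError(
                f"exhaustive enumeration would need {total} outcomes; use sampling"
            )
        null = np.empty(total)
        for i, combo in enumerate(itertools.product(*per_trial)):
            pts = np.concatenate(
                [trial_opts[t][list(ch)] for t, ch in enumerate(combo) if ch]
            )
            null[i] = _kl_statistic(pts, np.ones(len(pts)), fit_p)
        p = float(np.mean(null >= observed - 1e-12))
        return KLResult(d_kl=observed, null_samples=null, p_value=max(p, 1.0 / total),
                        n_reps=total, mode="exhaustive", seed=None)

    rng = np.random.default_rng(seed)
    null = np.empty(n_reps)
    tot_app = sum(n_app)
    for r in range(n_reps):
        pts = np.empty((tot_app, 2))
        pos = 0
        for t, k in enumerate(n_app):
            if k:
                pts[pos:pos + k] = trial_opts[t][rng.integers(0, 3, size=k)]
                pos += k
        null[r] = _kl_statistic(pts, np.ones(tot_app), fit_p)
    p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_reps)
    return KLResult(d_kl=observed, null_samples=null, p_value=p,
                    n_reps=n_reps, mode="sampled", seed=seed)


def direction_sign_test(n_agree: int, n_total: int) -> float:
    """One-tailed sign test: P(X >= n_agree) for X ~ Binomial(n_total, 1/2).

    Used for "did the morphospace shift go the expected way in k of n
    populations" — e.g. agreement in all 6 of 6 populations gives
    p = 0.5^6 = 0.015625.
    """
    if n_total < 1:
        raise InvalidInputError("n_total must be >= 1")
    if not 0 <= n_agree <= n_total:
        raise InvalidInputError("need 0 <= n_agree <= n_total")
    return float(binom.sf(n_agree - 1, n_total, 0.5))
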