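"""Calibration and cross-validation studies.

Each function here runs a self-contained study of one statistical property
of the package — sampler-vs-quadrature agreement, interval calibration, DIC
direction, closed-form-vs-Monte-Carlo KL agreement, permutation-test
uniformity, Mantel/MRM error rates, GLM parameter recovery, and convergence
diagnostics — on synthetic data with known truth, and returns the measured
quantities as plain numbers. The studies double as the package's acceptance
checks and as reproducible evidence for the methods note.

Problem sizes are package choices balancing Monte-Carlo precision against a
single-CPU run of a few minutes per study; every study is deterministic
given its seed.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import kstest, multivariate_normal

from .diagnostics import gelman_rubin, summarize
from .diapause_model import fit_diapause_glm
from .distance_analysis import mantel, partial_mantel, mrm
from .morphospace import BivariateFit, direction_sign_test, kl_divergence, kl_permutation_test
from .preference_model import (
    dic,
    fit_preference,
    fit_preference_constrained,
    quadrature_posterior_mean_binary,
)
from .synthetic_data import (
    gen_distance_system,
    gen_egg_counts,
    gen_hatch_data,
    gen_wing_trials,
)

__all__ = [
    "sign_test_exact",
    "quadrature_agreement",
    "coverage_calibration",
    "dic_direction",
    "kl_closed_form_agreement",
    "kl_null_calibration",
    "kl_exhaustive_agreement",
    "mantel_type1_error",
    "mantel_exhaustive_agreement",
    "mrm_exactness",
    "glm_recovery",
    "psrf_standard_fits",
]

# two-category fixtures (counts per female) for the quadrature cross-check
_QUAD_FIXTURES = (
    (np.array([[8, 2], [7, 3], [9, 1]]), 20.0),
    (np.array([[5, 5], [6, 4], [4, 6], [5, 5]]), 5.0),
    (np.array([[15, 1], [12, 4], [18, 0], [9, 3]]), 50.0),
)


def sign_test_exact() -> float:
    """The across-population direction test: all six populations shifting the
    expected way under a fair coin, P(X >= 6 | n = 6, p = 1/2)."""
    return direction_sign_test(6, 6)


def quadrature_agreement(seed: int = 0, n_iter: int = 8000, burn_in: int = 1500) -> dict:
    """MCMC posterior mean of pi_1 vs deterministic numerical integration on
    three fixed two-category datasets with the concentration pinned."""
    diffs = []
    from .preference_model import EggCountTable

    for k, (counts, w) in enumerate(_QUAD_FIXTURES):
        table = EggCountTable(
            f"fixture{k}", [f"f{i}" for i in range(counts.shape[0])],
            counts, ["plant_a", "plant_b"],
        )
        post = fit_preference(table, n_chains=2, n_iter=n_iter, burn_in=burn_in,
                              seed=seed + k, fixed_w=w)
        mc = float(post.pooled_pi()[:, 0].mean())
        oracle = quadrature_posterior_mean_binary(counts, w)
        diffs.append(abs(mc - oracle))
    return {"max_abs_diff": float(max(diffs)), "diffs": diffs}


def coverage_calibration(
    seed: int = 0,
    n_datasets: int = 200,
    n_females: int = 10,
    egg_mean: float = 20.0,
    w_max: float = 1e4,
    n_iter: int = 4000,
    burn_in: int = 800,
) -> dict:
    """Frequency with which 95% equal-tailed intervals for pi_1 cover the
    truth over synthetic two-plant experiments.

    Truths are drawn from the fitting prior (pi ~ Dirichlet(1,1),
    w ~ Uniform(0, w_max)), so a correct sampler covers at 0.95 in
    expectation regardless of sample size.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_datasets):
        pi1 = float(rng.uniform(1e-3, 1 - 1e-3))
        w = float(max(rng.uniform(0.0, w_max), 1e-2))
        table, _ = gen_egg_counts(np.array([pi1, 1 - pi1]), w, n_females,
                                  egg_mean, seed=int(rng.integers(2**31 - 1)))
        post = fit_preference(table, n_chains=1, n_iter=n_iter, burn_in=burn_in,
                              seed=int(rng.integers(2**31 - 1)), w_max=w_max)
        _, lo, hi = summarize(post.pooled_pi()[:, 0])
        hits += lo <= pi1 <= hi
    return {"coverage": hits / n_datasets, "n_datasets": n_datasets}


def dic_direction(
    seed: int = 0,
    n_reps: int = 50,
    n_females: int = 20,
    egg_mean: float = 20.0,
    w_true: float = 10.0,
    n_iter: int = 20_000,
    burn_in: int = 3000,
) -> dict:
    """DIC model-comparison direction on data with and without a population
    preference: with uniform pi the constrained model should usually win;
    with pi = (0.9, 0.1) the full model should earn considerable support
    (delta <= -7)."""
    rng = np.random.default_rng(seed)
    d_unif, d_skew = [], []
    for rep in range(n_reps):
        for pi_true, store in ((np.array([0.5, 0.5]), d_unif),
                               (np.array([0.9, 0.1]), d_skew)):
            table, _ = gen_egg_counts(pi_true, w_true, n_females, egg_mean,
                                      seed=int(rng.integers(2**31 - 1)))
            s = int(rng.integers(2**31 - 1))
            full = fit_preference(table, n_chains=2, n_iter=n_iter,
                                  burn_in=burn_in, seed=s)
            con = fit_preference_constrained(table, n_chains=2, n_iter=n_iter,
                                             burn_in=burn_in, seed=s + 1)
            store.append(dic(full, table) - dic(con, table))
    d_unif, d_skew = np.array(d_unif), np.array(d_skew)
    return {
        "uniform_constrained_rate": float(np.mean(d_unif > 0)),
        "skewed_considerable_rate": float(np.mean(d_skew <= -7)),
        "uniform_median_delta": float(np.median(d_unif)),
        "skewed_median_delta": float(np.median(d_skew)),
        "n_reps": n_reps,
    }


def kl_closed_form_agreement(seed: int = 0, n_draws: int = 1_000_000) -> dict:
    """Closed-form Gaussian KL vs a Monte-Carlo integration oracle (sample
    from the approached density, average the log-density ratio) on three
    fixture pairs, plus the identical-fit identity."""
    fixtures = [
        (BivariateFit([1.0, 0.0], np.diag([2.0, 1.0]), 5),
         BivariateFit([0.0, 0.0], np.eye(2), 5)),
        (BivariateFit([0.3, -0.5], [[1.0, 0.4], [0.4, 0.8]], 7),
         BivariateFit([0.0, 0.2], [[1.5, -0.2], [-0.2, 1.2]], 7)),
        (BivariateFit([-1.0, 1.0], [[0.6, 0.1], [0.1, 0.5]], 9),
         BivariateFit([0.0, 0.0], [[2.0, 0.9], [0.9, 1.1]], 9)),
    ]
    rng = np.random.default_rng(seed)
    rel_errs = []
    for fa, fp in fixtures:
        closed = kl_divergence(fa, fp)
        x = rng.multivariate_normal(fa.mean, fa.cov, size=n_draws)
        mc = float(np.mean(
            multivariate_normal.logpdf(x, fa.mean, fa.cov)
            - multivariate_normal.logpdf(x, fp.mean, fp.cov)))
        rel_errs.append(abs(closed - mc) / abs(mc))
    same = BivariateFit([0.2, 0.2], [[1.0, 0.3], [0.3, 0.9]], 6)
    return {
        "max_rel_err": float(max(rel_errs)),
        "identical_fit_kl": kl_divergence(same, same),
    }


def kl_null_calibration(
    seed: int = 0,
    n_datasets: int = 500,
    n_trials: int = 30,
    n_reps: int = 199,
) -> dict:
    """Uniformity of the KL permutation p-value when approaches really are
    uniform among the three presented models (KS test against U(0,1))."""
    rng = np.random.default_rng(seed)
    pvals = []
    for i in range(n_datasets):
        scores, trials, _ = gen_wing_trials(
            n_trials, model_pool_size=21, gamma=(0.0, 0.0),
            seed=int(rng.integers(2**31 - 1)))
        res = kl_permutation_test(trials, scores, n_reps=n_reps,
                                  seed=int(rng.integers(2**31 - 1)))
        pvals.append(res.p_value)
    return {"ks_p": float(kstest(pvals, "uniform").pvalue),
            "n_datasets": n_datasets}


def kl_exhaustive_agreement() -> dict:
    """Exhaustive permutation null on a two-trial fixture vs its independent
    9-outcome enumeration (mean-shift statistic; two approached points leave
    the covariance degenerate)."""
    from .morphospace import TrialTable

    scores = {"A": (0.0, 0.0), "B": (1.0, 0.2), "C": (0.1, 1.0),
              "D": (2.0, 1.5), "E": (-1.0, 0.5), "F": (0.5, -1.0)}
    trials = TrialTable(["t1", "t2"], [("A", "B", "C"), ("D", "E", "F")],
                        [["B"], ["E"]])
    res = kl_permutation_test(trials, scores, exhaustive=True)
    pres = np.array([scores[m] for t in trials.presented for m in t])
    mu = pres.mean(axis=0)
    d = pres - mu
    inv = np.linalg.inv(d.T @ d / len(pres))
    oracle = []
    import itertools

    for b1, b2 in itertools.product(range(3), repeat=2):
        pts = np.array([scores[trials.presented[0][b1]],
                        scores[trials.presented[1][b2]]])
        dd = mu - pts.mean(axis=0)
        oracle.append(0.5 * dd @ inv @ dd)
    diff = np.max(np.abs(np.sort(res.null_samples) - np.sort(oracle)))
    return {"max_abs_diff": float(diff), "n_outcomes": res.n_reps,
            "p_value": res.p_value}


def mantel_type1_error(
    seed: int = 0,
    n_reps: int = 1000,
    n_pops: int = 10,
    n_perm: int = 199,
    alpha: float = 0.05,
) -> dict:
    """Rejection rates of Mantel and partial Mantel at nominal 0.05 when the
    genetic matrix is independent noise (no geographic or phenotypic
    signal)."""
    rng = np.random.default_rng(seed)
    rej_m = rej_pm = 0
    for i in range(n_reps):
        sys_ = gen_distance_system(n_pops=n_pops, b_geo=0.0, b_pheno=0.0,
                                   noise_sd=0.05,
                                   seed=int(rng.integers(2**31 - 1)))
        s = int(rng.integers(2**31 - 1))
        rej_m += mantel(sys_.genetic, sys_.geographic,
                        n_perm=n_perm, seed=s).p <= alpha
        rej_pm += partial_mantel(sys_.genetic, sys_.phenotypic["trait_1"],
                                 sys_.geographic, n_perm=n_perm,
                                 seed=s + 1).p <= alpha
    return {"mantel_rate": rej_m / n_reps, "partial_mantel_rate": rej_pm / n_reps,
            "n_reps": n_reps}


def mantel_exhaustive_agreement(seed: int = 0) -> dict:
    """Sampled-mode Mantel p at large permutation count vs the exact
    24-permutation enumeration on a 4-population fixture."""
    rng = np.random.default_rng(seed)
    from .distance_analysis import DistanceMatrix

    def rand_dm():
        pts = rng.normal(size=(4, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        return DistanceMatrix(labels=list("abcd"), values=d)

    A, B = rand_dm(), rand_dm()
    ex = mantel(A, B, exhaustive=True)
    sam = mantel(A, B, n_perm=50_000, seed=seed)
    return {"abs_diff": abs(sam.p - ex.p), "exhaustive_p": ex.p,
            "sampled_p": sam.p}


def mrm_exactness(seed: int = 0) -> dict:
    """Zero-noise linear distance system: MRM must recover the construction
    exactly (R^2 = 1, coefficients equal to the generating values)."""
    b0, b_geo, b_ph = 0.05, 2e-4, 0.3
    sys_ = gen_distance_system(n_pops=8, b0=b0, b_geo=b_geo, b_pheno=b_ph,
                               noise_sd=0.0, seed=seed)
    res = mrm(sys_.genetic, [sys_.geographic, sys_.phenotypic["trait_1"]],
              n_perm=99, seed=seed, names=["geo", "ph"])
    coef_err = max(abs(res.coefficients["intercept"] - b0),
                   abs(res.coefficients["geo"] - b_geo),
                   abs(res.coefficients["ph"] - b_ph))
    return {"r_squared": res.r_squared, "max_coef_error": float(coef_err)}


def glm_recovery(
    seed: int = 0,
    n_reps: int = 100,
    n_females_per_cell: int = 15,
    n_iter: int = 4000,
    burn_in: int = 1500,
) -> dict:
    """Parameter recovery for the hatch GLM: frequency with which 95%
    intervals cover each generating treatment effect, and the exactness of
    the sum-to-zero location constraint in every draw."""
    alpha_true = {"DIA": -2.0, "DA11": 1.0, "DM11": 0.0, "DJ11": -1.0}
    beta_true = {t: 0.3 for t in alpha_true}
    tau_true = {t: 4.0 for t in alpha_true}
    rng = np.random.default_rng(seed)
    cover = np.zeros(4)
    sum_zero = True
    for rep in range(n_reps):
        table, _ = gen_hatch_data(alpha_true, beta_true, tau_true,
                                  n_females_per_cell, eggs_per_female=10,
                                  seed=int(rng.integers(2**31 - 1)))
        post = fit_diapause_glm(table, n_chains=1, n_iter=n_iter,
                                burn_in=burn_in,
                                seed=int(rng.integers(2**31 - 1)))
        a = post.pooled("alpha")
        for k, t in enumerate(post.treatments):
            _, lo, hi = summarize(a[:, k])
            cover[k] += lo <= alpha_true[t] <= hi
        sum_zero &= bool(np.all(post.beta_samples.sum(axis=-1) == 0.0))
    return {"min_alpha_coverage": float(cover.min() / n_reps),
            "alpha_coverage": (cover / n_reps).tolist(),
            "sum_to_zero_exact": sum_zero, "n_reps": n_reps}


def psrf_standard_fits(seed: int = 0) -> dict:
    """Gelman-Rubin PSRF on standard multi-chain synthetic fits (should sit
    below 1.1 everywhere), plus the identical-chain identity PSRF <= 1."""
    table, _ = gen_egg_counts(np.array([0.7, 0.3]), 10.0, 20, 20.0, seed=seed)
    post = fit_preference(table, n_chains=2, n_iter=10_000, burn_in=2000,
                          seed=seed)
    psrfs = [gelman_rubin(post.pi_samples[..., j]) for j in range(2)]
    psrfs.append(gelman_rubin(np.log(post.w_samples)))

    alpha = {"DIA": -1.0, "DA11": 1.0, "DM11": 0.0, "DJ11": -0.5}
    htable, _ = gen_hatch_data(alpha, {t: 0.3 for t in alpha},
                               {t: 4.0 for t in alpha}, 12, seed=seed + 1)
    gpost = fit_diapause_glm(htable, n_chains=2, n_iter=6000, burn_in=2000,
                             seed=seed + 1)
    for k in range(4):
        psrfs.append(gelman_rubin(gpost.alpha_samples[..., k]))

    chain = post.pi_samples[0, :, 0]
    identical = gelman_rubin(np.stack([chain, chain]))
    return {"max_psrf": float(np.max(psrfs)), "identical_chain_psrf": identical}
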