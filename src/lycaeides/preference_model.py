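"""Hierarchical Bayesian multinomial preference model.

The model treats the eggs a female lays (or the approaches a male makes) as a
multinomial draw governed by an individual-level preference simplex, with the
individual simplexes tied together by a population-level Dirichlet:

    x_i | p_i      ~ Multinomial(p_i, n_i)
    p_i | pi, w    ~ Dirichlet(w * pi)
    pi             ~ Dirichlet(1, ..., 1)
    w              ~ Uniform(0, w_max]

``pi`` is the population-level preference (the mean of the individual
simplexes) and ``w`` a concentration: lower values of ``w`` correspond to
increased interindividual variation. The Dirichlet shape vector is ``w * pi``
— the concentration is only interpretable relative to this parameterization.

Posterior sampling is a collapsed Metropolis-within-Gibbs. The individual
simplexes integrate out of the likelihood analytically (the compound
Dirichlet-multinomial), so the chain runs on (pi, w) alone: ``pi`` moves by
a logistic-normal random walk on the simplex and ``w`` by a log-scale
Gaussian random walk plus an independence step from its flat prior (which
teleports across scales when the concentration is weakly identified).
Proposal scales adapt toward 20-40% acceptance during burn-in and are frozen
afterwards. The individual simplexes are conjugate given (pi, w) —
p_i | x_i ~ Dirichlet(x_i + w*pi) — and are drawn exactly for every retained
iteration, avoiding the funnel-shaped joint geometry that makes un-collapsed
samplers mix slowly between hierarchy levels.

A constrained variant pins ``pi`` at the uniform simplex (no population-level
preference) while keeping individual variation; the Deviance Information
Criterion compares the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.special import betaln, gammaln

from .diagnostics import gelman_rubin, summarize
from .errors import InvalidInputError

__all__ = [
    "EggCountTable",
    "PreferencePosterior",
    "DICResult",
    "DICDetail",
    "fit_preference",
    "fit_preference_constrained",
    "dic",
    "dic_detail",
    "compare_dic",
    "contrast_preferences",
    "rank_letters",
    "quadrature_posterior_mean_binary",
]

_ADAPT_WINDOW = 50
_ADAPT_TARGET = 0.30


@dataclass
class EggCountTable:
    """Per-female count table over J >= 2 categories (host plants, wing models
    or hatched/unhatched eggs). Only females with at least one count enter."""

    population_id: str
    female_ids: list[str]
    counts: np.ndarray  # (n_females, J) non-negative integers
    category_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] < 1:
            raise InvalidInputError("count table must be a non-empty 2-D array")
        if self.counts.shape[1] < 2:
            raise InvalidInputError("need at least 2 categories")
        if len(self.category_labels) != self.counts.shape[1]:
            raise InvalidInputError("category labels do not match count columns")
        if len(set(self.category_labels)) != len(self.category_labels):
            raise InvalidInputError("category labels must be unique")
        if len(self.female_ids) != self.counts.shape[0]:
            raise InvalidInputError("female ids do not match count rows")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise InvalidInputError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise InvalidInputError("counts must be non-negative")
        if np.any(self.counts.sum(axis=1) < 1):
            bad = [self.female_ids[i] for i in np.flatnonzero(self.counts.sum(axis=1) < 1)]
            raise InvalidInputError(
                f"females with zero eggs cannot be included: {bad}"
            )

    @property
    def n_females(self) -> int:
        return self.counts.shape[0]

    @property
    def n_categories(self) -> int:
        return self.counts.shape[1]


@dataclass
class PreferencePosterior:
    """Retained MCMC draws from the preference model.

    Arrays are indexed [chain, iteration, ...]; iterations are post-burn-in.
    """

    pi_samples: np.ndarray  # (chains, kept, J)
    w_samples: np.ndarray  # (chains, kept)
    p_ind_samples: np.ndarray  # (chains, kept, n_females, J)
    burn_in: int
    seed: int
    acceptance_rates: dict = field(default_factory=dict)
    category_labels: list[str] = field(default_factory=list)
    female_ids: list[str] = field(default_factory=list)

    def pooled_pi(self) -> np.ndarray:
        """All chains concatenated, shape (draws, J)."""
        return self.pi_samples.reshape(-1, self.pi_samples.shape[-1])

    def pooled_w(self) -> np.ndarray:
        return self.w_samples.reshape(-1)

    def pooled_p_ind(self) -> np.ndarray:
        s = self.p_ind_samples.shape
        return self.p_ind_samples.reshape(-1, s[2], s[3])

    def summary(self, interval_mass: float = 0.95):
        """Posterior-summary table: parameter, median, ETPI bounds, PSRF."""
        import pandas as pd

        rows = []
        J = self.pi_samples.shape[-1]
        for j in range(J):
            label = self.category_labels[j] if self.category_labels else str(j)
            med, lo, hi = summarize(self.pi_samples[..., j], interval_mass)
            rhat = (
                gelman_rubin(self.pi_samples[..., j])
                if self.pi_samples.shape[0] >= 2
                else np.nan
            )
            rows.append((f"pi[{label}]", med, lo, hi, rhat))
        med, lo, hi = summarize(self.w_samples, interval_mass)
        rhat = gelman_rubin(self.w_samples) if self.w_samples.shape[0] >= 2 else np.nan
        rows.append(("w", med, lo, hi, rhat))
        return pd.DataFrame(
            rows, columns=["parameter", "median", "etpi_2.5", "etpi_97.5", "rhat"]
        )


@dataclass
class DICResult:
    dic_full: float
    dic_constrained: float
    delta: float
    support_label: str


@dataclass
class DICDetail:
    dic: float
    mean_deviance: float
    deviance_at_mean: float
    p_d: float


@njit(cache=True)
def _polya_loglik(counts, n_tot, pi, w):  # pragma: no cover - via fit_preference
    """Log Dirichlet-multinomial likelihood of all females (constants in the
    data dropped), with the individual simplexes integrated out."""
    F, J = counts.shape
    ll = 0.0
    for f in range(F):
        ll += math.lgamma(w) - math.lgamma(n_tot[f] + w)
        for j in range(J):
            a = w * pi[j]
            ll += math.lgamma(counts[f, j] + a) - math.lgamma(a)
    return ll


@njit(cache=True)
def _chain_kernel(counts, n_iter, burn_in, seed, w_max, use_fixed_w, fixed_w,
                  use_fix_pi, fix_pi):  # pragma: no cover - via fit_preference
    np.random.seed(seed)
    F, J = counts.shape
    kept = n_iter - burn_in

    n_tot = np.empty(F)
    col = np.zeros(J)
    for f in range(F):
        tot = 0.0
        for j in range(J):
            tot += counts[f, j]
            col[j] += counts[f, j]
        n_tot[f] = tot

    pi = np.empty(J)
    if use_fix_pi:
        for j in range(J):
            pi[j] = fix_pi[j]
    else:
        tot = 0.0
        for j in range(J):
            pi[j] = col[j] + 1.0
            tot += pi[j]
        for j in range(J):
            pi[j] /= tot
    w = fixed_w if use_fixed_w else 10.0

    s_pi = 0.15
    s_w = 1.0

    pi_out = np.empty((kept, J))
    w_out = np.empty(kept)
    p_out = np.empty((kept, F, J))

    acc_pi = 0.0
    acc_w = 0.0
    win_pi = 0.0
    win_w = 0.0

    ll = _polya_loglik(counts, n_tot, pi, w)

    for it in range(n_iter):
        # --- population simplex: logistic-normal random walk on the
        # collapsed (Polya) likelihood; flat Dirichlet prior ---
        if not use_fix_pi:
            zmax = 0.0  # reference category contributes z = 0
            z_new = np.empty(J - 1)
            for j in range(J - 1):
                z_new[j] = (np.log(pi[j]) - np.log(pi[J - 1])
                            + s_pi * np.random.normal())
                if z_new[j] > zmax:
                    zmax = z_new[j]
            tot = np.exp(-zmax)
            for j in range(J - 1):
                tot += np.exp(z_new[j] - zmax)
            pi_new = np.empty(J)
            for j in range(J):
                e = np.exp((z_new[j] if j < J - 1 else 0.0) - zmax)
                v = e / tot
                if v < 1e-12:
                    v = 1e-12
                pi_new[j] = v
            s = pi_new.sum()
            for j in range(J):
                pi_new[j] /= s
            ll_new = _polya_loglik(counts, n_tot, pi_new, w)
            lr = ll_new - ll
            for j in range(J):  # Jacobian of the additive-logistic transform
                lr += np.log(pi_new[j]) - np.log(pi[j])
            if np.log(np.random.random()) < lr:
                for j in range(J):
                    pi[j] = pi_new[j]
                ll = ll_new
                if it < burn_in:
                    win_pi += 1.0
                else:
                    acc_pi += 1.0

        # --- concentration: log-scale random walk + prior-independence step ---
        if not use_fixed_w:
            w_new = w * np.exp(s_w * np.random.normal())
            if 0.0 < w_new <= w_max:
                ll_new = _polya_loglik(counts, n_tot, pi, w_new)
                if np.log(np.random.random()) < ll_new - ll + np.log(w_new / w):
                    w = w_new
                    ll = ll_new
                    if it < burn_in:
                        win_w += 1.0
                    else:
                        acc_w += 1.0
            # independence proposal from the flat prior teleports across
            # scales when w is weakly identified (density cancels)
            w_new = np.random.random() * w_max
            if w_new > 0.0:
                ll_new = _polya_loglik(counts, n_tot, pi, w_new)
                if np.log(np.random.random()) < ll_new - ll:
                    w = w_new
                    ll = ll_new

        # --- burn-in adaptation toward ~30% acceptance ---
        if it < burn_in and (it + 1) % _ADAPT_WINDOW == 0:
            if not use_fix_pi:
                s_pi = min(max(s_pi * np.exp(win_pi / _ADAPT_WINDOW - _ADAPT_TARGET), 1e-3), 5.0)
                win_pi = 0.0
            if not use_fixed_w:
                s_w = min(max(s_w * np.exp(win_w / _ADAPT_WINDOW - _ADAPT_TARGET), 1e-3), 5.0)
                win_w = 0.0

        if it >= burn_in:
            k = it - burn_in
            for j in range(J):
                pi_out[k, j] = pi[j]
            w_out[k] = w
            # individual simplexes are conjugate given (pi, w):
            # p_i | x_i, pi, w ~ Dirichlet(x_i + w * pi), drawn exactly
            for f in range(F):
                tot = 0.0
                for j in range(J):
                    g = np.random.gamma(counts[f, j] + w * pi[j], 1.0)
                    if g < 1e-300:
                        g = 1e-300
                    p_out[k, f, j] = g
                    tot += g
                for j in range(J):
                    p_out[k, f, j] /= tot

    n_post = max(kept, 1)
    return (pi_out, w_out, p_out,
            1.0, acc_pi / n_post, acc_w / n_post)


def _run_chain(
    counts: np.ndarray,
    n_iter: int,
    burn_in: int,
    seed: int,
    w_max: float,
    fixed_w: float | None,
    fix_pi: np.ndarray | None,
):
    J = counts.shape[1]
    pi_out, w_out, p_out, r_p, r_pi, r_w = _chain_kernel(
        np.ascontiguousarray(counts, dtype=np.float64),
        n_iter, burn_in, seed, float(w_max),
        fixed_w is not None, float(fixed_w) if fixed_w is not None else 0.0,
        fix_pi is not None,
        np.ascontiguousarray(fix_pi if fix_pi is not None else np.zeros(J), dtype=np.float64),
    )
    rates = {
        "p_ind": float(r_p),
        "pi": float(r_pi) if fix_pi is None else float("nan"),
        "w": float(r_w) if fixed_w is None else float("nan"),
    }
    return pi_out, w_out, p_out, rates


def _validate_sampler_args(table: EggCountTable, n_chains: int, n_iter: int, burn_in: int):
    if not isinstance(table, EggCountTable):
        raise InvalidInputError("table must be an EggCountTable")
    if n_chains < 1:
        raise InvalidInputError("n_chains must be >= 1")
    if burn_in < 0 or n_iter <= burn_in:
        raise InvalidInputError("need n_iter > burn_in >= 0")


def fit_preference(
    table: EggCountTable,
    n_chains: int = 2,
    n_iter: int = 50_000,
    burn_in: int = 5_000,
    seed: int = 0,
    w_max: float = 1e4,
    fixed_w: float | None = None,
) -> PreferencePosterior:
    """Sample the posterior of the hierarchical preference model.

    Defaults mirror the study design: two 50,000-iteration chains with a
    5,000-iteration burn-in. ``fixed_w`` pins the concentration (used for
    deterministic cross-checks against numerical integration); ``w_max`` is
    the upper bound of the uniform prior on ``w``.
    """
    _validate_sampler_args(table, n_chains, n_iter, burn_in)
    if fixed_w is not None and fixed_w <= 0:
        raise InvalidInputError("fixed_w must be positive")
    streams = np.random.SeedSequence(seed).spawn(n_chains)
    pi_all, w_all, p_all, rates = [], [], [], []
    for ss in streams:
        pi_c, w_c, p_c, r = _run_chain(
            table.counts.astype(float), n_iter, burn_in,
            int(ss.generate_state(1)[0]), w_max, fixed_w, None,
        )
        pi_all.append(pi_c)
        w_all.append(w_c)
        p_all.append(p_c)
        rates.append(r)
    return PreferencePosterior(
        pi_samples=np.stack(pi_all),
        w_samples=np.stack(w_all),
        p_ind_samples=np.stack(p_all),
        burn_in=burn_in,
        seed=seed,
        acceptance_rates={k: float(np.mean([r[k] for r in rates])) for k in rates[0]},
        category_labels=list(table.category_labels),
        female_ids=list(table.female_ids),
    )


def fit_preference_constrained(
    table: EggCountTable,
    n_chains: int = 2,
    n_iter: int = 50_000,
    burn_in: int = 5_000,
    seed: int = 0,
    w_max: float = 1e4,
    fixed_w: float | None = None,
) -> PreferencePosterior:
    """Constrained model: the population simplex is pinned at (1/J, ..., 1/J)
    (no population-level preference); individual variation (w, p_i) remains
    free. ``pi_samples`` holds the constant uniform vector."""
    _validate_sampler_args(table, n_chains, n_iter, burn_in)
    J = table.n_categories
    fix_pi = np.full(J, 1.0 / J)
    streams = np.random.SeedSequence(seed).spawn(n_chains)
    pi_all, w_all, p_all, rates = [], [], [], []
    for ss in streams:
        pi_c, w_c, p_c, r = _run_chain(
            table.counts.astype(float), n_iter, burn_in,
            int(ss.generate_state(1)[0]), w_max, fixed_w, fix_pi,
        )
        pi_all.append(pi_c)
        w_all.append(w_c)
        p_all.append(p_c)
        rates.append(r)
    return PreferencePosterior(
        pi_samples=np.stack(pi_all),
        w_samples=np.stack(w_all),
        p_ind_samples=np.stack(p_all),
        burn_in=burn_in,
        seed=seed,
        acceptance_rates={k: float(np.mean([r[k] for r in rates])) for k in rates[0]},
        category_labels=list(table.category_labels),
        female_ids=list(table.female_ids),
    )


def _log_multinomial(counts: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Log multinomial pmf summed over females, vectorized over draws.

    counts: (F, J); p: (S, F, J) -> (S,)
    """
    n = counts.sum(axis=1)
    const = float(np.sum(gammaln(n + 1)) - np.sum(gammaln(counts + 1)))
    return const + np.einsum("fj,sfj->s", counts, np.log(p))


def multinomial_deviance(counts: np.ndarray, p: np.ndarray) -> float:
    """Deviance of the observation layer, -2 log Multinomial(x | p, n),
    summed over females. counts and p both (F, J)."""
    counts = np.asarray(counts, dtype=float)
    p = np.asarray(p, dtype=float)
    if p.shape != counts.shape:
        raise InvalidInputError("counts and p must have matching shapes")
    return float(-2.0 * _log_multinomial(counts, p[None])[0])


def _log_dirmult(counts: np.ndarray, pi: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Log Dirichlet-multinomial (Polya) likelihood of the count table with
    the individual simplexes integrated out, vectorized over draws.

    counts: (F, J); pi: (S, J); w: (S,) -> (S,)
    """
    n = counts.sum(axis=1)
    const = float(np.sum(gammaln(n + 1)) - np.sum(gammaln(counts + 1)))
    alpha = w[:, None] * pi  # (S, J)
    out = const + counts.shape[0] * gammaln(w)
    out = out - gammaln(n[None, :] + w[:, None]).sum(axis=1)
    out = out + gammaln(counts[None, :, :] + alpha[:, None, :]).sum(axis=(1, 2))
    out = out - counts.shape[0] * gammaln(alpha).sum(axis=1)
    return out


def dic_detail(posterior: PreferencePosterior, table: EggCountTable) -> DICDetail:
    """DIC focused on the population-level parameters, with components.

    The deviance integrates the individual simplexes out of the likelihood
    analytically (the compound Dirichlet-multinomial), so D is a function of
    the population preference and concentration alone:

        D(pi, w) = -2 sum_i log DirMult(x_i | w * pi, n_i).

    DIC = 2 * mean(D) - D(theta_hat) with the plug-in theta_hat at the
    posterior medians of pi (renormalized) and w; p_D = mean(D) - D(hat).
    Conditioning the deviance on the individual simplexes instead would let
    the constrained model act as a saturated model (small w frees every
    p_i), leaving DIC unable to distinguish the population-level
    hypotheses the comparison is for.
    """
    counts = np.asarray(table.counts, dtype=float)
    pi = posterior.pooled_pi()
    w = posterior.pooled_w()
    if pi.shape[1] != counts.shape[1]:
        raise InvalidInputError("posterior and table category counts do not match")
    if posterior.p_ind_samples.shape[2] not in (counts.shape[0], 1):
        raise InvalidInputError("posterior and table female counts do not match")
    d_draws = -2.0 * _log_dirmult(counts, pi, w)
    d_bar = float(np.mean(d_draws))
    pi_hat = np.median(pi, axis=0)
    pi_hat /= pi_hat.sum()
    w_hat = float(np.median(w))
    d_hat = float(-2.0 * _log_dirmult(counts, pi_hat[None], np.array([w_hat]))[0])
    return DICDetail(dic=2.0 * d_bar - d_hat, mean_deviance=d_bar,
                     deviance_at_mean=d_hat, p_d=d_bar - d_hat)


def dic(posterior: PreferencePosterior, table: EggCountTable) -> float:
    return dic_detail(posterior, table).dic


def compare_dic(dic_full: float, dic_constrained: float) -> DICResult:
    """Model support from the DIC difference (full minus constrained).

    delta <= -7: considerable support for the full model; (-7, -3]: moderate
    support for the full model; (-3, 3): ambiguous; >= 3: moderate support
    for the constrained model.
    """
    if not (np.isfinite(dic_full) and np.isfinite(dic_constrained)):
        raise InvalidInputError("DIC values must be finite")
    delta = dic_full - dic_constrained
    if delta <= -7:
        label = "considerable_full"
    elif delta <= -3:
        label = "moderate_full"
    elif delta < 3:
        label = "ambiguous"
    else:
        label = "moderate_constrained"
    return DICResult(dic_full=float(dic_full), dic_constrained=float(dic_constrained),
                     delta=float(delta), support_label=label)


def _paired(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("empty sample vector")
    n = max(a.size, b.size)
    if a.size != n:
        a = np.resize(a, n)  # cycle the shorter vector
    if b.size != n:
        b = np.resize(b, n)
    return a, b


def contrast_preferences(post_a: np.ndarray, post_b: np.ndarray) -> float:
    """P(a - b > 0) from paired posterior draws (shorter vector cycled).

    Exact ties count 0.5, so identical vectors give exactly 0.5.
    """
    a, b = _paired(post_a, post_b)
    return float(np.mean((a > b) + 0.5 * (a == b)))


def rank_letters(
    posteriors: Sequence[np.ndarray],
    threshold: float = 0.95,
    seed: int | None = None,
) -> list[str]:
    """Compact letter display for posterior rank differences.

    Two items receive no shared letter iff the posterior probability that one
    ranks above the other (from paired draws) reaches ``threshold``. Items
    are ordered by posterior median; letters mark maximal runs of mutually
    unseparated items. ``seed`` optionally shuffles each draw vector before
    pairing (pairing is positional otherwise).
    """
    if len(posteriors) < 2:
        raise InvalidInputError("need at least two posteriors")
    if not 0.5 < threshold < 1.0:
        raise InvalidInputError("threshold must lie in (0.5, 1)")
    draws = [np.asarray(p, dtype=float).ravel() for p in posteriors]
    if any(d.size == 0 for d in draws):
        raise InvalidInputError("empty sample vector")
    if seed is not None:
        rng = np.random.default_rng(seed)
        draws = [rng.permutation(d) for d in draws]
    k = len(draws)
    medians = [float(np.median(d)) for d in draws]
    order = np.argsort(medians)[::-1]  # descending

    def separated(i: int, j: int) -> bool:
        pij = contrast_preferences(draws[i], draws[j])
        return max(pij, 1.0 - pij) >= threshold

    # maximal windows of mutually unseparated items along the sorted order
    windows: list[tuple[int, int]] = []
    for start in range(k):
        end = start
        while end + 1 < k and all(
            not separated(order[a], order[end + 1]) for a in range(start, end + 1)
        ):
            end += 1
        windows.append((start, end))
    # drop windows contained in another
    windows = [
        w for w in windows
        if not any(o != w and o[0] <= w[0] and o[1] >= w[1] for o in windows)
    ]
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = ["" for _ in range(k)]
    for li, (s, e) in enumerate(sorted(windows)):
        for pos in range(s, e + 1):
            out[order[pos]] += letters[li % len(letters)]
    return out


def quadrature_posterior_mean_binary(
    counts: np.ndarray, w: float, n_grid: int = 4001
) -> float:
    """Deterministic posterior mean of pi_1 for the two-category model with
    the concentration pinned at ``w``.

    The individual simplexes integrate out in closed form (the compound
    Dirichlet-multinomial), leaving a one-dimensional marginal posterior for
    pi_1 under the flat Dirichlet(1,1) prior, evaluated here on a grid. This
    path shares no code with the MCMC sampler and serves as its cross-check.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise InvalidInputError("counts must be (n_females, 2)")
    if w <= 0:
        raise InvalidInputError("w must be positive")
    x = counts[:, 0]
    n = counts.sum(axis=1)
    grid = np.linspace(1e-6, 1 - 1e-6, n_grid)
    a = w * grid[:, None]
    b = w * (1 - grid)[:, None]
    ll = (betaln(x[None, :] + a, (n - x)[None, :] + b) - betaln(a, b)).sum(axis=1)
    post = np.exp(ll - ll.max())
    return float(np.trapezoid(post * grid, grid) / np.trapezoid(post, grid))
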