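"""Diapause-initiation and diapause-termination hatch models.

Two analyses share this module:

* Pre-winter hatch probability (DIA): the two-category case of the
  hierarchical preference model, with categories (hatched, unhatched). One
  minus the hatch probability approximates the probability of initiating
  diapause.

* A hierarchical binomial-logit GLM across winter-length treatments (DIA,
  DA11, DM11, DJ11) and two lab locations:

      x_ikl | p_ikl     ~ Binomial(p_ikl, n_ikl)
      logit(p_ikl)      = theta_ikl ~ Normal(mu_kl, 1/tau_kl)
      mu_kl             = alpha_k + beta_l(k),   sum_l beta_l(k) = 0
      alpha_k, beta_l(k) ~ Normal(0, 1e6)
      tau_kl            ~ Gamma(shape 1, scale 1)

  The sum-to-zero constraint on the location effects is enforced exactly by
  parameterizing each treatment's pair of effects as (+b_k, -b_k). Latent
  logits are updated by adaptive random-walk Metropolis; alpha, beta and tau
  have closed-form Normal/Gamma full conditionals and are Gibbs-sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.special import expit

from .errors import InvalidInputError
from .preference_model import EggCountTable, PreferencePosterior, contrast_preferences, fit_preference

__all__ = [
    "TREATMENTS",
    "HatchTable",
    "DiapausePosterior",
    "fit_hatch_dia",
    "pairwise_hatch",
    "fit_diapause_glm",
    "cell_probability",
]

TREATMENTS = ("DIA", "DA11", "DM11", "DJ11")

_PRIOR_PREC = 1e-6  # Normal(0, 1e6) prior on alpha and beta
_GAMMA_SHAPE = 1.0  # Gamma(shape 1, scale 1) prior on tau
_GAMMA_RATE = 1.0


@dataclass
class HatchTable:
    """Per-female binomial hatch records across treatments and lab locations.

    Missing cells (a population lacking a treatment or location) are allowed.
    """

    population_id: str
    female_ids: list[str]
    treatments: list[str]
    locations: list[str]
    hatched: np.ndarray  # (rows,) non-negative integers
    total: np.ndarray  # (rows,) positive integers

    def __post_init__(self) -> None:
        self.hatched = np.asarray(self.hatched, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        n = self.hatched.shape[0]
        if not (len(self.female_ids) == len(self.treatments) == len(self.locations)
                == self.total.shape[0] == n):
            raise InvalidInputError("hatch table columns have unequal lengths")
        if n < 1:
            raise InvalidInputError("hatch table is empty")
        bad = [t for t in self.treatments if t not in TREATMENTS]
        if bad:
            raise InvalidInputError(f"unknown treatment labels: {sorted(set(bad))}")
        if len(set(self.locations)) > 2:
            raise InvalidInputError("at most two lab locations are supported")
        if np.any(self.total < 1):
            raise InvalidInputError("every row needs total >= 1")
        if np.any(self.hatched < 0) or np.any(self.hatched > self.total):
            rows = np.flatnonzero((self.hatched < 0) | (self.hatched > self.total))
            raise InvalidInputError(f"hatched outside [0, total] at rows {rows.tolist()}")

    @property
    def n_rows(self) -> int:
        return self.hatched.shape[0]


@dataclass
class DiapausePosterior:
    """Draws from the hierarchical hatch GLM, indexed [chain, iteration, ...].

    ``beta_samples[..., k, :]`` holds the two location effects for treatment
    k; within every draw they sum to zero exactly. Cells absent from the data
    are listed in ``unobserved_cells`` — their tau (and, for fully absent
    treatments, alpha/beta) draws are prior-dominated.
    """

    alpha_samples: np.ndarray  # (chains, kept, K)
    beta_samples: np.ndarray  # (chains, kept, K, 2)
    tau_samples: np.ndarray  # (chains, kept, K, 2)
    theta_samples: np.ndarray  # (chains, kept, rows)
    treatments: list[str]
    locations: list[str]
    unobserved_cells: list[tuple[str, str]]
    burn_in: int
    seed: int
    acceptance_rates: dict = field(default_factory=dict)

    def pooled(self, name: str) -> np.ndarray:
        arr = getattr(self, f"{name}_samples")
        return arr.reshape(-1, *arr.shape[2:])


def fit_hatch_dia(
    table: HatchTable,
    n_chains: int = 2,
    n_iter: int = 50_000,
    burn_in: int = 5_000,
    seed: int = 0,
    w_max: float = 1e4,
    fixed_w: float | None = None,
) -> PreferencePosterior:
    """Pre-winter hatch probability via the two-category preference model.

    Restricted to DIA rows; categories are (hatched, unhatched), so
    ``pi_samples[..., 0]`` is the population hatch probability.
    """
    if any(t != "DIA" for t in table.treatments):
        raise InvalidInputError("fit_hatch_dia expects rows restricted to DIA")
    counts = np.column_stack([table.hatched, table.total - table.hatched])
    egg = EggCountTable(
        population_id=table.population_id,
        female_ids=list(table.female_ids),
        counts=counts,
        category_labels=["hatched", "unhatched"],
    )
    return fit_preference(egg, n_chains=n_chains, n_iter=n_iter, burn_in=burn_in,
                          seed=seed, w_max=w_max, fixed_w=fixed_w)


def pairwise_hatch(post_a: np.ndarray, post_b: np.ndarray) -> float:
    """P(hatch probability of population a exceeds that of population b)."""
    return contrast_preferences(post_a, post_b)


def _alpha_conditional(theta_resid, tau_row, prior_prec=_PRIOR_PREC):
    """Normal full conditional (mean, sd) for a treatment effect given the
    latent logits minus the location effect."""
    prec = prior_prec + float(np.sum(tau_row))
    mean = float(np.sum(tau_row * theta_resid)) / prec
    return mean, 1.0 / np.sqrt(prec)


def _beta_conditional(theta_resid, sign, tau_row, prior_prec=_PRIOR_PREC):
    """Normal full conditional (mean, sd) for the free location scalar b_k
    (effects are +b for the first location, -b for the second)."""
    prec = prior_prec + float(np.sum(tau_row))
    mean = float(np.sum(tau_row * sign * theta_resid)) / prec
    return mean, 1.0 / np.sqrt(prec)


def _tau_conditional(resid, shape=_GAMMA_SHAPE, rate=_GAMMA_RATE):
    """Gamma full conditional (shape, rate) for a cell precision."""
    return shape + resid.size / 2.0, rate + float(np.sum(resid**2)) / 2.0


def _run_glm_chain(x, n, k_idx, sign, cell_idx, K, n_cells, n_iter, burn_in, rng):
    R = x.shape[0]
    kept = n_iter - burn_in

    # crude empirical initialization
    p0 = (x + 0.5) / (n + 1.0)
    theta = np.log(p0 / (1.0 - p0))
    alpha = np.zeros(K)
    for k in range(K):
        m = k_idx == k
        if m.any():
            alpha[k] = theta[m].mean()
    b = np.zeros(K)
    tau = np.ones((K, 2))

    step = np.full(R, 0.8)
    acc = np.zeros(R)
    win = np.zeros(R)
    n_post = 0

    a_out = np.empty((kept, K))
    b_out = np.empty((kept, K, 2))
    t_out = np.empty((kept, K, 2))
    th_out = np.empty((kept, R))

    obs_cell = np.zeros((K, 2), dtype=bool)
    for k in range(K):
        for l in range(2):
            obs_cell[k, l] = np.any(cell_idx == k * 2 + l)
    obs_treat = obs_cell.any(axis=1)
    # a treatment observed at a single location cannot separate alpha from
    # beta; its location effect is sampled from the prior conditional anyway
    two_loc = obs_cell.all(axis=1)

    for it in range(n_iter):
        mu_cell = alpha[:, None] + np.stack([b, -b], axis=1)
        mu_row = mu_cell.reshape(-1)[cell_idx]
        tau_row = tau.reshape(-1)[cell_idx]

        # latent logits: vectorized random-walk Metropolis
        prop = theta + step * rng.standard_normal(R)
        def _loglik(t):
            return x * t - n * np.logaddexp(0.0, t)
        log_r = (_loglik(prop) - _loglik(theta)
                 - 0.5 * tau_row * ((prop - mu_row) ** 2 - (theta - mu_row) ** 2))
        ok = np.log(rng.random(R)) < log_r
        theta[ok] = prop[ok]
        if it < burn_in:
            win += ok
        else:
            acc += ok

        # Gibbs: treatment effects, location effects, precisions
        for k in range(K):
            rows_k = k_idx == k
            if obs_treat[k]:
                sgn = sign[rows_k]
                tr = tau.reshape(-1)[cell_idx[rows_k]]
                m, s = _alpha_conditional(theta[rows_k] - sgn * b[k], tr)
                alpha[k] = m + s * rng.standard_normal()
                if two_loc[k]:
                    m, s = _beta_conditional(theta[rows_k] - alpha[k], sgn, tr)
                else:
                    m, s = 0.0, 1.0 / np.sqrt(_PRIOR_PREC)
                b[k] = m + s * rng.standard_normal()
            else:
                alpha[k] = rng.normal(0.0, 1.0 / np.sqrt(_PRIOR_PREC))
                b[k] = rng.normal(0.0, 1.0 / np.sqrt(_PRIOR_PREC))
            for l in range(2):
                rows_c = cell_idx == k * 2 + l
                if rows_c.any():
                    mu_kl = alpha[k] + (b[k] if l == 0 else -b[k])
                    sh, ra = _tau_conditional(theta[rows_c] - mu_kl)
                else:
                    sh, ra = _GAMMA_SHAPE, _GAMMA_RATE
                tau[k, l] = rng.gamma(sh, 1.0 / ra)

        if it < burn_in and (it + 1) % 50 == 0:
            rate = win / 50.0
            step = np.clip(step * np.exp(rate - 0.35), 1e-2, 10.0)
            win[:] = 0.0

        if it >= burn_in:
            j = it - burn_in
            a_out[j] = alpha
            b_out[j, :, 0] = b
            b_out[j, :, 1] = -b
            t_out[j] = tau
            th_out[j] = theta
            n_post += 1

    return a_out, b_out, t_out, th_out, float(np.mean(acc / max(n_post, 1)))


def fit_diapause_glm(
    table: HatchTable,
    n_chains: int = 3,
    n_iter: int = 75_000,
    burn_in: int = 50_000,
    seed: int = 0,
) -> DiapausePosterior:
    """Sample the hierarchical binomial-logit GLM for one population.

    Defaults mirror the study design: three 75,000-iteration chains after a
    50,000-iteration burn-in. Fitting is per population; a female appearing
    in several treatments contributes independent binomial rows.
    """
    if burn_in < 0 or n_iter <= burn_in:
        raise InvalidInputError("need n_iter > burn_in >= 0")
    if n_chains < 1:
        raise InvalidInputError("n_chains must be >= 1")
    locs = sorted(set(table.locations))
    if len(locs) == 1:
        locs = [locs[0], f"{locs[0]}::absent"]
    K = len(TREATMENTS)
    k_idx = np.array([TREATMENTS.index(t) for t in table.treatments])
    l_idx = np.array([locs.index(loc) for loc in table.locations])
    sign = np.where(l_idx == 0, 1.0, -1.0)
    cell_idx = k_idx * 2 + l_idx

    unobserved = [
        (TREATMENTS[k], locs[l])
        for k in range(K)
        for l in range(2)
        if not np.any(cell_idx == k * 2 + l)
    ]
    if unobserved:
        warnings.warn(
            f"cells without data yield prior-dominated draws: {unobserved}",
            stacklevel=2,
        )

    x = table.hatched.astype(float)
    n = table.total.astype(float)
    streams = np.random.SeedSequence(seed).spawn(n_chains)
    a_all, b_all, t_all, th_all, rates = [], [], [], [], []
    for ss in streams:
        a, bb, t, th, r = _run_glm_chain(
            x, n, k_idx, sign, cell_idx, K, 2 * K, n_iter, burn_in,
            np.random.default_rng(ss),
        )
        a_all.append(a)
        b_all.append(bb)
        t_all.append(t)
        th_all.append(th)
        rates.append(r)
    return DiapausePosterior(
        alpha_samples=np.stack(a_all),
        beta_samples=np.stack(b_all),
        tau_samples=np.stack(t_all),
        theta_samples=np.stack(th_all),
        treatments=list(TREATMENTS),
        locations=locs,
        unobserved_cells=unobserved,
        burn_in=burn_in,
        seed=seed,
        acceptance_rates={"theta": float(np.mean(rates))},
    )


def cell_probability(posterior: DiapausePosterior, treatment: str, location: str) -> np.ndarray:
    """Posterior draws of the expected hatch probability for one
    treatment-by-location cell: inverse-logit(alpha_k + beta_l(k))."""
    if treatment not in posterior.treatments:
        raise InvalidInputError(f"unknown treatment {treatment!r}")
    if location not in posterior.locations:
        raise InvalidInputError(f"unknown location {location!r}")
    k = posterior.treatments.index(treatment)
    l = posterior.locations.index(location)
    mu = posterior.pooled("alpha")[:, k] + posterior.pooled("beta")[:, k, l]
    return expit(mu)
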