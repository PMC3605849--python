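"""Synthetic data generators with recorded ground truth.

No raw field data accompany the study design this package implements, so
every pipeline input is emulated from the generative model the corresponding
analysis assumes:

* egg counts: individual preference simplexes drawn Dirichlet(w * pi),
  multinomial egg allocation, zero-truncated Poisson clutch totals (only
  females that laid eggs enter the data);
* hatch counts: latent per-female logits Normal(alpha_k + beta_l(k),
  1/tau_kl) with sum-to-zero location effects, binomial hatching;
* wing-model trials: model morphospace scores from a bivariate normal,
  three models presented per trial, one approach drawn with probability
  proportional to exp(gamma' score) (gamma = 0 is the uniform null);
* distance systems: genetic distance as a linear function of geographic and
  phenotypic distance plus symmetric noise, with optional truncated-normal
  posterior draws around each trait value.

Every generator is seeded and returns a ``SyntheticTruth`` carrying the
parameters that produced the data, for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.special import expit

from .diapause_model import TREATMENTS, HatchTable
from .distance_analysis import DistanceMatrix, geographic_distance, phenotype_distance
from .errors import InvalidInputError
from .morphospace import TrialTable
from .preference_model import EggCountTable

__all__ = [
    "SyntheticTruth",
    "gen_egg_counts",
    "gen_hatch_data",
    "gen_wing_trials",
    "gen_distance_system",
    "DistanceSystem",
]

GENERATOR_VERSION = "1.0"


@dataclass
class SyntheticTruth:
    parameters: dict
    seed: int
    generator: str
    version: str = GENERATOR_VERSION


def _zero_truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Poisson conditioned on being positive (females that laid no eggs are
    not observed)."""
    out = rng.poisson(mean, size=size)
    while np.any(out == 0):
        zeros = out == 0
        out[zeros] = rng.poisson(mean, size=int(zeros.sum()))
    return out


def gen_egg_counts(
    pi: np.ndarray,
    w: float,
    n_females: int,
    egg_mean: float = 20.0,
    seed: int = 0,
    population_id: str = "synthetic",
    category_labels: list[str] | None = None,
) -> tuple[EggCountTable, SyntheticTruth]:
    """Multinomial egg counts with Dirichlet-distributed individual
    preferences around the population simplex ``pi`` (concentration ``w``)."""
    pi = np.asarray(pi, dtype=float)
    if pi.ndim != 1 or pi.size < 2 or np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise InvalidInputError("pi must be a strictly positive simplex of length >= 2")
    if w <= 0:
        raise InvalidInputError("w must be positive")
    if n_females < 1:
        raise InvalidInputError("need >= 1 female")
    if egg_mean <= 0:
        raise InvalidInputError("egg_mean must be positive")
    rng = np.random.default_rng(seed)
    J = pi.size
    totals = _zero_truncated_poisson(rng, egg_mean, n_females)
    p_ind = rng.dirichlet(w * pi, size=n_females)
    counts = np.stack([rng.multinomial(n, p) for n, p in zip(totals, p_ind)])
    labels = category_labels or [f"plant_{j + 1}" for j in range(J)]
    table = EggCountTable(
        population_id=population_id,
        female_ids=[f"F{i + 1:03d}" for i in range(n_females)],
        counts=counts,
        category_labels=list(labels),
    )
    truth = SyntheticTruth(
        parameters={"pi": pi.tolist(), "w": float(w), "egg_mean": float(egg_mean),
                    "p_ind": p_ind.tolist()},
        seed=seed, generator="gen_egg_counts",
    )
    return table, truth


def gen_hatch_data(
    alpha: dict,
    beta: dict,
    tau: dict,
    n_females_per_cell: int,
    eggs_per_female: int = 10,
    seed: int = 0,
    population_id: str = "synthetic",
    locations: tuple[str, str] = ("Reno", "Laramie"),
) -> tuple[HatchTable, SyntheticTruth]:
    """Binomial hatch counts under the hierarchical logit model.

    ``alpha`` maps treatment -> treatment effect, ``beta`` maps treatment ->
    effect of the first location (the second is its negation, so effects sum
    to zero per treatment), ``tau`` maps (treatment, location) -> precision
    of the among-female logit variation. Treatments absent from ``alpha``
    are left unobserved. The experimental protocol caps each female's
    contribution at 10 eggs; exceeding it warns but proceeds.
    """
    if eggs_per_female < 1:
        raise InvalidInputError("eggs_per_female must be >= 1")
    if eggs_per_female > 10:
        warnings.warn("more than 10 eggs per female exceeds the design cap", stacklevel=2)
    if n_females_per_cell < 1:
        raise InvalidInputError("need >= 1 female per cell")
    bad = [t for t in alpha if t not in TREATMENTS]
    if bad:
        raise InvalidInputError(f"unknown treatments: {bad}")
    rng = np.random.default_rng(seed)
    rows_f, rows_t, rows_l, rows_h, rows_n = [], [], [], [], []
    theta_truth = {}
    fem = 0
    for t in TREATMENTS:
        if t not in alpha:
            continue
        b = float(beta.get(t, 0.0))
        for li, loc in enumerate(locations):
            tau_kl = float(tau[(t, loc)]) if (t, loc) in tau else float(tau.get(t, 1.0))
            if tau_kl <= 0:
                raise InvalidInputError("precisions must be positive")
            mu = float(alpha[t]) + (b if li == 0 else -b)
            theta = rng.normal(mu, 1.0 / np.sqrt(tau_kl), size=n_females_per_cell)
            hatched = rng.binomial(eggs_per_female, expit(theta))
            for i in range(n_females_per_cell):
                fem += 1
                rows_f.append(f"F{fem:04d}")
                rows_t.append(t)
                rows_l.append(loc)
                rows_h.append(int(hatched[i]))
                rows_n.append(eggs_per_female)
            theta_truth[(t, loc)] = theta.tolist()
    if not rows_f:
        raise InvalidInputError("alpha specified no treatments")
    table = HatchTable(
        population_id=population_id,
        female_ids=rows_f, treatments=rows_t, locations=rows_l,
        hatched=np.array(rows_h), total=np.array(rows_n),
    )
    truth = SyntheticTruth(
        parameters={"alpha": dict(alpha), "beta": {t: float(beta.get(t, 0.0)) for t in alpha},
                    "tau": {f"{k}": v for k, v in tau.items()},
                    "theta": {f"{k}": v for k, v in theta_truth.items()},
                    "eggs_per_female": eggs_per_female},
        seed=seed, generator="gen_hatch_data",
    )
    return table, truth


def gen_wing_trials(
    n_trials: int,
    model_pool_size: int = 21,
    morphospace_mean: np.ndarray = (0.0, 0.0),
    morphospace_cov: np.ndarray = ((1.0, 0.0), (0.0, 1.0)),
    gamma: np.ndarray = (0.0, 0.0),
    seed: int = 0,
) -> tuple[dict, TrialTable, SyntheticTruth]:
    """Wing-model trials over a bivariate-normal morphospace.

    Each trial presents 3 distinct models drawn uniformly from the pool and
    records one approach, chosen among the presented three with probability
    proportional to exp(gamma' score). ``gamma = 0`` gives the uniform-null
    approach process.

    Returns (scores, trials, truth) where ``scores`` maps model_id ->
    (PC1, PC2).
    """
    if model_pool_size < 3:
        raise InvalidInputError("need a pool of >= 3 models")
    if n_trials < 1:
        raise InvalidInputError("need >= 1 trial")
    mean = np.asarray(morphospace_mean, dtype=float)
    cov = np.asarray(morphospace_cov, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if np.any(np.linalg.eigvalsh(cov) <= 0):
        raise InvalidInputError("morphospace covariance must be positive definite")
    rng = np.random.default_rng(seed)
    ids = [f"M{i + 1:03d}" for i in range(model_pool_size)]
    pts = rng.multivariate_normal(mean, cov, size=model_pool_size)
    scores = {m: tuple(p) for m, p in zip(ids, pts)}
    trial_ids, presented, approaches = [], [], []
    for t in range(n_trials):
        pick = rng.choice(model_pool_size, size=3, replace=False)
        util = pts[pick] @ gamma
        prob = np.exp(util - util.max())
        prob /= prob.sum()
        chosen = pick[rng.choice(3, p=prob)]
        trial_ids.append(f"T{t + 1:04d}")
        presented.append(tuple(ids[i] for i in pick))
        approaches.append([ids[chosen]])
    trials = TrialTable(trial_ids=trial_ids, presented=presented, approaches=approaches)
    truth = SyntheticTruth(
        parameters={"gamma": gamma.tolist(), "mean": mean.tolist(), "cov": cov.tolist(),
                    "model_pool_size": model_pool_size},
        seed=seed, generator="gen_wing_trials",
    )
    return scores, trials, truth


@dataclass
class DistanceSystem:
    labels: list
    coordinates: dict
    traits: dict  # trait name -> {label: value}
    trait_posteriors: dict  # trait name -> {label: draw vector} (may be empty)
    geographic: DistanceMatrix
    phenotypic: dict  # trait name -> DistanceMatrix
    genetic: DistanceMatrix
    truth: SyntheticTruth = field(default=None)


def gen_distance_system(
    n_pops: int,
    b0: float = 0.02,
    b_geo: float = 5e-4,
    b_pheno: dict | float = 0.1,
    noise_sd: float = 0.01,
    seed: int = 0,
    posterior_sd: float | None = None,
    n_posterior_draws: int = 1000,
    region: tuple[float, float, float, float] = (42.0, 45.0, -111.5, -108.0),
) -> DistanceSystem:
    """Populations on a map with traits, and a genetic distance matrix built
    as a linear function of geography and phenotype differences plus
    symmetric Gaussian noise (clipped at zero).

    ``b_pheno`` is either a scalar (one trait named "trait_1") or a mapping
    trait name -> coefficient. With ``posterior_sd`` set, each trait value
    also gets Normal(point, posterior_sd) posterior draws truncated to
    [0, 1], emulating preference-type posteriors.
    """
    if n_pops < 4:
        raise InvalidInputError("need >= 4 populations")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    if np.isscalar(b_pheno):
        b_pheno = {"trait_1": float(b_pheno)}
    rng = np.random.default_rng(seed)
    labels = [f"P{i + 1:02d}" for i in range(n_pops)]
    lat0, lat1, lon0, lon1 = region
    coords = {
        l: (float(rng.uniform(lat0, lat1)), float(rng.uniform(lon0, lon1)))
        for l in labels
    }
    geo = geographic_distance(coords)
    traits = {
        t: {l: float(rng.uniform(0.0, 1.0)) for l in labels} for t in b_pheno
    }
    pheno = {t: phenotype_distance(traits[t], kind=f"phenotypic:{t}") for t in traits}
    G = b0 + b_geo * geo.values
    for t, coef in b_pheno.items():
        G = G + coef * pheno[t].values
    if noise_sd > 0:
        eps = rng.normal(0.0, noise_sd, size=(n_pops, n_pops))
        eps = np.triu(eps, 1)
        G = G + eps + eps.T
    G = np.clip(G, 0.0, None)
    np.fill_diagonal(G, 0.0)
    genetic = DistanceMatrix(labels=labels, values=(G + G.T) / 2.0, kind="genetic_F")

    posteriors: dict = {}
    if posterior_sd is not None:
        for t in traits:
            posteriors[t] = {}
            for l in labels:
                d = rng.normal(traits[t][l], posterior_sd, size=n_posterior_draws)
                # truncate to [0, 1] by redrawing (preference-type traits)
                while np.any((d < 0) | (d > 1)):
                    bad = (d < 0) | (d > 1)
                    d[bad] = rng.normal(traits[t][l], posterior_sd, size=int(bad.sum()))
                posteriors[t][l] = d
    truth = SyntheticTruth(
        parameters={"b0": b0, "b_geo": b_geo, "b_pheno": {k: float(v) for k, v in b_pheno.items()},
                    "noise_sd": noise_sd, "traits": traits,
                    "posterior_sd": posterior_sd},
        seed=seed, generator="gen_distance_system",
    )
    return DistanceSystem(
        labels=labels, coordinates=coords, traits=traits,
        trait_posteriors=posteriors, geographic=geo, phenotypic=pheno,
        genetic=genetic, truth=truth,
    )
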