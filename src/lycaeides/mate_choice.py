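"""Conspecific mate-preference analysis (paired-model presentation assay).

Males from each population are shown one *L. idas* and one *L. melissa* wing
model; approaches are pooled across males within a population (individual
variation is disregarded in this design), giving a two-category multinomial
with a flat Dirichlet(1, 1) prior on the population approach preference —
i.e. a conjugate Beta posterior for pi_idas.

From two populations' posteriors, the expected conspecific-pairing log odds
summarizes how much more often a random female would be approached by a
conspecific male than a heterospecific one, under equal abundance of both
species and sexes:

    log[(p_ii + p_mm) / (p_im + p_mi)]          (sum-ratio form, default)
    log[(p_ii * p_mm) / (p_im * p_mi)]          (product form, optional)

where p_ii is the idas-male preference for idas models and p_mm the
melissa-male preference for melissa models (p_im = 1 - p_ii etc.). Both
forms are 0 at indifference (all probabilities 1/2) and increase in p_ii and
p_mm; the form used is recorded with every result.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError
from .preference_model import PreferencePosterior, _paired

__all__ = ["fit_approach_preference", "conspecific_log_odds"]

_CLAMP = 1e-6  # keeps the log finite at degenerate preference draws


def fit_approach_preference(
    approaches_idas: np.ndarray | int,
    approaches_melissa: np.ndarray | int,
    n_chains: int = 2,
    n_iter: int = 50_000,
    burn_in: int = 5_000,
    seed: int = 0,
) -> PreferencePosterior:
    """Posterior of the population-level preference for idas models.

    Per-male counts are pooled; with the flat prior the posterior is exactly
    Beta(a + 1, b + 1), sampled directly (one stream per nominal chain so
    convergence diagnostics still apply). ``pi_samples[..., 0]`` is
    pi_idas.
    """
    a = int(np.sum(approaches_idas))
    b = int(np.sum(approaches_melissa))
    if a < 0 or b < 0:
        raise InvalidInputError("approach counts must be non-negative")
    if a + b == 0:
        raise InvalidInputError("zero total approaches")
    if burn_in < 0 or n_iter <= burn_in:
        raise InvalidInputError("need n_iter > burn_in >= 0")
    kept = n_iter - burn_in
    streams = np.random.SeedSequence(seed).spawn(max(n_chains, 1))
    draws = np.stack(
        [np.random.default_rng(ss).beta(a + 1, b + 1, size=kept) for ss in streams]
    )
    pi = np.stack([draws, 1.0 - draws], axis=-1)
    return PreferencePosterior(
        pi_samples=pi,
        w_samples=np.full(draws.shape, np.nan),  # no individual level in this design
        p_ind_samples=pi[:, :, None, :],
        burn_in=burn_in,
        seed=seed,
        acceptance_rates={"pi": 1.0},
        category_labels=["idas", "melissa"],
        female_ids=["pooled"],
    )


def conspecific_log_odds(
    idas_pref_draws: np.ndarray,
    melissa_pref_draws: np.ndarray,
    form: str = "sum",
) -> np.ndarray:
    """Posterior draws of the expected conspecific-pairing log odds.

    ``idas_pref_draws`` are draws of the idas-male preference for idas
    models (p_ii); ``melissa_pref_draws`` are draws of the melissa-male
    preference for *idas* models, so p_mm = 1 - that. Draws are paired by
    index (cycled if lengths differ) and clamped to [1e-6, 1 - 1e-6] before
    the log, so the output is always finite.
    """
    if form not in ("sum", "product"):
        raise InvalidInputError("form must be 'sum' or 'product'")
    p_ii, mel_idas = _paired(idas_pref_draws, melissa_pref_draws)
    p_ii = np.clip(p_ii, _CLAMP, 1.0 - _CLAMP)
    p_mm = np.clip(1.0 - mel_idas, _CLAMP, 1.0 - _CLAMP)
    p_im = 1.0 - p_ii
    p_mi = 1.0 - p_mm
    if form == "sum":
        return np.log((p_ii + p_mm) / (p_im + p_mi))
    return np.log((p_ii * p_mm) / (p_im * p_mi))
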