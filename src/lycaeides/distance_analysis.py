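"""Distance-matrix correlation analyses.

Pairwise population divergence is compared across data types: genetic
distance (a genome-level F parameter supplied as a matrix), great-circle
geographic distance, and phenotypic distances built as absolute differences
of posterior point estimates. Association is tested with Mantel tests
(simultaneous row/column permutation), partial Mantel tests (correlation of
residual matrices after regressing both distances on geography), multiple
regression on distance matrices (MRM), and a Monte-Carlo partial Mantel that
propagates posterior uncertainty by resampling the trait point estimates.

Permutation p-values use the add-one rule; the default alternative is
one-sided ("greater"), matching directional isolation-by-distance
hypotheses. The residual-matrix partial Mantel permutes labels of the
residual matrices, a variant known to be somewhat anti-conservative; it is
retained because it is the procedure under study, and the choice is recorded
in every result.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, InvalidInputError

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "MRMResult",
    "phenotype_distance",
    "geographic_distance",
    "mantel",
    "partial_mantel",
    "mrm",
    "monte_carlo_partial_mantel",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray  # (n, n) symmetric, zero diagonal, non-negative
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InvalidInputError("matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise InvalidInputError("labels must be unique")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise InvalidInputError("matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise InvalidInputError("diagonal must be exactly zero")
        if np.any(self.values < 0):
            raise InvalidInputError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    alternative: str  # "greater" | "two-sided"
    mode: str  # "sampled" | "exhaustive"
    seed: int | None = None
    metadata: dict = field(default_factory=dict)


@dataclass
class MRMResult:
    coefficients: dict  # predictor name -> OLS coefficient (plus "intercept")
    r_squared: float
    coefficient_p: dict
    overall_p: float
    n_perm: int
    seed: int | None = None
    metadata: dict = field(default_factory=dict)


def phenotype_distance(point_estimates: dict, kind: str = "phenotypic") -> DistanceMatrix:
    """Pairwise |difference| matrix of scalar trait point estimates."""
    labels = list(point_estimates)
    if len(labels) < 3:
        raise InvalidInputError("need >= 3 populations for a permutation test")
    v = np.array([float(point_estimates[k]) for k in labels])
    return DistanceMatrix(labels=labels, values=np.abs(v[:, None] - v[None, :]), kind=kind)


def geographic_distance(coordinates: dict) -> DistanceMatrix:
    """Great-circle distances (km) from (lat, lon) in degrees, spherical
    Earth of radius 6371.0088 km (haversine formula)."""
    labels = list(coordinates)
    lat = np.radians([coordinates[k][0] for k in labels])
    lon = np.radians([coordinates[k][1] for k in labels])
    if np.any(np.abs(lat) > np.pi / 2 + 1e-12) or np.any(np.abs(lon) > np.pi + 1e-12):
        raise InvalidInputError("latitude must be in [-90, 90], longitude in [-180, 180]")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(labels=labels, values=d, kind="geographic")


def _check_pair(A: DistanceMatrix, B: DistanceMatrix) -> None:
    if A.labels != B.labels:
        raise InvalidInputError("distance matrices must share identical labels")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        raise DegenerateInputError("zero variance in a distance triangle")
    return float(np.clip(xc @ yc / (sx * sy), -1.0, 1.0))


def _perm_triangles(values: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Upper triangles of values[perm][:, perm] for a batch of permutations."""
    iu0, iu1 = np.triu_indices(values.shape[0], 1)
    return values[perms[:, iu0], perms[:, iu1]]


def mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "greater",
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel test: Pearson correlation of unfolded distance triangles, with
    significance from simultaneous row/column permutation of B.

    ``exhaustive=True`` enumerates all n! label permutations (n <= 8); the
    p-value is then the exact fraction of permutations (identity included)
    at least as extreme as the observed correlation.
    """
    _check_pair(A, B)
    n = A.n
    if n < 3:
        raise InvalidInputError("need >= 3 populations")
    if alternative not in ("greater", "two-sided"):
        raise InvalidInputError("alternative must be 'greater' or 'two-sided'")
    a = A.condensed()
    r_obs = _pearson(a, B.condensed())

    if exhaustive:
        if n > 8:
            raise InvalidInputError("exhaustive mode limited to n <= 8")
        perms = np.array(list(itertools.permutations(range(n))))
        tris = _perm_triangles(B.values, perms)
        r_perm = np.array([_pearson(a, t) for t in tris])
        if alternative == "greater":
            extreme = r_perm >= r_obs - 1e-12
        else:
            extreme = np.abs(r_perm) >= abs(r_obs) - 1e-12
        p = float(np.mean(extreme))
        return MantelResult(r=r_obs, p=p, n_perm=math.factorial(n),
                            alternative=alternative, mode="exhaustive", seed=None,
                            metadata={"kinds": (A.kind, B.kind)})

    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    tris = _perm_triangles(B.values, perms)
    # vectorized Pearson across permuted triangles
    ac = a - a.mean()
    tc = tris - tris.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac @ ac) * (tc**2).sum(axis=1))
    if np.any(denom == 0):
        raise DegenerateInputError("zero variance in a permuted triangle")
    r_perm = tc @ ac / denom
    if alternative == "greater":
        count = int(np.sum(r_perm >= r_obs - 1e-12))
    else:
        count = int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))
    p = (1.0 + count) / (1.0 + n_perm)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, alternative=alternative,
                        mode="sampled", seed=seed,
                        metadata={"kinds": (A.kind, B.kind)})


def _residual_matrix(Y: DistanceMatrix, Z: DistanceMatrix) -> DistanceMatrix:
    """Refold OLS residuals of Y's triangle on Z's triangle (with intercept)
    into a symmetric zero-diagonal matrix."""
    y = Y.condensed()
    z = Z.condensed()
    if np.std(z) == 0:
        raise DegenerateInputError("controlling matrix has zero variance")
    X = np.column_stack([np.ones_like(z), z])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = Y.n
    M = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    M[iu] = resid
    M = M + M.T
    out = DistanceMatrix.__new__(DistanceMatrix)  # residuals may be negative
    out.labels = list(Y.labels)
    out.values = M
    out.kind = f"residual:{Y.kind}"
    return out


def partial_mantel(
    G: DistanceMatrix,
    P: DistanceMatrix,
    Z: DistanceMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Partial Mantel test of G vs P controlling for Z: both triangles are
    OLS-regressed on Z's triangle, residuals are refolded into matrices, and
    a Mantel test runs on the residual matrices."""
    _check_pair(G, P)
    _check_pair(G, Z)
    if G.n < 4:
        raise InvalidInputError("partial Mantel needs >= 4 populations")
    rg = _residual_matrix(G, Z)
    rp = _residual_matrix(P, Z)
    if np.std(rg.condensed()) < 1e-12 * max(np.std(G.condensed()), 1e-300) or (
        np.std(rp.condensed()) < 1e-12 * max(np.std(P.condensed()), 1e-300)
    ):
        raise DegenerateInputError("residuals are numerically zero (collinear with Z)")
    res = mantel(rg, rp, n_perm=n_perm, seed=seed, alternative=alternative)
    res.metadata = {"kinds": (G.kind, P.kind), "controlled_for": Z.kind,
                    "scheme": "residual-matrix permutation"}
    return res


def mrm(
    G: DistanceMatrix,
    predictors: list[DistanceMatrix],
    n_perm: int = 10_000,
    seed: int = 0,
    names: list[str] | None = None,
) -> MRMResult:
    """Multiple regression on distance matrices.

    OLS of G's unfolded triangle on the predictors' triangles; coefficient
    and R-squared significance by permuting rows/columns of the response
    matrix and re-estimating (add-one rule, two-sided on |coefficient|,
    one-sided on R-squared).
    """
    if not predictors:
        raise InvalidInputError("need >= 1 predictor matrix")
    for P in predictors:
        _check_pair(G, P)
    if names is None:
        names = [P.kind for P in predictors]
    if len(names) != len(predictors) or len(set(names)) != len(names):
        raise InvalidInputError("predictor names must be unique and match predictors")
    y = G.condensed()
    X = np.column_stack([np.ones_like(y)] + [P.condensed() for P in predictors])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X[:, 1:], rowvar=False)
        pairs = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise InvalidInputError(f"rank-deficient design; collinear predictors: {pairs or names}")

    pinv = np.linalg.pinv(X)
    beta = pinv @ y
    fitted = X @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise DegenerateInputError("response triangle has zero variance")
    sse = float(np.sum((y - fitted) ** 2))
    r2 = 1.0 - sse / sst

    rng = np.random.default_rng(seed)
    n = G.n
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    ys = _perm_triangles(G.values, perms)  # (n_perm, m)
    betas = ys @ pinv.T  # (n_perm, k)
    fits = betas @ X.T
    sse_p = np.sum((ys - fits) ** 2, axis=1)
    sst_p = np.sum((ys - ys.mean(axis=1, keepdims=True)) ** 2, axis=1)
    r2_p = 1.0 - sse_p / sst_p
    coef_counts = np.sum(np.abs(betas) >= np.abs(beta)[None, :] - 1e-12, axis=0)
    coef_p = (1.0 + coef_counts) / (1.0 + n_perm)
    overall_p = (1.0 + float(np.sum(r2_p >= r2 - 1e-12))) / (1.0 + n_perm)

    keys = ["intercept"] + list(names)
    return MRMResult(
        coefficients=dict(zip(keys, beta.tolist())),
        r_squared=float(r2),
        coefficient_p=dict(zip(keys, coef_p.tolist())),
        overall_p=float(overall_p),
        n_perm=n_perm,
        seed=seed,
        metadata={"response": G.kind, "scheme": "response-matrix permutation"},
    )


def monte_carlo_partial_mantel(
    posterior_draws: dict,
    G: DistanceMatrix,
    Z: DistanceMatrix,
    n_outer: int = 1000,
    n_perm_inner: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
    kind: str = "phenotypic",
) -> dict:
    """Partial Mantel with posterior uncertainty in the trait estimates.

    Each outer iteration draws one posterior value per population (draws are
    cycled when a population has fewer than ``n_outer``), rebuilds the
    |difference| phenotype matrix, and runs the partial Mantel test. Returns
    median and 2.5/97.5 percentiles of r and of p across iterations;
    iterations hitting a degenerate configuration are dropped and counted.
    """
    if n_outer < 1:
        raise InvalidInputError("n_outer must be >= 1")
    labels = list(G.labels)
    missing = [l for l in labels if l not in posterior_draws]
    if missing:
        raise InvalidInputError(f"populations without posterior draws: {missing}")
    draws = {l: np.asarray(posterior_draws[l], dtype=float).ravel() for l in labels}
    if any(d.size == 0 for d in draws.values()):
        raise InvalidInputError("empty posterior draw vector")
    rng = np.random.default_rng(seed)
    rs, ps = [], []
    dropped = 0
    for it in range(n_outer):
        est = {l: float(draws[l][it % draws[l].size]) for l in labels}
        P = phenotype_distance(est, kind=kind)
        try:
            res = partial_mantel(G, P, Z, n_perm=n_perm_inner,
                                 seed=int(rng.integers(2**31 - 1)),
                                 alternative=alternative)
        except DegenerateInputError:
            dropped += 1
            continue
        rs.append(res.r)
        ps.append(res.p)
    if not rs:
        raise DegenerateInputError("every Monte-Carlo iteration was degenerate")
    rs_arr, ps_arr = np.array(rs), np.array(ps)
    q = [0.5, 0.025, 0.975]
    r_med, r_lo, r_hi = np.quantile(rs_arr, q)
    p_med, p_lo, p_hi = np.quantile(ps_arr, q)
    return {
        "r_median": float(r_med), "r_etpi": (float(r_lo), float(r_hi)),
        "p_median": float(p_med), "p_etpi": (float(p_lo), float(p_hi)),
        "n_iterations": len(rs), "n_dropped": dropped,
        "alternative": alternative,
    }
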