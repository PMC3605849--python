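import numpy as np
import pytest

from lycaeides.distance_analysis import (
    DistanceMatrix,
    geographic_distance,
    mantel,
    monte_carlo_partial_mantel,
    mrm,
    partial_mantel,
    phenotype_distance,
)
from lycaeides.errors import DegenerateInputError, InvalidInputError
from lycaeides.synthetic_data import gen_distance_system


def _dm(values, kind="generic"):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(labels=[f"p{i}" for i in range(values.shape[0])],
                          values=values, kind=kind)


def _random_dm(rng, n):
    pts = rng.normal(size=(n, 2))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    return _dm(d)


class TestPhenotypeDistance:
    def test_equal_estimates_give_zero_matrix(self):
        D = phenotype_distance({"a": 0.4, "b": 0.4, "c": 0.4})
        assert np.all(D.values == 0)

    def test_hand_arithmetic(self):
        D = phenotype_distance({"a": 0.2, "b": 0.5, "c": 0.9})
        iu = np.triu_indices(3, 1)
        assert sorted(np.round(D.values[iu], 10)) == [0.3, 0.4, 0.7]

    def test_triangle_inequality(self):
        rng = np.random.default_rng(0)
        est = {f"p{i}": rng.uniform() for i in range(6)}
        D = phenotype_distance(est).values
        n = D.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-12

    def test_two_labels_rejected(self):
        with pytest.raises(InvalidInputError):
            phenotype_distance({"a": 0.1, "b": 0.2})


class TestGeographicDistance:
    def test_identical_points_zero(self):
        D = geographic_distance({"a": (43.5, -110.7), "b": (43.5, -110.7), "c": (44, -110)})
        assert D.values[0, 1] == 0.0

    def test_antipodal_meridian_arc(self):
        D = geographic_distance({"a": (0.0, 0.0), "b": (0.0, 180.0), "c": (0.0, 90.0)})
        assert D.values[0, 1] == pytest.approx(np.pi * 6371.0088, rel=1e-6)

    def test_matches_haversine_hand_computation(self):
        lat1, lon1 = np.radians((43.0, -110.0))
        lat2, lon2 = np.radians((44.0, -109.0))
        h = (np.sin((lat2 - lat1) / 2) ** 2
             + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
        expected = 2 * 6371.0088 * np.arcsin(np.sqrt(h))
        D = geographic_distance({"a": (43.0, -110.0), "b": (44.0, -109.0), "c": (45.0, -108.0)})
        assert D.values[0, 1] == pytest.approx(expected, abs=1e-9)

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(InvalidInputError):
            geographic_distance({"a": (95.0, 0.0), "b": (0, 0), "c": (1, 1)})


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        A = _random_dm(rng, 6)
        res = mantel(A, A, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        A = _random_dm(rng, 6)
        B = _dm(2.0 * A.values + 3.0 * (1 - np.eye(6)))
        res = mantel(A, B, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_sampled_p_matches_exhaustive_enumeration_4x4(self):
        rng = np.random.default_rng(3)
        A, B = _random_dm(rng, 4), _random_dm(rng, 4)
        ex = mantel(A, B, exhaustive=True)
        assert ex.n_perm == 24
        sam = mantel(A, B, n_perm=20000, seed=5)
        assert sam.p == pytest.approx(ex.p, abs=0.02)

    def test_matches_scikit_bio_oracle(self):
        pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(4)
        A, B = _random_dm(rng, 8), _random_dm(rng, 8)
        r_skbio, p_skbio, _ = skbio_mantel(
            SkbioDM(A.values), SkbioDM(B.values), method="pearson",
            permutations=999, alternative="greater")
        res = mantel(A, B, n_perm=999, seed=6)
        assert res.r == pytest.approx(r_skbio, abs=1e-10)
        assert res.p == pytest.approx(p_skbio, abs=0.05)

    def test_label_mismatch_rejected(self):
        A = _dm(np.zeros((4, 4)) + 1 - np.eye(4))
        B = DistanceMatrix(labels=list("wxyz"), values=A.values)
        with pytest.raises(InvalidInputError):
            mantel(A, B)

    def test_zero_variance_degenerate(self):
        A = _dm(1 - np.eye(4))
        rng = np.random.default_rng(5)
        with pytest.raises(DegenerateInputError):
            mantel(A, _random_dm(rng, 4), n_perm=9, seed=0)


class TestPartialMantel:
    def test_perfect_partial_correlation(self):
        rng = np.random.default_rng(6)
        G = _random_dm(rng, 7)
        P = _dm(G.values.copy())
        Z = _random_dm(rng, 7)
        res = partial_mantel(G, P, Z, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_collinear_with_control_degenerate(self):
        rng = np.random.default_rng(7)
        Z = _random_dm(rng, 6)
        G = _dm(0.5 * Z.values + 0.1 * (1 - np.eye(6)))
        P = _random_dm(rng, 6)
        with pytest.raises(DegenerateInputError):
            partial_mantel(G, P, Z, n_perm=9, seed=0)

    def test_matches_residual_correlation_oracle(self):
        rng = np.random.default_rng(8)
        G, P, Z = (_random_dm(rng, 5) for _ in range(3))
        res = partial_mantel(G, P, Z, n_perm=9, seed=0)
        iu = np.triu_indices(5, 1)
        g, p, z = G.values[iu], P.values[iu], Z.values[iu]

        def resid(y):
            X = np.column_stack([np.ones_like(z), z])
            return y - X @ np.linalg.lstsq(X, y, rcond=None)[0]

        expected = np.corrcoef(resid(g), resid(p))[0, 1]
        assert res.r == pytest.approx(expected, abs=1e-10)


class TestMRM:
    def test_exact_linear_construction_recovered(self):
        sys_ = gen_distance_system(n_pops=8, b0=0.05, b_geo=2e-4,
                                   b_pheno=0.3, noise_sd=0.0, seed=1)
        res = mrm(sys_.genetic, [sys_.geographic, sys_.phenotypic["trait_1"]],
                  n_perm=99, seed=0, names=["geo", "trait_1"])
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)
        assert res.coefficients["intercept"] == pytest.approx(0.05, abs=1e-8)
        assert res.coefficients["geo"] == pytest.approx(2e-4, abs=1e-8)
        assert res.coefficients["trait_1"] == pytest.approx(0.3, abs=1e-8)

    def test_coefficients_match_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        G, P1, P2 = (_random_dm(rng, 7) for _ in range(3))
        res = mrm(G, [P1, P2], n_perm=9, seed=0, names=["a", "b"])
        iu = np.triu_indices(7, 1)
        X = np.column_stack([np.ones(len(iu[0])), P1.values[iu], P2.values[iu]])
        beta = np.linalg.solve(X.T @ X, X.T @ G.values[iu])
        assert res.coefficients["intercept"] == pytest.approx(beta[0], abs=1e-10)
        assert res.coefficients["a"] == pytest.approx(beta[1], abs=1e-10)
        assert res.coefficients["b"] == pytest.approx(beta[2], abs=1e-10)

    def test_single_predictor_reproduces_mantel_r(self):
        rng = np.random.default_rng(10)
        G, P = _random_dm(rng, 7), _random_dm(rng, 7)
        res = mrm(G, [P], n_perm=9, seed=0, names=["p"])
        r = mantel(G, P, n_perm=9, seed=0).r
        assert np.sign(res.coefficients["p"]) * np.sqrt(res.r_squared) == pytest.approx(
            r, abs=1e-10)

    def test_collinear_predictors_named(self):
        rng = np.random.default_rng(11)
        P = _random_dm(rng, 6)
        G = _random_dm(rng, 6)
        P2 = _dm(2.0 * P.values)
        with pytest.raises(InvalidInputError, match="collinear"):
            mrm(G, [P, P2], n_perm=9, seed=0, names=["p", "p_scaled"])


class TestMonteCarloPartialMantel:
    def test_point_mass_posteriors_zero_width(self):
        sys_ = gen_distance_system(n_pops=8, noise_sd=0.02, seed=2)
        draws = {l: np.full(50, sys_.traits["trait_1"][l]) for l in sys_.labels}
        out = monte_carlo_partial_mantel(draws, sys_.genetic, sys_.geographic,
                                         n_outer=20, n_perm_inner=99, seed=0)
        assert out["r_etpi"][0] == pytest.approx(out["r_etpi"][1])
        assert out["n_dropped"] == 0

    def test_vanishing_sd_collapses_to_point_estimate(self):
        sys_ = gen_distance_system(n_pops=8, noise_sd=0.02, seed=3)
        P = sys_.phenotypic["trait_1"]
        ref = partial_mantel(sys_.genetic, P, sys_.geographic, n_perm=99, seed=1)
        rng = np.random.default_rng(4)
        draws = {l: sys_.traits["trait_1"][l] + 1e-9 * rng.standard_normal(50)
                 for l in sys_.labels}
        out = monte_carlo_partial_mantel(draws, sys_.genetic, sys_.geographic,
                                         n_outer=20, n_perm_inner=99, seed=1)
        assert out["r_median"] == pytest.approx(ref.r, abs=1e-6)

    def test_interval_contains_point_estimate_under_moderate_sd(self):
        hits = 0
        for rep in range(10):
            sys_ = gen_distance_system(n_pops=10, noise_sd=0.02, seed=100 + rep,
                                       posterior_sd=0.05)
            P = sys_.phenotypic["trait_1"]
            ref = partial_mantel(sys_.genetic, P, sys_.geographic, n_perm=199, seed=rep)
            out = monte_carlo_partial_mantel(sys_.trait_posteriors["trait_1"],
                                             sys_.genetic, sys_.geographic,
                                             n_outer=60, n_perm_inner=199, seed=rep)
            if out["r_etpi"][0] - 1e-9 <= ref.r <= out["r_etpi"][1] + 1e-9:
                hits += 1
        assert hits >= 9

    def test_missing_population_rejected(self):
        sys_ = gen_distance_system(n_pops=6, seed=5)
        draws = {l: np.array([0.5]) for l in sys_.labels[:-1]}
        with pytest.raises(InvalidInputError):
            monte_carlo_partial_mantel(draws, sys_.genetic, sys_.geographic,
                                       n_outer=5, n_perm_inner=9, seed=0)
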