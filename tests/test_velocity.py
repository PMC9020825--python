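"""Steady-state gamma fits, velocity signs, graph cosines and driver ranking."""

import numpy as np
import pandas as pd
import pytest

from drivereg import (compute_velocity, fit_gamma, rank_driver_genes,
                      velocity_confidence, velocity_graph)


def _df(arr, cols=None):
    arr = np.atleast_2d(np.asarray(arr, float))
    cols = cols or [f"g{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols)


class TestFitGamma:
    def test_exact_line_recovers_slope(self):
        s = np.linspace(0.1, 5, 40)
        fits = fit_gamma(_df(2 * s[:, None].T).T, _df(s[:, None].T).T)
        assert fits["gamma_hat"].iloc[0] == pytest.approx(2.0)
        assert fits["fitted"].iloc[0]

    def test_noiseless_steady_state_recovery(self):
        # cells at steady state of alpha in [0.5, 3], beta=1, gamma=0.5:
        # (u, s) = (alpha, 2 alpha) so the slope is gamma/beta = 0.5
        alpha = np.linspace(0.5, 3.0, 60)
        fits = fit_gamma(pd.DataFrame({"g": alpha}),
                         pd.DataFrame({"g": alpha / 0.5}))
        assert fits["gamma_hat"].iloc[0] == pytest.approx(0.5, rel=0.10)

    def test_too_few_cells_flagged_unfit(self):
        u = pd.DataFrame({"g": [1.0] * 5 + [0.0] * 20})
        s = pd.DataFrame({"g": [2.0] * 5 + [0.0] * 20})
        fits = fit_gamma(u, s, min_cells=10)
        assert not fits["fitted"].iloc[0]
        assert np.isnan(fits["gamma_hat"].iloc[0])

    def test_all_zero_gene_excluded(self):
        z = pd.DataFrame({"g": np.zeros(30)})
        assert not fit_gamma(z, z)["fitted"].iloc[0]

    def test_gamma_recovery_over_random_draws(self):
        # noiseless steady-state populations for 50 random (beta, gamma)
        rng = np.random.default_rng(9)
        for _ in range(50):
            b, g = rng.uniform(0.3, 2.0, size=2)
            alpha = rng.uniform(0.2, 4.0, size=80)
            fits = fit_gamma(pd.DataFrame({"x": alpha / b}),
                             pd.DataFrame({"x": alpha / g}))
            assert abs(fits["gamma_hat"].iloc[0] - g / b) / (g / b) <= 0.10


class TestComputeVelocity:
    def test_steady_state_cells_have_zero_velocity(self):
        s = np.linspace(0.5, 4, 30)
        u, sdf = _df((0.7 * s)[None, :]).T, _df(s[None, :]).T
        u.columns = sdf.columns = ["g"]
        fits = fit_gamma(u, sdf)
        v = compute_velocity(u, sdf, fits)
        np.testing.assert_allclose(v["g"], 0.0, atol=1e-12)

    def test_induction_cells_have_positive_velocity(self):
        s = pd.DataFrame({"g": np.linspace(0.5, 4, 30)})
        u = pd.DataFrame({"g": 0.7 * s["g"]})
        fits = fit_gamma(u, s)
        v = compute_velocity(u + 0.3, s, fits)   # shifted above the line
        assert (v["g"] > 0).all()

    def test_toy_hand_computation(self):
        fits = pd.DataFrame({"gamma_hat": [0.5], "fitted": [True]}, index=["g"])
        u = pd.DataFrame({"g": [1.0, 2.0, 0.5, 0.0, 3.0]})
        s = pd.DataFrame({"g": [2.0, 2.0, 2.0, 1.0, 4.0]})
        v = compute_velocity(u, s, fits)
        np.testing.assert_allclose(v["g"], [0.0, 1.0, -0.5, -0.5, 1.0])

    def test_unfitted_genes_excluded(self):
        fits = pd.DataFrame({"gamma_hat": [0.5, np.nan], "fitted": [True, False]},
                            index=["a", "b"])
        v = compute_velocity(_df([[1, 1]], ["a", "b"]), _df([[1, 1]], ["a", "b"]), fits)
        assert list(v.columns) == ["a"]


class TestVelocityGraphAndConfidence:
    def test_parallel_and_antiparallel_scores(self):
        X = _df([[0.0, 0.0], [1.0, 0.0], [-2.0, 0.0]], ["a", "b"])
        V = _df([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]], ["a", "b"])
        knn = np.array([[1, 2], [0, 2], [0, 1]])
        g = velocity_graph(V, X, knn)
        assert g[0, 1] == pytest.approx(1.0)    # displacement parallel to v
        assert g[0, 2] == pytest.approx(-1.0)   # antiparallel

    def test_matches_brute_force_cosines(self, rng):
        X = _df(rng.normal(size=(3, 4)))
        V = _df(rng.normal(size=(3, 4)), list(X.columns))
        knn = np.array([[1, 2], [0, 2], [0, 1]])
        g = velocity_graph(V, X, knn)
        for i in range(3):
            for j in knn[i]:
                d = X.to_numpy()[j] - X.to_numpy()[i]
                ref = (V.to_numpy()[i] @ d) / (np.linalg.norm(V.to_numpy()[i]) * np.linalg.norm(d))
                assert g[i, j] == pytest.approx(ref)

    def test_zero_velocity_cell_scores_zero(self):
        X = _df([[0.0, 0.0], [1.0, 1.0]], ["a", "b"])
        V = _df([[0.0, 0.0], [1.0, 0.0]], ["a", "b"])
        g = velocity_graph(V, X, np.array([[1], [0]]))
        assert g[0, 1] == 0.0

    def test_uniform_field_confidence_one(self):
        V = _df(np.tile([1.0, 2.0], (5, 1)), ["a", "b"])
        knn = np.array([[1, 2], [0, 2], [3, 4], [0, 1], [2, 3]])
        conf = velocity_confidence(V, knn)
        np.testing.assert_allclose(conf, 1.0)

    def test_negated_neighbors_confidence_minus_one(self):
        V = _df([[1.0, 0.0], [-1.0, 0.0], [-1.0, 0.0]], ["a", "b"])
        conf = velocity_confidence(V, np.array([[1, 2], [0, 0], [0, 0]]))
        assert conf.iloc[0] == pytest.approx(-1.0)

    def test_permutation_equivariance(self, rng):
        # shuffling cells shuffles velocities identically
        u = pd.DataFrame(rng.uniform(0, 3, (50, 4)), columns=list("abcd"))
        s = pd.DataFrame(rng.uniform(0.1, 3, (50, 4)), columns=list("abcd"))
        fits = fit_gamma(u, s)
        v = compute_velocity(u, s, fits)
        perm = rng.permutation(50)
        v_perm = compute_velocity(u.iloc[perm], s.iloc[perm], fits)
        np.testing.assert_allclose(v_perm.to_numpy(), v.to_numpy()[perm])


class TestRankDriverGenes:
    def _inputs(self, rng, n=60):
        labels = pd.Series(["c"] * n, index=range(n))
        s = pd.DataFrame({
            "dyn": np.linspace(0.1, 4, n),             # sweeps its range
            "flat": np.full(n, 2.0),                   # constant
            "noise": rng.uniform(1.8, 2.2, n),
        }, index=range(n))
        u = pd.DataFrame({
            "dyn": 0.5 * s["dyn"] + 0.3 * np.sin(np.linspace(0, 3, n)),
            "flat": np.full(n, 1.0),
            "noise": 0.5 * s["noise"],
        }, index=range(n))
        return u, s, labels

    def test_constant_gene_ranked_last_with_zero_score(self, rng):
        u, s, labels = self._inputs(rng)
        out = rank_driver_genes(u, s, labels, "c", top_n=10)
        assert out["driver_score"].loc["flat"] == 0.0
        assert list(out.index).index("flat") == len(out) - 1

    def test_truncation_contract(self, rng):
        u, s, labels = self._inputs(rng)
        out = rank_driver_genes(u, s, labels, "c", top_n=100)
        assert len(out) <= 3

    def test_missing_cluster_raises(self, rng):
        u, s, labels = self._inputs(rng)
        with pytest.raises(KeyError):
            rank_driver_genes(u, s, labels, "nope")

    def test_small_cluster_rejected(self, rng):
        u, s, labels = self._inputs(rng, n=10)
        with pytest.raises(ValueError):
            rank_driver_genes(u, s, labels, "c", min_cluster_cells=20)

    def test_mitochondrial_genes_excluded(self, rng):
        u, s, labels = self._inputs(rng)
        u["mt-x"], s["mt-x"] = u["dyn"], s["dyn"]
        out = rank_driver_genes(u, s, labels, "c")
        assert "mt-x" not in out.index
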