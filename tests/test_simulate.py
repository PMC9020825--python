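"""Generator correctness: closed-form kinetics vs an ODE oracle, count noise,
and consistency of the planted truth with the generated data."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import pearsonr

from drivereg import (KineticParams, SimConfig, build_benchmark_dataset,
                      kinetics_closed_form, sample_counts, sample_topology,
                      simulate_latent_kinetics, steady_state)
from drivereg.simulate import BRANCH_A, BRANCH_B, PROGENITOR, LineageTopology


def _ode_oracle(u0, s0, alpha, beta, gamma, t):
    sol = solve_ivp(lambda _, y: [alpha - beta * y[0], beta * y[0] - gamma * y[1]],
                    (0.0, t), [u0, s0], rtol=1e-10, atol=1e-12)
    return sol.y[0, -1], sol.y[1, -1]


class TestClosedFormKinetics:
    def test_reaches_steady_state(self):
        u, s = kinetics_closed_form(0.0, 0.0, alpha=1.0, beta=1.0, gamma=1.0, tau=60.0)
        assert u == pytest.approx(1.0, abs=1e-12)
        assert s == pytest.approx(1.0, abs=1e-12)

    def test_null_transcription_stays_at_zero(self):
        u, s = kinetics_closed_form(0.0, 0.0, alpha=0.0, beta=1.3, gamma=0.7, tau=2.5)
        assert u == 0.0 and s == 0.0

    def test_matches_numerical_integration(self):
        u, s = kinetics_closed_form(0.0, 0.0, alpha=2.0, beta=1.0, gamma=0.5, tau=1.0)
        u_ref, s_ref = _ode_oracle(0.0, 0.0, 2.0, 1.0, 0.5, 1.0)
        assert u == pytest.approx(u_ref, abs=1e-6)
        assert s == pytest.approx(s_ref, abs=1e-6)

    def test_random_parameter_draws_match_ode_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a = rng.uniform(0.0, 3.0)
            b, g = rng.uniform(0.1, 3.0, size=2)
            u0, s0 = rng.uniform(0.0, 2.0, size=2)
            t = rng.uniform(0.0, 10.0)
            u, s = kinetics_closed_form(u0, s0, a, b, g, t)
            u_ref, s_ref = _ode_oracle(u0, s0, a, b, g, t)
            assert abs(u - u_ref) <= 1e-6 and abs(s - s_ref) <= 1e-6

    def test_beta_equals_gamma_limit(self):
        u, s = kinetics_closed_form(0.3, 0.1, 1.5, 0.8, 0.8, 2.0)
        u_ref, s_ref = _ode_oracle(0.3, 0.1, 1.5, 0.8, 0.8, 2.0)
        assert u == pytest.approx(u_ref, abs=1e-8)
        assert s == pytest.approx(s_ref, abs=1e-8)

    def test_rejects_nonpositive_rates(self):
        with pytest.raises(ValueError):
            kinetics_closed_form(0, 0, 1.0, 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            KineticParams(alpha_progenitor=[1.0], alpha_branch_a=[1.0],
                          alpha_branch_b=[1.0], beta=[1.0], gamma=[-1.0], t_switch=1.0)


class TestLatentSimulation:
    def _params(self):
        return KineticParams(alpha_progenitor=[1.0, 2.0], alpha_branch_a=[1.0, 0.5],
                             alpha_branch_b=[4.0, 2.0], beta=[1.0, 1.0],
                             gamma=[0.5, 1.0], t_switch=2.0)

    def test_continuous_at_switch(self):
        params = self._params()
        eps = 1e-9
        topo = LineageTopology(t=np.array([2.0 - eps, 2.0, 2.0]),
                               branch=np.array([PROGENITOR, BRANCH_A, BRANCH_B], object),
                               t_switch=2.0, t_max=4.0)
        U, S = simulate_latent_kinetics(topo, params, initial_state=(0.0, 0.0))
        np.testing.assert_allclose(U[0], U[1], atol=1e-6)
        np.testing.assert_allclose(U[1], U[2], atol=1e-12)
        np.testing.assert_allclose(S[0], S[1], atol=1e-6)

    def test_steady_initial_state_keeps_progenitors_on_fixed_point(self):
        params = self._params()
        topo = sample_topology(200, t_max=4.0, t_switch=2.0, rng=0)
        U, S = simulate_latent_kinetics(topo, params)
        pre = topo.t < 2.0
        u_star, s_star = steady_state(params.alpha_progenitor, params.beta, params.gamma)
        np.testing.assert_allclose(U[pre], np.tile(u_star, (pre.sum(), 1)), rtol=1e-12)
        np.testing.assert_allclose(S[pre], np.tile(s_star, (pre.sum(), 1)), rtol=1e-12)

    def test_progenitors_are_pre_switch_cells(self):
        topo = sample_topology(500, t_max=10.0, t_switch=4.0, rng=1)
        assert ((topo.branch == PROGENITOR) == (topo.t < 4.0)).all()
        with pytest.raises(ValueError):
            LineageTopology(t=np.array([1.0]), branch=np.array([BRANCH_B], object),
                            t_switch=4.0, t_max=10.0)


class TestCountSampling:
    def test_zero_latent_gives_zero_counts(self):
        Z = np.zeros((5, 3))
        ds = sample_counts(Z, Z, rng=0)
        assert ds.spliced.nnz == 0 and ds.unspliced.nnz == 0

    def test_seed_determinism(self):
        L = np.random.default_rng(5).uniform(0, 4, size=(20, 10))
        a = sample_counts(L, L / 3, rng=99)
        b = sample_counts(L, L / 3, rng=99)
        assert (a.spliced != b.spliced).nnz == 0
        assert (a.unspliced != b.unspliced).nnz == 0

    def test_empirical_mean_matches_scaled_latent(self):
        # one gene holding 30% of a cell's latent mass, 10k replicate cells
        latent = np.tile([[3.0, 7.0]], (10_000, 1))
        ds = sample_counts(latent, latent, depth=100.0, dispersion=0.4,
                           depth_sigma=0.0, rng=3)
        x = np.asarray(ds.spliced[:, 0].todense()).ravel()
        expected = 30.0  # 3/10 of depth 100
        se = x.std(ddof=1) / np.sqrt(len(x))
        assert abs(x.mean() - expected) < 3 * se

    def test_zero_dispersion_is_poisson(self):
        latent = np.tile([[5.0, 5.0]], (20_000, 1))
        ds = sample_counts(latent, latent, depth=20.0, dispersion=0.0,
                           depth_sigma=0.0, rng=8)
        x = np.asarray(ds.spliced[:, 0].todense()).ravel()
        # Poisson: variance == mean (within sampling error)
        assert x.var(ddof=1) == pytest.approx(x.mean(), rel=0.05)

    def test_rejects_negative_dispersion(self):
        with pytest.raises(ValueError):
            sample_counts(np.ones((2, 2)), np.ones((2, 2)), dispersion=-0.1, rng=0)


class TestBenchmarkTruth:
    def test_zero_planted_drivers_gives_empty_truth(self):
        cfg = SimConfig(n_cells=50, n_genes=80, n_drivers=0, n_regulons=0,
                        n_signature=0, n_mito=4, n_cycle=0)
        _, truth = build_benchmark_dataset(cfg, seed=0)
        assert truth.driver_genes == []

    def test_planted_driver_count_matches_config(self, small_config, small_benchmark):
        _, truth = small_benchmark
        assert len(truth.driver_genes) == small_config.n_drivers

    def test_tf_target_coupling_in_latent_space(self, small_benchmark):
        ds, truth = small_benchmark
        for tf, targets in truth.regulon_map.items():
            j = ds.var_names.get_loc(tf)
            cols = ds.var_names.get_indexer(targets)
            r, _ = pearsonr(truth.latent_s[:, j], truth.latent_s[:, cols].mean(axis=1))
            assert r > 0.3, f"regulon {tf} decoupled from its targets (r={r:.2f})"

    def test_ligand_receptor_branch_bias(self, small_benchmark):
        ds, truth = small_benchmark
        b = truth.branch.to_numpy()
        S = pd.DataFrame(truth.latent_s, columns=ds.var_names)
        for ligand, receptor, _pathway, sign in truth.ligand_receptor_pairs:
            bias = S[ligand][b == BRANCH_A].mean() - S[ligand][b == BRANCH_B].mean()
            rbias = S[receptor][b == BRANCH_A].mean() - S[receptor][b == BRANCH_B].mean()
            assert np.sign(bias) == sign
            assert np.sign(rbias) == -sign

    def test_layers_share_index_ordering(self, small_benchmark):
        ds, _ = small_benchmark
        assert ds.spliced.shape == ds.unspliced.shape
        assert len(ds.var_names) == ds.spliced.shape[1]
        assert ds.obs.index.is_unique and ds.var_names.is_unique

    def test_planted_sets_exceeding_genes_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_cells=10, n_genes=50, n_drivers=100)

    def test_seed_reproducibility(self, small_config):
        a, _ = build_benchmark_dataset(small_config, seed=3)
        b, _ = build_benchmark_dataset(small_config, seed=3)
        assert (a.spliced != b.spliced).nnz == 0
        assert a.obs["cluster"].equals(b.obs["cluster"])
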