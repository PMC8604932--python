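import numpy as np
import pandas as pd
import pytest

from compnoise.io import CountMatrix
from compnoise.model import (
    ModelSpec,
    PosteriorSummary,
    SizeFactors,
    estimate_size_factors,
    fit_noise_model,
    fit_trend_map,
    rbf_basis,
    residual_overdispersion,
)

from conftest import SHORT_SPEC, model_counts


class TestSizeFactors:
    def test_identical_cells_get_unit_factors(self):
        counts = np.tile([[5], [3], [7]], (1, 6))
        cm = CountMatrix(counts, ["g1", "g2", "g3"], [f"c{j}" for j in range(6)])
        np.testing.assert_allclose(estimate_size_factors(cm, [3]).values, 1.0)
        np.testing.assert_allclose(estimate_size_factors(cm).values, 1.0)

    def test_doubled_cell_has_double_factor_in_library_mode(self):
        base = np.array([[2], [4], [1]])
        counts = np.hstack([base, 2 * base])
        cm = CountMatrix(counts, ["g1", "g2", "g3"], ["c1", "c2"])
        sf = estimate_size_factors(cm)  # library-size mode
        assert sf.values[1] == pytest.approx(2 * sf.values[0])

    def test_pooled_factors_match_explicit_linear_system(self):
        """Brute-force oracle: build every pool equation by hand and solve
        the same least-squares problem with numpy.lstsq."""
        rng = np.random.default_rng(7)
        counts = rng.poisson(rng.uniform(2, 10, size=6)[None, :] * rng.uniform(0.5, 3, size=12)[:, None])
        counts[counts.sum(axis=1) == 0, 0] += 1
        cm = CountMatrix(counts, [f"g{i}" for i in range(12)], [f"c{j}" for j in range(6)])
        pool_size = 3
        totals = counts.sum(axis=0).astype(float)
        order = np.argsort(totals, kind="stable")
        ref = counts.mean(axis=1)
        rows, rhs = [], []
        for start in range(6):
            members = order[(start + np.arange(pool_size)) % 6]
            row = np.zeros(6)
            row[members] = 1.0
            pooled = counts[:, members].sum(axis=1)
            rows.append(row)
            rhs.append(np.median(pooled[ref > 0] / ref[ref > 0]))
        lib = totals / totals.mean()
        for j in range(6):
            row = np.zeros(6)
            row[j] = 0.1
            rows.append(row)
            rhs.append(0.1 * lib[j])
        expected = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)[0]
        expected = np.clip(expected, 1e-8, None)
        expected /= expected.mean()
        got = estimate_size_factors(cm, [pool_size]).values
        np.testing.assert_allclose(got, expected, rtol=1e-6)

    def test_zero_total_cell_is_rejected_with_guidance(self):
        cm = CountMatrix([[1, 0], [2, 0]], ["g1", "g2"], ["ok", "empty"])
        with pytest.raises(ValueError, match="filter these cells"):
            estimate_size_factors(cm)


class TestTrend:
    def test_trend_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        logmu = rng.normal(1, 1, 60)
        logdelta = -0.5 - 0.7 * logmu + rng.normal(0, 0.3, 60)
        centers = np.linspace(logmu.min(), logmu.max(), 8)
        width = 1.2 * (centers[1] - centers[0])
        sigma2, tau2 = 0.09, 25.0
        beta = fit_trend_map(logmu, logdelta, centers, width, sigma2, tau2)
        # independent oracle: augmented least squares (ridge as data augmentation)
        B = np.hstack([np.ones((60, 1)), logmu[:, None],
                       np.exp(-((logmu[:, None] - centers[None, :]) ** 2) / (2 * width**2))])
        K = B.shape[1]
        A_aug = np.vstack([B / np.sqrt(sigma2), np.eye(K) / np.sqrt(tau2)])
        y_aug = np.concatenate([logdelta / np.sqrt(sigma2), np.zeros(K)])
        oracle = np.linalg.lstsq(A_aug, y_aug, rcond=None)[0]
        np.testing.assert_allclose(beta, oracle, atol=1e-8)

    def test_basis_contains_intercept_and_linear_term(self):
        x = np.array([0.0, 1.0, 2.0])
        B = rbf_basis(x, np.array([0.0, 2.0]), 1.0)
        np.testing.assert_allclose(B[:, 0], 1.0)
        np.testing.assert_allclose(B[:, 1], x)


class TestFitNoiseModel:
    def test_seeded_determinism(self):
        cm, meta, truth = model_counts(seed=2, G=30, N=80, n_batches=2)
        sf = SizeFactors(truth["s"], cm.cell_ids)
        spec = ModelSpec(n_iter=120, burn_in=60, thin=2, seed=9)
        a = fit_noise_model(cm, meta, sf, spec)
        b = fit_noise_model(cm, meta, sf, spec)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.delta, b.delta)
        np.testing.assert_array_equal(a.eps, b.eps)
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_single_replicate_batch_rejected(self):
        cm, meta, truth = model_counts(seed=2, G=10, N=40, n_batches=1)
        sf = SizeFactors(truth["s"], cm.cell_ids)
        with pytest.raises(ValueError, match="replicate batches"):
            fit_noise_model(cm, meta, sf, SHORT_SPEC)

    def test_chain_validity_positive_draws_finite_logpost(self, model_fit):
        _, _, _, ps = model_fit
        assert ps.n_draws == SHORT_SPEC.n_stored
        assert np.all(ps.mu > 0)
        assert np.all(ps.delta >= 0)
        assert np.all(ps.theta >= 0)
        assert np.all(np.isfinite(ps.log_post))

    def test_eps_draws_center_near_zero_each_iteration(self, model_fit):
        _, _, _, ps = model_fit
        per_draw_mean = ps.eps.mean(axis=1)
        assert np.abs(per_draw_mean).max() < 0.15

    def test_recovery_of_mu_and_delta_on_model_data(self, model_fit):
        from scipy.stats import spearmanr
        _, _, truth, ps = model_fit
        assert spearmanr(truth["mu"], ps.median_mu().values).statistic > 0.95
        assert spearmanr(truth["delta"], ps.median_delta().values).statistic > 0.7

    def test_pure_poisson_data_gives_near_zero_overdispersion(self):
        cm, meta, truth = model_counts(
            seed=4, G=60, N=500, n_batches=2, trend=(-30.0, 0.0), sigma_eps=0.0
        )
        sf = SizeFactors(truth["s"], cm.cell_ids)
        ps = fit_noise_model(cm, meta, sf, ModelSpec(n_iter=500, burn_in=250, thin=5, seed=3))
        frac_small = (ps.median_delta().values < 0.05).mean()
        assert frac_small >= 0.9

    def test_technical_biological_separation(self):
        """Between-replicate variability loads on theta, not delta."""
        med_deltas, med_thetas = {}, {}
        for th in (0.0, 0.1):
            cm, meta, truth = model_counts(seed=6, G=60, N=240, n_batches=4, theta=th)
            sf = SizeFactors(truth["s"], cm.cell_ids)
            ps = fit_noise_model(cm, meta, sf, ModelSpec(n_iter=500, burn_in=250, thin=5, seed=5))
            med_deltas[th] = ps.median_delta().values
            med_thetas[th] = np.median(ps.theta)
        assert med_thetas[0.1] > 0.05
        assert med_thetas[0.0] < 0.02
        # biological over-dispersion essentially unchanged
        ratio = np.median(med_deltas[0.1] / med_deltas[0.0])
        assert 0.7 < ratio < 1.4

    def test_moment_identity_on_generated_counts(self):
        """Sample variance tracks m + delta m^2 when nu = s is fixed."""
        cm, meta, truth = model_counts(seed=8, G=40, N=2000, n_batches=2, s_logsd=0.0)
        m = cm.counts.mean(axis=1)
        v = cm.counts.var(axis=1)
        expected = m + truth["delta"] * m**2
        rel = (v - expected) / expected
        assert np.abs(np.median(rel)) < 0.1

    def test_posterior_round_trip_through_store(self, model_fit, tmp_path):
        _, _, _, ps = model_fit
        ps.to_dir(tmp_path / "store")
        back = PosteriorSummary.from_dir(tmp_path / "store")
        np.testing.assert_array_equal(back.mu, ps.mu)
        np.testing.assert_array_equal(back.eps, ps.eps)
        assert back.gene_ids == ps.gene_ids


class TestResidualOverdispersion:
    def test_eps_uncorrelated_with_mean(self, model_fit):
        _, _, _, ps = model_fit
        r = np.corrcoef(ps.median_eps().values, np.log(ps.median_mu().values))[0, 1]
        assert abs(r) < 0.15

    def test_zero_residual_scatter_gives_small_eps(self):
        cm, meta, truth = model_counts(seed=12, G=60, N=400, n_batches=2, sigma_eps=0.0)
        sf = SizeFactors(truth["s"], cm.cell_ids)
        ps = fit_noise_model(cm, meta, sf, ModelSpec(n_iter=500, burn_in=250, thin=5, seed=7))
        assert np.median(np.abs(ps.median_eps().values)) < 0.2

    def test_trend_fit_is_gene_order_invariant(self):
        rng = np.random.default_rng(13)
        logmu = rng.normal(1, 1, 50)
        logdelta = -0.6 - 0.4 * logmu + rng.normal(0, 0.4, 50)
        centers = np.linspace(logmu.min(), logmu.max(), 10)
        width = 1.2 * (centers[1] - centers[0])
        beta = fit_trend_map(logmu, logdelta, centers, width, 0.2, 25.0)
        resid = logdelta - rbf_basis(logmu, centers, width) @ beta
        perm = rng.permutation(50)
        beta_p = fit_trend_map(logmu[perm], logdelta[perm], centers, width, 0.2, 25.0)
        resid_p = logdelta[perm] - rbf_basis(logmu[perm], centers, width) @ beta_p
        np.testing.assert_allclose(resid_p, resid[perm], atol=1e-10)

    def test_summary_table_covers_all_genes(self, model_fit):
        _, _, _, ps = model_fit
        tab = residual_overdispersion(ps)
        assert list(tab.index) == ps.gene_ids
        assert np.all(tab["eps_lo90"] <= tab["eps_median"])
        assert np.all(tab["eps_median"] <= tab["eps_hi90"])
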