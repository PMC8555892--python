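"""Bayesian replication-rate inference: noise, grid posterior, combination."""

import numpy as np
import pandas as pd
import pytest

from taukinetics import core, inference, synthetic
from taukinetics.inference import (GridSpec, KappaPosterior, MeasurementSet,
                                   PosteriorGrid)


def _ms(times, values, region="PV", subject="S1"):
    return MeasurementSet(pd.DataFrame({
        "subject": subject, "region": region,
        "time_years": times, "value": values}))


class TestNoiseSD:
    def test_two_replicates_hand_arithmetic(self):
        ms = _ms([0.0, 0.0, 10.0, 10.0], [10.0, 1000.0, 5.0, 5.0])
        # group at t=0 has log10 values (1, 3): SD sqrt(2); t=10 contributes 0
        sd = inference.estimate_noise_sd(ms)
        assert sd == pytest.approx(np.sqrt(((1 - 2) ** 2 + (3 - 2) ** 2) / 2))

    def test_identical_replicates_degenerate(self):
        ms = _ms([0.0, 0.0, 5.0, 5.0], [7.0, 7.0, 7.0, 7.0])
        with pytest.warns(UserWarning, match="degenerate"):
            assert inference.estimate_noise_sd(ms) == 0.0

    def test_no_replicates_rejected(self):
        ms = _ms([0.0, 10.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="replicate"):
            inference.estimate_noise_sd(ms)

    def test_lognormal_replicates_recover_sigma(self, rng):
        sigma = 0.3
        rows = []
        for g in range(200):
            for _ in range(3):
                rows.append({"subject": f"S{g}", "region": "PV",
                             "time_years": float(g % 4),
                             "value": 10 ** rng.normal(2.0, sigma)})
        sd = inference.estimate_noise_sd(MeasurementSet(pd.DataFrame(rows)))
        assert abs(sd - sigma) < 0.03


class TestPosteriorGrid:
    def test_normalization_and_prior_dominance_with_weak_data(self):
        # a single observation leaves the posterior close to the prior along
        # unconstrained directions; with huge noise it reverts to the prior
        ms = _ms([0.0, 10.0], [5.0, 5.0])
        grid = inference.posterior_grid(ms, sigma=1e6)
        assert grid.density.sum() == pytest.approx(1.0, abs=1e-12)
        marg = inference.marginal_kappa(grid)
        # 1/kappa prior on a log-spaced grid: flat mass per node
        assert np.ptp(marg.mass) < 1e-6

    def test_recovers_generating_kappa(self, rng):
        kappa, f0, alpha, sigma = 0.17, 1e-4, 100.0, 0.2
        times = np.array([0.0, 21.0, 29.0, 34.0])
        rows = []
        for t in times:
            for _ in range(5):
                s = alpha * core.logistic_fraction(t, kappa, f0)
                rows.append({"subject": "S1", "region": "PV", "time_years": t,
                             "value": s * 10 ** rng.normal(0, sigma)})
        grid = inference.posterior_grid(MeasurementSet(pd.DataFrame(rows)), sigma)
        post = inference.marginal_kappa(grid)
        assert abs(post.mean - kappa) < post.sd + 0.02

    def test_doubling_noise_widens_posterior(self, devos_like):
        g1 = inference.posterior_grid(devos_like, sigma=0.3, region="PV")
        g2 = inference.posterior_grid(devos_like, sigma=0.6, region="PV")
        assert inference.marginal_kappa(g2).sd > inference.marginal_kappa(g1).sd

    def test_narrow_grid_records_boundary_warning(self, devos_like):
        spec = GridSpec(n_kappa=20, kappa_bounds=(1e-3, 1e-2))
        grid = inference.posterior_grid(devos_like, sigma=0.3, grid_spec=spec,
                                        region="PV")
        assert "warning" in grid.meta


class TestMarginalization:
    def _separable_grid(self):
        spec = GridSpec(n_kappa=40, n_f0=30, n_alpha=20)
        k, f0, a = spec.axes(max_value=1.0)
        pk = np.exp(-0.5 * ((np.log(k) - np.log(0.2)) / 0.4) ** 2)
        pf = np.exp(-0.5 * ((np.log10(f0) + 5) / 1.0) ** 2)
        pa = np.linspace(1, 2, a.size)
        dens = pk[:, None, None] * pf[None, :, None] * pa[None, None, :]
        dens /= dens.sum()
        return PosteriorGrid(kappa_axis=k, f0_axis=f0, alpha_axis=a, density=dens), pk

    def test_separable_density_marginal(self):
        grid, pk = self._separable_grid()
        marg = inference.marginal_kappa(grid)
        np.testing.assert_allclose(marg.mass, pk / pk.sum(), rtol=1e-10)

    def test_delta_density_marginal(self):
        grid, _ = self._separable_grid()
        dens = np.zeros_like(grid.density)
        dens[17, 3, 5] = 1.0
        grid2 = PosteriorGrid(grid.kappa_axis, grid.f0_axis, grid.alpha_axis, dens)
        marg = inference.marginal_kappa(grid2)
        assert marg.mass[17] == 1.0

    def test_monte_carlo_marginal_agrees(self, rng):
        grid, _ = self._separable_grid()
        marg = inference.marginal_kappa(grid)
        flat = grid.density.ravel()
        draws = rng.choice(flat.size, size=1_000_000, p=flat)
        k_idx = np.unravel_index(draws, grid.density.shape)[0]
        mc_mass = np.bincount(k_idx, minlength=grid.kappa_axis.size) / draws.size
        tv = 0.5 * np.abs(mc_mass - marg.mass).sum()
        assert tv < 0.005


class TestCombination:
    @staticmethod
    def _gaussian_post(mean, sd, axis):
        m = np.exp(-0.5 * ((axis - mean) / sd) ** 2)
        return KappaPosterior(kappa_axis=axis, mass=m)

    def test_flat_posterior_is_identity(self):
        axis = np.linspace(0.01, 0.5, 400)
        p = self._gaussian_post(0.17, 0.05, axis)
        flat = KappaPosterior(kappa_axis=axis, mass=np.ones_like(axis))
        combined = inference.combine_marginals([p, flat])
        np.testing.assert_allclose(combined.mass, p.mass, atol=1e-12)

    def test_two_gaussians_precision_weighted(self):
        axis = np.linspace(1e-4, 0.4, 4000)
        pa = self._gaussian_post(0.17, 0.05, axis)
        pb = self._gaussian_post(0.08, 0.02, axis)
        combined = inference.combine_marginals([pa, pb])
        assert combined.mean == pytest.approx(0.0924, abs=5e-4)
        assert combined.sd == pytest.approx(0.0186, abs=5e-4)

    def test_k_identical_posteriors_narrow_by_sqrt_k(self):
        axis = np.linspace(1e-4, 0.6, 6000)
        p = self._gaussian_post(0.2, 0.05, axis)
        combined = inference.combine_marginals([p] * 4)
        assert combined.sd == pytest.approx(0.05 / 2, rel=0.01)

    def test_permutation_invariance_and_associativity(self):
        axis = np.geomspace(0.01, 1.0, 300)
        posts = [self._gaussian_post(m, s, axis)
                 for m, s in ((0.17, 0.05), (0.08, 0.03), (0.2, 0.1))]
        a = inference.combine_marginals(posts)
        b = inference.combine_marginals(posts[::-1])
        c = inference.combine_marginals(
            [inference.combine_marginals(posts[:2]), posts[2]])
        np.testing.assert_allclose(a.mass, b.mass, atol=1e-12)
        np.testing.assert_allclose(a.mass, c.mass, atol=1e-12)

    def test_disjoint_support_rejected(self):
        axis = np.linspace(0.01, 1.0, 100)
        p1 = KappaPosterior(axis, np.r_[np.ones(50), np.zeros(50)])
        p2 = KappaPosterior(axis, np.r_[np.zeros(50), np.ones(50)])
        with pytest.raises(ValueError, match="disjoint"):
            inference.combine_marginals([p1, p2])


class TestMedianFit:
    def test_noiseless_exact_recovery(self):
        kappa, f0, alpha = 0.2, 1e-4, 50.0
        t = np.array([0.0, 10.0, 21.0, 29.0, 34.0])
        med = alpha * core.logistic_fraction(t, kappa, f0)
        fit = inference.lsq_median_fit(t, med)
        assert fit["kappa"] == pytest.approx(kappa, rel=1e-4)
        assert fit["residual"] < 1e-10

    def test_noisy_medians_within_ten_percent(self, rng):
        kappa, f0, alpha = 0.2, 1e-4, 50.0
        t = np.array([0.0, 10.0, 21.0, 29.0, 34.0])
        med = (alpha * core.logistic_fraction(t, kappa, f0)
               * 10 ** rng.normal(0, 0.05, t.size))
        fit = inference.lsq_median_fit(t, med)
        assert fit["kappa"] == pytest.approx(kappa, rel=0.10)

    def test_time_shift_reparameterization(self):
        # shifting the clock leaves kappa unchanged and maps f0 through the
        # logistic flow
        kappa, f0, alpha, c = 0.2, 1e-4, 50.0, 7.0
        t = np.array([0.0, 10.0, 21.0, 29.0, 34.0])
        med = alpha * core.logistic_fraction(t + c, kappa, f0)
        fit = inference.lsq_median_fit(t, med)
        f0_shifted = core.logistic_fraction(c, kappa, f0)
        assert fit["kappa"] == pytest.approx(kappa, rel=1e-3)
        assert fit["f0"] == pytest.approx(f0_shifted, rel=1e-2)


class TestCoverage:
    def test_combined_interval_covers_truth_majority_of_runs(self):
        # 1-SD credible-interval coverage across replicated study designs
        hits = 0
        n_runs = 40
        for seed in range(n_runs):
            ms = synthetic.gen_seed_dataset(
                synthetic.GeneratorSpec(seed=500 + seed, scenario="devos-like"))
            res = inference.infer_dataset_kappa(ms)
            s = res["summary"]
            hits += abs(s.mean - 0.17) <= s.sd
        assert hits / n_runs >= 0.6


class TestValidation:
    def test_requires_two_timepoints(self):
        with pytest.raises(ValueError):
            _ms([0.0, 0.0], [1.0, 2.0])

    def test_rejects_nonpositive_values(self):
        with pytest.raises(ValueError):
            _ms([0.0, 1.0], [1.0, -2.0])
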