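"""Reaction-diffusion simulator: scheme accuracy, regimes, fits, interventions."""

import numpy as np
import pandas as pd
import pytest

from taukinetics import core, fkpp
from .conftest import replication_limited_stage_profiles


@pytest.fixture(scope="module")
def interval_geom():
    return fkpp.Geometry(n_points=201, r_max=1.0)


class TestSimulate:
    def test_uniform_field_follows_closed_form(self, interval_geom):
        # the diffusion term vanishes on uniform fields, leaving pure logistic
        ic = np.full(interval_geom.n_points, 0.01)
        traj = fkpp.simulate(ic, D=0.3, kappa=0.17, geometry=interval_geom,
                             t_grid=np.linspace(0, 10, 21))
        for t, prof in zip(traj.times, traj.profiles):
            expected = core.logistic_fraction(t, 0.17, 0.01)
            assert np.abs(prof - expected).max() < 1e-5

    def test_pure_diffusion_conserves_mass_and_flattens(self, interval_geom):
        ic = fkpp.gaussian_bump(interval_geom, width_frac=0.05, amplitude=0.8)
        traj = fkpp.simulate(ic, D=0.05, kappa=0.0, geometry=interval_geom,
                             t_grid=np.linspace(0, 50, 11))
        means = traj.spatial_mean()
        assert np.abs(means - means[0]).max() < 1e-6  # zero-flux mass balance
        final = traj.profiles[-1]
        assert final.max() - final.min() < 1e-3  # relaxed to the spatial mean

    def test_solution_stays_in_unit_interval(self, interval_geom, rng):
        ic = rng.uniform(0, 1, interval_geom.n_points)
        traj = fkpp.simulate(ic, D=0.1, kappa=1.0, geometry=interval_geom,
                             t_grid=np.linspace(0, 20, 40))
        assert traj.profiles.min() >= 0.0
        assert traj.profiles.max() <= 1.0 + 1e-9

    def test_comparison_principle(self, interval_geom, rng):
        # pointwise-larger initial data stay pointwise larger
        for _ in range(3):
            base = rng.uniform(0.0, 0.5, interval_geom.n_points)
            upper = np.clip(base + rng.uniform(0.0, 0.3, interval_geom.n_points), 0, 1)
            t_grid = np.linspace(0, 10, 11)
            lo = fkpp.simulate(base, 0.05, 1.0, interval_geom, t_grid)
            hi = fkpp.simulate(upper, 0.05, 1.0, interval_geom, t_grid)
            assert np.all(hi.profiles >= lo.profiles - 1e-9)

    def test_refinement_convergence(self):
        coarse_geom = fkpp.Geometry(n_points=201, r_max=1.0)
        fine_geom = fkpp.Geometry(n_points=401, r_max=1.0)
        t_grid = np.linspace(0, 10, 6)
        ic_c = fkpp.gaussian_bump(coarse_geom, width_frac=0.05)
        ic_f = fkpp.gaussian_bump(fine_geom, width_frac=0.05)
        c = fkpp.simulate(ic_c, 0.01, 1.0, coarse_geom, t_grid, dt=0.02)
        f = fkpp.simulate(ic_f, 0.01, 1.0, fine_geom, t_grid, dt=0.01)
        diff = np.abs(c.profiles[-1] - f.profiles[-1][::2]).max()
        assert diff < 1e-3

    def test_oversized_step_raises_named_limit(self, interval_geom):
        ic = np.full(interval_geom.n_points, 0.01)
        with pytest.raises(fkpp.SolverError, match="maximum"):
            fkpp.simulate(ic, 0.1, kappa=2.0, geometry=interval_geom,
                          t_grid=np.linspace(0, 5, 6), dt=1.0)

    def test_front_speed_matches_pulled_front_theory(self):
        geom = fkpp.Geometry(n_points=1201, r_max=4.0)
        ic = fkpp.gaussian_bump(geom, width_frac=0.01 / 4.0)
        for D in (0.01, 0.0025):
            v_theory = core.front_speed(D, 1.0)
            t_end = min(30.0, 3.5 / v_theory)
            traj = fkpp.simulate(ic, D, 1.0, geom,
                                 np.linspace(0, t_end, 120), dt=0.02)
            v = fkpp.measure_front_speed(traj)
            assert abs(v - v_theory) / v_theory < 0.10


class TestClassifyRegime:
    def test_uniform_initial_condition_is_replication_limited(self, interval_geom):
        ic = np.full(interval_geom.n_points, 0.01)
        traj = fkpp.simulate(ic, 0.5, 1.0, interval_geom, np.linspace(0, 20, 50))
        label, chi = fkpp.classify_regime(traj)
        assert label == "replication_limited"
        assert chi == 0.0

    @pytest.mark.parametrize("ratio, expected", [
        (0.00025, "spreading_limited"),
        (0.025, "replication_limited"),
    ])
    def test_reference_parameter_pairs(self, interval_geom, ratio, expected):
        ic = fkpp.gaussian_bump(interval_geom, width_frac=0.01)
        traj = fkpp.simulate(ic, ratio, 1.0, interval_geom,
                             np.linspace(0, 60, 400))
        label, _ = fkpp.classify_regime(traj)
        assert label == expected

    def test_transition_brackets_predicted_threshold(self, interval_geom):
        # the label switch for a compact bump falls within a factor of 3
        # of D/kappa = 0.0025 r_max²
        ic = fkpp.gaussian_bump(interval_geom, width_frac=0.01)
        labels = {}
        for mult in (1 / 3, 1.0, 3.0):
            ratio = 0.0025 * mult
            traj = fkpp.simulate(ic, ratio, 1.0, interval_geom,
                                 np.linspace(0, 60, 400))
            labels[mult], _ = fkpp.classify_regime(traj)
        assert labels[1 / 3] == "spreading_limited"
        assert labels[3.0] == "replication_limited"

    def test_unreached_threshold_is_inconclusive(self, interval_geom):
        ic = np.full(interval_geom.n_points, 1e-4)
        traj = fkpp.simulate(ic, 0.01, 0.1, interval_geom, np.linspace(0, 5, 6))
        with pytest.raises(fkpp.RegimeInconclusiveError):
            fkpp.classify_regime(traj)


class TestRegionalFit:
    def test_noiseless_parameter_recovery(self, rng):
        df, _ = replication_limited_stage_profiles(D=0.35, P_max=500.0, t_start=5.0, rng=rng)
        fit = fkpp.fit_regional_model(df, kappa=0.14)
        assert fit.D == pytest.approx(0.35, rel=0.05)
        assert fit.P_max == pytest.approx(500.0, rel=0.05)
        assert fit.t_start == pytest.approx(5.0, abs=1.0)
        assert not fit.warnings

    def test_noisy_median_recovery_within_factor_two(self, rng):
        Ds = []
        for _ in range(20):
            df, _ = replication_limited_stage_profiles(D=0.35, noise_sigma=0.2, rng=rng)
            Ds.append(fkpp.fit_regional_model(df, kappa=0.14).D)
        med = np.median(Ds)
        assert 0.5 < med / 0.35 < 2.0

    def test_missing_anchor_stage_rejected(self, rng):
        df, _ = replication_limited_stage_profiles(rng=rng)
        with pytest.raises(ValueError, match="anchor"):
            fkpp.fit_regional_model(df[df.stage != "III"], kappa=0.14)


class TestIntervention:
    def test_factor_one_gives_zero_delays(self, rng):
        df, _ = replication_limited_stage_profiles(rng=rng)
        fit = fkpp.fit_regional_model(df, kappa=0.14)
        delays = fkpp.intervention_compare(fit, factor=1.0)
        assert delays["delay_D"] == pytest.approx(0.0, abs=1e-6)
        assert delays["delay_kappa"] == pytest.approx(0.0, abs=1e-6)

    def test_replication_limited_asymmetry(self, rng):
        # in the fitted human configuration, slowing replication delays
        # half-maximal accumulation far more than slowing spreading
        df, _ = replication_limited_stage_profiles(rng=rng)
        fit = fkpp.fit_regional_model(df, kappa=0.14)
        delays = fkpp.intervention_compare(fit, factor=3.0)
        assert delays["delay_kappa"] > delays["delay_D"]
        assert delays["delay_kappa"] > 10 * max(delays["delay_D"], 1e-6)

    def test_uniform_field_logistic_timing(self):
        # with a uniform initial condition, slowing D does nothing and the
        # half-max time scales as 1/kappa
        geom = fkpp.Geometry.region_chain()
        f0 = 1e-3
        ic = np.full(geom.n_points, f0)
        fit = fkpp.RegionalFit(D=0.5, P_max=1.0, t_start=0.0, kappa=0.14,
                               residual=0.0, stage_times={"III": 0.0, "VI": 34.0},
                               initial_profile=ic, geometry=geom)
        delays = fkpp.intervention_compare(fit, factor=3.0, horizon=400.0)
        t_half = core.half_occupancy_time(0.14, f0)
        assert delays["delay_D"] == pytest.approx(0.0, abs=0.05)
        assert delays["delay_kappa"] == pytest.approx(2.0 * t_half, rel=0.02)


class TestGeometryAndTrajectory:
    def test_region_chain_defaults(self):
        geom = fkpp.Geometry.region_chain()
        assert geom.region_labels == fkpp.REGION_LABELS
        assert geom.n_points == 6
        assert geom.spacing * (geom.n_points - 1) == pytest.approx(geom.r_max)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            fkpp.Geometry.region_chain(labels=("EC", "EC", "PV"))

    def test_trajectory_validation(self, interval_geom):
        with pytest.raises(ValueError):
            fkpp.FieldTrajectory(times=[0.0, 1.0],
                                 profiles=np.full((2, 201), 1.5),
                                 geometry=interval_geom)

    def test_long_format_export(self, interval_geom):
        ic = np.full(interval_geom.n_points, 0.01)
        traj = fkpp.simulate(ic, 0.0, 0.5, interval_geom, [0.0, 1.0])
        df = traj.to_frame()
        assert set(df.columns) == {"time", "node", "f"}
        assert len(df) == 2 * interval_geom.n_points
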