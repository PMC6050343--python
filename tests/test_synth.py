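"""Synthetic plate generator: calibration, determinism, noise recovery."""

import numpy as np
import pytest

from icpkit.kinetics import assay_cv, fit_progress_curve, fold_change
from icpkit.synth import (
    GeneratorParams,
    PlateDesign,
    default_calibration,
    generate_plate,
    generate_timecourse,
)


@pytest.fixture(scope="module")
def params():
    return default_calibration()


@pytest.fixture(scope="module")
def design():
    return PlateDesign()


def _net_fold(plate, conc, at=8.0):
    net = plate.net_signals(at)
    nc = net[net["group"] == 0.0]["net"].mean()
    sample = net[net["group"] == conc]["net"].mean()
    return fold_change(sample, nc)


class TestCalibration:
    def test_noise_free_fold_changes_exact(self, params, design):
        """Net fold changes at 8 min reproduce the calibration triple."""
        plate = generate_plate(design, params, seed=0, noise=False)
        for conc, expected in ((3.0, 1.5), (30.0, 3.8), (300.0, 7.3)):
            assert _net_fold(plate, conc) == pytest.approx(expected, abs=1e-9)

    def test_nc_fold_is_unity(self, params, design):
        plate = generate_plate(design, params, seed=0, noise=False)
        assert _net_fold(plate, 0.0) == pytest.approx(1.0)

    def test_growth_coefficients_satisfy_fold_equations(self, params):
        nc_net = params.nc_net(8.0)
        for conc, expected in ((3.0, 1.5), (30.0, 3.8), (300.0, 7.3)):
            a, b = params.growth_coefficients(conc)
            assert 1.0 + (64.0 * a + 8.0 * b) / nc_net == pytest.approx(expected)

    def test_top_anchor_matches_published_fit_derivative(self, params):
        a, b = params.growth_coefficients(300.0)
        assert 2.0 * a == pytest.approx(1017.94)
        assert b == pytest.approx(160.63)

    def test_cv_parameters(self, params):
        assert params.intra_cv == 9.80
        assert params.inter_cv == 9.45

    def test_interpolated_concentration_between_anchors(self, params):
        a3, _ = params.growth_coefficients(3.0)
        a10, _ = params.growth_coefficients(10.0)
        a30, _ = params.growth_coefficients(30.0)
        assert a3 < a10 < a30


class TestTimecourse:
    def test_nc_monotone_and_plateaus_by_5_min(self, params):
        t, rfu = generate_timecourse(0.0, params, noise=False)
        assert np.all(np.diff(rfu) >= 0.0)
        late_growth = rfu[-1] - rfu[t >= 5.0][0]
        assert late_growth < 0.01 * params.nc_amplitude

    def test_nc_bounded_by_baseline_plus_amplitude(self, params):
        _, rfu = generate_timecourse(0.0, params, noise=False)
        assert rfu.max() <= params.nc_baseline + params.nc_amplitude + 1e-9

    def test_same_seed_identical(self, params):
        _, a = generate_timecourse(30.0, params, noise=True, rng=123)
        _, b = generate_timecourse(30.0, params, noise=True, rng=123)
        np.testing.assert_array_equal(a, b)

    def test_quadratic_coefficient_recovery_noise_free(self, params):
        t, sample = generate_timecourse(300.0, params, noise=False)
        _, nc = generate_timecourse(0.0, params, noise=False)
        fit = fit_progress_curve(t, sample - nc)
        a, b = params.growth_coefficients(300.0)
        assert fit.a == pytest.approx(a, abs=1e-8)
        assert fit.b == pytest.approx(b, abs=1e-8)
        assert fit.c == pytest.approx(0.0, abs=1e-8)

    def test_noisy_coefficient_recovery_within_ci(self, params):
        """Over many noisy replicates the fitted quadratic coefficient is
        an unbiased estimate of the generator value (multiplicative gain
        noise averages out)."""
        rng = np.random.default_rng(2024)
        t = np.linspace(0.0, 8.0, 17)
        a_true, b_true = params.growth_coefficients(300.0)
        _, nc = generate_timecourse(0.0, params, noise=False, times=t)
        a_hat = []
        for _ in range(500):
            _, noisy = generate_timecourse(300.0, params, noise=True, rng=rng, times=t)
            fit = fit_progress_curve(t, noisy - nc)
            a_hat.append(fit.a)
        a_hat = np.asarray(a_hat)
        se = a_hat.std(ddof=1) / np.sqrt(len(a_hat))
        assert abs(a_hat.mean() - a_true) < 4.0 * se + 1e-9

    def test_quench_scales_whole_signal(self, params):
        _, plain = generate_timecourse(30.0, params, noise=False)
        _, quenched = generate_timecourse(30.0, params, noise=False, quench=True)
        np.testing.assert_allclose(quenched, params.quench * plain, rtol=1e-12)


class TestPlate:
    def test_well_count(self, params, design):
        plate = generate_plate(design, params, seed=1)
        wells = plate.frame.groupby(["device", "well"]).ngroups
        assert wells == design.n_wells == 144

    def test_noise_off_replicates_identical(self, params, design):
        plate = generate_plate(design, params, seed=1, noise=False)
        at8 = plate.net_signals(8.0)
        for _, sub in at8.groupby(["device", "group"]):
            assert sub["net"].std() == pytest.approx(0.0, abs=1e-10)

    def test_seed_determinism(self, params, design):
        a = generate_plate(design, params, seed=7).frame
        b = generate_plate(design, params, seed=7).frame
        assert a.equals(b)

    def test_ensemble_mean_converges_to_noise_free(self, params):
        """Monte-Carlo mean approaches the deterministic curve ~ 1/sqrt(n)."""
        design = PlateDesign(n_devices=1, concentrations=(300.0,), n_replicates=1)
        clean = generate_plate(design, params, seed=0, noise=False)
        clean8 = clean.net_signals(8.0)["net"].iloc[0]
        rng_seeds = range(1000)
        nets = []
        for s in rng_seeds:
            noisy = generate_plate(design, params, seed=s, noise=True)
            nets.append(noisy.net_signals(8.0)["net"].iloc[0])
        nets = np.asarray(nets)
        sigma = np.hypot(params.sigma_well, params.sigma_device) * clean8
        assert abs(nets.mean() - clean8) < 4.0 * sigma / np.sqrt(len(nets))


class TestCVRecovery:
    def test_cv_recovery_monte_carlo(self, params, design):
        """assay_cv on the generated ensemble recovers the nominal
        intra/inter CV parameters within 15% relative."""
        intra, inter = [], []
        for seed in range(200):
            plate = generate_plate(design, params, seed=seed, noise=True)
            i, e = assay_cv(plate, at_time=8.0)
            intra.append(i)
            inter.append(e)
        intra_hat = float(np.mean(intra))
        inter_hat = float(np.mean(inter))
        assert abs(intra_hat - 9.80) / 9.80 < 0.15
        assert abs(inter_hat - 9.45) / 9.45 < 0.15


class TestValidation:
    def test_quench_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            GeneratorParams(quench=1.5)

    def test_non_plateauing_tau_rejected(self):
        with pytest.raises(ValueError, match="plateau"):
            GeneratorParams(nc_tau=3.0)

    def test_negative_concentration_rejected(self, params):
        with pytest.raises(ValueError):
            params.growth_coefficients(-1.0)
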