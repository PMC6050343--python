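"""Assay quantification: rates, fits, fold changes, CVs, bracketing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from icpkit.kinetics import (
    BracketResult,
    KineticsSpec,
    PlateData,
    QuadraticFit,
    acceleration_factor,
    assay_cv,
    bracket_concentration,
    convert_rate,
    fit_progress_curve,
    fold_change,
    kruskal_wallis,
    michaelis_menten_rate,
    pcf_from_reference,
    reaction_rate_at,
)


class TestMichaelisMenten:
    def test_zero_substrate_gives_zero_rate(self):
        spec = KineticsSpec(k_m=5.0, c_substrate=0.0, v_max=10.0)
        assert michaelis_menten_rate(spec) == 0.0

    def test_half_saturation_at_km(self):
        spec = KineticsSpec(k_m=5.0, c_substrate=5.0, v_max=10.0)
        assert michaelis_menten_rate(spec) == pytest.approx(5.0)

    def test_rate_proportional_to_enzyme(self):
        lo = KineticsSpec(k_m=2.0, c_substrate=7.0, k_cat=3.0, c_enzyme=1.0)
        hi = KineticsSpec(k_m=2.0, c_substrate=7.0, k_cat=3.0, c_enzyme=2.0)
        assert michaelis_menten_rate(hi) == pytest.approx(2.0 * michaelis_menten_rate(lo))

    def test_inconsistent_vmax_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            KineticsSpec(k_m=1.0, c_substrate=1.0, v_max=5.0, k_cat=1.0, c_enzyme=1.0)

    def test_nonpositive_km_rejected(self):
        with pytest.raises(ValueError, match="k_m"):
            KineticsSpec(k_m=0.0, c_substrate=1.0, v_max=1.0)


class TestProgressCurve:
    @pytest.mark.parametrize(
        "coeffs",
        [(2.0, 3.0, 4.0), (0.0, 0.0, 5.0), (0.0, 3.0, 1.0)],
    )
    def test_exact_polynomial_recovery(self, coeffs):
        a, b, c = coeffs
        t = np.arange(0.0, 6.0)
        y = a * t**2 + b * t + c
        fit = fit_progress_curve(t, y)
        assert (fit.a, fit.b, fit.c) == pytest.approx(coeffs, abs=1e-10)

    def test_three_points_interpolate(self):
        t = np.array([0.0, 1.0, 2.0])
        y = np.array([1.0, 0.0, 3.0])
        fit = fit_progress_curve(t, y)
        assert fit.a * 4 + fit.b * 2 + fit.c == pytest.approx(3.0, abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-16)

    def test_too_few_distinct_times_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_progress_curve([1.0, 1.0, 1.0, 2.0], [1, 2, 3, 4])

    @given(
        a=st.floats(-50, 50), b=st.floats(-50, 50), c=st.floats(-50, 50),
        t=st.floats(0, 20),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rate_is_analytic_derivative(self, a, b, c, t):
        """y'(t) of the stored quadratic is exactly 2 a t + b."""
        fit = QuadraticFit(a=a, b=b, c=c)
        eps = 1e-5
        y = lambda s: a * s**2 + b * s + c  # noqa: E731
        numeric = (y(t + eps) - y(t - eps)) / (2 * eps)
        assert reaction_rate_at(fit, t) == pytest.approx(2 * a * t + b)
        assert reaction_rate_at(fit, t) == pytest.approx(numeric, rel=1e-4, abs=1e-4)


class TestPrintedRates:
    """Rate evaluation at the published fit coefficients."""

    def test_static_incubation_rate_at_8_hours(self):
        fit = QuadraticFit.from_derivative(46.88, 29.33, time_unit="h")
        assert reaction_rate_at(fit, 8.0) == pytest.approx(404.37)

    def test_accelerated_rate_at_8_minutes(self):
        fit = QuadraticFit.from_derivative(1017.94, 160.63, time_unit="min")
        assert reaction_rate_at(fit, 8.0) == pytest.approx(8304.15)

    def test_unit_conversion_h_to_min(self):
        assert convert_rate(404.37, "h", "min") == pytest.approx(6.7395)

    def test_acceleration_factor_exceeds_thousandfold(self):
        factor = acceleration_factor(8304.15, convert_rate(404.37, "h", "min"))
        assert factor == pytest.approx(1232.0, rel=1e-3)
        assert factor > 1.0e3

    def test_zero_rate_fit(self):
        fit = QuadraticFit(a=0.0, b=0.0, c=7.0)
        for t in (0.0, 3.0, 100.0):
            assert reaction_rate_at(fit, t) == 0.0


class TestFoldChange:
    def test_equal_signals(self):
        assert fold_change(100.0, 100.0) == 1.0

    def test_ratio(self):
        assert fold_change(730.0, 100.0) == pytest.approx(7.3)

    def test_nonpositive_nc_rejected(self):
        with pytest.raises(ValueError):
            fold_change(10.0, 0.0)

    def test_equal_rates_unit_acceleration(self):
        assert acceleration_factor(5.0, 5.0) == 1.0


def _plate_from_nets(device_nets):
    """Build a two-timepoint plate whose net signals equal the given
    per-device replicate values (one concentration group)."""
    rows = []
    for d, nets in enumerate(device_nets):
        for r, net in enumerate(nets):
            for t, rfu in ((0.0, 100.0), (8.0, 100.0 + net)):
                rows.append(
                    {"device": d + 1, "well": f"A{r+1}", "group": 300.0,
                     "class": "standard", "time_min": t, "rfu": rfu}
                )
    return PlateData(pd.DataFrame(rows))


class TestAssayCV:
    def test_identical_replicates_zero_cv(self):
        plate = _plate_from_nets([[50.0, 50.0, 50.0], [50.0, 50.0, 50.0]])
        intra, inter = assay_cv(plate, at_time=8.0)
        assert intra == 0.0 and inter == 0.0

    def test_hand_computed_example(self):
        plate = _plate_from_nets([[100.0, 110.0, 90.0], [95.0, 105.0, 100.0]])
        intra, inter = assay_cv(plate, at_time=8.0)
        assert intra == pytest.approx(7.5)     # mean of 10% and 5%
        assert inter == pytest.approx(0.0)     # both device means are 100

    def test_single_device_rejected_for_inter(self):
        plate = _plate_from_nets([[100.0, 110.0, 90.0]])
        with pytest.raises(ValueError):
            assay_cv(plate, at_time=8.0)


class TestBracketing:
    REFS = [(3.0, 2000.0), (30.0, 4000.0), (300.0, 8000.0)]

    def test_between_first_pair(self):
        res = bracket_concentration(3000.0, self.REFS)
        assert (res.c_low, res.c_high) == (3.0, 30.0)
        assert not res.open_ended

    def test_log_linear_point_estimate(self):
        res = bracket_concentration(3000.0, self.REFS)
        assert res.point_estimate == pytest.approx(9.4868, rel=1e-3)

    def test_exact_reference_hit(self):
        res = bracket_concentration(4000.0, self.REFS)
        assert res.c_low == res.c_high == 30.0
        assert res.point_estimate == 30.0

    def test_out_of_span_flagged_open(self):
        low = bracket_concentration(100.0, self.REFS)
        high = bracket_concentration(1.0e5, self.REFS)
        assert low.open_ended and low.c_low is None and low.c_high == 3.0
        assert high.open_ended and high.c_low == 300.0 and high.c_high is None

    def test_non_monotone_refs_rejected(self):
        with pytest.raises(ValueError):
            bracket_concentration(1.0, [(3.0, 5.0), (30.0, 4.0)])


class TestPCFFromReference:
    CURVE = [(1.0, 10.0), (10.0, 100.0), (100.0, 1000.0)]

    def test_exact_reference_point(self):
        est = pcf_from_reference(1000.0, self.CURVE, initial_concentration=1.0)
        assert est.pcf == pytest.approx(100.0)
        assert not est.extrapolated

    def test_linear_inverse_interpolation(self):
        est = pcf_from_reference(550.0, self.CURVE, initial_concentration=1.0)
        assert est.apparent_concentration == pytest.approx(55.0)

    def test_extrapolation_flagged(self):
        est = pcf_from_reference(2000.0, self.CURVE, initial_concentration=1.0)
        assert est.extrapolated

    def test_non_monotone_curve_rejected(self):
        with pytest.raises(ValueError):
            pcf_from_reference(5.0, [(1.0, 10.0), (2.0, 5.0)], 1.0)


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        h, p = kruskal_wallis([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert h == pytest.approx(3.857, abs=1e-3)
        assert 0.0 < p < 0.06

    def test_identical_groups(self):
        h, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert h == 0.0 and p == 1.0

    def test_permutation_invariance_of_group_order(self):
        g = [[1.0, 5.0, 2.0], [7.0, 3.0], [9.0, 4.0, 6.0]]
        h1, _ = kruskal_wallis(g)
        h2, _ = kruskal_wallis(g[::-1])
        assert h1 == pytest.approx(h2)

    def test_permutation_p_close_to_chi2_for_moderate_n(self):
        rng = np.random.default_rng(7)
        groups = [list(rng.normal(loc, 1.0, 8)) for loc in (0.0, 0.4, 1.0)]
        _, p_chi2 = kruskal_wallis(groups)
        _, p_perm = kruskal_wallis(groups, method="permutation", n_permutations=4000, seed=1)
        assert p_perm == pytest.approx(p_chi2, abs=0.05)


class TestPlateData:
    def test_csv_round_trip(self, tmp_path):
        plate = _plate_from_nets([[10.0, 20.0, 30.0]])
        path = tmp_path / "plate.csv"
        plate.to_csv(path)
        back = PlateData.from_csv(path)
        pd.testing.assert_frame_equal(
            back.frame.reset_index(drop=True), plate.frame.reset_index(drop=True),
            check_dtype=False,
        )

    def test_negative_rfu_rejected(self):
        frame = _plate_from_nets([[10.0]]).frame.copy()
        frame.loc[0, "rfu"] = -1.0
        with pytest.raises(ValueError):
            PlateData(frame)
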