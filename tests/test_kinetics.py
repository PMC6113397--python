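"""Rate, first-order and dose-response estimators on exact and randomized inputs."""

import numpy as np
import pytest

from halosyn.kinetics import (
    DoseResponse,
    KineticsError,
    TimeSeries,
    co_yield,
    first_order_fit,
    four_pl,
    ic50_fit,
    max_rate,
    mitigation_margin,
)


def linear_series(rate, n=10, days=60.0, intercept=0.0):
    t = np.linspace(0.0, days, n)
    return TimeSeries(times=t, values=intercept + rate * t, analyte="Cl")


class TestMaxRate:
    def test_exact_slope_recovered_for_any_window(self):
        ts = linear_series(0.59)
        for w in (3, 4, 7, 10):
            fit = max_rate(ts, window_points=w)
            assert fit.parameters["rate"] == pytest.approx(0.59, rel=1e-12)
            assert fit.residual_sd == pytest.approx(0.0, abs=1e-10)

    def test_constant_series_rate_zero(self):
        ts = TimeSeries(np.linspace(0, 30, 7), np.full(7, 5.0))
        assert max_rate(ts).parameters["rate"] == pytest.approx(0.0, abs=1e-12)

    def test_max_window_found_on_piecewise_course(self):
        """A lag phase then a steep phase: the window lands on the steep part."""
        t = np.arange(0.0, 10.0)
        v = np.where(t < 5, 0.1 * t, 0.1 * 5 + 1.0 * (t - 5))
        fit = max_rate(TimeSeries(t, v), window_points=4)
        assert fit.parameters["rate"] == pytest.approx(1.0, rel=1e-9)
        assert fit.detail["window_days"][0] >= 5.0

    def test_window_bounds_validated(self):
        ts = linear_series(1.0, n=5)
        with pytest.raises(KineticsError):
            max_rate(ts, window_points=2)
        with pytest.raises(KineticsError):
            max_rate(ts, window_points=6)


class TestFirstOrder:
    def test_exact_decay_recovered(self):
        t = np.linspace(0.0, 14.0, 8)
        ts = TimeSeries(t, 100.0 * np.exp(-0.16 * t))
        fit = first_order_fit(ts, direction="decay")
        assert fit.parameters["k"] == pytest.approx(-0.16, rel=1e-8)
        assert fit.parameters["a0"] == pytest.approx(100.0, rel=1e-8)

    def test_flat_series_gives_zero_k(self):
        ts = TimeSeries(np.linspace(0, 14, 8), np.full(8, 7.0))
        assert first_order_fit(ts).parameters["k"] == pytest.approx(0.0, abs=1e-10)

    def test_scale_equivariance(self):
        t = np.linspace(0.0, 14.0, 8)
        rng = np.random.default_rng(5)
        y = 10.0 * np.exp(-0.14 * t) * (1 + rng.normal(0, 0.05, t.size))
        k1 = first_order_fit(TimeSeries(t, y)).parameters["k"]
        k2 = first_order_fit(TimeSeries(t, 37.0 * y)).parameters["k"]
        assert k2 == pytest.approx(k1, rel=1e-7)

    def test_decay_requires_positive_values(self):
        ts = TimeSeries(np.linspace(0, 14, 8), np.r_[np.full(7, 2.0), 0.0])
        with pytest.raises(KineticsError):
            first_order_fit(ts, direction="decay")


class TestMitigation:
    @pytest.mark.parametrize(
        "k_prod, k_rem, margin, mitigates",
        [(0.10, -0.14, 0.04, True), (0.07, -0.16, 0.09, True), (0.1, -0.1, 0.0, False)],
    )
    def test_reported_constant_pairs(self, k_prod, k_rem, margin, mitigates):
        m, flag = mitigation_margin(k_prod, k_rem)
        assert m == pytest.approx(margin)
        assert flag is mitigates

    def test_sign_conventions_enforced(self):
        with pytest.raises(KineticsError):
            mitigation_margin(-0.1, -0.1)
        with pytest.raises(KineticsError):
            mitigation_margin(0.1, 0.1)


class TestIc50:
    DOSES = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 6.0])

    def test_noise_free_recovery(self):
        resp = four_pl(self.DOSES, 100.0, 0.0, 2.24, 2.0)
        fit = ic50_fit(DoseResponse(self.DOSES, resp))
        assert fit.converged
        assert fit.parameters["ic50"] == pytest.approx(2.24, rel=1e-6)

    def test_noise_free_recovery_of_all_parameters_randomized(self):
        """All four parameters come back to 1e-4 relative over 50 random truths."""
        rng = np.random.default_rng(20240901)
        for _ in range(50):
            truth = dict(
                top=rng.uniform(5.0, 50.0),
                bottom=rng.uniform(0.0, 2.0),
                ic50=rng.uniform(0.8, 3.5),
                hill=rng.uniform(1.0, 3.0),
            )
            resp = four_pl(self.DOSES, truth["top"], truth["bottom"],
                           truth["ic50"], truth["hill"])
            fit = ic50_fit(DoseResponse(self.DOSES, resp))
            assert fit.converged
            for name, value in truth.items():
                assert fit.parameters[name] == pytest.approx(value, rel=1e-4, abs=1e-4), name

    def test_zero_dose_control_sits_on_top_plateau(self):
        assert four_pl(0.0, 12.0, 1.0, 2.24, 2.0) == pytest.approx(12.0)
        assert four_pl(2.24, 12.0, 0.0, 2.24, 2.0) == pytest.approx(6.0)

    def test_monotonically_increasing_responses_flagged(self):
        resp = np.array([1.0, 2.0, 3.0, 5.0, 8.0, 12.0])
        fit = ic50_fit(DoseResponse(self.DOSES, resp))
        assert not fit.converged
        assert fit.standard_errors == {}

    def test_needs_four_distinct_doses(self):
        with pytest.raises(KineticsError):
            DoseResponse(np.array([0, 1, 1, 2.0]), np.array([9, 5, 5, 1.0]))


class TestCoYield:
    def test_pure_culture_yield(self):
        """0.9 μmol CO at 11.2 μmol Cl- is a yield of 0.0804."""
        y, projected = co_yield(0.9, 11.2, project_to_cl_umol=70.0)
        assert y == pytest.approx(0.0804, abs=5e-4)
        assert projected == pytest.approx(5.6, abs=0.05)

    def test_round_trip_and_linearity(self):
        y, proj = co_yield(0.9, 11.2, 11.2)
        assert proj == pytest.approx(0.9)
        _, p1 = co_yield(0.9, 11.2, 10.0)
        _, p2 = co_yield(0.9, 11.2, 20.0)
        assert p2 == pytest.approx(2 * p1)
        with pytest.raises(KineticsError):
            co_yield(1.0, 0.0)
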