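"""Unit and property tests for the one-compartment kinetic model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tbikinetics.model import (
    ConcentrationCurve,
    InjuryScenario,
    KineticParameters,
    amounts_at,
    curve_over_grid,
    half_life_from_ke,
    ka_from_tmax,
    ke_from_half_life,
    plasma_concentration,
    plasma_concentration_arrays,
    time_of_peak,
)

GFAP = KineticParameters(ka=0.08, ke=0.0193, F=0.8)
NOMINAL = InjuryScenario(D0=400_000.0, Vd=5000.0)


def bateman_oracle(params, scenario, t):
    """Direct high-precision evaluation of the bi-exponential solution."""
    ka, ke = params.ka, params.ke
    return (
        params.F
        * scenario.D0
        * ka
        / (scenario.Vd * (ka - ke))
        * (math.exp(-ke * t) - math.exp(-ka * t))
    )


class TestPlasmaConcentration:
    def test_zero_at_injury_time(self):
        assert plasma_concentration(GFAP, NOMINAL, 0.0) == 0.0

    def test_linear_in_released_amount(self):
        zero = InjuryScenario(D0=0.0, Vd=5000.0)
        t = np.linspace(0, 100, 11)
        assert np.all(plasma_concentration(GFAP, zero, t) == 0.0)
        double = InjuryScenario(D0=800_000.0, Vd=5000.0)
        np.testing.assert_allclose(
            plasma_concentration(GFAP, double, t),
            2 * plasma_concentration(GFAP, NOMINAL, t),
            rtol=1e-12,
        )

    def test_matches_direct_evaluation_at_5h(self):
        # frozen from the closed-form oracle evaluated independently
        assert plasma_concentration(GFAP, NOMINAL, 5.0) == pytest.approx(
            20.048962767845893, rel=1e-12
        )
        assert plasma_concentration(GFAP, NOMINAL, 5.0) == pytest.approx(
            bateman_oracle(GFAP, NOMINAL, 5.0), rel=1e-14
        )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            plasma_concentration(GFAP, NOMINAL, -1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            KineticParameters(ka=-0.1, ke=0.02)
        with pytest.raises(ValueError):
            KineticParameters(ka=0.1, ke=0.0)
        with pytest.raises(ValueError):
            KineticParameters(ka=0.1, ke=0.02, F=1.5)
        with pytest.raises(ValueError):
            InjuryScenario(D0=1.0, Vd=0.0)

    def test_degenerate_limit_continuity(self):
        """Near ka == ke the formula hands over smoothly to the analytic limit."""
        ka = 0.1
        limit = KineticParameters(ka=ka, ke=ka)
        nearby = KineticParameters(ka=ka * (1 + 1e-8), ke=ka)
        for t in (0.5, 5.0, 30.0):
            c_lim = plasma_concentration(limit, NOMINAL, t)
            c_near = plasma_concentration(nearby, NOMINAL, t)
            assert c_near == pytest.approx(c_lim, rel=1e-6)

    @given(
        ka=st.floats(0.001, 2.0),
        ke=st.floats(0.001, 2.0),
        t=st.floats(0.0, 500.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_nonnegative_everywhere(self, ka, ke, t):
        params = KineticParameters(ka=ka, ke=ke)
        assert plasma_concentration(params, NOMINAL, t) >= 0.0

    def test_unimodal_rising_then_falling(self):
        tmax = time_of_peak(GFAP).Tmax
        rising = np.linspace(0.01, tmax - 0.1, 400)
        falling = np.linspace(tmax + 0.1, 500, 400)
        cr = plasma_concentration(GFAP, NOMINAL, rising)
        cf = plasma_concentration(GFAP, NOMINAL, falling)
        assert np.all(np.diff(cr) > 0)
        assert np.all(np.diff(cf) < 0)

    def test_array_variant_matches_scalar(self):
        ka = np.array([0.08, 0.09, 0.5])
        ke = np.array([0.0193, 0.0866, 0.462])
        cp = plasma_concentration_arrays(4e5, 5e3, ka, ke, 0.8, 5.0)
        for i in range(3):
            expected = plasma_concentration(
                KineticParameters(ka=ka[i], ke=ke[i]), NOMINAL, 5.0
            )
            assert cp[i] == pytest.approx(expected, rel=1e-14)


class TestAmounts:
    def test_initial_condition(self):
        s = amounts_at(GFAP, NOMINAL, 0.0)
        assert s.D_br == NOMINAL.D0
        assert s.D_bl == 0.0

    def test_everything_cleared_after_twenty_half_lives(self):
        t = 20 * half_life_from_ke(GFAP.ke)
        s = amounts_at(GFAP, NOMINAL, t)
        assert s.D_br < 1e-6 * NOMINAL.D0
        assert s.D_bl < 1e-3 * NOMINAL.D0

    def test_mass_balance_ode(self):
        """Central difference of D_bl matches inflow - outflow at t = 5 h."""
        h = 1e-4
        s = amounts_at(GFAP, NOMINAL, 5.0)
        dbl = (
            amounts_at(GFAP, NOMINAL, 5.0 + h).D_bl
            - amounts_at(GFAP, NOMINAL, 5.0 - h).D_bl
        ) / (2 * h)
        rhs = GFAP.F * GFAP.ka * s.D_br - GFAP.ke * s.D_bl
        assert dbl == pytest.approx(rhs, rel=1e-6)


class TestRateRelations:
    @pytest.mark.parametrize(
        "t_half, printed_ke, places",
        [(1.5, 0.462, 3), (8.0, 0.0866, 4), (10.0, 0.0693, 4), (36.0, 0.0193, 4), (500.0, 0.0014, 4)],
    )
    def test_ke_from_half_life_matches_printed(self, t_half, printed_ke, places):
        # agreement to half a unit in the last printed place (inclusive)
        assert abs(ke_from_half_life(t_half) - printed_ke) <= 0.5 * 10**-places + 1e-15

    def test_unit_case_and_exact_mode(self):
        assert half_life_from_ke(0.693) == pytest.approx(1.0)
        assert ke_from_half_life(1.0, exact=True) == pytest.approx(math.log(2))

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            ke_from_half_life(0.0)
        with pytest.raises(ValueError):
            half_life_from_ke(-1.0)

    @given(st.floats(1e-3, 1e3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_and_inverse_proportionality(self, x):
        assert half_life_from_ke(ke_from_half_life(x)) == pytest.approx(x, rel=1e-14)
        assert ke_from_half_life(2 * x) == pytest.approx(ke_from_half_life(x) / 2, rel=1e-14)


class TestTimeOfPeak:
    def test_closed_form_values(self):
        assert time_of_peak(KineticParameters(ka=0.009, ke=0.0014)).Tmax == pytest.approx(
            244.83583430460612, rel=1e-12
        )
        assert time_of_peak(GFAP).Tmax == pytest.approx(23.425396025750274, rel=1e-12)

    def test_equal_rates_limit(self):
        assert time_of_peak(KineticParameters(ka=0.1, ke=0.1)).Tmax == pytest.approx(10.0)

    def test_cmax_is_concentration_at_tmax(self):
        peak = time_of_peak(GFAP, NOMINAL)
        assert peak.Cmax == pytest.approx(
            plasma_concentration(GFAP, NOMINAL, peak.Tmax), rel=1e-12
        )

    def test_grid_argmax_agrees_with_closed_form(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            ka, ke = np.exp(rng.uniform(np.log(1e-3), np.log(1.0), size=2))
            if abs(ka - ke) / ke < 1e-6:
                continue
            params = KineticParameters(ka=ka, ke=ke)
            tmax = time_of_peak(params).Tmax
            grid = np.linspace(max(tmax - 5, 0.0), tmax + 5, 2001)  # 5e-3 resolution
            cp = plasma_concentration(params, NOMINAL, grid)
            assert abs(grid[np.argmax(cp)] - tmax) <= 2 * (grid[1] - grid[0])


class TestKaFromTmax:
    def bisect_oracle(self, tmax, ke, lo=None, hi=10.0, iters=200):
        """Plain bisection on the absorption-faster branch."""
        lo = ke * (1 + 1e-9) if lo is None else lo
        f = lambda ka: math.log(ka / ke) / (ka - ke) - tmax
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            if f(mid) > 0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def test_nfl_root_matches_bisection_oracle(self):
        root = ka_from_tmax(240.0, 0.0014)
        assert root == pytest.approx(self.bisect_oracle(240.0, 0.0014), rel=1e-10)
        assert root == pytest.approx(0.009281431460, rel=1e-9)
        assert round(root, 3) == 0.009  # printed value

    def test_round_trip_with_time_of_peak(self):
        for ka, ke in [(0.08, 0.0193), (0.5, 0.462), (0.2, 0.0014), (0.009, 0.0014)]:
            tmax = time_of_peak(KineticParameters(ka=ka, ke=ke)).Tmax
            assert ka_from_tmax(tmax, ke) == pytest.approx(ka, rel=1e-9)

    def test_slower_branch_is_the_mirror_root(self):
        # flip-flop kinetics: Tmax(ka, ke) == Tmax(ke, ka)
        tmax = time_of_peak(KineticParameters(ka=0.08, ke=0.0193)).Tmax
        ka_slow = ka_from_tmax(tmax, ke=0.08, branch="absorption-slower")
        assert ka_slow == pytest.approx(0.0193, rel=1e-9)

    def test_degenerate_tmax_ke_product(self):
        with pytest.warns(RuntimeWarning):
            assert ka_from_tmax(10.0, 0.1) == 0.1

    def test_no_root_on_requested_branch(self):
        # faster branch requires Tmax < 1/ke
        with pytest.raises(ValueError):
            ka_from_tmax(100.0, ke=0.1)
        with pytest.raises(ValueError):
            ka_from_tmax(1.0, ke=0.1, branch="absorption-slower")


class TestCurveOverGrid:
    def test_empty_grid(self):
        assert len(curve_over_grid(GFAP, NOMINAL, [])) == 0

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            curve_over_grid(GFAP, NOMINAL, [0.0, 2.0, 1.0])

    def test_auc_identity(self):
        """Trapezoid AUC over a long grid approaches F*D0/(ke*Vd)."""
        grid = np.arange(0.0, 2000.0, 0.1)
        curve = curve_over_grid(GFAP, NOMINAL, grid)
        analytic = GFAP.F * NOMINAL.D0 / (GFAP.ke * NOMINAL.Vd)
        assert analytic == pytest.approx(3316.0621761658, rel=1e-10)
        assert curve.auc() == pytest.approx(analytic, rel=1e-3)

    def test_csv_round_trip(self, tmp_path):
        grid = np.linspace(0, 48, 97)
        curve = curve_over_grid(GFAP, NOMINAL, grid)
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        back = ConcentrationCurve.from_csv(path)
        np.testing.assert_allclose(back.levels, curve.levels, rtol=1e-5)
        assert path.read_text().splitlines()[0] == "time_hr,level_pg_ml"
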