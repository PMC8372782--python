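"""HAM series routes, closed forms, Euler extraction and effective delays."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import cumulative_trapezoid, solve_ivp

from hampulse import (
    HamConfig,
    effective_delays,
    effective_delays_compact,
    euler_angles_exact,
    f_from_series,
    first_order_c0_for_90deg,
    flip_profile,
    ham_euler_angles,
    ham_trajectory,
    hat_transform,
    make_waveform,
    method1_series,
    method2_series,
    perturbation_f_first_order,
    perturbation_f_ratio,
    rect_y1_closed_form,
    rectangular,
    riccati_direct,
    standard_pulse,
    euler_profile,
)

TWO_PI = 2.0 * np.pi
W1_HARD = TWO_PI * 25000.0


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            HamConfig(order=0)
        with pytest.raises(ValueError):
            HamConfig(c0=0.0)
        with pytest.raises(ValueError):
            HamConfig(method="bogus")
        with pytest.raises(ValueError):
            HamConfig(order=4, method="riccati_direct")


class TestMethod1:
    @pytest.mark.parametrize("ratio", [0.3, 1.0, 2.5, np.sqrt(15.0)])
    def test_first_order_matches_rectangular_closed_form(self, rect_hard, ratio):
        offset = ratio * W1_HARD
        s = method1_series(rect_hard, offset, HamConfig(order=1, c0=-1.0))
        closed = rect_y1_closed_form(W1_HARD, rect_hard.times, offset, -1.0)
        # quadrature tolerance: trapezoid error scales as (Omega dt)^2 / 12
        tol = max(1e-7, 0.5 * (offset * rect_hard.dt) ** 2)
        assert np.abs(s.terms[1] - closed).max() < tol * np.abs(closed).max()

    def test_on_resonance_limit_of_closed_form(self, rect_hard):
        s = method1_series(rect_hard, 0.0, HamConfig(order=1, c0=-1.0))
        closed = rect_y1_closed_form(W1_HARD, rect_hard.times, 0.0, -1.0)
        assert np.abs(s.terms[1] - closed).max() < 1e-7
        # y(tau_p) = 1 - (omega1 tau_p)^2 / 8 at first order on resonance
        expect = 1.0 - (np.pi / 2) ** 2 / 8.0
        assert s.total()[-1] == pytest.approx(expect, abs=1e-9)

    def test_c0_minus_one_is_pure_iterated_integral(self, eburp2):
        """At c0 = -1 the pass-through term vanishes from the recursion."""
        s = method1_series(eburp2, TWO_PI * 2000.0, HamConfig(order=3, c0=-1.0))
        hat_m = hat_transform(eburp2, TWO_PI * 2000.0)
        t = eburp2.times
        inner = cumulative_trapezoid(np.conj(hat_m) * s.terms[2], t, initial=0.0)
        pure = -0.25 * cumulative_trapezoid(hat_m * inner, t, initial=0.0)
        np.testing.assert_allclose(s.terms[3], pure, atol=1e-12)

    def test_first_order_overestimates_beta(self, rect_hard):
        traj = ham_trajectory(rect_hard, 0.0, HamConfig(order=1, c0=-1.0))
        expect = (np.pi / 4) / (1.0 - np.pi ** 2 / 32.0)
        assert abs(traj.f[-1]) == pytest.approx(expect, rel=1e-9)
        beta = 2.0 * np.arctan(abs(traj.f[-1]))
        assert np.degrees(beta) == pytest.approx(97.3, abs=0.05)
        assert beta > np.pi / 2  # first order overshoots the rotation angle

    def test_error_non_increasing_with_order(self, rect_hard):
        offs = W1_HARD * np.linspace(0.0, np.sqrt(15.0), 21)
        exact = euler_profile(rect_hard, offs)["beta"]
        maxerr = []
        for order in (1, 2, 3):
            cfg = HamConfig(order=order, c0=-1.0)
            beta = np.array([2.0 * np.arctan(abs(ham_trajectory(rect_hard, o, cfg).f[-1]))
                             for o in offs])
            maxerr.append(np.abs(beta - exact).max())
        assert maxerr[0] >= maxerr[1] >= maxerr[2]
        assert maxerr[2] < 0.01

    def test_tuned_c0_restores_90_degrees_at_first_order(self, rect_hard):
        c0 = first_order_c0_for_90deg()
        assert c0 == pytest.approx(-0.914, abs=5e-4)
        traj = ham_trajectory(rect_hard, 0.0, HamConfig(order=1, c0=c0))
        assert 2.0 * np.arctan(abs(traj.f[-1])) == pytest.approx(np.pi / 2, abs=1e-6)


class TestMethod2:
    def test_on_resonance_reduces_to_initial_approximation(self, rect_hard):
        s = method2_series(rect_hard, 0.0, HamConfig(order=4, method="method2"))
        half = 0.5 * flip_profile(rect_hard).delta
        np.testing.assert_allclose(s.total(), np.cos(half), atol=1e-12)
        for term in s.terms[1:]:
            assert np.abs(term).max() == 0.0  # each term carries a power of Omega

    def test_matches_unexpanded_perturbation_ratio(self, rect_hard):
        offset = 0.2 * W1_HARD
        cfg = HamConfig(order=1, c0=-1.0, method="method2")
        f_ham = f_from_series(method2_series(rect_hard, offset, cfg))
        f_ref = perturbation_f_ratio(rect_hard, offset)
        assert np.abs(f_ham.f - f_ref.f).max() < 1e-12

    def test_expanded_first_order_agrees_to_second_order_in_offset(self, rect_hard):
        cfg = HamConfig(order=1, c0=-1.0, method="method2")
        devs = []
        for ratio in (0.1, 0.05):
            off = ratio * W1_HARD
            f_ham = f_from_series(method2_series(rect_hard, off, cfg)).f[-1]
            f_cf = perturbation_f_first_order(rect_hard, off).f[-1]
            devs.append(abs(f_ham - f_cf))
        assert devs[0] < 3e-2
        # halving the offset shrinks the discrepancy ~4x (O(Omega^2) residual)
        assert devs[1] < 0.35 * devs[0]

    def test_small_offset_phase_is_offset_times_delay(self, rect_hard):
        """gamma ~ Omega/omega_1 for a rectangular 90 pulse (tau_gamma = 1/omega1)."""
        ratio = 0.02
        cfg = HamConfig(order=1, c0=-1.0, method="method2")
        ang = ham_euler_angles(rect_hard, ratio * W1_HARD, cfg)
        assert ang.gamma == pytest.approx(ratio, rel=1e-3)

    def test_accuracy_window_degrades_monotonically(self, rect_hard):
        """Third-order offset power series: accurate to roughly Omega/omega1 = 1."""
        cfg = HamConfig(order=3, c0=-1.0, method="method2")
        ratios = np.linspace(0.1, 1.25, 12)
        exact = euler_profile(rect_hard, ratios * W1_HARD)["beta"]
        errs = np.array([abs(ham_euler_angles(rect_hard, r * W1_HARD, cfg).beta - b)
                         for r, b in zip(ratios, exact)])
        assert np.all(np.diff(errs) >= -1e-12)
        assert errs[ratios <= 0.9].max() < 0.05
        err_15 = abs(ham_euler_angles(rect_hard, 1.5 * W1_HARD, cfg).beta
                     - euler_angles_exact(rect_hard, 1.5 * W1_HARD).beta)
        assert err_15 > 0.1

    def test_initial_approximation_solves_on_resonance_ode(self):
        """cos(delta/2) satisfies y'' - (dln w/dt) y' + w^2 y / 4 = 0.

        Finite-difference residual shrinks ~4x per grid doubling (the check
        itself is O(dt^2); the solution is exact).
        """
        residuals = []
        for n_points in (400, 800):
            x = np.linspace(0, 1, n_points)
            amp = 2000.0 * np.exp(-0.5 * ((x - 0.5) / 0.15) ** 2)
            w = make_waveform("custom", {"omega_x": amp, "duration": 1e-3})
            t = w.times
            y0 = np.cos(0.5 * flip_profile(w).delta)
            dy = np.gradient(y0, t)
            d2y = np.gradient(dy, t)
            dlnw = np.gradient(np.log(w.omega_x), t)
            res = d2y - dlnw * dy + 0.25 * w.omega_x ** 2 * y0
            residuals.append(np.abs(res[2:-2]).max())
        assert residuals[1] < 0.35 * residuals[0]

    def test_rejects_unsupported_waveforms(self, wurst20, rect_hard):
        with pytest.raises(ValueError):
            method2_series(wurst20, 0.0, HamConfig(method="method2"))
        varying = make_waveform("custom", {
            "omega_x": rect_hard.omega_x, "duration": rect_hard.duration,
            "offset_law": np.linspace(0, 1e4, rect_hard.n_points)})
        with pytest.raises(ValueError):
            method2_series(varying, 0.0, HamConfig(method="method2"))


class TestRiccatiDirect:
    def test_on_resonance_is_exact(self, rect_hard):
        traj = riccati_direct(rect_hard, 0.0, HamConfig(order=1, method="riccati_direct"))
        half = 0.5 * flip_profile(rect_hard).delta
        np.testing.assert_allclose(traj.f, np.tan(half), atol=1e-12)

    def test_first_order_matches_independent_ode_solution(self, rect_hard):
        """f1 solves df1/dt - i Omega f1 = -i c0 Omega tan(delta/2)."""
        offset = 0.5 * W1_HARD
        traj = riccati_direct(rect_hard, offset, HamConfig(order=1, method="riccati_direct"))
        half = 0.5 * flip_profile(rect_hard).delta
        f1 = traj.f - np.tan(half)
        t = rect_hard.times

        def rhs(s, y):
            hh = 0.5 * W1_HARD * s
            r = 1j * offset * (y[0] + 1j * y[1]) + 1j * offset * np.tan(hh)
            return [r.real, r.imag]

        sol = solve_ivp(rhs, (0, rect_hard.duration), [0.0, 0.0], t_eval=t,
                        rtol=1e-10, atol=1e-13)
        f1_ode = sol.y[0] + 1j * sol.y[1]
        assert np.abs(f1 - f1_ode).max() < 1e-6

    def test_less_accurate_than_transformed_route(self, rect_hard):
        offset = 0.5 * W1_HARD
        exact = euler_angles_exact(rect_hard, offset).beta
        cfg_d = HamConfig(order=3, c0=-1.0, method="riccati_direct")
        cfg_1 = HamConfig(order=3, c0=-1.0, method="method1")
        err_d = abs(2 * np.arctan(abs(riccati_direct(rect_hard, offset, cfg_d).f[-1])) - exact)
        err_1 = abs(2 * np.arctan(abs(ham_trajectory(rect_hard, offset, cfg_1).f[-1])) - exact)
        assert err_d > err_1

    def test_singular_samples_flagged_for_inversion_pulse(self, reburp):
        traj = riccati_direct(reburp, TWO_PI * 500.0,
                              HamConfig(order=1, method="riccati_direct"))
        assert traj.singular[-1]  # delta(tau_p) = pi makes tan(delta/2) blow up

    def test_order_cap(self, rect_hard):
        with pytest.raises(ValueError):
            riccati_direct(rect_hard, 0.0, HamConfig(order=4, method="riccati_direct"))


class TestEulerFromF:
    def test_rectangular_alpha_equals_gamma(self, rect_hard):
        cfg = HamConfig(order=3, c0=-1.0)
        for ratio in (0.3, 1.1, 2.0):
            ang = ham_euler_angles(rect_hard, ratio * W1_HARD, cfg)
            assert ang.alpha == pytest.approx(ang.gamma, abs=1e-9)

    def test_symmetric_shape_alpha_equals_gamma(self, reburp):
        cfg = HamConfig(order=5, c0=-1.0)
        ang = ham_euler_angles(reburp, TWO_PI * 4000.0, cfg)
        assert ang.alpha == pytest.approx(ang.gamma, abs=1e-6)

    def test_on_resonance_x_rotation(self, eburp2):
        ang = ham_euler_angles(eburp2, 0.0, HamConfig(order=3, c0=-1.0))
        assert ang.alpha == pytest.approx(0.0, abs=1e-9)
        assert ang.gamma == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("off_hz", [1000.0, 3000.0, -2500.0])
    def test_time_reversal_alpha_matches_oracle(self, eburp2, off_hz):
        """The reversal convention (no conjugation) validated for an
        asymmetric shape where alpha != gamma."""
        exact = euler_angles_exact(eburp2, TWO_PI * off_hz)
        ang = ham_euler_angles(eburp2, TWO_PI * off_hz, HamConfig(order=7, c0=-1.0))
        assert ang.alpha == pytest.approx(exact.alpha, abs=2e-3)

    def test_alpha_integral_route_agrees_with_reversal(self, eburp2):
        cfg = HamConfig(order=7, c0=-1.0)
        off = TWO_PI * 2000.0
        via_rev = ham_euler_angles(eburp2, off, cfg)
        via_int = ham_euler_angles(eburp2, off, cfg, alpha_via_integral=True)
        assert via_int.alpha == pytest.approx(via_rev.alpha, abs=2e-3)


class TestEffectiveDelays:
    def test_rectangular_90(self, rect_hard):
        tau_a, tau_g = effective_delays(rect_hard)
        expect = 1.0 / W1_HARD  # = (2/pi) tau_p ~ 6.366 us at 25 kHz
        assert tau_a == pytest.approx(expect, rel=1e-6)
        assert tau_g == pytest.approx(expect, rel=1e-6)
        assert expect * 1e6 == pytest.approx(6.366, abs=1e-3)

    def test_compact_form_identity(self, rect_hard):
        tau_a, tau_g = effective_delays(rect_hard)
        compact = effective_delays_compact(rect_hard)
        assert compact.real == pytest.approx(tau_a, rel=1e-9)
        assert compact.imag == pytest.approx(tau_g, rel=1e-9)

    def test_symmetric_shape_has_equal_delays(self):
        x = np.linspace(0, 1, 501)
        tri = np.minimum(x, 1.0 - x)
        dur = 100e-6
        w = make_waveform("custom", {
            "omega_x": tri * (np.pi / 2) / np.trapezoid(tri, x * dur), "duration": dur})
        tau_a, tau_g = effective_delays(w)
        assert tau_a == pytest.approx(tau_g, rel=1e-9)

    def test_undefined_for_180_pulse(self, reburp):
        with pytest.raises(ValueError):
            effective_delays(reburp)


@given(amp_hz=st.floats(100.0, 30000.0), frac=st.floats(0.1, 1.0),
       ratio=st.floats(-1.0, 1.0))
@settings(max_examples=20, deadline=None)
def test_property_method1_converges_to_oracle(amp_hz, frac, ratio):
    """Order-6 method 1 reproduces the oracle rotation angle for arbitrary
    rectangular pulses up to a full on-resonance rotation and |Omega| <= omega1."""
    duration = frac / amp_hz  # flip angle frac * 2pi... capped below
    w = rectangular(amp_hz, 0.5 * duration, n_points=300)  # flip <= pi
    offset = ratio * TWO_PI * amp_hz
    traj = ham_trajectory(w, offset, HamConfig(order=6, c0=-1.0))
    beta = 2.0 * np.arctan(abs(traj.f[-1]))
    exact = euler_angles_exact(w, offset).beta
    assert abs(beta - exact) < 2e-3
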