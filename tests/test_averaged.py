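"""Closed-form averaged amplitude/frequency laws and waveform reconstruction."""

import numpy as np
import pytest

import toothvib as tv
from toothvib.averaged import EnvelopeLaw, phase_closed_form


class TestAmplitudeLaws:
    def test_no_mass_loss_returns_A0(self):
        assert tv.amplitude_with_reactive(0.7, 1.32, 1.32, 1.03) == pytest.approx(0.7)
        assert tv.amplitude_no_reactive(0.7, 1.32, 1.32, 1.03) == pytest.approx(0.7)

    def test_power_law_values(self):
        # frozen direct evaluations of the two mirror power laws
        assert tv.amplitude_with_reactive(1.0, 2.0, 1.0, 1.03) == pytest.approx(
            2.0 ** (1.0 / 4.03), rel=1e-12
        )
        assert tv.amplitude_with_reactive(1.0, 2.0, 1.0, 1.03) == pytest.approx(1.18767, abs=1e-5)
        assert tv.amplitude_no_reactive(1.0, 2.0, 1.0, 1.03) == pytest.approx(0.84198, abs=1e-5)

    def test_reciprocal_exponents_cancel(self):
        w = tv.amplitude_with_reactive(1.0, 1.5, 1.1, 1.05)
        n = tv.amplitude_no_reactive(1.0, 1.5, 1.1, 1.05)
        assert w * n == pytest.approx(1.0, rel=1e-12)

    def test_amplitude_independent_of_rigidity(self):
        # the law has no k in it; frequencies do
        law_a = EnvelopeLaw("with_reactive", 0.5, 1.03, 1.0, 1.32)
        law_b = EnvelopeLaw("with_reactive", 0.5, 1.03, 7.0, 1.32)
        m = np.linspace(0.9, 1.32, 7)
        np.testing.assert_allclose(law_a.amplitude(m), law_b.amplitude(m))
        assert not np.allclose(law_a.frequency(m), law_b.frequency(m))

    def test_monotone_along_mass_loss(self):
        m = np.linspace(1.32, 0.7, 50)
        A_w = tv.amplitude_with_reactive(0.58, 1.32, m, 1.03)
        A_n = tv.amplitude_no_reactive(0.58, 1.32, m, 1.03)
        assert np.all(np.diff(A_w) > 0)
        assert np.all(np.diff(A_n) < 0)

    def test_lower_order_grows_faster(self):
        # at fixed mass ratio > 1 the normalized envelope orders by 1/(alpha+3)
        vals = [tv.amplitude_with_reactive(1.0, 1.5, 1.0, a) for a in (1.01, 1.05, 1.1)]
        assert vals[0] > vals[1] > vals[2]

    def test_rejects_nonpositive_mass(self):
        with pytest.raises(ValueError):
            tv.amplitude_with_reactive(1.0, 1.32, 0.0, 1.03)
        with pytest.raises(ValueError):
            tv.amplitude_no_reactive(1.0, 1.32, -1.0, 1.03)


class TestFrequencyLaws:
    def test_linear_case_reduces_to_sqrt_k_over_m(self):
        m = np.linspace(0.8, 1.32, 9)
        om = tv.frequency_with_reactive(0.77, 1.32, m, 1.0, 1.0)
        np.testing.assert_allclose(om, np.sqrt(1.0 / m), rtol=1e-13)
        # and is independent of A0 at alpha = 1
        om2 = tv.frequency_with_reactive(0.12, 1.32, m, 1.0, 1.0)
        np.testing.assert_allclose(om, om2)

    def test_worked_example_power_law(self, molar_law):
        C, p = tv.power_law_coefficients(molar_law)
        assert p == pytest.approx(-2.03 / 4.03, rel=1e-13)
        assert C == pytest.approx(0.985612, abs=1e-5)
        # frequency at the initial mass
        assert molar_law.frequency(1.32) == pytest.approx(C * 1.32**p, rel=1e-12)
        assert molar_law.frequency(1.32) == pytest.approx(0.85698, abs=1e-4)

    def test_regimes_coincide_at_initial_mass(self, molar_law):
        m0 = molar_law.m0
        kwargs = dict(A0=molar_law.A0, alpha=molar_law.alpha, k=molar_law.k, m0=m0)
        laws = [EnvelopeLaw(regime=r, **kwargs)
                for r in ("with_reactive", "no_reactive", "constant_mass")]
        vals = [law.frequency(m0) for law in laws]
        np.testing.assert_allclose(vals, vals[0], rtol=1e-14)
        consistent = EnvelopeLaw(regime="no_reactive", freq_mode="consistent", **kwargs)
        assert consistent.frequency(m0) == pytest.approx(vals[0], rel=1e-14)

    def test_no_reactive_modes_disagree_away_from_m0(self):
        law_p = EnvelopeLaw("no_reactive", 0.58, 1.03, 1.0, 1.32, freq_mode="printed")
        law_c = EnvelopeLaw("no_reactive", 0.58, 1.03, 1.0, 1.32, freq_mode="consistent")
        # printed law falls with m/m0; consistent law rises
        assert law_p.frequency(1.0) < law_p.frequency(1.32)
        assert law_c.frequency(1.0) > law_c.frequency(1.32)
        ratio = law_p.frequency(1.32 * 0.8) / law_p.frequency(1.32)
        assert ratio == pytest.approx(0.8 ** (2.03 / 4.03), rel=1e-12)
        assert ratio == pytest.approx(0.89368, abs=1e-5)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            tv.frequency_no_reactive(0.5, 1.32, 1.0, 1.03, 1.0, mode="other")

    def test_constant_mass_frequency(self):
        assert tv.constant_mass_frequency(1.0, 1.0, 1.0, 1.0) == pytest.approx(1.0)
        assert tv.constant_mass_frequency(0.3, 1.0, 4.0, 2.0) == pytest.approx(
            np.sqrt(4.0 / 2.0)
        )

    def test_power_law_coefficients_linear_case(self):
        law = EnvelopeLaw("with_reactive", 0.9, 1.0, 1.0, 1.0)
        C, p = tv.power_law_coefficients(law)
        assert (C, p) == (pytest.approx(1.0), pytest.approx(-0.5))

    def test_power_law_constant_mass(self):
        law = EnvelopeLaw("constant_mass", 0.58345, 1.03, 1.0, 1.32)
        C, p = tv.power_law_coefficients(law)
        assert p == 0.0
        assert C == pytest.approx(tv.constant_mass_frequency(0.58345, 1.03, 1.0, 1.32))


class TestPhase:
    def test_constant_frequency_is_linear(self):
        law = EnvelopeLaw("constant_mass", 0.5, 1.03, 1.0, 1.32)
        sched = tv.MassSchedule(1.32, 0.0)
        t = np.linspace(0.0, 10.0, 101)
        psi = tv.accumulate_phase(law, sched, t, theta0=0.3)
        om = law.frequency(1.32)
        np.testing.assert_allclose(psi, 0.3 + om * t, rtol=1e-10)

    def test_simpson_matches_closed_form_antiderivative(self, molar_law, molar):
        t = np.linspace(0.0, 100.0, 2001)
        psi = tv.accumulate_phase(molar_law, molar.schedule, t)
        exact = phase_closed_form(molar_law, molar.schedule, t)
        assert np.max(np.abs(psi - exact)) < 1e-8

    def test_phase_nondecreasing(self, molar_law, molar):
        t = np.linspace(0.0, 300.0, 4001)
        psi = tv.accumulate_phase(molar_law, molar.schedule, t)
        assert np.all(np.diff(psi) > 0)

    def test_bad_grid_rejected(self, molar_law, molar):
        with pytest.raises(ValueError, match="grid"):
            tv.accumulate_phase(molar_law, molar.schedule, np.array([1.0, 2.0]))
        with pytest.raises(tv.MassHorizonError):
            tv.accumulate_phase(molar_law, molar.schedule, np.linspace(0.0, 700.0, 50))


class TestWaveform:
    def test_linear_case_is_sine_plus_offset(self):
        psi = np.linspace(0.0, 12.0, 400)
        A = np.full_like(psi, 0.7)
        u = tv.waveform(A, psi, 1.0, drive_over_k=0.02)
        np.testing.assert_allclose(u, 0.7 * np.sin(psi) + 0.02, atol=1e-12)

    def test_zero_drive_peak_is_envelope(self):
        o = tv.GtfOrder(1.03)
        psi = np.array([o.quarter_period])
        A = np.array([0.58345])
        u = tv.waveform(A, psi, 1.03)
        assert u[0] == pytest.approx(0.58345, rel=1e-10)

    def test_first_peak_of_worked_example(self, molar_law, molar):
        # positive peak: (A0**alpha + drive/k) ** (1/alpha)
        u_peak = tv.peak_displacement(molar_law, 1.32, drive_over_k=0.02)
        expected = (molar_law.A0**1.03 + 0.02) ** (1 / 1.03)
        assert u_peak == pytest.approx(expected, rel=1e-12)
        assert u_peak == pytest.approx(0.60317, abs=5e-5)  # frozen evaluation

    def test_signed_root_continuous_through_negative_bracket(self):
        o = tv.GtfOrder(1.03)
        psi = np.linspace(0.0, o.period, 4001)
        A = np.full_like(psi, 0.58345)
        u = tv.waveform(A, psi, 1.03, drive_over_k=0.02)
        assert np.all(np.isfinite(u))
        assert np.min(u) < 0  # the trough does go negative
        assert np.max(np.abs(np.diff(u))) < 0.01  # no jumps at the sign change

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            tv.waveform(np.ones(3), np.ones(4), 1.03)


class TestAnalyticTrajectory:
    def test_fields_consistent(self, molar_law, molar):
        t = np.linspace(0.0, 50.0, 2501)
        traj = tv.analytic_trajectory(molar_law, molar.schedule, t, drive_over_k=0.02)
        assert traj.A[0] == pytest.approx(molar_law.A0)
        assert np.all(np.diff(traj.psi) > 0)
        assert np.all(traj.A > 0)
        np.testing.assert_allclose(traj.m, molar.schedule.mass_at(t))
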