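import math

import numpy as np
import pytest
from pytest import approx
from scipy.integrate import solve_ivp

from magloss import (
    FieldExcitation,
    MaterialSpec,
    ParticleGroup,
    PowerResult,
    chord_susceptibility,
    complex_magnetization,
    langevin,
    langevin_alpha,
    sar,
    sar_sweep,
    volumetric_power,
)
from magloss.constants import K_B, MU0
from magloss.response import SusceptibilityResponse, initial_susceptibility

from conftest import M_D


def closed_form_power(chi, H, omega, tau):
    """Independent per-axis oracle: (mu0/2) chi H^2 omega^2 tau / (1+(omega tau)^2)."""
    return 0.5 * MU0 * chi * H**2 * omega**2 * tau / (1.0 + (omega * tau) ** 2)


class TestLangevin:
    def test_limits_and_reference_value(self):
        assert langevin(0.0) == 0.0
        # coth(1) - 1 from the double-precision closed form
        assert langevin(1.0) == approx(1.0 / math.tanh(1.0) - 1.0, rel=1e-14)
        assert langevin(1e6) == approx(1.0, abs=1e-5)

    def test_series_and_closed_form_agree_at_the_switch(self):
        # the implementation switches representation at alpha = 0.05; the
        # oracle is the truncated odd-power series, accurate to ~1e-15 there
        def series(a):
            return (a / 3 - a**3 / 45 + 2 * a**5 / 945 - a**7 / 4725
                    + 2 * a**9 / 93555)

        for a in (0.049, 0.05, 0.051, 1e-3, 1e-5):
            assert langevin(a) == approx(series(a), rel=1e-12)
        # above the switch the plain closed form is well conditioned
        for a in (0.1, 0.5, 2.0):
            assert langevin(a) == approx(1.0 / np.tanh(a) - 1.0 / a, rel=1e-13)

    def test_monotone_and_bounded(self):
        a = np.logspace(-6, 2, 200)
        L = langevin(a)
        assert np.all(np.diff(L) > 0)
        assert np.all((L >= 0) & (L < 1))

    def test_negative_argument_rejected(self):
        with pytest.raises(ValueError):
            langevin(-0.1)


class TestLangevinAlpha:
    def test_hand_arithmetic_value(self):
        V_p = math.pi / 6 * (7.5e-9) ** 3  # 2.2089e-25 m^3
        assert langevin_alpha(V_p, 4e5, 4.3e3, 293.0) == approx(0.1181, rel=1e-3)

    def test_linear_in_field(self):
        V_p = math.pi / 6 * (10e-9) ** 3
        a1 = langevin_alpha(V_p, 4e5, 2e3, 300.0)
        a2 = langevin_alpha(V_p, 4e5, 4e3, 300.0)
        assert a2 == approx(2 * a1, rel=1e-14)
        assert langevin_alpha(V_p, 4e5, 0.0, 300.0) == 0.0


class TestChordSusceptibility:
    def test_composed_oracle_value(self):
        V_p = math.pi / 6 * (7.5e-9) ** 3
        alpha = langevin_alpha(V_p, 4e5, 4.3e3, 293.0)
        chi = chord_susceptibility(0.01611, 4e5, 4.3e3, alpha)
        assert chi == approx(0.0589, rel=2e-3)

    def test_saturation_chord(self):
        chi = chord_susceptibility(0.01, 4e5, 4.3e3, 1e9)
        assert chi == approx(0.01 * 4e5 / 4.3e3, rel=1e-8)

    def test_zero_field_dispatches_to_initial_susceptibility(self):
        V_p = math.pi / 6 * (9e-9) ** 3
        chi0 = chord_susceptibility(0.02, 4e5, 0.0, 0.0, V_p=V_p, T=293.0)
        assert chi0 == approx(0.02 * MU0 * V_p * (4e5) ** 2 / (3 * K_B * 293.0),
                              rel=1e-14)
        with pytest.raises(ValueError, match="V_p and T"):
            chord_susceptibility(0.02, 4e5, 0.0, 0.0)

    def test_small_field_converges_to_initial_susceptibility(self):
        V_p = math.pi / 6 * (9e-9) ** 3
        chi0 = initial_susceptibility(0.02, V_p, 4e5, 293.0)
        alpha = langevin_alpha(V_p, 4e5, 1e-3, 293.0)
        chi = chord_susceptibility(0.02, 4e5, 1e-3, alpha, V_p=V_p, T=293.0)
        assert chi == approx(chi0, rel=1e-6)

    def test_twelve_group_band_at_4p3_kA_per_m(self, twelve_groups):
        """All chord susceptibilities of the size groups stay within [0, 0.17]."""
        for g in twelve_groups:
            alpha = langevin_alpha(g.V_p, M_D, 4.3e3, 298.15)
            chi = chord_susceptibility(g.phi_d, M_D, 4.3e3, alpha)
            assert 0.0 <= chi <= 0.17


class TestComplexMagnetization:
    def test_in_phase_and_minus_45_degree_points(self):
        h = complex(1000.0)
        assert complex_magnetization(0.1, h, 0.0, 1e-6) == approx(0.1 * h)
        omega, tau = 1e6, 1e-6  # omega*tau = 1
        M = complex_magnetization(0.1, h, omega, tau)
        assert abs(M) == approx(0.1 * abs(h) / math.sqrt(2), rel=1e-12)
        assert math.degrees(np.angle(M)) == approx(-45.0, abs=1e-9)

    def test_matches_debye_relaxation_ode_steady_state(self):
        """Brute-force oracle: integrate dM/dt = (chi h(t) - M)/tau to steady state."""
        chi, H, f, tau = 0.08, 4300.0, 2.0e5, 3.0e-7
        omega = 2 * math.pi * f

        def rhs(t, M):
            return (chi * H * np.cos(omega * t) - M[0]) / tau

        period = 1.0 / f
        t_end = 25 * tau + 10 * period
        sol = solve_ivp(rhs, (0.0, t_end), [0.0], rtol=1e-10, atol=1e-12,
                        dense_output=True)
        ts = np.linspace(t_end - period, t_end, 4001)
        M_t = sol.sol(ts)[0]
        a = 2.0 / period * np.trapezoid(M_t * np.cos(omega * ts), ts)
        b = -2.0 / period * np.trapezoid(M_t * np.sin(omega * ts), ts)
        M_hat = complex_magnetization(chi, complex(H), omega, tau)
        assert a == approx(M_hat.real, rel=1e-5)
        assert b == approx(M_hat.imag, rel=1e-5)


class TestVolumetricPower:
    def test_single_group_hand_value_at_peak(self):
        f = 395e3
        omega = 2 * math.pi * f
        field = FieldExcitation(H_x=4.3e3, H_y=0.0, f=f)
        resp = SusceptibilityResponse(0, 0, chi_x=0.1, chi_y=0.0)
        p = volumetric_power([resp], field, [1.0 / omega])
        assert p.P == approx(1.44e6, rel=2e-3)

    def test_complex_route_matches_closed_form_oracle(self, rng):
        for _ in range(1000):
            chi_x, chi_y = rng.uniform(0.0, 0.2, 2)
            H_x, H_y = rng.uniform(100.0, 1e4, 2)
            f = rng.uniform(5e4, 1e6)
            tau = 10 ** rng.uniform(-9, -3)
            omega = 2 * math.pi * f
            field = FieldExcitation(H_x=H_x, H_y=H_y, f=f, mode="rotating")
            resp = SusceptibilityResponse(0, 0, chi_x=chi_x, chi_y=chi_y)
            got = volumetric_power([resp], field, [tau]).P
            want = closed_form_power(chi_x, H_x, omega, tau) + closed_form_power(
                chi_y, H_y, omega, tau
            )
            assert got == approx(want, rel=1e-12)

    def test_rotating_is_exactly_twice_alternating(self):
        f, tau, chi, H = 402e3, 2e-7, 0.05, 3e3
        alt = volumetric_power(
            [SusceptibilityResponse(0, 0, chi, 0.0)],
            FieldExcitation(H_x=H, H_y=0.0, f=f), [tau],
        ).P
        rot = volumetric_power(
            [SusceptibilityResponse(0, 0, chi, chi)],
            FieldExcitation(H_x=H, H_y=H, f=f, mode="rotating"), [tau],
        ).P
        assert rot == 2.0 * alt

    def test_zero_field_gives_zero_power(self):
        field = FieldExcitation(H_x=0.0, H_y=0.0, f=1e5, mode="rotating")
        p = volumetric_power([SusceptibilityResponse(0, 0, 0.0, 0.0)], field, [1e-7])
        assert p.P == 0.0

    def test_additivity_over_groups(self, rng):
        f = 395e3
        field = FieldExcitation(H_x=4.3e3, H_y=0.0, f=f)
        chis = rng.uniform(0.0, 0.1, 12)
        taus = 10 ** rng.uniform(-9, -5, 12)
        resps = [SusceptibilityResponse(0, 0, c, 0.0) for c in chis]
        total = volumetric_power(resps, field, list(taus)).P
        singles = sum(
            volumetric_power([r], field, [t]).P for r, t in zip(resps, taus)
        )
        assert total == approx(singles, rel=1e-14)
        assert volumetric_power(resps, field, list(taus)).per_group.sum() == approx(
            total, rel=1e-14
        )

    def test_mismatched_groups_raise(self):
        field = FieldExcitation(H_x=1e3, H_y=0.0, f=1e5)
        with pytest.raises(ValueError, match="relaxation times"):
            volumetric_power(
                [SusceptibilityResponse(0, 0, 0.1, 0.0)] * 2, field, [1e-7]
            )

    def test_power_peaks_at_omega_tau_equal_one(self):
        omega = 2 * math.pi * 3e5
        field = FieldExcitation(H_x=4e3, H_y=0.0, f=3e5)
        taus = (1.0 / omega) * np.logspace(-3, 3, 121)
        powers = [
            volumetric_power([SusceptibilityResponse(0, 0, 0.1, 0.0)], field, [t]).P
            for t in taus
        ]
        assert int(np.argmax(powers)) == 60  # the grid point where omega*tau == 1


class TestSar:
    def test_arithmetic_and_conventions(self, material):
        p = PowerResult(P=1e6)
        assert sar(p, material) == approx(1e6 / (0.1057 * 4860.0), rel=1e-12)
        assert sar(p, material, "literal") == approx(1e6 / 4860.0, rel=1e-12)
        assert sar(PowerResult(P=0.0), material) == 0.0

    def test_proportional_to_power(self, material):
        assert sar(PowerResult(P=2e6), material) == approx(
            2 * sar(PowerResult(P=1e6), material), rel=1e-14
        )


class TestSarSweep:
    def test_single_point_consistency(self, twelve_groups, material, conditions):
        df = sar_sweep(twelve_groups, material, [4.3e3], [395e3],
                       "alternating", conditions)
        assert len(df) == 1
        assert df.loc[0, "SAR_W_per_g"] > 0
        assert df.loc[0, "P_W_per_m3"] == approx(
            df.loc[0, "SAR_W_per_g"] * 1e3 * 0.1057 * 4860.0, rel=1e-12
        )

    def test_rotating_doubles_each_sweep_point(self, twelve_groups, material,
                                               conditions):
        H = [1e3, 2e3, 3e3]
        alt = sar_sweep(twelve_groups, material, H, [402e3], "alternating",
                        conditions)
        rot = sar_sweep(twelve_groups, material, H, [402e3], "rotating", conditions)
        assert rot["SAR_W_per_g"].to_numpy() == approx(
            2 * alt["SAR_W_per_g"].to_numpy(), rel=1e-14
        )

    def test_monotone_in_field_and_frequency(self, twelve_groups, material,
                                             conditions):
        df = sar_sweep(
            twelve_groups, material, [1e3, 2e3, 4e3],
            [1e5, 2e5, 4e5], "alternating", conditions,
        )
        for f, sub in df.groupby("f_kHz"):
            assert sub["SAR_W_per_g"].is_monotonic_increasing
        for H, sub in df.groupby("H_kA_per_m"):
            assert sub.sort_values("f_kHz")["SAR_W_per_g"].is_monotonic_increasing

    def test_low_frequency_scaling_is_quadratic(self, material, conditions):
        """With omega*tau << 1 the dissipation grows as omega^2."""
        groups = [ParticleGroup(d_core=6e-9, phi_d=0.01)]
        df = sar_sweep(groups, material, [2e3], [1e4, 2e4], "alternating",
                       conditions)
        ratio = df.loc[1, "SAR_W_per_g"] / df.loc[0, "SAR_W_per_g"]
        assert ratio == approx(4.0, rel=1e-2)

    def test_validity_guard_warns_outside_envelope(self, material, conditions):
        big = [ParticleGroup(d_core=25e-9, phi_d=0.01)]
        with pytest.warns(UserWarning, match="20 nm"):
            sar_sweep(big, material, [1e3], [1e5], "alternating", conditions)
        small = [ParticleGroup(d_core=10e-9, phi_d=0.01)]
        with pytest.warns(UserWarning, match="10 mT"):
            sar_sweep(small, material, [1e4], [1e5], "alternating", conditions)
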