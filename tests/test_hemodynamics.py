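"""Unit and property tests for the reduced-order blood model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fgaorta.hemodynamics import (
    FlowParams,
    Waveform,
    axial_pressure_profile,
    equilibrium_radius,
    hoop_strain,
    poiseuille_gradient,
    sinusoid,
    sinusoid_pressure,
    tabulated,
    thinwall_hoop_stress,
    wall_shear,
    wall_shear_from_Q,
)


def default_flow(**kw):
    base = dict(mu=0.0035, Q_shear=11.91, Q_vol=1e-4, t_wall=0.00232,
                E_in=1.9e6, r_in=0.0168, r_out=0.01912)
    base.update(kw)
    return FlowParams(**base)


class TestWaveform:
    def test_sinusoid_peak_is_16000(self):
        w = sinusoid(16000.0)
        assert w(0.5) == pytest.approx(16000.0)
        t = np.linspace(0, 2, 2001)
        assert np.max(w(t)) == pytest.approx(16000.0)

    def test_sinusoid_formula(self):
        t = np.linspace(0, 4, 41)
        np.testing.assert_allclose(sinusoid(500.0)(t), 500.0 * np.sin(np.pi * t))
        np.testing.assert_allclose(sinusoid_pressure(t, 500.0),
                                   500.0 * np.sin(np.pi * t))

    def test_tabulated_periodic(self):
        w = tabulated([0.0, 0.5, 1.0], [0.0, 10.0, 0.0])
        assert w(0.25) == pytest.approx(5.0)
        assert w(1.25) == pytest.approx(w(0.25))
        assert w(-0.75) == pytest.approx(w(0.25))

    def test_tabulated_seam_discontinuity_rejected(self):
        with pytest.raises(ValueError):
            tabulated([0.0, 0.5, 1.0], [0.0, 10.0, 7.0])

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError):
            tabulated([0.0, 0.5, 0.5], [0.0, 1.0, 0.0])

    def test_table_round_trip(self, tmp_path):
        w = tabulated([0.0, 0.3, 1.1], [1.0, 4.0, 1.0])
        path = tmp_path / "wave.csv"
        w.to_table(path)
        w2 = Waveform.from_table(path)
        np.testing.assert_allclose(w2.times, w.times)
        np.testing.assert_allclose(w2.values, w.values)

    def test_sinusoid_not_exportable(self, tmp_path):
        with pytest.raises(ValueError):
            sinusoid(1.0).to_table(tmp_path / "x.csv")


class TestPointwiseRelations:
    def test_poiseuille_gradient_closed_form(self):
        assert poiseuille_gradient(1e-4, 0.0035, 0.0168) == pytest.approx(
            -8 * 0.0035 * 1e-4 / (np.pi * 0.0168**4))

    def test_poiseuille_gradient_negative_for_forward_flow(self):
        assert poiseuille_gradient(1e-4, 0.0035, 0.01) < 0

    def test_thinwall_hoop_stress(self):
        assert thinwall_hoop_stress(16000.0, 0.0168, 0.00232) == pytest.approx(
            16000.0 * 0.0168 / 0.00232)

    def test_hoop_strain(self):
        assert hoop_strain(0.017, 0.0168) == pytest.approx((0.017 - 0.0168) / 0.0168)

    def test_wall_shear_forms_agree(self):
        # tau = mu U / d written with the flow ratio Q_shear = U / d
        assert wall_shear(0.0035, 11.91, 1.0) == pytest.approx(
            wall_shear_from_Q(0.0035, 11.91))
        assert default_flow().tau == pytest.approx(0.0035 * 11.91)


class TestEquilibriumRadius:
    def test_closed_form(self):
        p = default_flow()
        P = 2000.0
        r = equilibrium_radius(P, p)
        # balance: P r / t = E (r - r_in) / r_in
        assert P * r / p.t_wall == pytest.approx(p.E_in * (r - p.r_in) / p.r_in)

    def test_zero_pressure_is_unloaded(self):
        p = default_flow()
        assert equilibrium_radius(0.0, p) == p.r_in

    def test_distension_limit_raises(self):
        p = default_flow()
        P_lim = p.E_in * p.t_wall / p.r_in
        with pytest.raises(ValueError):
            equilibrium_radius(P_lim * 1.01, p)

    @settings(max_examples=30, derandomize=True)
    @given(P=st.floats(0.0, 50000.0))
    def test_monotone_distension(self, P):
        p = default_flow(E_in=25e6)
        assert equilibrium_radius(P, p) >= p.r_in


class TestAxialPressureProfile:
    X = np.linspace(0.0, 0.05, 21)
    T = np.linspace(0.0, 1.0, 11)

    def test_zero_flow_profile_equals_inlet_waveform(self):
        w = sinusoid(16000.0)
        P = axial_pressure_profile(w, default_flow(Q_vol=0.0), self.X, self.T)
        np.testing.assert_allclose(P, np.broadcast_to(w(self.T), (self.X.size,
                                                                  self.T.size)))

    def test_zero_viscosity_profile_equals_inlet_waveform(self):
        w = sinusoid(16000.0)
        P = axial_pressure_profile(w, default_flow(mu=1e-300), self.X, self.T)
        np.testing.assert_allclose(P, np.broadcast_to(w(self.T),
                                                      (self.X.size, self.T.size)),
                                   rtol=1e-9, atol=1e-200)

    def test_positive_flow_nonincreasing_along_x(self):
        P = axial_pressure_profile(sinusoid(16000.0), default_flow(E_in=25e6),
                                   self.X, self.T)
        assert np.all(np.diff(P, axis=0) <= 1e-12)

    def test_inlet_value_matches_waveform(self):
        w = sinusoid(16000.0)
        P = axial_pressure_profile(w, default_flow(E_in=25e6), self.X, self.T)
        np.testing.assert_allclose(P[0, :], w(self.T))

    def test_wall_radius_override_is_quadrature(self):
        # fixed rigid radius: drop = integral of the constant gradient
        p = default_flow()
        r0 = p.r_in
        P = axial_pressure_profile(sinusoid(16000.0), p, self.X,
                                   np.array([0.5]),
                                   wall_radius=lambda x: np.full_like(x, r0))
        drop = poiseuille_gradient(p.Q_vol, p.mu, r0) * self.X
        np.testing.assert_allclose(P[:, 0], 16000.0 + drop, rtol=1e-10)

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            axial_pressure_profile(sinusoid(1.0), default_flow(),
                                   np.array([0.01, 0.02]), self.T)


class TestFlowParamsValidation:
    @pytest.mark.parametrize("kw", [
        {"mu": 0.0}, {"t_wall": -1.0}, {"r_in": 0.02, "r_out": 0.0168},
    ])
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            default_flow(**kw)

    def test_Q_vol_from_velocity(self):
        # U * pi r^2
        assert FlowParams.Q_vol_from_velocity(0.1, 0.0168) == pytest.approx(
            0.1 * np.pi * 0.0168**2)
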