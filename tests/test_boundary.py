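"""Waveform shape, BC assembly and the Reynolds-regime check."""

import numpy as np
import pytest

from laa_stasis.anatomy import DEFAULT_SPECS
from laa_stasis.boundary import (
    AF,
    HEALTHY,
    FluidProperties,
    Waveform,
    assemble_bcs,
    reynolds_number,
)
from laa_stasis.errors import TaggingError


class TestWaveform:
    def test_healthy_peak_is_032(self):
        """Healthy defaults reach exactly 0.32 m/s at the E-wave peak."""
        wf = Waveform.healthy()
        t = np.linspace(0.0, wf.T, 8001)
        assert np.max(wf(t)) == pytest.approx(0.32, abs=1e-12)
        assert wf(wf.e_peak_time) == pytest.approx(0.32, abs=1e-12)

    def test_zero_during_atrial_diastole(self):
        """Valve closed for the first 37.5% of the 0.8 s cycle."""
        wf = Waveform.healthy()
        t = np.linspace(0.0, wf.t_open - 1e-9, 200)
        assert np.all(wf(t) == 0.0)
        assert wf.t_open == pytest.approx(0.3)

    def test_af_removes_a_wave_only(self):
        """AF equals healthy outside the A-wave support; zero inside it."""
        h, a = Waveform.healthy(), Waveform.af()
        assert a.A_peak == 0.0
        t_e = np.linspace(h.e_window[0], h.e_window[1] - 1e-9, 100)
        np.testing.assert_allclose(a(t_e), h(t_e))
        assert a(h.a_peak_time) == pytest.approx(h(h.a_peak_time) - h.A_peak)
        assert h.a_peak_time == pytest.approx(0.75)
        assert h(h.a_peak_time) == pytest.approx(h.A_peak)

    def test_periodic_and_nonnegative(self):
        wf = Waveform.healthy()
        t = np.linspace(-2 * wf.T, 3 * wf.T, 700)
        np.testing.assert_allclose(wf(t), wf(t + wf.T), atol=1e-14)
        assert np.all(wf(t) >= 0.0)

    def test_af_cycle_integral_smaller(self):
        """Removing the A-wave removes ejected volume."""
        t = np.linspace(0.0, 0.8, 4001)
        vol_h = np.trapezoid(Waveform.healthy()(t), t)
        vol_a = np.trapezoid(Waveform.af()(t), t)
        assert vol_a < vol_h
        # the missing volume is exactly the A-wave pulse area: peak * width / 2
        assert vol_h - vol_a == pytest.approx(0.24 * 0.1 / 2, rel=1e-3)

    def test_continuity_at_phase_boundaries(self):
        """sin^2 pulses join the closed phase without jumps."""
        wf = Waveform.healthy()
        for edge in (wf.t_open, wf.e_window[1], wf.T):
            eps = 1e-9
            assert abs(wf(edge + eps) - wf(edge - eps)) < 1e-6

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            Waveform(T=-1.0)
        with pytest.raises(ValueError):
            Waveform(E_peak=-0.1)
        with pytest.raises(ValueError):
            Waveform(condition="flutter")


class TestWaveformProperties:
    """Invariants over the admissible parameter space."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        T=st.floats(0.4, 2.0),
        diastole=st.floats(0.1, 0.9),
        e_peak=st.floats(0.0, 1.0),
        a_peak=st.floats(0.0, 1.0),
        t=st.floats(-5.0, 5.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_periodic_nonnegative_closed_phase(self, T, diastole, e_peak, a_peak, t):
        wf = Waveform(T=T, diastole_fraction=diastole, E_peak=e_peak, A_peak=a_peak)
        v = wf(t)
        assert v >= 0.0
        assert wf(t + T) == pytest.approx(v, abs=1e-12)
        assert wf(0.5 * wf.t_open) == 0.0  # valve closed in atrial diastole

    @given(
        T=st.floats(0.4, 2.0),
        diastole=st.floats(0.1, 0.9),
        e_peak=st.floats(0.01, 1.0),
        a_peak=st.floats(0.01, 1.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_af_coincides_outside_a_wave_and_ejects_less(self, T, diastole, e_peak, a_peak):
        h = Waveform(T=T, diastole_fraction=diastole, E_peak=e_peak, A_peak=a_peak)
        a = Waveform(T=T, diastole_fraction=diastole, E_peak=e_peak, A_peak=a_peak,
                     condition=AF)
        t = np.linspace(0.0, h.a_window[0] - 1e-12, 50)
        np.testing.assert_allclose(a(t), h(t), atol=1e-14)
        grid = np.linspace(0.0, T, 2001)
        assert np.trapezoid(a(grid), grid) < np.trapezoid(h(grid), grid)


class TestReynolds:
    def test_value_at_mitral_peak(self):
        """rho*v*D/mu = 1060*0.32*0.025/0.0035 ~ 2423."""
        assert reynolds_number(0.32, 0.025) == pytest.approx(2423, rel=1e-3)

    def test_zero_velocity(self):
        assert reynolds_number(0.0, 0.025) == 0.0

    def test_scaling(self):
        props = FluidProperties()
        base = reynolds_number(0.2, 0.02, props)
        assert reynolds_number(0.4, 0.02, props) == pytest.approx(2 * base)
        assert reynolds_number(0.2, 0.04, props) == pytest.approx(2 * base)
        thick = FluidProperties(rho=props.rho, mu=2 * props.mu)
        assert reynolds_number(0.2, 0.02, thick) == pytest.approx(base / 2)

    def test_all_default_anatomies_laminar(self):
        """Peak mitral Reynolds number stays below 3000 for every default."""
        for spec in DEFAULT_SPECS.values():
            re = reynolds_number(0.32, spec.mitral_diameter)
            assert re < 3000

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            reynolds_number(0.3, 0.0)


class TestAssembleBCs:
    def test_partition_and_counts(self, channel_mesh):
        bcs = assemble_bcs(channel_mesh, HEALTHY, Waveform.healthy())
        n = (
            len(bcs.wall_edges)
            + len(bcs.mitral_edges)
            + sum(len(v) for v in bcs.pv_edges.values())
        )
        assert n == len(channel_mesh.boundary_edges)
        assert set(bcs.pv_edges) == {"pv_inlet_left", "pv_inlet_right"}

    def test_condition_changes_waveform_not_facets(self, channel_mesh):
        h = assemble_bcs(channel_mesh, HEALTHY, Waveform.healthy())
        a = assemble_bcs(channel_mesh, AF, Waveform.af())
        np.testing.assert_array_equal(h.wall_edges, a.wall_edges)
        np.testing.assert_array_equal(h.mitral_edges, a.mitral_edges)
        assert h.waveform.A_peak > 0 and a.waveform.A_peak == 0

    def test_unknown_label_raises(self, channel_mesh):
        import copy

        bad = copy.copy(channel_mesh)
        bad.boundary_labels = channel_mesh.boundary_labels.copy()
        bad.boundary_labels[0] = "lamina_terminalis"
        with pytest.raises(TaggingError):
            assemble_bcs(bad, HEALTHY, Waveform.healthy())
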