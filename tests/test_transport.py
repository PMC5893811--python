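"""Contrast transport: characteristics oracle, conservation, boundedness."""

import numpy as np
import pytest

from laa_stasis.boundary import Waveform, assemble_bcs
from laa_stasis.meshing import segments_from_polygon, triangulate_domain
from laa_stasis.operators import edge_fluxes
from laa_stasis.solver import FlowState, get_workspace
from laa_stasis import transport


def _state_with_velocity(ws, u, v, c):
    """Divergence-corrected fluxes for an imposed nodal velocity."""
    f_int, f_bnd = edge_fluxes(ws.fv, u, v)
    f_bnd[ws.fv_bnd_is_wall] = 0.0
    f_int, f_bnd, _ = transport.correct_fluxes(ws, f_int, f_bnd)
    return FlowState(0.0, u, v, np.zeros_like(u), c, f_int, f_bnd)


@pytest.fixture(scope="module")
def cavity_ws():
    sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], float)
    mesh = triangulate_domain(segments_from_polygon(sq), 0.05)
    bcs = assemble_bcs(mesh, "healthy", Waveform(E_peak=0.0, A_peak=0.0))
    return get_workspace(mesh, bcs)


class TestZeroVelocity:
    def test_contrast_unchanged(self, cavity_ws):
        ws = cavity_ws
        c0 = np.random.default_rng(0).uniform(0, 1, ws.mesh.n_cells)
        state = _state_with_velocity(ws, np.zeros(ws.mesh.n_vertices),
                                     np.zeros(ws.mesh.n_vertices), c0.copy())
        out = transport.advance_contrast(state, 0.1, ws)
        np.testing.assert_allclose(out.c, c0, atol=1e-14)


class TestUniformTranslation:
    def test_blob_centroid_moves_with_flow(self):
        """Method-of-characteristics oracle: centroid displacement = v*t."""
        segs = [
            ("wall_b", np.array([[0, 0], [4, 0]], float)),
            ("pv_inlet_r", np.array([[4, 0], [4, 1]], float)),
            ("wall_t", np.array([[4, 1], [0, 1]], float)),
            ("pv_inlet_l", np.array([[0, 1], [0, 0]], float)),
        ]
        mesh = triangulate_domain(segs, 0.05)
        bcs = assemble_bcs(mesh, "healthy", Waveform(E_peak=0.0, A_peak=0.0))
        ws = get_workspace(mesh, bcs)
        U = 1.0
        u = np.full(mesh.n_vertices, U)
        v = np.zeros(mesh.n_vertices)
        cent = mesh.cell_centroids
        c0 = ((np.abs(cent[:, 0] - 1.0) < 0.3) & (np.abs(cent[:, 1] - 0.5) < 0.25)).astype(float)
        state = _state_with_velocity(ws, u, v, c0.copy())
        vols = ws.cell_volumes
        mass0 = (vols * c0).sum()
        x0 = (vols * c0 * cent[:, 0]).sum() / mass0
        t_total, dt = 1.5, 0.01
        for _ in range(int(t_total / dt)):
            state = transport.advance_contrast(state, dt, ws)
        mass1 = (vols * state.c).sum()
        x1 = (vols * state.c * cent[:, 0]).sum() / mass1
        assert abs((x1 - x0) - U * t_total) < mesh.h  # within one cell size
        assert abs(mass1 - mass0) / mass0 < 0.01  # blob still fully inside

    def test_bounds_preserved(self, cavity_ws):
        ws = cavity_ws
        cent = ws.mesh.cell_centroids
        # rigid rotation around the cavity centre
        om = 2.0
        u = -om * (ws.mesh.vertices[:, 1] - 0.5)
        v = om * (ws.mesh.vertices[:, 0] - 0.5)
        c0 = (np.linalg.norm(cent - [0.3, 0.5], axis=1) < 0.15).astype(float)
        state = _state_with_velocity(ws, u, v, c0.copy())
        for _ in range(100):
            state = transport.advance_contrast(state, 0.02, ws)
        assert state.c.min() >= 0.0 and state.c.max() <= 1.0


class TestClosedCavityConservation:
    def test_total_contrast_conserved(self, cavity_ws):
        """Flux-form upwinding on divergence-free fluxes conserves exactly."""
        ws = cavity_ws
        om = 3.0
        u = -om * (ws.mesh.vertices[:, 1] - 0.5)
        v = om * (ws.mesh.vertices[:, 0] - 0.5)
        cent = ws.mesh.cell_centroids
        c0 = np.exp(-((cent[:, 0] - 0.4) ** 2 + (cent[:, 1] - 0.5) ** 2) / 0.02)
        state = _state_with_velocity(ws, u, v, c0.copy())
        vols = ws.cell_volumes
        mass0 = (vols * state.c).sum()
        n_steps = 100  # one full revolution: t = 2 pi / om
        dt = 2 * np.pi / om / n_steps
        for _ in range(n_steps):
            state = transport.advance_contrast(state, dt, ws)
        mass1 = (vols * state.c).sum()
        assert abs(mass1 - mass0) / mass0 < 1e-12


class TestSchemeGuards:
    def test_out_of_bounds_concentration_detected(self, cavity_ws):
        from laa_stasis.errors import SchemeError

        ws = cavity_ws
        c_bad = np.full(ws.mesh.n_cells, 1.5)
        state = _state_with_velocity(
            ws, np.zeros(ws.mesh.n_vertices), np.zeros(ws.mesh.n_vertices), c_bad
        )
        with pytest.raises(SchemeError):
            transport.advance_contrast(state, 0.1, ws)
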