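"""Transient incompressible laminar flow with virtual-contrast washout.

The momentum equation is advanced with a first-order fractional-step
(Chorin projection) scheme on vertex-based P1 elements:

1. semi-Lagrangian advection (RK2 departure points, P1 interpolation,
   MacCormack error compensation by default),
2. implicit viscous update (backward-Euler Helmholtz solve with strong
   wall/mitral Dirichlet rows) plus an optional body force,
3. pressure Poisson solve with Dirichlet total pressure 0 on the
   pulmonary-vein inlets (which also fixes the gauge),
4. velocity correction ``u -= dt/rho * grad p`` and re-imposition of the
   strong velocity boundary values.

Semi-Lagrangian advection and implicit diffusion leave no stability
time-step restriction; the Courant guard is an accuracy watchdog only.

After each projection, edge volume fluxes for the cell-centred contrast
scalar are rebuilt from the nodal velocity and passed through a small
TPFA flux-correction solve that zeroes every cell divergence exactly
(imbalance leaves through the open PV boundaries).  The corrected,
discretely divergence-free fluxes give the upwind scalar update a strict
maximum principle and exact conservation in closed domains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .boundary import BCSet, FluidProperties
from .errors import ConfigError, SolverError, StabilityError
from .meshing import Mesh
from .operators import (
    FVEdges,
    MeshInterpolator,
    P1Operators,
    assemble_p1,
    build_fv_edges,
    edge_fluxes,
)
from . import transport


@dataclass(frozen=True)
class SolverConfig:
    """Time-integration parameters.

    dt : time step in seconds (default 0.5 ms); must divide the period.
    n_cycles : number of cardiac cycles (default 4).
    T : cycle period in seconds.
    div_tol : admissible relative post-projection divergence (diagnostic
        computed with a direct pressure solve; violations raise).
    cfl_limit : accuracy guard on the semi-Lagrangian Courant number.
    """

    dt: float = 5e-4
    n_cycles: int = 4
    T: float = 0.8
    advection_scheme: str = "maccormack"
    open_boundary_stabilization: bool = True
    div_tol: float = 1e-8
    cfl_limit: float = 10.0
    on_cfl: str = "warn"  # or "raise"
    n_phases: int = 16  # velocity snapshots per cycle (periodicity, averaging)
    metrics_stride: int = 10
    force: Callable | None = None  # body force (x, y, t) -> (fx, fy)

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be >= 1")
        steps = self.T / self.dt
        if abs(steps - round(steps)) > 1e-8 * steps:
            raise ConfigError("dt must divide the cycle period T")

    @property
    def steps_per_cycle(self) -> int:
        return round(self.T / self.dt)

    @property
    def n_steps(self) -> int:
        return self.n_cycles * self.steps_per_cycle


@dataclass
class FlowState:
    """Velocity/pressure/contrast at one time instant.

    ``u, v, p`` live on vertices; the contrast concentration ``c`` is
    cell-centred and stays in [0, 1].  ``int_flux``/``bnd_flux`` cache the
    divergence-free edge fluxes of the most recent projection.
    """

    t: float
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    c: np.ndarray
    int_flux: np.ndarray | None = None
    bnd_flux: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def copy(self) -> "FlowState":
        return FlowState(
            self.t,
            self.u.copy(),
            self.v.copy(),
            self.p.copy(),
            self.c.copy(),
            None if self.int_flux is None else self.int_flux.copy(),
            None if self.bnd_flux is None else self.bnd_flux.copy(),
            dict(self.diagnostics),
        )


class SolverWorkspace:
    """Mesh- and BC-dependent assembled operators, built once per run."""

    def __init__(self, mesh: Mesh, bcs: BCSet):
        self.mesh = mesh
        self.bcs = bcs
        self.ops: P1Operators = assemble_p1(mesh)
        self.fv: FVEdges = build_fv_edges(mesh)
        self.interp = MeshInterpolator(mesh)

        be = mesh.boundary_edges
        mitral_nodes = np.unique(be[bcs.mitral_edges].ravel()) if len(bcs.mitral_edges) else np.empty(0, int)
        wall_nodes = np.unique(be[bcs.wall_edges].ravel()) if len(bcs.wall_edges) else np.empty(0, int)
        pv = bcs.all_pv_edges
        pv_nodes = np.unique(be[pv].ravel()) if len(pv) else np.empty(0, int)
        # junction nodes are no-slip: wall wins over mitral, pv keeps p-Dirichlet
        self.wall_nodes = wall_nodes
        self.mitral_nodes = np.setdiff1d(mitral_nodes, wall_nodes)
        self.pv_nodes = pv_nodes

        def _node_normals(edge_ids, nodes):
            acc = np.zeros((mesh.n_vertices, 2))
            for ei in edge_ids:
                a, b = be[ei]
                w = mesh.boundary_edge_lengths[ei]
                acc[a] += w * mesh.boundary_edge_normals[ei]
                acc[b] += w * mesh.boundary_edge_normals[ei]
            norms = np.linalg.norm(acc[nodes], axis=1)
            return acc[nodes] / np.maximum(norms, 1e-30)[:, None]

        self.mitral_normals = _node_normals(bcs.mitral_edges, self.mitral_nodes)
        # PV open boundaries carry p = 0 with a zero tangential-velocity
        # constraint; only the normal component is left free.  This also
        # stabilizes the otherwise uncontrolled tangential dof at open
        # outflow facets.
        self.pv_free_nodes = np.setdiff1d(pv_nodes, np.union1d(wall_nodes, mitral_nodes))
        self.pv_normals = _node_normals(pv, self.pv_free_nodes)

        # boundary-flux weights of the mitral plug for the pressure rhs:
        # integral of phi_i * v(t) over the mitral facets
        wm = np.zeros(mesh.n_vertices)
        for ei in bcs.mitral_edges:
            a, b = be[ei]
            wm[a] += 0.5 * mesh.boundary_edge_lengths[ei]
            wm[b] += 0.5 * mesh.boundary_edge_lengths[ei]
        self.mitral_weight = wm

        # Exact discrete projection operator G^T M_L^{-1} G: with a direct
        # solve the post-projection weak divergence vanishes to rounding at
        # every free node (a stiffness-matrix Laplacian would only give the
        # O(h^2) "approximate projection").  Dirichlet p = 0 on PV nodes
        # fixes the gauge; closed test domains pin one node instead.
        inv_ml = sp.diags(1.0 / self.ops.lumped_mass)
        A = (
            self.ops.grad_x.T @ inv_ml @ self.ops.grad_x
            + self.ops.grad_y.T @ inv_ml @ self.ops.grad_y
        ).tolil()
        if len(pv_nodes):
            dirichlet = pv_nodes
            self.pressure_pin = None
        else:
            dirichlet = np.array([0])  # gauge pin for closed/test domains
            self.pressure_pin = 0
        for i in dirichlet:
            A.rows[i] = [int(i)]
            A.data[i] = [1.0]
        self.pressure_dirichlet = dirichlet
        self.pressure_lu = splu(A.tocsc())

        # FV flux-correction operator (open boundaries = PV facets)
        labels = mesh.boundary_labels
        facet_is_pv = np.isin(np.arange(len(be)), pv)
        fv = self.fv
        m = mesh.n_cells
        L, R = fv.int_cells[:, 0], fv.int_cells[:, 1]
        t = fv.int_trans
        rows = np.concatenate([L, R, L, R])
        cols = np.concatenate([L, R, R, L])
        vals = np.concatenate([t, t, -t, -t])
        self.fv_bnd_is_pv = facet_is_pv[fv.bnd_facet]
        if self.fv_bnd_is_pv.any():
            cb = fv.bnd_cells[self.fv_bnd_is_pv]
            tb = fv.bnd_trans[self.fv_bnd_is_pv]
            rows = np.concatenate([rows, cb])
            cols = np.concatenate([cols, cb])
            vals = np.concatenate([vals, tb])
            self.fv_pin = None
        else:
            self.fv_pin = 0
        A = sp.coo_matrix((vals, (rows, cols)), shape=(m, m)).tolil()
        if self.fv_pin is not None:
            A.rows[0] = [0]
            A.data[0] = [1.0]
        self.fv_lu = splu(A.tocsc())

        # facet types for the scalar boundary treatment
        wall_set = np.isin(fv.bnd_facet, bcs.wall_edges)
        mitral_set = np.isin(fv.bnd_facet, bcs.mitral_edges)
        self.fv_bnd_is_wall = wall_set
        self.fv_bnd_is_mitral = mitral_set
        self.cell_volumes = mesh.cell_areas
        self.volume = float(self.cell_volumes.sum())
        self._visc_cache: dict = {}

    def viscous_lu(self, dt: float, nu: float):
        """Factorized backward-Euler Helmholtz operator M/dt + nu*K.

        Wall and mitral rows are strong Dirichlet, so the no-slip and plug
        values enter the viscous solve directly and no explicit diffusion
        time-step restriction applies.
        """
        key = (dt, nu)
        lu = self._visc_cache.get(key)
        if lu is None:
            H = (sp.diags(self.ops.lumped_mass / dt) + nu * self.ops.stiffness).tolil()
            for i in np.concatenate([self.wall_nodes, self.mitral_nodes]):
                H.rows[i] = [int(i)]
                H.data[i] = [1.0]
            lu = splu(H.tocsc())
            self._visc_cache[key] = lu
        return lu

    # ------------------------------------------------------------------
    def apply_velocity_bcs(self, u: np.ndarray, v: np.ndarray, t: float) -> None:
        if len(self.pv_free_nodes):
            nx, ny = self.pv_normals[:, 0], self.pv_normals[:, 1]
            un = u[self.pv_free_nodes] * nx + v[self.pv_free_nodes] * ny
            u[self.pv_free_nodes] = un * nx
            v[self.pv_free_nodes] = un * ny
        u[self.wall_nodes] = 0.0
        v[self.wall_nodes] = 0.0
        vm = self.bcs.waveform(t)
        u[self.mitral_nodes] = vm * self.mitral_normals[:, 0]
        v[self.mitral_nodes] = vm * self.mitral_normals[:, 1]

    def weak_divergence(self, u: np.ndarray, v: np.ndarray, t: float) -> np.ndarray:
        """Residual of weak continuity with the prescribed mitral flux."""
        r = self.ops.grad_x.T @ u + self.ops.grad_y.T @ v
        r -= self.bcs.waveform(t) * self.mitral_weight
        return r


def _advect(ws: SolverWorkspace, u: np.ndarray, v: np.ndarray, dt: float,
            scheme: str = "maccormack"):
    """Advect the velocity field along its own characteristics.

    ``semi_lagrangian``: RK2 departure points with P1 interpolation
    (first order in space).  ``maccormack`` (default): back-and-forth
    error compensation on top of it — the solution is advected forward,
    then backward along the same frozen velocity, and half the round-trip
    defect is removed, which cancels the leading truncation term
    (second order).  The compensated value is clamped to the min/max of
    the forward interpolation stencil, preserving monotone stability.
    """
    x, y = ws.mesh.vertices[:, 0], ws.mesh.vertices[:, 1]
    xm = x - 0.5 * dt * u
    ym = y - 0.5 * dt * v
    um, vm = ws.interp.sample([u, v], xm, ym)
    xd = x - dt * um
    yd = y - dt * vm
    (ua, va), bounds = ws.interp.sample([u, v], xd, yd, return_bounds=True)
    if scheme == "semi_lagrangian":
        return ua, va
    if scheme != "maccormack":
        raise ConfigError(f"unknown advection scheme {scheme!r}")
    # backward pass along the same characteristics
    xb = x + dt * um
    yb = y + dt * vm
    ub, vb = ws.interp.sample([ua, va], xb, yb)
    ua = ua + 0.5 * (u - ub)
    va = va + 0.5 * (v - vb)
    np.clip(ua, bounds[0][0], bounds[0][1], out=ua)
    np.clip(va, bounds[1][0], bounds[1][1], out=va)
    return ua, va


def initialize(mesh: Mesh, config: SolverConfig | None = None) -> FlowState:
    """Rest state with uniform unit contrast everywhere (washout start)."""
    n = mesh.n_vertices
    return FlowState(
        t=0.0,
        u=np.zeros(n),
        v=np.zeros(n),
        p=np.zeros(n),
        c=np.ones(mesh.n_cells),
    )


def momentum_step(
    state: FlowState,
    bcs: BCSet,
    props: FluidProperties,
    config: SolverConfig,
    workspace: SolverWorkspace | None = None,
) -> FlowState:
    """Advance velocity and pressure by one fractional step."""
    ws = workspace if workspace is not None else get_workspace(None, bcs)
    mesh, ops = ws.mesh, ws.ops
    dt = config.dt
    t_new = state.t + dt
    u, v = state.u, state.v

    # CFL accuracy guard
    umax = float(np.hypot(u, v).max())
    cfl = umax * dt / mesh.h
    if cfl > config.cfl_limit:
        msg = f"semi-Lagrangian Courant number {cfl:.2f} exceeds limit {config.cfl_limit}"
        if config.on_cfl == "raise":
            raise StabilityError(msg)
        import warnings

        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    # --- advection (semi-Lagrangian, optionally error-compensated)
    x, y = mesh.vertices[:, 0], mesh.vertices[:, 1]
    if umax > 0.0:
        ua, va = _advect(ws, u, v, dt, config.advection_scheme)
    else:
        ua, va = u.copy(), v.copy()

    # --- implicit viscosity (+ optional body force): (M/dt + nu K) u* = M/dt (u_a + dt f)
    nu = props.nu
    ml = ops.lumped_mass
    if config.force is not None:
        fx, fy = config.force(x, y, t_new)
        ua += dt * np.asarray(fx, dtype=float)
        va += dt * np.asarray(fy, dtype=float)
    rhs_u = ml / dt * ua
    rhs_v = ml / dt * va
    vm_t = bcs.waveform(t_new)
    rhs_u[ws.wall_nodes] = 0.0
    rhs_v[ws.wall_nodes] = 0.0
    rhs_u[ws.mitral_nodes] = vm_t * ws.mitral_normals[:, 0]
    rhs_v[ws.mitral_nodes] = vm_t * ws.mitral_normals[:, 1]
    lu = ws.viscous_lu(dt, nu)
    ua = lu.solve(rhs_u)
    va = lu.solve(rhs_v)

    ws.apply_velocity_bcs(ua, va, t_new)

    # --- pressure Poisson and projection.  PV openings hold total pressure
    # 0 rather than static pressure 0: where fluid enters, the static
    # pressure is lowered by the dynamic head (Bernoulli), so the open
    # boundary cannot feed a growing inflow jet with unbounded kinetic
    # energy — the standard directional do-nothing stabilization.
    rhs = (props.rho / dt) * ws.weak_divergence(ua, va, t_new)
    rhs[ws.pressure_dirichlet] = 0.0
    if config.open_boundary_stabilization and len(ws.pv_free_nodes):
        un_pv = (
            ua[ws.pv_free_nodes] * ws.pv_normals[:, 0]
            + va[ws.pv_free_nodes] * ws.pv_normals[:, 1]
        )
        rhs[ws.pv_free_nodes] = -0.5 * props.rho * np.minimum(un_pv, 0.0) ** 2
    p = ws.pressure_lu.solve(rhs)
    if not np.isfinite(p).all():
        raise SolverError("pressure solve produced non-finite values")
    un = ua - (dt / props.rho) * (ops.grad_x @ p) / ml
    vn = va - (dt / props.rho) * (ops.grad_y @ p) / ml

    # post-projection divergence diagnostic (free nodes only, before the
    # strong re-imposition of the velocity boundary values)
    r = ws.weak_divergence(un, vn, t_new)
    free = np.ones(mesh.n_vertices, bool)
    free[ws.pressure_dirichlet] = False
    div_l2 = math.sqrt(float((r[free] ** 2 / ml[free]).sum()))
    u_rms = math.sqrt(float((ml * (un**2 + vn**2)).sum()) / ws.volume)
    div_rel = div_l2 * mesh.h / max(u_rms * math.sqrt(ws.volume), 1e-14)
    if div_rel > config.div_tol and u_rms > 1e-12:
        raise SolverError(
            f"post-projection divergence {div_rel:.3e} exceeds tolerance {config.div_tol:.1e}"
        )

    ws.apply_velocity_bcs(un, vn, t_new)

    # --- divergence-free FV fluxes for the scalar
    f_int, f_bnd = edge_fluxes(ws.fv, un, vn)
    f_bnd[ws.fv_bnd_is_wall] = 0.0
    vm_new = bcs.waveform(t_new)
    f_bnd[ws.fv_bnd_is_mitral] = vm_new * ws.fv.bnd_length[ws.fv_bnd_is_mitral]
    f_int, f_bnd, fv_div = transport.correct_fluxes(ws, f_int, f_bnd)

    new = FlowState(t=t_new, u=un, v=vn, p=p, c=state.c, int_flux=f_int, bnd_flux=f_bnd)
    new.diagnostics = {
        "div_rel": div_rel,
        "div_l2": div_l2,
        "cfl": cfl,
        "fv_div_max": fv_div,
        "kinetic_energy": 0.5 * props.rho * float((ml * (un**2 + vn**2)).sum()),
    }
    return new


def contrast_step(
    state: FlowState,
    bcs: BCSet,
    config: SolverConfig,
    workspace: SolverWorkspace,
) -> FlowState:
    """Advance the contrast concentration with the cached fluxes."""
    return transport.advance_contrast(state, config.dt, workspace)


def get_workspace(mesh: Mesh | None, bcs: BCSet) -> SolverWorkspace:
    """Workspace cached on the BC set (operators depend on mesh + BCs)."""
    ws = getattr(bcs, "_workspace", None)
    if ws is None or (mesh is not None and ws.mesh is not mesh):
        if mesh is None:
            raise ValueError("mesh required to build a solver workspace")
        ws = SolverWorkspace(mesh, bcs)
        bcs._workspace = ws
    return ws


@dataclass
class RunResult:
    """Time series emitted by :func:`run`."""

    config: SolverConfig
    final_state: FlowState
    apeak_states: list[FlowState]  # one per cycle, at the A-wave peak phase
    phase_snapshots: dict  # (cycle, phase index) -> (t, u, v)
    metrics: "object"  # pandas.DataFrame: t, KE, div, contrast, cfl

    @property
    def last_apeak(self) -> FlowState:
        return self.apeak_states[-1]


def run(
    mesh: Mesh,
    bcs: BCSet,
    props: FluidProperties,
    config: SolverConfig,
    recorders: list[Callable] | None = None,
) -> RunResult:
    """Run ``n_cycles`` cardiac cycles from rest with uniform contrast.

    ``recorders`` are optional callables ``f(step_index, state)`` invoked
    after every full step.  The returned :class:`RunResult` always carries
    the per-cycle A-wave-peak states (the comparison instant for the
    stasis metrics), per-phase velocity snapshots for periodicity checks,
    and a step-metrics table.
    """
    import pandas as pd

    ws = get_workspace(mesh, bcs)
    state = initialize(mesh, config)

    spc = config.steps_per_cycle
    phase_steps = {
        round(k * spc / config.n_phases) % spc: k for k in range(config.n_phases)
    }
    apeak_step = round(bcs.waveform.a_peak_time / config.dt) % spc

    apeak_states: list[FlowState] = []
    phase_snapshots: dict = {}
    rows = []
    vols = ws.cell_volumes
    for istep in range(1, config.n_steps + 1):
        state = momentum_step(state, bcs, props, config, ws)
        state = contrast_step(state, bcs, config, ws)
        cycle_idx = (istep - 1) // spc
        step_in_cycle = istep % spc
        if step_in_cycle in phase_steps:
            phase_snapshots[(cycle_idx, phase_steps[step_in_cycle])] = (
                state.t,
                state.u.copy(),
                state.v.copy(),
            )
        if step_in_cycle == apeak_step:
            apeak_states.append(state.copy())
        if istep % config.metrics_stride == 0 or istep == config.n_steps:
            rows.append(
                {
                    "t": state.t,
                    "kinetic_energy": state.diagnostics.get("kinetic_energy", 0.0),
                    "div_rel": state.diagnostics.get("div_rel", 0.0),
                    "total_contrast": float((vols * state.c).sum()),
                    "cfl": state.diagnostics.get("cfl", 0.0),
                }
            )
        if recorders:
            for rec in recorders:
                rec(istep, state)
        if step_in_cycle == 0:  # end of a cycle: conservation diagnostics
            import logging

            logging.getLogger("laa_stasis").info(
                "cycle %d/%d: t=%.3f s, KE=%.4g J/m, div=%.2e, contrast=%.4g",
                cycle_idx + 1, config.n_cycles, state.t,
                state.diagnostics.get("kinetic_energy", 0.0),
                state.diagnostics.get("div_rel", 0.0),
                float((vols * state.c).sum()),
            )

    return RunResult(
        config=config,
        final_state=state,
        apeak_states=apeak_states,
        phase_snapshots=phase_snapshots,
        metrics=pd.DataFrame(rows),
    )
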