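"""Stagnation metrics: shear strain rate, centerline profiles, normalized
volume integrals, residual contrast and dye localization.

The shear strain rate (SSR) is the second invariant of the rate of
strain, ``sqrt(2 D:D)`` with ``D = (grad u + grad u^T)/2``: zero for
uniform flow and rigid rotation, and equal to the shear rate gamma for a
simple shear ``u = (gamma*y, 0)``.  Velocity gradients are cell-wise
linear (exact for affine fields), so those calibration cases hold to
rounding.

Regional integrals divide by the region measure — the appendage-
normalized quantities used to compare morphologies; residual contrast is
a percentage of the whole fluid domain (the washout headline number) or
of the appendage.  Dye localization is the contrast-weighted mean of the
normalized centerline arclength of the appendage cells: values near 1
mean the residue sits at the tip.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .centerline import Centerline
from .errors import FieldError, GeometryError, InterpolationError, RegionError
from .meshing import Mesh, REGION_LA, REGION_LAA, region_volumes
from .operators import MeshInterpolator, P1Operators, assemble_p1

DOMAIN = "domain"


def ssr_field(u: np.ndarray, v: np.ndarray, mesh: Mesh,
              ops: P1Operators | None = None) -> np.ndarray:
    """Cell-wise shear strain rate sqrt(2 D:D) of a nodal velocity (1/s)."""
    if ops is None:
        ops = assemble_p1(mesh)
    if np.any(ops.areas <= 0):
        raise GeometryError("mesh contains degenerate cells")
    uc = u[mesh.cells]
    vc = v[mesh.cells]
    ux = (ops.cell_bx * uc).sum(axis=1)
    uy = (ops.cell_by * uc).sum(axis=1)
    vx = (ops.cell_bx * vc).sum(axis=1)
    vy = (ops.cell_by * vc).sum(axis=1)
    # 2 D:D = 2(ux^2 + vy^2) + (uy + vx)^2
    return np.sqrt(2.0 * (ux**2 + vy**2) + (uy + vx) ** 2)


def centerline_profile(f: np.ndarray, centerline: Centerline, mesh: Mesh,
                       interp: MeshInterpolator | None = None) -> np.ndarray:
    """Sample a nodal or cell field at the centerline stations.

    Nodal fields are interpolated with P1 barycentric weights; cell
    fields take the containing cell's value.  A station outside the mesh
    raises :class:`InterpolationError`.
    """
    f = np.asarray(f, dtype=float)
    if interp is None:
        interp = MeshInterpolator(mesh)
    x, y = centerline.positions[:, 0], centerline.positions[:, 1]
    tri_idx, w = interp.locate(x, y)
    if (tri_idx < 0).any():
        raise InterpolationError("centerline station lies outside the mesh")
    if len(f) == mesh.n_vertices:
        return (f[mesh.cells[tri_idx]] * w).sum(axis=1)
    if len(f) == mesh.n_cells:
        return f[tri_idx]
    raise ValueError("field length matches neither vertices nor cells")


def _integral(f: np.ndarray, mesh: Mesh, cells: np.ndarray) -> float:
    areas = mesh.cell_areas[cells]
    if len(f) == mesh.n_vertices:
        return float((areas * f[mesh.cells[cells]].mean(axis=1)).sum())
    if len(f) == mesh.n_cells:
        return float((areas * f[cells]).sum())
    raise ValueError("field length matches neither vertices nor cells")


def _region_cells(mesh: Mesh, region: str) -> np.ndarray:
    if region == DOMAIN:
        return np.arange(mesh.n_cells)
    if region not in (REGION_LA, REGION_LAA):
        raise RegionError(f"unknown region {region!r}")
    cells = mesh.cells_in_region(region)
    if len(cells) == 0:
        raise RegionError(f"region {region!r} is empty")
    return cells


def normalized_volume_integral(f: np.ndarray, mesh: Mesh, region: str = REGION_LAA) -> float:
    """Region-mean of a field: (integral of f over region) / V_region."""
    cells = _region_cells(mesh, region)
    vol = float(mesh.cell_areas[cells].sum())
    return _integral(np.asarray(f, dtype=float), mesh, cells) / vol


def residual_contrast(c: np.ndarray, mesh: Mesh, normalization: str = DOMAIN,
                      tol: float = 1e-6) -> float:
    """Remaining contrast as % of the chosen reference volume.

    ``domain``: integral of c over the whole domain / V_domain — the
    washout headline number.  ``laa``: integral over the appendage /
    V_LAA — the per-appendage variant used for cross-shape comparison.
    """
    c = np.asarray(c, dtype=float)
    if c.min() < -tol or c.max() > 1.0 + tol:
        raise FieldError(f"contrast outside [0, 1]: [{c.min():.3g}, {c.max():.3g}]")
    if normalization == DOMAIN:
        cells = np.arange(mesh.n_cells)
    elif normalization.lower() == "laa":
        cells = _region_cells(mesh, REGION_LAA)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    vol = float(mesh.cell_areas[cells].sum())
    return 100.0 * _integral(c, mesh, cells) / vol


def dye_localization(c: np.ndarray, centerline: Centerline, mesh: Mesh) -> float:
    """Contrast-weighted mean normalized arclength of the appendage dye.

    Each LAA cell maps to its nearest centerline station; the result is
    the c-weighted mean of the station coordinate s in [0, 1].  Raises
    :class:`FieldError` when the appendage holds no dye.
    """
    from scipy.spatial import cKDTree

    c = np.asarray(c, dtype=float)
    if len(c) != mesh.n_cells:
        raise ValueError("dye localization requires a cell-centred contrast field")
    cells = _region_cells(mesh, REGION_LAA)
    w = mesh.cell_areas[cells] * c[cells]
    total = float(w.sum())
    if total <= 0.0:
        raise FieldError("no dye in the LAA: localization undefined")
    tree = cKDTree(centerline.positions)
    _, station = tree.query(mesh.cell_centroids[cells])
    return float((w * centerline.s[station]).sum() / total)


def periodicity_metric(series, cycle_a: int, cycle_b: int) -> float:
    """Relative L2 difference of velocity between two cycles.

    ``series`` is a :class:`~laa_stasis.solver.RunResult` or its
    ``phase_snapshots`` dict mapping (cycle, phase) -> (t, u, v).  The
    metric is ``sqrt(sum_ph |u_b - u_a|^2) / sqrt(sum_ph |u_a|^2)`` over
    all matched phases; 0 for identical cycles.
    """
    snaps = getattr(series, "phase_snapshots", series)
    phases_a = sorted(ph for (cy, ph) in snaps if cy == cycle_a)
    phases_b = sorted(ph for (cy, ph) in snaps if cy == cycle_b)
    if not phases_a or phases_a != phases_b:
        raise ValueError(
            f"cycles {cycle_a} and {cycle_b} have mismatched snapshot phases"
        )
    num = den = 0.0
    for ph in phases_a:
        _, ua, va = snaps[(cycle_a, ph)]
        _, ub, vb = snaps[(cycle_b, ph)]
        num += float(((ub - ua) ** 2 + (vb - va) ** 2).sum())
        den += float((ua**2 + va**2).sum())
    if den == 0.0:
        return 0.0
    return np.sqrt(num / den)


@dataclass
class StasisSummary:
    """Per-run stagnation metrics (one morphology under one condition)."""

    condition: str
    morphology_class: str
    mean_velocity_LAA: float  # m/s, |v| integral over LAA / V_LAA
    mean_ssr_LAA: float  # 1/s
    residual_contrast_domain: float  # % of domain volume
    residual_contrast_LAA: float  # % of LAA volume
    dye_localization: float  # normalized arclength in [0, 1]
    periodicity_metric: float
    centerline_s: list = field(default_factory=list)
    centerline_velocity: list = field(default_factory=list)
    centerline_ssr: list = field(default_factory=list)
    V_LA: float = 0.0
    V_LAA: float = 0.0
    n_averaging_phases: int = 0  # phases of the last cycle averaged over
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StasisSummary":
        with open(path) as fh:
            return cls(**json.load(fh))


def summarize(result, mesh: Mesh, centerline: Centerline, condition: str,
              morphology_class: str, provenance: dict | None = None) -> StasisSummary:
    """Aggregate one run into a :class:`StasisSummary`.

    Velocity/SSR integrals and centerline profiles are averaged over the
    recorded phases of the last cardiac cycle — the claims they support
    hold throughout the cycle, and a phase average is far less sensitive
    to the meandering of large atrial vortices than any single instant.
    Residual contrast and dye localization are end-of-run quantities;
    periodicity compares the last two cycles at matched phases.
    """
    from .errors import PipelineError

    last_cycle = result.config.n_cycles - 1
    phases = sorted(ph for (cy, ph) in result.phase_snapshots if cy == last_cycle)
    if not phases:
        raise PipelineError("run recorded no phase snapshots for the last cycle")
    ops = assemble_p1(mesh)
    interp = MeshInterpolator(mesh)
    vols = region_volumes(mesh)

    n = len(centerline)
    v_prof = np.zeros(n)
    s_prof = np.zeros(n)
    v_int = s_int = 0.0
    for ph in phases:
        _, u, v = result.phase_snapshots[(last_cycle, ph)]
        speed = np.hypot(u, v)
        ssr = ssr_field(u, v, mesh, ops)
        v_prof += centerline_profile(speed, centerline, mesh, interp)
        s_prof += centerline_profile(ssr, centerline, mesh, interp)
        v_int += normalized_volume_integral(speed, mesh, REGION_LAA)
        s_int += normalized_volume_integral(ssr, mesh, REGION_LAA)
    nph = len(phases)
    v_prof /= nph
    s_prof /= nph

    final = result.final_state
    per = (
        periodicity_metric(result, last_cycle - 1, last_cycle)
        if result.config.n_cycles >= 2
        else 0.0
    )

    laa_cells = mesh.cells_in_region(REGION_LAA)
    total_laa_dye = float((mesh.cell_areas[laa_cells] * final.c[laa_cells]).sum())
    loc = (
        dye_localization(final.c, centerline, mesh) if total_laa_dye > 0 else float("nan")
    )

    return StasisSummary(
        condition=condition,
        morphology_class=morphology_class,
        mean_velocity_LAA=v_int / nph,
        mean_ssr_LAA=s_int / nph,
        residual_contrast_domain=residual_contrast(final.c, mesh, DOMAIN),
        residual_contrast_LAA=residual_contrast(final.c, mesh, "laa"),
        dye_localization=loc,
        periodicity_metric=per,
        centerline_s=centerline.s.tolist(),
        centerline_velocity=v_prof.tolist(),
        centerline_ssr=s_prof.tolist(),
        V_LA=vols["V_LA"],
        V_LAA=vols["V_LAA"],
        n_averaging_phases=nph,
        provenance=provenance or {},
    )
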