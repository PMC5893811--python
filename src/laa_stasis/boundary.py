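"""Mitral-outlet waveforms, fluid properties and boundary-condition sets.

The transmitral velocity is modelled on a 0.8 s cardiac cycle split into
37.5% atrial diastole (mitral valve closed, zero outflow) and 62.5% atrial
emptying.  Emptying is biphasic: an early E-wave followed by the atrial
contraction A-wave, each a smooth sin^2 pulse.  Healthy defaults are
calibrated so the cycle maximum is 0.32 m/s (at the E peak) with the A
peak at t = 0.75 s.  Atrial fibrillation is modelled by removing the
A-wave (A peak set to zero); the E branch is untouched, so the two
conditions coincide outside the A-wave support.

Pulmonary-vein inlets are open boundaries at constant reference pressure
P_pv = 0; walls are rigid and no-slip; the mitral orifice carries a
spatially uniform (plug) outward normal velocity equal to the waveform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import TaggingError
from .meshing import Mesh

HEALTHY = "healthy"
AF = "af"

#: fraction of the atrial-emptying window occupied by the E-wave;
#: the remainder carries the A-wave (peaking at 0.75 s for T = 0.8 s)
_E_WINDOW_FRACTION = 0.8


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood analogue: rho = 1060 kg/m^3, mu = 0.0035 Pa s."""

    rho: float = 1060.0
    mu: float = 0.0035

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("density and viscosity must be positive")

    @property
    def nu(self) -> float:
        """Kinematic viscosity (m^2/s)."""
        return self.mu / self.rho


@dataclass(frozen=True)
class Waveform:
    """Periodic transmitral plug-velocity waveform.

    Parameters
    ----------
    T : cycle period in seconds.
    diastole_fraction : fraction of the cycle with the mitral valve closed
        (atrial diastole); emptying occupies the rest.
    E_peak, A_peak : peak velocities (m/s) of the two emptying waves.
    condition : "healthy" or "af"; "af" forces the A-wave to zero.
    """

    T: float = 0.8
    diastole_fraction: float = 0.375
    E_peak: float = 0.32
    A_peak: float = 0.24
    condition: str = HEALTHY

    def __post_init__(self):
        if self.T <= 0 or not (0.0 < self.diastole_fraction < 1.0):
            raise ValueError("invalid waveform timing parameters")
        if self.E_peak < 0 or self.A_peak < 0:
            raise ValueError("peak velocities must be nonnegative")
        if self.condition not in (HEALTHY, AF):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition == AF and self.A_peak != 0.0:
            object.__setattr__(self, "A_peak", 0.0)

    # --- phase geometry -------------------------------------------------
    @property
    def t_open(self) -> float:
        """Time within the cycle at which the mitral valve opens."""
        return self.diastole_fraction * self.T

    @property
    def e_window(self) -> tuple[float, float]:
        w = (1.0 - self.diastole_fraction) * self.T
        return (self.t_open, self.t_open + _E_WINDOW_FRACTION * w)

    @property
    def a_window(self) -> tuple[float, float]:
        return (self.e_window[1], self.T)

    @property
    def a_peak_time(self) -> float:
        """Phase of the A-wave maximum (0.75 s with default timing)."""
        a0, a1 = self.a_window
        return 0.5 * (a0 + a1)

    @property
    def e_peak_time(self) -> float:
        e0, e1 = self.e_window
        return 0.5 * (e0 + e1)

    @classmethod
    def healthy(cls, **kw) -> "Waveform":
        return cls(condition=HEALTHY, **kw)

    @classmethod
    def af(cls, **kw) -> "Waveform":
        """AF variant: identical timing, A-wave removed."""
        kw.setdefault("A_peak", 0.0)
        return cls(condition=AF, **kw)

    def __call__(self, t):
        return mitral_velocity(t, self)


def _pulse(t, window, peak):
    """sin^2 pulse supported on window, C1 at both ends, max = peak."""
    t0, t1 = window
    w = t1 - t0
    inside = (t >= t0) & (t < t1)
    out = np.zeros_like(t, dtype=float)
    out[inside] = peak * np.sin(np.pi * (t[inside] - t0) / w) ** 2
    return out


def mitral_velocity(t, wf: Waveform):
    """Plug velocity (m/s) across the mitral orifice at time(s) ``t``.

    Times wrap modulo the cycle period, so multi-cycle solver times can be
    passed directly.  Nonnegative and periodic by construction.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    tc = np.mod(t, wf.T)
    v = _pulse(np.atleast_1d(tc), wf.e_window, wf.E_peak)
    v += _pulse(np.atleast_1d(tc), wf.a_window, wf.A_peak)
    return float(v[0]) if scalar else v


def reynolds_number(v_peak: float, D: float, props: FluidProperties = FluidProperties()) -> float:
    """Peak-velocity Reynolds number rho*v*D/mu on the mitral orifice."""
    if D <= 0:
        raise ValueError("diameter must be positive")
    if v_peak < 0:
        raise ValueError("peak velocity must be nonnegative")
    return props.rho * v_peak * D / props.mu


@dataclass
class BCSet:
    """Partition of the boundary facets into wall / PV-inlet / mitral sets.

    ``pv_edges`` maps each pulmonary-vein label to its facet indices; all
    PV facets are open boundaries at reference pressure 0 (zero traction).
    """

    wall_edges: np.ndarray
    pv_edges: dict[str, np.ndarray]
    mitral_edges: np.ndarray
    waveform: Waveform
    condition: str = HEALTHY

    @property
    def all_pv_edges(self) -> np.ndarray:
        if not self.pv_edges:
            return np.empty(0, dtype=int)
        return np.concatenate(list(self.pv_edges.values()))


def assemble_bcs(mesh: Mesh, condition: str = HEALTHY, waveform: Waveform | None = None) -> BCSet:
    """Build the boundary-condition set for one cardiac condition.

    Every boundary facet must carry a label of the form ``wall*``,
    ``pv_inlet*`` or ``mitral_outlet*``; anything else raises
    :class:`TaggingError`.  The facet partition is independent of the
    condition — healthy and AF runs on one mesh share identical sets and
    differ only in the waveform.
    """
    if waveform is None:
        waveform = Waveform.healthy() if condition == HEALTHY else Waveform.af()
    elif waveform.condition != condition:
        raise ValueError("waveform condition does not match requested condition")

    wall, mitral = [], []
    pv: dict[str, list[int]] = {}
    for i, label in enumerate(mesh.boundary_labels):
        if label.startswith("wall"):
            wall.append(i)
        elif label.startswith("pv_inlet"):
            pv.setdefault(label, []).append(i)
        elif label.startswith("mitral_outlet"):
            mitral.append(i)
        else:
            raise TaggingError(f"boundary facet {i} has unknown label {label!r}")
    return BCSet(
        wall_edges=np.array(wall, dtype=int),
        pv_edges={k: np.array(v, dtype=int) for k, v in sorted(pv.items())},
        mitral_edges=np.array(mitral, dtype=int),
        waveform=waveform,
        condition=condition,
    )
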