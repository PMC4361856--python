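"""Cone+cylinder funnel restraint.

The funnel confines an unbound peptide near the membrane without biasing the
bound state: a cone whose wide end embraces the outer membrane surface
narrows with half-angle ``alpha`` until, at height ``Zcc`` above the membrane
centre, it hands over to a cylinder of radius ``Rcyl`` directed toward the
solvent.  A one-sided harmonic wall pushes back anything that crosses the
boundary; frames in which the wall is felt are excluded from all statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, SelectionError
from .model_io import AtomSelection, Trajectory

__all__ = ["FunnelGeometry", "boundary_radius", "bias_energy", "bias_force",
           "frame_bias_flags"]


@dataclass(frozen=True)
class FunnelGeometry:
    """Funnel restraint geometry and wall stiffness.

    Defaults follow the funnelled-sampling setup used for the glycopeptide
    study: half-angle 0.8 rad, cylinder radius 1 A, cone-to-cylinder switch
    35 A above the membrane centre.  ``k_wall`` and ``z_max`` are not fixed
    by that setup and are configurable.
    """

    alpha: float = 0.8            # cone half-angle, rad
    rcyl: float = 1.0             # cylinder radius, A
    zcc: float = 35.0             # cone-to-cylinder switch height, A
    axis_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    z_max: float | None = 45.0    # optional top wall, A
    k_wall: float = 10.0          # kcal/mol/A^2

    def __post_init__(self):
        if not (0.0 < self.alpha < np.pi / 2):
            raise ValueError(f"alpha must be in (0, pi/2), got {self.alpha}")
        if self.rcyl <= 0:
            raise ValueError("Rcyl must be positive")
        if self.z_max is not None and not (0.0 < self.zcc < self.z_max):
            raise ValueError("need 0 < Zcc < z_max")
        origin = np.asarray(self.axis_origin, dtype=float).reshape(3)
        direction = np.asarray(self.axis_direction, dtype=float).reshape(3)
        norm = np.linalg.norm(direction)
        if abs(norm - 1.0) > 1e-12:
            raise ValueError("axis_direction must be unit-norm to 1e-12")
        object.__setattr__(self, "axis_origin", origin)
        object.__setattr__(self, "axis_direction", direction)

    def axial_radial(self, point: np.ndarray) -> tuple[float, float, np.ndarray]:
        """Decompose a point into (z, rho, radial unit vector) w.r.t. the axis."""
        rel = np.asarray(point, dtype=float) - self.axis_origin
        z = float(rel @ self.axis_direction)
        radial = rel - z * self.axis_direction
        rho = float(np.linalg.norm(radial))
        return z, rho, radial


def boundary_radius(z, geometry: FunnelGeometry):
    """Funnel boundary radius r(z) = Rcyl + max(0, Zcc - z) * tan(alpha).

    Continuous, non-increasing up to Zcc, constant (= Rcyl) beyond.
    Accepts scalars or arrays.
    """
    z = np.asarray(z, dtype=float)
    r = geometry.rcyl + np.maximum(0.0, geometry.zcc - z) * np.tan(geometry.alpha)
    return float(r) if r.ndim == 0 else r


def bias_energy(point, geometry: FunnelGeometry) -> float:
    """One-sided harmonic wall energy at a point (kcal/mol).

    Zero on and inside the boundary (closed interior); 0.5*k*(rho - r(z))^2
    outside, plus 0.5*k*(z - z_max)^2 above an enabled top wall.
    """
    z, rho, _ = geometry.axial_radial(point)
    r = boundary_radius(z, geometry)
    energy = 0.0
    if rho > r:
        energy += 0.5 * geometry.k_wall * (rho - r) ** 2
    if geometry.z_max is not None and z > geometry.z_max:
        energy += 0.5 * geometry.k_wall * (z - geometry.z_max) ** 2
    return energy


def bias_force(point, geometry: FunnelGeometry) -> np.ndarray:
    """Analytic wall force, -grad(bias_energy), kcal/mol/A.

    Zero strictly inside, continuous across the boundary.  An exterior point
    exactly on the axis has no defined radial direction and raises.
    """
    z, rho, radial = geometry.axial_radial(point)
    r = boundary_radius(z, geometry)
    force = np.zeros(3)
    if rho > r:
        if rho < 1e-12:
            raise DegenerateGeometryError(
                "exterior point lies exactly on the funnel axis")
        excess = rho - r
        rho_hat = radial / rho
        # dE/drho = k*excess; dE/dz = k*excess * (-dr/dz),
        # dr/dz = -tan(alpha) in the conical section, 0 in the cylinder.
        drdz = -np.tan(geometry.alpha) if z < geometry.zcc else 0.0
        force -= geometry.k_wall * excess * rho_hat
        force -= geometry.k_wall * excess * (-drdz) * geometry.axis_direction
    if geometry.z_max is not None and z > geometry.z_max:
        force -= geometry.k_wall * (z - geometry.z_max) * geometry.axis_direction
    return force


def frame_bias_flags(trajectory: Trajectory, geometry: FunnelGeometry,
                     tracked_selection: AtomSelection) -> np.ndarray:
    """Per-frame flag: True iff the wall energy at the geometric centre of the
    tracked selection is positive.  Flagged frames must be dropped from all
    downstream statistics."""
    if len(tracked_selection) == 0:
        raise SelectionError("tracked selection is empty")
    tracked_selection.validate(trajectory.topology)
    idx = tracked_selection.indices
    flags = np.empty(trajectory.n_frames, dtype=bool)
    for k, frame in enumerate(trajectory.frames):
        center = frame.coordinates[idx].mean(axis=0)
        flags[k] = bias_energy(center, geometry) > 0.0
    return flags
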