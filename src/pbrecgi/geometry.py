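"""Torso-heart volume-conductor geometries and the synthetic phantom.

The phantom stands in for a CT-derived geometry: a spherical epicardial
surface inside a spherical (optionally ellipsoidal) torso, with body-surface
electrodes placed quasi-uniformly on the torso. Concentric spheres admit a
closed-form solution of the Laplace problem, which serves as the oracle for
the boundary-element transfer matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import TriSurfaceMesh, fibonacci_sphere_points, sphere_mesh


class GeometryError(ValueError):
    """Raised for invalid torso-heart configurations."""


@dataclass
class TorsoHeartGeometry:
    """Closed heart and torso surfaces with electrodes, homogeneous medium.

    Attributes
    ----------
    heart, torso : TriSurfaceMesh, mm
    electrodes : (n_e, 3) float array, mm, on (or very near) the torso surface
    conductivity : S/m; irrelevant to the transfer matrix in the homogeneous
        case, stored for provenance.
    """

    heart: TriSurfaceMesh
    torso: TriSurfaceMesh
    electrodes: np.ndarray
    conductivity: float = 0.2
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.electrodes = np.atleast_2d(np.asarray(self.electrodes, float))

    def validate(self, electrode_tol_mm: float = 5.0) -> None:
        if self.conductivity <= 0:
            raise GeometryError("conductivity must be positive")
        self.heart.validate()
        self.torso.validate()
        from .mesh import points_inside, distance_to_surface
        if not points_inside(self.torso, self.heart.vertices).all():
            raise GeometryError("heart vertices must lie strictly inside torso")
        if np.any(distance_to_surface(self.torso, self.electrodes)
                  > electrode_tol_mm):
            raise GeometryError(
                f"electrodes farther than {electrode_tol_mm} mm from torso")

    @property
    def n_electrodes(self) -> int:
        return len(self.electrodes)


def generate_phantom(heart_radius: float = 40.0,
                     torso_radius: float = 120.0,
                     n_heart_nodes: int = 1700,
                     n_electrodes: int = 200,
                     seed: int = 0,
                     n_torso_nodes: int = 1000,
                     torso_scale: tuple[float, float, float] = (1.0, 1.0, 1.0),
                     conductivity: float = 0.2,
                     validate: bool = True) -> TorsoHeartGeometry:
    """Build a concentric spherical torso-heart phantom.

    Electrodes are sampled quasi-uniformly on the torso surface (Fibonacci
    spiral, given a seeded random rotation so that they do not coincide with
    torso mesh vertices). Deterministic per seed.
    """
    if not (0 < heart_radius < torso_radius):
        raise GeometryError("require 0 < heart_radius < torso_radius")
    if n_heart_nodes < 4 or n_torso_nodes < 4 or n_electrodes < 4:
        raise GeometryError("node and electrode counts must be >= 4")

    heart = sphere_mesh(heart_radius, n_heart_nodes)
    torso = sphere_mesh(torso_radius, n_torso_nodes, scale=torso_scale)

    rng = np.random.default_rng(seed)
    # random rotation decouples the electrode spiral from the torso spiral
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(random_state=rng).as_matrix()
    pts = fibonacci_sphere_points(n_electrodes, torso_radius) @ rot.T
    electrodes = pts * np.asarray(torso_scale, float)

    geom = TorsoHeartGeometry(heart=heart, torso=torso, electrodes=electrodes,
                              conductivity=conductivity,
                              meta=dict(heart_radius=heart_radius,
                                        torso_radius=torso_radius,
                                        torso_scale=tuple(torso_scale),
                                        seed=seed))
    if validate:
        geom.validate()
    return geom


def match_electrodes_to_nodes(points: np.ndarray,
                              mesh: TriSurfaceMesh) -> np.ndarray:
    """Index of the nearest mesh vertex for each point (Euclidean).

    Ties are broken towards the lowest vertex index.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if len(points) == 0 or mesh.n_vertices == 0:
        raise ValueError("points and mesh must be nonempty")
    d2 = ((points[:, None, :] - mesh.vertices[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)
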