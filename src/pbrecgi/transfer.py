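"""Heart-to-body transfer matrix by a boundary-element method.

The torso volume between the epicardial surface and the body surface is a
source-free homogeneous conductor, so the potential satisfies Laplace's
equation with the epicardial potentials as Dirichlet data and a zero-flux
(insulated) condition on the body surface. Green's representation theorem
collocated at the surface nodes yields a dense linear system relating the
epicardial potentials, the epicardial normal current density, and the
body-surface potentials; eliminating the normal derivative gives the linear
map ``phi_B = A @ phi_H``.

Discretization: vertex collocation with piecewise-constant elements over the
barycentric dual areas. The singular double-layer diagonal is fixed by the
row-sum (auto solid angle) identity, which makes "constant in, constant out"
exact by construction: each row of A sums to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .geometry import TorsoHeartGeometry, match_electrodes_to_nodes
from .mesh import TriSurfaceMesh


class TransferMatrixError(RuntimeError):
    """Raised when the BEM system cannot be solved."""


@dataclass
class TransferMatrix:
    """Linear map from heart-node potentials to electrode potentials.

    ``A`` is dimensionless with shape (n_electrodes, n_heart_nodes); each row
    sums to 1 because a spatially constant epicardial potential produces the
    same constant everywhere in a source-free homogeneous conductor.
    """

    A: np.ndarray
    electrode_vertex_indices: np.ndarray | None = None
    torso_full: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_electrodes(self) -> int:
        return self.A.shape[0]

    @property
    def n_heart_nodes(self) -> int:
        return self.A.shape[1]

    def row_sum_deviation(self) -> float:
        return float(np.max(np.abs(self.A.sum(axis=1) - 1.0)))


@dataclass
class BodyPotentials:
    """Body-surface potential time series, mV, time in columns."""

    phi_B: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.phi_B = np.atleast_2d(np.asarray(self.phi_B, float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_electrodes(self) -> int:
        return self.phi_B.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.phi_B.shape[1]


# ---------------------------------------------------------------------------
# Analytic oracle: Laplace in a spherical annulus with zero outer flux
# ---------------------------------------------------------------------------

def analytic_spheres_attenuation(l: int, a: float, b: float) -> float:
    """Attenuation of a degree-``l`` spherical harmonic between concentric
    spheres of radii ``a < b``, with potential prescribed at ``r = a`` and
    zero normal flux at ``r = b``.

    The interior solution ``alpha r^l + beta r^-(l+1)`` with these boundary
    conditions gives the surface ratio

        (2l+1) a^(l+1) b^l / ((l+1) a^(2l+1) + l b^(2l+1))

    Degree 0 (constants) passes unattenuated.
    """
    if not (0 < a < b):
        raise ValueError("require 0 < a < b")
    if l < 0:
        raise ValueError("harmonic degree must be >= 0")
    num = (2 * l + 1) * a ** (l + 1) * b ** l
    den = (l + 1) * a ** (2 * l + 1) + l * b ** (2 * l + 1)
    return num / den


# ---------------------------------------------------------------------------
# BEM assembly
# ---------------------------------------------------------------------------

def _surface_data(mesh: TriSurfaceMesh):
    return mesh.vertices, mesh.vertex_normals(), mesh.vertex_dual_areas()


def _double_layer(x: np.ndarray, y: np.ndarray, ny: np.ndarray,
                  wy: np.ndarray) -> np.ndarray:
    """Collocated double-layer kernel  w_j * n_j.(x_i - y_j) / (4 pi r^3)."""
    d = x[:, None, :] - y[None, :, :]
    r3 = np.linalg.norm(d, axis=2) ** 3
    with np.errstate(divide="ignore", invalid="ignore"):
        k = (d * ny[None, :, :]).sum(axis=2) / (4.0 * np.pi * r3)
    k = np.where(np.isfinite(k), k, 0.0)
    return k * wy[None, :]


def _single_layer(x: np.ndarray, y: np.ndarray, wy: np.ndarray,
                  self_surface: bool) -> np.ndarray:
    """Collocated single-layer kernel  w_j / (4 pi r); the singular diagonal
    is approximated by the exact integral over a flat disk of equal area,
    integral(1/(4 pi r)) dS = R_eq / 2."""
    r = np.linalg.norm(x[:, None, :] - y[None, :, :], axis=2)
    with np.errstate(divide="ignore"):
        g = wy[None, :] / (4.0 * np.pi * r)
    if self_surface:
        np.fill_diagonal(g, np.sqrt(wy / np.pi) / 2.0)
    g = np.where(np.isfinite(g), g, 0.0)
    return g


def compute_transfer_matrix(geometry: TorsoHeartGeometry,
                            validate: bool = False) -> TransferMatrix:
    """Compute the heart-to-electrode transfer matrix for a homogeneous
    source-free volume conductor with an insulated body surface.

    Electrode values are taken at the nearest torso vertex (matching the
    nearest-node pairing convention used throughout the evaluation).
    """
    if validate:
        geometry.validate()
    heart, torso = geometry.heart, geometry.torso
    xb, nb, wb = _surface_data(torso)
    xh, nh, wh = _surface_data(heart)
    # domain-outward normal: along the torso normal on the body surface,
    # against the heart normal on the epicardium (it points into the heart)
    nh_dom = -nh

    H_BB = _double_layer(xb, xb, nb, wb)
    H_BH = _double_layer(xb, xh, nh_dom, wh)
    H_HB = _double_layer(xh, xb, nb, wb)
    H_HH = _double_layer(xh, xh, nh_dom, wh)
    G_BH = _single_layer(xb, xh, wh, self_surface=False)
    G_HH = _single_layer(xh, xh, wh, self_surface=True)

    # auto-solid-angle: diagonal of the same-surface double layer absorbs the
    # free term c(x) so that constants (with zero flux) solve the system
    # exactly -> rows of the full [H_.B | H_.H] blocks sum to zero.
    np.fill_diagonal(H_BB, 0.0)
    np.fill_diagonal(H_HH, 0.0)
    np.fill_diagonal(H_BB, -(H_BB.sum(axis=1) + H_BH.sum(axis=1)))
    np.fill_diagonal(H_HH, -(H_HH.sum(axis=1) + H_HB.sum(axis=1)))

    nb_n, nh_n = len(xb), len(xh)
    # unknowns: [phi_B ; gamma] with gamma the epicardial normal derivative
    lhs = np.block([[H_BB, -G_BH], [H_HB, -G_HH]])
    rhs = np.vstack([-H_BH, -H_HH])
    try:
        sol = linalg.solve(lhs, rhs)
    except linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
        raise TransferMatrixError(f"singular BEM system: {exc}") from exc
    torso_full = sol[:nb_n, :]

    idx = match_electrodes_to_nodes(geometry.electrodes, torso)
    return TransferMatrix(A=torso_full[idx, :].copy(),
                          electrode_vertex_indices=idx,
                          torso_full=torso_full)


# ---------------------------------------------------------------------------
# Forward projection with controlled sensor noise
# ---------------------------------------------------------------------------

def forward_project(A: TransferMatrix | np.ndarray,
                    phi_H: np.ndarray,
                    snr_db: float | None = None,
                    seed: int = 0,
                    dt: float = 1.0) -> BodyPotentials:
    """Project epicardial potentials to the body surface, phi_B = A phi_H,
    optionally adding zero-mean Gaussian sensor noise per electrode scaled
    to a requested signal-to-noise ratio (dB, power ratio of the centered
    signal to the noise). Deterministic per seed.
    """
    mat = A.A if isinstance(A, TransferMatrix) else np.asarray(A, float)
    phi_H = np.atleast_2d(np.asarray(phi_H, float))
    if mat.shape[1] != phi_H.shape[0]:
        raise ValueError(
            f"shape mismatch: A is {mat.shape}, phi_H is {phi_H.shape}")
    phi_B = mat @ phi_H
    if snr_db is not None:
        rng = np.random.default_rng(seed)
        sig_std = phi_B.std(axis=1, keepdims=True)
        noise_std = sig_std * 10.0 ** (-snr_db / 20.0)
        phi_B = phi_B + noise_std * rng.standard_normal(phi_B.shape)
    return BodyPotentials(phi_B=phi_B, dt=dt)
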