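"""Spatial basis construction from ensembles of simulated beats.

All simulated beats are concatenated column-wise into a single potential
matrix (nodes x (beats * steps)) and decomposed by SVD. The left singular
vectors form a spatial basis of epicardial potential patterns ordered by
their contribution to the ensemble; a truncated component range (2-10 by
default, 1-based) keeps the most influential patterns while discarding the
near-constant first component, which only reflects the -80 mV resting
offset of the simulated action potentials and plays no role when
reconstructing zero-referenced electrograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .propagation import SimulatedBeat


@dataclass
class PotentialEnsemble:
    """Concatenated per-node voltage matrix of several beats, mV."""

    matrix: np.ndarray  # (n_nodes, n_beats * n_steps)
    beat_boundaries: list[tuple[int, int]]
    origins: list[int] = field(default_factory=list)
    model: str = ""
    dt: float = 1.0

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_beats(self) -> int:
        return len(self.beat_boundaries)


@dataclass
class SpatialBasis:
    """Truncated orthonormal spatial components with retained singular values.

    ``component_range`` uses 1-based inclusive numbering of SVD components,
    so the default range (2, 10) keeps nine basis vectors.
    """

    U_k: np.ndarray  # (n_nodes, k), orthonormal columns
    singular_values: np.ndarray
    component_range: tuple[int, int]

    @property
    def k(self) -> int:
        return self.U_k.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.U_k.shape[0]


def assemble_ensemble(beats: list[SimulatedBeat]) -> PotentialEnsemble:
    """Concatenate beats column-wise in beat order."""
    if not beats:
        raise ValueError("need at least one beat")
    n = beats[0].n_nodes
    dt = beats[0].dt
    model = beats[0].model
    for b in beats:
        if b.n_nodes != n:
            raise ValueError(
                f"beat node count {b.n_nodes} != {n}: beats must share a mesh")
        if b.dt != dt:
            raise ValueError("beats must share the sampling interval")
    blocks, bounds, col = [], [], 0
    for b in beats:
        blocks.append(b.phi_H)
        bounds.append((col, col + b.n_steps))
        col += b.n_steps
    return PotentialEnsemble(matrix=np.hstack(blocks), beat_boundaries=bounds,
                             origins=[b.origin for b in beats], model=model,
                             dt=dt)


def _fix_signs(U: np.ndarray, V: np.ndarray | None):
    """Deterministic sign convention: the largest-magnitude entry of each
    spatial component is positive (linear-algebra backends only determine
    singular vectors up to sign)."""
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    U = U * signs
    if V is not None:
        V = V * signs
    return U, V


def compute_svd(ensemble: PotentialEnsemble | np.ndarray):
    """Thin SVD of the ensemble matrix, M = U diag(s) V^T.

    Returns ``(U, s, V)`` with singular values in non-increasing order and V
    as a (columns x rank) matrix of temporal components (diagnostic only;
    reconstruction uses the spatial basis U). For strongly rectangular
    matrices the decomposition goes through the smaller-dimension Gram
    matrix, which is much faster than a direct LAPACK SVD and accurate for
    the leading components that the truncated basis retains.
    """
    M = ensemble.matrix if isinstance(ensemble, PotentialEnsemble) else ensemble
    M = np.asarray(M, float)
    if M.size == 0:
        raise ValueError("empty ensemble")
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite entries in ensemble")
    n, m = M.shape
    if m >= 10 * n:
        # eigendecomposition of the (n x n) Gram matrix M M^T
        gram = M @ M.T
        evals, U = np.linalg.eigh(gram)
        order = np.argsort(evals)[::-1]
        evals, U = evals[order], U[:, order]
        s = np.sqrt(np.maximum(evals, 0.0))
        keep = s > max(1e-12 * (s[0] if s[0] > 0 else 1.0), 0.0)
        U, s = U[:, keep], s[keep]
        V = (M.T @ U) / s
    else:
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        V = Vt.T
    U, V = _fix_signs(U, V)
    return U, s, V


def truncate_basis(U: np.ndarray, singular_values: np.ndarray,
                   first: int = 2, last: int = 10,
                   rank_tol: float = 1e-10) -> SpatialBasis:
    """Keep SVD components ``first..last`` (1-based, inclusive).

    The default (2, 10) yields a 9-vector basis that excludes the
    near-constant offset component.
    """
    s = np.asarray(singular_values, float)
    if not (1 <= first <= last):
        raise ValueError("require 1 <= first <= last")
    rank = int(np.sum(s > rank_tol * (s[0] if len(s) and s[0] > 0 else 1.0)))
    if last > rank:
        raise ValueError(f"last component {last} exceeds rank {rank}")
    return SpatialBasis(U_k=np.ascontiguousarray(U[:, first - 1:last]),
                        singular_values=s[first - 1:last].copy(),
                        component_range=(first, last))
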