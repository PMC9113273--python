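"""Anisotropic network model: 3N x 3N Hessian, internal normal modes, and
mode-displaced conformers for motion visualization.

Where the GNM gives isotropic fluctuation magnitudes, the ANM gives
directions.  C-alpha atoms within a cutoff (default 15 A) are joined by
identical springs; the Hessian of the pairwise harmonic potential at
equilibrium has, for each connected pair (i, j), the off-diagonal 3x3
super-element

    H_ij = -gamma (r_ij r_ij^T) / |r_ij|^2,

with diagonal blocks H_ii = -sum_{j!=i} H_ij.  A connected,
non-degenerate structure has exactly six zero modes (rigid translations
and rotations); the remaining 3N-6 eigenvectors are internal motions.
A conformer displaced along internal mode nu with amplitude s is

    R' = R + s nu    (nu reshaped to N x 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import DegenerateGeometryError
from .structure_io import CalphaModel

__all__ = [
    "AnmParameters",
    "HessianMatrix",
    "ModeSet",
    "MotionTrajectory",
    "build_hessian",
    "anm_modes",
    "generate_motion",
    "auto_amplitude",
]


@dataclass(frozen=True)
class AnmParameters:
    """cutoff in angstroms (default 15.0); gamma sets the energy scale only."""

    cutoff: float = 15.0
    gamma: float = 1.0
    zero_mode_tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class HessianMatrix:
    matrix: np.ndarray  # (3N, 3N)
    parameters: AnmParameters

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0] // 3


@dataclass
class ModeSet:
    """Internal (nonzero) ANM modes, ascending by eigenvalue.

    ``eigenvectors[:, i]`` is the unit-norm 3N eigenvector of internal mode
    ``i`` (0-based here; user-facing mode numbering is 1-based, mode 1 =
    lowest frequency).
    """

    eigenvalues: np.ndarray  # (3N - 6,)
    eigenvectors: np.ndarray  # (3N, 3N - 6)
    n_removed: int

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


@dataclass
class MotionTrajectory:
    mode_index: int  # 1-based internal mode number
    amplitudes: np.ndarray
    frames: list[np.ndarray]  # each (N, 3)


def build_hessian(
    model: CalphaModel, params: AnmParameters | None = None
) -> HessianMatrix:
    """Assemble the ANM Hessian from C-alpha coordinates."""
    params = params or AnmParameters()
    coords = model.coordinates
    n = len(model)
    if n < 3:
        raise ValueError("ANM needs at least 3 residues")
    dist = squareform(pdist(coords))
    hessian = np.zeros((3 * n, 3 * n))
    gamma = params.gamma
    contact = np.triu(dist <= params.cutoff, k=1)
    for i, j in zip(*np.nonzero(contact)):
        if dist[i, j] < 1e-6:
            raise DegenerateGeometryError(
                f"connected residues {model.residues[i]} and "
                f"{model.residues[j]} have coincident coordinates"
            )
        r = coords[j] - coords[i]
        block = -gamma * np.outer(r, r) / float(r @ r)
        hessian[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
        hessian[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        hessian[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        hessian[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return HessianMatrix(matrix=hessian, parameters=params)


def anm_modes(h: HessianMatrix) -> ModeSet:
    """Diagonalize the Hessian and strip the six rigid-body modes.

    Raises :class:`DegenerateGeometryError` unless exactly six eigenvalues
    are numerically zero — more indicates a disconnected network or
    degenerate (e.g. collinear) geometry, fewer indicates a broken Hessian.
    """
    eigenvalues, eigenvectors = np.linalg.eigh(h.matrix)
    lam_max = eigenvalues[-1]
    if lam_max <= 0:
        raise DegenerateGeometryError("Hessian has no positive eigenvalue")
    tol = h.parameters.zero_mode_tolerance * lam_max
    n_zero = int(np.sum(np.abs(eigenvalues) < tol))
    if n_zero != 6:
        raise DegenerateGeometryError(
            f"expected 6 rigid-body modes, found {n_zero} near-zero "
            f"eigenvalues (disconnected network or degenerate geometry)"
        )
    # fix eigenvector signs for reproducibility
    vecs = eigenvectors[:, 6:]
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return ModeSet(
        eigenvalues=eigenvalues[6:].copy(),
        eigenvectors=vecs * signs,
        n_removed=6,
    )


def auto_amplitude(
    modes: ModeSet, mode_index: int, max_displacement: float = 2.0
) -> float:
    """Amplitude at which the most-displaced residue moves ``max_displacement`` A."""
    vec = _mode_vector(modes, mode_index)
    per_residue = np.linalg.norm(vec.reshape(-1, 3), axis=1)
    return max_displacement / float(per_residue.max())


def _mode_vector(modes: ModeSet, mode_index: int) -> np.ndarray:
    if not 1 <= mode_index <= modes.n_modes:
        raise ValueError(
            f"mode index {mode_index} out of range [1, {modes.n_modes}]"
        )
    return modes.eigenvectors[:, mode_index - 1]


def generate_motion(
    model: CalphaModel,
    modes: ModeSet,
    mode_index: int,
    s_max: float,
    n_frames: int = 11,
) -> MotionTrajectory:
    """Sweep a single internal mode symmetrically: s in [-s_max, +s_max].

    ``n_frames`` must be odd and >= 3 so the central frame is the
    undisplaced input structure (bit-equal to the model coordinates).
    """
    if s_max <= 0:
        raise ValueError("s_max must be positive")
    if n_frames < 3 or n_frames % 2 == 0:
        raise ValueError("n_frames must be odd and >= 3")
    direction = _mode_vector(modes, mode_index).reshape(-1, 3)
    amplitudes = np.linspace(-s_max, s_max, n_frames)
    amplitudes[n_frames // 2] = 0.0  # exact zero at the centre
    frames = [model.coordinates + s * direction for s in amplitudes]
    return MotionTrajectory(mode_index=mode_index, amplitudes=amplitudes, frames=frames)
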