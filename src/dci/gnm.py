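"""Gaussian network model: Kirchhoff matrix, mode-truncated pseudoinverse,
residue cross-correlations and the Euclidean dynamic distance matrix.

The GNM treats a protein as a network of C-alpha nodes joined by identical
harmonic springs whenever two nodes lie within a cutoff distance (default
7.0 A, inclusive).  Isotropic residue fluctuations are governed by the
connectivity (Kirchhoff) matrix Gamma:

    Gamma_ij = -gamma            if i != j and |R_i - R_j| <= cutoff
             = 0                 if i != j and |R_i - R_j| >  cutoff
    Gamma_ii = -sum_{j!=i} Gamma_ij

Gamma is a weighted graph Laplacian, singular with one zero mode for a
connected network (uniform translation of all fluctuations).  The
fluctuation covariance is the pseudoinverse over the internal modes,

    Gamma^-1 = sum_{i=2..N} (1/lambda_i) u_i u_i^T,

from which pairwise cross-correlations and the dynamic distance follow:

    C_ij = Gamma^-1_ij / sqrt(Gamma^-1_ii Gamma^-1_jj)
    D_ij = sqrt(2 (1 - C_ij))

D maps perfectly correlated residue pairs to 0 and perfectly anticorrelated
pairs to 2, and is the input to community detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import DegenerateGeometryError, DisconnectedNetworkError
from .structure_io import CalphaModel

__all__ = [
    "GnmParameters",
    "KirchhoffMatrix",
    "GnmCovariance",
    "CorrelationMatrix",
    "DynamicDistanceMatrix",
    "build_kirchhoff",
    "gnm_pseudoinverse",
    "cross_correlation",
    "dynamic_distance",
    "dynamic_distance_from_model",
]


@dataclass(frozen=True)
class GnmParameters:
    """Spring-network parameters.

    cutoff : contact distance in angstroms, boundary inclusive (default 7.0)
    gamma : uniform spring force constant (default 1.0; sets the energy
        scale only — correlations and distances are gamma-invariant)
    zero_mode_tolerance : eigenvalues below this fraction of the largest
        eigenvalue count as rigid-body (zero) modes
    """

    cutoff: float = 7.0
    gamma: float = 1.0
    zero_mode_tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class KirchhoffMatrix:
    matrix: np.ndarray  # (N, N)
    parameters: GnmParameters

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GnmCovariance:
    """Mode-truncated pseudoinverse of the Kirchhoff matrix.

    ``matrix[i, i]`` is the mean-square fluctuation of residue ``i`` (in
    units of kT/gamma); eigenpairs are stored ascending with the excluded
    rigid-body mode first.
    """

    matrix: np.ndarray  # (N, N)
    eigenvalues: np.ndarray  # (N,) ascending, includes the zero mode
    eigenvectors: np.ndarray  # (N, N), columns match eigenvalues
    n_excluded_modes: int = 1

    @property
    def fluctuations(self) -> np.ndarray:
        return np.diag(self.matrix).copy()


@dataclass
class CorrelationMatrix:
    matrix: np.ndarray  # (N, N), unit diagonal, entries in [-1, 1]


@dataclass
class DynamicDistanceMatrix:
    matrix: np.ndarray  # (N, N), zero diagonal, entries in [0, 2]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def build_kirchhoff(
    model: CalphaModel, params: GnmParameters | None = None
) -> KirchhoffMatrix:
    """Build the GNM connectivity matrix from C-alpha coordinates.

    Two residues are connected iff their C-alpha distance is <= cutoff
    (boundary inclusive).  Rows sum to zero; the diagonal carries node
    degrees (times gamma).
    """
    params = params or GnmParameters()
    n = len(model)
    if n < 2:
        raise ValueError("GNM needs at least 2 residues")
    dist = squareform(pdist(model.coordinates))
    adjacency = (dist <= params.cutoff).astype(float)
    np.fill_diagonal(adjacency, 0.0)
    gamma = params.gamma
    matrix = -gamma * adjacency
    np.fill_diagonal(matrix, gamma * adjacency.sum(axis=1))
    return KirchhoffMatrix(matrix=matrix, parameters=params)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each eigenvector's largest-magnitude component positive.

    Signs cancel in the pseudoinverse; fixing them keeps cached
    intermediates bit-reproducible across BLAS implementations.
    """
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def gnm_pseudoinverse(k: KirchhoffMatrix) -> GnmCovariance:
    """Eigendecompose Gamma and sum internal modes into the pseudoinverse.

    Exactly one mode (the uniform zero mode of a connected network) is
    excluded.  If more than one eigenvalue is numerically zero the spring
    network is disconnected and a :class:`DisconnectedNetworkError` is
    raised naming the component count, rather than silently dropping modes.
    """
    eigenvalues, eigenvectors = np.linalg.eigh(k.matrix)
    eigenvectors = _fix_signs(eigenvectors)
    lam_max = eigenvalues[-1]
    if lam_max <= 0:
        # all-zero Kirchhoff: every node is its own component
        raise DisconnectedNetworkError(k.matrix.shape[0], k.parameters.cutoff)
    tol = k.parameters.zero_mode_tolerance * lam_max
    n_zero = int(np.sum(eigenvalues < tol))
    if n_zero != 1:
        raise DisconnectedNetworkError(max(n_zero, 1), k.parameters.cutoff)
    inv_lam = 1.0 / eigenvalues[1:]
    u = eigenvectors[:, 1:]
    matrix = (u * inv_lam) @ u.T
    matrix = 0.5 * (matrix + matrix.T)
    return GnmCovariance(
        matrix=matrix,
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        n_excluded_modes=1,
    )


def cross_correlation(cov: GnmCovariance) -> CorrelationMatrix:
    """Normalize the covariance to pairwise cross-correlations in [-1, 1]."""
    diag = np.diag(cov.matrix)
    if np.any(diag <= 0):
        bad = int(np.argmin(diag))
        raise DegenerateGeometryError(
            f"nonpositive mean-square fluctuation at residue index {bad}"
        )
    norm = np.sqrt(np.outer(diag, diag))
    c = cov.matrix / norm
    c = np.clip(0.5 * (c + c.T), -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(matrix=c)


def dynamic_distance(c: CorrelationMatrix) -> DynamicDistanceMatrix:
    """Map correlations to distances: D_ij = sqrt(2 (1 - C_ij)).

    C is clipped to [-1, 1] first to absorb rounding, so D lands in [0, 2]
    with an exactly zero diagonal.
    """
    clipped = np.clip(c.matrix, -1.0, 1.0)
    d = np.sqrt(2.0 * (1.0 - clipped))
    np.fill_diagonal(d, 0.0)
    return DynamicDistanceMatrix(matrix=0.5 * (d + d.T))


def dynamic_distance_from_model(
    model: CalphaModel, params: GnmParameters | None = None
) -> DynamicDistanceMatrix:
    """Full GNM chain: coordinates -> Gamma -> Gamma^-1 -> C -> D."""
    k = build_kirchhoff(model, params)
    cov = gnm_pseudoinverse(k)
    c = cross_correlation(cov)
    return dynamic_distance(c)


def save_matrix_tsv(matrix: np.ndarray, residues, path) -> None:
    """Dump a residue-keyed square matrix as TSV (header row and column)."""
    keys = [str(r) for r in residues]
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(keys) + "\n")
        for key, row in zip(keys, matrix):
            fh.write(key + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def save_matrix_binary(matrix: np.ndarray, path) -> None:
    """Dump a matrix in a minimal binary container.

    Layout: ASCII magic ``DCIM1\\n``, two little-endian uint64 (rows, cols),
    then row-major float64 values.
    """
    m = np.ascontiguousarray(matrix, dtype="<f8")
    with open(path, "wb") as fh:
        fh.write(b"DCIM1\n")
        fh.write(np.array(m.shape, dtype="<u8").tobytes())
        fh.write(m.tobytes())


def load_matrix_binary(path) -> np.ndarray:
    with open(path, "rb") as fh:
        magic = fh.read(6)
        if magic != b"DCIM1\n":
            raise ValueError("not a DCIM1 matrix file")
        shape = np.frombuffer(fh.read(16), dtype="<u8")
        data = np.frombuffer(fh.read(), dtype="<f8")
    return data.reshape(int(shape[0]), int(shape[1])).copy()
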