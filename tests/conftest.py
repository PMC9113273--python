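"""Shared fixtures and generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from dci.structure_io import CalphaModel, ResidueKey


def random_connected_model(n: int, seed: int, jitter: float = 1.2) -> CalphaModel:
    """Compact jittered-lattice globule whose 7 A contact graph is connected."""
    rng = np.random.default_rng(seed)
    side = int(np.ceil(n ** (1.0 / 3.0)))
    pts = []
    for idx in range(n):
        i, rem = divmod(idx, side * side)
        j, k = divmod(rem, side)
        pts.append((4.0 * i, 4.0 * j, 4.0 * k))
    coords = np.array(pts) + rng.uniform(-jitter, jitter, size=(n, 3))
    residues = [ResidueKey("A", i + 1) for i in range(n)]
    return CalphaModel(residues, coords, source_id=f"globule-{n}-{seed}")


def random_correlation(n: int, seed: int) -> np.ndarray:
    """Random valid correlation matrix (PSD, unit diagonal)."""
    rng = np.random.default_rng(seed)
    factors = rng.normal(size=(n, n + 2))
    cov = factors @ factors.T
    d = np.sqrt(np.diag(cov))
    c = cov / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def random_distance_matrix(n: int, seed: int) -> np.ndarray:
    """Random valid dynamic distance matrix derived from a random correlation."""
    c = random_correlation(n, seed)
    d = np.sqrt(2.0 * (1.0 - c))
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T)


MINIMAL_PDB = "\n".join(
    [
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C",
        "ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C",
        "ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C",
        "END",
    ]
) + "\n"


@pytest.fixture
def minimal_pdb() -> str:
    return MINIMAL_PDB
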