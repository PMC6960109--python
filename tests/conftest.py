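"""Shared fixtures and helpers for the test-suite."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pytest

from dsnn.synthetic import FIXTURE_SPECS, generate_matrix
from dsnn.transforms import DCTBasisPair, dct_matrix


@dataclass
class DenseMatrixOperator:
    """Dense operator wrapper so the BPDN solver can be exercised on
    arbitrary explicit systems (oracle comparisons); the unknown is viewed
    as a 1 × N coefficient matrix."""

    A: np.ndarray
    mask = None
    basis = None

    @property
    def shape(self):
        return (1, self.A.shape[1])

    @property
    def n_measurements(self):
        return self.A.shape[0]

    def apply(self, Z):
        return self.A @ np.asarray(Z).ravel()

    def adjoint(self, v):
        return (self.A.T @ np.asarray(v)).reshape(1, -1)


@pytest.fixture
def dense_op() -> Callable[[np.ndarray], DenseMatrixOperator]:
    return DenseMatrixOperator


@pytest.fixture(scope="session")
def noisy_fixture():
    """The standard 100×200 noisy benchmark matrix (matrix, truth)."""
    matrix, truth, _ = generate_matrix(FIXTURE_SPECS["noisy100x200"])
    return matrix, truth


@pytest.fixture(scope="session")
def twoclass_fixture():
    """The 60×50 two-class matrix (matrix, truth, labels)."""
    matrix, truth, labels = generate_matrix(FIXTURE_SPECS["twoclass60x50"])
    return matrix, truth, labels


def materialize_sensing_matrix(mask, basis: DCTBasisPair) -> np.ndarray:
    """Brute-force oracle: the dense |observed| × (m·n) matrix equal to the
    masked synthesis operator, built from a row-selection matrix times the
    Kronecker form of the 2-D inverse DCT (row-major vectorization)."""
    m, n = basis.shape
    D_c, D_r = dct_matrix(m), dct_matrix(n)
    # row-major vec(A X B) = (A ⊗ B.T) vec(X); here X_out = D_c.T @ Z @ D_r.
    K = np.kron(D_c.T, D_r.T)  # A = D_c.T, B = D_r -> A ⊗ B.T
    sel = np.flatnonzero(mask.entries.ravel(order="C"))
    S = np.zeros((sel.size, m * n))
    S[np.arange(sel.size), sel] = 1.0
    return S @ K
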