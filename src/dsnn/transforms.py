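"""Orthonormal DCT bases, 2-D analysis/synthesis transforms, and the masked
sensing operator used by the compressive-sensing recovery stage.

The sparsifying transform is the orthonormal DCT-II applied on both axes of
the subjects × genes matrix (double sparsity): the analysis coefficients are
``Z = D_c @ X @ D_r.T``.  Because both factors are orthonormal, the analysis
and synthesis views are equivalent and the synthesis map ``Z -> D_c.T @ Z @ D_r``
composed with elementwise masking is the forward operator of the recovery
problem.  All transforms are applied matrix-free via ``scipy.fft``; the DCT
matrices themselves are materialized only on demand (small sizes, tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import fft as _fft

__all__ = [
    "ObservationMask",
    "DCTBasisPair",
    "SensingOperator",
    "dct_matrix",
    "forward_2d",
    "inverse_2d",
    "build_sensing_operator",
]


@dataclass(frozen=True)
class ObservationMask:
    """Binary m × n matrix of observed positions (1 = observed, 0 = missing)."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries)
        if arr.ndim != 2:
            raise ValueError("observation mask must be 2-D")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("observation mask entries must be 0 or 1")
        object.__setattr__(self, "entries", arr.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    @property
    def n_observed(self) -> int:
        return int(self.entries.sum())

    def as_bool(self) -> np.ndarray:
        return self.entries.astype(bool)

    def column_coverage_ok(self) -> bool:
        """True when every column has at least one observed entry (required by
        the Stage-2 column statistics)."""
        return bool((self.entries.sum(axis=0) > 0).all())


def dct_matrix(size: int) -> np.ndarray:
    """Orthonormal DCT-II matrix of the given size.

    Row k, column j equals ``c_k * cos(pi * (2j + 1) * k / (2N))`` with
    ``c_0 = 1/sqrt(N)`` and ``c_k = sqrt(2/N)`` otherwise, so ``D @ D.T = I``.
    """
    if size < 1:
        raise ValueError(f"DCT matrix size must be >= 1, got {size}")
    # DCT of the identity's columns stacks the basis into the matrix itself.
    return _fft.dct(np.eye(size), type=2, norm="ortho", axis=0)


@dataclass(frozen=True)
class DCTBasisPair:
    """Pair of orthonormal DCT-II matrices: D_c (m × m, column axis) and
    D_r (n × n, row axis)."""

    m: int
    n: int
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError("basis dimensions must be >= 1")

    @classmethod
    def for_shape(cls, shape: tuple[int, int]) -> "DCTBasisPair":
        return cls(m=int(shape[0]), n=int(shape[1]))

    @property
    def D_c(self) -> np.ndarray:
        if "D_c" not in self._cache:
            self._cache["D_c"] = dct_matrix(self.m)
        return self._cache["D_c"]

    @property
    def D_r(self) -> np.ndarray:
        if "D_r" not in self._cache:
            self._cache["D_r"] = dct_matrix(self.n)
        return self._cache["D_r"]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.m, self.n)


def _check_shape(X: np.ndarray, basis: DCTBasisPair, what: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape != basis.shape:
        raise ValueError(
            f"{what} shape {X.shape} does not match basis shape {basis.shape}"
        )
    return X


def forward_2d(X: np.ndarray, basis: DCTBasisPair) -> np.ndarray:
    """Analysis transform Z = D_c @ X @ D_r.T (2-D orthonormal DCT-II)."""
    X = _check_shape(X, basis, "matrix")
    return _fft.dctn(X, type=2, norm="ortho")


def inverse_2d(Z: np.ndarray, basis: DCTBasisPair) -> np.ndarray:
    """Synthesis transform X = D_c.T @ Z @ D_r (inverse 2-D DCT-II)."""
    Z = _check_shape(Z, basis, "coefficient matrix")
    return _fft.idctn(Z, type=2, norm="ortho")


@dataclass(frozen=True)
class SensingOperator:
    """Matrix-free map from DCT coefficients to the vector of observed entries.

    ``apply(Z)`` synthesizes ``D_c.T @ Z @ D_r`` and extracts the observed
    entries in row-major scan order; ``adjoint(v)`` embeds ``v`` at the
    observed positions (zero elsewhere) and analyzes back to the coefficient
    domain.  The pair satisfies the adjoint identity
    ``<apply(Z), v> == <Z, adjoint(v)>``.
    """

    mask: ObservationMask
    basis: DCTBasisPair
    apply: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    adjoint: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.basis.shape

    @property
    def n_measurements(self) -> int:
        return self.mask.n_observed


def build_sensing_operator(
    mask: ObservationMask, basis: DCTBasisPair
) -> SensingOperator:
    """Build the masked synthesis operator and its adjoint for the recovery
    problem.  The operator is never materialized densely."""
    if mask.shape != basis.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match basis shape {basis.shape}"
        )
    if mask.n_observed == 0:
        raise ValueError("observation mask has no observed entries")

    m, n = basis.shape
    flat_idx = np.flatnonzero(mask.entries.ravel(order="C"))

    def apply(Z: np.ndarray) -> np.ndarray:
        X = _fft.idctn(np.asarray(Z, dtype=float), type=2, norm="ortho")
        return X.ravel(order="C")[flat_idx]

    def adjoint(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if v.shape != (flat_idx.size,):
            raise ValueError(
                f"adjoint input length {v.shape} != number of observed entries "
                f"({flat_idx.size},)"
            )
        full = np.zeros(m * n)
        full[flat_idx] = v
        return _fft.dctn(full.reshape(m, n), type=2, norm="ortho")

    return SensingOperator(mask=mask, basis=basis, apply=apply, adjoint=adjoint)
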