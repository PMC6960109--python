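"""Masking/NMSE evaluation protocol.

A fully observed matrix serves as ground truth; entries are dropped uniformly
at random at a grid of observability levels, each incomplete matrix is
imputed, and the normalized mean squared error

    NMSE = ||X - X_hat||_F^2 / ||X||_F^2

is recorded per (observed fraction, repeat, ablation arm) and averaged over
repeats.  Sampling is exact-count (the requested fraction is honored exactly)
and a mask leaving any gene with no observed entry is redrawn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .pipeline import DSNNConfig, dsnn_impute
from .transforms import ObservationMask

__all__ = ["EvaluationRecord", "nmse", "random_mask", "run_masking_experiment"]

logger = logging.getLogger(__name__)

DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.1, 0.91, 0.1), 2))
DEFAULT_REPEATS = 30

RECORD_COLUMNS = ["observed_fraction", "repeat_index", "mode", "nmse"]


@dataclass(frozen=True)
class EvaluationRecord:
    observed_fraction: float
    repeat_index: int
    mode: str
    nmse: float


def nmse(X_original: np.ndarray, X_recovered: np.ndarray) -> float:
    """Normalized mean squared error between the ground-truth and recovered
    matrices (whole-matrix, squared Frobenius norms)."""
    X = np.asarray(X_original, dtype=float)
    Xh = np.asarray(X_recovered, dtype=float)
    if X.shape != Xh.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Xh.shape}")
    denom = float(np.linalg.norm(X) ** 2)
    if denom == 0.0:
        raise ValueError("ground-truth matrix has zero Frobenius norm")
    return float(np.linalg.norm(X - Xh) ** 2) / denom


def random_mask(
    m: int,
    n: int,
    observed_fraction: float,
    seed: int | np.random.Generator = 0,
    max_redraws: int = 100,
) -> ObservationMask:
    """Uniform random mask with exactly round(fraction * m * n) observed
    entries, redrawn (and logged) if any column ends up fully missing."""
    if not 0.0 < observed_fraction <= 1.0:
        raise ValueError("observed_fraction must be in (0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    k = int(round(observed_fraction * m * n))
    k = max(k, 1)
    for attempt in range(max_redraws):
        idx = rng.choice(m * n, size=k, replace=False)
        entries = np.zeros(m * n, dtype=np.uint8)
        entries[idx] = 1
        mask = ObservationMask(entries.reshape(m, n))
        if mask.column_coverage_ok():
            return mask
        logger.info(
            "random_mask: redraw %d (a column had no observed entries)", attempt + 1
        )
    raise RuntimeError(
        f"could not draw a column-covering mask at fraction {observed_fraction}"
    )


def run_masking_experiment(
    X: ExpressionMatrix,
    fractions=DEFAULT_FRACTIONS,
    n_repeats: int = DEFAULT_REPEATS,
    modes=("dsnn",),
    cfg: DSNNConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the masking protocol on a fully observed ground-truth matrix.

    For every fraction × repeat a fresh mask is drawn (shared across the
    ablation arms so they see identical missingness), the zero-filled matrix
    is imputed per arm, and NMSE against ``X`` is recorded.  Returns the
    long-format record table and the per-(fraction, mode) mean summary.
    All randomness derives from ``cfg.seed``.
    """
    cfg = cfg or DSNNConfig()
    for mode in modes:
        if mode not in ("dsnn", "stage1", "stage2"):
            raise ValueError(f"unknown mode {mode!r}")
    m, n = X.shape
    mask_rng, _ = cfg.spawn_rngs()
    rows = []
    for fraction in fractions:
        for repeat in range(n_repeats):
            mask = random_mask(m, n, fraction, seed=mask_rng)
            # One derived seed per (fraction, repeat), shared across arms so
            # they differ only in the method applied.
            run_seed = int(mask_rng.integers(2**31))
            for mode in modes:
                run_cfg = replace(cfg, mode=mode, seed=run_seed)
                imputed = dsnn_impute(X, mask, run_cfg)
                err = nmse(X.values, imputed.values)
                rows.append(
                    EvaluationRecord(
                        observed_fraction=float(fraction),
                        repeat_index=repeat,
                        mode=mode,
                        nmse=err,
                    )
                )
                logger.debug(
                    "fraction=%.2f repeat=%d mode=%s nmse=%.4g",
                    fraction,
                    repeat,
                    mode,
                    err,
                )
    records = pd.DataFrame([r.__dict__ for r in rows], columns=RECORD_COLUMNS)
    summary = (
        records.groupby(["observed_fraction", "mode"], as_index=False)["nmse"]
        .mean()
        .rename(columns={"nmse": "mean_nmse"})
    )
    return records, summary
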