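"""Synthetic expression-like matrices for development and testing.

Real microarray matrices are approximately low rank (genes are co-regulated)
and their rows and columns have rapidly decaying DCT spectra (expression
profiles vary slowly).  The generator reproduces exactly those two premises:
the ground truth is the inverse 2-D DCT of a coefficient matrix built as a
sum of ``rank`` outer products of sparse, low-frequency-biased coefficient
vectors, shifted into the non-negative raw-intensity regime, and the
observed matrix adds i.i.d. Gaussian noise.  An optional two-class structure
embeds the class difference as one of the rank-constrained factors (a
class-indicator row-loading times a smooth gene-loading), mimicking the
diffuse differential expression between normal and tumor cohorts.

Scale: entries live on the raw-intensity scale of the order 10^2–10^3 (entry
RMS of the leading structure about 200), so the denoising stage's default
calibration (SVT threshold in expression units) is exercised in the regime
it was designed for.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .io import ExpressionMatrix, write_matrix
from .transforms import DCTBasisPair, inverse_2d

__all__ = ["SyntheticSpec", "generate_matrix", "make_fixture_suite"]

#: entry-RMS of the leading (rank-1) component, raw-intensity units
_SIGNAL_RMS = 200.0
#: geometric decay of successive factor amplitudes
_FACTOR_DECAY = 0.55
#: support-inclusion decay scale (fraction of the axis): the support spreads
#: across the whole index range, thinning geometrically
_SUPPORT_SCALE = 0.35
#: amplitude decay scale (fraction of the axis): coefficient magnitudes fall
#: off with frequency so the spectrum decays smoothly, with genuine tails
_AMP_SCALE = 0.25


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic expression matrix (subjects × genes)."""

    m: int = 100
    n: int = 200
    rank: int = 5
    dct_sparsity: float = 0.1
    noise_sd: float = 20.0
    #: RMS per-gene expression difference between the two sample classes;
    #: realized as one of the rank-constrained factors (indicator row-loading
    #: times a smooth gene-loading), mimicking the diffuse differential
    #: expression of tumor vs normal cohorts
    class_shift: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError("dimensions must be positive")
        if not 1 <= self.rank <= min(self.m, self.n):
            raise ValueError("rank must satisfy 1 <= rank <= min(m, n)")
        if not 0.0 < self.dct_sparsity <= 1.0:
            raise ValueError("dct_sparsity must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _sparse_low_freq_vector(
    size: int, nnz: int, rng: np.random.Generator, include_dc: bool = False
) -> np.ndarray:
    """Unit-norm coefficient vector with ``nnz`` nonzeros whose support is
    drawn with geometrically decaying inclusion probability over frequency
    and whose magnitudes decay with frequency (smoothly decaying spectrum
    with tails over the full index range, as in real expression profiles)."""
    nnz = int(np.clip(nnz, 1, size))
    weights = np.exp(-np.arange(size) / max(_SUPPORT_SCALE * size, 1.0))
    if include_dc:
        support = [0]
        remaining = nnz - 1
        pool = np.arange(1, size)
        w = weights[1:]
    else:
        support = []
        remaining = nnz
        pool = np.arange(size)
        w = weights
    if remaining > 0 and pool.size > 0:
        p = w / w.sum()
        extra = rng.choice(pool, size=min(remaining, pool.size), replace=False, p=p)
        support.extend(extra.tolist())
    v = np.zeros(size)
    sup = np.asarray(support, dtype=int)
    amp = np.exp(-sup / max(_AMP_SCALE * size, 1.0))
    v[sup] = rng.standard_normal(len(sup)) * amp
    if include_dc:
        v[0] = abs(v[0]) + 1.0  # dominant positive DC weight
    nrm = np.linalg.norm(v)
    return v / nrm if nrm > 0 else v


def generate_matrix(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, np.ndarray, np.ndarray | None]:
    """Generate (noisy matrix, ground truth, labels).

    The ground truth is non-negative, has numerical rank <= spec.rank, and
    its 2-D DCT support covers about ``dct_sparsity * m * n`` coefficients
    concentrated at low frequencies.  The returned ExpressionMatrix adds
    N(0, noise_sd) noise, floored at zero (intensities cannot be negative).
    Labels (0 = first half of samples, 1 = second half) are returned only
    when ``class_shift`` is set; the class difference is itself one of the
    rank-constrained factors, so it is diffuse across genes (per-gene shift
    of RMS ``class_shift``) rather than a block shift on a few genes.
    """
    rng = np.random.default_rng(spec.seed)
    m, n, r = spec.m, spec.n, spec.rank
    basis = DCTBasisPair.for_shape((m, n))

    # Per-factor support sizes so that total nnz(Z) ~ dct_sparsity * m * n.
    budget = max(spec.dct_sparsity * m * n / r, 1.0)
    k_u = int(np.clip(round(np.sqrt(budget * m / n)), 1, m))
    k_v = int(np.clip(round(budget / k_u), 1, n))

    labels = None
    n_random = r - 1
    if spec.class_shift is not None:
        labels = (np.arange(m) >= m // 2).astype(int)
        n_random -= 1

    # Factor 1 is the pure-DC carrier: a constant positive matrix whose
    # amplitude is raised, after the other factors are drawn, until the
    # truth is non-negative with a noise-sized margin.  Raising it rescales
    # an existing rank-1 direction, so the rank bound is preserved.
    Z = np.zeros((m, n))
    amp = _SIGNAL_RMS * np.sqrt(m * n)
    for j in range(1, n_random + 1):
        u = _sparse_low_freq_vector(m, k_u, rng, include_dc=True)
        v = _sparse_low_freq_vector(n, k_v, rng, include_dc=True)
        Z += amp * _FACTOR_DECAY**j * np.outer(u, v)
    if labels is not None:
        # class factor: centered indicator row-loading times a smooth sparse
        # gene-loading; amplitude chosen so the per-gene class difference
        # has RMS class_shift in expression units
        u_class = np.where(labels == 1, 0.5, -0.5)
        u_class = u_class / np.linalg.norm(u_class)  # entries ±1/sqrt(m)
        u_class_coeff = basis.D_c @ u_class  # exact analysis coefficients
        v_class = _sparse_low_freq_vector(n, k_v, rng, include_dc=False)
        amp_class = spec.class_shift * np.sqrt(m * n) / 2.0
        Z += amp_class * np.outer(u_class_coeff, v_class)
    structure = inverse_2d(Z, basis)
    margin = max(4.0 * spec.noise_sd, 1.0)
    dc_level = max(_SIGNAL_RMS, margin - float(structure.min()))
    truth = structure + dc_level
    assert truth.min() > 0

    noisy = truth + rng.normal(0.0, spec.noise_sd, size=(m, n))
    noisy = np.maximum(noisy, 0.0)

    matrix = ExpressionMatrix(
        values=noisy,
        sample_ids=tuple(f"S{i:03d}" for i in range(m)),
        gene_ids=tuple(f"G{j:04d}" for j in range(n)),
        scale_tag="raw",
    )
    return matrix, truth, labels


#: the three standard fixtures used throughout the test-suite
FIXTURE_SPECS = {
    # exact-recovery regime: noiseless, 25 nonzero DCT coefficients
    "exact32": SyntheticSpec(
        m=32, n=32, rank=5, dct_sparsity=25 / 1024, noise_sd=0.0, seed=101
    ),
    # the standard noisy benchmark matrix
    "noisy100x200": SyntheticSpec(
        m=100, n=200, rank=5, dct_sparsity=0.1, noise_sd=20.0, seed=202
    ),
    # two well-separated classes for the classification protocol
    "twoclass60x50": SyntheticSpec(
        m=60,
        n=50,
        rank=4,
        dct_sparsity=0.04,
        noise_sd=20.0,
        class_shift=40.0,
        seed=303,
    ),
}


def make_fixture_suite(out_dir) -> list[Path]:
    """Write the standard small fixtures (matrix TSVs, a labels TSV for the
    two-class case, and a metadata JSON) and return the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    meta = {}
    for name, spec in FIXTURE_SPECS.items():
        matrix, truth, labels = generate_matrix(spec)
        path = out_dir / f"{name}.tsv"
        write_matrix(matrix, path, float_format="%.10g")
        written.append(path)
        meta[name] = asdict(spec)
        if labels is not None:
            lab_path = out_dir / f"{name}_labels.tsv"
            with open(lab_path, "w") as fh:
                for sid, lab in zip(matrix.sample_ids, labels):
                    fh.write(f"{sid}\t{lab}\n")
            written.append(lab_path)
    meta_path = out_dir / "fixtures.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    written.append(meta_path)
    return written
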