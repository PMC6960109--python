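"""Reading, writing and preprocessing of expression matrices.

Matrices are held internally as subjects × genes (rows = samples).  On disk
the default layout is the usual genes-in-rows delimited text: a header row of
sample ids and a first column of gene/probe ids; ``transpose=True`` accepts
files already laid out samples-in-rows.  Missing entries are marked by a
sentinel string (default ``"NA"``; empty fields count as missing), are
zero-filled in the value matrix, and are tracked in a separate
:class:`~dsnn.transforms.ObservationMask`.

Preprocessing follows the standard microarray pipeline: probes mapping to the
same gene symbol are averaged (missing-aware), and raw intensities may be
compressed with an entrywise log10(x + 1) to tame their dynamic range before
imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .transforms import ObservationMask

__all__ = [
    "ExpressionMatrix",
    "ProbeMap",
    "read_matrix",
    "write_matrix",
    "read_probe_map",
    "collapse_probes",
    "log_transform",
]

logger = logging.getLogger(__name__)

RAW = "raw"
LOG10P1 = "log10p1"


@dataclass(frozen=True)
class ExpressionMatrix:
    """Real-valued subjects × genes expression matrix with identifiers.

    ``scale_tag`` records whether values are raw intensities (``"raw"``,
    non-negative) or log10(x + 1)-compressed (``"log10p1"``).  Imputed
    matrices may carry small negative estimates on the raw scale; they set
    ``allow_negative=True`` to mark that the non-negativity contract of
    measured data no longer applies.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    scale_tag: str = RAW
    allow_negative: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("expression values must form a 2-D matrix")
        sample_ids = tuple(str(s) for s in self.sample_ids)
        gene_ids = tuple(str(g) for g in self.gene_ids)
        if len(sample_ids) != values.shape[0]:
            raise ValueError(
                f"{len(sample_ids)} sample ids for {values.shape[0]} rows"
            )
        if len(gene_ids) != values.shape[1]:
            raise ValueError(
                f"{len(gene_ids)} gene ids for {values.shape[1]} columns"
            )
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        if self.scale_tag not in (RAW, LOG10P1):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        if self.scale_tag == RAW and not self.allow_negative and (values < 0).any():
            raise ValueError("raw-scale expression values must be >= 0")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "gene_ids", gene_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, scale_tag: str | None = None) -> "ExpressionMatrix":
        return replace(
            self, values=values, scale_tag=scale_tag or self.scale_tag
        )


@dataclass(frozen=True)
class ProbeMap:
    """Mapping from microarray probe ids to gene symbols."""

    probe_ids: tuple[str, ...]
    gene_symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        probes = tuple(str(p) for p in self.probe_ids)
        genes = tuple(str(g) for g in self.gene_symbols)
        if len(probes) != len(genes):
            raise ValueError("probe_ids and gene_symbols differ in length")
        if len(set(probes)) != len(probes):
            raise ValueError("duplicate probe ids in probe map")
        if any(not g for g in genes):
            raise ValueError("empty gene symbol in probe map")
        object.__setattr__(self, "probe_ids", probes)
        object.__setattr__(self, "gene_symbols", genes)

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.probe_ids, self.gene_symbols))


def read_matrix(
    path,
    missing_sentinel: str = "NA",
    sep: str = "\t",
    transpose: bool = False,
    scale_tag: str = RAW,
) -> tuple[ExpressionMatrix, ObservationMask]:
    """Read a delimited expression matrix and its missingness mask.

    The default layout is genes in rows (first column gene/probe id, header
    row of sample ids); ``transpose=True`` reads files already laid out
    samples × genes.  Cells equal to ``missing_sentinel`` or empty are
    missing: the mask is 0 there and the value is set to 0.
    """
    # pandas silently pads short rows and mangles duplicate header names, so
    # validate the raw shape first.
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
        n_fields = len(header)
        if len(set(header[1:])) != len(header[1:]):
            raise ValueError(f"duplicate ids in the header of {path}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            if len(line.rstrip("\n").split(sep)) != n_fields:
                raise ValueError(
                    f"ragged row in {path}: line {lineno} has "
                    f"{len(line.rstrip(chr(10)).split(sep))} fields, expected {n_fields}"
                )
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            index_col=0,
            na_values=[missing_sentinel],
            keep_default_na=False,
            dtype=str,
            skip_blank_lines=False,
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    numeric = df.apply(pd.to_numeric, errors="raise")
    if not transpose:
        numeric = numeric.T  # disk layout genes × samples -> samples × genes
    sample_ids = [str(s) for s in numeric.index]
    gene_ids = [str(g) for g in numeric.columns]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"duplicate sample ids in {path}")
    values = numeric.to_numpy(dtype=float)
    observed = np.isfinite(values)
    values = np.where(observed, values, 0.0)
    matrix = ExpressionMatrix(
        values=values,
        sample_ids=sample_ids,
        gene_ids=gene_ids,
        scale_tag=scale_tag,
    )
    return matrix, ObservationMask(observed.astype(np.uint8))


def write_matrix(
    matrix: ExpressionMatrix,
    path,
    mask: ObservationMask | None = None,
    missing_sentinel: str = "NA",
    sep: str = "\t",
    transpose: bool = False,
    float_format: str = "%.6g",
) -> None:
    """Write a matrix (genes in rows by default) with the sentinel at masked
    positions.  Round-trips exactly with :func:`read_matrix` at the default
    6-significant-digit precision for values that fit it."""
    values = matrix.values.astype(object)
    if mask is not None:
        if mask.shape != matrix.shape:
            raise ValueError("mask shape does not match matrix shape")
        values = values.copy()
        values[~mask.as_bool()] = np.nan
    df = pd.DataFrame(values, index=matrix.sample_ids, columns=matrix.gene_ids)
    if not transpose:
        df = df.T
    df.to_csv(path, sep=sep, na_rep=missing_sentinel, float_format=float_format)


def read_probe_map(path, sep: str = "\t") -> ProbeMap:
    """Read a 2-column (probe_id, gene_symbol) table; a header is optional and
    detected by the literal column names."""
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment=None)
    if df.shape[1] < 2:
        raise ValueError(f"probe map {path} needs 2 columns, found {df.shape[1]}")
    first = [str(x).lower() for x in df.iloc[0, :2]]
    if first == ["probe_id", "gene_symbol"]:
        df = df.iloc[1:]
    return ProbeMap(
        probe_ids=tuple(df.iloc[:, 0].astype(str)),
        gene_symbols=tuple(df.iloc[:, 1].astype(str)),
    )


def collapse_probes(
    probe_matrix: ExpressionMatrix,
    probe_map: ProbeMap,
    mask: ObservationMask | None = None,
) -> tuple[ExpressionMatrix, ObservationMask]:
    """Collapse probe-level columns to gene-level columns by averaging.

    Probes mapping to the same gene symbol are averaged per sample over their
    non-missing entries only; if every probe for a gene is missing at a
    sample, the output entry is missing.  Probes absent from the map are
    dropped (logged).  Sample ids and count are preserved.
    """
    mapping = probe_map.as_dict()
    kept = [i for i, p in enumerate(probe_matrix.gene_ids) if p in mapping]
    dropped = len(probe_matrix.gene_ids) - len(kept)
    if not kept:
        raise ValueError("no probe ids in the matrix appear in the probe map")
    if dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", dropped)

    observed = (
        mask.as_bool()
        if mask is not None
        else np.ones(probe_matrix.shape, dtype=bool)
    )
    genes = sorted({mapping[probe_matrix.gene_ids[i]] for i in kept})
    gene_pos = {g: j for j, g in enumerate(genes)}
    m = probe_matrix.shape[0]
    sums = np.zeros((m, len(genes)))
    counts = np.zeros((m, len(genes)))
    for i in kept:
        j = gene_pos[mapping[probe_matrix.gene_ids[i]]]
        obs = observed[:, i]
        sums[:, j] += np.where(obs, probe_matrix.values[:, i], 0.0)
        counts[:, j] += obs
    out_observed = counts > 0
    with np.errstate(invalid="ignore"):
        means = np.where(out_observed, sums / np.maximum(counts, 1), 0.0)
    collapsed = ExpressionMatrix(
        values=means,
        sample_ids=probe_matrix.sample_ids,
        gene_ids=tuple(genes),
        scale_tag=probe_matrix.scale_tag,
    )
    return collapsed, ObservationMask(out_observed.astype(np.uint8))


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Entrywise x -> log10(x + 1) to compress the dynamic range of raw
    intensities; rejected when the matrix is already on the log scale."""
    if matrix.scale_tag != RAW:
        raise ValueError("log_transform requires a raw-scale matrix")
    if (matrix.values < 0).any():
        raise ValueError("log_transform requires non-negative entries")
    return matrix.with_values(np.log10(matrix.values + 1.0), scale_tag=LOG10P1)
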