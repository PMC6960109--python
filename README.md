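# dsnn-impute

Two-stage missing-value imputation for gene-expression matrices, with the
masking/NMSE evaluation protocol and classification-based validation that go
with it.

Microarray expression matrices routinely contain missing entries (bad
spots, scratched slides, low-quality scans). Discarding affected genes
loses information; re-assaying is expensive. This package imputes the
missing values by exploiting two structural properties of expression data:
expression profiles vary slowly across both genes and subjects, so the
matrix is sparse (compressible) in the 2-D discrete cosine transform
domain, and genes are co-regulated, so the matrix is approximately low
rank.

It is aimed at computational biologists who have a subjects × genes
intensity matrix with missing entries and want a complete matrix for
downstream analysis (classification, driver-gene ranking, enrichment), and
at methods researchers who want a tested reference implementation of
DCT-domain compressive-sensing imputation with nuclear-norm denoising.

## Method

Let `Y` be the m × n (subjects × genes) matrix, observed on the index set
given by the 0/1 mask `Φ` (0 = missing), and let `D_c`, `D_r` be orthonormal
DCT-II matrices.

**Stage 1 — compressive-sensing recovery.** The observed entries are
treated as compressive measurements of the full matrix, which is assumed
sparse in the 2-D DCT domain (double sparsity: rows and columns jointly).
The synthesis-prior basis-pursuit-denoise problem

    min ‖Z‖₁   subject to   ‖Φ∘(D_cᵀ Z D_r) − Φ∘Y‖₂ ≤ σ

is solved matrix-free by a spectral projected-gradient method on Lasso
subproblems with Newton root-finding on the Pareto curve; `σ = 0` (exact
interpolation of observed entries) is the default. The Stage-1 estimate is
`X̃ = D_cᵀ Z D_r`.

**Stage 2 — nuclear-norm denoising.** `X̃` is treated as a noisy version of
the underlying low-rank matrix. Entries deviating from their gene's
observed mean by at least `λ₂` observed standard deviations (`λ₂ = 0.2` by
default) are zeroed and re-initialized at random, then a Split-Bregman loop
with singular-value soft-thresholding (threshold `τ = 100` expression
units by default) re-estimates them:

    W ← SVT_τ(X̂ + B);   X̂ ← X̃_rec + I_zeroed∘W;   B ← X̂ + B − W

Retained Stage-1 values pass through unchanged; the final output is
complete by construction.

**Evaluation.** On a fully observed matrix, entries are dropped uniformly
at random (10–90% observability), imputed, and scored by
`NMSE = ‖X − X̂‖_F² / ‖X‖_F²`, averaged over repeats, for the full method
and its two single-stage ablations. Validation trains normal-vs-cancer
classifiers (KNN k = 3, linear SVM, with PCA / chi-square / mutual-information
feature reduction) on observed vs imputed matrices under repeated
stratified 5-fold cross-validation, reporting accuracy and support-weighted
F1.

## Worked example

```python
import numpy as np
from dsnn import (DSNNConfig, dsnn_impute, nmse, random_mask,
                  SyntheticSpec, generate_matrix)

# an expression-like matrix: low rank, decaying DCT spectra, noisy
matrix, truth, _ = generate_matrix(SyntheticSpec(m=100, n=200, seed=202))

# hide half the entries, then impute
mask = random_mask(100, 200, observed_fraction=0.5, seed=7)
imputed = dsnn_impute(matrix, mask, DSNNConfig(seed=7))

zero_fill = np.where(mask.as_bool(), matrix.values, 0.0)
print(f"NMSE zero-filled: {nmse(matrix.values, zero_fill):.4f}")
print(f"NMSE imputed:     {nmse(matrix.values, imputed.values):.4f}")
```

prints

```
NMSE zero-filled: 0.4968
NMSE imputed:     0.0361
```

i.e. leaving the missing half at zero is ~50% relative squared error, while
the imputed matrix is within ~4% of the original. The same pipeline runs
from the shell:

```bash
dsnn impute --input X.tsv --output Xhat.tsv --mode dsnn --seed 1
dsnn evaluate --input X.tsv --fractions 0.1:0.9:0.2 --repeats 5 \
              --modes dsnn,stage1,stage2 --out records.tsv
dsnn simulate --out fixtures/
dsnn classify --input X.tsv --labels labels.tsv --ratios 0.3 --out clf.tsv
```

Input files are delimited text with genes in rows, a header of sample ids,
and `NA` (configurable) for missing cells; `dsnn impute --transpose` accepts
samples-in-rows layouts. Probe-level matrices can be collapsed to gene
symbols with `dsnn.collapse_probes` and a 2-column probe map, and raw
intensities compressed with `dsnn.log_transform` (entrywise log10(x+1))
before imputation.

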