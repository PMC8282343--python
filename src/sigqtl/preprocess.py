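"""Expression preprocessing: gene filtering, log-CPM, confounder PCs, residuals.

The filtering rule drops a gene when its expression falls below 6 reads or
0.1 counts per million in at least 20% of samples (equivalently, a gene is
kept only if it clears both thresholds in strictly more than 80% of
samples).  Sex-chromosome genes are removed regardless.  Normalization is
the log2-CPM transform (prior count 0.5, library size + 1); downstream fits
are unweighted, so no precision weights are computed.  Technical/biological
covariates are summarised by their top principal components and regressed
out of the normalized expression gene by gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEX_CHROMS = {"X", "Y", "chrX", "chrY", "x", "y"}


class PreprocessError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Counts plus derived normalized/residualized views, gene annotation."""

    counts: pd.DataFrame  # genes x samples, nonnegative integers
    gene_meta: pd.DataFrame | None = None  # index gene_id; chrom, tss, strand
    normalized: pd.DataFrame | None = None
    residual: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if (c < 0).any():
            raise PreprocessError("counts must be nonnegative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_genes(self, genes: pd.Index) -> "ExpressionMatrix":
        return ExpressionMatrix(
            counts=self.counts.loc[genes],
            gene_meta=None if self.gene_meta is None else self.gene_meta.loc[genes],
            normalized=None if self.normalized is None else self.normalized.loc[genes],
            residual=None if self.residual is None else self.residual.loc[genes],
        )


@dataclass
class CovariateSet:
    """Raw sample covariates and (optionally) their top principal components."""

    raw: pd.DataFrame  # samples x covariates; may mix numeric/categorical
    pcs: pd.DataFrame | None = None  # samples x k
    variance_explained: np.ndarray | None = None
    dropped_constant: list[str] = field(default_factory=list)


def filter_genes(
    expr: ExpressionMatrix,
    min_count: float = 6,
    min_cpm: float = 0.1,
    min_fraction: float = 0.8,
) -> ExpressionMatrix:
    """Drop weakly expressed genes and sex-chromosome genes.

    A gene is kept iff (count >= min_count AND cpm >= min_cpm) in strictly
    more than ``min_fraction`` of samples.  CPM uses the library sizes of
    the input count matrix.  Idempotent up to the library-size recomputation
    on the filtered matrix (the keep rule is evaluated on input libsizes).
    """
    counts = expr.counts
    libsize = counts.sum(axis=0).to_numpy(float)
    if (libsize <= 0).any():
        bad = counts.columns[libsize <= 0][0]
        raise PreprocessError(f"sample {bad} has zero library size")

    keep = pd.Series(True, index=counts.index)
    if expr.gene_meta is not None and "chrom" in expr.gene_meta:
        chrom = expr.gene_meta["chrom"].astype(str)
        keep &= ~chrom.isin(SEX_CHROMS)

    cpm = counts.to_numpy(float) / libsize[None, :] * 1e6
    ok = (counts.to_numpy(float) >= min_count) & (cpm >= min_cpm)
    frac = ok.mean(axis=1)
    keep &= pd.Series(frac > min_fraction, index=counts.index)

    if not keep.any():
        raise PreprocessError("no genes pass the expression filter")
    return expr.subset_genes(counts.index[keep])


def normalize_logcpm(expr: ExpressionMatrix, prior_count: float = 0.5) -> ExpressionMatrix:
    """log2-CPM: log2((count + prior) / (libsize + 1) * 1e6)."""
    counts = expr.counts
    libsize = counts.sum(axis=0).to_numpy(float)
    if (libsize <= 0).any():
        bad = counts.columns[libsize <= 0][0]
        raise PreprocessError(f"sample {bad} has zero library size")
    logcpm = np.log2(
        (counts.to_numpy(float) + prior_count) / (libsize[None, :] + 1.0) * 1e6
    )
    return ExpressionMatrix(
        counts=counts,
        gene_meta=expr.gene_meta,
        normalized=pd.DataFrame(logcpm, index=counts.index, columns=counts.columns),
        residual=expr.residual,
    )


def encode_covariates(raw: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Numeric design from a raw covariate table.

    Categorical (object/category/bool) columns are one-hot encoded with the
    first level dropped; missing numeric values are median-imputed; constant
    columns are dropped (returned in the second element).
    """
    cols = {}
    for name in raw.columns:
        col = raw[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
            dummies = pd.get_dummies(col.astype(str), prefix=name, drop_first=True)
            for dcol in dummies.columns:
                cols[dcol] = dummies[dcol].astype(float)
        else:
            vals = col.astype(float)
            if vals.isna().any():
                vals = vals.fillna(vals.median())
            cols[name] = vals
    enc = pd.DataFrame(cols, index=raw.index)
    dropped = [c for c in enc.columns if enc[c].nunique() <= 1]
    return enc.drop(columns=dropped), dropped


def covariate_pcs(cov: CovariateSet, k: int = 3) -> CovariateSet:
    """Top-k principal components of the z-scored covariate matrix."""
    enc, dropped = encode_covariates(cov.raw)
    if enc.shape[1] == 0:
        raise PreprocessError("no usable covariate columns after encoding")
    X = enc.to_numpy(float)
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    n = X.shape[0]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2 / (n - 1)
    total = var.sum()
    k = min(k, len(s))
    pcs = U[:, :k] * s[:k]
    # deterministic sign: largest-magnitude loading positive
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            pcs[:, j] *= -1
    return CovariateSet(
        raw=cov.raw,
        pcs=pd.DataFrame(
            pcs, index=cov.raw.index, columns=[f"cvPC{i+1}" for i in range(k)]
        ),
        variance_explained=var[:k] / total,
        dropped_constant=dropped,
    )


def _design(cov: pd.DataFrame) -> np.ndarray:
    X = np.column_stack([np.ones(len(cov)), cov.to_numpy(float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by pivoted QR-style elimination
        bad = []
        keep = [0]
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) == len(keep) + 1:
                keep.append(j)
            else:
                bad.append(cov.columns[j - 1])
        raise PreprocessError(f"covariate matrix is rank-deficient; collinear: {bad}")
    return X


def residualize(expr: ExpressionMatrix, covariates: pd.DataFrame) -> ExpressionMatrix:
    """Per-gene OLS residuals of normalized expression on intercept+covariates."""
    if expr.normalized is None:
        raise PreprocessError("normalize_logcpm must run before residualize")
    if not expr.normalized.columns.equals(pd.Index(covariates.index)):
        if set(expr.normalized.columns) != set(covariates.index):
            raise PreprocessError("covariate rows do not match expression samples")
        covariates = covariates.loc[expr.normalized.columns]
    X = _design(covariates)
    Y = expr.normalized.to_numpy(float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ beta).T
    return ExpressionMatrix(
        counts=expr.counts,
        gene_meta=expr.gene_meta,
        normalized=expr.normalized,
        residual=pd.DataFrame(
            resid, index=expr.normalized.index, columns=expr.normalized.columns
        ),
    )


def expression_pcs(expr: ExpressionMatrix, k: int) -> pd.DataFrame:
    """Top-k PCs of residual (or normalized) expression across samples."""
    mat = expr.residual if expr.residual is not None else expr.normalized
    if mat is None:
        raise PreprocessError("no normalized/residual expression available")
    X = mat.to_numpy(float).T  # samples x genes
    if k >= X.shape[0]:
        raise PreprocessError(f"k={k} must be < n_samples={X.shape[0]}")
    if k == 0:
        return pd.DataFrame(index=mat.columns)
    Xc = X - X.mean(0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    pcs = U[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            pcs[:, j] *= -1
    return pd.DataFrame(
        pcs, index=mat.columns, columns=[f"exprPC{i+1}" for i in range(k)]
    )
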