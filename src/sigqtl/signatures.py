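"""Transcriptional signatures: elastic-net phenotype models on expression.

A transcriptional signature is a sparse linear model predicting a measured
variable (psychosocial, clinical, blood composition, ...) from residualized
gene expression,

    variable = intercept + b1*E(gene1) + b2*E(gene2) + ... ,

fit with elastic-net regularisation at a relaxed mixing parameter
(alpha = 0.1) so groups of co-regulated genes enter the model together.
Per-variable models are selected by cross-validated MSE along a descending
lambda path (leave-one-out by default), and the selected model's prediction
is then *imputed for every sample in the cohort* — including samples whose
variable was directly measured.  The imputed value is a denoised version of
the variable: measurement noise is replaced by the reproducible
transcriptome-correlated component, which is also what makes it usable as
the environment in downstream interaction tests.

The fraction of variance explained is defined from the cross-validated MSE,
r2 = 1 - cv_mse / var(y); it can be negative and is *not* clamped.  A
signature is called significant when r2 >= 0.01 (the 1%-of-variance rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _enet
from .preprocess import ExpressionMatrix


class SignatureError(ValueError):
    pass


@dataclass
class SignatureModel:
    """One variable's elastic-net signature model (original-scale weights)."""

    variable: str
    weights: pd.Series  # nonzero gene weights only
    intercept: float
    alpha: float
    lambda_: float
    cv_mse: float
    cv_mse_sd: float
    r2: float
    n_train: int
    in_sample_r2: float
    gene_subset: list[str] | None = None
    cv_predictions: pd.Series | None = None
    lambda_path: np.ndarray | None = None
    cv_mse_path: np.ndarray | None = None

    def predict(self, expr: ExpressionMatrix) -> pd.Series:
        """Imputed signature values for every sample of ``expr``."""
        if expr.residual is None:
            raise SignatureError("expression must be residualized before imputation")
        missing = [g for g in self.weights.index if g not in expr.residual.index]
        if missing:
            raise SignatureError(
                f"model for {self.variable!r} references genes absent from "
                f"expression: {missing[:5]}"
            )
        if len(self.weights):
            E = expr.residual.loc[self.weights.index].to_numpy()
            vals = self.intercept + self.weights.to_numpy() @ E
        else:
            vals = np.full(expr.residual.shape[1], self.intercept)
        return pd.Series(vals, index=expr.residual.columns, name=self.variable)


@dataclass
class SignatureMatrix:
    """Imputed signature values for the whole cohort plus selection flags."""

    values: pd.DataFrame  # samples x variables
    selected: dict[str, bool]
    source_models: dict[str, SignatureModel]
    r2_threshold: float = 0.01

    def selected_variables(self) -> list[str]:
        return [v for v, s in self.selected.items() if s]


def fit_signature(
    y: pd.Series,
    expr: ExpressionMatrix,
    alpha: float = 0.1,
    gene_subset: list[str] | None = None,
    cv: str = "loo",
    n_folds: int = 10,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
    selection: str = "min",
    tol: float = 1e-6,
    max_iter: int = 1000,
    min_train: int = 20,
    kfold_patience: int = 15,
) -> SignatureModel:
    """Fit one transcriptional signature with cross-validated lambda choice.

    ``cv="loo"`` performs true leave-one-out (n per-fold path solves, the
    default, following the reference procedure); ``cv="kfold"`` uses
    ``n_folds`` contiguous folds with early stopping along the path, for
    bulk fits.  ``selection`` picks the lambda with minimal CV MSE ("min")
    or the largest lambda within one SE of it ("1se").
    """
    if expr.residual is None:
        raise SignatureError("expression must be residualized before fitting")
    y = y.reindex(expr.residual.columns)
    train_mask = y.notna().to_numpy()
    n = int(train_mask.sum())
    if n < min_train:
        raise SignatureError(
            f"{y.name!r}: {n} non-missing values < minimum of {min_train}"
        )
    yt = y.to_numpy(float)[train_mask]
    if np.ptp(yt) == 0:
        raise SignatureError(f"{y.name!r} is constant on the training samples")

    resid = expr.residual
    if gene_subset is not None:
        present = [g for g in gene_subset if g in resid.index]
        if not present:
            raise SignatureError("gene_subset has no genes in the expression matrix")
        resid = resid.loc[present]
    genes = resid.index

    X = resid.to_numpy().T[train_mask]  # n x p
    mu = X.mean(0)
    sd = X.std(0, ddof=0)
    ok = sd > 0
    Xs = (X[:, ok] - mu[ok]) / sd[ok]
    y_mean = yt.mean()
    yc = yt - y_mean

    lambdas = _enet.lambda_grid(Xs, yc, alpha, n_lambda, lambda_min_ratio)
    if cv == "loo":
        folds = _enet.make_folds(n, n)
        patience = 0
    elif cv == "kfold":
        folds = _enet.make_folds(n, min(n_folds, n))
        patience = kfold_patience
    else:
        raise SignatureError(f"unknown cv scheme {cv!r}")
    G = Xs.T @ Xs
    cv_mse, cv_sd, pred = _enet.cv_path(
        Xs, yc, lambdas, alpha, folds, tol=tol, max_iter=max_iter, G=G,
        patience=patience,
    )
    l_min = int(np.argmin(cv_mse))
    if selection == "1se":
        limit = cv_mse[l_min] + cv_sd[l_min]
        l_star = int(np.where(cv_mse <= limit)[0][0])  # largest such lambda
    elif selection == "min":
        l_star = l_min
    else:
        raise SignatureError(f"unknown selection rule {selection!r}")

    # final model: path solved only down to the chosen lambda
    betas = _enet.enet_path_gram(
        G, Xs.T @ yc, n, lambdas[: l_star + 1], alpha, float(yc @ yc),
        tol=tol, max_iter=max_iter,
    )
    b_std = betas[:, -1]
    b_orig = np.zeros(len(genes))
    b_orig[ok] = b_std / sd[ok]
    intercept = float(y_mean - (b_orig[ok] * mu[ok]).sum())

    fitted = Xs @ b_std + y_mean
    ss_res = float(((yt - fitted) ** 2).sum())
    var_y = float(np.var(yt, ddof=1))
    in_r2 = 1.0 - ss_res / (var_y * (n - 1))

    nz = b_orig != 0
    weights = pd.Series(b_orig[nz], index=genes[nz], name=y.name)
    cv_pred = pd.Series(
        pred[:, l_star] + y_mean, index=y.index[train_mask], name=y.name
    )
    return SignatureModel(
        variable=str(y.name),
        weights=weights,
        intercept=intercept,
        alpha=alpha,
        lambda_=float(lambdas[l_star]),
        cv_mse=float(cv_mse[l_star]),
        cv_mse_sd=float(cv_sd[l_star]) if np.isfinite(cv_sd[l_star]) else 0.0,
        r2=1.0 - float(cv_mse[l_star]) / var_y,
        n_train=n,
        in_sample_r2=in_r2,
        gene_subset=list(gene_subset) if gene_subset is not None else None,
        cv_predictions=cv_pred,
        lambda_path=lambdas,
        cv_mse_path=cv_mse,
    )


def fit_all_signatures(
    phenotypes: pd.DataFrame,
    expr: ExpressionMatrix,
    alpha: float = 0.1,
    cv: str = "loo",
    skip_errors: bool = True,
    **kwargs,
) -> dict[str, SignatureModel]:
    """Fit a signature per phenotype column; unfittable columns are skipped."""
    models: dict[str, SignatureModel] = {}
    for var in phenotypes.columns:
        try:
            models[var] = fit_signature(phenotypes[var], expr, alpha=alpha,
                                        cv=cv, **kwargs)
        except SignatureError:
            if not skip_errors:
                raise
            warnings.warn(f"skipping signature for {var!r}", stacklevel=2)
    return models


def impute_signatures(
    models: list[SignatureModel] | dict[str, SignatureModel],
    expr: ExpressionMatrix,
    r2_threshold: float = 0.01,
) -> SignatureMatrix:
    """Impute every model on the full cohort (denoising: training samples too).

    ``selected`` flags variables whose cross-validated r2 meets the
    threshold (default: at least 1% of variance explained); unselected
    variables are still imputed but flagged.
    """
    if isinstance(models, dict):
        models = list(models.values())
    if not models:
        raise SignatureError("no signature models given")
    cols = {m.variable: m.predict(expr) for m in models}
    values = pd.DataFrame(cols)
    selected = {m.variable: bool(m.r2 >= r2_threshold) for m in models}
    return SignatureMatrix(
        values=values,
        selected=selected,
        source_models={m.variable: m for m in models},
        r2_threshold=r2_threshold,
    )


def compare_restricted(
    y: pd.Series,
    expr: ExpressionMatrix,
    full: SignatureModel,
    gene_subset: list[str],
    **fit_kwargs,
) -> tuple[float, float, int]:
    """r2 of the full model vs a model restricted to a fixed gene panel.

    Used to benchmark the unrestricted signature against a published panel
    (e.g. the 53-gene conserved transcriptional response to adversity);
    returns (r2_full, r2_restricted, n_subset_genes_present).
    """
    if expr.residual is None:
        raise SignatureError("expression must be residualized")
    present = [g for g in gene_subset if g in expr.residual.index]
    if not present:
        raise SignatureError("gene_subset has no genes in the expression matrix")
    restricted = fit_signature(y, expr, alpha=full.alpha, gene_subset=present,
                               **fit_kwargs)
    return full.r2, restricted.r2, len(present)


def correlate_signatures(
    sig: SignatureMatrix, p_mask: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson correlations between selected signatures.

    Returns (r, p, masked) DataFrames over the selected variables; ``masked``
    is True where p > p_mask (or where a signature is constant).  r is
    symmetric with unit diagonal.
    """
    sel = sig.selected_variables()
    if len(sel) < 2:
        raise SignatureError("need at least 2 selected signatures to correlate")
    V = sig.values[sel]
    k = len(sel)
    r = np.eye(k)
    p = np.zeros((k, k))
    masked = np.zeros((k, k), bool)
    const = [v for v in sel if np.ptp(V[v].to_numpy()) == 0]
    if const:
        warnings.warn(f"constant signatures masked: {const}", stacklevel=2)
    for i in range(k):
        for j in range(i + 1, k):
            if sel[i] in const or sel[j] in const:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                masked[i, j] = masked[j, i] = True
                continue
            ri, pi = stats.pearsonr(V[sel[i]], V[sel[j]])
            r[i, j] = r[j, i] = ri
            p[i, j] = p[j, i] = pi
            if pi > p_mask:
                masked[i, j] = masked[j, i] = True
    idx = pd.Index(sel)
    return (
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
        pd.DataFrame(masked, index=idx, columns=idx),
    )


def validate_longitudinal(
    obs1: pd.Series,
    obs2: pd.Series,
    sig1: pd.Series,
    sig2: pd.Series,
    min_pairs: int = 5,
) -> tuple[float, float]:
    """Spearman correlation of observed vs imputed longitudinal changes.

    Compares (obs2 - obs1) with (sig2 - sig1) over samples measured at both
    waves; the wave-2 signature must come from expression not in the
    training set.  Returns (rho, p).
    """
    common = obs1.dropna().index.intersection(obs2.dropna().index)
    common = common.intersection(sig1.index).intersection(sig2.index)
    if len(common) < min_pairs:
        raise SignatureError(
            f"only {len(common)} paired samples; need >= {min_pairs}"
        )
    d_obs = obs2[common] - obs1[common]
    d_sig = sig2[common] - sig1[common]
    rho, p = stats.spearmanr(d_obs, d_sig)
    return float(rho), float(p)
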