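"""Gene-by-environment interaction eQTL mapping.

For each eGene's lead cis variant and each transcriptional signature, fits

    expression ~ dosage + signature + dosage:signature  (+ optional covariates)

by OLS on residualized expression, with the signature quantile-normalized
(rank-based inverse normal transform) to damp outliers.  Because thousands
of interaction tests share structure, the observed interaction p-values are
corrected against a pooled permutation null: genotype dosages are permuted
(keeping the expression-signature pairing intact), the model refit, and the
interaction p-values pooled across all lead pairs of a signature form the
empirical null.  Storey q-values control FDR within each signature
separately, applied to the permutation-corrected p-values.

The module also hosts the shared statistical machinery (Storey q-values,
empirical p-values, the rank-normal transform) and the replication /
TWAS-overlap bookkeeping.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline


class GxeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# shared statistics
# ---------------------------------------------------------------------------

def qvalues(
    p: np.ndarray,
    pi0: float | None = None,
    lambdas: np.ndarray | None = None,
) -> np.ndarray:
    """Storey q-values.

    pi0 (the null proportion) is estimated on a lambda grid 0.05..0.95 with
    a cubic smoothing-spline extrapolation at the right end, clipped to
    (0, 1]; pass ``pi0=1.0`` to recover Benjamini-Hochberg exactly.  Falls
    back to pi0 = 1 when the smoother cannot be fit.
    """
    p = np.asarray(p, float)
    if p.ndim != 1:
        raise GxeError("p must be a 1-d array")
    if len(p) and (np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p))):
        raise GxeError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    if pi0 is None:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        pi0_l = np.array([np.mean(p > l) / (1.0 - l) for l in lambdas])
        try:
            spl = UnivariateSpline(lambdas, pi0_l, k=3)
            pi0 = float(spl(lambdas[-1]))
        except Exception:
            pi0 = 1.0
        if not np.isfinite(pi0) or pi0 <= 0:
            pi0 = 1.0
        pi0 = min(pi0, 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * ranked * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def empirical_pvalues(obs: np.ndarray, null: np.ndarray) -> np.ndarray:
    """p = (1 + #{null <= obs}) / (1 + n_null), vectorized over obs."""
    null_sorted = np.sort(np.asarray(null, float))
    counts = np.searchsorted(null_sorted, np.asarray(obs, float), side="right")
    return (1.0 + counts) / (1.0 + len(null_sorted))


def inverse_normal_transform(x: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Rank-based inverse normal transform with the Blom offset.

    Maps values to standard-normal quantiles at (rank - 3/8) / (n + 1/4);
    ties get average ranks; NaNs are preserved.  Monotone transforms of the
    input yield identical output.
    """
    arr = np.asarray(x, float)
    out = np.full(arr.shape, np.nan)
    finite = np.isfinite(arr)
    vals = arr[finite]
    n = len(vals)
    if n < 3:
        raise GxeError("need at least 3 finite values to quantile-normalize")
    if np.ptp(vals) == 0:
        raise GxeError("all values identical; cannot quantile-normalize")
    ranks = stats.rankdata(vals, method="average")
    out[finite] = stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index, name=x.name)
    return out


# ---------------------------------------------------------------------------
# interaction model
# ---------------------------------------------------------------------------

TERMS = ("intercept", "dosage", "signature", "interaction")


def fit_interaction(
    expr_g: np.ndarray,
    dosage: np.ndarray,
    env: np.ndarray,
    covariates: np.ndarray | None = None,
) -> dict[str, float]:
    """One OLS interaction fit; returns named estimates, SEs and p-values.

    Design: intercept + dosage + env + dosage*env, with optional covariate
    columns prepended as main effects.  ``env`` is expected to be already
    quantile-normalized.  Raises on a rank-deficient design, naming the
    offending term.
    """
    y = np.asarray(expr_g, float)
    d = np.asarray(dosage, float)
    e = np.asarray(env, float)
    if not (len(y) == len(d) == len(e)):
        raise GxeError("expression, dosage and environment lengths differ")
    cols = [np.ones_like(y), d, e, d * e]
    names = list(TERMS)
    if covariates is not None:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != len(y):
            raise GxeError("covariate shape does not match samples")
        for ci in range(C.shape[1]):
            cols.insert(1 + ci, C[:, ci])
            names.insert(1 + ci, f"cov{ci+1}")
    X = np.column_stack(cols)
    n, k = X.shape
    if n <= k:
        raise GxeError(f"too few samples ({n}) for {k} design columns")
    if np.linalg.matrix_rank(X) < k:
        keep = [0]
        for j in range(1, k):
            if np.linalg.matrix_rank(X[:, keep + [j]]) == len(keep) + 1:
                keep.append(j)
            else:
                raise GxeError(f"design is rank-deficient at term {names[j]!r}")
    XtX = X.T @ X
    Xty = X.T @ y
    b = np.linalg.solve(XtX, Xty)
    resid = y - X @ b
    sigma2 = float(resid @ resid) / (n - k)
    se = np.sqrt(np.diag(np.linalg.inv(XtX)) * sigma2)
    tvals = b / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), n - k)
    out: dict[str, float] = {"n": float(n)}
    for name, bi, si, pi in zip(names, b, se, pvals):
        if name.startswith("cov"):
            continue
        out[f"b_{name}"] = float(bi)
        out[f"se_{name}"] = float(si)
        out[f"p_{name}"] = float(pi)
    return out


def batch_interaction(
    Y: np.ndarray,
    D: np.ndarray,
    E: np.ndarray,
    covariates: np.ndarray | None = None,
    chunk: int = 4096,
) -> dict[str, np.ndarray]:
    """Vectorized interaction fits over T tests.

    Y, D, E: (T, n) arrays (rows are tests).  ``covariates`` (n, c) is
    shared across tests.  Returns arrays of shape (T,) per named quantity.
    Matches :func:`fit_interaction` row by row (tested against it).
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    D = np.atleast_2d(np.asarray(D, float))
    E = np.atleast_2d(np.asarray(E, float))
    T, n = Y.shape
    C = None
    if covariates is not None:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
    nc = 0 if C is None else C.shape[1]
    k = 4 + nc
    term_idx = {"intercept": 0, "dosage": 1, "signature": 2, "interaction": 3}
    if nc:  # covariates sit between dosage and signature in fit_interaction
        term_idx = {"intercept": 0, "dosage": 1, "signature": 2 + nc,
                    "interaction": 3 + nc}
    out = {f"{w}_{t}": np.empty(T) for t in TERMS for w in ("b", "se", "p")}
    ones = np.ones(n)
    for start in range(0, T, chunk):
        sl = slice(start, min(start + chunk, T))
        t = sl.stop - sl.start
        X = np.empty((t, n, k))
        X[:, :, 0] = ones
        X[:, :, 1] = D[sl]
        if nc:
            X[:, :, 2:2 + nc] = C[None, :, :]
            X[:, :, 2 + nc] = E[sl]
            X[:, :, 3 + nc] = D[sl] * E[sl]
        else:
            X[:, :, 2] = E[sl]
            X[:, :, 3] = D[sl] * E[sl]
        XtX = np.einsum("tnk,tnl->tkl", X, X, optimize=True)
        Xty = np.einsum("tnk,tn->tk", X, Y[sl], optimize=True)
        b = np.linalg.solve(XtX, Xty[..., None])[..., 0]
        resid = Y[sl] - np.einsum("tnk,tk->tn", X, b, optimize=True)
        sigma2 = np.einsum("tn,tn->t", resid, resid) / (n - k)
        inv = np.linalg.inv(XtX)
        for term, j in term_idx.items():
            se = np.sqrt(inv[:, j, j] * sigma2)
            tv = b[:, j] / se
            out[f"b_{term}"][sl] = b[:, j]
            out[f"se_{term}"][sl] = se
            out[f"p_{term}"][sl] = 2.0 * stats.t.sf(np.abs(tv), n - k)
    return out


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

@dataclass
class NullStore:
    """Pooled permutation null of interaction p-values for one signature."""

    signature_name: str
    null_p: np.ndarray
    seed: int

    @property
    def n_null(self) -> int:
        return len(self.null_p)

    def save(self, path) -> None:
        with gzip.open(path, "wt") as fh:
            fh.write(f"# signature={self.signature_name} seed={self.seed} "
                     f"n_null={self.n_null}\n")
            np.savetxt(fh, self.null_p, fmt="%.8g")

    @classmethod
    def load(cls, path) -> "NullStore":
        with gzip.open(path, "rt") as fh:
            header = fh.readline().strip().lstrip("# ")
            meta = dict(kv.split("=") for kv in header.split())
            vals = np.loadtxt(fh)
        store = cls(signature_name=meta["signature"],
                    null_p=np.atleast_1d(vals), seed=int(meta["seed"]))
        if store.n_null != int(meta["n_null"]):
            raise GxeError("null store is truncated")
        return store


def _null_pvals_one_pair(
    y: np.ndarray,
    d: np.ndarray,
    e: np.ndarray,
    n_rounds: int,
    rng: np.random.Generator,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Interaction p-values for ``n_rounds`` permutations of one pair's dosage.

    Moment-based batched OLS: all design moments not involving the dosage
    are permutation-invariant, so each permutation costs a handful of
    matrix-vector products.  The covariate path falls back to the generic
    batched solver.
    """
    n = len(y)
    order = np.argsort(rng.random((n_rounds, n)), axis=1)
    Dp = d[order]
    if covariates is not None:
        res = batch_interaction(np.broadcast_to(y, Dp.shape), Dp,
                                np.broadcast_to(e, Dp.shape),
                                covariates=covariates)
        return res["p_interaction"]
    e2 = e * e
    ey = e * y
    sde = Dp @ e
    sde2 = Dp @ e2
    sdy = Dp @ y
    sdey = Dp @ ey
    D2 = Dp * Dp
    sd2e = D2 @ e
    sd2e2 = D2 @ e2
    sd = float(d.sum())
    sd2 = float((d * d).sum())
    se_ = float(e.sum())
    se2 = float(e2.sum())
    sy = float(y.sum())
    sey = float(ey.sum())
    syy = float(y @ y)
    R = n_rounds
    XtX = np.empty((R, 4, 4))
    XtX[:, 0, 0] = n
    XtX[:, 0, 1] = XtX[:, 1, 0] = sd
    XtX[:, 0, 2] = XtX[:, 2, 0] = se_
    XtX[:, 0, 3] = XtX[:, 3, 0] = sde
    XtX[:, 1, 1] = sd2
    XtX[:, 1, 2] = XtX[:, 2, 1] = sde
    XtX[:, 1, 3] = XtX[:, 3, 1] = sd2e
    XtX[:, 2, 2] = se2
    XtX[:, 2, 3] = XtX[:, 3, 2] = sde2
    XtX[:, 3, 3] = sd2e2
    Xty = np.empty((R, 4))
    Xty[:, 0] = sy
    Xty[:, 1] = sdy
    Xty[:, 2] = sey
    Xty[:, 3] = sdey
    b = np.linalg.solve(XtX, Xty[..., None])[..., 0]
    rss = syy - np.einsum("rk,rk->r", b, Xty)
    df = n - 4
    sigma2 = np.maximum(rss, 0.0) / df
    inv33 = np.linalg.inv(XtX)[:, 3, 3]
    se_b = np.sqrt(inv33 * sigma2)
    tv = np.divide(b[:, 3], se_b, out=np.zeros(R), where=se_b > 0)
    return 2.0 * stats.t.sf(np.abs(tv), df)


def build_permutation_null(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    env: np.ndarray,
    n_null: int,
    seed: int,
    signature_name: str = "signature",
    covariates: np.ndarray | None = None,
    min_null_factor: int = 0,
) -> NullStore:
    """Pooled permutation null for one signature.

    ``pairs`` holds (expression, dosage) vectors for each lead gene-variant
    pair; ``env`` is the signature (already quantile-normalized), shared by
    all pairs.  Dosages are permuted (expression-environment pairing kept),
    the model refit, and interaction p-values pooled until ``n_null`` values
    are stored: rounds = ceil(n_null / n_pairs) permutations per pair.
    Deterministic given the seed; each pair gets its own derived stream.
    """
    if not pairs:
        raise GxeError("no lead pairs given")
    if n_null < 1:
        raise GxeError("n_null must be >= 1")
    if min_null_factor and n_null < min_null_factor * len(pairs):
        raise GxeError(
            f"n_null={n_null} < {min_null_factor}x the {len(pairs)} tests"
        )
    n_rounds = int(np.ceil(n_null / len(pairs)))
    collected = np.empty((len(pairs), n_rounds))
    for i, (y, d) in enumerate(pairs):
        rng = np.random.default_rng([int(seed), 7, i])
        collected[i] = _null_pvals_one_pair(np.asarray(y, float),
                                            np.asarray(d, float),
                                            np.asarray(env, float),
                                            n_rounds, rng,
                                            covariates=covariates)
    pooled = collected.ravel(order="F")[:n_null]
    return NullStore(signature_name=signature_name, null_p=pooled,
                     seed=int(seed))


def correct_and_qvalue(
    records: pd.DataFrame,
    null: NullStore,
    fdr_level: float = 0.10,
) -> pd.DataFrame:
    """Permutation-correct interaction p-values and add Storey q-values.

    ``p_interaction_permcorrected = (1 + #{null <= p}) / (1 + n_null)``;
    q-values are computed within the signature (all rows of ``records``
    must belong to the null's signature).  Adds a ``significant`` flag at
    ``q <= fdr_level``.
    """
    if null.n_null == 0:
        raise GxeError("empty null store")
    if "signature_name" in records.columns:
        sigs = set(records["signature_name"])
        if sigs - {null.signature_name}:
            raise GxeError(
                f"null store for {null.signature_name!r} does not match "
                f"records for {sorted(sigs)}"
            )
    out = records.copy()
    p_corr = empirical_pvalues(out["p_interaction"].to_numpy(), null.null_p)
    out["p_interaction_permcorrected"] = p_corr
    out["q_interaction_permcorrected"] = qvalues(p_corr)
    out["significant"] = out["q_interaction_permcorrected"] <= fdr_level
    return out


# ---------------------------------------------------------------------------
# replication and TWAS bookkeeping
# ---------------------------------------------------------------------------

def replication_enrichment(
    set_a: set[str],
    set_b: set[str],
    universe: set[str],
) -> tuple[float, float, tuple[int, int, int, int]]:
    """Fisher 2x2 enrichment of gene set A in gene set B over a universe.

    Returns (odds_ratio, two_sided_p, (both, a_only, b_only, neither)).
    The sample odds ratio ad/bc gets a 0.5 continuity correction when any
    cell is zero.
    """
    if not universe:
        raise GxeError("empty universe")
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise GxeError("gene sets must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    table = (a, b, c, d)
    if min(table) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(orr), float(p), table


def effect_concordance(
    records_measured: pd.DataFrame,
    records_signature: pd.DataFrame,
) -> tuple[float, float, int]:
    """Pearson correlation of standardized interaction effects (z-scores).

    Records are joined on (gene_id, variant_id, signature_name); z is
    b_interaction / se_interaction.  Returns (r, p, n_pairs).
    """
    keys = ["gene_id", "variant_id", "signature_name"]
    merged = records_measured.merge(
        records_signature, on=keys, suffixes=("_m", "_s")
    )
    if len(merged) < 3:
        raise GxeError(f"only {len(merged)} joined pairs; need >= 3")
    z_m = merged["b_interaction_m"] / merged["se_interaction_m"]
    z_s = merged["b_interaction_s"] / merged["se_interaction_s"]
    r, p = stats.pearsonr(z_m, z_s)
    return float(r), float(p), len(merged)


def twas_overlap(
    records: pd.DataFrame,
    twas_table: pd.DataFrame,
    marginal_fdr: float = 0.10,
    fdr_level: float = 0.10,
) -> pd.DataFrame:
    """Overlap of marginal-environment and GxE gene sets with TWAS hits.

    ``twas_table`` needs columns (gene_id, trait, significant).  For each
    signature two gene sets are formed: genes with a significant marginal
    signature effect (q_signature <= marginal_fdr) and genes with a
    significant interaction (q_interaction_permcorrected <= fdr_level);
    each is intersected with the TWAS-significant genes per trait.
    """
    required = {"gene_id", "trait", "significant"}
    missing = required - set(twas_table.columns)
    if missing:
        raise GxeError(f"twas_table is missing columns: {sorted(missing)}")
    rows = []
    for sig_name, grp in records.groupby("signature_name"):
        sets = {}
        if "q_signature" in grp:
            sets["marginal_env"] = set(
                grp.loc[grp["q_signature"] <= marginal_fdr, "gene_id"]
            )
        if "q_interaction_permcorrected" in grp:
            sets["gxe"] = set(
                grp.loc[grp["q_interaction_permcorrected"] <= fdr_level,
                        "gene_id"]
            )
        for trait, tgrp in twas_table.groupby("trait"):
            twas_genes = set(tgrp.loc[tgrp["significant"].astype(bool),
                                      "gene_id"])
            for set_name, genes in sets.items():
                overlap = sorted(genes & twas_genes)
                rows.append({
                    "signature_name": sig_name,
                    "trait": trait,
                    "gene_set": set_name,
                    "n_genes": len(genes),
                    "n_twas": len(twas_genes),
                    "n_overlap": len(overlap),
                    "overlap_genes": ",".join(overlap),
                })
    return pd.DataFrame(
        rows, columns=["signature_name", "trait", "gene_set", "n_genes",
                       "n_twas", "n_overlap", "overlap_genes"]
    )


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

GXE_COLUMNS = [
    "gene_id", "variant_id",
    "p_intercept", "p_dosage", "p_signature", "p_interaction",
    "b_intercept", "b_dosage", "b_signature", "b_interaction",
    "se_intercept", "se_dosage", "se_signature", "se_interaction",
    "q_intercept", "q_dosage", "q_signature", "q_interaction",
    "signature_name",
    "p_interaction_permcorrected", "q_interaction_permcorrected",
]


def map_interactions(
    leads: pd.DataFrame,
    expr_resid: pd.DataFrame,
    dosages: pd.DataFrame,
    signatures: pd.DataFrame,
    n_null: int,
    seed: int,
    covariates: pd.DataFrame | None = None,
    fdr_level: float = 0.10,
    quantile_normalize: bool = True,
) -> tuple[pd.DataFrame, dict[str, NullStore]]:
    """Interaction-eQTL scan of lead pairs against every signature column.

    ``leads`` needs columns (gene_id, variant_id).  Signatures are
    quantile-normalized, each lead pair is fit per signature, per-term
    Storey q-values are computed within signature, and interaction p-values
    are corrected against a pooled permutation null of ``n_null`` values
    per signature.  Returns (records in the 21-column layout plus the
    significance flag, null stores per signature).
    """
    samples = expr_resid.columns
    if not dosages.columns.equals(samples):
        dosages = dosages.loc[:, samples]
    sig_vals = signatures.loc[samples]
    Y = expr_resid.loc[leads["gene_id"]].to_numpy()
    D = dosages.loc[leads["variant_id"]].to_numpy()
    C = covariates.loc[samples].to_numpy() if covariates is not None else None

    frames = []
    stores: dict[str, NullStore] = {}
    for sig_name in sig_vals.columns:
        env = sig_vals[sig_name].to_numpy(float)
        if quantile_normalize:
            env = inverse_normal_transform(env)
        E = np.broadcast_to(env, Y.shape)
        res = batch_interaction(Y, D, E, covariates=C)
        df = pd.DataFrame({
            "gene_id": leads["gene_id"].to_numpy(),
            "variant_id": leads["variant_id"].to_numpy(),
        })
        for term in TERMS:
            df[f"p_{term}"] = res[f"p_{term}"]
        for term in TERMS:
            df[f"b_{term}"] = res[f"b_{term}"]
        for term in TERMS:
            df[f"se_{term}"] = res[f"se_{term}"]
        for term in TERMS:
            df[f"q_{term}"] = qvalues(res[f"p_{term}"])
        df["signature_name"] = sig_name
        pairs = [(Y[i], D[i]) for i in range(len(df))]
        store = build_permutation_null(pairs, env, n_null, seed,
                                       signature_name=sig_name,
                                       covariates=C)
        stores[sig_name] = store
        df = correct_and_qvalue(df, store, fdr_level=fdr_level)
        frames.append(df)
    records = pd.concat(frames, ignore_index=True)
    return records[GXE_COLUMNS + ["significant"]], stores
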