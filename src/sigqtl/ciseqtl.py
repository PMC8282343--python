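"""cis-eQTL mapping with adaptive permutations and beta approximation.

FastQTL-style scan on residualized expression: for each gene, every variant
within 1 Mb of the (strand-aware) transcription start site with cohort
MAF > 0.1 is tested by simple OLS of expression on dosage.  Gene-level
multiple testing across cis variants is handled by an adaptive permutation
pass: the expression vector is shuffled, the minimum nominal p-value over
the gene's variants recorded, and permutation stops early once enough
permutation minima beat the observed minimum.  A Beta(a, b) distribution is
fit by maximum likelihood to the permutation minima, giving a smooth
gene-level empirical p-value (the beta approximation) used for Storey
q-value FDR across genes; genes significant at the chosen FDR are eGenes.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gxe import qvalues
from .preprocess import ExpressionMatrix, expression_pcs, residualize
from .simdata import GenotypeMatrix


class CisError(ValueError):
    pass


@dataclass(frozen=True)
class CisScanConfig:
    """Parameters of the cis scan (defaults follow the reference analysis)."""

    window_bp: int = 1_000_000
    maf_min: float = 0.1
    perm_min: int = 1000
    perm_max: int = 10_000
    adaptive_stop_hits: int = 100
    fdr_level: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.perm_min > self.perm_max:
            raise CisError("perm_min must be <= perm_max")
        if not (0.0 < self.maf_min < 0.5):
            raise CisError("maf_min must lie in (0, 0.5)")
        if not (0.0 < self.fdr_level < 1.0):
            raise CisError("fdr_level must lie in (0, 1)")


#: column order of the permutation-pass output file (FastQTL layout)
EQTL_COLUMNS = [
    "gene_id", "n_variants", "beta_shape1", "beta_shape2", "dummy",
    "lead_variant_id", "tss_distance", "nominal_p", "slope",
    "perm_p_direct", "perm_p_beta",
]


def strand_aware_tss(annotation: pd.DataFrame) -> pd.Series:
    """TSS per gene; for minus-strand genes with start/end columns, the end.

    Annotations carrying an explicit ``tss`` column are returned as-is;
    BED-derived tables with (start, end, strand) use start for plus-strand
    and end for minus-strand genes.
    """
    if "tss" in annotation.columns:
        return annotation["tss"].astype(int)
    if not {"start", "end", "strand"} <= set(annotation.columns):
        raise CisError("annotation needs a tss column or start/end/strand")
    minus = annotation["strand"].astype(str) == "-"
    return annotation["end"].where(minus, annotation["start"]).astype(int)


def _norm_chrom(c) -> str:
    s = str(c)
    return s[3:] if s.lower().startswith("chr") else s


def cis_candidates(
    gene: str,
    annotation: pd.DataFrame,
    genotypes: GenotypeMatrix,
    config: CisScanConfig = CisScanConfig(),
) -> pd.Index:
    """Variants on the gene's chromosome within the cis window, MAF-filtered.

    Window test is inclusive: |pos - TSS| <= window_bp.  MAF is computed
    from dosages as min(m, 1-m) with m = mean(dosage)/2 and must strictly
    exceed ``maf_min``.
    """
    if gene not in annotation.index:
        raise CisError(f"gene {gene!r} absent from the annotation")
    tss = int(strand_aware_tss(annotation).loc[gene])
    chrom = _norm_chrom(annotation.loc[gene, "chrom"])
    meta = genotypes.meta
    vchrom = meta["chrom"].map(_norm_chrom)
    in_window = (vchrom == chrom) & (
        (meta["pos"] - tss).abs() <= config.window_bp
    )
    cand = meta.index[in_window]
    maf = genotypes.maf().loc[cand]
    return cand[maf > config.maf_min]


def nominal_scan(
    gene_expr_resid: np.ndarray,
    dosages: pd.DataFrame | np.ndarray,
) -> pd.DataFrame:
    """Per-variant OLS of expression on dosage (intercept included).

    Returns a DataFrame with slope, se, nominal_p and a ``tested`` flag;
    zero-variance variants are flagged untested (NaN statistics) rather
    than raising.  Two-sided t-test with df = n - 2.
    """
    if isinstance(dosages, pd.DataFrame):
        D = dosages.to_numpy(float)
        index = dosages.index
    else:
        D = np.atleast_2d(np.asarray(dosages, float))
        index = pd.RangeIndex(len(D))
    y = np.asarray(gene_expr_resid, float)
    n = len(y)
    if n < 10:
        raise CisError(f"need >= 10 samples, got {n}")
    yc = y - y.mean()
    Dc = D - D.mean(axis=1, keepdims=True)
    sxx = (Dc * Dc).sum(axis=1)
    sxy = Dc @ yc
    syy = float(yc @ yc)
    tested = sxx > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(tested, sxy / sxx, np.nan)
        rss = syy - np.where(tested, slope * sxy, 0.0)
        se = np.sqrt(np.maximum(rss, 0.0) / (n - 2) / sxx)
        tval = slope / se
    p = np.full(len(D), np.nan)
    finite = tested & np.isfinite(tval)
    p[finite] = 2.0 * stats.t.sf(np.abs(tval[finite]), n - 2)
    # exact fits (rss == 0) get p = 0 rather than NaN
    exact = tested & ~np.isfinite(tval) & (np.abs(slope) > 0)
    p[exact] = 0.0
    return pd.DataFrame(
        {"slope": slope, "se": se, "nominal_p": p, "tested": tested},
        index=index,
    )


def _min_p_from_r2(r2_max: np.ndarray, n: int) -> np.ndarray:
    """Nominal p of the strongest variant from its squared correlation."""
    df = n - 2
    r2_max = np.clip(r2_max, 0.0, 1.0 - 1e-300)
    t2 = df * r2_max / (1.0 - r2_max)
    return 2.0 * stats.t.sf(np.sqrt(t2), df)


def fit_beta_minp(pvals: np.ndarray) -> tuple[float, float, bool]:
    """Beta(a, b) fit to permutation minimum p-values.

    Maximum likelihood (location 0, scale 1) with a method-of-moments
    start; falls back to the moments estimate when the MLE optimizer fails
    (flagged in the third return value).  Shapes are clipped to
    [1e-3, 1e6].
    """
    x = np.clip(np.asarray(pvals, float), 1e-12, 1.0 - 1e-12)
    m, v = float(x.mean()), float(x.var())
    if v <= 0:
        return 1.0, 1.0, True
    common = m * (1.0 - m) / v - 1.0
    a0 = max(m * common, 1e-3)
    b0 = max((1.0 - m) * common, 1e-3)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, b, _, _ = stats.beta.fit(x, a0, b0, floc=0.0, fscale=1.0)
        if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
            raise ValueError
        fallback = False
    except Exception:
        a, b = a0, b0
        fallback = True
    a = float(np.clip(a, 1e-3, 1e6))
    b = float(np.clip(b, 1e-3, 1e6))
    return a, b, fallback


def permutation_pass(
    gene_expr_resid: np.ndarray,
    dosages: pd.DataFrame,
    config: CisScanConfig = CisScanConfig(),
    rng: np.random.Generator | None = None,
) -> dict:
    """Adaptive permutation pass for one gene.

    Shuffles the expression vector (dosages fixed), records the minimum
    nominal p over the gene's candidate variants per permutation, stops
    early once ``adaptive_stop_hits`` permutation minima beat the observed
    minimum (never before ``perm_min`` nor beyond ``perm_max``
    permutations), and summarises the null of minimum p-values by a
    Beta(a, b) maximum-likelihood fit.

    Returns a dict with the observed lead association, the direct
    permutation p-value (1 + hits) / (1 + P) and the beta-approximated
    permutation p-value BetaCDF(obs_min_p; a, b).
    """
    if len(dosages) < 1:
        raise CisError("no candidate variants for permutation pass")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    y = np.asarray(gene_expr_resid, float)
    n = len(y)
    D = dosages.to_numpy(float)
    Dc = D - D.mean(axis=1, keepdims=True)
    sxx = (Dc * Dc).sum(axis=1)
    ok = sxx > 0
    if not ok.any():
        raise CisError("all candidate variants have zero dosage variance")
    Dc = Dc[ok]
    sxx_ok = sxx[ok]
    scale = 1.0 / np.sqrt(sxx_ok)

    obs = nominal_scan(y, dosages)
    obs_ok = obs[obs["tested"]]
    yc = y - y.mean()
    syy = float(yc @ yc)
    r_obs = (Dc @ yc) * scale / np.sqrt(syy)
    obs_r2max = float(np.max(r_obs**2))
    obs_min_p = float(_min_p_from_r2(np.array([obs_r2max]), n)[0])

    hits = 0
    total = 0
    minima_r2: list[np.ndarray] = []
    chunk = config.perm_min
    while total < config.perm_max:
        todo = min(chunk, config.perm_max - total)
        perm_idx = np.argsort(rng.random((todo, n)), axis=1)
        Yp = yc[perm_idx]  # (todo, n) permuted centered expression
        R = (Dc @ Yp.T) * scale[:, None] / np.sqrt((Yp**2).sum(axis=1))[None, :]
        r2max = (R**2).max(axis=0)
        minima_r2.append(r2max)
        hits += int((r2max >= obs_r2max).sum())
        total += todo
        if total >= config.perm_min and hits >= config.adaptive_stop_hits:
            break
    perm_min_p = _min_p_from_r2(np.concatenate(minima_r2), n)
    perm_p_direct = (1.0 + hits) / (1.0 + total)
    a, b, mom_fallback = fit_beta_minp(perm_min_p)
    perm_p_beta = float(stats.beta.cdf(obs_min_p, a, b))

    # lead variant: smallest nominal p, then |tss_distance| (set by caller),
    # then lexicographic id
    best = obs_ok.sort_values(
        ["nominal_p"], kind="mergesort"
    )
    lead_candidates = best[best["nominal_p"] == best["nominal_p"].iloc[0]]
    lead = sorted(lead_candidates.index)[0]
    return {
        "n_variants": int(obs["tested"].sum()),
        "beta_shape1": a,
        "beta_shape2": b,
        "beta_mom_fallback": mom_fallback,
        "lead_variant_id": lead,
        "nominal_p": float(obs.loc[lead, "nominal_p"]),
        "slope": float(obs.loc[lead, "slope"]),
        "perm_p_direct": float(perm_p_direct),
        "perm_p_beta": perm_p_beta,
        "n_permutations": int(total),
    }


def map_cis(
    expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    annotation: pd.DataFrame,
    config: CisScanConfig = CisScanConfig(),
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Permutation pass over all genes; returns the 11-column table.

    Genes with no candidate variants are skipped.  Ties for the lead
    variant break by smallest nominal p, then smallest |tss_distance|,
    then variant id; per-gene RNG streams are derived from the config seed
    and the gene's name so results are invariant to gene and variant input
    order.
    """
    if expr.residual is None:
        raise CisError("expression must be residualized before the cis scan")
    tss_all = strand_aware_tss(annotation)
    rows = []
    gene_list = list(genes) if genes is not None else list(expr.residual.index)
    for gi, gene in enumerate(gene_list):
        if gene not in annotation.index:
            continue
        cand = cis_candidates(gene, annotation, genotypes, config)
        if len(cand) == 0:
            continue
        dos = genotypes.dosages.loc[cand, expr.residual.columns]
        y = expr.residual.loc[gene].to_numpy()
        # order-invariant seeding: stable hash of the gene id into the stream
        key = zlib.crc32(str(gene).encode()) % (2**31)
        rng = np.random.default_rng([int(config.seed), 11, key])
        tss = int(tss_all.loc[gene])
        # deterministic variant ordering for the scan
        pos = genotypes.meta.loc[cand, "pos"]
        order = np.lexsort((cand, pos.to_numpy()))
        dos = dos.iloc[order]
        res = permutation_pass(y, dos, config, rng=rng)
        lead = res["lead_variant_id"]
        # refine the lead tie-break with |tss distance|
        obs = nominal_scan(y, dos)
        pmin = obs["nominal_p"].min()
        tied = obs.index[obs["nominal_p"] == pmin]
        if len(tied) > 1:
            dist = (genotypes.meta.loc[tied, "pos"] - tss).abs()
            tied_sorted = sorted(tied, key=lambda v: (dist.loc[v], v))
            lead = tied_sorted[0]
            res["lead_variant_id"] = lead
            res["nominal_p"] = float(obs.loc[lead, "nominal_p"])
            res["slope"] = float(obs.loc[lead, "slope"])
        rows.append({
            "gene_id": gene,
            "n_variants": res["n_variants"],
            "beta_shape1": res["beta_shape1"],
            "beta_shape2": res["beta_shape2"],
            "dummy": 0,
            "lead_variant_id": lead,
            "tss_distance": int(genotypes.meta.loc[lead, "pos"] - tss),
            "nominal_p": res["nominal_p"],
            "slope": res["slope"],
            "perm_p_direct": res["perm_p_direct"],
            "perm_p_beta": res["perm_p_beta"],
        })
    if not rows:
        raise CisError("no genes had candidate variants")
    return pd.DataFrame(rows, columns=EQTL_COLUMNS)


def gene_fdr(records: pd.DataFrame, fdr_level: float = 0.10) -> pd.DataFrame:
    """Storey q-values over the beta-approximated permutation p-values.

    Adds ``qvalue`` and ``eGene`` (q <= fdr_level) columns.
    """
    p = records["perm_p_beta"].to_numpy(float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise CisError("perm_p_beta values outside [0, 1]")
    out = records.copy()
    out["qvalue"] = qvalues(p)
    out["eGene"] = out["qvalue"] <= fdr_level
    return out


def optimize_expression_pcs(
    expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    annotation: pd.DataFrame,
    config: CisScanConfig,
    pc_grid: list[int],
    genes: list[str] | None = None,
) -> tuple[int, dict[int, int], dict[int, pd.DataFrame]]:
    """Choose the number of expression PCs that maximises eGene count.

    For each k in ``pc_grid`` the top-k PCs of the residual expression are
    regressed out (on top of the existing covariate residualization), the
    permutation pass rerun and eGenes counted at the configured FDR; ties
    break toward the smallest k.  Returns (chosen_k, counts, records per k).
    """
    counts: dict[int, int] = {}
    tables: dict[int, pd.DataFrame] = {}
    n_samples = expr.residual.shape[1]
    for k in sorted(set(int(k) for k in pc_grid)):
        if k < 0:
            raise CisError("pc grid entries must be nonnegative")
        if k >= n_samples:
            raise CisError(f"k={k} must be < n_samples={n_samples}")
        if k == 0:
            expr_k = expr
        else:
            pcs = expression_pcs(expr, k)
            base = ExpressionMatrix(counts=expr.counts,
                                    gene_meta=expr.gene_meta,
                                    normalized=expr.residual)
            expr_k = residualize(base, pcs)
            expr_k = ExpressionMatrix(counts=expr.counts,
                                      gene_meta=expr.gene_meta,
                                      normalized=expr.normalized,
                                      residual=expr_k.residual)
        recs = gene_fdr(
            map_cis(expr_k, genotypes, annotation, config, genes=genes),
            config.fdr_level,
        )
        counts[k] = int(recs["eGene"].sum())
        tables[k] = recs
    chosen = max(sorted(counts), key=lambda k: counts[k])
    # ties -> smallest k (max on sorted keys returns the first maximum)
    return chosen, counts, tables
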