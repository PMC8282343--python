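"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of a pediatric-asthma blood-transcriptome
cohort: ~250 participants, ~50 psychosocial/clinical variables organised in
correlated category blocks with measurement noise and missingness,
negative-binomial RNA-seq counts driven by library size, technical
confounders, blood cell composition, cis-genetic effects, environmental main
effects and genotype-by-environment interactions, plus a second longitudinal
wave.  Every injected effect is exported in a :class:`TruthSet` so downstream
estimators can be scored against the truth.

Seeding: one master seed; each generation stage draws from
``np.random.default_rng([seed, STAGE])`` with a fixed stage offset, so stages
are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

# fixed stage offsets for derived RNG streams
_STAGE_GENOTYPES = 1
_STAGE_TRUTH = 2
_STAGE_PHENOTYPES = 3
_STAGE_EXPRESSION = 4
_STAGE_WAVE2 = 5

CELL_TYPES = ("neutrophils", "lymphocytes", "monocytes", "eosinophils")
#: Dirichlet concentrations for the four blood cell fractions (typical
#: pediatric whole-blood proportions ~55/35/7.5/3 % with realistic spread).
CELL_DIRICHLET_ALPHA = (11.0, 7.0, 1.5, 0.6)

DEFAULT_CATEGORY_BLOCKS: Mapping[str, int] = {
    "ses": 10,
    "social_relationships": 12,
    "emotionality": 10,
    "asthma": 10,
    "blood_composition": 4,
    "biomarkers": 4,
}


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    ``effect_sizes`` may be given explicitly as an (n_genes, 3) array of
    per-gene (beta_g, beta_e, beta_gxe) log-scale effects; when ``None`` a
    default allocation is drawn (seeded): a fraction of genes receive a
    cis-eQTL effect, each phenotype variable receives ``genes_per_signature``
    environmentally responsive genes, and GxE effects are placed on genes
    that have both.
    """

    n_samples: int = 250
    n_genes: int = 2000
    n_variants: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_phenotypes: int = 50
    category_blocks: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_BLOCKS)
    )
    block_loading: float = 0.75
    effect_sizes: np.ndarray | None = None
    # defaults used when effect_sizes is None
    frac_eqtl_genes: float = 0.3
    beta_g: float = 0.8
    genes_per_signature: int = 20
    beta_e: float = 0.25
    frac_gxe_genes: float = 0.05
    beta_gxe: float = 0.4
    nb_dispersion: float = 0.1
    libsize_range: tuple[float, float] = (1e6, 3e6)
    confounder_count: int = 3
    confounder_sd: float = 0.4
    cell_genes_per_type: int = 40
    cell_loading: float = 0.5
    noise_sd_phenotype: float = 1.0
    missing_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_variants", "n_phenotypes"):
            if getattr(self, name) < 1:
                raise SimConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimConfigError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.nb_dispersion < 0:
            raise SimConfigError("nb_dispersion must be >= 0")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise SimConfigError("missing_fraction must be in [0, 1)")
        if sum(self.category_blocks.values()) != self.n_phenotypes:
            raise SimConfigError(
                "category_blocks variable counts must sum to n_phenotypes"
            )
        if self.effect_sizes is not None:
            es = np.asarray(self.effect_sizes, float)
            if es.shape != (self.n_genes, 3):
                raise SimConfigError(
                    f"effect_sizes must have shape ({self.n_genes}, 3), got {es.shape}"
                )

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stage)])

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i:04d}" for i in range(self.n_samples)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"GENE{i:05d}" for i in range(self.n_genes)]

    @property
    def variant_ids(self) -> list[str]:
        return [f"var{i:06d}" for i in range(self.n_variants)]

    @property
    def variable_names(self) -> list[str]:
        names = []
        for cat, k in self.category_blocks.items():
            if cat == "blood_composition" and k == len(CELL_TYPES):
                names.extend(CELL_TYPES)
            else:
                names.extend(f"{cat}_{j}" for j in range(k))
        return names

    @property
    def variable_categories(self) -> list[str]:
        cats = []
        for cat, k in self.category_blocks.items():
            cats.extend([cat] * k)
        return cats


@dataclass
class GenotypeMatrix:
    """Per-sample allele dosages in [0, 2] with variant metadata."""

    dosages: pd.DataFrame  # variants x samples
    meta: pd.DataFrame  # index variant id; columns chrom, pos, maf_drawn

    @property
    def variant_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.columns

    def maf(self) -> pd.Series:
        """Cohort MAF from dosages: min(m, 1-m), m = mean(dosage)/2."""
        m = self.dosages.mean(axis=1) / 2.0
        return np.minimum(m, 1.0 - m)


@dataclass
class TruthSet:
    """Simulation ground truth used by parameter-recovery tests."""

    latent_traits: pd.DataFrame  # samples x variables, noise-free
    beta_g: np.ndarray  # per gene
    beta_e: np.ndarray
    beta_gxe: np.ndarray
    assigned_cis_variant: np.ndarray  # gene -> variant index (-1 = none)
    assigned_variable: np.ndarray  # gene -> phenotype variable index (-1 = none)
    confounders: np.ndarray  # samples x C
    confounder_loadings: np.ndarray  # genes x C
    cell_props: pd.DataFrame  # samples x 4, rows sum to 1
    cell_loadings: np.ndarray  # genes x 4
    base_log_abundance: np.ndarray  # per gene
    libsizes: np.ndarray  # per sample

    def __post_init__(self) -> None:
        n_genes = len(self.beta_g)
        for arr in (self.beta_e, self.beta_gxe, self.assigned_cis_variant,
                    self.assigned_variable):
            if len(arr) != n_genes:
                raise ValueError("truth arrays are not dimension-consistent")
        bad = (self.beta_gxe != 0) & (self.assigned_cis_variant < 0)
        if bad.any():
            raise ValueError(
                "every gene with nonzero beta_gxe needs an assigned cis variant"
            )

    def to_json(self) -> str:
        payload = {
            "latent_traits": {
                "index": list(self.latent_traits.index),
                "columns": list(self.latent_traits.columns),
                "values": self.latent_traits.to_numpy().tolist(),
            },
            "beta_g": self.beta_g.tolist(),
            "beta_e": self.beta_e.tolist(),
            "beta_gxe": self.beta_gxe.tolist(),
            "assigned_cis_variant": self.assigned_cis_variant.tolist(),
            "assigned_variable": self.assigned_variable.tolist(),
            "confounders": self.confounders.tolist(),
            "confounder_loadings": self.confounder_loadings.tolist(),
            "cell_props": {
                "index": list(self.cell_props.index),
                "columns": list(self.cell_props.columns),
                "values": self.cell_props.to_numpy().tolist(),
            },
            "cell_loadings": self.cell_loadings.tolist(),
            "base_log_abundance": self.base_log_abundance.tolist(),
            "libsizes": self.libsizes.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        d = json.loads(text)

        def df(key):
            return pd.DataFrame(
                np.asarray(d[key]["values"], float),
                index=d[key]["index"],
                columns=d[key]["columns"],
            )

        return cls(
            latent_traits=df("latent_traits"),
            beta_g=np.asarray(d["beta_g"], float),
            beta_e=np.asarray(d["beta_e"], float),
            beta_gxe=np.asarray(d["beta_gxe"], float),
            assigned_cis_variant=np.asarray(d["assigned_cis_variant"], int),
            assigned_variable=np.asarray(d["assigned_variable"], int),
            confounders=np.asarray(d["confounders"], float),
            confounder_loadings=np.asarray(d["confounder_loadings"], float),
            cell_props=df("cell_props"),
            cell_loadings=np.asarray(d["cell_loadings"], float),
            base_log_abundance=np.asarray(d["base_log_abundance"], float),
            libsizes=np.asarray(d["libsizes"], float),
        )


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

#: bp between consecutive gene TSSs on the single simulated chromosome
GENE_SPACING = 100_000


def gene_annotation(config: SimConfig) -> pd.DataFrame:
    """BED-like gene annotation: gene_id, chrom, tss, strand.

    Genes are laid out on one chromosome at ``GENE_SPACING`` intervals;
    every other gene is placed on the minus strand so strand-aware TSS
    handling is exercised downstream.
    """
    n = config.n_genes
    tss = (np.arange(n) + 1) * GENE_SPACING
    return pd.DataFrame(
        {
            "gene_id": config.gene_ids,
            "chrom": "1",
            "tss": tss,
            "strand": np.where(np.arange(n) % 2 == 0, "+", "-"),
        }
    ).set_index("gene_id")


def _variant_positions(config: SimConfig) -> np.ndarray:
    span = (config.n_genes + 20) * GENE_SPACING
    rng = config.rng(_STAGE_GENOTYPES)
    pos = np.sort(rng.integers(1, span, size=config.n_variants))
    return pos


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_genotypes(config: SimConfig, mode: str = "hard") -> GenotypeMatrix:
    """Draw genotype dosages, per variant Binomial(2, f) with f ~ U(maf_range).

    ``mode="hard"`` yields dosages in {0, 1, 2}; ``mode="dosage"`` adds
    truncated Gaussian imputation noise (sd 0.05) so values span [0, 2].
    """
    if mode not in ("hard", "dosage"):
        raise SimConfigError(f"unknown genotype mode {mode!r}")
    rng = config.rng(_STAGE_GENOTYPES)
    pos = _variant_positions(config)
    f = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_variants)
    dos = rng.binomial(2, f[:, None], size=(config.n_variants, config.n_samples))
    dos = dos.astype(float)
    if mode == "dosage":
        dos = np.clip(dos + rng.normal(0.0, 0.05, size=dos.shape), 0.0, 2.0)
    dosages = pd.DataFrame(dos, index=config.variant_ids, columns=config.sample_ids)
    meta = pd.DataFrame(
        {"chrom": "1", "pos": pos, "maf_drawn": f}, index=config.variant_ids
    )
    return GenotypeMatrix(dosages=dosages, meta=meta)


def _default_effect_sizes(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Allocate (beta_g, beta_e, beta_gxe) and gene->variant/variable maps."""
    n = config.n_genes
    beta_g = np.zeros(n)
    beta_e = np.zeros(n)
    beta_gxe = np.zeros(n)
    assigned_var = np.full(n, -1, dtype=int)

    n_eqtl = int(round(config.frac_eqtl_genes * n))
    eqtl_genes = rng.choice(n, size=n_eqtl, replace=False)
    beta_g[eqtl_genes] = config.beta_g * rng.choice([-1.0, 1.0], size=n_eqtl)

    n_vars = config.n_phenotypes
    per = min(config.genes_per_signature, max(1, n // max(n_vars, 1)))
    order = rng.permutation(n)
    k = 0
    for v in range(n_vars):
        take = order[k : k + per]
        k += per
        if len(take) == 0:
            break
        assigned_var[take] = v
        beta_e[take] = config.beta_e * rng.choice([-1.0, 1.0], size=len(take))

    n_gxe = int(round(config.frac_gxe_genes * n))
    candidates = np.where((beta_g != 0) & (assigned_var >= 0))[0]
    if n_gxe > 0 and len(candidates) > 0:
        gxe_genes = rng.choice(candidates, size=min(n_gxe, len(candidates)),
                               replace=False)
        beta_gxe[gxe_genes] = config.beta_gxe * rng.choice(
            [-1.0, 1.0], size=len(gxe_genes)
        )
    return beta_g, beta_e, beta_gxe, assigned_var, eqtl_genes


def gen_truth(config: SimConfig, genotypes: GenotypeMatrix | None = None) -> TruthSet:
    """Materialise latent traits, effect sizes and nuisance structure."""
    rng = config.rng(_STAGE_TRUTH)
    n, n_vars = config.n_samples, config.n_phenotypes
    names = config.variable_names
    cats = config.variable_categories

    # blood cell proportions and their clr-style latents
    props = rng.dirichlet(CELL_DIRICHLET_ALPHA, size=n)
    logp = np.log(np.clip(props, 1e-6, None))
    clr = logp - logp.mean(axis=1, keepdims=True)
    clr_std = (clr - clr.mean(0)) / clr.std(0, ddof=0)

    latent = np.empty((n, n_vars))
    blood_slot = 0
    for j, cat in enumerate(cats):
        if cat == "blood_composition" and blood_slot < len(CELL_TYPES):
            latent[:, j] = clr_std[:, blood_slot]
            blood_slot += 1
        else:
            latent[:, j] = np.nan  # filled by block factors below
    # correlated category blocks: shared factor per block
    rho = config.block_loading
    start = 0
    for cat, k in config.category_blocks.items():
        cols = np.arange(start, start + k)
        start += k
        if cat == "blood_composition":
            continue
        f = rng.standard_normal(n)
        eps = rng.standard_normal((n, k))
        latent[:, cols] = rho * f[:, None] + np.sqrt(1 - rho**2) * eps

    latent_df = pd.DataFrame(latent, index=config.sample_ids, columns=names)

    if config.effect_sizes is not None:
        es = np.asarray(config.effect_sizes, float)
        beta_g, beta_e, beta_gxe = es[:, 0].copy(), es[:, 1].copy(), es[:, 2].copy()
        assigned_var = np.full(config.n_genes, -1, int)
        need = np.where((beta_e != 0) | (beta_gxe != 0))[0]
        assigned_var[need] = rng.integers(0, n_vars, size=len(need))
    else:
        beta_g, beta_e, beta_gxe, assigned_var, _ = _default_effect_sizes(config, rng)

    # assign each genetically-affected gene a cis variant inside its window
    if genotypes is None:
        genotypes = gen_genotypes(config)
    pos = genotypes.meta["pos"].to_numpy()
    ann = gene_annotation(config)
    tss = ann["tss"].to_numpy()
    assigned_variant = np.full(config.n_genes, -1, int)
    need = np.where((beta_g != 0) | (beta_gxe != 0))[0]
    for g in need:
        lo = np.searchsorted(pos, tss[g] - 1_000_000, side="left")
        hi = np.searchsorted(pos, tss[g] + 1_000_000, side="right")
        if hi <= lo:  # no variant in window; drop the genetic effect
            beta_g[g] = 0.0
            beta_gxe[g] = 0.0
            continue
        assigned_variant[g] = int(rng.integers(lo, hi))

    conf = rng.standard_normal((n, config.confounder_count))
    load = np.zeros((config.n_genes, config.confounder_count))
    n_loaded = max(1, int(0.3 * config.n_genes))
    for c in range(config.confounder_count):
        idx = rng.choice(config.n_genes, size=n_loaded, replace=False)
        load[idx, c] = rng.normal(0.0, config.confounder_sd, size=n_loaded)

    cell_load = np.zeros((config.n_genes, len(CELL_TYPES)))
    free = np.ones(config.n_genes, bool)
    for t in range(len(CELL_TYPES)):
        pool = np.where(free)[0]
        take = rng.choice(pool, size=min(config.cell_genes_per_type, len(pool)),
                          replace=False)
        free[take] = False
        cell_load[take, t] = config.cell_loading * rng.choice(
            [-1.0, 1.0], size=len(take)
        )

    lo, hi = config.libsize_range
    libsizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    base = rng.normal(0.0, 1.0, size=config.n_genes)

    return TruthSet(
        latent_traits=latent_df,
        beta_g=beta_g,
        beta_e=beta_e,
        beta_gxe=beta_gxe,
        assigned_cis_variant=assigned_variant,
        assigned_variable=assigned_var,
        confounders=conf,
        confounder_loadings=load,
        cell_props=pd.DataFrame(props, index=config.sample_ids,
                                columns=list(CELL_TYPES)),
        cell_loadings=cell_load,
        base_log_abundance=base,
        libsizes=libsizes,
    )


def gen_phenotypes(config: SimConfig, truth: TruthSet) -> pd.DataFrame:
    """Observed phenotype table: latent + Gaussian noise, with missingness.

    Returns a samples x variables DataFrame whose ``attrs["categories"]``
    maps each variable to its category label.  ``missing_fraction`` of the
    samples are set missing per variable (seeded).
    """
    if config.missing_fraction >= 1.0:
        raise SimConfigError("missing_fraction must be < 1")
    rng = config.rng(_STAGE_PHENOTYPES)
    latent = truth.latent_traits.to_numpy()
    obs = latent + rng.normal(0.0, config.noise_sd_phenotype, size=latent.shape)
    n = config.n_samples
    n_miss = int(round(config.missing_fraction * n))
    for j in range(obs.shape[1]):
        if n_miss > 0:
            idx = rng.choice(n, size=n_miss, replace=False)
            obs[idx, j] = np.nan
    df = pd.DataFrame(obs, index=truth.latent_traits.index,
                      columns=truth.latent_traits.columns)
    df.attrs["categories"] = dict(
        zip(config.variable_names, config.variable_categories)
    )
    return df


def expression_log_mean(
    config: SimConfig, genotypes: GenotypeMatrix, truth: TruthSet
) -> np.ndarray:
    """Per gene x sample log of the NB mean (before count sampling)."""
    n_g, n_s = config.n_genes, config.n_samples
    dos = genotypes.dosages.to_numpy()
    latent = truth.latent_traits.to_numpy()

    eta = np.tile(truth.base_log_abundance[:, None], (1, n_s))
    has_var = truth.assigned_cis_variant >= 0
    if has_var.any():
        d = dos[truth.assigned_cis_variant[has_var], :]
        eta[has_var] += truth.beta_g[has_var, None] * d
    has_env = truth.assigned_variable >= 0
    if has_env.any():
        e = latent[:, truth.assigned_variable[has_env]].T
        eta[has_env] += truth.beta_e[has_env, None] * e
    both = has_var & has_env
    if both.any():
        d = dos[truth.assigned_cis_variant[both], :]
        e = latent[:, truth.assigned_variable[both]].T
        eta[both] += truth.beta_gxe[both, None] * d * e

    eta += truth.confounder_loadings @ truth.confounders.T
    logp = np.log(truth.cell_props.to_numpy())
    clr = logp - logp.mean(axis=1, keepdims=True)
    eta += truth.cell_loadings @ clr.T

    # normalise relative abundances so column sums track libsizes
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        rel = np.exp(eta)
        rel /= rel.sum(axis=0, keepdims=True)
        mu = rel * truth.libsizes[None, :]
        logmu = np.log(mu)
    if not np.all(np.isfinite(logmu)):
        g, s = np.argwhere(~np.isfinite(logmu))[0]
        raise FloatingPointError(
            f"nonfinite expression log-mean at gene {config.gene_ids[g]} "
            f"sample {config.sample_ids[s]}"
        )
    return logmu


def gen_expression(
    config: SimConfig, genotypes: GenotypeMatrix, truth: TruthSet,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Negative-binomial counts (genes x samples).

    var = mu + nb_dispersion * mu^2 (size = 1/dispersion); dispersion 0
    degenerates to Poisson.
    """
    if rng is None:
        rng = config.rng(_STAGE_EXPRESSION)
    mu = np.exp(expression_log_mean(config, genotypes, truth))
    disp = config.nb_dispersion
    if disp < 1e-12:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / disp
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)
    return pd.DataFrame(counts, index=config.gene_ids, columns=config.sample_ids)


@dataclass
class CohortBundle:
    """One wave of a simulated cohort."""

    config: SimConfig
    genotypes: GenotypeMatrix
    counts: pd.DataFrame  # genes x samples
    phenotypes: pd.DataFrame  # samples x variables
    annotation: pd.DataFrame
    truth: TruthSet


def simulate_cohort(config: SimConfig) -> CohortBundle:
    """Generate a full single-wave cohort."""
    genotypes = gen_genotypes(config)
    truth = gen_truth(config, genotypes)
    phenotypes = gen_phenotypes(config, truth)
    counts = gen_expression(config, genotypes, truth)
    return CohortBundle(
        config=config,
        genotypes=genotypes,
        counts=counts,
        phenotypes=phenotypes,
        annotation=gene_annotation(config),
        truth=truth,
    )


def gen_longitudinal_pair(
    config: SimConfig,
    drift_sd: float = 1.0,
    wave2_fraction: float = 1.0,
    drift_variables: Sequence[str] | None = None,
) -> tuple[CohortBundle, CohortBundle, TruthSet]:
    """Two-wave cohort: wave-2 latents = wave-1 latents + per-sample drift.

    Genotypes are identical across waves; expression and phenotype noise are
    redrawn at wave 2; a ``wave2_fraction`` subset of samples returns.
    Returns (wave1, wave2, wave1 truth); wave-2 truth is in the second bundle.
    """
    if not (0.0 < wave2_fraction <= 1.0):
        raise SimConfigError("wave2_fraction must be in (0, 1]")
    wave1 = simulate_cohort(config)
    rng = config.rng(_STAGE_WAVE2)

    latent2 = wave1.truth.latent_traits.copy()
    if drift_variables is None:
        drift_cols = list(latent2.columns)
    else:
        missing = set(drift_variables) - set(latent2.columns)
        if missing:
            raise SimConfigError(f"unknown drift variables: {sorted(missing)}")
        drift_cols = list(drift_variables)
    drift = rng.normal(0.0, drift_sd, size=(len(latent2), len(drift_cols)))
    latent2.loc[:, drift_cols] = latent2.loc[:, drift_cols].to_numpy() + drift

    truth2 = dataclasses.replace(wave1.truth, latent_traits=latent2)

    obs2 = latent2.to_numpy() + rng.normal(
        0.0, config.noise_sd_phenotype, size=latent2.shape
    )
    pheno2 = pd.DataFrame(obs2, index=latent2.index, columns=latent2.columns)
    pheno2.attrs["categories"] = dict(
        zip(config.variable_names, config.variable_categories)
    )
    counts2 = gen_expression(config, wave1.genotypes, truth2, rng=rng)

    n2 = int(round(wave2_fraction * config.n_samples))
    keep = pd.Index(sorted(rng.choice(config.n_samples, size=n2, replace=False)))
    keep_ids = latent2.index[keep]
    if not set(keep_ids).issubset(set(wave1.counts.columns)):
        raise SimConfigError("wave2 sample set must be a subset of wave1")

    wave2 = CohortBundle(
        config=config,
        genotypes=GenotypeMatrix(
            dosages=wave1.genotypes.dosages.loc[:, keep_ids],
            meta=wave1.genotypes.meta,
        ),
        counts=counts2.loc[:, keep_ids],
        phenotypes=pheno2.loc[keep_ids],
        annotation=wave1.annotation,
        truth=truth2,
    )
    return wave1, wave2, wave1.truth
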