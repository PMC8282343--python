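"""Readers and writers for the pipeline's on-disk dialects.

All tables are plain text: counts and dosage matrices as TSV, genotypes
optionally as VCF with a DS FORMAT field, a BED-like gene annotation, a
phenotype table whose second header row carries category labels, truth sets
as JSON, and the two association-result layouts (11-column space-delimited
eQTL table, 21-column tab-delimited GxE table).  Chromosome names are
normalised internally by stripping any "chr" prefix.  Floats are printed
with 6 significant digits; integers unformatted.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ciseqtl import EQTL_COLUMNS
from .gxe import GXE_COLUMNS
from .simdata import GenotypeMatrix, TruthSet


class IOError_(ValueError):
    pass


FLOAT_FMT = "%.6g"


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dups = index[index.duplicated()].unique().tolist()
        raise IOError_(f"duplicated {what}: {dups[:10]}")


def _norm_chrom(c) -> str:
    s = str(c)
    return s[3:] if s.lower().startswith("chr") else s


# ---------------------------------------------------------------------------
# counts / expression
# ---------------------------------------------------------------------------

def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "gene ids in counts")
    _check_unique(df.columns, "sample ids in counts")
    return df


def write_matrix(mat: pd.DataFrame, path, index_label: str = "id") -> None:
    mat.to_csv(path, sep="\t", index_label=index_label,
               float_format=FLOAT_FMT)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_dosages(genotypes: GenotypeMatrix, path) -> None:
    """TSV dialect: variant_id, chrom, pos, then one dosage column per sample."""
    out = pd.concat(
        [genotypes.meta[["chrom", "pos"]], genotypes.dosages], axis=1
    )
    out.to_csv(path, sep="\t", index_label="variant_id",
               float_format=FLOAT_FMT)


def read_dosages(path) -> GenotypeMatrix:
    """Read the dosage TSV dialect; validates dosages lie in [0, 2]."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "variant ids")
    meta = df[["chrom", "pos"]].copy()
    meta["chrom"] = meta["chrom"].map(_norm_chrom)
    dosages = df.drop(columns=["chrom", "pos"]).astype(float)
    bad = np.argwhere((dosages.to_numpy() < 0) | (dosages.to_numpy() > 2))
    if len(bad):
        r, c = bad[0]
        raise IOError_(
            f"dosage outside [0, 2] at line {r + 2} "
            f"(variant {dosages.index[r]}, sample {dosages.columns[c]})"
        )
    return GenotypeMatrix(dosages=dosages, meta=meta)


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with a DS FORMAT field (dosages)."""
    samples = list(genotypes.dosages.columns)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Genotype dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for vid, row in genotypes.dosages.iterrows():
            chrom = genotypes.meta.loc[vid, "chrom"]
            pos = genotypes.meta.loc[vid, "pos"]
            ds = "\t".join(FLOAT_FMT % v for v in row)
            fh.write(f"{chrom}\t{pos}\t{vid}\tA\tG\t.\t.\t.\tDS\t{ds}\n")


def read_vcf_dosages(path) -> GenotypeMatrix:
    """Read dosages from a VCF's DS FORMAT field (cyvcf2 when available)."""
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - cyvcf2 is a soft dependency
        return _read_vcf_dosages_text(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, rows = [], [], [], []
    for var in vcf:
        ds = var.format("DS")
        if ds is None:
            raise IOError_(f"variant {var.ID} has no DS field")
        ids.append(var.ID)
        chroms.append(_norm_chrom(var.CHROM))
        poss.append(var.POS)
        rows.append(np.asarray(ds, float).ravel())
    dosages = pd.DataFrame(rows, index=ids, columns=samples)
    if ((dosages.to_numpy() < 0) | (dosages.to_numpy() > 2)).any():
        raise IOError_("VCF DS values outside [0, 2]")
    meta = pd.DataFrame({"chrom": chroms, "pos": poss}, index=ids)
    return GenotypeMatrix(dosages=dosages, meta=meta)


def _read_vcf_dosages_text(path) -> GenotypeMatrix:
    samples: list[str] = []
    ids, chroms, poss, rows = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            fmt = fields[8].split(":")
            if "DS" not in fmt:
                raise IOError_(f"no DS field at line {lineno}")
            dsi = fmt.index("DS")
            vals = [float(f.split(":")[dsi]) for f in fields[9:]]
            ids.append(fields[2])
            chroms.append(_norm_chrom(fields[0]))
            poss.append(int(fields[1]))
            rows.append(vals)
    dosages = pd.DataFrame(rows, index=ids, columns=samples, dtype=float)
    meta = pd.DataFrame({"chrom": chroms, "pos": poss}, index=ids)
    return GenotypeMatrix(dosages=dosages, meta=meta)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def write_annotation(annotation: pd.DataFrame, path, bed_style: bool = False) -> None:
    """Annotation TSV (gene_id, chrom, tss, strand).

    With ``bed_style`` the TSS is stored 0-based as (start, end) = (tss-1,
    tss), the BED convention.
    """
    out = annotation.copy()
    if bed_style:
        out = pd.DataFrame({
            "chrom": out["chrom"],
            "start": out["tss"].astype(int) - 1,
            "end": out["tss"].astype(int),
            "strand": out["strand"],
        }, index=out.index)
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "gene ids in annotation")
    df["chrom"] = df["chrom"].map(_norm_chrom)
    if "tss" not in df.columns:
        if {"start", "end"} <= set(df.columns):
            minus = df.get("strand", "+").astype(str) == "-"
            # BED start is 0-based; the 1-based TSS is start+1 (+) or end (-)
            df["tss"] = np.where(minus, df["end"], df["start"] + 1).astype(int)
        else:
            raise IOError_("annotation needs tss or start/end columns")
    return df


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    """Sample-rows TSV whose second header row carries category labels."""
    cats = phenotypes.attrs.get("categories", {})
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(phenotypes.columns) + "\n")
        fh.write("category\t" + "\t".join(
            str(cats.get(c, "uncategorized")) for c in phenotypes.columns
        ) + "\n")
        for sid, row in phenotypes.iterrows():
            vals = "\t".join(
                "NA" if pd.isna(v) else FLOAT_FMT % v for v in row
            )
            fh.write(f"{sid}\t{vals}\n")


def read_phenotypes(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        catrow = fh.readline().rstrip("\n").split("\t")
        df = pd.read_csv(fh, sep="\t", names=header, index_col=0,
                         na_values=["NA"])
    _check_unique(df.index, "sample ids in phenotypes")
    df.attrs["categories"] = dict(zip(header[1:], catrow[1:]))
    return df


# ---------------------------------------------------------------------------
# truth, results
# ---------------------------------------------------------------------------

def write_truth(truth: TruthSet, path) -> None:
    Path(path).write_text(truth.to_json())


def read_truth(path) -> TruthSet:
    return TruthSet.from_json(Path(path).read_text())


def write_eqtl_table(records: pd.DataFrame, path) -> None:
    """11-column space-delimited permutation-pass table (FastQTL layout)."""
    records[EQTL_COLUMNS].to_csv(path, sep=" ", index=False,
                                 float_format=FLOAT_FMT)


def read_eqtl_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=" ")
    missing = set(EQTL_COLUMNS) - set(df.columns)
    if missing:
        raise IOError_(f"eQTL table missing columns: {sorted(missing)}")
    return df[EQTL_COLUMNS]


def write_gxe_table(records: pd.DataFrame, path) -> None:
    """21-column tab-delimited interaction-eQTL table."""
    records[GXE_COLUMNS].to_csv(path, sep="\t", index=False,
                                float_format=FLOAT_FMT)


def read_gxe_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(GXE_COLUMNS) - set(df.columns)
    if missing:
        raise IOError_(f"GxE table missing columns: {sorted(missing)}")
    return df[GXE_COLUMNS]


def write_signature_weights(models: dict, path) -> None:
    """Model-weight table: genes in rows, signatures in columns (zeros blank)."""
    cols = {}
    for name, model in models.items():
        cols[name] = model.weights
    df = pd.DataFrame(cols)
    df.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT)


def read_twas_table(path) -> pd.DataFrame:
    """External TWAS summary: gene_id, trait, p, significant columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "trait", "significant"}
    missing = required - set(df.columns)
    if missing:
        raise IOError_(f"TWAS table missing columns: {sorted(missing)}")
    return df


def align_samples(
    tables: dict[str, pd.Index],
    mode: str = "intersect",
) -> pd.Index:
    """Reconcile sample sets across inputs.

    ``mode="intersect"`` returns the common samples (in the order of the
    first table); ``mode="error"`` raises when the sets differ.
    """
    names = list(tables)
    common = tables[names[0]]
    for name in names[1:]:
        common = common.intersection(tables[name])
    if mode == "error":
        for name in names:
            extra = tables[name].difference(common)
            if len(extra):
                raise IOError_(
                    f"samples in {name} missing elsewhere: {list(extra)[:5]}"
                )
    elif mode != "intersect":
        raise IOError_(f"unknown sample alignment mode {mode!r}")
    first = tables[names[0]]
    return first[first.isin(common)]
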