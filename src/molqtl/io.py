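"""Tab-delimited readers/writers with strict schema validation.

Everything round-trips through plain TSV so every artifact stays
human-diffable. Genomic coordinates are written 1-based inclusive; lists
(gene ids, isoform ids) are comma-joined; replicate columns are encoded
as ``strain|replicate``.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import AnnotationSet, DataError, GenotypeMatrix, PhenotypeMatrix


def read_table(path, required_columns, index_col=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in ()} or None)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")
    if index_col is not None:
        if df[index_col].duplicated().any():
            dup = df.loc[df[index_col].duplicated(), index_col].iloc[0]
            raise DataError(f"{path}: duplicate id {dup!r} in column {index_col}")
        df = df.set_index(index_col)
    return df


def write_table(df: pd.DataFrame, path, index=True):
    df.to_csv(path, sep="\t", index=index, na_rep="NA")


# --- genotypes --------------------------------------------------------------

def write_genotypes(geno: GenotypeMatrix, path):
    df = geno.to_frame()
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def read_genotypes(path) -> GenotypeMatrix:
    df = read_table(path, ["snp_id", "chrom", "pos_bp"], index_col="snp_id")
    strains = [c for c in df.columns if c not in ("chrom", "pos_bp")]
    for col in strains:
        vals = pd.to_numeric(df[col], errors="coerce")
        raw_missing = df[col].isna() | df[col].astype(str).str.upper().eq("NA")
        bad = vals.isna() & ~raw_missing
        bad |= ~vals.isin([0, 1]) & ~vals.isna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise DataError(
                f"{path}: non-{{0,1,NA}} genotype call at SNP {row}, strain {col}"
            )
        df[col] = vals
    return GenotypeMatrix.from_frame(df)


# --- phenotypes -------------------------------------------------------------

def write_phenotypes(mat: PhenotypeMatrix, path):
    df = mat.values.copy()
    if mat.has_replicates:
        df.columns = [f"{s}|{r}" for s, r in df.columns]
    df.to_csv(path, sep="\t", na_rep="NA")


def read_phenotypes(path, kind: str) -> PhenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.index.duplicated().any():
        raise DataError(f"{path}: duplicate feature ids")
    if any("|" in str(c) for c in df.columns):
        tuples = [tuple(str(c).split("|", 1)) for c in df.columns]
        df.columns = pd.MultiIndex.from_tuples(tuples, names=["strain", "replicate"])
    return PhenotypeMatrix(values=df.astype(float), kind=kind)


# --- annotations ------------------------------------------------------------

def write_annotations(ann: AnnotationSet, out_dir):
    out_dir = str(out_dir)
    genes = ann.genes.reset_index()
    bed = genes[["chrom", "tss_bp", "tes_bp", "gene_id", "strand"]]
    bed.to_csv(f"{out_dir}/genes.tsv", sep="\t", index=False)

    ps = ann.probesets.copy()
    ps["gene_ids"] = ps["gene_ids"].apply(",".join)
    ps.to_csv(f"{out_dir}/probesets.tsv", sep="\t")
    ann.probes.to_csv(f"{out_dir}/probes.tsv", sep="\t", index=False)

    pep = ann.peptides.copy()
    pep["gene_ids"] = pep["gene_ids"].apply(",".join)
    pep["isoform_ids"] = pep["isoform_ids"].apply(",".join)
    pep.to_csv(f"{out_dir}/peptide_annotations.tsv", sep="\t")

    rows = [(t, ns, g) for t, (ns, gs) in ann.groups.items() for g in gs]
    pd.DataFrame(rows, columns=["term_id", "namespace", "gene_id"]).to_csv(
        f"{out_dir}/groups.tsv", sep="\t", index=False
    )


def read_annotations(in_dir) -> AnnotationSet:
    in_dir = str(in_dir)
    bed = read_table(f"{in_dir}/genes.tsv",
                     ["chrom", "tss_bp", "tes_bp", "gene_id", "strand"])
    if (bed["tss_bp"] > bed["tes_bp"]).any():
        row = bed.loc[bed["tss_bp"] > bed["tes_bp"]].iloc[0]
        raise DataError(f"genes.tsv: start > end for {row['gene_id']}")
    genes = bed.set_index("gene_id")[["chrom", "tss_bp", "tes_bp", "strand"]]

    ps = read_table(f"{in_dir}/probesets.tsv", ["probeset_id", "gene_ids"],
                    index_col="probeset_id")
    ps["gene_ids"] = ps["gene_ids"].apply(lambda s: tuple(str(s).split(",")))
    probes = read_table(f"{in_dir}/probes.tsv",
                        ["probeset_id", "chrom", "start_bp", "end_bp"])

    pep = read_table(f"{in_dir}/peptide_annotations.tsv",
                     ["peptide_id", "sequence", "gene_ids", "isoform_ids"],
                     index_col="peptide_id")
    pep["gene_ids"] = pep["gene_ids"].apply(lambda s: tuple(str(s).split(",")))
    pep["isoform_ids"] = pep["isoform_ids"].apply(lambda s: tuple(str(s).split(",")))

    grp = read_table(f"{in_dir}/groups.tsv", ["term_id", "namespace", "gene_id"])
    groups = {
        t: (sub["namespace"].iloc[0], list(sub["gene_id"]))
        for t, sub in grp.groupby("term_id")
    }
    return AnnotationSet(genes=genes, probesets=ps, probes=probes,
                         peptides=pep, groups=groups)


# --- truth ------------------------------------------------------------------

def write_truth(truth, out_dir):
    out_dir = str(out_dir)
    truth.heritability.rename("heritability").to_csv(
        f"{out_dir}/truth_heritability.tsv", sep="\t",
        index_label="feature_id")
    truth.qtls.to_csv(f"{out_dir}/truth_qtls.tsv", sep="\t", index=False)
    truth.trait_drivers.to_csv(f"{out_dir}/truth_trait_drivers.tsv", sep="\t",
                               index=False)
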