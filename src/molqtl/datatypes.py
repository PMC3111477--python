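"""Core data containers shared across the pipeline.

All phenotype values are log2-scale real numbers; genotype calls are
homozygous inbred codes in {0, 1} with NaN for missing. Genomic
coordinates are 1-based inclusive throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class ConfigError(ValueError):
    """Invalid simulator or pipeline configuration."""


class DataError(ValueError):
    """Input data violates a precondition."""


@dataclass
class SimConfig:
    """Parameters of the synthetic inbred-panel generator.

    Defaults emulate a ~100-strain mouse panel profiled for liver
    transcripts (3 biological replicates/strain) and peptides (one
    sample/strain plus 10 technical replicates of a reference strain).
    Sizes are deliberately desk-scale; raise ``n_snps``/``n_transcripts``
    for panel-scale runs.
    """

    n_strains: int = 97
    n_chromosomes: int = 19
    chrom_length_bp: int = 100_000_000
    n_snps: int = 2_000
    ld_block_mean_bp: int = 730_000
    maf_min: float = 0.10
    n_genes: Optional[int] = None          # None -> derived from n_transcripts
    n_transcripts: int = 300
    n_peptides: int = 400
    n_traits: int = 42
    n_bio_replicates_transcript: int = 3
    n_tech_replicates_peptide: int = 10
    heritability_range: tuple = (0.07, 0.95)
    frac_local_qtl: float = 0.30
    frac_distant_qtl: float = 0.30
    effect_size_range: tuple = (0.2, 0.5)  # fraction of genetic variance per QTL
    tech_noise_sd: float = 0.30
    tech_noise_dispersion: float = 0.75    # lognormal sigma of per-peptide tech noise
    missing_rate_peptide: float = 0.10
    n_families: int = 5                    # related strain subgroups (RI sets)
    frac_family_snps: float = 0.4          # blocks whose founder follows family lines
    frac_internal_kr: float = 0.25         # peptides carrying an internal K/R
    frac_multi_gene_peptide: float = 0.10  # peptides mapping ambiguously to 2 genes
    frac_multi_gene_probeset: float = 0.19
    max_isoform_clusters: int = 2
    frac_multi_isoform_peptide: float = 0.05
    n_probes_per_probeset: int = 11
    n_groups: int = 40
    group_size_range: tuple = (5, 40)
    trait_noise_sd: float = 0.5
    genotype_flip_rate: float = 0.03
    reference_strain_index: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_strains < 3:
            raise ConfigError("n_strains must be >= 3")
        if not (0 <= self.maf_min < 0.5):
            raise ConfigError("maf_min must lie in [0, 0.5)")
        if self.n_snps < self.n_chromosomes:
            raise ConfigError("n_snps must be >= n_chromosomes")
        lo, hi = self.heritability_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigError("heritability_range must be ordered within [0, 1]")
        for name in ("frac_local_qtl", "frac_distant_qtl", "missing_rate_peptide",
                     "frac_internal_kr", "frac_multi_gene_peptide",
                     "frac_multi_gene_probeset", "frac_multi_isoform_peptide"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must lie in [0, 1]")
        elo, ehi = self.effect_size_range
        if not (0 <= elo <= ehi <= 1):
            raise ConfigError("effect_size_range must be ordered within [0, 1]")
        if self.tech_noise_sd <= 0:
            raise ConfigError("tech_noise_sd must be positive")
        if not (0 <= self.reference_strain_index < self.n_strains):
            raise ConfigError("reference_strain_index out of range")

    @property
    def n_genes_effective(self) -> int:
        if self.n_genes is not None:
            return self.n_genes
        return max(10, int(round(0.75 * self.n_transcripts)))

    def child_seed(self, stage: str) -> int:
        """Fan the global seed out to a per-stage seed (< 2**31)."""
        h = self.seed & 0x7FFFFFFF
        for ch in stage:
            h = (h * 31 + ord(ch)) & 0xFFFFFFFF
        return h & 0x7FFFFFFF


@dataclass
class GenotypeMatrix:
    """Strains x SNPs homozygous calls with genomic coordinates."""

    strain_ids: list
    snp_ids: list
    chrom: np.ndarray       # str per SNP
    pos_bp: np.ndarray      # int per SNP, 1-based
    calls: np.ndarray       # (n_strains, n_snps) float in {0,1,nan}

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.strain_ids), len(self.snp_ids)):
            raise DataError("calls shape does not match strain/snp ids")
        ok = np.isnan(self.calls) | (self.calls == 0) | (self.calls == 1)
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise DataError(
                f"non-{{0,1,NA}} genotype call at strain "
                f"{self.strain_ids[bad[0]]}, SNP {self.snp_ids[bad[1]]}"
            )
        # positions must increase strictly within each chromosome
        for c in pd.unique(self.chrom):
            p = self.pos_bp[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise DataError(f"positions not strictly increasing on {c}")

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP over non-missing strains."""
        freq = np.nanmean(self.calls, axis=0)
        return np.minimum(freq, 1.0 - freq)

    def missingness(self) -> np.ndarray:
        return np.mean(np.isnan(self.calls), axis=0)

    def snp_index(self) -> pd.Index:
        return pd.Index(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.calls.T, index=self.snp_ids, columns=self.strain_ids)
        df.insert(0, "chrom", self.chrom)
        df.insert(1, "pos_bp", self.pos_bp)
        df.index.name = "snp_id"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        strains = [c for c in df.columns if c not in ("chrom", "pos_bp")]
        return cls(
            strain_ids=list(strains),
            snp_ids=list(df.index),
            chrom=df["chrom"].to_numpy(dtype=object),
            pos_bp=df["pos_bp"].to_numpy(dtype=np.int64),
            calls=df[strains].to_numpy(dtype=float).T,
        )


@dataclass
class PhenotypeMatrix:
    """Features x strain(/replicate) log2-scale measurements.

    ``values`` has feature ids as rows. Columns are either plain strain
    ids, or a (strain, replicate) MultiIndex when a replicate axis is
    present. ``kind`` tags the dataset: transcript, peptide, or trait.
    """

    values: pd.DataFrame
    kind: str = "transcript"

    def __post_init__(self):
        if self.kind not in ("transcript", "peptide", "trait"):
            raise DataError(f"unknown phenotype kind: {self.kind}")
        inf = np.isinf(self.values.to_numpy(dtype=float, na_value=np.nan))
        if inf.any():
            raise DataError("phenotype values must be finite or missing")

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    @property
    def has_replicates(self) -> bool:
        return isinstance(self.values.columns, pd.MultiIndex)

    @property
    def strain_ids(self) -> list:
        if self.has_replicates:
            return list(pd.unique(self.values.columns.get_level_values(0)))
        return list(self.values.columns)

    def strain_means(self) -> pd.DataFrame:
        """Average over replicates (identity if no replicate axis)."""
        if not self.has_replicates:
            return self.values
        out = self.values.T.groupby(level=0, sort=False).mean().T
        return out[self.strain_ids]


@dataclass
class AnnotationSet:
    """Gene models, probe layouts, peptide annotations, and group memberships.

    genes:     index gene_id -> chrom, tss_bp, tes_bp, strand
    probesets: index probeset_id -> gene_ids (tuple, possibly ambiguous)
    probes:    long table: probeset_id, chrom, start_bp, end_bp (25-mers)
    peptides:  index peptide_id -> sequence, gene_ids (tuple), isoform_ids
               (tuple), chrom, exon_start_bp, exon_end_bp
    groups:    dict term_id -> (namespace in {CC, MF, BP, pathway}, [gene_id])
    """

    genes: pd.DataFrame
    probesets: pd.DataFrame
    probes: pd.DataFrame
    peptides: pd.DataFrame
    groups: dict = field(default_factory=dict)

    def __post_init__(self):
        bad = self.genes[self.genes["tss_bp"] > self.genes["tes_bp"]]
        if len(bad):
            raise DataError(f"gene with tss_bp > tes_bp: {bad.index[0]}")
        if len(self.probes):
            lengths = self.probes["end_bp"] - self.probes["start_bp"] + 1
            if not (lengths == 25).all():
                raise DataError("all probe intervals must span exactly 25 bases")
        known = set(self.genes.index)
        for pid, row in self.peptides.iterrows():
            seq = row["sequence"]
            if not seq or not isinstance(seq, str):
                raise DataError(f"peptide {pid} has no sequence")
            if any(aa not in AMINO_ACIDS for aa in seq):
                raise DataError(f"peptide {pid} sequence has a non-standard residue")
            for g in row["gene_ids"]:
                if g not in known:
                    raise DataError(f"peptide {pid} annotated to unknown gene {g}")

    def unique_gene_of_probeset(self) -> pd.Series:
        """probeset_id -> gene_id for unambiguously annotated probesets."""
        s = self.probesets["gene_ids"].apply(lambda g: g[0] if len(g) == 1 else None)
        return s.dropna()

    def unique_gene_of_peptide(self) -> pd.Series:
        s = self.peptides["gene_ids"].apply(lambda g: g[0] if len(g) == 1 else None)
        return s.dropna()


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator for recovery testing.

    heritability:  feature_id -> target intraclass correlation
    qtls:          feature_id, snp_id, effect_var (fraction of the
                   feature's total single-replicate variance), locality
    trait_drivers: trait_id, feature_id, coefficient
    """

    heritability: pd.Series
    qtls: pd.DataFrame
    trait_drivers: pd.DataFrame
    gene_of_feature: pd.Series
    seed: int = 0

    def __post_init__(self):
        if len(self.qtls):
            tot = self.qtls.groupby("feature_id")["effect_var"].sum()
            h2 = self.heritability.reindex(tot.index)
            if (tot > h2 + 1e-9).any():
                raise ConfigError("QTL effect variance exceeds heritability target")


def config_to_dict(cfg: SimConfig) -> dict:
    return {f.name: getattr(cfg, f.name) for f in fields(cfg)}
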