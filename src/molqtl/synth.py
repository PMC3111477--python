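"""Synthetic inbred-panel generator with known ground truth.

Emulates a hybrid mouse diversity panel style experiment: block-structured
LD genotypes over ~100 fully homozygous strains, liver transcripts measured
in replicate on all strains, peptides measured once per strain plus
technical replicate runs of one reference strain, and clinical traits
driven by subsets of the molecular phenotypes.

The genetic architecture is gene-centric: each gene (or isoform cluster
within a gene) carries one standardized genetic profile across strains,
built from planted local/distant QTL effects plus a polygenic remainder.
Every feature of that gene mixes the shared profile (at its own
heritability) with feature-specific noise, which is what induces realistic
transcript-peptide concordance downstream.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    AMINO_ACIDS,
    AnnotationSet,
    ConfigError,
    DataError,
    GenotypeMatrix,
    PhenotypeMatrix,
    SimConfig,
    SimTruth,
)

LOCAL_WINDOW_BP = 2_000_000  # flank used when planting "local" QTLs


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(cfg: SimConfig):
    """Simulate block-structured homozygous genotypes.

    Returns ``(GenotypeMatrix, block_ids)`` where ``block_ids`` assigns each
    SNP to its true LD block. Within a block every SNP is a noisy copy of a
    founder strain-assignment column; across blocks founders are drawn
    independently. SNPs below the minor-allele-frequency floor are redrawn.
    """
    rng = np.random.default_rng(cfg.child_seed("genotypes"))
    n = cfg.n_strains
    # strains belong to related subgroups (classic + recombinant-inbred
    # sets); a fraction of blocks segregate along family lines, which is
    # what gives the panel its genome-wide population structure
    families = rng.integers(0, max(1, cfg.n_families), size=n)

    # spread SNPs over chromosomes as evenly as possible
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1

    chroms, positions, columns, block_ids = [], [], [], []
    structured_flags = []
    block_counter = 0
    for ci in range(cfg.n_chromosomes):
        m = int(per_chrom[ci])
        if m == 0:
            continue
        name = f"chr{ci + 1}"
        pos = np.sort(rng.choice(cfg.chrom_length_bp, size=m, replace=False)) + 1

        # tile the chromosome with exponential-length blocks
        edges = [0]
        while edges[-1] < cfg.chrom_length_bp:
            edges.append(edges[-1] + max(1, int(rng.exponential(cfg.ld_block_mean_bp))))
        edges = np.asarray(edges[1:])
        snp_block = np.searchsorted(edges, pos)  # local block index per SNP

        for b in np.unique(snp_block):
            idx = np.where(snp_block == b)[0]
            is_family = rng.random() < cfg.frac_family_snps
            if is_family:
                founder = _draw_family_founder(rng, families, cfg.maf_min)
            else:
                founder = _draw_founder(rng, n, cfg.maf_min)
            for _ in idx:
                columns.append(_mutate_column(rng, founder, cfg))
            block_ids.extend([block_counter] * len(idx))
            structured_flags.extend([is_family] * len(idx))
            block_counter += 1

        chroms.extend([name] * m)
        positions.extend(pos.tolist())

    calls = np.array(columns, dtype=float).T  # strains x snps
    snp_ids = [f"rs{i:06d}" for i in range(calls.shape[1])]
    strain_ids = [f"S{i:03d}" for i in range(n)]
    geno = GenotypeMatrix(
        strain_ids=strain_ids,
        snp_ids=snp_ids,
        chrom=np.asarray(chroms, dtype=object),
        pos_bp=np.asarray(positions, dtype=np.int64),
        calls=calls,
    )
    # family-aligned SNPs carry genome-wide structure and are not locally
    # mappable once kinship is corrected for; the truth generator uses the
    # flag to plant identifiable local effects
    geno.family_structured = np.asarray(structured_flags, dtype=bool)
    return geno, np.asarray(block_ids, dtype=int)


def _draw_founder(rng, n_strains, maf_min):
    p = rng.uniform(max(0.20, maf_min + 0.02), 0.80)
    col = (rng.random(n_strains) < p).astype(float)
    return _enforce_maf(rng, col, maf_min)


def _draw_family_founder(rng, families, maf_min):
    """Founder allele assigned per strain family, not per strain."""
    n_fam = families.max() + 1
    for _ in range(20):
        fam_allele = (rng.random(n_fam) < 0.5).astype(float)
        col = fam_allele[families]
        if maf_ok(col.mean(), maf_min, col.size):
            return col
    return _enforce_maf(rng, fam_allele[families], maf_min)


def _mutate_column(rng, founder, cfg):
    col = founder.copy()
    flips = rng.random(col.size) < cfg.genotype_flip_rate
    col[flips] = 1.0 - col[flips]
    for _ in range(20):
        f = col.mean()
        if maf_ok(f, cfg.maf_min, col.size):
            return col
        col = founder.copy()
        flips = rng.random(col.size) < cfg.genotype_flip_rate
        col[flips] = 1.0 - col[flips]
    return _enforce_maf(rng, col, cfg.maf_min)


def maf_ok(freq, maf_min, n):
    return min(freq, 1.0 - freq) >= maf_min - 1e-12


def _enforce_maf(rng, col, maf_min):
    """Flip randomly chosen strains until the MAF floor holds."""
    n = col.size
    need = int(np.ceil(maf_min * n))
    while min(col.sum(), n - col.sum()) < need:
        major = 1.0 if col.sum() > n / 2 else 0.0
        idx = rng.choice(np.where(col == major)[0])
        col[idx] = 1.0 - major
    return col


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def simulate_annotations(cfg: SimConfig) -> AnnotationSet:
    """Place genes, probesets (25-mer probes), tryptic peptides, and groups."""
    rng = np.random.default_rng(cfg.child_seed("annotations"))
    n_genes = cfg.n_genes_effective

    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    chrom = np.asarray(
        [f"chr{c + 1}" for c in rng.integers(0, cfg.n_chromosomes, n_genes)],
        dtype=object,
    )
    span = rng.integers(2_000, 200_000, n_genes)
    tss = rng.integers(1, cfg.chrom_length_bp - span - 1)
    genes = pd.DataFrame(
        {
            "chrom": chrom,
            "tss_bp": tss,
            "tes_bp": tss + span,
            "strand": rng.choice(["+", "-"], n_genes),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    # --- probesets: one gene each, a fraction ambiguously annotated --------
    ps_ids = [f"PS{i:05d}" for i in range(cfg.n_transcripts)]
    ps_gene = [gene_ids[i % n_genes] for i in range(cfg.n_transcripts)]
    gene_tuples = []
    for g in ps_gene:
        if rng.random() < cfg.frac_multi_gene_probeset:
            other = gene_ids[int(rng.integers(n_genes))]
            gene_tuples.append(tuple(sorted({g, other})) if other != g else (g,))
        else:
            gene_tuples.append((g,))
    probesets = pd.DataFrame(
        {"gene_ids": gene_tuples}, index=pd.Index(ps_ids, name="probeset_id")
    )

    probe_rows = []
    for pid, g in zip(ps_ids, ps_gene):
        row = genes.loc[g]
        lo, hi = int(row["tss_bp"]), int(row["tes_bp"])
        for _ in range(cfg.n_probes_per_probeset):
            start = int(rng.integers(lo, max(lo + 1, hi - 24)))
            probe_rows.append((pid, row["chrom"], start, start + 24))
    probes = pd.DataFrame(
        probe_rows, columns=["probeset_id", "chrom", "start_bp", "end_bp"]
    )

    # --- peptides: clustered on a gene subset so genes get 1..20 peptides --
    pool = rng.choice(n_genes, size=min(n_genes, max(1, cfg.n_peptides // 3)),
                      replace=False)
    weights = rng.dirichlet(np.full(pool.size, 0.6))
    pep_gene_idx = rng.choice(pool, size=cfg.n_peptides, p=weights)
    pep_ids = [f"PEP{i:05d}" for i in range(cfg.n_peptides)]

    cluster_of_gene = {}
    rows = []
    for pid, gi in zip(pep_ids, pep_gene_idx):
        g = gene_ids[int(gi)]
        if rng.random() < cfg.frac_multi_gene_peptide:
            other = gene_ids[int(rng.integers(n_genes))]
            gtuple = tuple(sorted({g, other})) if other != g else (g,)
        else:
            gtuple = (g,)
        n_clusters = cluster_of_gene.setdefault(
            g, int(rng.integers(1, cfg.max_isoform_clusters + 1))
        )
        primary = int(rng.integers(n_clusters))
        iso = [f"{g}.iso{primary}"]
        if n_clusters > 1 and rng.random() < cfg.frac_multi_isoform_peptide:
            iso.append(f"{g}.iso{(primary + 1) % n_clusters}")
        seq = _tryptic_sequence(rng, internal_kr=rng.random() < cfg.frac_internal_kr)
        grow = genes.loc[g]
        estart = int(rng.integers(grow["tss_bp"], grow["tes_bp"]))
        rows.append(
            (pid, seq, gtuple, tuple(iso), grow["chrom"], estart,
             min(int(grow["tes_bp"]), estart + 3 * len(seq) - 1))
        )
    peptides = pd.DataFrame(
        rows,
        columns=["peptide_id", "sequence", "gene_ids", "isoform_ids",
                 "chrom", "exon_start_bp", "exon_end_bp"],
    ).set_index("peptide_id")

    # --- GO-slim style groups and pathways ---------------------------------
    groups = {}
    namespaces = ["CC", "MF", "BP", "pathway"]
    lo, hi = cfg.group_size_range
    for t in range(cfg.n_groups):
        size = int(rng.integers(lo, min(hi, n_genes) + 1))
        members = [gene_ids[i] for i in rng.choice(n_genes, size=size, replace=False)]
        groups[f"T{t:04d}"] = (namespaces[t % len(namespaces)], members)

    return AnnotationSet(
        genes=genes, probesets=probesets, probes=probes,
        peptides=peptides, groups=groups,
    )


def _tryptic_sequence(rng, internal_kr: bool, min_len=8, max_len=25) -> str:
    """Random tryptic-style peptide: ends in K/R; internal K/R optional."""
    inner_alphabet = [a for a in AMINO_ACIDS if a not in "KR"]
    length = int(rng.integers(min_len, max_len + 1))
    inner = [inner_alphabet[i] for i in rng.integers(0, len(inner_alphabet), length - 1)]
    if internal_kr:
        inner[int(rng.integers(len(inner)))] = "K" if rng.random() < 0.5 else "R"
    return "".join(inner) + ("K" if rng.random() < 0.5 else "R")


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def make_truth(geno: GenotypeMatrix, ann: AnnotationSet, cfg: SimConfig) -> SimTruth:
    """Assign per-gene QTL architectures and per-feature heritabilities."""
    rng = np.random.default_rng(cfg.child_seed("truth"))
    pos = pd.Series(geno.pos_bp, index=geno.snp_ids)
    chrom = pd.Series(geno.chrom, index=geno.snp_ids)

    gene_rows = []
    for g, grow in ann.genes.iterrows():
        qtls = []
        if rng.random() < cfg.frac_local_qtl:
            in_window = (
                (chrom.values == grow["chrom"])
                & (pos.values >= grow["tss_bp"] - LOCAL_WINDOW_BP)
                & (pos.values <= grow["tes_bp"] + LOCAL_WINDOW_BP)
            )
            # prefer variants segregating within families: effects on
            # family-aligned SNPs are confounded with kinship and not
            # locally identifiable by design
            flags = getattr(geno, "family_structured", None)
            same = np.where(in_window & ~flags)[0] if flags is not None \
                else np.where(in_window)[0]
            if not same.size:
                same = np.where(in_window)[0]
            if same.size:
                qtls.append((geno.snp_ids[int(rng.choice(same))], "local"))
        if rng.random() < cfg.frac_distant_qtl:
            while True:
                j = int(rng.integers(geno.n_snps))
                is_local = (
                    chrom.values[j] == grow["chrom"]
                    and grow["tss_bp"] - LOCAL_WINDOW_BP
                    <= pos.values[j]
                    <= grow["tes_bp"] + LOCAL_WINDOW_BP
                )
                if not is_local:
                    qtls.append((geno.snp_ids[j], "distant"))
                    break
        lo, hi = cfg.effect_size_range
        fracs = rng.uniform(lo, hi, size=len(qtls))
        if fracs.sum() > 0.95:  # keep a polygenic remainder
            fracs *= 0.95 / fracs.sum()
        for (snp, loc), v in zip(qtls, fracs):
            gene_rows.append((g, snp, float(v), loc))
    gene_qtls = pd.DataFrame(
        gene_rows, columns=["gene_id", "snp_id", "gvar_frac", "locality"]
    )

    # features: probesets and peptides that map to a unique gene get the
    # gene's architecture; ambiguous ones still get simulated (first gene)
    feat_gene = {}
    for pid, gt in ann.probesets["gene_ids"].items():
        feat_gene[pid] = gt[0]
    for pid, gt in ann.peptides["gene_ids"].items():
        feat_gene[pid] = gt[0]
    gene_of_feature = pd.Series(feat_gene, name="gene_id")

    h_lo, h_hi = cfg.heritability_range
    h2 = pd.Series(
        rng.uniform(h_lo, h_hi, size=len(gene_of_feature)),
        index=gene_of_feature.index, name="heritability",
    )

    qtl_rows = []
    by_gene = gene_qtls.groupby("gene_id")
    for fid, g in gene_of_feature.items():
        if g in by_gene.groups:
            for _, r in by_gene.get_group(g).iterrows():
                qtl_rows.append(
                    (fid, r["snp_id"], float(h2[fid] * r["gvar_frac"]), r["locality"])
                )
    qtls = pd.DataFrame(
        qtl_rows, columns=["feature_id", "snp_id", "effect_var", "locality"]
    )

    # traits driven by 1-3 molecular features (transcript drivers, so the
    # trait simulator can run from the transcript matrix alone)
    features = [f for f in gene_of_feature.index if f in ann.probesets.index]
    drv_rows = []
    for t in range(cfg.n_traits):
        k = int(rng.integers(1, 4))
        for f in rng.choice(len(features), size=k, replace=False):
            coef = float(rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0]))
            drv_rows.append((f"trait{t:02d}", features[int(f)], coef))
    trait_drivers = pd.DataFrame(
        drv_rows, columns=["trait_id", "feature_id", "coefficient"]
    )

    truth = SimTruth(
        heritability=h2, qtls=qtls, trait_drivers=trait_drivers,
        gene_of_feature=gene_of_feature, seed=cfg.seed,
    )
    truth.gene_qtls = gene_qtls  # gene-level architecture, used by the simulator
    return truth


# ---------------------------------------------------------------------------
# molecular phenotypes
# ---------------------------------------------------------------------------

def _standardized_genotypes(geno: GenotypeMatrix, snp_ids) -> np.ndarray:
    idx = {s: j for j, s in enumerate(geno.snp_ids)}
    cols = []
    for s in snp_ids:
        if s not in idx:
            raise DataError(f"truth references unknown SNP {s}")
        c = geno.calls[:, idx[s]].copy()
        m = np.nanmean(c)
        c = np.where(np.isnan(c), m, c)
        sd = c.std()
        cols.append((c - m) / sd if sd > 0 else np.zeros_like(c))
    return np.column_stack(cols) if cols else np.empty((geno.n_strains, 0))


def _cluster_profiles(geno, ann, truth, cfg, rng):
    """One standardized genetic profile per (gene, isoform cluster).

    Cluster 0 carries the gene's planted QTL effects plus a polygenic
    remainder; further clusters get independent polygenic profiles, which
    models isoforms under distinct regulation.
    """
    gene_qtls = getattr(truth, "gene_qtls", None)
    if gene_qtls is None:
        # rebuild per-gene fractions from the feature table
        rows = []
        for fid, grp in truth.qtls.groupby("feature_id"):
            g = truth.gene_of_feature[fid]
            h = truth.heritability[fid]
            for _, r in grp.iterrows():
                rows.append((g, r["snp_id"], r["effect_var"] / max(h, 1e-12),
                             r["locality"]))
        gene_qtls = (
            pd.DataFrame(rows, columns=["gene_id", "snp_id", "gvar_frac", "locality"])
            .drop_duplicates(["gene_id", "snp_id"])
        )

    n = geno.n_strains
    profiles = {}

    def profile_for(gene, cluster):
        key = (gene, cluster)
        if key in profiles:
            return profiles[key]
        if cluster == 0 and gene in qtl_groups.groups:
            sub = qtl_groups.get_group(gene)
            Z = _standardized_genotypes(geno, list(sub["snp_id"]))
            v = sub["gvar_frac"].to_numpy()
            g = Z @ np.sqrt(v)
            rem = max(0.0, 1.0 - v.sum())
            g = g + np.sqrt(rem) * rng.standard_normal(n)
        else:
            g = rng.standard_normal(n)
        g = (g - g.mean()) / g.std()  # realized variance made exactly 1
        profiles[key] = g
        return g

    qtl_groups = gene_qtls.groupby("gene_id")
    return profile_for


def simulate_molecular_data(geno, ann, truth, cfg):
    """Simulate transcript and peptide matrices from planted truth.

    Returns ``(transcripts, peptides, tech_reps)``: a replicated transcript
    PhenotypeMatrix, a one-sample-per-strain peptide PhenotypeMatrix with
    injected missingness, and the technical-replicate run table for the
    reference strain.
    """
    rng = np.random.default_rng(cfg.child_seed("molecular"))
    profile_for = _cluster_profiles(geno, ann, truth, cfg, rng)
    strains = geno.strain_ids
    n = len(strains)
    r = cfg.n_bio_replicates_transcript

    iso_index = {}
    for pid, row in ann.peptides.iterrows():
        iso_index[pid] = row["isoform_ids"][0]

    # transcripts: strain value + replicate-level biological/technical noise
    t_ids = [f for f in truth.gene_of_feature.index if f in ann.probesets.index]
    cols = pd.MultiIndex.from_product(
        [strains, [f"rep{i + 1}" for i in range(r)]], names=["strain", "replicate"]
    )
    tvals = np.empty((len(t_ids), n * r))
    for i, fid in enumerate(t_ids):
        h2 = truth.heritability[fid]
        g = profile_for(truth.gene_of_feature[fid], 0)
        strain_val = np.sqrt(h2) * g
        reps = np.repeat(strain_val, r) + np.sqrt(1 - h2) * rng.standard_normal(n * r)
        tvals[i] = reps - reps.mean()
    transcripts = PhenotypeMatrix(
        values=pd.DataFrame(tvals, index=pd.Index(t_ids, name="feature_id"),
                            columns=cols),
        kind="transcript",
    )

    # peptides: one biological sample per strain plus technical runs of the
    # reference strain; per-peptide technical noise is lognormally dispersed
    p_ids = [f for f in truth.gene_of_feature.index if f in ann.peptides.index]
    ref = cfg.reference_strain_index
    pvals = np.empty((len(p_ids), n))
    tech = np.empty((len(p_ids), cfg.n_tech_replicates_peptide))
    for i, fid in enumerate(p_ids):
        h2 = truth.heritability[fid]
        gene = truth.gene_of_feature[fid]
        cluster = int(iso_index[fid].rsplit("iso", 1)[-1])
        g = profile_for(gene, cluster)
        tau = cfg.tech_noise_sd * rng.lognormal(0.0, cfg.tech_noise_dispersion)
        bio = np.sqrt(h2) * g + np.sqrt(1 - h2) * rng.standard_normal(n)
        y = bio + tau * rng.standard_normal(n)
        runs = bio[ref] + tau * rng.standard_normal(cfg.n_tech_replicates_peptide)
        mu = y.mean()
        pvals[i] = y - mu
        tech[i] = runs - mu
    if cfg.missing_rate_peptide > 0:
        mask = rng.random(pvals.shape) < cfg.missing_rate_peptide
        pvals[mask] = np.nan
    peptides = PhenotypeMatrix(
        values=pd.DataFrame(pvals, index=pd.Index(p_ids, name="feature_id"),
                            columns=strains),
        kind="peptide",
    )
    tech_reps = pd.DataFrame(
        tech, index=pd.Index(p_ids, name="peptide_id"),
        columns=[f"run{i + 1}" for i in range(cfg.n_tech_replicates_peptide)],
    )
    return transcripts, peptides, tech_reps


def simulate_null_phenotypes(K, n_phenotypes: int, genetic_fraction: float = 0.8,
                             seed: int = 0, prefix: str = "null") -> PhenotypeMatrix:
    """Phenotypes with genetic background but no SNP effect.

    y = u + e with Var(u) proportional to the kinship K and
    ``genetic_fraction`` of the total variance genetic. No individual SNP
    has a direct effect, so every association test against these
    phenotypes is a true null -- the calibration target for the mixed
    model.
    """
    import pandas as pd  # noqa: F811 - local alias keeps signature light

    Km = K.to_numpy(dtype=float) if hasattr(K, "to_numpy") else np.asarray(K, float)
    strains = list(K.index) if hasattr(K, "index") else [f"S{i:03d}" for i in range(Km.shape[0])]
    rng = np.random.default_rng(seed)
    n = Km.shape[0]
    w, U = np.linalg.eigh(Km)
    L = U * np.sqrt(np.maximum(w, 0.0))
    sg = np.sqrt(genetic_fraction)
    se = np.sqrt(1.0 - genetic_fraction)
    Y = sg * (L @ rng.standard_normal((n, n_phenotypes))) \
        + se * rng.standard_normal((n, n_phenotypes))
    values = pd.DataFrame(
        Y.T, index=pd.Index([f"{prefix}{i:04d}" for i in range(n_phenotypes)],
                            name="feature_id"),
        columns=strains,
    )
    return PhenotypeMatrix(values=values, kind="trait")


def simulate_traits(molecular: PhenotypeMatrix, truth: SimTruth,
                    cfg: SimConfig) -> PhenotypeMatrix:
    """Clinical traits as noisy linear combinations of driver strain means."""
    rng = np.random.default_rng(cfg.child_seed("traits"))
    means = molecular.strain_means()
    rows, ids = [], []
    for tid, grp in truth.trait_drivers.groupby("trait_id", sort=True):
        y = np.zeros(means.shape[1])
        for _, r in grp.iterrows():
            fid = r["feature_id"]
            if fid not in means.index:
                raise DataError(f"trait {tid} references unknown driver {fid}")
            x = means.loc[fid].to_numpy(dtype=float)
            x = np.where(np.isnan(x), np.nanmean(x), x)
            sd = x.std()
            y = y + r["coefficient"] * ((x - x.mean()) / sd if sd > 0 else x * 0)
        y = y + cfg.trait_noise_sd * rng.standard_normal(y.size)
        rows.append(y - y.mean())
        ids.append(tid)
    values = pd.DataFrame(
        np.asarray(rows), index=pd.Index(ids, name="trait_id"),
        columns=list(means.columns),
    )
    return PhenotypeMatrix(values=values, kind="trait")


# ---------------------------------------------------------------------------
# one-call panel
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPanel:
    cfg: SimConfig
    genotypes: GenotypeMatrix
    block_ids: np.ndarray
    annotations: AnnotationSet
    truth: SimTruth
    transcripts: PhenotypeMatrix
    peptides: PhenotypeMatrix
    tech_reps: pd.DataFrame
    traits: PhenotypeMatrix


def simulate_panel(cfg: SimConfig) -> SyntheticPanel:
    """Generate a complete synthetic panel (genotypes through traits)."""
    geno, blocks = simulate_genotypes(cfg)
    ann = simulate_annotations(cfg)
    truth = make_truth(geno, ann, cfg)
    transcripts, peptides, tech = simulate_molecular_data(geno, ann, truth, cfg)
    traits = simulate_traits(transcripts, truth, cfg)
    return SyntheticPanel(
        cfg=cfg, genotypes=geno, block_ids=blocks, annotations=ann, truth=truth,
        transcripts=transcripts, peptides=peptides, tech_reps=tech, traits=traits,
    )
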