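"""Post-association analysis: haplotype blocks, local/distant QTL
classification, hotspot sliding-window profiles, and eQTL-pQTL overlap.

Conventions: genomic coordinates are 1-based inclusive; a QTL is "local"
when its peak SNP lies within a window flanking 2 Mb on either side of
the gene's transcribed region (boundaries inclusive); sliding hotspot
windows are half-open ``[start, end)`` to avoid double counting.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import DataError, GenotypeMatrix

FLANK_BP = 2_000_000
WINDOW_BP = 2_000_000
STEP_BP = 50_000


# ---------------------------------------------------------------------------
# haplotype blocks
# ---------------------------------------------------------------------------

def haplotype_blocks(geno: GenotypeMatrix, r2_cut: float = 0.5):
    """Greedy blocks of consecutive SNPs with adjacent r^2 above the cut.

    Scanning left to right within each chromosome, a block extends while
    the next SNP's genotype r^2 with the previous SNP exceeds ``r2_cut``
    (strictly). Returns ``(blocks, summary)`` with per-block first/last
    SNP, SNP count and bp length, and mean/median/max length summary.
    """
    rows = []
    for c in pd.unique(geno.chrom):
        idx = np.where(geno.chrom == c)[0]
        pos = geno.pos_bp[idx]
        if np.any(np.diff(pos) <= 0):
            raise DataError(f"SNPs not sorted by position on {c}")
        calls = geno.calls[:, idx]
        mean = np.nanmean(calls, axis=0)
        filled = np.where(np.isnan(calls), mean, calls)
        start = 0
        for j in range(1, len(idx) + 1):
            if j < len(idx):
                a, b = filled[:, j - 1], filled[:, j]
                if a.std() == 0 or b.std() == 0:
                    r2 = 0.0
                else:
                    r2 = float(np.corrcoef(a, b)[0, 1] ** 2)
                if r2 > r2_cut:
                    continue
            rows.append((
                c, geno.snp_ids[idx[start]], geno.snp_ids[idx[j - 1]],
                int(pos[start]), int(pos[j - 1]), j - start,
                int(pos[j - 1] - pos[start] + 1),
            ))
            start = j
    blocks = pd.DataFrame(
        rows, columns=["chrom", "first_snp", "last_snp", "start_bp", "end_bp",
                       "n_snps", "length_bp"],
    )
    summary = {
        "n_blocks": len(blocks),
        "mean_bp": float(blocks["length_bp"].mean()) if len(blocks) else np.nan,
        "median_bp": float(blocks["length_bp"].median()) if len(blocks) else np.nan,
        "max_bp": int(blocks["length_bp"].max()) if len(blocks) else 0,
    }
    return blocks, summary


# ---------------------------------------------------------------------------
# local / distant classification
# ---------------------------------------------------------------------------

def classify_qtl(records: pd.DataFrame, genes: pd.DataFrame,
                 gene_of_phenotype: pd.Series, dataset: str,
                 flank_bp: int = FLANK_BP) -> pd.DataFrame:
    """Classify peak associations as local or distant QTL calls.

    A call is local iff the peak SNP sits on the gene's chromosome within
    ``[min(TSS,TES) - flank, max(TSS,TES) + flank]`` (inclusive); anything
    else, including any other chromosome, is distant. ``records`` should be
    peak (post-prune) associations; ``genes`` is the gene coordinate table.
    """
    rows = []
    for _, r in records.iterrows():
        fid = r["phenotype_id"]
        if fid not in gene_of_phenotype.index or \
                pd.isna(gene_of_phenotype.get(fid)):
            raise DataError(f"phenotype {fid} has no gene annotation")
        g = gene_of_phenotype[fid]
        if g not in genes.index:
            raise DataError(f"gene {g} missing coordinates")
        grow = genes.loc[g]
        lo = min(grow["tss_bp"], grow["tes_bp"]) - flank_bp
        hi = max(grow["tss_bp"], grow["tes_bp"]) + flank_bp
        local = (r["chrom"] == grow["chrom"]) and (lo <= r["pos_bp"] <= hi)
        rows.append((
            fid, g, r["snp_id"], r["chrom"], int(r["pos_bp"]), r["p"],
            r.get("q", np.nan), "local" if local else "distant", dataset,
        ))
    return pd.DataFrame(
        rows, columns=["phenotype_id", "gene_id", "snp_id", "chrom", "pos_bp",
                       "p", "q", "locality", "dataset"],
    )


# ---------------------------------------------------------------------------
# hotspot scan
# ---------------------------------------------------------------------------

def hotspot_scan(calls: pd.DataFrame, window_bp: int = WINDOW_BP,
                 step_bp: int = STEP_BP, chrom_lengths: dict | None = None
                 ) -> pd.DataFrame:
    """Sliding-window association counts along the genome.

    Windows of ``window_bp`` advance by ``step_bp`` per chromosome (the
    last window may truncate at the chromosome end); a call is counted in
    every window whose half-open span ``[start, end)`` contains its peak
    position. Counts and fractions of each dataset's total are reported
    per window per dataset.
    """
    datasets = sorted(calls["dataset"].unique()) if len(calls) else []
    totals = {d: int((calls["dataset"] == d).sum()) for d in datasets}
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(calls.loc[calls["chrom"] == c, "pos_bp"].max())
            for c in pd.unique(calls["chrom"])
        }
    rows = []
    for c, clen in chrom_lengths.items():
        starts = np.arange(1, max(clen, 1) + 1, step_bp, dtype=np.int64)
        sub = calls[calls["chrom"] == c]
        pos = {d: np.sort(sub.loc[sub["dataset"] == d, "pos_bp"].to_numpy())
               for d in datasets}
        for s in starts:
            e = min(s + window_bp, clen + 1)
            row = [c, int(s), int(e)]
            for d in datasets:
                cnt = int(np.searchsorted(pos[d], e, side="left")
                          - np.searchsorted(pos[d], s, side="left"))
                row.append(cnt)
                row.append(cnt / totals[d] if totals[d] else 0.0)
            rows.append(row)
    cols = ["chrom", "start_bp", "end_bp"]
    for d in datasets:
        cols += [f"count_{d}", f"frac_{d}"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# overlap analysis
# ---------------------------------------------------------------------------

@dataclass
class OverlapSummary:
    n_eqtl: int
    n_pqtl: int
    shared_local: int
    shared_distant: int
    same_peak_local: int
    same_peak_distant: int
    local_distances_bp: list = field(default_factory=list)
    distant_distances_bp: list = field(default_factory=list)


def _greedy_match(a: pd.DataFrame, b: pd.DataFrame, match_bp: int):
    """One-to-one nearest-first matching of peaks on the same chromosome."""
    pairs = []
    for c in set(a["chrom"]) & set(b["chrom"]):
        sa = a[a["chrom"] == c]
        sb = b[b["chrom"] == c]
        for ia, ra in sa.iterrows():
            for ib, rb in sb.iterrows():
                d = abs(int(ra["pos_bp"]) - int(rb["pos_bp"]))
                if d <= match_bp:
                    pairs.append((d, ia, ib, ra["snp_id"] == rb["snp_id"]))
    pairs.sort(key=lambda t: (t[0], str(t[1]), str(t[2])))
    used_a, used_b, matches = set(), set(), []
    for d, ia, ib, same in pairs:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        matches.append((d, same))
    return matches


def overlap_analysis(eqtls: pd.DataFrame, pqtls: pd.DataFrame,
                     match_bp: int = 2_000_000) -> OverlapSummary:
    """Shared genetic loci between transcript and protein datasets.

    Local QTLs of the two datasets are matched only within the same gene;
    distant QTLs are matched anywhere on the same chromosome. A pQTL and
    an eQTL are shared when their peak SNPs map within ``match_bp`` of
    each other; each QTL matches at most once (nearest peak first). Peaks
    on the identical SNP are additionally counted as same-peak.
    """
    e_loc = eqtls[eqtls["locality"] == "local"]
    p_loc = pqtls[pqtls["locality"] == "local"]
    local_matches = []
    for g in sorted(set(e_loc["gene_id"]) & set(p_loc["gene_id"])):
        local_matches.extend(_greedy_match(
            e_loc[e_loc["gene_id"] == g], p_loc[p_loc["gene_id"] == g], match_bp
        ))
    e_dist = eqtls[eqtls["locality"] == "distant"]
    p_dist = pqtls[pqtls["locality"] == "distant"]
    distant_matches = _greedy_match(e_dist, p_dist, match_bp)

    return OverlapSummary(
        n_eqtl=len(eqtls), n_pqtl=len(pqtls),
        shared_local=len(local_matches),
        shared_distant=len(distant_matches),
        same_peak_local=sum(1 for _, same in local_matches if same),
        same_peak_distant=sum(1 for _, same in distant_matches if same),
        local_distances_bp=[d for d, same in local_matches if not same],
        distant_distances_bp=[d for d, same in distant_matches if not same],
    )


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

def summarize_counts(calls_by_dataset: dict, n_phenotypes: dict) -> pd.DataFrame:
    """Association-count summary per dataset (one row each).

    ``calls_by_dataset`` maps dataset name to its QTL call table;
    ``n_phenotypes`` gives the total number of phenotypes mapped in each
    dataset (the denominator for the percentage columns).
    """
    rows = []
    for name, calls in calls_by_dataset.items():
        per_pheno = calls.groupby("phenotype_id").size() if len(calls) else pd.Series(dtype=int)
        n_local = int((calls["locality"] == "local").sum()) if len(calls) else 0
        local_phenos = (calls.loc[calls["locality"] == "local", "phenotype_id"]
                        .nunique() if len(calls) else 0)
        rows.append({
            "dataset": name,
            "n_phenotypes": n_phenotypes.get(name, 0),
            "total_associations": len(calls),
            "phenotypes_with_assoc": int((per_pheno >= 1).sum()),
            "phenotypes_with_local": int(local_phenos),
            "local_associations": n_local,
            "distant_associations": len(calls) - n_local,
            "phenotypes_with_multiple": int((per_pheno > 1).sum()),
        })
    return pd.DataFrame(rows).set_index("dataset")
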