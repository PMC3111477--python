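"""Quality filtering and normalization for peptide and transcript data.

Implements the filtering funnel used for a joint proteome-transcriptome
panel: basic peptide rules (missingness < 50%, no internal Lys/Arg, unique
gene annotation), the signal-to-noise filter against technical replicate
variance (cutoff 2), broad-sense heritability by one-way strain ANOVA with
a p<0.05 filter, masking of microarray probes that contain SNPs (probesets
with >= 8 masked 25-mer probes are dropped), log2 centering, and a
simplified SVD-based "eigenpeptide" normalization that removes systematic
trends from the peptide matrix.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnnotationSet, DataError, PhenotypeMatrix


# ---------------------------------------------------------------------------
# log2 centering
# ---------------------------------------------------------------------------

def log2_center(mat: PhenotypeMatrix, already_log: bool = True) -> PhenotypeMatrix:
    """Log2-transform (optionally) and zero-center each feature row.

    With ``already_log=False`` values are ratios and must be positive;
    a non-positive entry raises an error naming the offending feature.
    Centering uses the mean over non-missing entries only.
    """
    vals = mat.values.astype(float).copy()
    if not already_log:
        arr = vals.to_numpy()
        bad = (arr <= 0) & ~np.isnan(arr)
        if bad.any():
            fid = vals.index[np.argwhere(bad)[0][0]]
            raise DataError(f"non-positive value for feature {fid} with log2 requested")
        vals = np.log2(vals)
    centered = vals.sub(vals.mean(axis=1, skipna=True), axis=0)
    return PhenotypeMatrix(values=centered, kind=mat.kind)


# ---------------------------------------------------------------------------
# peptide basic filter
# ---------------------------------------------------------------------------

def peptide_basic_filter(peptides: PhenotypeMatrix, ann: AnnotationSet,
                         max_missing: float = 0.5):
    """Apply the three basic peptide rules; returns (retained_ids, log).

    Retained peptides have a) missingness strictly below ``max_missing``
    over the whole strain panel, b) no lysine/arginine at any position
    except the final residue, and c) exactly one annotated gene. The log
    has one row per (peptide, failed rule).
    """
    strain_cols = peptides.strain_ids
    vals = peptides.strain_means() if peptides.has_replicates else peptides.values
    missing = vals[strain_cols].isna().mean(axis=1) if not peptides.has_replicates \
        else vals.isna().mean(axis=1)

    retained, log_rows = [], []
    for pid in peptides.feature_ids:
        if pid not in ann.peptides.index:
            raise DataError(f"peptide {pid} has no annotation record")
        row = ann.peptides.loc[pid]
        seq = row["sequence"]
        if not seq:
            raise DataError(f"peptide {pid} has no sequence")
        fails = []
        if missing[pid] >= max_missing:
            fails.append("missingness")
        if any(aa in "KR" for aa in seq[:-1]):
            fails.append("internal_KR")
        if len(row["gene_ids"]) != 1:
            fails.append("ambiguous_gene")
        if fails:
            log_rows.extend((pid, f) for f in fails)
        else:
            retained.append(pid)
    log = pd.DataFrame(log_rows, columns=["peptide_id", "rule"])
    return retained, log


# ---------------------------------------------------------------------------
# signal-to-noise
# ---------------------------------------------------------------------------

SNR_SENTINEL = np.inf


def signal_to_noise(peptides: PhenotypeMatrix, tech_reps: pd.DataFrame,
                    cutoff: float = 2.0) -> pd.DataFrame:
    """Per-peptide ratio of panel variance to technical-replicate variance.

    S = var(values across strains) / var(technical replicate runs), both
    unbiased (n-1) sample variances over non-missing entries. A peptide
    passes iff S > cutoff. Zero technical variance with positive panel
    variance is flagged as a pass with an infinite sentinel ratio.
    """
    out = {}
    vals = peptides.values
    for pid in peptides.feature_ids:
        if pid not in tech_reps.index:
            raise DataError(f"peptide {pid} missing from technical replicate table")
        pop = vals.loc[pid].dropna().to_numpy(dtype=float)
        rep = tech_reps.loc[pid].dropna().to_numpy(dtype=float)
        if rep.size < 2:
            raise DataError(f"peptide {pid} has fewer than 2 technical replicates")
        if pop.size < 3:
            raise DataError(f"peptide {pid} has fewer than 3 panel values")
        v_pop = pop.var(ddof=1)
        v_tech = rep.var(ddof=1)
        if v_tech == 0:
            snr, ok = SNR_SENTINEL, v_pop > 0
        else:
            snr = v_pop / v_tech
            ok = snr > cutoff
        out[pid] = (v_pop, v_tech, snr, bool(ok))
    table = pd.DataFrame.from_dict(
        out, orient="index",
        columns=["var_population", "var_technical", "snr", "pass"],
    )
    table.index.name = "peptide_id"
    return table


# ---------------------------------------------------------------------------
# heritability ANOVA
# ---------------------------------------------------------------------------

def heritability_anova(mat: PhenotypeMatrix) -> pd.DataFrame:
    """One-way fixed-effect strain ANOVA per feature.

    Returns per feature:

    * ``h2``      - SS_strain / SS_total, the broad-sense heritability
                    statistic reported for panel data;
    * ``h2_vc``   - the ANOVA variance-component (intraclass correlation)
                    estimate sigma_strain^2/(sigma_strain^2+sigma_within^2)
                    from the same mean squares, which is the consistent
                    estimator of a planted variance fraction;
    * ``p_strain`` - p-value of the strain F-test;
    * ``pass``    - p_strain < 0.05.

    Unbalanced designs (1-2 replicates for some strains) are allowed.
    Features whose values are all identical get h2 = 0, p = 1.
    """
    if not mat.has_replicates:
        raise DataError("heritability_anova needs a replicate axis")
    vals = mat.values
    strain_of_col = vals.columns.get_level_values(0)

    records = {}
    arr = vals.to_numpy(dtype=float)
    strains = np.asarray(strain_of_col)
    for i, fid in enumerate(vals.index):
        y = arr[i]
        ok = ~np.isnan(y)
        yy, ss = y[ok], strains[ok]
        uniq, inv = np.unique(ss, return_inverse=True)
        if uniq.size < 2:
            raise DataError(f"feature {fid} observed in fewer than 2 strains")
        N, s = yy.size, uniq.size
        grand = yy.mean()
        n_i = np.bincount(inv)
        sum_i = np.bincount(inv, weights=yy)
        mean_i = sum_i / n_i
        ss_total = float(((yy - grand) ** 2).sum())
        ss_strain = float((n_i * (mean_i - grand) ** 2).sum())
        ss_within = ss_total - ss_strain
        if ss_total <= 0:
            records[fid] = (0.0, 0.0, 1.0, False)
            continue
        df_strain, df_within = s - 1, N - s
        if df_within <= 0:
            # no replication left after missingness: strain term saturates
            records[fid] = (1.0, 1.0, 1.0, False)
            continue
        ms_strain = ss_strain / df_strain
        ms_within = ss_within / df_within
        F = ms_strain / ms_within if ms_within > 0 else np.inf
        p = float(stats.f.sf(F, df_strain, df_within)) if np.isfinite(F) else 0.0
        h2 = ss_strain / ss_total
        # effective replicate number for unbalanced one-way designs
        r_eff = (N - (n_i ** 2).sum() / N) / (s - 1)
        sig_s = max(0.0, (ms_strain - ms_within) / r_eff)
        h2_vc = sig_s / (sig_s + ms_within) if (sig_s + ms_within) > 0 else 0.0
        records[fid] = (h2, h2_vc, p, p < 0.05)
    table = pd.DataFrame.from_dict(
        records, orient="index", columns=["h2", "h2_vc", "p_strain", "pass"]
    )
    table.index.name = "feature_id"
    return table


# ---------------------------------------------------------------------------
# transcript filter
# ---------------------------------------------------------------------------

def filter_transcripts(her: pd.DataFrame, ann: AnnotationSet,
                       forced_genes=(), p_cut: float = 0.05):
    """Retain probesets with heritable variation and unambiguous annotation.

    retained = (p_strain < p_cut AND exactly one gene)
               UNION (single-gene probesets whose gene is in ``forced_genes``,
               i.e. has a retained peptide).
    """
    unique_gene = ann.unique_gene_of_probeset()
    forced_genes = set(forced_genes)
    retained = []
    for pid in her.index:
        if pid not in unique_gene.index:
            continue
        if her.loc[pid, "p_strain"] < p_cut or unique_gene[pid] in forced_genes:
            retained.append(pid)
    return retained


# ---------------------------------------------------------------------------
# probe SNP masking
# ---------------------------------------------------------------------------

def mask_probes(ann: AnnotationSet, snp_positions: dict,
                exclude_at: int = 8):
    """Flag probes containing a SNP; exclude heavily masked probesets.

    ``snp_positions`` maps chromosome -> sorted 1-based positions. A probe
    is masked iff at least one SNP lies inside its inclusive interval. A
    probeset is excluded iff its masked-probe count >= ``exclude_at``.

    Returns ``(masked, excluded)`` where ``masked`` maps probeset_id to the
    row indices (within that probeset's probe list) of masked probes.
    """
    sorted_pos = {c: np.asarray(p, dtype=np.int64) for c, p in snp_positions.items()}
    masked: dict = {}
    for pid, grp in ann.probes.groupby("probeset_id", sort=False):
        hits = []
        for k, (_, row) in enumerate(grp.iterrows()):
            c = row["chrom"]
            if c not in sorted_pos:
                raise DataError(f"probe of {pid} on unknown chromosome {c}")
            pos = sorted_pos[c]
            lo = np.searchsorted(pos, row["start_bp"], side="left")
            hi = np.searchsorted(pos, row["end_bp"], side="right")
            if hi > lo:
                hits.append(k)
        masked[pid] = hits
    excluded = [pid for pid, h in masked.items() if len(h) >= exclude_at]
    return masked, excluded


# ---------------------------------------------------------------------------
# eigenpeptide normalization
# ---------------------------------------------------------------------------

def eigen_normalize(peptides: PhenotypeMatrix, n_trends: int) -> PhenotypeMatrix:
    """Remove the top systematic trends (eigenpeptides) by SVD.

    Missing cells are imputed to the feature mean for the decomposition
    only and restored to missing afterwards. Each (centered) feature row
    is projected off the top ``n_trends`` right-singular vectors of the
    feature x strain matrix. ``n_trends=0`` is the identity.
    """
    vals = peptides.values.astype(float)
    n_feat, n_col = vals.shape
    if n_trends >= min(n_feat, n_col):
        raise DataError("n_trends must be smaller than both matrix dimensions")
    if n_trends == 0:
        return PhenotypeMatrix(values=vals.copy(), kind=peptides.kind)
    arr = vals.to_numpy()
    mask = np.isnan(arr)
    row_mean = np.nanmean(arr, axis=1, keepdims=True)
    filled = np.where(mask, row_mean, arr)
    centered = filled - filled.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt[:n_trends]                      # (n_trends, strains)
    resid = centered - (centered @ v.T) @ v
    resid[mask] = np.nan
    out = pd.DataFrame(resid, index=vals.index, columns=vals.columns)
    return PhenotypeMatrix(values=out, kind=peptides.kind)
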