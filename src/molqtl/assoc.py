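"""Mixed-model genome-wide association for molecular phenotypes.

Model per phenotype: ``y = mu + x*beta + u + e`` with ``Var(u) =
sigma_g^2 K`` (K the identity-by-state kinship across strains) and
``Var(e) = sigma_e^2 I``. Variance components are estimated once per
phenotype under the null by restricted maximum likelihood over the ratio
``delta = sigma_e^2/sigma_g^2``, using the spectral decomposition of the
projected kinship (the EMMA formulation: a 1-D grid over ln delta with
local refinement). Each SNP is then tested by rotating phenotype and
design into the eigenbasis of ``K + delta I`` and running a standard
F-test of beta = 0 on the whitened data.

Also provides Storey q-values (with the large-scale subsample-averaging
mode), variance explained per association, and greedy LD pruning of
significant hits.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import DataError, GenotypeMatrix, PhenotypeMatrix

LOG_DELTA_BOUNDS = (-10.0, 10.0)
N_GRID = 100
RIDGE = 1e-6


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def ibs_kinship(geno: GenotypeMatrix) -> pd.DataFrame:
    """Identity-by-state kinship: fraction of jointly observed SNPs at
    which two strains carry the same allele."""
    if geno.n_strains < 2:
        raise DataError("kinship needs at least 2 strains")
    calls = geno.calls
    obs = ~np.isnan(calls)
    ones = np.where(obs, calls, 0.0)
    zeros = np.where(obs, 1.0 - calls, 0.0)
    matches = ones @ ones.T + zeros @ zeros.T
    denom = obs.astype(float) @ obs.astype(float).T
    if (denom == 0).any():
        i, j = np.argwhere(denom == 0)[0]
        raise DataError(
            f"strains {geno.strain_ids[i]} and {geno.strain_ids[j]} share no "
            "jointly observed SNPs"
        )
    K = matches / denom
    return pd.DataFrame(K, index=geno.strain_ids, columns=geno.strain_ids)


# ---------------------------------------------------------------------------
# REML variance components
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    delta: float
    loglik: float


def _projected_spectrum(K: np.ndarray, X: np.ndarray):
    """Nonzero eigenpairs of S K S with S the residual-maker of X."""
    n, q = X.shape
    Xq, _ = np.linalg.qr(X)
    S = np.eye(n) - Xq @ Xq.T
    M = S @ K @ S
    w, U = np.linalg.eigh(M)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    xi = w[: n - q]
    if xi.min() < -1e-6:
        raise DataError("kinship matrix not positive semidefinite after shift")
    return np.maximum(xi, 0.0), U[:, : n - q]


def _restricted_ll(delta, xi, eta2):
    nq = xi.size
    denom = xi + delta
    s1 = np.sum(eta2 / denom)
    return 0.5 * (nq * (np.log(nq / (2 * np.pi)) - 1.0 - np.log(s1))
                  - np.sum(np.log(denom)))


def _restricted_ll_grad(delta, xi, eta2):
    denom = xi + delta
    s1 = np.sum(eta2 / denom)
    s2 = np.sum(eta2 / denom ** 2)
    return 0.5 * (xi.size * s2 / s1 - np.sum(1.0 / denom))


def reml_fit(y, K, covariates=None) -> VarianceComponents:
    """REML estimate of the variance components for one phenotype.

    ``y`` is a complete phenotype vector over >= 10 strains, ``K`` the
    aligned kinship (array or DataFrame). ``covariates`` (n x c) are added
    to the intercept. The restricted likelihood is maximized in
    ``ln delta`` over [-10, 10] on a 100-interval grid followed by root
    refinement of the gradient in every sign-change interval. Ties are
    broken toward the largest delta, so an uninformative (identity)
    kinship degenerates to ordinary least squares.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise DataError("reml_fit requires a complete phenotype vector")
    if y.size < 10:
        raise DataError("reml_fit needs >= 10 strains")
    if y.std() == 0:
        raise DataError("degenerate phenotype: constant values")
    Km = K.to_numpy(dtype=float) if isinstance(K, pd.DataFrame) else np.asarray(K, float)
    if Km.shape != (y.size, y.size):
        raise DataError("kinship not aligned to phenotype strains")
    w_min = np.linalg.eigvalsh(Km).min()
    if w_min < -1e-8:
        Km = Km + RIDGE * np.eye(y.size)
        if np.linalg.eigvalsh(Km).min() < -1e-8:
            raise DataError("kinship matrix not positive semidefinite")

    n = y.size
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.hstack([X, C])
    xi, Ur = _projected_spectrum(Km, X)
    eta2 = (Ur.T @ y) ** 2

    grid = np.exp(np.linspace(*LOG_DELTA_BOUNDS, N_GRID + 1))
    ll = np.array([_restricted_ll(d, xi, eta2) for d in grid])
    grad = np.array([_restricted_ll_grad(d, xi, eta2) for d in grid])

    candidates = [grid[0], grid[-1]]
    for i in range(N_GRID):
        if grad[i] > 0 >= grad[i + 1]:
            try:
                root = optimize.brentq(
                    _restricted_ll_grad, grid[i], grid[i + 1], args=(xi, eta2)
                )
                candidates.append(root)
            except ValueError:
                pass
    candidates.extend(grid[np.argsort(ll)[-3:]])
    cand = np.asarray(sorted(set(candidates)))
    cand_ll = np.array([_restricted_ll(d, xi, eta2) for d in cand])
    best = cand_ll.max()
    # tie-break toward the largest delta (flat likelihood when K ~ I)
    near = np.where(cand_ll >= best - 1e-8 * (1.0 + abs(best)))[0]
    delta = float(cand[near[-1]])

    nq = xi.size
    sigma_g2 = float(np.sum(eta2 / (xi + delta)) / nq)
    sigma_e2 = float(delta * sigma_g2)
    return VarianceComponents(
        sigma_g2=sigma_g2, sigma_e2=sigma_e2, delta=delta,
        loglik=float(_restricted_ll(delta, xi, eta2)),
    )


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------

def variance_explained(y, x, beta) -> float:
    """VE = 1 - var(residuals after the SNP fit)/var(y), clamped to [0,1]."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    resid = y - beta * x
    vy = y.var()
    if vy == 0:
        return 0.0
    return float(np.clip(1.0 - resid.var() / vy, 0.0, 1.0))


def _snp_filter(geno: GenotypeMatrix, maf_min: float, miss_max: float):
    maf = geno.maf()
    miss = geno.missingness()
    return (maf >= maf_min - 1e-12) & (miss < miss_max)


def _whitened_scan(y, G, U, lam, delta):
    """Vectorized F-tests of beta = 0 on eigenbasis-whitened data.

    y: (n,) phenotype; G: (n, m) mean-imputed genotypes; U, lam: eigenpairs
    of the kinship; delta: REML variance ratio. Returns (beta, F, p).
    """
    n, m = G.shape
    t = 1.0 / np.sqrt(lam + delta)
    ys = t * (U.T @ y)
    As = t * (U.T @ np.ones(n))
    Gs = (U.T @ G) * t[:, None]

    Saa = float(As @ As)
    Say = float(As @ ys)
    Syy = float(ys @ ys)
    Sax = As @ Gs
    Sxy = ys @ Gs
    Sxx = np.einsum("ij,ij->j", Gs, Gs)

    det = Saa * Sxx - Sax ** 2
    ok = det > 1e-12 * max(Saa, 1.0)
    beta = np.zeros(m)
    F = np.zeros(m)
    p = np.ones(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (Saa * Sxy - Sax * Say) / det
        mu = (Say - Sax * b) / Saa
        rss1 = Syy - mu * Say - b * Sxy
        rss0 = Syy - Say ** 2 / Saa
        dff = n - 2
        Fall = (rss0 - rss1) * dff / np.maximum(rss1, 1e-300)
    beta[ok] = b[ok]
    F[ok] = np.maximum(Fall[ok], 0.0)
    p[ok] = stats.f.sf(F[ok], 1, dff)
    return beta, F, p


def gwas_scan(pheno: PhenotypeMatrix, geno: GenotypeMatrix, K=None,
              maf_min: float = 0.10, miss_max: float = 0.10,
              min_strains: int = 10, per_snp_reml: bool = False):
    """Genome scan of every phenotype against every passing SNP.

    With a kinship ``K`` the mixed model is used (variance components
    estimated once per phenotype under the null, then reused across SNPs;
    ``per_snp_reml=True`` re-estimates delta for every SNP instead). With
    ``K=None`` a naive no-kinship regression is run, which is useful as a
    contrast: on structured panels it inflates the type-I error the mixed
    model is there to control.

    Returns ``(records, skipped)``: a long DataFrame with columns
    phenotype_id, snp_id, chrom, pos_bp, beta, F, p, var_explained, and
    the list of phenotypes skipped for insufficient strain coverage.
    """
    means = pheno.strain_means() if isinstance(pheno, PhenotypeMatrix) else pheno
    strains = [s for s in means.columns if s in set(geno.strain_ids)]
    if len(strains) < min_strains:
        raise DataError("fewer than min_strains strains shared with genotypes")
    sidx = [geno.strain_ids.index(s) for s in strains]
    keep = _snp_filter(geno, maf_min, miss_max)
    snp_idx = np.where(keep)[0]
    calls = geno.calls[np.ix_(sidx, snp_idx)]
    col_mean = np.nanmean(calls, axis=0)
    Gfull = np.where(np.isnan(calls), col_mean, calls)
    snp_ids = [geno.snp_ids[j] for j in snp_idx]
    chrom = geno.chrom[snp_idx]
    pos = geno.pos_bp[snp_idx]

    Kfull = None
    if K is not None:
        Kdf = K if isinstance(K, pd.DataFrame) else pd.DataFrame(
            K, index=geno.strain_ids, columns=geno.strain_ids)
        Kfull = Kdf.loc[strains, strains].to_numpy(dtype=float)

    eig_cache: dict = {}
    frames, skipped = [], []
    for fid in means.index:
        y_all = means.loc[fid, strains].to_numpy(dtype=float)
        ok = ~np.isnan(y_all)
        if ok.sum() < min_strains:
            skipped.append(fid)
            continue
        y = y_all[ok]
        G = Gfull[ok]
        n = y.size
        key = ok.tobytes()
        if K is not None:
            if key not in eig_cache:
                Ksub = Kfull[np.ix_(ok, ok)]
                lam, U = np.linalg.eigh(Ksub)
                if lam.min() < -1e-8:
                    Ksub = Ksub + RIDGE * np.eye(n)
                    lam, U = np.linalg.eigh(Ksub)
                eig_cache[key] = (Ksub, lam, U)
            Ksub, lam, U = eig_cache[key]
            lam = np.maximum(lam, 0.0)
            if per_snp_reml:
                beta = np.empty(G.shape[1])
                F = np.empty(G.shape[1])
                p = np.empty(G.shape[1])
                for j in range(G.shape[1]):
                    vc = reml_fit(y, Ksub, covariates=G[:, [j]])
                    bj, Fj, pj = _whitened_scan(y, G[:, [j]], U, lam, vc.delta)
                    beta[j], F[j], p[j] = bj[0], Fj[0], pj[0]
            else:
                vc = reml_fit(y, Ksub)
                beta, F, p = _whitened_scan(y, G, U, lam, vc.delta)
        else:
            lam = np.ones(n)
            U = np.eye(n)
            beta, F, p = _whitened_scan(y, G, U, lam, 0.0)

        ve = np.array([variance_explained(y, G[:, j], beta[j])
                       for j in range(G.shape[1])])
        frames.append(pd.DataFrame({
            "phenotype_id": fid, "snp_id": snp_ids, "chrom": chrom,
            "pos_bp": pos, "beta": beta, "F": F, "p": p, "var_explained": ve,
        }))
    records = (pd.concat(frames, ignore_index=True) if frames
               else pd.DataFrame(columns=["phenotype_id", "snp_id", "chrom",
                                          "pos_bp", "beta", "F", "p",
                                          "var_explained"]))
    return records, skipped


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

def estimate_pi0(p: np.ndarray) -> float:
    """Storey smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1-lambda)) over lambda in
    {0, 0.05, ..., 0.90}; a cubic least-squares fit is evaluated at the
    largest lambda and clipped to (0, 1].
    """
    lambdas = np.arange(0.0, 0.95, 0.05)
    m = p.size
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_l, 3)
    pi0 = float(np.polyval(coef, lambdas[-1]))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def qvalues(p, pi0=None, subsample=None, seed: int = 0) -> np.ndarray:
    """Storey q-values; with ``pi0=1`` identical to Benjamini-Hochberg.

    ``subsample=(n_samples, size)`` activates the large-scale
    approximation: q-values are computed on random subsets (drawn without
    replacement) and averaged per test over the subsets containing it.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise DataError("p-values must lie in (0, 1]")
    if subsample is not None:
        n_samples, size = subsample
        if size > p.size:
            raise DataError("subsample size exceeds number of p-values")
        rng = np.random.default_rng(seed)
        acc = np.zeros(p.size)
        cnt = np.zeros(p.size)
        for _ in range(n_samples):
            idx = rng.choice(p.size, size=size, replace=False)
            acc[idx] += qvalues(p[idx], pi0=pi0)
            cnt[idx] += 1
        out = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
        missing = cnt == 0
        if missing.any():
            out[missing] = qvalues(p, pi0=pi0)[missing]
        return out

    m = p.size
    pi0_val = estimate_pi0(p) if pi0 is None else float(pi0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0_val * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _genotype_r2(geno: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    ia = geno.snp_ids.index(snp_a)
    ib = geno.snp_ids.index(snp_b)
    a = geno.calls[:, ia]
    b = geno.calls[:, ib]
    a = np.where(np.isnan(a), np.nanmean(a), a)
    b = np.where(np.isnan(b), np.nanmean(b), b)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def ld_prune(records: pd.DataFrame, geno: GenotypeMatrix,
             r2_cut: float = 0.5) -> pd.DataFrame:
    """Greedy LD pruning of significant associations per phenotype.

    Repeatedly takes the most significant unpruned SNP as a peak and
    prunes every remaining SNP whose genotype r^2 with it is >= r2_cut
    ("0.5 or larger"). Ties in p break toward the smaller genomic
    coordinate, so output is independent of input row order. Adds boolean
    ``pruned`` and ``is_peak`` columns.
    """
    known = set(geno.snp_ids)
    missing = set(records["snp_id"]) - known
    if missing:
        raise DataError(f"SNPs absent from genotype matrix: {sorted(missing)[:3]}")
    out = records.copy()
    out["pruned"] = False
    out["is_peak"] = False
    chrom_rank = {c: i for i, c in enumerate(pd.unique(geno.chrom))}
    for _, grp in records.groupby("phenotype_id", sort=False):
        rows = grp.sort_values(
            by=["p", "chrom", "pos_bp", "snp_id"],
            key=lambda col: col.map(chrom_rank) if col.name == "chrom" else col,
        )
        remaining = list(rows.index)
        while remaining:
            peak = remaining.pop(0)
            out.loc[peak, "is_peak"] = True
            keep = []
            for idx in remaining:
                r2 = _genotype_r2(geno, records.loc[peak, "snp_id"],
                                  records.loc[idx, "snp_id"])
                if r2 >= r2_cut:
                    out.loc[idx, "pruned"] = True
                else:
                    keep.append(idx)
            remaining = keep
    return out
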