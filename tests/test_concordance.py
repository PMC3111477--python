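"""Robust correlation and concordance-analysis tests."""
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from molqtl import concordance as cc
from molqtl.datatypes import AnnotationSet, DataError, PhenotypeMatrix


def direct_bicor(x, y):
    """Independent evaluation of the biweight midcorrelation formula."""
    def dev(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return v - v.mean()
        u = (v - med) / (9.0 * mad)
        w = (1 - u ** 2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w
    ax, ay = dev(np.asarray(x, float)), dev(np.asarray(y, float))
    return float((ax * ay).sum()
                 / np.sqrt((ax * ax).sum() * (ay * ay).sum()))


# --- bicor ------------------------------------------------------------------

def test_bicor_perfect_linear():
    x = np.linspace(-2, 2, 15)
    assert cc.bicor(x, 2 * x + 3) == pytest.approx(1.0)
    assert cc.bicor(x, -x) == pytest.approx(-1.0)


def test_bicor_outlier_matches_formula_and_beats_pearson(rng):
    x = np.linspace(0, 1, 20)
    y = 2 * x + rng.normal(0, 0.05, 20)
    y[3] = 40.0  # gross outlier
    got = cc.bicor(x, y)
    assert got == pytest.approx(direct_bicor(x, y), abs=1e-12)
    assert got > stats.pearsonr(x, y)[0]


def test_bicor_close_to_pearson_on_gaussian(rng):
    x = rng.standard_normal(200)
    y = 0.6 * x + 0.8 * rng.standard_normal(200)
    assert abs(cc.bicor(x, y) - stats.pearsonr(x, y)[0]) < 0.02


@given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
@settings(max_examples=25, deadline=None)
def test_bicor_invariant_under_positive_affine(a, b):
    x = np.array([0.5, -1.2, 2.0, 0.1, -0.4, 1.3, -2.2, 0.9])
    y = np.array([0.1, -0.9, 1.5, 0.7, -0.2, 1.1, -1.7, 0.3])
    assert cc.bicor(a * x + b, y) == pytest.approx(cc.bicor(x, y), abs=1e-9)


def test_bicor_pairwise_deletion_and_errors():
    x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
    y = np.array([1.1, 2.2, 3.0, np.nan, 5.2])
    r = cc.bicor(x, y)  # 3 complete pairs survive
    assert -1 <= r <= 1
    with pytest.raises(DataError):
        cc.bicor([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(DataError):
        cc.bicor([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


def test_bicor_mad_zero_falls_back_to_pearson(rng):
    # majority at one value makes MAD 0 while variance stays positive
    x = np.array([1.0] * 6 + [2.0, 3.0, 4.0, 8.0])
    y = rng.standard_normal(10)
    got = cc.bicor(x, y)
    ax = x - x.mean()

    def dev(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9.0 * mad)
        w = (1 - u ** 2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w
    ay = dev(y)
    expect = (ax * ay).sum() / np.sqrt((ax ** 2).sum() * (ay ** 2).sum())
    assert got == pytest.approx(expect, abs=1e-12)


# --- correlation test -------------------------------------------------------

def test_cor_test_reference_points():
    assert cc.cor_test(0.0, 50) == pytest.approx(1.0)
    assert cc.cor_test(1.0, 10) == 0.0
    # r ~ 0.46 at n = 97 sits at the 1e-6 scale
    assert 1e-7 < cc.cor_test(0.46, 97) < 1e-5
    t = 0.5 * np.sqrt(8 / (1 - 0.25))
    assert cc.cor_test(0.5, 10) == pytest.approx(2 * stats.t.sf(t, 8), abs=1e-10)
    with pytest.raises(DataError):
        cc.cor_test(0.5, 2)


# --- gene pairing -----------------------------------------------------------

def pair_fixture(rng, n_strains=30):
    strains = [f"S{i:03d}" for i in range(n_strains)]
    genes = pd.DataFrame({"chrom": "chr1", "tss_bp": 100, "tes_bp": 900,
                          "strand": "+"},
                         index=pd.Index(["GA", "GB", "GC"], name="gene_id"))
    pep_rows = {"pep1": "GA", "pep2": "GA", "pep3": "GA", "pep4": "GB",
                "pep5": "GC"}
    ps_rows = {"ps1": "GA", "ps2": "GA", "ps3": "GB"}
    pep = pd.DataFrame({
        "sequence": "ACDEFK", "gene_ids": pd.Series({k: (v,) for k, v in pep_rows.items()}),
        "isoform_ids": pd.Series({k: (f"{v}.iso0",) for k, v in pep_rows.items()}),
        "chrom": "chr1", "exon_start_bp": 100, "exon_end_bp": 130})
    pep.index.name = "peptide_id"
    ps = pd.DataFrame({"gene_ids": pd.Series({k: (v,) for k, v in ps_rows.items()})})
    ps.index.name = "probeset_id"
    ann = AnnotationSet(genes=genes, probesets=ps,
                        probes=pd.DataFrame(columns=["probeset_id", "chrom",
                                                     "start_bp", "end_bp"]),
                        peptides=pep, groups={})
    pmat = PhenotypeMatrix(values=pd.DataFrame(
        rng.standard_normal((5, n_strains)), index=list(pep_rows),
        columns=strains), kind="peptide")
    tmat = PhenotypeMatrix(values=pd.DataFrame(
        rng.standard_normal((3, n_strains)), index=list(ps_rows),
        columns=strains), kind="transcript")
    return pmat, tmat, ann


def test_gene_pair_cross_product(rng):
    pmat, tmat, ann = pair_fixture(rng)
    pairs = cc.build_gene_pairs(pmat, tmat, ann)
    # GA: 3 peptides x 2 probesets = 6; GB: 1 x 1; GC has no probeset
    assert len(pairs) == 7
    assert (pairs[pairs.gene_id == "GA"].shape[0]) == 6
    assert "GC" not in set(pairs.gene_id)
    # brute-force total
    pep_gene = ann.unique_gene_of_peptide()
    ps_gene = ann.unique_gene_of_probeset()
    expect = sum(
        (pep_gene == g).sum() * (ps_gene == g).sum()
        for g in set(pep_gene) & set(ps_gene)
    )
    assert len(pairs) == expect


def test_snr_strata_single_stratum_equals_global_median(rng):
    pmat, tmat, ann = pair_fixture(rng)
    pairs = cc.build_gene_pairs(pmat, tmat, ann)
    snr = pd.DataFrame({"snr": 5.0, "pass": True}, index=pmat.feature_ids)
    out = cc.snr_strata_summary(pairs, snr, edges=(0, 100))
    assert out.iloc[0] == pytest.approx(pairs["r"].median())


def test_snr_strata_hand_built():
    pairs = pd.DataFrame({
        "gene_id": "G", "peptide_id": ["a", "b", "c", "d"],
        "probeset_id": "ps", "n": 20,
        "r": [0.1, 0.2, 0.6, 0.8], "p": 0.5,
    })
    snr = pd.DataFrame({"snr": [1.0, 2.0, 10.0, 20.0]},
                       index=["a", "b", "c", "d"])
    out = cc.snr_strata_summary(pairs, snr, edges=(0, 5, 100),
                                percentile=False)
    assert out.iloc[0] == pytest.approx(0.15)   # a, b (snr < 5)
    assert out.iloc[1] == pytest.approx(0.7)    # c, d


# --- trait comparison -------------------------------------------------------

def test_identical_datasets_share_everything(rng):
    strains = [f"S{i:03d}" for i in range(40)]
    feats = pd.DataFrame(rng.standard_normal((6, 40)),
                         index=[f"f{i}" for i in range(6)], columns=strains)
    # traits strongly driven by features so significance exists
    traits = pd.DataFrame(
        feats.to_numpy()[:3] + 0.1 * rng.standard_normal((3, 40)),
        index=["t0", "t1", "t2"], columns=strains)
    a = PhenotypeMatrix(values=feats, kind="peptide")
    b = PhenotypeMatrix(values=feats.copy(), kind="transcript")
    tm = PhenotypeMatrix(values=traits, kind="trait")
    gene_of = pd.Series({f"f{i}": f"G{i}" for i in range(6)})
    out = cc.trait_correlation_compare(a, b, tm, gene_of, gene_of,
                                       fdr_levels=(0.05,))
    s = out[0.05]
    assert s["unique_a"] == 0 and s["unique_b"] == 0
    assert s["shared"] == s["relations_a"] == s["relations_b"]
    assert s["shared"] > 0


def test_planted_two_gene_toy_counts(rng):
    """Planted relations on different genes are counted unique, not shared."""
    n = 50
    strains = [f"S{i:03d}" for i in range(n)]
    base = rng.standard_normal(n)
    noise_a = rng.standard_normal((10, n))
    noise_b = rng.standard_normal((10, n))
    fa = pd.DataFrame(np.vstack([base, noise_a]),
                      index=["pepA"] + [f"pepN{i}" for i in range(10)],
                      columns=strains)
    fb = pd.DataFrame(np.vstack([base + 0.05 * rng.standard_normal(n), noise_b]),
                      index=["psB"] + [f"psN{i}" for i in range(10)],
                      columns=strains)
    traits = pd.DataFrame([base + 0.05 * rng.standard_normal(n)],
                          index=["t0"], columns=strains)
    gene_a = pd.Series({"pepA": "GA",
                        **{f"pepN{i}": f"GNA{i}" for i in range(10)}})
    gene_b = pd.Series({"psB": "GB",
                        **{f"psN{i}": f"GNB{i}" for i in range(10)}})
    out = cc.trait_correlation_compare(
        PhenotypeMatrix(values=fa, kind="peptide"),
        PhenotypeMatrix(values=fb, kind="transcript"),
        PhenotypeMatrix(values=traits, kind="trait"),
        gene_a, gene_b, fdr_levels=(0.05,))
    s = out[0.05]
    assert s["relation_set_a"] == {("GA", "t0")}
    assert s["relation_set_b"] == {("GB", "t0")}
    assert s["shared"] == 0 and s["unique_a"] == 1 and s["unique_b"] == 1


def test_no_shared_strains_errors(rng):
    a = PhenotypeMatrix(values=pd.DataFrame(rng.standard_normal((2, 5)),
                                            index=["x", "y"],
                                            columns=list("ABCDE")), kind="peptide")
    t = PhenotypeMatrix(values=pd.DataFrame(rng.standard_normal((1, 5)),
                                            index=["t"],
                                            columns=list("FGHIJ")), kind="trait")
    with pytest.raises(DataError):
        cc._feature_trait_pvalues(a, t)


# --- bootstrap group test ---------------------------------------------------

def test_bootstrap_whole_pool_gives_p_one():
    pool = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd"))
    gene_of = pd.Series({"a": "G1", "b": "G2", "c": "G3", "d": "G4"})
    out = cc.go_bootstrap_test(pool, gene_of,
                               {"T": ("BP", ["G1", "G2", "G3", "G4"])},
                               n_boot=100, seed=0)
    assert out.loc["T", "empirical_p"] == 1.0


def test_bootstrap_matches_exhaustive_enumeration():
    """5-element pool, groups of size 2: all 10 subsets enumerated."""
    vals = [0.01, 0.2, 0.5, 0.7, 0.9]
    pool = pd.Series(vals, index=list("abcde"))
    gene_of = pd.Series(dict(zip("abcde", ["G1", "G2", "G3", "G4", "G5"])))
    out = cc.go_bootstrap_test(pool, gene_of, {"T": ("MF", ["G1", "G2"])},
                               exhaustive=True)
    obs = (0.01 + 0.2) / 2
    null = [np.mean(pair) for pair in combinations(vals, 2)]
    le = sum(1 for v in null if v <= obs)
    ge = sum(1 for v in null if v >= obs)
    expect = min(1.0, (2 * min(le, ge) + 1) / (len(null) + 1))
    assert out.loc["T", "empirical_p"] == pytest.approx(expect)
    assert out.loc["T", "direction"] == "concordant"


def test_bootstrap_seed_reproducible(rng):
    pool = pd.Series(rng.random(30), index=[f"v{i}" for i in range(30)])
    gene_of = pd.Series({f"v{i}": f"G{i}" for i in range(30)})
    groups = {"T1": ("BP", [f"G{i}" for i in range(5)]),
              "T2": ("CC", [f"G{i}" for i in range(10, 18)])}
    a = cc.go_bootstrap_test(pool, gene_of, groups, n_boot=500, seed=7)
    b = cc.go_bootstrap_test(pool, gene_of, groups, n_boot=500, seed=7)
    pd.testing.assert_frame_equal(a, b)


def test_bootstrap_group_larger_than_pool_errors():
    pool = pd.Series([0.1, 0.2], index=["a", "b"])
    gene_of = pd.Series({"a": "G1", "b": "G2"})
    with pytest.raises(DataError):
        cc.go_bootstrap_test(pool, gene_of,
                             {"T": ("BP", ["G1", "G2", "G3"])}, n_boot=10)
    # ... but only when more member values than pool entries exist
    gene_of3 = pd.Series({"a": "G1", "b": "G1"})
    out = cc.go_bootstrap_test(pool, gene_of3, {"T": ("BP", ["G1"])}, n_boot=10)
    assert out.loc["T", "empirical_p"] == 1.0  # group == pool


# --- pathway concordance ----------------------------------------------------

def pathway_fixture(rng, copies=False):
    strains = [f"S{i:03d}" for i in range(100)]
    base = rng.standard_normal(100)
    if copies:
        pep = np.tile(base, (3, 1))
        ps = np.tile(base, (3, 1))
    else:
        pep = rng.standard_normal((3, 100))
        ps = rng.standard_normal((3, 100))
    pep_ids = ["pep0", "pep1", "pep2"]
    ps_ids = ["ps0", "ps1", "ps2"]
    genes = pd.DataFrame({"chrom": "chr1", "tss_bp": 1, "tes_bp": 10,
                          "strand": "+"},
                         index=pd.Index([f"G{i}" for i in range(6)],
                                        name="gene_id"))
    pep_df = pd.DataFrame({
        "sequence": "ACDK",
        "gene_ids": pd.Series({p: (f"G{i}",) for i, p in enumerate(pep_ids)}),
        "isoform_ids": pd.Series({p: (f"G{i}.iso0",)
                                  for i, p in enumerate(pep_ids)}),
        "chrom": "chr1", "exon_start_bp": 1, "exon_end_bp": 10})
    pep_df.index.name = "peptide_id"
    ps_df = pd.DataFrame({"gene_ids": pd.Series(
        {p: (f"G{i + 3}",) for i, p in enumerate(ps_ids)})})
    ps_df.index.name = "probeset_id"
    ann = AnnotationSet(genes=genes, probesets=ps_df,
                        probes=pd.DataFrame(columns=["probeset_id", "chrom",
                                                     "start_bp", "end_bp"]),
                        peptides=pep_df, groups={})
    groups = {"PW": ("pathway", [f"G{i}" for i in range(6)])}
    return (PhenotypeMatrix(values=pd.DataFrame(pep, index=pep_ids,
                                                columns=strains), kind="peptide"),
            PhenotypeMatrix(values=pd.DataFrame(ps, index=ps_ids,
                                                columns=strains), kind="transcript"),
            groups, ann)


def test_pathway_all_copies_gives_ones(rng):
    pmat, tmat, groups, ann = pathway_fixture(rng, copies=True)
    table, skipped = cc.pathway_concordance(pmat, tmat, groups, ann)
    row = table.loc["PW"]
    assert row["within_protein_r"] == pytest.approx(1.0)
    assert row["within_transcript_r"] == pytest.approx(1.0)
    assert row["cross_r"] == pytest.approx(1.0)


def test_pathway_independent_noise_near_zero(rng):
    pmat, tmat, groups, ann = pathway_fixture(rng)
    table, _ = cc.pathway_concordance(pmat, tmat, groups, ann)
    row = table.loc["PW"]
    for col in ("within_protein_r", "within_transcript_r", "cross_r"):
        assert abs(row[col]) < 0.2  # few pairs: loose bound on |mean|


def test_pathway_means_equal_bruteforce(rng):
    pmat, tmat, groups, ann = pathway_fixture(rng)
    table, _ = cc.pathway_concordance(pmat, tmat, groups, ann)
    pep = pmat.values
    ps = tmat.values

    def spear(a, b):
        return stats.spearmanr(a, b).statistic

    wp = np.mean([spear(pep.iloc[i], pep.iloc[j])
                  for i, j in combinations(range(3), 2)])
    wt = np.mean([spear(ps.iloc[i], ps.iloc[j])
                  for i, j in combinations(range(3), 2)])
    cx = np.mean([spear(pep.iloc[i], ps.iloc[j])
                  for i in range(3) for j in range(3)])
    assert table.loc["PW", "within_protein_r"] == pytest.approx(wp, abs=1e-12)
    assert table.loc["PW", "within_transcript_r"] == pytest.approx(wt, abs=1e-12)
    assert table.loc["PW", "cross_r"] == pytest.approx(cx, abs=1e-12)


def test_underpopulated_pathway_skipped(rng):
    pmat, tmat, groups, ann = pathway_fixture(rng)
    groups = {"ONLY_PEP": ("pathway", ["G0", "G1", "G2"])}
    table, skipped = cc.pathway_concordance(pmat, tmat, groups, ann)
    assert "ONLY_PEP" in skipped and len(table) == 0


# --- isoform clusters -------------------------------------------------------

def isoform_fixture(rng, two_clusters):
    strains = [f"S{i:03d}" for i in range(60)]
    g1 = rng.standard_normal(60)
    g2 = rng.standard_normal(60) if two_clusters else g1
    rows, iso = {}, {}
    for i in range(3):
        rows[f"a{i}"] = g1 + 0.3 * rng.standard_normal(60)
        iso[f"a{i}"] = ("GX.iso0",)
    for i in range(3):
        rows[f"b{i}"] = g2 + 0.3 * rng.standard_normal(60)
        iso[f"b{i}"] = ("GX.iso1",) if two_clusters else ("GX.iso0",)
    genes = pd.DataFrame({"chrom": "chr1", "tss_bp": 1, "tes_bp": 10,
                          "strand": "+"},
                         index=pd.Index(["GX"], name="gene_id"))
    pep = pd.DataFrame({
        "sequence": "ACDK", "gene_ids": pd.Series({p: ("GX",) for p in rows}),
        "isoform_ids": pd.Series(iso),
        "chrom": "chr1", "exon_start_bp": 1, "exon_end_bp": 10})
    pep.index.name = "peptide_id"
    ann = AnnotationSet(genes=genes, probesets=pd.DataFrame({"gene_ids": []}),
                        probes=pd.DataFrame(columns=["probeset_id", "chrom",
                                                     "start_bp", "end_bp"]),
                        peptides=pep, groups={})
    mat = PhenotypeMatrix(values=pd.DataFrame.from_dict(
        rows, orient="index", dtype=float).set_axis(strains, axis=1),
        kind="peptide")
    return mat, ann


def test_single_cluster_averages_coincide(rng):
    mat, ann = isoform_fixture(rng, two_clusters=False)
    out = cc.isoform_cluster_concordance(mat, ann)
    assert out["gene_level_mean"] == pytest.approx(out["cluster_level_mean"])


def test_two_cluster_structure_raises_cluster_mean(rng):
    mat, ann = isoform_fixture(rng, two_clusters=True)
    out = cc.isoform_cluster_concordance(mat, ann)
    assert out["cluster_level_mean"] > out["gene_level_mean"]


def test_singleton_clusters_excluded(rng):
    mat, ann = isoform_fixture(rng, two_clusters=True)
    # orphan one peptide into its own cluster
    ann.peptides.loc["b2", "isoform_ids"] = ("GX.iso9",)
    out = cc.isoform_cluster_concordance(mat, ann)
    assert "GX.iso9" not in out["per_cluster"].index
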