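"""End-to-end orchestration: simulate -> qc -> concordance -> gwas -> qtl.

A run directory collects per-stage TSV outputs plus a JSON manifest
(config hash, per-stage row counts). Stages whose outputs already exist
under a matching config hash are skipped on resume.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, concordance, io, qc, qtlmap, synth
from .datatypes import ConfigError, SimConfig

log = logging.getLogger("molqtl")


@dataclass
class RunConfig:
    """All pipeline thresholds, at their panel-study defaults."""

    out_dir: str = "run"
    seed: int = 0
    max_missing: float = 0.5
    snr_cutoff: float = 2.0
    herit_p: float = 0.05
    probe_mask_exclude_at: int = 8
    maf_min: float = 0.10
    geno_miss_max: float = 0.10
    ld_r2: float = 0.5
    flank_bp: int = 2_000_000
    hotspot_window_bp: int = 2_000_000
    hotspot_step_bp: int = 50_000
    fdr_levels: tuple = (0.05, 0.01, 0.001)
    n_boot: int = 100_000
    eigen_trends: int = 0
    sim: dict = field(default_factory=dict)
    stages: tuple = ("simulate", "qc", "concord", "gwas", "qtl")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "fdr_levels" in raw:
            raw["fdr_levels"] = tuple(raw["fdr_levels"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_done(out: Path, stage: str, cfg_hash: str) -> bool:
    marker = out / f".{stage}.done"
    if not marker.exists():
        return False
    try:
        return json.loads(marker.read_text())["config_hash"] == cfg_hash
    except Exception:
        return False


def _mark_done(out: Path, stage: str, cfg_hash: str, counts: dict):
    (out / f".{stage}.done").write_text(
        json.dumps({"config_hash": cfg_hash, "counts": counts}, indent=1)
    )


def run_pipeline(cfg: RunConfig, resume: bool = False) -> dict:
    """Run all configured stages; returns the manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    cfg_hash = cfg.config_hash()
    manifest = {"config_hash": cfg_hash, "stages": {}}

    try:
        sim_cfg = SimConfig(**{"seed": cfg.seed, **cfg.sim})

        if "simulate" in cfg.stages:
            if resume and _stage_done(out, "simulate", cfg_hash):
                log.info("simulate: outputs up to date, skipping")
            else:
                panel = synth.simulate_panel(sim_cfg)
                io.write_genotypes(panel.genotypes, out / "genotypes.tsv")
                io.write_phenotypes(panel.transcripts, out / "transcripts.tsv")
                io.write_phenotypes(panel.peptides, out / "peptides.tsv")
                io.write_table(panel.tech_reps, out / "tech_reps.tsv")
                io.write_phenotypes(panel.traits, out / "traits.tsv")
                io.write_annotations(panel.annotations, out)
                io.write_truth(panel.truth, out)
                counts = {
                    "snps": panel.genotypes.n_snps,
                    "transcripts": len(panel.transcripts.feature_ids),
                    "peptides": len(panel.peptides.feature_ids),
                }
                _mark_done(out, "simulate", cfg_hash, counts)
                manifest["stages"]["simulate"] = counts
                log.info("simulate: %s", counts)

        geno = io.read_genotypes(out / "genotypes.tsv")
        ann = io.read_annotations(out)
        transcripts = io.read_phenotypes(out / "transcripts.tsv", "transcript")
        peptides = io.read_phenotypes(out / "peptides.tsv", "peptide")
        tech = pd.read_csv(out / "tech_reps.tsv", sep="\t", index_col=0)
        traits = io.read_phenotypes(out / "traits.tsv", "trait")

        if "qc" in cfg.stages and not (resume and _stage_done(out, "qc", cfg_hash)):
            kept_pep, pep_log = qc.peptide_basic_filter(
                peptides, ann, max_missing=cfg.max_missing)
            snr = qc.signal_to_noise(
                concordance.PhenotypeMatrix(
                    values=peptides.values.loc[kept_pep], kind="peptide"),
                tech, cutoff=cfg.snr_cutoff)
            kept_pep = [p for p in kept_pep if snr.loc[p, "pass"]]
            her = qc.heritability_anova(transcripts)
            pep_genes = set(ann.unique_gene_of_peptide().reindex(kept_pep).dropna())
            kept_ps = qc.filter_transcripts(
                her, ann, forced_genes=pep_genes, p_cut=cfg.herit_p)
            snp_pos = {
                c: np.sort(geno.pos_bp[geno.chrom == c])
                for c in pd.unique(geno.chrom)
            }
            masked, excluded = qc.mask_probes(
                ann, snp_pos, exclude_at=cfg.probe_mask_exclude_at)
            kept_ps = [p for p in kept_ps if p not in set(excluded)]
            io.write_table(pep_log, out / "peptide_filter_log.tsv", index=False)
            io.write_table(snr, out / "snr.tsv")
            io.write_table(her, out / "heritability.tsv")
            pd.Series(kept_pep, name="peptide_id").to_csv(
                out / "kept_peptides.tsv", sep="\t", index=False)
            pd.Series(kept_ps, name="probeset_id").to_csv(
                out / "kept_probesets.tsv", sep="\t", index=False)
            counts = {"kept_peptides": len(kept_pep),
                      "kept_probesets": len(kept_ps),
                      "masked_probesets": len(excluded)}
            _mark_done(out, "qc", cfg_hash, counts)
            manifest["stages"]["qc"] = counts
            log.info("qc: %s", counts)

        needs_filtered = any(s in cfg.stages for s in ("concord", "gwas", "qtl"))
        if needs_filtered:
            kept_pep = pd.read_csv(out / "kept_peptides.tsv", sep="\t")["peptide_id"].tolist()
            kept_ps = pd.read_csv(out / "kept_probesets.tsv", sep="\t")["probeset_id"].tolist()
            snr = pd.read_csv(out / "snr.tsv", sep="\t", index_col=0)
            pep_f = concordance.PhenotypeMatrix(
                values=peptides.values.loc[kept_pep], kind="peptide")
            if cfg.eigen_trends > 0:
                pep_f = qc.eigen_normalize(pep_f, cfg.eigen_trends)
            tr_means = transcripts.strain_means()
            ps_f = concordance.PhenotypeMatrix(
                values=tr_means.loc[[p for p in kept_ps if p in tr_means.index]],
                kind="transcript")

        if "concord" in cfg.stages and not (resume and _stage_done(out, "concord", cfg_hash)):
            pairs = concordance.build_gene_pairs(pep_f, ps_f, ann)
            io.write_table(pairs, out / "gene_pairs.tsv", index=False)
            strata = concordance.snr_strata_summary(pairs, snr)
            strata.to_csv(out / "snr_strata.tsv", sep="\t")
            if len(pairs):
                pool = pairs.set_index("peptide_id")["p"]
                gene_of = pairs.set_index("peptide_id")["gene_id"]
                groups = concordance.restrict_groups(
                    ann.groups, pairs["gene_id"].unique())
                boot = concordance.go_bootstrap_test(
                    pool, gene_of, groups,
                    n_boot=min(cfg.n_boot, 20_000), seed=cfg.seed)
                io.write_table(boot, out / "group_bootstrap.tsv")
            pw, _ = concordance.pathway_concordance(pep_f, ps_f, ann.groups, ann)
            io.write_table(pw, out / "pathway_concordance.tsv")
            tc = concordance.trait_correlation_compare(
                pep_f, ps_f, traits,
                ann.unique_gene_of_peptide(), ann.unique_gene_of_probeset(),
                fdr_levels=cfg.fdr_levels)
            io.write_table(pd.DataFrame(tc).T.rename_axis("fdr_level"),
                           out / "trait_compare.tsv")
            counts = {"pairs": len(pairs)}
            _mark_done(out, "concord", cfg_hash, counts)
            manifest["stages"]["concord"] = counts
            log.info("concord: %s", counts)

        if "gwas" in cfg.stages and not (resume and _stage_done(out, "gwas", cfg_hash)):
            K = assoc.ibs_kinship(geno)
            calls = {}
            for name, mat in (("transcript", ps_f), ("protein", pep_f)):
                recs, skipped = assoc.gwas_scan(
                    mat, geno, K, maf_min=cfg.maf_min, miss_max=cfg.geno_miss_max)
                recs["q"] = assoc.qvalues(recs["p"].to_numpy())
                sig = recs[recs["q"] < cfg.fdr_levels[0]].copy()
                if len(sig):
                    sig = assoc.ld_prune(sig, geno, r2_cut=cfg.ld_r2)
                    sig = sig[sig["is_peak"]]
                io.write_table(sig, out / f"assoc_{name}.tsv", index=False)
                calls[name] = sig
                log.info("gwas %s: %d significant peaks (%d skipped phenotypes)",
                         name, len(sig), len(skipped))
            counts = {k: len(v) for k, v in calls.items()}
            _mark_done(out, "gwas", cfg_hash, counts)
            manifest["stages"]["gwas"] = counts

        if "qtl" in cfg.stages and not (resume and _stage_done(out, "qtl", cfg_hash)):
            blocks, bsum = qtlmap.haplotype_blocks(geno, r2_cut=cfg.ld_r2)
            io.write_table(blocks, out / "haplotype_blocks.tsv", index=False)
            qtl_calls = {}
            for name, fname, gene_of in (
                ("transcript", "assoc_transcript.tsv", ann.unique_gene_of_probeset()),
                ("protein", "assoc_protein.tsv", ann.unique_gene_of_peptide()),
            ):
                sig = pd.read_csv(out / fname, sep="\t")
                if len(sig):
                    qtl_calls[name] = qtlmap.classify_qtl(
                        sig, ann.genes, gene_of, name, flank_bp=cfg.flank_bp)
                else:
                    qtl_calls[name] = pd.DataFrame(
                        columns=["phenotype_id", "gene_id", "snp_id", "chrom",
                                 "pos_bp", "p", "q", "locality", "dataset"])
                io.write_table(qtl_calls[name], out / f"qtl_{name}.tsv", index=False)
            nonempty = [df for df in qtl_calls.values() if len(df)]
            all_calls = (pd.concat(nonempty, ignore_index=True)
                         if nonempty else next(iter(qtl_calls.values())))
            if len(all_calls):
                prof = qtlmap.hotspot_scan(
                    all_calls, window_bp=cfg.hotspot_window_bp,
                    step_bp=cfg.hotspot_step_bp)
                io.write_table(prof, out / "hotspots.tsv", index=False)
            ov = qtlmap.overlap_analysis(
                qtl_calls["transcript"], qtl_calls["protein"],
                match_bp=cfg.flank_bp)
            summary = qtlmap.summarize_counts(
                qtl_calls,
                {"transcript": len(ps_f.feature_ids),
                 "protein": len(pep_f.feature_ids)})
            io.write_table(summary, out / "qtl_summary.tsv")
            (out / "overlap.json").write_text(json.dumps({
                "shared_local": ov.shared_local,
                "shared_distant": ov.shared_distant,
                "same_peak_local": ov.same_peak_local,
                "same_peak_distant": ov.same_peak_distant,
            }, indent=1))
            counts = {"blocks": bsum["n_blocks"],
                      "shared_local": ov.shared_local}
            _mark_done(out, "qtl", cfg_hash, counts)
            manifest["stages"]["qtl"] = counts
            log.info("qtl: %s", counts)

        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest
    finally:
        log.removeHandler(fh)
        fh.close()
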