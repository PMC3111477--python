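# molqtl

Comparative transcriptome–proteome genetics for inbred strain panels:
quality filtering, robust concordance statistics, mixed-model molecular QTL
mapping, and post-association analysis — with a synthetic panel generator
that makes every stage testable against known ground truth.

## The scientific problem

In a panel of ~100 fully inbred mouse strains profiled for liver
transcripts (microarray, 3 biological replicates per strain) and peptides
(LC–MS against an ¹⁸O-labeled pooled reference, one sample per strain plus
~10 technical replicates of one reference strain), how well do transcript
and protein levels agree — overall, per gene, as a function of measurement
noise, in their relationships to clinical traits, and in the genomic loci
that control them (eQTL vs pQTL)?

Answering this requires a chain of methods this package implements:

* **Peptide QC** — keep peptides with < 50% missing values, no internal
  Lys/Arg (tryptic termini only), and a unique gene annotation; then filter
  on the signal-to-noise ratio `S = var(panel) / var(technical replicates)`
  at `S > 2`.
* **Transcript QC** — broad-sense heritability per probeset by one-way
  strain ANOVA, `H² = SS_strain / SS_total`, keeping probesets with a
  significant strain term (p < 0.05) and unique annotation; probes whose
  25-mer target contains a SNP are masked, and probesets with ≥ 8 masked
  probes are dropped. An SVD-based "eigenpeptide" normalization removes
  systematic trends from the peptide matrix.
* **Concordance** — the biweight midcorrelation (bicor: median/MAD weights,
  tuning constant 9) for every peptide × probeset pair of the same gene,
  trait-correlation sharing at matched FDR, bootstrap group tests for
  GO/pathway terms (mean p-value vs 100,000 subsets drawn without
  replacement), and isoform-cluster concordance.
* **Association** — the linear mixed model `y = μ + xβ + u + e` with
  `Var(u) = σ²_g K` (K the identity-by-state kinship) and
  `Var(e) = σ²_e I`. Variance components are fit by REML over
  `δ = σ²_e/σ²_g` using the spectral decomposition of the projected
  kinship; each SNP is tested by an F-test on data whitened in the
  eigenbasis of `K + δI`. FDR control uses Storey q-values (with the
  large-scale subsample-averaging mode); significant hits are LD-pruned at
  genotype `r² ≥ 0.5`.
* **QTL analysis** — peaks are local if within 2 Mb of the gene's
  transcribed region (4 Mb window), else distant; hotspot profiles count
  associations in 2 Mb windows slid every 50 kb; eQTL–pQTL overlap matches
  peaks within 2 Mb, one-to-one nearest-first; haplotype blocks are maximal
  runs of consecutive SNPs with adjacent `r² > 0.5`.

The `synth` module generates panels with this exact statistical structure
(family-structured LD genotypes with MAF ≥ 10%, gene-level genetic
architectures shared between a gene's transcripts and peptides, planted
local/distant QTL of controlled effect size, replicate structure, technical
noise, and trait drivers) and emits the ground truth for recovery testing.

## Worked example

Run the whole pipeline on a small synthetic panel:

```python
from molqtl.pipeline import RunConfig, run_pipeline

cfg = RunConfig(out_dir="/tmp/demo", seed=7, n_boot=2000,
                sim={"n_strains": 60, "n_snps": 500, "n_chromosomes": 5,
                     "chrom_length_bp": 30_000_000, "n_transcripts": 120,
                     "n_peptides": 180, "n_traits": 8, "n_genes": 90})
manifest = run_pipeline(cfg)
```

The manifest reports the filtering funnel and stage outputs:

```
"qc":      {"kept_peptides": 112, "kept_probesets": 98, "masked_probesets": 0}
"concord": {"pairs": 118}
"gwas":    {"transcript": 15, "protein": 4}
"qtl":     {"blocks": 161, "shared_local": 2}
```

Of 180 simulated peptides, 112 survive the missingness/tryptic/annotation
and S > 2 filters; 98 of 120 probesets pass the heritability and annotation
filters. The 118 gene-level peptide×probeset pairs yield the concordance
tables; the mixed-model scan finds 15 transcript and 4 protein
associations at 5% FDR after LD pruning, and `qtl_summary.tsv` breaks them
down in the style of a genome-wide association profile table:

```
dataset     n_phenotypes  total  with_assoc  with_local  local  distant  multiple
transcript  98            15     13          9           9      6        2
protein     112           4      4           4           4      0        0
```

`overlap.json` reports that 2 local QTL are shared between the transcript
and protein datasets, both at the identical peak SNP — on this small panel
every shared local pair maps to the same marker.

The same stages are exposed as subcommands of the `molqtl` CLI
(`simulate`, `qc`, `concord`, `gwas`, `qtl`, `report`, `run-all`), e.g.

```
molqtl run-all --seed 7 --out-dir run/
molqtl report --out-dir run/
```

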