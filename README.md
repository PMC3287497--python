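# methmir

Genome-wide interplay of two layers of gene repression: **promoter DNA
methylation** (transcriptional) and **miRNA targeting of 3'UTRs**
(post-transcriptional). The package extracts per-gene regulatory features
from standard genomics formats, segments methylomes into differentially and
partially methylated regions, and runs the rank-statistics battery that
tests whether the two layers complement each other — genes under strong
promoter methylation carrying fewer miRNA target sites, and vice versa.

It is written for regulatory/epigenomics analysts who have (or simulate):

- a gene annotation (GTF) and genome (FASTA),
- single-base bisulfite methylation calls for one or two cell lines,
- per-gene miRNA target predictions (e.g. mirTarget2- or PicTar-style),
- tissue-panel and/or RNA-seq expression tables,
- orthologous 3'UTR alignments.

## The quantities at the core

For each gene, the promoter window is **−1000..+200 bp** around the TSS of
the major transcript (longest CDS), and genes with distant alternative TSSs
(> 200 bp) or inconsistent 3'UTRs are excluded. Two methylation measures
are computed per promoter:

- **mCG/CG** (methylation broadness): the fraction of covered CpG sites
  called methylated,
- **CpG O/E** (normalized CpG content): `n_CpG · L / (n_C · n_G)` — a
  sequence-only proxy of germline methylation over evolutionary time
  (methylated cytosines deaminate, depleting CpGs), plus the count of
  CpG islands (Gardiner-Garden–Frommer rule).

miRNA regulation is measured as the number of unique predicted target
sites per gene (Nt, Np per prediction source) with 3'UTR length (UL) as a
capacity proxy. The battery reports Spearman's ρ between each methylation
measure and each burden measure, and the first-order **partial** Spearman
correlation conditioning on gene expression level,

ρ<sub>xy·z</sub> = (ρ<sub>xy</sub> − ρ<sub>xz</sub>ρ<sub>yz</sub>) /
√((1−ρ<sub>xz</sub>²)(1−ρ<sub>yz</sub>²)).

Methylomes are also segmented into **DMRs** (1-kb windows tested one-sided
by Fisher's exact test for higher methylation in the second cell line,
BH-adjusted, merged) and **PMDs** (runs of 10-kb windows with read-weighted
mean methylation strictly below 70%), and 3'UTR divergence is quantified by
the **Kimura two-parameter** distance
K = −½·ln[(1−2P−Q)·√(1−2Q)] plus lineage-specific indel rates polarized by
outgroup unanimity.

A first-class synthetic-genome generator (`methmir.synthetic`) emits every
input format with the couplings controlled through a Gaussian copula, so
the whole pipeline is testable end-to-end with no downloads.

## Worked example

```bash
python analysis/01_simulate.py --seed 1      # bundle -> scratch/bundle
python analysis/02_build_features.py         # feature table -> scratch/run
python analysis/03_correlation_battery.py
python analysis/04_methylation_domains.py
python analysis/05_cancer_and_tissues.py
```

The battery step prints (seed 1, 5000 simulated genes, 4762 retained):

```
 mcg_cg_H1 vs Nt  rho=-0.296*** partial=-0.232*** n=4762
    cpg_oe vs Nt  rho=+0.253*** partial=+0.230*** n=4762
methylation_vs_expression: rho=-0.468 (n=4762, p=1.1e-257)
methylation_vs_k3u:        rho=+0.145 (n=4762, p=9.1e-24)
```

Reading: promoter methylation broadness correlates negatively with miRNA
target burden (ρ = −0.296, recovering the configured population coupling
−0.29); the correlation weakens but stays highly significant after
conditioning on expression (−0.232), so it is not a by-product of
expression level; CpG O/E — an inverse methylation proxy — shows the
mirrored positive pattern. The domain step reports 20/20 planted DMRs and
5/5 planted PMDs recovered, with DMR genes hypomethylated (mCG/CG 0.18 vs
0.50 elsewhere), and the cancer step shows simulated cancer genes carrying
more target sites (19.1 vs 14.7) and less promoter methylation (0.38 vs
0.51) than other genes.

The same stages are exposed as a CLI (`methmir simulate|annotate|
methylation|segment|expression|targets|evolve|run`) and as a library
(`methmir.annotation`, `.methylome`, `.segmentation`, `.expression`,
`.mirna`, `.evolution`, `.stats`, `.synthetic`, `.pipeline`).

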