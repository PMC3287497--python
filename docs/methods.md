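# Methods

This note documents the models and procedures implemented in `methmir`,
the parameter choices that matter, what the synthetic generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Gene models and promoters

GTF input (1-based closed) is converted to 0-based half-open coordinates on
read; all interval arithmetic is half-open. Each gene's **major
transcript** is the one with the longest summed CDS, ties broken by longest
genomic span, then lexicographically smallest transcript id — a
deterministic, order-independent rule in the spirit of common
canonical-transcript conventions. A gene is retained only if

1. every alternative TSS lies within 200 bp (absolute genomic distance,
   strand-ignored) of the major TSS, and
2. all transcripts' 3'UTRs are mutually consistent: pairwise reciprocal
   overlap ≥ 80% on the same strand (threshold configurable), and
3. the major transcript has an annotated, non-empty 3'UTR.

The promoter window is [TSS−1000, TSS+200) on the plus strand and its
mirror image on the minus strand, clipped at position 0 with a flag.

## Methylation measures

**Site calling.** Call tables carry per-CpG methylated/total read counts.
Two callers are provided: a one-sided binomial test of each site against a
bisulfite error rate ε = 0.01, BH-adjusted over the call set at q ≤ 0.01
(default), and a simple fraction rule (mc/total ≥ 0.5, inclusive). The
caller is pluggable because upstream published call sets may have used
different procedures.

**mCG/CG** is the fraction of *covered* promoter CpG sites called
methylated; sites without coverage are excluded from numerator and
denominator, and the value is missing when no covered CpG remains. CpG
dinucleotides are enumerated on the forward genome strand (CpG is
palindromic); calls are attributed to a gene through its annotated strand
(sense-strand reporting convention; both-strand merging is a config
option).

**CpG O/E** = (n_CpG/L) / ((n_C/L)(n_G/L)) with an overlapping dinucleotide
scan and L (not L−1) in the denominator — the most literal reading of the
frequency definition; the difference is O(1/L). N-containing positions are
excluded from all counts and from L; the value is missing when C or G is
absent. **CpG islands** use the Gardiner-Garden–Frommer rule (200-bp
window sliding at 1 bp, GC ≥ 50%, O/E ≥ 0.6, overlapping qualifying
windows merged, merged length ≥ 200 bp): the field default, since no other
criteria are implied by the analysis.

## Segmentation

**DMRs.** Non-overlapping 1-kb windows; per window a 2×2 table of called
site states (methylated/unmethylated × cell line) is tested one-sided for
higher methylation in the second methylome. The one-sided Fisher p-value
is computed as the hypergeometric upper tail (identical by definition,
vectorizable genome-wide); a two-sided mode uses Fisher's exact test
directly. Windows with fewer than 5 covered sites in either line are
skipped; BH adjustment is applied across all tested windows (the only
place this package constructs a multiple-testing family); adjacent
significant windows merge. Window size, FDR, site minimum and merge gap
are configurable — DMRs enter the analysis only as a gene grouping.

**PMDs.** Non-overlapping 10-kb windows; a window is sub-threshold when
its read-weighted mean methylation (Σmc/Σtotal over CpG sites) is
*strictly* below 0.70; consecutive sub-threshold windows merge and runs ≥
`min_length` (default one window) are kept. Windows without coverage break
runs. The boundary at exactly 0.70 is excluded by the strict inequality.

**Gene membership** is promoter overlap ≥ 1 bp (whole-gene mode
available), giving an exhaustive, disjoint in/out partition; the
downstream comparisons concern promoter methylation, hence the promoter
rule.

## Expression

Probe-level matrices are collapsed by (i) averaging replicate samples by
label, (ii) discarding low-confidence probe sets (ids ending `_x_at` /
`_s_at`), (iii) averaging surviving probes per gene; genes with no
surviving probe are absent. No log transform is applied before averaging.
**Expression broadness (EB)** is the number of tissues with intensity at or
above 200 (inclusive — the threshold convention is stated nowhere more
precisely, so the inclusive reading is fixed and documented). Tissue-class
labels (germline vs somatic) are data, supplied as a TSV, not hard-coded.

## miRNA burden and 3'UTR evolution

Per-gene burden is the number of unique (miRNA, site-position) pairs after
exact-duplicate removal; when positions are absent, unique miRNAs are
counted (both modes exposed; sites is the default). Genes absent from a
table flagged genome-wide get 0; otherwise they stay missing, since
conflating absence with zero biases correlations. 3'UTR length is exposed
as a labeled projection (UL) so the battery can treat it as a third burden
measure.

**K2P distance**: transitions P and transversions Q are counted over
ungapped, non-N columns; K = −½ ln[(1−2P−Q)√(1−2Q)], reported missing when
saturated (log argument ≤ 0), an error when no comparable column exists.
**Focal-specific indels** use strict unanimity parsimony: a maximal column
run with the focal row gapped and *all* outgroup rows present is a
focal-specific deletion (conversely an insertion); columns where outgroups
disagree break runs and count nothing. Rates are summed event lengths over
total alignment columns. This is deliberately conservative and
deterministic; alignment construction itself is out of scope.

## Statistics

Spearman's ρ on midranks with a t-approximation p-value; 95% CIs by Fisher
z-transform with the Fieller-adjusted standard error 1.03/√(n−3). Partial
correlations use the first-order formula on the three pairwise rank
correlations, t-test on n−3 df. Mann-Whitney U is exact for min(n) ≤ 8
without ties, otherwise normal with tie correction. Fisher's exact test
returns the sample odds ratio, with p = 1 flagged on a degenerate margin.
The chi-square is Pearson's without continuity correction (1 df),
erroring on zero expected counts. Missing values are removed complete-case
per test and the effective n is always reported. In the battery, the
partial correlations for the mCG/CG rows condition on the same cell
line's expression (log RPKM) and the CpG O/E row conditions on mean
germline-panel intensity — CpG O/E reflects germline methylation, so the
germline panel is the matching covariate; both are configurable.

The cancer comparison reports group means (all-cancer, dominant,
recessive, others; ambiguous labels stay in all-cancer only) with
two-sided Mann-Whitney tests cancer-vs-others, and a chi-square comparing
promoter-CGI presence (≥ 1 island vs none) between dominant and recessive
genes — the analysis behind that comparison is stated only as a test on
CGI counts, so presence/absence is this package's concrete reading.

## The synthetic generator

Per gene, four latents are drawn from a Gaussian copula: methylation
propensity m\* (uniform marginal), target burden (negative binomial,
mean 15, size 4 — mirTarget2-scale counts; the PicTar-style source uses
mean 8, size 3 off a 0.9-correlated latent), expression, and 3'UTR
substitution rate (uniform 0.05–0.30 substitutions/site, human–mouse
scale). Latent correlations come from the rank inversion r = 2·sin(πρ/6)
with a Monte-Carlo correction for count discreteness; an unreachable
target raises an error stating the achievable bound. Default coupling
targets: ρ(m, Nt) = −0.29, ρ(m, expression) = −0.47, ρ(Nt, expression) =
+0.20 (the mediated component that makes partial correlations
informative), ρ(m, K3u) = +0.15, and ρ(CpG O/E, mean germline
expression) = +0.37 — the last is achieved for the *mean over the
germline panel*, so the per-tissue loading is back-calibrated by Monte
Carlo through the heavy-tailed intensity scale (per-tissue germline ρ
comes out near +0.10, somatic near 0).

Structure: 4 chromosomes; each gene occupies a locus of promoter (1200
bp), 200-bp 5' segment, CDS (300–1500 bp), 3'UTR (UL = 120 + 28·Nt +
noise, 60–4000 bp), separated by 8.3–9.0 kb spacers so a locus spans at
least one PMD window — with the background CpG rate of 0.04/bp and
background methylation 0.95, a 10-kb window containing one fully
unmethylated CGI promoter still averages ≈ 0.75, keeping the 70% domain
threshold structurally separated from isolated promoter dips. Promoter
sequence couples to m\*: CpG density 0.02–0.14 per 2-bp slot and GC
content 0.38–0.63, both decreasing in m\*, so CpG O/E, CGI counts and the
planted methylation all co-vary the way germline-hypomethylated CGI
promoters do. Reads per CpG are 1 + Poisson(11); methylated sites yield
methylated reads at 0.97, unmethylated at the 0.01 bisulfite error; ~2000
CHH-context sites exercise context filters.

Planted regions: 20 DMRs (a gene's promoter ± 400 bp; the reference line
at the gene's own low m\* < 0.4 across the whole block, the second line
at 0.9) and 5 PMDs (100 kb, every site of the second line at 0.4),
occupied by genes swapped in from the low-methylation stratum so the
region-gene contrasts exist by construction. Cancer labels (~4% of genes,
dominant:recessive 4:1 plus 5 ambiguous) are drawn with weight
exp(1.5·(rank(Nt) − rank(m\*))), recessive preferentially from the lowest
methylation stratum. Ortholog pairs evolve under the K2P process (κ = 2)
at each gene's true rate; 3-species MAF blocks carry planted
human-specific indels (≈ 0.01 events/bp/3) against chimp- and
macaque-like outgroups at divergences 0.02 and 0.06.

**What passing tests show — and don't.** The generator reproduces the
*correlational structure* the analysis assumes, with clean marginals and
planted regions of known location. It does not emulate real chromosomal
organization (CpG-island shores, repeat content, long-range methylation
autocorrelation), bimodal promoter methylation, mapping artifacts, or
biased coverage; recovery here demonstrates that the pipeline measures
what it claims under its own assumptions at realistic effect sizes, not
that those effect sizes would be recovered from any particular real data
set. Two emergent behaviors worth knowing: (i) measured CpG O/E is an
attenuated instrument (rank correlation ≈ 0.8 with the true latent,
because composition noise enters both numerator and denominator), so
CpG-O/E-row correlations sit ~15–20% below the latent couplings while
mCG/CG rows (reliability ≈ 0.98) recover theirs nearly exactly — the same
instrument-reliability gap expected between the two measures on real
data; (ii) occasional single-window domain calls beyond the planted ones
are genuine sub-70% fluctuation windows, a property of thresholding at
window granularity, and the planted-region contrasts are insensitive to
them. The DMR-gene target-burden contrast is weak at 20–25 genes per
bundle (the coupling only enters through m\*), so that comparison is
reported but carries little power at these problem sizes.

## Problem sizes and numerical choices

Default study: 5000 genes (~57 Mb genome, ~2.5 M CpG sites per methylome)
— large enough that Spearman sampling error (≈ 0.014) is well inside the
±0.05 recovery bands, small enough that generation plus the full pipeline
runs in about a minute on one core. Unit and property tests use 250-gene
bundles with proportionally fewer planted regions. Determinism: one
`numpy` Generator seeded from the config drives every draw; file emission
orders are sorted; two runs from the same seed are byte-identical
end-to-end (tested). Degenerate inputs error loudly rather than silently:
zero-variance correlation inputs, empty comparison groups, degenerate
conditioning (|ρ| = 1), missing columns, duplicate gene ids (naming the
offending input), windows < 1 bp, unpolarizable alignments.
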