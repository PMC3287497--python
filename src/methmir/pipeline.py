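"""End-to-end orchestration: from raw inputs to the per-gene feature table
and the correlation / group-comparison reports.

The per-gene feature table is the single source of truth: promoter
methylation broadness per cell line, CpG O/E, promoter CGI count, target
burdens (Nt, Np, UL), expression level and broadness, 3'UTR substitution
and indel rates, region membership flags and cancer labels, one row per
retained gene. Every reported statistic is recomputable from that table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from . import annotation, evolution, expression, methylome, mirna, \
    segmentation
from .stats import (chi_square_2x2, mann_whitney, partial_spearman,
                    per_tissue_correlation, spearman)

log = logging.getLogger("methmir")

__all__ = ["build_feature_table", "table1_battery", "region_comparison",
           "cancer_comparison", "run_all"]

METH_COLUMNS = ("mcg_cg_H1", "mcg_cg_IMR90", "cpg_oe")
BURDEN_COLUMNS = ("Nt", "Np", "UL")


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 \
        else ""


def build_feature_table(frames: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Left-join per-gene stage outputs on the annotated gene set.

    ``frames`` maps a stage name to a DataFrame indexed by gene_id; the
    frame under the key ``'genes'`` defines the gene universe (genes failing
    the annotation filters are absent, not null-rowed). Raises on duplicated
    gene_ids, naming the offending input.
    """
    if "genes" not in frames:
        raise ValueError("need a 'genes' frame defining the gene universe")
    out = frames["genes"].copy()
    if out.index.duplicated().any():
        raise ValueError("duplicate gene_id in input 'genes'")
    for name, df in frames.items():
        if name == "genes":
            continue
        if df.index.duplicated().any():
            raise ValueError(f"duplicate gene_id in input {name!r}")
        out = out.join(df, how="left")
    return out


def table1_battery(features: pd.DataFrame,
                   meth_columns=METH_COLUMNS,
                   burden_columns=BURDEN_COLUMNS,
                   covariates: dict[str, str] | None = None) -> pd.DataFrame:
    """Raw and partial Spearman correlations of each promoter methylation
    measure against each target-burden measure.

    ``covariates`` maps each methylation column to the expression column
    conditioned on in the partial correlation (defaults: the same cell
    line's expression for the mCG/CG rows, mean germline expression for the
    CpG O/E row).
    """
    if covariates is None:
        covariates = {
            "mcg_cg_H1": "log_rpkm_H1",
            "mcg_cg_IMR90": "log_rpkm_IMR90",
            "cpg_oe": "mean_germline_expression",
        }
    rows = []
    for m in meth_columns:
        if m not in features.columns:
            raise ValueError(f"missing methylation column {m!r}")
        cov = covariates.get(m)
        for b in burden_columns:
            if b not in features.columns:
                raise ValueError(f"missing burden column {b!r}")
            try:
                raw = spearman(features[m], features[b])
            except ValueError as exc:
                raise ValueError(f"{exc} in column {b!r} vs {m!r}") from exc
            rec = {"methylation": m, "burden": b, "rho": raw.rho,
                   "n": raw.n, "p_value": raw.p_value,
                   "stars": _stars(raw.p_value)}
            if cov is not None and cov in features.columns:
                part = partial_spearman(features[m], features[b],
                                        features[cov], conditioned_on=cov)
                rec.update({"partial_rho": part.rho, "partial_n": part.n,
                            "partial_p": part.p_value,
                            "partial_stars": _stars(part.p_value),
                            "covariate": cov})
            rows.append(rec)
    return pd.DataFrame(rows)


def region_comparison(features: pd.DataFrame, flag_column: str,
                      measures=("mcg_cg_H1", "Nt")) -> pd.DataFrame:
    """Group means (in-region vs other genes) with two-sided Mann-Whitney
    p-values for each measure."""
    if flag_column not in features.columns:
        raise ValueError(f"missing flag column {flag_column!r}")
    flag = features[flag_column].astype(bool)
    if flag.sum() == 0 or (~flag).sum() == 0:
        raise ValueError("empty group")
    rows = []
    for m in measures:
        a = features.loc[flag, m].dropna()
        b = features.loc[~flag, m].dropna()
        u, p = mann_whitney(a, b, alternative="two-sided")
        rows.append({"measure": m, "region": flag_column,
                     "mean_in": float(a.mean()), "n_in": int(a.size),
                     "mean_out": float(b.mean()), "n_out": int(b.size),
                     "mw_u": u, "p_value": p})
    return pd.DataFrame(rows)


def cancer_comparison(features: pd.DataFrame,
                      measures=("Nt", "mcg_cg_H1", "cpg_oe", "cgi_count")
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cancer-gene group summary and tests.

    Groups: all cancer genes (dominant + recessive + ambiguous), dominant,
    recessive, others. Ambiguously classified genes are excluded from the
    dominant/recessive rows but kept in the all-cancer row. Returns
    (group-means table, tests table) where tests are two-sided Mann-Whitney
    cancer-vs-others per measure plus a chi-square on promoter CGI presence
    (>= 1 CGI vs none) dominant vs recessive.
    """
    if "cancer_label" not in features.columns:
        raise ValueError("missing cancer_label column")
    lab = features["cancer_label"].fillna("none")
    groups = {
        "cancer": lab.isin(["dominant", "recessive", "ambiguous"]),
        "dominant": lab == "dominant",
        "recessive": lab == "recessive",
        "others": lab == "none",
    }
    mean_rows = []
    for name, mask in groups.items():
        if mask.sum() == 0:
            log.warning("cancer comparison: label class %r absent", name)
            continue
        row = {"group": name, "n_genes": int(mask.sum())}
        for m in measures:
            vals = features.loc[mask, m].dropna()
            row[f"mean_{m}"] = float(vals.mean()) if vals.size else np.nan
            row[f"n_{m}"] = int(vals.size)
        mean_rows.append(row)
    means = pd.DataFrame(mean_rows)

    test_rows = []
    cancer_mask, other_mask = groups["cancer"], groups["others"]
    for m in measures:
        a = features.loc[cancer_mask, m].dropna()
        b = features.loc[other_mask, m].dropna()
        if a.size and b.size:
            u, p = mann_whitney(a, b, alternative="two-sided")
            test_rows.append({"test": f"mann_whitney_{m}", "statistic": u,
                              "p_value": p})
    if groups["dominant"].sum() and groups["recessive"].sum() \
            and "cgi_count" in features.columns:
        dom = features.loc[groups["dominant"], "cgi_count"].dropna()
        rec = features.loc[groups["recessive"], "cgi_count"].dropna()
        table = [[int((dom >= 1).sum()), int((dom == 0).sum())],
                 [int((rec >= 1).sum()), int((rec == 0).sum())]]
        try:
            stat, p = chi_square_2x2(table)
        except ValueError:
            log.warning("cancer comparison: degenerate CGI table %s, "
                        "chi-square skipped", table)
        else:
            test_rows.append({"test": "chi2_cgi_dominant_vs_recessive",
                              "statistic": stat, "p_value": p})
    return means, pd.DataFrame(test_rows)


def _conventional_paths(bundle_dir: Path) -> dict[str, Path]:
    b = Path(bundle_dir)
    return {k: b / v for k, v in {
        "genome": "genome.fa", "gtf": "annotation.gtf",
        "calls_H1": "calls_H1.tsv", "calls_IMR90": "calls_IMR90.tsv",
        "targets": "targets.tsv", "expression": "expression_probes.tsv",
        "probe_map": "probe_map.tsv", "tissue_classes": "tissue_classes.tsv",
        "rpkm_H1": "rpkm_H1.tsv", "rpkm_IMR90": "rpkm_IMR90.tsv",
        "utr3_pairs": "utr3_pairs.fa", "utr3_maf": "utr3_alignments.maf",
        "cancer_labels": "cancer_labels.tsv",
    }.items()}


def run_all(bundle_dir, out_dir, call_method: str = "binomial",
            eb_threshold: float = 200.0, dmr_fdr: float = 0.05,
            dmr_window: int = 1000, pmd_window: int = 10000,
            pmd_threshold: float = 0.70, pmd_min_length: int = 10000,
            min_coverage: int = 1) -> dict:
    """Execute every stage on a bundle directory and write the reports.

    Returns a dict of the in-memory results (feature table, battery,
    region and cancer comparisons, per-tissue profile, region sets, genes).
    Deterministic given its inputs.
    """
    paths = _conventional_paths(bundle_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    transcripts = annotation.read_gtf(paths["gtf"])
    genes = annotation.build_gene_models(transcripts)
    log.info("annotation: %d transcripts -> %d retained genes",
             len(transcripts), len(genes))

    fasta = Fasta(str(paths["genome"]))
    genome_cpg: dict[str, np.ndarray] = {}
    promoter_seq: dict[str, str] = {}
    for chrom in fasta.keys():
        genome_cpg[chrom] = methylome.find_cpg_sites(str(fasta[chrom][:]))
    comp_rows = []
    for g in genes:
        s, e = g.promoter_interval
        seq = str(fasta[g.chrom][s:e])
        promoter_seq[g.gene_id] = seq
        comp = methylome.cpg_oe(seq)
        comp_rows.append((g.gene_id, comp.cpg_oe if comp.cpg_oe is not None
                          else np.nan,
                          methylome.count_promoter_cgis(seq)))
    comp_df = pd.DataFrame(comp_rows,
                           columns=["gene_id", "cpg_oe", "cgi_count"]
                           ).set_index("gene_id")

    calls = {cell: methylome.read_calls(paths[f"calls_{cell}"])
             for cell in ("H1", "IMR90")}
    meth_frames = {}
    for cell in ("H1", "IMR90"):
        t = methylome.promoter_methylation_table(
            genes, calls[cell], genome_cpg, cell_line=cell,
            method=call_method, min_coverage=min_coverage)
        meth_frames[cell] = t.rename(columns={
            "mcg_cg": f"mcg_cg_{cell}", "n_cpg_covered": f"n_cpg_{cell}"}
        ).drop(columns=["cell_line"])

    dmrs = segmentation.detect_dmrs(calls["H1"], calls["IMR90"],
                                    window=dmr_window, fdr=dmr_fdr,
                                    call_method=call_method)
    pmds = segmentation.detect_pmds(calls["IMR90"], window=pmd_window,
                                    threshold=pmd_threshold,
                                    min_length=pmd_min_length)
    in_dmr = segmentation.assign_genes_to_regions(genes, dmrs)
    in_pmd = segmentation.assign_genes_to_regions(genes, pmds)
    log.info("segmentation: %d DMRs, %d PMDs", len(dmrs), len(pmds))

    probe_matrix = expression.read_matrix(paths["expression"])
    probe_map = pd.read_csv(paths["probe_map"], sep="\t",
                            index_col=0)["gene_id"]
    tissue_classes = expression.read_tissue_classes(paths["tissue_classes"])
    gene_expr = expression.collapse_probes(probe_matrix, probe_map)
    eb = expression.expression_broadness(gene_expr, threshold=eb_threshold)
    germ_cols = [c for c in gene_expr.columns
                 if tissue_classes.get(c) == "germline"]
    germ_mean = gene_expr[germ_cols].mean(axis=1).rename(
        "mean_germline_expression")

    rpkm = {}
    for cell in ("H1", "IMR90"):
        r = pd.read_csv(paths[f"rpkm_{cell}"], sep="\t",
                        index_col="gene_id")["rpkm"]
        rpkm[cell] = np.log1p(r).rename(f"log_rpkm_{cell}")

    targets = mirna.read_target_table(paths["targets"])
    nt = mirna.count_target_sites(targets, source="mirtarget2", genes=genes,
                                  genome_wide=True).rename("Nt")
    np_ = mirna.count_target_sites(targets, source="pictar", genes=genes,
                                   genome_wide=True).rename("Np")
    ul = mirna.utr_length_proxy(genes)

    pairs = evolution.read_pair_fasta(paths["utr3_pairs"])
    k_rows = []
    for gid, seqs in pairs.items():
        if len(seqs) != 2:
            continue
        (sa, sb) = list(seqs.values())
        ap = evolution.k2p_distance(sa, sb, gene_id=gid)
        k_rows.append((gid, np.nan if ap.k3u is None else ap.k3u))
    k3u = pd.DataFrame(k_rows, columns=["gene_id", "k3u"]
                       ).set_index("gene_id")

    maf = evolution.read_maf_by_gene(paths["utr3_maf"])
    i_rows = []
    for gid, rows_ in maf.items():
        summ = evolution.human_specific_indels(rows_, focal="human",
                                               gene_id=gid)
        i_rows.append((gid, summ.insertion_rate, summ.deletion_rate))
    indels = pd.DataFrame(i_rows, columns=["gene_id", "insertion_rate",
                                           "deletion_rate"]
                          ).set_index("gene_id")

    cancer = pd.read_csv(paths["cancer_labels"], sep="\t",
                         index_col="gene_id")["cancer_label"]

    gene_frame = pd.DataFrame({
        "chrom": [g.chrom for g in genes],
        "strand": [g.strand for g in genes],
        "tss": [g.major_tss for g in genes],
    }, index=pd.Index([g.gene_id for g in genes], name="gene_id"))

    features = build_feature_table({
        "genes": gene_frame,
        "meth_H1": meth_frames["H1"],
        "meth_IMR90": meth_frames["IMR90"],
        "composition": comp_df,
        "targets_nt": nt.to_frame(),
        "targets_np": np_.to_frame(),
        "utr_length": ul.to_frame(),
        "expression_eb": eb,
        "germline_expression": germ_mean.to_frame(),
        "rpkm_H1": rpkm["H1"].to_frame(),
        "rpkm_IMR90": rpkm["IMR90"].to_frame(),
        "k3u": k3u,
        "indels": indels,
        "cancer": cancer.to_frame(),
    })
    features["cancer_label"] = features["cancer_label"].fillna("none")
    features["in_DMR"] = in_dmr.reindex(features.index).fillna(
        False).astype(bool)
    features["in_PMD"] = in_pmd.reindex(features.index).fillna(
        False).astype(bool)

    battery = table1_battery(features)
    dmr_cmp = region_comparison(features, "in_DMR") \
        if features["in_DMR"].any() else pd.DataFrame()
    pmd_cmp = region_comparison(features, "in_PMD") \
        if features["in_PMD"].any() else pd.DataFrame()
    cancer_means, cancer_tests = cancer_comparison(features)
    tissue_profile = per_tissue_correlation(features["cpg_oe"], gene_expr,
                                            tissue_classes)

    float_fmt = "%.6g"
    features.to_csv(out / "gene_features.tsv", sep="\t",
                    float_format=float_fmt)
    battery.to_csv(out / "table1_battery.tsv", sep="\t", index=False,
                   float_format=float_fmt)
    dmr_cmp.to_csv(out / "dmr_comparison.tsv", sep="\t", index=False,
                   float_format=float_fmt)
    pmd_cmp.to_csv(out / "pmd_comparison.tsv", sep="\t", index=False,
                   float_format=float_fmt)
    cancer_means.to_csv(out / "cancer_groups.tsv", sep="\t", index=False,
                        float_format=float_fmt)
    cancer_tests.to_csv(out / "cancer_tests.tsv", sep="\t", index=False,
                        float_format=float_fmt)
    tissue_profile.to_csv(out / "per_tissue_correlation.tsv", sep="\t",
                          index=False, float_format=float_fmt)
    segmentation.write_regions_bed(dmrs, out / "dmrs.bed")
    segmentation.write_regions_bed(pmds, out / "pmds.bed")

    with open(out / "summary.txt", "w") as fh:
        fh.write(f"retained genes\t{len(genes)}\n")
        fh.write(f"DMRs called\t{len(dmrs)}\n")
        fh.write(f"PMDs called\t{len(pmds)}\n")
        for _, r in battery.iterrows():
            fh.write(f"spearman\t{r['methylation']}\t{r['burden']}\t"
                     f"{r['rho']:.4f}{r['stars']}\tn={r['n']}\n")

    return {"features": features, "battery": battery, "dmrs": dmrs,
            "pmds": pmds, "dmr_comparison": dmr_cmp,
            "pmd_comparison": pmd_cmp, "cancer_means": cancer_means,
            "cancer_tests": cancer_tests, "tissue_profile": tissue_profile,
            "genes": genes}
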