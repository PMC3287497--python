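"""Methylome segmentation: differentially methylated regions (DMRs) and
partially methylated domains (PMDs).

DMRs: fixed non-overlapping windows; in each window the called site states
of the two cell lines form a 2x2 table tested one-sided (Fisher's exact
test, computed as the hypergeometric tail) for higher methylation in the
second methylome; windows are BH-adjusted genome-wide and adjacent
significant windows merged.

PMDs: long domains whose read-weighted mean methylation (sum mc / sum total
over CpG sites) stays strictly below a threshold (default 70%) across
consecutive windows of 10 kb, kept when at least ``min_length`` long.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as _ss
from statsmodels.stats.multitest import multipletests

from .methylome import call_methylated_sites

__all__ = ["detect_dmrs", "detect_pmds", "assign_genes_to_regions",
           "write_regions_bed"]


def _window_counts(calls: pd.DataFrame, state: np.ndarray, window: int):
    """Per (chrom, window-index): number of called-methylated and covered
    CpG sites."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in calls.groupby("chrom", sort=True):
        w = (sub["pos"].to_numpy() // window)
        st = state[sub.index.to_numpy()]
        nbin = int(w.max()) + 1 if w.size else 0
        tot = np.bincount(w, minlength=nbin)
        meth = np.bincount(w, weights=st.astype(np.int64), minlength=nbin)
        out[chrom] = (meth.astype(np.int64), tot)
    return out


def detect_dmrs(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                window: int = 1000, fdr: float = 0.05,
                min_sites: int = 5, merge_gap_windows: int = 1,
                call_method: str = "binomial", two_sided: bool = False,
                **call_kwargs) -> pd.DataFrame:
    """Windows where cell line B is more methylated than A, merged to DMRs.

    Returns a BED-like DataFrame (chrom, start, end, n_windows, min_q) with
    attrs['kind'] = 'DMR'. Windows with fewer than ``min_sites`` covered CpG
    sites in either call set are skipped.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    a_cg = calls_a[calls_a["context"] == "CG"].reset_index(drop=True)
    b_cg = calls_b[calls_b["context"] == "CG"].reset_index(drop=True)
    st_a = call_methylated_sites(a_cg, method=call_method, **call_kwargs)
    st_b = call_methylated_sites(b_cg, method=call_method, **call_kwargs)
    counts_a = _window_counts(a_cg, st_a, window)
    counts_b = _window_counts(b_cg, st_b, window)

    recs = []  # (chrom, widx, p)
    for chrom in sorted(set(counts_a) & set(counts_b)):
        meth_a, tot_a = counts_a[chrom]
        meth_b, tot_b = counts_b[chrom]
        n = min(tot_a.size, tot_b.size)
        ma, ta = meth_a[:n], tot_a[:n]
        mb, tb = meth_b[:n], tot_b[:n]
        ok = (ta >= min_sites) & (tb >= min_sites)
        idx = np.flatnonzero(ok)
        if idx.size == 0:
            continue
        N = ta[idx] + tb[idx]
        K = ma[idx] + mb[idx]
        if two_sided:
            p = np.array([_ss.fisher_exact(
                [[ma[i], ta[i] - ma[i]], [mb[i], tb[i] - mb[i]]])[1]
                for i in idx])
        else:
            # one-sided Fisher (enrichment of methylated sites in B) is the
            # hypergeometric upper tail
            p = _ss.hypergeom.sf(mb[idx] - 1, N, K, tb[idx])
        for i, pv in zip(idx, p):
            recs.append((chrom, int(i), float(pv)))

    cols = ["chrom", "start", "end", "n_windows", "min_q"]
    if not recs:
        out = pd.DataFrame(columns=cols)
        out.attrs["kind"] = "DMR"
        return out
    pvals = np.array([r[2] for r in recs])
    reject, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")

    sig = [(recs[i][0], recs[i][1], qvals[i])
           for i in range(len(recs)) if reject[i] and qvals[i] <= fdr]
    sig.sort()
    merged = []
    for chrom, widx, q in sig:
        start, end = widx * window, (widx + 1) * window
        if merged and merged[-1][0] == chrom and \
                start - merged[-1][2] < merge_gap_windows * window:
            c, s0, _, nw, q0 = merged[-1]
            merged[-1] = (c, s0, end, nw + 1, min(q0, q))
        else:
            merged.append((chrom, start, end, 1, q))
    out = pd.DataFrame(merged, columns=cols)
    out.attrs["kind"] = "DMR"
    return out


def detect_pmds(calls: pd.DataFrame, window: int = 10000,
                threshold: float = 0.70, min_length: int = 10000
                ) -> pd.DataFrame:
    """Partially methylated domains of one methylome.

    Consecutive windows with read-weighted mean methylation strictly below
    ``threshold`` are merged; merged runs shorter than ``min_length`` are
    dropped. Windows without covered CpG sites break runs. Returns a
    BED-like DataFrame (chrom, start, end, mean_methylation) with
    attrs['kind'] = 'PMD'.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    cg = calls[calls["context"] == "CG"]
    regions = []
    for chrom, sub in cg.groupby("chrom", sort=True):
        w = sub["pos"].to_numpy() // window
        nbin = int(w.max()) + 1 if w.size else 0
        mc = np.bincount(w, weights=sub["mc_reads"].to_numpy(), minlength=nbin)
        tot = np.bincount(w, weights=sub["total_reads"].to_numpy(),
                          minlength=nbin)
        with np.errstate(divide="ignore", invalid="ignore"):
            mean = np.where(tot > 0, mc / tot, np.nan)
        below = (tot > 0) & (mean < threshold)
        i = 0
        while i < below.size:
            if below[i]:
                j = i
                while j + 1 < below.size and below[j + 1]:
                    j += 1
                start, end = i * window, (j + 1) * window
                if end - start >= min_length:
                    m = mc[i:j + 1].sum() / tot[i:j + 1].sum()
                    regions.append((chrom, start, end, float(m)))
                i = j + 1
            else:
                i += 1
    out = pd.DataFrame(regions,
                       columns=["chrom", "start", "end", "mean_methylation"])
    out.attrs["kind"] = "PMD"
    return out


def assign_genes_to_regions(genes, regions: pd.DataFrame,
                            by: str = "promoter") -> pd.Series:
    """Boolean in-region flag per gene (>= 1 bp overlap of the promoter, or
    of the whole transcript span with ``by='gene'``).

    Returns a pandas Series indexed by gene_id; the in/out partition is
    exhaustive and disjoint by construction.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for _, r in regions.iterrows():
        by_chrom.setdefault(r["chrom"], []).append((int(r["start"]),
                                                    int(r["end"])))
    flags = {}
    for g in genes:
        if by == "promoter":
            s, e = g.promoter_interval
        elif by == "gene":
            s = min(g.promoter_interval[0], g.utr3_interval[0])
            e = max(g.promoter_interval[1], g.utr3_interval[1])
        else:
            raise ValueError("by must be 'promoter' or 'gene'")
        hit = any(s < re_ and rs < e for rs, re_ in by_chrom.get(g.chrom, ()))
        flags[g.gene_id] = hit
    return pd.Series(flags, name=f"in_{regions.attrs.get('kind', 'region')}")


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    regions.to_csv(path, sep="\t", index=False, header=True)
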