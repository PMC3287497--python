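"""Single-base methylome processing and promoter methylation metrics.

Two complementary per-promoter measures are computed:

* methylation broadness ``mCG/CG`` — the fraction of covered promoter CpG
  sites called methylated, from whole-genome bisulfite call sets;
* normalized CpG content ``CpG O/E`` — the observed CpG dinucleotide
  frequency over the product of C and G frequencies, a sequence-only proxy
  for germline methylation over evolutionary time (methylated cytosines
  deaminate and deplete CpGs).

CpG dinucleotides are enumerated on the forward genome strand (the
dinucleotide is palindromic); per-site calls are attributed to the gene via
its annotated strand, with the sense-strand convention used for reporting.
Promoter CpG islands are detected with the Gardiner-Garden-Frommer rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _ss
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PromoterMethylation",
    "SequenceComposition",
    "read_calls",
    "call_methylated_sites",
    "find_cpg_sites",
    "promoter_mcg_cg",
    "promoter_methylation_table",
    "cpg_oe",
    "count_promoter_cgis",
]

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "mc_reads", "total_reads"]


@dataclass
class PromoterMethylation:
    gene_id: str
    cell_line: str
    mcg_cg: float | None
    n_cpg_covered: int


@dataclass
class SequenceComposition:
    length: int
    n_c: int
    n_g: int
    n_cpg: int
    cpg_oe: float | None


def read_calls(path) -> pd.DataFrame:
    """Read a 6-column call table (chrom, 0-based pos, strand, context,
    mc_reads, total_reads); plain or gzip TSV."""
    df = pd.read_csv(path, sep="\t", names=CALL_COLUMNS, header=None,
                     comment="#",
                     dtype={"chrom": str, "pos": np.int64, "strand": str,
                            "context": str, "mc_reads": np.int64,
                            "total_reads": np.int64})
    if (df["mc_reads"] > df["total_reads"]).any() or (df["total_reads"] < 1).any():
        raise ValueError("invalid call counts: need 0 <= mc <= total, total >= 1")
    return df


def call_methylated_sites(calls: pd.DataFrame, method: str = "binomial",
                          error_rate: float = 0.01, fdr: float = 0.01,
                          threshold: float = 0.5) -> np.ndarray:
    """Boolean methylation state per call row.

    ``binomial``: one-sided binomial test of mc_reads/total_reads against the
    bisulfite error rate, BH-adjusted over the call set, q <= ``fdr``.
    ``fraction``: mc/total >= ``threshold`` (inclusive).
    """
    mc = calls["mc_reads"].to_numpy()
    tot = calls["total_reads"].to_numpy()
    if method == "fraction":
        return mc / tot >= threshold
    if method == "binomial":
        p = _ss.binom.sf(mc - 1, tot, error_rate)
        if p.size == 0:
            return np.zeros(0, dtype=bool)
        reject, _, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
        return reject
    raise ValueError(f"unknown calling method {method!r}")


def find_cpg_sites(seq: str | bytes) -> np.ndarray:
    """0-based start positions of CpG dinucleotides on the forward strand."""
    arr = np.frombuffer(seq.encode() if isinstance(seq, str) else bytes(seq),
                        dtype=np.uint8)
    arr = np.where((arr == ord("c")) | (arr == ord("g")) | (arr == ord("a"))
                   | (arr == ord("t")), arr - 32, arr)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))


def promoter_mcg_cg(promoter: tuple[int, int], cpg_positions: np.ndarray,
                    covered: np.ndarray, methylated: np.ndarray,
                    gene_id: str = "", cell_line: str = "") -> PromoterMethylation:
    """mCG/CG for one promoter.

    ``cpg_positions``: sorted genomic CpG positions on the chromosome;
    ``covered``: sorted positions with sequencing coverage; ``methylated``:
    sorted positions called methylated. Sites without coverage are excluded
    from numerator and denominator; with no covered promoter CpG the value
    is missing.
    """
    s, e = promoter
    in_prom = cpg_positions[(cpg_positions >= s) & (cpg_positions < e)]
    cov = in_prom[np.isin(in_prom, covered, assume_unique=False)]
    n = cov.size
    if n == 0:
        return PromoterMethylation(gene_id, cell_line, None, 0)
    m = int(np.isin(cov, methylated).sum())
    return PromoterMethylation(gene_id, cell_line, m / n, n)


def promoter_methylation_table(genes, calls: pd.DataFrame,
                               genome_cpg: dict[str, np.ndarray],
                               cell_line: str = "",
                               method: str = "binomial",
                               min_coverage: int = 1,
                               **call_kwargs) -> pd.DataFrame:
    """Vectorized mCG/CG over a list of GeneModel for one call set.

    Restricts to CG-context calls with coverage >= ``min_coverage`` that fall
    on a genomic CpG, calls site states once genome-wide, then tallies each
    promoter by binary search. Returns a DataFrame indexed by gene_id with
    ``mcg_cg`` and ``n_cpg_covered``.
    """
    cg = calls[(calls["context"] == "CG")
               & (calls["total_reads"] >= min_coverage)].reset_index(drop=True)
    state = call_methylated_sites(cg, method=method, **call_kwargs)
    pos_by_chrom: dict[str, np.ndarray] = {}
    meth_by_chrom: dict[str, np.ndarray] = {}
    for chrom, sub in cg.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        st = state[sub.index.to_numpy()]
        order = np.argsort(pos, kind="mergesort")
        pos, st = pos[order], st[order]
        if chrom in genome_cpg:
            gpos = genome_cpg[chrom]
            if gpos.size == 0:
                pos, st = pos[:0], st[:0]
            else:
                idx = np.searchsorted(gpos, pos).clip(0, gpos.size - 1)
                mask = gpos[idx] == pos
                pos, st = pos[mask], st[mask]
        pos_by_chrom[chrom] = pos
        # prefix sums of methylated states for O(log n) interval queries
        meth_by_chrom[chrom] = np.concatenate([[0], np.cumsum(st)])
    rows = []
    for g in genes:
        s, e = g.promoter_interval
        pos = pos_by_chrom.get(g.chrom)
        if pos is None or pos.size == 0:
            rows.append((g.gene_id, np.nan, 0))
            continue
        i, j = np.searchsorted(pos, [s, e])
        n = int(j - i)
        if n == 0:
            rows.append((g.gene_id, np.nan, 0))
        else:
            m = int(meth_by_chrom[g.chrom][j] - meth_by_chrom[g.chrom][i])
            rows.append((g.gene_id, m / n, n))
    out = pd.DataFrame(rows, columns=["gene_id", "mcg_cg", "n_cpg_covered"])
    if cell_line:
        out["cell_line"] = cell_line
    return out.set_index("gene_id")


def cpg_oe(seq: str) -> SequenceComposition:
    """Normalized CpG content of a sequence.

    cpg_oe = (n_CpG / L) / ((n_C / L) * (n_G / L)) = n_CpG * L / (n_C * n_G),
    with the dinucleotide scan overlapping and the denominator taken as the
    sequence length. Positions containing N are excluded from all counts and
    from the length; the ratio is missing when C or G is absent.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    valid = arr != ord("N")
    length = int(valid.sum())
    n_c = int((arr == ord("C")).sum())
    n_g = int((arr == ord("G")).sum())
    n_cpg = int(((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).sum())
    if length == 0 or n_c == 0 or n_g == 0:
        return SequenceComposition(length, n_c, n_g, n_cpg, None)
    return SequenceComposition(length, n_c, n_g, n_cpg,
                               n_cpg * length / (n_c * n_g))


def count_promoter_cgis(seq: str, window: int = 200, min_gc: float = 0.5,
                        min_oe: float = 0.6, min_length: int = 200) -> int:
    """Number of CpG islands in a sequence (Gardiner-Garden-Frommer).

    A 200-bp window sliding at 1-bp steps qualifies when GC >= 50% and
    CpG O/E >= 0.6; overlapping qualifying windows are merged and merged
    islands shorter than ``min_length`` discarded.
    """
    s = seq.upper()
    L = len(s)
    if L < window:
        return 0
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cpg = np.zeros(L, dtype=np.int64)
    is_cpg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cpg = np.concatenate([[0], np.cumsum(is_cpg)])
    starts = np.arange(0, L - window + 1)
    ends = starts + window
    wc = cum_c[ends] - cum_c[starts]
    wg = cum_g[ends] - cum_g[starts]
    # CpG dinucleotides fully inside the window
    wcpg = cum_cpg[ends - 1] - cum_cpg[starts]
    gc_ok = (wc + wg) / window >= min_gc
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(wc * wg > 0, wcpg * window / (wc * wg), 0.0)
    ok = gc_ok & (oe >= min_oe)
    if not ok.any():
        return 0
    qs = starts[ok]
    count = 0
    island_start = qs[0]
    prev = qs[0]
    for q in qs[1:]:
        if q >= prev + window:  # windows no longer overlap: close the island
            if prev + window - island_start >= min_length:
                count += 1
            island_start = q
        prev = q
    if prev + window - island_start >= min_length:
        count += 1
    return count
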