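#!/usr/bin/env python
"""Genes in differentially / partially methylated regions.

Compares promoter methylation broadness and miRNA target burden between
genes whose promoters fall in called DMRs (or PMDs) and all other genes,
and scores recovery of the planted regions against the bundle's ground
truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from methmir.pipeline import region_comparison

ROOT = Path(__file__).resolve().parents[1]


def overlap_hits(called: pd.DataFrame, truth: pd.DataFrame) -> int:
    hits = 0
    for _, t in truth.iterrows():
        ov = called[(called["chrom"] == t["chrom"])
                    & (called["start"] < t["end"])
                    & (called["end"] > t["start"])]
        hits += int(len(ov) > 0)
    return hits


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundle", type=Path,
                    default=ROOT / "scratch" / "bundle")
    ap.add_argument("--run", type=Path, default=ROOT / "scratch" / "run")
    args = ap.parse_args()

    f = pd.read_csv(args.run / "gene_features.tsv", sep="\t",
                    index_col="gene_id")
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    rows = []
    for flag in ("in_DMR", "in_PMD"):
        cmp_ = region_comparison(f, flag)
        rows.append(cmp_)
        for _, r in cmp_.iterrows():
            print(f"  {flag} {r['measure']:>10}: in={r['mean_in']:.3f} "
                  f"(n={r['n_in']}) vs out={r['mean_out']:.3f} "
                  f"(n={r['n_out']}), MW p={r['p_value']:.2g}")
    pd.concat(rows).to_csv(results / "region_comparisons.tsv", sep="\t",
                           index=False, float_format="%.5g")

    recovery = []
    for kind, bed in (("DMR", "dmrs.bed"), ("PMD", "pmds.bed")):
        called = pd.read_csv(args.run / bed, sep="\t")
        truth = pd.read_csv(args.bundle / f"truth_{kind.lower()}s.tsv",
                            sep="\t")
        hits = overlap_hits(called, truth)
        recovery.append({"kind": kind, "planted": len(truth),
                         "recovered": hits, "called": len(called)})
        print(f"  {kind}: {hits}/{len(truth)} planted regions recovered "
              f"({len(called)} called)")
    pd.DataFrame(recovery).to_csv(results / "region_recovery.tsv",
                                  sep="\t", index=False)
    print(f"-> {results / 'region_comparisons.tsv'}")


if __name__ == "__main__":
    main()
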