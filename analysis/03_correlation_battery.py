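#!/usr/bin/env python
"""The correlation battery: promoter methylation vs miRNA target burden.

For each methylation measure (mCG/CG in the two cell lines, CpG O/E) and
each burden measure (Nt, Np, 3'UTR length), the raw Spearman correlation
and the partial correlation conditioning on gene expression level. Also
the expression-level, expression-broadness and 3'UTR-divergence
correlations that frame the main result.
"""

import argparse
from pathlib import Path

import pandas as pd

from methmir.pipeline import table1_battery
from methmir.stats import spearman

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--run", type=Path, default=ROOT / "scratch" / "run")
    args = ap.parse_args()

    f = pd.read_csv(args.run / "gene_features.tsv", sep="\t",
                    index_col="gene_id")
    battery = table1_battery(f)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    battery.to_csv(results / "correlation_battery.tsv", sep="\t",
                   index=False, float_format="%.4f")

    print("correlation battery (raw | partial given expression):")
    for _, r in battery.iterrows():
        print(f"  {r['methylation']:>14} vs {r['burden']:<3} "
              f"rho={r['rho']:+.3f}{r['stars']:<3} "
              f"partial={r['partial_rho']:+.3f}{r['partial_stars']:<3} "
              f"n={r['n']}")

    side = []
    for label, x, y in [
        ("methylation_vs_expression", "mcg_cg_H1", "log_rpkm_H1"),
        ("methylation_vs_expression_broadness", "mcg_cg_H1", "eb"),
        ("cpgoe_vs_germline_expression", "cpg_oe",
         "mean_germline_expression"),
        ("methylation_vs_k3u", "mcg_cg_H1", "k3u"),
        ("methylation_vs_insertion_rate", "mcg_cg_H1", "insertion_rate"),
        ("methylation_vs_deletion_rate", "mcg_cg_H1", "deletion_rate"),
    ]:
        r = spearman(f[x], f[y])
        side.append({"comparison": label, "rho": r.rho, "n": r.n,
                     "p_value": r.p_value})
        print(f"  {label}: rho={r.rho:+.3f} (n={r.n}, p={r.p_value:.2g})")
    pd.DataFrame(side).to_csv(results / "framing_correlations.tsv",
                              sep="\t", index=False, float_format="%.4g")
    print(f"-> {results / 'correlation_battery.tsv'}")


if __name__ == "__main__":
    main()
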