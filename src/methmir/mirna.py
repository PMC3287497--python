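"""Per-gene miRNA target-site burden from prediction tables.

Prediction tables (mirTarget2-like, PicTar-like) are consumed as given —
target-site prediction itself is out of scope. The per-gene burden is the
number of unique (miRNA, site position) pairs; when positions are absent the
number of unique miRNAs is used. 3'UTR length serves as a third,
annotation-only proxy of target-site capacity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_target_table", "count_target_sites", "utr_length_proxy"]


def read_target_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "mirna_id", "source"}
    if not required.issubset(df.columns):
        raise ValueError(f"target table must have columns {sorted(required)}")
    return df


def count_target_sites(records: pd.DataFrame, source: str | None = None,
                       mode: str = "sites", genes=None,
                       genome_wide: bool = True) -> pd.Series:
    """Unique target-site count per gene.

    ``mode='sites'`` counts unique (mirna_id, position) pairs (falls back to
    unique miRNAs where position is absent); ``mode='mirnas'`` counts unique
    miRNAs. Exact duplicate records are counted once. With ``genes`` given
    and ``genome_wide=True``, genes absent from the table get count 0;
    otherwise they are left missing.
    """
    df = records
    if source is not None:
        df = df[df["source"] == source]
    has_pos = "position" in df.columns
    key_cols = ["gene_id", "mirna_id", "source"] + (["position"] if has_pos else [])
    df = df.drop_duplicates(subset=key_cols)
    if mode == "mirnas" or not has_pos:
        counts = df.groupby("gene_id")["mirna_id"].nunique()
    elif mode == "sites":
        counts = df.groupby("gene_id").apply(
            lambda g: g[["mirna_id", "position"]].drop_duplicates().shape[0],
            include_groups=False)
    else:
        raise ValueError("mode must be 'sites' or 'mirnas'")
    counts = counts.astype("int64")
    counts.name = "n_target_sites"
    if genes is not None:
        gene_ids = [g.gene_id if hasattr(g, "gene_id") else g for g in genes]
        counts = counts.reindex(gene_ids)
        if genome_wide:
            counts = counts.fillna(0).astype("int64")
    return counts


def utr_length_proxy(genes) -> pd.Series:
    """UL per gene: a labeled projection of 3'UTR length so the statistics
    battery can treat UL as a burden measure; genes lacking a 3'UTR are
    absent."""
    data = {g.gene_id: g.utr3_length for g in genes
            if getattr(g, "utr3_interval", None) is not None}
    s = pd.Series(data, dtype="int64", name="UL")
    return s
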