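"""Expression matrices: probe collapsing, expression level and broadness.

Expression broadness (EB) is the number of tissues in which a gene's
intensity reaches a fixed threshold (average-difference value >= 200 by
default, the conventional present-call cutoff for MAS5-style intensities).
Probe-level microarray matrices are collapsed to genes by dropping
low-confidence probe sets (Affymetrix ``_x_at``/``_s_at`` suffixes) and
averaging the remainder per gene; replicate samples are averaged by label
before the probe collapse. No log transform is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["collapse_probes", "expression_broadness", "read_matrix",
           "read_tissue_classes"]

LOW_CONFIDENCE_SUFFIXES = ("_x_at", "_s_at")


def read_matrix(path) -> pd.DataFrame:
    """TSV with first column = probe/gene ID, header = sample labels."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_tissue_classes(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def collapse_probes(probe_matrix: pd.DataFrame, probe_to_gene,
                    replicate_labels: dict[str, str] | None = None
                    ) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes x samples.

    ``probe_to_gene`` maps probe IDs to gene IDs (dict or Series); probes
    without a mapping or with a low-confidence suffix are discarded; genes
    with no surviving probe are absent from the output. ``replicate_labels``
    optionally maps sample columns to replicate-group labels averaged first.
    """
    m = probe_matrix
    if (m.to_numpy() < 0).any():
        raise ValueError("negative intensities in input matrix")
    if replicate_labels:
        groups = [replicate_labels.get(c, c) for c in m.columns]
        m = m.T.groupby(groups).mean().T
    if not isinstance(probe_to_gene, pd.Series):
        probe_to_gene = pd.Series(probe_to_gene)
    keep = [p for p in m.index
            if not str(p).endswith(LOW_CONFIDENCE_SUFFIXES)
            and p in probe_to_gene.index]
    m = m.loc[keep]
    gene_ids = probe_to_gene.loc[m.index]
    out = m.groupby(gene_ids.to_numpy()).mean()
    out.index.name = "gene_id"
    return out


def expression_broadness(matrix: pd.DataFrame, threshold: float = 200
                         ) -> pd.DataFrame:
    """Per-gene mean intensity and EB (tissues with intensity >= threshold).

    Inclusive threshold; returns a DataFrame indexed by gene_id with columns
    ``mean_level`` and ``eb``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    vals = matrix.to_numpy(dtype=float)
    out = pd.DataFrame({
        "mean_level": vals.mean(axis=1),
        "eb": (vals >= threshold).sum(axis=1).astype(int),
    }, index=matrix.index)
    out.index.name = "gene_id"
    return out
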