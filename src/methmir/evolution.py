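"""3'UTR evolutionary rates: Kimura two-parameter distances and
focal-species-specific indel rates.

The K2P distance separates transitions (A<->G, C<->T; proportion P) from
transversions (proportion Q) over ungapped, non-N alignment columns:

    K = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

and is reported missing (saturated) when a log argument is non-positive.

Focal-specific indels are polarized by strict unanimity parsimony: a maximal
run of columns where the focal row is gapped while *all* other rows have
bases is a focal-specific deletion; the converse run is a focal-specific
insertion; columns where the outgroup rows disagree break runs and are not
counted. Rates are summed indel lengths over total alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import AlignIO, SeqIO

__all__ = ["AlignedPair", "IndelSummary", "k2p_distance",
           "human_specific_indels", "read_pair_fasta", "read_maf_by_gene"]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_BASES = frozenset("ACGT")


@dataclass
class AlignedPair:
    gene_id: str
    p_transition: float
    q_transversion: float
    n_sites: int
    k3u: float | None  # substitutions per site; None when saturated


@dataclass
class IndelSummary:
    gene_id: str
    insertion_rate: float
    deletion_rate: float
    aligned_length: int


def k2p_distance(seq_a: str, seq_b: str, gene_id: str = "") -> AlignedPair:
    """K2P distance between two equal-length gapped sequences.

    Raises on length mismatch or when no ungapped, non-N column remains.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences differ in length")
    a = seq_a.upper()
    b = seq_b.upper()
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in _BASES or y not in _BASES:
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    p = ts / n
    q = tv / n
    arg1 = 1.0 - 2.0 * p - q
    arg2 = 1.0 - 2.0 * q
    if arg1 <= 0 or arg2 <= 0:
        return AlignedPair(gene_id, p, q, n, None)
    k = -0.5 * np.log(arg1 * np.sqrt(arg2))
    return AlignedPair(gene_id, p, q, n, float(k))


def human_specific_indels(rows: dict[str, str], focal: str = "human",
                          gene_id: str = "") -> IndelSummary:
    """Focal-specific insertion/deletion rates from one multiple alignment.

    ``rows`` maps species name to its gapped row; at least two non-focal
    rows are required to polarize events.
    """
    if focal not in rows:
        raise ValueError(f"focal species {focal!r} absent from alignment")
    others = [v for k, v in sorted(rows.items()) if k != focal]
    if len(others) < 2:
        raise ValueError("cannot polarize: need >= 2 non-focal rows")
    f = rows[focal].upper()
    L = len(f)
    if any(len(o) != L for o in others):
        raise ValueError("alignment rows differ in length")
    others = [o.upper() for o in others]

    ins_total = del_total = 0
    state = None  # 'ins' | 'del' | None
    run = 0
    for i in range(L + 1):
        if i < L:
            fg = f[i] == "-"
            og = [o[i] == "-" for o in others]
            if fg and not any(og):
                col = "del"
            elif (not fg) and all(og):
                col = "ins"
            else:
                col = None
        else:
            col = None
        if col == state:
            run += 1 if col else 0
            continue
        if state == "ins":
            ins_total += run
        elif state == "del":
            del_total += run
        state, run = col, (1 if col else 0)
    return IndelSummary(gene_id, ins_total / L if L else 0.0,
                        del_total / L if L else 0.0, L)


def read_pair_fasta(path) -> dict[str, dict[str, str]]:
    """Pairwise 3'UTR alignments from FASTA with ids ``<gene>|<species>``.

    Returns {gene_id: {species: gapped sequence}}.
    """
    out: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, _, species = rec.id.partition("|")
        out.setdefault(gene, {})[species or "seq"] = str(rec.seq)
    return out


def read_maf_by_gene(path) -> dict[str, dict[str, str]]:
    """MAF blocks keyed by gene, rows keyed by species.

    The MAF ``src`` field is ``<species>.<gene_id>``; multiple blocks of the
    same gene are concatenated in file order.
    """
    out: dict[str, dict[str, str]] = {}
    for block in AlignIO.parse(str(path), "maf"):
        rows: dict[str, str] = {}
        gene = None
        for rec in block:
            species, _, suffix = rec.id.partition(".")
            gene = suffix or gene
            rows[species] = str(rec.seq)
        if gene is None:
            continue
        acc = out.setdefault(gene, {})
        for sp, seq in rows.items():
            acc[sp] = acc.get(sp, "") + seq
    return out
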