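"""Gene structure handling: major-transcript selection, ambiguity filters,
promoter and 3'UTR intervals.

All coordinates are 0-based half-open internally; GTF input (1-based closed)
is converted on read. The promoter window is -1000..+200 bp around the TSS,
mirrored on the minus strand. Genes are retained only when every alternative
TSS lies within 200 bp of the major TSS and all annotated 3'UTRs of the gene
are mutually consistent (reciprocal overlap >= 80% on the same strand); this
keeps promoter methylation and 3'UTR-based quantities unambiguous.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "TranscriptModel",
    "GeneModel",
    "read_gtf",
    "select_major_transcript",
    "promoter_interval",
    "build_gene_models",
    "filter_unambiguous_genes",
    "write_gene_bed",
]


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tss: int                      # 0-based genomic position of the first transcribed base
    tx_interval: tuple[int, int]  # 0-based half-open genomic span
    cds_length: int = 0
    utr3_interval: tuple[int, int] | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.utr3_interval is not None:
            s, e = self.utr3_interval
            if e <= s:
                raise ValueError("3'UTR interval must be non-empty")

    @property
    def span(self) -> int:
        return self.tx_interval[1] - self.tx_interval[0]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    major_tss: int
    promoter_interval: tuple[int, int]
    utr3_interval: tuple[int, int]
    clipped: bool = False
    major_transcript_id: str | None = None
    alt_tss: list[int] = field(default_factory=list)

    @property
    def utr3_length(self) -> int:
        return self.utr3_interval[1] - self.utr3_interval[0]


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path) -> list[TranscriptModel]:
    """Read transcript models from a GTF file.

    Uses ``transcript`` features for the span/TSS, sums ``CDS`` feature
    lengths, and takes the union span of ``three_prime_utr`` features.
    """
    tx: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, feature, start, end, _, strand, _, attrs = f[:9]
            if feature not in ("transcript", "CDS", "three_prime_utr"):
                continue
            a = dict(_ATTR_RE.findall(attrs))
            tid = a.get("transcript_id")
            gid = a.get("gene_id")
            if tid is None or gid is None:
                continue
            s0, e0 = int(start) - 1, int(end)  # to 0-based half-open
            rec = tx.setdefault(tid, {
                "gene_id": gid, "chrom": chrom, "strand": strand,
                "tx": None, "cds": 0, "utr3": None,
            })
            if feature == "transcript":
                rec["tx"] = (s0, e0)
            elif feature == "CDS":
                rec["cds"] += e0 - s0
            else:
                u = rec["utr3"]
                rec["utr3"] = (s0, e0) if u is None else (min(u[0], s0),
                                                          max(u[1], e0))
    out = []
    for tid, rec in tx.items():
        if rec["tx"] is None:
            continue
        s0, e0 = rec["tx"]
        tss = s0 if rec["strand"] == "+" else e0 - 1
        out.append(TranscriptModel(
            transcript_id=tid, gene_id=rec["gene_id"], chrom=rec["chrom"],
            strand=rec["strand"], tss=tss, tx_interval=(s0, e0),
            cds_length=rec["cds"], utr3_interval=rec["utr3"]))
    return out


def select_major_transcript(transcripts: list[TranscriptModel]) -> TranscriptModel:
    """Deterministic major-transcript choice: longest CDS, then longest
    genomic span, then lexicographically smallest transcript_id.

    Order-independent by construction; raises on an empty list or mixed
    gene_ids.
    """
    if not transcripts:
        raise ValueError("no transcripts")
    if len({t.gene_id for t in transcripts}) != 1:
        raise ValueError("transcripts from more than one gene")
    return min(transcripts,
               key=lambda t: (-t.cds_length, -t.span, t.transcript_id))


def promoter_interval(tss: int, strand: str, window_up: int = 1000,
                      window_down: int = 200) -> tuple[int, int, bool]:
    """Promoter window around the TSS, strand-aware, clipped at position 0.

    Plus strand: [tss - window_up, tss + window_down); minus strand is the
    mirror image. Returns (start, end, clipped).
    """
    if tss < 0:
        raise ValueError("tss must be >= 0")
    if strand == "+":
        start, end = tss - window_up, tss + window_down
    elif strand == "-":
        start, end = tss - window_down, tss + window_up
    else:
        raise ValueError("strand must be + or -")
    clipped = start < 0
    return max(start, 0), end, clipped


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def _gene_is_unambiguous(transcripts: list[TranscriptModel],
                         major: TranscriptModel,
                         tss_tolerance: int,
                         utr3_overlap: float) -> bool:
    for t in transcripts:
        if abs(t.tss - major.tss) > tss_tolerance:
            return False
    utrs = [(t.utr3_interval, t.strand) for t in transcripts
            if t.utr3_interval is not None]
    for i in range(len(utrs)):
        for j in range(i + 1, len(utrs)):
            if utrs[i][1] != utrs[j][1]:
                return False
            if _reciprocal_overlap(utrs[i][0], utrs[j][0]) < utr3_overlap:
                return False
    return True


def build_gene_models(transcripts: list[TranscriptModel],
                      tss_tolerance: int = 200,
                      utr3_overlap: float = 0.8,
                      window_up: int = 1000,
                      window_down: int = 200) -> list[GeneModel]:
    """Group transcripts by gene, pick the major transcript, drop genes with
    distant alternative TSSs (> ``tss_tolerance`` bp) or inconsistent 3'UTRs,
    and emit promoter/3'UTR intervals.

    Genes whose major transcript has no annotated 3'UTR are dropped (a 3'UTR
    is required by every downstream quantity).
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    out = []
    for gid in sorted(by_gene):
        group = by_gene[gid]
        major = select_major_transcript(group)
        if major.utr3_interval is None:
            continue
        if not _gene_is_unambiguous(group, major, tss_tolerance, utr3_overlap):
            continue
        start, end, clipped = promoter_interval(major.tss, major.strand,
                                                window_up, window_down)
        out.append(GeneModel(
            gene_id=gid, chrom=major.chrom, strand=major.strand,
            major_tss=major.tss, promoter_interval=(start, end),
            utr3_interval=major.utr3_interval, clipped=clipped,
            major_transcript_id=major.transcript_id,
            alt_tss=sorted(t.tss for t in group)))
    return out


def filter_unambiguous_genes(genes: list[GeneModel],
                             tss_tolerance: int = 200) -> list[GeneModel]:
    """Retain genes whose recorded alternative TSSs all lie within
    ``tss_tolerance`` bp of the major TSS. Idempotent; subset of input."""
    return [g for g in genes
            if all(abs(t - g.major_tss) <= tss_tolerance for t in g.alt_tss)]


def write_gene_bed(genes: list[GeneModel], path) -> None:
    """BED6 + gene_id, UL, clipped-flag columns (promoter intervals)."""
    with open(path, "w") as fh:
        for g in genes:
            s, e = g.promoter_interval
            fh.write(f"{g.chrom}\t{s}\t{e}\t{g.gene_id}\t0\t{g.strand}"
                     f"\t{g.utr3_length}\t{int(g.clipped)}\n")
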