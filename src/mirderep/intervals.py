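"""Merged exon/intron gene annotations and a toy union-mode read counter.

For exon/intron (mature vs pre-mRNA) analyses, every transcript's exons are
collapsed into a single per-gene exon union, and the intron union is the
remainder of the gene span — i.e. all introns combined into one annotation.
All coordinates are 0-based half-open internally; GTF (1-based inclusive) is
converted at the I/O boundary.

The counter implements union-mode semantics on single-end records: a read is
assigned to a gene if any aligned block overlaps the gene's interval set and
the strand rule passes; reads overlapping the interval sets of two or more
genes are discarded as ambiguous.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GeneModel",
    "IntervalSet",
    "AlignmentRecord",
    "merge_intervals",
    "merge_gene_intervals",
    "count_union_mode",
    "read_gtf",
    "read_sam",
    "read_alignment_tsv",
]

Interval = tuple[int, int]


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Union of half-open intervals as a sorted disjoint list."""
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if s >= e:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(span: Interval, blocks: list[Interval]) -> list[Interval]:
    """span minus a sorted disjoint block list."""
    out, cur = [], span[0]
    for s, e in blocks:
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < span[1]:
        out.append((cur, span[1]))
    return out


@dataclass
class GeneModel:
    """A gene as a set of transcripts, each a list of exon intervals."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, list[Interval]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        for tx, exons in self.transcripts.items():
            merged = merge_intervals(exons)
            flat = sorted(exons)
            if len(merged) != len(flat):
                raise ValueError(f"{self.gene_id}/{tx}: overlapping exons within transcript")


@dataclass
class IntervalSet:
    gene_id: str
    chrom: str
    strand: str
    kind: str  # "exon_union" | "intron_union"
    intervals: list[Interval]

    def overlaps(self, blocks: list[Interval]) -> bool:
        # both lists sorted and disjoint; sweep
        i = j = 0
        iv = self.intervals
        while i < len(iv) and j < len(blocks):
            a, b = iv[i]
            c, d = blocks[j]
            if a < d and c < b:
                return True
            if b <= d:
                i += 1
            else:
                j += 1
        return False


@dataclass
class AlignmentRecord:
    read_id: str
    chrom: str
    blocks: list[Interval]
    strand: str


def merge_gene_intervals(models: list[GeneModel]) -> dict[str, tuple[IntervalSet, IntervalSet]]:
    """Per-gene exon union and merged-intron annotation.

    The exon union is the interval union of all transcripts' exons; the
    intron union is the gene span (min exon start to max exon end across
    transcripts) minus the exon union.  Single-exon genes get an empty
    intron union.
    """
    out = {}
    for model in models:
        model.validate()
        all_exons = [iv for exons in model.transcripts.values() for iv in exons]
        if not all_exons:
            raise ValueError(f"{model.gene_id}: gene model has no exons")
        exon_union = merge_intervals(all_exons)
        span = (exon_union[0][0], exon_union[-1][1])
        intron_union = _subtract(span, exon_union)
        out[model.gene_id] = (
            IntervalSet(model.gene_id, model.chrom, model.strand, "exon_union", exon_union),
            IntervalSet(model.gene_id, model.chrom, model.strand, "intron_union", intron_union),
        )
    return out


def count_union_mode(
    alignments: list[AlignmentRecord],
    annot: list[IntervalSet],
    strandedness: int = 0,
) -> pd.Series:
    """Union-mode counting of single-end records against gene interval sets.

    ``strandedness`` 0 ignores strand, 1 requires read strand == gene strand,
    2 requires the opposite (reverse-stranded libraries).  A read overlapping
    the sets of two or more distinct genes is ambiguous and counted for none.
    """
    if strandedness not in (0, 1, 2):
        raise ValueError(f"unknown strandedness code {strandedness!r}")
    by_chrom: dict[str, list[IntervalSet]] = {}
    for ivs in annot:
        if not ivs.intervals:
            continue
        by_chrom.setdefault(ivs.chrom, []).append(ivs)
    counts = {ivs.gene_id: 0 for ivs in annot}
    for rec in alignments:
        blocks = merge_intervals(rec.blocks)
        hits: set[str] = set()
        for ivs in by_chrom.get(rec.chrom, ()):
            if strandedness == 1 and rec.strand != ivs.strand:
                continue
            if strandedness == 2 and rec.strand == ivs.strand:
                continue
            if ivs.overlaps(blocks):
                hits.add(ivs.gene_id)
        if len(hits) == 1:
            counts[hits.pop()] += 1
    return pd.Series(counts, name="count").sort_index()


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str) -> list[GeneModel]:
    """Parse exon features from a GTF into gene models.

    Requires ``gene_id`` and ``transcript_id`` attributes; 1-based inclusive
    coordinates are converted to 0-based half-open.  A gene spanning two
    chromosomes or strands is rejected.
    """
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{ln}: malformed GTF line")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            at = dict(_ATTR_RE.findall(attrs))
            try:
                gid, tid = at["gene_id"], at["transcript_id"]
            except KeyError as exc:
                raise ValueError(f"{path}:{ln}: missing {exc} attribute") from None
            iv = (int(start) - 1, int(end))
            g = genes.setdefault(gid, GeneModel(gid, chrom, strand))
            if g.chrom != chrom or g.strand != strand:
                raise ValueError(f"{gid}: exons span multiple chromosomes or strands")
            g.transcripts.setdefault(tid, []).append(iv)
    return list(genes.values())


def read_sam(path: str) -> list[AlignmentRecord]:
    """Load single-end alignments from a SAM file (minimal subset) via pysam."""
    import pysam

    out = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            out.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    blocks=[(int(s), int(e)) for s, e in aln.get_blocks()],
                    strand="-" if aln.is_reverse else "+",
                )
            )
    return out


def read_alignment_tsv(path: str) -> list[AlignmentRecord]:
    """Equivalent TSV input: read_id, chrom, strand, blocks as 's-e;s-e'."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        blocks = [
            (int(b.split("-")[0]), int(b.split("-")[1])) for b in str(row.blocks).split(";")
        ]
        out.append(AlignmentRecord(str(row.read_id), str(row.chrom), blocks, str(row.strand)))
    return out
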