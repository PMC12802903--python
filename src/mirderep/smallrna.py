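"""Mature-miRNA quantification from small-RNA FASTQ by exact-prefix matching.

Pipeline: quality filter (all bases at or above Q30 by default), 3'-adapter
location and removal, stripping of the randomized 4-nt ligation flanks, then
exact matching of the first k nucleotides (k = 18 or 19 by library
convention) of each insert against a dictionary of mature miRNA sequences.
Reads matching spike-in species or internal size standards are removed from
the biological counts but tallied, and read accounting is conserved at every
stage: filtered + dropped + matched + removed + unmatched = reads in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "MirnaDictionary",
    "ReadTally",
    "MirnaCounts",
    "load_mirna_dictionary",
    "read_fastq",
    "quality_filter",
    "trim_adapters",
    "match_prefix",
    "quantify_reads",
    "mirna_cpm",
]

FastqRecord = tuple[str, str, str]  # (read_id, sequence, Phred+33 quality string)


def _normalize_seq(seq: str) -> str:
    return seq.strip().upper().replace("U", "T")


@dataclass
class MirnaDictionary:
    """Mature miRNA dictionary with spike-in / size-standard annotation.

    ``table`` is indexed by mirna_id with columns family, sequence (DNA
    alphabet), is_spike_in, is_size_standard.  At load time the first-k
    prefixes are checked for collisions: two non-identical sequences sharing
    a k-prefix are an ambiguity error; identical full sequences (paralog
    duplicates) are collapsed into one entry listing all ids when
    ``collapse_identical`` is enabled, otherwise they error too — silent
    double counting is worse than a loud failure.
    """

    table: pd.DataFrame
    prefix_len: int
    prefix_map: dict[str, str] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.prefix_map:
            self.prefix_map = {
                row.sequence[: self.prefix_len]: mid
                for mid, row in self.table.iterrows()
            }

    def is_removed(self, mirna_id: str) -> bool:
        row = self.table.loc[mirna_id]
        return bool(row["is_spike_in"] or row["is_size_standard"])


def load_mirna_dictionary(
    source: str | pd.DataFrame,
    prefix_len: int = 19,
    collapse_identical: bool = False,
) -> MirnaDictionary:
    """Load a dictionary from TSV (mirna_id, family, sequence, is_spike_in
    [, is_size_standard]) or an equivalent DataFrame.

    Sequences are uppercased and U->T normalized; chemistry annotations
    (leading ``App``, trailing ``ddC``) are stripped if present.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t")
    required = {"mirna_id", "family", "sequence", "is_spike_in"}
    if not required.issubset(df.columns):
        raise ValueError(f"dictionary needs columns {sorted(required)}")
    if "is_size_standard" not in df.columns:
        df["is_size_standard"] = False
    if df["mirna_id"].duplicated().any():
        raise ValueError("duplicate mirna_id in dictionary")

    def clean(seq: str) -> str:
        seq = seq.strip()
        if seq.startswith("App"):
            seq = seq[3:]
        if seq.endswith("ddC"):
            seq = seq[:-3]
        s = _normalize_seq(seq)
        if set(s) - set("ACGT"):
            raise ValueError(f"non-ACGTU characters in sequence {seq!r}")
        return s

    df["sequence"] = df["sequence"].map(clean)
    short = df["sequence"].str.len() < prefix_len
    if short.any():
        bad = df.loc[short, "mirna_id"].tolist()
        raise ValueError(f"sequences shorter than prefix length {prefix_len}: {bad}")

    # collapse exact full-sequence duplicates (same species under two names)
    if df["sequence"].duplicated().any():
        if not collapse_identical:
            dups = df[df["sequence"].duplicated(keep=False)]["mirna_id"].tolist()
            raise ValueError(
                f"identical mature sequences for {dups}; "
                "pass collapse_identical=True to merge them into one entry"
            )
        df = (
            df.groupby("sequence", sort=False)
            .agg(
                mirna_id=("mirna_id", "/".join),
                family=("family", "first"),
                is_spike_in=("is_spike_in", "any"),
                is_size_standard=("is_size_standard", "any"),
            )
            .reset_index()[["mirna_id", "family", "sequence", "is_spike_in", "is_size_standard"]]
        )

    prefixes = df["sequence"].str[:prefix_len]
    coll = prefixes.duplicated(keep=False)
    if coll.any():
        pairs = df.loc[coll].groupby(prefixes[coll])["mirna_id"].apply(list).to_dict()
        raise ValueError(
            f"distinct dictionary entries share a {prefix_len}-nt prefix: {pairs}; "
            "collapse or disambiguate before quantifying"
        )
    table = df.set_index("mirna_id")
    return MirnaDictionary(table=table, prefix_len=prefix_len)


def read_fastq(path: str) -> list[FastqRecord]:
    """Read Phred+33 FASTQ into (id, sequence, quality-string) records."""
    out = []
    for rec in SeqIO.parse(path, "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        out.append((rec.id, str(rec.seq).upper(), "".join(chr(q + 33) for q in quals)))
    return out


@dataclass
class ReadTally:
    """Stage-by-stage read accounting; conserved by construction."""

    reads_in: int = 0
    q_filtered: int = 0
    adapter_dropped: int = 0
    matched: int = 0
    removed: int = 0  # spike-ins + size standards
    unmatched: int = 0

    def check(self) -> None:
        total = self.q_filtered + self.adapter_dropped + self.matched + self.removed + self.unmatched
        if total != self.reads_in:
            raise AssertionError(f"read accounting broken: {total} != {self.reads_in}")


@dataclass
class MirnaCounts:
    counts: pd.Series  # mirna_id -> raw count (biological species only)
    removed_counts: pd.Series  # spike-in / size-standard species
    tally: ReadTally


def quality_filter(
    reads: list[FastqRecord], min_q: int = 30, min_frac: float = 1.0
) -> tuple[list[FastqRecord], int]:
    """Keep reads where at least ``min_frac`` of bases have quality >= min_q.

    Defaults require every base at Q30 or better (inclusive threshold).
    Returns (kept reads, number filtered).
    """
    kept, dropped = [], 0
    cutoff = min_q + 33
    for rec in reads:
        qual = rec[2]
        if len(qual) != len(rec[1]):
            raise ValueError(f"malformed record {rec[0]!r}: quality/sequence length mismatch")
        n_ok = sum(1 for ch in qual if ord(ch) >= cutoff)
        if len(qual) and n_ok / len(qual) >= min_frac:
            kept.append(rec)
        else:
            dropped += 1
    return kept, dropped


def trim_adapters(
    reads: list[FastqRecord],
    adapter3_invariant: str,
    n_random_5p: int = 4,
    n_random_3p: int = 4,
    min_insert: int = 16,
) -> tuple[list[FastqRecord], int]:
    """Remove the 3' adapter and the randomized ligation flanks.

    The adapter is located by the leftmost exact occurrence of the first
    8 nt of its invariant portion; the adapter and everything 3' of it are
    removed, then ``n_random_5p``/``n_random_3p`` randomized nucleotides are
    stripped from the insert ends.  Reads with no adapter hit, or whose
    pre-strip insert is shorter than ``n_random_5p + n_random_3p +
    min_insert``, are dropped and tallied (never raised).
    """
    adapter = _normalize_seq(adapter3_invariant)
    if adapter.startswith("APP"):
        adapter = adapter[3:]
    if len(adapter) < 8:
        raise ValueError("adapter invariant must be at least 8 nt")
    probe = adapter[:8]
    kept, dropped = [], 0
    for rid, seq, qual in reads:
        idx = seq.find(probe)
        if idx < 0 or idx < n_random_5p + n_random_3p + min_insert:
            dropped += 1
            continue
        end = idx - n_random_3p
        kept.append((rid, seq[n_random_5p:end], qual[n_random_5p:end]))
    return kept, dropped


def match_prefix(
    reads: list[FastqRecord], dictionary: MirnaDictionary, k: int | None = None
) -> MirnaCounts:
    """Count reads to dictionary entries by exact first-k-nt identity.

    A read counts to the unique entry whose first k nt equal the read's
    first k nt; spike-ins and size standards are tallied separately and
    removed from biological counts; anything else is unmatched.
    """
    k = k or dictionary.prefix_len
    if k != dictionary.prefix_len:
        raise ValueError("prefix length must match the dictionary's collision check")
    bio = pd.Series(
        0, index=dictionary.table.index[~dictionary.table[["is_spike_in", "is_size_standard"]].any(axis=1)], dtype=int
    )
    removed = pd.Series(
        0, index=dictionary.table.index[dictionary.table[["is_spike_in", "is_size_standard"]].any(axis=1)], dtype=int
    )
    tally = ReadTally(reads_in=len(reads))
    pm = dictionary.prefix_map
    for _rid, seq, _q in reads:
        if len(seq) < k:
            tally.unmatched += 1
            continue
        hit = pm.get(seq[:k])
        if hit is None:
            tally.unmatched += 1
        elif dictionary.is_removed(hit):
            removed[hit] += 1
            tally.removed += 1
        else:
            bio[hit] += 1
            tally.matched += 1
    return MirnaCounts(counts=bio, removed_counts=removed, tally=tally)


def quantify_reads(
    reads: list[FastqRecord],
    dictionary: MirnaDictionary,
    adapter3_invariant: str,
    k: int | None = None,
    min_q: int = 30,
    min_frac: float = 1.0,
    n_random_5p: int = 4,
    n_random_3p: int = 4,
) -> MirnaCounts:
    """Full per-sample pipeline: quality filter -> adapter trim -> prefix match."""
    passed, n_filtered = quality_filter(reads, min_q=min_q, min_frac=min_frac)
    trimmed, n_dropped = trim_adapters(
        passed, adapter3_invariant, n_random_5p=n_random_5p, n_random_3p=n_random_3p
    )
    result = match_prefix(trimmed, dictionary, k=k)
    result.tally.reads_in = len(reads)
    result.tally.q_filtered = n_filtered
    result.tally.adapter_dropped = n_dropped
    result.tally.check()
    return result


def mirna_cpm(counts: pd.DataFrame, size_factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts-per-million over normalized counts, per sample.

    Each sample's counts are divided by its size factor, then expressed as a
    fraction of the sample's normalized total times 1e6, so every column sums
    to exactly one million.
    """
    if size_factors is None:
        size_factors = pd.Series(1.0, index=counts.columns)
    if (size_factors.loc[counts.columns] <= 0).any():
        raise ValueError("size factors must be > 0")
    norm = counts / size_factors.loc[counts.columns]
    totals = norm.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero-total samples, CPM undefined: {bad}")
    return norm / totals * 1e6
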