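"""Reading, writing and preprocessing of short-read sequence files.

Mirrors the standard MiSeq-era preprocessing applied to ligation/recombination
product libraries: quality filtering (keep a read if a minimum fraction of its
bases reaches a Phred threshold), collapsing of identical sequences into
counted records, anchored trimming of constant primer-binding flanks, and
splitting by product length.  Parsing is delegated to Biopython; quality
encoding is fixed to Phred+33.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Read",
    "CollapsedRecord",
    "TrimmedRead",
    "FormatError",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_fastq",
    "quality_filter",
    "collapse",
    "trim_constant",
    "split_by_length",
]

_ALPHABET = set("ACGTUN")


class FormatError(ValueError):
    """Raised when a sequence file violates its format contract."""


@dataclass(frozen=True)
class Read:
    """A single sequencing read (or synthetic product read).

    Parameters
    ----------
    id : str
        Record identifier.
    seq : str
        Nucleotide sequence over ``A C G T U N`` (case-normalised to upper).
    qual : tuple of int, optional
        Per-base Phred scores; must match ``seq`` in length when present.
    """

    id: str
    seq: str
    qual: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        if not seq:
            raise FormatError(f"read {self.id!r}: empty sequence")
        bad = set(seq) - _ALPHABET
        if bad:
            raise FormatError(f"read {self.id!r}: invalid characters {sorted(bad)}")
        if self.qual is not None:
            qual = tuple(int(q) for q in self.qual)
            object.__setattr__(self, "qual", qual)
            if len(qual) != len(seq):
                raise FormatError(
                    f"read {self.id!r}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            if any(q < 0 for q in qual):
                raise FormatError(f"read {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CollapsedRecord:
    """A distinct sequence with its copy count in a collapsed read set."""

    seq: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")


@dataclass(frozen=True)
class TrimmedRead:
    """A read after constant-flank trimming, with per-side bookkeeping."""

    read: Read
    trimmed5: bool = False
    trimmed3: bool = False


def read_fasta(path: str | Path) -> Iterator[Read]:
    """Stream reads from a FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield Read(id=rec.id, seq=str(rec.seq))


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream reads from a Phred+33 FASTQ file.

    Raises
    ------
    FormatError
        On malformed records, reporting the approximate file line.
    """
    n = 0
    with open(path) as handle:
        it = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual_str = next(it)
            except StopIteration:
                return
            except ValueError as exc:  # biopython's record-level diagnosis
                raise FormatError(
                    f"{path}: malformed FASTQ record near line {4 * n + 1}: {exc}"
                ) from exc
            n += 1
            if len(qual_str) != len(seq):
                raise FormatError(
                    f"{path}: record near line {4 * (n - 1) + 1}: quality string "
                    f"length {len(qual_str)} != sequence length {len(seq)}"
                )
            qual = tuple(ord(c) - 33 for c in qual_str)
            if any(q < 0 for q in qual):
                raise FormatError(
                    f"{path}: record near line {4 * (n - 1) + 1}: "
                    "quality character below Phred+33 offset"
                )
            yield Read(id=title.split()[0], seq=seq, qual=qual)


def _as_seqrecord(read: Read) -> SeqRecord:
    rec = SeqRecord(Seq(read.seq), id=read.id, description="")
    if read.qual is not None:
        rec.letter_annotations["phred_quality"] = list(read.qual)
    return rec


def write_fasta(records: Iterable[Read | CollapsedRecord], path: str | Path) -> int:
    """Write reads or collapsed records to FASTA; returns the record count.

    Collapsed records are written with ``seq<i>-<count>`` identifiers, the
    convention of read-collapsing toolkits.
    """
    out = []
    for i, rec in enumerate(records):
        if isinstance(rec, CollapsedRecord):
            out.append(SeqRecord(Seq(rec.seq), id=f"seq{i + 1}-{rec.count}", description=""))
        else:
            out.append(SeqRecord(Seq(rec.seq), id=rec.id, description=""))
    return SeqIO.write(out, str(path), "fasta")


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads (which must carry qualities) as Phred+33 FASTQ."""
    recs = []
    for read in reads:
        if read.qual is None:
            raise ValueError(f"read {read.id!r} has no qualities; cannot write FASTQ")
        recs.append(_as_seqrecord(read))
    return SeqIO.write(recs, str(path), "fastq")


def quality_filter(
    reads: Iterable[Read], min_q: int = 20, min_fraction: float = 0.9
) -> Iterator[Read]:
    """Keep reads whose fraction of bases at Phred >= ``min_q`` reaches ``min_fraction``.

    The boundary is inclusive (9 of 10 bases at Q>=20 passes a 90% filter),
    matching fastx_toolkit semantics.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError(f"min_fraction must be in [0, 1], got {min_fraction}")
    for read in reads:
        if read.qual is None:
            raise ValueError(f"read {read.id!r} has no qualities; quality filter undefined")
        good = sum(1 for q in read.qual if q >= min_q)
        if good / len(read) >= min_fraction:
            yield read


def collapse(reads: Iterable[Read | str]) -> list[CollapsedRecord]:
    """Collapse identical sequences into counted records.

    Output is sorted by descending count, then lexicographically, and its
    counts sum to the number of input reads.
    """
    counts: collections.Counter[str] = collections.Counter(
        r if isinstance(r, str) else r.seq for r in reads
    )
    return [
        CollapsedRecord(seq=s, count=c)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_constant(
    reads: Iterable[Read],
    adapter5: str = "",
    adapter3: str = "",
    max_mismatch: int = 0,
) -> Iterator[TrimmedRead]:
    """Remove terminus-anchored constant flanks within a Hamming tolerance.

    Constant regions here are fixed-length primer-binding sites, so trimming
    is anchored at the read termini and allows substitutions only (no indels).
    Untrimmable reads pass through, flagged.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    a5 = adapter5.upper()
    a3 = adapter3.upper()
    for read in reads:
        seq, qual = read.seq, read.qual
        t5 = t3 = False
        if a5 and len(seq) > len(a5) and _hamming(seq[: len(a5)], a5) <= max_mismatch:
            seq = seq[len(a5):]
            qual = qual[len(a5):] if qual is not None else None
            t5 = True
        if a3 and len(seq) > len(a3) and _hamming(seq[-len(a3):], a3) <= max_mismatch:
            seq = seq[: -len(a3)]
            qual = qual[: -len(a3)] if qual is not None else None
            t3 = True
        yield TrimmedRead(read=Read(id=read.id, seq=seq, qual=qual), trimmed5=t5, trimmed3=t3)


def split_by_length(
    records: Iterable[Read | CollapsedRecord | str],
) -> tuple[dict[int, list], dict[int, int]]:
    """Partition records by sequence length.

    Returns ``(buckets, histogram)`` where ``buckets[L]`` holds every record of
    length ``L`` and ``histogram[L]`` the molecule count at that length
    (weighted by copy count for collapsed records).  The histogram is the basis
    of product-size distribution plots.
    """
    buckets: dict[int, list] = {}
    hist: collections.Counter[int] = collections.Counter()
    for rec in records:
        seq = rec if isinstance(rec, str) else rec.seq
        weight = rec.count if isinstance(rec, CollapsedRecord) else 1
        buckets.setdefault(len(seq), []).append(rec)
        hist[len(seq)] += weight
    return buckets, dict(sorted(hist.items()))
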