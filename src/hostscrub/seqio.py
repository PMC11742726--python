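"""FASTQ I/O, paired-end bookkeeping, and pre-filtration.

Reads move through the filtration pipeline as :class:`ReadPair` objects so
that mate synchrony is maintained at every stage.  The pre-filtration step
mirrors the common quality-control convention for metagenomic data: clip
3'-adapter read-through against an explicit adapter list and drop any pair
in which either mate falls below a minimum length (default 45 bp).  Dropping
the whole pair when one mate fails keeps downstream both-mates bookkeeping
consistent and is the privacy-conservative choice.

Quality-window trimming is deliberately not performed here; only length and
adapter clipping are applied.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadRecord",
    "ReadPair",
    "DEFAULT_ADAPTERS",
    "read_fastq",
    "write_fastq",
    "quality_length_filter",
    "resync_pairs",
]

#: Common Illumina 3' adapter sequences (TruSeq R1/R2, Nextera transposase).
#: An explicit list keeps adapter clipping deterministic and testable.
DEFAULT_ADAPTERS: tuple[str, ...] = (
    "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA",  # TruSeq indexed adapter (read 1)
    "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT",  # TruSeq universal adapter (read 2)
    "CTGTCTCTTATACACATCT",  # Nextera transposase sequence
)


class FastqFormatError(ValueError):
    """Malformed FASTQ input (ragged record, mate mismatch, truncation)."""


@dataclass
class ReadRecord:
    """A single sequenced read.

    ``mate`` is 1 or 2 for paired reads and 0 for unpaired.  ``origin_label``
    is ground truth ("human" / "microbial") and is only ever set by the
    simulator; real data carries "unknown".  ``placement`` optionally records
    where a simulated read was drawn from, as
    ``(genome_id, start, end, strand, mapq)`` in 0-based half-open genome
    coordinates — it is simulator metadata and never written to FASTQ.
    """

    read_id: str
    sequence: str
    qualities: Optional[str] = None
    mate: int = 0
    origin_label: str = "unknown"
    placement: Optional[tuple] = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FastqFormatError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if self.mate not in (0, 1, 2):
            raise ValueError(f"read {self.read_id!r}: mate must be 0, 1 or 2")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadPair:
    """A read and its optional mate; single-end data has ``r2 is None``."""

    r1: ReadRecord
    r2: Optional[ReadRecord] = None

    def __post_init__(self) -> None:
        if self.r2 is not None:
            if canonical_id(self.r1.read_id) != canonical_id(self.r2.read_id):
                raise FastqFormatError(
                    f"mate id mismatch: {self.r1.read_id!r} vs {self.r2.read_id!r}"
                )

    @property
    def read_id(self) -> str:
        return canonical_id(self.r1.read_id)

    def mates(self) -> Iterator[ReadRecord]:
        yield self.r1
        if self.r2 is not None:
            yield self.r2


def canonical_id(read_id: str) -> str:
    """Strip mate suffixes (``/1``, ``/2``) and trailing description."""
    base = read_id.split(None, 1)[0]
    if base.endswith("/1") or base.endswith("/2"):
        base = base[:-2]
    return base


def _open_text(path: str | Path, mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")  # type: ignore[return-value]
    return open(path, mode)


def _fastq_records(path: str | Path, mate: int) -> Iterator[ReadRecord]:
    with _open_text(path, "r") as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"{path}: ragged record {title!r} "
                    f"(seq {len(seq)} bp, qual {len(qual)})"
                )
            yield ReadRecord(
                read_id=title.split(None, 1)[0],
                sequence=seq.upper(),
                qualities=qual,
                mate=mate,
            )


def read_fastq(
    path: str | Path, paired_with: Optional[str | Path] = None
) -> Iterator[ReadPair]:
    """Stream FASTQ records as :class:`ReadPair`.

    ``paired_with`` names the R2 file; R1/R2 are matched positionally and a
    canonical-id mismatch at any ordinal, or unequal record counts, aborts the
    stream with :class:`FastqFormatError`.  Gzip is autodetected from the
    ``.gz`` suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if paired_with is None:
        for rec in _fastq_records(path, mate=0):
            yield ReadPair(rec)
        return
    path2 = Path(paired_with)
    if not path2.exists():
        raise FileNotFoundError(str(path2))
    it1 = _fastq_records(path, mate=1)
    it2 = _fastq_records(path2, mate=2)
    ordinal = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        ordinal += 1
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            raise FastqFormatError(
                f"paired files out of sync at record {ordinal}: "
                f"{'R1' if r1 is None else 'R2'} exhausted first"
            )
        if canonical_id(r1.read_id) != canonical_id(r2.read_id):
            raise FastqFormatError(
                f"R1/R2 id mismatch at record {ordinal}: "
                f"{r1.read_id!r} vs {r2.read_id!r}"
            )
        yield ReadPair(r1, r2)


def _write_record(handle: IO[str], rec: ReadRecord) -> None:
    qual = rec.qualities if rec.qualities is not None else "I" * len(rec.sequence)
    handle.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{qual}\n")


def write_fastq(
    pairs: Iterable[ReadPair],
    out1: str | Path,
    out2: Optional[str | Path] = None,
) -> int:
    """Write pairs to FASTQ (gzip by suffix); returns the pair count written.

    Paired input requires ``out2``.  Reads without qualities are written with
    a constant placeholder quality (Phred 40).
    """
    n = 0
    h1 = _open_text(out1, "w")
    h2 = _open_text(out2, "w") if out2 is not None else None
    try:
        for pair in pairs:
            if pair.r2 is not None and h2 is None:
                raise ValueError("paired input but no out2 given")
            _write_record(h1, pair.r1)
            if pair.r2 is not None:
                _write_record(h2, pair.r2)  # type: ignore[arg-type]
            n += 1
    finally:
        h1.close()
        if h2 is not None:
            h2.close()
    return n


def trim_adapter(
    sequence: str,
    adapters: Sequence[str],
    min_overlap: int = 8,
) -> int:
    """Return the clip point for 3'-adapter read-through.

    The adapter's 5' start is matched exactly against the read suffix: the
    earliest position ``i`` such that ``sequence[i:]`` equals a prefix of some
    adapter with at least ``min_overlap`` bases of overlap.  Returns
    ``len(sequence)`` when nothing matches.
    """
    L = len(sequence)
    best = L
    for adapter in adapters:
        # earliest i wins; overlap is capped by both read tail and adapter.
        for i in range(max(0, L - len(adapter) - 0), L - min_overlap + 1):
            overlap = min(L - i, len(adapter))
            if overlap >= min_overlap and sequence[i : i + overlap] == adapter[:overlap]:
                best = min(best, i)
                break
        # also catch a full adapter embedded earlier in the read
        pos = sequence.find(adapter)
        if pos != -1:
            best = min(best, pos)
    return best


def quality_length_filter(
    pairs: Iterable[ReadPair],
    min_len: int = 45,
    adapters: Optional[Sequence[str]] = DEFAULT_ADAPTERS,
    min_overlap: int = 8,
) -> Iterator[ReadPair]:
    """Adapter-clip then length-filter read pairs.

    A pair is dropped entirely when either mate's post-trim length is below
    ``min_len``.  An empty adapter list (or ``None``) disables clipping.
    N bases are retained; classification downstream handles them.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    adapters = tuple(adapters or ())

    def cut_of(rec: ReadRecord) -> int:
        if not adapters:
            return len(rec.sequence)
        return trim_adapter(rec.sequence, adapters, min_overlap)

    for pair in pairs:
        cuts = [cut_of(m) for m in pair.mates()]
        if any(c < min_len for c in cuts):
            continue
        mates = [
            m
            if c >= len(m.sequence)
            else replace(
                m,
                sequence=m.sequence[:c],
                qualities=m.qualities[:c] if m.qualities is not None else None,
            )
            for m, c in zip(pair.mates(), cuts)
        ]
        yield ReadPair(mates[0], mates[1] if len(mates) > 1 else None)


def resync_pairs(
    survivors1: Iterable[ReadRecord],
    survivors2: Iterable[ReadRecord],
) -> tuple[list[ReadPair], list[ReadRecord]]:
    """Re-pair two independently filtered mate streams by canonical id.

    Returns the id-intersection as pairs (ordered by the first stream) and
    every unmatched record from either stream as orphans — orphans are
    reported, never silently dropped.  A duplicated id within one stream is
    an error.
    """
    by_id2: dict[str, ReadRecord] = {}
    order2: list[str] = []
    for rec in survivors2:
        cid = canonical_id(rec.read_id)
        if cid in by_id2:
            raise ValueError(f"duplicate id in second stream: {cid!r}")
        by_id2[cid] = rec
        order2.append(cid)
    pairs: list[ReadPair] = []
    orphans: list[ReadRecord] = []
    seen1: set[str] = set()
    matched2: set[str] = set()
    for rec in survivors1:
        cid = canonical_id(rec.read_id)
        if cid in seen1:
            raise ValueError(f"duplicate id in first stream: {cid!r}")
        seen1.add(cid)
        mate = by_id2.get(cid)
        if mate is not None:
            pairs.append(ReadPair(rec, mate))
            matched2.add(cid)
        else:
            orphans.append(rec)
    for cid in order2:
        if cid not in matched2:
            orphans.append(by_id2[cid])
    return pairs, orphans
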