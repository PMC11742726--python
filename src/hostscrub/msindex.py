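"""Searchable host-reference index and per-read pseudo-matching lengths.

The index answers, for every read position ``i``, the length of the longest
prefix of ``read[i:]`` that occurs anywhere in the indexed references on
either strand — the classic *matching statistics*.  Per-position matching
lengths are the exact, reproducible limit of the pseudo-matching lengths
(PMLs) that run-length-compressed full-text indexes report, and they are what
the scoring layer (:mod:`hostscrub.pmlscore`) consumes.

Backend: a suffix automaton built over the concatenation of all references
and their reverse complements, with a sentinel between segments so matches
never span reference boundaries.  Construction is online and linear;
matching statistics for a read of length ``L`` are computed in ``O(L)`` by
first finding, for each read prefix, its longest suffix that is a reference
substring (the standard automaton walk with suffix links), then converting
those suffix-match lengths into per-position prefix-match lengths with a
monotone two-pointer sweep.

``N`` (or any non-ACGT symbol) in a read matches nothing and resets the
walk; non-ACGT stretches in references are replaced by sentinels so they are
never matchable.  This is conservative: N runs can never inflate host
scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqio import ReadRecord

__all__ = [
    "HostIndex",
    "PMLVector",
    "build_index",
    "matching_lengths",
    "reverse_complement",
    "read_fasta",
]

INDEX_FORMAT_VERSION = 1

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_SENTINEL = "\x00"
_VALID = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Load a (possibly gzipped) multi-record FASTA as ``(id, sequence)``."""
    import gzip

    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:  # type: ignore[operator]
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]


class _SuffixAutomaton:
    """Online suffix automaton over a text; dict transitions per state."""

    __slots__ = ("trans", "link", "length", "_last")

    def __init__(self) -> None:
        self.trans: list[dict[str, int]] = [{}]
        self.link: list[int] = [-1]
        self.length: list[int] = [0]
        self._last = 0

    def extend(self, ch: str) -> None:
        trans, link, length = self.trans, self.link, self.length
        cur = len(trans)
        trans.append({})
        length.append(length[self._last] + 1)
        link.append(-1)
        p = self._last
        while p != -1 and ch not in trans[p]:
            trans[p][ch] = cur
            p = link[p]
        if p == -1:
            link[cur] = 0
        else:
            q = trans[p][ch]
            if length[p] + 1 == length[q]:
                link[cur] = q
            else:
                clone = len(trans)
                trans.append(dict(trans[q]))
                length.append(length[p] + 1)
                link.append(link[q])
                while p != -1 and trans[p].get(ch) == q:
                    trans[p][ch] = clone
                    p = link[p]
                link[q] = clone
                link[cur] = clone
        self._last = cur

    def feed(self, text: str) -> None:
        for ch in text:
            self.extend(ch)

    def suffix_match_lengths(self, query: str) -> np.ndarray:
        """For each prefix end ``j``, the longest suffix of ``query[:j+1]``
        that is a substring of the text (0 for unmatchable characters)."""
        trans, link, length = self.trans, self.link, self.length
        out = np.zeros(len(query), dtype=np.int64)
        cur, l = 0, 0
        for j, ch in enumerate(query):
            if ch in trans[cur]:
                cur = trans[cur][ch]
                l += 1
            else:
                while cur != -1 and ch not in trans[cur]:
                    cur = link[cur]
                if cur == -1:
                    cur, l = 0, 0
                else:
                    l = length[cur] + 1
                    cur = trans[cur][ch]
            out[j] = l
        return out


@dataclass
class PMLVector:
    """Per-position pseudo-matching lengths of one read.

    Invariants: ``len(values) == L``; ``0 <= values[i] <= L - i``; and the
    matching-statistics slack ``values[i+1] >= values[i] - 1``.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("PMLVector requires a non-empty 1-D value array")
        if (self.values < 0).any():
            raise ValueError("matching lengths must be non-negative")

    @property
    def read_length(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.read_length


class HostIndex:
    """Longest-match index over host reference sequences, both strands."""

    def __init__(self, references: Sequence[tuple[str, str]], name: str = "host"):
        refs = [(rid, seq.upper()) for rid, seq in references]
        if not refs or any(not seq for _, seq in refs):
            raise ValueError("at least one non-empty reference is required")
        for rid, seq in refs:
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"reference {rid!r} contains non-nucleotide characters: {sorted(bad)}"
                )
        self.name = name
        self.source_ids = [rid for rid, _ in refs]
        self.total_length = sum(len(seq) for _, seq in refs)
        self._references = refs
        self._automaton = _SuffixAutomaton()
        for _, seq in refs:
            for strand_seq in (seq, reverse_complement(seq)):
                # N stretches become sentinels: never matchable, and they
                # break adjacency so matches cannot bridge them.
                self._automaton.feed(strand_seq.replace("N", _SENTINEL))
                self._automaton.extend(_SENTINEL)

    # -- queries ---------------------------------------------------------

    def query(self, s: str) -> int:
        """Length of the longest prefix of ``s`` occurring in any reference
        (either strand); ``query("") == 0``."""
        trans = self._automaton.trans
        cur, l = 0, 0
        for ch in s.upper():
            nxt = trans[cur].get(ch)
            if nxt is None:
                break
            cur = nxt
            l += 1
        return l

    def matching_statistics(self, sequence: str) -> np.ndarray:
        """Exact matching statistics: ``ms[i]`` is the longest prefix of
        ``sequence[i:]`` found in the index."""
        seq = sequence.upper()
        L = len(seq)
        sfx = self._automaton.suffix_match_lengths(seq)
        # minimal start of the longest substring ending at j; non-decreasing
        start = np.arange(1, L + 1) - sfx
        ms = np.zeros(L, dtype=np.int64)
        j = -1
        for i in range(L):
            if j < i - 1:
                j = i - 1
            while j + 1 < L and start[j + 1] <= i:
                j += 1
            ms[i] = max(0, j + 1 - i)
        return ms

    # -- serialization ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize to a single JSON artifact (sources + version tag).

        The automaton is cheap to rebuild relative to its in-memory size, so
        the artifact stores the source sequences and the index is
        reconstructed on load.
        """
        payload = {
            "format": "hostscrub-index",
            "version": INDEX_FORMAT_VERSION,
            "name": self.name,
            "references": [[rid, seq] for rid, seq in self._references],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "HostIndex":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "hostscrub-index":
            raise ValueError(f"{path}: not a hostscrub index artifact")
        if payload.get("version") != INDEX_FORMAT_VERSION:
            raise ValueError(
                f"{path}: index format version {payload.get('version')} "
                f"!= supported {INDEX_FORMAT_VERSION}"
            )
        return cls(
            [(rid, seq) for rid, seq in payload["references"]],
            name=payload["name"],
        )


def build_index(
    references: Iterable[tuple[str, str]], name: str = "host"
) -> HostIndex:
    """Build a :class:`HostIndex` over ``(id, sequence)`` references."""
    return HostIndex(list(references), name=name)


def matching_lengths(read: ReadRecord | str, index: HostIndex) -> PMLVector:
    """Per-position pseudo-matching lengths of a read against the index."""
    seq = read.sequence if isinstance(read, ReadRecord) else read
    if not seq:
        raise ValueError("read sequence must be non-empty")
    return PMLVector(index.matching_statistics(seq))
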