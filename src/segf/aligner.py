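"""Strand-aware exact-occurrence search over a set of named references.

The pipeline's alignment filters keep only full-length, gapless, 100%
identical matches, and on the genome side only queries with a single such
occurrence genome-wide. Under those filters the surviving hit set of any
general-purpose aligner is exactly the exact-match set, so both the
target-gene search and the genome search are served by one fixed-k hash
index: forward-strand k-mers are tabulated; a minus-strand query is answered
by looking up its reverse complement.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, NamedTuple

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_DNA_ALPHABET = frozenset("ACGTN")

INDEX_FORMAT = "segf-exact-index"
INDEX_VERSION = 1


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"invalid base(s) in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def _rc_unchecked(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AlignmentHit(NamedTuple):
    """One exact full-length occurrence of a query on a reference.

    ``pos`` is the 0-based start on the forward strand; for strand '-' the
    reference bases at [pos, pos+k) equal the query's reverse complement.
    """

    query_id: str
    ref: str
    pos: int
    strand: str


class MappingStatus(NamedTuple):
    status: str  # 'unmapped' | 'unique' | 'multi'
    hit: AlignmentHit | None


class ExactIndex:
    """Fixed-k hash table over the forward-strand k-mers of named references.

    k-mers containing N are not indexed (they can never match exactly), and
    references shorter than k contribute nothing.
    """

    def __init__(self, references: dict[str, str], k: int):
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        self.k = k
        self.references = dict(references)
        table: dict[str, list[tuple[str, int]]] = {}
        for name in sorted(self.references):
            seq = self.references[name]
            if len(seq) < k:
                continue
            has_n = "N" in seq
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if has_n and "N" in kmer:
                    continue
                table.setdefault(kmer, []).append((name, i))
        self._table = table

    def occurrences(self, query: str) -> list[tuple[str, int, str]]:
        """All exact occurrences of ``query`` on both strands.

        Deterministic order: (ref name, pos, strand). A palindromic query
        matching one locus on both strands yields two occurrences.
        """
        if len(query) != self.k:
            raise ValueError(f"query length {len(query)} != index k {self.k}")
        out: list[tuple[str, int, str]] = []
        for ref, pos in self._table.get(query, ()):
            out.append((ref, pos, "+"))
        for ref, pos in self._table.get(_rc_unchecked(query), ()):
            out.append((ref, pos, "-"))
        out.sort()
        return out

    def to_file(self, path: str | os.PathLike) -> None:
        """Serialize as a single versioned JSON file (references + k)."""
        payload = {
            "format": INDEX_FORMAT,
            "version": INDEX_VERSION,
            "k": self.k,
            "references": self.references,
        }
        with open(path, "wt") as handle:
            json.dump(payload, handle)

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "ExactIndex":
        with open(path, "rt") as handle:
            payload = json.load(handle)
        if payload.get("format") != INDEX_FORMAT:
            raise ValueError(f"{path}: not a {INDEX_FORMAT} file")
        if payload.get("version") != INDEX_VERSION:
            raise ValueError(f"{path}: unsupported index version {payload.get('version')}")
        return cls(payload["references"], payload["k"])


def build_index(references: dict[str, str], k: int) -> ExactIndex:
    return ExactIndex(references, k)


def find_occurrences(index: ExactIndex, query_id: str, query: str) -> list[AlignmentHit]:
    """Exact full-length occurrences of ``query`` as AlignmentHits."""
    return [
        AlignmentHit(query_id=query_id, ref=ref, pos=pos, strand=strand)
        for ref, pos, strand in index.occurrences(query)
    ]


def classify_mapping(hits: Iterable[AlignmentHit]) -> MappingStatus:
    """unmapped (0 hits), unique (exactly 1, attached), or multi (>= 2).

    Uniqueness is counted across both strands and all references.
    """
    hits = list(hits)
    if len({h.query_id for h in hits}) > 1:
        raise ValueError("hits passed to classify_mapping span multiple query ids")
    if not hits:
        return MappingStatus(status="unmapped", hit=None)
    if len(hits) == 1:
        return MappingStatus(status="unique", hit=hits[0])
    return MappingStatus(status="multi", hit=None)
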