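"""Readers and writers for the formats the fusion pipeline touches.

FASTQ (plain or gzipped, 4-line records), FASTA (via Biopython), the
gene-definition BED dialect (chrom, start, end, symbol), exon-model BED, and
the tab-delimited fusion report.

All genomic coordinates are 0-based half-open everywhere inside the package.
The bundled 14-gene panel fixture is already stored in that convention.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass
from importlib import resources
from typing import IO, Iterable, Iterator

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

GZIP_MAGIC = b"\x1f\x8b"


@dataclass(frozen=True)
class Read:
    """One single-end sequencing read.

    ``id`` is the FASTQ header up to the first whitespace; ``seq`` is
    uppercase DNA over {A, C, G, T, N}; ``qual`` is the per-base quality
    string of the same length.
    """

    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be non-empty")
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )


@dataclass(frozen=True)
class GeneRegion:
    """A panel gene's genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    symbol: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.symbol!r}: start {self.start} >= end {self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class ExonModel:
    """Exon intervals for one gene: 0-based half-open, sorted, non-overlapping."""

    symbol: str
    exons: tuple[tuple[int, int], ...]


def _open_maybe_gzip(path: str | os.PathLike) -> IO[str]:
    """Open text transparently; gzip is detected by magic bytes, not suffix."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == GZIP_MAGIC:
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fastq(path: str | os.PathLike) -> Iterator[Read]:
    """Stream 4-line FASTQ records from a plain or gzipped file.

    Sequences are uppercased. A truncated trailing record or a seq/qual
    length mismatch raises ``ValueError`` naming the 1-based record index.
    """
    with _open_maybe_gzip(path) as handle:
        record_idx = 0
        while True:
            header = handle.readline()
            if not header:
                return
            if header.strip() == "":
                # tolerate trailing blank lines only
                if handle.read(1) == "":
                    return
                raise ValueError(f"blank line inside FASTQ at record {record_idx + 1}")
            record_idx += 1
            seq = handle.readline()
            plus = handle.readline()
            qual = handle.readline()
            if not qual:
                raise ValueError(f"truncated FASTQ record {record_idx} in {path}")
            if not header.startswith("@"):
                raise ValueError(f"record {record_idx}: header does not start with '@'")
            if not plus.startswith("+"):
                raise ValueError(f"record {record_idx}: separator line does not start with '+'")
            seq = seq.strip().upper()
            qual = qual.strip()
            if len(seq) != len(qual):
                raise ValueError(
                    f"record {record_idx}: sequence length {len(seq)} != quality length {len(qual)}"
                )
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"record {record_idx}: invalid base(s) {sorted(bad)} in sequence"
                )
            read_id = header[1:].split(None, 1)[0] if header[1:].strip() else ""
            yield Read(id=read_id, seq=seq, qual=qual)


def write_fastq(reads: Iterable[Read], path: str | os.PathLike) -> int:
    """Write reads as 4-line FASTQ; gzip-compress when the path ends in .gz."""
    opener = gzip.open if str(path).endswith(".gz") else open
    n = 0
    with opener(path, "wt") as handle:
        for read in reads:
            handle.write(f"@{read.id}\n{read.seq}\n+\n{read.qual}\n")
            n += 1
    return n


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA file into a name -> uppercase sequence mapping."""
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        genome[record.id] = str(record.seq).upper()
    return genome


def write_fasta(sequences: dict[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "wt") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_gene_bed(path: str | os.PathLike) -> list[GeneRegion]:
    """Parse the gene-definition BED dialect: chrom, start, end, symbol.

    Lines starting with '#' are ignored. Coordinates are taken as 0-based
    half-open (BED standard). Raises ``ValueError`` with the offending line
    number on start >= end or a duplicate gene symbol.
    """
    regions: list[GeneRegion] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"line {lineno}: expected >= 4 tab-separated columns")
            chrom, start_s, end_s, symbol = fields[0], fields[1], fields[2], fields[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(f"line {lineno}: start {start} >= end {end}")
            if symbol in seen:
                raise ValueError(f"line {lineno}: duplicate gene symbol {symbol!r}")
            seen.add(symbol)
            regions.append(GeneRegion(chrom=chrom, start=start, end=end, symbol=symbol))
    return regions


def write_gene_bed(regions: Iterable[GeneRegion], path: str | os.PathLike) -> None:
    with open(path, "wt") as handle:
        for r in regions:
            handle.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.symbol}\n")


def read_exon_bed(path: str | os.PathLike) -> dict[str, ExonModel]:
    """Parse exon intervals (chrom, start, end, symbol) into per-gene models.

    Intervals for a gene are sorted; overlapping or book-ended intervals are
    merged so every model satisfies the sorted/non-overlapping invariant.
    """
    by_symbol: dict[str, list[tuple[int, int]]] = {}
    with _open_maybe_gzip(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"line {lineno}: expected >= 4 tab-separated columns")
            start, end = int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"line {lineno}: start {start} >= end {end}")
            by_symbol.setdefault(fields[3], []).append((start, end))
    models: dict[str, ExonModel] = {}
    for symbol, intervals in by_symbol.items():
        intervals.sort()
        merged: list[tuple[int, int]] = []
        for start, end in intervals:
            if merged and start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        models[symbol] = ExonModel(symbol=symbol, exons=tuple(merged))
    return models


def bundled_panel_path() -> str:
    """Path of the packaged 14-gene panel BED fixture."""
    return str(resources.files("segf.data").joinpath("panel_14gene_hg19.bed"))


def load_bundled_panel() -> list[GeneRegion]:
    return read_gene_bed(bundled_panel_path())


def extract_target_sequences(
    genome: dict[str, str], panel: Iterable[GeneRegion]
) -> dict[str, str]:
    """Cut each panel gene's sequence out of the genome, keyed by symbol.

    The resulting named set is the target reference the head/tail segments
    are searched against; keeping genes separate (rather than concatenating
    them) lets every target hit carry its gene identity directly.
    """
    targets: dict[str, str] = {}
    for region in panel:
        if region.chrom not in genome:
            raise ValueError(f"gene {region.symbol!r}: chromosome {region.chrom!r} not in genome")
        chrom_seq = genome[region.chrom]
        if region.end > len(chrom_seq):
            raise ValueError(
                f"gene {region.symbol!r}: end {region.end} beyond chromosome "
                f"{region.chrom!r} length {len(chrom_seq)}"
            )
        targets[region.symbol] = chrom_seq[region.start : region.end]
    return targets


FUSION_TSV_COLUMNS = ("gene_a", "gene_b", "support_reads", "read_ids", "annot_a", "annot_b")


def write_fusion_tsv(calls, path: str | os.PathLike, comments: Iterable[str] = ()) -> None:
    """Write fusion calls as TSV: header + one row per call.

    Rows are ordered by descending support, then lexicographic gene pair,
    so output is deterministic. Optional '#' comment lines go above the
    header (used by the CLI for its config fingerprint).
    """
    ordered = sorted(calls, key=lambda c: (-c.support, c.gene_a, c.gene_b))
    with open(path, "wt") as handle:
        for comment in comments:
            handle.write(f"# {comment}\n")
        handle.write("\t".join(FUSION_TSV_COLUMNS) + "\n")
        for call in ordered:
            handle.write(
                f"{call.gene_a}\t{call.gene_b}\t{call.support}\t"
                f"{','.join(call.read_ids)}\t{call.annot_a}\t{call.annot_b}\n"
            )


def read_fusion_tsv(path: str | os.PathLike) -> list[dict]:
    """Read a fusion report back as a list of row dicts (support as int)."""
    rows: list[dict] = []
    with _open_maybe_gzip(path) as handle:
        header: list[str] | None = None
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            fields = line.split("\t")
            row = dict(zip(header, fields))
            row["support_reads"] = int(row["support_reads"])
            row["read_ids"] = tuple(row["read_ids"].split(",")) if row["read_ids"] else ()
            rows.append(row)
    return rows
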