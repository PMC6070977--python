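"""Intersection filtering and support-count fusion calling.

A head or tail segment becomes evidence only when it (a) maps uniquely to
the genome with a full-length exact match, (b) matches a panel gene's target
sequence exactly, and (c) its unique genomic location falls inside that
gene's interval. A read whose head and tail evidence name two different
genes is one fusion observation; gene pairs supported by at least
``min_support`` distinct reads become calls.
"""

from __future__ import annotations

import os
from typing import Iterable, NamedTuple

from . import annotate as _annotate
from .aligner import ExactIndex, build_index, classify_mapping, find_occurrences
from .io_formats import (
    ExonModel,
    GeneRegion,
    Read,
    extract_target_sequences,
    read_exon_bed,
    read_fasta,
    read_fastq,
    read_gene_bed,
)
from .psc import DEFAULT_REMAIN_LEN, DEFAULT_TRIM_LEN, PSCSkip, dedup_pscs, extract_psc

DEFAULT_MIN_SUPPORT = 3

REJECT_REASONS = (
    "genome_unmapped",
    "genome_multi",
    "no_target_hit",
    "location_outside_panel",
)


class SegmentEvidence(NamedTuple):
    """One accepted segment: the gene it belongs to and its unique genome hit."""

    read_id: str
    end: str  # 'head' | 'tail'
    gene: str
    chrom: str
    pos: int
    strand: str


class Rejection(NamedTuple):
    read_id: str
    end: str
    reason: str


class PairedObservation(NamedTuple):
    """Head and tail evidence of one read naming two different genes."""

    read_id: str
    head: SegmentEvidence
    tail: SegmentEvidence


class FusionCall(NamedTuple):
    gene_a: str
    gene_b: str
    support: int
    read_ids: tuple[str, ...]
    observations: tuple[PairedObservation, ...]
    annot_a: str = _annotate.GENE_ONLY
    annot_b: str = _annotate.GENE_ONLY

    @property
    def breakpoint_side_positions(self) -> tuple[tuple[int, int], ...]:
        """Per supporting read: (head hit genomic start, tail hit genomic start)."""
        return tuple((obs.head.pos, obs.tail.pos) for obs in self.observations)


def validate_panel(panel: Iterable[GeneRegion]) -> list[GeneRegion]:
    """Panel regions must be mutually disjoint so a genome-unique segment
    can belong to at most one gene."""
    panel = list(panel)
    by_chrom: dict[str, list[GeneRegion]] = {}
    for region in panel:
        by_chrom.setdefault(region.chrom, []).append(region)
    for chrom, regions in by_chrom.items():
        regions = sorted(regions, key=lambda r: r.start)
        for prev, cur in zip(regions, regions[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"panel genes {prev.symbol} and {cur.symbol} overlap on {chrom}"
                )
    return panel


def screen_segment(
    segment: tuple[str, str, str],
    target_index: ExactIndex,
    genome_index: ExactIndex,
    panel_by_symbol: dict[str, GeneRegion],
) -> SegmentEvidence | Rejection:
    """Screen one (read_id, end, sequence) segment through both searches.

    Rejections are data, tagged with one of ``REJECT_REASONS``.
    """
    read_id, end, seq = segment
    status = classify_mapping(find_occurrences(genome_index, read_id, seq))
    if status.status == "unmapped":
        return Rejection(read_id, end, "genome_unmapped")
    if status.status == "multi":
        return Rejection(read_id, end, "genome_multi")
    chrom, pos, strand = status.hit.ref, status.hit.pos, status.hit.strand
    target_occ = target_index.occurrences(seq)
    if not target_occ:
        return Rejection(read_id, end, "no_target_hit")
    hit_genes = {ref for ref, _, _ in target_occ}
    for gene in sorted(hit_genes):
        region = panel_by_symbol[gene]
        if region.chrom == chrom and region.contains(pos):
            return SegmentEvidence(
                read_id=read_id, end=end, gene=gene, chrom=chrom, pos=pos, strand=strand
            )
    return Rejection(read_id, end, "location_outside_panel")


def call_fusions(
    evidence: Iterable[SegmentEvidence], min_support: int = DEFAULT_MIN_SUPPORT
) -> list[FusionCall]:
    """Pair head/tail evidence per read and call gene pairs above threshold.

    A read contributes one observation for its unordered gene pair iff both
    ends survived screening and name two different genes. Support counts
    distinct read ids. Calls are ordered by descending support, then by
    gene pair.
    """
    if min_support < 1:
        raise ValueError(f"min_support must be >= 1, got {min_support}")
    per_read: dict[str, dict[str, SegmentEvidence]] = {}
    for ev in evidence:
        per_read.setdefault(ev.read_id, {})[ev.end] = ev
    by_pair: dict[tuple[str, str], dict[str, PairedObservation]] = {}
    for read_id, ends in per_read.items():
        head, tail = ends.get("head"), ends.get("tail")
        if head is None or tail is None or head.gene == tail.gene:
            continue
        pair = tuple(sorted((head.gene, tail.gene)))
        by_pair.setdefault(pair, {})[read_id] = PairedObservation(read_id, head, tail)
    calls: list[FusionCall] = []
    for (gene_a, gene_b), obs_by_read in by_pair.items():
        if len(obs_by_read) < min_support:
            continue
        read_ids = tuple(sorted(obs_by_read))
        calls.append(
            FusionCall(
                gene_a=gene_a,
                gene_b=gene_b,
                support=len(read_ids),
                read_ids=read_ids,
                observations=tuple(obs_by_read[r] for r in read_ids),
            )
        )
    calls.sort(key=lambda c: (-c.support, c.gene_a, c.gene_b))
    return calls


def call_from_reads(
    reads: Iterable[Read],
    genome: dict[str, str],
    panel: list[GeneRegion],
    exon_models: dict[str, ExonModel] | None = None,
    *,
    trim_len: int = DEFAULT_TRIM_LEN,
    remain_len: int = DEFAULT_REMAIN_LEN,
    min_support: int = DEFAULT_MIN_SUPPORT,
    dedup_psc: bool = False,
    genome_index: ExactIndex | None = None,
    target_index: ExactIndex | None = None,
) -> tuple[list[FusionCall], dict]:
    """In-memory pipeline core: reads -> PSCs -> screening -> calls + report."""
    panel = validate_panel(panel)
    panel_by_symbol = {g.symbol: g for g in panel}
    if genome_index is None:
        genome_index = build_index(genome, remain_len)
    if genome_index.k != remain_len:
        raise ValueError(
            f"genome index k {genome_index.k} != remain_len {remain_len}"
        )
    if target_index is None:
        targets = extract_target_sequences(genome, panel)
        target_index = build_index(targets, remain_len)

    counters: dict[str, int] = {
        "reads_in": 0,
        "pscs_made": 0,
        "skipped_too_short": 0,
        "skipped_ambiguous_base": 0,
        "segments_accepted": 0,
    }
    for reason in REJECT_REASONS:
        counters[f"rejected_{reason}"] = 0

    def pairs():
        for read in reads:
            counters["reads_in"] += 1
            result = extract_psc(read, trim_len=trim_len, remain_len=remain_len)
            if isinstance(result, PSCSkip):
                counters[f"skipped_{result.reason}"] += 1
                continue
            yield result

    pair_iter = dedup_pscs(pairs(), counters) if dedup_psc else pairs()

    evidence: list[SegmentEvidence] = []
    for pair in pair_iter:
        counters["pscs_made"] += 1
        for end, seq in (("head", pair.head), ("tail", pair.tail)):
            result = screen_segment(
                (pair.read_id, end, seq), target_index, genome_index, panel_by_symbol
            )
            if isinstance(result, SegmentEvidence):
                counters["segments_accepted"] += 1
                evidence.append(result)
            else:
                counters[f"rejected_{result.reason}"] += 1

    calls = call_fusions(evidence, min_support=min_support)
    calls = _annotate.annotate_calls(calls, exon_models, panel)
    counters["calls"] = len(calls)
    report = {
        "parameters": {
            "trim_len": trim_len,
            "remain_len": remain_len,
            "min_support": min_support,
            "dedup_psc": dedup_psc,
        },
        "counters": counters,
        "calls": [
            {
                "gene_a": c.gene_a,
                "gene_b": c.gene_b,
                "support": c.support,
                "annot_a": c.annot_a,
                "annot_b": c.annot_b,
            }
            for c in calls
        ],
    }
    return calls, report


def run_pipeline(
    fastq_paths: Iterable[str | os.PathLike],
    genome_path: str | os.PathLike,
    panel_path: str | os.PathLike,
    *,
    exon_path: str | os.PathLike | None = None,
    trim_len: int = DEFAULT_TRIM_LEN,
    remain_len: int = DEFAULT_REMAIN_LEN,
    min_support: int = DEFAULT_MIN_SUPPORT,
    dedup_psc: bool = False,
) -> tuple[list[FusionCall], dict]:
    """End-to-end pipeline on files.

    Multiple FASTQ paths (e.g. the two mates of a paired-end run) are
    consumed as independent single-end streams; when more than one file is
    given, read ids are suffixed with the stream index so mates sharing a
    header can never be cross-paired. Deterministic for fixed inputs and
    options.
    """
    genome = read_fasta(genome_path)
    panel = read_gene_bed(panel_path)
    exon_models = read_exon_bed(exon_path) if exon_path else None
    fastq_paths = list(fastq_paths)

    def reads():
        for i, path in enumerate(fastq_paths, start=1):
            for read in read_fastq(path):
                if len(fastq_paths) > 1:
                    read = Read(id=f"{read.id}/s{i}", seq=read.seq, qual=read.qual)
                yield read

    return call_from_reads(
        reads(),
        genome,
        panel,
        exon_models,
        trim_len=trim_len,
        remain_len=remain_len,
        min_support=min_support,
        dedup_psc=dedup_psc,
    )
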