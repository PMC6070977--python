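"""Synthetic test worlds: genome, panel, wild-type and fusion-supporting reads.

The generator emulates a targeted capture experiment at desk scale: a small
multi-chromosome genome of uniform-random DNA carrying a 14-gene panel,
151 bp single-end reads with substitution noise confined to the first and
last 10 sequencing cycles (the low-quality cycles the pipeline trims), and
fusion-supporting reads that span a junction between two panel genes —
optionally with a linker sequence inserted at the junction, the "complex"
three-part fusion configuration.

Every fusion-supporting read is placed so that its head and tail segments
fall wholly inside the two partner genes; the discarded middle carries the
junction (and any linker). That makes recovery tests sharp: each planted
read is in principle detectable.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import GeneRegion, Read
from .psc import DEFAULT_REMAIN_LEN, DEFAULT_TRIM_LEN

DEFAULT_READ_LEN = 151
DEFAULT_END_LEN = 10
DEFAULT_END_ERROR_RATE = 0.02

#: Panel gene symbols (lung-cancer fusion panel: ALK-EML4, ROS1-SLC34A2,
#: RET-CCDC6 partners and friends).
DEFAULT_PANEL_SYMBOLS = (
    "ALK", "EML4", "ROS1", "CD74", "SLC34A2", "RET", "CCDC6",
    "KIF5B", "SDC4", "EZR", "TPM3", "LRIG3", "GOPC", "HPRT1",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Synthetic linker observed in engineered complex-fusion reference standards.
COMPLEX_FUSION_LINKER = "GAAGTTCCTATTCCGAAGTTCCTATTCTTCAAATAGTATAGGAACTTC"


@dataclass(frozen=True)
class FusionSpec:
    """One planted fusion: gene pair, junction, linker, read fraction."""

    gene_a: str
    gene_b: str
    fraction: float
    breakpoint_a: int | None = None  # absolute coordinate inside gene_a
    breakpoint_b: int | None = None
    linker: str = ""

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("fusion partners must be distinct genes")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must be in [0, 1], got {self.fraction}")
        if set(self.linker) - set("ACGT"):
            raise ValueError("linker must be over {A,C,G,T}")

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))

    @property
    def label(self) -> str:
        return "fusion:%s--%s" % self.pair


@dataclass
class TruthManifest:
    """Per-read truth labels plus the planted specs and label counts."""

    labels: dict[str, str]  # read_id -> 'wild_type' | 'fusion:<A>--<B>'
    counts: dict[str, int]
    specs: list[FusionSpec] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.labels)

    def planted_pairs(self) -> set[tuple[str, str]]:
        return {spec.pair for spec in self.specs if self.counts.get(spec.label, 0) > 0}

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "labels": self.labels,
            "counts": self.counts,
            "specs": [
                {
                    "gene_a": s.gene_a,
                    "gene_b": s.gene_b,
                    "fraction": s.fraction,
                    "breakpoint_a": s.breakpoint_a,
                    "breakpoint_b": s.breakpoint_b,
                    "linker": s.linker,
                }
                for s in self.specs
            ],
        }
        with open(path, "wt") as handle:
            json.dump(payload, handle)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "TruthManifest":
        with open(path, "rt") as handle:
            payload = json.load(handle)
        return cls(
            labels=payload["labels"],
            counts=payload["counts"],
            specs=[FusionSpec(**s) for s in payload["specs"]],
        )


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def make_genome(
    seed: int,
    *,
    n_chroms: int = 3,
    gene_len: int = 1000,
    gap: int = 300,
    symbols: Sequence[str] = DEFAULT_PANEL_SYMBOLS,
    chrom_len: int | None = None,
    panel_layout: Sequence[tuple[str, int, int, str]] | None = None,
) -> tuple[dict[str, str], list[GeneRegion]]:
    """Build a uniform-random genome carrying a disjoint gene panel.

    With the default layout the panel's 14 genes are spread across
    ``n_chroms`` chromosomes, each gene ``gene_len`` bp separated by ``gap``
    bp of intergenic sequence. An explicit ``panel_layout`` (chrom, start,
    end, symbol) overrides the automatic one; regions must be mutually
    disjoint and fit inside their chromosomes. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    if panel_layout is not None:
        panel = [GeneRegion(*row) for row in panel_layout]
    else:
        panel = []
        per_chrom = [len(symbols) // n_chroms] * n_chroms
        for i in range(len(symbols) % n_chroms):
            per_chrom[i] += 1
        idx = 0
        for c, count in enumerate(per_chrom, start=1):
            pos = gap
            for _ in range(count):
                panel.append(GeneRegion(f"chr{c}", pos, pos + gene_len, symbols[idx]))
                pos += gene_len + gap
                idx += 1
    # disjointness check
    by_chrom: dict[str, list[GeneRegion]] = {}
    for region in panel:
        by_chrom.setdefault(region.chrom, []).append(region)
    chrom_lengths: dict[str, int] = {}
    for chrom, regions in by_chrom.items():
        regions = sorted(regions, key=lambda r: r.start)
        for prev, cur in zip(regions, regions[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"panel regions {prev.symbol} and {cur.symbol} overlap on {chrom}"
                )
        needed = regions[-1].end + gap
        length = chrom_len if chrom_len is not None else needed
        if length < regions[-1].end:
            raise ValueError(
                f"chromosome {chrom} length {length} cannot hold region ending at "
                f"{regions[-1].end}"
            )
        chrom_lengths[chrom] = length
    genome = {
        chrom: _random_dna(rng, length) for chrom, length in sorted(chrom_lengths.items())
    }
    return genome, panel


def _fusion_read_seq(
    rng: np.random.Generator,
    genome: dict[str, str],
    region_a: GeneRegion,
    region_b: GeneRegion,
    bp_a: int,
    bp_b: int,
    linker: str,
    read_len: int,
    flank: int,
) -> str:
    """One junction-spanning read: A-part + linker + B-part.

    The start is uniform over placements keeping >= ``flank`` bases of both
    genes inside the read, so head and tail segments always fall wholly in
    the two partner genes.
    """
    a_lo = flank
    a_hi = read_len - len(linker) - flank
    a_hi = min(a_hi, bp_a - region_a.start)
    a_lo = max(a_lo, read_len - len(linker) - (region_b.end - bp_b))
    if a_hi < a_lo:
        raise ValueError(
            f"infeasible fusion geometry for {region_a.symbol}-{region_b.symbol}: "
            f"read {read_len} bp, linker {len(linker)} bp, flank {flank} bp"
        )
    a = int(rng.integers(a_lo, a_hi + 1))
    b = read_len - len(linker) - a
    seq_a = genome[region_a.chrom][bp_a - a : bp_a]
    seq_b = genome[region_b.chrom][bp_b : bp_b + b]
    return seq_a + linker + seq_b


def simulate_reads(
    genome: dict[str, str],
    panel: Sequence[GeneRegion],
    specs: Sequence[FusionSpec],
    depth: float,
    *,
    read_len: int = DEFAULT_READ_LEN,
    trim_len: int = DEFAULT_TRIM_LEN,
    remain_len: int = DEFAULT_REMAIN_LEN,
    degrade_ends: bool = True,
    end_len: int = DEFAULT_END_LEN,
    end_error_rate: float = DEFAULT_END_ERROR_RATE,
    seed: int = 0,
) -> tuple[list[Read], TruthManifest]:
    """Draw single-end reads at the given mean depth over the genome.

    Total read count is round(depth * genome_length / read_len). Each
    spec's fraction of reads spans its fusion junction; the rest are
    wild-type reads drawn uniformly from either strand of the genome.
    Substitution noise is applied only inside the first/last ``end_len``
    cycles (rate ``end_error_rate`` per base); interior bases are
    error-free so the 100%-identity filter's behaviour stays analyzable.
    Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    by_symbol = {g.symbol: g for g in panel}
    genome_len = sum(len(s) for s in genome.values())
    n_total = int(round(depth * genome_len / read_len))
    if sum(s.fraction for s in specs) > 1.0:
        raise ValueError("fusion fractions sum to more than 1")

    flank = trim_len + remain_len
    if read_len < 2 * flank:
        raise ValueError(
            f"read_len {read_len} too short for trim_len {trim_len} + remain_len {remain_len}"
        )

    seqs: list[str] = []
    labels: list[str] = []
    for spec in specs:
        region_a, region_b = by_symbol[spec.gene_a], by_symbol[spec.gene_b]
        bp_a = spec.breakpoint_a if spec.breakpoint_a is not None else (region_a.start + region_a.end) // 2
        bp_b = spec.breakpoint_b if spec.breakpoint_b is not None else (region_b.start + region_b.end) // 2
        if not region_a.contains(bp_a) or not region_b.contains(bp_b):
            raise ValueError(f"breakpoints outside genes for {spec.gene_a}-{spec.gene_b}")
        n_fusion = int(round(spec.fraction * n_total))
        for _ in range(n_fusion):
            seqs.append(
                _fusion_read_seq(
                    rng, genome, region_a, region_b, bp_a, bp_b, spec.linker, read_len, flank
                )
            )
            labels.append(spec.label)

    # wild-type reads: chromosome weighted by usable start positions
    n_wt = n_total - len(seqs)
    chrom_names = sorted(genome)
    usable = np.array([max(len(genome[c]) - read_len + 1, 0) for c in chrom_names], dtype=float)
    if usable.sum() == 0:
        raise ValueError("no chromosome long enough for read_len")
    chrom_idx = rng.choice(len(chrom_names), size=n_wt, p=usable / usable.sum())
    for c, chrom in enumerate(chrom_names):
        n_c = int(np.count_nonzero(chrom_idx == c))
        if n_c == 0:
            continue
        starts = rng.integers(0, len(genome[chrom]) - read_len + 1, size=n_c)
        chrom_seq = genome[chrom]
        for start in starts:
            seqs.append(chrom_seq[start : start + read_len])
            labels.append("wild_type")

    # random strand
    flip = rng.random(n_total) < 0.5
    for i in np.flatnonzero(flip):
        seqs[i] = seqs[i].translate(_COMPLEMENT)[::-1]

    # output order is drawn before noise so the same seed yields the same
    # read identities regardless of the error-rate setting
    order = rng.permutation(n_total)

    # substitution noise in the degraded end cycles only
    if degrade_ends and end_error_rate > 0 and n_total > 0:
        end_positions = list(range(end_len)) + list(range(read_len - end_len, read_len))
        err = rng.random((n_total, len(end_positions))) < end_error_rate
        alt = rng.integers(1, 4, size=int(err.sum()))  # offset from current base
        base_order = "ACGT"
        k = 0
        for i, j in np.argwhere(err):
            pos = end_positions[j]
            seq = seqs[i]
            cur = base_order.find(seq[pos])
            if cur < 0:  # N stays N
                k += 1
                continue
            new = base_order[(cur + alt[k]) % 4]
            k += 1
            seqs[i] = seq[:pos] + new + seq[pos + 1 :]

    qual = (
        "#" * end_len + "I" * (read_len - 2 * end_len) + "#" * end_len
        if degrade_ends
        else "I" * read_len
    )
    reads = [Read(id=f"r{i:07d}", seq=seqs[j], qual=qual) for i, j in enumerate(order)]
    read_labels = {f"r{i:07d}": labels[j] for i, j in enumerate(order)}

    counts: dict[str, int] = {}
    for label in read_labels.values():
        counts[label] = counts.get(label, 0) + 1
    counts.setdefault("wild_type", 0)
    manifest = TruthManifest(labels=read_labels, counts=counts, specs=list(specs))
    return reads, manifest
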