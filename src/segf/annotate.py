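"""Intron/exon annotation of fusion-call evidence against optional exon models."""

from __future__ import annotations

from bisect import bisect_right

from .io_formats import ExonModel, GeneRegion

GENE_ONLY = "gene_only"
EXON = "exon"
INTRON = "intron"
MIXED = "mixed"


def classify_position(
    pos: int, gene: GeneRegion, exons: ExonModel | None
) -> str:
    """Label one genomic coordinate within a gene as exon / intron / gene_only.

    Exon intervals are half-open; with no exon model supplied the gene-level
    label ``gene_only`` is returned. Every in-gene coordinate gets exactly
    one of {exon, intron} when a model is present.
    """
    if not gene.contains(pos):
        raise ValueError(
            f"position {pos} outside gene {gene.symbol} [{gene.start}, {gene.end})"
        )
    if exons is None:
        return GENE_ONLY
    starts = [s for s, _ in exons.exons]
    i = bisect_right(starts, pos) - 1
    if i >= 0 and exons.exons[i][0] <= pos < exons.exons[i][1]:
        return EXON
    return INTRON


def _majority_label(labels: list[str]) -> str:
    if not labels:
        return GENE_ONLY
    if all(lab == GENE_ONLY for lab in labels):
        return GENE_ONLY
    n_exon = labels.count(EXON)
    n_intron = labels.count(INTRON)
    if n_exon > n_intron:
        return EXON
    if n_intron > n_exon:
        return INTRON
    return MIXED


def annotate_calls(calls, exon_models: dict[str, ExonModel] | None, panel) -> list:
    """Fill per-gene intron/exon labels on each call.

    The anchor coordinate of each supporting segment is its genomic start.
    The call-level label per gene is the majority label over supporting
    segments; an exact tie is reported as ``mixed``; genes with no exon
    model get ``gene_only``.
    """
    from .fusion_caller import FusionCall  # local import avoids a cycle

    by_symbol = {g.symbol: g for g in panel}
    annotated: list[FusionCall] = []
    for call in calls:
        labels_a: list[str] = []
        labels_b: list[str] = []
        for obs in call.observations:
            for ev in (obs.head, obs.tail):
                model = exon_models.get(ev.gene) if exon_models else None
                label = classify_position(ev.pos, by_symbol[ev.gene], model)
                (labels_a if ev.gene == call.gene_a else labels_b).append(label)
        annotated.append(
            call._replace(annot_a=_majority_label(labels_a), annot_b=_majority_label(labels_b))
        )
    return annotated
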