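"""Operon inference from bridging-read evidence.

Adjacent same-strand genes are linked when at least ``bridging_reads_min``
whole-transcriptome read intervals span the entire intergenic gap (both
flanking gene edges).  Maximal linked chains of two or more genes form
primary operons; an operon is validated when its first gene (in
transcription order) carries an assigned TSS, and every internal gene with
an assigned TSS opens a suffix sub-operon.  Genes in no chain are
monocistronic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from bactx.core import FORWARD, FeatureRecord, GenomeAnnotation
from bactx.tss import TSSRecord

ReadInterval = tuple[int, int, str]  # (start, end, strand), half-open


@dataclass(frozen=True)
class Operon:
    gene_ids: tuple[str, ...]  # transcription order
    strand: str
    validated: bool
    sub_operons: tuple[tuple[int, tuple[str, ...]], ...] = ()


def count_bridging_reads(
    gene_a: FeatureRecord,
    gene_b: FeatureRecord,
    intervals: Sequence[ReadInterval],
) -> int:
    """Same-strand read intervals covering both the last base of the
    upstream gene and the first base of the downstream gene.  Overlapping
    genes (gap 0) reduce to covering the junction base(s)."""
    first, second = (gene_a, gene_b) if gene_a.start <= gene_b.start else (gene_b, gene_a)
    p1, p2 = first.end - 1, second.start
    lo, hi = min(p1, p2), max(p1, p2)
    return sum(
        1
        for (s, e, strand) in intervals
        if strand == gene_a.strand and s <= lo and e > hi
    )


def adjacent_same_strand_pairs(
    genes: Sequence[FeatureRecord],
) -> list[tuple[FeatureRecord, FeatureRecord]]:
    """Consecutive genes in genomic order sharing a strand.  An
    opposite-strand gene between two genes breaks their adjacency."""
    ordered = sorted(genes, key=lambda f: (f.start, f.end))
    return [
        (a, b)
        for a, b in zip(ordered, ordered[1:])
        if a.strand == b.strand
    ]


def compute_bridging_counts(
    annotation: GenomeAnnotation, intervals: Sequence[ReadInterval]
) -> dict[tuple[str, str], int]:
    """Bridging counts for every same-strand adjacent CDS pair, keyed by
    (upstream-in-genomic-order id, downstream id)."""
    return {
        (a.feature_id, b.feature_id): count_bridging_reads(a, b, intervals)
        for a, b in adjacent_same_strand_pairs(annotation.cds())
    }


def infer_operons(
    annotation: GenomeAnnotation,
    bridging_counts: dict[tuple[str, str], int],
    classified_tss: Sequence[TSSRecord],
    config,
) -> tuple[list[Operon], list[str]]:
    """Build primary operons, sub-operons and the monocistronic gene list."""
    genes = sorted(annotation.cds(), key=lambda f: (f.start, f.end))
    has_tss = {
        t.assigned_feature_id
        for t in classified_tss
        if t.tss_class in ("primary", "secondary")
    }
    linked = set()
    for a, b in adjacent_same_strand_pairs(genes):
        if bridging_counts.get((a.feature_id, b.feature_id), 0) >= config.bridging_reads_min:
            linked.add((a.feature_id, b.feature_id))

    operons: list[Operon] = []
    in_operon: set[str] = set()
    chain: list[FeatureRecord] = []

    def flush(chain: list[FeatureRecord]) -> None:
        if len(chain) < 2:
            return
        tx_order = chain if chain[0].strand == FORWARD else chain[::-1]
        ids = tuple(f.feature_id for f in tx_order)
        subs = tuple(
            (k, ids[k:]) for k in range(1, len(ids)) if ids[k] in has_tss
        )
        operons.append(
            Operon(
                gene_ids=ids,
                strand=chain[0].strand,
                validated=ids[0] in has_tss,
                sub_operons=subs,
            )
        )
        in_operon.update(ids)

    for g in genes:
        if chain and (chain[-1].feature_id, g.feature_id) in linked:
            chain.append(g)
        else:
            flush(chain)
            chain = [g]
    flush(chain)

    monocistronic = [f.feature_id for f in genes if f.feature_id not in in_operon]
    return operons, monocistronic


def operon_summary(
    operons: Sequence[Operon], monocistronic: Sequence[str]
) -> dict[str, int]:
    return {
        "operons": len(operons),
        "validated_operons": sum(1 for o in operons if o.validated),
        "sub_operons": sum(len(o.sub_operons) for o in operons),
        "genes_in_operons": sum(len(o.gene_ids) for o in operons),
        "monocistronic": len(monocistronic),
        "largest_operon": max((len(o.gene_ids) for o in operons), default=0),
    }
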