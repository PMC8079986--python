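"""Translation-start corrections driven by intragenic TSS, plus start-codon
usage statistics.

A CDS qualifies for a corrected TLS when an intragenic same-strand TSS lies
within the first ``tls_scan_fraction`` of its length, an in-frame
ATG/GTG/TTG exists downstream of that TSS within the same bound, the
whole-transcriptome coverage at the original TLS does not exceed
``old_tls_coverage_max`` (default 0: no reads map there), and no
primary/secondary TSS is assigned upstream of the CDS.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from bactx.core import (
    FORWARD,
    FeatureRecord,
    GenomeAnnotation,
    ValidationError,
    tls_position,
)
from bactx.profiles import StrandProfile
from bactx.tss import TSSRecord

logger = logging.getLogger(__name__)

START_CODONS = ("ATG", "GTG", "TTG")


@dataclass(frozen=True)
class TLSProposal:
    feature_id: str
    old_tls: int
    new_tls: int
    new_start_codon: str
    supporting_tss: int
    old_tls_coverage: int


def _codon_at_offset(annotation: GenomeAnnotation, cds: FeatureRecord, offset: int) -> str:
    """Codon starting `offset` nt into the CDS, read 5'->3' on its strand."""
    if cds.strand == FORWARD:
        s = cds.start + offset
        return annotation.subsequence(s, s + 3, FORWARD)
    e = cds.end - offset
    return annotation.subsequence(e - 3, e, "-")


def _tls_offset_to_coord(cds: FeatureRecord, offset: int) -> int:
    """Genome coordinate of the base at strand-aware CDS offset."""
    return cds.start + offset if cds.strand == FORWARD else cds.end - 1 - offset


def propose_tls_corrections(
    annotation: GenomeAnnotation,
    classified_tss: Sequence[TSSRecord],
    profile: StrandProfile,
    config,
    old_tls_coverage_max: int = 0,
) -> list[TLSProposal]:
    """Propose at most one corrected TLS per CDS (first qualifying in-frame
    start codon downstream of the supporting intragenic TSS)."""
    intragenic = [t for t in classified_tss if t.tss_class == "intragenic"]
    assigned_features = {
        t.assigned_feature_id
        for t in classified_tss
        if t.tss_class in ("primary", "secondary")
    }
    proposals: list[TLSProposal] = []
    for cds in annotation.cds():
        if cds.length < 9:
            logger.warning("CDS %s shorter than 3 codons; skipped", cds.feature_id)
            continue
        bound = int(config.tls_scan_fraction * cds.length)
        # Intragenic same-strand TSS inside this CDS, within the scan bound.
        in_cds = sorted(
            (
                t
                for t in intragenic
                if t.strand == cds.strand and cds.start <= t.position < cds.end
            ),
            key=lambda t: _offset(cds, t.position),
        )
        proposal = None
        for t in in_cds:
            tss_offset = _offset(cds, t.position)
            if tss_offset >= bound:
                continue
            if cds.feature_id in assigned_features:
                break  # a TSS upstream of the CDS exists; no alteration
            cov = int(profile.coverage(cds.strand)[tls_position(cds)])
            if cov > old_tls_coverage_max:
                break
            # First in-frame start codon strictly downstream of the TSS,
            # still within the scan bound.
            o = tss_offset + 1
            o += (-o) % 3
            while o < bound and o + 3 <= cds.length:
                codon = _codon_at_offset(annotation, cds, o)
                if codon in START_CODONS:
                    proposal = TLSProposal(
                        feature_id=cds.feature_id,
                        old_tls=tls_position(cds),
                        new_tls=_tls_offset_to_coord(cds, o),
                        new_start_codon=codon,
                        supporting_tss=t.position,
                        old_tls_coverage=cov,
                    )
                    break
                o += 3
            if proposal is not None:
                break
        if proposal is not None:
            proposals.append(proposal)
    return proposals


def _offset(cds: FeatureRecord, position: int) -> int:
    """Strand-aware offset of a genome position from the CDS TLS."""
    return (
        position - cds.start if cds.strand == FORWARD else cds.end - 1 - position
    )


def apply_tls_corrections(
    annotation: GenomeAnnotation, proposals: Sequence[TLSProposal]
) -> GenomeAnnotation:
    """Move CDS starts to their proposed TLS; stop codon and frame are
    preserved, the CDS shrinks."""
    by_id = {p.feature_id: p for p in proposals}
    new_features = []
    for f in annotation.features:
        p = by_id.get(f.feature_id)
        if p is None or f.kind != "CDS":
            new_features.append(f)
            continue
        if f.strand == FORWARD:
            new = FeatureRecord(
                f.feature_id, f.kind, p.new_tls, f.end, f.strand, f.product
            )
        else:
            new = FeatureRecord(
                f.feature_id, f.kind, f.start, p.new_tls + 1, f.strand, f.product
            )
        if new.length % 3 != (f.length % 3) or new.length >= f.length:
            raise ValidationError(
                f"proposal for {f.feature_id} violates frame or does not shrink"
            )
        new_features.append(new)
    return annotation.with_features(new_features)


def start_codon_usage(annotation: GenomeAnnotation) -> dict[str, float | int]:
    """Fractions of ATG/GTG/TTG start codons over CDS with a recognized
    start codon; unrecognized codons are counted separately as `other`."""
    counts: Counter[str] = Counter()
    other = 0
    for cds in annotation.cds():
        if cds.length < 3:
            other += 1
            continue
        codon = _codon_at_offset(annotation, cds, 0)
        if codon in START_CODONS:
            counts[codon] += 1
        else:
            other += 1
    recognized = sum(counts.values())
    out: dict[str, float | int] = {
        c: (counts[c] / recognized if recognized else 0.0) for c in START_CODONS
    }
    out["other"] = other
    out["n_recognized"] = recognized
    return out


def novel_cds_candidates(
    annotation: GenomeAnnotation,
    classified_tss: Sequence[TSSRecord],
    max_scan: int = 600,
    min_length_aa: int = 30,
) -> list[tuple[int, int, str, int]]:
    """Candidate novel CDS intervals downstream of intergenic TSS, flagged
    for external review only (no protein-evidence integration).

    Returns (start, end, strand, tss_position) tuples for the first ORF
    (ATG/GTG/TTG ... stop) beginning within `max_scan` nt of the TSS.
    """
    stops = {"TAA", "TAG", "TGA"}
    out = []
    n = len(annotation.sequence)
    for t in classified_tss:
        if t.tss_class != "intergenic":
            continue
        if t.strand == FORWARD:
            window = annotation.sequence[t.position : min(t.position + max_scan, n)]
        else:
            window = annotation.subsequence(
                max(t.position + 1 - max_scan, 0), t.position + 1, "-"
            )
        found = None
        for i in range(len(window) - 2):
            if window[i : i + 3] not in START_CODONS:
                continue
            j = i + 3
            while j + 3 <= len(window):
                if window[j : j + 3] in stops:
                    if (j - i) // 3 >= min_length_aa:
                        found = (i, j + 3)
                    break
                j += 3
            if found:
                break
        if found:
            i, j = found
            if t.strand == FORWARD:
                out.append((t.position + i, t.position + j, FORWARD, t.position))
            else:
                out.append((t.position + 1 - j, t.position + 1 - i, "-", t.position))
    return out
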