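"""Attenuator leader-peptide detection: small ORFs in 5' leaders, residue
enrichment scoring, and a Rho-independent terminator heuristic.

The terminator search enumerates perfect reverse-complement stem-loops
(stem >= min_stem, loop 3-9) and requires at least three T within the
10 nt after the stem's 3' arm; hairpins lacking the T-stretch are still
reported, flagged non-canonical, since attenuators without a clear
uridine stretch occur.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from Bio.Data import CodonTable

from bactx.core import (
    FORWARD,
    FeatureRecord,
    GenomeAnnotation,
    ValidationError,
    revcomp,
    tls_position,
    upstream_interval,
)
from bactx.tss import TSSRecord

logger = logging.getLogger(__name__)

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_TABLE = CodonTable.unambiguous_dna_by_id[11].forward_table


@dataclass(frozen=True)
class AttenuatorConfig:
    min_length_aa: int = 8
    max_length_aa: int = 35
    min_enrichment: float = 3.0
    min_residue_count: int = 2
    min_stem: int = 6
    loop_range: tuple[int, int] = (3, 9)
    u_window: int = 10
    min_u: int = 3
    leader_window: int = 250  # fallback when no TSS is assigned
    terminator_window: int = 80


@dataclass(frozen=True)
class TerminatorHit:
    stem_length: int
    loop_length: int
    u_stretch_length: int
    position: int  # stem start, window-relative
    canonical: bool


@dataclass(frozen=True)
class LeaderOrf:
    start: int  # leader-relative, 0-based
    end: int  # exclusive, includes stop codon
    peptide: str

    @property
    def length_aa(self) -> int:
        return len(self.peptide)


@dataclass(frozen=True)
class Composition:
    residue_counts: dict[str, int]
    length: int
    enriched_residue: Optional[str]
    enrichment: float


@dataclass(frozen=True)
class LeaderPeptideHit:
    upstream_of: str
    orf_start: int  # genome coordinate of first base of start codon
    orf_end: int  # genome coordinate one past the stop codon (strand-aware 3')
    strand: str
    peptide: str
    length_aa: int
    residue_counts: dict[str, int]
    enriched_residue: str
    enrichment: float
    terminator: Optional[TerminatorHit]
    leaderless_start: bool


def translate_orf(dna: str) -> str:
    """Translate an ORF (start codon through stop), forcing the initiator
    to M for GTG/TTG starts; the stop is not included in the peptide."""
    peptide = []
    for i in range(0, len(dna) - 2, 3):
        codon = dna[i : i + 3]
        if codon in STOP_CODONS:
            break
        peptide.append(_TABLE[codon])
    if peptide:
        peptide[0] = "M"
    return "".join(peptide)


def find_leader_orfs(leader_sequence: str, config: AttenuatorConfig | None = None) -> list[LeaderOrf]:
    """All forward-frame ORFs (ATG/GTG/TTG start, in-frame stop, fully
    contained in the leader) whose peptide length falls inside the config
    bounds, 5'-most first.  ORFs containing N are skipped with a warning."""
    config = config or AttenuatorConfig()
    seq = leader_sequence.upper()
    orfs: list[LeaderOrf] = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] not in START_CODONS:
            continue
        j = i + 3
        while j + 3 <= len(seq):
            codon = seq[j : j + 3]
            if "N" in codon or "N" in seq[i : i + 3]:
                logger.warning("ORF at %d contains N; skipped", i)
                j = None
                break
            if codon in STOP_CODONS:
                break
            j += 3
        else:
            j = None
        if j is None or j + 3 > len(seq):
            continue
        length_aa = (j - i) // 3
        if config.min_length_aa <= length_aa <= config.max_length_aa:
            orfs.append(LeaderOrf(start=i, end=j + 3, peptide=translate_orf(seq[i : j + 3])))
    return orfs


def residue_composition(
    peptide: str, background: dict[str, float] | None = None, min_count: int = 2
) -> Composition:
    """Exact residue counts plus the most enriched residue (fold over
    background, default uniform 1/20) among residues with count >= 2;
    ties resolve alphabetically."""
    bad = set(peptide) - set(AMINO_ACIDS)
    if bad:
        raise ValidationError(f"invalid residues {sorted(bad)} in peptide")
    counts = Counter(peptide)
    n = len(peptide)
    enriched, best = None, 0.0
    for aa in sorted(counts):
        if counts[aa] < min_count:
            continue
        bg = (background or {}).get(aa, 1 / 20)
        fold = (counts[aa] / n) / bg
        if fold > best:
            enriched, best = aa, fold
    return Composition(
        residue_counts=dict(counts), length=n, enriched_residue=enriched, enrichment=best
    )


def find_terminator(
    dna_window: str, config: AttenuatorConfig | None = None
) -> Optional[TerminatorHit]:
    """Best stem-loop in a window: perfect reverse-complement stems >=
    min_stem with loop 3-9 nt.  Canonical hits (>= min_u T in the u_window
    after the stem) are preferred; otherwise the best hairpin is returned
    flagged non-canonical.  Selection: longest stem, ties most upstream."""
    config = config or AttenuatorConfig()
    w = dna_window.upper()
    n = len(w)
    if n < 2 * config.min_stem + config.loop_range[0]:
        return None
    hits: list[TerminatorHit] = []
    lo_loop, hi_loop = config.loop_range
    for i in range(n):
        for stem in range(config.min_stem, (n - i) // 2 + 1):
            arm = w[i : i + stem]
            if "N" in arm:
                break
            for loop in range(lo_loop, hi_loop + 1):
                j = i + stem + loop
                if j + stem > n:
                    break
                if w[j : j + stem] == revcomp(arm):
                    tail = w[j + stem : j + stem + config.u_window]
                    u = tail.count("T")
                    hits.append(
                        TerminatorHit(
                            stem_length=stem,
                            loop_length=loop,
                            u_stretch_length=u,
                            position=i,
                            canonical=u >= config.min_u,
                        )
                    )
    if not hits:
        return None
    return min(hits, key=lambda h: (not h.canonical, -h.stem_length, h.position))


def _leader_region(
    target: FeatureRecord,
    primary_tss: Optional[TSSRecord],
    genome: GenomeAnnotation,
    config: AttenuatorConfig,
) -> tuple[str, int]:
    """Leader sequence 5'->3' plus the genome coordinate of its first base
    (strand-aware 5' end)."""
    tls = tls_position(target)
    if primary_tss is not None and primary_tss.utr_length and primary_tss.utr_length > 0:
        length = primary_tss.utr_length
    else:
        length = config.leader_window
    s, e, _ = upstream_interval(tls, length, target.strand, len(genome.sequence))
    seq = genome.subsequence(s, e, target.strand)
    five_prime = s if target.strand == FORWARD else e - 1
    return seq, five_prime


def _to_genome_coord(five_prime: int, offset: int, strand: str) -> int:
    return five_prime + offset if strand == FORWARD else five_prime - offset


def scan_attenuators(
    annotation: GenomeAnnotation,
    classified_tss: Sequence[TSSRecord],
    target_gene_filter: Optional[Callable[[FeatureRecord], bool]] = None,
    config: AttenuatorConfig | None = None,
) -> list[LeaderPeptideHit]:
    """Scan 5' leaders of target CDS for enriched small ORFs followed by a
    terminator signature.

    The leader is [TSS, TLS) when the target has an assigned primary TSS
    with a non-zero UTR, else a fixed window upstream of the TLS.  A hit
    requires an enriched residue at fold >= min_enrichment with count >=
    min_residue_count.  Output order is independent of gene iteration
    order (sorted by target id, then ORF start).
    """
    config = config or AttenuatorConfig()
    primary_by_feature = {
        t.assigned_feature_id: t for t in classified_tss if t.tss_class == "primary"
    }
    tss_positions = {(t.position, t.strand) for t in classified_tss}
    hits: list[LeaderPeptideHit] = []
    for target in annotation.cds():
        if target_gene_filter is not None and not target_gene_filter(target):
            continue
        leader, five_prime = _leader_region(
            target, primary_by_feature.get(target.feature_id), annotation, config
        )
        if len(leader) < 3 * (config.min_length_aa + 1):
            continue
        for orf in find_leader_orfs(leader, config):
            comp = residue_composition(orf.peptide, min_count=config.min_residue_count)
            if comp.enriched_residue is None or comp.enrichment < config.min_enrichment:
                continue
            term = find_terminator(leader[orf.end :], config)
            g_start = _to_genome_coord(five_prime, orf.start, target.strand)
            g_end = _to_genome_coord(five_prime, orf.end, target.strand)
            leaderless_start = any(
                (_to_genome_coord(five_prime, orf.start - d, target.strand), target.strand)
                in tss_positions
                for d in range(0, 4)
            )
            hits.append(
                LeaderPeptideHit(
                    upstream_of=target.feature_id,
                    orf_start=g_start,
                    orf_end=g_end,
                    strand=target.strand,
                    peptide=orf.peptide,
                    length_aa=orf.length_aa,
                    residue_counts=comp.residue_counts,
                    enriched_residue=comp.enriched_residue,
                    enrichment=comp.enrichment,
                    terminator=term,
                    leaderless_start=leaderless_start,
                )
            )
    hits.sort(key=lambda h: (h.upstream_of, h.orf_start))
    return hits


def biosynthesis_filter(feature: FeatureRecord) -> bool:
    """Convenience target filter: amino-acid biosynthesis / tRNA-ligase
    style products."""
    keywords = ("biosynthesis", "trna ligase", "trna synthetase", "synthase", "import")
    p = feature.product.lower()
    return any(k in p for k in keywords)
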