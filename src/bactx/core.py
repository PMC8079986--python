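"""Domain types, coordinate conventions, and readers/writers for FASTA,
GFF3 and bedGraph.

Coordinate convention: 0-based half-open everywhere internally; GFF3
1-based inclusive boundaries are converted only at I/O time.  On the
reverse strand "upstream" means larger coordinate; :func:`upstream_interval`
and :func:`tls_position` own that arithmetic so no downstream stage
re-derives it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

FORWARD = "+"
REVERSE = "-"
STRANDS = (FORWARD, REVERSE)

FEATURE_KINDS = ("CDS", "rRNA", "tRNA", "ncRNA", "leader_peptide")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when a domain object violates an invariant."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over A/C/G/T/N."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FeatureRecord:
    """A typed annotation feature with 0-based half-open coordinates."""

    feature_id: str
    kind: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"feature {self.feature_id}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(
                f"feature {self.feature_id}: unknown strand {self.strand!r}"
            )
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(
                f"feature {self.feature_id}: unknown kind {self.kind!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def frame_ok(self) -> bool:
        """CDS length divisible by 3 (flagged, never rejected)."""
        return self.kind != "CDS" or self.length % 3 == 0


def tls_position(feature: FeatureRecord) -> int:
    """Genome coordinate of the first base of the start codon."""
    return feature.start if feature.strand == FORWARD else feature.end - 1


def upstream_interval(anchor: int, length: int, strand: str, genome_length: int):
    """Half-open genome interval of `length` bases immediately upstream of
    `anchor` (anchor excluded), clipped at chromosome edges.

    Returns (start, end, truncated).
    """
    if strand == FORWARD:
        start, end = anchor - length, anchor
        truncated = start < 0
        return max(start, 0), max(end, 0), truncated
    start, end = anchor + 1, anchor + 1 + length
    truncated = end > genome_length
    return min(start, genome_length), min(end, genome_length), truncated


@dataclass
class GenomeAnnotation:
    """Genome sequence plus its typed feature repertoire."""

    sequence_id: str
    sequence: str
    features: list[FeatureRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    def validate(self) -> None:
        if len(self.sequence) == 0:
            raise ValidationError("empty genome sequence")
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise ValidationError(
                    f"feature {f.feature_id} extends past sequence end "
                    f"({f.end} > {n})"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def subsequence(self, start: int, end: int, strand: str = FORWARD) -> str:
        """Extract [start, end); reverse strand yields the reverse
        complement (5'->3' on that strand)."""
        s = self.sequence[start:end]
        return s if strand == FORWARD else revcomp(s)

    def cds(self) -> list[FeatureRecord]:
        return [f for f in self.features if f.kind == "CDS"]

    def with_features(self, features: Iterable[FeatureRecord]) -> "GenomeAnnotation":
        return GenomeAnnotation(self.sequence_id, self.sequence, list(features))


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds governing TSS detection, classification and the
    downstream accounting rules."""

    min_read_starts: int = 10
    percent_increase: float = 1000.0
    low_coverage_percent_increase: float = 100.0
    max_tss_tls_distance: int = 500
    leaderless_max_utr: int = 3
    bridging_reads_min: int = 5
    tls_scan_fraction: float = 0.25
    collapse_window: int = 2

    def __post_init__(self) -> None:
        if self.min_read_starts <= 0 or self.percent_increase <= 0:
            raise ValidationError("detection thresholds must be > 0")
        if self.low_coverage_percent_increase <= 0:
            raise ValidationError("low-coverage threshold must be > 0")
        if self.max_tss_tls_distance <= 0 or self.bridging_reads_min <= 0:
            raise ValidationError("distance/bridging thresholds must be > 0")
        if not self.leaderless_max_utr < self.max_tss_tls_distance:
            raise ValidationError("leaderless_max_utr must be < max_tss_tls_distance")
        if not 0 < self.tls_scan_fraction <= 1:
            raise ValidationError("tls_scan_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, record_id: str | None = None) -> GenomeAnnotation:
    """Read a genome sequence from FASTA.

    Sequences are uppercased and non-ACGTN letters are mapped to N with a
    logged warning.  Multi-record files require `record_id` to pick the
    chromosome; duplicate ids are a format error.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or invalid FASTA")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate record ids")
    if record_id is not None:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise FormatError(f"{path}: record {record_id!r} not found")
        rec = matches[0]
    elif len(records) == 1:
        rec = records[0]
    else:
        raise FormatError(
            f"{path}: multi-record FASTA ({len(records)} records); "
            "pass record_id to select the chromosome"
        )
    seq = str(rec.seq).upper()
    cleaned = []
    n_bad = 0
    for c in seq:
        if c in "ACGTN":
            cleaned.append(c)
        else:
            cleaned.append("N")
            n_bad += 1
    if n_bad:
        logger.warning("%s: %d non-ACGTN letters mapped to N", path, n_bad)
    return GenomeAnnotation(rec.id, "".join(cleaned))


def write_fasta(annotation: GenomeAnnotation, path: str | Path, width: int = 70) -> None:
    rec = SeqRecord(Seq(annotation.sequence), id=annotation.sequence_id, description="")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")
    # Biopython wraps at 60; that is fine for round-trips (sequence-level
    # identity is what the contract guarantees).


# ---------------------------------------------------------------------------
# GFF3

_KIND_ALIASES = {k.lower(): k for k in FEATURE_KINDS}


def read_gff3(path: str | Path) -> list[FeatureRecord]:
    """Parse CDS/rRNA/tRNA/ncRNA/leader_peptide features from GFF3.

    GFF3 1-based inclusive coordinates become 0-based half-open; other
    feature types (gene, region, ...) are skipped.
    """
    out: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # malformed attribute column etc.
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            kind = _KIND_ALIASES.get(feat.featuretype.lower())
            if kind is None:
                continue
            if feat.start > feat.end:
                raise FormatError(f"{path}:{lineno}: start > end")
            if feat.strand not in STRANDS:
                raise FormatError(
                    f"{path}:{lineno}: unknown strand symbol {feat.strand!r}"
                )
            fid = feat.attributes.get("ID", [None])[0] or f"feature_{lineno}"
            product = feat.attributes.get("product", [""])[0]
            out.append(
                FeatureRecord(
                    feature_id=fid,
                    kind=kind,
                    start=feat.start - 1,
                    end=feat.end,
                    strand=feat.strand,
                    product=product,
                )
            )
    return sorted(out, key=lambda f: (f.start, f.end))


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write features as GFF3 with deterministic ordering (start, then
    strand).  Converts internal half-open coordinates back to 1-based
    inclusive."""
    annotation.validate()
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            f"##sequence-region {annotation.sequence_id} 1 {len(annotation.sequence)}\n"
        )
        for f in sorted(annotation.features, key=lambda f: (f.start, f.strand)):
            attrs = f"ID={f.feature_id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                "\t".join(
                    [
                        annotation.sequence_id,
                        "bactx",
                        f.kind,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        "0" if f.kind == "CDS" else ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def load_annotation(fasta_path: str | Path, gff_path: str | Path) -> GenomeAnnotation:
    ann = read_fasta(fasta_path)
    ann = ann.with_features(read_gff3(gff_path))
    ann.validate()
    return ann


# ---------------------------------------------------------------------------
# bedGraph


def read_profile_bedgraph(path: str | Path, length: int) -> np.ndarray:
    """Read a 4-column bedGraph into a dense per-base integer vector.

    Coordinates are 0-based half-open; absent positions are 0 and
    overlapping intervals sum.
    """
    vec = np.zeros(length, dtype=np.int64)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                start, end, value = int(cols[1]), int(cols[2]), int(round(float(cols[3])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if start < 0 or end > length or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside [0, {length})"
                )
            vec[start:end] += value
    return vec


def write_profile_bedgraph(
    vector: np.ndarray, path: str | Path, sequence_id: str
) -> None:
    """Write a dense vector as run-length-encoded bedGraph, omitting zeros."""
    vec = np.asarray(vector)
    with open(path, "w") as fh:
        if len(vec) == 0:
            return
        boundaries = np.flatnonzero(np.diff(vec)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(vec)]])
        for s, e in zip(starts, ends):
            v = vec[s]
            if v != 0:
                fh.write(f"{sequence_id}\t{s}\t{e}\t{v}\n")
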