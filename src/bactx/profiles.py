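"""Strand-specific 5'-read-start and coverage vectors, profile pooling, and
per-gene transcription strength (rpkm)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from bactx.core import (
    FORWARD,
    FeatureRecord,
    GenomeAnnotation,
    ValidationError,
    read_profile_bedgraph,
    write_profile_bedgraph,
)


@dataclass
class StrandProfile:
    """Per-base, per-strand integer vectors of 5'-read-start counts and of
    whole-transcriptome coverage."""

    read_starts_fwd: np.ndarray
    read_starts_rev: np.ndarray
    coverage_fwd: np.ndarray
    coverage_rev: np.ndarray
    total_mapped_reads: int

    def __post_init__(self) -> None:
        vecs = [
            self.read_starts_fwd,
            self.read_starts_rev,
            self.coverage_fwd,
            self.coverage_rev,
        ]
        self.read_starts_fwd, self.read_starts_rev, self.coverage_fwd, self.coverage_rev = (
            np.asarray(v, dtype=np.int64) for v in vecs
        )
        lengths = {len(v) for v in self.vectors()}
        if len(lengths) != 1:
            raise ValidationError(f"profile vectors differ in length: {lengths}")
        for v in self.vectors():
            if (v < 0).any():
                raise ValidationError("negative counts in profile")
        peak = max(
            (int(v.max()) for v in (self.read_starts_fwd, self.read_starts_rev) if len(v)),
            default=0,
        )
        if self.total_mapped_reads < peak:
            raise ValidationError(
                "total_mapped_reads below maximal single-position read-start count"
            )

    def vectors(self) -> tuple[np.ndarray, ...]:
        return (
            self.read_starts_fwd,
            self.read_starts_rev,
            self.coverage_fwd,
            self.coverage_rev,
        )

    def __len__(self) -> int:
        return len(self.read_starts_fwd)

    @classmethod
    def zeros(cls, length: int, total_mapped_reads: int = 0) -> "StrandProfile":
        z = lambda: np.zeros(length, dtype=np.int64)
        return cls(z(), z(), z(), z(), total_mapped_reads)

    def read_starts(self, strand: str) -> np.ndarray:
        return self.read_starts_fwd if strand == FORWARD else self.read_starts_rev

    def coverage(self, strand: str) -> np.ndarray:
        return self.coverage_fwd if strand == FORWARD else self.coverage_rev


def combine_profiles(profiles: Sequence[StrandProfile]) -> StrandProfile:
    """Element-wise pooling of replicate profiles (counts and totals sum)."""
    if not profiles:
        raise ValidationError("no profiles to combine")
    lengths = {len(p) for p in profiles}
    if len(lengths) != 1:
        raise ValidationError(f"profiles differ in genome length: {lengths}")
    return StrandProfile(
        read_starts_fwd=sum(p.read_starts_fwd for p in profiles),
        read_starts_rev=sum(p.read_starts_rev for p in profiles),
        coverage_fwd=sum(p.coverage_fwd for p in profiles),
        coverage_rev=sum(p.coverage_rev for p in profiles),
        total_mapped_reads=sum(p.total_mapped_reads for p in profiles),
    )


def assigned_reads(
    feature: FeatureRecord, profile: StrandProfile, counting: str = "starts"
) -> float:
    """Reads assigned to a feature.

    `starts` (default): sum of strand-matched 5' read starts inside the
    feature interval.  `coverage`: mean strand-matched whole-transcriptome
    coverage over the feature, a cruder proxy retained as a config switch.
    """
    if counting == "starts":
        return float(profile.read_starts(feature.strand)[feature.start : feature.end].sum())
    if counting == "coverage":
        return float(profile.coverage(feature.strand)[feature.start : feature.end].mean())
    raise ValueError(f"unknown counting mode {counting!r}")


def rpkm(feature: FeatureRecord, profile: StrandProfile, counting: str = "starts") -> float:
    """Transcription strength: reads per kilobase per million mapped reads."""
    if feature.length == 0:
        raise ValidationError("zero-length feature")
    if profile.total_mapped_reads <= 0:
        raise ValidationError("total_mapped_reads must be > 0 for rpkm")
    reads = assigned_reads(feature, profile, counting)
    return reads * 1e9 / (profile.total_mapped_reads * feature.length)


def rpkm_table(
    annotation: GenomeAnnotation, profile: StrandProfile, counting: str = "starts"
) -> pd.DataFrame:
    """Per-CDS transcription strength table."""
    rows = []
    for f in annotation.cds():
        rows.append(
            {
                "feature_id": f.feature_id,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
                "reads": assigned_reads(f, profile, counting),
                "rpkm": rpkm(f, profile, counting),
            }
        )
    return pd.DataFrame(
        rows, columns=["feature_id", "start", "end", "strand", "reads", "rpkm"]
    )


def read_profile(
    directory: str | Path, length: int, total_mapped_reads: int | None = None
) -> StrandProfile:
    """Load a profile from a directory of four bedGraph files named
    starts_fwd/starts_rev/coverage_fwd/coverage_rev (.bedgraph)."""
    directory = Path(directory)
    vecs = {
        name: read_profile_bedgraph(directory / f"{name}.bedgraph", length)
        for name in ("starts_fwd", "starts_rev", "coverage_fwd", "coverage_rev")
    }
    if total_mapped_reads is None:
        total_mapped_reads = int(vecs["starts_fwd"].sum() + vecs["starts_rev"].sum())
    return StrandProfile(
        vecs["starts_fwd"],
        vecs["starts_rev"],
        vecs["coverage_fwd"],
        vecs["coverage_rev"],
        total_mapped_reads,
    )


def write_profile(profile: StrandProfile, directory: str | Path, sequence_id: str) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, vec in zip(
        ("starts_fwd", "starts_rev", "coverage_fwd", "coverage_rev"),
        profile.vectors(),
    ):
        write_profile_bedgraph(vec, directory / f"{name}.bedgraph", sequence_id)
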