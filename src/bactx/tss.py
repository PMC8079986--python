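"""TSS calling from the 5'-end read-start track, genomic-context
classification, and 5'-UTR statistics.

A position is a TSS candidate when it carries at least ``min_read_starts``
read starts and the increase relative to its strand-aware upstream
neighbor, ``100 * (n_i - n_up) / max(n_up, 1)``, reaches the configured
percent threshold (1000% in standard mode, 100% in low-coverage mode).
Adjacent candidates within a small window are collapsed to the strongest
stack, replacing the manual review of indistinct read stacks with an
explicit rule.

Classification precedence: (1) gene-associated (primary/secondary, TLS
within the distance cap downstream); (2) antisense (inside an
opposite-strand gene or its established 5'-UTR); (3) intragenic;
(4) intergenic.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from bactx.core import (
    FORWARD,
    REVERSE,
    DetectionConfig,
    GenomeAnnotation,
    ValidationError,
    tls_position,
)
from bactx.profiles import StrandProfile

TSS_CLASSES = ("primary", "secondary", "antisense", "intragenic", "intergenic")


@dataclass(frozen=True)
class TSSRecord:
    """A called transcription start site."""

    position: int
    strand: str
    read_start_count: int
    percent_increase: float
    tss_class: Optional[str] = None
    assigned_feature_id: Optional[str] = None
    utr_length: Optional[int] = None
    leaderless: Optional[bool] = None


def _candidates_one_strand(
    read_starts: np.ndarray, strand: str, min_starts: int, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Positions passing both thresholds on one strand, plus the percent
    increase at each.  The missing neighbor at the chromosome edge counts
    as 0."""
    rs = read_starts.astype(np.float64)
    prev = np.empty_like(rs)
    if strand == FORWARD:
        prev[0] = 0.0
        prev[1:] = rs[:-1]
    else:
        prev[-1] = 0.0
        prev[:-1] = rs[1:]
    increase = 100.0 * (rs - prev) / np.maximum(prev, 1.0)
    mask = (read_starts >= min_starts) & (increase >= threshold)
    positions = np.flatnonzero(mask)
    return positions, increase[positions]


def _collapse_stacks(
    positions: np.ndarray,
    increases: np.ndarray,
    read_starts: np.ndarray,
    strand: str,
    window: int,
) -> list[tuple[int, float]]:
    """Within runs of candidates spaced <= window apart, keep only the
    position with the maximal read-start count; ties go to the most
    upstream position (strand-aware)."""
    if len(positions) == 0:
        return []
    kept: list[tuple[int, float]] = []
    cluster: list[int] = [0]
    inc_by_idx = dict(zip(positions.tolist(), increases.tolist()))

    def flush(cluster_idx: list[int]) -> None:
        pos = positions[cluster_idx]
        counts = read_starts[pos]
        best = counts.max()
        tied = pos[counts == best]
        winner = int(tied.min() if strand == FORWARD else tied.max())
        kept.append((winner, inc_by_idx[winner]))

    for i in range(1, len(positions)):
        if positions[i] - positions[cluster[-1]] <= window:
            cluster.append(i)
        else:
            flush(cluster)
            cluster = [i]
    flush(cluster)
    return kept


def detect_tss(
    profile: StrandProfile, config: DetectionConfig, mode: str = "standard"
) -> list[TSSRecord]:
    """Call unclassified TSS candidates from the 5'-read-start track.

    ``mode`` selects the percent-increase threshold: ``standard`` uses
    ``config.percent_increase``, ``low_coverage`` uses
    ``config.low_coverage_percent_increase``.
    """
    if mode == "standard":
        threshold = config.percent_increase
    elif mode == "low_coverage":
        threshold = config.low_coverage_percent_increase
    else:
        raise ValueError(f"unknown detection mode {mode!r}")
    records: list[TSSRecord] = []
    for strand in (FORWARD, REVERSE):
        rs = profile.read_starts(strand)
        positions, increases = _candidates_one_strand(
            rs, strand, config.min_read_starts, threshold
        )
        for pos, inc in _collapse_stacks(
            positions, increases, rs, strand, config.collapse_window
        ):
            records.append(
                TSSRecord(
                    position=pos,
                    strand=strand,
                    read_start_count=int(rs[pos]),
                    percent_increase=float(inc),
                )
            )
    records.sort(key=lambda r: (r.position, r.strand))
    return records


def _distance_to_tls(pos: int, strand: str, tls: int) -> int:
    """Strand-aware distance from a TSS to a downstream TLS; negative when
    the TLS is upstream of the TSS."""
    return tls - pos if strand == FORWARD else pos - tls


def classify_tss(
    tss_list: Sequence[TSSRecord],
    annotation: GenomeAnnotation,
    config: DetectionConfig,
) -> list[TSSRecord]:
    """Assign a class, feature, UTR length and leaderless flag to each TSS.

    Two passes: pass 1 assigns gene-associated TSS (primary = strongest
    per feature, others secondary); pass 2 resolves the rest against
    opposite-strand genes and the 5'-UTRs established in pass 1.
    """
    genome_len = len(annotation.sequence)
    for t in tss_list:
        if not 0 <= t.position < genome_len:
            raise ValidationError(f"TSS position {t.position} outside genome")

    features = annotation.features
    by_strand = {s: [f for f in features if f.strand == s] for s in (FORWARD, REVERSE)}

    # Pass 1: gene association via nearest downstream TLS within the cap.
    assignments: dict[int, tuple[str, int]] = {}  # tss index -> (feature_id, utr)
    per_feature: dict[str, list[int]] = defaultdict(list)
    for i, t in enumerate(tss_list):
        best: tuple[int, str] | None = None
        for f in by_strand[t.strand]:
            d = _distance_to_tls(t.position, t.strand, tls_position(f))
            if 0 <= d <= config.max_tss_tls_distance:
                if best is None or d < best[0]:
                    best = (d, f.feature_id)
        if best is not None:
            assignments[i] = (best[1], best[0])
            per_feature[best[1]].append(i)

    classified: list[Optional[TSSRecord]] = [None] * len(tss_list)
    for fid, idxs in per_feature.items():
        # Primary: highest read-start count; ties go to the TSS closest to
        # the TLS (smallest UTR).
        ranked = sorted(
            idxs,
            key=lambda i: (-tss_list[i].read_start_count, assignments[i][1]),
        )
        for rank, i in enumerate(ranked):
            utr = assignments[i][1]
            classified[i] = replace(
                tss_list[i],
                tss_class="primary" if rank == 0 else "secondary",
                assigned_feature_id=fid,
                utr_length=utr,
                leaderless=utr <= config.leaderless_max_utr,
            )

    # 5'-UTR intervals established by primary TSS (half-open, genomic).
    utr_intervals: dict[str, list[tuple[int, int]]] = {FORWARD: [], REVERSE: []}
    for i, rec in enumerate(classified):
        if rec is None or rec.tss_class != "primary" or rec.utr_length == 0:
            continue
        if rec.strand == FORWARD:
            utr_intervals[FORWARD].append((rec.position, rec.position + rec.utr_length))
        else:
            utr_intervals[REVERSE].append(
                (rec.position - rec.utr_length + 1, rec.position + 1)
            )

    opposite = {FORWARD: REVERSE, REVERSE: FORWARD}

    # Pass 2: antisense / intragenic / intergenic.
    for i, t in enumerate(tss_list):
        if classified[i] is not None:
            continue
        opp = opposite[t.strand]
        in_opp_feature = any(
            f.start <= t.position < f.end for f in by_strand[opp]
        )
        in_opp_utr = any(s <= t.position < e for s, e in utr_intervals[opp])
        if in_opp_feature or in_opp_utr:
            cls = "antisense"
        elif any(f.start <= t.position < f.end for f in by_strand[t.strand]):
            cls = "intragenic"
        else:
            cls = "intergenic"
        classified[i] = replace(t, tss_class=cls)

    return [r for r in classified if r is not None]


@dataclass(frozen=True)
class UTRHistogram:
    """Binned 5'-UTR length distribution with a dedicated leaderless bin."""

    leaderless: int
    bins: tuple[tuple[int, int, int], ...]  # (low, high, count), inclusive bounds
    overflow: int

    @property
    def total(self) -> int:
        return self.leaderless + sum(c for _, _, c in self.bins) + self.overflow


def utr_histogram(
    tss_list: Sequence[TSSRecord], bin_width: int = 5, max_length: int = 500
) -> UTRHistogram:
    """Bin UTR lengths of primary/secondary TSS.

    Leaderless lengths (0-3) form their own category; the remainder falls
    into [4, 5] and then [k*w+1, (k+1)*w] bins; lengths beyond
    ``max_length`` pool into an overflow bin.
    """
    lengths = [
        t.utr_length
        for t in tss_list
        if t.tss_class in ("primary", "secondary")
    ]
    if any(u is None or u < 0 for u in lengths):
        raise ValidationError("primary/secondary TSS with missing or negative UTR")
    edges: list[tuple[int, int]] = [(4, bin_width)]
    hi = bin_width
    while hi < max_length:
        lo, hi = hi + 1, min(hi + bin_width, max_length)
        edges.append((lo, hi))
    counts = [0] * len(edges)
    leaderless = 0
    overflow = 0
    for u in lengths:
        if u <= 3:
            leaderless += 1
        elif u > max_length:
            overflow += 1
        else:
            for j, (lo, hi) in enumerate(edges):
                if lo <= u <= hi:
                    counts[j] += 1
                    break
    return UTRHistogram(
        leaderless=leaderless,
        bins=tuple((lo, hi, c) for (lo, hi), c in zip(edges, counts)),
        overflow=overflow,
    )


def tss_summary(tss_list: Sequence[TSSRecord]) -> dict[str, int]:
    """Per-class TSS counts plus the total."""
    counts = Counter(t.tss_class for t in tss_list)
    out = {cls: counts.get(cls, 0) for cls in TSS_CLASSES}
    out["total"] = len(tss_list)
    return out


def leaderless_fraction(tss_list: Sequence[TSSRecord]) -> Optional[float]:
    """Fraction of primary TSS flagged leaderless; None when no primary TSS."""
    primary = [t for t in tss_list if t.tss_class == "primary"]
    if not primary:
        return None
    return sum(1 for t in primary if t.leaderless) / len(primary)
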