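"""Promoter (-10/-35) and ribosome-binding-site motif discovery.

The search is a fixed-width ZOOPS (zero-or-one occurrence per sequence) EM
over anchor-relative placements: each input window is anchored at its 3'
end (the TSS for promoter runs, the TLS for RBS runs) and a placement is
only allowed when the gap between the motif's 3' end and the anchor falls
inside the configured spacer range.  The background is a 0-order model
estimated from the input; the best of several seeded random restarts by
log-likelihood wins.  Log-likelihood is asserted non-decreasing at every
EM step.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from bactx.core import FORWARD, GenomeAnnotation, ValidationError, revcomp, upstream_interval

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class MotifSearchConfig:
    """Window geometry and EM settings for the motif searches."""

    promoter_window: int = 70
    minus10_spacer_range: tuple[int, int] = (4, 9)
    minus35_spacer_range: tuple[int, int] = (15, 19)
    rbs_window: int = 20
    rbs_spacer_range: tuple[int, int] = (4, 9)
    rbs_utr_range: tuple[int, int] = (10, 150)
    width: int = 6
    em_restarts: int = 5
    max_iter: int = 200
    tol: float = 1e-6
    pseudocount: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (
            self.minus10_spacer_range,
            self.minus35_spacer_range,
            self.rbs_spacer_range,
            self.rbs_utr_range,
        ):
            if lo > hi:
                raise ValidationError("empty range in motif config")
        if self.promoter_window < self.width + self.minus10_spacer_range[1]:
            raise ValidationError("promoter window shorter than width + max spacer")
        if self.rbs_window < self.width + self.rbs_spacer_range[1]:
            raise ValidationError("rbs window shorter than width + max spacer")


@dataclass
class MotifModel:
    """Fixed-width motif with per-sequence placements and spacer stats."""

    width: int
    pfm: np.ndarray  # (width, 4) column-stochastic over ACGT
    placements: list[Optional[int]]  # best start offset per sequence, or None
    spacer_distribution: dict[int, int]  # anchor distance -> count
    consensus: str
    log_likelihood: float

    def __post_init__(self) -> None:
        col_sums = self.pfm.sum(axis=1)
        if not np.allclose(col_sums, 1.0, atol=1e-9):
            raise ValidationError("pfm columns must sum to 1")
        if len(self.consensus) != self.width:
            raise ValidationError("consensus length must equal width")


@dataclass(frozen=True)
class SpacerStats:
    n: int
    mean: Optional[float]
    min: Optional[int]
    max: Optional[int]
    histogram: dict[int, int]


@dataclass(frozen=True)
class Window:
    """An anchor-relative upstream sequence window (5'->3' on the anchor's
    strand)."""

    sequence: str
    truncated: bool


def extract_windows(
    anchors: Sequence[tuple[int, str]],
    genome: GenomeAnnotation,
    window: int,
) -> list[Window]:
    """Sequences immediately upstream of each (position, strand) anchor,
    5'->3' on the anchor's strand; edge-truncated windows are flagged."""
    n = len(genome.sequence)
    out = []
    for pos, strand in anchors:
        s, e, truncated = upstream_interval(pos, window, strand, n)
        out.append(Window(genome.subsequence(s, e, strand), truncated))
    return out


def _encode(seq: str) -> Optional[np.ndarray]:
    """Integer-encode an ACGT string; None when it contains anything else
    (windows with N are skipped by the scanners)."""
    try:
        return np.array([_BASE_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError:
        return None


def _allowed_offsets(seq_len: int, width: int, spacer_range: tuple[int, int]) -> list[int]:
    """Start offsets whose motif-end-to-anchor gap lies in spacer_range.
    The anchor sits immediately after the last window base."""
    lo, hi = spacer_range
    return [
        seq_len - width - s for s in range(lo, hi + 1) if seq_len - width - s >= 0
    ]


def _consensus_from_pfm(pfm: np.ndarray, threshold: float = 0.5) -> str:
    letters = []
    for col in pfm:
        i = int(np.argmax(col))
        letters.append(BASES[i] if col[i] >= threshold else "n")
    return "".join(letters)


def em_find_motif(
    sequences: Sequence[str],
    width: int,
    spacer_range: tuple[int, int],
    config: MotifSearchConfig | None = None,
) -> MotifModel:
    """ZOOPS EM motif search over anchor-constrained placements.

    Sequences containing non-ACGT letters get placement None and do not
    contribute to the model.  Deterministic for a fixed config seed,
    independent of input order (the RNG is seeded from the config alone).
    """
    config = config or MotifSearchConfig()
    if len(sequences) < 10:
        raise ValidationError(f"need >= 10 sequences, got {len(sequences)}")
    too_short = [
        i for i, s in enumerate(sequences) if len(s) < width + spacer_range[1]
    ]
    if too_short:
        raise ValidationError(
            f"sequences too short for width {width} + spacer {spacer_range[1]}: "
            f"indices {too_short}"
        )

    encoded = [_encode(s) for s in sequences]
    usable = [i for i, e in enumerate(encoded) if e is not None]
    if len(usable) < 10:
        raise ValidationError("fewer than 10 N-free sequences")

    # 0-order background from the input.
    all_bases = np.concatenate([encoded[i] for i in usable])
    bg = np.bincount(all_bases, minlength=4).astype(np.float64)
    bg = (bg + 1.0) / (bg.sum() + 4.0)

    offsets = {
        i: _allowed_offsets(len(sequences[i]), width, spacer_range) for i in usable
    }
    # Per-sequence stack of candidate motif windows, shape (n_offsets, width).
    windows = {
        i: np.stack([encoded[i][o : o + width] for o in offsets[i]]) for i in usable
    }
    bg_scores = {i: bg[windows[i]].prod(axis=1) for i in usable}

    rng = np.random.default_rng(config.seed)
    best: tuple[float, np.ndarray, float, dict[int, np.ndarray]] | None = None

    for _ in range(max(1, config.em_restarts)):
        pfm = rng.dirichlet(np.full(4, 2.0), size=width)
        lam = 0.5
        prev_obj = -np.inf
        ll = -np.inf
        posteriors: dict[int, np.ndarray] = {}
        for _ in range(config.max_iter):
            # E-step.  The objective this EM ascends is the data
            # log-likelihood plus the Dirichlet(1 + pseudocount) log-prior
            # on the pfm (the pseudocounted M-step is its exact maximizer);
            # monotonicity is asserted on that objective.
            ll = 0.0
            counts = np.full((width, 4), config.pseudocount)
            lam_acc = 0.0
            for i in usable:
                motif_scores = pfm[np.arange(width), windows[i]].prod(axis=1)
                ratio = motif_scores / bg_scores[i]
                J = len(offsets[i])
                weights = (lam / J) * ratio
                denom = (1.0 - lam) + weights.sum()
                ll += float(np.log(denom))
                z = weights / denom  # posterior per offset; 1-sum(z) = absent
                posteriors[i] = z
                lam_acc += z.sum()
                for j, w in enumerate(windows[i]):
                    counts[np.arange(width), w] += z[j]
            obj = ll + config.pseudocount * float(np.log(pfm).sum())
            if obj + 1e-9 < prev_obj:
                raise AssertionError("EM objective decreased")
            converged = obj - prev_obj < config.tol
            prev_obj = obj
            # M-step
            pfm = counts / counts.sum(axis=1, keepdims=True)
            lam = min(max(lam_acc / len(usable), 1e-6), 1 - 1e-6)
            if converged:
                break
        if best is None or ll > best[0]:
            best = (ll, pfm.copy(), lam, {i: z.copy() for i, z in posteriors.items()})

    assert best is not None
    ll_best, pfm, lam, posteriors = best

    placements: list[Optional[int]] = [None] * len(sequences)
    spacers: Counter[int] = Counter()
    for i in usable:
        z = posteriors[i]
        j = int(np.argmax(z))
        if z[j] >= 0.5:
            off = offsets[i][j]
            placements[i] = off
            spacers[len(sequences[i]) - (off + width)] += 1

    return MotifModel(
        width=width,
        pfm=pfm,
        placements=placements,
        spacer_distribution=dict(sorted(spacers.items())),
        consensus=_consensus_from_pfm(pfm),
        log_likelihood=float(ll_best),
    )


def match_pattern_fraction(
    sequences: Sequence[str],
    pattern: str,
    spacer_range: tuple[int, int],
) -> tuple[float, list[Optional[int]]]:
    """Fraction of sequences carrying an exact match to `pattern` ('n'
    matches any base) at an anchor distance inside `spacer_range`, plus the
    per-sequence hit offset (smallest spacer wins)."""
    if not pattern:
        raise ValidationError("empty pattern")
    width = len(pattern)
    hits: list[Optional[int]] = []
    for seq in sequences:
        found = None
        for off in sorted(
            _allowed_offsets(len(seq), width, spacer_range), reverse=True
        ):  # largest offset = smallest spacer first
            window = seq[off : off + width]
            if len(window) == width and all(
                p == "n" or p == c for p, c in zip(pattern, window)
            ):
                found = off
                break
        hits.append(found)
    n_hit = sum(1 for h in hits if h is not None)
    fraction = n_hit / len(sequences) if sequences else 0.0
    return fraction, hits


def spacer_stats(model: MotifModel) -> SpacerStats:
    """Mean/range/histogram of anchor distances over placed sequences."""
    hist = dict(model.spacer_distribution)
    n = sum(hist.values())
    if n == 0:
        return SpacerStats(n=0, mean=None, min=None, max=None, histogram={})
    total = sum(d * c for d, c in hist.items())
    return SpacerStats(
        n=n,
        mean=total / n,
        min=min(hist),
        max=max(hist),
        histogram=hist,
    )


@dataclass
class RBSResult:
    model: Optional[MotifModel]
    placement_fraction: Optional[float]
    spacer_mean: Optional[float]
    n_sequences: int
    insufficient_data: bool = False


def find_rbs(
    annotation: GenomeAnnotation,
    classified_tss,
    config: MotifSearchConfig | None = None,
) -> RBSResult:
    """RBS motif search over CDS with a primary TSS and a UTR inside the
    configured range; windows are taken immediately upstream of each TLS."""
    from bactx.core import tls_position

    config = config or MotifSearchConfig()
    lo, hi = config.rbs_utr_range
    eligible_ids = {
        t.assigned_feature_id
        for t in classified_tss
        if t.tss_class == "primary" and t.utr_length is not None and lo <= t.utr_length <= hi
    }
    cds = [f for f in annotation.cds() if f.feature_id in eligible_ids]
    if len(cds) < 10:
        return RBSResult(None, None, None, len(cds), insufficient_data=True)
    anchors = [(tls_position(f), f.strand) for f in cds]
    windows = extract_windows(anchors, annotation, config.rbs_window)
    seqs = [w.sequence for w in windows if not w.truncated]
    model = em_find_motif(seqs, config.width, config.rbs_spacer_range, config)
    placed = sum(1 for p in model.placements if p is not None)
    stats = spacer_stats(model)
    return RBSResult(
        model=model,
        placement_fraction=placed / len(seqs),
        spacer_mean=stats.mean,
        n_sequences=len(seqs),
    )


def longest_complement(seq_a: str, seq_b: str) -> int:
    """Length of the longest contiguous substring of `seq_a` that is the
    reverse complement of a substring of `seq_b` (both given 5'->3'; U is
    treated as T)."""
    a = seq_a.upper().replace("U", "T")
    b = revcomp(seq_b.upper().replace("U", "T"))
    if not a or not b:
        return 0
    # Longest common substring of a and revcomp(b), classic DP.
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best
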