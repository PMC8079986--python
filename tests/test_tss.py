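"""TSS detection against an exhaustive per-position oracle, classification
rule fixtures, and UTR statistics."""

import numpy as np
import pytest

from bactx.core import DetectionConfig, FeatureRecord, GenomeAnnotation, ValidationError
from bactx.tss import (
    TSSRecord,
    classify_tss,
    detect_tss,
    leaderless_fraction,
    tss_summary,
    utr_histogram,
)
from conftest import make_profile


def oracle_detect(profile, config, mode="standard"):
    """Independent brute-force reimplementation: per-position threshold scan
    followed by the same +/-window collapse rule."""
    threshold = (
        config.percent_increase
        if mode == "standard"
        else config.low_coverage_percent_increase
    )
    out = []
    for strand in "+-":
        rs = profile.read_starts(strand)
        cands = []
        for i in range(len(rs)):
            up = i - 1 if strand == "+" else i + 1
            prev = rs[up] if 0 <= up < len(rs) else 0
            inc = 100.0 * (rs[i] - prev) / max(prev, 1)
            if rs[i] >= config.min_read_starts and inc >= threshold:
                cands.append(i)
        # collapse clusters chained at distance <= window
        clusters = []
        for i in cands:
            if clusters and i - clusters[-1][-1] <= config.collapse_window:
                clusters[-1].append(i)
            else:
                clusters.append([i])
        for cl in clusters:
            best = max(rs[i] for i in cl)
            tied = [i for i in cl if rs[i] == best]
            out.append((min(tied) if strand == "+" else max(tied), strand))
    return sorted(out)


class TestDetect:
    def test_nine_reads_not_called(self, config):
        prof = make_profile(100, starts_fwd=[(50, 9)])
        assert detect_tss(prof, config) == []

    def test_ten_reads_called_at_zero_background(self, config):
        prof = make_profile(100, starts_fwd=[(50, 10)])
        [rec] = detect_tss(prof, config)
        assert rec.position == 50
        assert rec.read_start_count == 10
        assert rec.percent_increase == pytest.approx(1000.0)

    def test_percent_increase_arithmetic(self, config):
        # 50 starts over an upstream neighbor of 4: (50-4)/4 = 1150% >= 1000%.
        prof = make_profile(100, starts_fwd=[(49, 4), (50, 50)])
        positions = [r.position for r in detect_tss(prof, config)]
        assert 50 in positions

    def test_increase_below_threshold_rejected(self, config):
        # 30 over 4: 650% < 1000%.
        prof = make_profile(100, starts_fwd=[(49, 4), (50, 30)])
        assert [r.position for r in detect_tss(prof, config)] == []

    def test_low_coverage_mode(self, config):
        prof = make_profile(100, starts_fwd=[(49, 4), (50, 30)])
        recs = detect_tss(prof, config, mode="low_coverage")
        assert [r.position for r in recs] == [50]

    def test_all_zero_profile_empty(self, config):
        assert detect_tss(make_profile(500), config) == []

    def test_reverse_strand_upstream_neighbor(self, config):
        # On the reverse strand the upstream neighbor is position i+1.
        prof = make_profile(100, starts_rev=[(50, 50), (51, 4)])
        recs = detect_tss(prof, config)
        assert [(r.position, r.strand) for r in recs] == [(50, "-")]
        # 50 is blocked by its high upstream neighbor; 51 qualifies itself
        prof2 = make_profile(100, starts_rev=[(50, 50), (51, 40)])
        assert [(r.position, r.strand) for r in detect_tss(prof2, config)] == [(51, "-")]

    def test_chromosome_edge_neighbor_is_zero(self, config):
        prof = make_profile(100, starts_fwd=[(0, 10)], starts_rev=[(99, 10)])
        recs = detect_tss(prof, config)
        assert {(r.position, r.strand) for r in recs} == {(0, "+"), (99, "-")}

    def test_stack_collapse_keeps_strongest(self, config):
        prof = make_profile(100, starts_fwd=[(50, 20), (52, 30)])
        [rec] = detect_tss(prof, config)
        assert rec.position == 52

    def test_stack_collapse_tie_most_upstream(self, config):
        prof = make_profile(100, starts_fwd=[(50, 20), (52, 20)])
        [rec] = detect_tss(prof, config)
        assert rec.position == 50

    def test_three_planted_stacks(self, config):
        prof = make_profile(1000, starts_fwd=[(100, 15), (500, 50)], starts_rev=[(800, 12)])
        recs = detect_tss(prof, config)
        assert [(r.position, r.strand) for r in recs] == [
            (100, "+"),
            (500, "+"),
            (800, "-"),
        ]
        assert oracle_detect(prof, config) == [(100, "+"), (500, "+"), (800, "-")]

    @pytest.mark.parametrize("mode", ["standard", "low_coverage"])
    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random(self, config, mode, seed):
        rng = np.random.default_rng(seed)
        length = 2000
        prof = make_profile(length)
        prof.read_starts_fwd[:] = rng.poisson(0.5, length)
        prof.read_starts_rev[:] = rng.poisson(0.5, length)
        for _ in range(15):  # plant some stacks
            prof.read_starts_fwd[rng.integers(0, length)] += rng.integers(5, 60)
            prof.read_starts_rev[rng.integers(0, length)] += rng.integers(5, 60)
        prof.total_mapped_reads = int(
            prof.read_starts_fwd.sum() + prof.read_starts_rev.sum()
        )
        got = sorted((r.position, r.strand) for r in detect_tss(prof, config, mode))
        assert got == oracle_detect(prof, config, mode)


def _ann(features, length=3000):
    return GenomeAnnotation("chr", "A" * length, features)


def _tss(pos, strand="+", count=20):
    return TSSRecord(position=pos, strand=strand, read_start_count=count, percent_increase=2000.0)


class TestClassify:
    def test_primary_with_utr(self, config):
        ann = _ann([FeatureRecord("g", "CDS", 500, 800, "+")])
        [rec] = classify_tss([_tss(440)], ann, config)
        assert rec.tss_class == "primary"
        assert rec.assigned_feature_id == "g"
        assert rec.utr_length == 60
        assert rec.leaderless is False

    def test_tss_at_tls_is_leaderless(self, config):
        ann = _ann([FeatureRecord("g", "CDS", 500, 800, "+")])
        [rec] = classify_tss([_tss(500)], ann, config)
        assert rec.utr_length == 0
        assert rec.leaderless is True

    def test_leaderless_boundary_3_vs_4(self, config):
        ann = _ann([FeatureRecord("g", "CDS", 500, 800, "+")])
        [at3] = classify_tss([_tss(497)], ann, config)
        [at4] = classify_tss([_tss(496)], ann, config)
        assert at3.utr_length == 3 and at3.leaderless is True
        assert at4.utr_length == 4 and at4.leaderless is False

    def test_distance_boundary_500_vs_501(self, config):
        ann = _ann([FeatureRecord("g", "CDS", 1000, 1300, "+")])
        [at500] = classify_tss([_tss(500)], ann, config)
        [at501] = classify_tss([_tss(499)], ann, config)
        assert at500.tss_class == "primary"
        assert at501.tss_class == "intergenic"

    def test_secondary_ranking_by_count(self, config):
        ann = _ann([FeatureRecord("g", "CDS", 500, 800, "+")])
        recs = classify_tss([_tss(450, count=10), _tss(400, count=90)], ann, config)
        by_pos = {r.position: r for r in recs}
        assert by_pos[400].tss_class == "primary"
        assert by_pos[450].tss_class == "secondary"
        assert by_pos[450].utr_length == 50

    def test_tie_on_count_closest_wins(self, config):
        ann = _ann([FeatureRecord("g", "CDS", 500, 800, "+")])
        recs = classify_tss([_tss(400, count=30), _tss(450, count=30)], ann, config)
        by_pos = {r.position: r for r in recs}
        assert by_pos[450].tss_class == "primary"
        assert by_pos[400].tss_class == "secondary"

    def test_antisense_inside_opposite_feature(self, config):
        ann = _ann([FeatureRecord("g", "CDS", 500, 800, "-")])
        [rec] = classify_tss([_tss(600, "+")], ann, config)
        assert rec.tss_class == "antisense"

    def test_antisense_in_opposite_utr(self, config):
        # Forward gene with a primary TSS 100 nt upstream establishes a UTR;
        # a reverse TSS inside that UTR is antisense, not intergenic.
        ann = _ann([FeatureRecord("g", "CDS", 500, 800, "+")])
        recs = classify_tss([_tss(400, "+"), _tss(450, "-")], ann, config)
        by_strand = {r.strand: r for r in recs}
        assert by_strand["+"].tss_class == "primary"
        assert by_strand["-"].tss_class == "antisense"

    def test_intragenic(self, config):
        ann = _ann([FeatureRecord("g", "CDS", 500, 2000, "+")])
        [rec] = classify_tss([_tss(1000)], ann, config)
        assert rec.tss_class == "intragenic"

    def test_intergenic(self, config):
        ann = _ann([FeatureRecord("g", "CDS", 2000, 2300, "+")])
        [rec] = classify_tss([_tss(100)], ann, config)
        assert rec.tss_class == "intergenic"

    def test_reverse_strand_assignment(self, config):
        ann = _ann([FeatureRecord("g", "CDS", 500, 800, "-")])
        [rec] = classify_tss([_tss(860, "-")], ann, config)
        assert rec.tss_class == "primary"
        assert rec.utr_length == 61  # 860 - 799

    def test_nearest_tls_wins(self, config):
        ann = _ann(
            [
                FeatureRecord("near", "CDS", 600, 900, "+"),
                FeatureRecord("far", "CDS", 1000, 1300, "+"),
            ]
        )
        [rec] = classify_tss([_tss(550)], ann, config)
        assert rec.assigned_feature_id == "near"

    def test_position_outside_genome_errors(self, config):
        ann = _ann([])
        with pytest.raises(ValidationError):
            classify_tss([_tss(5000)], ann, config)

    def test_permutation_invariance(self, config, rng):
        ann = _ann(
            [
                FeatureRecord("a", "CDS", 500, 800, "+"),
                FeatureRecord("b", "CDS", 1200, 1600, "-"),
                FeatureRecord("c", "CDS", 2000, 2400, "+"),
            ]
        )
        tss = [
            _tss(450, "+", 40),
            _tss(420, "+", 10),
            _tss(1700, "-", 25),
            _tss(900, "+", 15),
            _tss(2100, "-", 12),
        ]
        ref = sorted(
            classify_tss(tss, ann, config), key=lambda r: (r.position, r.strand)
        )
        for _ in range(5):
            perm = list(rng.permutation(len(tss)))
            got = sorted(
                classify_tss([tss[i] for i in perm], ann, config),
                key=lambda r: (r.position, r.strand),
            )
            assert got == ref

    def test_exactly_one_primary_per_assigned_feature(self, config, rng):
        ann = _ann(
            [
                FeatureRecord("a", "CDS", 500, 800, "+"),
                FeatureRecord("b", "CDS", 1200, 1600, "+"),
            ]
        )
        tss = [_tss(int(p), "+", int(c)) for p, c in
               zip(rng.integers(300, 1200, 30), rng.integers(10, 99, 30))]
        tss = [t for i, t in enumerate(tss)
               if t.position not in {u.position for u in tss[:i]}]
        recs = classify_tss(tss, ann, config)
        for fid in ("a", "b"):
            assigned = [r for r in recs if r.assigned_feature_id == fid]
            primaries = [r for r in assigned if r.tss_class == "primary"]
            if assigned:
                assert len(primaries) == 1


class TestHistogramAndSummary:
    def _classified(self, utrs):
        return [
            TSSRecord(
                position=i * 10,
                strand="+",
                read_start_count=20,
                percent_increase=2000.0,
                tss_class="primary",
                assigned_feature_id=f"g{i}",
                utr_length=u,
                leaderless=u <= 3,
            )
            for i, u in enumerate(utrs)
        ]

    def test_direct_binning(self):
        h = utr_histogram(self._classified([0, 2, 7, 12]))
        assert h.leaderless == 2
        bins = {(lo, hi): c for lo, hi, c in h.bins}
        assert bins[(6, 10)] == 1
        assert bins[(11, 15)] == 1
        assert h.total == 4

    def test_empty_input(self):
        h = utr_histogram([])
        assert h.leaderless == 0 and h.overflow == 0 and h.total == 0

    def test_overflow_pooling(self):
        h = utr_histogram(self._classified([600]))
        assert h.overflow == 1

    def test_thousand_lengths_vs_independent_tally(self, rng):
        utrs = [int(u) for u in rng.integers(0, 550, size=1000)]
        h = utr_histogram(self._classified(utrs))
        assert h.leaderless == sum(1 for u in utrs if u <= 3)
        assert h.overflow == sum(1 for u in utrs if u > 500)
        for lo, hi, c in h.bins:
            assert c == sum(1 for u in utrs if lo <= u <= hi)
        assert h.total == 1000

    def test_summary_counts(self):
        recs = self._classified([0, 5, 9]) + [
            TSSRecord(900, "+", 15, 2000.0, tss_class="antisense")
        ]
        s = tss_summary(recs)
        assert s == {
            "primary": 3,
            "secondary": 0,
            "antisense": 1,
            "intragenic": 0,
            "intergenic": 0,
            "total": 4,
        }

    def test_summary_empty(self):
        s = tss_summary([])
        assert s["total"] == 0 and all(s[k] == 0 for k in s)

    def test_leaderless_fraction(self):
        recs = self._classified([0, 2, 50, 100])
        assert leaderless_fraction(recs) == 0.5
        assert leaderless_fraction([]) is None
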