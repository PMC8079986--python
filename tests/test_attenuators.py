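"""Leader-peptide ORF discovery, residue enrichment, and terminator
heuristics — each checked against brute-force oracles."""

import numpy as np
import pytest

from bactx.attenuators import (
    AttenuatorConfig,
    find_leader_orfs,
    find_terminator,
    residue_composition,
    scan_attenuators,
    translate_orf,
)
from bactx.core import FeatureRecord, GenomeAnnotation, ValidationError, revcomp
from bactx.simulate import DEFAULT_LEADER_PEPTIDES, encode_peptide, random_dna
from bactx.tss import TSSRecord


def oracle_orfs(seq, cfg):
    """Brute force: every (start-codon, in-frame stop) pair fully inside the
    leader, forward strand only."""
    starts, stops = ("ATG", "GTG", "TTG"), ("TAA", "TAG", "TGA")
    out = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] not in starts:
            continue
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in stops:
                if cfg.min_length_aa <= (j - i) // 3 <= cfg.max_length_aa:
                    out.append((i, j + 3))
                break
    return out


def oracle_terminator(window, cfg):
    """O(n^3) enumeration over all substring pairs."""
    w = window.upper()
    hits = []
    for i in range(len(w)):
        for stem in range(cfg.min_stem, len(w)):
            arm = w[i : i + stem]
            if len(arm) < stem:
                break
            for loop in range(cfg.loop_range[0], cfg.loop_range[1] + 1):
                j = i + stem + loop
                if j + stem > len(w):
                    continue
                if w[j : j + stem] == revcomp(arm):
                    u = w[j + stem : j + stem + cfg.u_window].count("T")
                    hits.append((stem, loop, u, i, u >= cfg.min_u))
    if not hits:
        return None
    return min(hits, key=lambda h: (not h[4], -h[0], h[3]))


class TestLeaderOrfs:
    def test_twelve_aa_leader(self, rng):
        dna = encode_peptide(rng, "MRAVRLLLSEPR")
        leader = "GCGC" + dna + "GCGCGC"
        orfs = find_leader_orfs(leader)
        assert any(o.peptide == "MRAVRLLLSEPR" and o.length_aa == 12 for o in orfs)

    def test_no_start_codon_empty(self):
        assert find_leader_orfs("GCGCCC" * 40) == []

    def test_gtg_start_translates_as_m(self):
        dna = "GTG" + "CTG" * 9 + "TAA"
        [orf] = find_leader_orfs("CC" + dna + "CC")
        assert orf.peptide.startswith("M")
        assert orf.peptide == "M" + "L" * 9

    def test_orf_with_n_skipped(self, caplog):
        dna = "ATG" + "CTG" * 4 + "CNG" + "CTG" * 4 + "TAA"
        with caplog.at_level("WARNING"):
            assert find_leader_orfs("CC" + dna + "CC") == []

    def test_brute_force_oracle_500_random(self, rng):
        cfg = AttenuatorConfig()
        for _ in range(500):
            leader = random_dna(rng, int(rng.integers(60, 200)), 0.6)
            got = [(o.start, o.end) for o in find_leader_orfs(leader, cfg)]
            assert got == oracle_orfs(leader, cfg)


class TestResidueComposition:
    @pytest.mark.parametrize(
        "peptide,length,residue,count",
        [
            ("MRFGLLLLSCRGEGL", 15, "L", 5),
            ("MRAVRLLLSEPR", 12, "L", 3),
            ("MFAHSTRNWWWTAHPAAH", 18, "W", 3),
            ("MMTRTCTQLWRAA", 13, "W", 1),
            ("MNVIGRNIFATARATSSPVAAA", 22, "A", 6),
            ("MRTRILVLGKRVG", 13, "R", 3),
            ("MSTTSDRTPATEATTTPGARCMCRRMCAF", 29, "T", 7),
            ("MKRVRPFLETTPGFVPAR", 18, "T", 2),
        ],
    )
    def test_reference_leader_peptides(self, peptide, length, residue, count):
        comp = residue_composition(peptide)
        assert comp.length == length
        assert comp.residue_counts.get(residue, 0) == count

    def test_enrichment_closed_form(self):
        comp = residue_composition("M" * 10)
        assert comp.enriched_residue == "M"
        assert comp.enrichment == pytest.approx(20.0)

    def test_counts_sum_to_length(self, rng):
        for _ in range(20):
            pep = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=15))
            comp = residue_composition(pep)
            assert sum(comp.residue_counts.values()) == comp.length == 15

    def test_tie_resolves_alphabetically(self):
        comp = residue_composition("MAALL")
        assert comp.enriched_residue == "A"

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValidationError):
            residue_composition("MXZ")


class TestTerminator:
    cfg = AttenuatorConfig()

    def test_constructed_hairpin(self):
        stem = "GCCGGCC"
        window = "CC" + stem + "AAAT" + revcomp(stem) + "TTTTTT" + "ACGA"
        hit = find_terminator(window, self.cfg)
        assert hit is not None
        assert hit.stem_length == 7
        assert hit.u_stretch_length >= 3
        assert hit.canonical

    def test_homopolymer_no_hit(self):
        assert find_terminator("A" * 80, self.cfg) is None

    def test_hairpin_without_u_is_noncanonical(self):
        stem = "GCCGGCC"
        window = "AA" + stem + "AAAT" + revcomp(stem) + "GAGCAG" + "ACGA"
        hit = find_terminator(window, self.cfg)
        assert hit is not None
        assert hit.u_stretch_length < 3
        assert not hit.canonical

    def test_window_too_short_no_hit(self):
        assert find_terminator("ACGT" * 3, self.cfg) is None

    def test_exhaustive_oracle_100_random(self, rng):
        n_with_hit = 0
        for trial in range(100):
            window = random_dna(rng, int(rng.integers(30, 120)), 0.7)
            if trial % 3 == 0:  # plant a hairpin in a third of the trials
                stem = random_dna(rng, int(rng.integers(6, 10)), 0.8)
                insert = stem + random_dna(rng, 4, 0.5) + revcomp(stem) + "TTTTT"
                pos = int(rng.integers(0, max(len(window) - len(insert), 1)))
                window = window[:pos] + insert + window[pos + len(insert):]
            got = find_terminator(window, self.cfg)
            expected = oracle_terminator(window, self.cfg)
            if expected is None:
                assert got is None
            else:
                n_with_hit += 1
                stem, loop, u, i, canonical = expected
                assert (got.stem_length, got.loop_length, got.position) == (stem, loop, i)
                assert got.canonical == canonical
        assert n_with_hit >= 20  # the planted cases must actually exercise hits


class TestScan:
    def _fixture(self, peptide, rng, with_tss=True):
        orf_dna = encode_peptide(rng, peptide)
        stem = random_dna(rng, 8, 0.8)
        leader = orf_dna + "GC" + stem + "GCAA" + revcomp(stem) + "TTTTTTTT" + "GCGC"
        gene = "ATG" + "GCC" * 40 + "TGA"
        pad = random_dna(rng, 300, 0.72)
        seq = pad + leader + gene + random_dna(rng, 50, 0.72)
        gene_start = len(pad) + len(leader)
        ann = GenomeAnnotation(
            "c", seq, [FeatureRecord("target", "CDS", gene_start, gene_start + len(gene), "+")]
        )
        tss = []
        if with_tss:
            tss = [
                TSSRecord(len(pad), "+", 50, 5000.0, tss_class="primary",
                          assigned_feature_id="target", utr_length=len(leader),
                          leaderless=False)
            ]
        return ann, tss, peptide

    def test_ilvl_style_leader(self, rng):
        ann, tss, peptide = self._fixture("MRTRILVLGKRVG", rng)
        hits = scan_attenuators(ann, tss)
        match = [h for h in hits if h.peptide == peptide]
        assert len(match) == 1
        assert match[0].length_aa == 13
        assert match[0].terminator is not None and match[0].terminator.canonical
        assert match[0].leaderless_start

    def test_no_small_orf_no_hit(self):
        ann = GenomeAnnotation(
            "c",
            "GC" * 300 + "ATG" + "GCC" * 40 + "TGA" + "GC" * 25,
            [FeatureRecord("t", "CDS", 600, 726, "+")],
        )
        assert scan_attenuators(ann, []) == []

    def test_enrichment_threshold_filters(self, rng):
        # A peptide with no residue reaching 3x uniform enrichment.
        ann, tss, _ = self._fixture("MACDEFGHIKLNPQRSVWYT", rng)
        hits = scan_attenuators(ann, tss)
        assert all(h.peptide != "MACDEFGHIKLNPQRSVWYT" for h in hits)

    def test_iteration_order_independence(self, rng):
        data_rng = np.random.default_rng(0)
        ann, tss, _ = self._fixture("MRTRILVLGKRVG", data_rng)
        a = scan_attenuators(ann, tss)
        b = scan_attenuators(ann, tss)
        assert a == b

    def test_all_reference_peptides_recovered(self, rng):
        """Planted synonymous re-encodings of every reference peptide are
        recovered with correct lengths and residue counts."""
        from bactx.simulate import SimulationConfig, generate
        from bactx.core import DetectionConfig
        from bactx.tss import classify_tss, detect_tss

        data = generate(SimulationConfig(seed=23, background_rate=0.0))
        det = DetectionConfig()
        classified = classify_tss(detect_tss(data.profile, det), data.annotation, det)
        hits = scan_attenuators(data.annotation, classified)
        by_target = {(h.upstream_of, h.peptide) for h in hits}
        assert len(data.truth.attenuators) == 8
        for truth in data.truth.attenuators:
            assert (truth.target_gene, truth.peptide) in by_target
            [hit] = [
                h for h in hits
                if h.upstream_of == truth.target_gene and h.peptide == truth.peptide
            ]
            assert hit.length_aa == len(truth.peptide)
            comp = residue_composition(truth.peptide)
            assert hit.residue_counts == comp.residue_counts


class TestTranslate:
    def test_translate_simple(self):
        assert translate_orf("ATGCTGCTGTAA") == "MLL"

    def test_ttg_forced_to_m(self):
        assert translate_orf("TTGCTGTAA") == "ML"
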