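"""Synthetic genomes with planted ground truth.

Generates a high-GC bacterial genome with planted promoters (-10/-35 with
configurable spacer laws), RBS motifs, a configurable leaderless fraction,
operon structures with bridging reads, attenuator leaders (synonymous
re-encodings of configured peptides followed by a stem-loop + T stretch),
5'-end read stacks at every planted TSS, and gene-body coverage — plus the
matching GroundTruth so every pipeline stage can be scored offline.

Everything is drawn from a single seeded generator in a fixed order, so a
given config is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Data import CodonTable

from bactx.core import (
    FORWARD,
    REVERSE,
    FeatureRecord,
    GenomeAnnotation,
    ValidationError,
    revcomp,
)
from bactx.profiles import StrandProfile

_TABLE = CodonTable.unambiguous_dna_by_id[11].forward_table
_STOPS = ("TAA", "TAG", "TGA")
_STARTS = ("ATG", "GTG", "TTG")

_SYN: dict[str, list[str]] = {}
for codon, aa in _TABLE.items():
    _SYN.setdefault(aa, []).append(codon)
_SYN["M"] = ["ATG"]

#: The eight reference leader peptides used as the default attenuator set
#: (name, peptide, product label given to the downstream target gene).
DEFAULT_LEADER_PEPTIDES: tuple[tuple[str, str, str], ...] = (
    ("alaL", "MNVIGRNIFATARATSSPVAAA", "alanyl-tRNA synthetase"),
    ("ilvL", "MRTRILVLGKRVG", "acetolactate synthase"),
    ("thrL", "MKRVRPFLETTPGFVPAR", "threonine-tRNA ligase"),
    ("trpL2", "MMTRTCTQLWRAA", "tryptophan-tRNA ligase"),
    ("leuL2", "MRAVRLLLSEPR", "leucine-tRNA ligase"),
    ("leuL1", "MRFGLLLLSCRGEGL", "2-isopropylmalate synthase"),
    ("trpL1", "MFAHSTRNWWWTAHPAAH", "anthranilate synthase"),
    ("metL", "MSTTSDRTPATEATTTPGARCMCRRMCAF", "methionine import system"),
)


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 100_000
    gc_content: float = 0.72
    n_genes: int = 80
    operon_spec: tuple[int, ...] = (3, 3, 2, 4, 2, 3, 2, 5, 2, 3)
    sub_operon_operons: int = 3  # first N operons get one internal TSS
    leaderless_fraction: float = 0.17
    utr_length_distribution: tuple[str, dict] = (
        "gamma",
        {"shape": 2.0, "scale": 26.0, "min": 4, "max": 300},
    )
    minus10_consensus: str = "TATAAT"
    minus10_mutation_rate: float = 0.1
    minus10_spacer_weights: dict[int, float] = field(
        default_factory=lambda: {4: 0.05, 5: 0.20, 6: 0.30, 7: 0.25, 8: 0.15, 9: 0.05}
    )
    minus35_consensus: str = "TTGACA"
    minus35_mutation_rate: float = 0.25
    minus35_spacer_range: tuple[int, int] = (15, 19)
    rbs_consensus: str = "AGGAGG"
    rbs_mutation_rate: float = 0.1
    rbs_spacer_range: tuple[int, int] = (5, 8)
    gene_length_range: tuple[int, int] = (300, 900)
    min_intergenic: int = 40
    tss_signal_mean: float = 50.0
    tss_dispersion: float = 0.5
    background_rate: float = 0.02
    bridge_reads_per_junction: tuple[str, dict] = ("poisson_min", {"mean": 20, "min": 5})
    coverage_read_length: int = 75
    attenuator_peptides: tuple[tuple[str, str, str], ...] = DEFAULT_LEADER_PEPTIDES

    def __post_init__(self) -> None:
        if not 0 <= self.gc_content <= 1:
            raise ValidationError("gc_content must be in [0, 1]")
        if not 0 <= self.leaderless_fraction <= 1:
            raise ValidationError("leaderless_fraction must be in [0, 1]")
        if sum(self.operon_spec) + len(self.attenuator_peptides) > self.n_genes:
            raise ValidationError("operon_spec + attenuators exceed n_genes")


@dataclass(frozen=True)
class TruthTSS:
    position: int
    strand: str
    tss_class: str
    gene: str
    utr_length: int
    leaderless: bool


@dataclass(frozen=True)
class TruthAttenuator:
    name: str
    target_gene: str
    peptide: str
    orf_start: int
    orf_end: int


@dataclass
class GroundTruth:
    sequence_id: str
    tss: list[TruthTSS]
    operons: list[tuple[str, ...]]  # transcription-order gene ids
    sub_operons: list[tuple[str, ...]]
    monocistronic: list[str]
    attenuators: list[TruthAttenuator]
    expression: dict[str, int]  # gene id -> coverage read count


@dataclass
class SyntheticDataset:
    annotation: GenomeAnnotation
    profile: StrandProfile
    truth: GroundTruth
    read_intervals: list[tuple[int, int, str]]


# ---------------------------------------------------------------------------
# sequence building blocks


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    idx = rng.choice(4, size=length, p=_base_probs(gc))
    return "".join("ACGT"[i] for i in idx)


def _mutate(rng: np.random.Generator, motif: str, rate: float) -> str:
    out = []
    for c in motif:
        if rng.random() < rate:
            out.append(rng.choice([b for b in "ACGT" if b != c]))
        else:
            out.append(c)
    return "".join(out)


def _weighted_choice(rng: np.random.Generator, weights: dict[int, float]) -> int:
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=p / p.sum()))


def _draw_utr(rng: np.random.Generator, law: tuple[str, dict]) -> int:
    name, params = law
    if name == "gamma":
        u = params["min"] + int(round(rng.gamma(params["shape"], params["scale"])))
        return int(min(u, params["max"]))
    if name == "uniform":
        return int(rng.integers(params["min"], params["max"] + 1))
    raise ValidationError(f"unknown UTR law {name!r}")


def _draw_bridge(rng: np.random.Generator, law: tuple[str, dict]) -> int:
    name, params = law
    if name == "poisson_min":
        floor = params.get("min", 0)
        return floor + int(rng.poisson(max(params["mean"] - floor, 0)))
    if name == "constant":
        return int(params["value"])
    raise ValidationError(f"unknown bridge law {name!r}")


def _random_codons(rng: np.random.Generator, n: int, gc: float) -> str:
    """n random non-stop codons drawn with per-base GC bias."""
    out = []
    while len(out) < n:
        codon = random_dna(rng, 3, gc)
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def encode_peptide(rng: np.random.Generator, peptide: str) -> str:
    """Synonymous-codon re-encoding of a peptide: a random start codon for
    the initiator M, random synonymous codons elsewhere, a random stop."""
    parts = [str(rng.choice(_STARTS, p=[0.5, 0.4, 0.1]))]
    for aa in peptide[1:]:
        parts.append(str(rng.choice(_SYN[aa])))
    parts.append(str(rng.choice(_STOPS)))
    return "".join(parts)


def _promoter_block(rng: np.random.Generator, cfg: SimulationConfig) -> str:
    """[-35][spacer][-10][spacer]; the TSS sits immediately after."""
    s35 = int(rng.integers(cfg.minus35_spacer_range[0], cfg.minus35_spacer_range[1] + 1))
    s10 = _weighted_choice(rng, cfg.minus10_spacer_weights)
    return (
        _mutate(rng, cfg.minus35_consensus, cfg.minus35_mutation_rate)
        + random_dna(rng, s35, cfg.gc_content)
        + _mutate(rng, cfg.minus10_consensus, cfg.minus10_mutation_rate)
        + random_dna(rng, s10, cfg.gc_content)
    )


def _gene_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    """A CDS of `length` nt (multiple of 3): start codon, non-stop body,
    stop codon."""
    assert length % 3 == 0 and length >= 9
    start = str(rng.choice(_STARTS, p=[0.55, 0.40, 0.05]))
    body = _random_codons(rng, length // 3 - 2, gc)
    return start + body + str(rng.choice(_STOPS))


# ---------------------------------------------------------------------------
# cassette construction (sense coordinates; 5' end at offset 0)


@dataclass
class _Unit:
    seq: str
    genes: list[tuple[int, int]]  # cassette intervals, transcription order
    tss: list[tuple[int, int, int]]  # (cassette offset, gene index, utr)
    bridges: list[tuple[int, int]]  # junction span intervals for bridging reads
    attenuator: Optional[tuple[str, str, int, int]] = None  # name, peptide, orf span
    is_operon: bool = False


def _build_unit(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    n_genes: int,
    with_internal_tss: bool,
) -> _Unit:
    parts: list[str] = [random_dna(rng, 4, cfg.gc_content), _promoter_block(rng, cfg)]
    pos = sum(len(p) for p in parts)
    tss: list[tuple[int, int, int]] = []
    genes: list[tuple[int, int]] = []
    bridges: list[tuple[int, int]] = []

    leaderless = rng.random() < cfg.leaderless_fraction
    utr = 0 if leaderless else _draw_utr(rng, cfg.utr_length_distribution)
    tss.append((pos, 0, utr))
    if utr > 0:
        r = int(rng.integers(cfg.rbs_spacer_range[0], cfg.rbs_spacer_range[1] + 1))
        rbs = _mutate(rng, cfg.rbs_consensus, cfg.rbs_mutation_rate)
        if utr >= r + len(rbs):
            utr_seq = (
                random_dna(rng, utr - r - len(rbs), cfg.gc_content)
                + rbs
                + random_dna(rng, r, cfg.gc_content)
            )
        else:
            utr_seq = random_dna(rng, utr, cfg.gc_content)
        parts.append(utr_seq)
        pos += utr

    for k in range(n_genes):
        if k > 0:
            junction_at = pos  # last base of upstream gene is pos - 1
            if with_internal_tss and k == 1:
                pad = random_dna(rng, 10, cfg.gc_content)
                promoter = _promoter_block(rng, cfg)
                v = int(rng.integers(4, 21))
                gap_seq = pad + promoter + random_dna(rng, v, cfg.gc_content)
                tss.append((pos + len(pad) + len(promoter), k, v))
            else:
                gap_seq = random_dna(rng, int(rng.integers(20, 61)), cfg.gc_content)
            parts.append(gap_seq)
            pos += len(gap_seq)
            bridges.append((junction_at - 16, pos + 15))
        lo, hi = cfg.gene_length_range
        glen = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
        parts.append(_gene_seq(rng, glen, cfg.gc_content))
        genes.append((pos, pos + glen))
        pos += glen

    return _Unit(
        seq="".join(parts),
        genes=genes,
        tss=tss,
        bridges=bridges,
        is_operon=n_genes >= 2,
    )


def _build_attenuator_unit(
    rng: np.random.Generator, cfg: SimulationConfig, name: str, peptide: str
) -> _Unit:
    parts = [random_dna(rng, 4, cfg.gc_content), _promoter_block(rng, cfg)]
    pos = sum(len(p) for p in parts)
    tss_offset = pos
    orf = encode_peptide(rng, peptide)
    orf_span = (pos, pos + len(orf))
    parts.append(orf)
    pos += len(orf)
    pad1 = random_dna(rng, 5, cfg.gc_content)
    stem = random_dna(rng, 8, max(cfg.gc_content, 0.6))
    loop = random_dna(rng, 4, cfg.gc_content)
    terminator = stem + loop + revcomp(stem) + "T" * 8
    pad2 = random_dna(rng, 8, cfg.gc_content)
    parts.extend([pad1, terminator, pad2])
    pos += len(pad1) + len(terminator) + len(pad2)
    lo, hi = cfg.gene_length_range
    glen = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
    parts.append(_gene_seq(rng, glen, cfg.gc_content))
    unit = _Unit(
        seq="".join(parts),
        genes=[(pos, pos + glen)],
        tss=[(tss_offset, 0, pos - tss_offset)],
        bridges=[],
        attenuator=(name, peptide, orf_span[0], orf_span[1]),
    )
    return unit


# ---------------------------------------------------------------------------
# generation


def generate(config: SimulationConfig) -> SyntheticDataset:
    """Generate (annotation, profile, truth, read intervals) for the
    configured genome.  Deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    genome = np.array(list(random_dna(rng, L, config.gc_content)))

    # Build units: operons, attenuator units, then singles.
    n_operon_genes = sum(config.operon_spec)
    n_singles = config.n_genes - n_operon_genes - len(config.attenuator_peptides)
    units: list[_Unit] = []
    unit_meta: list[Optional[tuple[str, str, str]]] = []
    for i, size in enumerate(config.operon_spec):
        units.append(
            _build_unit(rng, config, size, with_internal_tss=i < config.sub_operon_operons)
        )
        unit_meta.append(None)
    for name, peptide, product in config.attenuator_peptides:
        units.append(_build_attenuator_unit(rng, config, name, peptide))
        unit_meta.append((name, peptide, product))
    for _ in range(n_singles):
        units.append(_build_unit(rng, config, 1, with_internal_tss=False))
        unit_meta.append(None)

    # Shuffle placement order but keep rng-determinism.
    order = rng.permutation(len(units))
    total_len = sum(len(units[i].seq) for i in order)
    slack = L - total_len - (len(units) + 1) * config.min_intergenic
    if slack < 0:
        raise ValidationError(
            f"infeasible packing: {total_len} nt of units into {L} nt genome"
        )
    extra_gaps = rng.multinomial(slack, np.full(len(units), 1 / len(units)))

    features: list[FeatureRecord] = []
    truth_tss: list[TruthTSS] = []
    truth_operons: list[tuple[str, ...]] = []
    truth_subs: list[tuple[str, ...]] = []
    truth_mono: list[str] = []
    truth_att: list[TruthAttenuator] = []
    bridge_jobs: list[tuple[int, int, str]] = []  # genome-space bridge spans
    gene_counter = 0
    cursor = config.min_intergenic

    for slot, i in enumerate(order):
        unit = units[i]
        meta = unit_meta[i]
        strand = FORWARD if rng.random() < 0.5 else REVERSE
        M = len(unit.seq)
        cassette = unit.seq if strand == FORWARD else revcomp(unit.seq)
        genome[cursor : cursor + M] = list(cassette)

        def to_genome(offset: int) -> int:
            return cursor + offset if strand == FORWARD else cursor + M - 1 - offset

        def to_genome_interval(a: int, b: int) -> tuple[int, int]:
            if strand == FORWARD:
                return cursor + a, cursor + b
            return cursor + M - b, cursor + M - a

        gene_ids = []
        for gi, (a, b) in enumerate(unit.genes):
            gene_counter += 1
            fid = f"gene_{gene_counter:04d}"
            gs, ge = to_genome_interval(a, b)
            product = meta[2] if meta and gi == 0 else ""
            features.append(FeatureRecord(fid, "CDS", gs, ge, strand, product))
            gene_ids.append(fid)

        for offset, gi, utr in unit.tss:
            truth_tss.append(
                TruthTSS(
                    position=to_genome(offset),
                    strand=strand,
                    tss_class="primary",
                    gene=gene_ids[gi],
                    utr_length=utr,
                    leaderless=utr <= 3,
                )
            )
        for a, b in unit.bridges:
            s, e = to_genome_interval(max(a, 0), min(b, M))
            bridge_jobs.append((s, e, strand))
        if unit.is_operon:
            truth_operons.append(tuple(gene_ids))
            if len(unit.tss) > 1:  # internal TSS -> suffix sub-operon
                truth_subs.append(tuple(gene_ids[1:]))
        else:
            truth_mono.extend(gene_ids)
        if unit.attenuator is not None:
            name, peptide, oa, ob = unit.attenuator
            truth_att.append(
                TruthAttenuator(
                    name=name,
                    target_gene=gene_ids[0],
                    peptide=peptide,
                    orf_start=to_genome(oa),
                    orf_end=to_genome(ob),
                )
            )
        cursor += M + config.min_intergenic + int(extra_gaps[slot])

    sequence = "".join(genome)
    annotation = GenomeAnnotation("synthetic_1", sequence, features)
    annotation.validate()

    # Profiles: 5'-read-start stacks + Poisson background; coverage reads.
    starts = {s: np.zeros(L, dtype=np.int64) for s in (FORWARD, REVERSE)}
    r = 1.0 / config.tss_dispersion
    for t in truth_tss:
        draw = int(
            rng.negative_binomial(r, r / (r + config.tss_signal_mean))
        )
        starts[t.strand][t.position] += max(draw, 10)
    if config.background_rate > 0:
        for s in (FORWARD, REVERSE):
            starts[s] += rng.poisson(config.background_rate, L)

    read_intervals: list[tuple[int, int, str]] = []
    expression: dict[str, int] = {}
    rlen = config.coverage_read_length
    for f in features:
        depth = 1 + int(rng.poisson(2))
        n_reads = 0
        for _ in range(depth):
            p = f.start
            while p < f.end:
                read_intervals.append((p, min(p + rlen, f.end), f.strand))
                n_reads += 1
                p += max(rlen - 25, 1)
        expression[f.feature_id] = n_reads
    for s, e, strand in bridge_jobs:
        n = _draw_bridge(rng, config.bridge_reads_per_junction)
        for _ in range(n):
            read_intervals.append((max(s, 0), min(e, L), strand))

    coverage = {s: np.zeros(L + 1, dtype=np.int64) for s in (FORWARD, REVERSE)}
    for s_, e_, strand in read_intervals:
        coverage[strand][s_] += 1
        coverage[strand][e_] -= 1
    cov = {s: np.cumsum(coverage[s][:-1]) for s in (FORWARD, REVERSE)}

    total = int(
        starts[FORWARD].sum() + starts[REVERSE].sum() + len(read_intervals)
    )
    profile = StrandProfile(
        read_starts_fwd=starts[FORWARD],
        read_starts_rev=starts[REVERSE],
        coverage_fwd=cov[FORWARD],
        coverage_rev=cov[REVERSE],
        total_mapped_reads=max(total, 1),
    )

    truth = GroundTruth(
        sequence_id="synthetic_1",
        tss=sorted(truth_tss, key=lambda t: (t.position, t.strand)),
        operons=truth_operons,
        sub_operons=truth_subs,
        monocistronic=sorted(truth_mono),
        attenuators=truth_att,
        expression=expression,
    )
    return SyntheticDataset(annotation, profile, truth, read_intervals)


def plant_motif_windows(
    n: int,
    window: int,
    motif: str,
    spacer_range: tuple[int, int],
    gc: float,
    mutation_rate: float,
    rng: np.random.Generator,
) -> tuple[list[str], list[int]]:
    """n background windows with a mutated copy of `motif` planted at an
    anchor spacer drawn uniformly from spacer_range.  Returns (windows,
    planted start offsets)."""
    seqs, offsets = [], []
    for _ in range(n):
        s = int(rng.integers(spacer_range[0], spacer_range[1] + 1))
        off = window - len(motif) - s
        base = list(random_dna(rng, window, gc))
        base[off : off + len(motif)] = list(_mutate(rng, motif, mutation_rate))
        seqs.append("".join(base))
        offsets.append(off)
    return seqs, offsets


# ---------------------------------------------------------------------------
# evaluation


def evaluate(pipeline_output, truth: GroundTruth, tolerance: int = 0) -> dict:
    """Score pipeline output against planted truth.

    Expects an object with attributes `sequence_id`, `classified_tss`,
    `operons`, `monocistronic` and `attenuator_hits` (a
    :class:`bactx.pipeline.PipelineResult`).
    """
    if pipeline_output.sequence_id != truth.sequence_id:
        raise ValidationError("mismatched genome ids")
    predicted = pipeline_output.classified_tss
    truth_by_key = {}
    for t in truth.tss:
        truth_by_key[(t.position, t.strand)] = t

    matched = 0
    class_confusion: dict[str, int] = {}
    utr_matches = 0
    used = set()
    for p in predicted:
        hit = None
        for d in range(-tolerance, tolerance + 1):
            key = (p.position + d, p.strand)
            if key in truth_by_key and key not in used:
                hit = truth_by_key[key]
                used.add(key)
                break
        if hit is None:
            continue
        matched += 1
        pair = f"{hit.tss_class}->{p.tss_class}"
        class_confusion[pair] = class_confusion.get(pair, 0) + 1
        if p.utr_length == hit.utr_length:
            utr_matches += 1

    precision = matched / len(predicted) if predicted else 0.0
    recall = matched / len(truth.tss) if truth.tss else 0.0

    pred_operons = {tuple(o.gene_ids) for o in pipeline_output.operons}
    true_operons = {tuple(o) for o in truth.operons}
    operon_match = (
        len(pred_operons & true_operons) / len(true_operons) if true_operons else 1.0
    )

    recovered = 0
    hit_peptides = {
        (h.upstream_of, h.peptide) for h in pipeline_output.attenuator_hits
    }
    for a in truth.attenuators:
        if (a.target_gene, a.peptide) in hit_peptides:
            recovered += 1
    att_recovery = recovered / len(truth.attenuators) if truth.attenuators else 1.0

    return {
        "tss": {
            "precision": precision,
            "recall": recall,
            "n_predicted": len(predicted),
            "n_truth": len(truth.tss),
            "class_confusion": class_confusion,
            "utr_match_fraction": utr_matches / matched if matched else 0.0,
        },
        "operons": {
            "exact_match_rate": operon_match,
            "n_predicted": len(pred_operons),
            "n_truth": len(true_operons),
            "monocistronic_match": set(pipeline_output.monocistronic)
            == set(truth.monocistronic),
        },
        "attenuators": {
            "recovery_rate": att_recovery,
            "n_truth": len(truth.attenuators),
        },
    }
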