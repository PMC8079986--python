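"""End-to-end orchestration: TSS -> classification -> TLS correction ->
UTR/motifs -> operons -> attenuators, with a consolidated report."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from bactx import attenuators as att
from bactx import motifs as mot
from bactx import operons as ops
from bactx import tls as tlsmod
from bactx import tss as tssmod
from bactx.core import DetectionConfig, GenomeAnnotation, tls_position
from bactx.profiles import StrandProfile, rpkm_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    motifs: mot.MotifSearchConfig = field(default_factory=mot.MotifSearchConfig)
    attenuators: att.AttenuatorConfig = field(default_factory=att.AttenuatorConfig)
    detection_mode: str = "standard"
    rpkm_counting: str = "starts"
    old_tls_coverage_max: int = 0
    minus10_pattern: str = "TAnnnT"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}

        def build(klass, section):
            data = dict(raw.get(section, {}))
            for k, v in data.items():
                if isinstance(v, list):
                    data[k] = tuple(v)
            return klass(**data)

        return cls(
            detection=build(DetectionConfig, "detection"),
            motifs=build(mot.MotifSearchConfig, "motifs"),
            attenuators=build(att.AttenuatorConfig, "attenuators"),
            detection_mode=raw.get("detection_mode", "standard"),
            rpkm_counting=raw.get("rpkm_counting", "starts"),
            old_tls_coverage_max=raw.get("old_tls_coverage_max", 0),
            minus10_pattern=raw.get("minus10_pattern", "TAnnnT"),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    sequence_id: str
    classified_tss: list
    tss_summary: dict
    utr_histogram: tssmod.UTRHistogram
    leaderless_fraction: Optional[float]
    tls_proposals: list
    corrected_annotation: GenomeAnnotation
    start_codons_before: dict
    start_codons_after: dict
    motif_reports: dict
    operons: list
    monocistronic: list
    operon_summary: dict
    attenuator_hits: list
    rpkm: pd.DataFrame
    config: PipelineConfig

    def to_report(self) -> dict:
        """JSON-serializable summary mirroring the pipeline's accounting."""

        def motif_section(sec):
            if sec is None or sec.get("insufficient_data"):
                return {"insufficient_data": True, **{k: sec.get(k) for k in ("n_sequences",)}} if sec else None
            out = dict(sec)
            model = out.pop("model", None)
            if model is not None:
                out["consensus"] = model.consensus
                out["pfm"] = model.pfm.tolist()
            return out

        return {
            "sequence_id": self.sequence_id,
            "tss_summary": self.tss_summary,
            "utr_histogram": {
                "leaderless": self.utr_histogram.leaderless,
                "bins": list(self.utr_histogram.bins),
                "overflow": self.utr_histogram.overflow,
            },
            "leaderless_fraction": self.leaderless_fraction,
            "n_tls_proposals": len(self.tls_proposals),
            "start_codons_before": self.start_codons_before,
            "start_codons_after": self.start_codons_after,
            "motifs": {k: motif_section(v) for k, v in self.motif_reports.items()},
            "operon_summary": self.operon_summary,
            "n_attenuator_hits": len(self.attenuator_hits),
            "attenuators": [
                {
                    "upstream_of": h.upstream_of,
                    "peptide": h.peptide,
                    "length_aa": h.length_aa,
                    "enriched_residue": h.enriched_residue,
                    "terminator": dataclasses.asdict(h.terminator) if h.terminator else None,
                }
                for h in self.attenuator_hits
            ],
            "rpkm": self.rpkm.to_dict(orient="records"),
            "config": self.config.to_dict(),
        }


def _log_stage(name: str, n_in: int, n_out: int) -> None:
    logger.info("stage=%s inputs=%d outputs=%d", name, n_in, n_out)


def _motif_run(
    seqs: list[str], spacer_range, pattern: str, config: mot.MotifSearchConfig
) -> dict:
    if len(seqs) < 10:
        return {"insufficient_data": True, "n_sequences": len(seqs)}
    model = mot.em_find_motif(seqs, config.width, spacer_range, config)
    stats = mot.spacer_stats(model)
    frac, _ = mot.match_pattern_fraction(seqs, pattern, spacer_range)
    placed = sum(1 for p in model.placements if p is not None)
    return {
        "insufficient_data": False,
        "n_sequences": len(seqs),
        "model": model,
        "placement_fraction": placed / len(seqs),
        "pattern": pattern,
        "pattern_fraction": frac,
        "spacer_mean": stats.mean,
        "spacer_histogram": stats.histogram,
    }


def _minus35_sequences(seqs: list[str], model: mot.MotifModel) -> list[str]:
    """The part of each promoter window upstream of its -10 placement; the
    -35 search anchors on the -10 element, not the TSS."""
    out = []
    for s, p in zip(seqs, model.placements):
        if p is not None:
            out.append(s[:p])
    return out


def run_pipeline(
    annotation: GenomeAnnotation,
    profile: StrandProfile,
    read_intervals: Optional[Sequence[tuple[int, int, str]]] = None,
    bridging_counts: Optional[dict[tuple[str, str], int]] = None,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Execute all stages in order and assemble the report.

    Bridging evidence comes either from whole-transcriptome read intervals
    or from precomputed per-junction counts; with neither, every junction
    counts 0 and all genes come out monocistronic.
    """
    config = config or PipelineConfig()
    annotation.validate()

    raw = tssmod.detect_tss(profile, config.detection, mode=config.detection_mode)
    _log_stage("detect_tss", len(profile), len(raw))

    classified = tssmod.classify_tss(raw, annotation, config.detection)
    _log_stage("classify_tss", len(raw), len(classified))
    summary = tssmod.tss_summary(classified)

    proposals = tlsmod.propose_tls_corrections(
        annotation, classified, profile, config.detection, config.old_tls_coverage_max
    )
    corrected = tlsmod.apply_tls_corrections(annotation, proposals)
    _log_stage("tls_correction", len(annotation.cds()), len(proposals))
    codons_before = tlsmod.start_codon_usage(annotation)
    codons_after = tlsmod.start_codon_usage(corrected)

    histogram = tssmod.utr_histogram(classified)
    lf = tssmod.leaderless_fraction(classified)

    # Promoter motifs on primary-TSS windows, split by leaderless flag.
    primary = [t for t in classified if t.tss_class == "primary"]
    motif_reports: dict[str, Optional[dict]] = {}
    mcfg = config.motifs
    for label, group in (
        ("minus10_leaderless", [t for t in primary if t.leaderless]),
        ("minus10_leadered", [t for t in primary if not t.leaderless]),
    ):
        windows = mot.extract_windows(
            [(t.position, t.strand) for t in group], annotation, mcfg.promoter_window
        )
        seqs = [w.sequence for w in windows if not w.truncated]
        report = _motif_run(
            seqs, mcfg.minus10_spacer_range, config.minus10_pattern, mcfg
        )
        motif_reports[label] = report
        m35_label = label.replace("minus10", "minus35")
        if not report["insufficient_data"]:
            m35_seqs = [
                s for s in _minus35_sequences(seqs, report["model"])
                if len(s) >= mcfg.width + mcfg.minus35_spacer_range[1]
            ]
            motif_reports[m35_label] = _motif_run(
                m35_seqs, mcfg.minus35_spacer_range, "nTGACn", mcfg
            )
        else:
            motif_reports[m35_label] = {"insufficient_data": True, "n_sequences": 0}
    _log_stage("motifs", len(primary), sum(1 for v in motif_reports.values() if v))

    rbs = mot.find_rbs(annotation, classified, mcfg)
    motif_reports["rbs"] = {
        "insufficient_data": rbs.insufficient_data,
        "n_sequences": rbs.n_sequences,
        "model": rbs.model,
        "placement_fraction": rbs.placement_fraction,
        "spacer_mean": rbs.spacer_mean,
    }

    if bridging_counts is None:
        bridging_counts = (
            ops.compute_bridging_counts(annotation, read_intervals)
            if read_intervals is not None
            else {}
        )
    operons, mono = ops.infer_operons(
        annotation, bridging_counts, classified, config.detection
    )
    op_summary = ops.operon_summary(operons, mono)
    _log_stage("operons", len(annotation.cds()), len(operons))

    hits = att.scan_attenuators(annotation, classified, config=config.attenuators)
    _log_stage("attenuators", len(annotation.cds()), len(hits))

    strengths = (
        rpkm_table(annotation, profile, config.rpkm_counting)
        if profile.total_mapped_reads > 0
        else pd.DataFrame(columns=["feature_id", "start", "end", "strand", "reads", "rpkm"])
    )

    return PipelineResult(
        sequence_id=annotation.sequence_id,
        classified_tss=classified,
        tss_summary=summary,
        utr_histogram=histogram,
        leaderless_fraction=lf,
        tls_proposals=proposals,
        corrected_annotation=corrected,
        start_codons_before=codons_before,
        start_codons_after=codons_after,
        motif_reports=motif_reports,
        operons=operons,
        monocistronic=mono,
        operon_summary=op_summary,
        attenuator_hits=hits,
        rpkm=strengths,
        config=config,
    )


def write_report(result: PipelineResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_report(), fh, indent=2, default=str)
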