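# bactx

A bacterial primary-transcriptome genome-reannotation toolkit. Starting from
a genome (FASTA), an annotation (GFF3), and strand-specific per-base profiles
of 5'-read-start counts and whole-transcriptome coverage (bedGraph), it:

- calls transcription start sites (TSS) from 5'-end read-start stacks
  (≥ 10 read starts and a ≥ 1000% increase over the strand-aware upstream
  neighbor; a 100% low-coverage mode is available),
- classifies TSS by genomic context (primary / secondary / antisense /
  intragenic / intergenic, with a 500 nt TSS-to-TLS cap) and derives 5'-UTR
  lengths and leaderless transcripts (UTR 0–3 nt),
- proposes translation-start (TLS) corrections from intragenic TSS within
  the first 25% of a CDS,
- discovers −10/−35 promoter and ribosome-binding-site motifs with a
  fixed-width ZOOPS EM over spacer-constrained placements, plus consensus
  pattern-match fractions and spacer statistics,
- infers operons and sub-operons from reads bridging intergenic gaps
  (≥ 5 bridging reads per junction), and
- detects attenuator leader peptides (small leader ORFs with residue
  enrichment) with a Rho-independent terminator heuristic
  (stem-loop + T-stretch).

A synthetic-data module generates high-GC genomes with planted promoters,
RBS motifs, operons, attenuator leaders, read stacks and bridging reads —
with the matching ground truth — so the whole pipeline is testable offline,
and an evaluation module scores pipeline output against that truth.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite: worked examples for
the reference leader peptides, threshold-boundary checks, closed-loop and
noisy recovery on synthetic genomes, motif recovery, and oracle-equivalence
trials (every fast path is checked against an independent brute-force
implementation).

## CLI

```bash
# generate a synthetic dataset with ground truth
bactx simulate --seed 1 --out sim/

# run the full pipeline and write the consolidated report
bactx run --fasta sim/genome.fasta --gff sim/annotation.gff3 \
    --profile-dir sim/profile --reads-bed sim/reads.bed --out-dir out/

# score the run against the planted truth
bactx evaluate --fasta sim/genome.fasta --gff sim/annotation.gff3 \
    --profile-dir sim/profile --reads-bed sim/reads.bed \
    --truth sim/truth.json --out eval.json
```

Individual stages are exposed as `detect`, `classify`, `correct-tls`,
`motifs`, `operons` and `attenuators`. `bactx run` accepts a YAML config
(`--config`) whose sections mirror the `DetectionConfig`,
`MotifSearchConfig` and `AttenuatorConfig` field names; the effective
config is echoed into the report. Exit codes: 0 success, 2 validation or
format error, 3 stage failure.

## Layout

```
src/bactx/
  core.py         domain types, coordinates, FASTA/GFF3/bedGraph I/O
  profiles.py     strand profiles, pooling, rpkm
  tss.py          TSS detection, classification, UTR statistics
  tls.py          translation-start correction, start-codon usage
  motifs.py       ZOOPS EM motif search, spacer stats, anti-SD matching
  operons.py      bridging-read operon inference
  attenuators.py  leader ORFs, residue enrichment, terminator heuristic
  simulate.py     synthetic genomes with planted ground truth, evaluation
  pipeline.py     stage orchestration and report assembly
  cli.py          click CLI
```
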