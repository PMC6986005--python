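"""End-to-end pipeline: simulate -> fish -> structure -> map -> features.

Configuration is a strict schema (unknown keys are errors); every stage
parameter defaults to the values the individual modules document, all
randomness flows from one seed, and a manifest with SHA-256 checksums makes
a run verifiable: identical config + seed => identical bytes.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from . import io as pio
from .align import TargetIndex, spliced_map, write_sam
from .classify import build_index, filter_pool
from .features import call_editing, call_introns, call_operons, editing_summary
from .structure import canonicalize, coverage_stats, genome_summary
from .synthetic import (GenomeSpec, generate_genome, mix_decoy_reads,
                        scaled_spec, simulate_genomic_reads, simulate_isoseq)

log = logging.getLogger("plastokit")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    enabled: bool = True
    scale: int = 20               # region lengths divided by this factor
    full_content: bool = False    # full 107-gene content instead of scaled
    n_genomic_reads: int = 1000
    genomic_mean_len: int = 1500
    genomic_error_rate: float = 0.12
    decoy_fraction: float = 0.5
    isoseq_depth: int = 60
    isoseq_error_rate: float = 0.01
    intron_retention: float = 0.2


class FishConfig(_Strict):
    enabled: bool = True
    k: int = 15
    min_frac: float = 0.02
    min_hits: int = 25


class StructureConfig(_Strict):
    enabled: bool = True
    min_ir: int = 1000


class MapConfig(_Strict):
    enabled: bool = True
    k: int = 13
    min_intron: int = 50
    max_intron: int = 5000


class FeaturesConfig(_Strict):
    enabled: bool = True
    intron_min_support: int = 3
    editing_min_cov: int = 10
    editing_min_eff: float = 0.10
    editing_err: float = 0.02
    editing_alpha: float = 0.05
    operon_min_genes: int = 2
    operon_min_support: int = 3
    operon_cds_cov: float = 0.5


class DivergenceConfig(_Strict):
    enabled: bool = False
    msa_dir: str | None = None
    deletion: str = "pairwise"


class PipelineConfig(_Strict):
    outdir: str = "plastokit_run"
    seed: int = 7
    genome_fasta: str | None = None    # skip simulation, use provided inputs
    annotation_gff3: str | None = None
    reads_fastq: str | None = None
    transcripts_fastq: str | None = None
    simulate: SimulateConfig = SimulateConfig()
    fish: FishConfig = FishConfig()
    structure: StructureConfig = StructureConfig()
    map: MapConfig = MapConfig()
    features: FeaturesConfig = FeaturesConfig()
    divergence: DivergenceConfig = DivergenceConfig()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    seed = config.seed
    log.info("run: outdir=%s seed=%d", out, seed)

    genome = annotation = truth = None
    reads = transcripts = None

    if config.simulate.enabled:
        sc = config.simulate
        if sc.full_content:
            spec = GenomeSpec(seed=seed)
        else:
            spec = scaled_spec(factor=sc.scale, seed=seed)
        genome, annotation, truth = generate_genome(spec)
        pure = simulate_genomic_reads(genome, sc.n_genomic_reads,
                                      sc.genomic_mean_len,
                                      sc.genomic_error_rate, seed=seed + 1)
        decoy_genome = _decoy_genome(len(genome), seed + 2)
        reads = mix_decoy_reads(pure, decoy_genome, sc.decoy_fraction,
                                seed=seed + 3,
                                error_rate=sc.genomic_error_rate)
        transcripts = simulate_isoseq(genome, truth, sc.isoseq_depth,
                                      sc.isoseq_error_rate, seed=seed + 4,
                                      intron_retention=sc.intron_retention)
        pio.write_fasta(genome, out / "genome.fasta", seed=seed)
        pio.write_gff3(annotation, out / "annotation.gff3")
        pio.write_genbank(genome, annotation, out / "annotation.gb")
        pio.write_fastq(reads, out / "genomic_reads.fastq", seed=seed)
        pio.write_fastq(transcripts, out / "transcripts.fastq", seed=seed)
        pio.write_truth_sam(
            [r for r in reads if r.origin == "chloroplast"],
            genome, out / "truth_alignments.sam")
        written += [out / f for f in
                    ("genome.fasta", "annotation.gff3", "annotation.gb",
                     "genomic_reads.fastq", "transcripts.fastq",
                     "truth_alignments.sam")]
        written += pio.write_truth_tables(truth, out)
    else:
        if config.genome_fasta is None:
            raise ValueError("simulate disabled and no genome_fasta given")
        genome = pio.parse_fasta(config.genome_fasta)
        if config.annotation_gff3:
            annotation = pio.parse_gff3(config.annotation_gff3)
        if config.reads_fastq:
            reads = pio.parse_fastq(config.reads_fastq)
        if config.transcripts_fastq:
            transcripts = pio.parse_fastq(config.transcripts_fastq)

    if config.fish.enabled and reads is not None:
        fc = config.fish
        kidx = build_index(genome, k=fc.k)
        selected, report = filter_pool(reads, kidx, min_frac=fc.min_frac,
                                       min_hits=fc.min_hits)
        report.to_csv(out / "fish_report.tsv", sep="\t", index=False)
        pio.write_fastq(selected, out / "selected_reads.fastq", seed=seed)
        written += [out / "fish_report.tsv", out / "selected_reads.fastq"]
        log.info("fish: %d/%d reads selected", len(selected), len(reads))
        reads = selected

    partition = None
    if config.structure.enabled:
        genome, partition = canonicalize(genome, min_ir=config.structure.min_ir)
        pio.partition_to_bed(partition, genome.id, out / "partition.bed")
        summary = genome_summary(genome, partition, reads=reads,
                                 annotation=annotation)
        with open(out / "genome_summary.tsv", "w") as fh:
            for key, val in summary.items():
                fh.write(f"{key}\t{val}\n")
        written += [out / "partition.bed", out / "genome_summary.tsv"]
        if (out / "truth_alignments.sam").exists():
            _, mean_cov = coverage_stats(out / "truth_alignments.sam",
                                         len(genome))
            with open(out / "coverage.tsv", "w") as fh:
                fh.write(f"mean_depth\t{mean_cov:.3f}\n")
            written.append(out / "coverage.tsv")

    alignments = None
    if config.map.enabled and transcripts is not None:
        mc = config.map
        tindex = TargetIndex.build(genome, k=mc.k)
        alignments = [a for a in
                      (spliced_map(tx, tindex, min_intron=mc.min_intron,
                                   max_intron=mc.max_intron)
                       for tx in transcripts) if a is not None]
        write_sam(alignments, genome, out / "transcripts.sam")
        written.append(out / "transcripts.sam")
        log.info("map: %d/%d transcripts aligned", len(alignments),
                 len(transcripts))

    if config.features.enabled and alignments and annotation is not None:
        fc = config.features
        introns = call_introns(alignments, annotation, genome=genome,
                               min_support=fc.intron_min_support)
        pio.write_introns_gff3(introns, genome.id, len(genome),
                               out / "introns.gff3")
        sites = call_editing(alignments, genome, annotation,
                             min_cov=fc.editing_min_cov,
                             min_eff=fc.editing_min_eff,
                             err=fc.editing_err, alpha=fc.editing_alpha,
                             intron_calls=introns)
        pio.write_editing_tsv(sites, out / "editing.tsv")
        with open(out / "editing_summary.json", "w") as fh:
            json.dump(editing_summary(sites), fh, indent=1, sort_keys=True)
        operons = call_operons(alignments, annotation,
                               min_genes=fc.operon_min_genes,
                               min_support=fc.operon_min_support,
                               cds_cov=fc.operon_cds_cov)
        pio.write_operons_gff3(operons, genome.id, len(genome),
                               out / "operons.gff3")
        written += [out / "introns.gff3", out / "editing.tsv",
                    out / "editing_summary.json", out / "operons.gff3"]

    if config.divergence.enabled and config.divergence.msa_dir:
        from .divergence import rank_markers, score_marker
        records = []
        for fa in sorted(Path(config.divergence.msa_dir).glob("*.fa*")):
            msa = pio.parse_marker_fasta(fa)
            records.append(score_marker(msa, deletion=config.divergence.deletion))
        ranked = rank_markers(records)
        with open(out / "divergence.tsv", "w") as fh:
            fh.write("marker\taligned_length\tvariable_sites\tmean_distance\n")
            for r in ranked:
                fh.write(f"{r.marker}\t{r.aligned_length}\t{r.variable_sites}"
                         f"\t{r.mean_distance:.4f}\n")
        written.append(out / "divergence.tsv")

    manifest = {
        "seed": seed,
        "config": json.loads(config.model_dump_json()),
        "files": {p.name: pio.sha256_of(p) for p in sorted(set(written))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _decoy_genome(length: int, seed: int):
    """An unrelated random genome standing in for non-plastid DNA."""
    import numpy as np

    from ._seq import random_seq_exact_gc
    from .models import CircularGenome

    rng = np.random.default_rng(seed)
    return CircularGenome(id="decoy", sequence=random_seq_exact_gc(rng, length, 0.42))
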