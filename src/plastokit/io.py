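"""Format boundaries: FASTA, FASTQ, GenBank, GFF3, BED and TSV.

Internal coordinates are 0-based half-open everywhere; the 1-based
inclusive convention of GenBank/GFF3 (and SAM POS) exists only inside this
module.  Every writer/parser pair round-trips its in-memory object.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .models import Annotation, CircularGenome, GeneModel, GroundTruth

_FIXED_DATE = "01-JAN-2000"  # constant so emitted GenBank is byte-stable


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def write_fasta(genome: CircularGenome, path, seed: int | None = None) -> None:
    desc = "topology=circular" if genome.circular else "topology=linear"
    if seed is not None:
        desc += f" seed={seed}"
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description=desc)
    SeqIO.write([rec], str(path), "fasta")


def parse_fasta(path) -> CircularGenome:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: empty FASTA")
    rec = records[0]
    circular = "topology=circular" in rec.description
    return CircularGenome(id=rec.id, sequence=str(rec.seq).upper(),
                          circular=circular)


def write_fastq(reads, path, seed: int | None = None, quality: int = 30) -> None:
    """Reads (anything with .id/.sequence) as FASTQ at a constant quality."""
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"@plastokit_seed={seed} comment=header-only-record\n")
            fh.write("N\n+\n!\n")
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qchar * len(r.sequence)}\n")


def parse_fastq(path):
    """FASTQ records as simple (id, sequence) read objects."""
    from dataclasses import dataclass

    @dataclass(frozen=True)
    class _Read:
        id: str
        sequence: str

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        if rec.id.startswith("plastokit_seed="):
            continue
        out.append(_Read(id=rec.id, sequence=str(rec.seq).upper()))
    return out


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_FEATURE_TYPES = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def write_genbank(genome: CircularGenome, annotation: Annotation, path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                    description="synthetic plastome")
    rec.annotations.update({
        "molecule_type": "DNA",
        "topology": "circular" if genome.circular else "linear",
        "date": _FIXED_DATE,
        "data_file_division": "PLN",
    })
    for g in sorted(annotation, key=lambda x: x.start):
        strand = 1 if g.strand == "+" else -1
        locs = [SimpleLocation(s, e, strand) for s, e in g.exons]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(
            locs if strand == 1 else locs[::-1])
        quals = {"gene": [g.name]}
        rec.features.append(SeqFeature(loc, type="gene", qualifiers=dict(quals)))
        if g.gene_type == "CDS":
            quals["codon_start"] = [str(g.codon_start)]
            quals["transl_table"] = ["11"]
        rec.features.append(SeqFeature(loc, type=_FEATURE_TYPES[g.gene_type],
                                       qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


def parse_genbank(path) -> tuple[CircularGenome, Annotation]:
    """GenBank record -> genome + gene models.

    join()/complement() locations become exon interval lists; exons are
    stored in genome order with the strand recorded, and ``codon_start``
    is honoured for CDS features.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ParseError(f"{path}: no GenBank records")
    rec = records[0]
    circular = rec.annotations.get("topology", "linear") == "circular"
    genome = CircularGenome(id=rec.id, sequence=str(rec.seq).upper(),
                            circular=circular)
    genes: list[GeneModel] = []
    seen: set[tuple] = set()
    for f in rec.features:
        if f.type not in _FEATURE_TYPES:
            continue
        name = (f.qualifiers.get("gene") or f.qualifiers.get("locus_tag")
                or ["?"])[0]
        if f.location is None or f.location.strand is None:
            raise ParseError(f"{path}: feature {name}: unknown strand")
        try:
            exons = sorted((int(p.start), int(p.end)) for p in f.location.parts)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: feature {name}: bad location") from exc
        for s, e in exons:
            if e > len(genome) or s < 0:
                raise ParseError(f"{path}: feature {name}: coordinate overflow")
        key = (name, tuple(exons))
        if key in seen:
            continue
        seen.add(key)
        codon_start = int(f.qualifiers.get("codon_start", ["1"])[0])
        genes.append(GeneModel(name=name,
                               strand="+" if f.location.strand >= 0 else "-",
                               exons=tuple(exons), gene_type=f.type,
                               codon_start=codon_start))
    return genome, Annotation(genome_id=rec.id, genome_length=len(genome),
                              genes=genes)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(annotation: Annotation, path, partition=None) -> None:
    """Genes and exons as GFF3 (1-based inclusive); optionally the
    quadripartite regions as region features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {annotation.genome_id} 1 "
                 f"{annotation.genome_length}\n")
        sid = annotation.genome_id
        if partition is not None:
            for name, (s, e) in partition.intervals().items():
                fh.write(f"{sid}\tplastokit\tregion\t{s + 1}\t{e}\t.\t+\t.\t"
                         f"ID=region_{name};Name={name.upper()}\n")
        for i, g in enumerate(sorted(annotation, key=lambda x: x.start)):
            gid = f"gene{i:04d}"
            attrs = f"ID={gid};Name={g.name};gene_biotype={g.gene_type}"
            if g.gene_type == "CDS" and g.codon_start != 1:
                attrs += f";codon_start={g.codon_start}"
            fh.write(f"{sid}\tplastokit\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            for j, (s, e) in enumerate(g.exons):
                fh.write(f"{sid}\tplastokit\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={gid}.exon{j};Parent={gid}\n")


def parse_gff3(path) -> Annotation:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genome_id, genome_length = "", 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                genome_id, genome_length = parts[1], int(parts[3])
                break
    genes = []
    for f in db.features_of_type("gene"):
        exons = sorted((c.start - 1, c.end) for c in db.children(f, featuretype="exon"))
        if not exons:
            exons = [(f.start - 1, f.end)]
        name = f.attributes.get("Name", [f.id])[0]
        biotype = f.attributes.get("gene_biotype", ["CDS"])[0]
        codon_start = int(f.attributes.get("codon_start", ["1"])[0])
        if f.strand not in "+-":
            raise ParseError(f"{path}: gene {name}: unknown strand")
        genes.append(GeneModel(name=name, strand=f.strand, exons=tuple(exons),
                               gene_type=biotype, codon_start=codon_start))
        genome_id = genome_id or f.seqid
    return Annotation(genome_id=genome_id, genome_length=genome_length,
                      genes=genes)


def partition_to_bed(partition, genome_id: str, path) -> None:
    with open(path, "w") as fh:
        for name, (s, e) in partition.intervals().items():
            fh.write(f"{genome_id}\t{s}\t{e}\t{name.upper()}\n")


# ---------------------------------------------------------------------------
# truth + result tables
# ---------------------------------------------------------------------------

def write_truth_tables(truth: GroundTruth, outdir) -> list[Path]:
    """Ground truth as TSV files (regions, introns, editing, units)."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    p = outdir / "truth_regions.tsv"
    pd.DataFrame([{"region": k, "start": v[0], "end": v[1]}
                  for k, v in truth.region_coords.items()]).to_csv(
        p, sep="\t", index=False)
    written.append(p)

    p = outdir / "truth_introns.tsv"
    pd.DataFrame([{"gene": i.gene, "donor": i.donor, "acceptor": i.acceptor,
                   "length": i.length} for i in truth.introns]).to_csv(
        p, sep="\t", index=False)
    written.append(p)

    p = outdir / "truth_editing.tsv"
    pd.DataFrame([{"position": s.position, "strand": s.strand,
                   "efficiency": s.efficiency, "category": s.category}
                  for s in truth.editing_sites]).to_csv(p, sep="\t", index=False)
    written.append(p)

    p = outdir / "truth_units.tsv"
    pd.DataFrame([{"unit": u.id, "genes": "+".join(u.gene_names),
                   "strand": u.strand, "start": u.start, "end": u.end}
                  for u in truth.units]).to_csv(p, sep="\t", index=False)
    written.append(p)
    return written


def write_truth_sam(reads, genome: CircularGenome, path) -> None:
    """True source intervals of simulated genomic reads as SAM records."""
    import pysam

    n = len(genome)
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": genome.id, "LN": n}],
    })
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = r.id
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = 0
            a.reference_start = r.source_start % n
            span = r.source_end - r.source_start
            a.cigartuples = [(0, span)]
            a.mapping_quality = 255
            out.write(a)


def write_editing_tsv(sites, path) -> None:
    import pandas as pd

    pd.DataFrame([{
        "position": s.position, "strand": s.strand, "gene": s.gene,
        "category": s.category, "edited": s.edited, "covering": s.covering,
        "efficiency": round(s.efficiency, 4), "p_value": f"{s.p_value:.3g}",
        "q_value": f"{s.q_value:.3g}",
        "codon_position": s.codon_position if s.codon_position else "",
        "aa_change": s.aa_change,
    } for s in sites]).to_csv(path, sep="\t", index=False)


def write_introns_gff3(calls, genome_id: str, genome_length: int, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome_id} 1 {genome_length}\n")
        for i, c in enumerate(calls):
            fh.write(f"{genome_id}\tplastokit\tintron\t{c.donor + 1}\t"
                     f"{c.acceptor}\t{c.support}\t.\t.\t"
                     f"ID=intron{i};gene={c.gene};"
                     f"motif_match={'yes' if c.motif_match else 'no'}\n")


def write_operons_gff3(calls, genome_id: str, genome_length: int, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome_id} 1 {genome_length}\n")
        for c in calls:
            attrs = (f"ID={c.name};genes={'+'.join(c.genes)};"
                     f"support={c.support}")
            if c.subset_of:
                attrs += f";subset_of={c.subset_of}"
            fh.write(f"{genome_id}\tplastokit\toperon\t{c.start + 1}\t{c.end}"
                     f"\t{c.support}\t{c.strand}\t.\t{attrs}\n")


def parse_marker_fasta(path, marker: str | None = None):
    """Aligned FASTA -> MarkerAlignment (gap character '-')."""
    from .divergence import MarkerAlignment

    path = Path(path)
    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ParseError(f"{path}: empty FASTA")
    return MarkerAlignment(marker=marker or path.stem, sequences=seqs)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
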