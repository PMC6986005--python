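"""Ground-truthed synthetic plastomes, long reads and full-length cDNAs.

The generator emulates the statistical structure the downstream analyses
assume: a circular quadripartite genome (LSC + IRa + SSC + IRb with the two
IRs exact reverse complements), genes carrying 0-2 group-II introns with the
conserved 5' GTGYG / 3' AY boundary motifs, polycistronic transcription
units, per-site C->U editing with fixed efficiencies, indel-dominated
sequencing errors, and heavy-tailed read lengths.  Every output carries its
planted truth so each pipeline stage is testable by recovery.

All randomness flows from a single seed through spawned child generators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._seq import random_seq_exact_gc, revcomp
from .models import (Annotation, CircularGenome, EditingTruth, GeneModel,
                     GroundTruth, IntronTruth, LongRead, LongReadSet,
                     TranscriptionUnit, TranscriptRead, TranscriptReadSet)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_STOPS = {"TAA", "TAG", "TGA"}

# error model: substitution : insertion : deletion = 1 : 2 : 2
_ERR_KINDS = np.array(["S", "I", "D"])
_ERR_PROBS = np.array([0.2, 0.4, 0.4])

#: realistic plastid gene-name catalogues used to label synthetic genes
CDS_NAMES = (
    "psbA matK rps16 psbK psbI atpA atpF atpH atpI rps2 rpoC2 rpoC1 rpoB "
    "petN psbM psbD psbC psbZ rps14 psaB psaA ycf3 rps4 ndhJ ndhK ndhC atpE "
    "atpB rbcL accD psaI ycf4 cemA petA psbJ psbL psbF psbE petL petG psaJ "
    "rpl33 rps18 rpl20 rps12 clpP psbB psbT psbN psbH petB petD rpoA rps11 "
    "rpl36 rps8 rpl14 rpl16 rps3 rpl22 rps19 rpl2 rpl23 ycf2 ndhB rps7 ycf1 "
    "ndhF rpl32 ccsA ndhD psaC ndhE ndhG ndhI ndhA ndhH rps15"
).split()
TRNA_NAMES = (
    "trnH-GUG trnK-UUU trnQ-UUG trnS-GCU trnG-UCC trnR-UCU trnC-GCA trnD-GUC "
    "trnY-GUA trnE-UUC trnT-GGU trnS-UGA trnG-GCC trnM-CAU trnV-UAC trnF-GAA "
    "trnL-UAA trnT-UGU trnS-GGA trnfM-CAU trnP-UGG trnW-CCA trnL-CAA "
    "trnI-CAU trnN-GUU"
).split()
RRNA_NAMES = ("rrn16", "rrn23", "rrn4.5", "rrn5")
RRNA_LENGTHS = {"rrn16": 1490, "rrn23": 2810, "rrn4.5": 95, "rrn5": 121}

#: polycistronic units mirroring the functional complexes of a plastome
#: (ATP synthase, PSII, PSI, NADH dehydrogenase, RNA polymerase, ribosome)
DEFAULT_OPERON_UNITS = (
    ("atpI", "atpH", "atpF", "atpA"),
    ("atpB", "atpE"),
    ("psbD", "psbC", "psbZ"),
    ("psbB", "psbT", "psbH", "petB", "petD"),
    ("psaA", "psaB"),
    ("rps15", "ndhH", "ndhA", "ndhI"),
    ("rpl23", "rpl2", "rps19"),
    ("rpoB", "rpoC1", "rpoC2", "rps2"),
    ("rpl22", "rps3", "rpl16", "rpl14", "rps8", "rpl36", "rps11", "rpoA"),
)

#: nine introns in seven genes; two genes carry two introns each
DEFAULT_INTRON_PLAN = {
    "ycf3": 2, "clpP": 2, "atpF": 1, "rpoC1": 1, "rpl2": 1, "rps12": 1,
    "ndhA": 1,
}

#: per-site editing efficiencies: skewed high, min 0.21, median 0.93, max 1.0
DEFAULT_EDITING_EFFICIENCIES = (
    0.21, 0.33, 0.47, 0.58, 0.66, 0.72, 0.77, 0.81, 0.84, 0.86, 0.88, 0.89,
    0.90, 0.91, 0.92, 0.92, 0.93, 0.93, 0.93, 0.94, 0.94, 0.95, 0.95, 0.96,
    0.96, 0.97, 0.97, 0.98, 0.98, 0.99, 0.99, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
)

YCF2_LENGTH = 6930
YCF2_REPEATS = ((2599, 45), (5065, 48))  # (offset within gene, copy length)


class SpecSizingError(ValueError):
    """Planted content does not fit the region it was assigned to."""


@dataclass(frozen=True)
class EditingPlan:
    """How many editing sites to plant per category and at what efficiency."""

    efficiencies: tuple[float, ...] = DEFAULT_EDITING_EFFICIENCIES
    n_cds: int = 30
    n_intron: int = 1
    n_intergenic: int = 6

    def __post_init__(self):
        if self.n_cds + self.n_intron + self.n_intergenic != len(self.efficiencies):
            raise ValueError("category counts must sum to the number of efficiencies")
        for e in self.efficiencies:
            if not 0.0 < e <= 1.0:
                raise ValueError(f"editing efficiency {e} outside (0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.efficiencies)


@dataclass(frozen=True)
class GenomeSpec:
    """Blueprint for one synthetic plastome."""

    lsc_len: int = 91210
    ssc_len: int = 14058
    ir_len: int = 31844
    gc_by_region: dict = field(default_factory=lambda: {
        "lsc": 0.3347, "ssc": 0.3017, "ir": 0.4006})
    cds_genes: tuple[str, ...] = tuple(CDS_NAMES)
    trna_genes: tuple[str, ...] = tuple(TRNA_NAMES)
    rrna_genes: tuple[str, ...] = tuple(RRNA_NAMES)
    cds_len_range: tuple[int, int] = (300, 900)
    intron_plan: dict = field(default_factory=lambda: dict(DEFAULT_INTRON_PLAN))
    intron_len_range: tuple[int, int] = (500, 1200)
    operon_plan: tuple = DEFAULT_OPERON_UNITS
    editing_plan: EditingPlan = field(default_factory=EditingPlan)
    utr_len: int = 30
    intron_retention: float = 0.2
    intra_unit_gap_range: tuple[int, int] = (60, 120)
    inter_unit_gap_range: tuple[int, int] = (120, 300)
    seed: int = 0

    def __post_init__(self):
        if min(self.lsc_len, self.ssc_len, self.ir_len) <= 0:
            raise ValueError("all region lengths must be positive")
        if self.ir_len < 1000:
            raise ValueError("ir_len must be >= 1000")
        names = set(self.cds_genes)
        for unit in self.operon_plan:
            if len(unit) < 1:
                raise ValueError("operon unit sizes must be >= 1")
            missing = set(unit) - names
            if missing:
                raise ValueError(f"operon genes not in cds_genes: {sorted(missing)}")
        for g, c in self.intron_plan.items():
            if g not in names:
                raise ValueError(f"intron gene {g!r} not in cds_genes")
            if not 0 <= c <= 2:
                raise ValueError("per-gene intron count must be 0-2")

    @property
    def n_genes(self) -> int:
        return len(self.cds_genes) + len(self.trna_genes) + len(self.rrna_genes)

    @property
    def genome_length(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


def study_spec(seed: int = 0) -> GenomeSpec:
    """Full-scale study conditions: 107 genes, 9 introns/7 genes, 9 operons,
    37 editing sites (30 CDS / 1 intron / 6 intergenic)."""
    return GenomeSpec(seed=seed)


def scaled_spec(factor: int = 20, seed: int = 7) -> GenomeSpec:
    """Region lengths divided by ``factor`` with reduced gene content; used
    for fast structural and pipeline tests."""
    return GenomeSpec(
        lsc_len=91210 // factor, ssc_len=14058 // factor, ir_len=31844 // factor,
        cds_genes=("psbA", "rbcL", "atpB", "atpE", "ycf3", "clpP", "matK",
                   "ndhA"),
        trna_genes=("trnH-GUG", "trnL-UAA"),
        rrna_genes=(),
        cds_len_range=(150, 270),
        intron_plan={"ycf3": 1, "clpP": 1},
        intron_len_range=(80, 150),
        intra_unit_gap_range=(40, 80),
        inter_unit_gap_range=(80, 160),
        operon_plan=(("atpB", "atpE"), ("psbA", "rbcL", "matK")),
        editing_plan=EditingPlan(
            efficiencies=(0.21, 0.6, 0.9, 0.93, 1.0, 1.0),
            n_cds=4, n_intron=1, n_intergenic=1),
        seed=seed,
    )


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _random_codons(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """Random stop-free codon string with per-base GC near ``gc``."""
    bases = "ACGT"
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = []
    while len(out) < n_codons:
        cod = "".join(bases[i] for i in rng.choice(4, size=3, p=probs))
        if cod not in _STOPS:
            out.append(cod)
    return "".join(out)


def _random_cds(rng: np.random.Generator, length: int, gc: float) -> str:
    """ATG ... TAA coding sequence of exactly ``length`` (multiple of 3)."""
    assert length % 3 == 0 and length >= 9
    return "ATG" + _random_codons(rng, length // 3 - 2, gc) + "TAA"


def _make_ycf2(rng: np.random.Generator, gc: float) -> str:
    """The largest plastid ORF with its two internal tandem duplications.

    Flanking bases are adjusted so each duplication is maximal at exactly
    its planted length (no chance single-base extension).
    """
    s = list(_random_cds(rng, YCF2_LENGTH, gc))
    for off, ln in YCF2_REPEATS:
        s[off + ln:off + 2 * ln] = s[off:off + ln]
        if s[off - 1] == s[off + ln - 1]:  # blocks left extension
            s[off - 1] = next(b for b in "ACGT" if b != s[off + ln - 1])
        if s[off + 2 * ln] == s[off + ln]:  # blocks right extension
            s[off + 2 * ln] = next(b for b in "ACGT" if b != s[off + ln])
    return "".join(s)


def _random_intron(rng: np.random.Generator, length: int, gc: float,
                   prev_exon_char: str, next_exon_char: str) -> str:
    """Group-II intron: 5' GTGYG ... AY 3', boundaries made shift-unambiguous.

    The terminal Y is chosen so the last intron base differs from the exon
    base preceding the donor (no 1-bp left slide); callers must also ensure
    the exon base after the acceptor is not G (no 1-bp right slide).
    """
    assert length >= 12
    y5 = "CT"[rng.integers(0, 2)]
    y3_choices = [c for c in "CT" if c != prev_exon_char] or ["C"]
    y3 = y3_choices[int(rng.integers(0, len(y3_choices)))]
    mid = random_seq_exact_gc(rng, length - 7, gc)
    return f"GTG{y5}G{mid}A{y3}"


@dataclass
class _GenePlan:
    name: str
    gene_type: str
    coding_seq: str              # coding orientation, introns not yet inserted
    intron_lengths: list[int]


def _plan_genes(spec: GenomeSpec, rng: np.random.Generator) -> dict[str, _GenePlan]:
    plans: dict[str, _GenePlan] = {}
    for name in spec.cds_genes:
        if name == "ycf2":
            seq = _make_ycf2(rng, spec.gc_by_region["lsc"])
        else:
            lo, hi = spec.cds_len_range
            n_int_ = spec.intron_plan.get(name, 0)
            # intron hosts need room for shift-free junctions and exon margins
            lo = max(lo, 300 * n_int_ + 180) if n_int_ else lo
            hi = max(hi, lo + 60)
            n_cod = int(rng.integers(lo // 3, hi // 3 + 1))
            seq = _random_cds(rng, max(3 * n_cod, 9), spec.gc_by_region["lsc"])
        n_int = spec.intron_plan.get(name, 0)
        ilo, ihi = spec.intron_len_range
        ilens = [int(rng.integers(ilo, ihi + 1)) for _ in range(n_int)]
        plans[name] = _GenePlan(name, "CDS", seq, ilens)
    for name in spec.trna_genes:
        plans[name] = _GenePlan(name, "tRNA",
                                random_seq_exact_gc(rng, 75, spec.gc_by_region["lsc"]), [])
    for name in spec.rrna_genes:
        ln = RRNA_LENGTHS.get(name, 1200)
        plans[name] = _GenePlan(name, "rRNA",
                                random_seq_exact_gc(rng, ln, spec.gc_by_region["ssc"]), [])
    return plans


def _insert_introns(plan: _GenePlan, rng: np.random.Generator, gc: float):
    """Insert planted introns into a coding sequence.

    Returns ``(full_seq, exon_segments, intron_segments)`` in coding
    coordinates of the final (intron-containing) sequence.
    """
    seq = plan.coding_seq
    if not plan.intron_lengths:
        return seq, [(0, len(seq))], []
    margin = 60
    n = len(seq)
    points = []
    attempts = 0
    while len(points) < len(plan.intron_lengths):
        p = int(rng.integers(margin, n - margin))
        if seq[p] != "G" and all(abs(p - q) >= 2 * margin for q in points):
            points.append(p)
        attempts += 1
        if attempts > 1000:
            raise SpecSizingError(f"gene {plan.name}: cannot place introns "
                                  f"(coding length {n} too small)")
    points.sort()
    pieces, exons, introns_ = [], [], []
    cursor = 0     # position in final sequence
    prev = 0       # position in coding sequence
    for p, ilen in zip(points, plan.intron_lengths):
        exon = seq[prev:p]
        pieces.append(exon)
        exons.append((cursor, cursor + len(exon)))
        cursor += len(exon)
        intron = _random_intron(rng, ilen, gc, prev_exon_char=seq[p - 1],
                                next_exon_char=seq[p])
        pieces.append(intron)
        introns_.append((cursor, cursor + len(intron)))
        cursor += len(intron)
        prev = p
    tail = seq[prev:]
    pieces.append(tail)
    exons.append((cursor, cursor + len(tail)))
    return "".join(pieces), exons, introns_


def generate_genome(spec: GenomeSpec):
    """Build one synthetic plastome.

    Returns ``(CircularGenome, Annotation, GroundTruth)``.  The emitted
    sequence is on the canonical rotation LSC + IRa + SSC + IRb; the IRb
    interval is the exact reverse complement of IRa; genes never overlap;
    region GC matches the spec to well within 1.5 percentage points.
    """
    rng_genes, rng_layout, rng_seq, rng_edit = _rngs(spec.seed, 4)
    plans = _plan_genes(spec, rng_genes)

    # realise gene sequences with introns, in coding orientation
    built: dict[str, tuple[str, list, list]] = {}
    for name, plan in plans.items():
        gc = spec.gc_by_region["lsc"]
        built[name] = _insert_introns(plan, rng_genes, gc)

    # -- transcription units ------------------------------------------------
    unit_gene_lists: list[tuple[str, ...]] = []
    assigned: set[str] = set()
    for unit in spec.operon_plan:
        if isinstance(unit, int):
            free = [g for g in spec.cds_genes if g not in assigned]
            unit = tuple(free[:unit])
        unit_gene_lists.append(tuple(unit))
        assigned |= set(unit)
    for name in list(spec.cds_genes) + list(spec.trna_genes) + list(spec.rrna_genes):
        if name not in assigned:
            unit_gene_lists.append((name,))
            assigned.add(name)

    # -- region assignment: the ndhA unit and the rRNAs to SSC, rest to LSC --
    def to_ssc(genes: tuple[str, ...]) -> bool:
        return "ndhA" in genes or any(g.startswith("rrn") for g in genes)

    lsc_units = [u for u in unit_gene_lists if not to_ssc(u)]
    ssc_units = [u for u in unit_gene_lists if to_ssc(u)]
    rng_layout.shuffle(lsc_units)
    rng_layout.shuffle(ssc_units)

    margin = 100

    def layout(units, region_len, region_name):
        """Assign region-local coordinates; returns placed gene intervals."""
        placements = []  # (unit genes, [(gene, local_start)], strand)
        pos = margin
        for genes in units:
            strand = "+-"[int(rng_layout.integers(0, 2))]
            order = genes if strand == "+" else tuple(reversed(genes))
            pos += spec.utr_len
            gene_pos = []
            glo, ghi = spec.intra_unit_gap_range
            for i, g in enumerate(order):
                if i > 0:
                    pos += int(rng_layout.integers(glo, ghi + 1))
                gene_pos.append((g, pos))
                pos += len(built[g][0])
            pos += spec.utr_len
            placements.append((genes, gene_pos, strand))
            ulo, uhi = spec.inter_unit_gap_range
            pos += int(rng_layout.integers(ulo, uhi + 1))
        if pos + margin > region_len:
            raise SpecSizingError(
                f"{region_name}: planted content needs {pos + margin} bp "
                f"but the region is {region_len} bp")
        return placements

    lsc_placed = layout(lsc_units, spec.lsc_len, "LSC")
    ssc_placed = layout(ssc_units, spec.ssc_len, "SSC")

    # -- assemble region sequences with exact-GC intergenic fill ------------
    def fill_region(placed, region_len, gc):
        arr = np.full(region_len, -1, dtype=np.int16)
        lookup = {"A": 0, "C": 1, "G": 2, "T": 3}
        genic_gc = 0
        genic_n = 0
        for genes, gene_pos, strand in placed:
            for g, local in gene_pos:
                full, _, _ = built[g]
                seq = full if strand == "+" else revcomp(full)
                codes = [lookup[c] for c in seq]
                arr[local:local + len(seq)] = codes
                genic_gc += sum(1 for c in seq if c in "GC")
                genic_n += len(seq)
        free = int((arr == -1).sum())
        want_gc = int(round(gc * region_len)) - genic_gc
        want_gc = min(max(want_gc, 0), free)
        fill_codes = np.concatenate([
            np.where(rng_seq.integers(0, 2, want_gc) == 0, 1, 2),
            np.where(rng_seq.integers(0, 2, free - want_gc) == 0, 0, 3),
        ]).astype(np.int16)
        rng_seq.shuffle(fill_codes)
        arr[arr == -1] = fill_codes
        return "".join("ACGT"[c] for c in arr)

    lsc_seq = fill_region(lsc_placed, spec.lsc_len, spec.gc_by_region["lsc"])
    ssc_seq = fill_region(ssc_placed, spec.ssc_len, spec.gc_by_region["ssc"])
    ira_seq = random_seq_exact_gc(rng_seq, spec.ir_len, spec.gc_by_region["ir"])
    irb_seq = revcomp(ira_seq)

    seq = list(lsc_seq + ira_seq + ssc_seq + irb_seq)
    L, I, S = spec.lsc_len, spec.ir_len, spec.ssc_len
    n = len(seq)

    # keep the planted IR inextensible at both boundaries
    if seq[L - 1] == _COMP[seq[0]]:
        alt = [b for b in "ACGT" if b != _COMP[seq[0]] and
               (b in "GC") == (seq[L - 1] in "GC")]
        seq[L - 1] = alt[0]
    if seq[L + I] == _COMP[seq[L + I + S - 1]]:
        alt = [b for b in "ACGT" if b != _COMP[seq[L + I + S - 1]] and
               (b in "GC") == (seq[L + I] in "GC")]
        seq[L + I] = alt[0]
    sequence = "".join(seq)

    # -- genomic gene models and truth --------------------------------------
    genes: list[GeneModel] = []
    introns: list[IntronTruth] = []
    units: list[TranscriptionUnit] = []
    region_offset = {"lsc": 0, "ssc": L + I}
    unit_counter = 0
    for placed, region in ((lsc_placed, "lsc"), (ssc_placed, "ssc")):
        off = region_offset[region]
        for genes_in_unit, gene_pos, strand in placed:
            member_names = []
            starts, ends = [], []
            for g, local in gene_pos:
                full, exon_segs, intron_segs = built[g]
                g0 = off + local
                glen = len(full)
                if strand == "+":
                    exons = tuple((g0 + s, g0 + e) for s, e in exon_segs)
                    g_introns = [(g0 + s, g0 + e) for s, e in intron_segs]
                else:
                    exons = tuple(sorted((g0 + glen - e, g0 + glen - s)
                                         for s, e in exon_segs))
                    g_introns = sorted((g0 + glen - e, g0 + glen - s)
                                       for s, e in intron_segs)
                genes.append(GeneModel(name=g, strand=strand, exons=exons,
                                       gene_type=plans[g].gene_type))
                for ds, de in g_introns:
                    introns.append(IntronTruth(gene=g, donor=ds, acceptor=de))
                member_names.append(g)
                starts.append(g0)
                ends.append(g0 + glen)
            unit_counter += 1
            tx_order = tuple(genes_in_unit)  # transcription order
            units.append(TranscriptionUnit(
                id=f"unit{unit_counter:03d}",
                gene_names=tx_order, strand=strand,
                start=min(starts) - spec.utr_len,
                end=max(ends) + spec.utr_len))

    annotation = Annotation(genome_id=f"synthetic_plastome_seed{spec.seed}",
                            genome_length=n, genes=genes)
    genome = CircularGenome(id=annotation.genome_id, sequence=sequence)

    editing = _plant_editing(spec, genome, annotation, introns, units, rng_edit)

    truth = GroundTruth(
        region_coords={"lsc": (0, L), "ira": (L, L + I),
                       "ssc": (L + I, L + I + S), "irb": (L + I + S, n)},
        annotation=annotation, introns=introns, editing_sites=editing,
        units=units, seed=spec.seed)
    return genome, annotation, truth


def _plant_editing(spec, genome, annotation, introns, units, rng):
    """Choose genomic positions for the planned editing sites.

    A site is a C on its transcript strand (genome C for plus-strand units,
    genome G for minus-strand); sites keep clear of exon junctions and of
    transcript ends so alignment noise cannot shadow them.  The intron-
    category site is planted fully edited (efficiency 1.0), as group-II
    intron sites are typically observed in unspliced molecules.
    """
    plan = spec.editing_plan
    if plan.n_sites == 0:
        return []
    effs = list(plan.efficiencies)
    rng.shuffle(effs)
    # hand the intron site an efficiency of 1.0 when one is planned
    if plan.n_intron > 0:
        if 1.0 in effs:
            effs.remove(1.0)
            intron_effs = [1.0] * min(plan.n_intron, 1)
            while len(intron_effs) < plan.n_intron:
                intron_effs.append(effs.pop())
        else:
            intron_effs = [effs.pop() for _ in range(plan.n_intron)]
    else:
        intron_effs = []

    seq = genome.sequence
    used: set[int] = set()
    sites: list[EditingTruth] = []
    unit_of_gene = {g: u for u in units for g in u.gene_names}

    def strand_c_positions(lo, hi, strand, margin_lo=0, margin_hi=0):
        want = "C" if strand == "+" else "G"
        return [p for p in range(lo + margin_lo, hi - margin_hi)
                if seq[p] == want]

    # CDS sites: spread over editable coding genes (ycf2 excluded: its
    # internal tandem repeats would confound per-base mismatch assignment)
    cds_genes = [g for g in annotation
                 if g.gene_type == "CDS" and g.name != "ycf2"
                 and g.name in unit_of_gene]
    rng.shuffle(cds_genes)
    need = plan.n_cds
    gi = 0
    while need > 0 and cds_genes:
        g = cds_genes[gi % len(cds_genes)]
        gi += 1
        cands = []
        for s, e in g.exons:
            cands.extend(strand_c_positions(s, e, g.strand, 8, 8))
        cands = [p for p in cands if all(abs(p - q) >= 6 for q in used)]
        if not cands:
            continue
        p = int(cands[int(rng.integers(0, len(cands)))])
        used.add(p)
        sites.append(EditingTruth(position=p, strand=g.strand,
                                  efficiency=effs.pop(), category="CDS"))
        need -= 1
    if need > 0:
        raise SpecSizingError("not enough editable C positions for CDS sites")

    # intron sites
    for i in range(plan.n_intron):
        intr = introns[i % len(introns)] if introns else None
        if intr is None:
            raise SpecSizingError("intron editing site planned but no introns planted")
        g = annotation.by_name(intr.gene)
        cands = strand_c_positions(intr.donor, intr.acceptor, g.strand, 12, 12)
        cands = [p for p in cands if all(abs(p - q) >= 6 for q in used)]
        p = int(cands[int(rng.integers(0, len(cands)))])
        used.add(p)
        sites.append(EditingTruth(position=p, strand=g.strand,
                                  efficiency=intron_effs[i], category="intron"))

    # intergenic sites: inside unit UTR extensions, clear of transcript tips
    utr_units = [u for u in units]
    rng.shuffle(utr_units)
    need = plan.n_intergenic
    ui = 0
    genic = [(g.start, g.end) for g in annotation]
    while need > 0:
        if ui >= 4 * len(utr_units):
            raise SpecSizingError("not enough editable C positions in UTRs")
        u = utr_units[ui % len(utr_units)]
        ui += 1
        first = min(g for g in (annotation.by_name(nm).start for nm in u.gene_names))
        last = max(g for g in (annotation.by_name(nm).end for nm in u.gene_names))
        windows = [(u.start + 8, first), (last, u.end - 8)]
        cands = []
        for lo, hi in windows:
            cands.extend(strand_c_positions(lo, hi, u.strand))
        cands = [p for p in cands
                 if all(abs(p - q) >= 6 for q in used)
                 and not any(s <= p < e for s, e in genic)]
        if not cands:
            continue
        p = int(cands[int(rng.integers(0, len(cands)))])
        used.add(p)
        sites.append(EditingTruth(position=p, strand=u.strand,
                                  efficiency=effs.pop(), category="intergenic"))
        need -= 1

    sites.sort(key=lambda s: s.position)
    return sites


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Indel-dominated errors (sub:ins:del = 1:2:2) at total rate ``rate``."""
    if rate <= 0 or not seq:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = np.sort(rng.choice(len(seq), size=min(n_err, len(seq)), replace=False))
    kinds = _ERR_KINDS[rng.choice(3, size=len(pos), p=_ERR_PROBS)]
    bases = "ACGT"
    out = []
    prev = 0
    for p, kind in zip(pos, kinds):
        out.append(seq[prev:p])
        if kind == "S":
            alts = [b for b in bases if b != seq[p]]
            out.append(alts[int(rng.integers(0, 3))])
            prev = p + 1
        elif kind == "I":
            out.append(bases[int(rng.integers(0, 4))])
            prev = p  # keep the original base after the insertion
        else:  # deletion
            prev = p + 1
    out.append(seq[prev:])
    return "".join(out)


def simulate_genomic_reads(genome: CircularGenome, n: int, mean_len: int,
                           error_rate: float, seed: int = 0,
                           origin: str = "chloroplast") -> LongReadSet:
    """Long genomic reads with log-normal lengths and indel-dominated errors.

    Lengths are drawn log-normal (shape 0.5) and truncated to
    ``[300, 3 * mean_len]``; starts are uniform on the circle, so reads may
    wrap the origin; strands are random.  Truth intervals are recorded on
    each read.
    """
    if not 0 <= error_rate < 0.3:
        raise ValueError("error_rate must be in [0, 0.3)")
    if n == 0:
        return LongReadSet(reads=[], seed=seed)
    rng = np.random.default_rng(seed)
    sigma = 0.5
    mu = math.log(mean_len) - sigma ** 2 / 2
    lo, hi = min(300, mean_len), 3 * mean_len
    lengths = []
    while len(lengths) < n:
        draw = rng.lognormal(mu, sigma, size=n)
        lengths.extend(int(x) for x in draw if lo <= x <= hi)
    lengths = lengths[:n]
    reads = []
    glen = len(genome)
    for i, ln in enumerate(lengths):
        start = int(rng.integers(0, glen))
        end = start + ln
        raw = genome.fetch(start, end)
        strand = "+-"[int(rng.integers(0, 2))]
        if strand == "-":
            raw = revcomp(raw)
        seq = apply_errors(raw, error_rate, rng)
        reads.append(LongRead(id=f"read{i:06d}", sequence=seq,
                              source_start=start, source_end=end,
                              strand=strand, origin=origin))
    return LongReadSet(reads=reads, seed=seed)


def mix_decoy_reads(reads: LongReadSet, decoy_genome: CircularGenome,
                    fraction: float, seed: int = 0,
                    error_rate: float = 0.12) -> LongReadSet:
    """Replace each read with a decoy-genome read with probability ``fraction``.

    Output size equals input size; every read keeps a truthful ``origin``
    label so classifier sensitivity and false-positive rate are measurable.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(reads)
    if n == 0 or fraction == 0:
        return LongReadSet(reads=list(reads), seed=seed)
    take = rng.random(n) < fraction
    mean_len = max(300, int(round(reads.total_bases() / n)))
    decoys = simulate_genomic_reads(decoy_genome, int(take.sum()), mean_len,
                                    error_rate, seed=int(rng.integers(2 ** 31)),
                                    origin="decoy")
    out = []
    di = iter(decoys)
    for r, is_decoy in zip(reads, take):
        if is_decoy:
            d = next(di)
            out.append(LongRead(id=f"decoy_{d.id}", sequence=d.sequence,
                                source_start=d.source_start,
                                source_end=d.source_end, strand=d.strand,
                                origin="decoy"))
        else:
            out.append(r)
    return LongReadSet(reads=out, seed=seed)


def simulate_isoseq(genome: CircularGenome, truth: GroundTruth, depth: int,
                    error_rate: float = 0.01, seed: int = 0,
                    intron_retention: float = 0.2) -> TranscriptReadSet:
    """Full-length cDNAs: one molecule per transcription unit per depth unit.

    Introns are spliced out (each independently retained with the spec's
    retention probability, emulating incomplete splicing of group-II
    introns); at each planted editing site a covering molecule carries T for
    C with probability equal to the site efficiency (strand-aware); minus-
    strand units emit the reverse complement.  Each read records its true
    unit.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    spec_retention = intron_retention
    introns_by_unit: dict[str, list[IntronTruth]] = {}
    gene_unit = {g: u.id for u in truth.units for g in u.gene_names}
    for intr in truth.introns:
        uid = gene_unit.get(intr.gene)
        if uid:
            introns_by_unit.setdefault(uid, []).append(intr)
    sites_by_unit: dict[str, list[EditingTruth]] = {}
    for site in truth.editing_sites:
        for u in truth.units:
            if u.start <= site.position < u.end and site.strand == u.strand:
                sites_by_unit.setdefault(u.id, []).append(site)
                break

    reads = []
    idx = 0
    for u in truth.units:
        u_introns = sorted(introns_by_unit.get(u.id, []), key=lambda i: i.donor)
        u_sites = sites_by_unit.get(u.id, [])
        for _ in range(depth):
            keep_introns = [i for i in u_introns
                            if rng.random() < spec_retention]
            # genomic segments retained in the molecule (plus-strand order)
            segs = []
            cursor = u.start
            for intr in u_introns:
                if intr in keep_introns:
                    continue
                segs.append((cursor, intr.donor))
                cursor = intr.acceptor
            segs.append((cursor, u.end))
            pieces = [list(genome.fetch(s, e)) for s, e in segs]
            for site in u_sites:
                # skip sites inside spliced-out introns
                for seg_i, (s, e) in enumerate(segs):
                    if s <= site.position < e:
                        if rng.random() < site.efficiency:
                            local = site.position - s
                            pieces[seg_i][local] = (
                                "T" if site.strand == "+" else "A")
                        break
            mol = "".join("".join(p) for p in pieces)
            if u.strand == "-":
                mol = revcomp(mol)
            mol = apply_errors(mol, error_rate, rng)
            reads.append(TranscriptRead(id=f"tx{idx:06d}", sequence=mol,
                                        unit_id=u.id, strand=u.strand,
                                        span=(u.start, u.end)))
            idx += 1
    return TranscriptReadSet(reads=reads, seed=seed)


# ---------------------------------------------------------------------------
# synthetic marker alignments for the divergence module
# ---------------------------------------------------------------------------

def simulate_marker_alignment(n_taxa: int, length: int, subs_per_taxon,
                              seed: int = 0) -> tuple[dict[str, str], dict]:
    """Star-phylogeny marker with planted, disjoint substitutions.

    Each taxon receives its own substitutions at positions no other taxon
    touches, so the true p-distance between taxa *i* and *j* is exactly
    ``(k_i + k_j) / length``.  Returns ``(alignment, expected_distances)``.
    """
    rng = np.random.default_rng(seed)
    if isinstance(subs_per_taxon, int):
        subs_per_taxon = [subs_per_taxon] * n_taxa
    total = sum(subs_per_taxon)
    if total > length:
        raise ValueError("more substitutions than sites")
    ancestor = random_seq_exact_gc(rng, length, 0.4)
    pool = rng.choice(length, size=total, replace=False)
    msa = {}
    names = [f"taxon{i+1}" for i in range(n_taxa)]
    start = 0
    for name, k in zip(names, subs_per_taxon):
        s = list(ancestor)
        for p in pool[start:start + k]:
            alts = [b for b in "ACGT" if b != s[p]]
            s[p] = alts[int(rng.integers(0, 3))]
        start += k
        msa[name] = "".join(s)
    expected = {}
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            expected[(names[i], names[j])] = (
                (subs_per_taxon[i] + subs_per_taxon[j]) / length)
    return msa, expected
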