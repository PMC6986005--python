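"""Intron, C->U editing and operon calling from transcript alignments.

These are the three transcriptomic readouts a full-length-cDNA experiment
gives over a plastome: splice junctions cluster into intron calls; per-base
mismatch pileups at C positions (strand-aware) yield editing sites with an
efficiency (edited / covering molecules) filtered by a one-sided binomial
test against the sequencing error rate with Benjamini-Hochberg control; and
transcripts covering identical ordered gene sets define polycistronic
transcription units (operons).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from Bio.Seq import Seq

from .models import Annotation, CircularGenome, GeneModel

PLASTID_CODON_TABLE = 11  # bacterial/plastid genetic code


# ---------------------------------------------------------------------------
# introns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntronCall:
    gene: str
    donor: int
    acceptor: int
    support: int
    motif_match: bool

    @property
    def length(self) -> int:
        return self.acceptor - self.donor


def _junction_support(aln, junction, flank=10):
    """True when the read spans >= ``flank`` bp into both flanking exons."""
    for i in range(len(aln.blocks) - 1):
        if (aln.blocks[i].t_end, aln.blocks[i + 1].t_start) == junction:
            left = aln.blocks[i].t_end - aln.blocks[i].t_start
            right = aln.blocks[i + 1].t_end - aln.blocks[i + 1].t_start
            return left >= flank and right >= flank
    return False


def call_introns(alignments, annotation: Annotation,
                 genome: CircularGenome | None = None,
                 min_support: int = 3, min_frac: float = 0.05,
                 min_len: int = 50, max_len: int = 5000,
                 cluster_window: int = 10) -> list[IntronCall]:
    """Cluster junctions and call one intron per cluster at the modal pair.

    Junctions within ``cluster_window`` bp of each other are one cluster;
    the exact (donor, acceptor) seen most often becomes the call boundary.
    Calls are assigned to the gene containing them; support counts only
    reads spanning at least 10 bp into both flanking exons, and a call
    additionally needs support from at least ``min_frac`` of the same-strand
    reads whose alignment spans the junction (rare recurrent mismapping at
    deep coverage cannot reach a few-percent spliced fraction, while genuine
    introns are spliced in most molecules).
    """
    junctions: Counter = Counter()
    for aln in alignments:
        for j in aln.introns():
            if min_len <= j[1] - j[0] <= max_len and _junction_support(aln, j):
                junctions[(j, aln.strand)] += 1

    # cluster by proximity of donor coordinates
    items = sorted(junctions.items(), key=lambda kv: kv[0][0])
    clusters: list[list] = []
    for (j, strand), count in items:
        placed = False
        for cl in clusters:
            (j0, s0), _ = cl[0]
            if s0 == strand and abs(j[0] - j0[0]) <= cluster_window \
                    and abs(j[1] - j0[1]) <= cluster_window:
                cl.append(((j, strand), count))
                placed = True
                break
        if not placed:
            clusters.append([((j, strand), count)])

    calls = []
    for cl in clusters:
        total = sum(c for _, c in cl)
        if total < min_support:
            continue
        (j, strand), _ = max(cl, key=lambda kv: (kv[1], -kv[0][0][0]))
        donor, acceptor = j
        # denominator: same-strand reads covering either junction flank
        cover_d = sum(1 for a in alignments if a.strand == strand
                      and a.t_start <= donor <= a.t_end)
        cover_a = sum(1 for a in alignments if a.strand == strand
                      and a.t_start <= acceptor <= a.t_end)
        spanning = max(cover_d, cover_a)
        if spanning and total < min_frac * spanning:
            continue
        host = None
        for g in annotation:
            if g.strand == strand and g.start <= donor and acceptor <= g.end:
                host = g.name
                break
        motif = False
        if genome is not None:
            t = genome.sequence + genome.sequence
            from .align import _match_motif
            motif = _match_motif(t, donor, acceptor, strand)
        calls.append(IntronCall(gene=host or "intergenic", donor=donor,
                                acceptor=acceptor, support=total,
                                motif_match=motif))
    calls.sort(key=lambda c: c.donor)
    return calls


def compare_intron_lengths(annotations: dict[str, Annotation],
                           genes: list[str] | None = None) -> pd.DataFrame:
    """Long-format table of gene / exon / intron lengths across species.

    A gene present in a species but carrying no intron at a given index is
    reported with status ``absent`` (the grass clpP/rpoC1 pattern) rather
    than a zero length.
    """
    if genes is None:
        genes = sorted({g.name for ann in annotations.values() for g in ann})
    max_introns = {}
    for ann in annotations.values():
        for g in ann:
            max_introns[g.name] = max(max_introns.get(g.name, 0),
                                      len(g.introns()))
    rows = []
    for species, ann in annotations.items():
        present = {g.name: g for g in ann}
        for name in genes:
            if name not in present:
                continue
            g = present[name]
            introns = g.introns()
            exons = [e - s for s, e in g.exons]
            for idx in range(max(max_introns.get(name, 0), 0)):
                if idx < len(introns):
                    ilen, status = introns[idx][1] - introns[idx][0], "present"
                else:
                    ilen, status = None, "absent"
                rows.append({"species": species, "gene": name,
                             "intron_index": idx + 1, "gene_span": g.span,
                             "exonic_length": sum(exons),
                             "intron_length": ilen, "status": status})
            if max_introns.get(name, 0) == 0:
                rows.append({"species": species, "gene": name,
                             "intron_index": 0, "gene_span": g.span,
                             "exonic_length": sum(exons),
                             "intron_length": None, "status": "intronless"})
    return pd.DataFrame(rows)


def intron_length_from_annotation(annotation: Annotation, gene: str,
                                  index: int = 0) -> int:
    """Length of the ``index``-th intron of ``gene`` per its annotation."""
    g = annotation.by_name(gene)
    introns = g.introns()
    if index >= len(introns):
        raise ValueError(f"{gene} has {len(introns)} introns; index {index}")
    s, e = introns[index]
    return e - s


# ---------------------------------------------------------------------------
# editing
# ---------------------------------------------------------------------------

@dataclass
class EditingSite:
    position: int
    strand: str
    ref_base: str            # C on the transcript strand
    edited: int
    covering: int
    efficiency: float
    p_value: float
    q_value: float
    category: str = ""       # CDS | intron | intergenic
    gene: str = ""
    codon_position: int | None = None
    aa_change: str = ""      # e.g. "S>L"; "L>L (synonymous)"


def call_editing(alignments, genome: CircularGenome, annotation: Annotation,
                 min_cov: int = 10, min_eff: float = 0.10, err: float = 0.02,
                 alpha: float = 0.05, intron_calls=None) -> list[EditingSite]:
    """Call C->U editing sites from strand-aware mismatch pileups.

    A candidate is any genomic position covered by >= ``min_cov``
    same-strand transcripts whose reference base is C on that strand
    (genome C for plus, genome G for minus).  The site is called when the
    edited fraction is >= ``min_eff`` and a one-sided binomial test of the
    edited count against the error rate ``err`` survives Benjamini-Hochberg
    correction across all candidates at ``alpha``.
    """
    n = len(genome)
    cov = {"+": np.zeros(n, dtype=np.int32), "-": np.zeros(n, dtype=np.int32)}
    edited = {"+": defaultdict(int), "-": defaultdict(int)}
    for aln in alignments:
        c = cov[aln.strand]
        for b in aln.blocks:
            lo, hi = b.t_start, b.t_end
            if hi <= n:
                c[lo:hi] += 1
            else:
                c[lo % n:] += 1
                c[:hi - n] += 1
        # pileup semantics: a read contributes to the denominator only where
        # it has an aligned base, so per-read deletions are subtracted
        if aln.cigar:
            tpos = aln.t_start
            for op, ln in aln.cigar:
                if op == "D":
                    for p in range(tpos, tpos + ln):
                        c[p % n] -= 1
                if op in ("=", "X", "D", "N", "M"):
                    tpos += ln
        want = ("C", "T") if aln.strand == "+" else ("G", "A")
        for pos, ref, alt in aln.mismatches:
            if (ref, alt) == want:
                edited[aln.strand][pos % n] += 1

    seq = genome.sequence
    rows = []  # (strand, pos, k, ncov)
    for strand in "+-":
        want_ref = "C" if strand == "+" else "G"
        c = cov[strand]
        cand = np.flatnonzero(c >= min_cov)
        for pos in cand:
            if seq[pos] != want_ref:
                continue
            rows.append((strand, int(pos), edited[strand].get(int(pos), 0),
                         int(c[pos])))
    if not rows:
        return []
    ks = np.array([r[2] for r in rows])
    ns = np.array([r[3] for r in rows])
    pvals = binom.sf(ks - 1, ns, err)  # P(X >= k)
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")

    sites = []
    for (strand, pos, k, ncov), p, q, rej in zip(rows, pvals, qvals, reject):
        eff = k / ncov
        if not rej or eff < min_eff:
            continue
        site = EditingSite(position=pos, strand=strand,
                           ref_base="C", edited=k, covering=ncov,
                           efficiency=eff, p_value=float(p), q_value=float(q))
        annotate_editing(site, annotation, genome, intron_calls=intron_calls)
        sites.append(site)
    sites.sort(key=lambda s: s.position)
    return sites


def annotate_editing(site: EditingSite, annotation: Annotation,
                     genome: CircularGenome, intron_calls=None) -> EditingSite:
    """Attach category, codon position and amino-acid consequence.

    CDS sites are translated under the plastid/bacterial code (table 11);
    a site inside a called intron is categorised ``intron``; anything else
    is ``intergenic``.  The reference base must read C on the site strand.
    """
    base = genome.sequence[site.position]
    expected = "C" if site.strand == "+" else "G"
    if base != expected:
        raise ValueError(
            f"editing site at {site.position}:{site.strand} has reference "
            f"base {base}, not C on its strand")
    # inside a CDS exon on the same strand?
    for g in annotation:
        if g.gene_type != "CDS" or g.strand != site.strand:
            continue
        if any(s <= site.position < e for s, e in g.exons):
            site.category = "CDS"
            site.gene = g.name
            _codon_consequence(site, g, genome)
            return site
    # inside a called (or annotated) intron?
    intron_spans = []
    if intron_calls:
        intron_spans = [(c.donor, c.acceptor, c.gene) for c in intron_calls]
    else:
        intron_spans = [(s, e, g.name) for g in annotation
                        for s, e in g.introns()]
    for s, e, gname in intron_spans:
        if s <= site.position < e:
            site.category = "intron"
            site.gene = gname
            return site
    site.category = "intergenic"
    return site


def _codon_consequence(site: EditingSite, gene: GeneModel,
                       genome: CircularGenome) -> None:
    cds = gene.spliced_sequence(genome)
    # map genomic position to coding coordinate
    offset = 0
    coding_pos = None
    exons = gene.exons if gene.strand == "+" else list(reversed(gene.exons))
    for s, e in exons:
        if s <= site.position < e:
            within = (site.position - s) if gene.strand == "+" \
                else (e - 1 - site.position)
            coding_pos = offset + within
            break
        offset += e - s
    if coding_pos is None:
        return
    ci = coding_pos // 3
    site.codon_position = coding_pos % 3 + 1
    codon = cds[3 * ci:3 * ci + 3]
    if len(codon) < 3:
        return
    edited_codon = (codon[:coding_pos % 3] + "T" + codon[coding_pos % 3 + 1:])
    aa_before = str(Seq(codon).translate(table=PLASTID_CODON_TABLE))
    aa_after = str(Seq(edited_codon).translate(table=PLASTID_CODON_TABLE))
    if aa_before == aa_after:
        site.aa_change = f"{aa_before}>{aa_after} (synonymous)"
    else:
        site.aa_change = f"{aa_before}>{aa_after}"


def editing_summary(sites: list[EditingSite]) -> dict:
    """Category totals, per-gene counts and efficiency min/median/max."""
    out: dict = {"total": len(sites)}
    cats = Counter(s.category for s in sites)
    out["by_category"] = {"CDS": cats.get("CDS", 0),
                          "intron": cats.get("intron", 0),
                          "intergenic": cats.get("intergenic", 0)}
    per_gene = Counter(s.gene for s in sites if s.gene)
    out["by_gene"] = dict(sorted(per_gene.items()))
    if sites:
        effs = np.array([s.efficiency for s in sites])
        out["efficiency"] = {"min": float(effs.min()),
                             "median": float(np.median(effs)),
                             "max": float(effs.max())}
    else:
        out["efficiency"] = {"min": 0.0, "median": 0.0, "max": 0.0}
    return out


def combine_site_sets(known: set[int], new: set[int]) -> dict:
    """Set arithmetic for merging editing catalogues from two platforms."""
    overlap = known & new
    return {"known": len(known), "new": len(new), "overlap": len(overlap),
            "combined": len(known | new)}


# ---------------------------------------------------------------------------
# operons
# ---------------------------------------------------------------------------

@dataclass
class OperonCall:
    name: str
    genes: tuple[str, ...]   # transcription order
    strand: str
    start: int
    end: int
    support: int
    subset_of: str = ""      # name of a superset operon, when one exists

    @property
    def span(self) -> int:
        return self.end - self.start


def _covered_genes(aln, annotation: Annotation, cds_cov: float):
    """Genes whose exonic span is covered >= ``cds_cov`` by this read,
    ordered in transcription direction."""
    covered = []
    for g in annotation:
        if g.strand != aln.strand:
            continue
        need = cds_cov * g.exonic_length
        got = 0
        for es, ee in g.exons:
            for b in aln.blocks:
                got += max(0, min(ee, b.t_end) - max(es, b.t_start))
        if got >= need:
            covered.append(g)
    covered.sort(key=lambda g: g.start, reverse=(aln.strand == "-"))
    return tuple(g.name for g in covered)


def call_operons(alignments, annotation: Annotation, min_genes: int = 2,
                 min_support: int = 3, cds_cov: float = 0.5) -> list[OperonCall]:
    """Group transcripts by identical ordered covered-gene sets.

    Groups with >= ``min_genes`` genes and >= ``min_support`` supporting
    transcripts become operon calls, named by the gene-family prefix of
    their first gene (title-cased) with _1/_2 ordinals when a family yields
    several operons.  A call whose gene set is a contiguous subset of a
    larger call is cross-referenced, never merged.
    """
    groups: Counter = Counter()
    strands: dict[tuple, str] = {}
    for aln in alignments:
        genes = _covered_genes(aln, annotation, cds_cov)
        if len(genes) >= min_genes:
            groups[genes] += 1
            strands[genes] = aln.strand

    raw = []
    for genes, count in groups.items():
        if count < min_support:
            continue
        models = [annotation.by_name(nm) for nm in genes]
        raw.append((genes, strands[genes], min(m.start for m in models),
                    max(m.end for m in models), count))
    raw.sort(key=lambda r: r[2])

    calls = []
    family_members: dict[str, list[int]] = defaultdict(list)
    for i, (genes, strand, start, end, count) in enumerate(raw):
        fam = annotation.by_name(genes[0]).family
        family_members[fam].append(i)
        calls.append(OperonCall(name="", genes=genes, strand=strand,
                                start=start, end=end, support=count))
    for fam, idxs in family_members.items():
        title = fam[:1].upper() + fam[1:]
        if len(idxs) == 1:
            calls[idxs[0]].name = title
        else:
            for ordinal, i in enumerate(idxs, start=1):
                calls[i].name = f"{title}_{ordinal}"
    # subset cross-references (identical ordered sub-runs only)
    for c in calls:
        for other in calls:
            if other is c or len(other.genes) <= len(c.genes):
                continue
            og = other.genes
            runs = [og[i:i + len(c.genes)] for i in range(len(og) - len(c.genes) + 1)]
            if c.genes in runs:
                c.subset_of = other.name
                break
    return calls
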