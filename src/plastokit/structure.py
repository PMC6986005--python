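"""Quadripartite plastome architecture and genome-level statistics.

Most land-plant plastomes carry two exact, oppositely oriented copies of a
large block (IRa/IRb) separating a large and a small single-copy region
(LSC/SSC).  This module finds maximal inverted repeats by seed-and-extend,
derives the canonical LSC+IRa+SSC+IRb rotation, and computes the region
statistics (lengths, GC) a genome report tabulates, plus same-strand
(direct) repeat detection and alignment coverage.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._seq import gc_percent, kmer_codes, kmer_rc_codes
from .models import CircularGenome

_MAX_KMER_OCC = 100  # ignore k-mer seeds more repetitive than this


class NoInvertedRepeatError(ValueError):
    """Raised when no inverted repeat of the required size exists.

    Some plastomes (e.g. many conifers and some legumes) genuinely lack the
    large IR; callers can catch this and treat the genome as IR-less.
    """


@dataclass(frozen=True)
class RepeatPair:
    """Two maximal exactly matching copies; inverted or direct."""

    start1: int
    start2: int
    length: int
    inverted: bool

    @property
    def interval1(self) -> tuple[int, int]:
        return (self.start1, self.start1 + self.length)

    @property
    def interval2(self) -> tuple[int, int]:
        return (self.start2, self.start2 + self.length)


@dataclass(frozen=True)
class QuadripartitePartition:
    """LSC/IRa/SSC/IRb intervals on the canonical rotation.

    Canonical rotation: position 0 is the LSC start (immediately after the
    IRb end on the circle), so regions tile the genome in the order
    LSC, IRa, SSC, IRb.
    """

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]
    canonical_offset: int  # rotation applied to the input to reach canonical

    @property
    def region_lengths(self) -> dict[str, int]:
        return {
            "lsc": self.lsc[1] - self.lsc[0],
            "ira": self.ira[1] - self.ira[0],
            "ssc": self.ssc[1] - self.ssc[0],
            "irb": self.irb[1] - self.irb[0],
        }

    @property
    def genome_length(self) -> int:
        return sum(self.region_lengths.values())

    def intervals(self) -> dict[str, tuple[int, int]]:
        return {"lsc": self.lsc, "ira": self.ira, "ssc": self.ssc, "irb": self.irb}


@dataclass(frozen=True)
class RegionStats:
    region: str
    length: int
    gc: float  # percent


def _seed_hits(query_codes, query_valid, target_codes, target_valid):
    """(p, q) pairs with query code at p equal to target code at q."""
    t_ok = np.flatnonzero(target_valid)
    t_codes = target_codes[t_ok]
    order = np.argsort(t_codes, kind="stable")
    t_sorted = t_codes[order]
    t_pos = t_ok[order]
    q_ok = np.flatnonzero(query_valid)
    lo = np.searchsorted(t_sorted, query_codes[q_ok], side="left")
    hi = np.searchsorted(t_sorted, query_codes[q_ok], side="right")
    counts = hi - lo
    keep = (counts > 0) & (counts <= _MAX_KMER_OCC)
    ps, los, his = q_ok[keep], lo[keep], hi[keep]
    out_p, out_q = [], []
    for p, a, b in zip(ps, los, his):
        for q in t_pos[a:b]:
            out_p.append(int(p))
            out_q.append(int(q))
    return out_p, out_q


def _merge_runs(positions: list[int], k: int) -> list[tuple[int, int]]:
    """Merge k-length windows starting at ``positions`` into covered runs."""
    runs = []
    for p in sorted(set(positions)):
        if runs and p <= runs[-1][1]:
            runs[-1][1] = max(runs[-1][1], p + k)
        else:
            runs.append([p, p + k])
    return [(a, b) for a, b in runs]


def find_inverted_repeats(genome: CircularGenome, min_len: int = 1000) -> list[RepeatPair]:
    """Maximal exact inverted-repeat pairs of length >= ``min_len``.

    Seed-and-extend: k-mer hits between the sequence and its reverse
    complement are grouped by anti-diagonal (the sum of paired base
    coordinates is constant along an inverted match), merged into runs and
    extended to inextensibility.  The circle is handled by doubling the
    sequence and normalising coordinates modulo the genome length.
    """
    if min_len < 50:
        raise ValueError("min_len must be >= 50")
    s = genome.sequence.upper()
    n = len(s)
    s2 = s + s if genome.circular else s
    k = min(21, min_len)
    codes2, valid2 = kmer_codes(s2, k)
    rc_codes, rc_valid = kmer_rc_codes(s2, k)
    n_query = min(n, len(rc_codes))
    ps, qs = _seed_hits(rc_codes[:n_query], rc_valid[:n_query], codes2, valid2)

    # group seeds by base-level anti-diagonal A = p + (q + k - 1)
    by_anti: dict[int, list[int]] = {}
    for p, q in zip(ps, qs):
        by_anti.setdefault(p + q + k - 1, []).append(p)

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    found: dict[tuple, RepeatPair] = {}
    lim = len(s2)
    for A, plist in by_anti.items():
        for i0, i1 in _merge_runs(plist, k):
            # keep only the half of a run below the anti-diagonal midpoint
            half = (A + 1) // 2
            i1 = min(i1, half)
            if i1 <= i0:
                continue
            # extend left (partner interval extends right)
            while i0 > 0 and A - (i0 - 1) < lim and s2[i0 - 1] == comp.get(s2[A - (i0 - 1)], "?"):
                i0 -= 1
            # extend right, stopping before the intervals would cross
            while i1 < lim and A - i1 >= 0 and i1 < A - i1 and s2[i1] == comp.get(s2[A - i1], "?"):
                i1 += 1
            length = i1 - i0
            if length < min_len:
                continue
            j0 = A - i1 + 1
            a, b = i0 % n, j0 % n
            key = tuple(sorted([(a, length), (b, length)]))
            if key not in found:
                s1, s2_ = key[0][0], key[1][0]
                found[key] = RepeatPair(start1=s1, start2=s2_, length=length, inverted=True)
    return sorted(found.values(), key=lambda r: (-r.length, r.start1, r.start2))


def find_direct_repeats(seq, window: int = 10000, min_len: int = 20) -> list[RepeatPair]:
    """Maximal exact same-strand repeat pairs with copies within ``window`` bp.

    Accepts a plain string (treated as linear) or a :class:`CircularGenome`.
    Tandem (adjacent) duplications are included; overlapping periodic
    arrays are reported as a single maximal pair.
    """
    if min_len < 20:
        raise ValueError("min_len must be >= 20")
    if isinstance(seq, CircularGenome):
        s = seq.sequence.upper()
        circular = seq.circular
    else:
        s = str(seq).upper()
        circular = False
    n = len(s)
    s2 = s + s if circular else s
    k = min(20, min_len)
    codes, valid = kmer_codes(s2, k)
    n_query = min(n, len(codes))
    ps, qs = _seed_hits(codes[:n_query], valid[:n_query], codes, valid)

    by_diag: dict[int, list[int]] = {}
    for p, q in zip(ps, qs):
        d = q - p
        if d <= 0:  # keep p < q only; (p, q) and (q, p) are the same pair
            continue
        by_diag.setdefault(d, []).append(p)

    found: dict[tuple, RepeatPair] = {}
    lim = len(s2)
    for d, plist in by_diag.items():
        for i0, i1 in _merge_runs(plist, k):
            while i0 > 0 and s2[i0 - 1] == s2[i0 - 1 + d]:
                i0 -= 1
            while i1 + d < lim and s2[i1] == s2[i1 + d]:
                i1 += 1
            length = i1 - i0
            if length < min_len:
                continue
            separation = d - length  # negative when copies overlap (periodic)
            if separation > window:
                continue
            a, b = i0 % n if circular else i0, (i0 + d) % n if circular else i0 + d
            key = tuple(sorted([(a, length), (b, length)]))
            if key not in found:
                found[key] = RepeatPair(start1=key[0][0], start2=key[1][0],
                                        length=length, inverted=False)
    return sorted(found.values(), key=lambda r: (-r.length, r.start1, r.start2))


def partition_quadripartite(genome: CircularGenome, min_ir: int = 1000) -> QuadripartitePartition:
    """Resolve LSC/IRa/SSC/IRb from the largest inverted repeat pair.

    The longer of the two single-copy arcs becomes the LSC; on a tie the
    arc with the lexicographically smaller sequence does.  The canonical
    rotation places position 0 at the LSC start.
    """
    if not genome.circular:
        raise ValueError("quadripartite partitioning requires a circular genome")
    pairs = find_inverted_repeats(genome, min_len=max(50, min_ir))
    pairs = [p for p in pairs if p.length >= min_ir]
    if not pairs:
        raise NoInvertedRepeatError(
            f"no inverted repeat >= {min_ir} bp in genome {genome.id}")
    top = pairs[0]
    n = len(genome)
    ir_len = top.length
    a, b = top.start1, top.start2  # a < b on the current rotation
    arc1 = ((a + ir_len) % n, (b - (a + ir_len)) % n)          # between copy1 and copy2
    arc2 = ((b + ir_len) % n, (n - 2 * ir_len - arc1[1]))       # wraps past origin
    l1, l2 = arc1[1], arc2[1]
    if l1 > l2:
        lsc_start, lsc_len, ssc_len = arc1[0], l1, l2
    elif l2 > l1:
        lsc_start, lsc_len, ssc_len = arc2[0], l2, l1
    else:
        seq1 = genome.fetch(arc1[0], arc1[0] + l1)
        seq2 = genome.fetch(arc2[0], arc2[0] + l2)
        if seq1 <= seq2:
            lsc_start, lsc_len, ssc_len = arc1[0], l1, l2
        else:
            lsc_start, lsc_len, ssc_len = arc2[0], l2, l1
    return QuadripartitePartition(
        lsc=(0, lsc_len),
        ira=(lsc_len, lsc_len + ir_len),
        ssc=(lsc_len + ir_len, lsc_len + ir_len + ssc_len),
        irb=(lsc_len + ir_len + ssc_len, n),
        canonical_offset=lsc_start % n,
    )


def canonicalize(genome: CircularGenome, min_ir: int = 1000):
    """Return ``(rotated_genome, partition)`` on the canonical rotation."""
    part = partition_quadripartite(genome, min_ir=min_ir)
    off = part.canonical_offset
    seq = genome.sequence[off:] + genome.sequence[:off]
    return CircularGenome(id=genome.id, sequence=seq, circular=True), part


def weighted_overall_gc(stats: list[RegionStats]) -> float:
    """Length-weighted mean GC% across regions, rounded to 2 dp."""
    total = sum(s.length for s in stats)
    return round(sum(s.gc * s.length for s in stats) / total, 2)


def region_gc(genome: CircularGenome, partition: QuadripartitePartition):
    """Per-region GC% (2 dp) plus the length-weighted overall GC%.

    The genome must already be on the canonical rotation of ``partition``
    (as returned by :func:`canonicalize`).
    """
    if len(genome) != partition.genome_length:
        raise ValueError("partition does not tile this genome")
    stats = []
    for name, (s, e) in partition.intervals().items():
        seq = genome.fetch(s, e)
        stats.append(RegionStats(region=name, length=e - s, gc=round(gc_percent(seq), 2)))
    return stats, weighted_overall_gc(stats)


def _iter_ref_blocks(rec):
    """Reference-consuming blocks of a pysam record; deletions covered, N not."""
    pos = rec.reference_start
    for op, ln in rec.cigartuples or []:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference and count as covered
            yield pos, pos + ln
            pos += ln
        elif op == 3:  # N: intron skip, reference consumed but not covered
            pos += ln


def coverage_stats(alignments, genome_len: int, reference_name: str | None = None):
    """Per-base depth vector and mean depth over a circular reference.

    ``alignments`` may be a SAM file path, an iterable of pysam aligned
    segments, or an iterable of plain ``(start, end)`` reference intervals
    (ends past ``genome_len`` wrap through the origin).
    """
    depth = np.zeros(genome_len, dtype=np.int64)

    def add(s, e):
        if e - s > genome_len:
            depth[:] += (e - s) // genome_len
            e = s + (e - s) % genome_len
        s_, e_ = s % genome_len, None
        ln = e - s
        e_ = s_ + ln
        if e_ <= genome_len:
            depth[s_:e_] += 1
        else:
            depth[s_:] += 1
            depth[:e_ - genome_len] += 1

    if isinstance(alignments, (str, Path)):
        import pysam
        with pysam.AlignmentFile(str(alignments), "r", check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                if reference_name is not None and rec.reference_name != reference_name:
                    raise ValueError(
                        f"alignment reference {rec.reference_name!r} != {reference_name!r}")
                for s, e in _iter_ref_blocks(rec):
                    add(s, e)
    else:
        for item in alignments:
            if isinstance(item, tuple) and len(item) == 2 \
                    and isinstance(item[0], numbers.Integral):
                add(int(item[0]), int(item[1]))
            else:
                rec = item
                if getattr(rec, "is_unmapped", False):
                    continue
                if reference_name is not None and rec.reference_name != reference_name:
                    raise ValueError(
                        f"alignment reference {rec.reference_name!r} != {reference_name!r}")
                for s, e in _iter_ref_blocks(rec):
                    add(s, e)
    mean = float(depth.sum()) / genome_len
    return depth, mean


def mean_read_length(total_nucleotides: int, n_reads: int) -> int:
    """Rounded mean read length from sequencing totals."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    return int(round(total_nucleotides / n_reads))


def genome_summary(genome: CircularGenome, partition: QuadripartitePartition | None = None,
                   reads=None, read_stats: tuple[int, int] | None = None,
                   annotation=None) -> dict:
    """Assemble the genome-report statistics into one flat record.

    ``reads`` is any iterable with sequence-bearing elements; alternatively
    pass ``read_stats=(n_reads, total_nucleotides)`` when only the totals
    are known (e.g. from a sequencing report).
    """
    rec: dict = {"genome_id": genome.id, "genome_size_bp": len(genome)}
    if partition is not None:
        rl = partition.region_lengths
        rec.update(lsc_bp=rl["lsc"], ssc_bp=rl["ssc"], ir_bp=rl["ira"])
        stats, overall = region_gc(genome, partition)
        for s in stats:
            rec[f"gc_{s.region}_percent"] = s.gc
        rec["gc_overall_percent"] = overall
    else:
        rec["gc_overall_percent"] = round(gc_percent(genome.sequence), 2)
    if reads is not None:
        seqs = [getattr(r, "sequence", r) for r in reads]
        read_stats = (len(seqs), sum(len(s) for s in seqs))
    if read_stats is not None:
        n, total = read_stats
        rec["read_count"] = n
        rec["total_read_bases"] = total
        if n > 0:
            rec["mean_read_length_bp"] = mean_read_length(total, n)
    if annotation is not None:
        by_type: dict[str, int] = {}
        for g in annotation:
            by_type[g.gene_type] = by_type.get(g.gene_type, 0) + 1
        rec["gene_count"] = len(annotation)
        for t, c in sorted(by_type.items()):
            rec[f"gene_count_{t}"] = c
    return rec
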