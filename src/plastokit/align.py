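"""Spliced mapping of full-length cDNAs onto a circular plastome.

Seed-and-chain: exact k-mer anchors between the query and the (doubled)
target are grouped into diagonal bands, one band per exon block; target
gaps between consecutive blocks in ``[min_intron, max_intron]`` with a
near-zero query gap are interpreted as introns.  Junctions are placed by
maximising flank matches, breaking exact ties leftmost and preferring
boundaries that carry the group-II motif (5' GTGYG ... AY 3', strand-aware).
Blocks are then polished with banded edit distance (edlib), which yields the
substitution list used by the editing caller.

SAM I/O round-trips blocks, strand and mismatches: introns use the N
operation, mismatch reference bases travel in an MD tag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._seq import kmer_codes, revcomp
from .models import CircularGenome

_MOTIF5 = re.compile(r"GTG[CT]G")
_MOTIF3 = re.compile(r"A[CT]")


@dataclass(frozen=True)
class AlignmentBlock:
    """One gap-free-ish exon block (indels inside are recorded in the cigar)."""

    t_start: int
    t_end: int
    q_start: int
    q_end: int


@dataclass
class TranscriptAlignment:
    read_id: str
    strand: str                       # transcription strand on the target
    blocks: list[AlignmentBlock]
    mismatches: list[tuple[int, str, str]]  # (target pos, ref base, read base)
    cigar: list[tuple[str, int]]      # ops over =,X,I,D,N in target order
    score: int
    query_length: int
    query_plus: str = ""              # query projected to the target plus strand

    @property
    def t_start(self) -> int:
        return self.blocks[0].t_start

    @property
    def t_end(self) -> int:
        return self.blocks[-1].t_end

    def introns(self) -> list[tuple[int, int]]:
        return [(self.blocks[i].t_end, self.blocks[i + 1].t_start)
                for i in range(len(self.blocks) - 1)]


@dataclass
class TargetIndex:
    """Sorted k-mer index of the doubled circular target."""

    genome: CircularGenome
    k: int
    codes: np.ndarray = field(repr=False)
    positions: np.ndarray = field(repr=False)

    @classmethod
    def build(cls, genome: CircularGenome, k: int = 13) -> "TargetIndex":
        seq = genome.sequence
        if genome.circular:
            seq = seq + seq
        codes, valid = kmer_codes(seq, k)
        pos = np.flatnonzero(valid)
        c = codes[pos]
        order = np.argsort(c, kind="stable")
        return cls(genome=genome, k=k, codes=c[order],
                   positions=pos[order].astype(np.int64))

    def lookup(self, query_codes: np.ndarray, query_valid: np.ndarray,
               max_occ: int = 8) -> tuple[np.ndarray, np.ndarray]:
        """Anchor (qpos, tpos) pairs for query k-mers occurring <= max_occ."""
        qpos_all = np.flatnonzero(query_valid)
        qc = query_codes[qpos_all]
        lo = np.searchsorted(self.codes, qc, side="left")
        hi = np.searchsorted(self.codes, qc, side="right")
        cnt = hi - lo
        keep = (cnt > 0) & (cnt <= max_occ)
        qpos_all, lo, cnt = qpos_all[keep], lo[keep], cnt[keep]
        qpos = np.repeat(qpos_all, cnt)
        idx = np.concatenate([np.arange(a, a + c) for a, c in zip(lo, cnt)]) \
            if len(lo) else np.empty(0, dtype=int)
        tpos = self.positions[idx]
        return qpos, tpos


def _chain_blocks(qpos, tpos, k, min_intron, max_intron, band=30):
    """Chain anchors into per-exon blocks via diagonal bands.

    Anchors are clustered into bands of near-constant diagonal; the chain
    of bands maximising total anchor support under query/target ordering
    constraints is selected by a small DP, so a handful of anchors on a
    chance repeat cannot hijack a well-supported exon.  Returns a list of
    ``(qpos_array, tpos_array)`` per block, query-ordered; consecutive
    blocks separated by a target gap below ``min_intron`` are merged.
    """
    if len(qpos) == 0:
        return []
    diag = (tpos - qpos).astype(np.int64)
    order = np.lexsort((tpos, qpos))
    q, t, d = qpos[order], tpos[order], diag[order]

    # build query-ordered bands greedily, tracking local diagonal drift:
    # an anchor joins a band when its diagonal is within ``drift`` of the
    # band's most recent anchor (indel errors shift the diagonal gradually,
    # so comparing to the running tail follows the drift without merging
    # across a >= min_intron jump)
    drift = min(25, max(10, min_intron // 2))
    open_bands: list[list[int]] = []   # lists of anchor indices
    tails: list[tuple[int, int]] = []  # (q_last, d_last) per open band
    for i in range(len(q)):
        placed = False
        for bi in range(len(open_bands) - 1, -1, -1):
            q_last, d_last = tails[bi]
            if q[i] - q_last > 400:
                continue
            if abs(int(d[i]) - d_last) <= drift and q[i] >= q_last:
                open_bands[bi].append(i)
                tails[bi] = (int(q[i]), int(d[i]))
                placed = True
                break
        if not placed:
            open_bands.append([i])
            tails.append((int(q[i]), int(d[i])))
    bands = []
    for idxs in open_bands:
        if len(idxs) >= 2:
            arr = np.array(idxs)
            bands.append((q[arr], t[arr]))
    if not bands:
        return []
    bands.sort(key=lambda b: (b[0][0], b[1][0]))

    nb = len(bands)
    score = [len(b[0]) for b in bands]
    best = list(score)
    prev = [-1] * nb
    for i in range(nb):
        qi0, ti0 = bands[i][0][0], bands[i][1][0]
        di = ti0 - qi0
        for j in range(i):
            qj1, tj1 = bands[j][0][-1], bands[j][1][-1]
            dj = tj1 - qj1
            if qi0 < qj1 - k or ti0 < tj1 - k:
                continue
            dgap = di - dj
            qgap = qi0 - (qj1 + k)
            if dgap > max_intron or dgap < -band:
                continue
            if dgap > band and qgap > 50:  # intron-like jump needs tight q gap
                continue
            if best[j] + score[i] > best[i]:
                best[i] = best[j] + score[i]
                prev[i] = j
    end = int(np.argmax(best))
    chain_idx = []
    while end != -1:
        chain_idx.append(end)
        end = prev[end]
    chain_idx.reverse()

    # merge consecutive chained bands whose target gap is sub-intron
    merged = []
    for idx in chain_idx:
        qb, tb = bands[idx]
        if merged:
            qp, tp = merged[-1]
            dgap = (tb[0] - qb[0]) - (tp[-1] - qp[-1])
            if dgap < min_intron:
                merged[-1] = (np.concatenate([qp, qb]), np.concatenate([tp, tb]))
                continue
        merged.append((qb, tb))
    return merged


def _match_motif(t, donor, acceptor, strand):
    if strand == "+":
        return (_MOTIF5.fullmatch(t[donor:donor + 5]) is not None
                and _MOTIF3.fullmatch(t[acceptor - 2:acceptor]) is not None)
    five = revcomp(t[acceptor - 5:acceptor])
    three = revcomp(t[donor:donor + 2])
    return (_MOTIF5.fullmatch(five) is not None
            and _MOTIF3.fullmatch(three) is not None)


def _place_junction(q, t, qa, qb, k, d1, d2, strand):
    """Joint placement of one splice junction.

    The split point scans ``[qa, qb]`` (between the flanking exact anchors);
    for each candidate the left flank is aligned start-anchored on the donor
    diagonal and the right flank end-anchored on the acceptor diagonal, both
    with free inner ends, so indel errors near the junction cannot bias the
    boundary.  Minimal total edit cost wins; exact ties resolve to a
    group-II-motif-bearing boundary when one exists, else leftmost.
    Returns ``(q_split, donor, acceptor)`` in target coordinates.
    """
    qa = max(qa, 0)
    qb = min(qb, len(q))
    if qb < qa:
        qb = qa
    pad = 8
    qe = min(qb + k, len(q))
    cands = []  # (cost, qs, donor, acceptor)
    for qs in range(qa, qb + 1):
        left = q[qa:qs]
        if left:
            t1 = t[qa + d1: qs + d1 + pad]
            r = edlib.align(left, t1, mode="SHW")
            dl = r["editDistance"]
            donor = qa + d1 + r["locations"][0][1] + 1
        else:
            dl, donor = 0, qa + d1
        rightq = q[qs:qe]
        if rightq:
            t2_lo = max(0, qs + d2 - pad)
            t2 = t[t2_lo: qe + d2]
            r = edlib.align(rightq[::-1], t2[::-1], mode="SHW")
            dr = r["editDistance"]
            acceptor = len(t2) - (r["locations"][0][1] + 1) + t2_lo
        else:
            dr, acceptor = 0, qs + d2
        cands.append((dl + dr, qs, donor, acceptor))
    # rank: edit cost with a 2-edit bonus for a group-II-motif boundary,
    # then closeness of the implied intron length to the anchor-diagonal
    # length d2-d1 (exact when no indel error sits between the flanking
    # anchors and the junction), then leftmost
    expected_len = d2 - d1

    def key(c):
        cost, qs, donor, acceptor = c
        motif = _match_motif(t, donor, acceptor, strand)
        return (cost - (2 if motif else 0),
                abs((acceptor - donor) - expected_len), qs)

    cost, qs, donor, acceptor = min(cands, key=key)
    return qs, donor, acceptor


def _edlib_ops(cigar: str):
    for m in re.finditer(r"(\d+)([=XIDN])", cigar):
        yield m.group(2), int(m.group(1))


def _polish_block(q_seg, t, t_lo, t_hi, anchor):
    """Align a query segment inside the target window.

    ``anchor`` is 'both', 'left' (start fixed at t_lo, end free) or
    'right' (end fixed at t_hi, start free) or 'none' (both free).
    Returns (t_start, t_end, ops) with ops over =,X,I,D on target coords.
    """
    window = t[t_lo:t_hi]
    if anchor == "both":
        res = edlib.align(q_seg, window, mode="NW", task="path")
        start, end = 0, len(window)
    elif anchor == "left":
        res = edlib.align(q_seg, window, mode="SHW", task="path")
        start, end = 0, res["locations"][0][1] + 1
    elif anchor == "right":
        res = edlib.align(q_seg[::-1], window[::-1], mode="SHW", task="path")
        loc_end = res["locations"][0][1] + 1
        start, end = len(window) - loc_end, len(window)
    else:  # none
        res = edlib.align(q_seg, window, mode="HW", task="path")
        s, e = res["locations"][0]
        start, end = s, e + 1
    ops = list(_edlib_ops(res["cigar"]))
    if anchor == "right":
        ops = ops[::-1]
    return t_lo + start, t_lo + end, ops, res["editDistance"]


def spliced_map(query, target, min_intron: int = 50, max_intron: int = 5000,
                k: int = 13, min_score: int = 40):
    """Map one cDNA to the (circular) target; returns a
    :class:`TranscriptAlignment` or ``None`` when no chain scores.

    ``target`` may be a :class:`CircularGenome` or a prebuilt
    :class:`TargetIndex` (build one when mapping many reads).
    """
    index = target if isinstance(target, TargetIndex) else TargetIndex.build(target, k=k)
    genome = index.genome
    k = index.k
    seq = getattr(query, "sequence", query)
    rid = getattr(query, "id", "")
    if len(seq) < 100:
        raise ValueError("query shorter than 100 bp")

    t = genome.sequence + genome.sequence if genome.circular else genome.sequence
    n = len(genome)

    best = None
    for strand, q in (("+", seq), ("-", revcomp(seq))):
        codes, valid = kmer_codes(q, k)
        qpos, tpos = index.lookup(codes, valid)
        if len(qpos) > 1200:
            # dense anchor sets carry redundant evidence; thin by query
            # position (junction placement re-scans between kept anchors)
            stride = int(np.ceil(len(qpos) / 900))
            keep = qpos % stride == 0
            qpos, tpos = qpos[keep], tpos[keep]
        chains = _chain_blocks(qpos, tpos, k, min_intron, max_intron)
        if not chains:
            continue
        n_anch = sum(len(c[0]) for c in chains)
        if best is None or n_anch > best[0]:
            best = (n_anch, strand, q, chains)
    if best is None:
        return None
    _, strand, q, chains = best

    # junction placement between consecutive blocks
    splits = []   # (query split, donor, acceptor) per junction
    for i in range(len(chains) - 1):
        qp1, tp1 = chains[i]
        qp2, tp2 = chains[i + 1]
        d1 = int(tp1[-1] - qp1[-1])
        d2 = int(tp2[0] - qp2[0])
        qs, donor, acceptor = _place_junction(
            q, t, int(qp1[-1]), int(qp2[0]), k, d1, d2, strand)
        splits.append((qs, donor, acceptor))

    # assemble per-block query ranges and polish
    ops_all: list[tuple[str, int]] = []
    blocks: list[AlignmentBlock] = []
    mismatches: list[tuple[int, str, str]] = []
    edits = 0
    margin = 16
    for bi, (qp, tp) in enumerate(chains):
        q_lo = 0 if bi == 0 else splits[bi - 1][0]
        q_hi = len(q) if bi == len(chains) - 1 else splits[bi][0]
        if q_hi <= q_lo:
            continue
        d_first = int(tp[0] - qp[0])
        d_last = int(tp[-1] - qp[-1])
        if bi == 0 and bi == len(chains) - 1:
            t_lo = max(0, q_lo + d_first - margin)
            t_hi = min(len(t), q_hi + d_last + margin)
            anchor = "none"
        elif bi == 0:
            t_lo = max(0, q_lo + d_first - margin)
            t_hi = splits[0][1]
            anchor = "right"
        elif bi == len(chains) - 1:
            t_lo = splits[bi - 1][2]
            t_hi = min(len(t), q_hi + d_last + margin)
            anchor = "left"
        else:
            t_lo = splits[bi - 1][2]
            t_hi = splits[bi][1]
            anchor = "both"
        if t_hi <= t_lo:
            continue
        ts, te, ops, dist = _polish_block(q[q_lo:q_hi], t, t_lo, t_hi, anchor)
        edits += dist
        if blocks:
            gap = ts - blocks[-1].t_end
            if gap >= 1:
                ops_all.append(("N", gap))
        # record mismatches while walking ops
        tcur, qcur = ts, q_lo
        for op, ln in ops:
            if op == "X":
                for j in range(ln):
                    mismatches.append((tcur + j, t[tcur + j], q[qcur + j]))
                tcur += ln
                qcur += ln
            elif op == "=":
                tcur += ln
                qcur += ln
            elif op == "I":
                qcur += ln
            elif op == "D":
                tcur += ln
        ops_all.extend(ops)
        blocks.append(AlignmentBlock(t_start=ts, t_end=te, q_start=q_lo, q_end=q_hi))
    if not blocks:
        return None

    matched = sum(ln for op, ln in ops_all if op == "=")
    score = matched - edits
    if score < min_score:
        return None

    # normalise circular coordinates: prefer the copy starting inside [0, n)
    if blocks[0].t_start >= n:
        blocks = [AlignmentBlock(b.t_start - n, b.t_end - n, b.q_start, b.q_end)
                  for b in blocks]
        mismatches = [(p - n, r, a) for p, r, a in mismatches]
    # merge compacted ops
    merged: list[tuple[str, int]] = []
    for op, ln in ops_all:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))

    return TranscriptAlignment(read_id=rid, strand=strand, blocks=blocks,
                               mismatches=mismatches, cigar=merged,
                               score=score, query_length=len(q), query_plus=q)


# ---------------------------------------------------------------------------
# SAM I/O
# ---------------------------------------------------------------------------

_OP_CODE = {"=": 7, "X": 8, "I": 1, "D": 2, "N": 3, "M": 0, "S": 4}
_CODE_OP = {v: k for k, v in _OP_CODE.items()}


def _md_tag(cigar, t_start, refseq) -> str:
    """MD string from the cigar and the reference sequence."""
    out = []
    match = 0
    tpos = t_start
    for op, ln in cigar:
        if op == "=":
            match += ln
            tpos += ln
        elif op == "X":
            for j in range(ln):
                out.append(str(match))
                out.append(refseq[tpos + j])
                match = 0
            tpos += ln
        elif op == "D":
            out.append(str(match))
            out.append("^" + refseq[tpos:tpos + ln])
            match = 0
            tpos += ln
        elif op == "N":
            tpos += ln
        # I consumes query only and does not appear in MD
    out.append(str(match))
    return "".join(out)


def write_sam(alignments, target: CircularGenome, path) -> None:
    """Write alignments as plain SAM 1.6 against ``target``.

    An alignment wrapping the circular origin is emitted as two records:
    a primary for the part inside the reference and a supplementary for the
    wrapped remainder (soft-clipped on the already-emitted side).
    """
    import pysam

    n = len(target)
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": target.id, "LN": n}],
        "PG": [{"ID": "plastokit", "PN": "plastokit"}],
    })
    refseq = target.sequence + target.sequence

    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for ai, aln in enumerate(alignments):
            for pi, (t_start, cigar, q_lo, q_hi) in enumerate(_split_at_origin(aln, n)):
                rec = pysam.AlignedSegment(header)
                rec.query_name = aln.read_id or f"query{ai}"
                rec.flag = (16 if aln.strand == "-" else 0) | (2048 if pi > 0 else 0)
                rec.reference_id = 0
                rec.reference_start = t_start % n
                full = []
                if q_lo > 0:
                    full.append(("S", q_lo))
                full.extend(cigar)
                if q_hi < aln.query_length:
                    full.append(("S", aln.query_length - q_hi))
                rec.cigartuples = [(_OP_CODE[op], ln) for op, ln in full]
                rec.query_sequence = aln.query_plus or None
                rec.mapping_quality = 60
                rec.set_tag("MD", _md_tag(cigar, t_start, refseq))
                rec.set_tag("AS", aln.score)
                rec.set_tag("NM", sum(l for o, l in cigar if o in "XID"))
                out.write(rec)


def _split_at_origin(aln: TranscriptAlignment, n: int):
    """Yield ``(t_start, cigar, q_lo, q_hi)`` parts, cut at the origin."""
    if aln.t_end <= n:
        return [(aln.t_start, aln.cigar, 0, aln.query_length)]
    parts = []
    cur_ops: list[tuple[str, int]] = []
    tpos, qpos = aln.t_start, 0
    part_t, part_qlo = aln.t_start, 0
    for op, ln in aln.cigar:
        consumes_t = op in "=XDN"
        consumes_q = op in "=XI"
        while consumes_t and tpos < n < tpos + ln:
            take = n - tpos
            if take:
                cur_ops.append((op, take))
                tpos += take
                if consumes_q:
                    qpos += take
            if cur_ops:
                parts.append((part_t, cur_ops, part_qlo, qpos))
            cur_ops = []
            part_t, part_qlo = tpos, qpos
            ln -= take
        if ln:
            cur_ops.append((op, ln))
            if consumes_t:
                tpos += ln
            if consumes_q:
                qpos += ln
    if cur_ops:
        parts.append((part_t, cur_ops, part_qlo, qpos))
    return parts


def _blocks_from(ops, t_start, q_start):
    blocks = []
    tpos, qpos = t_start, q_start
    blk_t, blk_q = tpos, qpos
    for op, ln in ops:
        if op == "N":
            if tpos > blk_t:
                blocks.append(AlignmentBlock(blk_t, tpos, blk_q, qpos))
            tpos += ln
            blk_t, blk_q = tpos, qpos
        else:
            if op in "=X":
                tpos += ln
                qpos += ln
            elif op == "I":
                qpos += ln
            elif op == "D":
                tpos += ln
    if tpos > blk_t:
        blocks.append(AlignmentBlock(blk_t, tpos, blk_q, qpos))
    return blocks


_MD_RE = re.compile(r"(\d+)|\^([A-Z]+)|([A-Z])")


def read_sam(path) -> list[TranscriptAlignment]:
    """Read SAM produced by :func:`write_sam` (or compatible aligner output).

    Mismatches are reconstructed from the cigar (=/X) or, for aligners that
    emit plain M, from the MD tag.  Supplementary records continuing a
    primary across the circular origin are merged back (blocks shifted by
    the reference length).
    """
    import pysam

    out: dict[str, TranscriptAlignment] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        n_ref = fh.header.to_dict().get("SQ", [{}])[0].get("LN", 0)
        for rec in fh:
            if rec.is_unmapped:
                continue
            strand = "-" if rec.is_reverse else "+"
            ops = [(_CODE_OP.get(c, "M"), l) for c, l in rec.cigartuples]
            lead_clip = ops[0][1] if ops and ops[0][0] == "S" else 0
            ops = [(op, l) for op, l in ops if op != "S"]
            blocks = _blocks_from(ops, rec.reference_start, lead_clip)
            mism = _mismatches_from(rec, ops, lead_clip)
            supplementary = bool(rec.flag & 2048)
            if supplementary and rec.query_name in out:
                base = out[rec.query_name]
                shift = n_ref
                base.blocks.extend(AlignmentBlock(b.t_start + shift, b.t_end + shift,
                                                  b.q_start, b.q_end) for b in blocks)
                base.mismatches.extend((p + shift, r, a) for p, r, a in mism)
                continue
            aln = TranscriptAlignment(
                read_id=rec.query_name, strand=strand, blocks=blocks,
                mismatches=mism, cigar=ops,
                score=int(rec.get_tag("AS")) if rec.has_tag("AS") else 0,
                query_length=rec.query_length or sum(l for o, l in ops if o in "=XIM"),
                query_plus=rec.query_sequence or "")
            out[rec.query_name] = aln
            order.append(rec.query_name)
    return [out[name] for name in order]


def _mismatches_from(rec, ops, lead_clip=0):
    seq = rec.query_sequence or ""
    mism = []
    has_x = any(op == "X" for op, _ in ops)
    if has_x:
        tpos, qpos = rec.reference_start, lead_clip
        md_ref = _md_ref_bases(rec)
        mi = 0
        for op, ln in ops:
            if op == "X":
                for j in range(ln):
                    ref = md_ref[mi] if mi < len(md_ref) else "N"
                    mi += 1
                    mism.append((tpos + j, ref, seq[qpos + j] if seq else "N"))
                tpos += ln
                qpos += ln
            elif op in ("=", "M"):
                tpos += ln
                qpos += ln
            elif op == "I":
                qpos += ln
            elif op in ("D", "N"):
                tpos += ln
    elif rec.has_tag("MD"):
        # plain-M cigar: walk MD against the query
        tpos, qpos = rec.reference_start, lead_clip
        md = rec.get_tag("MD")
        qoff = []  # map aligned-ref offsets to query positions
        for op, ln in ops:
            if op == "M":
                for j in range(ln):
                    qoff.append(qpos + j)
                tpos += ln
                qpos += ln
            elif op == "I":
                qpos += ln
            elif op == "D":
                qoff.extend([None] * ln)
                tpos += ln
            elif op == "N":
                qoff.extend([-1] * ln)  # placeholder; MD skips N
        # rebuild with N excluded (MD does not cover N)
        qoff = [x for x in qoff if x != -1]
        ref_cursor = 0
        tmap = _ref_positions(rec.reference_start, ops)
        for m in _MD_RE.finditer(md):
            if m.group(1):
                ref_cursor += int(m.group(1))
            elif m.group(2):
                ref_cursor += len(m.group(2))
            else:
                qp = qoff[ref_cursor] if ref_cursor < len(qoff) else None
                tp = tmap[ref_cursor] if ref_cursor < len(tmap) else None
                if qp is not None and tp is not None:
                    mism.append((tp, m.group(3), seq[qp] if seq else "N"))
                ref_cursor += 1
    return mism


def _md_ref_bases(rec):
    if not rec.has_tag("MD"):
        return []
    bases = []
    for m in _MD_RE.finditer(rec.get_tag("MD")):
        if m.group(3):
            bases.append(m.group(3))
    return bases


def _ref_positions(start, ops):
    """Reference position of every MD-covered (M/D) column, N excluded."""
    tmap = []
    tpos = start
    for op, ln in ops:
        if op in ("M", "=", "X"):
            tmap.extend(range(tpos, tpos + ln))
            tpos += ln
        elif op == "D":
            tmap.extend(range(tpos, tpos + ln))
            tpos += ln
        elif op == "N":
            tpos += ln
    return tmap
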