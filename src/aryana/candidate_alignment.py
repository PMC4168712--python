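"""Precise alignment of a read to one candidate region.

The seeds stored on a candidate tag are first reduced to an anchor chain: a
greedy (longest-first) consistent subset that is collinear and disjoint in
both read and genome coordinates.  Anchors are exact matches and contribute
zero-cost M runs; only the gaps between anchors — and the two flanks — are
aligned, with a banded unit-cost edit-distance DP.

The DP is indexed by position ``i`` in the read segment and by ``offset``,
the difference between reference and read positions, restricted to
``|offset| < d``.  Cell ``(i, offset)`` compares read base ``i`` with
reference base ``i + offset``:

    D[i][offset] = min( D[i-1][offset] + (0 if match else 1),   # M
                        D[i-1][offset+1] + 1,                   # I (read base)
                        D[i][offset-1] + 1 )                    # D (ref base)

which runs in O(d n) instead of the full quadratic table.  Mismatches and
indels cost 1 alike.

Interior gaps are aligned end-to-end (``global``).  The window around the
candidate is padded by ``e`` on both sides, and that padding must never
inflate the distance, so the flanks leave the unused window unpenalized:
``free_ref_end`` takes the minimum over final offsets (trailing reference is
slack), and ``free_ref_start`` is the same on reversed sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fm_index import ReferenceSet, revcomp
from .tag_scoring import SeedInfo, TagRecord

INF = np.iinfo(np.int32).max // 2


class BandInfeasible(Exception):
    """The optimal path cannot fit in the band; retry with a larger d."""


@dataclass(frozen=True)
class AnchorBlock:
    read_start: int
    genome_start: int  # global forward coordinate
    length: int

    @property
    def read_end(self) -> int:
        return self.read_start + self.length

    @property
    def genome_end(self) -> int:
        return self.genome_start + self.length

    @property
    def offset(self) -> int:
        return self.genome_start - self.read_start


@dataclass
class AlignmentResult:
    """A placed read: where, how, and at what cost."""

    seq_id: int
    pos: int  # 0-based leftmost coordinate within the sequence
    strand: str
    cigar: list[tuple[str, int]]  # ops over {M, I, D}, merged runs
    edit_distance: int
    tag_score: int
    tag_key: tuple[int, str]  # (tag_id, strand) identity of the candidate
    mapq: int = 0

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def read_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MI")

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


def select_anchor_chain(
    seeds: list[SeedInfo], d: int, ref: ReferenceSet | None = None
) -> list[AnchorBlock]:
    """Greedy consistent subset of a tag's seeds, as ordered anchor blocks.

    Seeds are taken longest first (ties: leftmost in the read, then lowest
    genome position).  A seed is accepted iff, against every accepted block,
    it is disjoint in both read and genome coordinates, preserves order
    (read order equals genome order), lies in the same reference sequence,
    and its diagonal offset differs by less than ``d``.
    """
    order = sorted(seeds, key=lambda s: (-s[0], s[1], s[2]))
    accepted: list[AnchorBlock] = []
    chain_seq = -1
    for length, rpos, gpos in order:
        if ref is not None:
            seq = ref.seq_of(gpos)
            if accepted and seq != chain_seq:
                continue
        cand = AnchorBlock(rpos, gpos, length)
        ok = True
        for b in accepted:
            read_before = cand.read_end <= b.read_start
            read_after = cand.read_start >= b.read_end
            gen_before = cand.genome_end <= b.genome_start
            gen_after = cand.genome_start >= b.genome_end
            if not (
                (read_before and gen_before) or (read_after and gen_after)
            ) or abs(cand.offset - b.offset) >= d:
                ok = False
                break
        if ok:
            accepted.append(cand)
            if ref is not None and len(accepted) == 1:
                chain_seq = ref.seq_of(gpos)
    accepted.sort(key=lambda b: b.read_start)
    return accepted


def _banded_core(
    ref_gap: np.ndarray, read_gap: np.ndarray, d: int
) -> tuple[np.ndarray, np.ndarray]:
    """Fill the band.  Returns (rows, offsets) where rows[i, j] is the cost of
    aligning read_gap[:i] to ref_gap[:i + offsets[j]]."""
    n, rn = len(read_gap), len(ref_gap)
    offsets = np.arange(-(d - 1), d, dtype=np.int64)  # |offset| < d
    W = offsets.size
    rows = np.full((n + 1, W), INF, dtype=np.int64)
    feas0 = (offsets >= 0) & (offsets <= rn)
    rows[0, feas0] = offsets[feas0]
    for i in range(1, n + 1):
        prev = rows[i - 1]
        ref_idx = i + offsets  # 1-based ref position compared at this cell
        feas = (ref_idx >= 0) & (ref_idx <= rn)
        # M: needs a ref base (ref_idx >= 1)
        m_ok = feas & (ref_idx >= 1)
        mcost = np.full(W, INF, dtype=np.int64)
        if rn > 0:
            ri = np.where(m_ok, ref_idx - 1, 0)
            mism = (ref_gap[ri] != read_gap[i - 1]).astype(np.int64)
            mcost[m_ok] = prev[m_ok] + mism[m_ok]
        # I: from offset+1 in the previous row
        icost = np.full(W, INF, dtype=np.int64)
        icost[:-1] = prev[1:] + 1
        cand = np.minimum(mcost, icost)
        cand[~feas] = INF
        # D: within-row propagation from offset-1; running-min scan
        shifted = cand - offsets
        np.minimum.accumulate(shifted, out=shifted)
        cur = np.minimum(cand, shifted + offsets)
        cur[~feas] = INF
        np.clip(cur, None, INF, out=cur)
        rows[i] = cur
    return rows, offsets


def _traceback(
    rows: np.ndarray,
    offsets: np.ndarray,
    ref_gap: np.ndarray,
    read_gap: np.ndarray,
    end_j: int,
) -> list[str]:
    """Recover one optimal op path (preference M, then D, then I)."""
    ops: list[str] = []
    i, j = len(read_gap), end_j
    rn = len(ref_gap)
    while i > 0 or offsets[j] > 0:
        off = int(offsets[j])
        cost = int(rows[i, j])
        ref_idx = i + off
        if i > 0 and 1 <= ref_idx <= rn:
            sub = int(ref_gap[ref_idx - 1] != read_gap[i - 1])
            if int(rows[i - 1, j]) + sub == cost:
                ops.append("M")
                i -= 1
                continue
        if j > 0 and ref_idx >= 1 and int(rows[i, j - 1]) + 1 == cost:
            ops.append("D")
            j -= 1
            continue
        if i > 0 and j + 1 < offsets.size and int(rows[i - 1, j + 1]) + 1 == cost:
            ops.append("I")
            i -= 1
            j += 1
            continue
        raise AssertionError("banded traceback lost the path")
    ops.reverse()
    return ops


def banded_gap_align(
    ref_gap: np.ndarray,
    read_gap: np.ndarray,
    d: int,
    mode: str = "global",
) -> tuple[int, list[str], int]:
    """Minimal unit-cost edit path within the band.

    Returns ``(distance, ops, ref_used)`` where ``ops`` is a list of single
    ops over {M, I, D} covering all of ``read_gap`` and ``ref_used`` bases of
    ``ref_gap`` — its prefix in ``global``/``free_ref_end`` mode, its suffix
    in ``free_ref_start`` mode (the remainder is unpenalized window slack).

    Raises :class:`BandInfeasible` when no end cell is reachable in the band
    (in particular when ``|len(ref_gap) - len(read_gap)| >= d`` in global
    mode).
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    n, rn = len(read_gap), len(ref_gap)
    if mode == "free_ref_start":
        dist, ops, used = banded_gap_align(
            ref_gap[::-1], read_gap[::-1], d, "free_ref_end"
        )
        return dist, ops[::-1], used
    if mode not in ("global", "free_ref_end"):
        raise ValueError(f"unknown mode {mode!r}")
    if n == 0 and mode == "free_ref_end":
        return 0, [], 0
    if n == 0:  # global: all deletions
        if rn >= d:
            raise BandInfeasible(f"|{rn} - 0| >= d={d}")
        return rn, ["D"] * rn, rn
    rows, offsets = _banded_core(ref_gap, read_gap, d)
    last = rows[n]
    if mode == "global":
        final = rn - n
        if abs(final) >= d:
            raise BandInfeasible(f"|{rn} - {n}| >= d={d}")
        j = int(final + d - 1)
    else:
        feas = (n + offsets >= 0) & (n + offsets <= rn) & (last < INF)
        if not feas.any():
            raise BandInfeasible("no reachable end cell in the band")
        js = np.flatnonzero(feas)
        j = int(js[np.argmin(last[js])])  # ties: smaller offset (less ref)
    if last[j] >= INF:
        raise BandInfeasible("end cell unreachable in the band")
    ops = _traceback(rows, offsets, ref_gap, read_gap, j)
    return int(last[j]), ops, n + int(offsets[j])


def _merge_ops(chunks: list[list[str] | str]) -> list[tuple[str, int]]:
    merged: list[tuple[str, int]] = []
    for chunk in chunks:
        for op in chunk:
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + 1)
            else:
                merged.append((op, 1))
    return merged


def align_to_candidate(
    read: np.ndarray,
    ref: ReferenceSet,
    tag: TagRecord,
    e: int,
    d: int,
    genome: np.ndarray | None = None,
) -> AlignmentResult | None:
    """Full alignment of ``read`` against the region voted by ``tag``.

    Reverse-strand candidates align the reverse-complemented read against
    the forward reference (the tag's stored seeds already use those read
    coordinates) and are reported with strand '-'.  Returns None when a gap
    stays infeasible even after one retry with a doubled band.
    """
    if not tag.seeds:
        raise ValueError("candidate tag has no seeds")
    genome = ref.forward() if genome is None else genome
    work = read if tag.strand == "+" else revcomp(read)
    R = len(work)
    chain = select_anchor_chain(tag.seeds, d, ref=ref)
    if not chain:
        return None
    seq_id = ref.seq_of(chain[0].genome_start)
    seq_lo = int(ref.starts[seq_id])
    seq_hi = seq_lo + len(ref.seqs[seq_id])

    first, last = chain[0], chain[-1]
    win_lo = max(first.genome_start - first.read_start - e, seq_lo)
    win_hi = min(last.genome_end + (R - last.read_end) + e, seq_hi)

    def gap(ref_lo: int, ref_hi: int, r_lo: int, r_hi: int, mode: str):
        rg, dg = genome[ref_lo:ref_hi], work[r_lo:r_hi]
        try:
            return banded_gap_align(rg, dg, d, mode)
        except BandInfeasible:
            return banded_gap_align(rg, dg, 2 * d, mode)  # single retry

    try:
        chunks: list[list[str] | str] = []
        total = 0
        # left flank: read prefix against the window's left slack
        if first.read_start > 0 or win_lo < first.genome_start:
            dist, ops, used = gap(
                win_lo, first.genome_start, 0, first.read_start, "free_ref_start"
            )
            pos = first.genome_start - used
            total += dist
            chunks.append(ops)
        else:
            pos = first.genome_start
        # anchors and interior gaps
        for a, b in zip(chain, chain[1:]):
            chunks.append("M" * a.length)
            dist, ops, _ = gap(a.genome_end, b.genome_start, a.read_end, b.read_start, "global")
            total += dist
            chunks.append(ops)
        chunks.append("M" * last.length)
        # right flank
        if last.read_end < R:
            dist, ops, _used = gap(last.genome_end, win_hi, last.read_end, R, "free_ref_end")
            total += dist
            chunks.append(ops)
    except BandInfeasible:
        return None

    return AlignmentResult(
        seq_id=seq_id,
        pos=pos - seq_lo,
        strand=tag.strand,
        cigar=_merge_ops(chunks),
        edit_distance=total,
        tag_score=tag.score,
        tag_key=(tag.tag_id, tag.strand),
    )


def rank_candidates(
    results: list[AlignmentResult],
) -> tuple[AlignmentResult, AlignmentResult | None] | None:
    """Best result and the best result from a different tag.

    Order: minimal edit distance, then higher tag score, then lowest
    coordinate, then '+' strand.  Returns None for an empty list (the read
    is unaligned).
    """
    if not results:
        return None
    ranked = sorted(
        results,
        key=lambda r: (r.edit_distance, -r.tag_score, (r.seq_id, r.pos), r.strand),
    )
    best = ranked[0]
    runner = next((r for r in ranked[1:] if r.tag_key != best.tag_key), None)
    return best, runner
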