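"""End-to-end alignment of single and paired reads, and SAM emission.

Single-read alignment has two phases: (1) advance the tag-table serial,
extract seeds (granting scores to tags) and take the top-``t`` tags; (2)
align the read precisely to each candidate region, rank the results and
assign a mapping quality.  A read with no seeds, or whose every candidate is
dropped, is reported unaligned.

Paired reads are aligned independently to produce up to ``t`` finalists per
end; every cross pair on one sequence with facing (FR) orientation and an
outer distance inside the configured insert bounds is enumerated, and the
pair with the highest total score (per-end score = read length minus edit
distance) wins.  If no pair qualifies, each end reports its individual best
without the proper-pair flag.

Mapping quality is derived from the score gap between the best and the best
different-tag candidate: 60 when there is no rival, 0 on a tie, otherwise
``min(60, floor(60 * (s_best - s_runner) / max(s_best, 1)))``.

Concurrency: worker threads share only the read-only index; each worker owns
a private tag table, so a 1-worker and an N-worker run produce identical
records.
"""

from __future__ import annotations

import logging
import threading
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from . import __version__
from .candidate_alignment import (
    AlignmentResult,
    align_to_candidate,
    rank_candidates,
)
from .fm_index import FMIndex, decode_seq, encode_seq, revcomp
from .seeding import DEFAULT_SEED_SCHEDULE, dynamic_seed_length, extract_seeds
from .tag_scoring import DEFAULT_CAPACITY, TagTable, tag_index

logger = logging.getLogger(__name__)

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80


@dataclass(frozen=True)
class AlignerParams:
    """All tunables of the engine (see the methods note for rationale)."""

    seed_schedule: tuple[tuple[int, int], ...] = DEFAULT_SEED_SCHEDULE
    c: int = 10  # tag length = read length * c
    P: int = 50  # per-seed located-hit cap
    t: int = 10  # candidate tags per read
    e: int = 20  # flank extension (bp)
    d: int = 21  # DP band half-width
    min_insert: int = 0
    max_insert: int = 1000
    orientation: str = "FR"
    workers: int = 1
    table_capacity: int = DEFAULT_CAPACITY

    def __post_init__(self) -> None:
        for name in ("c", "P", "t", "e", "d", "workers", "table_capacity"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.min_insert > self.max_insert:
            raise ValueError("min_insert must be <= max_insert")
        if self.orientation != "FR":
            raise ValueError("only FR orientation is supported")


@dataclass
class ReadRecord:
    id: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")


@dataclass
class SamRecord:
    qname: str
    flag: int
    rname: str = "*"
    pos: int = 0  # 1-based; 0 for unaligned
    mapq: int = 0
    cigar: str = "*"
    rnext: str = "*"
    pnext: int = 0
    tlen: int = 0
    seq: str = "*"
    qual: str = "*"
    nm: int | None = None

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    def to_line(self) -> str:
        fields = [
            self.qname,
            str(self.flag),
            self.rname,
            str(self.pos),
            str(self.mapq),
            self.cigar,
            self.rnext,
            str(self.pnext),
            str(self.tlen),
            self.seq,
            self.qual,
        ]
        if self.nm is not None:
            fields.append(f"NM:i:{self.nm}")
        return "\t".join(fields)


def compute_mapq(
    best: AlignmentResult, runner_up: AlignmentResult | None, read_length: int
) -> int:
    """Confidence from the best-vs-runner-up score gap, on the 0-60 scale."""
    s_best = read_length - best.edit_distance
    if runner_up is None:
        return 60
    s_run = read_length - runner_up.edit_distance
    if s_run >= s_best:
        return 0
    return min(60, (60 * (s_best - s_run)) // max(s_best, 1))


class Aligner:
    """Stateful façade: one index plus parameters; thread-safe for reads."""

    def __init__(self, idx: FMIndex, params: AlignerParams | None = None):
        self.idx = idx
        self.params = params or AlignerParams()
        self.genome = idx.ref.forward()  # cached concatenated forward codes
        self._local = threading.local()

    def _table(self) -> TagTable:
        table = getattr(self._local, "table", None)
        if table is None:
            table = TagTable(self.params.table_capacity, self.params.t)
            self._local.table = table
        return table

    # -- phase 1 + 2 --------------------------------------------------------

    def candidates(self, read: ReadRecord) -> list[AlignmentResult]:
        """Finalist alignments of one read, one per surviving top tag."""
        p = self.params
        codes = encode_seq(read.sequence)
        R = len(codes)
        table = self._table()
        table.advance_read()
        k = dynamic_seed_length(R, p.seed_schedule)
        L = R * p.c

        def sink(est: int, hit) -> None:
            table.grant_score(
                tag_index(est, L),
                hit.strand,
                (hit.length, hit.read_offset, hit.genome_position),
            )

        extract_seeds(self.idx, codes, k, p.P, sink)
        results = []
        for rec in table.top_tags(p.t):
            aln = align_to_candidate(codes, self.idx.ref, rec, p.e, p.d, self.genome)
            if aln is not None:
                results.append(aln)
        return results

    def align_single(self, read: ReadRecord) -> SamRecord:
        ranked = rank_candidates(self.candidates(read))
        if ranked is None:
            return self._unaligned(read, 0)
        best, runner = ranked
        best.mapq = compute_mapq(best, runner, len(read.sequence))
        return self._to_sam(read, best, 0)

    # -- paired-end ---------------------------------------------------------

    def align_pair(
        self, read1: ReadRecord, read2: ReadRecord
    ) -> tuple[SamRecord, SamRecord]:
        c1, c2 = self.candidates(read1), self.candidates(read2)
        pair = select_pair(
            c1,
            c2,
            len(read1.sequence),
            len(read2.sequence),
            self.params.min_insert,
            self.params.max_insert,
        )
        base1 = FLAG_PAIRED | FLAG_READ1
        base2 = FLAG_PAIRED | FLAG_READ2
        if pair is not None:
            a1, a2, outer = pair
            a1.mapq = _pair_mapq(a1, c1, len(read1.sequence))
            a2.mapq = _pair_mapq(a2, c2, len(read2.sequence))
            s1 = self._to_sam(read1, a1, base1 | FLAG_PROPER)
            s2 = self._to_sam(read2, a2, base2 | FLAG_PROPER)
            _set_mates(s1, s2, outer)
            return s1, s2
        # no valid pair: individual bests
        r1, r2 = rank_candidates(c1), rank_candidates(c2)
        if r1 is not None:
            b1, ru1 = r1
            b1.mapq = compute_mapq(b1, ru1, len(read1.sequence))
            s1 = self._to_sam(read1, b1, base1)
        else:
            s1 = self._unaligned(read1, base1)
        if r2 is not None:
            b2, ru2 = r2
            b2.mapq = compute_mapq(b2, ru2, len(read2.sequence))
            s2 = self._to_sam(read2, b2, base2)
        else:
            s2 = self._unaligned(read2, base2)
        _set_mates(s1, s2, None)
        return s1, s2

    # -- record building ----------------------------------------------------

    def _to_sam(self, read: ReadRecord, aln: AlignmentResult, flag: int) -> SamRecord:
        if aln.strand == "-":
            flag |= FLAG_REVERSE
            seq = decode_seq(revcomp(encode_seq(read.sequence)))
            qual = read.qualities[::-1] if read.qualities else "*"
        else:
            seq = read.sequence.upper()
            qual = read.qualities or "*"
        return SamRecord(
            qname=read.id,
            flag=flag,
            rname=self.idx.ref.names[aln.seq_id],
            pos=aln.pos + 1,
            mapq=aln.mapq,
            cigar=aln.cigar_string(),
            seq=seq,
            qual=qual,
            nm=aln.edit_distance,
        )

    def _unaligned(self, read: ReadRecord, flag: int) -> SamRecord:
        return SamRecord(
            qname=read.id,
            flag=flag | FLAG_UNMAPPED,
            seq=read.sequence.upper(),
            qual=read.qualities or "*",
        )

    # -- batch APIs ---------------------------------------------------------

    def map_single(self, reads: Iterable[ReadRecord]) -> Iterator[SamRecord]:
        if self.params.workers == 1:
            for read in reads:
                yield self.align_single(read)
        else:
            with ThreadPoolExecutor(self.params.workers) as pool:
                yield from pool.map(self.align_single, reads, chunksize=64)

    def map_pairs(
        self, pairs: Iterable[tuple[ReadRecord, ReadRecord]]
    ) -> Iterator[SamRecord]:
        if self.params.workers == 1:
            results = (self.align_pair(r1, r2) for r1, r2 in pairs)
        else:
            pool = ThreadPoolExecutor(self.params.workers)
            results = pool.map(lambda p: self.align_pair(*p), pairs, chunksize=64)
        for s1, s2 in results:
            yield s1
            yield s2


def _pair_score(aln: AlignmentResult, read_len: int) -> int:
    return read_len - aln.edit_distance


def select_pair(
    cands1: list[AlignmentResult],
    cands2: list[AlignmentResult],
    len1: int,
    len2: int,
    min_insert: int,
    max_insert: int,
) -> tuple[AlignmentResult, AlignmentResult, int] | None:
    """Best valid FR pair among the two finalist lists, or None.

    Valid: same sequence, opposite strands, the forward-strand end leftmost,
    and an outer (outermost-to-outermost) distance within the insert bounds.
    Ranked by total score (descending), then total edit distance, then the
    leftmost coordinate pair.  Returns the two results plus the outer
    distance.
    """
    best = None
    for a1 in cands1:
        for a2 in cands2:
            if a1.seq_id != a2.seq_id or a1.strand == a2.strand:
                continue
            fwd, rev = (a1, a2) if a1.strand == "+" else (a2, a1)
            if fwd.pos > rev.pos:
                continue
            outer = rev.pos + rev.ref_span - fwd.pos
            if not min_insert <= outer <= max_insert:
                continue
            total = _pair_score(a1, len1) + _pair_score(a2, len2)
            key = (
                -total,
                a1.edit_distance + a2.edit_distance,
                (fwd.seq_id, fwd.pos),
                (rev.seq_id, rev.pos),
            )
            if best is None or key < best[0]:
                best = (key, a1, a2, outer)
    if best is None:
        return None
    return best[1], best[2], best[3]


def _pair_mapq(
    chosen: AlignmentResult, cands: list[AlignmentResult], read_len: int
) -> int:
    runner = None
    for c in cands:
        if c.tag_key == chosen.tag_key:
            continue
        if runner is None or c.edit_distance < runner.edit_distance:
            runner = c
    return max(0, compute_mapq(chosen, runner, read_len))


def _set_mates(s1: SamRecord, s2: SamRecord, outer: int | None) -> None:
    for me, mate in ((s1, s2), (s2, s1)):
        if mate.is_unmapped:
            me.flag |= FLAG_MATE_UNMAPPED
        else:
            if mate.is_reverse:
                me.flag |= FLAG_MATE_REVERSE
            if not me.is_unmapped:
                me.rnext = "=" if me.rname == mate.rname else mate.rname
                me.pnext = mate.pos
    if outer is not None and not s1.is_unmapped and not s2.is_unmapped:
        left_first = (s1.pos, s1.is_reverse) <= (s2.pos, s2.is_reverse)
        s1.tlen = outer if left_first else -outer
        s2.tlen = -outer if left_first else outer


# ---------------------------------------------------------------------------
# Formats


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Plain or gzipped FASTQ."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield ReadRecord(entry.name, entry.sequence, entry.quality)


def sam_header(idx: FMIndex, cmdline: str | None = None) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for name, length in zip(idx.ref.names, idx.ref.lengths()):
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    pg = f"@PG\tID:aryana\tPN:aryana\tVN:{__version__}"
    if cmdline:
        pg += f"\tCL:{cmdline}"
    lines.append(pg)
    return lines


def write_sam(
    out: TextIO | str | Path,
    idx: FMIndex,
    records: Iterable[SamRecord],
    cmdline: str | None = None,
) -> dict[str, int]:
    """Write a SAM file; returns per-stage counts for logging."""
    own = isinstance(out, (str, Path))
    fh = open(out, "w") if own else out
    counts = {"reads": 0, "aligned": 0, "proper_pairs": 0}
    try:
        for line in sam_header(idx, cmdline):
            fh.write(line + "\n")
        for rec in records:
            fh.write(rec.to_line() + "\n")
            counts["reads"] += 1
            if not rec.is_unmapped:
                counts["aligned"] += 1
            if rec.flag & FLAG_PROPER:
                counts["proper_pairs"] += 1
    finally:
        if own:
            fh.close()
    logger.info(
        "wrote %d records (%d aligned, %d in proper pairs)",
        counts["reads"],
        counts["aligned"],
        counts["proper_pairs"],
    )
    return counts
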