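"""Per-read tag scores in a reset-free open-addressing hash table.

The genome is cut into consecutive non-overlapping partitions ("tags") of
length ``L = R * c`` (read length times a small constant, 10 by default).
Every located seed occurrence votes for the tag containing the estimated
start of the read, ``m - n`` (genome position of the seed minus read offset
of the seed), with a score equal to the seed length; a tag's score is the sum
of the seed lengths granted to it.

The table is never cleared between reads: each record carries the serial
number of the read that wrote it, and records from earlier serials are
treated as empty by lookups.  Advancing the serial therefore invalidates the
whole table in O(1).  A small always-sorted list tracks the ``t``
highest-scoring visible records so candidate selection never scans slots.

Strand is part of the record key: a forward and a reverse placement at the
same coordinate are different alignments and must not pool their evidence.
Ties are broken by lower tag id, then ``+`` before ``-`` — deterministic by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: seed info stored per grant: (seed length, read offset, global genome position)
SeedInfo = tuple[int, int, int]

_MULT = 0x9E3779B97F4A7C15  # 64-bit golden-ratio multiplier
_MASK64 = (1 << 64) - 1
_SERIAL_MAX = (1 << 32) - 1

DEFAULT_CAPACITY = 1 << 18
DEFAULT_TOP_T = 10


def estimated_read_start(m: int, n: int) -> int:
    """Estimated genome start of a read given a seed at genome position ``m``
    preceded by ``n`` read bases; clamped to 0 at the sequence start."""
    return max(m - n, 0)


def tag_index(est_start: int, L: int) -> int:
    """Tag (partition) containing a genome coordinate: floor(est_start / L)."""
    if L < 1:
        raise ValueError("tag length must be >= 1")
    return est_start // L


@dataclass(eq=False)  # identity semantics: two records are the same object or not
class TagRecord:
    """Accumulator for one (tag, strand) candidate region of one read."""

    tag_id: int
    strand: str
    read_serial: int
    score: int = 0
    seeds: list[SeedInfo] = field(default_factory=list)

    def sort_key(self) -> tuple[int, int, str]:
        # descending score, then lower tag id, then '+' before '-'
        return (-self.score, self.tag_id, self.strand)


class TagTable:
    """Open-addressing hash table of :class:`TagRecord` with serial-based
    invalidation and an always-current top-``t`` list.

    ``capacity`` must be a power of two (linear probing with a multiplicative
    hash).  One table serves one worker; the only state shared between
    workers is the read-only index.
    """

    def __init__(self, capacity: int = DEFAULT_CAPACITY, t: int = DEFAULT_TOP_T):
        if capacity < 1 or capacity & (capacity - 1):
            raise ValueError("capacity must be a positive power of two")
        if t < 1:
            raise ValueError("t must be >= 1")
        self.capacity = capacity
        self.t = t
        self._mask = capacity - 1
        self._shift = 64 - (capacity.bit_length() - 1)
        self._slots: list[TagRecord | None] = [None] * capacity
        self.current_serial = 1
        self._top: list[TagRecord] = []  # sorted by TagRecord.sort_key

    # -- keys ----------------------------------------------------------------

    def _hash(self, tag_id: int, strand: str) -> int:
        key = (tag_id << 1) | (1 if strand == "-" else 0)
        return ((key * _MULT) & _MASK64) >> self._shift

    def _live(self, rec: TagRecord | None) -> bool:
        return rec is not None and rec.read_serial == self.current_serial

    # -- operations ----------------------------------------------------------

    def grant_score(self, tag_id: int, strand: str, seed: SeedInfo) -> TagRecord:
        """Add a seed's length to the (tag, strand) record of the current
        read, creating the record if absent, and keep the top list current."""
        slot = self._hash(tag_id, strand)
        rec = None
        for _ in range(self.capacity):
            cur = self._slots[slot]
            if not self._live(cur):
                # stale or empty: claim it for this key
                rec = TagRecord(tag_id, strand, self.current_serial)
                self._slots[slot] = rec
                break
            if cur.tag_id == tag_id and cur.strand == strand:
                rec = cur
                break
            slot = (slot + 1) & self._mask
        else:
            rec = self._evict_and_claim(tag_id, strand)
        rec.score += seed[0]
        rec.seeds.append(seed)
        self._update_top(rec)
        return rec

    def _evict_and_claim(self, tag_id: int, strand: str) -> TagRecord:
        """Pathological full-table case: overwrite the lowest-score live
        record that is not in the top list."""
        logger.warning("tag table full (capacity %d); evicting", self.capacity)
        top_ids = {id(r) for r in self._top}
        victim_slot = min(
            (
                s
                for s, r in enumerate(self._slots)
                if self._live(r) and id(r) not in top_ids
            ),
            key=lambda s: (self._slots[s].score, self._slots[s].tag_id),
        )
        rec = TagRecord(tag_id, strand, self.current_serial)
        self._slots[victim_slot] = rec
        return rec

    def _update_top(self, rec: TagRecord) -> None:
        top = self._top
        if rec not in top:
            if len(top) >= self.t:
                # scores only grow, so a record below the current floor can
                # only re-enter via a later grant, which lands back here
                if rec.sort_key() >= top[-1].sort_key():
                    return
            top.append(rec)
        top.sort(key=TagRecord.sort_key)
        del top[self.t :]

    def advance_read(self) -> int:
        """Invalidate every record without touching slot memory; returns the
        new serial.  On (rare) serial wraparound the table is fully cleared."""
        if self.current_serial >= _SERIAL_MAX:
            logger.info("tag table serial wrapped; clearing %d slots", self.capacity)
            self._slots = [None] * self.capacity
            self.current_serial = 0
        self.current_serial += 1
        self._top = []
        return self.current_serial

    def top_tags(self, t: int | None = None) -> list[TagRecord]:
        """Up to ``t`` visible records, descending score (ties: lower tag id,
        then '+')."""
        t = self.t if t is None else t
        if t > self.t:
            raise ValueError("cannot report more than the tracked top-t")
        return list(self._top[:t])

    def visible_records(self) -> list[TagRecord]:
        """All live records, in top order (test/diagnostic helper: scans)."""
        recs = [r for r in self._slots if self._live(r)]
        recs.sort(key=TagRecord.sort_key)
        return recs
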