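"""Greedy right-to-left extraction of maximal, minimally-overlapping seeds.

A valid seed set satisfies four conditions: every seed is at least ``k`` bp
long; no two seeds' read intervals overlap by ``k`` or more bases; every seed
has at least one exact match in the (doubled) reference; and the set is
maximal — extending any seed breaks one of the other conditions or loses the
exact match.

Extraction scans the read from its right end.  Each iteration probes the
rightmost uncovered ``k``-window left-to-right; if the probe fails after
``j < k`` symbols, every window containing the failing position must also
fail, so the scan jumps left past it.  If the whole window matches, the match
is extended maximally leftward with backward search, every located occurrence
(up to the per-seed cap ``P``) grants its length in score to the tag holding
the estimated read start, and the scan resumes keeping the leftmost ``k - 1``
seed letters available for the next window.

Reverse-strand bookkeeping: a hit located on the ``-`` strand corresponds to
the reverse complement of the read aligning to the forward genome, so its
``read_offset`` is stored in reverse-complement read coordinates.  That makes
``genome_position - read_offset`` a consistent estimate of the (reverse
complemented) read's start for every seed of one read, exactly as on the
forward strand, and lets all downstream per-strand processing work in one
coordinate system.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .fm_index import FMIndex
from .tag_scoring import estimated_read_start

INF_LEN = 2**62

#: k schedule fixed by read length: (exclusive upper bound on read length, k)
DEFAULT_SEED_SCHEDULE: tuple[tuple[int, int], ...] = (
    (50, 16),
    (200, 20),
    (500, 24),
    (INF_LEN, 28),
)


@dataclass(frozen=True)
class SeedHit:
    """One located exact occurrence of one maximal seed.

    ``read_offset`` is the 0-based position of the seed's leftmost base in
    the read for ``+`` hits, and in the reverse-complemented read for ``-``
    hits.  ``genome_position`` is the global 0-based forward coordinate of
    the occurrence's leftmost base; ``seq_id``/``seq_offset`` its
    per-sequence split.
    """

    read_offset: int
    length: int
    genome_position: int
    strand: str
    seq_id: int
    seq_offset: int


def dynamic_seed_length(
    read_length: int, schedule: tuple[tuple[int, int], ...] = DEFAULT_SEED_SCHEDULE
) -> int:
    """Minimum seed length for a read: 16 below 50 bp, growing with length."""
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    for bound, k in schedule:
        if read_length < bound:
            return k
    return schedule[-1][1]


GrantSink = Callable[[int, SeedHit], None]


def extract_seeds(
    idx: FMIndex,
    read: np.ndarray,
    k: int,
    P: int,
    sink: GrantSink | None = None,
    on_jump: Callable[[int, int], None] | None = None,
) -> list[SeedHit]:
    """Extract the greedy maximal seed set of ``read`` and locate its hits.

    For each located hit (at most ``P`` per seed, in ascending BWT-row
    order; junction/boundary-rejected rows do not count against ``P``) one
    grant ``(estimated read start, hit)`` is delivered to ``sink``.  Returns
    all located hits.  Reads shorter than ``k`` get a single attempt with
    ``k`` reduced to the read length.  ``on_jump``, if given, observes every
    failed probe as ``(window start, matched length)`` — a diagnostics hook.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    R = len(read)
    k = min(k, R)
    hits: list[SeedHit] = []
    right = R - 1
    while right >= k - 1:
        # probe the k-window [right-k+1, right] left to right
        win_start = right - k + 1
        matched = idx.match_left_to_right(read, win_start, k)
        if matched < k:
            # the window fails at win_start+matched; skip everything to its right
            if on_jump is not None:
                on_jump(win_start, matched)
            right = right - k + matched
            continue
        interval, matched = idx.match_right_to_left(read, right, INF_LEN)
        n_left = right - matched + 1  # read bases before the seed
        granted = 0
        for row in range(interval.begin, interval.end + 1):
            loc = idx.locate_global(row, matched)
            if loc is None:
                continue
            gpos, strand = loc
            if strand == "+":
                read_offset = n_left
            else:
                read_offset = R - n_left - matched
            seq_id, seq_offset = idx.ref.split(gpos)
            hit = SeedHit(
                read_offset=read_offset,
                length=matched,
                genome_position=gpos,
                strand=strand,
                seq_id=seq_id,
                seq_offset=seq_offset,
            )
            hits.append(hit)
            if sink is not None:
                sink(estimated_read_start(gpos, read_offset), hit)
            granted += 1
            if granted >= P:
                break
        right = right - matched + k - 1
    return hits
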