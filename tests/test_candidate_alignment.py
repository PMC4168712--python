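"""Anchor chains, the banded offset DP (vs an unbanded oracle), candidate
alignment and ranking."""

import edlib
import numpy as np
import pytest

from aryana.candidate_alignment import (
    AlignmentResult,
    BandInfeasible,
    align_to_candidate,
    banded_gap_align,
    rank_candidates,
    select_anchor_chain,
)
from aryana.fm_index import decode_seq, encode_seq
from aryana.tag_scoring import TagRecord

from conftest import random_ref


# ---------------------------------------------------------------------------
# anchor chain


def naive_greedy_chain(seeds, d):
    """Independent restatement of the acceptance rule: take seeds longest
    first and re-derive acceptance from the definition for each one."""
    order = sorted(seeds, key=lambda s: (-s[0], s[1], s[2]))
    chain = []
    for L, r, g in order:
        ok = True
        for L2, r2, g2 in chain:
            disjoint_consistent = (r + L <= r2 and g + L <= g2) or (
                r >= r2 + L2 and g >= g2 + L2
            )
            if not disjoint_consistent or abs((g - r) - (g2 - r2)) >= d:
                ok = False
        if ok:
            chain.append((L, r, g))
    return sorted((r, g, L) for L, r, g in chain)


def test_single_seed_is_a_chain():
    chain = select_anchor_chain([(20, 0, 100)], d=21)
    assert [(b.read_start, b.genome_start, b.length) for b in chain] == [(0, 100, 20)]


def test_two_consistent_seeds_kept_in_order():
    chain = select_anchor_chain([(20, 30, 130), (20, 0, 100)], d=21)
    assert [(b.read_start, b.genome_start, b.length) for b in chain] == [
        (0, 100, 20),
        (30, 130, 20),
    ]


def test_longer_seed_wins_a_conflict():
    chain = select_anchor_chain([(20, 0, 100), (25, 10, 500)], d=21)
    assert [(b.read_start, b.genome_start, b.length) for b in chain] == [(10, 500, 25)]


def test_greedy_chain_matches_naive_restatement(rng):
    for _ in range(300):
        n = int(rng.integers(1, 8))
        seeds = [
            (int(rng.integers(8, 30)), int(rng.integers(0, 60)), int(rng.integers(0, 120)))
            for _ in range(n)
        ]
        d = int(rng.integers(2, 30))
        got = select_anchor_chain(seeds, d)
        assert [(b.read_start, b.genome_start, b.length) for b in got] == [
            (r, g, L) for r, g, L in naive_greedy_chain(seeds, d)
        ]


# ---------------------------------------------------------------------------
# banded DP


def _check_path(ref, read, ops, dist):
    i = j = cost = 0
    for op in ops:
        if op == "M":
            cost += int(ref[j] != read[i])
            i += 1
            j += 1
        elif op == "I":
            cost += 1
            i += 1
        else:
            cost += 1
            j += 1
    assert i == len(read)
    assert cost == dist


def test_identity_and_single_deletion():
    d, ops, used = banded_gap_align(encode_seq("ACGT"), encode_seq("ACGT"), 3)
    assert (d, "".join(ops), used) == (0, "MMMM", 4)
    d, ops, used = banded_gap_align(encode_seq("ACGT"), encode_seq("AGT"), 3)
    assert d == 1 and ops.count("D") == 1 and used == 4


def test_banded_distance_equals_unbanded_oracle(rng):
    """With d exceeding both lengths the band is the full matrix: 500 random
    pairs must match edlib's global edit distance, and every path must be
    internally consistent."""
    for _ in range(500):
        a = rng.integers(1, 5, int(rng.integers(0, 31))).astype(np.uint8)
        b = rng.integers(1, 5, int(rng.integers(0, 31))).astype(np.uint8)
        dist, ops, used = banded_gap_align(a, b, 31)
        res = edlib.align(decode_seq(b), decode_seq(a), mode="NW", task="distance")
        assert dist == res["editDistance"]
        assert used == len(a)
        _check_path(a, b, ops, dist)


def test_band_monotone_in_d_and_converges(rng):
    for _ in range(40):
        a = rng.integers(1, 5, int(rng.integers(1, 25))).astype(np.uint8)
        b = rng.integers(1, 5, int(rng.integers(1, 25))).astype(np.uint8)
        exact = edlib.align(decode_seq(b), decode_seq(a), mode="NW", task="distance")[
            "editDistance"
        ]
        prev = None
        for d in range(1, 30):
            try:
                dist, _, _ = banded_gap_align(a, b, d)
            except BandInfeasible:
                assert abs(len(a) - len(b)) >= d
                continue
            if prev is not None:
                assert dist <= prev
            prev = dist
        assert prev == exact


def test_infeasible_band_raises():
    with pytest.raises(BandInfeasible):
        banded_gap_align(encode_seq("ACGTACGT"), encode_seq("AC"), 3)


def test_free_ref_modes_ignore_window_slack():
    dist, ops, used = banded_gap_align(
        encode_seq("ACGTTTTTT"), encode_seq("ACG"), 5, "free_ref_end"
    )
    assert (dist, "".join(ops), used) == (0, "MMM", 3)
    dist, ops, used = banded_gap_align(
        encode_seq("TTTTTTACG"), encode_seq("ACG"), 5, "free_ref_start"
    )
    assert (dist, "".join(ops), used) == (0, "MMM", 3)


def test_empty_read_gap():
    dist, ops, used = banded_gap_align(encode_seq("ACG"), encode_seq(""), 5)
    assert (dist, ops, used) == (3, ["D", "D", "D"], 3)
    dist, ops, used = banded_gap_align(encode_seq("ACG"), encode_seq(""), 5, "free_ref_end")
    assert (dist, ops, used) == (0, [], 0)


# ---------------------------------------------------------------------------
# align_to_candidate


def _tag_for(seeds, strand="+", tag_id=0):
    rec = TagRecord(tag_id=tag_id, strand=strand, read_serial=1)
    for s in seeds:
        rec.score += s[0]
        rec.seeds.append(s)
    return rec


def _cigar_sums(aln):
    read = sum(n for op, n in aln.cigar if op in "MI")
    ref = sum(n for op, n in aln.cigar if op in "MD")
    return read, ref


def test_error_free_read_single_anchor_full_match(small_ref):
    read = small_ref.seqs[0][1000:1100].copy()
    tag = _tag_for([(100, 0, 1000)])
    aln = align_to_candidate(read, small_ref, tag, e=20, d=21)
    assert aln.cigar == [("M", 100)]
    assert aln.edit_distance == 0 and aln.pos == 1000 and aln.strand == "+"


def test_mismatch_between_anchors(small_ref):
    read = small_ref.seqs[0][1000:1100].copy()
    read[50] = (read[50] % 4) + 1
    tag = _tag_for([(50, 0, 1000), (49, 51, 1051)])
    aln = align_to_candidate(read, small_ref, tag, e=20, d=21)
    assert aln.edit_distance == 1
    assert aln.cigar == [("M", 100)]
    assert aln.pos == 1000


def test_deletion_between_anchors(small_ref):
    # read skips 2 reference bases between the anchors
    seq = small_ref.seqs[0]
    read = np.concatenate([seq[1000:1050], seq[1052:1102]])
    tag = _tag_for([(50, 0, 1000), (50, 50, 1052)])
    aln = align_to_candidate(read, small_ref, tag, e=20, d=21)
    assert aln.edit_distance == 2
    assert ("D", 2) in aln.cigar
    r, g = _cigar_sums(aln)
    assert r == 100 and g == 102


def test_insertion_between_anchors(small_ref):
    seq = small_ref.seqs[0]
    ins = encode_seq("AC")
    read = np.concatenate([seq[1000:1050], ins, seq[1050:1098]])
    tag = _tag_for([(50, 0, 1000), (48, 52, 1050)])
    aln = align_to_candidate(read, small_ref, tag, e=20, d=21)
    assert aln.edit_distance <= 2  # the inserted bases may partially match
    assert _cigar_sums(aln)[0] == 100


def test_flank_errors_absorbed_without_clipping(small_ref):
    """Errors outside the anchors are aligned end-to-end; the window padding
    never inflates the distance."""
    seq = small_ref.seqs[0]
    read = seq[1000:1100].copy()
    read[2] = (read[2] % 4) + 1
    read[97] = (read[97] % 4) + 1
    tag = _tag_for([(90, 5, 1005)])
    aln = align_to_candidate(read, small_ref, tag, e=20, d=21)
    assert aln.pos == 1000
    assert aln.edit_distance == 2
    r, g = _cigar_sums(aln)
    assert r == 100


def test_minus_strand_candidate_uses_reverse_complement(small_ref):
    from aryana.fm_index import revcomp

    seq = small_ref.seqs[0]
    read = revcomp(seq[1000:1100])  # a perfect reverse-strand read
    # seeds live in revcomp(read) == forward coordinates
    tag = _tag_for([(100, 0, 1000)], strand="-")
    aln = align_to_candidate(read, small_ref, tag, e=20, d=21)
    assert aln.strand == "-" and aln.pos == 1000
    assert aln.cigar == [("M", 100)] and aln.edit_distance == 0


def test_candidate_dropped_when_band_cannot_bracket(small_ref):
    # anchor at the far right, 90 read bases to place before a window whose
    # left slack was clipped away by the sequence start
    seq = small_ref.seqs[0]
    read = np.concatenate([encode_seq("A" * 90), seq[5:15]])
    tag = _tag_for([(10, 90, 5)])
    aln = align_to_candidate(read, small_ref, tag, e=20, d=21)
    assert aln is None


# ---------------------------------------------------------------------------
# ranking


def _result(dist, score, pos, strand="+", tag=0, seq_id=0):
    return AlignmentResult(
        seq_id=seq_id,
        pos=pos,
        strand=strand,
        cigar=[("M", 100)],
        edit_distance=dist,
        tag_score=score,
        tag_key=(tag, strand),
    )


def test_rank_prefers_lower_distance_then_score():
    a, b = _result(3, 100, 500, tag=1), _result(7, 300, 900, tag=2)
    best, runner = rank_candidates([b, a])
    assert best is a and runner is b
    a, b = _result(3, 180, 500, tag=1), _result(3, 150, 900, tag=2)
    best, runner = rank_candidates([b, a])
    assert best is a and runner is b


def test_runner_up_must_come_from_a_different_tag():
    a = _result(2, 100, 500, tag=4)
    same = _result(5, 90, 510, tag=4)
    other = _result(6, 80, 900, tag=8)
    best, runner = rank_candidates([a, same, other])
    assert best is a and runner is other


def test_rank_matches_exhaustive_comparison(rng):
    for _ in range(200):
        n = int(rng.integers(1, 7))
        results = [
            _result(
                int(rng.integers(0, 6)),
                int(rng.integers(50, 200)),
                int(rng.integers(0, 1000)),
                strand="+" if rng.random() < 0.5 else "-",
                tag=int(rng.integers(0, 4)),
            )
            for _ in range(n)
        ]
        best, runner = rank_candidates(results)
        key = lambda r: (r.edit_distance, -r.tag_score, (r.seq_id, r.pos), r.strand)
        exp_best = min(results, key=key)
        assert key(best) == key(exp_best)
        others = [r for r in results if r.tag_key != best.tag_key]
        if others:
            assert runner is not None and key(runner) == key(min(others, key=key))
        else:
            assert runner is None


def test_empty_candidate_list_signals_unaligned():
    assert rank_candidates([]) is None
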