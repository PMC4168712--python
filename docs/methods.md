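# Methods

## The alignment model

`aryana` places short reads on a reference genome by seed-and-extend with
unit-cost edit distance. The pipeline for one read:

1. **Exact search structure.** The reference sequences are concatenated into
   a forward text `F` (length `G`), and the index is built over
   `T = F + rc(F) + $`. Because `rc(F + rc(F)) = F + rc(F)`, the doubled text
   contains every substring together with its reverse complement; one
   backward-search primitive over the BWT of `T` therefore answers both a
   right-to-left suffix extension (`match_right_to_left`, returning the
   suffix-array interval) and, applied to complemented symbols in forward
   order, a left-to-right extension (`match_left_to_right`, returning only a
   length). `N` is mapped to a sentinel outside the search alphabet, so no
   exact match ever crosses an `N` in the reference or the read. Hits located
   in the reverse half of `T` at position `p` are folded to forward
   coordinate `2G − p − len` with strand `−`; hits spanning the
   forward/reverse junction, a boundary between concatenated sequences, or
   the terminator are discarded.

2. **Seed extraction.** A greedy scan from the right end of the read
   extracts a maximal set of seeds, each at least `k` bp, any two
   overlapping by at most `k − 1` read bases, each with at least one exact
   match. A failing `k`-window probe at position `j` certifies that every
   window containing the failing base also fails, so the scan jumps past it;
   a succeeding probe is extended maximally leftward and the `k − 1`
   leftmost seed letters stay available to the next window. `k` follows a
   read-length schedule: 16 below 50 bp, 20 below 200 bp, 24 below 500 bp,
   28 above.

3. **Tag scoring.** The genome is partitioned into tags of length
   `L = R·c` (`R` read length, `c = 10`). Each located seed occurrence — at
   most `P = 50` per seed, in ascending BWT-row order — votes for the tag
   containing the estimated read start `m − n` (`m` genome position of the
   seed, `n` read bases before it), with score equal to the seed length.
   For reverse-strand hits `n` is taken in reverse-complement read
   coordinates, which makes the estimate identical across all seeds of one
   error-free read on either strand. Records are keyed by (tag, strand) in
   an open-addressing hash table (multiplicative hash, linear probing,
   power-of-two capacity, default 2^18 per worker). Each record carries the
   serial of the read that wrote it; advancing the serial invalidates the
   whole table in O(1), so the table is never cleared between reads. A
   sorted list of the `t = 10` best visible records is maintained after
   every grant; since scores only grow within a read, a record evicted from
   the list can only re-enter on its own next grant, which is exactly when
   it is reconsidered.

4. **Precise alignment.** For each top tag, its stored seeds are reduced to
   an anchor chain, greedy longest-first (ties: leftmost in the read, then
   lowest genome position), accepting a seed iff it is disjoint and
   collinear with every accepted block, lies in the same sequence, and its
   diagonal offset differs by less than `d` from each accepted block.
   Anchors are exact and contribute zero-cost `M` runs. The region is padded
   by `e = 20` bp on both sides; interior gaps are aligned globally and the
   flanks with free reference ends, using the banded DP over (read position
   `i`, offset = reference − read position), `|offset| < d`:

       D[i][off] = min( D[i−1][off] + [ref[i+off] ≠ read[i]],
                        D[i−1][off+1] + 1,       # read-only base (I)
                        D[i][off−1] + 1 )        # reference-only base (D)

   which costs `O(d·n)`. Mismatches and indels cost 1 alike. The DP
   tie-breaks `M` over `D` over `I` during traceback, deterministically.
   A gap whose band is infeasible is retried once with `2d`; if it still
   fails the candidate is dropped. Candidates are ranked by edit distance,
   then tag score, then coordinate, then `+` strand.

5. **Reporting.** Reads align end-to-end (CIGAR over `M`, `I`, `D`; no
   clipping), with `NM` = mismatches + indel bases. Mapping quality is
   `min(60, ⌊60·(s_best − s_runner)/max(s_best, 1)⌋)` with
   `s(x) = R − edit(x)`, the runner-up being the best candidate from a
   different tag; 60 with no rival, 0 on a tie. Paired ends are aligned
   independently; among all cross pairs on one sequence with FR orientation
   and outer distance within `[min_insert, max_insert]` the pair with the
   highest total score wins (ties: smaller total edit distance, then
   leftmost). Without a valid pair, each end reports its individual best
   without the proper-pair flag.

## Parameters

| name | default | meaning |
|------|---------|---------|
| `k` schedule | 16/20/24/28 | minimum seed length by read length (<50, <200, <500, ≥500 bp) |
| `c` | 10 | tag length multiplier, `L = R·c` |
| `P` | 50 | located hits granted per seed |
| `t` | 10 | candidate tags taken to precise alignment |
| `e` | 20 bp | window padding on each side of a candidate region |
| `d` | 21 | DP band half-width (`e + 1`: an indel larger than the flank slack cannot be bracketed by the window anyway); one retry at `2d` |
| `min_insert`, `max_insert` | 0, 1000 bp | accepted outer distance for proper pairs |
| capacity | 2^18 | tag-table slots per worker |

The growth points of the `k` schedule beyond the 16-for-short-reads rule are
this package's choice and are tunable from the CLI
(`--seed-len-schedule`). Tie-breaks (lower tag id, `+` before `−`, `M` over
`D` over `I`) exist purely for determinism: two runs on identical input are
byte-identical, and worker count never changes the emitted record set
because workers share only the read-only index and own their tag tables.

## The simulator, and what passing does not show

`simulate_genome` draws i.i.d. bases at a chosen GC content;
`simulate_reads` takes uniform positions and a fair strand coin, substitutes
each base with probability `sub_rate` (uniform over the three alternatives),
and opens indels with probability `indel_rate` (default `sub_rate/10`,
insertion/deletion equiprobable, length 1 plus a geometric extension with
parameter 0.3). Reads are always exactly `read_len` bases, as a sequencer
emits a fixed number of cycles; deletions consume extra template. Paired
mode draws fragment sizes from a normal distribution and emits facing FR
ends. Truth (sequence, strand, 0-based leftmost template coordinate, error
counts) is written to a 6-column TSV sidecar, which the evaluator treats as
authoritative.

The evaluator counts a read correct iff it is aligned to the true sequence
and strand with its leftmost coordinate within a tolerance, 20 bp by
default — equal to `e`, since bracketed indels can shift the reported
leftmost coordinate by at most the flank slack; simulator-style evaluators
commonly use a wiggle of this magnitude. Recall is correct/total, precision
correct/aligned.

An i.i.d. genome has essentially no repeat structure, a uniform error
profile has no quality ramp, and indels carry no platform idiosyncrasies
(homopolymer slips, flow errors). Accuracy measured here is therefore an
upper bound on what the same engine achieves on a mammalian genome with
repeats and real error profiles; the benchmark values from the literature
are used as floors, not as two-sided targets. By default no score threshold
suppresses reporting — a read with at least one seed always reports its
best candidate — which favors recall over precision on repetitive
references; on the synthetic genomes used here the distinction is mostly
invisible.

## Numerical and degenerate-input choices

- The suffix array is built by prefix doubling with numpy sorts
  (`O(n log² n)`); construction speed is not a contract, correctness is
  (inverse-BWT and sorted-rotation checks). The full suffix array and a
  full cumulative occurrence table are kept in memory — at the megabase
  scales this package targets, sampling would only add code.
- The on-disk index is a versioned numpy archive of names, lengths, forward
  codes, suffix array and BWT; rank tables are rebuilt at load (a few
  cumulative sums).
- DP border: row 0 costs `|offset|` for non-negative offsets and is
  infeasible where the offset implies a negative reference position.
- Empty gaps (adjacent anchors) short-circuit to pure `D`/`I` runs.
- Estimated read starts are clamped to 0 at the sequence start.
- A read shorter than `k` gets one probe with `k` reduced to the read
  length; an all-`N` read has no seeds and is reported unaligned with
  FLAG 4.
- Serial wraparound of the tag table (once per 2^32 reads) falls back to a
  full clear; a full table evicts the lowest-scoring live record outside
  the top list (pathological, logged).

## Problem sizes in the shipped checks

The test suite exercises oracle equivalence on random genomes up to a few
kbp (FM search vs direct scans; banded DP vs an unbanded edit-distance
library; greedy decisions vs exhaustive restatements) and runs the
simulation sweeps on a seeded 1 Mbp genome with 2,000 reads per condition
(1,000 at 500 bp) — sizes chosen so the whole suite stays interactive while
sampling error remains far below the margins being asserted.
`scripts/acceptance.py` runs the same sweeps at 10,000 reads (5,000 at
500 bp). Recall at these scales is insensitive to the read count beyond the
second decimal.

## Known limitations

- No clipped (local) alignment: a read whose true placement runs off a
  sequence end, or whose flank cannot fit the band even after the `2d`
  retry, is dropped from that candidate rather than soft-clipped.
- Unit costs only; no affine gaps, no base-quality awareness.
- One reported alignment per read; no secondary/supplementary records.
- The index holds the full suffix array in memory: fine for microbial and
  desk-scale genomes, not sized for mammalian references.
- Threads share nothing but the index; scaling is limited by the
  interpreter, and the worker option exists for the determinism contract
  more than for throughput.
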