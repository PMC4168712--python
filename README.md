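# aryana

A seed-and-extend short-read aligner, with a built-in read simulator and
mapping evaluator. It maps Illumina-style single-end and paired-end reads
(FASTQ) against a reference genome (FASTA) and writes SAM, and it is aimed
at people who want a complete, inspectable alignment engine at desk scale —
methods work, teaching, and benchmarking on microbial or synthetic genomes —
rather than a production mapper for mammalian references.

## The algorithm

Alignment of a read `r` (length `R`) runs in two phases over an FM-index
built on the doubled text `T = F · rc(F)` (`F` the concatenated reference,
`rc` reverse complement), so forward and reverse strand are searched with
one backward-search primitive:

1. **Seeding and scoring.** A greedy right-to-left scan extracts a maximal
   set of seeds, each of length ≥ `k` (16–28, by read length), pairwise read
   overlap < `k`, each with an exact match in `T`; windows proven matchless
   are jumped over. Every located occurrence of a seed (genome position
   `m`, `n` read bases before it) grants its length in score to the *tag* —
   the genome partition of length `L = R·c` — containing the estimated read
   start `m − n`. Scores live in a reset-free open-addressing hash table:
   records are stamped with a per-read serial, so starting the next read
   invalidates the table in O(1) without clearing it, and a sorted list
   tracks the `t` = 10 best (tag, strand) records at all times.

2. **Gap-filling banded alignment.** Each top tag's seeds are reduced to a
   greedy collinear anchor chain; only the gaps between anchors (and the
   flanks, padded by `e` = 20 bp) are aligned, by a unit-cost edit-distance
   DP indexed by read position and diagonal offset, banded to
   `|offset| < d` = 21:

   `D[i][off] = min(D[i−1][off] + [ref[i+off] ≠ read[i]], D[i−1][off+1] + 1, D[i][off−1] + 1)`

   The best candidate by edit distance becomes the SAM record (end-to-end
   CIGAR over M/I/D, `NM` tag, MAPQ from the best-vs-runner-up score gap).
   Paired ends combine per-end finalists under FR orientation and insert
   bounds, maximizing total score.

Full model details, parameter rationale and limitations are in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate a 50 kbp genome with one hundred 100 bp reads at 2% substitution
error, index, align, evaluate:

```bash
aryana simulate --length 50000 -n 100 --read-len 100 --sub-rate 0.02 --seed 11 -o wk
aryana index wk.fa -o wk
aryana align -x wk -U wk.fq -S wk.sam
aryana evaluate wk.sam wk.truth.tsv
```

which prints

```
reads     100
aligned   100
correct   100
recall    100.00
precision 100.00
```

`recall` is the fraction of simulated reads placed on the true sequence and
strand within 20 bp of the true leftmost coordinate; `precision` is the
same count divided by the number of aligned reads. The SAM itself starts

```
@HD  VN:1.6  SO:unknown
@SQ  SN:sim1 LN:50000
sim_0  0  sim1  48529  60  100M  *  0  0  GGACCTGTGG...
```

— read `sim_0` mapped forward (FLAG 0) at position 48529 with a full-length
match (`100M`) and mapping quality 60. Paired-end reads go through
`aryana align -x wk -1 r1.fq -2 r2.fq -S out.sam`, and every parameter
(`-c`, `-P`, `-t`, `-e`, `-d`, insert bounds, seed-length schedule, worker
count) is exposed on the command line. The same functionality is available
as a library (`aryana.FMIndex`, `aryana.Aligner`, `aryana.simulate_reads`,
`aryana.evaluate_alignments`).

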