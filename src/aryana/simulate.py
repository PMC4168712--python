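"""Synthetic genomes, dwgsim-style Illumina reads, and mapping evaluation.

The simulator draws i.i.d. bases at a chosen GC content, extracts reads at
uniform positions on either strand, and corrupts them with a uniform
per-base substitution rate plus geometrically-extended indels, recording the
pre-error origin of every read.  The evaluator scores a SAM file against
those truth records: a read is correctly placed iff it is aligned to the
true sequence and strand with its leftmost coordinate within a small
positional tolerance; recall is correct/total and precision correct/aligned.

Truth travels two ways: encoded in the read name (underscore-separated
fields, in the style of dwgsim) and, authoritatively, in a 6-column
tab-separated sidecar file::

    read_id  sequence_name  strand  position(0-based leftmost)  substitutions  indel_bases

Reads are always exactly ``read_len`` bases: deletions consume extra
template, insertions consume less, mirroring how a sequencer emits a fixed
number of cycles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .engine import ReadRecord, SamRecord
from .fm_index import CODE_A, CODE_T, ReferenceSet, decode_seq, revcomp

DEFAULT_TOLERANCE = 20  # bp; matches the flank extension e


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    seq_name: str
    strand: str
    pos: int  # 0-based leftmost forward coordinate of the template
    subs: int
    indel_bases: int


@dataclass(frozen=True)
class EvalSummary:
    n_reads: int
    n_aligned: int
    n_correct: int

    @property
    def recall(self) -> float:
        return 100.0 * self.n_correct / self.n_reads if self.n_reads else 0.0

    @property
    def precision(self) -> float:
        return 100.0 * self.n_correct / self.n_aligned if self.n_aligned else 0.0


def simulate_genome(
    length: int, gc: float = 0.5, seed: int | np.random.Generator = 0, name: str = "sim1"
) -> ReferenceSet:
    """A single random sequence of i.i.d. bases with P(G) + P(C) = gc."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at, gcp = (1.0 - gc) / 2.0, gc / 2.0
    codes = rng.choice(
        np.arange(CODE_A, CODE_T + 1, dtype=np.uint8),
        size=length,
        p=[at, gcp, gcp, at],
    )
    return ReferenceSet(names=[name], seqs=[codes])


def _corrupt(
    template: np.ndarray,
    read_len: int,
    sub_rate: float,
    indel_rate: float,
    indel_ext: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int, int, int]:
    """Walk a template emitting exactly ``read_len`` bases with errors.

    Returns (read codes, template bases consumed, substitutions, indel bases).
    """
    out = np.empty(read_len, dtype=np.uint8)
    n_out = 0
    tpos = 0
    subs = 0
    indel_bases = 0
    tlen = len(template)
    while n_out < read_len:
        if indel_rate > 0.0 and rng.random() < indel_rate:
            size = int(rng.geometric(1.0 - indel_ext))  # 1 + geometric extension
            if rng.random() < 0.5:  # insertion into the read
                for _ in range(size):
                    if n_out >= read_len:
                        break
                    out[n_out] = rng.integers(CODE_A, CODE_T + 1)
                    n_out += 1
                    indel_bases += 1
                continue
            # deletion: skip template bases
            size = min(size, tlen - tpos)
            tpos += size
            indel_bases += size
        if tpos >= tlen:
            # template exhausted (long deletions near the end): pad as insertion
            out[n_out] = rng.integers(CODE_A, CODE_T + 1)
            n_out += 1
            indel_bases += 1
            continue
        base = template[tpos]
        tpos += 1
        if sub_rate > 0.0 and rng.random() < sub_rate:
            base = (base - CODE_A + rng.integers(1, 4)) % 4 + CODE_A
            subs += 1
        out[n_out] = base
        n_out += 1
    return out, tpos, subs, indel_bases


def simulate_reads(
    ref: ReferenceSet,
    n: int,
    read_len: int,
    sub_rate: float,
    indel_rate: float | None = None,
    indel_ext: float = 0.3,
    paired: bool = False,
    insert_mean: float = 500.0,
    insert_sd: float = 50.0,
    seed: int | np.random.Generator = 0,
    id_prefix: str = "sim",
) -> tuple[list[ReadRecord], list[TruthRecord]]:
    """Simulate ``n`` reads (or ``n`` FR pairs when ``paired``).

    ``indel_rate`` defaults to a tenth of the substitution rate.  Paired mode
    draws fragment (outer) sizes from a normal distribution and emits the
    two ends facing each other; in the returned list the ends of pair ``i``
    are adjacent, named ``.../1`` and ``.../2``.
    """
    if not (0.0 <= sub_rate < 1.0):
        raise ValueError("sub_rate must be in [0, 1)")
    indel_rate = sub_rate / 10.0 if indel_rate is None else indel_rate
    if not (0.0 <= indel_rate < 1.0):
        raise ValueError("indel_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    lengths = np.array(ref.lengths(), dtype=np.float64)
    margin = read_len // 4  # slack so deletions rarely run off the template
    if paired:
        need = int(insert_mean + 6 * insert_sd) + margin
    else:
        need = read_len + margin
    if any(int(l) < need for l in lengths):
        raise ValueError(
            f"sequence shorter than the {need} bp needed for these reads/inserts"
        )

    reads: list[ReadRecord] = []
    truths: list[TruthRecord] = []
    quals = "I" * read_len
    for i in range(n):
        seq_i = int(rng.choice(len(lengths), p=lengths / lengths.sum()))
        seq = ref.seqs[seq_i]
        name = ref.names[seq_i]
        if not paired:
            start = int(rng.integers(0, len(seq) - read_len - margin + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            template = seq[start : start + read_len + margin]
            if strand == "-":
                # sequence the reverse strand right-to-left: corrupt the
                # reverse complement, whose template start is the rightmost
                # forward base
                codes, span, subs, ind = _corrupt(
                    revcomp(template), read_len, sub_rate, indel_rate, indel_ext, rng
                )
                pos = start + len(template) - span
            else:
                codes, span, subs, ind = _corrupt(
                    template, read_len, sub_rate, indel_rate, indel_ext, rng
                )
                pos = start
            rid = f"{id_prefix}_{i}"
            reads.append(ReadRecord(rid, decode_seq(codes), quals))
            truths.append(TruthRecord(rid, name, strand, pos, subs, ind))
        else:
            frag = int(round(rng.normal(insert_mean, insert_sd)))
            frag = max(frag, read_len + margin)
            frag = min(frag, len(seq))
            start = int(rng.integers(0, len(seq) - frag + 1))
            fragment = seq[start : start + frag]
            # which physical end becomes read 1 is a fair coin
            r1_forward = rng.random() < 0.5
            ends = []
            for end_no, forward in ((1, r1_forward), (2, not r1_forward)):
                if forward:
                    codes, span, subs, ind = _corrupt(
                        fragment, read_len, sub_rate, indel_rate, indel_ext, rng
                    )
                    ends.append((end_no, "+", start, codes, subs, ind))
                else:
                    codes, span, subs, ind = _corrupt(
                        revcomp(fragment), read_len, sub_rate, indel_rate, indel_ext, rng
                    )
                    ends.append((end_no, "-", start + frag - span, codes, subs, ind))
            for end_no, strand, pos, codes, subs, ind in sorted(ends):
                rid = f"{id_prefix}_{i}/{end_no}"
                reads.append(ReadRecord(rid, decode_seq(codes), quals))
                truths.append(TruthRecord(rid, name, strand, pos, subs, ind))
    return reads, truths


# ---------------------------------------------------------------------------
# Truth and read files


def write_truth(truths: Iterable[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tseq_name\tstrand\tpos\tsubs\tindel_bases\n")
        for t in truths:
            fh.write(
                f"{t.read_id}\t{t.seq_name}\t{t.strand}\t{t.pos}\t{t.subs}\t{t.indel_bases}\n"
            )


def read_truth(path: str | Path) -> list[TruthRecord]:
    truths = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id\t"):
            raise ValueError(f"{path}: not a truth file (bad header)")
        for line in fh:
            rid, name, strand, pos, subs, ind = line.rstrip("\n").split("\t")
            truths.append(
                TruthRecord(rid, name, strand, int(pos), int(subs), int(ind))
            )
    return truths


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.qualities or 'I' * len(r.sequence)}\n")


# ---------------------------------------------------------------------------
# Evaluation


def _normalize(rec) -> tuple[str, bool, str | None, str | None, int | None]:
    """(read id, aligned, seq name, strand, 0-based pos) from a SamRecord or
    a pysam AlignedSegment."""
    if isinstance(rec, SamRecord):
        if rec.is_unmapped:
            return rec.qname, False, None, None, None
        return (
            rec.qname,
            True,
            rec.rname,
            "-" if rec.is_reverse else "+",
            rec.pos - 1,
        )
    # pysam AlignedSegment
    if rec.is_unmapped:
        return rec.query_name, False, None, None, None
    return (
        rec.query_name,
        True,
        rec.reference_name,
        "-" if rec.is_reverse else "+",
        rec.reference_start,
    )


def iter_sam(path: str | Path):
    """Primary records of a SAM file, via pysam."""
    import pysam

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            yield rec


def evaluate_alignments(
    records: Iterable | str | Path,
    truths: Iterable[TruthRecord],
    tolerance: int = DEFAULT_TOLERANCE,
) -> EvalSummary:
    """Score alignments against simulator truth.

    ``records`` may be SamRecords, pysam segments, or a path to a SAM file.
    A read counts as correct iff it is aligned on the true sequence and
    strand with its leftmost coordinate within ``tolerance`` bp of the truth.
    A record whose name has no truth entry is an error (it would silently
    deflate recall otherwise).
    """
    by_id: dict[str, TruthRecord] = {}
    for t in truths:
        if t.read_id in by_id:
            raise ValueError(f"duplicate truth id {t.read_id!r}")
        by_id[t.read_id] = t
    if isinstance(records, (str, Path)):
        records = iter_sam(records)
    n_reads = len(by_id)
    n_aligned = 0
    n_correct = 0
    seen = set()
    for rec in records:
        rid, aligned, rname, strand, pos = _normalize(rec)
        truth = by_id.get(rid)
        if truth is None:
            raise ValueError(f"SAM read {rid!r} has no truth record")
        if rid in seen:
            raise ValueError(f"SAM read {rid!r} reported twice")
        seen.add(rid)
        if not aligned:
            continue
        n_aligned += 1
        if (
            rname == truth.seq_name
            and strand == truth.strand
            and abs(pos - truth.pos) <= tolerance
        ):
            n_correct += 1
    return EvalSummary(n_reads=n_reads, n_aligned=n_aligned, n_correct=n_correct)
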