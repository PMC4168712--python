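"""BWT/FM-index over the forward genome concatenated with its reverse complement.

The index is built over ``T = F + rc(F) + $`` where ``F`` is the concatenation
of all reference sequences and ``rc`` the reverse complement.  Because
``rc(F + rc(F)) = F + rc(F)``, the doubled text is its own reverse complement:
every substring occurs together with its reverse complement, which is what
allows a single backward-search primitive to serve both a right-to-left suffix
extension and (applied to the complement strand) a left-to-right prefix
extension.

Two search primitives are exposed:

``match_right_to_left``
    classic backward search: extend a match leftward from a read position one
    symbol per step, keeping the suffix-array interval of the current match.

``match_left_to_right``
    how far a substring starting at a read position extends to the right while
    still matching somewhere; implemented as backward search over the reverse
    complement of that substring, so only a length (no positions) is returned.

Row-to-position resolution (`bwt_position`) folds hits that land in the
reverse half back onto forward coordinates with a ``-`` strand bit, and
rejects hits that span the forward/reverse junction or a boundary between two
concatenated sequences.

Coordinates are 0-based half-open throughout; SAM emission converts to
1-based elsewhere.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

# --------------------------------------------------------------------------
# Alphabet
#
# 0 is the terminator (sorts first), 1..4 are A,C,G,T, 5 is N.  N is a
# sentinel outside the search alphabet: queries containing it stop extension
# and reference Ns can never be part of an exact match.
TERM = 0
CODE_A, CODE_C, CODE_G, CODE_T, CODE_N = 1, 2, 3, 4, 5
_ALPHABET = 6

_ENCODE = np.full(256, CODE_N, dtype=np.uint8)
for _i, _b in enumerate(b"\0ACGTN"):
    _ENCODE[_b] = _i
for _i, _b in enumerate(b"\0acgtn"):
    _ENCODE[_b] = _i

_DECODE = np.frombuffer(b"$ACGTN", dtype=np.uint8)

# complement of a code; terminator and N map to themselves
_COMP = np.array([0, CODE_T, CODE_G, CODE_C, CODE_A, CODE_N], dtype=np.uint8)

INDEX_FORMAT_VERSION = 1
INDEX_SUFFIX = ".ari.npz"


def encode_seq(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (case-insensitive; any
    letter outside ACGT becomes N)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def revcomp_str(seq: str) -> str:
    return decode_seq(revcomp(encode_seq(seq)))


class ReferenceError(ValueError):
    """Raised for unusable reference input (empty, or all-N)."""


@dataclass
class ReferenceSet:
    """An ordered set of reference sequences with global coordinates.

    ``starts[i]`` is the 0-based start of sequence ``i`` in the concatenated
    forward genome; ``G`` is the total forward length.  Sequences are stored
    as uint8 code arrays.
    """

    names: list[str]
    seqs: list[np.ndarray]
    starts: np.ndarray = field(init=False)
    G: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.seqs:
            raise ReferenceError("reference contains no sequences")
        lengths = [len(s) for s in self.seqs]
        if any(n == 0 for n in lengths):
            raise ReferenceError("reference contains an empty sequence")
        self.starts = np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(np.int64)
        self.G = int(sum(lengths))

    @classmethod
    def from_fasta(cls, path: str | Path | io.TextIOBase) -> "ReferenceSet":
        """Load a (possibly multi-record, line-wrapped) FASTA file."""
        handle = open(path) if isinstance(path, (str, Path)) else path
        try:
            names, seqs = [], []
            for rec in SeqIO.parse(handle, "fasta"):
                names.append(rec.id)
                seqs.append(encode_seq(str(rec.seq)))
        finally:
            if isinstance(path, (str, Path)):
                handle.close()
        return cls(names=names, seqs=seqs)

    @classmethod
    def from_strings(cls, seqs: dict[str, str]) -> "ReferenceSet":
        return cls(names=list(seqs), seqs=[encode_seq(s) for s in seqs.values()])

    def forward(self) -> np.ndarray:
        """Concatenated forward genome as codes."""
        return np.concatenate(self.seqs)

    def lengths(self) -> list[int]:
        return [len(s) for s in self.seqs]

    def seq_of(self, gpos: int) -> int:
        """Index of the sequence containing global forward coordinate gpos."""
        return int(np.searchsorted(self.starts, gpos, side="right")) - 1

    def split(self, gpos: int) -> tuple[int, int]:
        """(sequence index, within-sequence offset) for a global coordinate."""
        i = self.seq_of(gpos)
        return i, int(gpos - self.starts[i])

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, codes in zip(self.names, self.seqs):
                fh.write(f">{name}\n")
                s = decode_seq(codes)
                for j in range(0, len(s), width):
                    fh.write(s[j : j + width] + "\n")


@dataclass(frozen=True)
class SAInterval:
    """Inclusive range of BWT rows whose suffixes share the query as prefix.

    An empty interval is represented with begin > end.
    """

    begin: int
    end: int

    @property
    def width(self) -> int:
        return max(0, self.end - self.begin + 1)

    def __bool__(self) -> bool:  # non-empty
        return self.begin <= self.end


def suffix_array(text: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n) with numpy sorts).

    Requires the last symbol to be a unique minimum (the terminator), which
    guarantees well-defined suffix order.
    """
    n = int(text.size)
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = text.astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        r1, r2 = rank[sa], key2[sa]
        bump = np.empty(n, dtype=np.int64)
        bump[0] = 0
        bump[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        order = np.cumsum(bump)
        if order[-1] == n - 1:
            return sa.astype(np.int64)
        rank = np.empty(n, dtype=np.int64)
        rank[sa] = order
        k *= 2


class FMIndex:
    """FM-index over the doubled reference text.

    Holds the BWT, the per-symbol first-row table, a full cumulative
    occurrence table (rank in O(1)) and the full suffix array (locate in
    O(1)); neither is sampled at the genome scales this package targets.
    The index keeps its :class:`ReferenceSet` so alignment can read reference
    bases back without a second file.
    """

    def __init__(self, ref: ReferenceSet, sa: np.ndarray, bwt: np.ndarray):
        self.ref = ref
        self.G = ref.G
        self.doubled_length = 2 * ref.G
        self.n = self.doubled_length + 1  # text + terminator
        self.sa = sa
        self.bwt = bwt
        # cumulative occurrence counts: occ[i, c] = # of c in bwt[:i]
        occ = np.zeros((self.n + 1, _ALPHABET), dtype=np.int32)
        for c in range(_ALPHABET):
            np.cumsum(bwt == c, out=occ[1:, c])
        self._occ = occ
        counts = occ[-1]
        self.first_occ = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        self._occ_item = occ.item  # bound method: fastest scalar access

    # -- construction -------------------------------------------------------

    @classmethod
    def build(cls, ref: ReferenceSet) -> "FMIndex":
        fwd = ref.forward()
        if not np.any((fwd >= CODE_A) & (fwd <= CODE_T)):
            raise ReferenceError("reference has no A/C/G/T base")
        text = np.concatenate([fwd, revcomp(fwd), [TERM]]).astype(np.uint8)
        sa = suffix_array(text)
        bwt = text[sa - 1]  # sa==0 wraps to text[-1], the terminator's left
        return cls(ref, sa, bwt)

    def text(self) -> np.ndarray:
        """The indexed doubled text (without terminator), reconstructed from
        the reference; used by tests and inverse-BWT checks."""
        fwd = self.ref.forward()
        return np.concatenate([fwd, revcomp(fwd)]).astype(np.uint8)

    def inverse_bwt(self) -> np.ndarray:
        """Reconstruct the doubled text (plus terminator) from the BWT alone
        by LF-walking; a structural self-check."""
        n = self.n
        out = np.empty(n, dtype=np.uint8)
        row = 0  # row of the suffix starting at the terminator's successor, text[0]
        # LF(row) maps to the row of the suffix one position earlier; walking
        # forward instead: row 0 is the terminator suffix, whose BWT symbol is
        # the last text character.  Reconstruct right-to-left.
        for i in range(n - 1, -1, -1):
            c = int(self.bwt[row])
            out[i] = c
            row = int(self.first_occ[c]) + int(self._occ_item((row, c)))
        # out currently starts with the terminator rotated to the front
        return np.roll(out, -1)

    # -- search -------------------------------------------------------------

    def _step(self, lo: int, hi: int, c: int) -> tuple[int, int]:
        base = int(self.first_occ[c])
        item = self._occ_item
        return base + item((lo, c)), base + item((hi + 1, c)) - 1

    def match_right_to_left(
        self, read: np.ndarray, right: int, max_len: int
    ) -> tuple[SAInterval, int]:
        """Backward search: extend leftward from read[right].

        Stops when the interval would become empty, a non-ACGT symbol is hit,
        or ``max_len`` symbols have matched.  Returns the last non-empty
        interval (the full row range when nothing matched) and the matched
        length.
        """
        if not 0 <= right < len(read):
            raise IndexError("right outside the read")
        lo, hi = 0, self.n - 1
        matched = 0
        i = right
        while matched < max_len and i >= 0:
            c = int(read[i])
            if c < CODE_A or c > CODE_T:
                break
            lo2, hi2 = self._step(lo, hi, c)
            if lo2 > hi2:
                break
            lo, hi = lo2, hi2
            matched += 1
            i -= 1
        return SAInterval(lo, hi), matched

    def match_left_to_right(self, read: np.ndarray, start: int, max_len: int) -> int:
        """Length of the longest match extending rightward from read[start].

        Runs backward search over the complemented symbols in forward order,
        which is backward search of the reverse complement of the substring;
        since the doubled text is reverse-complement closed this equals the
        maximal rightward extension of the substring itself.  Only the length
        is meaningful (the interval locates the complement strand).
        """
        if not 0 <= start < len(read):
            raise IndexError("start outside the read")
        lo, hi = 0, self.n - 1
        matched = 0
        stop = min(len(read), start + max_len)
        j = start
        while j < stop:
            c = int(_COMP[read[j]])
            if c < CODE_A or c > CODE_T:
                break
            lo2, hi2 = self._step(lo, hi, c)
            if lo2 > hi2:
                break
            lo, hi = lo2, hi2
            matched += 1
            j += 1
        return matched

    # -- locate -------------------------------------------------------------

    def locate_global(self, row: int, match_len: int) -> tuple[int, str] | None:
        """Resolve a BWT row to (global forward coordinate of the match's
        leftmost forward base, strand), or None if the hit spans the
        forward/reverse junction, a sequence boundary, or the terminator.
        """
        if match_len < 1:
            raise ValueError("match_len must be >= 1")
        p = int(self.sa[row])
        G = self.G
        if p + match_len > self.doubled_length:
            return None  # runs into the terminator
        if p < G:
            if p + match_len > G:
                return None  # spans the forward/reverse junction
            gpos, strand = p, "+"
        else:
            gpos, strand = 2 * G - p - match_len, "-"
        i = self.ref.seq_of(gpos)
        if gpos + match_len > int(self.ref.starts[i]) + len(self.ref.seqs[i]):
            return None  # spans two concatenated sequences
        return gpos, strand

    def bwt_position(self, row: int, match_len: int) -> tuple[int, int, str] | None:
        """(sequence id, 0-based within-sequence coordinate, strand) of the
        leftmost forward base of the match at this BWT row; None when the hit
        must be discarded (junction- or boundary-spanning)."""
        loc = self.locate_global(row, match_len)
        if loc is None:
            return None
        gpos, strand = loc
        i, off = self.ref.split(gpos)
        return i, off, strand

    # -- persistence --------------------------------------------------------
    #
    # On-disk format (<prefix>.ari.npz): a numpy archive with
    #   version      [1]               format version
    #   names        unicode array     sequence names
    #   lengths      int64             per-sequence lengths
    #   fwd          uint8             concatenated forward genome codes
    #   sa           int32/int64       full suffix array of the doubled text
    #   bwt          uint8             BWT of the doubled text + terminator
    # first_occ and the occurrence table are rebuilt at load time (a few
    # cumulative sums), so the archive stays small relative to the rank
    # structures.

    def save(self, prefix: str | Path) -> Path:
        path = Path(str(prefix) + INDEX_SUFFIX)
        sa = self.sa.astype(np.int32) if self.n < 2**31 else self.sa
        np.savez(
            path,
            version=np.array([INDEX_FORMAT_VERSION], dtype=np.int64),
            names=np.array(self.ref.names),
            lengths=np.array(self.ref.lengths(), dtype=np.int64),
            fwd=self.ref.forward(),
            sa=sa,
            bwt=self.bwt,
        )
        return path

    @classmethod
    def load(cls, prefix: str | Path) -> "FMIndex":
        path = Path(str(prefix))
        if not path.name.endswith(INDEX_SUFFIX):
            path = Path(str(prefix) + INDEX_SUFFIX)
        with np.load(path) as z:
            version = int(z["version"][0])
            if version != INDEX_FORMAT_VERSION:
                raise ValueError(
                    f"index format version {version} not supported "
                    f"(expected {INDEX_FORMAT_VERSION})"
                )
            names = [str(x) for x in z["names"]]
            lengths = z["lengths"]
            fwd = z["fwd"]
            sa = z["sa"].astype(np.int64)
            bwt = z["bwt"]
        seqs, pos = [], 0
        for n in lengths:
            seqs.append(fwd[pos : pos + int(n)])
            pos += int(n)
        return cls(ReferenceSet(names=names, seqs=seqs), sa, bwt)
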