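"""Shared fixtures and naive reference oracles.

The oracles deliberately avoid every data structure the package builds: they
scan plain strings / arrays, so agreement with the FM-index or the banded DP
is evidence, not circularity.
"""

from __future__ import annotations

import numpy as np
import pytest

from aryana.fm_index import FMIndex, ReferenceSet, decode_seq, encode_seq, revcomp


def doubled_text(ref: ReferenceSet) -> np.ndarray:
    fwd = ref.forward()
    return np.concatenate([fwd, revcomp(fwd)])


def naive_count(text: np.ndarray, pattern: np.ndarray) -> int:
    """Occurrences of pattern in text by direct scan (N never matches)."""
    m = len(pattern)
    if m == 0:
        return len(text) + 1
    if m > len(text) or np.any(pattern == 5):  # CODE_N
        return 0
    windows = np.lib.stride_tricks.sliding_window_view(text, m)
    return int(np.all(windows == pattern, axis=1).sum())


def naive_max_left_extension(text: np.ndarray, read: np.ndarray, right: int, max_len: int) -> int:
    """Longest suffix of read[..right] (up to max_len) occurring in text."""
    best = 0
    for m in range(1, min(max_len, right + 1) + 1):
        if naive_count(text, read[right - m + 1 : right + 1]) > 0:
            best = m
        else:
            break
    return best


def naive_max_right_extension(text: np.ndarray, read: np.ndarray, start: int, max_len: int) -> int:
    best = 0
    stop = min(len(read), start + max_len)
    for m in range(1, stop - start + 1):
        if naive_count(text, read[start : start + m]) > 0:
            best = m
        else:
            break
    return best


def random_ref(rng: np.random.Generator, length: int, name: str = "r") -> ReferenceSet:
    return ReferenceSet(
        names=[name], seqs=[rng.integers(1, 5, length).astype(np.uint8)]
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_ref() -> ReferenceSet:
    """A 3 kbp random reference whose 16-mers are all unique (checked), so
    error-free reads have unambiguous placements."""
    local = np.random.default_rng(7)
    ref = random_ref(local, 3000, "chrS")
    text = doubled_text(ref)
    k = 16
    kmers = {tuple(text[i : i + k]) for i in range(len(text) - k + 1)}
    assert len(kmers) == len(text) - k + 1, "fixture genome has repeated 16-mers"
    return ref


@pytest.fixture(scope="session")
def small_idx(small_ref) -> FMIndex:
    return FMIndex.build(small_ref)


@pytest.fixture(scope="session")
def multi_ref() -> ReferenceSet:
    """Two sequences, to exercise boundary rejection and name plumbing."""
    local = np.random.default_rng(13)
    return ReferenceSet(
        names=["chrA", "chrB"],
        seqs=[
            local.integers(1, 5, 1500).astype(np.uint8),
            local.integers(1, 5, 900).astype(np.uint8),
        ],
    )


@pytest.fixture(scope="session")
def multi_idx(multi_ref) -> FMIndex:
    return FMIndex.build(multi_ref)
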