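"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately naive (exhaustive enumeration, full-scan
comparison) and never call the code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from primerspec.io_formats import SequenceRecord, reverse_complement

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def brute_force_global_score(a: str, b: str, reward=1, penalty=-1, gap=-2) -> int:
    """Optimum global alignment score by enumerating every alignment path.

    Exponential: only usable for very short strings.  Independent of the
    dynamic-programming implementation under test.
    """
    best = -(10 ** 9)
    stack = [(0, 0, 0)]
    while stack:
        i, j, sc = stack.pop()
        if i == len(a) and j == len(b):
            best = max(best, sc)
            continue
        if i < len(a) and j < len(b):
            s = reward if (a[i] == b[j] and a[i] != "N") else penalty
            stack.append((i + 1, j + 1, sc + s))
        if i < len(a):
            stack.append((i + 1, j, sc + gap))
        if j < len(b):
            stack.append((i, j + 1, sc + gap))
    return best


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def longest_match_run(a: str, b: str) -> int:
    """Longest stretch of consecutive identical (non-N) positions."""
    best = run = 0
    for x, y in zip(a, b):
        if x == y and x != "N":
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def best_segment_score(a: str, b: str, reward=1, penalty=-1) -> int:
    """Best-scoring ungapped sub-segment (Kadane) of an aligned pair."""
    best = cur = 0
    for x, y in zip(a, b):
        cur = max(0, cur + (reward if (x == y and x != "N") else penalty))
        best = max(best, cur)
    return best


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def full_scan_sites(
    primer: str,
    db: list[SequenceRecord],
    word_size: int = 7,
) -> set[tuple[str, str, int]]:
    """Brute-force oracle: every full-primer placement, on both strands,
    whose longest run of consecutive matches reaches the word size.

    Independent of the seed-and-extend engine: alignments are evaluated
    at every offset via a full-matrix scan.  Returns
    {(subject_id, strand, subject_start_of_placement)} with the start in
    subject plus-strand coordinates.
    """
    sites = set()
    L = len(primer)
    p = _encode(primer)
    n_pat = _encode("N" * L)
    for rec in db:
        for strand, sseq in (("plus", rec.seq),
                             ("minus", reverse_complement(rec.seq))):
            if len(sseq) < L:
                continue
            s = _encode(sseq)
            windows = np.lib.stride_tricks.sliding_window_view(s, L)
            matches = (windows == p) & (windows != n_pat[0]) & (p != n_pat[0])
            run_ok = matches[:, : L - word_size + 1].copy()
            for k in range(1, word_size):
                run_ok &= matches[:, k : L - word_size + 1 + k]
            hit_rows = np.nonzero(run_ok.any(axis=1))[0]
            for off in hit_rows:
                off = int(off)
                start = off if strand == "plus" else len(sseq) - off - L
                sites.add((rec.id, strand, start))
    return sites


def hits_to_sites(hits, primer_len: int, subject_lengths) -> set[tuple[str, str, int]]:
    """Map engine hits to full-primer placements via their diagonals,
    keeping only placements that fit entirely inside the subject."""
    sites = set()
    for h in hits:
        if h.strand == "plus":
            start = h.s_start - h.q_start
        else:
            start = h.s_start + h.q_end - primer_len
        if 0 <= start and start + primer_len <= subject_lengths[h.subject_id]:
            sites.add((h.subject_id, h.strand, start))
    return sites


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


def random_dna(rng, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
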