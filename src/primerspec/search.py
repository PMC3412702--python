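"""Word-indexed seed-and-extend local search with Karlin-Altschul E-values.

The engine mirrors the sensitive settings a primer-specificity search
needs rather than a general-purpose homology search: a short word size
(default 7), a very permissive E-value cutoff (default 30,000), unit
match/mismatch scores and a large per-subject cap.  At one reward to one
penalty, a target can carry up to about 35% mismatches to a short primer
and still produce a positive-scoring seed-anchored segment, provided at
least one exact word survives — the deliberate sensitivity/word-size
trade-off this module exposes.

Extension is ungapped with an X-drop rule; gapped completion of partial
alignments is the realignment module's job, so the local stage only has
to find *where* a primer might sit, not to account for every base.

E-values follow the ungapped Karlin-Altschul theory:

    E = K * m * n * exp(-lambda * S)

with lambda the positive root of  sum_ij p_i p_j exp(lambda * s_ij) = 1
and K computed from the standard series over partial-sum distributions
(see :func:`karlin_params`).  Both constants are solved numerically so
the scoring scheme stays configurable.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom

from .errors import (
    AllMaskedQueryError,
    EmptyDatabaseError,
    InvalidScoringError,
    SequenceError,
)
from .io_formats import Interval, SequenceRecord, merge_intervals, reverse_complement

logger = logging.getLogger(__name__)

#: Uniform background composition over A, C, G, T.
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class SearchParams:
    """Tunable knobs of the local search.

    Defaults are the sensitive primer-search settings: word size 7,
    E-value cutoff 30,000, +1/-1 scoring, up to 50,000 database subjects
    reported, X-drop of 6 score units (crosses runs of up to three
    consecutive mismatches at unit scoring).
    """

    word_size: int = 7
    evalue_cutoff: float = 30_000.0
    reward: int = 1
    penalty: int = -1
    max_db_seqs: int = 50_000
    xdrop: int = 6

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise InvalidScoringError("word_size must be >= 4")
        if not (self.reward > 0 > self.penalty):
            raise InvalidScoringError("need reward > 0 > penalty")
        if self.evalue_cutoff <= 0 or self.max_db_seqs <= 0 or self.xdrop < 0:
            raise InvalidScoringError("invalid search parameter")


class Seed(NamedTuple):
    """An exact word match; q_start is on the query's plus strand."""

    q_start: int
    subject_id: str
    s_start: int
    strand: str


@dataclass
class WordIndex:
    """Exact-word lookup table over the database subjects.

    Words containing N are never posted, so masked regions can neither
    seed nor be seeded.
    """

    word_size: int
    postings: dict[str, list[tuple[str, int]]]
    subjects: dict[str, SequenceRecord] = field(default_factory=dict)
    subject_order: dict[str, int] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.subjects.values())


@dataclass(frozen=True)
class KarlinParams:
    """lambda (nats per score unit) and K for an ungapped scoring scheme."""

    lam: float
    k: float


@dataclass
class LocalHit:
    """An ungapped local alignment segment between query and subject.

    Coordinates are 0-based half-open on the plus strands of both
    sequences; strand "minus" means the query segment aligns to the
    reverse complement of the subject segment (query position q pairs
    with subject position s_start + (q_end - 1 - q)).
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    score: int
    identities: int
    evalue: float = math.inf

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


def build_index(db: Sequence[SequenceRecord], word_size: int) -> WordIndex:
    """Post every ACGT word of length ``word_size`` of every subject."""
    if not db:
        raise EmptyDatabaseError("cannot index an empty database")
    if word_size < 4:
        raise InvalidScoringError("word_size must be >= 4")
    postings: dict[str, list[tuple[str, int]]] = defaultdict(list)
    subjects: dict[str, SequenceRecord] = {}
    order: dict[str, int] = {}
    for pos, rec in enumerate(db):
        if rec.id in subjects:
            raise EmptyDatabaseError(f"duplicate subject id {rec.id!r}")
        subjects[rec.id] = rec
        order[rec.id] = pos
        seq = rec.seq
        # next_n_at[i] = first N at or after i; windows touching an N are
        # skipped without rescanning the word.
        next_n_at = [len(seq)] * (len(seq) + 1)
        nn = len(seq)
        for i in range(len(seq) - 1, -1, -1):
            if seq[i] == "N":
                nn = i
            next_n_at[i] = nn
        for i in range(len(seq) - word_size + 1):
            if next_n_at[i] < i + word_size:
                continue
            postings[seq[i : i + word_size]].append((rec.id, i))
    return WordIndex(word_size=word_size, postings=dict(postings),
                     subjects=subjects, subject_order=order)


def _scan_strand(seq: str, index: WordIndex, strand: str, qlen: int) -> list[Seed]:
    w = index.word_size
    seeds = []
    for i in range(len(seq) - w + 1):
        word = seq[i : i + w]
        if "N" in word:
            continue
        for sid, off in index.postings.get(word, ()):
            q_plus = i if strand == "plus" else qlen - i - w
            seeds.append(Seed(q_plus, sid, off, strand))
    return seeds


def seed_hits(query: SequenceRecord, index: WordIndex) -> list[Seed]:
    """Exact word matches of both query strands against the index.

    Returned q_start values are plus-strand query offsets; for minus
    seeds the word matches the subject via the query's reverse
    complement.
    """
    qlen = len(query)
    seeds = _scan_strand(query.seq, index, "plus", qlen)
    seeds += _scan_strand(reverse_complement(query.seq), index, "minus", qlen)
    return seeds


def _pair_score(a: str, b: str, reward: int, penalty: int) -> int:
    # N never matches anything, including another N.
    return reward if (a == b and a != "N") else penalty


def extend_seed(
    query: SequenceRecord,
    subject: SequenceRecord,
    seed: Seed,
    params: SearchParams,
) -> LocalHit:
    """X-drop ungapped extension of an exact word match.

    Extension runs independently left and right of the seed, tracking
    the best running score and stopping once it falls more than
    ``params.xdrop`` below the best.  The returned segment is the
    maximal-scoring ungapped stretch containing the seed.
    """
    w = index_w = params.word_size
    qlen = len(query)
    if seed.strand == "plus":
        qs = query.seq
        i0 = seed.q_start
    else:
        qs = reverse_complement(query.seq)
        i0 = qlen - seed.q_start - w
    ss = subject.seq
    j0 = seed.s_start
    r, p, xdrop = params.reward, params.penalty, params.xdrop

    # right extension (past the seed's end)
    run = 0
    best_r = 0
    end_i = i0 + index_w
    i, j = i0 + index_w, j0 + index_w
    while i < len(qs) and j < len(ss):
        run += _pair_score(qs[i], ss[j], r, p)
        if run > best_r:
            best_r = run
            end_i = i + 1
        elif best_r - run > xdrop:
            break
        i += 1
        j += 1

    # left extension (before the seed's start)
    run = 0
    best_l = 0
    start_i = i0
    i, j = i0 - 1, j0 - 1
    while i >= 0 and j >= 0:
        run += _pair_score(qs[i], ss[j], r, p)
        if run > best_l:
            best_l = run
            start_i = i
        elif best_l - run > xdrop:
            break
        i -= 1
        j -= 1

    score = index_w * r + best_r + best_l
    start_j = j0 - (i0 - start_i)
    end_j = j0 + (end_i - i0)
    identities = sum(
        1 for a, b in zip(qs[start_i:end_i], ss[start_j:end_j])
        if a == b and a != "N"
    )
    if seed.strand == "plus":
        q_lo, q_hi = start_i, end_i
    else:
        q_lo, q_hi = qlen - end_i, qlen - start_i
    return LocalHit(
        query_id=query.id,
        subject_id=subject.id,
        q_start=q_lo,
        q_end=q_hi,
        s_start=start_j,
        s_end=end_j,
        strand=seed.strand,
        score=score,
        identities=identities,
    )


def karlin_params(
    reward: int,
    penalty: int,
    background: Sequence[float] = UNIFORM_BACKGROUND,
) -> KarlinParams:
    """Solve lambda and K for a two-valued ungapped scoring scheme.

    lambda is the positive root of E[exp(lambda*X)] = 1 where X is the
    per-position score under the background composition (bracketed
    root-finding to 1e-9 relative tolerance).  K uses the standard
    ungapped series

        sigma = sum_{k>=1} (1/k) * ( E[e^{lambda S_k}; S_k < 0] + P(S_k >= 0) )
        K = lambda * exp(-2*sigma) / ( H * (1 - exp(-lambda*g)) )

    with S_k the k-step partial sums, H = lambda * E[X e^{lambda X}] the
    relative entropy, and g the lattice span (gcd) of the score values.
    The series is truncated once a term falls below 1e-12.
    """
    if reward <= 0 or penalty >= 0:
        raise InvalidScoringError("need reward > 0 > penalty")
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
        raise InvalidScoringError("background must be 4 probabilities summing to 1")
    p_match = float(np.sum(bg * bg))
    mean = p_match * reward + (1 - p_match) * penalty
    if mean >= 0:
        raise InvalidScoringError(
            f"expected per-position score {mean:.3f} is non-negative"
        )

    def f(lam: float) -> float:
        return (
            p_match * math.exp(lam * reward)
            + (1 - p_match) * math.exp(lam * penalty)
            - 1.0
        )

    hi = 1.0
    while f(hi) <= 0:
        hi *= 2.0
    lam = float(brentq(f, 1e-12, hi, xtol=1e-300, rtol=1e-13))

    # series for sigma, truncated at 1e-12
    sigma = 0.0
    k = 0
    while True:
        k += 1
        m = np.arange(k + 1)
        pmf = binom.pmf(m, k, p_match)
        s = reward * m + penalty * (k - m)
        term = float(
            np.sum(np.where(s < 0, pmf * np.exp(lam * s), pmf))
        )
        sigma += term / k
        if term / k < 1e-12 or k > 10_000:
            break

    ex = p_match * reward * math.exp(lam * reward) + (1 - p_match) * penalty * math.exp(
        lam * penalty
    )
    h = lam * ex
    g = math.gcd(reward, -penalty)
    k_const = lam * math.exp(-2.0 * sigma) / (h * (1.0 - math.exp(-lam * g)))
    return KarlinParams(lam=lam, k=k_const)


def evalue(score: float, query_len: int, db_len: int, kp: KarlinParams) -> float:
    """E = K * m * n * exp(-lambda * S), uncorrected for edge effects."""
    if score < 0:
        raise InvalidScoringError("score must be non-negative")
    return kp.k * query_len * db_len * math.exp(-kp.lam * score)


def _dedupe(hits: Iterable[LocalHit]) -> list[LocalHit]:
    seen: dict[tuple, LocalHit] = {}
    for h in hits:
        key = (h.subject_id, h.strand, h.q_start, h.q_end, h.s_start, h.s_end)
        if key not in seen:
            seen[key] = h
    return list(seen.values())


def search(
    query: SequenceRecord,
    db: Sequence[SequenceRecord] | WordIndex,
    params: SearchParams | None = None,
    background: Sequence[float] = UNIFORM_BACKGROUND,
) -> list[LocalHit]:
    """Seed, extend, score and E-filter the query against the database.

    Both query strands are scanned.  Hits above the E-value cutoff are
    dropped; if hits span more than ``max_db_seqs`` subjects, subjects
    are ranked by their best E-value (ties keep database order) and the
    excess is dropped with a warning.
    """
    params = params or SearchParams()
    if len(query) < params.word_size:
        raise SequenceError("query shorter than the word size")
    if set(query.seq) == {"N"}:
        raise AllMaskedQueryError(f"query {query.id!r} is entirely masked")
    index = db if isinstance(db, WordIndex) else build_index(db, params.word_size)
    if index.word_size != params.word_size:
        raise InvalidScoringError("index word size differs from params.word_size")

    kp = karlin_params(params.reward, params.penalty, background)
    db_len = index.total_length
    qlen = len(query)

    hits = []
    for seed in seed_hits(query, index):
        subject = index.subjects[seed.subject_id]
        hits.append(extend_seed(query, subject, seed, params))
    hits = _dedupe(hits)
    for h in hits:
        h.evalue = evalue(h.score, qlen, db_len, kp)
    hits = [h for h in hits if h.evalue <= params.evalue_cutoff]

    by_subject: dict[str, float] = {}
    for h in hits:
        by_subject[h.subject_id] = min(
            by_subject.get(h.subject_id, math.inf), h.evalue
        )
    if len(by_subject) > params.max_db_seqs:
        ranked = sorted(
            by_subject, key=lambda sid: (by_subject[sid], index.subject_order[sid])
        )
        keep = set(ranked[: params.max_db_seqs])
        dropped = len(by_subject) - len(keep)
        logger.warning(
            "hit list spans %d subjects; keeping the best %d by E-value "
            "(%d dropped)", len(by_subject), params.max_db_seqs, dropped,
        )
        hits = [h for h in hits if h.subject_id in keep]

    hits.sort(
        key=lambda h: (index.subject_order[h.subject_id], h.strand, h.s_start,
                       h.q_start, h.s_end)
    )
    return hits


def prescreen_similarity(
    template: SequenceRecord,
    db: Sequence[SequenceRecord],
    prescreen_word: int = 16,
    min_run: int = 50,
) -> list[Interval]:
    """Template regions sharing long exact runs with non-intended subjects.

    A fast large-word pre-screen: exact matches of length
    ``prescreen_word`` are extended (exactly, no mismatches) and template
    intervals covered by runs of at least ``min_run`` bases on either
    strand are merged and returned sorted.  The caller passes only the
    unintended subjects in ``db``.
    """
    if prescreen_word < 16:
        raise InvalidScoringError("prescreen_word must be >= 16")
    if not db:
        return []
    index = build_index(db, prescreen_word)
    tlen = len(template)
    intervals = []
    for strand, scan_seq in (
        ("plus", template.seq),
        ("minus", reverse_complement(template.seq)),
    ):
        # segments already found per (subject, diagonal), to skip seeds
        # interior to a known run
        found: dict[tuple[str, int], list[tuple[int, int]]] = defaultdict(list)
        w = prescreen_word
        for i in range(len(scan_seq) - w + 1):
            word = scan_seq[i : i + w]
            if "N" in word:
                continue
            for sid, j in index.postings.get(word, ()):
                diag = j - i
                if any(a <= i < b for a, b in found[(sid, diag)]):
                    continue
                sseq = index.subjects[sid].seq
                lo_i, lo_j = i, j
                while lo_i > 0 and lo_j > 0 and scan_seq[lo_i - 1] == sseq[lo_j - 1] \
                        and scan_seq[lo_i - 1] != "N":
                    lo_i -= 1
                    lo_j -= 1
                hi_i, hi_j = i + w, j + w
                while hi_i < len(scan_seq) and hi_j < len(sseq) \
                        and scan_seq[hi_i] == sseq[hi_j] and scan_seq[hi_i] != "N":
                    hi_i += 1
                    hi_j += 1
                found[(sid, diag)].append((lo_i, hi_i))
                if hi_i - lo_i >= min_run:
                    if strand == "plus":
                        t_lo, t_hi = lo_i, hi_i
                    else:
                        t_lo, t_hi = tlen - hi_i, tlen - lo_i
                    intervals.append(
                        Interval(template.id, t_lo, t_hi, "similar")
                    )
    return merge_intervals(intervals)
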