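"""Needleman-Wunsch realignment with exact per-primer mismatch accounting.

A local aligner maximises score, so it silently drops mismatches at (or
near) alignment ends — exactly the positions that matter most for
whether a primer extends.  This module guarantees a complete alignment
over every primer base: a partial local hit is widened on the subject
side and globally realigned, so the mismatch counts (total and within
the 3'-terminal window) are exact no matter how truncated the local
stage's segment was.

Scoring is +1 match, -1 mismatch, -2 per gap column by default.  Gap
columns count as mismatches for all specificity thresholds: the
conservative reading when only "mismatches" are specified, since an
unpaired primer base destabilises the duplex at least as much as a
mispaired one.  N in either sequence counts as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

from .errors import EmptyWindowError, SequenceError
from .io_formats import Interval, SequenceRecord, reverse_complement


@dataclass(frozen=True)
class Scoring:
    reward: int = 1
    penalty: int = -1
    gap: int = -2


@dataclass(frozen=True)
class GlobalAlignment:
    """A gap-aware pairwise alignment with per-column status.

    aligned_a / aligned_b are equal-length strings over {A,C,G,T,N,-};
    columns holds "match" / "mismatch" / "gap" per position.
    """

    aligned_a: str
    aligned_b: str
    score: int
    columns: tuple[str, ...]

    @property
    def match_columns(self) -> int:
        return sum(1 for c in self.columns if c == "match")

    @property
    def mismatch_columns(self) -> int:
        return sum(1 for c in self.columns if c == "mismatch")

    @property
    def gap_columns(self) -> int:
        return sum(1 for c in self.columns if c == "gap")


class _PrimerLike(Protocol):  # pragma: no cover - typing only
    seq: str
    template_interval: Interval
    strand: str


@dataclass(frozen=True)
class PrimerTargetAlignment:
    """A full-length alignment of one primer to one subject site.

    ``strand`` is the strand of the subject whose plus-strand sequence
    the primer matches ("plus": the primer sequence reads along the
    subject plus strand; "minus": along its reverse complement).
    ``total_mismatches`` counts mismatch plus gap columns;
    ``three_prime_window_mismatches`` counts those among the last
    ``w3`` primer bases (default window 5).
    """

    primer_seq: str
    subject_id: str
    subject_window: Interval
    strand: str
    total_mismatches: int
    gap_columns: int
    three_prime_window_mismatches: int
    alignment: GlobalAlignment

    def site_key(self) -> tuple[str, str, int, int]:
        return (self.subject_id, self.strand,
                self.subject_window.start, self.subject_window.end)


def _col_status(a: str, b: str) -> str:
    if a == "-" or b == "-":
        return "gap"
    if a == b and a != "N":
        return "match"
    return "mismatch"


def nw_global(a: str, b: str, scoring: Scoring = Scoring()) -> GlobalAlignment:
    """Optimal global alignment by dynamic programming.

    Traceback tie-break prefers diagonal over up (gap in ``b``) over
    left (gap in ``a``), which keeps output deterministic and pushes
    unavoidable gaps toward the ends.
    """
    if not a or not b:
        raise SequenceError("nw_global requires two non-empty sequences")
    m, n = len(a), len(b)
    r, p, g = scoring.reward, scoring.penalty, scoring.gap
    h = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        h[i][0] = i * g
    for j in range(1, n + 1):
        h[0][j] = j * g
    for i in range(1, m + 1):
        ai = a[i - 1]
        row, prev = h[i], h[i - 1]
        for j in range(1, n + 1):
            bj = b[j - 1]
            diag = prev[j - 1] + (r if (ai == bj and ai != "N") else p)
            up = prev[j] + g
            left = row[j - 1] + g
            row[j] = max(diag, up, left)
    return _traceback(a, b, h, scoring, m, n, stop_row0=False)


def _traceback(
    a: str,
    b: str,
    h: list[list[int]],
    scoring: Scoring,
    i: int,
    j: int,
    stop_row0: bool,
) -> GlobalAlignment:
    """Shared traceback; ``stop_row0`` stops at row 0 (free b-prefix)."""
    r, p, g = scoring.reward, scoring.penalty, scoring.gap
    score = h[i][j]
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if stop_row0 and i == 0:
            break
        if i > 0 and j > 0:
            s = r if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else p
            if h[i][j] == h[i - 1][j - 1] + s:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and h[i][j] == h[i - 1][j] + g:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        out_a.append("-")
        out_b.append(b[j - 1])
        j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    cols = tuple(_col_status(x, y) for x, y in zip(aligned_a, aligned_b))
    return GlobalAlignment(aligned_a, aligned_b, score, cols)


def fit_primer(
    a: str, b: str, scoring: Scoring = Scoring()
) -> tuple[GlobalAlignment, int, int]:
    """Fitting alignment: all of ``a`` (the primer) inside ``b``.

    Leading/trailing unaligned ``b`` is free; primer overhangs beyond
    ``b`` are charged as gap columns.  Returns the alignment plus the
    half-open interval of ``b`` actually consumed.
    """
    if not a or not b:
        raise SequenceError("fit_primer requires two non-empty sequences")
    m, n = len(a), len(b)
    r, p, g = scoring.reward, scoring.penalty, scoring.gap
    h = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        h[i][0] = i * g
    for i in range(1, m + 1):
        ai = a[i - 1]
        row, prev = h[i], h[i - 1]
        for j in range(1, n + 1):
            bj = b[j - 1]
            diag = prev[j - 1] + (r if (ai == bj and ai != "N") else p)
            up = prev[j] + g
            left = row[j - 1] + g
            row[j] = max(diag, up, left)
    j_best = 0
    for j in range(1, n + 1):
        if h[m][j] > h[m][j_best]:
            j_best = j
    aln = _traceback(a, b, h, scoring, m, j_best, stop_row0=True)
    consumed = sum(1 for c in aln.aligned_b if c != "-")
    return aln, j_best - consumed, j_best


def _window_counts(aln: GlobalAlignment, primer_len: int, w3: int) -> tuple[int, int, int]:
    """(total_mismatches, gap_columns, mismatches in the 3' window)."""
    total = 0
    gaps = 0
    win = 0
    primer_pos = 0  # index of the next primer base to be consumed
    for ca, status in zip(aln.aligned_a, aln.columns):
        # a column belongs to the primer base it consumes; an insertion in
        # the target (gap in the primer) is attributed to the upcoming base
        in_window = primer_pos >= primer_len - w3
        if ca != "-":
            primer_pos += 1
        if status == "match":
            continue
        total += 1
        if status == "gap":
            gaps += 1
        if in_window:
            win += 1
    return total, gaps, win


def full_primer_alignment(
    primer: _PrimerLike,
    hit,
    subject: SequenceRecord,
    w3: int = 5,
    scoring: Scoring = Scoring(),
) -> PrimerTargetAlignment:
    """Complete primer-to-subject alignment from a (possibly partial) hit.

    If the local hit already covers every primer base the segment is
    converted column-by-column.  Otherwise the subject window implied by
    the hit's diagonal is widened by the uncovered primer length on each
    side plus a 3-base margin (clipped to the subject) and the whole
    primer is realigned into it, charging unaligned primer overhangs as
    gap columns.
    """
    p_s, p_e = primer.template_interval.start, primer.template_interval.end
    o_s, o_e = max(p_s, hit.q_start), min(p_e, hit.q_end)
    if o_s >= o_e:
        raise SequenceError("hit does not overlap the primer's query interval")
    site_strand = (
        "plus" if (primer.strand == "plus") == (hit.strand == "plus") else "minus"
    )
    # map the covered query sub-interval onto the subject via the diagonal
    if hit.strand == "plus":
        ws = hit.s_start + (o_s - hit.q_start)
        we = ws + (o_e - o_s)
    else:
        ws = hit.s_start + (hit.q_end - o_e)
        we = ws + (o_e - o_s)

    pseq = primer.seq
    if o_s == p_s and o_e == p_e:
        target = subject.seq[ws:we]
        if site_strand == "minus":
            target = reverse_complement(target)
        cols = tuple(_col_status(x, y) for x, y in zip(pseq, target))
        score = sum(
            scoring.reward if c == "match" else scoring.penalty for c in cols
        )
        aln = GlobalAlignment(pseq, target, score, cols)
        win_s, win_e = ws, we
    else:
        left_uncov = o_s - p_s
        right_uncov = p_e - o_e
        if hit.strand == "plus":
            ws -= left_uncov + 3
            we += right_uncov + 3
        else:
            ws -= right_uncov + 3
            we += left_uncov + 3
        ws = max(0, ws)
        we = min(len(subject), we)
        if ws >= we:
            raise EmptyWindowError(
                f"empty realignment window on {subject.id!r} after clipping"
            )
        target = subject.seq[ws:we]
        if site_strand == "minus":
            target = reverse_complement(target)
        aln, t_lo, t_hi = fit_primer(pseq, target, scoring)
        if t_lo == t_hi:  # primer aligned entirely against gaps
            raise EmptyWindowError(
                f"no subject bases consumed on {subject.id!r}"
            )
        if site_strand == "plus":
            win_s, win_e = ws + t_lo, ws + t_hi
        else:
            win_s, win_e = we - t_hi, we - t_lo

    total, gaps, win = _window_counts(aln, len(pseq), w3)
    return PrimerTargetAlignment(
        primer_seq=pseq,
        subject_id=subject.id,
        subject_window=Interval(subject.id, win_s, win_e, "site"),
        strand=site_strand,
        total_mismatches=total,
        gap_columns=gaps,
        three_prime_window_mismatches=win,
        alignment=aln,
    )


def mismatches_in_window(aln: PrimerTargetAlignment, k: int) -> int:
    """Mismatch + gap columns among the k 3'-most primer bases."""
    if not 1 <= k <= len(aln.primer_seq):
        raise SequenceError("window must be between 1 and the primer length")
    _, _, win = _window_counts(aln.alignment, len(aln.primer_seq), k)
    return win
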