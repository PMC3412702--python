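"""Amplicon enumeration, mismatch-based target classification and the
word-size miss-probability analytics.

The specificity rule, with default thresholds: an unintended target is
*ignored* when at least one primer has 6 or more total mismatches to it
(too degenerate to amplify), *tolerated* when at least one primer has 2
or more mismatches within the last 5 bases at its 3' end (3'-end
mismatches block polymerase extension), and *blocking* otherwise.  A
primer pair is specific only if no unintended amplicon is blocking.

Amplicons are enumerated across all orientations: a plus-strand site of
one primer paired with a minus-strand site of the other (their 3' ends
facing inward), and additionally sites of the *same* primer on both
strands — a forward primer can act as its own reverse primer if it also
matches the minus strand downstream.

The miss-probability calculation quantifies the seeding blind spot of a
word-based search: a target whose mismatch placement leaves no run of
consecutive matches at least as long as the word size can never be
seeded, however few mismatches it has.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .design import Primer, PrimerPair
from .errors import ConfigError, SequenceError
from .io_formats import SequenceRecord
from .realign import PrimerTargetAlignment, Scoring, full_primer_alignment
from .search import LocalHit


@dataclass(frozen=True)
class SpecificityThresholds:
    """Mismatch thresholds for unintended-target classification."""

    min_3p_mismatches: int = 2
    window_3p: int = 5
    ignore_total_mismatches: int = 6
    max_offtarget_product: int = 4000

    def __post_init__(self) -> None:
        if self.window_3p < 1:
            raise ConfigError("window_3p must be >= 1")
        if self.ignore_total_mismatches <= self.min_3p_mismatches:
            raise ConfigError(
                "ignore_total_mismatches must exceed min_3p_mismatches"
            )


@dataclass(frozen=True)
class Amplicon:
    """An oriented pair of primer sites implying a PCR product.

    ``fwd_site`` is the plus-strand site (5' end leftmost on the
    subject), ``rev_site`` the minus-strand site; product length is the
    inclusive span between the two 5'-most subject coordinates.  ``kind``
    is "pair" when the sites belong to different primers and
    "single_primer" when one primer binds both strands.
    """

    subject_id: str
    fwd_site: PrimerTargetAlignment
    rev_site: PrimerTargetAlignment
    product_length: int
    kind: str


_STATUS_ORDER = {"intended": 0, "blocking": 1, "tolerated": 2, "ignored": 3}


@dataclass(frozen=True)
class TargetClassification:
    amplicon: Amplicon
    status: str

    def sort_key(self) -> tuple:
        return (
            _STATUS_ORDER[self.status],
            self.amplicon.subject_id,
            self.amplicon.product_length,
            self.amplicon.fwd_site.subject_window.start,
        )


@dataclass(frozen=True)
class SpecificityVerdict:
    pair: PrimerPair
    specific: bool
    classifications: tuple[TargetClassification, ...]


@dataclass(frozen=True)
class MissProbabilityResult:
    """Exhaustive count of mismatch placements invisible to word seeding."""

    primer_len: int
    n_mismatches: int
    word_size: int
    total_arrangements: int
    missed_arrangements: int
    fraction: float


def project_hits_to_primer(
    template_hits: Sequence[LocalHit],
    primer: Primer,
    subjects: Mapping[str, SequenceRecord],
    w3: int = 5,
    scoring: Scoring = Scoring(),
) -> list[PrimerTargetAlignment]:
    """Slice template-level hits down to full-primer site alignments.

    A single search with the template as query carries alignment
    information for every candidate primer; each hit overlapping the
    primer's template interval is realigned over the full primer.
    Duplicate sites (same subject, window, strand) keep the alignment
    with fewest mismatches.
    """
    sites: dict[tuple, PrimerTargetAlignment] = {}
    p_iv = primer.template_interval
    for hit in template_hits:
        if hit.q_end <= p_iv.start or hit.q_start >= p_iv.end:
            continue
        subject = subjects[hit.subject_id]
        aln = full_primer_alignment(primer, hit, subject, w3=w3, scoring=scoring)
        key = aln.site_key()
        prev = sites.get(key)
        if prev is None or aln.total_mismatches < prev.total_mismatches:
            sites[key] = aln
    return sorted(
        sites.values(),
        key=lambda a: (a.subject_id, a.strand, a.subject_window.start),
    )


def enumerate_amplicons(
    fwd_sites: Sequence[PrimerTargetAlignment],
    rev_sites: Sequence[PrimerTargetAlignment],
    thresholds: SpecificityThresholds,
) -> list[Amplicon]:
    """All inward-facing site pairings implying a product.

    A plus-strand site A and minus-strand site B on the same subject
    form an amplicon when A's 5' end lies left of B's 5' end (3' ends
    facing inward) and the product is no longer than
    ``max_offtarget_product``.  Site lists are per primer; pairings
    within one primer's own list are single-primer amplicons.
    """
    out = []
    groups = (("fwd", fwd_sites), ("rev", rev_sites))
    for role_a, sites_a in groups:
        for role_b, sites_b in groups:
            for a in sites_a:
                if a.strand != "plus":
                    continue
                for b in sites_b:
                    if b.strand != "minus":
                        continue
                    if a.subject_id != b.subject_id:
                        continue
                    if role_a == role_b and a is b:
                        continue
                    a5 = a.subject_window.start
                    b5 = b.subject_window.end - 1
                    if a5 >= b5:
                        continue
                    product = b5 - a5 + 1
                    if product > thresholds.max_offtarget_product:
                        continue
                    out.append(
                        Amplicon(
                            subject_id=a.subject_id,
                            fwd_site=a,
                            rev_site=b,
                            product_length=product,
                            kind="pair" if role_a != role_b else "single_primer",
                        )
                    )
    # Two primers can occupy the same pair of site windows (e.g. one
    # primer's weak chance alignment over the other's true site): keep
    # the best-supported amplicon per window pairing — fewest worst-site
    # mismatches, preferring a true pair over a single-primer product.
    best: dict[tuple, Amplicon] = {}
    for amp in out:
        key = (
            amp.subject_id,
            amp.fwd_site.site_key(),
            amp.rev_site.site_key(),
        )
        rank = (
            max(amp.fwd_site.total_mismatches, amp.rev_site.total_mismatches),
            0 if amp.kind == "pair" else 1,
        )
        prev = best.get(key)
        if prev is None or rank < (
            max(prev.fwd_site.total_mismatches, prev.rev_site.total_mismatches),
            0 if prev.kind == "pair" else 1,
        ):
            best[key] = amp
    unique = list(best.values())
    unique.sort(
        key=lambda a: (
            a.subject_id,
            a.fwd_site.subject_window.start,
            a.product_length,
        )
    )
    return unique


def classify_amplicon(
    a: Amplicon,
    intended_ids: Iterable[str],
    thr: SpecificityThresholds,
) -> TargetClassification:
    """Apply the mismatch rule to one amplicon.

    intended -> subject is an allowed target; ignored -> some primer has
    at least ``ignore_total_mismatches`` total mismatches; tolerated ->
    some primer has at least ``min_3p_mismatches`` mismatches in its
    3'-terminal window; blocking -> neither escape applies, so the
    amplicon could amplify.
    """
    if a.subject_id in set(intended_ids):
        status = "intended"
    else:
        worst_total = max(
            a.fwd_site.total_mismatches, a.rev_site.total_mismatches
        )
        worst_3p = max(
            a.fwd_site.three_prime_window_mismatches,
            a.rev_site.three_prime_window_mismatches,
        )
        if worst_total >= thr.ignore_total_mismatches:
            status = "ignored"
        elif worst_3p >= thr.min_3p_mismatches:
            status = "tolerated"
        else:
            status = "blocking"
    return TargetClassification(amplicon=a, status=status)


def pair_verdict(
    pair: PrimerPair,
    amplicons: Sequence[Amplicon],
    intended_ids: Iterable[str],
    thr: SpecificityThresholds,
) -> SpecificityVerdict:
    """Classify every amplicon; the pair is specific iff none blocks."""
    ids = set(intended_ids)
    classifications = sorted(
        (classify_amplicon(a, ids, thr) for a in amplicons),
        key=TargetClassification.sort_key,
    )
    specific = not any(c.status == "blocking" for c in classifications)
    return SpecificityVerdict(
        pair=pair, specific=specific, classifications=tuple(classifications)
    )


def splice_variant_allowance(
    intended_ids: Iterable[str], variant_ids: Iterable[str]
) -> frozenset[str]:
    """Expand the intended-target set with allowed splice-variant ids."""
    return frozenset(intended_ids) | frozenset(variant_ids)


def miss_probability(
    primer_len: int, n_mismatches: int, word_size: int
) -> MissProbabilityResult:
    """Fraction of mismatch placements that defeat word seeding.

    Exhaustively enumerates ordered placements of ``n_mismatches``
    distinct positions along the primer; an arrangement is missed when
    every run of consecutive matching positions is shorter than
    ``word_size``.  Orderings of the same position set share their fate,
    so sets are enumerated and scaled by n!.
    """
    if not 0 <= n_mismatches <= primer_len:
        raise SequenceError("need 0 <= n_mismatches <= primer_len")
    if word_size > primer_len:
        raise SequenceError("word_size exceeds the primer length")
    missed_sets = 0
    total_sets = 0
    for positions in combinations(range(primer_len), n_mismatches):
        total_sets += 1
        runs = []
        prev = -1
        for p in positions:
            runs.append(p - prev - 1)
            prev = p
        runs.append(primer_len - 1 - prev)
        if all(r < word_size for r in runs):
            missed_sets += 1
    orderings = math.factorial(n_mismatches)
    total = total_sets * orderings
    missed = missed_sets * orderings
    return MissProbabilityResult(
        primer_len=primer_len,
        n_mismatches=n_mismatches,
        word_size=word_size,
        total_arrangements=total,
        missed_arrangements=missed,
        fraction=missed / total,
    )
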