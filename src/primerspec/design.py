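"""Candidate primer-pair generation and placement constraints.

A deliberately simple designer: every template window within the
configured length bounds, on either strand, that passes melting
temperature, GC, homopolymer and self-complementarity thresholds
becomes a candidate primer; orientation-valid pairs within the product
size range are ranked by a weighted penalty against the configured
optima.  Placement constraints then enforce exon-junction spanning,
intron spanning, SNP avoidance and a soft preference for keeping at
least one primer of each pair out of regions flagged as highly similar
to unintended sequences.

Melting temperatures use the unified nearest-neighbor thermodynamic
parameters (SantaLucia 1998) with monovalent-salt correction and a
primer concentration term, as provided by Biopython's Tm_NN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from .errors import ConfigError, SequenceError, TemplateTooLongError
from .io_formats import Interval, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

#: Hard cap on template length; longer inputs must use a target region.
MAX_TEMPLATE_LENGTH = 50_000

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class DesignConfig:
    """Primer design thresholds and penalty weights.

    Lengths are bases, temperatures degrees Celsius, GC a fraction.
    ``junction_min_5p``/``junction_min_3p`` are the minimum bases a
    junction-spanning primer must keep on each side of the junction,
    measured in primer orientation.
    """

    primer_len_min: int = 15
    primer_len_opt: int = 20
    primer_len_max: int = 25
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    max_tm_diff: float = 3.0
    gc_min: float = 0.20
    gc_max: float = 0.80
    product_min: int = 70
    product_max: int = 1000
    product_opt: int | None = None
    target_region: Interval | None = None
    num_pairs_requested: int = 5
    junction_required: bool = False
    junction_min_5p: int = 4
    junction_min_3p: int = 4
    intron_required: bool = False
    intron_min: int = 1000
    snp_avoid: bool = False
    max_poly_x: int = 5
    max_self_any: int = 12
    max_self_3p: int = 6
    max_hairpin: int = 6
    # penalty weights: per deg C of Tm deviation, per base of length
    # deviation, per base of product-size deviation
    w_tm: float = 1.0
    w_len: float = 0.5
    w_product: float = 0.01
    # cap on primers per strand fed into pairing, best-first
    max_candidates_per_strand: int = 100
    na_mM: float = 50.0
    primer_nM: float = 50.0

    def __post_init__(self) -> None:
        if not (self.primer_len_min <= self.primer_len_opt <= self.primer_len_max):
            raise ConfigError("primer length bounds must chain min <= opt <= max")
        if not (self.tm_min <= self.tm_opt <= self.tm_max):
            raise ConfigError("Tm bounds must chain min <= opt <= max")
        if not (0 <= self.gc_min <= self.gc_max <= 1):
            raise ConfigError("GC bounds must satisfy 0 <= min <= max <= 1")
        if self.product_min <= self.primer_len_max:
            raise ConfigError("product_min must exceed the maximum primer length")
        if self.product_min > self.product_max:
            raise ConfigError("product bounds must satisfy min <= max")


@dataclass(frozen=True)
class Primer:
    """A candidate primer anchored on the template plus strand.

    For a minus-strand (reverse) primer, ``seq`` is the reverse
    complement of the template slice at ``template_interval``.
    """

    seq: str
    template_interval: Interval
    strand: str
    tm: float
    gc: float
    self_any: int
    self_3p: int
    hairpin: int

    @property
    def five_prime(self) -> int:
        """Template offset of the 5' base."""
        if self.strand == "plus":
            return self.template_interval.start
        return self.template_interval.end - 1

    @property
    def three_prime(self) -> int:
        """Template offset of the 3' base."""
        if self.strand == "plus":
            return self.template_interval.end - 1
        return self.template_interval.start


@dataclass(frozen=True)
class PrimerPair:
    forward: Primer
    reverse: Primer
    product_length: int
    penalty: float

    def __post_init__(self) -> None:
        if self.forward.strand != "plus" or self.reverse.strand != "minus":
            raise ConfigError("pair orientation must be plus forward, minus reverse")


@dataclass(frozen=True)
class ExonModel:
    """Ordered exons tiling the template, with genomic intron sizes.

    Exon intervals are template (mRNA) coordinates: contiguous,
    starting at 0.  ``intron_lengths[i]`` is the genomic intron between
    exon i and exon i+1; junction offsets are the template positions
    where one exon ends and the next begins.
    """

    exons: tuple[Interval, ...]
    intron_lengths: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.exons:
            raise ConfigError("exon model needs at least one exon")
        if self.exons[0].start != 0:
            raise ConfigError("first exon must start at template position 0")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end != b.start:
                raise ConfigError("exons must tile the template contiguously")
        if self.intron_lengths and len(self.intron_lengths) != len(self.exons) - 1:
            raise ConfigError("need one intron length per junction")

    @property
    def junctions(self) -> tuple[int, ...]:
        return tuple(e.end for e in self.exons[:-1])

    def exon_index_of(self, template_pos: int) -> int:
        for i, e in enumerate(self.exons):
            if e.start <= template_pos < e.end:
                return i
        raise ConfigError(f"position {template_pos} outside the exon model")


def melting_temp(seq: str, na_mM: float = 50.0, primer_nM: float = 50.0) -> float:
    """Nearest-neighbor duplex melting temperature in degrees Celsius.

    Unified NN parameters with the SantaLucia (1998) monovalent-salt
    entropy correction at the given Na+ concentration and primer
    concentration (the template is assumed not self-complementary and in
    excess-primer conditions).  Deterministic to well under 0.1 C.
    """
    if len(seq) < 8:
        raise SequenceError("melting_temp requires length >= 8")
    if set(seq) - set("ACGT"):
        raise SequenceError("melting_temp requires an unambiguous ACGT sequence")
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=_mt.DNA_NN3,
            Na=na_mM,
            dnac1=primer_nM,
            dnac2=0,
            saltcorr=5,
        )
    )


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def self_scores(seq: str) -> tuple[int, int, int]:
    """(self_any, self_3p, hairpin) complementarity scores.

    Two copies of the primer annealed antiparallel pair base i with base
    j at constant i + j; the score of an offset is the number of
    complementary (i, j) pairs, each physical pair counted once.
    self_any maximises over all offsets; self_3p only over offsets where
    the 3'-terminal base is inside the duplex; hairpin folds a single
    copy back on itself, counting pairs whose enclosed loop is at least
    3 bases.
    """
    if set(seq) - set("ACGT"):
        raise SequenceError("self_scores requires an unambiguous ACGT sequence")
    n = len(seq)
    self_any = self_3p = hairpin = 0
    for c in range(1, 2 * n - 2):
        pairs = 0
        loop_pairs = 0
        i_lo = max(0, c - n + 1)
        for i in range(i_lo, (c + 1) // 2):
            j = c - i
            if j <= i or j >= n:
                continue
            if _COMP[seq[i]] == seq[j]:
                pairs += 1
                if j - i - 1 >= 3:
                    loop_pairs += 1
        self_any = max(self_any, pairs)
        if c >= n - 1:  # the 3' terminus (index n-1) lies inside the duplex
            self_3p = max(self_3p, pairs)
        hairpin = max(hairpin, loop_pairs)
    return self_any, self_3p, hairpin


def _passes_filters(seq: str, cfg: DesignConfig) -> tuple[bool, float, float, tuple[int, int, int]]:
    gc = gc_fraction(seq)
    if not (cfg.gc_min <= gc <= cfg.gc_max):
        return False, 0.0, gc, (0, 0, 0)
    if max_homopolymer(seq) > cfg.max_poly_x:
        return False, 0.0, gc, (0, 0, 0)
    tm = melting_temp(seq, cfg.na_mM, cfg.primer_nM)
    if not (cfg.tm_min <= tm <= cfg.tm_max):
        return False, tm, gc, (0, 0, 0)
    scores = self_scores(seq)
    if (
        scores[0] > cfg.max_self_any
        or scores[1] > cfg.max_self_3p
        or scores[2] > cfg.max_hairpin
    ):
        return False, tm, gc, scores
    return True, tm, gc, scores


def candidate_primers(template: SequenceRecord, cfg: DesignConfig) -> list[Primer]:
    """Every window on either strand passing all per-primer thresholds.

    Ordered deterministically by (start, length, strand).  Windows
    containing N (masked or ambiguous template bases) are skipped.
    """
    if len(template) > MAX_TEMPLATE_LENGTH:
        raise TemplateTooLongError(
            f"template is {len(template)} bases; the maximum is "
            f"{MAX_TEMPLATE_LENGTH} — restrict design with a target region"
        )
    out = []
    seq = template.seq
    for start in range(len(seq)):
        for length in range(cfg.primer_len_min, cfg.primer_len_max + 1):
            end = start + length
            if end > len(seq):
                break
            window = seq[start:end]
            if "N" in window:
                continue
            for strand in ("plus", "minus"):
                pseq = window if strand == "plus" else reverse_complement(window)
                ok, tm, gc, scores = _passes_filters(pseq, cfg)
                if not ok:
                    continue
                out.append(
                    Primer(
                        seq=pseq,
                        template_interval=Interval(template.id, start, end, "primer"),
                        strand=strand,
                        tm=tm,
                        gc=gc,
                        self_any=scores[0],
                        self_3p=scores[1],
                        hairpin=scores[2],
                    )
                )
    return out


def _primer_penalty(p: Primer, cfg: DesignConfig) -> float:
    return cfg.w_tm * abs(p.tm - cfg.tm_opt) + cfg.w_len * abs(
        len(p.seq) - cfg.primer_len_opt
    )


def pair_penalty(f: Primer, r: Primer, product: int, cfg: DesignConfig) -> float:
    """Sum of weighted deviations from the configured optima."""
    pen = _primer_penalty(f, cfg) + _primer_penalty(r, cfg)
    product_opt = cfg.product_opt if cfg.product_opt is not None else cfg.product_min
    pen += cfg.w_product * abs(product - product_opt)
    return pen


def candidate_pairs(primers: Sequence[Primer], cfg: DesignConfig) -> list[PrimerPair]:
    """All orientation-valid pairs in product range, ranked by penalty.

    The per-strand candidate lists are truncated to the best
    ``max_candidates_per_strand`` primers (by individual penalty) before
    pairing, to keep the pair set tractable on long templates.  Ties in
    pair penalty break by (forward start, reverse start).
    """
    fwd = [p for p in primers if p.strand == "plus"]
    rev = [p for p in primers if p.strand == "minus"]
    keyf = lambda p: (_primer_penalty(p, cfg), p.template_interval.start, len(p.seq))
    fwd = sorted(fwd, key=keyf)[: cfg.max_candidates_per_strand]
    rev = sorted(rev, key=keyf)[: cfg.max_candidates_per_strand]

    pairs = []
    for f in fwd:
        for r in rev:
            if f.five_prime >= r.five_prime:
                continue
            product = r.template_interval.end - f.template_interval.start
            if not (cfg.product_min <= product <= cfg.product_max):
                continue
            if abs(f.tm - r.tm) > cfg.max_tm_diff:
                continue
            if cfg.target_region is not None:
                tr = cfg.target_region
                if not (
                    f.template_interval.start <= tr.start
                    and r.template_interval.end >= tr.end
                ):
                    continue
            pairs.append(
                PrimerPair(f, r, product, pair_penalty(f, r, product, cfg))
            )
    pairs.sort(
        key=lambda pp: (
            pp.penalty,
            pp.forward.template_interval.start,
            pp.reverse.template_interval.start,
        )
    )
    return pairs


def spans_junction(
    p: Primer, exon_model: ExonModel, min_5p: int, min_3p: int
) -> bool:
    """True if the primer covers an exon-exon junction with enough bases
    on each side, sides measured in the primer's own 5'->3' orientation."""
    s, e = p.template_interval.start, p.template_interval.end
    for j in exon_model.junctions:
        if not (s < j < e):
            continue
        left, right = j - s, e - j
        five, three = (left, right) if p.strand == "plus" else (right, left)
        if five >= min_5p and three >= min_3p:
            return True
    return False


def spans_intron(pair: PrimerPair, exon_model: ExonModel, intron_min: int) -> bool:
    """True if the primers sit in different exons and the genomic introns
    between those exons total at least ``intron_min`` bases.

    A primer is assigned to the exon holding its 3'-terminal base (the
    extension-critical end)."""
    if not exon_model.intron_lengths:
        return False
    i_f = exon_model.exon_index_of(pair.forward.three_prime)
    i_r = exon_model.exon_index_of(pair.reverse.three_prime)
    if i_f == i_r:
        return False
    lo, hi = min(i_f, i_r), max(i_f, i_r)
    return sum(exon_model.intron_lengths[lo:hi]) >= intron_min


def overlaps_snp(p: Primer, snps: Sequence[Interval]) -> bool:
    """True if any SNP interval intersects the primer's template span."""
    return any(p.template_interval.overlaps(s) for s in snps)


def apply_placement_constraints(
    pairs: Sequence[PrimerPair],
    masked: Sequence[Interval],
    exon_model: ExonModel | None,
    snps: Sequence[Interval],
    cfg: DesignConfig,
) -> list[PrimerPair]:
    """Enforce hard junction/intron/SNP constraints, then softly prefer
    pairs with at least one primer wholly outside every masked
    (high-similarity) interval.

    The masked-region preference reorders rather than filters: pairs
    satisfying it rank first; if none do, the original ranking is
    returned with a warning.
    """
    if (cfg.junction_required or cfg.intron_required) and exon_model is None:
        raise ConfigError("junction/intron constraints require an exon model")
    kept = []
    for pp in pairs:
        if cfg.junction_required and not (
            spans_junction(pp.forward, exon_model, cfg.junction_min_5p, cfg.junction_min_3p)
            or spans_junction(pp.reverse, exon_model, cfg.junction_min_5p, cfg.junction_min_3p)
        ):
            continue
        if cfg.intron_required and not spans_intron(pp, exon_model, cfg.intron_min):
            continue
        if cfg.snp_avoid and (
            overlaps_snp(pp.forward, snps) or overlaps_snp(pp.reverse, snps)
        ):
            continue
        kept.append(pp)
    if not masked or not kept:
        return kept

    def outside(p: Primer) -> bool:
        return not any(p.template_interval.overlaps(m) for m in masked)

    preferred = [pp for pp in kept if outside(pp.forward) or outside(pp.reverse)]
    if not preferred:
        logger.warning(
            "no candidate pair keeps a primer outside high-similarity "
            "regions; returning the unfiltered ranking"
        )
        return kept
    rest = [pp for pp in kept if not (outside(pp.forward) or outside(pp.reverse))]
    return preferred + rest
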