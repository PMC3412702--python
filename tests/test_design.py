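"""Primer candidate generation, thermodynamics and placement constraints."""

import logging

import pytest

from conftest import random_dna
from primerspec.design import (
    DesignConfig,
    ExonModel,
    Primer,
    apply_placement_constraints,
    candidate_pairs,
    candidate_primers,
    gc_fraction,
    max_homopolymer,
    melting_temp,
    overlaps_snp,
    pair_penalty,
    self_scores,
    spans_intron,
    spans_junction,
)
from primerspec.errors import ConfigError, SequenceError, TemplateTooLongError
from primerspec.io_formats import Interval, SequenceRecord, reverse_complement


class TestMeltingTemp:
    def test_matches_independent_nn_table_evaluation(self):
        # frozen value from a by-hand evaluation of the unified NN table
        # (SantaLucia 1998) at 50 mM Na+, 50 nM primer
        assert melting_temp("ACGTACGTACGTACGTACGT") == pytest.approx(54.93, abs=0.1)

    def test_reverse_complement_symmetry(self, rng):
        for _ in range(10):
            s = random_dna(rng, 20)
            assert melting_temp(s) == pytest.approx(
                melting_temp(reverse_complement(s)), abs=1e-6
            )

    def test_longer_repeat_melts_higher(self):
        tms = [melting_temp("GC" * n) for n in (5, 7, 9, 11)]
        assert tms == sorted(tms)
        assert all(a < b for a, b in zip(tms, tms[1:]))

    def test_n_rejected(self):
        with pytest.raises(SequenceError):
            melting_temp("ACGTNACGTACGT")


class TestSelfScores:
    def test_homopolymer_cannot_self_pair(self):
        assert self_scores("AAAAAAAAAA")[0] == 0

    def test_palindrome_scores_half_length(self):
        # GAATTC is fully self-complementary; the pads (C...A) cannot pair
        self_any, self_3p, _ = self_scores("CCGAATTCAA")
        assert self_any == 3

    def test_stem_loop_hairpin(self):
        self_any, self_3p, hairpin = self_scores("GGGGAAATTTCCCC")
        assert hairpin >= 4

    def test_3p_score_requires_terminus_in_duplex(self):
        # complementary run at the 5' end only: self_any sees it, the 3'
        # variant is bounded by offsets containing the terminus
        self_any, self_3p, _ = self_scores("GGGGCCCCATATAGGG")
        assert self_any >= self_3p


class TestCandidatePrimers:
    CFG = DesignConfig(tm_min=45, tm_max=70, max_self_any=20, max_self_3p=20,
                       max_hairpin=20)

    def test_random_template_yields_audited_candidates(self, rng):
        tmpl = SequenceRecord("t", random_dna(rng, 200))
        primers = candidate_primers(tmpl, self.CFG)
        assert primers
        for p in primers:
            assert self.CFG.primer_len_min <= len(p.seq) <= self.CFG.primer_len_max
            assert self.CFG.gc_min <= p.gc <= self.CFG.gc_max
            assert self.CFG.tm_min <= p.tm <= self.CFG.tm_max
            assert max_homopolymer(p.seq) <= self.CFG.max_poly_x
            if p.strand == "minus":
                iv = p.template_interval
                assert p.seq == reverse_complement(tmpl.seq[iv.start:iv.end])

    def test_all_a_template_yields_nothing(self):
        tmpl = SequenceRecord("t", "A" * 120)
        assert candidate_primers(tmpl, self.CFG) == []

    def test_brute_force_refilter_agrees(self, rng):
        """An independent re-filter of every window reproduces the
        candidate set exactly."""
        tmpl = SequenceRecord("t", random_dna(rng, 100))
        cfg = self.CFG
        got = {
            (p.template_interval.start, p.template_interval.end, p.strand)
            for p in candidate_primers(tmpl, cfg)
        }
        expect = set()
        for start in range(100):
            for length in range(cfg.primer_len_min, cfg.primer_len_max + 1):
                end = start + length
                if end > 100:
                    continue
                for strand in ("plus", "minus"):
                    s = tmpl.seq[start:end]
                    if strand == "minus":
                        s = reverse_complement(s)
                    gc = gc_fraction(s)
                    if not (cfg.gc_min <= gc <= cfg.gc_max):
                        continue
                    if max_homopolymer(s) > cfg.max_poly_x:
                        continue
                    tm = melting_temp(s)
                    if not (cfg.tm_min <= tm <= cfg.tm_max):
                        continue
                    sa, s3, hp = self_scores(s)
                    if sa > cfg.max_self_any or s3 > cfg.max_self_3p \
                            or hp > cfg.max_hairpin:
                        continue
                    expect.add((start, end, strand))
        assert got == expect

    def test_oversized_template_rejected(self):
        tmpl = SequenceRecord("t", "ACGT" * 13_000)
        with pytest.raises(TemplateTooLongError):
            candidate_primers(tmpl, self.CFG)


def _primer(seq, start, strand, tm=60.0):
    return Primer(
        seq=seq,
        template_interval=Interval("t", start, start + len(seq)),
        strand=strand,
        tm=tm,
        gc=0.5,
        self_any=0,
        self_3p=0,
        hairpin=0,
    )


class TestCandidatePairs:
    CFG = DesignConfig()

    def test_single_valid_pair(self):
        f = _primer("A" * 20, 0, "plus")
        r = _primer("C" * 20, 80, "minus")
        pairs = candidate_pairs([f, r], self.CFG)
        assert len(pairs) == 1
        assert pairs[0].product_length == 100

    def test_wrong_orientation_yields_nothing(self):
        r = _primer("C" * 20, 0, "minus")
        f = _primer("A" * 20, 80, "plus")
        assert candidate_pairs([f, r], self.CFG) == []

    def test_tm_difference_gate(self):
        f = _primer("A" * 20, 0, "plus", tm=58.0)
        r = _primer("C" * 20, 80, "minus", tm=62.5)
        assert candidate_pairs([f, r], self.CFG) == []

    def test_penalty_ordering_matches_independent_recompute(self, rng):
        primers = []
        for i in range(10):
            start = int(rng.integers(0, 300))
            tm = float(rng.uniform(57, 63))
            ln = int(rng.integers(15, 26))
            primers.append(_primer("A" * ln, start, "plus", tm))
            primers.append(_primer("C" * ln, start + 300, "minus", tm))
        pairs = candidate_pairs(primers, self.CFG)
        assert pairs
        for pp in pairs:
            assert pp.penalty == pytest.approx(
                pair_penalty(pp.forward, pp.reverse, pp.product_length, self.CFG)
            )
        penalties = [pp.penalty for pp in pairs]
        assert penalties == sorted(penalties)


EXONS = ExonModel(
    exons=(Interval("t", 0, 100), Interval("t", 100, 220), Interval("t", 220, 300)),
    intron_lengths=(1500, 800),
)


class TestSpansJunction:
    def test_plus_strand_covered_junction(self):
        p = _primer("A" * 20, 92, "plus")  # covers 92..112, junction at 100
        assert spans_junction(p, EXONS, 4, 4)

    def test_insufficient_five_prime_overlap(self):
        p = _primer("A" * 20, 98, "plus")  # only 2 bases 5' of the junction
        assert not spans_junction(p, EXONS, 4, 4)

    def test_minus_strand_sides_swap(self):
        """For a minus-strand primer the 5' side lies template-rightward:
        a primer at 98..118 has 2 template-left bases, which are its
        3' side; with min_3p=2 it passes, with min_3p=4 it fails."""
        p = _primer("A" * 20, 98, "minus")
        assert spans_junction(p, EXONS, 4, 2)
        assert not spans_junction(p, EXONS, 4, 4)
        # and the mirrored requirement on the 5' side (18 bases) is easy
        assert spans_junction(p, EXONS, 18, 2)
        assert not spans_junction(p, EXONS, 19, 2)


class TestSpansIntron:
    def _pair(self, f_start, r_start):
        f = _primer("A" * 20, f_start, "plus")
        r = _primer("C" * 20, r_start, "minus")
        from primerspec.design import PrimerPair

        return PrimerPair(f, r, r_start + 20 - f_start, 0.0)

    def test_different_exons_with_big_intron(self):
        assert spans_intron(self._pair(10, 150), EXONS, 1000)

    def test_same_exon_fails(self):
        assert not spans_intron(self._pair(110, 180), EXONS, 1000)

    def test_small_intron_fails(self):
        assert not spans_intron(self._pair(110, 250), EXONS, 1000)  # 800 < 1000


class TestOverlapsSnp:
    def test_snp_inside_primer(self):
        p = _primer("A" * 20, 10, "plus")
        assert overlaps_snp(p, [Interval("t", 15, 16, "rs1")])

    def test_snp_at_half_open_end_excluded(self):
        p = _primer("A" * 20, 10, "plus")  # interval [10, 30)
        assert not overlaps_snp(p, [Interval("t", 30, 31, "rs2")])

    def test_empty_snp_list(self):
        assert not overlaps_snp(_primer("A" * 20, 10, "plus"), [])


class TestApplyPlacementConstraints:
    def _pairs(self):
        from primerspec.design import PrimerPair

        out = []
        for f_start, r_start in [(10, 150), (110, 180), (30, 170)]:
            f = _primer("A" * 20, f_start, "plus")
            r = _primer("C" * 20, r_start, "minus")
            out.append(PrimerPair(f, r, r_start + 20 - f_start, 0.0))
        return out

    def test_fully_masked_returns_unfiltered_with_warning(self, caplog):
        pairs = self._pairs()
        masked = [Interval("t", 0, 300, "similar")]
        with caplog.at_level(logging.WARNING, logger="primerspec.design"):
            kept = apply_placement_constraints(pairs, masked, None, [],
                                               DesignConfig())
        assert kept == pairs
        assert any("high-similarity" in r.message for r in caplog.records)

    def test_pair_outside_mask_ranks_first(self):
        pairs = self._pairs()
        masked = [Interval("t", 0, 60, "similar")]  # hits pair 1 fwd & pair 3 fwd
        kept = apply_placement_constraints(pairs, masked, None, [], DesignConfig())
        # every pair keeps a primer outside the mask (reverses unaffected)
        assert kept == pairs
        masked = [Interval("t", 0, 200, "similar")]  # covers everything but 220+
        kept = apply_placement_constraints(pairs, masked, None, [], DesignConfig())
        assert kept == pairs  # fallback: nothing satisfies, order preserved

    def test_junction_requirement_filters(self):
        cfg = DesignConfig(junction_required=True)
        pairs = self._pairs()
        kept = apply_placement_constraints(pairs, [], EXONS, [], cfg)
        # only pairs with a primer spanning junction 100 or 220 survive
        for pp in kept:
            assert (
                spans_junction(pp.forward, EXONS, 4, 4)
                or spans_junction(pp.reverse, EXONS, 4, 4)
            )

    def test_junction_requirement_with_no_spanning_pair_is_empty(self):
        from primerspec.design import PrimerPair

        cfg = DesignConfig(junction_required=True)
        f = _primer("A" * 20, 10, "plus")
        r = _primer("C" * 20, 60, "minus")
        pairs = [PrimerPair(f, r, 70, 0.0)]
        assert apply_placement_constraints(pairs, [], EXONS, [], cfg) == []

    def test_snp_avoidance_is_hard(self):
        cfg = DesignConfig(snp_avoid=True)
        pairs = self._pairs()
        snps = [Interval("t", 15, 16, "rs1")]  # inside pair 1's forward
        kept = apply_placement_constraints(pairs, [], None, snps, cfg)
        assert all(not overlaps_snp(pp.forward, snps) for pp in kept)
        assert len(kept) == len(pairs) - 1

    def test_junction_required_without_model_raises(self):
        with pytest.raises(ConfigError):
            apply_placement_constraints(
                self._pairs(), [], None, [], DesignConfig(junction_required=True)
            )
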