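# primerspec

Target-specific PCR primer design and specificity checking against local
sequence databases.

## The problem

A usable PCR primer pair must do two things: amplify the intended
template efficiently, and amplify *nothing else*.  The second property
is the hard one.  Transcripts and genomic regions share stretches of
sequence — paralogs, splice variants, fortuitous matches — and a primer
pair designed purely on melting temperature and GC content will often
bind unintended targets with only one or two mismatches, enough to
amplify.  Screening candidates by eye against a database search is slow
and error-prone, and a plain local-alignment search is the wrong
instrument for the job twice over:

1. **Local aligners maximise score**, so they silently drop mismatches
   at (or near) alignment ends.  A single mismatch at a primer's
   3'-terminal base — the position that most determines whether the
   polymerase extends — can be invisible in a local alignment.
2. **Word-seeded searches need an exact match run.**  A target with few
   mismatches, placed so that no run of consecutive matches reaches the
   seeding word size, is never found.

`primerspec` addresses both.  It designs candidate pairs (or accepts
pre-existing ones), finds every plausible binding site with a
word-seeded local search run at deliberately sensitive settings, then
**globally realigns every partial hit over the full primer** with
Needleman–Wunsch so the mismatch accounting is exact, enumerates
amplicons across all primer orientations (including single-primer
products, where one primer binds both strands), and classifies each
unintended target by a mismatch rule.

## The method in brief

**Search.** A word index over the database (word size *w* = 7 by
default) seeds ungapped X-drop extensions on both strands, scored +1
match / −1 mismatch.  Hits are filtered by Karlin–Altschul E-value

    E = K · m · n · e^(−λS)

with λ the positive root of Σᵢⱼ pᵢpⱼ e^(λsᵢⱼ) = 1 and K from the
standard ungapped series, both solved numerically for the configured
scoring scheme (for +1/−1 at uniform base composition, λ = ln 3 and
K = 1/3).  The default cutoff E ≤ 30 000 is extremely permissive on
purpose: a potential amplification target with up to ~35% mismatches to
a short primer must still surface.

**One search per job.**  Every candidate primer is a sub-region of the
template, so the (masked) template is searched once and the hits are
projected onto each primer.  For primer-only checking, the two primers
are joined into an *artificial template* — `forward + 20×N +
revcomp(reverse)` — so one search treats each primer separately (N
never seeds).  Because E-values scale with query length, the E cutoff
in template mode is rescaled by `template_length / artificial_length`,
which makes verdicts equivalent between the two modes.

**Realignment.**  Any hit that does not cover a primer end-to-end is
widened on the subject side and globally realigned, charging unaligned
primer overhangs as gap columns.  Every reported site therefore carries
an exact total mismatch count and an exact count within the 3'-terminal
window.

**Specificity rule** (defaults): an unintended amplicon is *ignored*
when some primer has ≥ 6 total mismatches to it, *tolerated* when some
primer has ≥ 2 mismatches in its last 5 bases at the 3' end, and
*blocking* otherwise.  A pair is **specific** iff nothing blocks.

**The blind spot, quantified.**  Word seeding has a principled failure
mode: `primerspec.miss_probability(L, k, w)` exhaustively enumerates
mismatch placements that leave no match run of length ≥ w.  For a
20-base primer with 2 mismatches at w = 7, exactly 2 of the 380 ordered
placements (positions 7 and 14) are invisible — a miss probability of
about 0.5%.

Design constraints — exon-junction spanning, intron spanning, SNP
avoidance, and a soft preference for placing at least one primer
outside regions highly similar to unintended sequences (found by a fast
large-word pre-screen) — are applied between candidate generation and
specificity checking.

## Worked example

Build a small synthetic database: a 1200-base template plus three
random decoys and one planted "paralog" carrying both primer sites of
the template region 300–640, with two substitutions in the forward
site (primer positions 5 and 18):

```python
from primerspec.fixtures import make_template, make_decoys, plant_pair_target
from primerspec.io_formats import Interval, write_fasta

tmpl = make_template(1200, 0.5, seed=7)
db = [tmpl] + make_decoys(3, 800, seed=8)
plant_pair_target(db, tmpl, Interval(tmpl.id, 300, 320),
                  Interval(tmpl.id, 620, 640),
                  fwd_mismatches=(5, 18), subject_id="paralog", seed=9)
write_fasta([tmpl], "template.fa")
write_fasta(db, "db.fa")
```

Checking the pair that sits exactly on the planted region:

```bash
$ echo template_7 > allow.txt
$ primerspec check --fwd GATTGCCCATGCGGCTTCAT --rev AGCGCAGTACTCTATCGAGT \
      --db db.fa --allow-ids allow.txt
Mode: check
Specific pairs found: 0
Search summary: 14 hits examined

Pair 1: NOT SPECIFIC
  Forward 5'->3': GATTGCCCATGCGGCTTCAT  (Tm 57.8 C, GC 0.55)
  Reverse 5'->3': AGCGCAGTACTCTATCGAGT  (Tm 54.2 C, GC 0.50)
  ...
    paralog: blocking, product 340 (pair)
      forward-acting site, 2 mismatch(es), 1 in 3' window:
        Primer    1  GATTGCCCATGCGGCTTCAT  20
        Target  101  ....C............T..  120
```

The paralog site has only 2 mismatches and just 1 of them in the last
five 3' bases — not enough to prevent amplification, so the pair is
rejected (exit status 1).  Dots mark identity to the primer; target
coordinates are 1-based on the subject plus strand, descending for
minus-strand sites.

Asking the designer for fresh pairs against the same database instead:

```bash
$ primerspec design --template template.fa --db db.fa --num-pairs 2
Mode: design
Specific pairs found: 2
Search summary: 167 hits examined

Pair 1: SPECIFIC
  Forward 5'->3': GACAGCGCGATTCCTCTCGC  (Tm 60.1 C, GC 0.65)
  Reverse 5'->3': AGGCAGCACTCGAGCCTCAA  (Tm 60.0 C, GC 0.60)
  Product length on template: 106
  ...
```

The returned pairs avoid the template stretch cloned into the paralog:
the pre-screen flags it as high-similarity and the specificity check
vetoes anything that still amplifies there.

Both commands accept `--json out.json` for a machine-readable result
and a YAML `--config` mirroring every parameter.

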