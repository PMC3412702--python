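# Methods

This note documents the models and procedures implemented in
`primerspec`, the defaults and why they were chosen, the numerical
choices that affect results, and what the synthetic-data tests do and
do not demonstrate.

## 1. Search model

### Seeding and extension

The database is indexed by exact words of length `word_size` (default
7).  Words containing N are never posted, so masked or ambiguous
regions can neither seed nor be seeded.  Both query strands are
scanned.  Each exact word match is extended without gaps,
independently leftward and rightward, under an X-drop rule: extension
stops once the running score falls more than `xdrop` (default 6 score
units) below the best seen.  At ±1 scoring this crosses runs of up to
three consecutive mismatches, which is what the high-mismatch
sensitivity target requires; gapped completion is deliberately *not*
done here because the realignment stage (below) guarantees full primer
coverage anyway, and primers are short enough that a gapped local
stage would add cost without information.

The scoring defaults — reward +1, penalty −1 — are a 1:1 ratio chosen
for sensitivity: the flatter the score surface, the further an
extension survives through mismatches.  `max_db_seqs` (default 50 000)
caps the number of subjects reported; when exceeded, subjects are
ranked by their best E-value with ties kept in database order
(determinism), and a warning is logged.

A deliberate consequence of word seeding is the *blind spot*: a target
site whose mismatch placement leaves every run of consecutive matches
shorter than the word can never be found.  `miss_probability(L, k, w)`
quantifies this exactly by enumerating position sets (orderings of the
same set share their fate, so sets are enumerated and scaled by k!).
For (20, 2, 7): 380 ordered arrangements, 2 missed (mismatches at
positions 7 and 14), ≈ 0.5%.

### E-value statistics

Ungapped Karlin–Altschul statistics: E = K·m·n·e^(−λS), with m the
query length, n the total database length, no edge-effect correction
(short-query correction is deliberately omitted; the cutoffs in play
are so permissive that the correction could only change outcomes for
scores near zero).  λ is the positive root of E[e^(λX)] = 1 under the
background base composition (uniform by default), solved by bracketed
Brent root-finding to better than 1e-9 relative tolerance.  K uses the
standard ungapped series

    σ = Σ_{k≥1} (1/k) · ( E[e^{λS_k}; S_k < 0] + P(S_k ≥ 0) )
    K = λ·e^{−2σ} / ( H · (1 − e^{−λg}) )

where S_k are k-step partial sums of the per-position score,
H = λ·E[X·e^{λX}] is the relative entropy, and g is the lattice span
(gcd) of the score values.  The series is truncated when a term falls
below 1e-12.  For +1/−1 at uniform composition this yields λ = ln 3
and K = 1/3 — the latter derivable in closed form by a gambler's-ruin
argument (excursion rate 1/E[T] = 1/2 per diagonal position, times the
ladder constant 2/3), which the test suite freezes as an independent
check alongside published constants for the 1:−2, 2:−3 and 1:−3
schemes.

### Similarity pre-screen

Before design, the template is screened against the unintended
subjects with a fast large-word exact-run scan (word 16, minimum run
50) standing in for a megablast-style search; template intervals
covered by such runs are merged and flagged as high-similarity.  The
word and run lengths are package choices: 16 is a typical large-word
seed, and 50 bases of verbatim identity is comfortably above chance at
these database sizes while short enough to catch any region that could
host a perfectly-matching primer.

## 2. Realignment and mismatch accounting

Local alignment maximises score and therefore excludes mismatches at
(and sometimes near) segment ends — precisely the 3'-end positions
that decide primer extension.  Every hit that does not cover its
primer end-to-end is realigned: the subject window implied by the
hit's diagonal is widened by the uncovered primer length on each side
plus a 3-base margin (allowing small indel slippage without
re-searching), clipped to the subject, and the full primer is aligned
into it by Needleman–Wunsch in *fitting* mode — subject flanks free,
primer fully consumed, primer overhangs beyond the subject charged as
gap columns.

Numerical conventions:

- Scoring +1 / −1 / −2 per gap column (linear).  Gaps in primer–target
  duplexes are rare and should cost more than a mismatch; an affine
  model adds parameters without changing any decision at these lengths.
- Traceback tie-break: diagonal > up > left, making output
  deterministic.
- In fitting mode the end cell is the leftmost maximal entry of the
  final row.
- N in either sequence counts as a mismatch (N never matches, never
  seeds).
- **Gap columns count as mismatches** in every specificity threshold.
  Only "mismatches" are specified by the classification rule;
  counting an unpaired primer base as at least as disruptive as a
  mispaired one is the conservative (specificity-preserving) reading.
- The 3'-window count includes mismatch and gap columns attributed to
  the last `window_3p` primer bases; an insertion in the target is
  attributed to the upcoming primer base.

One consequence documented throughout the tests: the realignment
reports the *optimal* alignment of primer to site.  A synthetic target
constructed with k substitutions may realign with fewer than k
reported mismatches when a gap or a register shift scores better than
the planted substitution pattern.  Recovery tests therefore assert
"never more than planted", not equality.

## 3. Primer design

A deliberately simple generator stands in for a full-featured design
engine: every window of length 15–25 on either strand passing all
per-primer thresholds becomes a candidate.

| parameter | default | note |
|---|---|---|
| length min/opt/max | 15 / 20 / 25 | bases |
| Tm min/opt/max | 57 / 60 / 63 °C | nearest-neighbor, see below |
| max pair ΔTm | 3 °C | |
| GC | 0.20–0.80 | fraction |
| product | 70–1000 | bases; optimum defaults to the minimum (qPCR-style short products) |
| max homopolymer | 5 | poly-X runs longer than this reject |
| self_any / self_3p / hairpin | ≤ 12 / 6 / 6 | complementary-pair counts, see below |

Melting temperatures use the unified nearest-neighbor parameters
(SantaLucia 1998) with the monovalent-salt entropy correction, at
50 mM Na⁺ and 50 nM primer, via Biopython's `Tm_NN`; the test suite
pins a value computed by hand from the published table.
Self-complementarity scores count complementary base pairs in the best
antiparallel annealing register of two primer copies (each physical
pair counted once); `self_3p` restricts to registers containing the
3'-terminal base, and the hairpin score folds a single copy back on
itself requiring a loop of at least 3 bases.  These are count-based
scores without mismatch penalties, so the acceptance thresholds are
set higher than tools that penalise interrupting mismatches; the
defaults keep clearly self-complementary oligos out while passing most
random-composition windows.

Pairs are ranked by a penalty of weighted deviations from the optima:
1.0 per °C of Tm deviation, 0.5 per base of length deviation, 0.01 per
base of product-size deviation; ties break by (forward start, reverse
start).  To keep pairing tractable on long templates, only the best
100 primers per strand (by individual penalty) enter pairing; the cap
is configurable and does not affect the candidate-audit contract of
`candidate_primers` itself.

Placement constraints: junction spanning requires at least one primer
of a pair to cover an exon–exon junction with ≥ 4 bases on each side
(sides measured in primer orientation; both minimums adjustable);
intron spanning assigns each primer to the exon holding its 3' base
and requires the genomic introns between the two exons to total at
least `intron_min` (default 1000); SNP avoidance is a hard filter when
enabled.  The high-similarity preference is *soft*: pairs keeping at
least one primer wholly outside every flagged interval rank first, and
if no pair can, the unfiltered ranking is returned with a warning.

## 4. Specificity classification

Sites of both primers on each subject are combined into amplicons:
every plus-strand site whose 5' end lies left of a minus-strand site's
5' end, 3' ends facing inward, with product length (inclusive span
between the two 5'-most subject coordinates) at most
`max_offtarget_product`.  Pairings within one primer's own site list
are *single-primer* amplicons — a forward primer can act as its own
reverse primer on the minus strand.  `max_offtarget_product` defaults
to 4000 bases, well beyond any product a standard PCR protocol would
amplify efficiently; it is exposed in the configuration because the
boundary is a judgement call.  When two different primers occupy the
same pair of site windows, the better-supported amplicon (fewest
worst-site mismatches, pair preferred over single-primer) is kept.

Classification, per amplicon, against the intended-id set (the
template id plus any user allow-list, e.g. splice variants of the same
gene):

1. **intended** — the subject is an allowed target;
2. **ignored** — some primer has ≥ `ignore_total_mismatches` (6) total
   mismatches: too degenerate to amplify;
3. **tolerated** — some primer has ≥ `min_3p_mismatches` (2)
   mismatches within its last `window_3p` (5) 3' bases: 3'-end
   mismatches block polymerase extension;
4. **blocking** — otherwise.

"Some primer" is evaluated per amplicon over its two sites.  A pair is
specific iff no amplicon blocks.  Both thresholds are monotone in the
expected direction (property-tested): raising the ignore threshold can
only move targets out of *ignored*; raising the 3'-window requirement
can only move *tolerated* toward *blocking*.

Intended-target identification is by subject id, not by alignment
identity: with a local database there is no accession service to
resolve equivalent entries, and id matching is deterministic.

## 5. The two entry modes

*Design* mode searches the template once — masked down to the union of
candidate-primer intervals so irrelevant regions cannot generate hits —
and projects hits per primer.  *Check* mode builds the artificial
template `forward + N×20 + revcomp(reverse)` (spacer length must be at
least the word size so it can never seed) and searches it unscaled at
the user's E cutoff.  Because E ∝ query length, design mode rescales
the cutoff by `template_length / artificial_length`, taking
`2·len_opt + spacer` as the reference artificial length; the scaling
is exactly linear, and the reference length is the one open choice (a
run's actual primer lengths vary by a few bases either side of the
optimum, a < 10% effect on a cutoff that is orders of magnitude away
from any decision boundary).

Verdict equivalence between the modes holds exactly for every site
retaining a word-size match run to its primer: the check-mode word set
is a subset of the design-mode word set (masking keeps whole candidate
islands), and any site seedable in one mode is seedable in the other
*at the same diagonal*, after which realignment normalises the
alignment.  Sites *without* such a run can only ever be reached in
design mode, by extension from a neighbouring candidate's seed; they
realign far beyond the ignore threshold.  The equivalence test
therefore compares verdicts over reportable targets (every primer
below the ignore threshold), which is also what the reports print.

The design loop examines candidate pairs in penalty order in a single
ranked stream and stops once the requested number of specific pairs is
found.  If any specific pair exists only specific pairs are reported;
otherwise every examined pair is reported with its targets.

## 6. Synthetic data and what the tests show

The fixture generators produce: random templates of controlled GC;
random decoy subjects; planted targets copying a template site with
substitutions at exact 1-based positions (counted along the
primer-binding orientation, reverse-complemented for minus-strand
plants) between GC-matched flanks; paired-site plants preserving the
template spacing (or an explicit override); and toy splice-variant
families made by deleting exons, with ground truth of which
exon/junction combinations identify each variant.  All randomness
flows from explicit integer seeds through local numpy generators.

What they emulate well: controlled mismatch counts and placements,
strand effects, near-target/decoy contrast, variant structure.  What
they do not emulate: real transcriptome redundancy and repeat
structure, biased base composition, homopolymer-rich regions,
sequencing error, or thermodynamic amplification efficiency.  A pair
passing every test here is guaranteed correct *relative to the stated
mismatch rules*, not guaranteed to amplify cleanly in a real reaction.

Problem sizes used by the test-bed checks, chosen to exercise the
mechanisms at comfortable margins: oracle-equivalence compares the
engine against a full-scan brute-force aligner on 50 databases of
roughly 5 kb (3 decoys of 1.5 kb plus planted sites, 0–5 mismatches,
both strands); mode-equivalence designs against a 1.6 kb template with
4 decoys and 2 planted near-targets and re-checks 20 pairs; recovery
fixtures plant 4 recoverable patterns and 1 blind-spot pattern per
seed across 3 seeds.

Chance similarity is real data's revenge on synthetic fixtures: random
sequence occasionally contains GC-rich near-matches of a primer (the
tests surfaced 3-mismatch gapped chance sites), and fixtures cannot
assume their planted sites are the only ones.  Tests therefore assert
subject-level recovery and bounds, not global uniqueness of
alignments.

## 7. Known limitations

- Ungapped-only local extension; a target findable only through a
  gapped *seed-stage* alignment (indel inside the only seedable run)
  is missed.  Short primers make this a corner case.
- No thermodynamic model of mismatched-duplex stability or
  amplification efficiency; classification is purely count-based.
- Uniform-background E-values by default; composition-adjusted
  statistics are not implemented (the background is a parameter).
- The word-size blind spot is inherent to seeding and is quantified,
  not worked around.
- Intended targets are recognised by sequence id only.
- Template inputs are capped at 50 000 bases; longer sequences must be
  restricted via a target region.
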