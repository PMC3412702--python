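"""Orchestration of the two entry modes and report generation.

Template (design) mode: candidate pairs are generated from the
template, regions of the template without candidate primers are masked
out, and a *single* search of the masked template against the database
supplies the alignment information for every pair — any primer is a
sub-region of the template, so one search replaces hundreds.

Primer-only (check) mode: the two primers are joined into an artificial
template — forward primer, a spacer of N's, then the reverse complement
of the reverse primer — so one search treats each primer separately (N
never seeds) yet runs as a single query.

Because an E-value scales with query length, a raw template-mode search
would judge the same primer-target match more harshly than a check-mode
search of a short artificial template.  The user's E-value cutoff is
therefore rescaled by the ratio of the template length to the
artificial-template length, making verdicts equivalent between the two
modes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .design import (
    DesignConfig,
    ExonModel,
    Primer,
    PrimerPair,
    apply_placement_constraints,
    candidate_pairs,
    candidate_primers,
    gc_fraction,
    melting_temp,
    self_scores,
)
from .errors import ConfigError, EmptyDatabaseError, SequenceError
from .io_formats import (
    Interval,
    SequenceRecord,
    merge_intervals,
    render_alignment,
    reverse_complement,
)
from .search import SearchParams, build_index, prescreen_similarity, search
from .specificity import (
    SpecificityThresholds,
    SpecificityVerdict,
    enumerate_amplicons,
    pair_verdict,
    project_hits_to_primer,
    splice_variant_allowance,
)

logger = logging.getLogger(__name__)

ARTIFICIAL_TEMPLATE_ID = "artificial_template"


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a design or check run."""

    mode: str = "design"
    search: SearchParams = field(default_factory=SearchParams)
    thresholds: SpecificityThresholds = field(default_factory=SpecificityThresholds)
    design: DesignConfig = field(default_factory=DesignConfig)
    intended_ids: tuple[str, ...] = ()
    spacer_len: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("design", "check"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.spacer_len < max(self.search.word_size, 1):
            raise ConfigError(
                "spacer_len must be at least the word size so the spacer "
                "can never seed"
            )


@dataclass
class RunResult:
    """Verdicts plus the rendered report and an audit trail.

    If any examined pair is specific, ``verdicts`` holds only specific
    pairs; otherwise it holds every examined pair.
    """

    verdicts: list[SpecificityVerdict]
    specific_found: int
    report: str
    audit: dict


def build_artificial_template(
    fwd: str, rev: str, spacer_len: int = 20
) -> SequenceRecord:
    """Join two primers into one searchable query.

    forward + N*spacer + reverse_complement(reverse): the forward primer
    occupies the prefix and the reverse primer matches the minus strand
    of the suffix exactly, so a single search scores each primer
    independently.
    """
    for name, p in (("forward", fwd), ("reverse", rev)):
        if not 10 <= len(p) <= 40:
            raise SequenceError(f"{name} primer must be 10-40 bases")
        if set(p) - set("ACGT"):
            raise SequenceError(f"{name} primer must be unambiguous ACGT")
    seq = fwd + "N" * spacer_len + reverse_complement(rev)
    return SequenceRecord(id=ARTIFICIAL_TEMPLATE_ID, seq=seq,
                          description="forward + N spacer + revcomp(reverse)")


def adjust_evalue_cutoff(
    e_user: float, query_len: int, artificial_len: int
) -> float:
    """Rescale the E cutoff linearly in query length (template mode only)."""
    if query_len <= 0 or artificial_len <= 0:
        raise ConfigError("lengths must be positive")
    return e_user * query_len / artificial_len


def mask_noncandidate_regions(
    template: SequenceRecord, primer_intervals: Sequence[Interval]
) -> SequenceRecord:
    """Replace every template base outside candidate primers with N."""
    merged = merge_intervals(primer_intervals)
    out = ["N"] * len(template)
    for iv in merged:
        out[iv.start : iv.end] = template.seq[iv.start : iv.end]
    return SequenceRecord(
        id=template.id, seq="".join(out), description=template.description
    )


def _pair_sites(
    pair: PrimerPair,
    hits,
    subjects: Mapping[str, SequenceRecord],
    thresholds: SpecificityThresholds,
    cache: dict,
):
    sites = []
    for primer in (pair.forward, pair.reverse):
        key = (primer.seq, primer.template_interval.start,
               primer.template_interval.end, primer.strand)
        if key not in cache:
            cache[key] = project_hits_to_primer(
                hits, primer, subjects, w3=thresholds.window_3p
            )
        sites.append(cache[key])
    return sites


def run_design(
    template: SequenceRecord,
    db: Sequence[SequenceRecord],
    cfg: RunConfig,
    exon_model: ExonModel | None = None,
    snps: Sequence[Interval] = (),
) -> RunResult:
    """Design target-specific primer pairs for a template.

    Pre-screens the template for regions highly similar to unintended
    subjects, generates and constraint-filters candidate pairs, masks
    non-candidate template regions, runs one search at the rescaled E
    cutoff, and walks pairs in penalty order until the requested number
    of specific pairs is found or candidates are exhausted.
    """
    if not db:
        raise EmptyDatabaseError("specificity checking needs a database")
    intended = splice_variant_allowance({template.id}, cfg.intended_ids)

    decoys = [r for r in db if r.id not in intended]
    masked_regions = prescreen_similarity(template, decoys)

    primers = candidate_primers(template, cfg.design)
    pairs = candidate_pairs(primers, cfg.design)
    pairs = apply_placement_constraints(
        pairs, masked_regions, exon_model, snps, cfg.design
    )
    if not pairs:
        return RunResult(
            verdicts=[],
            specific_found=0,
            report="No candidate primer pairs satisfy the design constraints.\n",
            audit={"total_hits": 0, "pairs_examined": 0,
                   "params": _params_echo(cfg)},
        )

    intervals = []
    for pp in pairs:
        intervals.append(pp.forward.template_interval)
        intervals.append(pp.reverse.template_interval)
    masked_template = mask_noncandidate_regions(template, intervals)

    artificial_len = 2 * cfg.design.primer_len_opt + cfg.spacer_len
    cutoff = adjust_evalue_cutoff(
        cfg.search.evalue_cutoff, len(template), artificial_len
    )
    params = replace(cfg.search, evalue_cutoff=cutoff)
    index = build_index(db, params.word_size)
    hits = search(masked_template, index, params)

    cache: dict = {}
    verdicts_all: list[SpecificityVerdict] = []
    specific = 0
    for pp in pairs:
        fwd_sites, rev_sites = _pair_sites(
            pp, hits, index.subjects, cfg.thresholds, cache
        )
        amps = enumerate_amplicons(fwd_sites, rev_sites, cfg.thresholds)
        v = pair_verdict(pp, amps, intended, cfg.thresholds)
        verdicts_all.append(v)
        if v.specific:
            specific += 1
            if specific >= cfg.design.num_pairs_requested:
                break

    verdicts = [v for v in verdicts_all if v.specific] or verdicts_all
    audit = {
        "total_hits": len(hits),
        "pairs_examined": len(verdicts_all),
        "masked_similarity_regions": len(masked_regions),
        "evalue_cutoff_adjusted": cutoff,
        "params": _params_echo(cfg),
    }
    report = _render_report("design", verdicts, specific, audit)
    return RunResult(verdicts=verdicts, specific_found=specific,
                     report=report, audit=audit)


def _primer_from_seq(
    seq: str, interval: Interval, strand: str, cfg: DesignConfig
) -> Primer:
    sa, s3, hp = self_scores(seq)
    return Primer(
        seq=seq,
        template_interval=interval,
        strand=strand,
        tm=melting_temp(seq, cfg.na_mM, cfg.primer_nM),
        gc=gc_fraction(seq),
        self_any=sa,
        self_3p=s3,
        hairpin=hp,
    )


def run_check(
    fwd: str,
    rev: str,
    db: Sequence[SequenceRecord],
    cfg: RunConfig,
) -> RunResult:
    """Check the specificity of a pre-existing primer pair.

    Builds the artificial template, searches it at the user's E cutoff
    (no rescaling: this *is* the reference case), projects hits onto the
    two primer segments and classifies every amplicon against the
    intended-target id set.
    """
    if not db:
        raise EmptyDatabaseError("specificity checking needs a database")
    art = build_artificial_template(fwd, rev, cfg.spacer_len)
    f_primer = _primer_from_seq(
        fwd, Interval(art.id, 0, len(fwd), "forward"), "plus", cfg.design
    )
    r_primer = _primer_from_seq(
        rev, Interval(art.id, len(art) - len(rev), len(art), "reverse"),
        "minus", cfg.design,
    )
    pair = PrimerPair(
        forward=f_primer, reverse=r_primer,
        product_length=len(art), penalty=0.0,
    )

    index = build_index(db, cfg.search.word_size)
    hits = search(art, index, cfg.search)
    cache: dict = {}
    fwd_sites, rev_sites = _pair_sites(
        pair, hits, index.subjects, cfg.thresholds, cache
    )
    amps = enumerate_amplicons(fwd_sites, rev_sites, cfg.thresholds)
    intended = splice_variant_allowance(set(), cfg.intended_ids)
    v = pair_verdict(pair, amps, intended, cfg.thresholds)

    audit = {
        "total_hits": len(hits),
        "pairs_examined": 1,
        "params": _params_echo(cfg),
    }
    report = _render_report("check", [v], int(v.specific), audit)
    return RunResult(verdicts=[v], specific_found=int(v.specific),
                     report=report, audit=audit)


def _params_echo(cfg: RunConfig) -> dict:
    return {
        "word_size": cfg.search.word_size,
        "evalue_cutoff": cfg.search.evalue_cutoff,
        "reward": cfg.search.reward,
        "penalty": cfg.search.penalty,
        "max_db_seqs": cfg.search.max_db_seqs,
        "min_3p_mismatches": cfg.thresholds.min_3p_mismatches,
        "window_3p": cfg.thresholds.window_3p,
        "ignore_total_mismatches": cfg.thresholds.ignore_total_mismatches,
        "max_offtarget_product": cfg.thresholds.max_offtarget_product,
        "spacer_len": cfg.spacer_len,
        "seed": cfg.seed,
    }


def _render_report(
    mode: str,
    verdicts: Sequence[SpecificityVerdict],
    specific_found: int,
    audit: dict,
) -> str:
    """Plain-text report with dot-notation alignments.

    Amplicons whose worst primer site reaches the ignore threshold are
    classified internally (and serialised to JSON) but not printed:
    they are, by definition, not a concern for amplification.
    """
    ignore_at = audit["params"]["ignore_total_mismatches"]
    lines = [
        f"Mode: {mode}",
        f"Specific pairs found: {specific_found}",
        f"Search summary: {audit['total_hits']} hits examined",
        "",
    ]
    for i, v in enumerate(verdicts, start=1):
        f, r = v.pair.forward, v.pair.reverse
        lines.append(f"Pair {i}: {'SPECIFIC' if v.specific else 'NOT SPECIFIC'}")
        lines.append(
            f"  Forward 5'->3': {f.seq}  (Tm {f.tm:.1f} C, GC {f.gc:.2f})"
        )
        lines.append(
            f"  Reverse 5'->3': {r.seq}  (Tm {r.tm:.1f} C, GC {r.gc:.2f})"
        )
        lines.append(f"  Product length on template: {v.pair.product_length}")
        shown = [
            c for c in v.classifications
            if c.status != "ignored"
            and max(c.amplicon.fwd_site.total_mismatches,
                    c.amplicon.rev_site.total_mismatches) < ignore_at
        ]
        lines.append(f"  Targets ({len(shown)} reported):")
        for c in shown:
            a = c.amplicon
            lines.append(
                f"    {a.subject_id}: {c.status}, product {a.product_length}"
                f" ({a.kind})"
            )
            for site, label in ((a.fwd_site, "forward-acting"),
                                (a.rev_site, "reverse-acting")):
                lines.append(
                    f"      {label} site, {site.total_mismatches} mismatch(es),"
                    f" {site.three_prime_window_mismatches} in 3' window:"
                )
                for ln in render_alignment(site).splitlines():
                    lines.append("        " + ln)
        lines.append("")
    return "\n".join(lines) + "\n"


def result_to_json(result: RunResult) -> dict:
    """Versioned machine-readable form of a run result."""
    pairs = []
    for v in result.verdicts:
        f, r = v.pair.forward, v.pair.reverse
        targets = []
        for c in v.classifications:
            a = c.amplicon
            targets.append(
                {
                    "subject": a.subject_id,
                    "status": c.status,
                    "kind": a.kind,
                    "product_length": a.product_length,
                    "fwd_mismatches": a.fwd_site.total_mismatches,
                    "rev_mismatches": a.rev_site.total_mismatches,
                    "fwd_3p_mismatches": a.fwd_site.three_prime_window_mismatches,
                    "rev_3p_mismatches": a.rev_site.three_prime_window_mismatches,
                    "alignments": {
                        "forward": render_alignment(a.fwd_site),
                        "reverse": render_alignment(a.rev_site),
                    },
                }
            )
        pairs.append(
            {
                "forward": {"seq": f.seq, "tm": round(f.tm, 2),
                            "start": f.template_interval.start,
                            "end": f.template_interval.end},
                "reverse": {"seq": r.seq, "tm": round(r.tm, 2),
                            "start": r.template_interval.start,
                            "end": r.template_interval.end},
                "product": v.pair.product_length,
                "penalty": round(v.pair.penalty, 4),
                "specific": v.specific,
                "targets": targets,
            }
        )
    return {
        "schema_version": 1,
        "specific_found": result.specific_found,
        "pairs": pairs,
        "audit": result.audit,
    }


def dump_json(result: RunResult) -> str:
    """Deterministic (byte-stable) JSON serialisation."""
    return json.dumps(result_to_json(result), sort_keys=True, indent=2)
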