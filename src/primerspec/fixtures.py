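"""Deterministic synthetic templates, databases and planted targets.

The generators build the test bed for every other module: random
templates of controlled GC, decoy databases, off-target subjects
carrying copies of template sites with mismatches at exact positions
(on either strand), and toy splice-variant families.  Every planted
site returns its ground truth — coordinates, strand, mismatch count and
positions — so recovery can be checked exactly.

All randomness flows from a single integer seed through a local
numpy Generator; no global random state is touched.  Flanking sequence
is GC-matched to the source template so planted sites are not trivially
distinguishable by composition.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .design import ExonModel
from .errors import SequenceError
from .io_formats import Interval, SequenceRecord, reverse_complement, write_fasta

_BASES = np.array(list("ACGT"))
_OTHER = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for planting one copy of a template site into a subject.

    ``mismatch_positions`` are 1-based along the primer-binding
    orientation of the site (position 1 = the site's 5' end as read by
    a plus-strand primer).  ``strand`` minus embeds the reverse
    complement.  ``product_offset`` only applies to paired-site
    planting (see :func:`plant_pair_target`).
    """

    base_template_interval: Interval
    mismatch_positions: tuple[int, ...] = ()
    strand: str = "plus"
    subject_id: str = "planted"
    flank_left: int = 100
    flank_right: int = 100
    product_offset: int | None = None


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted site, in subject coordinates."""

    subject_id: str
    start: int
    end: int
    strand: str
    mismatch_positions: tuple[int, ...]
    source_interval: Interval


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def make_template(length: int, gc: float = 0.5, seed: int = 0) -> SequenceRecord:
    """Reproducible pseudo-random template of given length and GC."""
    if length <= 0:
        raise SequenceError("template length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise SequenceError("gc must be a fraction in [0, 1]")
    seq = random_sequence(length, gc, _rng(seed))
    return SequenceRecord(id=f"template_{seed}", seq=seq,
                          description=f"synthetic template gc={gc}")


def _mutate(site: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    out = list(site)
    for pos in positions:
        if not 1 <= pos <= len(site):
            raise SequenceError(
                f"mismatch position {pos} outside the site (length {len(site)})"
            )
        i = pos - 1
        out[i] = _OTHER[out[i]][rng.integers(0, 3)]
    return "".join(out)


def plant_target(
    db: list[SequenceRecord],
    template: SequenceRecord,
    spec: PlantSpec,
    seed: int = 0,
) -> tuple[SequenceRecord, PlantedSite]:
    """Copy a template site into a new subject with exact mismatches.

    The copied site gets substitutions at exactly the listed positions
    (each guaranteed to differ from the original base), is reverse
    complemented for a minus-strand plant, and is embedded between
    GC-matched random flanks.  The record is appended to ``db`` and the
    ground-truth coordinates are returned.
    """
    rng = _rng(seed)
    iv = spec.base_template_interval
    site = template.seq[iv.start : iv.end]
    mutated = _mutate(site, spec.mismatch_positions, rng)
    placed = mutated if spec.strand == "plus" else reverse_complement(mutated)
    gc = (site.count("G") + site.count("C")) / len(site)
    left = random_sequence(spec.flank_left, gc, rng) if spec.flank_left else ""
    right = random_sequence(spec.flank_right, gc, rng) if spec.flank_right else ""
    rec = SequenceRecord(
        id=spec.subject_id,
        seq=left + placed + right,
        description=f"planted from {template.id}:{iv.start}-{iv.end}",
    )
    db.append(rec)
    truth = PlantedSite(
        subject_id=spec.subject_id,
        start=len(left),
        end=len(left) + len(placed),
        strand=spec.strand,
        mismatch_positions=tuple(spec.mismatch_positions),
        source_interval=iv,
    )
    return rec, truth


def plant_pair_target(
    db: list[SequenceRecord],
    template: SequenceRecord,
    fwd_interval: Interval,
    rev_interval: Interval,
    fwd_mismatches: Sequence[int] = (),
    rev_mismatches: Sequence[int] = (),
    subject_id: str = "planted_pair",
    flank: int = 100,
    product_offset: int | None = None,
    seed: int = 0,
) -> tuple[SequenceRecord, PlantedSite, PlantedSite]:
    """Plant a full amplifiable region carrying both primer sites.

    Copies the template stretch from the forward site's start to the
    reverse site's end (or rebuilds it at ``product_offset`` spacing
    with random filler) and mutates each primer site.  Forward-site
    mismatch positions count along the template plus strand; reverse
    positions count along the reverse primer's 5'->3' orientation.
    """
    rng = _rng(seed)
    f_site = template.seq[fwd_interval.start : fwd_interval.end]
    r_site = template.seq[rev_interval.start : rev_interval.end]
    f_mut = _mutate(f_site, fwd_mismatches, rng)
    # reverse-primer position p (1-based, primer 5'->3') sits at 1-based
    # template-slice position len - p + 1
    r_mut = _mutate(
        r_site, [len(r_site) - p + 1 for p in rev_mismatches], rng
    )
    gc = (template.seq.count("G") + template.seq.count("C")) / len(template)
    if product_offset is None:
        middle = template.seq[fwd_interval.end : rev_interval.start]
    else:
        gap = product_offset - len(f_site) - len(r_site)
        if gap < 0:
            raise SequenceError("product_offset shorter than the two sites")
        middle = random_sequence(gap, gc, rng)
    left = random_sequence(flank, gc, rng) if flank else ""
    right = random_sequence(flank, gc, rng) if flank else ""
    core = f_mut + middle + r_mut
    rec = SequenceRecord(
        id=subject_id,
        seq=left + core + right,
        description=f"planted pair from {template.id}",
    )
    db.append(rec)
    f_truth = PlantedSite(
        subject_id=subject_id,
        start=len(left),
        end=len(left) + len(f_mut),
        strand="plus",
        mismatch_positions=tuple(fwd_mismatches),
        source_interval=fwd_interval,
    )
    r_start = len(left) + len(f_mut) + len(middle)
    r_truth = PlantedSite(
        subject_id=subject_id,
        start=r_start,
        end=r_start + len(r_mut),
        strand="minus",
        mismatch_positions=tuple(rev_mismatches),
        source_interval=rev_interval,
    )
    return rec, f_truth, r_truth


def make_decoys(
    n: int, length: int, gc: float = 0.5, seed: int = 0, prefix: str = "decoy"
) -> list[SequenceRecord]:
    """Unrelated random subjects for background noise."""
    rng = _rng(seed)
    return [
        SequenceRecord(
            id=f"{prefix}_{i+1}",
            seq=random_sequence(length, gc, rng),
            description="random decoy",
        )
        for i in range(n)
    ]


def make_variant_family(
    template: SequenceRecord,
    exon_model: ExonModel,
    drop_exons: Sequence[Sequence[int]],
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[dict]]:
    """Toy splice variants made by deleting exons from the template.

    ``drop_exons`` holds, per variant, the 0-based indices of exons to
    delete.  Returns the variant records plus ground truth: which exons
    each variant keeps and which exon-exon junction pairs it contains.
    """
    records = []
    info = []
    for vi, drops in enumerate(drop_exons, start=1):
        drops = set(drops)
        kept = [i for i in range(len(exon_model.exons)) if i not in drops]
        if not kept:
            raise SequenceError("a variant must keep at least one exon")
        seq = "".join(
            template.seq[exon_model.exons[i].start : exon_model.exons[i].end]
            for i in kept
        )
        junction_pairs = list(zip(kept, kept[1:]))
        rec = SequenceRecord(
            id=f"{template.id}_variant_{vi}",
            seq=seq,
            description=f"variant keeping exons {kept}",
        )
        records.append(rec)
        info.append({"id": rec.id, "kept_exons": kept,
                     "junctions": junction_pairs})
    return records, info


def write_fixture(
    out_dir: str | Path,
    db: Sequence[SequenceRecord],
    truths: Sequence[PlantedSite] = (),
    intervals: Sequence[Interval] = (),
) -> None:
    """Write a fixture as multi-FASTA + BED + ground-truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(db, out / "db.fa")
    if intervals:
        with open(out / "annotations.bed", "w") as fh:
            for iv in intervals:
                fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.label}\n")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump([asdict(t) for t in truths], fh, indent=2, sort_keys=True,
                  default=str)
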