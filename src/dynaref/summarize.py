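"""Summary reports over classified positions.

Category counts split by chromosome class (autosome / heterosome /
chondriosome by default), major-probability histograms, indel-length
histograms (high-probability events only), pairwise population
intersections with the same-allele / different-allele distinction,
codon-level effect tallies of MAIR substitutions inside coding
annotation, and interval-catalog hit counting. All reports are pure
functions of their inputs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .consensus import DELETION, INSERTION, SUBSTITUTION, MairEdit
from .errors import ConfigurationError
from .popstats import (CATEGORIES, INDEL_HIGH, MAJOR_DIFF, MINOR_COMMON, RARE,
                       DynamicPosition)

CHROMOSOME_CLASSES = ("autosome", "heterosome", "chondriosome")


def default_human_class_map() -> dict[str, str]:
    """Human chromosome -> class map (with and without the 'chr' prefix)."""
    mapping: dict[str, str] = {}
    for i in range(1, 23):
        mapping[str(i)] = "autosome"
    for name in ("X", "Y"):
        mapping[name] = "heterosome"
    for name in ("MT", "M"):
        mapping[name] = "chondriosome"
    mapping.update({f"chr{k}": v for k, v in mapping.items()})
    return mapping


@dataclass
class SummaryReport:
    population_id: str
    # category group -> chromosome class -> count ("total" included)
    counts: dict[str, dict[str, int]]
    prob_bin_edges: np.ndarray
    prob_hist: np.ndarray
    indel_length_hist: dict[str, Counter]  # kind -> Counter(length)


@dataclass
class IntersectionReport:
    population_a: str
    population_b: str
    category: str
    a_only: int
    b_only: int
    shared: int
    same: int
    diff: int


def summarize_population(
    positions: Sequence[DynamicPosition],
    chromosome_class_map: Mapping[str, str],
    *,
    prob_bin_width: float = 0.05,
) -> SummaryReport:
    """Per-population summary: class-split counts, probability histogram,
    and the indel-length histogram restricted to events above 50%
    population probability."""
    pop = positions[0].population_id if positions else "ALL"
    groups = {"dynamic_positions": lambda dp: True,
              "indels": lambda dp: INDEL_HIGH in dp.categories,
              "rare_variations": lambda dp: RARE in dp.categories}
    counts = {g: {c: 0 for c in (*CHROMOSOME_CLASSES, "other", "total")}
              for g in groups}
    for dp in positions:
        cls = chromosome_class_map.get(dp.chrom, "other")
        for g, member in groups.items():
            if member(dp):
                counts[g][cls] += 1
                counts[g]["total"] += 1
    edges = np.arange(0.0, 1.0 + prob_bin_width / 2, prob_bin_width)
    probs = [dp.major_prob for dp in positions]
    hist, _ = np.histogram(probs, bins=edges)
    lengths: dict[str, Counter] = {INSERTION: Counter(), DELETION: Counter()}
    for dp in positions:
        for ev in dp.high_indels:
            if ev.population_prob > 0.5:
                n = len(ev.payload) if ev.kind == INSERTION else int(ev.payload)
                lengths[ev.kind][n] += 1
    return SummaryReport(
        population_id=pop, counts=counts,
        prob_bin_edges=edges, prob_hist=hist, indel_length_hist=lengths,
    )


def _signature(dp: DynamicPosition, category: str) -> frozenset:
    """The allele/indel identity of a position within one category."""
    if category == MAJOR_DIFF:
        return frozenset({(SUBSTITUTION, dp.major_allele)})
    if category == INDEL_HIGH:
        return frozenset((e.kind, e.payload) for e in dp.high_indels)
    if category == MINOR_COMMON:
        return frozenset(dp.common_minor_alleles)
    if category == RARE:
        return frozenset(dp.rare_alleles)
    raise ConfigurationError(f"unknown category {category!r}")


def intersect_populations(
    positions_a: Iterable[DynamicPosition],
    positions_b: Iterable[DynamicPosition],
    category: str,
) -> IntersectionReport:
    """Set arithmetic on one category of two populations.

    A shared position counts as "same" when the two populations agree on at
    least one substituted nucleotide / indel event (kind plus
    sequence/length), "diff" otherwise.
    """
    if category not in CATEGORIES:
        raise ConfigurationError(f"unknown category {category!r}")
    a = {(dp.chrom, dp.pos): dp for dp in positions_a
         if category in dp.categories}
    b = {(dp.chrom, dp.pos): dp for dp in positions_b
         if category in dp.categories}
    pa = next(iter(a.values())).population_id if a else "A"
    pb = next(iter(b.values())).population_id if b else "B"
    shared_keys = a.keys() & b.keys()
    same = sum(
        1 for k in shared_keys
        if _signature(a[k], category) & _signature(b[k], category)
    )
    return IntersectionReport(
        population_a=pa, population_b=pb, category=category,
        a_only=len(a) - len(shared_keys), b_only=len(b) - len(shared_keys),
        shared=len(shared_keys), same=same, diff=len(shared_keys) - same,
    )


# ---------------------------------------------------------------------------
# codon-level effect tally

@dataclass(frozen=True)
class CodingSegment:
    """One CDS segment of a transcript (1-based inclusive coordinates).

    ``phase`` follows the GFF convention (bases to skip before the first
    complete codon); None marks a transcript without frame information,
    whose substitutions are tallied as 'unknown'.
    """

    chrom: str
    start: int
    end: int
    strand: str  # "+" | "-"
    transcript_id: str
    phase: int | None = 0


EFFECTS = ("synonymous", "nonsynonymous", "stop_gain", "stop_loss", "unknown")


def read_cds_gff(path) -> list[CodingSegment]:
    """Load CDS features from a GFF3 file via gffutils."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    segments = []
    for feat in db.features_of_type("CDS"):
        parent = feat.attributes.get("Parent", [feat.id])[0]
        phase = None if feat.frame in (None, ".") else int(feat.frame)
        segments.append(CodingSegment(
            chrom=feat.seqid, start=feat.start, end=feat.end,
            strand=feat.strand, transcript_id=parent, phase=phase,
        ))
    return segments


def _transcript_layout(segments: Sequence[CodingSegment]):
    """Concatenated coding sequence layout of one transcript.

    Returns (ordered segments, cumulative offsets, strand, has_frame).
    """
    strand = segments[0].strand
    ordered = sorted(segments, key=lambda s: s.start, reverse=(strand == "-"))
    offsets = []
    acc = 0
    for seg in ordered:
        offsets.append(acc)
        acc += seg.end - seg.start + 1
    has_frame = all(s.phase is not None for s in segments)
    first_phase = ordered[0].phase if has_frame else 0
    return ordered, offsets, strand, has_frame, first_phase or 0


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def tally_effects(
    mair: Sequence[MairEdit],
    coding_annotation: Sequence[CodingSegment],
    reference: Mapping[str, str],
) -> dict[str, int]:
    """Codon-translation tally of MAIR substitutions inside CDS.

    Each substitution falling in a transcript's CDS is classified by
    translating the reference codon against the edited codon
    (synonymous / nonsynonymous / stop_gain / stop_loss); substitutions in
    transcripts lacking frame information, or whose codon is incomplete,
    count as 'unknown'. Indel edits and substitutions outside any CDS are
    not tallied (the table is exonic substitutions only).
    """
    by_transcript: dict[str, list[CodingSegment]] = {}
    for seg in coding_annotation:
        by_transcript.setdefault(seg.transcript_id, []).append(seg)
    layouts = {t: _transcript_layout(segs) for t, segs in by_transcript.items()}

    trees: dict[str, IntervalTree] = {}
    for t, segs in by_transcript.items():
        for k, seg in enumerate(segs):
            trees.setdefault(seg.chrom, IntervalTree()).addi(
                seg.start, seg.end + 1, (t, seg)
            )

    tally = dict.fromkeys(EFFECTS, 0)
    for edit in mair:
        if edit.kind != SUBSTITUTION:
            continue
        hits = trees.get(edit.chrom, IntervalTree())[edit.pos]
        for hit in sorted(hits, key=lambda h: h.data[0]):
            transcript, _seg = hit.data
            ordered, offsets, strand, has_frame, phase = layouts[transcript]
            if not has_frame:
                tally["unknown"] += 1
                continue
            coding = "".join(
                reference[s.chrom][s.start - 1 : s.end] for s in ordered
            ) if strand == "+" else "".join(
                reference[s.chrom][s.start - 1 : s.end][::-1].translate(_COMPLEMENT)
                for s in ordered
            )
            # coding-space offset of the edited base
            cpos = None
            for seg, off in zip(ordered, offsets):
                if seg.start <= edit.pos <= seg.end:
                    local = (edit.pos - seg.start if strand == "+"
                             else seg.end - edit.pos)
                    cpos = off + local
                    break
            if cpos is None:
                continue
            cpos -= phase
            if cpos < 0:
                tally["unknown"] += 1
                continue
            codon_start = (cpos // 3) * 3 + phase
            codon = coding[codon_start : codon_start + 3]
            if len(codon) < 3 or "N" in codon:
                tally["unknown"] += 1
                continue
            alt = str(edit.payload).upper()
            if strand == "-":
                alt = alt.translate(_COMPLEMENT)
            within = cpos % 3
            alt_codon = codon[:within] + alt + codon[within + 1 :]
            ref_aa = str(Seq(codon).translate())
            alt_aa = str(Seq(alt_codon).translate())
            if ref_aa == alt_aa:
                tally["synonymous"] += 1
            elif alt_aa == "*":
                tally["stop_gain"] += 1
            elif ref_aa == "*":
                tally["stop_loss"] += 1
            else:
                tally["nonsynonymous"] += 1
    return tally


# ---------------------------------------------------------------------------
# interval-catalog hit counting

@dataclass(frozen=True)
class CatalogEntry:
    """One labeled interval (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    label: str


def read_catalog_bed(path) -> list[CatalogEntry]:
    """Load a BED-like labeled catalog (0-based half-open on disk)."""
    entries = []
    with open(path) as handle:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, label = line.rstrip("\n").split("\t")[:4]
            entries.append(CatalogEntry(
                chrom=chrom, start=int(start) + 1, end=int(end), label=label,
            ))
    return entries


def _edit_span(edit: MairEdit) -> tuple[int, int]:
    """Reference positions touched by an edit (1-based inclusive).

    Insertions are boundary events; they count as touching their anchor
    base.
    """
    if edit.kind == DELETION:
        return edit.pos + 1, edit.pos + int(edit.payload)
    return edit.pos, edit.pos


def count_catalog_hits(
    mair: Sequence[MairEdit],
    catalog: Sequence[CatalogEntry],
) -> dict[str, tuple[int, int]]:
    """Per label: (entries overlapped by >=1 MAIR edit, total entries).

    Overlap is 1-based inclusive on both sides.
    """
    trees: dict[str, IntervalTree] = {}
    for edit in mair:
        s, e = _edit_span(edit)
        trees.setdefault(edit.chrom, IntervalTree()).addi(s, e + 1)
    hits: dict[str, int] = {}
    totals: dict[str, int] = {}
    for entry in catalog:
        totals[entry.label] = totals.get(entry.label, 0) + 1
        tree = trees.get(entry.chrom)
        if tree is not None and tree.overlap(entry.start, entry.end + 1):
            hits[entry.label] = hits.get(entry.label, 0) + 1
    return {label: (hits.get(label, 0), total)
            for label, total in sorted(totals.items())}
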