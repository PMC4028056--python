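"""Population-level dynamic-information statistics and classification.

Every covered sample (one with a retained unit at the position) casts
exactly one dominant-nucleotide vote, regardless of its read depth — the
equal-weighting principle that makes heterogeneous platforms and coverages
commensurable. The vote distribution yields the major allele, its
population probability (fraction of covered samples voting for it),
minor-allele sample fractions, and a population-level comentropy.

A position is *dynamic* when at least one of four circumstances holds:

* ``MAJOR_DIFF`` — the population major allele differs from the reference
  base;
* ``INDEL_HIGH`` — an indel is supported by at least 50% of covered
  samples;
* ``MINOR_COMMON`` — some minor allele exceeds 5% of samples;
* ``RARE`` — some minor allele is present at no more than 5%.

The first two categories together form the MAIR (major allele and indel
positions against the reference) — the edit set that turns the reference
into the population consensus. The 5% boundary itself belongs to RARE, so
common and rare minors partition the minor alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cdp import CDPRecord
from .consensus import DELETION, INSERTION, SUBSTITUTION, MairEdit
from .entropy_filter import (DEFAULT_FILTER, FilterConfig, Unit, build_unit,
                             comentropy, dominant_nucleotide)
from .errors import ConfigurationError
from .pileup_io import NUCLEOTIDES

MAJOR_DIFF = "MAJOR_DIFF"
INDEL_HIGH = "INDEL_HIGH"
MINOR_COMMON = "MINOR_COMMON"
RARE = "RARE"
CATEGORIES = (MAJOR_DIFF, INDEL_HIGH, MINOR_COMMON, RARE)


@dataclass(frozen=True)
class ClassificationConfig:
    """Frequency boundaries of the four-circumstance classification.

    ``rare_max`` (inclusive) caps rare minors, ``minor_min`` (exclusive)
    floors common minors, ``indel_high_min`` (inclusive) floors
    high-probability indels. Defaults: 5% / 5% / 50%.
    """

    rare_max: float = 0.05
    minor_min: float = 0.05
    indel_high_min: float = 0.50

    def __post_init__(self) -> None:
        if not 0 < self.rare_max <= self.minor_min < self.indel_high_min <= 1:
            raise ConfigurationError(
                "require 0 < rare_max <= minor_min < indel_high_min <= 1"
            )


DEFAULT_CLASSIFICATION = ClassificationConfig()


@dataclass
class IndelEvent:
    """One indel event pooled over a population at one anchor position."""

    chrom: str
    pos: int
    kind: str                 # "insertion" | "deletion"
    payload: str | int        # inserted sequence / deleted length
    support_samples: int
    population_prob: float    # support_samples / n_covered


@dataclass
class PopulationStats:
    chrom: str
    pos: int
    ref_base: str
    population_id: str
    n_covered: int
    dominant_votes: dict[str, int]
    pooled_counts: dict[str, int]
    major_allele: str
    major_prob: float
    minor_freqs: dict[str, float]
    pop_comentropy: float
    indel_events: list[IndelEvent] = field(default_factory=list)


@dataclass
class DynamicPosition:
    """A classified position with its category set and payload."""

    chrom: str
    pos: int
    ref_base: str
    population_id: str
    categories: frozenset[str]
    major_allele: str
    major_prob: float
    n_covered: int
    minor_freqs: dict[str, float]
    rare_alleles: dict[str, float]
    common_minor_alleles: dict[str, float]
    high_indels: list[IndelEvent]

    @property
    def in_mair(self) -> bool:
        return bool(self.categories & {MAJOR_DIFF, INDEL_HIGH})


def collect_units(
    record: CDPRecord,
    manifest: Sequence[str],
    config: FilterConfig = DEFAULT_FILTER,
) -> dict[str, Unit]:
    """Retained (built and filter-passing) units per sample at a CDP."""
    units: dict[str, Unit] = {}
    for sample_id, call in zip(manifest, record.sample_evidence):
        unit = build_unit(
            call, record.key.chrom, record.key.pos, config,
            sample_id=sample_id, ref_base=record.ref_base,
        )
        if unit is not None and unit.passed:
            units[sample_id] = unit
    return units


def population_stats(
    record: CDPRecord,
    units: Mapping[str, Unit],
    population: Sequence[str],
    manifest: Sequence[str],
    population_id: str = "ALL",
) -> PopulationStats | None:
    """Pool one population's retained units at one CDP.

    Returns None when no sample in the population is covered (the position
    is not estimable there). An indel event supports a sample when that
    covered sample shows at least one indel read; its population
    probability shares the covered-samples denominator with the votes.
    """
    index = {s: i for i, s in enumerate(manifest)}
    missing = [s for s in population if s not in index]
    if missing:
        raise ConfigurationError(
            f"population {population_id!r} names samples absent from the "
            f"manifest: {missing[:5]}"
        )
    ref = record.ref_base
    votes: dict[str, int] = {}
    pooled: dict[str, int] = {}
    indels: dict[tuple[str, str | int], int] = {}
    n_covered = 0
    for s in population:
        unit = units.get(s)
        if unit is None:
            continue
        n_covered += 1
        nuc = dominant_nucleotide(unit, ref)
        votes[nuc] = votes.get(nuc, 0) + 1
        for n, c in unit.counts.items():
            pooled[n] = pooled.get(n, 0) + c
        call = record.sample_evidence[index[s]]
        for seq, _count in call.insertions:
            key = (INSERTION, seq)
            indels[key] = indels.get(key, 0) + 1
        for length, _count in call.deletions:
            key = (DELETION, length)
            indels[key] = indels.get(key, 0) + 1
    if n_covered == 0:
        return None
    top = max(votes.values())
    tied = sorted(n for n, v in votes.items() if v == top)
    major = ref if ref in tied else tied[0]
    fracs = {n: v / n_covered for n, v in votes.items()}
    events = [
        IndelEvent(
            chrom=record.key.chrom, pos=record.key.pos, kind=kind,
            payload=payload, support_samples=c,
            population_prob=c / n_covered,
        )
        for (kind, payload), c in sorted(indels.items(), key=lambda kv: str(kv[0]))
    ]
    return PopulationStats(
        chrom=record.key.chrom, pos=record.key.pos, ref_base=ref,
        population_id=population_id, n_covered=n_covered,
        dominant_votes=votes, pooled_counts=pooled,
        major_allele=major, major_prob=fracs[major],
        minor_freqs={n: f for n, f in fracs.items() if n != major},
        pop_comentropy=comentropy(list(fracs.values())),
        indel_events=events,
    )


def classify(
    stats: PopulationStats,
    ref_base: str | None = None,
    config: ClassificationConfig = DEFAULT_CLASSIFICATION,
) -> DynamicPosition | None:
    """Apply the four-circumstance classification to one position.

    Returns None when no circumstance applies (the position is static) or
    when the reference base is not a nucleotide ('N' positions can never
    become dynamic). Categories may co-occur.
    """
    ref = (ref_base or stats.ref_base).upper()
    if ref not in NUCLEOTIDES:
        return None
    categories: set[str] = set()
    if stats.major_allele != ref:
        categories.add(MAJOR_DIFF)
    common = {n: f for n, f in stats.minor_freqs.items() if f > config.minor_min}
    rare = {n: f for n, f in stats.minor_freqs.items()
            if 0 < f <= config.rare_max}
    if common:
        categories.add(MINOR_COMMON)
    if rare:
        categories.add(RARE)
    high = [e for e in stats.indel_events
            if e.population_prob >= config.indel_high_min]
    if high:
        categories.add(INDEL_HIGH)
    if not categories:
        return None
    return DynamicPosition(
        chrom=stats.chrom, pos=stats.pos, ref_base=ref,
        population_id=stats.population_id, categories=frozenset(categories),
        major_allele=stats.major_allele, major_prob=stats.major_prob,
        n_covered=stats.n_covered, minor_freqs=dict(stats.minor_freqs),
        rare_alleles=rare, common_minor_alleles=common, high_indels=high,
    )


def extract_rare(positions: Iterable[DynamicPosition]) -> pd.DataFrame:
    """Rare-variation table: one row per (population, position, allele)."""
    rows = [
        {"population": dp.population_id, "chrom": dp.chrom, "pos": dp.pos,
         "allele": allele, "frequency": freq}
        for dp in positions if RARE in dp.categories
        for allele, freq in sorted(dp.rare_alleles.items())
    ]
    df = pd.DataFrame(
        rows, columns=["population", "chrom", "pos", "allele", "frequency"]
    )
    return df.sort_values(["population", "chrom", "pos", "allele"],
                          ignore_index=True)


def compute_mair(positions: Iterable[DynamicPosition]) -> list[MairEdit]:
    """The MAIR edit set: substitutions from MAJOR_DIFF, indels from
    INDEL_HIGH, each carrying its population probability."""
    edits: list[MairEdit] = []
    for dp in positions:
        if MAJOR_DIFF in dp.categories:
            edits.append(MairEdit(
                chrom=dp.chrom, pos=dp.pos, kind=SUBSTITUTION,
                payload=dp.major_allele, population_prob=dp.major_prob,
                population_id=dp.population_id,
            ))
        if INDEL_HIGH in dp.categories:
            for ev in dp.high_indels:
                edits.append(MairEdit(
                    chrom=dp.chrom, pos=dp.pos, kind=ev.kind,
                    payload=ev.payload, population_prob=ev.population_prob,
                    population_id=dp.population_id,
                ))
    edits.sort(key=lambda e: (e.chrom, e.pos, e.kind, str(e.payload)))
    return edits


# ---------------------------------------------------------------------------
# flat-file export/import (three-part storage: dynamic / indel / rare)

def _fmt_freqs(freqs: Mapping[str, float]) -> str:
    return ",".join(f"{n}:{f:.10g}" for n, f in sorted(freqs.items())) or "."


def _parse_freqs(text: str) -> dict[str, float]:
    if text == ".":
        return {}
    return {k: float(v) for k, v in
            (item.split(":") for item in text.split(","))}


def _fmt_indels(events: Sequence[IndelEvent]) -> str:
    return ";".join(
        f"{e.kind}:{e.payload}:{e.support_samples}:{e.population_prob:.10g}"
        for e in events
    ) or "."


def _parse_indels(text: str, chrom: str, pos: int) -> list[IndelEvent]:
    if text == ".":
        return []
    out = []
    for item in text.split(";"):
        kind, payload, support, prob = item.split(":")
        out.append(IndelEvent(
            chrom=chrom, pos=pos, kind=kind,
            payload=int(payload) if kind == DELETION else payload,
            support_samples=int(support), population_prob=float(prob),
        ))
    return out


_DYN_COLUMNS = ["chrom", "pos", "ref", "population", "categories", "major",
                "major_prob", "n_covered", "minor_freqs", "rare_alleles",
                "common_minor_alleles", "high_indels"]


def write_dynamic_tsv(positions: Iterable[DynamicPosition], dest) -> None:
    """Flat TSV of classified positions (1-based inclusive coordinates)."""
    close = False
    if isinstance(dest, (str, Path)):
        handle = open(dest, "wt")
        close = True
    else:
        handle = dest
    try:
        handle.write("# dynamic positions; coordinates 1-based inclusive\n")
        handle.write("\t".join(_DYN_COLUMNS) + "\n")
        for dp in positions:
            handle.write("\t".join([
                dp.chrom, str(dp.pos), dp.ref_base, dp.population_id,
                ",".join(sorted(dp.categories)), dp.major_allele,
                f"{dp.major_prob:.10g}", str(dp.n_covered),
                _fmt_freqs(dp.minor_freqs), _fmt_freqs(dp.rare_alleles),
                _fmt_freqs(dp.common_minor_alleles),
                _fmt_indels(dp.high_indels),
            ]) + "\n")
    finally:
        if close:
            handle.close()


def read_dynamic_tsv(source) -> list[DynamicPosition]:
    out: list[DynamicPosition] = []
    with open(source) as handle:
        for line in handle:
            if line.startswith("#") or line.startswith("chrom\t"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, pos = f[0], int(f[1])
            out.append(DynamicPosition(
                chrom=chrom, pos=pos, ref_base=f[2], population_id=f[3],
                categories=frozenset(f[4].split(",")), major_allele=f[5],
                major_prob=float(f[6]), n_covered=int(f[7]),
                minor_freqs=_parse_freqs(f[8]), rare_alleles=_parse_freqs(f[9]),
                common_minor_alleles=_parse_freqs(f[10]),
                high_indels=_parse_indels(f[11], chrom, pos),
            ))
    return out


def write_mair_tsv(edits: Sequence[MairEdit], dest) -> None:
    close = False
    if isinstance(dest, (str, Path)):
        handle = open(dest, "wt")
        close = True
    else:
        handle = dest
    try:
        handle.write(
            "# MAIR edits; 1-based anchors; insertions placed after the "
            "anchor base, deletions remove bases starting at pos+1\n"
        )
        handle.write("chrom\tpos\tkind\tpayload\tpopulation_prob\tpopulation\n")
        for e in edits:
            handle.write(
                f"{e.chrom}\t{e.pos}\t{e.kind}\t{e.payload}\t"
                f"{e.population_prob:.10g}\t{e.population_id or '.'}\n"
            )
    finally:
        if close:
            handle.close()


def read_mair_tsv(source) -> list[MairEdit]:
    out: list[MairEdit] = []
    with open(source) as handle:
        for line in handle:
            if line.startswith("#") or line.startswith("chrom\t"):
                continue
            chrom, pos, kind, payload, prob, pop = line.rstrip("\n").split("\t")
            out.append(MairEdit(
                chrom=chrom, pos=int(pos), kind=kind,
                payload=int(payload) if kind == DELETION else payload,
                population_prob=float(prob),
                population_id=None if pop == "." else pop,
            ))
    return out


def write_dynamic_vcf(
    positions: Iterable[DynamicPosition],
    dest,
    reference: Mapping[str, str] | None = None,
) -> None:
    """VCF 4.2 export of classified positions.

    Point records use ALT = major allele for MAJOR_DIFF (``.`` otherwise)
    with INFO POP/CAT/MAP/NCOV/AF. High-probability indels are emitted as
    separate anchor-base records when a reference is supplied.
    """
    close = False
    if isinstance(dest, (str, Path)):
        handle = open(dest, "wt")
        close = True
    else:
        handle = dest
    try:
        handle.write("##fileformat=VCFv4.2\n")
        for ident, desc, typ, num in [
            ("POP", "Population identifier", "String", "1"),
            ("CAT", "Dynamic-position categories", "String", "."),
            ("MAP", "Major allele probability (fraction of covered samples)",
             "Float", "1"),
            ("NCOV", "Covered samples (retained units)", "Integer", "1"),
            ("AF", "Minor allele sample fractions as allele:freq", "String", "."),
        ]:
            handle.write(
                f'##INFO=<ID={ident},Number={num},Type={typ},'
                f'Description="{desc}">\n'
            )
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for dp in positions:
            cats = ",".join(sorted(dp.categories))
            info = (f"POP={dp.population_id};CAT={cats};"
                    f"MAP={dp.major_prob:.6g};NCOV={dp.n_covered}")
            if dp.minor_freqs:
                info += ";AF=" + ",".join(
                    f"{n}:{f:.6g}" for n, f in sorted(dp.minor_freqs.items())
                )
            alt = dp.major_allele if MAJOR_DIFF in dp.categories else "."
            handle.write(
                f"{dp.chrom}\t{dp.pos}\t.\t{dp.ref_base}\t{alt}\t.\tPASS\t{info}\n"
            )
            if reference is not None:
                seq = reference.get(dp.chrom, "")
                for ev in dp.high_indels:
                    anchor = seq[dp.pos - 1] if dp.pos <= len(seq) else "N"
                    if ev.kind == INSERTION:
                        ref_f, alt_f = anchor, anchor + str(ev.payload)
                    else:
                        length = int(ev.payload)
                        ref_f = anchor + seq[dp.pos : dp.pos + length]
                        alt_f = anchor
                    handle.write(
                        f"{dp.chrom}\t{dp.pos}\t.\t{ref_f}\t{alt_f}\t.\tPASS\t"
                        f"POP={dp.population_id};CAT=INDEL_HIGH;"
                        f"MAP={ev.population_prob:.6g};NCOV={dp.n_covered}\n"
                    )
    finally:
        if close:
            handle.close()


def classify_columns(
    columns,
    manifest: Sequence[str],
    populations: Mapping[str, Sequence[str]],
    filter_config: FilterConfig = DEFAULT_FILTER,
    class_config: ClassificationConfig = DEFAULT_CLASSIFICATION,
):
    """Streaming pipeline core: columns -> per-population classified positions.

    Returns ``(cdp_keys, {population: [DynamicPosition, ...]},
    n_total_positions)``. Units are built once per CDP and shared across
    populations, so union populations (pooled sample sets) reuse the same
    per-sample evidence.
    """
    from .cdp import CDPKey, CDPRecord, is_candidate  # local to avoid cycle

    for name, samples in populations.items():
        unknown = [s for s in samples if s not in manifest]
        if unknown:
            raise ConfigurationError(
                f"population {name!r} names samples absent from the "
                f"manifest: {unknown[:5]}"
            )
    keys: set[CDPKey] = set()
    per_pop: dict[str, list[DynamicPosition]] = {p: [] for p in populations}
    n_total = 0
    for col in columns:
        n_total += 1
        if not is_candidate(col):
            continue
        record = CDPRecord(
            key=CDPKey(col.chrom, col.pos), ref_base=col.ref_base,
            sample_evidence=col.samples,
        )
        keys.add(record.key)
        units = collect_units(record, manifest, filter_config)
        if not units:
            continue
        for pop_name, samples in populations.items():
            stats = population_stats(record, units, samples, manifest,
                                     population_id=pop_name)
            if stats is None:
                continue
            dp = classify(stats, config=class_config)
            if dp is not None:
                per_pop[pop_name].append(dp)
    return keys, per_pop, n_total
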