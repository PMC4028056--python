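"""Candidate dynamic position (CDP) extraction.

Step one of the two-step candidate extraction: scan the multi-sample
position stream and keep every position where at least one sample shows any
non-reference evidence — a single mismatching read or a single indel event
qualifies. Detection is deliberately maximally inclusive; all stringency
lives downstream in the entropy filter and the population statistics, so
rare variants supported by few samples survive this step.

The result is a non-redundant key set plus, per candidate position, the
per-sample evidence restricted to that position. On typical low-coverage
population data this discards the overwhelming all-reference majority of
positions (the "reduction ratio").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

from .errors import DomainError
from .pileup_io import PileupColumn, SampleCall


class CDPKey(NamedTuple):
    chrom: str
    pos: int  # 1-based


@dataclass
class CDPRecord:
    """One candidate position with its per-sample evidence.

    ``sample_evidence`` is ordered like the dataset's sample manifest.
    """

    key: CDPKey
    ref_base: str
    sample_evidence: list[SampleCall]


def is_candidate(column: PileupColumn) -> bool:
    """True iff any sample shows a non-reference read or an indel event."""
    ref = column.ref_base
    return any(call.has_nonreference(ref) for call in column.samples)


def iter_cdp_records(columns: Iterable[PileupColumn]) -> Iterator[CDPRecord]:
    """Lazily yield the CDP records of a position stream (streaming form)."""
    for col in columns:
        if is_candidate(col):
            yield CDPRecord(
                key=CDPKey(col.chrom, col.pos),
                ref_base=col.ref_base,
                sample_evidence=col.samples,
            )


def extract_cdps(
    columns: Iterable[PileupColumn],
) -> tuple[set[CDPKey], list[CDPRecord]]:
    """Materialize the non-redundant CDP key set and its records.

    For large streams prefer :func:`iter_cdp_records`, which does not hold
    the evidence in memory.
    """
    keys: set[CDPKey] = set()
    records: list[CDPRecord] = []
    for rec in iter_cdp_records(columns):
        keys.add(rec.key)
        records.append(rec)
    return keys, records


def reduction_ratio(n_total_positions: int, n_cdps: int) -> float:
    """Fraction of positions discarded by candidate extraction."""
    if n_total_positions <= 0:
        raise DomainError("total position count must be positive")
    if not 0 <= n_cdps <= n_total_positions:
        raise DomainError("CDP count must lie in [0, total]")
    return 1.0 - n_cdps / n_total_positions


def write_cdp_bed(keys: Iterable[CDPKey], dest) -> None:
    """Export the CDP set as sorted BED (0-based half-open intervals)."""
    close = False
    if isinstance(dest, (str, Path)):
        handle = open(dest, "wt")
        close = True
    else:
        handle = dest
    try:
        handle.write(
            "# candidate dynamic positions; 0-based half-open intervals "
            "(converted from 1-based pileup coordinates)\n"
        )
        for chrom, pos in sorted(keys):
            handle.write(f"{chrom}\t{pos - 1}\t{pos}\n")
    finally:
        if close:
            handle.close()
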