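"""Virtual consensus genome (VCG) construction and coordinate liftover.

Applies the MAIR edit set — major-allele substitutions and high-probability
indels against the reference — to the linear reference, producing a hard
consensus sequence (no ambiguity codes) that standard aligners accept,
together with a monotone reference<->consensus coordinate map.

Indel anchoring follows the pileup convention: an insertion is placed
*after* its 1-based anchor base; a deletion removes bases starting at
``pos + 1``. Overlapping edits are resolved deterministically before
application (higher population probability wins; ties prefer deletion over
insertion over substitution, then the leftmost edit, then input order), and
every dropped edit is reported with its reason so the construction is
auditable.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import BoundsError, ConfigurationError
from .pileup_io import write_fasta  # re-exported convenience  # noqa: F401

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"
_KINDS = (SUBSTITUTION, INSERTION, DELETION)

# conflict-resolution preference among kinds (smaller wins at equal prob)
_KIND_PRIORITY = {DELETION: 0, INSERTION: 1, SUBSTITUTION: 2}
# left-to-right application order at a shared anchor
_APPLY_ORDER = {SUBSTITUTION: 0, INSERTION: 1, DELETION: 2}


@dataclass(frozen=True)
class MairEdit:
    """One reference edit derived from the MAIR table.

    ``pos`` is the 1-based anchor: the substituted base itself, the base an
    insertion follows, or the base a deletion starts after.
    """

    chrom: str
    pos: int
    kind: str
    payload: str | int  # new base / inserted sequence / deleted length
    population_prob: float = 1.0
    population_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"unknown edit kind {self.kind!r}")
        if self.kind == DELETION:
            if int(self.payload) < 1:
                raise ConfigurationError("deletion length must be >= 1")
        elif not self.payload:
            raise ConfigurationError("empty edit payload")

    def span(self) -> tuple[int, int]:
        """Occupied interval in doubled coordinates (for overlap tests).

        Bases sit at even coordinates 2p, inter-base gaps at odd 2p+1. A
        substitution occupies its base; an insertion its following gap; a
        deletion the gap after its anchor through its last removed base.
        Substitution+insertion at one anchor are therefore compatible, while
        two indels at one anchor, or a deletion spanning another edit's
        anchor, conflict.
        """
        p = self.pos
        if self.kind == SUBSTITUTION:
            return (2 * p, 2 * p)
        if self.kind == INSERTION:
            return (2 * p + 1, 2 * p + 1)
        return (2 * p + 1, 2 * (p + int(self.payload)))


@dataclass
class EditReport:
    applied: list[MairEdit] = field(default_factory=list)
    dropped: list[tuple[MairEdit, str]] = field(default_factory=list)


class LiftoverMap:
    """Monotone reference<->consensus coordinate correspondence.

    Stored per chromosome as ordered segments ``(ref_start, ref_end,
    offset)``: reference positions inside a segment map to ``pos + offset``
    on the consensus; reference positions in no segment were deleted.
    Consensus positions inside an inserted stretch have no reference image.
    """

    DELETED = -1  # array-API sentinel; scalar API returns None

    def __init__(self) -> None:
        self._segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def set_chrom(self, chrom: str, segments: Sequence[tuple[int, int, int]]) -> None:
        if segments:
            starts, ends, offs = (np.asarray(a, dtype=np.int64)
                                  for a in zip(*segments))
        else:
            starts = ends = offs = np.empty(0, dtype=np.int64)
        self._segments[chrom] = (starts, ends, offs)

    def chroms(self) -> list[str]:
        return list(self._segments)

    def segments(self, chrom: str) -> list[tuple[int, int, int]]:
        starts, ends, offs = self._segments[chrom]
        return list(zip(starts.tolist(), ends.tolist(), offs.tolist()))

    def _lookup(self, chrom: str, pos, reverse: bool) -> np.ndarray:
        starts, ends, offs = self._segments[chrom]
        p = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if reverse:
            starts, ends = starts + offs, ends + offs
        idx = np.searchsorted(starts, p, side="right") - 1
        out = np.full(p.shape, self.DELETED, dtype=np.int64)
        ok = idx >= 0
        safe = np.where(ok, idx, 0)
        ok &= p <= ends[safe]
        off = offs[safe]
        out[ok] = (p[ok] - off[ok]) if reverse else (p[ok] + off[ok])
        return out

    def to_consensus(self, chrom: str, pos: int) -> int | None:
        """Consensus coordinate of a reference position (None if deleted)."""
        v = int(self._lookup(chrom, pos, reverse=False)[0])
        return None if v == self.DELETED else v

    def to_reference(self, chrom: str, pos: int) -> int | None:
        """Reference coordinate of a consensus position (None if inserted)."""
        v = int(self._lookup(chrom, pos, reverse=True)[0])
        return None if v == self.DELETED else v

    def to_consensus_array(self, chrom: str, positions) -> np.ndarray:
        return self._lookup(chrom, positions, reverse=False)

    def to_reference_array(self, chrom: str, positions) -> np.ndarray:
        return self._lookup(chrom, positions, reverse=True)

    def write_tsv(self, dest) -> None:
        close = False
        if isinstance(dest, (str, Path)):
            handle = open(dest, "wt")
            close = True
        else:
            handle = dest
        try:
            handle.write(
                "# reference->consensus liftover; 1-based inclusive segments; "
                "consensus = reference + offset inside a segment\n"
            )
            handle.write("chrom\tref_start\tref_end\toffset\n")
            for chrom in self._segments:
                for s, e, o in self.segments(chrom):
                    handle.write(f"{chrom}\t{s}\t{e}\t{o}\n")
        finally:
            if close:
                handle.close()

    @classmethod
    def read_tsv(cls, source) -> "LiftoverMap":
        lmap = cls()
        per: dict[str, list[tuple[int, int, int]]] = {}
        with open(source) as handle:
            for line in handle:
                if line.startswith("#") or line.startswith("chrom\t"):
                    continue
                chrom, s, e, o = line.rstrip("\n").split("\t")
                per.setdefault(chrom, []).append((int(s), int(e), int(o)))
        for chrom, segs in per.items():
            lmap.set_chrom(chrom, segs)
        return lmap


def liftover(chrom: str, pos: int, lmap: LiftoverMap,
             direction: str = "to_consensus") -> int | None:
    """Functional wrapper: map one coordinate through a liftover map."""
    if direction == "to_consensus":
        return lmap.to_consensus(chrom, pos)
    if direction == "to_reference":
        return lmap.to_reference(chrom, pos)
    raise ConfigurationError(f"unknown liftover direction {direction!r}")


def resolve_conflicts(
    edits: Sequence[MairEdit],
) -> tuple[list[MairEdit], list[tuple[MairEdit, str]]]:
    """Deterministically reconcile overlapping edits.

    Greedy acceptance in preference order: higher ``population_prob`` first,
    then deletion > insertion > substitution, then leftmost position, then
    stable input order. An edit overlapping an already accepted one is
    dropped with a reason naming the winner.
    """
    order = sorted(
        range(len(edits)),
        key=lambda i: (-edits[i].population_prob,
                       _KIND_PRIORITY[edits[i].kind],
                       edits[i].pos, i),
    )
    kept: list[MairEdit] = []
    dropped: list[tuple[MairEdit, str]] = []
    accepted: dict[str, tuple[list[int], list[int], list[MairEdit]]] = {}
    for i in order:
        e = edits[i]
        lo, hi = e.span()
        starts, ends, owners = accepted.setdefault(e.chrom, ([], [], []))
        j = bisect.bisect_right(starts, hi) - 1
        winner = None
        if j >= 0 and ends[j] >= lo:
            winner = owners[j]
        if winner is not None:
            dropped.append(
                (e, f"overlaps kept {winner.kind} at {winner.chrom}:{winner.pos}")
            )
            continue
        k = bisect.bisect_left(starts, lo)
        starts.insert(k, lo)
        ends.insert(k, hi)
        owners.insert(k, e)
        kept.append(e)
    kept.sort(key=lambda e: (e.chrom, e.pos, _APPLY_ORDER[e.kind]))
    return kept, dropped


def build_vcg(
    reference: Mapping[str, str],
    edits: Iterable[MairEdit],
) -> tuple[dict[str, str], LiftoverMap, EditReport]:
    """Apply a MAIR edit set to the reference.

    Returns the consensus sequences, the reference<->consensus liftover map,
    and a report listing applied and dropped edits. Out-of-bounds edits
    raise :class:`BoundsError`; substitutions whose payload equals the
    reference base are rejected (logged, not fatal).
    """
    report = EditReport()
    valid: list[MairEdit] = []
    for e in edits:
        if e.chrom not in reference:
            raise BoundsError(f"edit on unknown chromosome {e.chrom!r}")
        L = len(reference[e.chrom])
        if not 1 <= e.pos <= L:
            raise BoundsError(
                f"{e.kind} anchor {e.chrom}:{e.pos} outside 1..{L}"
            )
        if e.kind == DELETION and e.pos + int(e.payload) > L:
            raise BoundsError(
                f"deletion at {e.chrom}:{e.pos} length {e.payload} runs past "
                f"chromosome end {L}"
            )
        if e.kind == SUBSTITUTION and str(e.payload).upper() == reference[e.chrom][e.pos - 1]:
            report.dropped.append((e, "substitution payload equals reference base"))
            continue
        valid.append(e)

    kept, conflict_dropped = resolve_conflicts(valid)
    report.dropped.extend(conflict_dropped)
    report.applied = kept

    by_chrom: dict[str, list[MairEdit]] = {}
    for e in kept:
        by_chrom.setdefault(e.chrom, []).append(e)

    consensus: dict[str, str] = {}
    lmap = LiftoverMap()
    for chrom, seq in reference.items():
        L = len(seq)
        parts: list[str] = []
        segments: list[tuple[int, int, int]] = []
        cursor = 1          # next unconsumed 1-based reference position
        seg_start = 1       # start of the current identity segment
        delta = 0           # consensus offset of the current segment
        for e in by_chrom.get(chrom, ()):
            p = e.pos
            if e.kind == SUBSTITUTION:
                parts.append(seq[cursor - 1 : p - 1])
                parts.append(str(e.payload).upper())
                cursor = p + 1
            elif e.kind == INSERTION:
                ins = str(e.payload).upper()
                parts.append(seq[cursor - 1 : p])
                parts.append(ins)
                cursor = p + 1
                if seg_start <= p:
                    segments.append((seg_start, p, delta))
                seg_start = p + 1
                delta += len(ins)
            else:  # deletion of bases p+1 .. p+length
                length = int(e.payload)
                parts.append(seq[cursor - 1 : p])
                cursor = p + length + 1
                if seg_start <= p:
                    segments.append((seg_start, p, delta))
                seg_start = p + length + 1
                delta -= length
        parts.append(seq[cursor - 1 :])
        if seg_start <= L:
            segments.append((seg_start, L, delta))
        consensus[chrom] = "".join(parts)
        lmap.set_chrom(chrom, segments)
    return consensus, lmap, report


def write_edits_vcf(
    edits: Sequence[MairEdit], reference: Mapping[str, str], dest
) -> None:
    """Provenance VCF of the applied edit set (VCF 4.2, anchor-base style)."""
    close = False
    if isinstance(dest, (str, Path)):
        handle = open(dest, "wt")
        close = True
    else:
        handle = dest
    try:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write('##INFO=<ID=PP,Number=1,Type=Float,'
                     'Description="Population probability of the edit">\n')
        handle.write('##INFO=<ID=POP,Number=1,Type=String,'
                     'Description="Population identifier">\n')
        for chrom, seq in reference.items():
            handle.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for e in sorted(edits, key=lambda e: (e.chrom, e.pos)):
            seq = reference[e.chrom]
            anchor = seq[e.pos - 1]
            if e.kind == SUBSTITUTION:
                ref, alt = anchor, str(e.payload).upper()
            elif e.kind == INSERTION:
                ref, alt = anchor, anchor + str(e.payload).upper()
            else:
                length = int(e.payload)
                ref, alt = anchor + seq[e.pos : e.pos + length], anchor
            info = f"PP={e.population_prob:.6g}"
            if e.population_id:
                info += f";POP={e.population_id}"
            handle.write(
                f"{e.chrom}\t{e.pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n"
            )
    finally:
        if close:
            handle.close()
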