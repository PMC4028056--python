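"""Position-based pileup and reference FASTA I/O.

Reads multi-sample ``samtools mpileup`` text and turns the read-based
alignment information into position-based records: one
:class:`PileupColumn` per genomic position, holding an ordered
:class:`SampleCall` (nucleotide counts plus indel events) per sample.

Conventions, stated once and used everywhere:

* Coordinates are 1-based inclusive (the pileup convention).
* Strand is ignored: ``.``/``,`` and upper/lowercase read bases are merged.
* Base quality strings are accepted (auto-detected by column count) but
  discarded — downstream filtering is entropy-based, not quality-based.
* Indel events (``+n<seq>`` / ``-n<seq>``) attach to the preceding (anchor)
  base; the event substring is consumed and recorded, never counted as
  point bases.
* ``*`` (deleted-base placeholder), ``N`` read bases, and ``<``/``>``
  reference skips count toward depth but never toward nucleotide counts.
* Files ending in ``.gz`` are read transparently.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO

from .errors import FastaError, PileupFormatError, PileupParseError

NUCLEOTIDES = ("A", "C", "G", "T")

# read-level symbols that contribute to depth but are not A/C/G/T evidence
_NON_NUCLEOTIDE_READS = frozenset("Nn*<>")
_POINT_BASES = frozenset(".,ACGTacgt") | _NON_NUCLEOTIDE_READS


@dataclass
class SampleCall:
    """One sample's evidence at one position.

    ``depth`` counts every read symbol (including ``*`` placeholders and
    reference skips); ``sum(base_counts.values()) <= depth`` always holds.
    """

    depth: int = 0
    base_counts: dict[str, int] = field(default_factory=dict)
    insertions: list[tuple[str, int]] = field(default_factory=list)
    deletions: list[tuple[int, int]] = field(default_factory=list)

    def total_bases(self) -> int:
        return sum(self.base_counts.values())

    def has_nonreference(self, ref_base: str) -> bool:
        ref = ref_base.upper()
        if self.insertions or self.deletions:
            return True
        return any(n != ref and c > 0 for n, c in self.base_counts.items())


@dataclass
class PileupColumn:
    """One genomic position across all samples of a dataset."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    samples: list[SampleCall]


def _context(chrom, pos, sample_index) -> str:
    parts = []
    if chrom is not None:
        parts.append(f"{chrom}:{pos}")
    if sample_index is not None:
        parts.append(f"sample index {sample_index}")
    return (" at " + ", ".join(parts)) if parts else ""


def parse_base_string(
    bases: str,
    ref_base: str,
    *,
    chrom: str | None = None,
    pos: int | None = None,
    sample_index: int | None = None,
) -> SampleCall:
    """Tokenize one mpileup base string into a :class:`SampleCall`.

    Raises :class:`PileupParseError` (naming position and sample index when
    known) for a malformed indel length prefix or a dangling ``^`` marker.
    """
    ref = ref_base.upper()
    ref_is_nuc = ref in NUCLEOTIDES

    # fast path: the overwhelmingly common all-reference column
    if bases and not bases.strip(".,"):
        counts = {ref: len(bases)} if ref_is_nuc else {}
        return SampleCall(depth=len(bases), base_counts=counts)

    counts: dict[str, int] = {}
    ins: dict[str, int] = {}
    dels: dict[int, int] = {}
    depth = 0
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            # read-start marker: next char is mapping quality, consumed blindly
            if i + 1 >= n:
                raise PileupParseError(
                    f"dangling '^' read-start marker{_context(chrom, pos, sample_index)}"
                )
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(
                    f"malformed indel length prefix after '{c}'"
                    f"{_context(chrom, pos, sample_index)}"
                )
            length = int(bases[i + 1 : j])
            seq = bases[j : j + length]
            if len(seq) < length:
                raise PileupParseError(
                    f"indel sequence shorter than declared length {length}"
                    f"{_context(chrom, pos, sample_index)}"
                )
            if c == "+":
                key = seq.upper()
                ins[key] = ins.get(key, 0) + 1
            else:
                dels[length] = dels.get(length, 0) + 1
            i = j + length
            continue
        if c in ".,":
            depth += 1
            if ref_is_nuc:
                counts[ref] = counts.get(ref, 0) + 1
        elif c in "ACGTacgt":
            depth += 1
            u = c.upper()
            counts[u] = counts.get(u, 0) + 1
        elif c in _NON_NUCLEOTIDE_READS:
            depth += 1
        else:
            raise PileupParseError(
                f"unrecognized base-string character {c!r}"
                f"{_context(chrom, pos, sample_index)}"
            )
        i += 1
    return SampleCall(
        depth=depth,
        base_counts=counts,
        insertions=sorted(ins.items()),
        deletions=sorted(dels.items()),
    )


def _open_text(source, mode: str = "rt") -> IO[str]:
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_pileup(
    source, manifest: Sequence[str]
) -> Iterator[PileupColumn]:
    """Stream :class:`PileupColumn` records from multi-sample mpileup text.

    ``source`` may be a path (``.gz`` transparently) or an open text stream /
    iterable of lines. Per-sample fields may come as (depth, bases, quals)
    triplets or (depth, bases) pairs; the layout is detected from the column
    count against ``len(manifest)``. Positions must be strictly increasing
    within a chromosome.
    """
    close = False
    if isinstance(source, (str, Path)):
        handle: Iterable[str] = _open_text(source)
        close = True
    else:
        handle = source
    n_samples = len(manifest)
    last: dict[str, int] = {}
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            ncols = len(fields)
            if ncols == 3 + 3 * n_samples:
                step = 3
            elif ncols == 3 + 2 * n_samples:
                step = 2
            else:
                raise PileupFormatError(
                    f"line {lineno}: {ncols} columns do not match "
                    f"{n_samples} samples (expected {3 + 2 * n_samples} or "
                    f"{3 + 3 * n_samples})"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise PileupFormatError(
                    f"line {lineno}: non-integer position {pos_s!r}"
                ) from exc
            if pos < 1:
                raise PileupFormatError(f"line {lineno}: position {pos} < 1")
            if chrom in last and pos <= last[chrom]:
                raise PileupFormatError(
                    f"line {lineno}: non-monotone position {pos} on {chrom} "
                    f"(previous {last[chrom]})"
                )
            last[chrom] = pos
            ref = ref.upper()
            calls = []
            for k in range(n_samples):
                depth_s = fields[3 + k * step]
                bases = fields[4 + k * step]
                try:
                    declared = int(depth_s)
                except ValueError as exc:
                    raise PileupFormatError(
                        f"line {lineno}: non-integer depth {depth_s!r} for "
                        f"sample {manifest[k]}"
                    ) from exc
                if declared == 0:
                    calls.append(SampleCall())
                    continue
                calls.append(
                    parse_base_string(
                        bases, ref, chrom=chrom, pos=pos, sample_index=k
                    )
                )
            yield PileupColumn(chrom=chrom, pos=pos, ref_base=ref, samples=calls)
    finally:
        if close:
            handle.close()  # type: ignore[union-attr]


def format_sample_call(call: SampleCall, ref_base: str) -> tuple[str, str]:
    """Render one SampleCall back to a canonical (bases, quals) pair.

    Reference matches become ``.``; mismatches uppercase letters; the
    ``depth − Σbase_counts`` remainder becomes ``*`` placeholders; indel
    events attach after the leading symbols. Round-trips through
    :func:`parse_base_string` on (depth, base_counts, indels).
    """
    if call.depth == 0:
        return "*", "*"
    ref = ref_base.upper()
    symbols: list[str] = []
    for nuc in NUCLEOTIDES:
        c = call.base_counts.get(nuc, 0)
        symbols.extend(("." if nuc == ref else nuc) * c)
    symbols.extend("*" * (call.depth - call.total_bases()))
    events: list[str] = []
    for seq, c in call.insertions:
        events.extend([f"+{len(seq)}{seq}"] * c)
    for length, c in call.deletions:
        events.extend([f"-{length}{'N' * length}"] * c)
    for i, ev in enumerate(events):
        if i < len(symbols):
            symbols[i] = symbols[i] + ev
        else:
            symbols.append(ev)  # parser tolerates unanchored events
    return "".join(symbols), "I" * call.depth


def write_pileup(
    columns: Iterable[PileupColumn], dest, *, with_quals: bool = True
) -> None:
    """Write columns as multi-sample mpileup text (path or text handle)."""
    close = False
    if isinstance(dest, (str, Path)):
        handle = _open_text(dest, "wt")
        close = True
    else:
        handle = dest
    try:
        for col in columns:
            fields = [col.chrom, str(col.pos), col.ref_base]
            for call in col.samples:
                bases, quals = format_sample_call(call, col.ref_base)
                fields.append(str(call.depth))
                fields.append(bases)
                if with_quals:
                    fields.append(quals)
            handle.write("\t".join(fields) + "\n")
    finally:
        if close:
            handle.close()


def read_reference(path) -> dict[str, str]:
    """Read a (possibly gzipped, possibly multi-record) FASTA.

    Sequences are uppercased; duplicate record names raise
    :class:`FastaError`.
    """
    ref: dict[str, str] = {}
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in ref:
                raise FastaError(f"duplicate FASTA record name {record.id!r}")
            ref[record.id] = str(record.seq).upper()
    return ref


def write_fasta(sequences: Mapping[str, str], dest, *, width: int = 60) -> None:
    """Write sequences as FASTA with fixed-width line wrapping."""
    close = False
    if isinstance(dest, (str, Path)):
        handle = _open_text(dest, "wt")
        close = True
    else:
        handle = dest
    try:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
    finally:
        if close:
            handle.close()
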