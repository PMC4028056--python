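"""Per-(sample, position) units, comentropy, and the unit filter.

Each base position on each sample is a *unit*: the vector of nucleotide
counts observed there. The comentropy (Shannon entropy, base 2) of the
unit's nucleotide distribution,

    H(x) = -sum_i p(x_i) * log2 p(x_i),

measures how ambiguous the evidence is; a unit is retained only when H
stays at or below an arity-specific threshold (binary <= 0.95, ternary
<= 1.50, quaternary <= 1.92 bits) and the unit holds at least two mapped
nucleotide reads. Retained units each contribute one dominant-nucleotide
vote to population statistics — the device that keeps heterogeneous-depth
samples equally weighted.

Only detected nucleotide types (A/C/G/T with count > 0) enter the
distribution: deletion placeholders and indel events contribute neither to
arity nor to p(x_i). Unary units trivially have H = 0 and always pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ContractError, DomainError
from .pileup_io import NUCLEOTIDES, SampleCall

_LOG2 = (None, 0.0, 1.0, math.log2(3.0), 2.0)


@dataclass(frozen=True)
class FilterConfig:
    """Unit-filter thresholds.

    ``min_reads`` is the minimum nucleotide-read count per unit (default 2);
    ``max_h_*`` are inclusive comentropy ceilings in bits per arity.
    """

    min_reads: int = 2
    max_h_binary: float = 0.95
    max_h_ternary: float = 1.50
    max_h_quaternary: float = 1.92

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ConfigurationError("min_reads must be >= 1")
        for arity, thr in ((2, self.max_h_binary), (3, self.max_h_ternary),
                           (4, self.max_h_quaternary)):
            if not 0.0 < thr <= _LOG2[arity] + 1e-12:
                raise ConfigurationError(
                    f"threshold for arity {arity} must lie in (0, log2 {arity}]"
                )

    def threshold_for(self, arity: int) -> float | None:
        """Inclusive H ceiling for a unit of the given arity (None = no bound)."""
        if arity <= 1:
            return None
        return {2: self.max_h_binary, 3: self.max_h_ternary,
                4: self.max_h_quaternary}[arity]


DEFAULT_FILTER = FilterConfig()


@dataclass
class Unit:
    """One sample's nucleotide-count distribution at one position."""

    sample_id: str | None
    chrom: str
    pos: int
    counts: dict[str, int]       # observed types only (count > 0)
    depth: int                   # total nucleotide reads in the unit
    arity: int                   # number of distinct observed types, 1..4
    probs: dict[str, float]      # p(x_i) = count_i / depth
    comentropy: float            # H in bits
    passed: bool
    ref_base: str | None = None


def comentropy(probs: Sequence[float]) -> float:
    """H = -sum p log2 p over a probability vector, with 0*log2(0) := 0.

    Raises :class:`DomainError` for negative components or a sum that
    deviates from 1 by more than 1e-9.
    """
    p = np.asarray(probs, dtype=float)
    if p.size == 0:
        raise DomainError("empty probability vector")
    if np.any(p < 0):
        raise DomainError("negative probability component")
    total = float(p.sum())
    if abs(total - 1.0) > 1e-9:
        raise DomainError(f"probabilities sum to {total}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def build_unit(
    sample_call: SampleCall,
    chrom: str,
    pos: int,
    config: FilterConfig = DEFAULT_FILTER,
    *,
    sample_id: str | None = None,
    ref_base: str | None = None,
) -> Unit | None:
    """Build the unit for one sample call, or None below the depth rule.

    Units with fewer than ``config.min_reads`` nucleotide reads are never
    built — too little evidence to assess. Otherwise the unit carries its
    arity, probabilities, comentropy, and filter verdict.
    """
    counts = {n: c for n, c in sample_call.base_counts.items()
              if c > 0 and n in NUCLEOTIDES}
    depth = sum(counts.values())
    if depth < config.min_reads:
        return None
    probs = {n: c / depth for n, c in counts.items()}
    h = comentropy(list(probs.values()))
    arity = len(counts)
    thr = config.threshold_for(arity)
    passed = thr is None or h <= thr
    return Unit(
        sample_id=sample_id, chrom=chrom, pos=pos, counts=counts,
        depth=depth, arity=arity, probs=probs, comentropy=h,
        passed=passed, ref_base=ref_base,
    )


def passes_unit_filter(unit: Unit, config: FilterConfig = DEFAULT_FILTER) -> bool:
    """True iff the unit's comentropy is at or below its arity threshold."""
    thr = config.threshold_for(unit.arity)
    return thr is None or unit.comentropy <= thr


def dominant_nucleotide(unit: Unit, ref_base: str | None = None) -> str:
    """The highest-count nucleotide of a retained unit.

    Top-count ties break toward the reference base when it is among the tied
    maxima, else alphabetically — deterministic and conservative toward the
    reference. Calling this on a failed unit is a contract violation.
    """
    if not unit.passed:
        raise ContractError(
            f"dominant_nucleotide called on failed unit at {unit.chrom}:{unit.pos}"
        )
    top = max(unit.counts.values())
    tied = sorted(n for n, c in unit.counts.items() if c == top)
    ref = (ref_base or unit.ref_base or "").upper()
    if ref in tied:
        return ref
    return tied[0]
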