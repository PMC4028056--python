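"""Synthetic low-coverage diploid population pileups with truth tables.

Emulates the study conditions the pipeline is designed for: N diploid
samples sequenced at low coverage (per-position depth ~ Poisson, mean 3x by
default, the middle of the 2-4x regime), a uniform per-base miscall rate
(0.005 by default), planted SNVs and indels at chosen population allele
frequencies, and diploid genotypes drawn at Hardy-Weinberg proportions.
Each read at a planted site is drawn from one of the sample's two haplotype
alleles with equal probability, then miscalled to a uniform other base with
the error rate. Reads covering a deleted base on a deletion-carrying
haplotype appear as ``*`` placeholders; the deletion event itself is
reported at its anchor base, matching the pileup convention.

Everything is deterministic given the seed: the same configuration
reproduces the same bytes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .consensus import DELETION, INSERTION
from .errors import ConfigurationError
from .pileup_io import NUCLEOTIDES


@dataclass(frozen=True)
class SnvSpec:
    chrom: str
    pos: int           # 1-based
    alt: str
    freq: float        # population allele frequency in (0, 1]


@dataclass(frozen=True)
class IndelSpec:
    chrom: str
    pos: int           # 1-based anchor; insertion after it, deletion from pos+1
    kind: str          # "insertion" | "deletion"
    payload: str | int # inserted sequence / deleted length
    freq: float


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_samples: int = 20
    coverage_lambda: float = 3.0
    error_rate: float = 0.005
    reference: Mapping[str, str] | None = None
    reference_length: int = 10_000
    chrom_name: str = "chr1"
    snvs: tuple[SnvSpec, ...] = ()
    indels: tuple[IndelSpec, ...] = ()
    populations: Mapping[str, tuple[str, ...]] | None = None

    def sample_names(self) -> list[str]:
        return [f"S{i:03d}" for i in range(self.n_samples)]


@dataclass
class TruthTable:
    """Exactly what was drawn: variant metadata, per-sample genotypes
    (alt-allele dosage 0/1/2), and realized mean coverage per sample."""

    variants: pd.DataFrame     # id, chrom, pos, kind, ref, alt, freq
    genotypes: pd.DataFrame    # index: variant id; columns: samples
    coverage: pd.Series        # mean realized depth per sample


@dataclass
class SimResult:
    config: SimulationConfig
    reference: dict[str, str]
    manifest: list[str]
    pileup_text: str
    truth: TruthTable


def _random_reference(rng: np.random.Generator, length: int,
                      chrom: str) -> dict[str, str]:
    bases = rng.choice(list(NUCLEOTIDES), size=length)
    return {chrom: "".join(bases)}


def _variant_id(kind: str, chrom: str, pos: int, payload) -> str:
    return f"{kind}:{chrom}:{pos}:{payload}"


def simulate(config: SimulationConfig) -> SimResult:
    """Run the simulation; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    if config.reference is not None:
        reference = {c: s.upper() for c, s in config.reference.items()}
    else:
        reference = _random_reference(rng, config.reference_length,
                                      config.chrom_name)
    manifest = config.sample_names()
    n = config.n_samples
    eps = config.error_rate

    variants: list[dict] = []
    for v in config.snvs:
        _check_variant(reference, v.chrom, v.pos, v.freq)
        ref_base = reference[v.chrom][v.pos - 1]
        if v.alt.upper() == ref_base:
            raise ConfigurationError(
                f"planted SNV alt equals reference at {v.chrom}:{v.pos}"
            )
        variants.append({"id": _variant_id("snv", v.chrom, v.pos, v.alt),
                         "chrom": v.chrom, "pos": v.pos, "kind": "snv",
                         "ref": ref_base, "alt": v.alt.upper(),
                         "freq": v.freq, "spec": v})
    for v in config.indels:
        _check_variant(reference, v.chrom, v.pos, v.freq)
        if v.kind not in (INSERTION, DELETION):
            raise ConfigurationError(f"unknown indel kind {v.kind!r}")
        if v.kind == DELETION and v.pos + int(v.payload) > len(reference[v.chrom]):
            raise ConfigurationError(
                f"planted deletion at {v.chrom}:{v.pos} runs past chromosome end"
            )
        variants.append({"id": _variant_id(v.kind, v.chrom, v.pos, v.payload),
                         "chrom": v.chrom, "pos": v.pos, "kind": v.kind,
                         "ref": reference[v.chrom][v.pos - 1],
                         "alt": str(v.payload), "freq": v.freq, "spec": v})

    # Hardy-Weinberg genotypes: alt dosage ~ Binomial(2, f) per sample
    genotypes = {
        v["id"]: rng.binomial(2, v["freq"], size=n) for v in variants
    }

    # per-chromosome event lookup tables
    snv_at: dict[tuple[str, int], list[dict]] = {}
    ins_at: dict[tuple[str, int], list[dict]] = {}
    del_anchor_at: dict[tuple[str, int], list[dict]] = {}
    del_span_at: dict[tuple[str, int], list[dict]] = {}
    for v in variants:
        key = (v["chrom"], v["pos"])
        if v["kind"] == "snv":
            snv_at.setdefault(key, []).append(v)
        elif v["kind"] == INSERTION:
            ins_at.setdefault(key, []).append(v)
        else:
            del_anchor_at.setdefault(key, []).append(v)
            for off in range(1, int(v["alt"]) + 1):
                del_span_at.setdefault((v["chrom"], v["pos"] + off), []).append(v)

    dots = ["." * d for d in range(64)]
    quals = ["I" * d for d in range(64)]
    others = {b: [x for x in NUCLEOTIDES if x != b] for b in NUCLEOTIDES}
    others["N"] = list(NUCLEOTIDES)

    lines: list[str] = []
    coverage_sums = np.zeros(n)
    total_len = 0
    for chrom, seq in reference.items():
        L = len(seq)
        total_len += L
        depths = rng.poisson(config.coverage_lambda, size=(n, L))
        err_counts = (rng.binomial(depths, eps) if eps > 0
                      else np.zeros_like(depths))
        coverage_sums += depths.sum(axis=1)

        # render default cells, then overwrite special ones
        cells = [[None] * L for _ in range(n)]
        for s in range(n):
            row = depths[s]
            crow = cells[s]
            for p in range(L):
                d = int(row[p])
                crow[p] = dots[d] if d < 64 else "." * d

        if eps > 0:
            for s, p in zip(*np.nonzero(err_counts)):
                d = int(depths[s, p])
                e = int(err_counts[s, p])
                ref_base = seq[p]
                errs = rng.choice(others[ref_base], size=e)
                cells[s][p] = ("." * (d - e)) + "".join(errs)

        special = sorted(
            {pos for (c, pos) in list(snv_at) + list(ins_at)
             + list(del_anchor_at) + list(del_span_at) if c == chrom}
        )
        for pos in special:
            p = pos - 1
            ref_base = seq[p]
            snvs_here = snv_at.get((chrom, pos), [])
            ins_here = ins_at.get((chrom, pos), [])
            del_here = del_anchor_at.get((chrom, pos), [])
            delspan_here = del_span_at.get((chrom, pos), [])
            for s in range(n):
                d = int(depths[s, p])
                if d == 0:
                    cells[s][p] = ""
                    continue
                # haplotype alleles for this sample at this locus
                symbols = []
                for _read in range(d):
                    base = ref_base
                    suffix = ""
                    deleted = False
                    for v in snvs_here:
                        g = genotypes[v["id"]][s]
                        if g and rng.random() < g / 2.0:
                            base = v["alt"]
                    for v in delspan_here:
                        g = genotypes[v["id"]][s]
                        if g and rng.random() < g / 2.0:
                            deleted = True
                    for v in ins_here:
                        g = genotypes[v["id"]][s]
                        if g and rng.random() < g / 2.0:
                            suffix += f"+{len(v['alt'])}{v['alt']}"
                    for v in del_here:
                        g = genotypes[v["id"]][s]
                        if g and rng.random() < g / 2.0:
                            length = int(v["alt"])
                            suffix += f"-{length}{seq[p + 1 : p + 1 + length]}"
                    if deleted:
                        symbols.append("*")
                        continue
                    if eps > 0 and rng.random() < eps:
                        base = str(rng.choice(others[base]))
                    symbols.append(("." if base == ref_base else base) + suffix)
                cells[s][p] = "".join(symbols)

        # every read emits exactly one symbol, so the drawn depth is the
        # rendered depth even at indel positions
        for p in range(L):
            fields = [chrom, str(p + 1), seq[p]]
            for s in range(n):
                d = int(depths[s, p])
                if d == 0:
                    fields += ["0", "*", "*"]
                else:
                    fields += [str(d), cells[s][p],
                               quals[d] if d < 64 else "I" * d]
            lines.append("\t".join(fields))

    genotype_df = pd.DataFrame(
        genotypes, index=manifest
    ).T if variants else pd.DataFrame(columns=manifest)
    variants_df = pd.DataFrame(
        [{k: v[k] for k in ("id", "chrom", "pos", "kind", "ref", "alt", "freq")}
         for v in variants],
        columns=["id", "chrom", "pos", "kind", "ref", "alt", "freq"],
    )
    truth = TruthTable(
        variants=variants_df,
        genotypes=genotype_df,
        coverage=pd.Series(coverage_sums / max(total_len, 1), index=manifest),
    )
    return SimResult(
        config=config, reference=reference, manifest=manifest,
        pileup_text="\n".join(lines) + ("\n" if lines else ""),
        truth=truth,
    )


def _check_variant(reference, chrom, pos, freq) -> None:
    if chrom not in reference:
        raise ConfigurationError(f"variant on unknown chromosome {chrom!r}")
    if not 1 <= pos <= len(reference[chrom]):
        raise ConfigurationError(f"variant position {chrom}:{pos} out of range")
    if reference[chrom][pos - 1] == "N":
        raise ConfigurationError(
            f"variant planted on reference 'N' at {chrom}:{pos}"
        )
    if not 0 < freq <= 1:
        raise ConfigurationError(f"variant frequency {freq} outside (0, 1]")


def regenerate(config: SimulationConfig) -> SimResult:
    """Alias of :func:`simulate` stating the reproducibility contract:
    identical seed and config produce identical bytes."""
    return simulate(config)


def sha256_of(result: SimResult) -> str:
    return hashlib.sha256(result.pileup_text.encode()).hexdigest()


# ---------------------------------------------------------------------------
# flat on-disk config form (key<TAB>value lines; variants repeatable)

def config_to_text(config: SimulationConfig) -> str:
    lines = [
        f"seed\t{config.seed}",
        f"n_samples\t{config.n_samples}",
        f"coverage_lambda\t{config.coverage_lambda:.10g}",
        f"error_rate\t{config.error_rate:.10g}",
        f"reference_length\t{config.reference_length}",
        f"chrom_name\t{config.chrom_name}",
    ]
    for v in config.snvs:
        lines.append(f"snv\t{v.chrom},{v.pos},{v.alt},{v.freq:.10g}")
    for v in config.indels:
        lines.append(
            f"indel\t{v.chrom},{v.pos},{v.kind},{v.payload},{v.freq:.10g}"
        )
    if config.populations:
        for name, samples in config.populations.items():
            lines.append(f"population\t{name}={','.join(samples)}")
    return "\n".join(lines) + "\n"


def config_from_text(text: str) -> SimulationConfig:
    kwargs: dict = {}
    snvs: list[SnvSpec] = []
    indels: list[IndelSpec] = []
    populations: dict[str, tuple[str, ...]] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, value = line.split("\t", 1)
        if key == "snv":
            chrom, pos, alt, freq = value.split(",")
            snvs.append(SnvSpec(chrom, int(pos), alt, float(freq)))
        elif key == "indel":
            chrom, pos, kind, payload, freq = value.split(",")
            indels.append(IndelSpec(
                chrom, int(pos), kind,
                int(payload) if kind == DELETION else payload, float(freq),
            ))
        elif key == "population":
            name, samples = value.split("=", 1)
            populations[name] = tuple(samples.split(","))
        elif key in ("seed", "n_samples", "reference_length"):
            kwargs[key] = int(value)
        elif key in ("coverage_lambda", "error_rate"):
            kwargs[key] = float(value)
        elif key == "chrom_name":
            kwargs[key] = value
        else:
            raise ConfigurationError(f"unknown config key {key!r}")
    return SimulationConfig(
        snvs=tuple(snvs), indels=tuple(indels),
        populations=populations or None, **kwargs,
    )


def write_truth(truth: TruthTable, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth.variants.to_csv(directory / "truth_variants.tsv", sep="\t",
                          index=False)
    truth.genotypes.to_csv(directory / "truth_genotypes.tsv", sep="\t",
                           index_label="variant")
    truth.coverage.rename("mean_depth").to_csv(
        directory / "truth_coverage.tsv", sep="\t", index_label="sample"
    )
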