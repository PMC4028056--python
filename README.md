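# dynaref

Population consensus reference genomes from multi-sample, low-coverage
pileup data.

A single linear reference genome describes none of the populations mapped
against it: at millions of positions the population's *major* allele
differs from the reference base, indels segregate at high frequency, and
minor alleles carry most of the between-individual variation. `dynaref`
turns a multi-sample `samtools mpileup` stream (tens to hundreds of
genomes at 2–4× coverage) into:

* a catalog of **dynamic positions** — positions where a population
  differs from the reference in one of four ways: a different major
  allele, a high-probability indel (≥ 50% of samples), a common minor
  allele (> 5%), or a rare variation (≤ 5%);
* the **MAIR** set (major allele and indel positions against the
  reference) — the edit list that converts the reference into the
  population consensus;
* a **virtual consensus genome** (plain FASTA, usable by BWA/Bowtie-class
  aligners) with a reference↔consensus coordinate liftover map;
* summary reports: per-chromosome-class counts, major-probability and
  indel-length distributions, pairwise population intersections with a
  same-allele/different-allele split, codon-level effect tallies, and
  interval-catalog hit counts.

## The model

Each (sample, position) pair is a *unit*: the vector of nucleotide counts
observed in that sample's reads. Instead of base-quality filtering —
unreliable when pooling heterogeneous low-coverage platforms — units are
filtered by their **comentropy** (Shannon entropy, base 2):

```
H(x) = − Σᵢ p(xᵢ) log₂ p(xᵢ)
```

where `xᵢ` ranges over the detected nucleotide types and
`p(xᵢ) = countᵢ / n_reads`. A unit is retained when it has at least two
mapped reads and `H` does not exceed its arity's ceiling: binary ≤ 0.95,
ternary ≤ 1.50, quaternary ≤ 1.92 bits. Uniform (maximally ambiguous)
evidence such as a 1:1 binary unit (H = 1) is discarded.

Every retained unit casts exactly one dominant-nucleotide vote, so each
sample is weighted equally regardless of its depth. The vote distribution
at a position gives the major allele and its probability
(`votes / covered samples`), minor-allele sample fractions, and a
population-level comentropy. Indel support is likewise counted per sample
against the covered-samples denominator. Populations can be pooled
(`CHN = CHB ∪ CHS` style) by concatenating sample sets — never by
averaging sub-population statistics.

Candidate extraction is deliberately inclusive (any single non-reference
read or indel event makes a position a candidate); all stringency lives in
the entropy filter and the population statistics. On low-coverage data
this step typically discards the overwhelming all-reference majority of
positions.

## Worked example

Simulate 20 diploid samples at 4× over a 2 kb genome with three planted
variants — a fixed substitution, a 30%-frequency SNV, and an 80%-frequency
insertion — then run the full pipeline with two 10-sample populations and
their union:

```bash
dynaref simulate --seed 11 --n-samples 20 --length 2000 --coverage 4 \
    --error-rate 0.002 --snv chr1:500:C:1.0 --snv chr1:900:A:0.3 \
    --indel chr1:1200:ins:GT:0.8 --out demo/sim

dynaref run --pileup demo/sim/samples.pileup \
    --reference demo/sim/reference.fa --manifest demo/sim/manifest.txt \
    --population N=S000,...,S009 --population S=S010,...,S019 \
    --union NS=N+S --out demo/run
```

The run reports `298 CDPs / 2000 positions; dynamic: {'N': 3, 'S': 3,
'NS': 3}`: sequencing errors make ~15% of positions *candidates*, but the
entropy filter and population statistics reduce them to exactly the three
planted sites. `demo/run/dynamic_NS.tsv` contains:

```
chrom  pos   ref  population  categories    major  major_prob    n_covered  ...
chr1   500   T    NS          MAJOR_DIFF    C      1             16
chr1   900   G    NS          MINOR_COMMON  G      0.7647058824  17   A:0.2352941176
chr1   1200  G    NS          INDEL_HIGH    G      1             19   insertion:GT:19:1
```

The fixed difference is a major-allele difference with probability 1; the
30% allele is a common minor at an estimated 24% of covered samples; the
insertion is supported by all 19 covered samples. The MAIR table holds the
two consensus-changing edits (the substitution and the insertion), and
`vcg_NS.fa` is the 2002 bp consensus with `liftover_NS.tsv` mapping
reference coordinates onto it.

Each stage is also available separately (`extract`, `stats`, `consensus`,
`summarize`, `compare`), consuming the previous stage's files, and the
whole pipeline is importable as a library (`dynaref.cli.run_pipeline`).

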