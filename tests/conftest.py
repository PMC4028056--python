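import io

import pytest

from dynaref import (PileupColumn, SampleCall, SimulationConfig, SnvSpec,
                     simulate)


@pytest.fixture
def toy_reference():
    return {"chr1": "ACGTACGTACGTACGTACGT", "chr2": "TTTTACGTACGTACGT"}


@pytest.fixture
def small_sim():
    """Error-free 3-sample simulation with one fixed difference."""
    config = SimulationConfig(
        seed=7, n_samples=3, coverage_lambda=4.0, error_rate=0.0,
        reference={"chr1": "ACGTACGTAC"}, snvs=(SnvSpec("chr1", 5, "G", 1.0),),
    )
    return simulate(config)


def make_column(chrom, pos, ref, sample_counts, insertions=None,
                deletions=None):
    """Build a PileupColumn from per-sample count dicts (test helper)."""
    samples = []
    for i, counts in enumerate(sample_counts):
        samples.append(SampleCall(
            depth=sum(counts.values()),
            base_counts=dict(counts),
            insertions=list((insertions or {}).get(i, [])),
            deletions=list((deletions or {}).get(i, [])),
        ))
    return PileupColumn(chrom=chrom, pos=pos, ref_base=ref, samples=samples)
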