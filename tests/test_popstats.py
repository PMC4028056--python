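"""Equal-weight population statistics and the four-circumstance
classification."""

import io

import pytest

from dynaref import (CDPKey, CDPRecord, ClassificationConfig,
                     ConfigurationError, SampleCall,
                     classify, collect_units, compute_mair, extract_rare,
                     population_stats, read_dynamic_tsv, write_dynamic_tsv,
                     write_dynamic_vcf)
from dynaref.popstats import (INDEL_HIGH, MAJOR_DIFF, MINOR_COMMON, RARE,
                              IndelEvent, PopulationStats)


def make_record(ref, per_sample_counts, insertions=None, deletions=None):
    calls = []
    for i, counts in enumerate(per_sample_counts):
        calls.append(SampleCall(
            depth=sum(counts.values()), base_counts=dict(counts),
            insertions=list((insertions or {}).get(i, [])),
            deletions=list((deletions or {}).get(i, [])),
        ))
    return CDPRecord(key=CDPKey("chr1", 42), ref_base=ref,
                     sample_evidence=calls)


def stats_for(record, manifest, population=None, pop_id="POP"):
    units = collect_units(record, manifest)
    return population_stats(record, units, population or manifest, manifest,
                            population_id=pop_id)


def make_stats(votes, ref="A", indels=(), n_covered=None):
    """Directly assemble PopulationStats from a vote distribution."""
    n = n_covered or sum(votes.values())
    top = max(votes.values())
    tied = sorted(k for k, v in votes.items() if v == top)
    major = ref if ref in tied else tied[0]
    fracs = {k: v / n for k, v in votes.items()}
    from dynaref import comentropy
    return PopulationStats(
        chrom="chr1", pos=42, ref_base=ref, population_id="POP",
        n_covered=n, dominant_votes=dict(votes), pooled_counts={},
        major_allele=major, major_prob=fracs[major],
        minor_freqs={k: f for k, f in fracs.items() if k != major},
        pop_comentropy=comentropy(list(fracs.values())),
        indel_events=list(indels),
    )


def test_dominant_vote_ratios():
    """10 samples, 8 vote A and 2 vote G: major A at 0.8, minor G at 0.2."""
    counts = [{"A": 3}] * 8 + [{"G": 4}] * 2
    record = make_record("A", counts)
    manifest = [f"s{i}" for i in range(10)]
    stats = stats_for(record, manifest)
    assert stats.n_covered == 10
    assert stats.major_allele == "A" and stats.major_prob == 0.8
    assert stats.minor_freqs == {"G": 0.2}
    assert sum(stats.minor_freqs.values()) + stats.major_prob == pytest.approx(1.0)


def test_equal_weighting_ignores_depth():
    """Scaling one sample's reads tenfold changes nothing downstream."""
    manifest = ["a", "b", "c"]
    rec1 = make_record("A", [{"A": 2}, {"A": 3}, {"G": 2}])
    rec2 = make_record("A", [{"A": 20}, {"A": 3}, {"G": 20}])
    s1, s2 = stats_for(rec1, manifest), stats_for(rec2, manifest)
    assert s1.dominant_votes == s2.dominant_votes
    assert s1.major_prob == s2.major_prob
    assert s1.minor_freqs == s2.minor_freqs


def test_unestimable_position_returns_none():
    """All units failing the filter leaves the position unestimable."""
    record = make_record("A", [{"A": 1, "G": 1}, {"C": 1}])
    assert stats_for(record, ["a", "b"]) is None


def test_union_population_equals_concatenated_manifest():
    """Pooled-union statistics come from the pooled sample set."""
    counts = [{"A": 3}] * 4 + [{"G": 3}] * 2 + [{"A": 4}] * 3 + [{"G": 5}] * 1
    manifest = [f"s{i}" for i in range(10)]
    record = make_record("A", counts)
    chb, chs = manifest[:6], manifest[6:]
    union = stats_for(record, manifest, chb + chs, pop_id="CHN")
    direct = stats_for(record, manifest, manifest, pop_id="CHN")
    assert union.dominant_votes == direct.dominant_votes
    assert union.major_prob == direct.major_prob


def test_unknown_population_sample_is_configuration_error():
    record = make_record("A", [{"A": 2}])
    units = collect_units(record, ["a"])
    with pytest.raises(ConfigurationError):
        population_stats(record, units, ["ghost"], ["a"])


def test_indel_population_probability_uses_covered_denominator():
    counts = [{"A": 3}] * 4
    record = make_record("A", counts, insertions={0: [("AG", 1)],
                                                  1: [("AG", 2)]})
    stats = stats_for(record, ["a", "b", "c", "d"])
    [event] = stats.indel_events
    # sample-presence support: two samples carry the event, reads irrelevant
    assert event.support_samples == 2 and event.population_prob == 0.5


# --- classification ---------------------------------------------------------

def test_circumstance_one_major_diff():
    dp = classify(make_stats({"G": 10}, ref="A"))
    assert dp.categories == {MAJOR_DIFF} and dp.in_mair


def test_circumstance_four_rare():
    dp = classify(make_stats({"A": 96, "G": 4}, ref="A"))
    assert dp.categories == {RARE} and not dp.in_mair
    assert dp.rare_alleles == {"G": 0.04}


def test_circumstance_three_minor_common():
    dp = classify(make_stats({"A": 90, "G": 10}, ref="A"))
    assert dp.categories == {MINOR_COMMON}
    assert dp.common_minor_alleles == {"G": 0.10}


def test_circumstance_two_indel_high():
    ev = IndelEvent("chr1", 42, "deletion", 2, 6, 0.6)
    dp = classify(make_stats({"A": 10}, ref="A", indels=[ev]))
    assert dp.categories == {INDEL_HIGH} and dp.in_mair


def test_five_percent_boundary_belongs_to_rare():
    dp = classify(make_stats({"A": 95, "G": 5}, ref="A"))
    assert dp.categories == {RARE}


def test_indel_fifty_percent_boundary_is_inclusive():
    ev = IndelEvent("chr1", 42, "insertion", "T", 50, 0.50)
    dp = classify(make_stats({"A": 100}, ref="A", indels=[ev]))
    assert INDEL_HIGH in dp.categories
    low = IndelEvent("chr1", 42, "insertion", "T", 49, 0.49)
    assert classify(make_stats({"A": 100}, ref="A", indels=[low])) is None


def test_static_position_returns_none():
    assert classify(make_stats({"A": 10}, ref="A")) is None


def test_n_reference_never_dynamic():
    assert classify(make_stats({"G": 10}, ref="N")) is None


def test_categories_co_occur():
    ev = IndelEvent("chr1", 42, "deletion", 1, 60, 0.6)
    dp = classify(make_stats({"G": 90, "C": 6, "T": 4}, ref="A", indels=[ev]))
    assert dp.categories == {MAJOR_DIFF, INDEL_HIGH, MINOR_COMMON, RARE}


def test_partition_sanity():
    """Frequencies referenced by each category satisfy its inequalities."""
    config = ClassificationConfig()
    dp = classify(make_stats({"A": 80, "G": 12, "C": 5, "T": 3}, ref="A"),
                  config=config)
    assert all(f > config.minor_min for f in dp.common_minor_alleles.values())
    assert all(0 < f <= config.rare_max for f in dp.rare_alleles.values())


def test_extract_rare_and_mair_tables():
    dps = [
        classify(make_stats({"A": 97, "G": 3}, ref="A")),
        classify(make_stats({"G": 10}, ref="A")),
    ]
    rare = extract_rare(dps)
    assert len(rare) == 1
    assert rare.loc[0, "allele"] == "G"
    assert rare.loc[0, "frequency"] == pytest.approx(0.03)
    mair = compute_mair(dps)
    assert len(mair) == 1 and mair[0].kind == "substitution"
    assert mair[0].payload == "G"


def test_extract_rare_empty():
    assert extract_rare([]).empty


def test_mair_subset_of_dynamic():
    dps = [classify(make_stats({"G": 10}, ref="A")),
           classify(make_stats({"A": 96, "G": 4}, ref="A"))]
    mair = compute_mair(dps)
    keys = {(d.chrom, d.pos) for d in dps}
    assert all((e.chrom, e.pos) in keys for e in mair)


def test_dynamic_tsv_round_trip(tmp_path):
    ev = IndelEvent("chr1", 42, "deletion", 2, 6, 0.6)
    dps = [classify(make_stats({"G": 90, "C": 10}, ref="A", indels=[ev]))]
    path = tmp_path / "dyn.tsv"
    write_dynamic_tsv(dps, path)
    back = read_dynamic_tsv(path)
    assert len(back) == 1
    b = back[0]
    assert b.categories == dps[0].categories
    assert b.major_prob == pytest.approx(dps[0].major_prob)
    assert b.high_indels[0].payload == 2
    assert b.high_indels[0].kind == "deletion"


def test_vcf_export_structure(tmp_path):
    ref = {"chr1": "A" * 50}
    ev = IndelEvent("chr1", 42, "insertion", "TT", 60, 0.6)
    dps = [classify(make_stats({"G": 10}, ref="A")),
           classify(make_stats({"A": 10}, ref="A", indels=[ev]))]
    buf = io.StringIO()
    write_dynamic_vcf(dps, buf, ref)
    lines = buf.getvalue().splitlines()
    assert lines[0] == "##fileformat=VCFv4.2"
    data = [l for l in lines if not l.startswith("#")]
    assert any("\tA\tG\t" in l and "CAT=MAJOR_DIFF" in l for l in data)
    assert any("\tA\tATT\t" in l for l in data)  # anchor-base insertion
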