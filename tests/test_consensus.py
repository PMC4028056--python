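"""Consensus construction, conflict resolution, and liftover."""

import numpy as np
import pytest

from dynaref import (BoundsError, LiftoverMap, MairEdit, build_vcg, liftover,
                     resolve_conflicts)

# ---------------------------------------------------------------------------
# naive string-rewriting oracle, independent of the implementation

def naive_apply(seq, edits):
    """Rewrite the sequence position by position; also return the oracle
    reference->consensus map (None for deleted positions)."""
    out_for = ["" for _ in range(len(seq) + 1)]   # emitted text per ref pos
    post = ["" for _ in range(len(seq) + 1)]      # insertion after ref pos
    deleted = set()
    for e in edits:
        if e.kind == "substitution":
            out_for[e.pos] = str(e.payload).upper()
        elif e.kind == "insertion":
            post[e.pos] += str(e.payload).upper()
        else:
            deleted.update(range(e.pos + 1, e.pos + 1 + int(e.payload)))
    pieces = []
    mapping = {}
    emitted = 0
    for p in range(1, len(seq) + 1):
        if p in deleted:
            mapping[p] = None
        else:
            piece = out_for[p] or seq[p - 1]
            pieces.append(piece)
            emitted += len(piece)
            mapping[p] = emitted
        pieces.append(post[p])
        emitted += len(post[p])
    return "".join(pieces), mapping


def rng_edit_set(rng, length, n_edits, max_indel=5):
    """Random non-conflicting edit set over a toy chromosome."""
    positions = sorted(
        rng.choice(np.arange(1, length - max_indel - 1, max_indel + 2),
                   size=n_edits, replace=False)
    )
    edits = []
    for pos in positions:
        kind = rng.choice(["substitution", "insertion", "deletion"])
        if kind == "substitution":
            payload = "ACGT"[rng.integers(4)]
        elif kind == "insertion":
            payload = "".join(rng.choice(list("ACGT"),
                                         size=rng.integers(1, max_indel + 1)))
        else:
            payload = int(rng.integers(1, max_indel + 1))
        edits.append(MairEdit("chr1", int(pos), kind, payload,
                              float(rng.random())))
    return edits


def test_no_edits_is_identity(toy_reference):
    cons, lmap, report = build_vcg(toy_reference, [])
    assert cons == toy_reference
    assert report.applied == [] and report.dropped == []
    for chrom, seq in toy_reference.items():
        for p in (1, len(seq) // 2, len(seq)):
            assert lmap.to_consensus(chrom, p) == p


def test_worked_example():
    ref = {"chr1": "ACGTACGT"}
    edits = [MairEdit("chr1", 3, "substitution", "T"),
             MairEdit("chr1", 5, "insertion", "AA"),
             MairEdit("chr1", 6, "deletion", 1)]
    cons, lmap, _ = build_vcg(ref, edits)
    assert cons["chr1"] == "ACTTAAACT"
    assert len(cons["chr1"]) == 8 + 2 - 1
    assert lmap.to_consensus("chr1", 8) == 9
    assert lmap.to_consensus("chr1", 7) is None  # deleted base
    assert liftover("chr1", 8, lmap) == 9


def test_insertion_shifts_downstream_positions():
    ref = {"c": "ACGTACGT"}
    cons, lmap, _ = build_vcg(ref, [MairEdit("c", 3, "insertion", "TT")])
    assert lmap.to_consensus("c", 3) == 3
    assert lmap.to_consensus("c", 4) == 6
    assert lmap.to_reference("c", 6) == 4
    assert lmap.to_reference("c", 4) is None  # inserted base has no image


def test_substitution_payload_equal_reference_is_rejected(toy_reference):
    edits = [MairEdit("chr1", 1, "substitution", "A")]  # ref base is A
    cons, _, report = build_vcg(toy_reference, edits)
    assert cons == toy_reference
    assert report.applied == []
    [(dropped, reason)] = report.dropped
    assert "reference" in reason


@pytest.mark.parametrize(
    "edit",
    [MairEdit("chr1", 0, "substitution", "T"),
     MairEdit("chr1", 99, "substitution", "T"),
     MairEdit("chr1", 19, "deletion", 5),
     MairEdit("nope", 1, "substitution", "T")],
)
def test_bounds_errors(toy_reference, edit):
    with pytest.raises(BoundsError):
        build_vcg(toy_reference, [edit])


def test_conflict_resolution_rules():
    disjoint = [MairEdit("c", 2, "substitution", "T", 0.9),
                MairEdit("c", 8, "insertion", "GG", 0.3)]
    kept, dropped = resolve_conflicts(disjoint)
    assert len(kept) == 2 and not dropped

    spanning = [MairEdit("c", 5, "deletion", 3, 0.9),
                MairEdit("c", 7, "substitution", "T", 0.6)]
    kept, dropped = resolve_conflicts(spanning)
    assert [e.kind for e in kept] == ["deletion"]
    assert dropped[0][0].kind == "substitution"

    # equal probability, same anchor: deterministic, stable across runs
    twins = [MairEdit("c", 5, "insertion", "AA", 0.5),
             MairEdit("c", 5, "insertion", "GG", 0.5)]
    results = {tuple(e.payload for e in resolve_conflicts(twins)[0])
               for _ in range(5)}
    assert results == {("AA",)}  # first in input order wins


def test_substitution_and_insertion_share_an_anchor():
    ref = {"c": "ACGT"}
    cons, _, report = build_vcg(ref, [
        MairEdit("c", 2, "substitution", "G", 0.9),
        MairEdit("c", 2, "insertion", "TT", 0.8)])
    assert cons["c"] == "AGTTGT"
    assert len(report.applied) == 2


def test_random_edit_sets_match_naive_oracle():
    rng = np.random.default_rng(42)
    for _ in range(50):
        length = 200
        seq = "".join(rng.choice(list("ACGT"), size=length))
        edits = rng_edit_set(rng, length, n_edits=8)
        cons, lmap, report = build_vcg({"chr1": seq}, edits)
        applied = report.applied
        expected, mapping = naive_apply(seq, applied)
        assert cons["chr1"] == expected
        got = lmap.to_consensus_array("chr1", np.arange(1, length + 1))
        want = np.array([-1 if mapping[p] is None else mapping[p]
                         for p in range(1, length + 1)])
        assert np.array_equal(got, want)


def test_length_conservation_and_round_trip():
    rng = np.random.default_rng(9)
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        edits = rng_edit_set(rng, 300, n_edits=10)
        cons, lmap, report = build_vcg({"chr1": seq}, edits)
        net = sum(len(e.payload) if e.kind == "insertion"
                  else -int(e.payload) if e.kind == "deletion" else 0
                  for e in report.applied)
        assert len(cons["chr1"]) == len(seq) + net
        fwd = lmap.to_consensus_array("chr1", np.arange(1, 301))
        kept = fwd >= 0
        back = lmap.to_reference_array("chr1", fwd[kept])
        assert np.array_equal(back, np.arange(1, 301)[kept])


def test_idempotence_empty_mair(toy_reference):
    cons, _, _ = build_vcg(toy_reference, [])
    assert cons == toy_reference


def test_liftover_tsv_round_trip(tmp_path):
    ref = {"c": "ACGTACGTAC"}
    _, lmap, _ = build_vcg(ref, [MairEdit("c", 3, "insertion", "TT"),
                                 MairEdit("c", 6, "deletion", 2)])
    path = tmp_path / "lift.tsv"
    lmap.write_tsv(path)
    back = LiftoverMap.read_tsv(path)
    for p in range(1, 11):
        assert back.to_consensus("c", p) == lmap.to_consensus("c", p)
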