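"""Edit algebra, dataset parsing, antisymmetric augmentation, filtering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddgraph.records import (
    AMINO_ACIDS,
    Dataset,
    Edit,
    EditError,
    MutationRecord,
    apply_edits,
    augment_antisymmetric,
    edits_to_notation,
    filter_records,
    invert_edits,
    invert_record,
    parse_dataset,
    parse_edit_notation,
    sequence_identity,
    split_by_identity,
)

AA = list(AMINO_ACIDS)


# ---------------------------------------------------------------------------
# notation and application
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "notation,wild,expected_mut",
    [
        ("A2G", "CAD", "CGD"),
        ("A2G:D3K", "CAD", "CGK"),
        ("C2del", "ACD", "AD"),
        ("C2_D3del", "ACDEF", "AEF"),
        ("2insGG", "ACDEF", "ACGGDEF"),
        ("0insWW", "ACD", "WWACD"),
        ("A1C:3insY:F5del", "ACDEF", "CCDYE"),
    ],
)
def test_notation_round_trip_through_application(notation, wild, expected_mut):
    edits = parse_edit_notation(notation, wild)
    assert apply_edits(wild, edits) == expected_mut


def test_single_substitution_token_fields():
    (e,) = parse_edit_notation("A2G", "CAD")
    assert (e.kind, e.position, e.wild_span, e.mut_span) == ("substitution", 1, "A", "G")


@pytest.mark.parametrize(
    "notation,wild",
    [
        ("A2G", "CCD"),  # wild letter mismatch
        ("A9G", "CAD"),  # out of range
        ("Q5xx", "QQQQQ"),  # bad token
        ("C2del:C2del", "ACD"),  # overlapping
    ],
)
def test_bad_notation_raises(notation, wild):
    with pytest.raises(EditError):
        parse_edit_notation(notation, wild)


def test_apply_edits_length_bookkeeping_examples():
    assert apply_edits("ACDEF", [Edit("substitution", 2, "D", "K")]) == "ACKEF"
    assert apply_edits("ACDEF", [Edit("deletion", 1, wild_span="CD")]) == "AEF"
    out = apply_edits("ACDEF", [Edit("insertion", 1, mut_span="GG")])
    assert out == "ACGGDEF" and len(out) == 5 + 2


def test_overlapping_edits_rejected():
    with pytest.raises(EditError):
        apply_edits("ACDEF", [Edit("deletion", 1, wild_span="CD"), Edit("substitution", 2, "D", "K")])


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------


def _random_edits(seq, rng):
    kind = rng.integers(0, 3)
    n = len(seq)
    if kind == 0:
        k = int(rng.integers(1, 4))
        positions = sorted(rng.choice(n, size=min(k, n), replace=False).tolist())
        return [
            Edit("substitution", p, seq[p], AA[(AA.index(seq[p]) + 1) % 20]) for p in positions
        ]
    if kind == 1:
        span = "".join(rng.choice(AA, size=int(rng.integers(1, 4))))
        return [Edit("insertion", int(rng.integers(-1, n)), mut_span=span)]
    k = int(rng.integers(1, min(4, n - 1)))
    start = int(rng.integers(0, n - k + 1))
    return [Edit("deletion", start, wild_span=seq[start : start + k])]


def test_invert_record_negates_and_swaps():
    r = MutationRecord("p", "AC", "AG", 1.5, edits=[Edit("substitution", 1, "C", "G")])
    ri = invert_record(r)
    assert (ri.wild_seq, ri.mut_seq, ri.ddg, ri.direction) == ("AG", "AC", -1.5, "inverse")


def test_inverting_insertion_yields_matching_deletion():
    r = MutationRecord(
        "p", "ACDEF", "ACGGDEF", 0.3, edits=[Edit("insertion", 1, mut_span="GG")]
    )
    ri = invert_record(r)
    assert ri.edits[0].kind == "deletion"
    assert ri.edits[0].wild_span == "GG"
    assert apply_edits(ri.wild_seq, ri.edits) == r.wild_seq


def test_invert_is_involution_on_random_records(rng):
    for _ in range(200):
        n = int(rng.integers(5, 30))
        seq = "".join(rng.choice(AA, size=n))
        edits = _random_edits(seq, rng)
        mut = apply_edits(seq, edits)
        r = MutationRecord("p", seq, mut, float(rng.normal()), edits=edits)
        rr = invert_record(invert_record(r))
        assert rr == r
        # applying inverse edits to the mutant recovers the wild exactly
        assert apply_edits(mut, invert_edits(edits)) == seq


def test_notation_serialisation_round_trips(rng):
    for _ in range(100):
        n = int(rng.integers(5, 25))
        seq = "".join(rng.choice(AA, size=n))
        edits = _random_edits(seq, rng)
        notation = edits_to_notation(edits)
        assert parse_edit_notation(notation, seq) == sorted(
            edits, key=lambda e: (e.position, 1 if e.kind == "insertion" else 0)
        )


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _toy_dataset(ddgs):
    recs = [
        MutationRecord("p", "ACDEF", "AC" + a + "EF", g)
        for a, g in zip("KLMNPQRSTVWY", ddgs)
    ]
    return Dataset(records=recs)


def test_augment_doubles_and_sums_to_zero():
    d = augment_antisymmetric(_toy_dataset([1.0, -0.5, 2.0]))
    assert len(d) == 6
    assert math.fsum(r.ddg for r in d.records) == 0.0


def test_augment_empty_dataset():
    assert len(augment_antisymmetric(Dataset())) == 0


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=12))
def test_augment_mean_ddg_zero_property(ddgs):
    d = augment_antisymmetric(_toy_dataset(ddgs[:12]))
    assert abs(np.mean([r.ddg for r in d.records])) < 1e-12
    assert len(d) == 2 * len(ddgs[:12])


def test_augment_rejects_already_augmented():
    d = augment_antisymmetric(_toy_dataset([1.0]))
    with pytest.raises(ValueError):
        augment_antisymmetric(d)


# ---------------------------------------------------------------------------
# parsing and filtering
# ---------------------------------------------------------------------------


def test_parse_dataset_with_explicit_mutant(tmp_path):
    f = tmp_path / "d.csv"
    f.write_text(
        "protein_id,wt_seq,mut_seq,ddG,reliable\n"
        "p1,ACDEF,ACKEF,1.2,true\n"
        "p1,ACDEF,AEF,-0.4,true\n"
        "p2,GHIKL,GHIKLM,0.0,false\n"
    )
    d = parse_dataset(f)
    assert len(d) == 3 and not d.row_errors
    assert d.records[1].mut_seq == "AEF"
    assert d.records[2].reliable is False


def test_parse_dataset_bad_ddg_reports_row_number(tmp_path):
    f = tmp_path / "d.csv"
    f.write_text("protein_id,wt_seq,mut_seq,ddG\np1,ACDEF,ACKEF,abc\np1,ACDEF,ACLEF,1.0\n")
    d = parse_dataset(f)
    assert len(d) == 1
    assert len(d.row_errors) == 1
    assert d.row_errors[0][0] == 2  # first data line, counting the header as line 1


def test_parse_dataset_via_notation_matches_apply(tmp_path):
    f = tmp_path / "d.csv"
    f.write_text("protein_id,wt_seq,mutation,ddG\np1,CAD,A2G,0.7\n")
    d = parse_dataset(f)
    assert d.records[0].mut_seq == apply_edits("CAD", parse_edit_notation("A2G", "CAD"))


def test_parse_dataset_missing_column_raises(tmp_path):
    f = tmp_path / "d.csv"
    f.write_text("protein_id,wt_seq,ddG\np1,ACDEF,1.0\n")
    with pytest.raises(KeyError):
        parse_dataset(f)


def test_filter_unreliable_and_nonstandard():
    recs = [
        MutationRecord("p", "ACDEF", "ACKEF", 1.0, reliable=True),
        MutationRecord("p", "ACDEF", "ACLEF", 1.0, reliable=False),
        MutationRecord("p", "ACDEF", "ACMEF", 1.0, reliable=False),
    ]
    # non-standard letters cannot be built via the validating constructor
    bad = MutationRecord("p", "ACDEF", "ACKEF", 1.0)
    bad.wild_seq = "ACXEF"
    d, report = filter_records(Dataset(records=recs + [bad]))
    assert len(d) == 1
    assert report == {"unreliable": 2, "nonstandard": 1, "too_long": 0}


def test_filter_clean_input_is_identity(small_corpus):
    d = Dataset(records=[r.record for r in small_corpus])
    out, report = filter_records(d)
    assert len(out) == len(d) and sum(report.values()) == 0


# ---------------------------------------------------------------------------
# sequence identity
# ---------------------------------------------------------------------------


def test_identity_basic_values():
    assert sequence_identity("ACD", "ACD") == 100.0
    assert sequence_identity("ACD", "ACE") == pytest.approx(200 / 3, abs=0.05)
    assert sequence_identity("A", "G") == 0.0


def test_identity_symmetric(rng):
    for _ in range(20):
        a = "".join(rng.choice(AA, size=int(rng.integers(5, 40))))
        b = "".join(rng.choice(AA, size=int(rng.integers(5, 40))))
        assert sequence_identity(a, b) == pytest.approx(sequence_identity(b, a), abs=1e-9)


def test_split_by_identity_excludes_identical_and_keeps_random(rng):
    train_seqs = ["".join(rng.choice(AA, size=50)) for _ in range(3)]
    train = Dataset(records=[MutationRecord("t", s, s[:-1] + "A" if s[-1] != "A" else s[:-1] + "C", 0.0) for s in train_seqs])
    test_recs = [MutationRecord("x", train_seqs[0], train_seqs[0][:-1] + ("C" if train_seqs[0][-1] != "C" else "D"), 0.0)]
    test_recs += [
        MutationRecord(f"r{i}", "".join(rng.choice(AA, size=50)), "".join(rng.choice(AA, size=50)), 0.0)
        for i in range(5)
    ]
    kept = split_by_identity(train, Dataset(records=test_recs), threshold=25.0)
    kept_ids = {r.protein_id for r in kept.records}
    assert "x" not in kept_ids  # identical wild sequence excluded
    assert len(kept_ids) == 5  # unrelated random sequences retained
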