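"""Exactness, determinism and construction invariants of the generator."""

import numpy as np
import pytest

from ddgraph.graphs import ContactMap
from ddgraph.records import AMINO_ACIDS, Edit, apply_edits
from ddgraph.synthetic import (
    SyntheticEnergyModel,
    augment_samples,
    build_samples,
    generate_dataset,
    generate_protein,
    mutate_contacts,
    true_energy,
    write_corpus,
)

AA_IDX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def brute_force_energy(seq, cm, m):
    e = sum(m.singleton_term[AA_IDX[a]] for a in seq)
    for i in range(len(seq)):
        for j in range(i + 1, len(seq)):
            if cm.probs[i, j] >= m.cutoff:
                e += cm.probs[i, j] * m.pair_term[AA_IDX[seq[i]], AA_IDX[seq[j]]]
    return e


# ---------------------------------------------------------------------------
# proteins and energies
# ---------------------------------------------------------------------------


def test_generate_protein_shape_and_determinism():
    seq, cm = generate_protein(5, seed=11)
    assert len(seq) == 5 and cm.n == 5
    assert np.array_equal(cm.probs, cm.probs.T)
    assert np.all(np.diag(cm.probs) == 0)
    seq2, cm2 = generate_protein(5, seed=11)
    assert seq == seq2 and np.array_equal(cm.probs, cm2.probs)


def test_backbone_band_survives_default_cutoff():
    _, cm = generate_protein(30, seed=1)
    band = np.diag(cm.probs, k=1)
    assert np.all(band >= 0.1)


def test_true_energy_zero_tables():
    m = SyntheticEnergyModel(np.zeros((20, 20)), np.zeros(20))
    seq, cm = generate_protein(10, seed=2)
    assert true_energy(seq, cm, m) == 0.0


def test_true_energy_two_residue_hand_sum():
    pair = np.zeros((20, 20))
    ia, ic = AA_IDX["A"], AA_IDX["C"]
    pair[ia, ic] = pair[ic, ia] = 2.0
    singleton = np.zeros(20)
    singleton[ia], singleton[ic] = 1.0, -1.0
    m = SyntheticEnergyModel(pair, singleton)
    cm = ContactMap(np.array([[0.0, 0.5], [0.5, 0.0]]))
    assert true_energy("AC", cm, m) == pytest.approx(0.5 * 2.0 + 1.0 - 1.0)


def test_true_energy_matches_brute_force(rng, energy_model):
    for _ in range(100):
        n = int(rng.integers(5, 25))
        seq, cm = generate_protein(n, seed=int(rng.integers(0, 2**31)))
        assert true_energy(seq, cm, energy_model) == pytest.approx(
            brute_force_energy(seq, cm, energy_model), abs=1e-12
        )


# ---------------------------------------------------------------------------
# mutant contact maps
# ---------------------------------------------------------------------------


def test_substitution_keeps_map():
    _, cm = generate_protein(12, seed=3)
    out = mutate_contacts(cm, [Edit("substitution", 4, "A", "C")])
    assert np.array_equal(out.probs, cm.probs)


def test_deletion_removes_rows_and_columns():
    _, cm = generate_protein(12, seed=4)
    out = mutate_contacts(cm, [Edit("deletion", 3, wild_span="AAA")])
    assert out.n == 9
    keep = [i for i in range(12) if i not in (3, 4, 5)]
    assert np.array_equal(out.probs, cm.probs[np.ix_(keep, keep)])


def test_insertion_grows_map_with_backbone_contacts():
    _, cm = generate_protein(10, seed=5)
    out = mutate_contacts(cm, [Edit("insertion", 2, mut_span="WW")])
    assert out.n == 12
    assert np.array_equal(out.probs, out.probs.T)
    assert np.all(np.diag(out.probs) == 0)
    # inserted rows 3 and 4 carry backbone contacts only
    assert out.probs[3, 4] == 0.9 and out.probs[2, 3] == 0.9 and out.probs[4, 5] == 0.9
    inserted = out.probs[[3, 4]].copy()
    inserted[0, [2, 4]] = 0
    inserted[1, [3, 5]] = 0
    assert np.all(inserted == 0)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def test_labels_are_exact(small_corpus, energy_model):
    for sr in small_corpus:
        e_w = true_energy(sr.record.wild_seq, sr.wild_cm, energy_model)
        e_m = true_energy(sr.record.mut_seq, sr.mut_cm, energy_model)
        assert sr.record.ddg == pytest.approx(e_m - e_w, abs=1e-12)
        assert apply_edits(sr.record.wild_seq, sr.record.edits) == sr.record.mut_seq


def test_singleton_only_ddg_closed_form():
    m = SyntheticEnergyModel.random(seed=5, pair_scale=0.0)
    recs = generate_dataset(60, edit_profile=(0.5, 0.5, 0.0, 0.0), model=m, seed=5)
    for sr in recs:
        expected = sum(
            m.singleton_term[AA_IDX[e.mut_span]] - m.singleton_term[AA_IDX[e.wild_span]]
            for e in sr.record.edits
        )
        assert sr.record.ddg == pytest.approx(expected, abs=1e-12)


def test_profile_all_substitutions():
    recs = generate_dataset(50, edit_profile=(1.0, 0.0, 0.0, 0.0), seed=1)
    assert all(
        len(sr.record.edits) == 1 and sr.record.edits[0].kind == "substitution" for sr in recs
    )


def test_edit_type_fractions_follow_profile():
    profile = (0.4, 0.2, 0.2, 0.2)
    recs = generate_dataset(4000, edit_profile=profile, seed=9)
    kinds = []
    for sr in recs:
        e = sr.record.edits
        if all(x.kind == "substitution" for x in e):
            kinds.append(0 if len(e) == 1 else 1)
        elif e[0].kind == "insertion":
            kinds.append(2)
        else:
            kinds.append(3)
    fractions = np.bincount(kinds, minlength=4) / len(kinds)
    assert fractions == pytest.approx(profile, abs=0.05)


def test_augmented_samples_keep_exactness_and_pairing(small_corpus):
    samples = augment_samples(build_samples(small_corpus))
    assert len(samples) == 2 * len(small_corpus)
    direct = {s.pair_id: s for s in samples if s.direction == "direct"}
    inverse = {s.pair_id: s for s in samples if s.direction == "inverse"}
    for k, s in direct.items():
        assert inverse[k].ddg == -s.ddg
        assert inverse[k].wild is s.mut and inverse[k].mut is s.wild


def test_corpus_serialization_is_byte_deterministic(tmp_path, energy_model):
    recs = generate_dataset(30, model=energy_model, seed=13, n_proteins=5)
    write_corpus(recs, tmp_path / "a", energy_model)
    recs2 = generate_dataset(30, model=energy_model, seed=13, n_proteins=5)
    write_corpus(recs2, tmp_path / "b", energy_model)
    a = (tmp_path / "a" / "dataset.csv").read_bytes()
    assert a == (tmp_path / "b" / "dataset.csv").read_bytes()
    for f in sorted((tmp_path / "a" / "contacts").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / "contacts" / f.name).read_bytes()
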