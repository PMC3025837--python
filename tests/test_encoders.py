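"""Encoder correctness against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secpred.encoders import (
    ATCHLEY_FACTORS,
    CANONICAL_FEATURES,
    FEATURE_DIMS,
    combine,
    encode_composition,
    encode_dipeptide,
    encode_factors,
    encode_pssm,
    encode_record,
    factor_table,
    read_libsvm,
    write_libsvm,
)
from secpred.sequences import ALPHABET, NCBI_ORDER, PSSMProfile, SequenceRecord
from secpred.simulate import generate_pssm

residue_text = st.text(alphabet=ALPHABET, min_size=2, max_size=100)


def record_of(residues, rid="t"):
    return SequenceRecord(id=rid, residues=residues)


# --- independent oracles (plain python tallies, no numpy vectorisation) ----

def oracle_composition(seq):
    return [seq.count(a) / len(seq) for a in ALPHABET]


def oracle_dipeptide(seq):
    out = []
    for a in ALPHABET:
        for b in ALPHABET:
            count = sum(
                1 for i in range(len(seq) - 1) if seq[i] == a and seq[i + 1] == b
            )
            out.append(count / (len(seq) - 1))
    return out


def oracle_factors(seq):
    out = []
    for a in ALPHABET:
        comp = seq.count(a) / len(seq)
        for f in range(5):
            out.append(comp * ATCHLEY_FACTORS[a][f])
    return out


def oracle_pssm(seq, scores):
    out = []
    for a in NCBI_ORDER:
        for j in range(20):
            total = sum(scores[i][j] for i in range(len(seq)) if seq[i] == a)
            out.append(1.0 / (1.0 + math.exp(-total / len(seq))))
    return out


class TestComposition:
    def test_single_letter(self):
        v = encode_composition(record_of("AAAA"))
        assert v.values[ALPHABET.index("A")] == 1.0
        assert v.values.sum() == pytest.approx(1.0)
        assert np.count_nonzero(v.values) == 1

    def test_four_distinct(self):
        v = encode_composition(record_of("ACDE"))
        expected = np.zeros(20)
        for a in "ACDE":
            expected[ALPHABET.index(a)] = 0.25
        np.testing.assert_allclose(v.values, expected)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(residues=residue_text)
    def test_matches_oracle_and_sums_to_one(self, residues):
        v = encode_composition(record_of(residues))
        np.testing.assert_allclose(v.values, oracle_composition(residues), atol=1e-12)
        assert v.values.sum() == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(residues=residue_text)
    def test_permutation_invariant(self, residues):
        shuffled = "".join(sorted(residues))
        np.testing.assert_allclose(
            encode_composition(record_of(residues)).values,
            encode_composition(record_of(shuffled)).values,
        )


class TestDipeptide:
    def test_enumerable_pairs(self):
        v = encode_dipeptide(record_of("ACAC"))
        ai, ci = ALPHABET.index("A"), ALPHABET.index("C")
        assert v.values[ai * 20 + ci] == pytest.approx(2 / 3)
        assert v.values[ci * 20 + ai] == pytest.approx(1 / 3)
        assert np.count_nonzero(v.values) == 2

    def test_two_residues(self):
        v = encode_dipeptide(record_of("AA"))
        assert v.values[0] == 1.0 and v.values.sum() == 1.0

    def test_too_short(self):
        with pytest.raises(ValueError, match="length >= 2"):
            encode_dipeptide(record_of("A"))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(residues=residue_text)
    def test_matches_oracle(self, residues):
        v = encode_dipeptide(record_of(residues))
        np.testing.assert_allclose(v.values, oracle_dipeptide(residues), atol=1e-12)
        assert v.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_order_sensitive_unlike_composition(self, make_random_record):
        record = make_random_record(50)
        reverse = record_of(record.residues[::-1])
        assert not np.allclose(
            encode_dipeptide(record).values, encode_dipeptide(reverse).values
        )
        np.testing.assert_allclose(
            encode_composition(record).values, encode_composition(reverse).values
        )


class TestFactors:
    def test_single_letter_reduces_to_table_row(self):
        v = encode_factors(record_of("AAAA"))
        block = v.values[5 * ALPHABET.index("A"): 5 * ALPHABET.index("A") + 5]
        np.testing.assert_allclose(block, ATCHLEY_FACTORS["A"])
        assert np.count_nonzero(v.values) == 5

    def test_zero_table_gives_zero_vector(self):
        zero = {a: (0.0,) * 5 for a in ALPHABET}
        assert not encode_factors(record_of("ACDE"), table=zero).values.any()

    def test_incomplete_table_rejected(self):
        partial = {a: ATCHLEY_FACTORS[a] for a in "ACDE"}
        with pytest.raises(ValueError, match="missing"):
            encode_factors(record_of("ACDE"), table=partial)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(residues=residue_text)
    def test_matches_outer_product_oracle(self, residues):
        v = encode_factors(record_of(residues))
        np.testing.assert_allclose(v.values, oracle_factors(residues), atol=1e-12)

    def test_table_shape(self):
        assert factor_table().shape == (20, 5)


class TestPssmEncoding:
    def test_zero_scores_give_half_everywhere(self, make_random_record):
        record = make_random_record(30)
        profile = PSSMProfile(record.id, np.zeros((30, 20)), record.residues)
        v = encode_pssm(record, profile)
        np.testing.assert_allclose(v.values, 0.5)

    def test_single_residue_collapse(self):
        record = record_of("A" * 50)
        scores = np.tile(np.arange(20, dtype=float), (50, 1))
        profile = PSSMProfile(record.id, scores, record.residues)
        v = encode_pssm(record, profile).values.reshape(20, 20)
        a_row = NCBI_ORDER.index("A")
        np.testing.assert_allclose(
            v[a_row], 1 / (1 + np.exp(-np.arange(20, dtype=float)))
        )
        mask = np.ones(20, bool)
        mask[a_row] = False
        np.testing.assert_allclose(v[mask], 0.5)

    def test_length_mismatch_rejected(self, make_random_record):
        record = make_random_record(30)
        other = make_random_record(31)
        profile = generate_pssm(other, noise=0, seed=0)
        with pytest.raises(ValueError, match="rows"):
            encode_pssm(record, profile)

    def test_residue_mismatch_rejected(self, make_random_record):
        record = make_random_record(30)
        other = make_random_record(30)
        assert record.residues != other.residues
        profile = generate_pssm(other, noise=0, seed=0)
        profile.sequence_id = record.id
        with pytest.raises(ValueError, match="disagrees"):
            encode_pssm(record, profile)

    def test_matches_triple_loop_oracle(self, rng, make_random_record):
        for _ in range(10):
            record = make_random_record(40)
            scores = rng.integers(-8, 9, size=(40, 20)).astype(float)
            profile = PSSMProfile(record.id, scores, record.residues)
            v = encode_pssm(record, profile)
            np.testing.assert_allclose(
                v.values, oracle_pssm(record.residues, scores), atol=1e-12
            )

    def test_values_strictly_inside_unit_interval(self, rng, make_random_record):
        record = make_random_record(60)
        scores = rng.integers(-10, 11, size=(60, 20)).astype(float)
        v = encode_pssm(record, PSSMProfile(record.id, scores, record.residues))
        assert np.all(v.values > 0) and np.all(v.values < 1)


class TestCombine:
    def test_selected_triple_is_900_dims(self, make_random_record):
        record = make_random_record(50)
        profile = generate_pssm(record, noise=0, seed=0)
        blocks = encode_record(record, CANONICAL_FEATURES, profile=profile)
        v = combine(blocks, {"factors", "dipeptides", "pssm"})
        assert v.dim == 900
        assert v.schema == (("dipeptides", 400), ("factors", 100), ("pssm", 400))

    def test_singleton_mask_is_identity(self, make_random_record):
        record = make_random_record(50)
        blocks = encode_record(record, ("frequencies",))
        v = combine(blocks, {"frequencies"})
        np.testing.assert_array_equal(v.values, blocks["frequencies"].values)

    def test_all_fifteen_masks_dims(self, make_random_record):
        import itertools

        record = make_random_record(50)
        profile = generate_pssm(record, noise=0, seed=0)
        blocks = encode_record(record, CANONICAL_FEATURES, profile=profile)
        masks = [
            set(c)
            for r in range(1, 5)
            for c in itertools.combinations(CANONICAL_FEATURES, r)
        ]
        assert len(masks) == 15
        for mask in masks:
            v = combine(blocks, mask)
            assert v.dim == sum(FEATURE_DIMS[m] for m in mask)

    def test_empty_mask_rejected(self, make_random_record):
        blocks = encode_record(make_random_record(50), ("frequencies",))
        with pytest.raises(ValueError, match="empty"):
            combine(blocks, set())

    def test_missing_block_rejected(self, make_random_record):
        blocks = encode_record(make_random_record(50), ("frequencies",))
        with pytest.raises(ValueError, match="not provided"):
            combine(blocks, {"frequencies", "pssm"})


class TestLibsvm:
    def test_single_nonzero_line(self, tmp_path):
        v = encode_composition(record_of("AAAA"))
        v.label = 1
        out = tmp_path / "v.svm"
        write_libsvm([v], out)
        assert out.read_text() == "+1 1:1.000000\n"

    def test_all_zero_vector_bare_label(self, tmp_path):
        from secpred.encoders import FeatureVector

        v = FeatureVector("z", np.zeros(20), (("frequencies", 20),), label=-1)
        out = tmp_path / "z.svm"
        write_libsvm([v], out)
        assert out.read_text() == "-1\n"

    def test_unlabelled_rejected(self, tmp_path):
        v = encode_composition(record_of("AAAA"))
        with pytest.raises(ValueError, match="label"):
            write_libsvm([v], tmp_path / "x.svm")

    def test_round_trip_within_format_precision(self, tmp_path, make_random_record):
        records = [make_random_record(60) for _ in range(5)]
        vectors = []
        for i, r in enumerate(records):
            v = encode_dipeptide(r)
            v.label = 1 if i % 2 == 0 else -1
            vectors.append(v)
        out = tmp_path / "d.svm"
        write_libsvm(vectors, out)
        X, y = read_libsvm(out, dim=400)
        np.testing.assert_array_equal(y, [v.label for v in vectors])
        np.testing.assert_allclose(
            X, np.vstack([v.values for v in vectors]), atol=5e-7
        )

    def test_deterministic_bytes(self, tmp_path, make_random_record):
        record = make_random_record(80)
        v = encode_composition(record)
        v.label = 1
        a, b = tmp_path / "a.svm", tmp_path / "b.svm"
        write_libsvm([v], a)
        write_libsvm([v], b)
        assert a.read_bytes() == b.read_bytes()
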