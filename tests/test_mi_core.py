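import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coevomi import (Alignment, InputError, column_entropy, joint_entropy,
                     mi_matrix, mutual_information, pair_count)
from coevomi.msa_io import ALPHABET_SIZE


def kl_form_mi(ci, cj, base=2.0):
    """Independent oracle: MI by direct sum of p(x,y) log p(x,y)/(p(x)p(y))."""
    ci, cj = np.asarray(ci), np.asarray(cj)
    n = len(ci)
    joint = np.zeros((ALPHABET_SIZE, ALPHABET_SIZE))
    for x, y in zip(ci, cj):
        joint[x, y] += 1.0 / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    total = 0.0
    for x in range(ALPHABET_SIZE):
        for y in range(ALPHABET_SIZE):
            if joint[x, y] > 0:
                total += joint[x, y] * math.log(joint[x, y] / (px[x] * py[y]), base)
    return total


def random_codes(rng, n, L):
    return rng.integers(0, ALPHABET_SIZE, size=(n, L), dtype=np.uint8)


class TestColumnEntropy:
    @pytest.mark.parametrize(
        "col,expected",
        [
            ("AAAA", 0.0),
            ("AACC", 1.0),
            ("AAAC", -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))),
        ],
    )
    def test_hand_values(self, col, expected):
        assert column_entropy(col) == pytest.approx(expected, abs=1e-12)

    def test_empty_column_rejected(self):
        with pytest.raises(InputError):
            column_entropy([])

    def test_range_bound(self, rng):
        for _ in range(20):
            col = rng.integers(0, ALPHABET_SIZE, size=rng.integers(1, 40))
            h = column_entropy(col)
            assert 0.0 <= h <= math.log2(ALPHABET_SIZE) + 1e-12


class TestJointEntropy:
    def test_identical_columns_joint_equals_marginal(self):
        assert joint_entropy("AACC", "AACC") == pytest.approx(1.0)

    def test_four_equiprobable_pairs(self):
        assert joint_entropy("AACC", "ACAC") == pytest.approx(2.0)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            joint_entropy("AAC", "AACC")

    def test_matches_exhaustive_pair_count_oracle(self, rng):
        for _ in range(20):
            ci, cj = random_codes(rng, 6, 2).T
            counts = np.zeros((ALPHABET_SIZE, ALPHABET_SIZE))
            for x, y in zip(ci, cj):
                counts[x, y] += 1
            p = counts[counts > 0] / 6
            expected = float(-(p * np.log2(p)).sum())
            assert joint_entropy(ci, cj) == pytest.approx(expected, abs=1e-12)

    def test_bounds_vs_marginals(self, rng):
        for _ in range(20):
            ci, cj = random_codes(rng, 12, 2).T
            hi, hj = column_entropy(ci), column_entropy(cj)
            hij = joint_entropy(ci, cj)
            assert max(hi, hj) - 1e-9 <= hij <= hi + hj + 1e-9


class TestMutualInformation:
    def test_self_information_equals_entropy(self):
        assert mutual_information("AACC", "AACC") == pytest.approx(1.0)

    def test_empirically_independent_columns(self):
        assert mutual_information("AACC", "ACAC") == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 8), st.integers(2, 6))
    def test_entropy_difference_form_agrees_with_kl_form(self, seed, n, L):
        """The two textbook MI forms agree to 1e-12 on random small columns."""
        r = np.random.default_rng(seed)
        codes = random_codes(r, n, L)
        for j in range(1, L):
            assert mutual_information(codes[:, 0], codes[:, j]) == pytest.approx(
                kl_form_mi(codes[:, 0], codes[:, j]), abs=1e-12
            )

    def test_data_processing_bound(self, rng):
        for _ in range(30):
            ci, cj = random_codes(rng, 15, 2).T
            mi = mutual_information(ci, cj)
            assert -1e-9 <= mi <= min(column_entropy(ci), column_entropy(cj)) + 1e-9


class TestMIMatrix:
    def test_matches_pairwise_calls(self, random_alignment):
        m = mi_matrix(random_alignment)
        L = random_alignment.n_columns
        for i in range(L):
            for j in range(L):
                ci = random_alignment.codes[:, i]
                cj = random_alignment.codes[:, j]
                expected = (column_entropy(ci) if i == j
                            else mutual_information(ci, cj))
                assert m[i, j] == pytest.approx(expected, abs=1e-12)

    def test_exactly_symmetric(self, random_alignment):
        m = mi_matrix(random_alignment)
        np.testing.assert_array_equal(m, m.T)

    def test_diagonal_holds_column_entropy(self, random_alignment):
        m = mi_matrix(random_alignment)
        for i in range(random_alignment.n_columns):
            assert m[i, i] == pytest.approx(
                column_entropy(random_alignment.codes[:, i]), abs=1e-12
            )

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_sequence_permutation(self, seed):
        r = np.random.default_rng(seed)
        codes = random_codes(r, 10, 5)
        aln = Alignment(ids=[f"s{i}" for i in range(10)], codes=codes)
        perm = r.permutation(10)
        aln_p = Alignment(ids=[f"s{i}" for i in perm], codes=codes[perm])
        np.testing.assert_array_equal(mi_matrix(aln), mi_matrix(aln_p))

    def test_single_column_matrix(self):
        aln = Alignment(ids=["a", "b"], codes=np.array([[0], [1]], dtype=np.uint8))
        m = mi_matrix(aln)
        assert m.shape == (1, 1)
        assert m[0, 0] == pytest.approx(1.0)

    def test_nat_base_is_ln2_rescale(self, random_alignment):
        bits = mi_matrix(random_alignment)
        nats = mi_matrix(random_alignment, base=math.e)
        np.testing.assert_allclose(nats, bits * math.log(2), atol=1e-12)


class TestPairCount:
    @pytest.mark.parametrize("L,expected", [(100, 5050), (1, 1), (10, 55), (4, 10)])
    def test_counts(self, L, expected):
        # oracle: enumerate pairs i <= j
        assert expected == sum(1 for i in range(L) for j in range(i, L))
        assert pair_count(L) == expected

    def test_invalid(self):
        with pytest.raises(InputError):
            pair_count(0)
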