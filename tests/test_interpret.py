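"""Entropy profiles, class logos, attention summaries and alignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoreads import interpret


def brute_force_entropy(column: list[str]) -> float:
    """Direct evaluation of H = -sum_b p(b) log2 p(b) over one column."""
    h = 0.0
    for b in "ACGT":
        p = column.count(b) / len(column)
        if p > 0:
            h -= p * np.log2(p)
    return h


class TestEntropyProfile:
    def test_uniform_column_is_two_bits(self):
        profile = interpret.entropy_profile(["A", "C", "G", "T"])
        assert profile.H[0] == pytest.approx(2.0)

    def test_two_equal_bases_is_one_bit(self):
        profile = interpret.entropy_profile(["A", "A", "C", "C"])
        assert profile.H[0] == pytest.approx(1.0)

    def test_constant_column_is_zero(self):
        profile = interpret.entropy_profile(["G"] * 7)
        assert profile.H[0] == 0.0

    def test_matches_brute_force_on_random_columns(self):
        rng = np.random.default_rng(0)
        n_cols, n_seqs = 1000, 25
        mat = rng.choice(list("ACGT"), size=(n_seqs, n_cols))
        seqs = ["".join(row) for row in mat]
        profile = interpret.entropy_profile(seqs)
        for col in range(n_cols):
            expected = brute_force_entropy([s[col] for s in seqs])
            assert abs(profile.H[col] - expected) < 1e-12

    def test_bounds_and_maximum_iff_equifrequent(self):
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(16)]
        profile = interpret.entropy_profile(seqs)
        assert np.all(profile.H >= 0) and np.all(profile.H <= 2.0 + 1e-12)
        equifrequent = np.all(profile.freqs == 0.25, axis=1)
        np.testing.assert_array_equal(profile.H > 2.0 - 1e-12, equifrequent)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            interpret.entropy_profile(["AC", "ACG"])


class TestClassLogo:
    @pytest.fixture
    def random_group(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(60)]
        labels = list(rng.choice(["x", "y", "z"], 60))
        return seqs, labels

    def test_single_class_equals_pooled_profile(self):
        seqs = ["ACGT", "AGGT", "ACGA"]
        logo = interpret.class_logo(seqs, ["only"] * 3)
        profile = interpret.entropy_profile(seqs)
        np.testing.assert_allclose(
            logo.S[0], profile.freqs * profile.H[:, None], atol=1e-12)

    def test_zero_entropy_position_has_zero_letters(self, random_group):
        seqs, labels = random_group
        seqs = ["A" + s[1:] for s in seqs]  # force an invariant position
        logo = interpret.class_logo(seqs, labels)
        assert np.all(logo.S[:, 0, :] == 0.0)

    def test_letter_heights_stack_to_pooled_entropy(self, random_group):
        # algebraic identity: sum_b S_c(b,l) = H(l) since sum_b f_c = 1
        seqs, labels = random_group
        logo = interpret.class_logo(seqs, labels)
        stacked = logo.S.sum(axis=2)
        for ci in range(len(logo.classes)):
            np.testing.assert_allclose(stacked[ci], logo.H, atol=1e-12)

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            interpret.class_logo(["AC"], ["x"], classes=["x", "ghost"])


class TestSmoothing:
    def test_constant_vector_unchanged(self):
        v = np.full(30, 0.7)
        np.testing.assert_allclose(interpret.smooth_attention(v, 9), v)

    def test_interior_position_is_nine_wide_mean(self):
        rng = np.random.default_rng(3)
        v = rng.random(50)
        out = interpret.smooth_attention(v, 9)
        assert out[20] == pytest.approx(v[16:25].mean())

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(4)
        v = rng.random(31)
        out = interpret.smooth_attention(v, 7)
        for i in range(31):
            window = v[max(0, i - 3): min(31, i + 4)]
            assert out[i] == pytest.approx(window.mean(), abs=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            interpret.smooth_attention(np.ones(10), 4)

    def test_interior_support_preserves_mass(self):
        v = np.zeros(40)
        v[10:30] = np.random.default_rng(5).random(20)
        out = interpret.smooth_attention(v, 9)
        assert out.sum() == pytest.approx(v.sum(), abs=1e-10)


class TestMeanAttention:
    def test_single_read_class_is_identity(self):
        v = np.array([0.5, 0.3, 0.2])
        out = interpret.mean_attention([v], ["a"], window=3)
        np.testing.assert_array_equal(out.A[0], v)

    def test_two_reads_average(self):
        u, v = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        out = interpret.mean_attention([u, v], ["a", "a"], window=1)
        np.testing.assert_array_equal(out.A[0], [0.5, 0.5])

    def test_rows_of_unit_sum_vectors_have_unit_sum(self):
        rng = np.random.default_rng(6)
        att = rng.dirichlet(np.ones(20), size=100)
        labels = rng.choice(["a", "b"], 100)
        out = interpret.mean_attention(att, labels, window=5)
        np.testing.assert_allclose(out.A.sum(axis=1), 1.0, atol=1e-5)

    def test_empty_class_omitted_with_warning(self):
        with pytest.warns(UserWarning, match="no reads"):
            out = interpret.mean_attention(
                [np.ones(4) / 4], ["a"], classes=["a", "b"], window=1)
        assert out.classes == ["a"]

    def test_invalid_grouping_rejected(self):
        with pytest.raises(ValueError, match="grouping"):
            interpret.mean_attention([np.ones(4) / 4], ["a"], grouping="bogus")


@st.composite
def gapped_alignment(draw):
    n_seq = draw(st.integers(2, 5))
    n_col = draw(st.integers(4, 20))
    rows = []
    for _ in range(n_seq):
        row = draw(st.lists(st.sampled_from("ACGT-"), min_size=n_col,
                            max_size=n_col))
        if all(c == "-" for c in row):
            row[0] = "A"
        rows.append("".join(row))
    return rows


class TestAlignAttention:
    def test_gapless_alignment_is_identity(self):
        aln = {"a": "ACGT", "b": "TTTT"}
        att = {"a": np.array([0.1, 0.2, 0.3, 0.4]),
               "b": np.array([0.25] * 4)}
        out = interpret.align_attention(aln, att)
        np.testing.assert_array_equal(out.per_sequence[0], att["a"])
        np.testing.assert_allclose(
            out.column_mean, (att["a"] + att["b"]) / 2)

    def test_gap_insertion_pattern(self):
        out = interpret.align_attention(
            {"s": "AC-G"}, {"s": np.array([1.0, 2.0, 3.0])})
        row = out.per_sequence[0]
        assert row[0] == 1.0 and row[1] == 2.0 and np.isnan(row[2]) and row[3] == 3.0

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(gapped_alignment())
    def test_round_trip_recovers_inputs_bit_exactly(self, rows):
        rng = np.random.default_rng(7)
        aln = {f"s{i}": row for i, row in enumerate(rows)}
        att = {sid: rng.random(sum(c != "-" for c in row))
               for sid, row in aln.items()}
        out = interpret.align_attention(aln, att)
        for i, sid in enumerate(out.ids):
            recovered = out.per_sequence[i][~np.isnan(out.per_sequence[i])]
            np.testing.assert_array_equal(recovered, att[sid])

    def test_length_mismatch_names_sequence(self):
        with pytest.raises(ValueError, match="bad_seq"):
            interpret.align_attention({"bad_seq": "AC-G"},
                                      {"bad_seq": np.ones(5)})


class TestRegionAttention:
    def regions(self, *spans):
        return pd.DataFrame([{"name": n, "start": s, "end": e}
                             for n, s, e in spans])

    def test_partition_sums_to_total(self):
        rng = np.random.default_rng(8)
        att = rng.dirichlet(np.ones(30))
        table = interpret.region_attention(
            att, self.regions(("V1", 1, 10), ("V2", 11, 20), ("V3", 21, 30)))
        assert table.attention_sums.iloc[0].sum() == pytest.approx(1.0, abs=1e-5)

    def test_single_region_covers_everything(self):
        att = np.full(10, 0.1)
        table = interpret.region_attention(att, self.regions(("all", 1, 10)))
        assert table.attention_sums.iloc[0, 0] == pytest.approx(1.0)

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            interpret.region_attention(
                np.ones(10) / 10, self.regions(("a", 1, 6), ("b", 5, 10)))

    def test_out_of_bounds_region_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            interpret.region_attention(
                np.ones(10) / 10, self.regions(("a", 1, 11)))
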