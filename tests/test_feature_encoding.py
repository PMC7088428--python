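"""The 239-feature encoding: block definitions, oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import submitoloc as sm
from submitoloc.constants import AMINO_ACIDS
from submitoloc.feature_encoding import (
    BLOCK_LAYOUT,
    N_FEATURES,
    default_grouping_scheme,
    default_physchem_scales,
)

sequences = st.text(alphabet=AMINO_ACIDS, min_size=12, max_size=80)


class TestCcd:
    def test_homopolymer(self):
        values = sm.encode_ccd("AAAA")
        comp, centroid, dist = values[:20], values[20:40], values[40:]
        assert comp[0] == 1.0 and comp[1:].sum() == 0.0
        assert centroid[0] == pytest.approx((1 + 2 + 3 + 4) / 4 / 4)  # 0.625
        assert dist.sum() == pytest.approx(np.std([1, 2, 3, 4]) / 4)

    def test_single_occurrence_has_zero_spread(self):
        values = sm.encode_ccd("GAG")
        idx_a = AMINO_ACIDS.index("A")
        assert values[20 + idx_a] == pytest.approx(2 / 3)
        assert values[40 + idx_a] == 0.0

    def test_against_brute_force_position_statistics(self):
        sequence = "ACACAC"
        values = sm.encode_ccd(sequence)
        for aa in set(sequence):
            idx = AMINO_ACIDS.index(aa)
            positions = [i + 1 for i, r in enumerate(sequence) if r == aa]
            assert values[idx] == pytest.approx(len(positions) / len(sequence))
            assert values[20 + idx] == pytest.approx(
                np.mean(positions) / len(sequence)
            )
            assert values[40 + idx] == pytest.approx(
                np.std(np.array(positions) / len(sequence))
            )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sm.encode_ccd("")


class TestSaac:
    def test_clean_three_way_split(self):
        values = sm.encode_saac("AAACCCGGG")
        parts = values.reshape(3, 20)
        assert parts[0, AMINO_ACIDS.index("A")] == 1.0
        assert parts[1, AMINO_ACIDS.index("C")] == 1.0
        assert parts[2, AMINO_ACIDS.index("G")] == 1.0

    def test_split_sizes_for_length_ten(self):
        # floor(10/3)=3, floor(20/3)-3=3, 10-6=4
        values = sm.encode_saac("AAA" + "CCC" + "GGGG")
        parts = values.reshape(3, 20)
        assert parts[2, AMINO_ACIDS.index("G")] == 1.0

    @given(sequences)
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_each_part_composition_sums_to_one(self, sequence):
        parts = sm.encode_saac(sequence).reshape(3, 20)
        assert np.allclose(parts.sum(axis=1), 1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sm.encode_saac("AC")


class TestFgSse:
    def test_uniform_hydrophobic_window(self):
        sequence = "L" * 10  # one window, all hydrophobic
        sse = sm.assign_sse(sequence)
        values = sm.encode_fg_sse(sequence, sse)
        peptide = values[17:22]  # order: hydrophobic, hydrophilic, neutral, polar, nonpolar
        assert peptide[0] == 1.0
        assert peptide[1] == 0.0 and peptide[3] == 0.0

    def test_all_coil_zeroes_helix_and_sheet_features(self):
        sequence = "G" * 20  # poly-Gly assigns all-coil
        sse = sm.assign_sse(sequence)
        assert set(sse.states) == {"C"}
        values = sm.encode_fg_sse(sequence, sse)
        per_state_group = values[25:76].reshape(17, 3)
        per_state_pept = values[76:88].reshape(4, 3)
        assert np.all(per_state_group[:, :2] == 0.0)  # H and E columns
        assert np.all(per_state_pept[:, :2] == 0.0)

    def test_global_group_frequencies_match_hand_counts(self):
        sequence = "AVLKKKDDEFWYSTCMNQPG" + "AVLKKKDDEF"  # 30-mer
        sse = sm.assign_sse(sequence)
        values = sm.encode_fg_sse(sequence, sse)
        scheme = default_grouping_scheme()
        for idx, members in enumerate(scheme.all_groups.values()):
            expected = sum(aa in members for aa in sequence) / len(sequence)
            assert values[idx] == pytest.approx(expected)

    def test_sse_content_block_equals_assignment_content(self):
        sequence = "MAEAAAKLVVGGDEFWYPSTHRINQC"
        sse = sm.assign_sse(sequence)
        values = sm.encode_fg_sse(sequence, sse)
        assert tuple(values[22:25]) == pytest.approx(sse.content)

    def test_state_length_mismatch_rejected(self):
        sse = sm.assign_sse("A" * 10)
        with pytest.raises(ValueError, match="length"):
            sm.encode_fg_sse("A" * 12, sse)

    def test_short_sequence_rejected(self):
        sse = sm.assign_sse("A" * 8)
        with pytest.raises(ValueError):
            sm.encode_fg_sse("A" * 8, sse)


class TestPhyschem:
    def test_single_residue_returns_scale_values(self):
        scales = default_physchem_scales()
        values = sm.encode_physchem("A")
        expected = [mapping["A"] for mapping in scales.scales.values()]
        assert np.allclose(values, expected)

    def test_two_residue_mean(self):
        from submitoloc.feature_encoding import PhyschemScales

        toy = PhyschemScales(
            scales={"toy": {aa: (1.0 if aa == "C" else 0.0) for aa in AMINO_ACIDS}}
        )
        assert sm.encode_physchem("AC", toy)[0] == pytest.approx(0.5)

    def test_against_brute_force_mean(self, rng):
        sequence = "".join(rng.choice(list(AMINO_ACIDS), size=50))
        scales = default_physchem_scales()
        values = sm.encode_physchem(sequence)
        for idx, mapping in enumerate(scales.scales.values()):
            expected = sum(mapping[aa] for aa in sequence) / len(sequence)
            assert values[idx] == pytest.approx(expected, abs=1e-12)


class TestFullEncoding:
    def test_dimensions_and_layout(self):
        vector = sm.encode("ACDEFGHIKLMNPQRSTVWY" * 5)
        assert vector.values.shape == (N_FEATURES,)
        assert {name: len(vector.block(name)) for name in BLOCK_LAYOUT} == {
            "ccd": 60,
            "saac": 60,
            "fg_sse": 88,
            "physchem": 31,
        }

    def test_blocks_equal_individual_encoders(self):
        sequence = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        vector = sm.encode(sequence)
        sse = sm.assign_sse(sequence)
        assert np.array_equal(vector.block("ccd"), sm.encode_ccd(sequence))
        assert np.array_equal(vector.block("saac"), sm.encode_saac(sequence))
        assert np.array_equal(
            vector.block("fg_sse"), sm.encode_fg_sse(sequence, sse)
        )
        assert np.array_equal(
            vector.block("physchem"), sm.encode_physchem(sequence)
        )

    def test_deterministic(self):
        sequence = "ACDEFGHIKLMNPQRSTVWY" * 3
        assert np.array_equal(sm.encode(sequence).values, sm.encode(sequence).values)

    @given(sequences)
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_frequency_features_bounded_and_compositions_normalized(self, sequence):
        vector = sm.encode(sequence)
        ccd, saac, fg = vector.block("ccd"), vector.block("saac"), vector.block("fg_sse")
        assert np.all(ccd >= 0) and np.all(ccd <= 1)
        assert np.all(saac >= 0) and np.all(saac <= 1)
        assert np.all(fg >= 0) and np.all(fg <= 1)
        assert np.allclose(ccd[:20].sum(), 1.0)
        assert np.allclose(saac.reshape(3, 20).sum(axis=1), 1.0)

    @given(sequences)
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_composition_invariant_under_permutation(self, sequence):
        rng = np.random.default_rng(0)
        shuffled = "".join(rng.permutation(list(sequence)))
        original = sm.encode(sequence)
        permuted = sm.encode(shuffled)
        assert np.allclose(original.block("ccd")[:20], permuted.block("ccd")[:20])

    def test_feature_names_align_with_layout(self):
        names = sm.feature_names()
        assert len(names) == N_FEATURES
        assert names[0] == "ccd.comp.A"
        assert names[60].startswith("saac.n.")
        assert names[120].startswith("group.")
        assert names[208].startswith("physchem.")

    def test_encode_dataset_shape_and_labels(self, small_dataset):
        records, _ = small_dataset
        frame = sm.encode_dataset(records[:8])
        assert frame.shape == (8, N_FEATURES + 1)
        assert list(frame.columns[:-1]) == sm.feature_names()
        assert frame["label"].nunique() >= 1


class TestSchemeValidation:
    def test_default_scheme_counts(self):
        scheme = default_grouping_scheme()
        assert len(scheme.functional_groups) == 10
        assert len(scheme.physchem_groups) == 7
        assert len(scheme.all_groups) == 17

    def test_default_scales_count_and_coverage(self):
        scales = default_physchem_scales()
        assert len(scales) == 31
        for mapping in scales.scales.values():
            assert set(mapping) >= set(AMINO_ACIDS)

    def test_incomplete_scale_rejected(self):
        from submitoloc.feature_encoding import PhyschemScales

        with pytest.raises(ValueError, match="missing"):
            PhyschemScales(scales={"bad": {"A": 1.0}})
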