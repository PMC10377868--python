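import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbpred.descriptors import (
    CODON_DEGENERACY,
    DIMENSIONS,
    N_SENSE_CODONS,
    AACEncoder,
    CTDCEncoder,
    CTDDEncoder,
    CTDEncoder,
    CTDTEncoder,
    DCEncoder,
    DDEEncoder,
    encode_dataset,
    get_encoder,
    load_property_partitions,
)
from hbpred.sequences import ALPHABET, DataError, LabeledDataset, ProteinSequence

import bruteforce as bf
from conftest import make_dataset

valid_sequences = st.text(alphabet=ALPHABET, min_size=2, max_size=80)

DIP_INDEX = {d: i for i, d in enumerate(bf.DIPEPTIDES)}


class TestAAC:
    def test_single_letter_sequence(self):
        v = AACEncoder().encode("AAAA")
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_direct_counts(self):
        v = AACEncoder().encode("ACDC")
        assert v[ALPHABET.index("A")] == 0.25
        assert v[ALPHABET.index("C")] == 0.5
        assert v[ALPHABET.index("D")] == 0.25
        assert v.sum() == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(valid_sequences)
    def test_composition_sums_to_one(self, seq):
        assert AACEncoder().encode(seq).sum() == pytest.approx(1.0, abs=1e-12)


class TestDC:
    def test_homopolymer(self):
        v = DCEncoder().encode("AAAA")
        assert v[DIP_INDEX["AA"]] == 1.0 and v.sum() == 1.0

    def test_overlapping_windows(self):
        v = DCEncoder().encode("ACAC")
        assert v[DIP_INDEX["AC"]] == pytest.approx(2 / 3)
        assert v[DIP_INDEX["CA"]] == pytest.approx(1 / 3)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(valid_sequences)
    def test_frequencies_sum_to_one(self, seq):
        assert DCEncoder().encode(seq).sum() == pytest.approx(1.0, abs=1e-12)


class TestDDE:
    def test_theoretical_mean_from_codon_degeneracy(self):
        # TF(AA) = (4/61)^2, by direct multiplication of table entries
        enc = DDEEncoder()
        assert enc._tf[DIP_INDEX["AA"]] == pytest.approx(16 / 3721)
        assert enc._tf[DIP_INDEX["LS"]] == pytest.approx((6 / 61) * (6 / 61))

    def test_homotripeptide_closed_form(self):
        # L=3, F(AA)=1: DDE(AA) = (1-TF)/sqrt(TF(1-TF)/2), TF=16/3721
        tf = 16 / 3721
        expected = (1 - tf) / math.sqrt(tf * (1 - tf) / 2)
        v = DDEEncoder().encode("AAA")
        assert v[DIP_INDEX["AA"]] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(21.520339216657344)

    def test_absent_dipeptides_score_negative(self):
        v = DDEEncoder().encode("ACACAC")
        absent = [i for i, d in enumerate(bf.DIPEPTIDES) if d not in {"AC", "CA"}]
        assert (v[absent] < 0).all()

    def test_codon_table_sums_to_61_sense_codons(self):
        assert sum(CODON_DEGENERACY.values()) == N_SENSE_CODONS == 61
        assert set(CODON_DEGENERACY) == set(ALPHABET)

    def test_matches_bruteforce_on_random_sequences(self, random_sequences):
        enc = DDEEncoder()
        for seq in random_sequences[:30]:
            np.testing.assert_allclose(
                enc.encode(seq), bf.dde_naive(seq), atol=1e-10
            )


class TestCTDCatalogue:
    def test_thirteen_properties_three_disjoint_groups_each(self):
        table = load_property_partitions()
        props = table["property"].unique()
        assert len(props) == 13
        for prop in props:
            groups = table[table["property"] == prop]["residues"]
            joined = "".join(groups)
            assert sorted(joined) == sorted(ALPHABET)  # partition, no overlap

    def test_table2_style_feature_names_exist(self):
        names = set(CTDCEncoder().get_feature_names_out())
        assert {"solventaccess.G3", "hydrophobicity_ARGP820101.G2",
                "polarity.G3", "hydrophobicity_ZIMJ680101.G1",
                "secondarystruct.G1"} <= names


class TestCTDC:
    def test_single_group_sequence(self):
        # K and R are the only members of charge group 1
        v = CTDCEncoder().encode("KRKRKR")
        names = list(CTDCEncoder().get_feature_names_out())
        assert v[names.index("charge.G1")] == 1.0
        assert v[names.index("charge.G2")] == 0.0
        assert v[names.index("charge.G3")] == 0.0

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(valid_sequences)
    def test_groups_of_each_property_sum_to_one(self, seq):
        v = CTDCEncoder().encode(seq).reshape(13, 3)
        np.testing.assert_allclose(v.sum(axis=1), 1.0, atol=1e-12)


class TestCTDT:
    def test_sequence_within_one_group_has_no_transitions(self):
        v = CTDTEncoder().encode("KRKRKR").reshape(13, 3)
        names = [p for p in dict.fromkeys(load_property_partitions()["property"])]
        assert (v[names.index("charge")] == 0.0).all()

    def test_strict_alternation_crosses_every_adjacent_pair(self):
        # K (charge G1) alternating with D (charge G3) -> T13 = 1
        v = CTDTEncoder().encode("KDKDKD")
        names = list(CTDTEncoder().get_feature_names_out())
        assert v[names.index("charge.T13")] == 1.0

    def test_matches_bruteforce_pair_counter(self, random_sequences):
        enc = CTDTEncoder()
        for seq in random_sequences[:15]:
            np.testing.assert_allclose(enc.encode(seq), bf.ctdt_naive(seq), atol=1e-12)

    def test_hand_enumerated_six_residue_sequence(self):
        # KDAKEC / charge: groups K|D E|A C -> pairs at positions 1-5:
        # KD(13) DA(23) AK(12) KE(13) EC(23); L-1 = 5
        v = CTDTEncoder().encode("KDAKEC")
        names = list(CTDTEncoder().get_feature_names_out())
        assert v[names.index("charge.T12")] == pytest.approx(1 / 5)
        assert v[names.index("charge.T13")] == pytest.approx(2 / 5)
        assert v[names.index("charge.T23")] == pytest.approx(2 / 5)


class TestCTDD:
    def test_uniform_occupancy_percentiles(self):
        # every residue of KKKKKKKK is in charge G1
        v = CTDDEncoder().encode("K" * 8)
        names = list(CTDDEncoder().get_feature_names_out())
        assert v[names.index("charge.G1.P100")] == 100.0
        assert v[names.index("charge.G1.P1")] == pytest.approx(1 / 8 * 100)

    def test_absent_group_reports_zero(self):
        v = CTDDEncoder().encode("K" * 8)  # charge G3 (D, E) absent
        names = list(CTDDEncoder().get_feature_names_out())
        for pct in (1, 25, 50, 75, 100):
            assert v[names.index(f"charge.G3.P{pct}")] == 0.0

    def test_hand_traced_eight_residue_sequence(self):
        # DKDKKKDA, charge G3 = {D, E}: occurrences at positions 1, 3, 7 (n=3)
        # targets: P1->1, P25->1, P50->1, P75->2, P100->3
        v = CTDDEncoder().encode("DKDKKKDA")
        names = list(CTDDEncoder().get_feature_names_out())
        got = [v[names.index(f"charge.G3.P{p}")] for p in (1, 25, 50, 75, 100)]
        assert got == pytest.approx([12.5, 12.5, 12.5, 37.5, 87.5])

    def test_matches_bruteforce_scan(self, random_sequences):
        enc = CTDDEncoder()
        for seq in random_sequences[:15]:
            np.testing.assert_allclose(enc.encode(seq), bf.ctdd_naive(seq), atol=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(valid_sequences)
    def test_values_bounded_and_nondecreasing_in_percentile(self, seq):
        v = CTDDEncoder().encode(seq).reshape(39, 5)
        assert (v >= 0).all() and (v <= 100).all()
        present = v.sum(axis=1) > 0
        assert (np.diff(v[present], axis=1) >= -1e-12).all()


class TestCTDConcatenation:
    def test_block_structure(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        full = CTDEncoder().encode(seq)
        assert len(full) == 273
        np.testing.assert_array_equal(full[:39], CTDCEncoder().encode(seq))
        np.testing.assert_array_equal(full[39:78], CTDTEncoder().encode(seq))
        np.testing.assert_array_equal(full[78:], CTDDEncoder().encode(seq))


@pytest.mark.parametrize("descriptor,dim", sorted(DIMENSIONS.items()))
def test_fixed_output_dimension(descriptor, dim):
    enc = get_encoder(descriptor)
    vec = enc.encode("ACDEFGHIKLMNPQRSTVWY" * 2)
    assert len(vec) == len(enc.get_feature_names_out()) == dim


def test_encoding_depends_only_on_residue_string():
    seq = "MKLVVSACDE"
    for descriptor in DIMENSIONS:
        enc = get_encoder(descriptor)
        alone = enc.transform([seq])[0]
        in_batch = enc.transform(["AC" * 30, seq, "KRKR"])[1]
        np.testing.assert_array_equal(alone, in_batch)


class TestEncodeDataset:
    def test_matrix_shape_and_labels(self):
        ds = make_dataset(5, 4)
        frame = encode_dataset(ds, "dde")
        assert frame.shape == (9, 401)
        assert list(frame.columns[:1]) == ["label"]
        assert frame["label"].tolist() == [1] * 5 + [0] * 4

    def test_rows_match_single_sequence_encoding(self):
        ds = make_dataset(2, 2, seed=5)
        frame = encode_dataset(ds, "aac")
        np.testing.assert_allclose(
            frame.iloc[0, 1:].to_numpy(float),
            AACEncoder().encode(ds.sequences[0]),
        )

    def test_empty_dataset_keeps_full_header(self):
        ds = LabeledDataset(sequences=[], labels=np.array([], dtype=int))
        frame = encode_dataset(ds, "aac")
        assert frame.shape == (0, 21)

    def test_unvalidated_record_error_names_it(self):
        ds = LabeledDataset(
            sequences=[ProteinSequence("badrec", "ACXE")], labels=np.array([1])
        )
        with pytest.raises(DataError, match="badrec"):
            encode_dataset(ds, "aac")

    def test_unknown_descriptor_lists_choices(self):
        with pytest.raises(DataError, match="aac"):
            get_encoder("nope")
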