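import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import acpkit as ak
from acpkit.encoders import (
    _cksaagp_names,
    _cksaap_names,
    _ct_names,
    _ctd_names,
    _grouped_kmer_names,
    _kmer_names,
    _paac_names,
)

import oracles

EXAMPLE = "CRACRKDSMVN"  # the standard worked-example peptide

peptide_seqs = st.text(alphabet=ak.ALPHABET, min_size=5, max_size=30)


def as_named(vector, names):
    return dict(zip(names, vector))


# ---------------------------------------------------------------------------
# k-mer family
# ---------------------------------------------------------------------------

class TestKmerFamily:
    def test_aac_homopolymer(self):
        vec = as_named(ak.encode_kmer_family("AAAA", "AAC"), _kmer_names(1))
        assert vec["A"] == 1.0
        assert sum(v for k, v in vec.items() if k != "A") == 0.0

    def test_aac_worked_example_counts(self):
        # manual letter count: C x2, R x2, A x1 out of 11
        vec = as_named(ak.encode_kmer_family(EXAMPLE, "AAC"), _kmer_names(1))
        assert vec["C"] == pytest.approx(2 / 11)
        assert vec["R"] == pytest.approx(2 / 11)
        assert vec["A"] == pytest.approx(1 / 11)

    def test_dpc_forced_homopolymer(self):
        vec = as_named(ak.encode_kmer_family("AAAA", "DPC"), _kmer_names(2))
        assert vec["AA"] == 1.0

    @pytest.mark.parametrize("scheme,minimum", [("DPC", 2), ("TPC", 3)])
    def test_length_minima(self, scheme, minimum):
        with pytest.raises(ak.EncoderLengthError, match=scheme):
            ak.encode_kmer_family("A" * (minimum - 1), scheme)

    @given(seq=peptide_seqs)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_composition_vectors_sum_to_one(self, seq):
        for scheme in ("AAC", "DPC", "TPC"):
            assert ak.encode_kmer_family(seq, scheme).sum() == pytest.approx(1.0)


class TestCksaap:
    def test_worked_example_gap0_numerators(self):
        vec = as_named(ak.encode_cksaap(EXAMPLE, kmax=0), _cksaap_names(0))
        assert vec["CR.gap0"] == pytest.approx(2 / 10)
        assert vec["AC.gap0"] == pytest.approx(1 / 10)
        assert vec["AA.gap0"] == 0.0
        assert vec["CQ.gap0"] == 0.0

    def test_gap1_enumerated_by_hand(self):
        # AAAA has A..A pairs at (1,3) and (2,4): 2 / (N-2) = 1.0
        vec = as_named(ak.encode_cksaap("AAAA", kmax=1), _cksaap_names(1))
        assert vec["AA.gap1"] == 1.0

    def test_gap_blocks_each_sum_to_one(self, rng):
        seq = "".join(ak.ALPHABET[i] for i in rng.integers(0, 20, 25))
        vec = ak.encode_cksaap(seq, kmax=3)
        for k in range(4):
            assert vec[400 * k: 400 * (k + 1)].sum() == pytest.approx(1.0)

    def test_too_short_for_gap(self):
        with pytest.raises(ak.EncoderLengthError):
            ak.encode_cksaap("ACDEF", kmax=4)


class TestGroupedFamily:
    def test_gaac_homopolymer_glycine(self):
        vec = as_named(
            ak.encode_grouped_family("GGGG", "GAAC"), _grouped_kmer_names(1)
        )
        assert vec["aliphatic"] == 1.0

    @given(seq=peptide_seqs)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_gaac_sums_to_one(self, seq):
        assert ak.encode_grouped_family(seq, "GAAC").sum() == pytest.approx(1.0)

    def test_gdpc_positive_charge_pair(self):
        # K and R both sit in the positive-charge group
        vec = as_named(
            ak.encode_grouped_family("KRKR", "GDPC"), _grouped_kmer_names(2)
        )
        assert vec["positivecharge.positivecharge"] == 1.0

    def test_partition_covers_alphabet(self):
        assert sorted("".join(ak.GAAC_GROUPS.values())) == sorted(ak.ALPHABET)


class TestConjointTriad:
    def test_single_class_homopolymer(self):
        vec = ak.encode_ct("GGG")
        assert (vec > 0).sum() == 1

    def test_classwise_equivalent_triads_share_feature(self):
        # G, L, M and V, F, T are classwise identical triads
        v1 = ak.encode_ct("GLM")
        v2 = ak.encode_ct("VFT")
        assert np.array_equal(v1 > 0, v2 > 0)

    def test_gavgav_single_unit_frequency(self):
        # G, A, V share a class: 4 overlapping triads, all the same unit
        vec = ak.encode_ct("GAVGAV")
        assert vec.max() == pytest.approx(4 / 4)
        assert (vec > 0).sum() == 1

    def test_minmax_normalization_variant(self):
        vec = ak.encode_ct("GAVGAVKKR", normalization="minmax")
        assert vec.max() == pytest.approx(1.0)
        assert vec.min() == 0.0

    def test_classes_partition_alphabet(self):
        assert sorted("".join(ak.CT_CLASSES)) == sorted(ak.ALPHABET)


class TestCtd:
    def test_homopolymer_transitions_are_zero(self):
        assert not ak.encode_ctd("AAAAA", "T").any()

    def test_homopolymer_distribution_endpoints(self):
        vec = as_named(ak.encode_ctd("AAAAA", "D"), _ctd_names("D"))
        for prop, groups in ak.CTD_PROPERTIES.items():
            g = next(i for i, members in enumerate(groups, 1) if "A" in members)
            assert vec[f"{prop}.{g}.residue0"] == pytest.approx(20.0)
            assert vec[f"{prop}.{g}.residue100"] == pytest.approx(100.0)

    def test_absent_group_distribution_is_zero(self):
        vec = as_named(ak.encode_ctd("KKKKK", "D"), _ctd_names("D"))
        # K is in charge group 1; groups 2 and 3 never occur
        for g in (2, 3):
            for pt in (0, 25, 50, 75, 100):
                assert vec[f"charge.{g}.residue{pt}"] == 0.0

    @given(seq=peptide_seqs)
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_composition_sums_to_one_per_property(self, seq):
        vec = ak.encode_ctd(seq, "C")
        for p in range(len(ak.CTD_PROPERTIES)):
            assert vec[3 * p: 3 * p + 3].sum() == pytest.approx(1.0)

    def test_all_properties_partition_alphabet(self):
        for prop, groups in ak.CTD_PROPERTIES.items():
            assert sorted("".join(groups)) == sorted(ak.ALPHABET), prop


class TestPaacFamily:
    def test_lambda_zero_equals_aac(self):
        aac = ak.encode_kmer_family(EXAMPLE, "AAC")
        assert np.allclose(ak.encode_paac_family(EXAMPLE, "PAAC", lam=0), aac)

    @pytest.mark.parametrize("scheme", ["PAAC", "APAAC"])
    def test_weight_zero_composition_equals_aac(self, scheme):
        aac = ak.encode_kmer_family(EXAMPLE, "AAC")
        vec = ak.encode_paac_family(EXAMPLE, scheme, lam=5, w=0.0)
        assert np.allclose(vec[:20], aac)

    def test_homopolymer_order_terms_vanish(self):
        # identical residues have zero scale difference, so theta_1 = 0
        vec = as_named(
            ak.encode_paac_family("AAAAAAAAAA", "PAAC", lam=1),
            _paac_names("PAAC", 1),
        )
        assert vec["Xc2.lambda1"] == 0.0
        assert vec["Xc1.A"] == pytest.approx(1.0)

    def test_length_must_exceed_lambda(self):
        with pytest.raises(ak.EncoderLengthError):
            ak.encode_paac_family("ACDEF", "PAAC", lam=5)

    def test_dimensions(self):
        assert len(ak.encode_paac_family(EXAMPLE, "PAAC", lam=8)) == 28
        assert len(ak.encode_paac_family(EXAMPLE, "APAAC", lam=8)) == 36


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence (per encoder; the full 50-peptide sweep
# is in the acceptance tests)
# ---------------------------------------------------------------------------

ORACLE_CASES = [
    ("AAC", lambda s: ak.encode_kmer_family(s, "AAC"),
     lambda s: oracles.kmer_oracle(s, 1)),
    ("DPC", lambda s: ak.encode_kmer_family(s, "DPC"),
     lambda s: oracles.kmer_oracle(s, 2)),
    ("CKSAAP", lambda s: ak.encode_cksaap(s, kmax=3),
     lambda s: oracles.cksaap_oracle(s, 3)),
    ("GAAC", lambda s: ak.encode_grouped_family(s, "GAAC"),
     lambda s: oracles.grouped_kmer_oracle(s, 1)),
    ("GDPC", lambda s: ak.encode_grouped_family(s, "GDPC"),
     lambda s: oracles.grouped_kmer_oracle(s, 2)),
    ("CKSAAGP", lambda s: ak.encode_grouped_family(s, "CKSAAGP", 3),
     lambda s: oracles.cksaagp_oracle(s, 3)),
    ("CT", ak.encode_ct, oracles.ct_oracle),
    ("CTDC", lambda s: ak.encode_ctd(s, "C"),
     lambda s: oracles.ctd_oracle(s, "C")),
    ("CTDT", lambda s: ak.encode_ctd(s, "T"),
     lambda s: oracles.ctd_oracle(s, "T")),
    ("CTDD", lambda s: ak.encode_ctd(s, "D"),
     lambda s: oracles.ctd_oracle(s, "D")),
    ("PAAC", lambda s: ak.encode_paac_family(s, "PAAC", lam=4, w=0.05),
     lambda s: oracles.paac_oracle(s, 4, 0.05)),
    ("APAAC", lambda s: ak.encode_paac_family(s, "APAAC", lam=4, w=0.05),
     lambda s: oracles.apaac_oracle(s, 4, 0.05)),
]


@pytest.mark.parametrize("name,impl,oracle", ORACLE_CASES,
                         ids=[c[0] for c in ORACLE_CASES])
def test_encoder_matches_brute_force(name, impl, oracle, rng):
    for _ in range(5):
        length = int(rng.integers(5, 31))
        seq = "".join(ak.ALPHABET[i] for i in rng.integers(0, 20, length))
        np.testing.assert_allclose(
            impl(seq), np.asarray(oracle(seq)), atol=1e-12,
            err_msg=f"{name} disagrees with enumeration oracle on {seq}",
        )


# ---------------------------------------------------------------------------
# Naming grammar
# ---------------------------------------------------------------------------

SEVEN = [
    "GL.gap4", "hydrophobicity_PRAM900101.Tr2332", "polarizability.2.residue0",
    "Pc1.C", "Xc1.K", "Pc2.Hydrophobicity.8", "secondarystruct.1.residue0",
]

ALL_NAME_SETS = [
    _kmer_names(1), _kmer_names(2), _kmer_names(3)[:100], _cksaap_names(2),
    _grouped_kmer_names(1), _grouped_kmer_names(2), _grouped_kmer_names(3),
    _cksaagp_names(1), _ct_names()[:50], _ctd_names("C"), _ctd_names("T"),
    _ctd_names("D"), _paac_names("PAAC", 8), _paac_names("APAAC", 8),
]


class TestFeatureNames:
    @pytest.mark.parametrize("name", SEVEN)
    def test_seven_model_features_parse(self, name):
        parsed = ak.FeatureName.parse(name)
        assert parsed.render() == name

    def test_render_parse_identity_across_all_encoders(self):
        for names in ALL_NAME_SETS:
            for name in names:
                assert ak.FeatureName.parse(name).render() == name

    @pytest.mark.parametrize("bad", [
        "notAFeature", "GLKK", "AB.gap-1", "Xc1.GG", "Pc2.Mass.3",
        "polarity.G4", "ct890", "aliphatic.nothere", "charge.Tr2112",
    ])
    def test_bad_names_rejected(self, bad):
        with pytest.raises(ak.FeatureNameError):
            ak.FeatureName.parse(bad)

    def test_parsing_is_case_sensitive(self):
        with pytest.raises(ak.FeatureNameError):
            ak.FeatureName.parse("gl.gap4")


class TestResolveFeature:
    def test_gl_gap4_resolves_to_cksaap(self):
        res = ak.resolve_feature("GL.gap4")
        assert res.encoder == "CKSAAP"
        assert res.compute("G" + "AAAA" + "L") == pytest.approx(1.0)

    def test_xc1_k_resolves_to_paac_composition(self):
        res = ak.resolve_feature("Xc1.K")
        assert res.encoder == "PAAC"
        full = ak.encode_paac_family(EXAMPLE, "PAAC", lam=8, w=0.05)
        assert res.compute(EXAMPLE) == pytest.approx(full[res.index])

    def test_unparseable_name_is_resolution_error(self):
        with pytest.raises(ak.FeatureNameError):
            ak.resolve_feature("notAFeature")

    @pytest.mark.parametrize("name,encoder", [
        ("K", "AAC"), ("GL", "DPC"), ("GLK", "TPC"), ("aliphatic", "GAAC"),
        ("ct117", "CT"), ("polarity.G2", "CTDC"), ("charge.Tr1331", "CTDT"),
        ("solventaccess.3.residue75", "CTDD"), ("Xc2.lambda3", "PAAC"),
        ("Pc2.Hydrophilicity.2", "APAAC"), ("aromatic.uncharged.gap2", "CKSAAGP"),
        ("aliphatic.aromatic.uncharged", "GTPC"),
    ])
    def test_resolution_encoder_dispatch(self, name, encoder):
        assert ak.resolve_feature(name).encoder == encoder

    def test_resolution_indexes_full_encoder_output(self, small_dataset):
        for name, compute_full in [
            ("GL.gap4", lambda s: ak.encode_cksaap(s, kmax=4)),
            ("secondarystruct.1.residue0", lambda s: ak.encode_ctd(s, "D")),
        ]:
            res = ak.resolve_feature(name)
            seq = small_dataset.peptides[0].sequence
            assert res.compute(seq) == pytest.approx(compute_full(seq)[res.index])


# ---------------------------------------------------------------------------
# Dataset-level encoding
# ---------------------------------------------------------------------------

class TestEncodeDataset:
    def test_matrix_shape_and_names(self, small_dataset):
        m = ak.encode_dataset(small_dataset, "AAC")
        assert m.shape == (50, 20)
        assert m.names == list(_kmer_names(1))
        assert m.ids == small_dataset.ids

    def test_peptide_id_attached_to_length_errors(self):
        peps = [ak.Peptide(id="tiny", sequence="AC")]
        with pytest.raises(ak.EncoderLengthError, match="tiny"):
            ak.encode_dataset(peps, "TPC")

    def test_skip_short_drops_with_warning(self):
        peps = [ak.Peptide(id="ok", sequence="ACDEFGHIK"),
                ak.Peptide(id="tiny", sequence="AC")]
        with pytest.warns(UserWarning, match="tiny"):
            m = ak.encode_dataset(peps, "TPC", skip_short=True)
        assert m.ids == ["ok"]

    def test_permutation_covariance(self, small_dataset, rng):
        m = ak.encode_dataset(small_dataset, "AAC")
        order = rng.permutation(len(small_dataset))
        shuffled = [small_dataset.peptides[i] for i in order]
        m2 = ak.encode_dataset(shuffled, "AAC")
        assert m2.names == m.names
        np.testing.assert_array_equal(m2.values, m.values[order])

    def test_encode_many_aligns_rows_when_skipping(self):
        peps = [ak.Peptide(id="long", sequence="ACDEFGHIKLMNP"),
                ak.Peptide(id="mid", sequence="ACDEFGH"),
                ak.Peptide(id="tiny", sequence="ACD")]
        with pytest.warns(UserWarning):
            m = ak.encode_many(peps, ["AAC", ("PAAC", {"lambda": 8})],
                               skip_short=True)
        # only 'long' satisfies lambda=8 (N >= 9)
        assert m.ids == ["long"]
        assert m.shape == (1, 48)

    def test_table_round_trip(self, small_dataset, tmp_path):
        m = ak.encode_dataset(small_dataset, "CTDC")
        path = tmp_path / "table.tsv"
        m.to_table(path)
        back = ak.FeatureMatrix.from_table(path)
        assert back.names == m.names
        np.testing.assert_allclose(back.values, m.values)


class TestEncodeSelected:
    def test_empty_manifest_gives_zero_columns(self, small_dataset):
        m = ak.encode_selected(small_dataset, [])
        assert m.shape == (50, 0)

    def test_seven_feature_model_is_total(self, small_dataset):
        names = ak.seven_feature_manifest()
        m = ak.encode_selected(small_dataset, names)
        assert m.names == names
        assert np.isfinite(m.values).all()

    def test_columns_match_full_encoder_output(self, small_dataset):
        sel = ak.encode_selected(small_dataset, ["GL.gap4", "Pc1.C"])
        full_cksaap = ak.encode_dataset(small_dataset, "CKSAAP", kmax=4)
        full_apaac = ak.encode_dataset(small_dataset, "APAAC")
        np.testing.assert_allclose(
            sel.data["GL.gap4"], full_cksaap.data["GL.gap4"]
        )
        np.testing.assert_allclose(sel.data["Pc1.C"], full_apaac.data["Pc1.C"])

    def test_column_order_follows_input(self, small_dataset):
        names = ["Xc1.K", "K", "GL.gap4"]
        assert ak.encode_selected(small_dataset, names).names == names

    def test_manifest_file_round_trip(self, tmp_path):
        path = tmp_path / "model.manifest"
        ak.write_manifest(SEVEN, path)
        assert ak.read_manifest(path) == SEVEN

    def test_manifest_comments_ignored(self, tmp_path):
        path = tmp_path / "model.manifest"
        path.write_text("# a comment\nGL.gap4  # trailing\n\nXc1.K\n")
        assert ak.read_manifest(path) == ["GL.gap4", "Xc1.K"]

    def test_shipped_manifest_matches_expected_names(self):
        assert ak.seven_feature_manifest() == SEVEN


DIMENSION_CONTRACT = [
    ("AAC", {}, 20), ("DPC", {}, 400), ("TPC", {}, 8000),
    ("CKSAAP", {"kmax": 5}, 2400), ("GAAC", {}, 5), ("GDPC", {}, 25),
    ("GTPC", {}, 125), ("CKSAAGP", {"kmax": 5}, 150), ("CT", {}, 343),
    ("CTDC", {}, 39), ("CTDT", {}, 39), ("CTDD", {}, 195),
    ("PAAC", {"lambda": 8}, 28), ("APAAC", {"lambda": 8}, 36),
]


@pytest.mark.parametrize("encoder,params,dim", DIMENSION_CONTRACT,
                         ids=[c[0] for c in DIMENSION_CONTRACT])
def test_dimension_contract(encoder, params, dim, small_dataset):
    m = ak.encode_dataset(small_dataset, encoder, **params)
    assert m.shape[1] == dim
    assert len(set(m.names)) == dim
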