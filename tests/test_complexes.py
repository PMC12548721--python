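"""Component-string parsing and whole-complex fingerprint assembly."""

import numpy as np
import pytest

from electrum import (
    ComplexFingerprinter,
    atomic_fingerprint,
    electrum_fingerprint,
    encode_metal,
    ligands_only_fingerprint,
    parse_complex_string,
)
from electrum.errors import MissingMetalError, MultinuclearError, SmilesParseError


class TestParsing:
    def test_direct_split(self):
        parsed = parse_complex_string("N.N.Cl.Cl.[Pt]")
        assert parsed.metal_symbol == "Pt"
        assert sorted(parsed.ligand_smiles) == ["Cl", "Cl", "N", "N"]

    def test_metal_position_is_irrelevant(self):
        assert parse_complex_string("[Pt].N.Cl").metal_symbol == "Pt"

    @pytest.mark.parametrize("token", ["[Ru]", "[Ru+2]", "Ru", "[101Ru]"])
    def test_metal_token_annotations_ignored(self, token):
        assert parse_complex_string(f"N.{token}").metal_symbol == "Ru"

    def test_charge_does_not_change_encoding(self):
        a = electrum_fingerprint(parse_complex_string("N.[Ru]")).combined
        b = electrum_fingerprint(parse_complex_string("N.[Ru+2]")).combined
        assert np.array_equal(a, b)

    def test_no_metal_is_an_error(self):
        with pytest.raises(MissingMetalError):
            parse_complex_string("CCO")

    def test_two_metals_is_an_error(self):
        with pytest.raises(MultinuclearError):
            parse_complex_string("[Fe].[Fe].C#O")

    def test_metalloligand_is_an_error(self):
        with pytest.raises(MultinuclearError):
            parse_complex_string("C[Fe]C.[Pt]")

    def test_empty_component_is_an_error(self):
        with pytest.raises(SmilesParseError):
            parse_complex_string("N..Cl.[Pt]")

    def test_empty_string_is_an_error(self):
        with pytest.raises(SmilesParseError):
            parse_complex_string("")

    def test_bare_nonmetal_symbol_is_a_ligand(self):
        parsed = parse_complex_string("Cl.[Pt]")
        assert parsed.ligand_smiles == ("Cl",)


class TestElectrumAssembly:
    def test_combined_width_598_at_default(self):
        fp = electrum_fingerprint(parse_complex_string("N.N.Cl.Cl.[Pt]"))
        assert fp.combined.shape == (598,)
        assert fp.ligand_part.shape == (512,)
        assert fp.metal_part.shape == (86,)

    def test_metal_block_matches_encoding_bit_for_bit(self):
        fp = electrum_fingerprint(parse_complex_string("C#O.C#O.[Fe]"))
        assert np.array_equal(fp.combined[512:], encode_metal("Fe"))

    def test_permutation_invariance(self):
        a = electrum_fingerprint(parse_complex_string("C.N.[Zn]")).combined
        b = electrum_fingerprint(parse_complex_string("N.C.[Zn]")).combined
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_duplicate_additivity(self, k):
        one = ligands_only_fingerprint(parse_complex_string("C#O.[Fe]"))
        many = ligands_only_fingerprint(
            parse_complex_string(".".join(["C#O"] * k + ["[Fe]"]))
        )
        assert np.array_equal(many, k * one)

    def test_stereoisomer_collapse_diamminedichloroplatinum(self):
        # square-planar cis/trans isomerism is invisible to the encoding
        cis = electrum_fingerprint(parse_complex_string("N.N.Cl.Cl.[Pt]")).combined
        trans = electrum_fingerprint(parse_complex_string("Cl.N.Cl.N.[Pt]")).combined
        assert np.array_equal(cis, trans)

    @pytest.mark.parametrize("size", [256, 512, 1024])
    def test_bit_size_variants(self, size):
        fp = electrum_fingerprint(parse_complex_string("N.[Cu]"), size=size)
        assert fp.combined.shape == (size + 86,)


class TestBaselines:
    def test_ligands_only_discards_metal(self):
        pt = ligands_only_fingerprint(parse_complex_string("N.N.Cl.Cl.[Pt]"))
        pd_ = ligands_only_fingerprint(parse_complex_string("N.N.Cl.Cl.[Pd]"))
        assert np.array_equal(pt, pd_)
        assert pt.shape == (512,)
        assert pt.sum() > 0

    def test_atomic_trailing_feature_is_z(self):
        v = atomic_fingerprint(parse_complex_string("N.N.Cl.Cl.[Pt]"))
        assert v.shape == (513,)
        assert v[-1] == 78

    def test_atomic_differs_only_in_trailing_feature(self):
        a = atomic_fingerprint(parse_complex_string("N.N.Cl.Cl.[Pt]"))
        b = atomic_fingerprint(parse_complex_string("N.N.Cl.Cl.[Pd]"))
        assert np.array_equal(a[:-1], b[:-1])
        assert a[-1] != b[-1]


class TestTransformer:
    def test_transform_matrix_shapes(self):
        strings = ["N.N.Cl.Cl.[Pt]", "C#O.C#O.C#O.[Fe]"]
        for variant, width in [("electrum", 598), ("ligands", 512), ("atomic", 513)]:
            fper = ComplexFingerprinter(variant=variant).fit()
            assert fper.n_features_out_ == width
            assert fper.transform(strings).shape == (2, width)

    def test_sklearn_param_interface(self):
        fper = ComplexFingerprinter(n_bits=256)
        assert fper.get_params()["n_bits"] == 256
        fper.set_params(variant="atomic")
        assert fper.fit().n_features_out_ == 257

    def test_invalid_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            ComplexFingerprinter(variant="bogus").fit()

    def test_feature_names(self):
        names = ComplexFingerprinter().get_feature_names_out()
        assert len(names) == 598
        assert names[0] == "lig_0" and names[512] == "metal_1s_0"

    def test_works_in_sklearn_pipeline(self):
        from sklearn.pipeline import Pipeline
        from sklearn.linear_model import LogisticRegression

        strings = ["N.N.Cl.Cl.[Pt]", "C#O.C#O.C#O.[Fe]"] * 5
        y = [0, 1] * 5
        pipe = Pipeline(
            [("fp", ComplexFingerprinter()), ("clf", LogisticRegression())]
        )
        pipe.fit(strings, y)
        assert pipe.score(strings, y) == 1.0
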