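"""Circular environment enumeration, hashing and folding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from electrum import enumerate_environments, fold, ligand_fingerprint
from electrum.errors import SmilesParseError
from electrum.ligand import parse_smiles

MOLECULES = [
    "C", "CC", "CCO", "c1ccccc1", "c1ccncc1", "C#O", "C#N",
    "CC(=O)C=C(C)[O-]", "NCCN", "CP(C)C", "[O-]C(=O)C(=O)[O-]",
    "C1CCCCC1", "CC(C)CC1=CC=C(C=C1)C(C)C(=O)O",
]


def bfs_ball_growth_count(smiles: str, max_radius: int) -> int:
    """Independent oracle: per atom, count radii whose BFS ball strictly grows."""
    mol = parse_smiles(smiles)
    adj = {a.GetIdx(): set() for a in mol.GetAtoms()}
    for b in mol.GetBonds():
        adj[b.GetBeginAtomIdx()].add(b.GetEndAtomIdx())
        adj[b.GetEndAtomIdx()].add(b.GetBeginAtomIdx())
    total = 0
    for start in adj:
        ball = {start}
        total += 1  # radius 0 always emits
        for _ in range(max_radius):
            grown = ball | {j for i in ball for j in adj[i]}
            if len(grown) > len(ball):
                total += 1
            ball = grown
    return total


class TestEnumeration:
    @pytest.mark.parametrize(
        "smiles, expected",
        [("C", 1), ("CC", 4), ("c1ccccc1", 18)],
    )
    def test_identifier_counts_small_graphs(self, smiles, expected):
        assert len(enumerate_environments(smiles, 2)) == expected

    @pytest.mark.parametrize("smiles", MOLECULES)
    @pytest.mark.parametrize("radius", [0, 1, 2, 3])
    def test_count_matches_bfs_oracle(self, smiles, radius):
        envs = enumerate_environments(smiles, radius)
        assert len(envs) == bfs_ball_growth_count(smiles, radius)

    @pytest.mark.parametrize("smiles", MOLECULES)
    def test_at_most_three_per_atom_at_radius_two(self, smiles):
        n_heavy = parse_smiles(smiles).GetNumAtoms()
        assert len(enumerate_environments(smiles, 2)) <= 3 * n_heavy

    def test_unparseable_smiles_carries_input(self):
        with pytest.raises(SmilesParseError, match="not-a-smiles"):
            enumerate_environments("not-a-smiles(", 2)

    def test_empty_string_is_an_error(self):
        with pytest.raises(SmilesParseError):
            ligand_fingerprint("")

    def test_identifiers_nonnegative(self):
        for env in enumerate_environments("CC(=O)C=C(C)[O-]", 2):
            assert env.identifier >= 0
            assert 0 <= env.radius <= 2


class TestSpellingInvariance:
    @pytest.mark.parametrize("a, b", [("OCC", "CCO"), ("c1ccncc1", "n1ccccc1")])
    def test_alternative_spellings_hash_identically(self, a, b):
        assert np.array_equal(
            ligand_fingerprint(a).counts, ligand_fingerprint(b).counts
        )

    @pytest.mark.parametrize("smiles", MOLECULES)
    def test_randomized_atom_orderings(self, smiles):
        ref = ligand_fingerprint(smiles).counts
        mol = parse_smiles(smiles)
        n = mol.GetNumAtoms()
        rng = np.random.default_rng(42)
        for _ in range(5):
            order = [int(i) for i in rng.permutation(n)]
            renumbered = Chem.RenumberAtoms(mol, order)
            respelled = Chem.MolToSmiles(renumbered, canonical=False)
            assert np.array_equal(ligand_fingerprint(respelled).counts, ref)

    def test_stereo_descriptors_ignored(self):
        assert np.array_equal(
            ligand_fingerprint("C/C=C/C").counts,
            ligand_fingerprint("C/C=C\\C").counts,
        )
        assert np.array_equal(
            ligand_fingerprint("N[C@@H](C)C(=O)O").counts,
            ligand_fingerprint("N[C@H](C)C(=O)O").counts,
        )


class TestFold:
    def test_modulo_placement(self):
        v = fold([0, 512, 1024], 512)
        assert v[0] == 3 and v.sum() == 3

    def test_empty_list(self):
        assert fold([], 64).sum() == 0

    @given(st.lists(st.integers(min_value=0, max_value=2**63), max_size=200),
           st.integers(min_value=1, max_value=1024))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_conservation(self, identifiers, size):
        assert fold(identifiers, size).sum() == len(identifiers)

    @given(st.lists(st.integers(min_value=0, max_value=2**63), max_size=200))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_double_fold_consistency(self, identifiers):
        b = 128
        wide = fold(identifiers, 2 * b)
        refolded = wide[:b] + wide[b:]
        assert np.array_equal(refolded, fold(identifiers, b))

    def test_size_must_be_positive(self):
        with pytest.raises(ValueError):
            fold([1, 2], 0)


class TestLigandFingerprint:
    def test_default_width(self):
        assert ligand_fingerprint("c1ccncc1").counts.shape == (512,)

    def test_single_heavy_atom_sums_to_one(self):
        assert ligand_fingerprint("O").counts.sum() == 1

    @pytest.mark.parametrize("size", [256, 512, 1024])
    def test_configurable_width(self, size):
        assert ligand_fingerprint("CCO", size=size).counts.shape == (size,)

    def test_sum_equals_environment_count(self):
        smiles = "CC(=O)C=C(C)[O-]"
        fp = ligand_fingerprint(smiles)
        assert fp.counts.sum() == len(enumerate_environments(smiles, 2))

    def test_runtime_scales_subquadratically_on_chains(self):
        # identifier count (the work driver) is exactly linear in chain length
        for n in (10, 50, 100):
            assert len(enumerate_environments("C" * n, 2)) == 3 * n
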