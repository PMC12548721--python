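"""Circular-substructure hashing and folding for single ligands.

Each ligand SMILES is converted into a fixed-length count vector the way
extended-connectivity fingerprints are built: every heavy atom seeds an
integer identifier from its local invariants, identifiers are refined
iteratively by mixing in sorted (bond order, neighbour identifier) pairs
out to ``max_radius`` bonds, and the emitted identifiers are folded into
the vector by taking them modulo the vector length.  Counts, not bits,
are kept, so an environment occurring twice contributes two.

Parsing is deliberately sanitisation-free: ligands cut out of metal
complexes often carry valences an organic-chemistry sanitiser rejects
(carbonyl carbon bound only to oxygen, naked halide donors, eta-bound
carbons), so the molecule is parsed raw and only the property cache and
ring perception are refreshed.

The integer hash is an 8-byte BLAKE2b digest of the packed invariant
tuple, pinned by :data:`HASH_VERSION`; fingerprints are only comparable
between runs that report the same hash version.  Identifiers depend only
on the molecular graph, never on the atom order of the input spelling,
and stereochemical annotations are ignored entirely (cis/trans and R/S
spellings of the same constitution hash identically).
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .errors import SmilesParseError

#: Version tag of the environment-identifier hash.  Bump on any change to
#: the atom invariants, the neighbour mixing rule, or the digest.
HASH_VERSION = "blake2b8-v1"

DEFAULT_N_BITS = 512
DEFAULT_RADIUS = 2


def parse_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string without valence sanitisation.

    Refreshes the property cache (implicit H counts) non-strictly and runs
    fast ring perception so atom invariants are available.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles, "empty string")
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise SmilesParseError(smiles)
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    return mol


@dataclass(frozen=True)
class EnvironmentIdentifier:
    """One hashed circular environment.

    ``atom_index`` is the centre atom's position in the parsed graph,
    ``radius`` the environment radius in bonds, and ``identifier`` the
    non-negative 64-bit hash of the environment.
    """

    atom_index: int
    radius: int
    identifier: int


@dataclass
class LigandFingerprint:
    """Folded count vector for a single ligand."""

    counts: np.ndarray
    source_smiles: str
    n_bits: int = field(init=False)

    def __post_init__(self):
        self.n_bits = int(self.counts.shape[0])


def _hash_ints(values: list[int]) -> int:
    packed = struct.pack(f"<{len(values)}Q", *(v % (1 << 64) for v in values))
    digest = hashlib.blake2b(packed, digest_size=8).digest()
    return int.from_bytes(digest, "little")


def _atom_invariants(atom: Chem.Atom) -> list[int]:
    return [
        atom.GetAtomicNum(),
        atom.GetDegree(),
        atom.GetFormalCharge(),
        atom.GetTotalNumHs(),
        int(atom.IsInRing()),
    ]


def _bond_code(bond: Chem.Bond) -> int:
    # 10x the conventional bond order; aromatic -> 15, unspecified -> 0
    return int(round(bond.GetBondTypeAsDouble() * 10))


def enumerate_environments(
    ligand_smiles: str, max_radius: int = DEFAULT_RADIUS
) -> list[EnvironmentIdentifier]:
    """Enumerate hashed circular environments of every heavy atom.

    Each atom emits one identifier at radius 0 and one per larger radius
    at which its environment's atom set strictly grows, so a terminal
    atom of a short chain stops emitting once the whole fragment is
    covered.  At most ``(max_radius + 1) * n_heavy_atoms`` identifiers
    are produced.
    """
    mol = parse_smiles(ligand_smiles)
    n = mol.GetNumAtoms()
    out: list[EnvironmentIdentifier] = []

    ids = [_hash_ints([0] + _atom_invariants(a)) for a in mol.GetAtoms()]
    envs = [{i} for i in range(n)]
    for i in range(n):
        out.append(EnvironmentIdentifier(i, 0, ids[i]))

    neighbours: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        code = _bond_code(bond)
        neighbours[i].append((code, j))
        neighbours[j].append((code, i))

    for radius in range(1, max_radius + 1):
        new_ids = list(ids)
        new_envs = list(envs)
        for i in range(n):
            if not neighbours[i]:
                continue
            pairs = sorted((code, ids[j]) for code, j in neighbours[i])
            payload = [radius, ids[i]]
            for code, nbr_id in pairs:
                payload.extend((code, nbr_id))
            new_ids[i] = _hash_ints(payload)
            grown = set(envs[i])
            for _, j in neighbours[i]:
                grown |= envs[j]
            new_envs[i] = grown
        for i in range(n):
            if len(new_envs[i]) > len(envs[i]):
                out.append(EnvironmentIdentifier(i, radius, new_ids[i]))
        ids, envs = new_ids, new_envs

    return out


def fold(identifiers: list[int] | list[EnvironmentIdentifier], size: int) -> np.ndarray:
    """Fold integer identifiers into a count vector of the given length.

    ``counts[i]`` is the number of identifiers congruent to i modulo
    ``size``; the vector sum always equals the identifier count.
    """
    if size < 1:
        raise ValueError(f"fold size must be >= 1, got {size}")
    counts = np.zeros(size, dtype=np.int64)
    for ident in identifiers:
        h = ident.identifier if isinstance(ident, EnvironmentIdentifier) else ident
        counts[h % size] += 1
    return counts


def ligand_fingerprint(
    ligand_smiles: str,
    size: int = DEFAULT_N_BITS,
    max_radius: int = DEFAULT_RADIUS,
) -> LigandFingerprint:
    """Hash and fold one ligand into a count vector of length ``size``."""
    envs = enumerate_environments(ligand_smiles, max_radius)
    return LigandFingerprint(counts=fold(envs, size), source_smiles=ligand_smiles)
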