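"""Decompose full complex SMILES into metal, ligands and coordination number.

The curation pipeline for crystallographic SMILES: parse without
sanitisation, drop disconnected fragments that do not contain the metal
(counterions, co-crystallised solvent), delete the single metal atom from
the molecular graph, and write each remaining connected component back
out as one ligand SMILES.  The coordination number is the metal's degree
in the parsed graph — the count of metal-incident edges — so a
polydentate or polyhapto ligand contributes one per bound atom.  Bond
order labels of the metal-incident edges are recorded verbatim but never
consumed by the fingerprint.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TypeVar

from rdkit import Chem

from .complexes import ComplexInput, parse_complex_string
from .elements import METALS
from .errors import MissingMetalError, MultinuclearError
from .ligand import parse_smiles

logger = logging.getLogger(__name__)


@dataclass
class ComplexRecord:
    """One decomposed mononuclear complex."""

    metal_symbol: str
    ligand_smiles: list[str]
    coordination_number: int
    bond_descriptors: list[tuple[int, str]] = field(default_factory=list)
    provenance_id: str | None = None


def decompose_complex(
    complex_smiles: str,
    metal_set: Iterable[str] = METALS,
    provenance_id: str | None = None,
) -> ComplexRecord:
    """Strip counterions, delete the metal, and recover the ligands.

    Raises
    ------
    MissingMetalError / MultinuclearError
        Zero or more than one atom from ``metal_set`` in the input.
    SmilesParseError
        Unparseable input.
    """
    metal_set = frozenset(metal_set)
    mol = parse_smiles(complex_smiles)

    metal_indices = [
        a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() in metal_set
    ]
    if not metal_indices:
        raise MissingMetalError(f"no metal atom in {complex_smiles!r}")
    if len(metal_indices) > 1:
        raise MultinuclearError(
            f"{len(metal_indices)} metal atoms in {complex_smiles!r}; only "
            "mononuclear complexes are supported"
        )
    metal_idx = metal_indices[0]

    frags = Chem.GetMolFrags(mol)
    metal_frag = next(f for f in frags if metal_idx in f)
    dropped = len(frags) - 1
    if dropped:
        logger.info(
            "dropped %d counterion/solvent fragment(s) from %r",
            dropped, complex_smiles,
        )

    # keep only the metal-containing fragment
    keep = set(metal_frag)
    rw = Chem.RWMol(mol)
    for idx in sorted(range(mol.GetNumAtoms()), reverse=True):
        if idx not in keep:
            rw.RemoveAtom(idx)
    # re-locate the metal after renumbering
    metal_idx = next(
        a.GetIdx() for a in rw.GetAtoms() if a.GetSymbol() in metal_set
    )
    metal_atom = rw.GetAtomWithIdx(metal_idx)
    metal_symbol = metal_atom.GetSymbol()

    donor_bonds = [
        (b.GetOtherAtomIdx(metal_idx), str(b.GetBondType()))
        for b in metal_atom.GetBonds()
    ]
    coordination_number = len(donor_bonds)

    rw.RemoveAtom(metal_idx)
    remaining = rw.GetMol()
    old_to_new = lambda i: i if i < metal_idx else i - 1  # noqa: E731

    if remaining.GetNumAtoms() == 0:
        ligand_frags: tuple[tuple[int, ...], ...] = ()
    else:
        ligand_frags = Chem.GetMolFrags(remaining)
    atom_to_ligand = {
        idx: li for li, frag in enumerate(ligand_frags) for idx in frag
    }
    ligand_smiles = [
        Chem.MolFragmentToSmiles(remaining, atomsToUse=list(frag), canonical=True)
        for frag in ligand_frags
    ]
    bond_descriptors = [
        (atom_to_ligand[old_to_new(donor)], label)
        for donor, label in donor_bonds
    ]

    return ComplexRecord(
        metal_symbol=metal_symbol,
        ligand_smiles=ligand_smiles,
        coordination_number=coordination_number,
        bond_descriptors=bond_descriptors,
        provenance_id=provenance_id,
    )


T = TypeVar("T")


def filter_by_class_support(
    records: Sequence[T],
    labels: Sequence[int],
    min_count: int = 1000,
) -> tuple[list[T], list[int]]:
    """Keep only records whose class label has at least ``min_count`` examples.

    Relative order is preserved; returns the surviving records and labels.
    """
    if len(records) != len(labels):
        raise ValueError("records and labels must have equal length")
    support = Counter(labels)
    kept = [
        (r, lab) for r, lab in zip(records, labels) if support[lab] >= min_count
    ]
    if not kept:
        return [], []
    recs, labs = zip(*kept)
    return list(recs), list(labs)


def complex_to_component_string(record: ComplexRecord) -> str:
    """Dot-join the ligand SMILES and append the bracketed metal symbol.

    The output round-trips through :func:`parse_complex_string`,
    recovering the metal and the ligand multiset.
    """
    return ".".join([*record.ligand_smiles, f"[{record.metal_symbol}]"])


def record_to_input(record: ComplexRecord) -> ComplexInput:
    """Parse the record's component string back into a fingerprint input."""
    return parse_complex_string(complex_to_component_string(record))
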