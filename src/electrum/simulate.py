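"""Synthetic mononuclear complexes for testing without external datasets.

Complexes are assembled from a pool of small, chemically plausible
ligands with declared donor atoms: a metal is drawn, a target
coordination number is drawn, and ligands are sampled until their
denticities sum to the target.  Each record carries both the
dot-separated component string consumed by the fingerprint modules and a
fully bonded complex SMILES consumed by the decomposition module, so the
generator's coordination-number label is recoverable two independent
ways.  Ligand atoms are written with explicit hydrogen counts frozen at
their free-ligand values, which keeps the ligands' atom environments
identical between the component string and the assembled complex.

The generator emulates the schema of curated crystallographic datasets
(ligand SMILES, metal symbol, integer coordination-number and
oxidation-state labels); it makes no attempt to match real abundance
distributions, geometric plausibility, or thermodynamic stability.  The
synthetic oxidation-state column is a deterministic stand-in computed
from the metal identity, not a chemical assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .elements import METALS
from .errors import ElectrumError
from .ligand import parse_smiles

DEFAULT_CN_RANGE = (2, 6)


class GenerationError(ElectrumError):
    """Raised when a requested coordination number cannot be assembled."""


@dataclass(frozen=True)
class LigandPoolEntry:
    """A pool ligand: its SMILES and the atom indices that bind the metal."""

    smiles: str
    donor_atoms: tuple[int, ...]

    @property
    def denticity(self) -> int:
        return len(self.donor_atoms)


#: Small real ligands spanning denticities 1-3.  Donor indices follow the
#: atom order of the SMILES as written.
DEFAULT_LIGAND_POOL: tuple[LigandPoolEntry, ...] = (
    LigandPoolEntry("F", (0,)),
    LigandPoolEntry("Cl", (0,)),
    LigandPoolEntry("Br", (0,)),
    LigandPoolEntry("I", (0,)),
    LigandPoolEntry("O", (0,)),                    # aqua
    LigandPoolEntry("N", (0,)),                    # ammine
    LigandPoolEntry("S", (0,)),                    # sulfide donor
    LigandPoolEntry("C#N", (0,)),                  # cyanide, C-bound
    LigandPoolEntry("C#O", (0,)),                  # carbonyl
    LigandPoolEntry("CC#N", (2,)),                 # acetonitrile, N-bound
    LigandPoolEntry("c1ccncc1", (3,)),             # pyridine
    LigandPoolEntry("CP(C)C", (1,)),               # trimethylphosphine
    LigandPoolEntry("C=C", (0, 1)),                # eta-2 ethylene
    LigandPoolEntry("NCCN", (0, 3)),               # ethylenediamine
    LigandPoolEntry("NCCO", (0, 3)),               # aminoethanol chelate
    LigandPoolEntry("[O-]C(=O)C(=O)[O-]", (0, 5)),  # oxalate
    LigandPoolEntry("CC(=O)C=C(C)[O-]", (2, 6)),   # acetylacetonate-like
    LigandPoolEntry("c1ccnc(c1)-c1ccccn1", (3, 11)),  # 2,2'-bipyridine
    LigandPoolEntry("NCCNCCN", (0, 3, 6)),         # diethylenetriamine
    LigandPoolEntry("NCCOCCN", (0, 3, 6)),         # amino-ether chelate
)


@dataclass(frozen=True)
class SyntheticComplex:
    """One generated record."""

    component_string: str
    complex_smiles: str
    metal_symbol: str
    coordination_number: int
    ligand_smiles: tuple[str, ...]
    oxidation_state: int


@dataclass
class SyntheticDataset:
    """Generated complexes plus the parameters that produced them."""

    records: list[SyntheticComplex]
    seed: int
    metal_set: tuple[str, ...]
    cn_range: tuple[int, int]
    labels: np.ndarray | None = field(default=None)

    def __len__(self) -> int:
        return len(self.records)

    def component_strings(self) -> list[str]:
        return [r.component_string for r in self.records]

    def complex_smiles(self) -> list[str]:
        return [r.complex_smiles for r in self.records]

    def coordination_numbers(self) -> np.ndarray:
        return np.array([r.coordination_number for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "component_string": self.component_strings(),
                "complex_smiles": self.complex_smiles(),
                "metal": [r.metal_symbol for r in self.records],
                "coordination_number": self.coordination_numbers(),
                "oxidation_state": [r.oxidation_state for r in self.records],
            }
        )
        if self.labels is not None:
            df["label"] = self.labels
        return df


def assemble_complex_smiles(
    metal_symbol: str, ligands: Sequence[LigandPoolEntry]
) -> str:
    """Bond the pool ligands to a metal atom and emit one complex SMILES.

    Every declared donor atom gets a single bond to the metal; hydrogen
    counts on all ligand atoms are frozen at their free-ligand values so
    assembly does not alter the ligand's atom environments.
    """
    combined = Chem.RWMol()
    metal = Chem.Atom(metal_symbol)
    metal.SetNoImplicit(True)
    metal_idx = combined.AddAtom(metal)

    donor_indices: list[int] = []
    for entry in ligands:
        mol = parse_smiles(entry.smiles)
        offset = combined.GetNumAtoms()
        for atom in mol.GetAtoms():
            new_atom = Chem.Atom(atom)
            # freeze H counts: implicit-H re-perception after bonding to the
            # metal (or after re-parsing the complex) must not alter them
            new_atom.SetNumExplicitHs(atom.GetTotalNumHs())
            new_atom.SetNoImplicit(True)
            combined.AddAtom(new_atom)
        for bond in mol.GetBonds():
            combined.AddBond(
                offset + bond.GetBeginAtomIdx(),
                offset + bond.GetEndAtomIdx(),
                bond.GetBondType(),
            )
        donor_indices.extend(offset + d for d in entry.donor_atoms)

    for donor in donor_indices:
        combined.AddBond(metal_idx, donor, Chem.BondType.SINGLE)
    mol = combined.GetMol()
    mol.UpdatePropertyCache(strict=False)
    # write every atom bracketed with its H count: unsanitised re-parsing
    # must not re-derive implicit hydrogens on hypervalent donors
    return Chem.MolToSmiles(mol, canonical=True, allHsExplicit=True)


def _sample_ligands(
    rng: np.random.Generator,
    pool: Sequence[LigandPoolEntry],
    target_cn: int,
    max_attempts: int = 100,
) -> list[LigandPoolEntry]:
    for _ in range(max_attempts):
        chosen: list[LigandPoolEntry] = []
        remaining = target_cn
        while remaining > 0:
            eligible = [e for e in pool if e.denticity <= remaining]
            if not eligible:
                break
            entry = eligible[rng.integers(len(eligible))]
            chosen.append(entry)
            remaining -= entry.denticity
        if remaining == 0:
            return chosen
    raise GenerationError(
        f"coordination number {target_cn} unreachable from the ligand pool"
    )


def generate_complexes(
    n: int,
    metal_set: Iterable[str] = METALS,
    ligand_pool: Sequence[LigandPoolEntry] = DEFAULT_LIGAND_POOL,
    cn_range: tuple[int, int] = DEFAULT_CN_RANGE,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate ``n`` synthetic mononuclear complexes.

    Deterministic for a given seed and parameter set: regeneration is
    bit-identical.
    """
    if not ligand_pool:
        raise ValueError("ligand pool must be non-empty")
    lo, hi = cn_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid coordination-number range {cn_range}")
    if lo < min(e.denticity for e in ligand_pool):
        raise GenerationError(
            f"coordination number {lo} unreachable from the ligand pool"
        )
    metals = sorted(frozenset(metal_set))
    rng = np.random.default_rng(seed)

    records = []
    for _ in range(n):
        metal = metals[rng.integers(len(metals))]
        target_cn = int(rng.integers(lo, hi + 1))
        ligands = _sample_ligands(rng, ligand_pool, target_cn)
        component = ".".join([*(e.smiles for e in ligands), f"[{metal}]"])
        full = assemble_complex_smiles(metal, ligands)
        records.append(
            SyntheticComplex(
                component_string=component,
                complex_smiles=full,
                metal_symbol=metal,
                coordination_number=target_cn,
                ligand_smiles=tuple(e.smiles for e in ligands),
                oxidation_state=2 + metals.index(metal) % 3,
            )
        )
    return SyntheticDataset(
        records=records, seed=seed, metal_set=tuple(metals), cn_range=cn_range
    )


def inject_signal(
    dataset: SyntheticDataset,
    mode: str = "metal_dependent",
    seed: int = 0,
    n_classes: int = 2,
) -> SyntheticDataset:
    """Attach a classification label column with controllable signal.

    ``metal_dependent`` labels are a deterministic function of the metal
    identity alone, so only encodings that carry the metal can beat
    chance; ``ligand_dependent`` labels depend on the ligands' total
    heavy-atom count; ``none`` draws independent random labels that no
    encoding can learn.
    """
    n = len(dataset)
    metals = list(dataset.metal_set)
    if mode == "metal_dependent":
        labels = np.array(
            [metals.index(r.metal_symbol) % n_classes for r in dataset.records]
        )
    elif mode == "ligand_dependent":
        sizes = [
            sum(parse_smiles(s).GetNumAtoms() for s in r.ligand_smiles)
            for r in dataset.records
        ]
        labels = np.array([s % n_classes for s in sizes])
    elif mode == "none":
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, n_classes, size=n)
    else:
        raise ValueError(f"unknown signal mode {mode!r}")
    return SyntheticDataset(
        records=dataset.records,
        seed=dataset.seed,
        metal_set=dataset.metal_set,
        cn_range=dataset.cn_range,
        labels=labels,
    )
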