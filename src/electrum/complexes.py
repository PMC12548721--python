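"""Whole-complex fingerprints from dot-separated component strings.

A mononuclear complex is written as its ligand SMILES and its metal,
joined by dots (``"N.N.Cl.Cl.[Pt]"``).  Exactly one component must be a
single-atom metal; its position in the string is irrelevant.  Three
encodings are produced from the same parsed input:

``electrum``
    The element-wise sum of the folded per-ligand count vectors (the
    ligand part, length B, default 512) concatenated with the 86-bit
    electron-configuration encoding of the metal — 598 features at the
    default size.  Summation makes the descriptor invariant to ligand
    order and exactly additive in repeated ligands.
``ligands``
    The ligand part alone, with the metal discarded (negative control).
``atomic``
    The ligand part with the metal's atomic number appended as a single
    trailing scalar feature (length B + 1).

Because the ligand hash ignores stereochemistry, stereoisomers such as
cis- and trans-diamminedichloroplatinum(II) map to the same fingerprint;
this is a known limitation of the representation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import elements
from .elements import METALS, N_METAL_BITS, atomic_number, encode_metal
from .errors import MissingMetalError, MultinuclearError, SmilesParseError
from .ligand import DEFAULT_N_BITS, DEFAULT_RADIUS, ligand_fingerprint, parse_smiles

logger = logging.getLogger(__name__)

VARIANTS = ("electrum", "ligands", "atomic")

# bracketed single-atom SMILES: optional isotope, symbol, optional chirality/
# hydrogen/charge decorations, e.g. "[Ru]", "[Ru+2]", "[195Pt]"
_BRACKET_ATOM = re.compile(
    r"^\[(?P<isotope>\d+)?(?P<symbol>[A-Z][a-z]?)"
    r"(?P<rest>(?:@{1,2}|H\d?|\+{1,3}|-{1,3}|[+-]\d+)*)\]$"
)
_BARE_SYMBOL = re.compile(r"^[A-Z][a-z]?$")


@dataclass(frozen=True)
class ComplexInput:
    """A parsed dot-separated component string."""

    raw: str
    ligand_smiles: tuple[str, ...]
    metal_symbol: str


def _metal_symbol_of(component: str, metal_set: frozenset[str]) -> str | None:
    """Return the metal symbol if the component is a single-atom metal token."""
    if _BARE_SYMBOL.match(component) and component in metal_set:
        return component
    m = _BRACKET_ATOM.match(component)
    if m and m.group("symbol") in metal_set:
        if m.group("rest") or m.group("isotope"):
            logger.debug(
                "metal token %r carries annotations; they are ignored for encoding",
                component,
            )
        return m.group("symbol")
    return None


def _contains_metal_atom(smiles: str, metal_set: frozenset[str]) -> bool:
    mol = parse_smiles(smiles)
    return any(a.GetSymbol() in metal_set for a in mol.GetAtoms())


def parse_complex_string(
    raw: str, metal_set: Iterable[str] = METALS
) -> ComplexInput:
    """Split a component string into its ligands and its metal.

    Raises
    ------
    MissingMetalError
        No component is a single-atom metal from ``metal_set``.
    MultinuclearError
        More than one metal component, or a metal atom embedded in a
        larger ligand fragment (metalloligands are unsupported).
    SmilesParseError
        Empty component or unparseable ligand.
    """
    metal_set = frozenset(metal_set)
    if not raw or not raw.strip():
        raise SmilesParseError(raw, "empty component string")
    components = [c.strip() for c in raw.split(".")]
    if any(not c for c in components):
        raise SmilesParseError(raw, "empty component between dots")

    metals: list[str] = []
    ligands: list[str] = []
    for comp in components:
        symbol = _metal_symbol_of(comp, metal_set)
        if symbol is not None:
            metals.append(symbol)
        else:
            ligands.append(comp)

    if len(metals) == 0:
        raise MissingMetalError(f"no metal component in {raw!r}")
    if len(metals) > 1:
        raise MultinuclearError(
            f"{len(metals)} metal components in {raw!r}; only mononuclear "
            "complexes are supported"
        )
    if not ligands:
        raise SmilesParseError(raw, "no ligand components")
    for lig in ligands:
        if _contains_metal_atom(lig, metal_set):
            raise MultinuclearError(
                f"ligand component {lig!r} embeds a metal atom; "
                "metalloligands are unsupported"
            )
    return ComplexInput(raw=raw, ligand_smiles=tuple(ligands), metal_symbol=metals[0])


@dataclass
class ElectrumFingerprint:
    """Ligand count vector plus 86-bit metal block."""

    ligand_part: np.ndarray
    metal_part: np.ndarray
    source: ComplexInput

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.ligand_part, self.metal_part.astype(np.int64)])


def _ligand_part(
    parsed: ComplexInput, size: int, max_radius: int
) -> np.ndarray:
    total = np.zeros(size, dtype=np.int64)
    for lig in parsed.ligand_smiles:
        total += ligand_fingerprint(lig, size, max_radius).counts
    return total


def electrum_fingerprint(
    parsed: ComplexInput,
    size: int = DEFAULT_N_BITS,
    max_radius: int = DEFAULT_RADIUS,
) -> ElectrumFingerprint:
    """Assemble the full fingerprint: summed ligand part + metal block."""
    return ElectrumFingerprint(
        ligand_part=_ligand_part(parsed, size, max_radius),
        metal_part=encode_metal(parsed.metal_symbol),
        source=parsed,
    )


def ligands_only_fingerprint(
    parsed: ComplexInput,
    size: int = DEFAULT_N_BITS,
    max_radius: int = DEFAULT_RADIUS,
) -> np.ndarray:
    """The summed ligand part alone; the metal is discarded."""
    return _ligand_part(parsed, size, max_radius)


def atomic_fingerprint(
    parsed: ComplexInput,
    size: int = DEFAULT_N_BITS,
    max_radius: int = DEFAULT_RADIUS,
) -> np.ndarray:
    """Ligand part with the metal's raw atomic number as one trailing feature."""
    return np.concatenate(
        [
            _ligand_part(parsed, size, max_radius),
            np.array([atomic_number(parsed.metal_symbol)], dtype=np.int64),
        ]
    )


class ComplexFingerprinter(BaseEstimator, TransformerMixin):
    """Encode component strings into fingerprint matrices.

    A stateless scikit-learn transformer: ``fit`` only validates the
    parameters, ``transform`` maps an iterable of dot-separated component
    strings to a dense integer matrix.

    Parameters
    ----------
    variant : {"electrum", "ligands", "atomic"}, default "electrum"
        Which encoding to emit.
    n_bits : int, default 512
        Length of the folded ligand part.
    radius : int, default 2
        Maximum circular-environment radius in bonds.
    metal_set : iterable of str, optional
        Symbols accepted as the metal component; defaults to the
        package's 48-element metal set.

    Attributes
    ----------
    n_features_out_ : int
        Columns of the transformed matrix: ``n_bits + 86`` for electrum,
        ``n_bits`` for ligands, ``n_bits + 1`` for atomic.
    """

    def __init__(
        self,
        variant: str = "electrum",
        n_bits: int = DEFAULT_N_BITS,
        radius: int = DEFAULT_RADIUS,
        metal_set: Iterable[str] | None = None,
    ):
        self.variant = variant
        self.n_bits = n_bits
        self.radius = radius
        self.metal_set = metal_set

    def _validate(self) -> frozenset[str]:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"variant must be one of {VARIANTS}, got {self.variant!r}"
            )
        if self.n_bits < 1:
            raise ValueError("n_bits must be positive")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        return frozenset(self.metal_set) if self.metal_set is not None else METALS

    def fit(self, X=None, y=None) -> "ComplexFingerprinter":
        self._validate()
        extra = {"electrum": N_METAL_BITS, "ligands": 0, "atomic": 1}[self.variant]
        self.n_features_out_ = self.n_bits + extra
        return self

    def encode_one(self, component_string: str) -> np.ndarray:
        """Fingerprint a single component string as a 1-D integer vector."""
        metal_set = self._validate()
        parsed = parse_complex_string(component_string, metal_set)
        if self.variant == "electrum":
            return electrum_fingerprint(parsed, self.n_bits, self.radius).combined
        if self.variant == "ligands":
            return ligands_only_fingerprint(parsed, self.n_bits, self.radius)
        return atomic_fingerprint(parsed, self.n_bits, self.radius)

    def transform(self, X: Sequence[str]) -> np.ndarray:
        """Encode a sequence of component strings into a (n, d) matrix."""
        self.fit()
        rows = [self.encode_one(s) for s in X]
        if not rows:
            return np.zeros((0, self.n_features_out_), dtype=np.int64)
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        self.fit()
        names = [f"lig_{i}" for i in range(self.n_bits)]
        if self.variant == "electrum":
            offset = 0
            for label, cap in elements.SUBSHELLS:
                names += [f"metal_{label}_{k}" for k in range(cap)]
                offset += cap
        elif self.variant == "atomic":
            names.append("metal_Z")
        return np.asarray(names, dtype=object)
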