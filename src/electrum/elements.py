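"""Ground-state electron configurations and the 86-bit metal encoding.

The metal block of the fingerprint is a fixed-width binary vector with one
bit per electron slot of the 15 subshells through 6p, laid out in Madelung
filling order (1s 2s 2p 3s 3p 4s 3d 4p 5s 4d 5p 6s 4f 5d 6p; 86 slots in
total, the electron count of radon).  Within each subshell block the first
k bits are set, where k is the neutral ground-state occupancy of that
subshell, so the popcount of the encoding equals min(Z, 86).

Configurations come from an embedded table
(``data/electron_configurations.csv``) that records tabulated neutral
ground states, including the aufbau exceptions (Cr, Cu, Nb, Mo, Ru, Rh,
Pd, Ag, La, Ce, Gd, Pt, Au).  Elements heavier than radon keep only their
in-window electrons: protactinium's five electrons beyond the radon core
(7s/5f/6d) are dropped with a warning.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .errors import UnsupportedElementError

logger = logging.getLogger(__name__)

#: (label, capacity) pairs in Madelung filling order.
SUBSHELLS: tuple[tuple[str, int], ...] = (
    ("1s", 2), ("2s", 2), ("2p", 6), ("3s", 2), ("3p", 6), ("4s", 2),
    ("3d", 10), ("4p", 6), ("5s", 2), ("4d", 10), ("5p", 6), ("6s", 2),
    ("4f", 14), ("5d", 10), ("6p", 6),
)

#: Width of the metal block: total slot count of the subshells above.
N_METAL_BITS: int = sum(cap for _, cap in SUBSHELLS)  # 86

#: The transition and post-transition metals covered by the complex
#: datasets this package targets (including Pd and Ag, which dominate
#: curated crystallographic complex sets).
METALS: frozenset[str] = frozenset({
    "Ag", "Bi", "Cd", "Ce", "Cr", "Co", "Cu", "Dy", "Er", "Eu", "Gd",
    "Ga", "Ge", "Au", "Hf", "Ho", "In", "Ir", "Fe", "La", "Pb", "Lu",
    "Mn", "Hg", "Mo", "Nd", "Ni", "Nb", "Os", "Pa", "Pd", "Pt", "Pr",
    "Re", "Rh", "Ru", "Sm", "Sc", "Ta", "Tc", "Tb", "Tl", "Tm", "Sn",
    "Ti", "W", "V", "Y", "Zn", "Zr",
})


@dataclass(frozen=True)
class ElectronConfiguration:
    """Neutral-atom ground-state subshell occupancies.

    Attributes
    ----------
    element_symbol : str
        Chemical symbol.
    atomic_number : int
        Z of the neutral atom.
    occupancies : tuple of (str, int)
        ``(subshell label, electron count)`` pairs in Madelung order for
        the 15 subshells through 6p.  For elements beyond radon only the
        in-window electrons appear, so the occupancy sum is min(Z, 86).
    """

    element_symbol: str
    atomic_number: int
    occupancies: tuple[tuple[str, int], ...]

    @property
    def n_electrons_in_window(self) -> int:
        return sum(n for _, n in self.occupancies)


@lru_cache(maxsize=1)
def _configuration_table() -> dict[str, ElectronConfiguration]:
    path = resources.files("electrum.data").joinpath("electron_configurations.csv")
    table: dict[str, ElectronConfiguration] = {}
    with path.open() as fh:
        reader = csv.DictReader(fh)
        labels = [label for label, _ in SUBSHELLS]
        for row in reader:
            occ = tuple((label, int(row[label])) for label in labels)
            cfg = ElectronConfiguration(
                element_symbol=row["symbol"],
                atomic_number=int(row["atomic_number"]),
                occupancies=occ,
            )
            table[cfg.element_symbol] = cfg
    return table


def supported_elements() -> list[str]:
    """Symbols present in the embedded configuration table."""
    return sorted(_configuration_table(), key=atomic_number)


def ground_state_configuration(element_symbol: str) -> ElectronConfiguration:
    """Look up the tabulated neutral ground-state configuration.

    Raises
    ------
    UnsupportedElementError
        If the symbol is absent from the embedded table.
    """
    try:
        return _configuration_table()[element_symbol]
    except KeyError:
        raise UnsupportedElementError(element_symbol) from None


def atomic_number(element_symbol: str) -> int:
    """Z of a supported element (used by the Atomic baseline encoding)."""
    return ground_state_configuration(element_symbol).atomic_number


def encode_metal(element_symbol: str) -> np.ndarray:
    """86-bit binary electron-configuration encoding of a neutral atom.

    One slot per electron through the 6p subshell; within each subshell
    block the first k slots are set, k being the ground-state occupancy.
    ``popcount == min(Z, 86)``; radon sets every bit.

    Returns
    -------
    numpy.ndarray of uint8, shape (86,)
    """
    cfg = ground_state_configuration(element_symbol)
    if cfg.atomic_number > N_METAL_BITS:
        logger.warning(
            "%s has Z=%d > %d; electrons beyond the 6p window are not encoded",
            element_symbol, cfg.atomic_number, N_METAL_BITS,
        )
    bits = np.zeros(N_METAL_BITS, dtype=np.uint8)
    offset = 0
    for (label, cap), (occ_label, occ) in zip(SUBSHELLS, cfg.occupancies):
        assert label == occ_label
        bits[offset:offset + occ] = 1
        offset += cap
    return bits
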