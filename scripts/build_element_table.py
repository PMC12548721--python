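"""Regenerate the embedded ground-state electron-configuration table.

Fills subshells in Madelung order (1s 2s 2p 3s 3p 4s 3d 4p 5s 4d 5p 6s 4f
5d 6p) and then applies the tabulated ground-state exceptions, so the table
matches standard neutral-atom configurations rather than strict aufbau
filling.  Covers every element with Z <= 86 plus protactinium, whose five
electrons beyond the radon core lie outside the 86-slot window and are
therefore not stored.

Run from the repository root:

    python scripts/build_element_table.py
"""

import csv
import pathlib

from rdkit import Chem

SUBSHELLS = [
    ("1s", 2), ("2s", 2), ("2p", 6), ("3s", 2), ("3p", 6), ("4s", 2),
    ("3d", 10), ("4p", 6), ("5s", 2), ("4d", 10), ("5p", 6), ("6s", 2),
    ("4f", 14), ("5d", 10), ("6p", 6),
]

# symbol -> {subshell: occupancy} overrides relative to Madelung filling
EXCEPTIONS = {
    "Cr": {"3d": 5, "4s": 1},
    "Cu": {"3d": 10, "4s": 1},
    "Nb": {"4d": 4, "5s": 1},
    "Mo": {"4d": 5, "5s": 1},
    "Ru": {"4d": 7, "5s": 1},
    "Rh": {"4d": 8, "5s": 1},
    "Pd": {"4d": 10, "5s": 0},
    "Ag": {"4d": 10, "5s": 1},
    "La": {"4f": 0, "5d": 1},
    "Ce": {"4f": 1, "5d": 1},
    "Gd": {"4f": 7, "5d": 1},
    "Pt": {"5d": 9, "6s": 1},
    "Au": {"5d": 10, "6s": 1},
}


def madelung_fill(n_electrons: int) -> dict[str, int]:
    occ = {}
    left = n_electrons
    for label, cap in SUBSHELLS:
        occ[label] = min(left, cap)
        left -= occ[label]
    return occ


def main() -> None:
    pt = Chem.GetPeriodicTable()
    rows = []
    for z in range(1, 87):
        symbol = pt.GetElementSymbol(z)
        occ = madelung_fill(z)
        occ.update(EXCEPTIONS.get(symbol, {}))
        assert sum(occ.values()) == z, symbol
        rows.append((symbol, z, occ))
    # Pa: [Rn] 5f2 6d1 7s2 -- everything past the radon core is out of window
    rows.append(("Pa", 91, madelung_fill(86)))

    out = pathlib.Path(__file__).resolve().parents[1] / "src" / "electrum" / "data" / "electron_configurations.csv"
    with out.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["symbol", "atomic_number"] + [s for s, _ in SUBSHELLS])
        for symbol, z, occ in rows:
            writer.writerow([symbol, z] + [occ[s] for s, _ in SUBSHELLS])
    print(f"wrote {len(rows)} rows to {out}")


if __name__ == "__main__":
    main()
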