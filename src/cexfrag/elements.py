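"""Atomic mass constants.

A small, versioned constants table rather than a dependency: every m/z this
package prints traces back to these numbers, so they are pinned here and
exportable to JSON.  Monoisotopic masses are CODATA/AME2020 values for the
principal isotope; average atomic weights are the IUPAC 2021 conventional
values.  All masses in unified atomic mass units (u).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

CONSTANTS_VERSION = "CODATA2018/AME2020 + IUPAC-2021"

#: Electron rest mass in u (CODATA 2018).
ELECTRON_MASS = 0.000548579909

#: Van der Waals radii (Å), used only by the surrogate force field's
#: short-range repulsion.
VDW_RADIUS = {"H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

#: Standard atomic masses of the most abundant isotope (u).
MONOISOTOPIC_MASS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

#: IUPAC conventional atomic weights (u).
AVERAGE_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}

#: Atomic masses used for dynamics (u); average weights are adequate here.
DYNAMICS_MASS = AVERAGE_MASS


@dataclass(frozen=True)
class ElementTable:
    """Lookup for per-element monoisotopic and average masses.

    Separated from module-level dicts so an alternative table (e.g. a future
    IUPAC revision) can be swapped in without touching callers.
    """

    monoisotopic: dict
    average: dict
    electron_mass: float = ELECTRON_MASS
    version: str = CONSTANTS_VERSION

    def __post_init__(self) -> None:
        for table in (self.monoisotopic, self.average):
            for sym, m in table.items():
                if m <= 0:
                    raise ValueError(f"non-positive mass for {sym}")
        if not 0 < self.electron_mass < 1e-3:
            raise ValueError("electron mass out of range")

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "electron_mass_u": self.electron_mass,
                "monoisotopic_u": self.monoisotopic,
                "average_u": self.average,
            },
            indent=2,
            sort_keys=True,
        )


DEFAULT_ELEMENTS = ElementTable(MONOISOTOPIC_MASS, AVERAGE_MASS)
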