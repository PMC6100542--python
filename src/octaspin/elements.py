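"""Pauling electronegativities for the elements appearing in the ligand library.

Values are the standard Pauling scale to two decimals (Allred's 1961
thermochemical revision, as tabulated in CRC Handbook of Chemistry and
Physics). The table is immutable at runtime: descriptor values must not
drift between featurization calls.
"""

from __future__ import annotations

from types import MappingProxyType
from typing import Mapping

#: Pauling electronegativity, dimensionless.
PAULING: Mapping[str, float] = MappingProxyType(
    {
        "H": 2.20,
        "B": 2.04,
        "C": 2.55,
        "N": 3.04,
        "O": 3.44,
        "F": 3.98,
        "P": 2.19,
        "S": 2.58,
        "Cl": 3.16,
        "Br": 2.96,
        "I": 2.66,
        # first-row transition metals (present for completeness; the metal
        # never enters an intra-ligand electronegativity difference)
        "Cr": 1.66,
        "Mn": 1.55,
        "Fe": 1.83,
        "Co": 1.88,
        "Ni": 1.91,
    }
)


class ElectronegativityLookupError(KeyError):
    """Raised when an element has no tabulated electronegativity."""


class ElectronegativityTable:
    """Read-only element -> Pauling electronegativity mapping."""

    def __init__(self, values: Mapping[str, float] = PAULING) -> None:
        for el, chi in values.items():
            if not 0.5 < chi < 4.5:
                raise ValueError(f"implausible electronegativity for {el}: {chi}")
        self._values = MappingProxyType(dict(values))

    def __contains__(self, element: str) -> bool:
        return element in self._values

    def __getitem__(self, element: str) -> float:
        try:
            return self._values[element]
        except KeyError:
            raise ElectronegativityLookupError(
                f"no Pauling electronegativity tabulated for element {element!r}"
            ) from None

    def items(self):
        return self._values.items()


#: Shared default instance.
DEFAULT_TABLE = ElectronegativityTable()
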