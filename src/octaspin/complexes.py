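"""Octahedral complex specifications and construction rules.

A complex is a first-row transition metal in a common oxidation state with
one equatorial and one axial ligand type filling the six octahedral
coordination sites (four equatorial, two axial), plus the Hartree-Fock
exchange fraction a_HF of the hybrid functional the target property refers
to. High- and low-spin multiplicities are fixed per metal/oxidation state
from the atomic spectra ground and lowest consistent excited configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .ligands import LigandGraph

__all__ = [
    "ComplexSpec",
    "ValidationReport",
    "spin_pair_for",
    "validate_complex",
    "SPIN_PAIRS",
    "METALS",
]

METALS = ("Cr", "Mn", "Fe", "Co", "Ni")

#: (metal, oxidation) -> (high-spin, low-spin) multiplicity. Cr2+/Mn3+ use
#: the quintet-triplet pair (no tabulated Mn3+ singlet); Ni is 2+ only.
SPIN_PAIRS: dict[tuple[str, int], tuple[int, int]] = {
    ("Cr", 2): (5, 3),
    ("Cr", 3): (4, 2),
    ("Mn", 2): (6, 2),
    ("Mn", 3): (5, 3),
    ("Fe", 2): (5, 1),
    ("Fe", 3): (6, 2),
    ("Co", 2): (4, 2),
    ("Co", 3): (5, 1),
    ("Ni", 2): (3, 1),
}

#: Copies of the equatorial/axial ligand needed to fill each slot, by denticity.
EQ_COPIES = {1: 4, 2: 2, 4: 1}
AX_COPIES = {1: 2, 2: 1}


class SpinStateDomainError(ValueError):
    """Metal/oxidation state outside the supported domain."""


def spin_pair_for(metal: str, oxidation: int) -> tuple[int, int]:
    """Return the fixed (high, low) spin multiplicities for a metal/oxidation state."""
    try:
        return SPIN_PAIRS[(metal, oxidation)]
    except KeyError:
        raise SpinStateDomainError(
            f"{metal}({oxidation}) outside the supported domain: "
            + ", ".join(f"{m}{o}+" for m, o in SPIN_PAIRS)
        ) from None


@dataclass(frozen=True)
class ComplexSpec:
    """One octahedral complex: metal, oxidation state, ligand filling, a_HF."""

    metal: str
    oxidation: int
    eq_ligand: LigandGraph
    ax_ligand: LigandGraph
    a_hf: float = 0.20
    spin_pair: tuple[int, int] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.spin_pair is None and (self.metal, self.oxidation) in SPIN_PAIRS:
            object.__setattr__(self, "spin_pair", SPIN_PAIRS[(self.metal, self.oxidation)])

    @property
    def is_homoleptic(self) -> bool:
        return self.eq_ligand == self.ax_ligand

    @property
    def eq_copies(self) -> int:
        return EQ_COPIES[self.eq_ligand.denticity]

    @property
    def ax_copies(self) -> int:
        return AX_COPIES[self.ax_ligand.denticity]

    def ligand_copies(self) -> list[LigandGraph]:
        """All ligand copies in the complex (equatorial first)."""
        out: list[LigandGraph] = []
        if self.eq_ligand.denticity in EQ_COPIES:
            out += [self.eq_ligand] * EQ_COPIES[self.eq_ligand.denticity]
        if self.ax_ligand.denticity in AX_COPIES:
            out += [self.ax_ligand] * AX_COPIES[self.ax_ligand.denticity]
        return out

    def at_a_hf(self, a_hf: float) -> "ComplexSpec":
        return replace(self, a_hf=a_hf)

    def label(self) -> str:
        return f"{self.metal}({self.oxidation}) eq={self.eq_ligand.name} ax={self.ax_ligand.name} a_HF={self.a_hf:.2f}"


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    messages: tuple[str, ...]

    def __bool__(self) -> bool:
        return self.ok


def validate_complex(spec: ComplexSpec) -> ValidationReport:
    """Check every ComplexSpec invariant; report all violations, raise nothing."""
    messages: list[str] = []
    if spec.metal not in METALS:
        messages.append(f"metal {spec.metal!r} not one of {METALS}")
    if (spec.metal, spec.oxidation) not in SPIN_PAIRS:
        messages.append(
            f"{spec.metal}({spec.oxidation}) has no defined high/low spin pair "
            f"(supported: {', '.join(f'{m}{o}+' for m, o in SPIN_PAIRS)})"
        )
    elif spec.spin_pair is not None and spec.spin_pair != SPIN_PAIRS[(spec.metal, spec.oxidation)]:
        messages.append(
            f"spin pair {spec.spin_pair} does not match the fixed pair "
            f"{SPIN_PAIRS[(spec.metal, spec.oxidation)]} for {spec.metal}({spec.oxidation})"
        )
    d_eq = spec.eq_ligand.denticity
    d_ax = spec.ax_ligand.denticity
    if d_eq not in EQ_COPIES:
        messages.append(
            f"equatorial ligand {spec.eq_ligand.name!r} has denticity {d_eq}; the "
            "equatorial slot holds 4 monodentate, 2 bidentate or 1 tetradentate ligand"
        )
    if d_ax not in AX_COPIES:
        messages.append(
            f"axial ligand {spec.ax_ligand.name!r} has denticity {d_ax}; the axial "
            "slot holds 2 monodentate or 1 bidentate ligand"
        )
    if not messages:
        total = sum(l.denticity for l in spec.ligand_copies())
        if total != 6:  # unreachable given the slot tables; kept as a belt-and-braces check
            messages.append(f"coordination number {total} != 6")
    if not 0.0 <= spec.a_hf <= 0.30:
        messages.append(f"a_HF {spec.a_hf} outside the sampled range [0.00, 0.30]")
    return ValidationReport(ok=not messages, messages=tuple(messages))
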