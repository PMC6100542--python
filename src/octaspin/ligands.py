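"""Ligand molecular graphs and the bundled 16-ligand library.

A ligand is represented purely by connectivity: element-labelled atoms
(hydrogens included but flagged as not heavy), bonds with fractional bond
orders (1, 1.5, 2, 3), the metal-binding "connecting" atoms, formal charge
and denticity. No 3D information is stored anywhere — the descriptor set is
deliberately graph-theoretic so that it is invariant to conformation and
insensitive to molecule size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping, Sequence

import networkx as nx

from .elements import DEFAULT_TABLE, ElectronegativityTable

__all__ = [
    "LigandGraph",
    "LigandLibraryError",
    "load_ligand_library",
]


class LigandLibraryError(RuntimeError):
    """Raised when the bundled ligand library is missing or corrupt."""


@dataclass(frozen=True)
class LigandGraph:
    """Connectivity graph of a single ligand.

    Parameters
    ----------
    name:
        Short identifier used in datasets and CLI input (e.g. ``"CO"``,
        ``"en"``).
    atoms:
        Element symbols, one per atom; hydrogens included.
    bonds:
        ``(i, j, order)`` triples with ``order > 0`` (1, 1.5, 2 or 3).
    connecting_atoms:
        Indices of the atoms that bind the metal; length equals denticity.
    charge:
        Formal charge of the free ligand (0 to -2 in the training domain).
    denticity:
        Number of metal-binding atoms contributed by one ligand copy.
    """

    name: str
    atoms: tuple[str, ...]
    bonds: tuple[tuple[int, int, float], ...]
    connecting_atoms: tuple[int, ...]
    charge: int
    denticity: int
    full_name: str = ""
    index: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants --------------------------------------------------------

    def validate(self, table: ElectronegativityTable = DEFAULT_TABLE) -> None:
        n = len(self.atoms)
        if n == 0:
            raise ValueError(f"{self.name}: ligand has no atoms")
        if not self.connecting_atoms:
            raise ValueError(f"{self.name}: no connecting atoms")
        if len(self.connecting_atoms) != self.denticity:
            raise ValueError(
                f"{self.name}: denticity {self.denticity} != "
                f"{len(self.connecting_atoms)} connecting atoms"
            )
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"{self.name}: bond ({i}, {j}) references invalid atoms")
            if order <= 0:
                raise ValueError(f"{self.name}: non-positive bond order {order}")
        for idx in self.connecting_atoms:
            if not 0 <= idx < n:
                raise ValueError(f"{self.name}: connecting atom index {idx} out of range")
        for el in self.atoms:
            table[el]  # raises ElectronegativityLookupError if unknown
        if not nx.is_connected(self.to_graph()):
            raise ValueError(f"{self.name}: ligand graph is disconnected")

    # -- graph views -------------------------------------------------------

    def to_graph(self) -> nx.Graph:
        """Full molecular graph (hydrogens included), bond order on edges."""
        g = nx.Graph()
        for i, el in enumerate(self.atoms):
            g.add_node(i, element=el, heavy=el != "H")
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=float(order))
        return g

    def heavy_atoms(self) -> list[int]:
        return [i for i, el in enumerate(self.atoms) if el != "H"]

    @property
    def n_atoms(self) -> int:
        """Total atom count, hydrogens included."""
        return len(self.atoms)

    @property
    def is_atomic(self) -> bool:
        return len(self.atoms) == 1

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "atoms": list(self.atoms),
            "bonds": [[i, j, order] for i, j, order in self.bonds],
            "connecting_atoms": list(self.connecting_atoms),
            "charge": self.charge,
            "denticity": self.denticity,
        }
        if self.full_name:
            d["full_name"] = self.full_name
        if self.index is not None:
            d["index"] = self.index
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "LigandGraph":
        return cls(
            name=str(d["name"]),
            atoms=tuple(d["atoms"]),
            bonds=tuple((int(i), int(j), float(o)) for i, j, o in d["bonds"]),
            connecting_atoms=tuple(int(i) for i in d["connecting_atoms"]),
            charge=int(d["charge"]),
            denticity=int(d["denticity"]),
            full_name=str(d.get("full_name", "")),
            index=d.get("index"),
        )


class LigandLibrary(Mapping[str, LigandGraph]):
    """Name-indexed, insertion-ordered collection of ligands."""

    def __init__(self, ligands: Sequence[LigandGraph]) -> None:
        self._ligands: dict[str, LigandGraph] = {}
        for lig in ligands:
            if lig.name in self._ligands:
                raise LigandLibraryError(f"duplicate ligand name {lig.name!r}")
            self._ligands[lig.name] = lig

    def __getitem__(self, name: str) -> LigandGraph:
        try:
            return self._ligands[name]
        except KeyError:
            raise KeyError(
                f"unknown ligand {name!r}; known ligands: {', '.join(self._ligands)}"
            ) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._ligands)

    def __len__(self) -> int:
        return len(self._ligands)


def load_ligand_library(path: str | None = None) -> LigandLibrary:
    """Load the ligand library (the bundled 16-ligand set by default).

    The bundled set spans the spectrochemical series from weak-field chloride
    to strong-field carbonyl: nine monodentate, six bidentate and one
    tetradentate ligand, with Cl, S, C, N and O connecting atoms. Every entry
    is validated against the LigandGraph invariants at load time.
    """
    try:
        if path is None:
            src = resources.files("octaspin.data").joinpath("ligands.json")
            raw = src.read_text()
            origin = str(src)
        else:
            with open(path) as fh:
                raw = fh.read()
            origin = path
        doc = json.loads(raw)
        ligands = [LigandGraph.from_dict(d) for d in doc["ligands"]]
    except (OSError, json.JSONDecodeError, KeyError, TypeError) as exc:
        raise LigandLibraryError(
            f"could not load ligand library from {path or 'bundled octaspin/data/ligands.json'}: {exc}"
        ) from exc
    return LigandLibrary(ligands)
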