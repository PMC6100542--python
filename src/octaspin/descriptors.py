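"""Heuristic graph descriptors for octahedral transition-metal complexes.

The descriptor philosophy balances metal-proximal information (the identity
and bonding environment of the atom that touches the metal) against
deliberate blindness to distant substitutions, so that e.g. a substituted
porphyrin featurizes identically to base porphine. Building blocks:

* Pauling electronegativity differences between each ligand connecting atom
  and its bonded neighbours (hydrogens included, the metal excluded), pooled
  over all ligand copies in the complex into max/min/sum statistics;
* the truncated Kier shape index: the second-order Kier index
  2-kappa = (A-1)(A-2)^2 / (2P)^2 evaluated on the heavy-atom subgraph of
  atoms within three bonds of a connecting atom, where 2P counts unique
  length-two paths and A counts the retained heavy atoms;
* the maximum bond order at the connecting atom (rigidity proxy, 0 for an
  atomic ligand);
* categorical metal identity and ligand connecting-atom element, plus
  oxidation state, ligand formal charge, denticity and the exchange
  fraction a_HF.

Seven nested descriptor sets (a-g) are assembled from these blocks; set g
(15 descriptors: 5 whole-complex, 5 per ligand class) is the production
input space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .complexes import ComplexSpec
from .elements import DEFAULT_TABLE, ElectronegativityTable
from .ligands import LigandGraph

__all__ = [
    "DeltaChiSet",
    "DescriptorVector",
    "DESCRIPTOR_SETS",
    "delta_chi",
    "complex_chi_stats",
    "truncated_kier",
    "count_length2_paths",
    "connecting_bond_order",
    "featurize",
]

DESCRIPTOR_SETS = ("a", "b", "c", "d", "e", "f", "g")

#: Connecting-atom element levels in the training domain (Fig-1 palette order).
CONNECTING_ATOM_LEVELS = ("Cl", "S", "C", "N", "O")

#: Bond-radius (in bonds) of the Kier truncation around the connecting atoms.
KIER_TRUNCATION_RADIUS = 3


@dataclass(frozen=True)
class DeltaChiSet:
    """Electronegativity differences chi(connecting atom) - chi(neighbour).

    One entry per (connecting atom, bonded ligand atom) pair; empty for
    atomic ligands, which have no intra-ligand neighbours.
    """

    ligand: str
    values: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.values)


def delta_chi(
    ligand: LigandGraph, table: ElectronegativityTable = DEFAULT_TABLE
) -> DeltaChiSet:
    """Intra-ligand electronegativity differences at the connecting atom(s).

    The difference is taken from the connecting atom to every atom bonded to
    it within the ligand (hydrogens count; the metal is never a neighbour).
    """
    values: list[float] = []
    for c in ligand.connecting_atoms:
        chi_c = table[ligand.atoms[c]]
        for nb in ligand.neighbors(c):
            values.append(round(chi_c - table[ligand.atoms[nb]], 12))
    return DeltaChiSet(ligand=ligand.name, values=tuple(values))


def complex_chi_stats(
    spec: ComplexSpec, table: ElectronegativityTable = DEFAULT_TABLE
) -> tuple[float, float, float]:
    """(max, min, sum) of delta-chi pooled over every ligand copy in the complex.

    Each of the six coordination sites contributes through its ligand copy
    (four equatorial + two axial for monodentates, etc.), so a homoleptic
    hexacarbonyl sums six copies of the single CO difference. Atomic ligands
    contribute empty sets; if every ligand is atomic the statistics are all
    zero by convention.
    """
    pooled: list[float] = []
    for lig in spec.ligand_copies():
        pooled.extend(delta_chi(lig, table).values)
    if not pooled:
        return (0.0, 0.0, 0.0)
    return (max(pooled), min(pooled), sum(pooled))


def _truncated_heavy_subgraph(ligand: LigandGraph) -> nx.Graph:
    """Heavy-atom subgraph of atoms within three bonds of any connecting atom.

    Distances are measured on the full molecular graph (hydrogens present);
    only heavy atoms are retained in the returned subgraph.
    """
    g = ligand.to_graph()
    keep: set[int] = set()
    for c in ligand.connecting_atoms:
        keep.update(
            nx.single_source_shortest_path_length(g, c, cutoff=KIER_TRUNCATION_RADIUS)
        )
    heavy = [i for i in keep if ligand.atoms[i] != "H"]
    return g.subgraph(heavy)


def count_length2_paths(graph: nx.Graph) -> int:
    """Number of unique length-two paths (unordered triples, distinct endpoints)."""
    return sum(d * (d - 1) // 2 for _, d in graph.degree())


def truncated_kier(ligand: LigandGraph) -> float:
    """Truncated second-order Kier shape index of a ligand.

    2-kappa = (A-1)(A-2)^2 / (2P)^2 where A is the number of heavy atoms
    within three bonds of a connecting atom and 2P the number of unique
    length-two paths among them; the normalization is the product of the
    linear-alkane extreme path counts for A atoms. Zero when no length-two
    path exists (atomic and diatomic ligands, bare donor atoms).
    """
    sub = _truncated_heavy_subgraph(ligand)
    p2 = count_length2_paths(sub)
    if p2 == 0:
        return 0.0
    a = sub.number_of_nodes()
    return (a - 1) * (a - 2) ** 2 / p2**2


def connecting_bond_order(ligand: LigandGraph) -> float:
    """Maximum bond order incident to a connecting atom; 0 for atomic ligands."""
    best = 0.0
    for c in ligand.connecting_atoms:
        for i, j, order in ligand.bonds:
            if c in (i, j):
                best = max(best, float(order))
    return best


@dataclass(frozen=True)
class DescriptorVector:
    """Named descriptor values for one complex under one descriptor set.

    ``values`` maps stable column identifiers to raw (un-normalized) values;
    categorical columns (listed in ``categorical``) hold string levels, the
    rest are floats. Encoding to a numeric design matrix is a separate,
    statistics-carrying step (:mod:`octaspin.encoding`).
    """

    set_id: str
    values: dict[str, float | str]
    categorical: tuple[str, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.values)

    def __len__(self) -> int:
        return len(self.values)


def _per_ligand_block(
    ligand: LigandGraph, side: str, set_id: str, table: ElectronegativityTable
) -> tuple[dict[str, float | str], list[str]]:
    vals: dict[str, float | str] = {}
    cats: list[str] = []
    if set_id == "a":
        vals[f"lig_{side}"] = ligand.name
        cats.append(f"lig_{side}")
    else:
        conn_el = ligand.atoms[ligand.connecting_atoms[0]]
        vals[f"L_{side}"] = conn_el
        cats.append(f"L_{side}")
    vals[f"C_{side}"] = float(ligand.charge)
    if set_id in ("b", "c", "d", "e"):
        vals[f"natoms_{side}"] = float(ligand.n_atoms)
    if set_id in ("f", "g"):
        vals[f"k_{side}"] = truncated_kier(ligand)
    if set_id in ("e", "g"):
        vals[f"b_{side}"] = connecting_bond_order(ligand)
    vals[f"D_{side}"] = float(ligand.denticity)
    return vals, cats


def featurize(
    spec: ComplexSpec,
    set_id: str = "g",
    include_a_hf: bool = True,
    table: ElectronegativityTable = DEFAULT_TABLE,
) -> DescriptorVector:
    """Assemble the descriptor vector of a complex for one of the sets a-g.

    Whole-complex block: metal identity (categorical), oxidation state,
    electronegativity statistics (sets c-g) and a_HF; per-ligand blocks for
    the equatorial and axial ligand classes. Homoleptic complexes have
    identical equatorial and axial blocks by construction. ``include_a_hf``
    is switched off when featurizing for the exchange-sensitivity model,
    whose target is itself the derivative with respect to a_HF.
    """
    if set_id not in DESCRIPTOR_SETS:
        raise ValueError(f"unknown descriptor set {set_id!r}; expected one of {DESCRIPTOR_SETS}")
    values: dict[str, float | str] = {"metal": spec.metal, "ox": float(spec.oxidation)}
    categorical: list[str] = ["metal"]
    if set_id in ("c", "d", "e", "f", "g"):
        mx, mn, sm = complex_chi_stats(spec, table)
        values["me"] = mx
        if set_id == "c":
            values["mi"] = mn
        values["se"] = sm
    if include_a_hf:
        values["a_hf"] = float(spec.a_hf)
    for side, ligand in (("eq", spec.eq_ligand), ("ax", spec.ax_ligand)):
        block, cats = _per_ligand_block(ligand, side, set_id, table)
        values.update(block)
        categorical.extend(cats)
    return DescriptorVector(set_id=set_id, values=values, categorical=tuple(categorical))


def featurize_many(
    specs: Iterable[ComplexSpec],
    set_id: str = "g",
    include_a_hf: bool = True,
    table: ElectronegativityTable = DEFAULT_TABLE,
) -> list[DescriptorVector]:
    return [featurize(s, set_id=set_id, include_a_hf=include_a_hf, table=table) for s in specs]
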