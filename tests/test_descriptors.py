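"""Electronegativity, Kier-shape, bond-order descriptors and encodings."""

import dataclasses
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octaspin.complexes import ComplexSpec
from octaspin.descriptors import (
    complex_chi_stats,
    connecting_bond_order,
    count_length2_paths,
    delta_chi,
    featurize,
    featurize_many,
    truncated_kier,
    _truncated_heavy_subgraph,
)
from octaspin.encoding import (
    EncodingMeta,
    OutOfVocabularyError,
    apply_encoding,
    encode,
    fit_encoding,
)
from octaspin.ligands import LigandGraph


def brute_force_length2_paths(graph):
    """Independent oracle: enumerate all unordered atom triples i-j-k."""
    nodes = list(graph.nodes)
    count = 0
    for center in nodes:
        for a, b in combinations(graph[center], 2):
            assert a != b
            count += 1
    return count


class TestDeltaChi:
    def test_atomic_ligand_empty(self, library):
        assert delta_chi(library["Cl"]).values == ()

    def test_carbonyl(self, library):
        assert delta_chi(library["CO"]).values == pytest.approx([-0.89])

    def test_ammonia_counts_hydrogens(self, library):
        assert delta_chi(library["NH3"]).values == pytest.approx([0.84, 0.84, 0.84])

    def test_all_chloride_convention(self, library):
        spec = ComplexSpec("Fe", 2, library["Cl"], library["Cl"])
        assert complex_chi_stats(spec) == (0.0, 0.0, 0.0)

    def test_hexacarbonyl_multiplicity(self, hexacarbonyl):
        mx, mn, sm = complex_chi_stats(hexacarbonyl)
        assert (mx, mn) == pytest.approx((-0.89, -0.89))
        assert sm == pytest.approx(6 * -0.89)

    def test_heteroleptic_straddles_zero(self, library):
        spec = ComplexSpec("Fe", 2, library["H2O"], library["CO"])
        mx, mn, sm = complex_chi_stats(spec)
        # brute-force pooling oracle: 4 aqua copies (2 O-H each) + 2 carbonyls
        pooled = [1.24] * 8 + [-0.89] * 2
        assert mx == pytest.approx(max(pooled)) and mn == pytest.approx(min(pooled))
        assert sm == pytest.approx(sum(pooled))
        assert mn < 0 < mx


class TestTruncatedKier:
    def test_atomic_and_diatomic_are_zero(self, library):
        for name in ("Cl", "CN", "CO", "H2O", "NH3"):
            assert truncated_kier(library[name]) == 0.0

    def test_linear_three_atom_chain(self, library):
        # S-C-N: A=3, one length-2 path -> (A-1)(A-2)^2 / 1 = 2
        assert truncated_kier(library["SCN"]) == pytest.approx(2.0)

    @pytest.mark.parametrize("n_heavy", [3, 4])
    def test_linear_chain_closed_form(self, n_heavy):
        """On an untruncated linear chain 2P = A-2 and the index reduces to A-1."""
        atoms = tuple("C" * n_heavy)
        bonds = tuple((i, i + 1, 1.0) for i in range(n_heavy - 1))
        chain = LigandGraph(
            name="chain", atoms=atoms, bonds=bonds, connecting_atoms=(0,), charge=0, denticity=1
        )
        sub = _truncated_heavy_subgraph(chain)
        assert count_length2_paths(sub) == n_heavy - 2
        assert truncated_kier(chain) == pytest.approx(n_heavy - 1)

    def test_path_count_matches_enumeration_on_all_ligands(self, library):
        for lig in library.values():
            sub = _truncated_heavy_subgraph(lig)
            assert count_length2_paths(sub) == brute_force_length2_paths(sub)

    def test_size_robustness(self, library):
        """Heavy atoms beyond three bonds of the connecting atom are invisible."""
        pisc = library["pisc"]
        n = pisc.n_atoms
        # para-substitute the phenyl ring (atom 5 is >3 bonds from the isocyanide C)
        decorated = dataclasses.replace(
            pisc,
            name="pisc-para-methyl",
            atoms=pisc.atoms + ("C", "H", "H", "H"),
            bonds=pisc.bonds
            + ((5, n, 1.0), (n, n + 1, 1.0), (n, n + 2, 1.0), (n, n + 3, 1.0)),
        )
        assert truncated_kier(decorated) == pytest.approx(truncated_kier(pisc))
        assert connecting_bond_order(decorated) == connecting_bond_order(pisc)
        assert delta_chi(decorated).values == delta_chi(pisc).values

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_permutation_invariance(self, seed):
        """Relabeling atom indices never changes any scalar descriptor."""
        from octaspin.ligands import load_ligand_library

        library = load_ligand_library()
        rng = np.random.default_rng(seed)
        name = rng.choice(["acac", "en", "phen", "SCN", "por"])
        lig = library[name]
        perm = rng.permutation(lig.n_atoms)
        inv = np.argsort(perm)
        shuffled = LigandGraph(
            name=lig.name,
            atoms=tuple(lig.atoms[inv[i]] for i in range(lig.n_atoms)),
            bonds=tuple((int(perm[i]), int(perm[j]), o) for i, j, o in lig.bonds),
            connecting_atoms=tuple(int(perm[c]) for c in lig.connecting_atoms),
            charge=lig.charge,
            denticity=lig.denticity,
        )
        assert truncated_kier(shuffled) == pytest.approx(truncated_kier(lig))
        assert connecting_bond_order(shuffled) == connecting_bond_order(lig)
        assert sorted(delta_chi(shuffled).values) == pytest.approx(sorted(delta_chi(lig).values))


class TestBondOrder:
    @pytest.mark.parametrize(
        "name, expected", [("Cl", 0.0), ("CO", 3.0), ("H2O", 1.0), ("NCS", 2.0), ("acac", 1.5)]
    )
    def test_values(self, library, name, expected):
        assert connecting_bond_order(library[name]) == expected


class TestFeaturize:
    def test_set_g_is_15_dimensional(self, hexacarbonyl):
        vec = featurize(hexacarbonyl, "g")
        assert len(vec) == 15
        assert set(vec.categorical) == {"metal", "L_eq", "L_ax"}

    def test_homoleptic_symmetry(self, hexaammine):
        vec = featurize(hexaammine, "g")
        for key in ("L", "C", "k", "b", "D"):
            assert vec.values[f"{key}_eq"] == vec.values[f"{key}_ax"]

    def test_a_hf_excluded_for_sensitivity_inputs(self, hexacarbonyl):
        vec = featurize(hexacarbonyl, "g", include_a_hf=False)
        assert "a_hf" not in vec.values
        assert len(vec) == 14

    @pytest.mark.parametrize(
        "set_id, n_discrete_levels, n_continuous",
        [("a", 37, 6), ("b", 15, 8), ("c", 15, 11), ("d", 15, 10),
         ("e", 15, 12), ("f", 15, 10), ("g", 15, 12)],
    )
    def test_variable_counts_per_set(self, library, set_id, n_discrete_levels, n_continuous):
        """Discrete level and continuous variable counts of the descriptor-set ladder."""
        specs = [
            ComplexSpec("Fe", 2, eq, ax)
            for eq in library.values()
            for ax in library.values()
            if ax.denticity <= 2
        ]
        vectors = featurize_many(specs, set_id=set_id)
        meta = fit_encoding(vectors, mode="lasso")
        assert sum(len(meta.levels[c]) for c in meta.categorical) == n_discrete_levels
        assert len(meta.feature_names) - len(meta.categorical) == n_continuous


class TestEncoding:
    def _vectors(self, library):
        specs = [
            ComplexSpec(m, o, library[eq], library[ax], a_hf=a)
            for (m, o) in [("Fe", 2), ("Co", 3), ("Mn", 2), ("Ni", 2), ("Cr", 3)]
            for eq, ax, a in [("NH3", "Cl", 0.0), ("CO", "CO", 0.2), ("H2O", "CN", 0.1)]
        ]
        return featurize_many(specs, set_id="g")

    def test_ann_mode_has_27_nodes(self, library):
        X, meta = encode(self._vectors(library), mode="ann")
        assert X.shape[1] == meta.n_columns == 27

    def test_lasso_reference_coding(self, library):
        vectors = self._vectors(library)
        X, meta = encode(vectors, mode="lasso")
        cobalt_cols = [i for i, c in enumerate(meta.column_names) if c.startswith("metal=")]
        assert len(cobalt_cols) == 4  # Co dropped as the reference level
        co_rows = [i for i, v in enumerate(vectors) if v.values["metal"] == "Co"]
        assert np.all(X[np.ix_(co_rows, cobalt_cols)] == 0)

    def test_onehot_block_sums_to_one(self, library):
        X, meta = encode(self._vectors(library), mode="ann")
        metal_cols = [i for i, c in enumerate(meta.column_names) if c.startswith("metal=")]
        assert np.all(X[:, metal_cols].sum(axis=1) == 1)

    def test_constant_column_maps_to_zero(self, library):
        vectors = featurize_many(
            [ComplexSpec("Fe", 2, library["CO"], library["CO"], a_hf=0.2)] * 3, set_id="g"
        )
        X, meta = encode(vectors, mode="ann")
        continuous = [i for i, c in enumerate(meta.column_names) if "=" not in c]
        assert np.all(X[:, continuous] == 0.0)

    def test_transform_reuses_training_statistics(self, library):
        vectors = self._vectors(library)
        meta = fit_encoding(vectors, mode="ann")
        X1 = apply_encoding(vectors, meta)
        X2 = apply_encoding(vectors, meta)
        np.testing.assert_array_equal(X1, X2)
        # applying to a subset must not re-fit the statistics
        X_sub = apply_encoding(vectors[:2], meta)
        np.testing.assert_array_equal(X_sub, X1[:2])

    def test_out_of_vocabulary_raises(self, library):
        vectors = featurize_many(
            [ComplexSpec("Fe", 2, library["NH3"], library["NH3"])], set_id="a"
        )
        meta = fit_encoding(vectors, mode="ann")
        pyridine = LigandGraph(
            name="py",
            atoms=("N", "C", "C", "C", "C", "C"),
            bonds=tuple((i, (i + 1) % 6, 1.5) for i in range(6)),
            connecting_atoms=(0,),
            charge=0,
            denticity=1,
        )
        other = featurize_many([ComplexSpec("Fe", 2, pyridine, pyridine)], set_id="a")
        with pytest.raises(OutOfVocabularyError, match="py"):
            apply_encoding(other, meta)

    def test_meta_json_roundtrip(self, library):
        meta = fit_encoding(self._vectors(library), mode="ann")
        back = EncodingMeta.from_json(meta.to_json())
        assert back.column_names == meta.column_names
        assert back.means == meta.means and back.stds == meta.stds
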