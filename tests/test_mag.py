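"""Edge-list graph: validation, implicit hydrogens, ring summaries."""

import pytest

from magsolex.fixtures import example_molecule, random_molecule
from magsolex.mag import (
    MAGEdge,
    MAGMolecule,
    ValenceError,
    implicit_hydrogens,
    renumber,
    ring_summaries,
    validate,
)


class TestValidation:
    def test_catalog_molecules_are_valid(self, catalog):
        for name, (mag, _) in catalog.items():
            assert validate(mag).ok, f"{name}: {validate(mag)}"

    def test_type_code_outside_table_is_flagged(self):
        mag = MAGMolecule([MAGEdge(0, 1, 999, 1, 7)])
        assert any("Type 7" in m for m in validate(mag).issues)

    def test_duplicate_bond_is_flagged(self):
        mag = MAGMolecule(
            [MAGEdge(0, 1, 999, 1, 0), MAGEdge(0, 1, 999, 1, 0), MAGEdge(1, 2, 999, 1, 0)]
        )
        assert any("duplicate" in m for m in validate(mag).issues)

    def test_atom_numbering_gap_is_flagged(self):
        mag = MAGMolecule([MAGEdge(0, 2, 999, 1, 0)])
        assert any("gap" in m for m in validate(mag).issues)

    def test_disconnected_graph_is_flagged(self):
        mag = MAGMolecule([MAGEdge(0, 1, 999, 1, 0), MAGEdge(2, 3, 999, 1, 0)])
        assert any("connected" in m for m in validate(mag).issues)

    def test_valence_overflow_is_flagged(self):
        # a carbon with five single bonds
        edges = [MAGEdge(0, i, 999, 1, 0) for i in range(1, 6)]
        assert any("valence" in m for m in validate(MAGMolecule(edges)).issues)


class TestImplicitHydrogens:
    @pytest.mark.parametrize(
        "name,total",
        [
            ("benzene", 6),
            ("cyclohexane", 12),
            ("dmen", 16),          # C14H16 by valence completion
            ("naphthalene", 8),
            ("tetralin", 12),
            ("cis_2_butene", 8),
        ],
    )
    def test_totals(self, catalog, name, total):
        mag, _ = catalog[name]
        assert implicit_hydrogens(mag)[1] == total

    def test_per_atom_counts_for_benzene(self, catalog):
        per_atom, _ = implicit_hydrogens(catalog["benzene"][0])
        assert per_atom == [1] * 6

    def test_negative_hydrogen_raises_naming_the_atom(self):
        edges = [MAGEdge(0, i, 999, 1, 0) for i in range(1, 6)]
        with pytest.raises(ValenceError, match="atom 0"):
            implicit_hydrogens(MAGMolecule(edges))

    def test_acyclic_all_carbon_molecules_have_even_hydrogen(self):
        # C_n H_{2n+2} parity on random paraffin-like subgraphs
        for seed in range(30):
            mag, _ = random_molecule(seed)
            counts = mag.element_counts()
            if set(counts) == {"C"} and not mag.ring_ids():
                assert implicit_hydrogens(mag)[1] % 2 == 0


class TestRingSummaries:
    def test_benzene_single_aromatic_ring(self, catalog):
        (ring,) = ring_summaries(catalog["benzene"][0])
        assert ring.size == 6 and ring.aromatic and not ring.fused

    def test_fused_bicycle_shares_two_atoms(self, catalog):
        rings = ring_summaries(catalog["naphthalene"][0])
        assert len(rings) == 2
        assert all(r.aromatic for r in rings)
        assert rings[0].fused == {1: 2} and rings[1].fused == {0: 2}

    def test_tetralin_mixed_saturation(self, catalog):
        rings = ring_summaries(catalog["tetralin_branched_chain"][0])
        assert rings[0].aromatic and rings[0].size == 6
        assert not rings[1].aromatic and rings[1].size == 6
        assert rings[1].fused[0] == 2

    def test_row_count_equals_bond_count_and_width_is_fixed(self, catalog):
        for name, (mag, _) in catalog.items():
            m = mag.matrix()
            assert len(m) == len(mag.edges)
            assert all(len(row) == 5 for row in m)


class TestRenumber:
    def test_renumber_preserves_elements_and_hydrogens(self, catalog):
        mag, _ = catalog["amine_example"]
        perm = list(reversed(range(mag.n_atoms)))
        m2 = renumber(mag, perm)
        assert sorted(m2.elements) == sorted(mag.elements)
        assert implicit_hydrogens(m2)[1] == implicit_hydrogens(mag)[1]

    def test_renumber_rejects_non_permutation(self, catalog):
        mag, _ = catalog["benzene"]
        with pytest.raises(Exception):
            renumber(mag, [0] * mag.n_atoms)
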