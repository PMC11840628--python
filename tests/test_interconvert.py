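"""Graph -> attribute derivation, atom counting, SMILES export."""

import numpy as np
import pytest

from magsolex.attributes import ATTR_INDEX, SOLexMolecule, aggregate_global, solex_equal
from magsolex.interconvert import (
    InconsistentAttributesError,
    atom_counts,
    smiles_from_mag,
    solex_from_mag,
    stoichiometric_table,
)
from magsolex.fixtures import example_molecule, random_molecule
from magsolex.mag import implicit_hydrogens

from conftest import rdkit_canonical


def _unit_solex(**attrs) -> SOLexMolecule:
    row = np.zeros((1, 42), dtype=int)
    for name, v in attrs.items():
        row[0, ATTR_INDEX[name]] = v
    return aggregate_global(row)


class TestAtomCounts:
    @pytest.mark.parametrize(
        "attrs,formula",
        [
            ({"A6": 1}, {"C": 6, "H": 6}),          # benzene increment
            ({"N6": 1}, {"C": 6, "H": 12}),         # cyclohexane increment
            ({"N5": 1}, {"C": 5, "H": 10}),
            ({"Rp": 2, "Rm": 2}, {"C": 4, "H": 10}),  # n-butane
        ],
    )
    def test_single_attribute_increments(self, attrs, formula):
        counts = atom_counts(_unit_solex(**attrs))
        assert {k: v for k, v in counts.items() if v} == formula

    def test_named_compound_formula(self, dmen):
        counts = atom_counts(dmen[1])
        assert (counts["C"], counts["H"]) == (14, 16)

    def test_zero_row_gives_zero_atoms(self):
        counts = atom_counts(_unit_solex())
        assert all(v == 0 for v in counts.values())

    def test_malformed_row_raises(self):
        # a branch point with no chain carbons implies negative hydrogen
        with pytest.raises(InconsistentAttributesError):
            atom_counts(_unit_solex(br=1))

    def test_stoichiometric_table_shape(self):
        assert stoichiometric_table().shape == (42, 7)


class TestSolexFromMag:
    def test_benzene_is_one_a6(self, catalog):
        sol = solex_from_mag(catalog["benzene"][0])
        assert sol.value("A6") == 1
        assert sol.count_vector().sum() == 1

    def test_fused_naphthenic_next_to_aromatic_is_n4a(self, catalog):
        sol = solex_from_mag(catalog["amine_example"][0])
        assert sol.value("A6") == 1 and sol.value("N4a") == 1

    def test_naphthalene_is_a6_plus_a4(self, catalog):
        sol = solex_from_mag(catalog["naphthalene"][0])
        assert sol.value("A6") == 1 and sol.value("A4") == 1

    def test_roundtrip_matches_stored_solex_for_all_fixtures(self, catalog):
        for name, (mag, sol) in catalog.items():
            assert solex_equal(sol, solex_from_mag(mag)), name

    def test_hydrogen_consistency_on_fixtures_and_random_molecules(self, catalog):
        for name, (mag, sol) in catalog.items():
            assert atom_counts(sol)["H"] == implicit_hydrogens(mag)[1], name
        for seed in range(200):
            mag, sol = random_molecule(seed)
            assert atom_counts(sol)["H"] == implicit_hydrogens(mag)[1], seed

    def test_heavy_atom_totals_match_graph(self, catalog):
        for name, (mag, sol) in catalog.items():
            counts = atom_counts(sol)
            heavy = sum(v for k, v in counts.items() if k != "H")
            assert heavy == sum(mag.element_counts().values()), name


class TestSmiles:
    @pytest.mark.parametrize(
        "name,reference",
        [
            ("benzene", "c1ccccc1"),
            ("ethane", "CC"),
            ("naphthalene", "c1ccc2ccccc2c1"),
            ("dmen", "CCc1ccc(C)c2cc(C)ccc12"),
            ("trans_2_butene", "C/C=C/C"),
            ("cis_2_butene", r"C/C=C\C"),
            ("oxy_isomer_D", "OC(=O)CCCC1CCCCC1"),
        ],
    )
    def test_canonical_equality_against_oracle(self, catalog, name, reference):
        emitted = smiles_from_mag(catalog[name][0])
        assert rdkit_canonical(emitted) == rdkit_canonical(reference)

    def test_every_fixture_smiles_parses_with_right_heavy_atoms(self, catalog):
        from rdkit import Chem

        for name, (mag, _) in catalog.items():
            s = smiles_from_mag(mag)
            mol = Chem.MolFromSmiles(s)
            assert mol is not None, f"{name}: {s}"
            expected = sum(mag.element_counts().values())
            assert mol.GetNumHeavyAtoms() == expected, name

    def test_random_molecule_smiles_parse(self):
        from rdkit import Chem

        for seed in range(60):
            mag, _ = random_molecule(seed)
            s = smiles_from_mag(mag)
            mol = Chem.MolFromSmiles(s)
            assert mol is not None, f"seed {seed}: {s}"
            assert mol.GetNumHeavyAtoms() == sum(mag.element_counts().values())
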