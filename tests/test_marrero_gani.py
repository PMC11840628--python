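"""First-order group identification (gated vs exhaustive) and correlations."""

import pytest

from magsolex.interconvert import atom_counts
from magsolex.marrero_gani import (
    CALIBRATION_DATA,
    MG_GROUPS,
    UncoveredAtomError,
    first_order_constants,
    identify_groups_exhaustive,
    identify_groups_gated,
    mg_properties,
)
from magsolex.fixtures import example_molecule, random_molecule


class TestIdentification:
    def test_worked_naphthalene_example(self, dmen):
        """One free methyl, five aromatic CH, two fused junctions, two
        methyl-substituted and one methylene-substituted aromatic carbons."""
        res = identify_groups_gated(*dmen)
        assert res.groups == {
            "CH3": 1, "aCH": 5, "aCfaC": 2, "aC-CH3": 2, "aC-CH2": 1
        }

    def test_benzene_and_ethane(self, catalog):
        assert identify_groups_gated(*catalog["benzene"]).groups == {"aCH": 6}
        assert identify_groups_exhaustive(catalog["ethane"][0]).groups == {"CH3": 2}

    def test_carboxylic_acid_case(self, catalog):
        groups = identify_groups_exhaustive(catalog["oxy_isomer_D"][0]).groups
        assert groups["COOH"] == 1

    def test_oxygenated_isomers_have_distinct_vectors(self, catalog):
        vecs = {
            case: tuple(sorted(identify_groups_exhaustive(catalog[f"oxy_isomer_{case}"][0]).groups.items()))
            for case in "ABCD"
        }
        assert len(set(vecs.values())) == 4

    def test_butene_pair_maps_to_internal_olefin_group(self, catalog):
        for name in ("cis_2_butene", "trans_2_butene"):
            groups = identify_groups_gated(*catalog[name]).groups
            assert groups == {"CH3": 2, "CH=CH": 1}


class TestOracleEquivalence:
    def test_gated_equals_exhaustive_on_fixtures(self, catalog):
        for name, (mag, sol) in catalog.items():
            g = identify_groups_gated(mag, sol)
            e = identify_groups_exhaustive(mag)
            assert g.groups == e.groups, name

    def test_gated_equals_exhaustive_on_random_molecules(self):
        for seed in range(300):
            mag, sol = random_molecule(seed)
            g = identify_groups_gated(mag, sol)
            e = identify_groups_exhaustive(mag)
            assert g.groups == e.groups, seed
            assert g.visits <= e.visits, seed

    def test_gated_scan_saves_visits_when_a_gate_is_false(self, catalog):
        # a pure hydrocarbon ring molecule has every heteroatom gate false
        mag, sol = catalog["dmen"]
        g = identify_groups_gated(mag, sol)
        e = identify_groups_exhaustive(mag)
        assert g.visits < e.visits

    def test_heavy_atom_completeness(self, catalog):
        for name, (mag, sol) in catalog.items():
            res = identify_groups_gated(mag, sol)
            counts = atom_counts(sol)
            heavy = sum(v for k, v in counts.items() if k != "H")
            assert res.heavy_atoms() == heavy, name


class TestConstants:
    def test_every_group_has_constants_for_every_property(self):
        import math

        consts = first_order_constants()
        for g in MG_GROUPS:
            for prop, v in consts[g].items():
                assert not math.isnan(v), (g, prop)

    def test_calibration_residuals_are_modest_for_hydrocarbons(self):
        # the fit should reproduce its own anchors to within the few-percent
        # scatter typical of first-order group contributions
        consts = first_order_constants()
        for name in ("n-octane", "toluene", "naphthalene", "cyclohexane"):
            vec, tc, _pc, _vc, tb, _tm = CALIBRATION_DATA[name]
            ps = mg_properties(vec)
            assert abs(ps.Tb - tb) / tb < 0.05, name
            assert abs(ps.Tc - tc) / tc < 0.05, name


class TestProperties:
    def test_empty_vector_raises(self):
        with pytest.raises(ValueError):
            mg_properties({})

    def test_estimates_increase_with_chain_length(self):
        a = mg_properties({"CH3": 2, "CH2": 4})
        b = mg_properties({"CH3": 2, "CH2": 8})
        assert b.Tb > a.Tb and b.Tc > a.Tc and b.Vc > a.Vc
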