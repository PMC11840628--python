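"""Reaction rules: gates, transformations, strict atom balance."""

import pytest

from magsolex.attributes import solex_equal
from magsolex.interconvert import solex_from_mag
from magsolex.isomers import canonical_form
from magsolex.mag import implicit_hydrogens
from magsolex.reactions import (
    InapplicableRuleError,
    can_dealkylate,
    can_saturate,
    dealkylate,
    dealkylation_sites,
    saturate_aromatic_ring,
    saturation_sites,
)
from magsolex.fixtures import example_molecule, random_molecule


def _elements_with_h(mag):
    counts = mag.element_counts()
    counts["H"] = implicit_hydrogens(mag)[1]
    return counts


class TestGates:
    @pytest.mark.parametrize(
        "name,expected",
        [("tetralin_branched_chain", True), ("benzene", True), ("cyclohexane", False)],
    )
    def test_saturation_gate(self, catalog, name, expected):
        assert can_saturate(catalog[name][1]) is expected

    @pytest.mark.parametrize(
        "name,expected",
        [("tetralin_branched_chain", True), ("ethylbenzene", True), ("benzene", False)],
    )
    def test_dealkylation_gate(self, catalog, name, expected):
        assert can_dealkylate(catalog[name][1]) is expected

    def test_gate_soundness_on_random_molecules(self):
        for seed in range(100):
            mag, sol = random_molecule(seed)
            if not can_saturate(sol):
                assert saturation_sites(mag) == []
            if not can_dealkylate(sol):
                assert dealkylation_sites(mag) == []


class TestSaturation:
    def test_benzene_to_cyclohexane_consumes_three_h2(self, catalog):
        out = saturate_aromatic_ring(catalog["benzene"], 0)
        assert out.h2_consumed == 3
        (product, psol) = out.products[0]
        assert psol.value("N6") == 1 and psol.value("A6") == 0

    def test_naphthalene_partial_saturation_gives_tetralin(self, catalog):
        out = saturate_aromatic_ring(catalog["naphthalene"], 0)
        assert out.h2_consumed == 2
        psol = out.products[0][1]
        assert psol.value("A6") == 1 and psol.value("N4a") == 1

    def test_worked_example_flips_exactly_the_six_ring0_rows(self, catalog):
        mag, sol = catalog["tetralin_branched_chain"]
        out = saturate_aromatic_ring((mag, sol), 0)
        product, psol = out.products[0]
        assert [e.type for e in product.edges[:6]] == [1] * 6
        assert [e.type for e in product.edges[6:]] == [e.type for e in mag.edges[6:]]
        assert psol.value("A6") == 0 and psol.value("N6") == 1
        assert psol.value("N4a") == 0 and psol.value("N4n") == 1

    def test_non_aromatic_ring_is_inapplicable(self, catalog):
        with pytest.raises(InapplicableRuleError):
            saturate_aromatic_ring(catalog["cyclohexane"], 0)


class TestDealkylation:
    def test_worked_example_removes_one_row_and_methylates_the_ring(self, catalog):
        mag, sol = catalog["tetralin_branched_chain"]
        out = dealkylate((mag, sol), 6)
        ring_prod, paraffin = out.products
        assert len(ring_prod[0].edges) + len(paraffin[0].edges) == len(mag.edges) - 1
        assert ring_prod[1].value("MEn") == 1
        assert paraffin[1].value("Rp") == 2  # propane
        assert out.h2_consumed == 1

    def test_ethylbenzene_gives_toluene_and_methane(self, catalog):
        mag, sol = catalog["ethylbenzene"]
        out = dealkylate((mag, sol), 0)
        ring_prod, paraffin = out.products
        assert out.h2_consumed == 1
        assert ring_prod[1].value("MEa") == 1
        assert paraffin[0].n_atoms == 1
        # full ledger: C8H10 + H2 -> C7H8 + CH4
        tot_c = sum(p[0].element_counts().get("C", 0) for p in out.products)
        tot_h = sum(implicit_hydrogens(p[0])[1] for p in out.products)
        assert tot_c == 8 and tot_h == 10 + 2 * out.h2_consumed

    def test_methyl_chain_is_inapplicable(self, catalog):
        with pytest.raises(InapplicableRuleError, match="methyl"):
            dealkylate(catalog["toluene"], 0)


class TestConservation:
    def test_elements_balance_on_random_applicable_molecules(self):
        applied = 0
        for seed in range(200):
            mag, sol = random_molecule(seed)
            for rid in saturation_sites(mag)[:1]:
                out = saturate_aromatic_ring((mag, sol), rid)
                before = _elements_with_h(mag)
                after = _elements_with_h(out.products[0][0])
                before["H"] += 2 * out.h2_consumed
                assert before == after, seed
                applied += 1
            for site in dealkylation_sites(mag)[:1]:
                out = dealkylate((mag, sol), site)
                before = _elements_with_h(mag)
                before["H"] += 2 * out.h2_consumed
                total = {}
                for pmag, _ in out.products:
                    for el, n in _elements_with_h(pmag).items():
                        total[el] = total.get(el, 0) + n
                assert {k: v for k, v in before.items() if v} == \
                       {k: v for k, v in total.items() if v}, seed
                applied += 1
        assert applied > 100  # the default conditions make both rules common

    def test_products_carry_consistent_solex(self):
        for seed in range(60):
            mag, sol = random_molecule(seed)
            for site in dealkylation_sites(mag)[:1]:
                for pmag, psol in dealkylate((mag, sol), site).products:
                    assert solex_equal(psol, solex_from_mag(pmag)), seed


class TestOrderIndependence:
    def test_the_two_rules_commute_on_the_worked_example(self, catalog):
        start = catalog["tetralin_branched_chain"]
        # saturate then dealkylate
        sat = saturate_aromatic_ring(start, 0)
        deal_after = dealkylate(sat.products[0], dealkylation_sites(sat.products[0][0])[0])
        forms_a = sorted(canonical_form(p[0])[0] for p in deal_after.products)
        # dealkylate then saturate
        deal = dealkylate(start, dealkylation_sites(start[0])[0])
        sat_after = saturate_aromatic_ring(deal.products[0], 0)
        forms_b = sorted([
            canonical_form(sat_after.products[0][0])[0],
            canonical_form(deal.products[1][0])[0],
        ])
        assert forms_a == forms_b
        assert sat.h2_consumed + deal_after.h2_consumed == \
               deal.h2_consumed + sat_after.h2_consumed
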