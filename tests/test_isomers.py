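"""Identity verdicts: attribute gate, canonical graphs, stereo codes."""

import itertools

import networkx as nx
import numpy as np
import pytest

from magsolex.interconvert import solex_from_mag
from magsolex.isomers import canonical_form, same_molecule
from magsolex.mag import MAGEdge, MAGMolecule, renumber
from magsolex.fixtures import example_molecule, random_molecule


def _pair_of(mag):
    return (mag, solex_from_mag(mag))


class TestSameMolecule:
    def test_geometric_isomers_differ_at_the_stereo_stage(self, catalog):
        v = same_molecule(catalog["cis_2_butene"], catalog["trans_2_butene"])
        assert not v.equal and v.stage == "stereo"

    def test_optical_pair_differs_at_the_stereo_stage(self, catalog):
        v = same_molecule(catalog["optical_R"], catalog["optical_S"])
        assert not v.equal and v.stage == "stereo"

    def test_oxygenated_isomers_all_mutually_distinct(self, catalog):
        cases = [catalog[f"oxy_isomer_{c}"] for c in "ABCD"]
        for a, b in itertools.combinations(cases, 2):
            v = same_molecule(a, b)
            assert not v.equal

    def test_identity_under_random_renumbering(self, catalog):
        rng = np.random.default_rng(1)
        for name in ("dmen", "oxy_isomer_A", "cis_2_butene", "monocore_example"):
            mag, sol = catalog[name]
            for _ in range(10):
                perm = list(map(int, rng.permutation(mag.n_atoms)))
                v = same_molecule((mag, sol), _pair_of(renumber(mag, perm)))
                assert v.equal, (name, v.stage, v.detail)

    def test_gate_stage_reported_when_attributes_differ(self, catalog):
        v = same_molecule(catalog["benzene"], catalog["cyclohexane"])
        assert not v.equal and v.stage == "solex_gate"

    def test_gate_soundness_attribute_difference_implies_nonisomorphic(self):
        # whenever the attribute gate fires, a full graph-isomorphism oracle
        # agrees the constitutions differ
        from magsolex.attributes import solex_equal

        import warnings

        mols = [random_molecule(s) for s in range(40)]
        checked = 0
        for (ma, sa), (mb, sb) in itertools.combinations(mols, 2):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # cross-shape comparisons intended
                if ma.n_atoms != mb.n_atoms or solex_equal(sa, sb):
                    continue
            ga, gb = ma.to_networkx(), mb.to_networkx()
            iso = nx.is_isomorphic(
                ga, gb,
                node_match=lambda x, y: x["element"] == y["element"],
                edge_match=lambda x, y: x["type"] == y["type"],
            )
            assert not iso
            checked += 1
            if checked >= 100:
                break
        assert checked > 10


class TestCanonicalForm:
    def test_benzene_automorphisms_collapse_to_one_form(self, catalog):
        mag, _ = catalog["benzene"]
        forms = set()
        for shift in range(6):
            perm = [(i + shift) % 6 for i in range(6)]
            forms.add(canonical_form(renumber(mag, perm))[0])
        perm = list(reversed(range(6)))
        forms.add(canonical_form(renumber(mag, perm))[0])
        assert len(forms) == 1

    def test_random_permutations_yield_one_canonical_list(self, catalog):
        rng = np.random.default_rng(7)
        mag, _ = catalog["tetralin_branched_chain"]
        base = canonical_form(mag)[0]
        for _ in range(50):
            perm = list(map(int, rng.permutation(mag.n_atoms)))
            assert canonical_form(renumber(mag, perm))[0] == base

    def test_agrees_with_isomorphism_oracle_on_small_enumerated_set(self):
        # small builder grammar: all trees of methyl/ethyl/propyl branches on
        # a 4-carbon backbone plus ring/no-ring variants, <= 10 heavy atoms
        def chain_mol(branches):
            edges = []
            n = 4
            for i in range(3):
                edges.append(MAGEdge(i, i + 1, 999, 1, 0))
            for pos, ln in branches:
                prev = pos
                for _ in range(ln):
                    edges.append(MAGEdge(prev, n, 999, 1, 0))
                    prev = n
                    n += 1
            return MAGMolecule(edges)

        options = []
        for b1 in [(), ((1, 1),), ((2, 1),), ((1, 2),), ((1, 1), (2, 1)),
                   ((1, 1), (2, 2)), ((1, 2), (2, 1)), ((1, 3),), ((2, 3),)]:
            options.append(chain_mol(b1))
        for a, b in itertools.combinations(options, 2):
            iso = nx.is_isomorphic(
                a.to_networkx(), b.to_networkx(),
                node_match=lambda x, y: x["element"] == y["element"],
                edge_match=lambda x, y: x["type"] == y["type"],
            )
            same_form = canonical_form(a)[0] == canonical_form(b)[0]
            assert iso == same_form, (a.matrix(), b.matrix())

    def test_constitutional_isomers_get_distinct_forms(self):
        # n-octane vs 2-methylheptane vs 2,2-dimethylhexane
        def linear(n):
            return MAGMolecule([MAGEdge(i, i + 1, 999, 1, 0) for i in range(n - 1)])

        def methylated(positions, backbone):
            edges = [MAGEdge(i, i + 1, 999, 1, 0) for i in range(backbone - 1)]
            n = backbone
            for p in positions:
                edges.append(MAGEdge(p, n, 999, 1, 0))
                n += 1
            return MAGMolecule(edges)

        forms = {
            canonical_form(linear(8))[0],
            canonical_form(methylated([1], 7))[0],
            canonical_form(methylated([1, 1], 6))[0],
        }
        assert len(forms) == 3
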