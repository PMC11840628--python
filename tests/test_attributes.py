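"""Attribute enumeration, topology codes and global-row aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magsolex.attributes import (
    ATTRIBUTES,
    ATTR_INDEX,
    CodeCapacityError,
    CodeRangeError,
    SOLexMolecule,
    aggregate_global,
    decode_arr,
    decode_rcn,
    encode_arr,
    encode_rcn,
    solex_equal,
)
from magsolex.fixtures import example_molecule


class TestEnumeration:
    def test_forty_four_unique_attributes_with_pinned_indices(self):
        assert len(ATTRIBUTES) == 44
        assert len({a.name for a in ATTRIBUTES}) == 44
        # the reaction and scan gates address these positions directly
        assert [ATTRIBUTES[i].family for i in (0, 1, 2)] == ["aromatic_ring"] * 3
        assert ATTR_INDEX["Rp"] == 19 and ATTR_INDEX["Rm"] == 20
        assert ATTR_INDEX["RCn"] == 42 and ATTR_INDEX["Arr"] == 43


class TestCodes:
    @pytest.mark.parametrize(
        "lengths,expected",
        [([4, 3], "04030000"), ([4], "04000000"), ([], "00000000")],
    )
    def test_rcn_encoding(self, lengths, expected):
        assert encode_rcn(lengths).digits == expected

    @pytest.mark.parametrize(
        "cores,expected", [([2, 3], "2300"), ([1], "1000"), ([], "0000")]
    )
    def test_arr_encoding(self, cores, expected):
        assert encode_arr(cores).digits == expected

    def test_code_capacity_and_range_errors(self):
        with pytest.raises(CodeCapacityError):
            encode_rcn([1, 2, 3, 4, 5])
        with pytest.raises(CodeRangeError):
            encode_rcn([100])
        with pytest.raises(CodeCapacityError):
            encode_arr([1, 2, 3, 4, 5])
        with pytest.raises(CodeRangeError):
            encode_arr([10])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.integers(1, 99), max_size=4))
    def test_rcn_roundtrip(self, lengths):
        assert list(decode_rcn(encode_rcn(lengths))) == lengths

    def test_arr_roundtrip_exhaustive(self):
        # every ascending subset of up to four partner cores
        from itertools import combinations

        for k in range(5):
            for combo in combinations(range(1, 10), k):
                assert decode_arr(encode_arr(list(combo))) == combo


class TestAggregation:
    def _three_core(self):
        rows = np.zeros((3, 42), dtype=int)
        rows[:, ATTR_INDEX["Rm"]] = [3, 24, 9]
        return aggregate_global(rows, links=[(1, 2, 4), (1, 3, 3)])

    def test_global_rm_includes_connecting_carbons(self):
        mol = self._three_core()
        assert mol.value("Rm") == 43

    def test_global_rcn_is_total_connecting_carbons(self):
        assert self._three_core().value("RCn") == 7

    def test_global_arr_is_core_count(self):
        assert self._three_core().value("Arr") == 3

    def test_per_core_codes(self):
        mol = self._three_core()
        assert mol.rcn[0].digits == "04030000"
        assert mol.arr[0].digits == "2300"
        assert mol.rcn[1].digits == "04000000"
        assert mol.arr[2].digits == "1000"

    def test_monocore_global_equals_core_row(self):
        rows = np.zeros((1, 42), dtype=int)
        rows[0, ATTR_INDEX["A6"]] = 1
        rows[0, ATTR_INDEX["Rm"]] = 5
        mol = aggregate_global(rows)
        m = mol.matrix
        # identical on every counting column and on RCn; the global Arr entry
        # carries the core count by definition
        assert np.array_equal(m[0, :43], m[1, :43])

    def test_inconsistent_links_rejected(self):
        rows = np.zeros((2, 42), dtype=int)
        with pytest.raises(Exception):
            aggregate_global(rows, links=[(1, 5, 2)])


class TestEquality:
    def test_self_equality(self):
        _, sol = example_molecule("dmen")
        assert solex_equal(sol, sol)

    def test_cis_trans_share_one_solex(self):
        _, a = example_molecule("cis_2_butene")
        _, b = example_molecule("trans_2_butene")
        assert solex_equal(a, b)

    def test_benzene_differs_from_cyclohexane(self):
        _, a = example_molecule("benzene")
        _, b = example_molecule("cyclohexane")
        assert not solex_equal(a, b)

    def test_core_shape_mismatch_compares_globals_with_warning(self):
        _, mono = example_molecule("benzene")
        _, multi = example_molecule("threecore_example")
        with pytest.warns(UserWarning):
            assert not solex_equal(mono, multi)
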