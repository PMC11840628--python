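"""Joback & Reid group counts and property correlations from the attribute row.

The 23 structural groups used here are the classic Joback first-order groups
restricted to the chemistry the attribute vocabulary can express, with the
aromatic carbons split three ways (unsubstituted ``aCH``, peripheral
condensed ``aC``, substituted ``aC``) so that fused-ring accounting stays
explicit.  Group counts come from a single matrix multiplication: the global
attribute row (42 counting columns) times a fixed 42 x 23 increment table.
Each table row encodes both what an attribute *adds* and what it *converts* —
e.g. a fused aromatic ring (``A4``) adds four carbons but also turns two
existing aromatic CH into condensed aC, and a ring methyl (``MEa``) moves a
chain carbon from CH2 to CH3 while substituting one ring position — so ring,
chain and substitution bookkeeping always balances atom-for-atom.

Property estimates then follow the published correlations:

.. math::

    T_b = 198.2 + \\sum_i N_i \\Delta T_{b,i} \\qquad
    T_m = 122.5 + \\sum_i N_i \\Delta T_{m,i}

    T_c = T_b \\left[0.584 + 0.965 \\Sigma T_c - (\\Sigma T_c)^2\\right]^{-1}
    \\qquad
    P_c = \\left[0.113 + 0.0032\\, n_A - \\Sigma P_c\\right]^{-2}
    \\qquad
    V_c = 17.5 + \\Sigma V_c

with :math:`n_A` the total atom count including hydrogen, temperatures in K,
pressure in bar and volume in cm3/mol.

A note on constants: the two condensed/substituted aromatic-carbon groups use
the Joback *ring* ``>C<`` constants and the aromatic CH uses the ring
``=CH-`` constants.  With that assignment the five properties of the worked
naphthalene example in the test-suite reproduce the published reference
values to the printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attributes import ATTR_INDEX, N_COUNT_ATTRIBUTES, SOLexMolecule

__all__ = [
    "JobackGroup",
    "JOBACK_GROUPS",
    "JOBACK_GROUP_INDEX",
    "joback_table",
    "joback_groups",
    "joback_properties",
    "PropertySet",
    "NegativeGroupCountError",
]


class NegativeGroupCountError(ValueError):
    """The multiplication produced a negative count: the SOLex is malformed."""


@dataclass(frozen=True)
class PropertySet:
    """Critical constants plus boiling and melting points for one molecule."""

    Tc: float  # K
    Pc: float  # bar
    Vc: float  # cm3/mol
    Tb: float  # K
    Tm: float  # K

    def as_dict(self) -> dict[str, float]:
        return {"Tc": self.Tc, "Pc": self.Pc, "Vc": self.Vc, "Tb": self.Tb, "Tm": self.Tm}


@dataclass(frozen=True)
class JobackGroup:
    name: str
    elements: dict  # heavy-atom content, e.g. {"C": 1}
    hydrogens: int
    dTc: float
    dPc: float
    dVc: float
    dTb: float
    dTm: float


# Contribution constants from the published Joback & Reid table.
# fmt: off
JOBACK_GROUPS: tuple[JobackGroup, ...] = (
    JobackGroup("CH3",     {"C": 1}, 3, 0.0141, -0.0012, 65.0, 23.58,  -5.10),
    JobackGroup("CH2",     {"C": 1}, 2, 0.0189,  0.0000, 56.0, 22.88,  11.27),
    JobackGroup("CH",      {"C": 1}, 1, 0.0164,  0.0020, 41.0, 21.74,  12.64),
    JobackGroup("C",       {"C": 1}, 0, 0.0067,  0.0043, 27.0, 18.25,  46.43),
    JobackGroup("=CH",     {"C": 1}, 1, 0.0129, -0.0006, 46.0, 24.96,   8.73),
    JobackGroup("aCH",     {"C": 1}, 1, 0.0082,  0.0011, 41.0, 26.73,   8.13),
    JobackGroup("aC_pc",   {"C": 1}, 0, 0.0042,  0.0061, 27.0, 21.32,  60.15),
    JobackGroup("aC_sub",  {"C": 1}, 0, 0.0042,  0.0061, 27.0, 21.32,  60.15),
    JobackGroup("rCH2",    {"C": 1}, 2, 0.0100,  0.0025, 48.0, 27.15,   7.75),
    JobackGroup("rCH",     {"C": 1}, 1, 0.0122,  0.0004, 38.0, 21.78,  19.88),
    JobackGroup("rC",      {"C": 1}, 0, 0.0042,  0.0061, 27.0, 21.32,  60.15),
    JobackGroup("r=CH",    {"C": 1}, 1, 0.0082,  0.0011, 41.0, 26.73,   8.13),
    JobackGroup("OH",      {"O": 1}, 1, 0.0741,  0.0112, 28.0, 92.88,  44.45),
    JobackGroup("O_chain", {"O": 1}, 0, 0.0168,  0.0015, 18.0, 22.42,  22.23),
    JobackGroup("O_ring",  {"O": 1}, 0, 0.0098,  0.0048, 13.0, 31.22,  23.05),
    JobackGroup("C=O",     {"C": 1, "O": 1}, 0, 0.0380, 0.0031, 62.0, 76.75, 61.20),
    JobackGroup("CHO",     {"C": 1, "O": 1}, 1, 0.0379, 0.0030, 82.0, 72.24, 36.90),
    JobackGroup("COOH",    {"C": 1, "O": 2}, 1, 0.0791, 0.0077, 89.0, 169.09, 155.50),
    JobackGroup("NH2",     {"N": 1}, 2, 0.0243,  0.0109, 38.0, 73.23,  66.89),
    JobackGroup("NH_ring", {"N": 1}, 1, 0.0130,  0.0114, 29.0, 52.82, 101.51),
    JobackGroup("=N_ring", {"N": 1}, 0, 0.0085,  0.0076, 34.0, 57.55,  68.40),
    JobackGroup("S_ring",  {"S": 1}, 0, 0.0019,  0.0051, 38.0, 52.10,  79.93),
    JobackGroup("S_chain", {"S": 1}, 0, 0.0119,  0.0049, 54.0, 68.78,  34.40),
)
# fmt: on

JOBACK_GROUP_INDEX = {g.name: i for i, g in enumerate(JOBACK_GROUPS)}
N_JOBACK = len(JOBACK_GROUPS)
assert N_JOBACK == 23

# SOLex attribute -> Joback group increments.  Written as sparse
# {group: delta} rows; anything not listed is zero.
_TABLE_ROWS: dict[str, dict[str, int]] = {
    # aromatic ring increments
    "A6": {"aCH": 6},
    "A4": {"aCH": 2, "aC_pc": 2},
    "A3": {"rCH2": 1, "aC_pc": 2},
    "A2": {"aC_pc": 2},
    # naphthenic ring increments (additions net of junction conversions)
    "N6": {"rCH2": 6},
    "N5": {"rCH2": 5},
    "N4a": {"rCH2": 4, "aCH": -2, "aC_pc": 2},
    "N4n": {"rCH2": 2, "rCH": 2},
    "N3a": {"rCH2": 3, "aCH": -2, "aC_pc": 2},
    "N3m": {"rCH2": 2, "rCH": 1, "aCH": -1, "aC_pc": 1},
    "N3n": {"rCH2": 1, "rCH": 2},
    "N2a": {"rCH2": 2, "aCH": -2, "aC_pc": 2},
    "N2f": {"rCH2": 1, "rCH": 1, "aCH": -1, "aC_pc": 1},
    "N2m": {"rCH2": 1, "rCH": 1, "aCH": -1, "aC_pc": 1},
    "N2n": {"rCH": 2},
    "N1": {"rCH2": -1, "rCH": 2},
    # hydrogen deficiency
    "IHo": {"CH2": -2, "=CH": 2},
    "IHn": {"rCH2": -2, "r=CH": 2},
    # chain carbons and topology
    "Rn": {"rCH2": -1, "rCH": 1},
    "Rp": {"CH3": 1},
    "Rm": {"CH2": 1},
    "Ra": {"aCH": -1, "aC_sub": 1},
    "br": {"CH2": -1, "CH": 1},
    "br2": {"CH2": -1, "C": 1},
    "MEa": {"CH2": -1, "CH3": 1, "aCH": -1, "aC_sub": 1},
    "MEn": {"CH2": -1, "CH3": 1, "rCH2": -1, "rCH": 1},
    "AAa": {"aCH": -2, "aC_sub": 2},
    "AAn": {"aCH": -1, "aC_sub": 1, "rCH2": -1, "rCH": 1},
    # heteroatom substitutions
    "NS": {"rCH2": -1, "S_ring": 1},
    "RS": {"CH2": -1, "S_chain": 1},
    "ANa": {"aCH": -1, "=N_ring": 1},
    "ANn": {"aCH": -1, "NH_ring": 1},
    "NN": {"rCH2": -1, "NH_ring": 1},
    "RN": {"CH2": -1, "CH": 1, "NH2": 1},
    "NO": {"rCH2": -1, "O_ring": 1},
    "RO": {"CH2": -1, "O_chain": 1},
    "KO": {"CH2": -1, "C=O": 1},
    "OH": {"CH2": -1, "CH": 1, "OH": 1},
    "CHO": {"CH3": -1, "CHO": 1},
    "COOH": {"CH3": -1, "COOH": 1},
    # metals have no Joback image
    "Ni": {},
    "V": {},
}


def joback_table() -> np.ndarray:
    """The 42 x 23 attribute -> group increment matrix."""
    t = np.zeros((N_COUNT_ATTRIBUTES, N_JOBACK))
    for attr, row in _TABLE_ROWS.items():
        for group, delta in row.items():
            t[ATTR_INDEX[attr], JOBACK_GROUP_INDEX[group]] = delta
    return t


_TABLE = None


def joback_groups(solex: SOLexMolecule) -> dict[str, int]:
    """Joback group counts by multiplying the global row with the table."""
    global _TABLE
    if _TABLE is None:
        _TABLE = joback_table()
    vec = solex.count_vector() @ _TABLE
    counts = {g.name: int(round(v)) for g, v in zip(JOBACK_GROUPS, vec)}
    bad = [name for name, v in counts.items() if v < 0]
    if bad:
        raise NegativeGroupCountError(
            f"negative counts for group(s) {bad}: inconsistent attribute row"
        )
    return {name: v for name, v in counts.items() if v}


def joback_properties(groups: dict[str, int], n_atoms: int) -> PropertySet:
    """Joback & Reid correlations for Tc, Pc, Vc, Tb and Tm.

    ``n_atoms`` is the total atom count including hydrogens (it enters the
    critical-pressure correlation).
    """
    if not groups or all(v == 0 for v in groups.values()):
        raise ValueError("cannot estimate properties from an empty group vector")
    s_tc = s_pc = s_vc = s_tb = s_tm = 0.0
    for name, n in groups.items():
        g = JOBACK_GROUPS[JOBACK_GROUP_INDEX[name]]
        s_tc += n * g.dTc
        s_pc += n * g.dPc
        s_vc += n * g.dVc
        s_tb += n * g.dTb
        s_tm += n * g.dTm
    tb = 198.2 + s_tb
    tm = 122.5 + s_tm
    tc = tb / (0.584 + 0.965 * s_tc - s_tc**2)
    pc_base = 0.113 + 0.0032 * n_atoms - s_pc
    if pc_base <= 0:
        raise ValueError("critical-pressure correlation outside its domain")
    pc = pc_base**-2
    vc = 17.5 + s_vc
    return PropertySet(Tc=tc, Pc=pc, Vc=vc, Tb=tb, Tm=tm)


def group_hydrogens(groups: dict[str, int]) -> int:
    """Hydrogen total implied by a group vector (for conservation checks)."""
    return sum(n * JOBACK_GROUPS[JOBACK_GROUP_INDEX[name]].hydrogens
               for name, n in groups.items())


def group_heavy_atoms(groups: dict[str, int]) -> int:
    """Heavy atoms implied by a group vector."""
    return sum(
        n * sum(JOBACK_GROUPS[JOBACK_GROUP_INDEX[name]].elements.values())
        for name, n in groups.items()
    )
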