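"""Extended structure-oriented-lumping (SOLex) attribute matrices.

A SOLex record summarises one molecule as a small integer matrix: one row per
*core* (a block of concatenated rings) plus a leading *global* row (core
position 0) holding the totals for the whole molecule.  Each of the 44 columns
is a structural increment: ring increments classified by how many new carbons
the ring adds and by the saturation of its fused neighbours, chain-carbon
counts, branch points, ring methyls, hydrogen-deficiency counters, heteroatom
substituents, metals, and two inter-core topology codes (``RCn`` and ``Arr``).

The representation is deliberately lossy — it cannot place atoms — but it is
cheap to query, which is what makes it useful as a gate in front of the full
edge-list graph (:mod:`magsolex.mag`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SOLexAttribute",
    "ATTRIBUTES",
    "ATTR_INDEX",
    "N_ATTRIBUTES",
    "N_COUNT_ATTRIBUTES",
    "IDX_RCN",
    "IDX_ARR",
    "RCnCode",
    "ArrCode",
    "encode_rcn",
    "decode_rcn",
    "encode_arr",
    "decode_arr",
    "SOLexMolecule",
    "SOLexMixture",
    "aggregate_global",
    "solex_equal",
    "SOLexError",
    "CodeCapacityError",
    "CodeRangeError",
]

MAX_LINKS_PER_CORE = 4  # the RCn/Arr code width admits no more
MAX_CORES = 9           # Arr digits are single decimal digits


class SOLexError(ValueError):
    """Malformed SOLex data."""


class CodeCapacityError(SOLexError):
    """More inter-core links than the RCn/Arr code can hold."""


class CodeRangeError(SOLexError):
    """A chain length or core index outside the code's digit range."""


@dataclass(frozen=True)
class SOLexAttribute:
    index: int
    name: str
    family: str


# fmt: off
_ATTRIBUTE_SPECS = [
    # -- ring increments -------------------------------------------------
    # aromatic rings, by the number of carbons the ring adds when fused
    # onto the already-counted ring system
    ("A6",   "aromatic_ring"),      # 0: free-standing 6-carbon aromatic ring
    ("A4",   "aromatic_ring"),      # 1: ortho-fused aromatic, 4 new carbons
    ("A3",   "aromatic_ring"),      # 2: peri-fused aromatic (phenalene type)
    ("A2",   "aromatic_ring"),      # 3: doubly ortho-fused (pyrene type)
    # naphthenic rings, same increment logic, subtype letters encode the
    # saturation of the fused neighbours (a=aromatic, n=naphthenic, m/f mixed)
    ("N6",   "naphthenic_ring"),    # 4
    ("N5",   "naphthenic_ring"),    # 5
    ("N4a",  "naphthenic_ring"),    # 6
    ("N4n",  "naphthenic_ring"),    # 7
    ("N3a",  "naphthenic_ring"),    # 8
    ("N3m",  "naphthenic_ring"),    # 9
    ("N3n",  "naphthenic_ring"),    # 10
    ("N2a",  "naphthenic_ring"),    # 11
    ("N2m",  "naphthenic_ring"),    # 12
    ("N2f",  "naphthenic_ring"),    # 13
    ("N2n",  "naphthenic_ring"),    # 14
    ("N1",   "naphthenic_ring"),    # 15
    # -- hydrogen deficiency --------------------------------------------
    ("IHo",  "hydrogen_deficiency"),  # 16: olefinic/chain unsaturation
    ("IHn",  "hydrogen_deficiency"),  # 17: unsaturation inside naphthenic rings
    # -- aliphatic carbon & chain topology ------------------------------
    ("Rn",   "aliphatic_carbon"),   # 18: chain attachment on a naphthenic ring
    ("Rp",   "aliphatic_carbon"),   # 19: terminal CH3 carbon of a free chain
    ("Rm",   "aliphatic_carbon"),   # 20: chain carbon counted as CH2
    ("Ra",   "aliphatic_carbon"),   # 21: chain attachment on an aromatic ring
    ("br",   "branch"),             # 22: ternary branch point in a chain
    ("br2",  "branch"),             # 23: quaternary carbon in a chain
    ("MEa",  "ring_methyl"),        # 24: methyl on an aromatic ring
    ("MEn",  "ring_methyl"),        # 25: methyl on a naphthenic ring
    ("AAa",  "topology"),           # 26: direct bond joining two aromatic rings
    ("AAn",  "topology"),           # 27: direct aromatic-naphthenic ring bond
    # -- heteroatoms ----------------------------------------------------
    ("NS",   "heteroatom"),         # 28: S replacing CH2 in a naphthenic ring
    ("RS",   "heteroatom"),         # 29: S replacing CH2 in a chain (sulfide)
    ("ANa",  "heteroatom"),         # 30: N replacing CH in an aromatic 6-ring
    ("ANn",  "heteroatom"),         # 31: NH in an aromatic 5-ring (pyrrolic)
    ("NN",   "heteroatom"),         # 32: NH replacing CH2 in a naphthenic ring
    ("RN",   "heteroatom"),         # 33: amine NH2 attached to a chain carbon
    ("NO",   "heteroatom"),         # 34: O replacing CH2 in a naphthenic ring
    ("RO",   "heteroatom"),         # 35: ether O replacing CH2 in a chain
    ("KO",   "heteroatom"),         # 36: ketone =O on an interior chain carbon
    ("OH",   "heteroatom"),         # 37: hydroxyl on a chain carbon
    ("CHO",  "heteroatom"),         # 38: terminal chain carbon as aldehyde
    ("COOH", "heteroatom"),         # 39: terminal chain carbon as carboxyl
    ("Ni",   "metal"),              # 40
    ("V",    "metal"),              # 41
    # -- inter-core topology codes --------------------------------------
    ("RCn",  "topology"),           # 42: WWXXYYZZ chain-length code / total
    ("Arr",  "topology"),           # 43: WXYZ connected-core code / core count
]
# fmt: on

ATTRIBUTES: tuple[SOLexAttribute, ...] = tuple(
    SOLexAttribute(i, name, family) for i, (name, family) in enumerate(_ATTRIBUTE_SPECS)
)
ATTR_INDEX: dict[str, int] = {a.name: a.index for a in ATTRIBUTES}
N_ATTRIBUTES = len(ATTRIBUTES)
N_COUNT_ATTRIBUTES = N_ATTRIBUTES - 2  # everything but RCn/Arr

IDX_RCN = ATTR_INDEX["RCn"]
IDX_ARR = ATTR_INDEX["Arr"]

# Index positions other modules rely on (reaction gates address raw indices).
assert N_ATTRIBUTES == 44
assert len(ATTR_INDEX) == 44, "attribute names must be unique"
assert [ATTRIBUTES[i].family for i in (0, 1, 2)] == ["aromatic_ring"] * 3
assert ATTR_INDEX["Rp"] == 19 and ATTR_INDEX["Rm"] == 20
assert IDX_RCN == 42 and IDX_ARR == 43


# ---------------------------------------------------------------------------
# RCn / Arr codes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RCnCode:
    """Per-core chain-length code: four two-digit pairs ``WWXXYYZZ``.

    Pair *k* is the length (in carbons) of the *k*-th connecting chain leaving
    this core, in the order of the partner cores listed by the matching
    :class:`ArrCode`; unused pairs are ``00``.
    """

    digits: str = "00000000"

    def __post_init__(self) -> None:
        if len(self.digits) != 8 or not self.digits.isdigit():
            raise SOLexError(f"RCn code must be 8 digits, got {self.digits!r}")

    @property
    def lengths(self) -> tuple[int, ...]:
        pairs = [int(self.digits[i : i + 2]) for i in range(0, 8, 2)]
        return tuple(p for p in pairs if p > 0)

    def as_int(self) -> int:
        return int(self.digits)

    @classmethod
    def from_int(cls, value: int) -> "RCnCode":
        return cls(f"{value:08d}")


@dataclass(frozen=True)
class ArrCode:
    """Per-core connectivity code: four digits ``WXYZ``.

    Each digit is the (1-based) index of a core this core is linked to, in
    ascending order; unused digits are ``0``.
    """

    digits: str = "0000"

    def __post_init__(self) -> None:
        if len(self.digits) != 4 or not self.digits.isdigit():
            raise SOLexError(f"Arr code must be 4 digits, got {self.digits!r}")

    @property
    def connected(self) -> tuple[int, ...]:
        return tuple(int(d) for d in self.digits if d != "0")

    def as_int(self) -> int:
        return int(self.digits)

    @classmethod
    def from_int(cls, value: int) -> "ArrCode":
        return cls(f"{value:04d}")


def encode_rcn(chain_lengths: Sequence[int]) -> RCnCode:
    """Pack up to four connecting-chain lengths into a ``WWXXYYZZ`` code."""
    if len(chain_lengths) > MAX_LINKS_PER_CORE:
        raise CodeCapacityError(
            f"a core supports at most {MAX_LINKS_PER_CORE} links, got {len(chain_lengths)}"
        )
    for n in chain_lengths:
        if not 1 <= n <= 99:
            raise CodeRangeError(f"connecting-chain length {n} outside 1..99")
    digits = "".join(f"{n:02d}" for n in chain_lengths).ljust(8, "0")
    return RCnCode(digits)


def decode_rcn(code: RCnCode) -> tuple[int, ...]:
    return code.lengths


def encode_arr(connected_cores: Sequence[int]) -> ArrCode:
    """Pack the indices of the cores linked to this one into a ``WXYZ`` code."""
    if len(connected_cores) > MAX_LINKS_PER_CORE:
        raise CodeCapacityError(
            f"a core supports at most {MAX_LINKS_PER_CORE} links, got {len(connected_cores)}"
        )
    for c in connected_cores:
        if not 1 <= c <= MAX_CORES:
            raise CodeRangeError(f"core index {c} outside 1..{MAX_CORES}")
    digits = "".join(str(c) for c in sorted(connected_cores)).ljust(4, "0")
    return ArrCode(digits)


def decode_arr(code: ArrCode) -> tuple[int, ...]:
    return code.connected


# ---------------------------------------------------------------------------
# SOLex molecule
# ---------------------------------------------------------------------------

@dataclass
class SOLexMolecule:
    """Per-core attribute rows plus the derived global row.

    ``core_counts`` has shape ``(n_cores, 42)`` and holds the 42 counting
    attributes for each core; the topology codes are kept as zero-padded
    strings (``rcn``/``arr``, one per core) so that leading zeros survive.
    The integer matrix exposed by :attr:`matrix` — shape
    ``(n_cores + 1, 44)`` — renders codes as integers and puts the totals in
    row 0: every counting column is summed over the cores (``Rm`` additionally
    receives the inter-core connecting carbons), the global ``RCn`` entry is
    the total number of connecting carbons and the global ``Arr`` entry is the
    number of cores.
    """

    core_counts: np.ndarray
    rcn: list[RCnCode] = field(default_factory=list)
    arr: list[ArrCode] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.core_counts = np.asarray(self.core_counts, dtype=np.int64)
        if self.core_counts.ndim != 2 or self.core_counts.shape[1] != N_COUNT_ATTRIBUTES:
            raise SOLexError(
                f"core_counts must be (n_cores, {N_COUNT_ATTRIBUTES}), got {self.core_counts.shape}"
            )
        if self.core_counts.shape[0] < 1:
            raise SOLexError("a molecule has at least one core")
        if (self.core_counts < 0).any():
            raise SOLexError("attribute counts are non-negative")
        if not self.rcn:
            self.rcn = [RCnCode() for _ in range(self.n_cores)]
        if not self.arr:
            self.arr = [ArrCode() for _ in range(self.n_cores)]
        if len(self.rcn) != self.n_cores or len(self.arr) != self.n_cores:
            raise SOLexError("one RCn and one Arr code per core required")
        for c, (r, a) in enumerate(zip(self.rcn, self.arr), start=1):
            if len(r.lengths) != len(a.connected):
                raise SOLexError(
                    f"core {c}: RCn lists {len(r.lengths)} chains but Arr lists "
                    f"{len(a.connected)} partners"
                )
            if c in a.connected:
                raise SOLexError(f"core {c} lists itself in its Arr code")
            for p in a.connected:
                if p > self.n_cores:
                    raise SOLexError(f"core {c} links to nonexistent core {p}")

    @property
    def n_cores(self) -> int:
        return self.core_counts.shape[0]

    @property
    def connecting_carbons(self) -> int:
        # every chain is coded from both of its end cores
        return sum(sum(r.lengths) for r in self.rcn) // 2

    @property
    def global_counts(self) -> np.ndarray:
        g = self.core_counts.sum(axis=0)
        g[ATTR_INDEX["Rm"]] += self.connecting_carbons
        return g

    @property
    def matrix(self) -> np.ndarray:
        """Full ``(n_cores + 1, 44)`` integer matrix, global row first."""
        m = np.zeros((self.n_cores + 1, N_ATTRIBUTES), dtype=np.int64)
        m[0, :N_COUNT_ATTRIBUTES] = self.global_counts
        m[0, IDX_RCN] = self.connecting_carbons
        m[0, IDX_ARR] = self.n_cores
        m[1:, :N_COUNT_ATTRIBUTES] = self.core_counts
        m[1:, IDX_RCN] = [r.as_int() for r in self.rcn]
        m[1:, IDX_ARR] = [a.as_int() for a in self.arr]
        return m

    def value(self, name: str, core: int = 0) -> int:
        """Attribute value by name; ``core=0`` addresses the global row."""
        return int(self.matrix[core, ATTR_INDEX[name]])

    def global_row(self) -> np.ndarray:
        return self.matrix[0]

    def count_vector(self) -> np.ndarray:
        """Global row restricted to the 42 counting attributes."""
        return self.global_counts.copy()


@dataclass
class SOLexMixture:
    """An ordered collection of molecules sharing the attribute enumeration."""

    molecules: list[SOLexMolecule] = field(default_factory=list)

    def global_matrix(self) -> np.ndarray:
        """One global row per molecule: the mixture-level matrix."""
        if not self.molecules:
            return np.zeros((0, N_ATTRIBUTES), dtype=np.int64)
        return np.stack([m.global_row() for m in self.molecules])

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self):
        return iter(self.molecules)


def aggregate_global(
    core_rows: Sequence[Sequence[int]] | np.ndarray,
    links: Iterable[tuple[int, int, int]] = (),
) -> SOLexMolecule:
    """Assemble a molecule from per-core counting rows and inter-core links.

    Parameters
    ----------
    core_rows
        ``(n_cores, 42)`` counting attributes per core (no codes).
    links
        ``(core_a, core_b, n_carbons)`` triples, cores 1-based.  The RCn and
        Arr codes of both end cores are derived from these, and the global row
        follows from the stored invariants.
    """
    core_rows = np.asarray(core_rows, dtype=np.int64)
    if core_rows.ndim == 1:
        core_rows = core_rows[None, :]
    n_cores = core_rows.shape[0]
    if n_cores > MAX_CORES:
        raise CodeRangeError(f"at most {MAX_CORES} cores supported, got {n_cores}")
    per_core: dict[int, list[tuple[int, int]]] = {c: [] for c in range(1, n_cores + 1)}
    for a, b, length in links:
        if a == b:
            raise SOLexError(f"link joins core {a} to itself")
        for c in (a, b):
            if not 1 <= c <= n_cores:
                raise SOLexError(f"link references nonexistent core {c}")
        per_core[a].append((b, length))
        per_core[b].append((a, length))
    rcn, arr = [], []
    for c in range(1, n_cores + 1):
        entries = sorted(per_core[c])
        arr.append(encode_arr([p for p, _ in entries]))
        rcn.append(encode_rcn([l for _, l in entries]))
    return SOLexMolecule(core_rows, rcn=rcn, arr=arr)


def solex_equal(a: SOLexMolecule, b: SOLexMolecule) -> bool:
    """True iff the two attribute matrices are identical.

    If the molecules do not have the same number of cores a full row-by-row
    comparison is impossible; only the global rows are compared and the
    partial comparison is flagged with a warning.
    """
    if a.n_cores != b.n_cores:
        warnings.warn(
            "core dimensions differ; comparing global rows only", stacklevel=2
        )
        return bool(np.array_equal(a.global_row(), b.global_row()))
    return bool(np.array_equal(a.matrix, b.matrix))
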