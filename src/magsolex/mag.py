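"""Molecule-as-a-graph (MAG): the lossless edge-list representation.

Every bond of a molecule is one row of a fixed five-column integer matrix:

======  =====================================================================
column  meaning
======  =====================================================================
``Ai``  first atom of the bond (0-based)
``Aj``  second atom of the bond
``Info``  ring number for ring bonds; ``999`` for a bond between aliphatic
        carbons; ``900``/``901`` marking *cis*/*trans* on a double bond;
        ``1000``–``1004`` declaring a heteroatom sitting at ``Aj``
        (S, N, OH, O, OOH-carboxyl respectively)
``Core``  core number (1-based), or ``998`` for bonds of a chain that
        connects two cores
``Type``  0 saturated aliphatic, 1 saturated naphthenic, 2 aromatic,
        3 unsaturated aliphatic, 4 unsaturated naphthenic, 5 metal–N,
        6 triple
======  =====================================================================

Hydrogen is never stored: each heavy atom's hydrogen count is implied by its
valence.  Adding a bond adds exactly one row; the column count never changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import networkx as nx

__all__ = [
    "MAGEdge",
    "MAGMolecule",
    "RingSummary",
    "ValidationReport",
    "MAGError",
    "ValenceError",
    "INFO_CIS",
    "INFO_TRANS",
    "INFO_ALIPHATIC",
    "INFO_S",
    "INFO_N",
    "INFO_OH",
    "INFO_O",
    "INFO_OOH",
    "CORE_LINK",
    "validate",
    "implicit_hydrogens",
    "ring_summaries",
    "renumber",
]

INFO_CIS = 900
INFO_TRANS = 901
INFO_ALIPHATIC = 999
INFO_S = 1000
INFO_N = 1001
INFO_OH = 1002
INFO_O = 1003
INFO_OOH = 1004
CORE_LINK = 998

HETERO_INFO = {INFO_S: "S", INFO_N: "N", INFO_OH: "O", INFO_O: "O", INFO_OOH: "OOH"}
SPECIAL_INFO = {INFO_CIS, INFO_TRANS, INFO_ALIPHATIC} | set(HETERO_INFO)

TYPE_SAT_ALIPHATIC = 0
TYPE_SAT_NAPHTHENIC = 1
TYPE_AROMATIC = 2
TYPE_UNSAT_ALIPHATIC = 3
TYPE_UNSAT_NAPHTHENIC = 4
TYPE_METAL_N = 5
TYPE_TRIPLE = 6
VALID_TYPES = range(7)

#: integer bond order per Type (aromatic handled separately, per ring)
_ORDER = {0: 1, 1: 1, 2: 1, 3: 2, 4: 2, 5: 1, 6: 3}

VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}


class MAGError(ValueError):
    """Malformed MAG data."""


class ValenceError(MAGError):
    """An atom's bonds exceed its valence."""


@dataclass(frozen=True)
class MAGEdge:
    ai: int
    aj: int
    info: int
    core: int
    type: int

    def astuple(self) -> tuple[int, int, int, int, int]:
        return (self.ai, self.aj, self.info, self.core, self.type)


@dataclass
class RingSummary:
    ring_id: int
    atoms: tuple[int, ...]
    aromatic: bool
    unsaturated_bonds: int
    core: int
    #: neighbouring ring id -> number of shared atoms (2 = ortho-fused,
    #: 1 = spiro, >2 = peri/multi-fused)
    fused: dict[int, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.atoms)


@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, msg: str) -> None:
        self.issues.append(msg)

    def __str__(self) -> str:
        return "valid" if self.ok else "; ".join(self.issues)


class MAGMolecule:
    """Ordered edge list plus the element map derived from the Info codes."""

    def __init__(self, edges: Sequence[MAGEdge | tuple], n_atoms: int | None = None):
        self.edges: list[MAGEdge] = [
            e if isinstance(e, MAGEdge) else MAGEdge(*e) for e in edges
        ]
        atoms: set[int] = set()
        for e in self.edges:
            atoms.add(e.ai)
            atoms.add(e.aj)
        derived = (max(atoms) + 1) if atoms else 0
        if n_atoms is None:
            n_atoms = derived
        elif n_atoms < derived:
            raise MAGError(f"n_atoms={n_atoms} but edges address atom {derived - 1}")
        #: single-atom molecules (e.g. methane) carry no edges, so the atom
        #: count may be declared explicitly
        self.n_atoms = n_atoms
        self._elements = self._derive_elements()

    # -- construction helpers -------------------------------------------
    def _derive_elements(self) -> list[str]:
        elems = ["C"] * self.n_atoms
        for e in self.edges:
            if e.info in HETERO_INFO:
                elems[e.aj] = HETERO_INFO[e.info]
            if e.type == TYPE_METAL_N:
                elems[e.ai] = "M"  # unspecified porphyrin metal
        return elems

    def element(self, atom: int) -> str:
        return self._elements[atom]

    @property
    def elements(self) -> list[str]:
        return list(self._elements)

    def element_counts(self) -> dict[str, int]:
        """Heavy-atom counts; the OOH composite contributes two oxygens."""
        counts: dict[str, int] = {}
        for el in self._elements:
            if el == "OOH":
                counts["O"] = counts.get("O", 0) + 2
            else:
                counts[el] = counts.get(el, 0) + 1
        return counts

    # -- views -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[MAGEdge]:
        return iter(self.edges)

    def matrix(self) -> list[tuple[int, int, int, int, int]]:
        return [e.astuple() for e in self.edges]

    def neighbors(self, atom: int) -> list[tuple[int, MAGEdge]]:
        out = []
        for e in self.edges:
            if e.ai == atom:
                out.append((e.aj, e))
            elif e.aj == atom:
                out.append((e.ai, e))
        return out

    def adjacency(self) -> dict[int, list[tuple[int, MAGEdge]]]:
        adj: dict[int, list[tuple[int, MAGEdge]]] = {a: [] for a in range(self.n_atoms)}
        for e in self.edges:
            adj[e.ai].append((e.aj, e))
            adj[e.aj].append((e.ai, e))
        return adj

    def ring_ids(self) -> list[int]:
        return sorted({e.info for e in self.edges if e.info not in SPECIAL_INFO})

    def ring_atoms(self, ring_id: int) -> set[int]:
        atoms: set[int] = set()
        for e in self.edges:
            if e.info == ring_id:
                atoms.add(e.ai)
                atoms.add(e.aj)
        return atoms

    def cores(self) -> list[int]:
        return sorted({e.core for e in self.edges if e.core != CORE_LINK})

    def aromatic_atoms(self) -> set[int]:
        out: set[int] = set()
        for e in self.edges:
            if e.type == TYPE_AROMATIC:
                out.add(e.ai)
                out.add(e.aj)
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for a in range(self.n_atoms):
            g.add_node(a, element=self._elements[a])
        for e in self.edges:
            g.add_edge(e.ai, e.aj, info=e.info, core=e.core, type=e.type)
        return g

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MAGMolecule) and self.matrix() == other.matrix()

    def __repr__(self) -> str:
        return f"MAGMolecule({self.n_atoms} atoms, {len(self.edges)} bonds)"


# ---------------------------------------------------------------------------
# hydrogen completion
# ---------------------------------------------------------------------------

def _bond_order_sum(mag: MAGMolecule) -> list[float]:
    """Total bond order per atom; aromatic handled per ring (each aromatic
    ring contributes order 3 across an atom's two in-ring bonds)."""
    orders = [0.0] * mag.n_atoms
    for e in mag.edges:
        if e.info == INFO_OOH:
            # carboxyl composite: one sigma to the acid OH plus a double bond
            # to the carbonyl oxygen, all hanging off the carbon at Ai
            orders[e.ai] += 3
            orders[e.aj] += 3
            continue
        o = 1.5 if e.type == TYPE_AROMATIC else _ORDER[e.type]
        orders[e.ai] += o
        orders[e.aj] += o
    return orders


def implicit_hydrogens(mag: MAGMolecule) -> tuple[list[int], int]:
    """Hydrogens implied by valence completion, per atom and in total.

    Aromatic carbons carry 1 H unless substituted or at a ring fusion;
    this falls out of counting each aromatic bond as order 1.5 and flooring
    the half-integer left at three-coordinate fusion atoms to zero.
    """
    orders = _bond_order_sum(mag)
    hs: list[int] = []
    for a in range(mag.n_atoms):
        el = mag.element(a)
        if el == "M":
            hs.append(0)
            continue
        if el == "OOH":
            hs.append(1)  # the acid hydrogen
            continue
        rem = VALENCE[el] - orders[a]
        if abs(rem - round(rem)) > 1e-9:
            # half-integer: three aromatic bonds at a fusion atom
            rem = rem + 0.5 if rem < 0 else rem - 0.5
        rem = round(rem)
        if rem < 0:
            raise ValenceError(f"atom {a} ({el}) exceeds its valence by {-rem}")
        hs.append(int(rem))
    return hs, sum(hs)


# ---------------------------------------------------------------------------
# rings
# ---------------------------------------------------------------------------

def ring_summaries(mag: MAGMolecule) -> list[RingSummary]:
    """One summary per distinct ring number in the Info column.

    A ring's atom set is every atom on a row carrying its number; an edge
    shared by two fused rings carries the lower ring number, but both shared
    atoms still show up in the higher ring's rows, so fusion is recovered by
    intersecting atom sets (2 shared atoms = ortho-fused, 1 = spiro).
    """
    summaries: list[RingSummary] = []
    rids = mag.ring_ids()
    atom_sets: dict[int, set[int]] = {rid: mag.ring_atoms(rid) for rid in rids}
    for rid in rids:
        atoms = atom_sets[rid]
        if len(atoms) < 3:
            raise MAGError(f"ring {rid} has fewer than 3 member atoms")
        own_edges = [e for e in mag.edges if e.info == rid]
        types = {e.type for e in own_edges}
        aromatic = TYPE_AROMATIC in types
        unsat = sum(1 for e in own_edges if e.type == TYPE_UNSAT_NAPHTHENIC)
        cores = {e.core for e in own_edges if e.core != CORE_LINK}
        core = min(cores) if cores else 0
        fused = {
            other: len(atoms & atom_sets[other])
            for other in rids
            if other != rid and atoms & atom_sets[other]
        }
        summaries.append(
            RingSummary(rid, tuple(sorted(atoms)), aromatic, unsat, core, fused)
        )
    return summaries


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate(mag: MAGMolecule) -> ValidationReport:
    """Collect every representation violation; an empty report means valid."""
    rep = ValidationReport()
    rids = set(mag.ring_ids())
    n_rings = len(rids)

    if mag.n_atoms == 0 and mag.edges:
        rep.add("edges present but no atoms")

    seen_pairs: set[tuple[int, int]] = set()
    for row, e in enumerate(mag.edges):
        if e.type not in VALID_TYPES:
            rep.add(f"row {row}: Type {e.type} outside 0..6")
        if e.info in SPECIAL_INFO:
            pass
        elif 0 <= e.info < n_rings:
            pass
        else:
            rep.add(f"row {row}: Info {e.info} is neither a ring number nor a code")
        if e.core != CORE_LINK and not 1 <= e.core <= 9:
            rep.add(f"row {row}: Core {e.core} outside 1..9 and not 998")
        if e.ai == e.aj:
            rep.add(f"row {row}: self-bond on atom {e.ai}")
        pair = (min(e.ai, e.aj), max(e.ai, e.aj))
        if pair in seen_pairs:
            rep.add(f"row {row}: duplicate bond {pair}")
        seen_pairs.add(pair)

    if rids and rids != set(range(n_rings)):
        rep.add(f"ring numbers {sorted(rids)} are not consecutive from 0")

    atoms = {a for e in mag.edges for a in (e.ai, e.aj)}
    if atoms:
        expected = set(range(max(atoms) + 1))
        missing = expected - atoms
        if missing:
            rep.add(f"gap in atom numbering: atoms {sorted(missing)} never bonded")
        if mag.n_atoms != max(atoms) + 1:
            rep.add(f"declared n_atoms={mag.n_atoms} != {max(atoms) + 1} from edges")
        g = mag.to_networkx()
        if not nx.is_connected(g):
            rep.add("graph is not connected")

    try:
        for rid in sorted(rids):
            if len(mag.ring_atoms(rid)) < 3:
                rep.add(f"ring {rid} has fewer than 3 member atoms")
    except MAGError as exc:  # pragma: no cover - defensive
        rep.add(str(exc))

    try:
        implicit_hydrogens(mag)
    except ValenceError as exc:
        rep.add(str(exc))
    except KeyError:
        pass  # invalid Type code, already reported above
    return rep


# ---------------------------------------------------------------------------
# renumbering
# ---------------------------------------------------------------------------

def renumber(mag: MAGMolecule, order: Sequence[int]) -> MAGMolecule:
    """Apply a permutation ``order[old] = new`` to all atom indices."""
    if sorted(order) != list(range(mag.n_atoms)):
        raise MAGError("order must be a permutation of the atom indices")
    new_edges = [
        replace(e, ai=order[e.ai], aj=order[e.aj]) for e in mag.edges
    ]
    return MAGMolecule(new_edges, n_atoms=mag.n_atoms)
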