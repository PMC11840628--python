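"""Deriving the attribute summary from the graph, atom counts, SMILES export.

The two representations describe the same molecule at different resolutions,
so each must be recoverable from the other to the extent its information
content allows: the graph determines the attribute matrix completely
(:func:`solex_from_mag`), while the attribute matrix determines only the
molecular formula (:func:`atom_counts`, through the stoichiometric matrix).

The classification rules implemented here give each SOLex attribute an exact
accounting meaning (how many carbons it adds, which existing groups it
converts).  Ring increments are counted in ring-number order: a ring
contributes as many new carbons as it has atoms not already counted by a
lower-numbered ring, which yields the A6/A4/A3/A2 aromatic and N6..N1
naphthenic series, with naphthenic subtypes read from the saturation of the
previously counted neighbours.  Chain carbons are ``Rp`` (terminal CH3) or
``Rm`` (everything else, including ring-methyl carbons and the inter-core
connecting carbons); ``Ra``/``Rn`` count chain attachments on aromatic and
naphthenic ring sites, ``MEa``/``MEn`` ring methyls, ``br``/``br2`` ternary
and quaternary branch carbons, ``IHo``/``IHn`` chain and in-ring double
bonds, and the heteroatom attributes the substitutions listed in
:mod:`magsolex.attributes`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import mag as M
from .attributes import (
    ATTR_INDEX,
    N_COUNT_ATTRIBUTES,
    SOLexMolecule,
    aggregate_global,
)
from .mag import (
    CORE_LINK,
    INFO_ALIPHATIC,
    INFO_CIS,
    INFO_N,
    INFO_O,
    INFO_OH,
    INFO_OOH,
    INFO_S,
    INFO_TRANS,
    MAGError,
    MAGMolecule,
    TYPE_AROMATIC,
    TYPE_TRIPLE,
    TYPE_UNSAT_ALIPHATIC,
    TYPE_UNSAT_NAPHTHENIC,
    implicit_hydrogens,
    ring_summaries,
)

__all__ = [
    "STOICH_COLUMNS",
    "stoichiometric_table",
    "atom_counts",
    "solex_from_mag",
    "smiles_from_mag",
    "UnclassifiableStructureError",
    "InconsistentAttributesError",
    "MoleculePerception",
    "perceive",
]


class UnclassifiableStructureError(MAGError):
    """A ring or atom pattern outside the 44-attribute vocabulary."""


class InconsistentAttributesError(ValueError):
    """An attribute row that implies a negative atom count."""


# ---------------------------------------------------------------------------
# structural perception shared by the converters and the group finders
# ---------------------------------------------------------------------------

@dataclass
class MoleculePerception:
    """Per-atom structural roles derived in one pass over the edge list."""

    mag: MAGMolecule
    hydrogens: list[int]
    aromatic_atoms: set[int]
    ring_membership: dict[int, list[int]]          # atom -> ring ids
    rings: list  # RingSummary list, by ring id
    #: heavy neighbours that form the molecular skeleton (C plus 2-coordinate
    #: heteroatoms); substituent tags (OH, =O, NH2, OOH) are excluded
    backbone: dict[int, list[int]] = field(default_factory=dict)
    #: atom -> list of (substituent atom, info code) for 1-coordinate tags
    substituents: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    def in_ring(self, atom: int) -> bool:
        return bool(self.ring_membership.get(atom))

    def is_aromatic(self, atom: int) -> bool:
        return atom in self.aromatic_atoms

    def ring_of(self, atom: int) -> list[int]:
        return self.ring_membership.get(atom, [])


def perceive(mag: MAGMolecule) -> MoleculePerception:
    hs, _ = implicit_hydrogens(mag)
    rings = ring_summaries(mag)
    membership: dict[int, list[int]] = {}
    ring_atom_sets = {}
    for r in rings:
        ring_atom_sets[r.ring_id] = set(r.atoms)
        for a in r.atoms:
            membership.setdefault(a, []).append(r.ring_id)
    # an atom declared by a heteroatom tagging edge belongs to a ring when its
    # other edges carry the ring number — membership above already covers it
    aromatic = mag.aromatic_atoms()
    degree: dict[int, int] = {a: 0 for a in range(mag.n_atoms)}
    for e in mag.edges:
        degree[e.ai] += 1
        degree[e.aj] += 1
    backbone: dict[int, list[int]] = {a: [] for a in range(mag.n_atoms)}
    substituents: dict[int, list[tuple[int, int]]] = {a: [] for a in range(mag.n_atoms)}
    for e in mag.edges:
        el_j = mag.element(e.aj)
        tag = (
            e.info in (INFO_OH, INFO_OOH)
            or (e.info == INFO_N and degree[e.aj] == 1)
            or (e.info == INFO_O and degree[e.aj] == 1)
        )
        if tag:
            substituents[e.ai].append((e.aj, e.info))
            continue
        backbone[e.ai].append(e.aj)
        backbone[e.aj].append(e.ai)
    return MoleculePerception(
        mag=mag,
        hydrogens=hs,
        aromatic_atoms=aromatic,
        ring_membership=membership,
        rings=rings,
        backbone=backbone,
        substituents=substituents,
    )


# ---------------------------------------------------------------------------
# MAG -> SOLex
# ---------------------------------------------------------------------------

def _classify_ring(n_new: int, aromatic: bool, arom_neighbors: int, total_neighbors: int) -> str:
    if aromatic:
        table = {6: "A6", 4: "A4", 3: "A3", 2: "A2"}
        name = table.get(n_new)
        if name is None:
            raise UnclassifiableStructureError(
                f"aromatic ring adding {n_new} carbons has no attribute"
            )
        return name
    if n_new == 6:
        return "N6"
    if n_new == 5:
        return "N5"
    if n_new == 4:
        return "N4a" if arom_neighbors >= 1 else "N4n"
    if n_new == 3:
        return "N3a" if arom_neighbors >= 2 else ("N3m" if arom_neighbors == 1 else "N3n")
    if n_new == 2:
        return {3: "N2a", 2: "N2f", 1: "N2m"}.get(arom_neighbors, "N2n")
    if n_new == 1:
        return "N1"
    raise UnclassifiableStructureError(
        f"naphthenic ring adding {n_new} carbons has no attribute"
    )


def solex_from_mag(mag: MAGMolecule) -> SOLexMolecule:
    """Derive the full per-core attribute matrix from the edge list."""
    p = perceive(mag)
    cores = mag.cores() or [1]
    n_cores = max(cores)
    rows = np.zeros((n_cores, N_COUNT_ATTRIBUTES), dtype=np.int64)

    def bump(name: str, core: int, n: int = 1) -> None:
        if core == CORE_LINK:
            raise UnclassifiableStructureError(
                "substituent or branch on an inter-core connecting chain"
            )
        rows[core - 1, ATTR_INDEX[name]] += n

    # --- rings ----------------------------------------------------------
    # Aromatic rings are counted before naphthenic ones (the numbering
    # convention also puts them first); within each class, ring-number order.
    # This keeps classification correct for freshly transformed molecules
    # whose ring numbers predate a saturation reaction.
    counted: set[int] = set()
    counted_rings: set[int] = set()
    ring_by_id = {r.ring_id: r for r in p.rings}
    ring_order = sorted(p.rings, key=lambda r: (not r.aromatic, r.ring_id))
    for r in ring_order:
        new_atoms = [a for a in r.atoms if a not in counted]
        neighbors = [o for o in r.fused if o in counted_rings]
        # a lone single-shared-atom neighbour is a true spiro junction; two
        # of them arise from peri-style fusions, which the N3/N2 increments
        # cover (the hinge atoms are invisible to the ring's own rows)
        if len(neighbors) == 1 and r.fused[neighbors[0]] == 1:
            raise UnclassifiableStructureError(
                f"ring {r.ring_id}: spiro fusion has no attribute"
            )
        arom_n = sum(1 for o in neighbors if ring_by_id[o].aromatic)
        name = _classify_ring(len(new_atoms), r.aromatic, arom_n, len(neighbors))
        bump(name, r.core)
        counted.update(r.atoms)
        counted_rings.add(r.ring_id)
        # in-ring heteroatoms substitute one ring carbon of the increment
        for a in new_atoms:
            el = mag.element(a)
            if el == "C":
                continue
            if el == "N":
                bump("ANa" if r.aromatic and r.size == 6 else
                     ("ANn" if r.aromatic else "NN"), r.core)
            elif el == "O" and not r.aromatic:
                bump("NO", r.core)
            elif el == "S" and not r.aromatic:
                bump("NS", r.core)
            else:
                raise UnclassifiableStructureError(
                    f"ring heteroatom {el} in {'aromatic' if r.aromatic else 'naphthenic'} ring"
                )
        # in-ring unsaturation (one IHn per ring double bond)
        if not r.aromatic and r.unsaturated_bonds:
            bump("IHn", r.core, r.unsaturated_bonds)
        if p_subs := [a for a in r.atoms if p.substituents[a]]:
            raise UnclassifiableStructureError(
                f"substituent tag on ring atom(s) {p_subs} (phenol-type sites "
                "are outside the attribute vocabulary)"
            )

    # --- chains ---------------------------------------------------------
    atom_core: dict[int, int] = {}
    for e in mag.edges:
        if e.core != CORE_LINK:
            atom_core.setdefault(e.ai, e.core)
            atom_core.setdefault(e.aj, e.core)
    link_atoms = {
        a
        for e in mag.edges
        if e.core == CORE_LINK
        for a in (e.ai, e.aj)
        if not p.in_ring(a)
    }
    tag_atoms = {s for subs in p.substituents.values() for s, _ in subs}

    for a in range(mag.n_atoms):
        el = mag.element(a)
        if el in ("M", "OOH") or a in tag_atoms:
            continue
        if p.in_ring(a):
            continue
        core = atom_core.get(a, 1)
        if a in link_atoms:
            # connecting carbons appear only in the global row (via RCn)
            if p.substituents[a] or len(p.backbone[a]) > 2:
                raise UnclassifiableStructureError(
                    f"atom {a}: substituent or branch on a connecting chain"
                )
            continue
        if el == "N":
            raise UnclassifiableStructureError(
                f"atom {a}: chain backbone nitrogen has no attribute "
                "(amines are substituent tags)"
            )
        if el == "O":
            # ether oxygen substitutes a chain-carbon position: the position
            # is counted in Rm and RO performs the CH2 -> O turn
            bump("Rm", core)
            bump("RO", core)
            continue
        if el == "S":
            bump("Rm", core)
            bump("RS", core)
            continue
        # carbon in a chain
        nb = p.backbone[a]
        ring_nb = [b for b in nb if p.in_ring(b)]
        subs = p.substituents[a]
        if len(nb) == 1 and ring_nb and not subs:
            # ring methyl: the carbon itself counts as a chain carbon (Rm),
            # the methyl attribute performs the CH2->CH3 + ring-site turn
            bump("Rm", core)
            bump("MEa" if p.is_aromatic(ring_nb[0]) else "MEn", core)
            continue
        terminal = len(nb) == 1 and not ring_nb
        has_oo = any(info == INFO_OOH for _, info in subs)
        has_oh = any(info == INFO_OH for _, info in subs)
        has_n = any(info == INFO_N for _, info in subs)
        dbl_o = any(info == INFO_O for _, info in subs)
        if (has_oh or has_n) and terminal:
            raise UnclassifiableStructureError(
                f"atom {a}: OH/NH2 on a terminal chain carbon (primary sites "
                "have no attribute-level accounting)"
            )
        if has_oo:
            bump("Rp", core)
            bump("COOH", core)
        elif dbl_o:
            if terminal:
                bump("Rp", core)
                bump("CHO", core)
            else:
                bump("Rm", core)
                bump("KO", core)
        elif terminal:
            bump("Rp", core)
        else:
            bump("Rm", core)
        if has_oh:
            bump("OH", core)
        if has_n:
            bump("RN", core)
        if len(nb) == 3:
            bump("br", core)
        elif len(nb) == 4:
            bump("br2", core)

    # --- chain attachments and direct ring-ring bonds -------------------
    for e in mag.edges:
        if e.info in (INFO_OH, INFO_OOH) or e.aj in tag_atoms or e.ai in tag_atoms:
            continue
        i_ring, j_ring = p.in_ring(e.ai), p.in_ring(e.aj)
        if i_ring and j_ring and not (set(p.ring_of(e.ai)) & set(p.ring_of(e.aj))):
            # direct bond between two rings (biphenyl-type bridge)
            both_arom = p.is_aromatic(e.ai) and p.is_aromatic(e.aj)
            either_arom = p.is_aromatic(e.ai) or p.is_aromatic(e.aj)
            if not either_arom:
                raise UnclassifiableStructureError(
                    "direct naphthenic-naphthenic ring bond has no attribute"
                )
            core = e.core if e.core != CORE_LINK else atom_core.get(e.ai, 1)
            bump("AAa" if both_arom else "AAn", core)
            continue
        if i_ring != j_ring:
            ring_atom = e.ai if i_ring else e.aj
            chain_atom = e.aj if i_ring else e.ai
            if mag.element(chain_atom) == "C" and len(p.backbone[chain_atom]) == 1 \
                    and not p.substituents[chain_atom]:
                continue  # ring methyl, counted via MEa/MEn
            core = atom_core.get(ring_atom, 1)
            bump("Ra" if p.is_aromatic(ring_atom) else "Rn", core)

    # --- chain unsaturation --------------------------------------------
    for e in mag.edges:
        if e.info in (INFO_O, INFO_OOH):
            continue
        in_ring_bond = p.in_ring(e.ai) and p.in_ring(e.aj) and bool(
            set(p.ring_of(e.ai)) & set(p.ring_of(e.aj))
        )
        if in_ring_bond:
            continue
        core = e.core if e.core != CORE_LINK else atom_core.get(e.ai, 1)
        if e.type == TYPE_UNSAT_ALIPHATIC:
            bump("IHo", core)
        elif e.type == TYPE_TRIPLE:
            bump("IHo", core, 2)

    # --- metals ---------------------------------------------------------
    # (metal centres are represented but not speciated; see mag module)

    # --- inter-core links ----------------------------------------------
    links = _collect_links(mag, p)
    return aggregate_global(rows, links)


def _collect_links(mag: MAGMolecule, p: MoleculePerception) -> list[tuple[int, int, int]]:
    """Recover (core_a, core_b, n_carbons) from the 998-labelled chains."""
    link_edges = [e for e in mag.edges if e.core == CORE_LINK]
    if not link_edges:
        return []
    # walk each connecting path from ring atom to ring atom
    adj: dict[int, list[int]] = {}
    for e in link_edges:
        adj.setdefault(e.ai, []).append(e.aj)
        adj.setdefault(e.aj, []).append(e.ai)
    atom_core: dict[int, int] = {}
    for e in mag.edges:
        if e.core != CORE_LINK:
            atom_core.setdefault(e.ai, e.core)
            atom_core.setdefault(e.aj, e.core)
    ring_ends = [a for a in adj if p.in_ring(a)]
    links = []
    seen_paths: set[frozenset[int]] = set()
    for start in sorted(ring_ends):
        for nxt in adj[start]:
            if p.in_ring(nxt):
                # zero-length link (direct ring-ring bond labelled 998)
                continue
            path = [start, nxt]
            while not p.in_ring(path[-1]):
                options = [b for b in adj[path[-1]] if b != path[-2]]
                if not options:
                    raise UnclassifiableStructureError(
                        f"dangling inter-core chain at atom {path[-1]}"
                    )
                path.append(options[0])
            key = frozenset(path)
            if key in seen_paths:
                continue
            seen_paths.add(key)
            core_a = atom_core[path[0]]
            core_b = atom_core[path[-1]]
            n_carbons = len(path) - 2
            links.append((min(core_a, core_b), max(core_a, core_b), n_carbons))
    return sorted(links)


# ---------------------------------------------------------------------------
# atom counting (SOLex -> molecular formula)
# ---------------------------------------------------------------------------

STOICH_COLUMNS = ("C", "H", "S", "N", "O", "Ni", "V")


def stoichiometric_table() -> np.ndarray:
    """The 42 x 7 attribute -> element increment matrix.

    Derived from the same per-attribute accounting that drives the Joback
    table, so the two can never disagree on the formula; built lazily to
    avoid a circular import with :mod:`magsolex.joback`.
    """
    from .joback import JOBACK_GROUPS, joback_table

    weights = np.zeros((len(JOBACK_GROUPS), len(STOICH_COLUMNS)))
    for gi, g in enumerate(JOBACK_GROUPS):
        for el, n in g.elements.items():
            weights[gi, STOICH_COLUMNS.index(el)] = n
        weights[gi, STOICH_COLUMNS.index("H")] = g.hydrogens
    table = joback_table() @ weights
    # contributions with no Joback image (metals) are patched directly
    table[ATTR_INDEX["Ni"], STOICH_COLUMNS.index("Ni")] = 1
    table[ATTR_INDEX["V"], STOICH_COLUMNS.index("V")] = 1
    return table


_STOICH_CACHE: np.ndarray | None = None


def atom_counts(solex: SOLexMolecule) -> dict[str, int]:
    """(C, H, S, N, O, Ni, V) from the global attribute row.

    The multiplication of the global row by the stoichiometric matrix; a
    negative count signals an attribute combination no molecule can have.
    """
    global _STOICH_CACHE
    if _STOICH_CACHE is None:
        _STOICH_CACHE = stoichiometric_table()
    vec = solex.count_vector() @ _STOICH_CACHE
    counts = {el: int(round(v)) for el, v in zip(STOICH_COLUMNS, vec)}
    bad = [el for el, v in counts.items() if v < 0]
    if bad:
        raise InconsistentAttributesError(
            f"attribute row implies negative counts for {bad}"
        )
    return counts


# ---------------------------------------------------------------------------
# SMILES export
# ---------------------------------------------------------------------------

def smiles_from_mag(mag: MAGMolecule) -> str:
    """Write a SMILES string for the graph.

    Aromatic ring atoms are emitted lowercase, ring closures use the ring
    bond that closes each cycle during the traversal, and *cis*/*trans*
    codes on a chain double bond become directional single bonds on the
    flanking substituents.  The output is syntactically standard SMILES; it
    is not canonical — tests canonicalise through an external toolkit.
    """
    if mag.n_atoms == 0:
        return ""
    if mag.n_atoms == 1:
        return {"C": "C", "N": "N", "O": "O", "S": "S"}[mag.element(0)]
    p = perceive(mag)
    adj = mag.adjacency()

    stereo_edges = [e for e in mag.edges if e.info in (INFO_CIS, INFO_TRANS)]

    def atom_symbol(a: int) -> str:
        el = mag.element(a)
        if el == "OOH":
            return "C(=O)O"  # expanded at the caller
        if el == "M":
            return "[Ni]"
        return el.lower() if p.is_aromatic(a) else el

    def bond_symbol(e: M.MAGEdge) -> str:
        if e.type == TYPE_AROMATIC:
            return ""
        if e.type in (TYPE_UNSAT_ALIPHATIC, TYPE_UNSAT_NAPHTHENIC):
            return "="
        if e.type == TYPE_TRIPLE:
            return "#"
        return ""

    visited: set[int] = set()
    closures: dict[tuple[int, int], int] = {}
    closure_no = iter(range(1, 100))
    open_at: dict[int, list[str]] = {a: [] for a in range(mag.n_atoms)}

    # pre-assign ring-closure digits by finding back edges of a DFS
    parent: dict[int, int | None] = {}
    order: list[int] = []

    def dfs_tree(start: int) -> None:
        stack = [(start, None)]
        while stack:
            a, par = stack.pop()
            if a in visited:
                continue
            visited.add(a)
            parent[a] = par
            order.append(a)
            for b, _e in sorted(adj[a], reverse=True):
                if b not in visited:
                    stack.append((b, a))

    start = 0
    if stereo_edges:
        # start from a terminal atom so both stereo substituents are written
        # as neighbours of the double bond
        terminals = [a for a in range(mag.n_atoms) if len(adj[a]) == 1]
        if terminals:
            start = terminals[0]
    dfs_tree(start)
    tree_pairs = {(parent[a], a) for a in order if parent[a] is not None}
    for e in mag.edges:
        if (e.ai, e.aj) in tree_pairs or (e.aj, e.ai) in tree_pairs:
            continue
        n = next(closure_no)
        closures[(e.ai, e.aj)] = n
        closures[(e.aj, e.ai)] = n
        sym = bond_symbol(e)
        open_at[e.ai].append(f"{sym}{n}" if sym and not p.is_aromatic(e.ai) else str(n))
        open_at[e.aj].append(str(n))

    children: dict[int, list[int]] = {a: [] for a in order}
    for a in order:
        if parent[a] is not None:
            children[parent[a]].append(a)

    edge_lookup: dict[tuple[int, int], M.MAGEdge] = {}
    for e in mag.edges:
        edge_lookup[(e.ai, e.aj)] = e
        edge_lookup[(e.aj, e.ai)] = e

    def stereo_mark(e: M.MAGEdge, pos: str) -> str:
        # first flank always "/": trans keeps the direction, cis flips it
        if pos == "before":
            return "/"
        return "/" if e.info == INFO_TRANS else "\\"

    def write(a: int) -> str:
        sym = atom_symbol(a)
        out = sym + "".join(open_at[a])
        kids = children[a]
        for i, b in enumerate(kids):
            if mag.element(b) == "OOH":
                # carboxyl oxygens expand inline on their carbon
                out += "(=O)O" if i < len(kids) - 1 else "(=O)O"
                continue
            e = edge_lookup[(a, b)]
            bsym = bond_symbol(e)
            mark = ""
            if e.info in (INFO_CIS, INFO_TRANS):
                pass  # direction goes on the flanking single bonds
            else:
                for se in stereo_edges:
                    if a in (se.ai, se.aj) and b not in (se.ai, se.aj):
                        mark = stereo_mark(se, "after")
                    elif b in (se.ai, se.aj) and a not in (se.ai, se.aj):
                        mark = stereo_mark(se, "before")
            body = mark + bsym + write(b)
            if i < len(kids) - 1:
                out += f"({body})"
            else:
                out += body
        return out

    return write(start)
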