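"""Molecule identity: attribute-row gate, canonical graph, stereo codes.

Telling two molecules apart proceeds in stages of increasing cost, mirroring
how the two representations divide the work: if the attribute matrices
differ the molecules differ (cheap, no graph inspection); if they agree the
graphs are compared in canonical form; only if the constitutions coincide do
the stereochemical annotations decide — the *cis*/*trans* codes 900/901, and
for optical isomers the order in which a quaternary carbon's bonds appear.

Canonicalisation uses iterative neighbourhood refinement (Weisfeiler–Lehman
colouring) with backtracking individualisation, so isomorphic graphs yield
identical canonical edge lists regardless of how atoms were numbered.  The
bond-order criterion for optical isomers is made numbering-independent by
translating each centre's substituents to canonical labels and comparing the
row-order sequences up to even permutations (the chirality-preserving ones).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

from .attributes import SOLexMolecule, solex_equal
from .mag import (
    INFO_CIS,
    INFO_TRANS,
    MAGMolecule,
)

__all__ = ["IdentityVerdict", "same_molecule", "canonical_form"]


@dataclass
class IdentityVerdict:
    equal: bool
    stage: str  # solex_gate | graph | stereo
    detail: str | None = None

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.equal


# ---------------------------------------------------------------------------
# canonical form
# ---------------------------------------------------------------------------

def _edge_kind(e) -> int:
    # constitutional bond kind: stereo annotations are not constitution
    return e.type


def _refine(colors: list[int], adj: list[list[tuple[int, int]]]) -> list[int]:
    n = len(colors)
    while True:
        sigs = [
            (colors[a], tuple(sorted((k, colors[b]) for b, k in adj[a])))
            for a in range(n)
        ]
        table: dict = {}
        new = []
        for s in sorted(set(sigs)):
            table[s] = len(table)
        new = [table[s] for s in sigs]
        if new == colors:
            return colors
        colors = new


def _form(mag: MAGMolecule, order: list[int]) -> tuple:
    """Edge list under the permutation ``order[old] = new``, sorted."""
    nodes = tuple(sorted((order[a], mag.element(a)) for a in range(mag.n_atoms)))
    edges = tuple(sorted(
        (min(order[e.ai], order[e.aj]), max(order[e.ai], order[e.aj]), _edge_kind(e))
        for e in mag.edges
    ))
    return (nodes, edges)


def canonical_form(mag: MAGMolecule) -> tuple[tuple, list[int]]:
    """Canonical (nodes, edges) form plus the old->new atom mapping."""
    n = mag.n_atoms
    if n == 0:
        return ((tuple(), tuple()), [])
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for e in mag.edges:
        adj[e.ai].append((e.aj, _edge_kind(e)))
        adj[e.aj].append((e.ai, _edge_kind(e)))

    init = [
        hash((mag.element(a), tuple(sorted(k for _, k in adj[a]))))
        for a in range(n)
    ]
    # intern to small ints
    table = {c: i for i, c in enumerate(sorted(set(init)))}
    init = [table[c] for c in init]

    best: dict = {"form": None, "order": None}

    def search(colors: list[int]) -> None:
        colors = _refine(colors, adj)
        classes: dict[int, list[int]] = {}
        for a, c in enumerate(colors):
            classes.setdefault(c, []).append(a)
        ambiguous = [(c, atoms) for c, atoms in classes.items() if len(atoms) > 1]
        if not ambiguous:
            order = [0] * n
            for a in range(n):
                order[a] = colors[a]
            # colors are a permutation of 0..n-1 once all classes are singleton
            rank = {c: i for i, c in enumerate(sorted(colors))}
            order = [rank[c] for c in colors]
            f = _form(mag, order)
            if best["form"] is None or f < best["form"]:
                best["form"] = f
                best["order"] = order
            return
        c, atoms = min(ambiguous)
        for a in atoms:
            nxt = list(colors)
            nxt[a] = max(colors) + 1
            search(nxt)

    search(init)
    return best["form"], best["order"]


# ---------------------------------------------------------------------------
# identity
# ---------------------------------------------------------------------------

def _stereo_bonds(mag: MAGMolecule, order: list[int]) -> set[tuple]:
    out = set()
    for e in mag.edges:
        if e.info in (INFO_CIS, INFO_TRANS):
            pair = frozenset((order[e.ai], order[e.aj]))
            out.add((pair, e.info))
    return out


def _parity(seq_a: tuple, seq_b: tuple) -> int:
    """0 if seq_b is an even permutation of seq_a, 1 if odd."""
    perm = [seq_a.index(x) for x in seq_b]
    seen = [False] * len(perm)
    parity = 0
    for i in range(len(perm)):
        if seen[i]:
            continue
        j, ln = i, 0
        while not seen[j]:
            seen[j] = True
            j = perm[j]
            ln += 1
        parity ^= (ln - 1) & 1
    return parity


def _quaternary_words(mag: MAGMolecule, order: list[int]) -> dict[int, tuple]:
    """For each quaternary carbon with four distinct canonical neighbour
    labels: centre label -> neighbour labels in bond-row order."""
    nb_rows: dict[int, list[int]] = {}
    for e in mag.edges:
        nb_rows.setdefault(e.ai, []).append(e.aj)
        nb_rows.setdefault(e.aj, []).append(e.ai)
    words = {}
    for a, nbs in nb_rows.items():
        if mag.element(a) != "C" or len(nbs) != 4:
            continue
        labels = tuple(order[b] for b in nbs)
        if len(set(labels)) == 4:
            words[order[a]] = labels
    return words


def same_molecule(
    a: tuple[MAGMolecule, SOLexMolecule],
    b: tuple[MAGMolecule, SOLexMolecule],
) -> IdentityVerdict:
    """Three-stage identity check; see the module docstring.

    The attribute stage is the fast gate: it is only worth inspecting the
    graphs when the attribute matrices are completely equal.
    """
    mag_a, sol_a = a
    mag_b, sol_b = b
    if not solex_equal(sol_a, sol_b):
        return IdentityVerdict(False, "solex_gate", "attribute matrices differ")

    form_a, order_a = canonical_form(mag_a)
    form_b, order_b = canonical_form(mag_b)
    if form_a != form_b:
        return IdentityVerdict(False, "graph", "canonical edge lists differ")

    st_a = _stereo_bonds(mag_a, order_a)
    st_b = _stereo_bonds(mag_b, order_b)
    if st_a != st_b:
        return IdentityVerdict(False, "stereo", f"cis/trans codes differ: {st_a} vs {st_b}")

    qa = _quaternary_words(mag_a, order_a)
    qb = _quaternary_words(mag_b, order_b)
    if set(qa) != set(qb):  # pragma: no cover - same constitution implies same centres
        return IdentityVerdict(False, "stereo", "stereocentre sets differ")
    for centre, word_a in qa.items():
        word_b = qb[centre]
        if set(word_a) != set(word_b):  # pragma: no cover
            return IdentityVerdict(False, "stereo", f"centre {centre} substituents differ")
        if _parity(word_a, word_b):
            return IdentityVerdict(
                False, "stereo",
                f"bond order at quaternary centre {centre} is an odd permutation",
            )
    return IdentityVerdict(True, "stereo", None)
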