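"""Reaction rules applied in parallel on the graph and the attribute matrix.

Two hydroprocessing-style transformations are implemented:

* aromatic ring saturation — an aromatic ring takes up hydrogen and becomes
  naphthenic; on the graph this flips the ring's bond rows from Type 2 to
  Type 1, and in the attribute matrix the ring increment moves from the
  aromatic to the naphthenic column (with fused neighbours reclassified,
  e.g. N4a to N4n);
* dealkylation — a ring-attached alkyl chain is cleaved between its first
  and second carbons under hydrogen, leaving a ring methyl and releasing the
  rest of the chain as a linear paraffin; on the graph exactly one bond row
  disappears.

Whether a molecule is subject to a rule at all is decided on the attribute
row alone, by the same cheap predicates used to gate group identification:
aromatic rings exist iff attribute indices 0+1+2 sum positive, alkyl chains
iff indices 19+20 do.  Products carry a freshly derived attribute matrix, so
the stored pair can always be cross-checked against the graph.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .attributes import SOLexMolecule
from .interconvert import perceive, solex_from_mag
from .mag import (
    CORE_LINK,
    MAGEdge,
    MAGMolecule,
    TYPE_AROMATIC,
    TYPE_SAT_NAPHTHENIC,
    implicit_hydrogens,
    ring_summaries,
)

__all__ = [
    "Molecule",
    "ReactionOutcome",
    "InapplicableRuleError",
    "can_saturate",
    "can_dealkylate",
    "saturate_aromatic_ring",
    "dealkylate",
    "saturation_sites",
    "dealkylation_sites",
]

Molecule = tuple[MAGMolecule, SOLexMolecule]


class InapplicableRuleError(ValueError):
    """The requested site does not satisfy the rule's precondition."""


@dataclass
class ReactionOutcome:
    products: list[Molecule]
    h2_consumed: int  # moles H2 per mole reactant (negative = released)


def can_saturate(solex: SOLexMolecule) -> bool:
    """Aromatic rings present: global attributes 0 + 1 + 2 > 0."""
    row = solex.global_row()
    return int(row[0] + row[1] + row[2]) > 0


def can_dealkylate(solex: SOLexMolecule) -> bool:
    """Alkyl chains present: global attributes 19 + 20 (Rp + Rm) > 0."""
    row = solex.global_row()
    return int(row[19] + row[20]) > 0


def saturation_sites(mag: MAGMolecule) -> list[int]:
    """Aromatic ring ids, ascending."""
    return [r.ring_id for r in ring_summaries(mag) if r.aromatic]


def dealkylation_sites(mag: MAGMolecule) -> list[int]:
    """Ring atoms bearing a cleavable chain (at least two chain carbons)."""
    p = perceive(mag)
    sites = []
    for e in mag.edges:
        ring, chain = None, None
        if p.in_ring(e.ai) != p.in_ring(e.aj):
            ring = e.ai if p.in_ring(e.ai) else e.aj
            chain = e.aj if p.in_ring(e.ai) else e.ai
        if ring is None or mag.element(chain) != "C" or chain in _tags(p):
            continue
        if e.core == CORE_LINK:
            continue
        nxt = [b for b in p.backbone[chain] if b != ring and not p.in_ring(b)]
        # the beta carbon becomes the paraffin's terminal: a substituent tag
        # there (e.g. a hydroxyl) has no attribute-level accounting on a
        # primary carbon, so such chains are not eligible
        if nxt and not p.substituents[min(nxt)]:
            sites.append(ring)
    return sorted(set(sites))


def _tags(p) -> set[int]:
    return {s for subs in p.substituents.values() for s, _ in subs}


def saturate_aromatic_ring(molecule: Molecule, ring_id: int) -> ReactionOutcome:
    """Hydrogenate one aromatic ring to its naphthenic counterpart."""
    mag, _solex = molecule
    rings = {r.ring_id: r for r in ring_summaries(mag)}
    if ring_id not in rings or not rings[ring_id].aromatic:
        raise InapplicableRuleError(f"ring {ring_id} is not an aromatic ring")
    new_edges = [
        replace(e, type=TYPE_SAT_NAPHTHENIC)
        if e.info == ring_id and e.type == TYPE_AROMATIC
        else e
        for e in mag.edges
    ]
    product = MAGMolecule(new_edges, n_atoms=mag.n_atoms)
    _, h_old = implicit_hydrogens(mag)
    _, h_new = implicit_hydrogens(product)
    return ReactionOutcome(
        products=[(product, solex_from_mag(product))],
        h2_consumed=(h_new - h_old) // 2,
    )


def dealkylate(molecule: Molecule, chain_attachment: int) -> ReactionOutcome:
    """Cleave the chain at ``chain_attachment`` (a ring atom index) between
    its alpha and beta carbons, keeping a methyl on the ring."""
    mag, _solex = molecule
    p = perceive(mag)
    if not p.in_ring(chain_attachment):
        raise InapplicableRuleError(f"atom {chain_attachment} is not a ring atom")
    alphas = sorted(
        b for b in p.backbone[chain_attachment]
        if not p.in_ring(b) and mag.element(b) == "C" and b not in _tags(p)
    )
    if not alphas:
        raise InapplicableRuleError(f"no chain attached at atom {chain_attachment}")
    alpha = alphas[0]
    betas = sorted(
        b for b in p.backbone[alpha] if b != chain_attachment and not p.in_ring(b)
    )
    if not betas:
        raise InapplicableRuleError(
            f"chain at atom {chain_attachment} is a methyl (length 1); "
            "dealkylation needs at least two chain carbons"
        )
    beta = betas[0]
    if p.substituents[beta]:
        raise InapplicableRuleError(
            f"beta carbon {beta} carries a substituent tag; the paraffin "
            "product would fall outside the attribute vocabulary"
        )

    cut_row = next(
        i for i, e in enumerate(mag.edges) if {e.ai, e.aj} == {alpha, beta}
    )
    kept = [e for i, e in enumerate(mag.edges) if i != cut_row]

    # split into the two connected components
    comp = _component(kept, alpha, mag.n_atoms)
    ring_edges = [e for e in kept if e.ai in comp and e.aj in comp]
    par_edges = [e for e in kept if e.ai not in comp and e.aj not in comp]
    assert len(ring_edges) + len(par_edges) == len(kept)

    ring_mag = _renumber_compact(ring_edges, mag)
    par_mag = _renumber_compact(par_edges, mag, single_atom_fallback=beta, core_reset=True)

    _, h_old = implicit_hydrogens(mag)
    h_new = implicit_hydrogens(ring_mag)[1] + implicit_hydrogens(par_mag)[1]
    return ReactionOutcome(
        products=[
            (ring_mag, solex_from_mag(ring_mag)),
            (par_mag, solex_from_mag(par_mag)),
        ],
        h2_consumed=(h_new - h_old) // 2,
    )


def _component(edges: list[MAGEdge], seed: int, n_atoms: int) -> set[int]:
    adj: dict[int, list[int]] = {}
    for e in edges:
        adj.setdefault(e.ai, []).append(e.aj)
        adj.setdefault(e.aj, []).append(e.ai)
    seen = {seed}
    stack = [seed]
    while stack:
        a = stack.pop()
        for b in adj.get(a, []):
            if b not in seen:
                seen.add(b)
                stack.append(b)
    return seen


def _renumber_compact(
    edges: list[MAGEdge],
    parent: MAGMolecule,
    single_atom_fallback: int | None = None,
    core_reset: bool = False,
) -> MAGMolecule:
    """Compress atom indices preserving their order (the parent followed the
    numbering convention, so the order survives the split)."""
    atoms = sorted({a for e in edges for a in (e.ai, e.aj)})
    if not atoms and single_atom_fallback is not None:
        return MAGMolecule([], n_atoms=1)
    remap = {a: i for i, a in enumerate(atoms)}
    out = [
        MAGEdge(remap[e.ai], remap[e.aj], e.info,
                1 if core_reset else e.core, e.type)
        for e in edges
    ]
    return MAGMolecule(out, n_atoms=len(atoms))
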