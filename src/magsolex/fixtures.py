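"""Reference molecules and a seeded generator of random valid molecules.

The catalog reconstructs the worked examples that exercise every part of the
representation: a large branched monocore molecule, a three-core molecule
with 4- and 3-carbon connecting chains, a tetralin bearing a branched side
chain, an amine, 4,6-dimethyl-1-ethylnaphthalene, four isomeric oxygenated
molecules, the 2-butene geometric pair and an optical pair, plus the
single-ring primitives used throughout the tests.  Where a published figure
pins only attribute totals (ring census, carbon counts, branch counts), the
catalog realises one concrete topology consistent with those totals; the
attribute-level quantities do not depend on the choice.

Every catalog entry is returned as a (MAG, SOLex) pair whose SOLex equals
``solex_from_mag`` of its MAG by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attributes import SOLexMolecule
from .interconvert import solex_from_mag
from .mag import (
    CORE_LINK,
    INFO_ALIPHATIC,
    INFO_CIS,
    INFO_N,
    INFO_O,
    INFO_OH,
    INFO_OOH,
    INFO_TRANS,
    MAGEdge,
    MAGMolecule,
)

__all__ = [
    "example_molecule",
    "catalog_names",
    "RandomMoleculeParams",
    "random_molecule",
    "reaction_products_example",
]


class _B:
    """Incremental molecule builder keeping the conventional numbering:
    ring atoms first (aromatic before naphthenic), then ring methyls,
    chains, branches and heteroatoms, core by core."""

    def __init__(self) -> None:
        self.edges: list[MAGEdge] = []
        self.n = 0
        self.rings = 0

    def atoms(self, k: int) -> list[int]:
        out = list(range(self.n, self.n + k))
        self.n += k
        return out

    def bond(self, ai: int, aj: int, info: int, core: int, type_: int) -> None:
        self.edges.append(MAGEdge(ai, aj, info, core, type_))

    def ring6(self, core: int, aromatic: bool, fuse: tuple[int, int] | None = None,
              hetero: dict[int, int] | None = None) -> list[int]:
        """A six-ring; ``fuse`` names an existing edge to share (ortho-fusion).

        ``hetero`` maps a position in the *new-atom* list to an Info code
        (e.g. ``{3: INFO_O}``) placing a heteroatom in the ring via the
        tagging-edge convention.
        """
        rid = self.rings
        self.rings += 1
        t = 2 if aromatic else 1
        if fuse is None:
            a = self.atoms(6)
            cycle = a
        else:
            a = self.atoms(4)
            cycle = [fuse[1], *a, fuse[0]]
        hetero = hetero or {}
        new_set = set(a)
        pairs = list(zip(cycle, cycle[1:] + cycle[:1]))
        if fuse is not None:
            pairs = [pr for pr in pairs if set(pr) != set(fuse)]
        for ai, aj in pairs:
            info = rid
            for pos, code in hetero.items():
                if a[pos] == aj and aj in new_set:
                    info = code
                    new_set.discard(aj)  # tag once
            self.bond(ai, aj, info, core, t)
        return cycle

    def ring5(self, core: int, aromatic: bool = False) -> list[int]:
        rid = self.rings
        self.rings += 1
        a = self.atoms(5)
        for ai, aj in zip(a, a[1:] + a[:1]):
            self.bond(ai, aj, rid, core, 2 if aromatic else 1)
        return a

    def ring_peri(self, core: int, path: tuple[int, int, int], aromatic: bool = False) -> list[int]:
        """Six-ring sharing the two adjacent existing edges along ``path``."""
        rid = self.rings
        self.rings += 1
        a = self.atoms(3)
        t = 2 if aromatic else 1
        cycle = [path[2], *a, path[0]]
        for ai, aj in zip(cycle, cycle[1:]):
            self.bond(ai, aj, rid, core, t)
        return a

    def ring_n2(self, core: int, path: tuple[int, int, int, int]) -> list[int]:
        """Six-ring sharing three consecutive existing edges (adds 2 atoms)."""
        rid = self.rings
        self.rings += 1
        a = self.atoms(2)
        cycle = [path[3], *a, path[0]]
        for ai, aj in zip(cycle, cycle[1:]):
            self.bond(ai, aj, rid, core, 1)
        return a

    def methyl(self, on: int, core: int) -> int:
        (m,) = self.atoms(1)
        self.bond(on, m, INFO_ALIPHATIC, core, 0)
        return m

    def chain(self, on: int, length: int, core: int) -> list[int]:
        a = self.atoms(length)
        prev = on
        for c in a:
            self.bond(prev, c, INFO_ALIPHATIC, core, 0)
            prev = c
        return a

    def link(self, a: int, b: int, length: int) -> list[int]:
        """Connecting chain of ``length`` carbons between two ring atoms."""
        mid = self.atoms(length)
        prev = a
        for c in mid:
            self.bond(prev, c, INFO_ALIPHATIC, CORE_LINK, 0)
            prev = c
        self.bond(prev, b, INFO_ALIPHATIC, CORE_LINK, 0)
        return mid

    def tag(self, on: int, code: int, core: int, type_: int = 0) -> int:
        (x,) = self.atoms(1)
        self.bond(on, x, code, core, type_)
        return x

    def mag(self) -> MAGMolecule:
        return MAGMolecule(self.edges)


def _pair(b: _B) -> tuple[MAGMolecule, SOLexMolecule]:
    mag = b.mag()
    return mag, solex_from_mag(mag)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _benzene():
    b = _B()
    b.ring6(1, aromatic=True)
    return _pair(b)


def _cyclohexane():
    b = _B()
    b.ring6(1, aromatic=False)
    return _pair(b)


def _cyclopentane():
    b = _B()
    b.ring5(1)
    return _pair(b)


def _naphthalene():
    b = _B()
    r = b.ring6(1, aromatic=True)
    b.ring6(1, aromatic=True, fuse=(r[1], r[2]))
    return _pair(b)


def _tetralin():
    b = _B()
    r = b.ring6(1, aromatic=True)
    b.ring6(1, aromatic=False, fuse=(r[1], r[2]))
    return _pair(b)


def _toluene():
    b = _B()
    r = b.ring6(1, aromatic=True)
    b.methyl(r[0], 1)
    return _pair(b)


def _ethylbenzene():
    b = _B()
    r = b.ring6(1, aromatic=True)
    b.chain(r[0], 2, 1)
    return _pair(b)


def _ethane():
    b = _B()
    a = b.atoms(2)
    b.bond(a[0], a[1], INFO_ALIPHATIC, 1, 0)
    return _pair(b)


def _propane():
    b = _B()
    a = b.atoms(3)
    b.bond(a[0], a[1], INFO_ALIPHATIC, 1, 0)
    b.bond(a[1], a[2], INFO_ALIPHATIC, 1, 0)
    return _pair(b)


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------

def _tetralin_branched_chain():
    # tetralin with a branched (isobutyl-like) chain on the naphthenic ring;
    # the chain bonds occupy rows 11-14 and the alpha-beta bond is row 12
    b = _B()
    r0 = b.ring6(1, aromatic=True)
    r1 = b.ring6(1, aromatic=False, fuse=(r0[1], r0[2]))
    c10, c11 = b.chain(r1[1], 2, 1)          # rows 11, 12
    b.methyl(c11, 1)                          # row 13
    b.methyl(c11, 1)                          # row 14
    return _pair(b)


def _dmen():
    """4,6-dimethyl-1-ethylnaphthalene."""
    b = _B()
    r0 = b.ring6(1, aromatic=True)
    r1 = b.ring6(1, aromatic=True, fuse=(r0[1], r0[2]))
    b.methyl(r0[3], 1)      # methyl at position 4
    b.methyl(r1[2], 1)      # methyl at position 6
    b.chain(r0[0], 2, 1)    # ethyl at position 1
    return _pair(b)


def _amine_example():
    # aromatic ring + fused naphthenic ring (N4a), chain on the naphthenic
    # ring carrying an amine at its interior carbon
    b = _B()
    r0 = b.ring6(1, aromatic=True)
    r1 = b.ring6(1, aromatic=False, fuse=(r0[1], r0[2]))
    c = b.chain(r1[1], 3, 1)
    b.tag(c[1], INFO_N, 1)
    return _pair(b)


def _monocore_example():
    """Large branched monocore molecule: 61 bonds, 27 chain carbons,
    six branch points, three ring methyls and one nitrogen."""
    b = _B()
    r0 = b.ring6(1, aromatic=True)                       # A6, bonds 0-5
    r1 = b.ring6(1, aromatic=True, fuse=(r0[1], r0[2]))  # A4
    r2 = b.ring6(1, aromatic=False, fuse=(r0[3], r0[4]))  # N4a
    # r2 cycle = [r0[4], n10, n11, n12, n13, r0[3]]
    n10, n11, n12, n13 = r2[1:5]
    r3 = b.ring6(1, aromatic=False, fuse=(n10, n11))      # N4n
    n14, n15, n16, n17 = r3[1:5]
    r4 = b.ring6(1, aromatic=False, fuse=(n14, n15))      # N4n
    # peri-fused ring over the adjacent edges (n17,n10) and (n10,n11): N3n
    b.ring_peri(1, (n17, n10, n11))
    # ring sharing three consecutive existing edges: N2n
    b.ring_n2(1, (r4[4], n14, n15, n16))
    # three ring methyls: two aromatic, one naphthenic
    b.methyl(r0[5], 1)
    b.methyl(r1[3], 1)
    b.methyl(n12, 1)
    # branched chain of 24 carbons on a naphthenic ring atom (18 backbone,
    # 6 single-carbon branches -> six ternary branch points)
    backbone = b.chain(n16, 18, 1)
    for i in (1, 3, 5, 7, 9, 11):
        b.methyl(backbone[i], 1)
    # a nitrogen on an interior chain carbon
    b.tag(backbone[2], INFO_N, 1)
    return _pair(b)


def _threecore_example():
    """Three cores: per-core interior chain carbons 3/24/9, linked by 4- and
    3-carbon chains from core 1; N and O heteroatoms in core 1."""
    b = _B()
    # core 1: naphthalene plus a fused naphthenic ring containing an oxygen
    r0 = b.ring6(1, aromatic=True)
    r1 = b.ring6(1, aromatic=True, fuse=(r0[1], r0[2]))
    r2 = b.ring6(1, aromatic=False, fuse=(r0[3], r0[4]), hetero={3: INFO_O})
    # side chain with 3 interior carbons and an amine on one of them
    c1 = b.chain(r2[1], 4, 1)
    b.tag(c1[1], INFO_N, 1)
    # core 2: naphthalene with two 13-carbon side chains (24 interior)
    s0 = b.ring6(2, aromatic=True)
    b.ring6(2, aromatic=True, fuse=(s0[1], s0[2]))
    b.chain(s0[3], 13, 2)
    b.chain(s0[4], 13, 2)
    # core 3: decalin-type with a branched 11-carbon side chain (9 interior)
    t0 = b.ring6(3, aromatic=False)
    b.ring6(3, aromatic=False, fuse=(t0[1], t0[2]))
    c3 = b.chain(t0[3], 10, 3)
    b.methyl(c3[2], 3)
    # links: core1-core2 by 4 carbons, core1-core3 by 3 carbons
    b.link(r0[5], s0[5], 4)
    b.link(r1[3], t0[4], 3)
    return _pair(b)


def _oxy_isomer(case: str):
    """Isomeric oxygenated molecules (all C10H18O2): a cyclohexane ring with
    a four-unit chain bearing (A) ketone+alcohol, (B) aldehyde+alcohol,
    (C) ether+aldehyde, (D) a carboxylic acid."""
    b = _B()
    r = b.ring6(1, aromatic=False)
    if case == "A":
        c = b.chain(r[0], 4, 1)
        b.tag(c[1], INFO_O, 1, type_=3)     # ketone C=O
        b.tag(c[2], INFO_OH, 1)             # alcohol
    elif case == "B":
        c = b.chain(r[0], 4, 1)
        b.tag(c[1], INFO_OH, 1)
        b.tag(c[3], INFO_O, 1, type_=3)     # terminal aldehyde
    elif case == "C":
        c1 = b.chain(r[0], 1, 1)
        o = b.tag(c1[0], INFO_O, 1)         # ether oxygen in the backbone
        c2 = b.chain(o, 3, 1)
        b.tag(c2[2], INFO_O, 1, type_=3)    # terminal aldehyde
    elif case == "D":
        c = b.chain(r[0], 4, 1)
        b.tag(c[3], INFO_OOH, 1, type_=3)   # carboxyl
    else:
        raise KeyError(case)
    return _pair(b)


def _butene(stereo: int):
    b = _B()
    a = b.atoms(4)
    b.bond(a[0], a[1], INFO_ALIPHATIC, 1, 0)
    b.bond(a[1], a[2], stereo, 1, 3)
    b.bond(a[2], a[3], INFO_ALIPHATIC, 1, 0)
    return _pair(b)


def _optical(order: str):
    """4-ethyl-4-methyloctane: a quaternary carbon bearing four distinct
    chains (1,2,3,4 carbons).  The two variants list the centre's bonds in
    different row orders, encoding an optical pair through bond order alone."""
    b = _B()
    (center,) = b.atoms(1)
    chains = {}
    for ln in (1, 2, 3, 4):
        first = b.atoms(1)[0]
        prev = first
        for _ in range(ln - 1):
            (nxt,) = b.atoms(1)
            b.bond(prev, nxt, INFO_ALIPHATIC, 1, 0)
            prev = nxt
        chains[ln] = first
    seq = (1, 2, 3, 4) if order == "R" else (2, 1, 3, 4)
    center_bonds = [MAGEdge(center, chains[ln], INFO_ALIPHATIC, 1, 0) for ln in seq]
    b.edges = center_bonds + b.edges
    return _pair(b)


def reaction_products_example():
    """The three products of applying both reaction rules (ring saturation,
    dealkylation) to the tetralin-with-branched-chain example, as validated
    (MAG, SOLex) pairs."""
    from .reactions import dealkylate, saturate_aromatic_ring

    mag, solex = _tetralin_branched_chain()
    sat = saturate_aromatic_ring((mag, solex), 0)
    deal = dealkylate((mag, solex), chain_attachment=6)
    return sat.products + deal.products


_CATALOG = {
    "benzene": _benzene,
    "cyclohexane": _cyclohexane,
    "cyclopentane": _cyclopentane,
    "naphthalene": _naphthalene,
    "tetralin": _tetralin,
    "toluene": _toluene,
    "ethylbenzene": _ethylbenzene,
    "ethane": _ethane,
    "propane": _propane,
    "monocore_example": _monocore_example,
    "threecore_example": _threecore_example,
    "tetralin_branched_chain": _tetralin_branched_chain,
    "amine_example": _amine_example,
    "dmen": _dmen,
    "oxy_isomer_A": lambda: _oxy_isomer("A"),
    "oxy_isomer_B": lambda: _oxy_isomer("B"),
    "oxy_isomer_C": lambda: _oxy_isomer("C"),
    "oxy_isomer_D": lambda: _oxy_isomer("D"),
    "cis_2_butene": lambda: _butene(INFO_CIS),
    "trans_2_butene": lambda: _butene(INFO_TRANS),
    "optical_R": lambda: _optical("R"),
    "optical_S": lambda: _optical("S"),
}


def catalog_names() -> list[str]:
    return list(_CATALOG)


def example_molecule(name: str) -> tuple[MAGMolecule, SOLexMolecule]:
    """Return the named catalog molecule as a (MAG, SOLex) pair."""
    try:
        build = _CATALOG[name]
    except KeyError:
        raise KeyError(f"unknown catalog molecule {name!r}; "
                       f"choose from {sorted(_CATALOG)}") from None
    return build()


# ---------------------------------------------------------------------------
# random molecules
# ---------------------------------------------------------------------------

@dataclass
class RandomMoleculeParams:
    """Knobs of the random generator; identical seed+params give identical
    molecules.  Defaults emulate mid-boiling petroleum-range molecules:
    one to three cores of one to three fused rings, short side chains, a
    modest heteroatom incidence and occasional chain stereo bonds."""

    seed: int = 0
    max_cores: int = 3
    ring_weights: tuple[float, ...] = (0.5, 0.35, 0.15)  # rings per core: 1,2,3
    max_chains_per_core: int = 2
    chain_lengths: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    branch_prob: float = 0.3
    hetero_prob: float = 0.15
    stereo_prob: float = 0.10
    olefin_prob: float = 0.10

    def __post_init__(self) -> None:
        if not 1 <= self.max_cores <= 4:
            raise ValueError("max_cores must be between 1 and 4")


def random_molecule(params: RandomMoleculeParams | int) -> tuple[MAGMolecule, SOLexMolecule]:
    """Generate a random molecule satisfying every representation invariant.

    Sampling order follows the structure of the representation itself:
    number of cores, rings per core (aromatic block first, then naphthenic
    fusions), side chains with branches and optional internal double bonds,
    heteroatom substitutions, then connecting chains between cores.
    """
    if isinstance(params, int):
        params = RandomMoleculeParams(seed=params)
    rng = np.random.default_rng(params.seed)
    b = _B()
    n_cores = int(rng.integers(1, params.max_cores + 1))
    core_sites: list[list[int]] = []   # candidate ring atoms per core

    for core in range(1, n_cores + 1):
        n_rings = int(rng.choice(len(params.ring_weights), p=np.asarray(params.ring_weights) /
                                 sum(params.ring_weights))) + 1
        aromatic_base = bool(rng.random() < 0.5)
        free_arom: list[tuple[int, int]] = []
        free_naph: list[tuple[int, int]] = []
        sites: list[int] = []

        if aromatic_base:
            r = b.ring6(core, aromatic=True)
            sites += r
            free_arom += list(zip(r, r[1:] + r[:1]))
        else:
            if n_rings == 1 and rng.random() < 0.3:
                r = b.ring5(core)
            else:
                r = b.ring6(core, aromatic=False)
            sites += r
            free_naph += list(zip(r, r[1:] + r[:1]))

        def _consume(edge: tuple[int, int]) -> None:
            # fusing saturates both edge atoms: drop every adjacent edge
            for lst in (free_arom, free_naph):
                lst[:] = [e for e in lst if not set(e) & set(edge)]

        for _ in range(n_rings - 1):
            if aromatic_base and free_arom and rng.random() < 0.5:
                edge = free_arom[int(rng.integers(len(free_arom)))]
                _consume(edge)
                kind = "A4" if rng.random() < 0.5 else "N4a"
                ring = b.ring6(core, aromatic=(kind == "A4"), fuse=edge)
                new = ring[1:5]
                if kind == "A4":
                    free_arom += list(zip(new, new[1:]))
                else:
                    free_naph += list(zip(new, new[1:]))
                sites += new
            elif free_naph:
                edge = free_naph[int(rng.integers(len(free_naph)))]
                _consume(edge)
                ring = b.ring6(core, aromatic=False, fuse=edge)
                new = ring[1:5]
                free_naph += list(zip(new, new[1:]))
                sites += new
        core_sites.append(sites)

        # ring heteroatom substitution (one per core at most).  The tagging
        # edge replaces one ring row, so both its atoms must stay reachable
        # through other rows of the same ring and the substituted atom must
        # carry nothing else.
        if rng.random() < params.hetero_prob:
            candidates = []
            for i, e in enumerate(b.edges):
                if e.core != core or e.type != 1 or e.info >= 900:
                    continue
                rid = e.info
                others = [e2 for j, e2 in enumerate(b.edges)
                          if j != i and e2.info == rid]
                cover = {a for e2 in others for a in (e2.ai, e2.aj)}
                deg = sum(1 for e2 in b.edges if e.aj in (e2.ai, e2.aj))
                if deg == 2 and e.ai in cover and e.aj in cover:
                    candidates.append(i)
            if candidates:
                i = candidates[int(rng.integers(len(candidates)))]
                e = b.edges[i]
                code = int(rng.choice([INFO_O, INFO_N, 1000]))
                b.edges[i] = MAGEdge(e.ai, e.aj, code, e.core, e.type)

        # side chains
        used: set[int] = set()
        for _ in range(int(rng.integers(0, params.max_chains_per_core + 1))):
            open_sites = [s for s in sites if s not in used and
                          _site_free(b, s)]
            if not open_sites:
                break
            s = open_sites[int(rng.integers(len(open_sites)))]
            used.add(s)
            ln = int(rng.choice(params.chain_lengths))
            if ln == 1:
                b.methyl(s, core)
                continue
            chain = b.chain(s, ln, core)
            branch_at = None
            if ln >= 3 and rng.random() < params.branch_prob:
                branch_at = int(rng.integers(0, ln - 2))
                b.methyl(chain[branch_at], core)
            if ln >= 4 and branch_at not in (1, 2) and rng.random() < params.olefin_prob:
                # internal double bond between chain[1] and chain[2]
                idx = next(i for i, e in enumerate(b.edges)
                           if {e.ai, e.aj} == {chain[1], chain[2]})
                info = INFO_ALIPHATIC
                if rng.random() < params.stereo_prob / max(params.olefin_prob, 1e-9):
                    info = int(rng.choice([INFO_CIS, INFO_TRANS]))
                e = b.edges[idx]
                b.edges[idx] = MAGEdge(e.ai, e.aj, info, e.core, 3)
            elif ln >= 4 and rng.random() < params.hetero_prob:
                positions = [i for i in range(1, ln - 1) if i != branch_at]
                if not positions:
                    continue
                c = chain[positions[int(rng.integers(len(positions)))]]
                choice = rng.random()
                if choice < 0.4:
                    b.tag(c, INFO_OH, core)
                elif choice < 0.7:
                    b.tag(c, INFO_N, core)
                else:
                    b.tag(c, INFO_O, core, type_=3)  # ketone

    # connecting chains: a tree over the cores, hub at core 1
    for core in range(2, n_cores + 1):
        a_site = next(s for s in core_sites[0] if _site_free(b, s))
        b_site = next(s for s in core_sites[core - 1] if _site_free(b, s))
        b.link(a_site, b_site, int(rng.integers(1, 7)))

    mag = b.mag()
    return mag, solex_from_mag(mag)


def _site_free(b: _B, atom: int) -> bool:
    """A ring atom can take a substituent if it still carries a hydrogen
    (exactly two ring bonds, no substituent, not a fusion atom, a carbon)."""
    deg = 0
    for e in b.edges:
        if atom in (e.ai, e.aj):
            deg += 1
            if e.info >= 1000 and e.aj == atom:
                return False  # heteroatom site
    return deg == 2
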