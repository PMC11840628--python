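"""Marrero–Gani first-order groups: gated identification and correlations.

Identifying Marrero–Gani (M&G) groups requires the full graph — the groups
encode local bonding arrangements (``aC-CH3`` is one group, not an aromatic
carbon plus a methyl) that the attribute summary cannot resolve.  Scanning
the whole edge list for every rule family is wasteful inside algorithms that
process thousands of molecules, so the identification is *gated*: a rule
family runs only when the attribute row says its structures exist at all
(e.g. the aromatic family only when attribute indices 0+1+2 sum positive),
and, per core, only over that core's rows.  The exhaustive scan — every rule
family over every row — serves as the reference implementation; both must
return identical group vectors, and both report how many edge rows they
visited so the saving is a measurable, hardware-independent quantity.

Property correlations (first order only)::

    Tc = 231.239 * ln(sum)     [K]
    Tb = 222.543 * ln(sum)     [K]
    Tm = 147.45  * ln(sum)     [K]
    Pc = 5.9827 + (sum + 0.108998)**-2   [bar]
    Vc = 7.95 + sum                      [cm3/mol]

The universal constants above are the published ones.  The per-group
contributions are *re-estimated* with the method's own procedure: ordinary
least squares in the transformed (sum) space against the experimental
dataset embedded below (standard critical-property compilation values for
~60 common compounds, fixed a priori).  The hydrocarbon families that matter
most here (alkanes, alkylbenzenes, fused aromatics, naphthenics) are densely
covered; the heteroatom families rest on fewer anchors and their constants
should be treated as indicative.  See docs/methods.md for the full
discussion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attributes import ATTR_INDEX, SOLexMolecule
from .interconvert import (
    MoleculePerception,
    UnclassifiableStructureError,
    perceive,
)
from .joback import PropertySet
from .mag import (
    CORE_LINK,
    INFO_N,
    INFO_O,
    INFO_OH,
    INFO_OOH,
    MAGMolecule,
    TYPE_TRIPLE,
    TYPE_UNSAT_ALIPHATIC,
    TYPE_UNSAT_NAPHTHENIC,
)

__all__ = [
    "MG_GROUPS",
    "ScanResult",
    "identify_groups_gated",
    "identify_groups_exhaustive",
    "mg_properties",
    "first_order_constants",
    "UncoveredAtomError",
]


class UncoveredAtomError(ValueError):
    """An atom matched by no first-order group rule."""


#: group name -> number of heavy atoms the group covers
MG_GROUPS: dict[str, int] = {
    "CH3": 1, "CH2": 1, "CH": 1, "C": 1,
    "CH2=CH": 2, "CH=CH": 2, "CH2=C": 2, "CH=C": 2,
    "aCH": 1, "aCfaC": 1, "aCfnA": 1, "aC": 1,
    "aC-CH3": 2, "aC-CH2": 2, "aC-CH": 2, "aC-C": 2,
    "CH2(cyc)": 1, "CH(cyc)": 1, "C(cyc)": 1, "CH=CH(cyc)": 2,
    "O(cyc)": 1, "NH(cyc)": 1, "S(cyc)": 1, "aN": 1,
    "OH": 1, "CH3CO": 3, "CH2CO": 3, "CHO": 2,
    "CH3O": 2, "CH2O": 2, "CH-O": 2, "COOH": 3,
    "NH2": 1, "CH3S": 2, "CH2S": 2,
}


@dataclass
class ScanResult:
    """Group vector plus the number of edge rows the scan visited."""

    groups: dict[str, int]
    visits: int

    def heavy_atoms(self) -> int:
        return sum(n * MG_GROUPS[g] for g, n in self.groups.items())


# ---------------------------------------------------------------------------
# rule families and their attribute gates
# ---------------------------------------------------------------------------

# family -> attribute names whose per-core sum gates the family
_FAMILY_GATES: dict[str, list[str]] = {
    "oxygen": ["NO", "RO", "KO", "OH", "CHO", "COOH"],
    "nitrogen": ["RN", "ANa", "ANn", "NN"],
    "sulfur": ["NS", "RS"],
    "aromatic": ["A6", "A4", "A3"],  # indices 0..2, the ring-saturation gate
    "naphthenic": ["N6", "N5", "N4a", "N4n", "N3a", "N3m", "N3n",
                   "N2a", "N2m", "N2f", "N2n", "N1"],
    "chain": ["Rp", "Rm"],
}
_FAMILY_ORDER = ("oxygen", "nitrogen", "sulfur", "aromatic", "naphthenic", "chain")


def _gate_value(solex: SOLexMolecule, family: str, core: int = 0) -> int:
    row = solex.matrix[core]
    return int(sum(row[ATTR_INDEX[a]] for a in _FAMILY_GATES[family]))


def _chain_h(p: MoleculePerception, a: int) -> int:
    return p.hydrogens[a]


def _match_family(
    mag: MAGMolecule,
    p: MoleculePerception,
    family: str,
    groups: dict[str, int],
    consumed: set[int],
) -> None:
    """Assign this family's groups, consuming atoms exactly once.

    Precedence inside a family and the family order itself resolve pattern
    overlaps (the larger, more specific group wins); remaining ties go to the
    lowest atom index, so assignment is deterministic.
    """

    def take(name: str, *atoms: int) -> None:
        groups[name] = groups.get(name, 0) + 1
        consumed.update(atoms)

    if family == "oxygen":
        for a in range(mag.n_atoms):
            if a in consumed or mag.element(a) != "C":
                continue
            subs = p.substituents[a]
            oo = [s for s, info in subs if info == INFO_OOH]
            dbl = [s for s, info in subs if info == INFO_O]
            if oo:
                take("COOH", a, *oo)
            elif dbl and len(p.backbone[a]) == 1:
                take("CHO", a, *dbl)
            elif dbl:
                # ketone: the group absorbs an alpha carbon, methyl preferred
                alphas = sorted(
                    b for b in p.backbone[a]
                    if b not in consumed and mag.element(b) == "C"
                    and not p.in_ring(b) and not p.substituents[b]
                )
                methyls = [b for b in alphas if p.hydrogens[b] == 3]
                ch2s = [b for b in alphas if p.hydrogens[b] == 2]
                if methyls:
                    take("CH3CO", a, *dbl, methyls[0])
                elif ch2s:
                    take("CH2CO", a, *dbl, ch2s[0])
                else:
                    raise UncoveredAtomError(
                        f"ketone carbon {a} without CH3/CH2 neighbour"
                    )
        for a in range(mag.n_atoms):
            if a in consumed or mag.element(a) != "O":
                continue
            if p.in_ring(a):
                take("O(cyc)", a)
                continue
            nb = [b for b in p.backbone[a] if mag.element(b) == "C"]
            if len(nb) == 2:
                # ether: absorb one alpha carbon, most-hydrogenated first
                cands = sorted(
                    (b for b in nb if b not in consumed and not p.in_ring(b)
                     and not p.substituents[b]),
                    key=lambda b: (-p.hydrogens[b], b),
                )
                if not cands:
                    raise UncoveredAtomError(f"ether oxygen {a} without free alpha carbon")
                b = cands[0]
                h = p.hydrogens[b]
                name = {3: "CH3O", 2: "CH2O", 1: "CH-O"}.get(h)
                if name is None:
                    raise UncoveredAtomError(f"ether alpha carbon {b} with {h} H")
                take(name, a, b)
        for a in range(mag.n_atoms):
            if a in consumed:
                continue
            for host, subs in p.substituents.items():
                for s, info in subs:
                    if s == a and info == INFO_OH:
                        take("OH", a)

    elif family == "nitrogen":
        for a in range(mag.n_atoms):
            if a in consumed or mag.element(a) != "N":
                continue
            if p.in_ring(a):
                take("aN" if p.is_aromatic(a) else "NH(cyc)", a)
            else:
                take("NH2", a)

    elif family == "sulfur":
        for a in range(mag.n_atoms):
            if a in consumed or mag.element(a) != "S":
                continue
            if p.in_ring(a):
                take("S(cyc)", a)
                continue
            nb = [b for b in p.backbone[a] if mag.element(b) == "C"]
            cands = sorted(
                (b for b in nb if b not in consumed and not p.in_ring(b)
                 and not p.substituents[b]),
                key=lambda b: (-p.hydrogens[b], b),
            )
            if not cands:
                raise UncoveredAtomError(f"sulfide sulfur {a} without free alpha carbon")
            b = cands[0]
            name = {3: "CH3S", 2: "CH2S"}.get(p.hydrogens[b])
            if name is None:
                raise UncoveredAtomError(f"sulfide alpha carbon {b}")
            take(name, a, b)

    elif family == "aromatic":
        for a in range(mag.n_atoms):
            if a in consumed or mag.element(a) != "C" or not p.is_aromatic(a):
                continue
            rings = [r for r in p.rings if a in r.atoms]
            arom_rings = [r for r in rings if r.aromatic]
            if len(arom_rings) >= 2:
                take("aCfaC", a)
                continue
            if len(rings) >= 2:
                take("aCfnA", a)
                continue
            # substituted?
            chain_subst = sorted(
                b for b in p.backbone[a]
                if not p.in_ring(b) and mag.element(b) == "C" and b not in consumed
                and not p.substituents[b]
            )
            if chain_subst:
                b = chain_subst[0]
                h = p.hydrogens[b]
                nb_b = len(p.backbone[b])
                name = {3: "aC-CH3", 2: "aC-CH2", 1: "aC-CH", 0: "aC-C"}.get(h)
                if name is None:  # pragma: no cover
                    raise UncoveredAtomError(f"aromatic substituent carbon {b}")
                take(name, a, b)
                continue
            other = [
                b for b in p.backbone[a]
                if (p.in_ring(b) and not set(p.ring_of(a)) & set(p.ring_of(b)))
                or (not p.in_ring(b) and mag.element(b) != "C")
                or (not p.in_ring(b) and b in consumed)
            ]
            if other or p.substituents[a] or p.hydrogens[a] == 0:
                take("aC", a)
            else:
                take("aCH", a)

    elif family == "naphthenic":
        # in-ring double bonds first (two-atom group)
        for e in mag.edges:
            if e.type == TYPE_UNSAT_NAPHTHENIC and e.ai not in consumed \
                    and e.aj not in consumed:
                take("CH=CH(cyc)", e.ai, e.aj)
        for a in range(mag.n_atoms):
            if a in consumed or mag.element(a) != "C":
                continue
            if not p.in_ring(a) or p.is_aromatic(a):
                continue
            h = p.hydrogens[a]
            name = {2: "CH2(cyc)", 1: "CH(cyc)", 0: "C(cyc)"}.get(h)
            if name is None:
                raise UncoveredAtomError(f"ring carbon {a} with {h} H")
            take(name, a)

    elif family == "chain":
        for e in mag.edges:
            if e.type in (TYPE_UNSAT_ALIPHATIC, TYPE_TRIPLE) \
                    and e.info not in (INFO_O, INFO_OOH) \
                    and e.ai not in consumed and e.aj not in consumed:
                hi, hj = sorted((p.hydrogens[e.ai], p.hydrogens[e.aj]), reverse=True)
                name = {(2, 1): "CH2=CH", (1, 1): "CH=CH",
                        (2, 0): "CH2=C", (1, 0): "CH=C"}.get((hi, hj))
                if name is None:
                    raise UncoveredAtomError(
                        f"olefinic pair ({e.ai},{e.aj}) with H ({hi},{hj})"
                    )
                take(name, e.ai, e.aj)
        for a in range(mag.n_atoms):
            if a in consumed or mag.element(a) != "C":
                continue
            if p.in_ring(a):
                continue
            h = p.hydrogens[a]
            # hydroxyl/amine hosts keep their own carbon group
            name = {3: "CH3", 2: "CH2", 1: "CH", 0: "C"}.get(h)
            if name is None:  # pragma: no cover
                raise UncoveredAtomError(f"chain carbon {a} with {h} H")
            take(name, a)


def _finish(mag: MAGMolecule, consumed: set[int], groups: dict[str, int]) -> None:
    left = [
        a for a in range(mag.n_atoms)
        if a not in consumed and mag.element(a) not in ("M",)
    ]
    if left:
        raise UncoveredAtomError(f"atoms {left} matched by no first-order group")


def _family_rows(mag: MAGMolecule, family: str, cores: list[int]) -> list[int]:
    """Row indices a gated scan of ``family`` must inspect."""
    rows = []
    for i, e in enumerate(mag.edges):
        if e.core in cores or (family == "chain" and e.core == CORE_LINK):
            rows.append(i)
    return rows


def identify_groups_exhaustive(mag: MAGMolecule) -> ScanResult:
    """Reference implementation: every rule family scans every edge row."""
    p = perceive(mag)
    groups: dict[str, int] = {}
    consumed: set[int] = set()
    visits = 0
    for family in _FAMILY_ORDER:
        visits += len(mag.edges)
        _match_family(mag, p, family, groups, consumed)
    _finish(mag, consumed, groups)
    return ScanResult(groups, visits)


def identify_groups_gated(mag: MAGMolecule, solex: SOLexMolecule) -> ScanResult:
    """Attribute-gated identification.

    A family is skipped outright when its global gate is zero; otherwise the
    scan is restricted to the rows of the cores whose per-core gate passes
    (plus the inter-core rows for the chain family).  When those rows are
    contiguous — the canonical ordering keeps each core's block together —
    the visit count is the block span; otherwise the scan falls back to the
    full row range.
    """
    p = perceive(mag)
    groups: dict[str, int] = {}
    consumed: set[int] = set()
    visits = 0
    n_rows = len(mag.edges)
    for family in _FAMILY_ORDER:
        if _gate_value(solex, family, core=0) == 0:
            continue  # no structures of this family anywhere in the molecule
        active = [
            c for c in range(1, solex.n_cores + 1)
            if _gate_value(solex, family, core=c) > 0
        ]
        rows = _family_rows(mag, family, active)
        if rows and rows[-1] - rows[0] + 1 == len(rows):
            visits += len(rows)
        else:
            visits += n_rows  # non-contiguous block: full scan fallback
        _match_family(mag, p, family, groups, consumed)
    _finish(mag, consumed, groups)
    return ScanResult(groups, visits)


# ---------------------------------------------------------------------------
# experimental calibration dataset
# ---------------------------------------------------------------------------

#: compound -> (group vector, Tc [K], Pc [bar], Vc [cm3/mol], Tb [K], Tm [K]).
#: None marks a property left out of the fit for that compound.  Values are
#: accepted experimental constants from the standard compilations.
CALIBRATION_DATA: dict[str, tuple[dict[str, int], float | None, float | None,
                                  float | None, float | None, float | None]] = {
    # --- n- and iso-alkanes -------------------------------------------
    "propane":        ({"CH3": 2, "CH2": 1}, 369.83, 42.48, 200.0, 231.02, 85.47),
    "n-butane":       ({"CH3": 2, "CH2": 2}, 425.12, 37.96, 255.0, 272.66, 134.86),
    "n-pentane":      ({"CH3": 2, "CH2": 3}, 469.70, 33.70, 313.0, 309.22, 143.42),
    "n-hexane":       ({"CH3": 2, "CH2": 4}, 507.60, 30.25, 371.0, 341.88, 177.83),
    "n-heptane":      ({"CH3": 2, "CH2": 5}, 540.20, 27.40, 428.0, 371.58, 182.57),
    "n-octane":       ({"CH3": 2, "CH2": 6}, 568.70, 24.90, 486.0, 398.83, 216.38),
    "n-decane":       ({"CH3": 2, "CH2": 8}, 617.70, 21.10, 601.0, 447.30, 243.51),
    "n-dodecane":     ({"CH3": 2, "CH2": 10}, 658.0, 18.20, 716.0, 489.47, 263.57),
    "isobutane":      ({"CH3": 3, "CH": 1}, 407.85, 36.40, 262.7, 261.34, 113.54),
    "2-methylbutane": ({"CH3": 3, "CH2": 1, "CH": 1}, 460.40, 33.80, 306.0, 300.99, 113.25),
    "2-methylpentane": ({"CH3": 3, "CH2": 2, "CH": 1}, 497.50, 30.10, 367.0, 333.41, 119.55),
    "neopentane":     ({"CH3": 4, "C": 1}, 433.80, 31.99, 307.0, 282.65, 256.60),
    "2,2-dimethylbutane": ({"CH3": 4, "CH2": 1, "C": 1}, 488.70, 30.80, 359.0, 322.88, 174.28),
    "2,2,4-trimethylpentane": ({"CH3": 5, "CH2": 1, "CH": 1, "C": 1},
                               543.90, 25.70, 468.0, 372.39, 165.78),
    # --- olefins -------------------------------------------------------
    "1-butene":       ({"CH2=CH": 1, "CH2": 1, "CH3": 1}, 419.50, 40.20, 240.8, 266.90, 87.80),
    "1-hexene":       ({"CH2=CH": 1, "CH2": 3, "CH3": 1}, 504.00, 31.43, 355.1, 336.63, 133.39),
    "cis-2-butene":   ({"CH=CH": 1, "CH3": 2}, 435.50, 42.10, 233.8, 276.87, 134.26),
    "trans-2-butene": ({"CH=CH": 1, "CH3": 2}, 428.60, 41.00, 237.7, 274.03, 167.62),
    "trans-2-pentene": ({"CH=CH": 1, "CH2": 1, "CH3": 2}, 475.00, 36.60, 300.0, 309.49, 132.89),
    "isobutylene":    ({"CH2=C": 1, "CH3": 2}, 417.90, 40.00, 238.9, 266.25, 132.81),
    "2-methyl-2-butene": ({"CH=C": 1, "CH3": 3}, 470.00, 34.20, 292.0, 311.71, 139.39),
    # --- alkylbenzenes and fused aromatics -----------------------------
    "benzene":        ({"aCH": 6}, 562.05, 48.98, 256.0, 353.24, 278.68),
    "toluene":        ({"aCH": 5, "aC-CH3": 1}, 591.75, 41.08, 316.0, 383.79, 178.18),
    "ethylbenzene":   ({"aCH": 5, "aC-CH2": 1, "CH3": 1}, 617.15, 36.09, 374.0, 409.36, 178.20),
    "o-xylene":       ({"aCH": 4, "aC-CH3": 2}, 630.30, 37.30, 370.0, 417.58, 247.98),
    "m-xylene":       ({"aCH": 4, "aC-CH3": 2}, 617.00, 35.40, 375.0, 412.34, 225.30),
    "p-xylene":       ({"aCH": 4, "aC-CH3": 2}, 616.20, 35.10, 378.0, 411.53, 286.41),
    "n-propylbenzene": ({"aCH": 5, "aC-CH2": 1, "CH2": 1, "CH3": 1},
                        638.35, 32.00, 440.0, 432.39, 173.59),
    "cumene":         ({"aCH": 5, "aC-CH": 1, "CH3": 2}, 631.00, 32.09, 427.0, 425.56, 177.14),
    "tert-butylbenzene": ({"aCH": 5, "aC-C": 1, "CH3": 3}, 660.00, 29.70, 497.0, 442.30, 215.30),
    "mesitylene":     ({"aCH": 3, "aC-CH3": 3}, 637.30, 31.30, 433.0, 437.89, 228.46),
    "1,2,4-trimethylbenzene": ({"aCH": 3, "aC-CH3": 3}, 649.10, 32.30, 435.0, 442.53, 229.38),
    "n-butylbenzene": ({"aCH": 5, "aC-CH2": 1, "CH2": 2, "CH3": 1},
                       660.50, 28.90, 497.0, 456.46, 185.30),
    "naphthalene":    ({"aCH": 8, "aCfaC": 2}, 748.40, 40.50, 407.0, 491.14, 353.43),
    "1-methylnaphthalene": ({"aCH": 7, "aCfaC": 2, "aC-CH3": 1},
                            772.00, 36.00, 465.0, 517.84, 242.67),
    "2-methylnaphthalene": ({"aCH": 7, "aCfaC": 2, "aC-CH3": 1},
                            761.00, 35.00, 462.0, 514.26, 307.73),
    "biphenyl":       ({"aCH": 10, "aC": 2}, 773.00, 38.50, 502.0, 528.15, 342.20),
    "anthracene":     ({"aCH": 10, "aCfaC": 4}, 873.00, 29.00, 554.0, 613.12, 488.93),
    "phenanthrene":   ({"aCH": 10, "aCfaC": 4}, 869.00, 28.70, 554.0, 610.03, 372.38),
    "tetralin":       ({"aCH": 4, "aCfnA": 2, "CH2(cyc)": 4}, 720.00, 36.50, 408.0, 480.77, 237.38),
    # --- naphthenics ---------------------------------------------------
    "cyclopentane":   ({"CH2(cyc)": 5}, 511.70, 45.10, 260.0, 322.40, 179.28),
    "cyclohexane":    ({"CH2(cyc)": 6}, 553.80, 40.70, 308.0, 353.87, 279.69),
    "methylcyclopentane": ({"CH2(cyc)": 4, "CH(cyc)": 1, "CH3": 1},
                           532.80, 37.85, 319.0, 344.96, 130.72),
    "methylcyclohexane": ({"CH2(cyc)": 5, "CH(cyc)": 1, "CH3": 1},
                          572.20, 34.70, 368.0, 374.08, 146.58),
    "ethylcyclohexane": ({"CH2(cyc)": 5, "CH(cyc)": 1, "CH2": 1, "CH3": 1},
                         609.00, 30.00, 430.0, 404.95, 161.84),
    "1,1-dimethylcyclohexane": ({"CH2(cyc)": 5, "C(cyc)": 1, "CH3": 2},
                                591.00, 29.60, 416.0, 392.70, 239.66),
    "trans-decalin":  ({"CH2(cyc)": 8, "CH(cyc)": 2}, 687.10, 31.40, 480.0, 460.46, 242.79),
    "cyclopentene":   ({"CH2(cyc)": 3, "CH=CH(cyc)": 1}, 506.50, 48.00, 245.0, 317.38, 135.08),
    "cyclohexene":    ({"CH2(cyc)": 4, "CH=CH(cyc)": 1}, 560.40, 43.50, 292.0, 356.13, 169.67),
    # --- oxygenates ----------------------------------------------------
    "2-butanone":     ({"CH3CO": 1, "CH2": 1, "CH3": 1}, 535.50, 41.50, 267.0, 352.79, 186.48),
    "2-pentanone":    ({"CH3CO": 1, "CH2": 2, "CH3": 1}, 561.10, 36.90, 301.0, 375.46, 196.30),
    "3-pentanone":    ({"CH2CO": 1, "CH2": 1, "CH3": 2}, 561.50, 37.30, 336.0, 375.14, 234.18),
    "2-hexanone":     ({"CH3CO": 1, "CH2": 3, "CH3": 1}, 587.60, 33.20, None, 400.70, 217.20),
    "butanal":        ({"CHO": 1, "CH2": 2, "CH3": 1}, 537.20, 43.20, 258.0, 347.94, 176.75),
    "pentanal":       ({"CHO": 1, "CH2": 3, "CH3": 1}, 566.10, 35.50, None, 376.15, 182.00),
    "dimethyl ether": ({"CH3O": 1, "CH3": 1}, 400.10, 54.00, 170.0, 248.31, 131.66),
    "diethyl ether":  ({"CH2O": 1, "CH2": 1, "CH3": 2}, 466.70, 36.40, 280.0, 307.58, 156.85),
    "dipropyl ether": ({"CH2O": 1, "CH2": 3, "CH3": 2}, 530.60, 30.30, 382.0, 363.23, 151.00),
    "diisopropyl ether": ({"CH-O": 1, "CH": 1, "CH3": 4}, 500.05, 28.80, 386.0, 341.45, 187.65),
    "2-propanol":     ({"OH": 1, "CH": 1, "CH3": 2}, 508.30, 47.62, 220.0, 355.41, 185.28),
    "2-butanol":      ({"OH": 1, "CH": 1, "CH2": 1, "CH3": 2}, 536.05, 41.79, 269.0, 372.66, 158.45),
    "cyclohexanol":   ({"OH": 1, "CH(cyc)": 1, "CH2(cyc)": 5}, 650.10, 42.60, None, 434.00, 296.60),
    "acetic acid":    ({"COOH": 1, "CH3": 1}, 591.95, 57.86, 171.0, 391.05, 289.81),
    "propanoic acid": ({"COOH": 1, "CH2": 1, "CH3": 1}, 600.81, 46.68, 230.0, 414.32, 252.45),
    "butanoic acid":  ({"COOH": 1, "CH2": 2, "CH3": 1}, 615.70, 40.64, 290.0, 436.87, 267.95),
    "tetrahydrofuran": ({"O(cyc)": 1, "CH2(cyc)": 4}, 540.20, 51.90, 224.0, 338.00, 164.65),
    "1,4-dioxane":    ({"O(cyc)": 2, "CH2(cyc)": 4}, 587.00, 52.10, 238.0, 374.47, 284.95),
    "tetrahydropyran": ({"O(cyc)": 1, "CH2(cyc)": 5}, 572.20, 47.70, 263.0, 361.15, 224.15),
    # --- amines --------------------------------------------------------
    "isopropylamine": ({"NH2": 1, "CH": 1, "CH3": 2}, 471.80, 45.40, 221.0, 305.55, 177.95),
    "sec-butylamine": ({"NH2": 1, "CH": 1, "CH2": 1, "CH3": 2}, 514.30, 42.00, None, 335.90, 168.50),
    "cyclohexylamine": ({"NH2": 1, "CH(cyc)": 1, "CH2(cyc)": 5}, 615.00, 41.50, None, 407.65, 255.45),
    "pyrrolidine":    ({"NH(cyc)": 1, "CH2(cyc)": 4}, 568.60, 56.30, 249.0, 359.71, 215.31),
    "piperidine":     ({"NH(cyc)": 1, "CH2(cyc)": 5}, 594.00, 47.00, 289.0, 379.55, 262.65),
    "pyridine":       ({"aN": 1, "aCH": 5}, 619.95, 56.70, 254.0, 388.41, 231.51),
    "2-methylpyridine": ({"aN": 1, "aCH": 4, "aC-CH3": 1}, 621.00, 46.00, 292.0, 402.55, 206.45),
    "quinoline":      ({"aN": 1, "aCH": 6, "aCfaC": 2}, 782.15, 48.50, 371.0, 510.31, 258.37),
    # --- sulfides ------------------------------------------------------
    "dimethyl sulfide": ({"CH3S": 1, "CH3": 1}, 503.04, 55.30, 201.0, 310.48, 174.88),
    "diethyl sulfide": ({"CH2S": 1, "CH2": 1, "CH3": 2}, 557.15, 39.60, 318.0, 365.25, 169.20),
    "tetrahydrothiophene": ({"S(cyc)": 1, "CH2(cyc)": 4}, 631.95, 51.50, 249.0, 394.27, 176.98),
    "thiacyclohexane": ({"S(cyc)": 1, "CH2(cyc)": 5}, 657.10, 44.50, None, 414.90, 292.30),
}

# universal constants of the first-order correlations
TC0 = 231.239   # K
TB0 = 222.543   # K
TM0 = 147.45    # K
PC1 = 5.9827    # bar
PC2 = 0.108998  # bar**-0.5
VC0 = 7.95      # cm3/mol

_PROPS = ("Tc", "Pc", "Vc", "Tb", "Tm")


def _transform(prop: str, value: float) -> float:
    if prop == "Tc":
        return float(np.exp(value / TC0))
    if prop == "Tb":
        return float(np.exp(value / TB0))
    if prop == "Tm":
        return float(np.exp(value / TM0))
    if prop == "Pc":
        return (value - PC1) ** -0.5 - PC2
    return value - VC0  # Vc


_CONSTANTS: dict[str, dict[str, float]] | None = None


def first_order_constants() -> dict[str, dict[str, float]]:
    """Per-group contributions, re-estimated from the calibration dataset.

    For each property the group sums are linear in the transformed
    experimental value, so the whole table is one ordinary-least-squares
    solve per property.  The result is cached; it is deterministic.
    """
    global _CONSTANTS
    if _CONSTANTS is not None:
        return _CONSTANTS
    names = list(MG_GROUPS)
    out: dict[str, dict[str, float]] = {g: {} for g in names}
    for pi, prop in enumerate(_PROPS):
        rows, ys = [], []
        for vector, *vals in CALIBRATION_DATA.values():
            v = vals[pi]
            if v is None:
                continue
            rows.append([vector.get(g, 0) for g in names])
            ys.append(_transform(prop, v))
        a = np.asarray(rows, dtype=float)
        y = np.asarray(ys, dtype=float)
        # weight for relative error: the temperatures enter through a log,
        # so a uniform relative residual in the transformed sum corresponds
        # to a uniform absolute temperature error
        w = 1.0 / np.abs(y)
        covered = a.any(axis=0)
        coef = np.full(len(names), np.nan)
        sol, *_ = np.linalg.lstsq(a[:, covered] * w[:, None], y * w, rcond=None)
        coef[covered] = sol
        for g, c in zip(names, coef):
            out[g][prop] = float(c)
    _CONSTANTS = out
    return out


def mg_properties(groups: dict[str, int]) -> PropertySet:
    """First-order property estimates from a group vector."""
    if not groups or all(v == 0 for v in groups.values()):
        raise ValueError("cannot estimate properties from an empty group vector")
    consts = first_order_constants()
    sums = {}
    for prop in _PROPS:
        s = 0.0
        for g, n in groups.items():
            c = consts[g][prop]
            if np.isnan(c):
                raise ValueError(f"no {prop} contribution available for group {g}")
            s += n * c
        sums[prop] = s
    return PropertySet(
        Tc=TC0 * float(np.log(sums["Tc"])),
        Pc=PC1 + (sums["Pc"] + PC2) ** -2,
        Vc=VC0 + sums["Vc"],
        Tb=TB0 * float(np.log(sums["Tb"])),
        Tm=TM0 * float(np.log(sums["Tm"])),
    )
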