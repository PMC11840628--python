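# Methods

## The two representations and what each asserts

A molecule is stored twice.  The **MAG** edge list is the ground truth: every
bond is a row `(Ai, Aj, Info, Core, Type)`, atoms are numbered from zero,
hydrogen is implicit and recovered by valence completion (C 4, N 3, O 2,
S 2; an aromatic bond counts 1.5 toward each atom, and the half-integer left
at a three-coordinate ring-fusion atom is floored to zero, which is exactly
"one hydrogen per unsubstituted aromatic CH").  The `Info` column is
overloaded by row kind: a ring number on ring bonds, 999 on chain bonds,
900/901 for *cis*/*trans* on a double-bond row, and 1000–1004 declaring that
the atom at `Aj` is S, N, OH-oxygen, oxygen, or a carboxyl oxygen pair.  The
`Core` column holds the core number, or 998 on bonds of an inter-core
connecting chain.

The **SOLex** matrix is a projection of the MAG: 44 integer attributes per
core plus a global row (position 0).  Every attribute has an exact
accounting meaning — how many carbons it adds and which existing groups it
converts — so that three linear maps share one bookkeeping discipline:

* attribute row × stoichiometric matrix (42 × 7) → molecular formula;
* attribute row × Joback table (42 × 23) → Joback group counts;
* per-core rows + link lengths → global row (aggregation).

The stoichiometric matrix is *derived from* the Joback table (each Joback
group carries its element content and hydrogen count), so formula and group
accounting cannot drift apart.  Both are pinned by a property enforced in the
test suite: for every fixture and for large sweeps of random molecules, the
hydrogen count from the attribute row must equal the hydrogen count from
valence completion of the graph, and group-implied heavy atoms must equal
the formula's.

## Attribute semantics (the decisions that were genuinely open)

The attribute set is fixed at 44 with pinned positions (indices 0–2 aromatic
ring increments, 19–20 the chain-carbon pair `Rp`/`Rm`, 42–43 the `RCn`/`Arr`
codes).  Where the published material leaves an attribute's identity or
bookkeeping open, this package fixes it as follows:

* **Ring increments count new atoms in construction order.**  A ring
  contributes as many atoms as it has not already been counted by an
  earlier ring: 6-4-3-2 for aromatic (`A6/A4/A3/A2`), 6-5-4-3-2-1 for
  naphthenic, with naphthenic subtypes read off the saturation of the
  already-counted fused neighbours (`N4a`/`N4n`; `N3a/m/n`; `N2a/m/f/n`).
  Aromatic rings are counted before naphthenic ones; this keeps
  classification stable for reaction products (saturating ring 0 of a fused
  aromatic pair must yield `A6 + N4a`, not an aromatic increment fused on a
  naphthenic base).
* **`Rm` is the generic chain carbon (CH2): side-chain interiors, ring-methyl
  carbons and inter-core connecting carbons.  `Rp` is a terminal CH3.**
  `Ra`/`Rn` count chain *attachments* and convert one aromatic/naphthenic
  ring CH site; `MEa`/`MEn` convert a ring site and turn their `Rm` carbon
  into CH3; `br`/`br2` convert CH2 → CH/C at ternary/quaternary chain
  carbons.  This is the unique assignment that simultaneously reproduces the
  reference worked example's Joback counts (3, 1, 5, 2, 3), the three-core
  example's per-core `Rm` = 3/24/9 with global 43, and the statement that
  dealkylation redistributes chain carbons between `Rp` and `Rm` (the
  paraffin product's terminals fall in `Rp`).
* **Heteroatoms are substitutions.**  In-ring N/S/O replace a ring position
  of the increment they appear in (`ANa`, `ANn`, `NN`, `NS`, `NO`); backbone
  chain O/S replace an `Rm` position (`RO`, `RS`); `OH`, `RN` (amine), `KO`
  (ketone) decorate an interior chain carbon; `CHO`, `COOH` convert a
  terminal one.  Six attribute identities could not be read from the source
  figure and were completed from the lineage of the representation
  (`A2`, `RS`, `RO`) plus the three oxygenate substituents (`OH`, `CHO`,
  `COOH`) needed for the oxygenated-isomer examples.
* **Codes.**  `RCn`/`Arr` are kept as zero-padded strings internally and
  rendered as integers on serialisation (fixed widths make that lossless).
  The global `Arr` entry is the core count, so for a monocore molecule the
  global row equals the core row on every column except `Arr` (1 vs 0).
  At most 9 cores and 4 links per core; violations are hard errors.

Known vocabulary limits, enforced as explicit errors rather than silent
miscounts: hydroxyl/amine on a *primary* chain carbon, phenol-type ring
substituents, aromatic five-rings, spiro fusions, chain backbone nitrogen,
substituents on connecting chains.  A single-carbon paraffin (methane) is
representable in the graph but sits one hydrogen outside the linear
stoichiometry (`Rp` counts it as CH3); the reaction ledger therefore uses
graph-side hydrogen counting, which is exact.

## Group identification and the gated scan

Marrero–Gani first-order groups are assigned on the graph by rule families
(oxygen, nitrogen, sulfur, aromatic, naphthenic, chain) in a fixed order
with a consumed-atom set; inside a family the larger/more specific group
wins and remaining ties go to the lowest atom index, so assignment is
deterministic.  Compound groups (`aC-CH3`, `CH3CO`, `CH2O`, …) consume all
their heavy atoms; completeness (every heavy atom in exactly one group) is a
tested invariant.

The *gated* scan runs a family only if the molecule-level attribute gate is
non-zero (e.g. aromatic rules only when attributes 0+1+2 > 0, chain rules
only when 19+20 > 0), and then only over the rows of cores whose per-core
gate passes (plus 998 rows for the chain family).  When those rows form a
contiguous block — the conventional ordering keeps each core's rows
together — the visit count is the block span; otherwise the family falls
back to a full-row scan.  The exhaustive reference scans every row for every
family.  Equivalence of the two outputs and the visit inequality (gated ≤
exhaustive, strict whenever a gate is false) replace any wall-clock claim
with a hardware-independent, testable statement.

## Property correlations and constants

**Joback.**  Contribution constants are the published Joback & Reid table.
The 23-group adaptation maps aromatic CH to the ring `=CH-` row and *both*
condensed and substituted aromatic carbons to the ring `>C<` row; with that
mapping all five worked-example values (Tb 532.07, Tm 459.87, Tc 773.68,
Pc 32.06, Vc 608.5) reproduce to the printed precision, which pins the
mapping.

**Marrero–Gani (first order).**  The correlation forms and universal
constants (231.239, 222.543, 147.45 K; 5.9827 bar, 0.108998 bar^-0.5;
7.95 cm³/mol) are the published ones.  The per-group contributions are
*re-estimated* here rather than transcribed: for each property the group
sums are linear in the transformed experimental value (exp(T/T0) for the
temperatures, (Pc − 5.9827)^-0.5 − 0.108998, Vc − 7.95), so the table is one
weighted least-squares solve per property over the embedded calibration
dataset (~80 compounds from the standard critical-property compilations:
alkanes, olefins, alkylbenzenes, fused aromatics, naphthenics, ethers,
ketones, aldehydes, alcohols, acids, amines, sulfides).  Rows are weighted
by 1/|y| so the fit targets uniform *relative* error in the transformed sum,
i.e. uniform absolute temperature error.  Consequences to keep in mind:

* hydrocarbon estimates track the experimental constants of the calibration
  families to a few percent (anchor residuals are tested);
* they are *not* digit-for-digit reproductions of any historical printing of
  the first-order table — for the worked alkylnaphthalene example, Tb and Tc
  land within ~1 % of the reference calculation, while Vc and Tm deviate
  more strongly (the reference Vc for that compound sits ~7 % below
  experiment, and melting points are intrinsically ill-conditioned for
  additive schemes — symmetry and packing effects scatter the anchors);
* heteroatom-family constants rest on few anchors and should be treated as
  indicative.

Second- and third-order contributions are out of scope throughout.

## Reactions

Applicability is decided on the attribute row (`can_saturate`:
indices 0+1+2 > 0; `can_dealkylate`: 19+20 > 0).  Saturation flips the
target ring's own rows from Type 2 to Type 1 — including a fusion row the
ring owns — and the product's attribute matrix is re-derived from the graph,
which automatically performs the neighbour reclassification (`N4a` → `N4n`).
Dealkylation cleaves between the α- and β-chain carbons, so a methyl always
remains on the ring; exactly one edge row disappears, the two components are
renumbered order-preservingly, and one H2 is consumed (the two new C–H
bonds).  Hydrogen uptake is always computed from valence completion, never
assumed, and elemental balance across products + H2 is a tested invariant.
Sites whose β-carbon carries a substituent tag are not eligible (the
paraffin product would need a primary-substituent attribute that does not
exist).

## Isomer identity

`same_molecule` is staged: attribute gate (cheap, decides all constitutional
differences the projection can see), canonical-graph comparison
(Weisfeiler–Lehman refinement with backtracking individualisation; initial
colour = element + incident bond-type multiset; stereo codes excluded from
constitution), then stereo: *cis*/*trans* codes compared on canonically
labelled bonds, and for each quaternary carbon with four distinct canonical
substituents the bond-row order of its neighbours compared up to even
permutations (odd = opposite handedness).  This strengthens the
numbering-dependent bond-order criterion into a numbering-independent one;
the original order-sensitive behaviour is what the comparison degrades to
when the canonical labels are ignored.

## Synthetic molecules

`random_molecule` samples along the structure of the representation: number
of cores (1–3 by default), rings per core (1–3, aromatic block first, then
ortho-fusions), side chains (1–6 carbons, branch probability 0.3), internal
double bonds (probability 0.1, occasionally *cis*/*trans*-annotated),
heteroatom substitutions (probability 0.15 per opportunity: ring N/S/O,
chain OH/NH2/ketone), and connecting chains of 1–6 carbons in a hub
topology.  These defaults emulate mid-boiling petroleum-range molecules:
small fused-ring cores with short, sparsely functionalised chains.  The
generator never emits the vocabulary-limit motifs listed above, so passing
the property suite says nothing about those motifs beyond the explicit
errors they raise; it also does not emulate real mixtures' composition
statistics — it exercises representational validity, not chemistry.
Identical seed and parameters give identical molecules.

## Problem sizes and numerics

The test suite sweeps 1000 random molecules for the scan-equivalence and
consistency properties and 200 applicable molecules for reaction balance
(a few seconds in total); canonicalisation backtracks only within colour
classes, which stays negligible at these sizes (≤ ~60 atoms).  All tables
are integer; property arithmetic is double precision with no iterative
steps, so results are deterministic to the last digit; the least-squares
calibration is a single `lstsq` solve cached per process.
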