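# Methods

## The topology model

An αβ-fold with a single open (non-barrel) β-sheet is abstracted to its
β-sheet topology: the number `n` of strands, the left-to-right order in
which the sequence-numbered strands appear in the sheet, and the up/down
orientation of the strand at each sheet position.  A raw grid is a pair
(permutation of `1..n`, orientation vector); the string dialect is
`order:orient`, e.g. `1342:uddd` (arrows `↑↓` are accepted on input).
Orientation vectors are indexed by sheet *position*;
`topology.orient_by_position` converts per-strand input.

Two raw grids describe the same physical object when related by one of the
three 180° rigid rotations of the sheet: about the in-plane strand axis
(positions reversed, orientations kept), about the in-plane position axis
(positions kept, orientations flipped), and about the sheet normal (both).
Mirror reflections are *not* identified — connection handedness makes folds
chiral.  Each orbit has exactly four members (no permutation of distinct
labels equals its own reversal), so there are `n!·2^(n-2)` distinct
topologies.  The canonical representative is the lexicographically smallest
image (order vector compared first, then orientations with `u < d`); direct
enumeration keeps the smaller member of each `(order, reversed-order)` pair
and orientation vectors starting with `u`, which yields the canonical set
without deduplication.  The choice of representative is a labelling
convention only: all counts and verdicts are orbit properties.

## Connections and the rule engine

The chain link between sequence-consecutive strands `i` and `i+1` of the
sheet (a β-X-β motif; X may be a loop or contain helices) is a *connection*
with kind (`para` if the strands point the same way, else `anti`), jump
distance (number of sheet positions strictly between the strands), span,
face and ending side.  A topology is *frustration-free* when none of three
rules is violated, and frustrated otherwise; violations are unioned, never
cancelled.

**Jump-distance rule.**  Parallel connections must have jump < 4 and
antiparallel connections jump < 2.  Exception: the antiparallel jump-2
connection of a Greek-key window.  A window is the four consecutive sheet
positions spanned by the connection; its strands are relabelled by sequence
rank and compared, up to sheet rotation, with the Greek-key arrangement and
its chain circular permutations (the permutant set is generated at import
by restarting the Greek-key chain at each strand).  For `n > 4` the window
test is purely local; the relabelled strands need not be consecutive in the
full chain.

**Geometry board.**  Rule evaluation uses a flat board: x = sheet position,
y ∈ [0,1] from bottom to top strand ends, plus a front/back face label.

* A parallel connection leaves the C-end of its first strand and enters the
  N-end of its second strand — opposite sheet edges — crossing one face as
  a diagonal.  The face realizes the right-handed crossover preference:
  `front` iff `travel_direction × orientation > 0`.  The global sign of
  this convention is arbitrary (verdicts only ever compare faces), which is
  verified by a global-flip test.
* An antiparallel connection with jump ≥ 1 bends around the sheet edge
  shared by its two strand ends (top if its first strand points up),
  arcing over the ends of the intervening strands.  The bend is labelled
  with a face by the same right-handed convention, but the overlap rule
  treats it as occupying the whole edge strip over its span, on both sides
  of the sheet plane.
* An antiparallel jump-0 connection is an edge hairpin: no face, inert.

**Connection-overlap rule.**  Two connections on the same region of the
same face (S-type) are disfavored.  On the board this is three collision
tests:

1. two parallel crossovers on the same face collide when their spans
   overlap with positive interior length, *except* when the spans have
   equal length and the same travel direction — then the two diagonals are
   geometrically parallel and stack side by side without touching.  This
   carve-out is exactly the geometry of the knot-forming all-parallel
   `3142` fold, whose two front-face crossovers run parallel;
2. an edge bend collides with any crossover that terminates at the bend's
   edge strictly inside the bend's span (the crossover must rise through
   the strip the bend occupies);
3. two bends around the same edge collide when their spans overlap with
   positive interior length.

Hairpins never collide; exempt Greek-key bends still participate (the
`1342:uddd` worked case shows an antiparallel jump-2 bend producing overlap
violations).

**Connection-ending rule.**  For two *parallel* connections whose second
strands (the later strand of each motif) occupy adjacent sheet positions
with equal orientations, arriving from different faces (D-type) is a
violation.  The ending side of a parallel connection equals its crossover
face read at the entry end, so with equal orientations D-type is equivalent
to opposite travel directions.  The rule is restricted to pairs that do
*not* share a strand: for chain-consecutive motifs the two helix faces are
already forced by crossover handedness and connectivity, so no free
preference exists.  This restriction is not optional — the consecutive pair
of `1342:uddd` is a proper rotation image of the order-132 all-parallel
three-strand pair, so any rotation-invariant rule must give both the same
verdict, and both are reference-clean.

**Calibration.**  Where the prose description of the rules leaves the face
and collision conventions underdetermined, they were fixed — once — by
requiring the engine to reproduce, simultaneously, the exact reference
anchors: 43 frustration-free / 53 frustrated of the 96 four-stranded
topologies, 10 frustration-free of the 12 three-stranded ones, the meander
and the knot-forming `3142:uuuu` clean, the Greek key and its circular
permutants clean, and `1342:uddd` violating jump + overlap but not ending.
Within the discrete family of conventions examined (face-dependent vs
edge-strip bend collisions, crossing vs span-overlap crossover collisions,
ending-rule pair restrictions), the convention set described above is the
only member satisfying all anchors at once.

## Symmetry and invariance guarantees

Every face/edge attribute is equivariant under the rotation group, so all
four images of a topology classify identically; the test suite checks this
exhaustively for n ≤ 4 and on seeded samples for n = 5–6, checks
free + frustrated = `n!·2^(n-2)`, and checks the orbit count against a
brute-force grouping of all `n!·2^n` raw grids.

## Observation frequency

For one Homology group (superfamily level) the occupation ratio of a
topology is the mean over its Family groups of the fraction of family
domains carrying the topology; the observation frequency is the sum of
occupation ratios over Homology groups.  Topology strings are
canonicalized on ingest so symmetry images aggregate.  A topology is
*unobserved* when its frequency is strictly below the threshold, kept as
the exact rational 1/4 to avoid float-boundary surprises.  Predicted novel
folds are the frustration-free, unobserved topologies.

The exchange format allows one row per (domain, qualifying sheet), so a
domain with several sheets contributes each topology once; exact duplicate
(domain, topology) rows are rejected.  The synthetic table generator
realizes requested family fractions exactly (a family with fraction p gets
`denominator(p)` domains, `numerator(p)` of them matching) and emulates
only the hierarchy arithmetic — not real curation: no barrel or multi-sheet
reassignments, no sequence-identity filtering, no uneven family sizes.
Tests passing on these tables validate the statistic, not any claim about
real domain databases.

## Coordinate extraction

Sheets qualify under four criteria: strands longer than two residues, at
least three strands, neighboring strands supported by at least two
main-chain hydrogen bonds, and no strand of another qualifying sheet
inserted between a sheet's sequence-consecutive strands.  Branched pairing
(degree ≥ 3) and cycles (barrels) are discarded; when two candidate sheets
interleave, both fail criterion 4 (the criterion is applied in a single
pass over candidates, not iterated to a fixpoint).  Sheets spanning chains
are not assembled.

Hydrogen bonds use a geometric stand-in for a secondary-structure program:
N···O ≤ 3.5 Å and C–O···N angle ≥ 90°, no explicit hydrogens.  For Cα-only
models (including the mock fixtures) pairing falls back to counting Cα–Cα
contacts ≤ 5.5 Å, with the same ≥ 2 support threshold.  Strand ranges are
preferably supplied externally (TSV `chain/start/end`, e.g. from DSSP or
STRIDE output); the built-in ladder detector (runs of ≥ 3 residues holding
long-range backbone hydrogen bonds) is a convenience, not a DSSP
reimplementation, and marginal ladders may differ.  Orientations are
propagated along the sheet path from pairwise para/anti labels (sign of the
direction-vector dot product); because only simple paths survive assembly,
propagation cannot conflict.  The extracted topology is canonicalized, so
path direction and residue numbering offsets are immaterial.

## Blueprints and mock geometry

Blueprint defaults: strand length 5 (allowed 4–7), helix length 13
(allowed 11–17); out-of-range overrides warn but proceed.  Loop ABEGO
patterns per connection unit, default first: para-αβ
GB | GBA | BAAB | GABA | BA; para-βα AB; anti-αβ GBB; anti-βα
BAB | GBB | AAAB; ββ hairpin BAAGB (right chirality, default) or GG (left);
α-turn connector GBB.  A parallel connection expands to loop–helix–loop, an
antiparallel bend to loop–helix–loop or, with `alpha_turns`, to a
helix–loop–helix α-turn; optional terminal helices attach with the
parallel-type αβ/βα loops.  Loop length equals pattern length.  Strand
register shifts and pleat assignment are not modelled (strands sit at zero
register), and no backbone fragment assembly, relaxation or sequence design
is performed — the blueprint is the hand-off artifact.

Mock coordinates place strands as straight Cα traces (spacing 4.8 Å, rise
3.4 Å).  Parallel crossover connectors are routed on whichever face makes
the strand–connector–strand path a right-handed screw, decided by a
circulation functional over the candidate 3-D polylines — an independent
derivation that the analytic face formula must match (tested over all n ≤ 4
connections).  Antiparallel bends arc beyond the shared edge (clearance
4 Å, lift 2.5 Å); hairpins stay in-plane.  The mocks are idealized fixtures:
no twist, no register shifts, no side chains, and connector pseudo-residues
are not physical loop conformations.

## Known limitations

* The overlap/ending conventions are calibrated at n = 3–4.  At n ≥ 5 the
  span-overlap collision test grows combinatorially aggressive, and the
  frustration-free totals (160, 398, 1125, 3087 for n = 5–8) are
  convention-sensitive and uncalibrated; they conserve totals but should
  not be read as reference reproductions.  `classify_all` reports them;
  nothing asserts them.
* Real domain-database ingestion (an adapter producing the domain TSV from
  an ECOD-style listing) is intentionally out of scope; observed/unobserved
  splits on real data additionally depend on database snapshot and manual
  curation.
* β-bulges, barrels, branched and multi-sheet folds are outside the model.
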