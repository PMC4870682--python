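# Methods

This note records the model, the numerical choices and the limits of what
the package's tests demonstrate.

## Topological model

A molecule is a rooted unordered tree of coarse-grained units. The root is
the core molecule with functionality BR ≥ 2; all other core units are AB2
monomers (one A-group bonds the parent, two B-groups may bond children).
Classification counts dendritic (two core children), linear (one) and
terminal (none) units over non-root core units only: the root is a distinct
chemical species and arms never re-classify the unit they attach to, so DB
is a core-only property. DB uses the Hölter–Frey form DB = 2D/(2D+L) by
default (with DB ≡ 0 when D = L = 0) because it assigns exactly 0 to a
finite linear chain and exactly 1 to a perfect dendrimer — the two boundary
cases the builder must reproduce verbatim. The Fréchet form
(D+T)/(D+L+T), which scores a finite chain at 2/(n−1) > 0, is available as
`degree_of_branching("frechet")` for comparison with that literature.

The Wiener index is computed by one subtree-size pass: for each bond the
product of component sizes on its two sides, summed over bonds. For trees
this equals the all-pairs bond-distance sum, which the tests verify
independently with networkx BFS on random trees. By default WI covers the
whole molecule (core + arms) with a `core_only` option.

Isomorphism-based deduplication uses AHU canonical codes (sorted child
codes in brackets). The code captures pure shape and ignores unit roles:
at the CG level all non-root beads are interchangeable, so two ensembles
differing only in which bead was labeled first are the same structure. The
tests check code equality against a brute-force permutation-matching
isomorphism oracle exhaustively for all rooted trees up to 7 nodes
(class counts 1, 1, 2, 4, 9, 20, 48).

## Chain-length statistics

Schulz-Zimm number density f(δ) ∝ δ^(u−1) e^(−uδ) with δ = DP/ADP and
u = 1/(PDI−1); Poisson number fraction e^(−λ) λ^(DP−1)/(DP−1)! with
λ = ADP−1, whose PDI is structurally 1 + (ADP−1)/ADP² (a supplied PDI is
ignored with a warning). The continuous Schulz-Zimm density is evaluated
on the integer grid [dp_min, dp_max] and renormalized rather than
integrated per bin — simpler, and its moments converge to the analytic
(u+1)/u as the grid widens (verified within 2% at ADP = 100,
dp_max = 20·ADP). Defaults: dp_min = 3 for cores (the smallest legal core)
and 1 for arms; dp_max = 20·ADP, far enough out that truncation error is
negligible at the PDIs of interest (≤ 2.5). Molecule counts per DP use
largest-remainder rounding with ties to the smaller DP, so an allocation
is deterministic and sums exactly to RNP. During ensemble generation the
effective dp_min is raised to BR+1 when necessary, since a core smaller
than root-plus-BR-children cannot exist.

## Growth rule and its statistics

Each frontier unit receives two judged attachment chances per attempt.
The judgment keeps the integer-truncation form randb = int(1/db)
(db ≤ 0.5; accept a chance iff draw mod randb == 0, probability 1/randb)
and randb = int(1/(1−db)) (db > 0.5; accept iff draw mod randb != 0,
probability 1 − 1/randb). Draws come from a seeded 64-bit generator on
[0, 2^62) so the modulus introduces no low-bit bias. A unit whose two
chances both fail is re-tried until it adds at least one child (cap: 100
double-attempts, then one child is force-added), which guarantees
termination; growth stops exactly at the target DP, with the first judged
slot taking the last unit of budget.

A short calculation explains why this targets DB: with per-chance
acceptance p and retry-until-success, a processed unit is dendritic with
probability p/(2−p) and linear otherwise, giving an expected Hölter DB of
exactly p. So db targets that are reciprocals of integers are hit in the
mean directly; other targets (e.g. 0.4, where int(1/0.4) = 2 gives
p = 0.5) rely on the accept/reject step — a structure is kept only if its
realized DB is within the tolerance (default 0.05) of the target — which
is also what pins the realized-DB *mean* near the target in all cases.
The boundary targets are special-cased, since the truncation rule divides
by zero there: db = 0 adds exactly one child per unit (the unique linear
chain) and db = 1 always adds two (a dendrimer; infeasible parities, such
as BR = 2 with even DP, surface as attempt exhaustion with an explicit
error naming the (DP, DB) pair).

## Arms

Eligible sites are the free B-groups: one per linear unit, BRT per
terminal unit (BRT ≤ 2 in AB2 chemistry); dendritic units and the root
have none. The arm count is round-half-up of GRA × (number of sites); the
alternative per-unit reading of the graft ratio is a config switch
(`per_unit`), relevant only at BRT = 2. Sites are drawn uniformly without
replacement; arm lengths from their own distribution with dp_min = 1, so
zero-length arms cannot occur. Grafting provably preserves the core's
D/L/T counts, DB and DP.

## Embedding and packing

CG geometry is a starting configuration, not an equilibrated one. Beads
are placed breadth-first at exactly one bond length (default 1.0 reduced
units) from their parent in a random direction; candidates closer than
0.8 bond lengths to any placed bead are rejected up to 50 times, then the
best candidate seen is kept (best-effort excluded volume — the tests
require ≥ 95% of non-bonded pairs beyond 0.8). The box is cubic with
volume (polymer beads + solvent beads)/number-density (default 0.1);
molecules are assigned to shuffled grid cells with uniform random
rotations and ±25% cell jitter, re-drawn until no inter-molecular pair is
closer than the cutoff (default 0.8), and solvent is inserted uniformly
under the same criterion. Packing is internal by design — no external
packer is invoked — because a jittered grid is sufficient for valid
starting configurations and keeps the tool dependency-free. All
coordinates are wrapped to [0, L).

## File formats

HOOMD XML is pinned to the v1 dialect (configuration/box/position/type/
bond, 0-based indices). CG GROMACS files use one bead per "atom", one
molecule per residue, names ROOT/DEN/LIN/TER/ARM/SOL; the itp bond
parameters b0/k are explicit placeholder config values, not fitted
constants; the .top lists species (distinct canonical topologies) in gro
order. The run report is a TSV of molecule_id, DP, D, L, T, DB, WI,
canonical code and arm count, so users can select structures (e.g. by WI)
for further work. A JSON dump of parent arrays and roles makes a CG run
reloadable for later back-mapping.

## Back-mapping

Templates are mol2 fragments with declared attachments
(slot, heavy atom, deletable hydrogen); slot 0 of every non-root template
is its parent hook, and remaining slots are consumed in declared order by
core children, then arms. Linear-unit templates may declare a second child
slot so that arms grafted onto linear units have somewhere to bond; a
template with fewer slots than a node needs is a hard error. Inequivalent
connection ways (A2_1/A2_2 linear variants, A11_1/A11_2 one-arm
terminals) are chosen uniformly at random per substitution, with optional
per-variant weights in the map file; choices are recorded per CG node in
the output structure's provenance.

Attachment geometry: both named hydrogens are deleted, and the fragment is
rigidly rotated so its attach vector anti-aligns with the host's vacated
H-direction, its heavy atom placed at the element-pair bond length
(C–C 1.54 Å, C–O 1.43 Å, C–N 1.47 Å, otherwise 1.50 Å). This placement is
a geometric convention; the subsequent relaxation is what produces
reasonable conformations. Deleted atoms are masked, not removed, during
assembly so bond indices stay stable; the final structure is compacted.

Relaxation is steepest descent with a backtracking step on a generic
geometric objective: harmonic bonds (r0 from the template or the table,
k = 300), harmonic angles (θ0 = 109.47°, k = 40), and a soft-core
quadratic repulsion (k = 50, range 2.5 Å) between atoms three or more
bonds apart. Units are arbitrary; the objective's job is to remove clashes
and restore bonded geometry, not to model a force field — full atom-type
perception and OPLS-style energetics are out of scope, and templates carry
their own atom-type labels into the outputs. Energy is non-increasing by
construction; iteration stops at a force tolerance or an iteration cap.
The exact bookkeeping identities — atoms = Σ template atoms − 2·(CG
bonds), bonds = Σ template bonds − (CG bonds), and CG-tree isomorphism of
the provenance-contracted molecular graph — are asserted in tests.

Tinker xyz output carries integer type codes from a label→code table
(auto-enumerated when not supplied) and full connectivity; GROMACS output
converts Å to nm and enumerates bonds and angles.

## Bundled fixtures

The toy template set (methane-like core, propane-like AB2 unit,
ethanol-like arm unit) is synthetic: hand-placed approximate geometries
whose only job is to exercise parsing, assembly, bookkeeping and
relaxation without any download. The propane skeleton serves every core
role via different attachment declarations, which is exactly how the map
file is meant to express variant chemistry. Passing tests on these
fixtures demonstrate assembly correctness, not chemical realism of any
specific polymer.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: ensembles of
5–100 molecules at DP 22–60, 10^5-draw distribution checks, exhaustive
isomorphism up to 7 nodes, back-mapping of ≲ 20-bead molecules. All
stochastic code takes a numpy Generator or an integer seed; a fixed seed
reproduces ensembles, coordinates and output files bit-for-bit.

## Known limitations

- The growth rule's raw DB distribution is centered at 1/int(1/db) (or
  its mirror), so targets far from reciprocals of integers (e.g. 0.45)
  reject more structures; the attempt cap and per-structure attempt log
  make pathological (DP, DB) pairs diagnosable.
- `unique_only` regenerates on collision; for small DP the number of
  distinct topologies is finite and an over-large RNP will exhaust
  attempts.
- The packer checks minimum distances against wrapped coordinates without
  periodic images; at the default low densities this is inconsequential
  for starting configurations.
- Relaxation is local and generic: it will not find good conformers, and
  assembled structures should be equilibrated by the target MD engine.
- Solvent is added as free beads at the box density; there is no
  solvation-shell logic.
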