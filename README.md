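# hyperbranch

Builder for **hyperbranched polymers (HBPs)** and **hyperbranched multi-arm
copolymers (HBMCs)** for molecular simulation. Unlike dendrimers, HBPs are
mixtures: molecules of the same degree of polymerization (DP) and degree of
branching (DB) still differ in topology, and a realistic simulation box needs
a polydisperse ensemble of them. `hyperbranch` generates such ensembles as
coarse-grained (CG) bead trees, characterizes and deduplicates them, packs
them into a periodic box, and back-maps selected structures to fully
atomistic models assembled from mol2 repeat-unit templates. Output goes
straight to HOOMD (XML), GROMACS (gro/itp/top) and Tinker (xyz).

Intended users: polymer simulators who need starting configurations of
HBPs/HBMCs with controlled DP, DB, polydispersity (PDI), graft ratio and arm
length — for DPD/CG work or all-atom MD.

## The model

A molecule is a rooted unordered tree. The central core unit has
functionality *BR*; every other core unit is an AB2 monomer (one parent
link, up to two child links). Counting dendritic (*D*, two core children),
linear (*L*, one) and terminal (*T*, none) units — root excluded — the
degree of branching is

    DB = 2D / (2D + L)        (Hölter–Frey; DB = 0 linear chain, DB = 1 dendrimer)

Topologies with equal DP and DB are distinguished by the **Wiener index**

    WI = Σ_s  V_L,s · V_R,s

summed over bonds *s*, where V_L,s and V_R,s are the unit counts on the two
sides of bond *s*; for a tree this equals the sum of all pairwise
bond-count distances. Low WI means a compact, dendrimer-like shape; high WI
a periphery-branched, star-like one.

Chain lengths are drawn from **Schulz-Zimm** (number density
f(δ) ∝ δ^(u−1) e^(−uδ), δ = DP/ADP, u = 1/(PDI−1), so PDI = (u+1)/u) or
**Poisson** (PDI fixed at 1 + (ADP−1)/ADP²) statistics, or held
monodisperse.

Growth targets DB with a stochastic rule: every frontier unit gets two
judged attachment chances, each accepted with probability 1/randb (targets
≤ 0.5, randb = int(1/db)) or 1 − 1/randb (targets > 0.5,
randb = int(1/(1−db))); a unit that adds nothing is re-tried. Grown
structures are accepted only if |DB − target| ≤ tolerance, and optionally
only if their AHU canonical code (rooted-tree isomorphism invariant) is new.

Arms are linear bead paths grafted at the free B-groups: one site per
linear unit, *BRT* per terminal unit; the graft ratio *GRA* is the fraction
of sites carrying an arm, and arm lengths follow their own distribution
(*ADPA*, *PDI_arm*).

Back-mapping replaces CG beads with all-atom mol2 fragments generation by
generation: the two attachment hydrogens of each new bond are deleted, the
fragment is rigidly placed along the vacated H-direction at a tabulated
bond length, and the partial structure is relaxed by steepest descent on a
generic geometric objective after each generation.

## Worked example

```sh
hyperbranch cg --adp 40 --rnp 5 --br 3 --db 0.4 --tolerance 0.05 \
    --mode monodisperse --unique --seed 7 --out run_cg
```

prints

```
wrote 5 molecules to run_cg
```

and `run_cg/report.tsv` contains one row per structure (the canonical-code
column is elided here):

```
molecule_id  DP  D  L   T   DB        WI    arm_units
0            40  7  22  10  0.388889  5424  0
1            40  7  22  10  0.388889  5518  0
2            40  8  20  11  0.444444  6067  0
3            40  8  20  11  0.444444  4829  0
4            40  7  22  10  0.388889  5902  0
```

Five 40-unit cores, pairwise non-isomorphic (rows 0, 1 and 4 share D/L/T
counts but have distinct canonical codes), each with DB = 2D/(2D+L) inside
the [0.35, 0.45] accept window. The WI column ranks them from compact to
star-like, so users can pick specific topologies for further study. The
same command with `--gra 0.5 --adpa 4` grafts monodisperse 4-bead arms on
half of the eligible sites, turning the HBPs into HBMCs.

Back-map structure 1 with the bundled toy templates:

```sh
hyperbranch fixtures --out templates
hyperbranch aa --cg-dir run_cg --map templates/units.map --select 1 1 --out run_aa
```

which writes `run_aa/structure_1.xyz` (Tinker format, 356 atoms with
connectivity for this structure and template set) and
`structure_1.gro`/`.itp` (GROMACS). The toy templates are synthetic
methane-/propane-/ethanol-like fragments; real chemistries drop in through
the same map-file format (`role variant path slot:heavy:H ...`, 1-based
mol2 atom indices).

## Parameter glossary (CLI flags)

| Flag | Meaning |
|---|---|
| `--adp` / `--mode` / `--pdi` | average core DP (≥ 3), distribution mode, PDI |
| `--rnp` | number of molecules to generate |
| `--br` | root-unit functionality (≥ 2; 2 ⇒ linear backbone seed) |
| `--db`, `--tolerance` | target degree of branching and accept window |
| `--unique` | discard isomorphic repeats (canonical-code dedup) |
| `--gra`, `--brt` | graft ratio; linking positions per terminal unit |
| `--adpa`, `--arm-mode`, `--pdi-arm` | arm length distribution |
| `--density`, `--solvent` | box bead density; solvent bead count |
| `--select N1 N2` (aa) | 1-based inclusive serial range to back-map |
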