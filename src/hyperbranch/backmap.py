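"""CG -> all-atom back-mapping by generation-wise template substitution.

Each CG bead is replaced by a mol2 repeat-unit fragment: generation 0 (the
core root) first, then each subsequent generation, then the arm beads.  A
new inter-unit bond consumes one attachment on each side — the two declared
hydrogens are deleted and the fragment is rigidly rotated/translated so its
attachment vector anti-aligns with the host's vacated H-direction at a
tabulated element-pair bond length.  After every generation the partial
structure is relaxed by steepest descent on a generic geometric objective
(harmonic bonds, harmonic tetrahedral angles, soft-core repulsion between
atoms three or more bonds apart).  Atom bookkeeping is exact:
atoms = Σ template atoms − 2·(CG bonds), bonds = Σ template bonds − 2·(CG
bonds) + (CG bonds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MapFileError, StructureError, TemplateError
from .mol2 import MapFile, RepeatUnitTemplate
from .topology import CGTopology

__all__ = [
    "AtomisticStructure",
    "BOND_LENGTHS",
    "assign_roles",
    "attach_fragment",
    "relax",
    "backmap",
    "write_tinker_xyz",
    "write_aa_gro_itp",
]

#: element-pair bond lengths in Angstrom for new inter-unit bonds
BOND_LENGTHS = {
    ("C", "C"): 1.54,
    ("C", "O"): 1.43,
    ("C", "N"): 1.47,
}
FALLBACK_BOND_LENGTH = 1.50


def bond_length_for(el_a: str, el_b: str) -> float:
    return BOND_LENGTHS.get((el_a, el_b), BOND_LENGTHS.get((el_b, el_a), FALLBACK_BOND_LENGTH))


class AtomisticStructure:
    """Growable all-atom structure with lazy deletion.

    Atoms live in parallel arrays; deleted hydrogens are masked rather than
    removed so bond indices stay stable during assembly, and :meth:`compact`
    produces the final dense structure.  ``unit_of_atom`` records which CG
    node each atom came from.
    """

    def __init__(self) -> None:
        self.elements: list[str] = []
        self.names: list[str] = []
        self.type_labels: list[str] = []
        self.charges: list[float] = []
        self.coords = np.empty((0, 3))
        self.alive: list[bool] = []
        self.unit_of_atom: list[int] = []
        self.bonds: list[tuple[int, int]] = []
        self.bond_r0: list[float] = []
        self.variant_of_unit: dict[int, str] = {}
        self.energy: float = float("nan")

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return sum(self.alive)

    @property
    def n_bonds(self) -> int:
        return sum(1 for i, j in self.bonds if self.alive[i] and self.alive[j])

    def live_bonds(self) -> list[tuple[int, int, float]]:
        return [
            (i, j, r0)
            for (i, j), r0 in zip(self.bonds, self.bond_r0)
            if self.alive[i] and self.alive[j]
        ]

    def add_fragment(self, template: RepeatUnitTemplate, cg_node: int,
                     coords: np.ndarray | None = None) -> int:
        """Append a template's atoms/bonds; returns the atom index offset."""
        mol = template.molecule
        offset = len(self.elements)
        xyz = mol.coordinates() if coords is None else coords
        for a, pos in zip(mol.atoms, xyz):
            self.elements.append(a.element)
            self.names.append(a.name)
            self.type_labels.append(a.type_label)
            self.charges.append(a.charge)
            self.alive.append(True)
            self.unit_of_atom.append(cg_node)
        self.coords = np.vstack([self.coords, xyz])
        for i, j, _ in mol.bonds:
            self.bonds.append((offset + i, offset + j))
            self.bond_r0.append(float(np.linalg.norm(xyz[i] - xyz[j])))
        return offset

    def delete_atom(self, idx: int) -> None:
        if not self.alive[idx]:
            raise StructureError(f"atom {idx} already deleted")
        self.alive[idx] = False

    def compact(self) -> "AtomisticStructure":
        """Dense copy with deleted atoms removed and bonds re-indexed."""
        new = AtomisticStructure()
        remap: dict[int, int] = {}
        for i, ok in enumerate(self.alive):
            if not ok:
                continue
            remap[i] = len(new.elements)
            new.elements.append(self.elements[i])
            new.names.append(self.names[i])
            new.type_labels.append(self.type_labels[i])
            new.charges.append(self.charges[i])
            new.alive.append(True)
            new.unit_of_atom.append(self.unit_of_atom[i])
        new.coords = self.coords[np.array(self.alive, dtype=bool)].copy()
        for (i, j), r0 in zip(self.bonds, self.bond_r0):
            if self.alive[i] and self.alive[j]:
                new.bonds.append((remap[i], remap[j]))
                new.bond_r0.append(r0)
        new.variant_of_unit = dict(self.variant_of_unit)
        new.energy = self.energy
        return new

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in self.elements]
        for i, j in self.bonds:
            if self.alive[i] and self.alive[j]:
                adj[i].add(j)
                adj[j].add(i)
        return adj


# ---------------------------------------------------------------------------
# role assignment

#: abstract role -> acceptable map-file role names, in preference order
ROLE_VARIANTS = {
    "root": ["A3_0"],
    "dendritic": ["A3_1"],
    "linear": ["A2_1", "A2_2"],
    "terminal0": ["A1"],
    "terminal1": ["A11_1", "A11_2"],
    "terminal2": ["A12"],
    "arm": ["L1"],
}


def assign_roles(topo: CGTopology) -> dict[int, str]:
    """Abstract template role per CG node.

    root -> A3_0; dendritic -> A3_1; linear -> A2 variants; terminal with
    0/1/2 arms -> A1 / A11 variants / A12; arm beads -> L1.  Terminals with
    more than two arms are unsupported in AB2 chemistry.
    """
    topo.classify()
    roles: dict[int, str] = {}
    for n in topo.nodes:
        if n.role == "arm":
            roles[n.id] = "arm"
        elif n.role == "root":
            roles[n.id] = "root"
        elif n.role == "dendritic":
            roles[n.id] = "dendritic"
        elif n.role == "linear":
            roles[n.id] = "linear"
        elif n.role == "terminal":
            n_arms = topo.arms_at(n.id)
            if n_arms > 2:
                raise TemplateError(
                    f"terminal unit {n.id} carries {n_arms} arms; at most 2 supported"
                )
            roles[n.id] = f"terminal{n_arms}"
        else:
            raise StructureError(f"node {n.id} has unclassified role {n.role!r}")
    return roles


# ---------------------------------------------------------------------------
# geometric attachment


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u onto unit vector v (Rodrigues)."""
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180 degrees about any axis perpendicular to u
        axis = np.cross(u, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(u, np.array([0.0, 1.0, 0.0]))
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    k = axis / s
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + s * kx + (1 - c) * (kx @ kx)


def attach_fragment(
    struct: AtomisticStructure,
    host_heavy: int,
    host_hydrogen: int,
    template: RepeatUnitTemplate,
    frag_heavy: int,
    frag_hydrogen: int,
    cg_node: int,
) -> int:
    """Bond a template fragment onto the growing structure.

    Deletes the host's and the fragment's attachment hydrogens, places the
    fragment so its heavy attach atom sits along the host's vacated
    H-direction at the element-pair bond length with the fragment's attach
    vector anti-aligned, and adds the new bond.  Returns the fragment's
    atom-index offset.
    """
    if not (struct.alive[host_heavy] and struct.alive[host_hydrogen]):
        raise TemplateError("host attachment atoms are deleted (slot already consumed?)")
    if struct.elements[host_hydrogen] != "H":
        raise TemplateError(f"host atom {host_hydrogen} is not a hydrogen")
    mol = template.molecule
    h_atom = mol.atoms[frag_hydrogen]
    if h_atom.element != "H":
        raise TemplateError(f"fragment atom {frag_hydrogen + 1} is not a hydrogen")

    hv = struct.coords[host_hydrogen] - struct.coords[host_heavy]
    nv = np.linalg.norm(hv)
    if nv < 1e-8:
        raise TemplateError("host heavy atom and hydrogen coincide")
    hv /= nv

    frag_xyz = mol.coordinates()
    fv = frag_xyz[frag_hydrogen] - frag_xyz[frag_heavy]
    nfv = np.linalg.norm(fv)
    if nfv < 1e-8:
        raise TemplateError("fragment heavy atom and hydrogen coincide")
    fv /= nfv

    blen = bond_length_for(struct.elements[host_heavy], mol.atoms[frag_heavy].element)
    rot = _rotation_between(fv, -hv)
    target = struct.coords[host_heavy] + hv * blen
    placed = (frag_xyz - frag_xyz[frag_heavy]) @ rot.T + target

    offset = struct.add_fragment(template, cg_node, coords=placed)
    struct.delete_atom(host_hydrogen)
    struct.delete_atom(offset + frag_hydrogen)
    struct.bonds.append((host_heavy, offset + frag_heavy))
    struct.bond_r0.append(blen)
    return offset


# ---------------------------------------------------------------------------
# relaxation

ANGLE_THETA0 = np.deg2rad(109.47)
K_BOND = 300.0
K_ANGLE = 40.0
K_REP = 50.0
REP_CUTOFF = 2.5  # Angstrom; soft-core repulsion range


def _interaction_lists(struct: AtomisticStructure):
    live = [i for i, ok in enumerate(struct.alive) if ok]
    bonds = struct.live_bonds()
    adj = struct.adjacency()
    angles = []
    for j in live:
        nb = sorted(adj[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                angles.append((nb[a], j, nb[b]))
    # exclusion: pairs within 2 bonds of each other
    excl: set[tuple[int, int]] = set()
    for i in live:
        frontier = {i}
        seen = {i}
        for _ in range(2):
            frontier = {k for f in frontier for k in adj[f]} - seen
            seen |= frontier
        for j in seen:
            if j > i:
                excl.add((i, j))
    return live, bonds, angles, excl


def _energy_gradient(struct, live, bonds, angles, excl):
    x = struct.coords
    grad = np.zeros_like(x)
    energy = 0.0
    for i, j, r0 in bonds:
        d = x[i] - x[j]
        r = np.linalg.norm(d)
        if r < 1e-10:
            raise FloatingPointError(f"coincident bonded atoms {i}, {j}")
        energy += K_BOND * (r - r0) ** 2
        g = 2.0 * K_BOND * (r - r0) * d / r
        grad[i] += g
        grad[j] -= g
    for i, j, k in angles:
        a = x[i] - x[j]
        b = x[k] - x[j]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na < 1e-10 or nb < 1e-10:
            continue
        ah, bh = a / na, b / nb
        cosT = float(np.clip(np.dot(ah, bh), -1.0, 1.0))
        sinT = np.sqrt(max(1.0 - cosT * cosT, 1e-12))
        theta = np.arccos(cosT)
        dE = 2.0 * K_ANGLE * (theta - ANGLE_THETA0)
        energy += K_ANGLE * (theta - ANGLE_THETA0) ** 2
        gi = dE * (cosT * ah - bh) / (na * sinT)
        gk = dE * (cosT * bh - ah) / (nb * sinT)
        grad[i] += gi
        grad[k] += gk
        grad[j] -= gi + gk
    # soft-core repulsion: atoms >= 3 bonds apart within the cutoff
    if len(live) > 1:
        lv = np.array(live)
        from scipy.spatial import cKDTree

        tree = cKDTree(x[lv])
        for a_loc, b_loc in tree.query_pairs(REP_CUTOFF):
            i, j = int(lv[a_loc]), int(lv[b_loc])
            if (min(i, j), max(i, j)) in excl:
                continue
            d = x[i] - x[j]
            r = float(np.linalg.norm(d))
            if r < 1e-10:
                raise FloatingPointError(f"coincident atoms {i}, {j}")
            energy += K_REP * (REP_CUTOFF - r) ** 2
            g = -2.0 * K_REP * (REP_CUTOFF - r) * d / r
            grad[i] += g
            grad[j] -= g
    return energy, grad


def relax(
    struct: AtomisticStructure,
    max_iter: int = 200,
    force_tol: float = 0.5,
) -> AtomisticStructure:
    """Steepest-descent minimization; energy never increases between
    accepted iterations.  Stops when the largest force component falls
    below ``force_tol`` (objective units per Angstrom) or at ``max_iter``.
    Mutates and returns ``struct``; ``struct.energy`` holds the final value.
    """
    live, bonds, angles, excl = _interaction_lists(struct)
    live_mask = np.zeros(len(struct.alive), dtype=bool)
    live_mask[live] = True
    energy, grad = _energy_gradient(struct, live, bonds, angles, excl)
    if not np.isfinite(energy):
        raise FloatingPointError("non-finite initial energy")
    step = 1e-3
    for _ in range(max_iter):
        gmax = float(np.abs(grad[live_mask]).max()) if live else 0.0
        if gmax < force_tol:
            break
        accepted = False
        for _ in range(30):
            trial = struct.coords.copy()
            trial[live_mask] -= step * grad[live_mask]
            saved = struct.coords
            struct.coords = trial
            e_new, g_new = _energy_gradient(struct, live, bonds, angles, excl)
            if np.isfinite(e_new) and e_new <= energy:
                energy, grad = e_new, g_new
                step *= 1.2
                accepted = True
                break
            struct.coords = saved
            step *= 0.5
        if not accepted:
            break
    struct.energy = float(energy)
    return struct


# ---------------------------------------------------------------------------
# full back-mapping


def _pick_variant(variants: list[RepeatUnitTemplate], rng: np.random.Generator):
    w = np.array([v.weight for v in variants], dtype=float)
    return variants[int(rng.choice(len(variants), p=w / w.sum()))]


def backmap(
    topo: CGTopology,
    mapfile: MapFile,
    rng: np.random.Generator | None = None,
    relax_iters: int = 150,
    force_tol: float = 2.0,
    do_relax: bool = True,
) -> AtomisticStructure:
    """Replace every CG bead with an all-atom fragment, generation by
    generation, relaxing after each generation; arms are substituted after
    the core.  Variant choices among inequivalent connection ways are drawn
    from ``rng`` (weighted if the map declares weights).

    Raises :class:`MapFileError` before any work if a needed role has no
    template.
    """
    if rng is None:
        rng = np.random.default_rng()
    roles = assign_roles(topo)
    needed = sorted(set(roles.values()))
    for abstract in needed:
        if not mapfile.variants(ROLE_VARIANTS[abstract]):
            raise MapFileError(
                f"map file provides no template for role(s) "
                f"{'/'.join(ROLE_VARIANTS[abstract])} required by this topology"
            )

    struct = AtomisticStructure()
    # per-node free attachment slots as global (heavy, hydrogen) indices
    free_slots: dict[int, list[tuple[int, int]]] = {}

    def substitute(node_id: int) -> None:
        abstract = roles[node_id]
        tmpl = _pick_variant(mapfile.variants(ROLE_VARIANTS[abstract]), rng)
        parent = topo.nodes[node_id].parent
        if parent is None:
            if len(tmpl.child_slots()) < len(topo.nodes[0].children):
                raise TemplateError(
                    f"root template {tmpl.variant} has {len(tmpl.child_slots())} "
                    f"slots but the root has {len(topo.nodes[0].children)} children"
                )
            offset = struct.add_fragment(tmpl, node_id)
            slots = tmpl.child_slots()
        else:
            p_slot = tmpl.parent_slot
            if p_slot is None:
                raise TemplateError(f"template {tmpl.variant} lacks a parent slot")
            if not free_slots.get(parent):
                raise TemplateError(
                    f"CG node {parent} has no free attachment slot left for child {node_id}"
                )
            host_heavy, host_h = free_slots[parent].pop(0)
            offset = attach_fragment(
                struct, host_heavy, host_h, tmpl, p_slot.heavy, p_slot.hydrogen,
                cg_node=node_id,
            )
            slots = tmpl.child_slots()
        struct.variant_of_unit[node_id] = tmpl.variant
        n_children = len(topo.nodes[node_id].children)
        if len(slots) < n_children:
            raise TemplateError(
                f"template {tmpl.role}/{tmpl.variant} has {len(slots)} child slots "
                f"but CG node {node_id} has {n_children} children"
            )
        free_slots[node_id] = [
            (offset + s.heavy, offset + s.hydrogen) for s in slots
        ]

    core_nodes = [n for n in topo.nodes if not n.is_arm]
    arm_nodes = [n for n in topo.nodes if n.is_arm]
    max_gen_core = max(n.generation for n in core_nodes)
    for g in range(0, max_gen_core + 1):
        layer = [n.id for n in core_nodes if n.generation == g]
        if not layer:
            continue
        for nid in layer:
            substitute(nid)
        if do_relax:
            relax(struct, max_iter=relax_iters, force_tol=force_tol)
    if arm_nodes:
        for n in sorted(arm_nodes, key=lambda n: (n.generation, n.id)):
            substitute(n.id)
        if do_relax:
            relax(struct, max_iter=relax_iters, force_tol=force_tol)
    return struct.compact()


# ---------------------------------------------------------------------------
# all-atom writers


def write_tinker_xyz(struct: AtomisticStructure, path, type_codes: dict | None = None):
    """Tinker xyz: count header, then per atom index, name, coordinates
    (Angstrom), numeric type code and bonded neighbor indices (1-based).

    ``type_codes`` maps template type labels to integer codes; labels absent
    from an explicit mapping raise an error, while the default mapping
    enumerates the distinct labels in first-use order starting at 1.
    """
    from pathlib import Path as _P

    path = _P(path)
    if any(not a for a in struct.alive):
        struct = struct.compact()
    if type_codes is None:
        type_codes = {}
        for lab in struct.type_labels:
            type_codes.setdefault(lab, len(type_codes) + 1)
    missing = sorted({lab for lab in struct.type_labels if lab not in type_codes})
    if missing:
        raise TemplateError(f"no Tinker type code for label(s): {', '.join(missing)}")
    adj: dict[int, list[int]] = {i: [] for i in range(len(struct.elements))}
    for i, j in struct.bonds:
        adj[i].append(j)
        adj[j].append(i)
    lines = [f"{len(struct.elements):6d}  generated structure"]
    for i in range(len(struct.elements)):
        nb = " ".join(f"{k + 1:6d}" for k in sorted(adj[i]))
        x, y, z = struct.coords[i]
        lines.append(
            f"{i + 1:6d}  {struct.names[i]:<4s}{x:12.6f}{y:12.6f}{z:12.6f}"
            f"{type_codes[struct.type_labels[i]]:6d} {nb}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_aa_gro_itp(struct: AtomisticStructure, path_prefix, molecule_name: str = "HBPAA"):
    """GROMACS all-atom files: .gro (nm) and .itp with atoms/bonds/angles."""
    from pathlib import Path as _P

    prefix = _P(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if any(not a for a in struct.alive):
        struct = struct.compact()
    n = len(struct.elements)
    lines = ["back-mapped all-atom structure", str(n)]
    for i in range(n):
        x, y, z = struct.coords[i] / 10.0  # Angstrom -> nm
        lines.append(
            f"{1:5d}{molecule_name[:5]:<5s}{struct.names[i][:5]:>5s}{(i + 1) % 100000:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    span = struct.coords.max(axis=0) - struct.coords.min(axis=0) + 20.0
    lines.append("".join(f"{v / 10.0:10.5f}" for v in span))
    gro = prefix.with_suffix(".gro")
    gro.write_text("\n".join(lines) + "\n")

    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j in struct.bonds:
        adj[i].add(j)
        adj[j].add(i)
    itp = [
        "[ moleculetype ]",
        f"{molecule_name}  3",
        "",
        "[ atoms ]",
        ";  nr  type  resnr  residue  atom  cgnr  charge",
    ]
    for i in range(n):
        itp.append(
            f"{i + 1:5d}  {struct.type_labels[i]:<8s}  1  {molecule_name[:5]}  "
            f"{struct.names[i]:<5s}  {i + 1:5d}  {struct.charges[i]:8.4f}"
        )
    itp += ["", "[ bonds ]", ";  i  j  funct  b0(nm)"]
    for (i, j), r0 in zip(struct.bonds, struct.bond_r0):
        itp.append(f"{i + 1:5d} {j + 1:5d}   1  {r0 / 10.0:.4f}")
    itp += ["", "[ angles ]", ";  i  j  k  funct  theta0"]
    for j in range(n):
        nb = sorted(adj[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                itp.append(f"{nb[a] + 1:5d} {j + 1:5d} {nb[b] + 1:5d}   1  109.47")
    itp_path = prefix.with_suffix(".itp")
    itp_path.write_text("\n".join(itp) + "\n")
    return {"gro": gro, "itp": itp_path}
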