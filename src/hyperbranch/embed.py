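"""3D embedding of CG trees and packing of molecules into a periodic box.

Geometry here is a *starting configuration* for DPD/CG simulation, in
reduced units (bond length 1 by default).  Beads are placed breadth-first
from the root, each child one bond length from its parent in a random
direction, with best-effort excluded volume.  Packing places embedded
molecules on a jittered grid with random rigid rotations in a cubic box
sized from the target number density, then optionally fills solvent beads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import PackingError, ValidationError
from .topology import CGTopology

__all__ = ["PackedEnsemble", "embed_molecule", "pack_box", "random_rotation"]

#: bead type label per node role (SOL is used for solvent)
ROLE_TYPES = {
    "root": "ROOT",
    "dendritic": "DEN",
    "linear": "LIN",
    "terminal": "TER",
    "arm": "ARM",
    "unclassified": "CG",
}


@dataclass
class PackedEnsemble:
    """Embedded, packed molecules plus optional solvent in a cubic box."""

    molecules: list[CGTopology]
    coords: list[np.ndarray]  # one (n_i, 3) array per molecule, wrapped
    box: tuple[float, float, float]
    solvent: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    @property
    def n_beads(self) -> int:
        return sum(len(c) for c in self.coords) + len(self.solvent)

    def bead_types(self) -> list[str]:
        types = [
            ROLE_TYPES[n.role]
            for topo in self.molecules
            for n in topo.nodes
        ]
        types.extend(["SOL"] * len(self.solvent))
        return types


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-8:
            return v / n


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via a random unit quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def embed_molecule(
    topo: CGTopology,
    bond_length: float = 1.0,
    rng: np.random.Generator | None = None,
    min_sep_factor: float = 0.8,
    retries: int = 50,
) -> np.ndarray:
    """Coordinates for every bead; bonds exactly ``bond_length`` long.

    Children are placed in node-id order (parents always first) at a random
    direction from their parent; a candidate closer than
    ``min_sep_factor * bond_length`` to any other placed bead is rejected up
    to ``retries`` times, after which the best candidate seen is accepted.
    """
    if rng is None:
        rng = np.random.default_rng()
    if bond_length <= 0:
        raise ValidationError("bond_length must be positive")
    n = len(topo)
    coords = np.zeros((n, 3))
    min_sep = min_sep_factor * bond_length
    for node in topo.nodes[1:]:
        i, p = node.id, node.parent
        others = np.delete(coords[:i], p, axis=0)
        best, best_min = None, -np.inf
        for _ in range(retries):
            cand = coords[p] + bond_length * _random_unit(rng)
            m = np.inf if len(others) == 0 else float(
                np.min(np.linalg.norm(others - cand, axis=1))
            )
            if m >= min_sep:
                best = cand
                break
            if m > best_min:
                best, best_min = cand, m
        coords[i] = best
    return coords


def pack_box(
    molecules: list[CGTopology],
    coords: list[np.ndarray],
    number_density: float = 0.1,
    rng: np.random.Generator | None = None,
    cutoff: float = 0.8,
    solvent_count: int = 0,
    max_retries: int = 200,
) -> PackedEnsemble:
    """Place embedded molecules (and solvent) in a cubic periodic box.

    The box volume is (polymer beads + solvent_count) / number_density.
    Molecules go to shuffled grid cells with a random rotation and jitter;
    a placement is retried until no inter-molecular bead pair is closer
    than ``cutoff``.  Solvent beads are inserted uniformly with the same
    minimum-distance criterion.  Raises :class:`PackingError` when the
    density leaves no room.
    """
    if rng is None:
        rng = np.random.default_rng()
    if number_density <= 0:
        raise ValidationError("number_density must be positive")
    if len(molecules) != len(coords):
        raise ValidationError("molecules and coords must have equal length")
    n_poly = sum(len(c) for c in coords)
    volume = (n_poly + solvent_count) / number_density
    box_l = volume ** (1.0 / 3.0)
    nmol = len(molecules)
    ncell = max(1, int(np.ceil(nmol ** (1.0 / 3.0))))
    cell = box_l / ncell
    cells = [
        (i, j, k) for i in range(ncell) for j in range(ncell) for k in range(ncell)
    ]
    order = rng.permutation(len(cells))[:nmol]

    placed: list[np.ndarray] = []
    placed_flat: np.ndarray | None = None
    for mol_xyz, cell_idx in zip(coords, order):
        centered = mol_xyz - mol_xyz.mean(axis=0)
        base = (np.array(cells[int(cell_idx)]) + 0.5) * cell
        ok = False
        for _ in range(max_retries):
            rot = random_rotation(rng)
            jitter = rng.uniform(-0.25, 0.25, size=3) * cell
            cand = centered @ rot.T + base + jitter
            if placed_flat is None or len(placed_flat) == 0:
                ok = True
            else:
                tree = cKDTree(placed_flat)
                d, _ = tree.query(_wrap(cand, box_l), k=1)
                ok = bool(np.min(d) >= cutoff)
            if ok:
                break
        if not ok:
            raise PackingError(
                f"could not place a molecule of {len(mol_xyz)} beads at density "
                f"{number_density} without overlap (cutoff {cutoff})"
            )
        wrapped = _wrap(cand, box_l)
        placed.append(wrapped)
        placed_flat = wrapped if placed_flat is None else np.vstack([placed_flat, wrapped])

    solvent = np.empty((0, 3))
    if solvent_count > 0:
        pts: list[np.ndarray] = []
        occupied = placed_flat if placed_flat is not None else np.empty((0, 3))
        for _ in range(solvent_count):
            for _ in range(max_retries):
                cand = rng.uniform(0.0, box_l, size=3)
                pool = occupied if not pts else np.vstack([occupied, np.array(pts)])
                if len(pool) == 0 or np.min(
                    np.linalg.norm(pool - cand, axis=1)
                ) >= cutoff:
                    pts.append(cand)
                    break
            else:
                raise PackingError(
                    f"could not insert solvent bead {len(pts) + 1}/{solvent_count}"
                )
        solvent = np.array(pts)

    return PackedEnsemble(
        molecules=list(molecules),
        coords=placed,
        box=(box_l, box_l, box_l),
        solvent=solvent,
    )


def _wrap(xyz: np.ndarray, box_l: float) -> np.ndarray:
    return np.mod(xyz, box_l)
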