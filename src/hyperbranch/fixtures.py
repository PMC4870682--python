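"""Bundled toy building blocks so every workflow runs with no download.

Three small synthetic fragments are generated programmatically:

* ``core_a3_0.mol2`` — a methane-like core (C + 4 H), usable as the central
  unit for root branch numbers up to 4;
* ``ab2_unit.mol2`` — a propane-like AB2 repeat unit (glycerol-inspired
  skeleton): parent hook on the central carbon, two child positions on the
  end carbons, which also serve as the two inequivalent connection ways of
  the linear unit and as arm positions on terminal units;
* ``arm_l1.mol2`` — an ethylene-oxide-like arm unit (ethanol skeleton):
  parent hook on C1, chain continuation through the hydroxyl hydrogen.

All geometries are synthetic and approximate; the relaxation step is what
makes assembled structures reasonable.  ``make_fixtures`` writes the mol2
files plus a map file wiring every repeat-unit role to them; the reference
topology helpers build tiny trees with known metrics.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mol2 import Mol2Atom, Mol2Molecule, write_mol2
from .topology import CGTopology

__all__ = [
    "make_fixtures",
    "methane_core",
    "propane_ab2",
    "ethanol_arm",
    "path_topology",
    "star_topology",
    "dendrimer_topology",
]

_T = 1.09 / np.sqrt(3.0)  # tetrahedral C-H offset per axis


def _atom(name: str, element: str, tlabel: str, x: float, y: float, z: float) -> Mol2Atom:
    return Mol2Atom(name=name, element=element, type_label=tlabel,
                    charge=0.0, xyz=np.array([x, y, z]))


def methane_core() -> Mol2Molecule:
    """CH4: atom 1 = C, atoms 2-5 = tetrahedral hydrogens."""
    atoms = [
        _atom("C1", "C", "C.3", 0.0, 0.0, 0.0),
        _atom("H1", "H", "H", _T, _T, _T),
        _atom("H2", "H", "H", _T, -_T, -_T),
        _atom("H3", "H", "H", -_T, _T, -_T),
        _atom("H4", "H", "H", -_T, -_T, _T),
    ]
    bonds = [(0, i, "1") for i in range(1, 5)]
    return Mol2Molecule(name="core_unit", atoms=atoms, bonds=bonds)


def propane_ab2() -> Mol2Molecule:
    """C3H8 skeleton for the AB2 repeat unit.

    Atom order: 1 C1, 2 C2, 3 C3, 4-6 H on C1, 7-8 H on C2, 9-11 H on C3.
    The parent hook is C2-H7; child/arm positions are C1-H4 and C3-H9.
    """
    atoms = [
        _atom("C1", "C", "C.3", -1.26, 0.73, 0.0),
        _atom("C2", "C", "C.3", 0.0, 0.0, 0.0),
        _atom("C3", "C", "C.3", 1.26, 0.73, 0.0),
        _atom("H4", "H", "H", -2.16, 0.17, 0.0),
        _atom("H5", "H", "H", -1.32, 1.36, 0.89),
        _atom("H6", "H", "H", -1.32, 1.36, -0.89),
        _atom("H7", "H", "H", 0.0, -0.63, 0.89),
        _atom("H8", "H", "H", 0.0, -0.63, -0.89),
        _atom("H9", "H", "H", 2.16, 0.17, 0.0),
        _atom("H10", "H", "H", 1.32, 1.36, 0.89),
        _atom("H11", "H", "H", 1.32, 1.36, -0.89),
    ]
    bonds = [(0, 1, "1"), (1, 2, "1"),
             (0, 3, "1"), (0, 4, "1"), (0, 5, "1"),
             (1, 6, "1"), (1, 7, "1"),
             (2, 8, "1"), (2, 9, "1"), (2, 10, "1")]
    return Mol2Molecule(name="ab2_unit", atoms=atoms, bonds=bonds)


def ethanol_arm() -> Mol2Molecule:
    """C2H5OH skeleton for the ethylene-oxide-like arm unit.

    Atom order: 1 C1, 2 C2, 3 O, 4 HO, 5-7 H on C1, 8-9 H on C2.
    Parent hook C1-H5; the chain continues through O-HO.
    """
    atoms = [
        _atom("C1", "C", "C.3", 0.0, 0.0, 0.0),
        _atom("C2", "C", "C.3", 1.52, 0.0, 0.0),
        _atom("O1", "O", "O.3", 2.03, 1.34, 0.0),
        _atom("HO", "H", "H", 2.99, 1.31, 0.0),
        _atom("H5", "H", "H", -0.39, -1.02, 0.0),
        _atom("H6", "H", "H", -0.39, 0.51, 0.89),
        _atom("H7", "H", "H", -0.39, 0.51, -0.89),
        _atom("H8", "H", "H", 1.91, -0.51, 0.89),
        _atom("H9", "H", "H", 1.91, -0.51, -0.89),
    ]
    bonds = [(0, 1, "1"), (1, 2, "1"), (2, 3, "1"),
             (0, 4, "1"), (0, 5, "1"), (0, 6, "1"),
             (1, 7, "1"), (1, 8, "1")]
    return Mol2Molecule(name="arm_unit", atoms=atoms, bonds=bonds)


MAP_TEXT = """\
# role   variant  mol2-path        slot:heavy:H triples (1-based atom indices)
# slot 0 of every non-root role is the parent hook
A3_0   ch4    core_a3_0.mol2  0:1:2 1:1:3 2:1:4 3:1:5
A3_1   prop   ab2_unit.mol2   0:2:7 1:1:4 2:3:9
A2_1   prop1  ab2_unit.mol2   0:2:7 1:1:4 2:3:9
A2_2   prop2  ab2_unit.mol2   0:2:7 1:3:9 2:1:4
A1     prop   ab2_unit.mol2   0:2:7
A11_1  prop1  ab2_unit.mol2   0:2:7 1:1:4
A11_2  prop2  ab2_unit.mol2   0:2:7 1:3:9
A12    prop   ab2_unit.mol2   0:2:7 1:1:4 2:3:9
L1     etoh   arm_l1.mol2     0:1:5 1:3:4
"""


def make_fixtures(outdir) -> dict[str, Path]:
    """Write the toy mol2 set and the map file; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "A3_0": write_mol2(methane_core(), outdir / "core_a3_0.mol2"),
        "AB2": write_mol2(propane_ab2(), outdir / "ab2_unit.mol2"),
        "L1": write_mol2(ethanol_arm(), outdir / "arm_l1.mol2"),
    }
    map_path = outdir / "units.map"
    map_path.write_text(MAP_TEXT)
    paths["map"] = map_path
    return paths


# -- reference CG topologies ------------------------------------------------


def path_topology(n: int) -> CGTopology:
    """A linear chain of n units rooted at one end-adjacent interior unit.

    Built as a root with two children extended alternately, matching the
    BR = 2 growth product; DB = 0 and WI = n(n^2-1)/6.
    """
    if n < 3:
        raise ValueError("path topology needs n >= 3")
    topo = CGTopology()
    topo.add_root()
    left = topo.add_child(0)
    right = topo.add_child(0)
    placed = 3
    toggle = True
    while placed < n:
        if toggle:
            left = topo.add_child(left)
        else:
            right = topo.add_child(right)
        toggle = not toggle
        placed += 1
    topo.classify()
    return topo


def star_topology(n_leaves: int) -> CGTopology:
    """A root with ``n_leaves`` children."""
    topo = CGTopology()
    topo.add_root()
    for _ in range(n_leaves):
        topo.add_child(0)
    topo.classify()
    return topo


def dendrimer_topology(br: int, layers: int) -> CGTopology:
    """Perfect dendrimer: root of functionality ``br``, then ``layers``
    complete generations of 2-functional units.  DB = 1 by construction."""
    topo = CGTopology()
    topo.add_root()
    frontier = [topo.add_child(0) for _ in range(br)]
    for _ in range(layers - 1):
        nxt = []
        for nid in frontier:
            nxt.append(topo.add_child(nid))
            nxt.append(topo.add_child(nid))
        frontier = nxt
    topo.classify()
    return topo
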