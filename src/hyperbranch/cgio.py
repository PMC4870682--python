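"""Writers for coarse-grained ensembles.

Formats: HOOMD XML v1 (DPD starting configurations), GROMACS .gro/.itp/.top
(CG simulation), a tab-separated run report of per-structure metrics
(DP, D, L, T, DB, WI, canonical code, arm units), and a JSON topology dump
for reading a CG run back (e.g. for later back-mapping).

Bead order everywhere is: molecules in ensemble order, breadth-first
(= node id) within a molecule, then solvent.  Bond indices are 0-based in
the XML and 1-based in GROMACS files, and never cross molecule boundaries.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

from .embed import ROLE_TYPES, PackedEnsemble
from .topology import CGTopology

__all__ = [
    "write_hoomd_xml",
    "write_gro_itp",
    "write_report",
    "save_topologies",
    "load_topologies",
]


def write_hoomd_xml(ensemble: PackedEnsemble, path, bond_type: str = "polymer") -> Path:
    """HOOMD XML v1: configuration / box / position / type / bond."""
    path = Path(path)
    natoms = ensemble.n_beads
    root = ET.Element("hoomd_xml", version="1.4")
    conf = ET.SubElement(
        root, "configuration", time_step="0", dimensions="3", natoms=str(natoms)
    )
    lx, ly, lz = ensemble.box
    ET.SubElement(conf, "box", lx=f"{lx:.6f}", ly=f"{ly:.6f}", lz=f"{lz:.6f}")

    pos_lines = []
    for xyz in ensemble.coords:
        pos_lines.extend(f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in xyz)
    pos_lines.extend(f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in ensemble.solvent)
    pos = ET.SubElement(conf, "position", num=str(natoms))
    pos.text = "\n" + "\n".join(pos_lines) + "\n"

    typ = ET.SubElement(conf, "type", num=str(natoms))
    typ.text = "\n" + "\n".join(ensemble.bead_types()) + "\n"

    bond_lines = []
    offset = 0
    for topo in ensemble.molecules:
        bond_lines.extend(
            f"{bond_type} {offset + i} {offset + j}" for i, j in topo.edges()
        )
        offset += len(topo)
    bonds = ET.SubElement(conf, "bond", num=str(len(bond_lines)))
    bonds.text = "\n" + "\n".join(bond_lines) + "\n" if bond_lines else ""

    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")
    return path


def _gro_atom_line(resnum: int, resname: str, atomname: str, atomnum: int, xyz) -> str:
    x, y, z = xyz
    return (
        f"{resnum % 100000:5d}{resname:<5s}{atomname:>5s}{atomnum % 100000:5d}"
        f"{x:8.3f}{y:8.3f}{z:8.3f}"
    )


def write_gro_itp(
    ensemble: PackedEnsemble,
    path_prefix,
    bond_r0: float = 1.0,
    bond_k: float = 1000.0,
) -> dict[str, Path]:
    """GROMACS CG files: one .gro, one .itp per species, one .top.

    One bead is one "atom", one molecule one residue (names from bead
    roles).  Species are distinct canonical topologies (code + arm count);
    bond b0/k are placeholder config values, not fitted parameters.
    Numbering wraps at 100000 per the gro fixed-width convention.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    lines = ["CG hyperbranched ensemble", str(ensemble.n_beads)]
    atomnum = 0
    resnum = 0
    for topo, mol_xyz in zip(ensemble.molecules, ensemble.coords):
        resnum += 1
        types = [ROLE_TYPES[n.role] for n in topo.nodes]
        for t, xyz in zip(types, mol_xyz):
            atomnum += 1
            lines.append(_gro_atom_line(resnum, "HBP", t, atomnum, xyz))
    for xyz in ensemble.solvent:
        resnum += 1
        atomnum += 1
        lines.append(_gro_atom_line(resnum, "SOL", "SOL", atomnum, xyz))
    lx, ly, lz = ensemble.box
    lines.append(f"{lx:10.5f}{ly:10.5f}{lz:10.5f}")
    gro_path = prefix.with_suffix(".gro")
    gro_path.write_text("\n".join(lines) + "\n")

    # species = distinct molecular graphs
    species_key: list[str] = []
    species_of: list[int] = []
    for topo in ensemble.molecules:
        key = f"{topo.canonical_code()}|arms={topo.arm_units}"
        if key not in species_key:
            species_key.append(key)
        species_of.append(species_key.index(key))

    out: dict[str, Path] = {"gro": gro_path}
    itp_names: list[str] = []
    for s_idx in range(len(species_key)):
        topo = ensemble.molecules[species_of.index(s_idx)]
        name = f"HBP{s_idx}"
        itp_names.append(name)
        itp = [
            "[ moleculetype ]",
            "; name  nrexcl",
            f"{name}  1",
            "",
            "[ atoms ]",
            ";  nr  type  resnr  residue  atom  cgnr  charge  mass",
        ]
        for n in topo.nodes:
            t = ROLE_TYPES[n.role]
            itp.append(
                f"{n.id + 1:5d}  {t:<5s}  1  HBP  {t:<5s}  {n.id + 1:5d}   0.000   1.000"
            )
        itp += ["", "[ bonds ]", ";  i  j  funct  b0  k"]
        for i, j in topo.edges():
            itp.append(f"{i + 1:5d} {j + 1:5d}   1  {bond_r0:.4f}  {bond_k:.1f}")
        p = prefix.parent / f"{prefix.name}_{name}.itp"
        p.write_text("\n".join(itp) + "\n")
        out[name] = p

    top = ["; CG topology", ""]
    top.extend(f'#include "{prefix.name}_{n}.itp"' for n in itp_names)
    top += ["", "[ system ]", "CG hyperbranched ensemble", "", "[ molecules ]"]
    # gro order must match: emit runs of consecutive species
    run_species, run_len = None, 0
    for s in species_of + [None]:
        if s == run_species:
            run_len += 1
            continue
        if run_species is not None:
            top.append(f"{itp_names[run_species]}  {run_len}")
        run_species, run_len = s, 1
    if len(ensemble.solvent):
        top.append(f"SOL  {len(ensemble.solvent)}")
    top_path = prefix.with_suffix(".top")
    top_path.write_text("\n".join(top) + "\n")
    out["top"] = top_path
    return out


REPORT_COLUMNS = [
    "molecule_id", "DP", "D", "L", "T", "DB", "WI", "canonical_code", "arm_units",
]


def write_report(molecules: list[CGTopology], path) -> Path:
    """Tab-separated per-structure metric table (one row per molecule)."""
    path = Path(path)
    rows = ["\t".join(REPORT_COLUMNS)]
    for topo in molecules:
        m = topo.metrics()
        m["DB"] = f"{m['DB']:.6f}"
        rows.append("\t".join(str(m[c]) for c in REPORT_COLUMNS))
    path.write_text("\n".join(rows) + "\n")
    return path


def save_topologies(molecules: list[CGTopology], path, meta: dict | None = None) -> Path:
    """JSON dump of an ensemble's topologies (parents + roles), reloadable."""
    path = Path(path)
    doc = {
        "meta": meta or {},
        "molecules": [
            {
                "molecule_id": t.molecule_id,
                "parents": [(-1 if n.parent is None else n.parent) for n in t.nodes],
                "roles": [n.role for n in t.nodes],
            }
            for t in molecules
        ],
    }
    path.write_text(json.dumps(doc, indent=1))
    return path


def load_topologies(path) -> tuple[list[CGTopology], dict]:
    """Inverse of :func:`save_topologies`."""
    doc = json.loads(Path(path).read_text())
    molecules = []
    for rec in doc["molecules"]:
        topo = CGTopology.from_parents(rec["parents"])
        for node, role in zip(topo.nodes, rec["roles"]):
            node.role = role
        topo.molecule_id = rec["molecule_id"]
        topo.classify()
        molecules.append(topo)
    return molecules, doc.get("meta", {})
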