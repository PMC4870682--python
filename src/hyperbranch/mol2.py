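"""TRIPOS mol2 repeat-unit templates and the role->template map file.

Back-mapping replaces each CG bead with an all-atom fragment read from a
mol2 file.  A fragment's reactive positions are *attachments*: (slot index,
heavy atom, deletable hydrogen), with 1-based atom indices in mol2 order.
By convention slot 0 of every non-core-root template is its parent hook;
higher slots are consumed in declared order by core children and then arms.

The map file is plain text, one template variant per line::

    # role  variant  mol2-path  slot:heavy:H  [slot:heavy:H ...]  [weight=W]
    A3_0  ch4   core_a3_0.mol2  0:1:2 1:1:3 2:1:4
    A2_1  prop  ab2_unit.mol2   0:2:7 1:1:4 2:3:9

Paths are resolved relative to the map file.  Roles follow the repeat-unit
taxonomy: A3_0 central core, A3_1 dendritic, A2_1/A2_2 the two linear-unit
connection ways, A1 bare terminal, A11_1/A11_2 terminal with one arm,
A12 terminal with two arms, L1 arm unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import MapFileError, Mol2ParseError, TemplateError

__all__ = [
    "Mol2Atom",
    "Mol2Molecule",
    "Attachment",
    "RepeatUnitTemplate",
    "MapFile",
    "parse_mol2",
    "write_mol2",
    "ROLE_NAMES",
]

ROLE_NAMES = ("A3_0", "A3_1", "A2_1", "A2_2", "A1", "A11_1", "A11_2", "A12", "L1")


@dataclass
class Mol2Atom:
    name: str
    element: str
    type_label: str
    charge: float
    xyz: np.ndarray  # (3,) Angstrom


@dataclass
class Mol2Molecule:
    name: str
    atoms: list[Mol2Atom]
    bonds: list[tuple[int, int, str]]  # 0-based endpoint indices, bond order

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    def neighbors(self, i: int) -> set[int]:
        out = set()
        for a, b, _ in self.bonds:
            if a == i:
                out.add(b)
            elif b == i:
                out.add(a)
        return out


def _element_of(type_label: str, name: str) -> str:
    token = type_label.split(".")[0]
    if token and token[0].isalpha():
        return token[:2].capitalize() if len(token) > 1 and token[1].islower() else token[0].upper()
    alpha = "".join(c for c in name if c.isalpha())
    return alpha[:1].upper() if alpha else "X"


def parse_mol2(path) -> Mol2Molecule:
    """Parse @<TRIPOS>MOLECULE/ATOM/BOND records, preserving atom order.

    Unknown sections are tolerated.  A missing section or an atom/bond
    count that disagrees with the MOLECULE header raises
    :class:`Mol2ParseError` with a line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    section = None
    section_line = {}
    mol_header: list[str] = []
    atom_lines: list[tuple[int, str]] = []
    bond_lines: list[tuple[int, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@<TRIPOS>"):
            section = line[len("@<TRIPOS>"):].upper()
            section_line[section] = lineno
            continue
        if section == "MOLECULE":
            mol_header.append(line)
        elif section == "ATOM":
            atom_lines.append((lineno, line))
        elif section == "BOND":
            bond_lines.append((lineno, line))
    if "MOLECULE" not in section_line:
        raise Mol2ParseError(f"{path}: missing @<TRIPOS>MOLECULE section")
    if "ATOM" not in section_line:
        raise Mol2ParseError(f"{path}: missing @<TRIPOS>ATOM section")
    if "BOND" not in section_line:
        raise Mol2ParseError(f"{path}: missing @<TRIPOS>BOND section")
    name = mol_header[0] if mol_header else path.stem
    declared_atoms = declared_bonds = None
    if len(mol_header) > 1:
        counts = mol_header[1].split()
        try:
            declared_atoms = int(counts[0])
            declared_bonds = int(counts[1]) if len(counts) > 1 else None
        except ValueError:
            raise Mol2ParseError(
                f"{path}: malformed MOLECULE count record",
                line=section_line["MOLECULE"] + 2,
            ) from None

    atoms: list[Mol2Atom] = []
    for lineno, line in atom_lines:
        f = line.split()
        if len(f) < 6:
            raise Mol2ParseError(f"{path}: malformed ATOM record", line=lineno)
        try:
            xyz = np.array([float(f[2]), float(f[3]), float(f[4])])
        except ValueError:
            raise Mol2ParseError(f"{path}: bad coordinates", line=lineno) from None
        charge = float(f[8]) if len(f) > 8 else 0.0
        atoms.append(
            Mol2Atom(name=f[1], element=_element_of(f[5], f[1]),
                     type_label=f[5], charge=charge, xyz=xyz)
        )
    bonds: list[tuple[int, int, str]] = []
    for lineno, line in bond_lines:
        f = line.split()
        if len(f) < 4:
            raise Mol2ParseError(f"{path}: malformed BOND record", line=lineno)
        try:
            i, j = int(f[1]) - 1, int(f[2]) - 1
        except ValueError:
            raise Mol2ParseError(f"{path}: bad bond indices", line=lineno) from None
        if not (0 <= i < len(atoms) and 0 <= j < len(atoms)):
            raise Mol2ParseError(f"{path}: bond index out of range", line=lineno)
        bonds.append((i, j, f[3]))
    if declared_atoms is not None and declared_atoms != len(atoms):
        raise Mol2ParseError(
            f"{path}: header declares {declared_atoms} atoms, found {len(atoms)}",
            line=section_line["ATOM"],
        )
    if declared_bonds is not None and declared_bonds != len(bonds):
        raise Mol2ParseError(
            f"{path}: header declares {declared_bonds} bonds, found {len(bonds)}",
            line=section_line["BOND"],
        )
    return Mol2Molecule(name=name, atoms=atoms, bonds=bonds)


def write_mol2(mol: Mol2Molecule, path) -> Path:
    path = Path(path)
    out = [
        "@<TRIPOS>MOLECULE",
        mol.name,
        f"{len(mol.atoms)} {len(mol.bonds)} 0 0 0",
        "SMALL",
        "USER_CHARGES",
        "@<TRIPOS>ATOM",
    ]
    for i, a in enumerate(mol.atoms, start=1):
        out.append(
            f"{i:>4d} {a.name:<6s} {a.xyz[0]:10.4f} {a.xyz[1]:10.4f} "
            f"{a.xyz[2]:10.4f} {a.type_label:<6s} 1 UNIT {a.charge:8.4f}"
        )
    out.append("@<TRIPOS>BOND")
    for k, (i, j, order) in enumerate(mol.bonds, start=1):
        out.append(f"{k:>4d} {i + 1:>4d} {j + 1:>4d} {order}")
    path.write_text("\n".join(out) + "\n")
    return path


@dataclass(frozen=True)
class Attachment:
    """One reactive position: a heavy atom and the hydrogen it sacrifices."""

    slot: int
    heavy: int  # 0-based atom index
    hydrogen: int  # 0-based atom index


@dataclass
class RepeatUnitTemplate:
    """An all-atom fragment with declared attachment points."""

    role: str
    variant: str
    molecule: Mol2Molecule
    attachments: list[Attachment]
    source_path: str = ""
    weight: float = 1.0

    def __post_init__(self):
        if self.role not in ROLE_NAMES:
            raise TemplateError(f"unknown role {self.role!r}; expected one of {ROLE_NAMES}")
        seen_slots = set()
        for att in self.attachments:
            if att.slot in seen_slots:
                raise TemplateError(
                    f"{self.role}/{self.variant}: duplicate slot {att.slot}"
                )
            seen_slots.add(att.slot)
            n = self.molecule.n_atoms
            if not (0 <= att.heavy < n and 0 <= att.hydrogen < n):
                raise TemplateError(
                    f"{self.role}/{self.variant}: attachment atom index out of range"
                )
            h_atom = self.molecule.atoms[att.hydrogen]
            if h_atom.element != "H":
                raise TemplateError(
                    f"{self.role}/{self.variant}: atom {att.hydrogen + 1} "
                    f"({h_atom.element}) is not a hydrogen"
                )
            if att.heavy not in self.molecule.neighbors(att.hydrogen):
                raise TemplateError(
                    f"{self.role}/{self.variant}: hydrogen {att.hydrogen + 1} is not "
                    f"bonded to heavy atom {att.heavy + 1}"
                )
        self.attachments = sorted(self.attachments, key=lambda a: a.slot)

    @property
    def parent_slot(self) -> Attachment | None:
        """Slot 0, the parent hook (None for the core root role A3_0)."""
        if self.role == "A3_0":
            return None
        return self.attachments[0]

    def child_slots(self) -> list[Attachment]:
        if self.role == "A3_0":
            return list(self.attachments)
        return list(self.attachments[1:])


@dataclass
class MapFile:
    """role -> list of template variants, parsed from the map-file dialect."""

    entries: dict[str, list[RepeatUnitTemplate]] = field(default_factory=dict)

    @classmethod
    def parse(cls, path) -> "MapFile":
        path = Path(path)
        entries: dict[str, list[RepeatUnitTemplate]] = {}
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) < 4:
                raise MapFileError(
                    f"{path}:{lineno}: expected 'role variant path slot:heavy:H ...'"
                )
            role, variant, mol2_path, *slot_tokens = tokens
            weight = 1.0
            if slot_tokens and slot_tokens[-1].startswith("weight="):
                weight = float(slot_tokens.pop().split("=", 1)[1])
            if not slot_tokens:
                raise MapFileError(f"{path}:{lineno}: no attachment slots declared")
            atts = []
            for tok in slot_tokens:
                parts = tok.split(":")
                if len(parts) != 3:
                    raise MapFileError(
                        f"{path}:{lineno}: bad slot triple {tok!r}, expected slot:heavy:H"
                    )
                slot, heavy, hyd = (int(p) for p in parts)
                atts.append(Attachment(slot=slot, heavy=heavy - 1, hydrogen=hyd - 1))
            full = (path.parent / mol2_path).resolve()
            if not full.exists():
                raise MapFileError(f"{path}:{lineno}: mol2 file not found: {full}")
            tmpl = RepeatUnitTemplate(
                role=role,
                variant=variant,
                molecule=parse_mol2(full),
                attachments=atts,
                source_path=str(full),
                weight=weight,
            )
            entries.setdefault(role, []).append(tmpl)
        return cls(entries=entries)

    def variants(self, roles: list[str]) -> list[RepeatUnitTemplate]:
        """All variants registered under any of the given role names."""
        out: list[RepeatUnitTemplate] = []
        for r in roles:
            out.extend(self.entries.get(r, []))
        return out
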