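"""Coarse-grained molecular trees and their topological metrics.

A hyperbranched molecule is a rooted unordered tree: one root (core) unit of
functionality BR, AB2-type core units carrying up to two children, and
optionally linear "arm" beads grafted on.  The metrics of interest are

* unit classification (dendritic D / linear L / terminal T, root excluded),
* degree of branching DB = 2D/(2D+L) (Hölter-Frey; Fréchet variant
  (D+T)/(D+L+T) selectable),
* Wiener index WI = Σ over bonds of V_L·V_R, the product of the component
  sizes either side of each bond — for a tree this equals the sum of
  pairwise graph distances,
* an AHU-style canonical code used to deduplicate isomorphic topologies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import StructureError, ValidationError

__all__ = [
    "CGNode",
    "CGTopology",
    "filter_unique",
]

CORE_ROLES = ("root", "dendritic", "linear", "terminal")


@dataclass
class CGNode:
    """One coarse-grained bead. ``role`` is stamped by classification."""

    id: int
    parent: int | None
    children: list[int] = field(default_factory=list)
    generation: int = 0
    role: str = "unclassified"

    @property
    def is_arm(self) -> bool:
        return self.role == "arm"


class CGTopology:
    """A rooted tree of coarse-grained units.

    Nodes are created in parent-before-child order, so node ids are a valid
    topological order.  Core metrics (D/L/T, DB) consider only non-arm nodes
    and core-core edges; the Wiener index covers the whole molecule by
    default.
    """

    def __init__(self) -> None:
        self.nodes: list[CGNode] = []
        self.molecule_id: int = 0
        self._dlt: tuple[int, int, int] | None = None

    # -- construction -----------------------------------------------------

    def add_root(self) -> int:
        if self.nodes:
            raise StructureError("topology already has a root")
        self.nodes.append(CGNode(id=0, parent=None, generation=0, role="root"))
        return 0

    def add_child(self, parent: int, role: str = "unclassified") -> int:
        if not 0 <= parent < len(self.nodes):
            raise StructureError(f"no such parent node {parent}")
        nid = len(self.nodes)
        pnode = self.nodes[parent]
        self.nodes.append(
            CGNode(id=nid, parent=parent, generation=pnode.generation + 1, role=role)
        )
        pnode.children.append(nid)
        self._dlt = None
        return nid

    @classmethod
    def from_parents(cls, parents) -> "CGTopology":
        """Build from a parent array (parents[0] must be None/-1 for the root).

        Raises :class:`StructureError` if the array does not describe a
        single rooted tree with parent ids preceding child ids.
        """
        topo = cls()
        for i, p in enumerate(parents):
            if i == 0:
                if p is not None and p != -1:
                    raise StructureError("node 0 must be the root")
                topo.add_root()
            else:
                if p is None or not 0 <= p < i:
                    raise StructureError(
                        f"parent of node {i} must be an earlier node, got {p!r}"
                    )
                topo.add_child(int(p))
        if not topo.nodes:
            raise StructureError("empty topology")
        return topo

    def copy(self) -> "CGTopology":
        new = CGTopology()
        new.molecule_id = self.molecule_id
        for n in self.nodes:
            new.nodes.append(
                CGNode(id=n.id, parent=n.parent, children=list(n.children),
                       generation=n.generation, role=n.role)
            )
        new._dlt = self._dlt
        return new

    # -- basic properties --------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edges(self) -> list[tuple[int, int]]:
        return [(n.parent, n.id) for n in self.nodes if n.parent is not None]

    def core_ids(self) -> list[int]:
        return [n.id for n in self.nodes if not n.is_arm]

    @property
    def dp(self) -> int:
        """Number of core repeat units (root included, arms excluded)."""
        return len(self.core_ids())

    @property
    def arm_units(self) -> int:
        return sum(1 for n in self.nodes if n.is_arm)

    def core_children(self, nid: int) -> list[int]:
        return [c for c in self.nodes[nid].children if not self.nodes[c].is_arm]

    def arms_at(self, nid: int) -> int:
        """Number of arms rooted directly at core node ``nid``."""
        return sum(
            1 for c in self.nodes[nid].children
            if self.nodes[c].is_arm and not self.nodes[nid].is_arm
        )

    # -- classification and DB --------------------------------------------

    def classify(self) -> tuple[int, int, int]:
        """Count dendritic/linear/terminal core units and stamp roles.

        A non-root core unit with two core children is dendritic, one is
        linear, none is terminal.  The root is its own species and is
        excluded from the counts; arm beads keep the ``arm`` role.
        """
        if self._dlt is not None:
            return self._dlt
        d = l = t = 0
        for n in self.nodes:
            if n.is_arm or n.parent is None:
                continue
            k = len(self.core_children(n.id))
            if k >= 3:
                raise StructureError(
                    f"core node {n.id} has {k} core children; AB2 units allow at most 2"
                )
            if k == 2:
                n.role, d = "dendritic", d + 1
            elif k == 1:
                n.role, l = "linear", l + 1
            else:
                n.role, t = "terminal", t + 1
        self._dlt = (d, l, t)
        return self._dlt

    def degree_of_branching(self, convention: str = "holter") -> float:
        """DB of the core per the chosen convention.

        ``holter``: DB = 2D/(2D+L), defined as 0 when D = L = 0 — a finite
        linear chain scores exactly 0 and a perfect dendrimer exactly 1.
        ``frechet``: DB = (D+T)/(D+L+T).
        """
        d, l, t = self.classify()
        if convention == "holter":
            return 2.0 * d / (2.0 * d + l) if (d or l) else 0.0
        if convention == "frechet":
            return (d + t) / (d + l + t) if (d or l or t) else 0.0
        raise ValidationError(f"unknown DB convention {convention!r}")

    # -- Wiener index -------------------------------------------------------

    def bond_splits(self, core_only: bool = False) -> list[tuple[tuple[int, int], int, int]]:
        """Per-bond component sizes (V_L, V_R) after deleting each bond."""
        ids = self.core_ids() if core_only else [n.id for n in self.nodes]
        keep = set(ids)
        n_total = len(keep)
        subtree = {i: 1 for i in keep}
        for nid in sorted(keep, reverse=True):  # children before parents
            p = self.nodes[nid].parent
            if p is not None and p in keep:
                subtree[p] += subtree[nid]
        out = []
        for nid in keep:
            p = self.nodes[nid].parent
            if p is not None and p in keep:
                vr = subtree[nid]
                out.append(((p, nid), n_total - vr, vr))
        return out

    def wiener_index(self, core_only: bool = False) -> int:
        """WI = Σ_s V_L,s · V_R,s over bonds s (= sum of pairwise distances)."""
        return sum(vl * vr for _, vl, vr in self.bond_splits(core_only=core_only))

    # -- canonical form ------------------------------------------------------

    def canonical_code(self) -> str:
        """AHU canonical encoding of the rooted unordered tree.

        Leaves encode as ``()``; an internal node concatenates its children's
        codes in sorted order inside one bracket pair.  Two topologies are
        isomorphic as rooted unordered trees iff their codes are equal.
        Roles are ignored: the code captures pure shape.
        """
        codes: dict[int, str] = {}
        for nid in range(len(self.nodes) - 1, -1, -1):  # children before parents
            ch = self.nodes[nid].children
            codes[nid] = "(" + "".join(sorted(codes[c] for c in ch)) + ")"
        return codes[0]

    # -- reporting -----------------------------------------------------------

    def metrics(self) -> dict:
        d, l, t = self.classify()
        return {
            "molecule_id": self.molecule_id,
            "DP": self.dp,
            "D": d,
            "L": l,
            "T": t,
            "DB": self.degree_of_branching(),
            "WI": self.wiener_index(),
            "canonical_code": self.canonical_code(),
            "arm_units": self.arm_units,
        }


def filter_unique(topologies) -> tuple[list[CGTopology], int]:
    """Keep the first occurrence of each canonical code, preserving order.

    Returns (kept, number discarded).
    """
    seen: set[str] = set()
    kept: list[CGTopology] = []
    discarded = 0
    for t in topologies:
        code = t.canonical_code()
        if code in seen:
            discarded += 1
        else:
            seen.add(code)
            kept.append(t)
    return kept, discarded
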