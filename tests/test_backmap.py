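"""CG -> all-atom back-mapping: assembly, relaxation, writers."""

import networkx as nx
import numpy as np
import pytest

from hyperbranch.backmap import (
    AtomisticStructure,
    assign_roles,
    attach_fragment,
    backmap,
    relax,
    write_aa_gro_itp,
    write_tinker_xyz,
)
from hyperbranch.distributions import DistributionSpec
from hyperbranch.errors import MapFileError, TemplateError
from hyperbranch.fixtures import dendrimer_topology, methane_core
from hyperbranch.grafting import ArmSpec, attach_arms
from hyperbranch.growth import grow_core
from hyperbranch.mol2 import Attachment, MapFile, RepeatUnitTemplate
from hyperbranch.topology import CGTopology


def ch4_template(role="A3_0"):
    return RepeatUnitTemplate(
        role=role, variant="ch4", molecule=methane_core(),
        attachments=[Attachment(slot=s, heavy=0, hydrogen=s + 1) for s in range(4)],
    )


def small_armed_molecule(rng, dp=8, gra=0.5, arm_len=2):
    core = grow_core(dp, 3, 0.5, rng)
    spec = ArmSpec(
        gra=gra, brt=1,
        arms=DistributionSpec(mode="monodisperse", adp=arm_len, dp_min=1),
    )
    return attach_arms(core, spec, rng)


class TestAssignRoles:
    def test_bare_core_uses_core_roles_only(self, rng):
        core = grow_core(15, 3, 0.5, rng)
        roles = set(assign_roles(core).values())
        assert roles <= {"root", "dendritic", "linear", "terminal0"}

    def test_terminal_with_two_arms_maps_to_a12_class(self, rng):
        core = grow_core(10, 3, 0.5, rng)
        spec = ArmSpec(
            gra=1.0, brt=2,
            arms=DistributionSpec(mode="monodisperse", adp=1, dp_min=1),
        )
        armed = attach_arms(core, spec, rng)
        roles = assign_roles(armed)
        terminals = [n.id for n in armed.nodes if n.role == "terminal"]
        assert all(roles[t] == "terminal2" for t in terminals)

    def test_arm_path_maps_to_arm_role(self, rng):
        armed = small_armed_molecule(rng, arm_len=4)
        roles = assign_roles(armed)
        arm_ids = [n.id for n in armed.nodes if n.is_arm]
        assert arm_ids and all(roles[i] == "arm" for i in arm_ids)


class TestAttachFragment:
    def test_methane_pair_becomes_ethane_like(self):
        struct = AtomisticStructure()
        tmpl = ch4_template()
        struct.add_fragment(tmpl, cg_node=0)
        attach_fragment(struct, host_heavy=0, host_hydrogen=1,
                        template=tmpl, frag_heavy=0, frag_hydrogen=1, cg_node=1)
        assert struct.n_atoms == 5 + 5 - 2
        assert struct.n_bonds == 4 + 4 - 2 + 1

    def test_new_bond_has_table_length(self):
        struct = AtomisticStructure()
        tmpl = ch4_template()
        struct.add_fragment(tmpl, cg_node=0)
        offset = attach_fragment(struct, 0, 1, tmpl, 0, 1, cg_node=1)
        d = np.linalg.norm(struct.coords[0] - struct.coords[offset])
        assert d == pytest.approx(1.54, abs=1e-6)  # C-C table value

    def test_consumed_slot_rejected(self):
        struct = AtomisticStructure()
        tmpl = ch4_template()
        struct.add_fragment(tmpl, cg_node=0)
        attach_fragment(struct, 0, 1, tmpl, 0, 1, cg_node=1)
        with pytest.raises(TemplateError, match="deleted"):
            attach_fragment(struct, 0, 1, tmpl, 0, 1, cg_node=2)


class TestRelax:
    def _bond_pair(self, r):
        struct = AtomisticStructure()
        tmpl = RepeatUnitTemplate(
            role="A1", variant="hh",
            molecule=methane_core(),
            attachments=[Attachment(slot=0, heavy=0, hydrogen=1)],
        )
        struct.add_fragment(tmpl, cg_node=0)
        # stretch one C-H bond to r
        direction = struct.coords[1] - struct.coords[0]
        struct.coords[1] = struct.coords[0] + r * direction / np.linalg.norm(direction)
        return struct

    def test_equilibrium_structure_unmoved(self):
        struct = self._bond_pair(1.09)
        before = struct.coords.copy()
        relax(struct, max_iter=50, force_tol=0.5)
        assert np.allclose(struct.coords, before, atol=0.05)

    def test_stretched_bond_recovers_r0(self):
        struct = self._bond_pair(2 * 1.09)
        # r0 was recorded at template load: re-pin it to the unstretched value
        struct.bond_r0[0] = 1.09
        relax(struct, max_iter=500, force_tol=0.01)
        d = np.linalg.norm(struct.coords[1] - struct.coords[0])
        assert d == pytest.approx(1.09, rel=0.01)

    def test_steric_clash_resolved(self):
        # two atoms 0.3 A apart, >= 3 bonds apart on the graph
        struct = AtomisticStructure()
        struct.elements = ["C", "C", "C", "C"]
        struct.names = ["C1", "C2", "C3", "C4"]
        struct.type_labels = ["C.3"] * 4
        struct.charges = [0.0] * 4
        struct.alive = [True] * 4
        struct.unit_of_atom = [0] * 4
        struct.coords = np.array(
            [[0.0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], [0.3, 0.05, 0.0]]
        )
        struct.bonds = [(0, 1), (1, 2), (2, 3)]
        struct.bond_r0 = [1.5, 1.5, 2.8]
        relax(struct, max_iter=400, force_tol=0.01)
        assert np.linalg.norm(struct.coords[3] - struct.coords[0]) > 1.0

    def test_energy_never_increases(self, rng, mapfile):
        armed = small_armed_molecule(rng)
        struct = backmap(armed, mapfile, rng=rng, do_relax=False)
        e_before, _ = _energy_of(struct)
        relax(struct, max_iter=80, force_tol=0.01)
        assert struct.energy <= e_before + 1e-9


def _energy_of(struct):
    from hyperbranch.backmap import _energy_gradient, _interaction_lists

    return _energy_gradient(struct, *_interaction_lists(struct))[:2]


class TestBackmap:
    def test_single_root_is_template_verbatim(self, mapfile, rng):
        topo = CGTopology()
        topo.add_root()
        topo.classify()
        struct = backmap(topo, mapfile, rng=rng, do_relax=False)
        assert struct.n_atoms == 5  # the methane-like core untouched
        assert struct.n_bonds == 4

    def test_atom_and_bond_bookkeeping_identities(self, mapfile, rng):
        armed = small_armed_molecule(rng, dp=9, gra=0.5, arm_len=2)
        struct = backmap(armed, mapfile, rng=rng, do_relax=False)
        n_cg_bonds = len(armed.edges())
        roles = assign_roles(armed)
        atoms_per = {"root": 5, "dendritic": 11, "linear": 11, "terminal0": 11,
                     "terminal1": 11, "terminal2": 11, "arm": 9}
        bonds_per = {"root": 4, "dendritic": 10, "linear": 10, "terminal0": 10,
                     "terminal1": 10, "terminal2": 10, "arm": 8}
        total_atoms = sum(atoms_per[r] for r in roles.values())
        total_bonds = sum(bonds_per[r] for r in roles.values())
        assert struct.n_atoms == total_atoms - 2 * n_cg_bonds
        assert struct.n_bonds == total_bonds - 2 * n_cg_bonds + n_cg_bonds

    def test_quotient_graph_isomorphic_to_cg_tree(self, mapfile, rng):
        armed = small_armed_molecule(rng, dp=8, gra=1.0, arm_len=3)
        struct = backmap(armed, mapfile, rng=rng, do_relax=False)
        q = nx.Graph()
        q.add_nodes_from(set(struct.unit_of_atom))
        for i, j in struct.bonds:
            a, b = struct.unit_of_atom[i], struct.unit_of_atom[j]
            if a != b:
                q.add_edge(a, b)
        cg = nx.Graph(armed.edges())
        cg.add_nodes_from(range(len(armed)))
        assert nx.is_isomorphic(q, cg)
        # provenance contraction is in fact the identity on node ids
        assert set(q.edges()) == {tuple(sorted(e)) for e in armed.edges()}

    def test_linear_variants_both_appear_over_seeds(self, mapfile):
        # the two inequivalent linear-unit connection ways must both occur
        chain = CGTopology.from_parents([None, 0, 0, 1, 3, 4, 2])
        chain.classify()
        linear_ids = [n.id for n in chain.nodes if n.role == "linear"]
        assert linear_ids
        picked = set()
        for seed in range(12):
            struct = backmap(chain, mapfile, rng=np.random.default_rng(seed),
                             do_relax=False)
            picked |= {struct.variant_of_unit[i] for i in linear_ids}
        assert {"prop1", "prop2"} <= picked

    def test_missing_role_fails_before_any_work(self, fixture_dir, rng):
        partial = (
            f"A3_0 ch4 {fixture_dir}/core_a3_0.mol2 0:1:2 1:1:3 2:1:4 3:1:5\n"
        )
        p = fixture_dir / "partial.map"
        p.write_text(partial)
        topo = grow_core(8, 3, 0.5, rng)
        with pytest.raises(MapFileError, match="no template"):
            backmap(topo, MapFile.parse(p), rng=rng)

    def test_fixed_seed_reproduces_structure(self, mapfile, rng):
        armed = small_armed_molecule(rng)
        a = backmap(armed, mapfile, rng=np.random.default_rng(4), relax_iters=30)
        b = backmap(armed, mapfile, rng=np.random.default_rng(4), relax_iters=30)
        assert np.array_equal(a.coords, b.coords)
        assert a.type_labels == b.type_labels


class TestAAWriters:
    @pytest.fixture
    def structure(self, mapfile, rng):
        topo = grow_core(6, 3, 0.5, rng)
        return backmap(topo, mapfile, rng=rng, relax_iters=30)

    def test_tinker_xyz_round_trip_connectivity(self, structure, tmp_path):
        p = write_tinker_xyz(structure, tmp_path / "s.xyz")
        lines = p.read_text().splitlines()
        n = int(lines[0].split()[0])
        assert n == structure.n_atoms
        bonds = set()
        for line in lines[1:]:
            f = line.split()
            idx = int(f[0])
            for nb in f[6:]:
                bonds.add(tuple(sorted((idx - 1, int(nb) - 1))))
        assert bonds == {tuple(sorted(b)) for b in structure.bonds}

    def test_two_atom_mutual_neighbors(self, tmp_path):
        struct = AtomisticStructure()
        struct.elements = ["C", "C"]
        struct.names = ["C1", "C2"]
        struct.type_labels = ["C.3"] * 2
        struct.charges = [0.0] * 2
        struct.alive = [True] * 2
        struct.unit_of_atom = [0, 0]
        struct.coords = np.array([[0.0, 0, 0], [1.54, 0, 0]])
        struct.bonds = [(0, 1)]
        struct.bond_r0 = [1.54]
        p = write_tinker_xyz(struct, tmp_path / "two.xyz")
        lines = p.read_text().splitlines()
        assert len(lines) == 3
        assert lines[1].split()[-1] == "2" and lines[2].split()[-1] == "1"

    def test_missing_type_code_is_an_error(self, structure, tmp_path):
        with pytest.raises(TemplateError, match="no Tinker type code"):
            write_tinker_xyz(structure, tmp_path / "s.xyz", type_codes={"C.3": 1})

    def test_gro_is_xyz_over_ten(self, structure, tmp_path):
        xyz_path = write_tinker_xyz(structure, tmp_path / "s.xyz")
        out = write_aa_gro_itp(structure, tmp_path / "s_aa")
        xyz_lines = xyz_path.read_text().splitlines()[1:]
        gro_lines = out["gro"].read_text().splitlines()[2:-1]
        for xl, gl in zip(xyz_lines, gro_lines):
            xa = np.array([float(v) for v in xl.split()[2:5]])
            ga = np.array([float(gl[20:28]), float(gl[28:36]), float(gl[36:44])])
            assert np.allclose(ga, xa / 10.0, atol=1.5e-3)

    def test_itp_sections_enumerated(self, structure, tmp_path):
        out = write_aa_gro_itp(structure, tmp_path / "s_aa")
        text = out["itp"].read_text()
        n_bond_lines = len([
            l for l in text.split("[ bonds ]")[1].split("[ angles ]")[0].splitlines()
            if l.strip() and not l.startswith(";")
        ])
        assert n_bond_lines == structure.n_bonds
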