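import numpy as np
import pytest

from yarivmd import interactions, synth, trajio
from oracles import random_rigid


def _topology_from_parts(names, elements, bonds, resid=0, resname="LIG"):
    return trajio.MolecularTopology(list(names), list(elements),
                                    np.full(len(names), resid),
                                    [resname] * len(names), bonds)


def _two_benzenes(offset, rot=None):
    """Topology + coords of two benzene molecules, second at ``offset``."""
    names, elements, bonds, xyz = synth.build_benzene()
    top = trajio.MolecularTopology(
        names + [n + "B" for n in names], elements * 2,
        np.array([0] * 6 + [1] * 6), ["BNZ"] * 12,
        np.vstack([bonds, bonds + 6]))
    second = xyz.copy()
    if rot is not None:
        second = second @ rot.T
    coords = np.vstack([xyz, second + np.asarray(offset, float)])
    return top, coords


def _galactose_on_benzene():
    """Constructed pose: pyranose above benzene, H on C3/C4/C5 aimed at the
    ring face, H on C1/C2 pointing away, exocyclic C6 with a remote H."""
    bnames, belems, bbonds, bxyz = synth.build_benzene()
    ring = synth.build_pyranose_templates()["chair"] + np.array([0, 0, 3.7])
    snames = ["O5", "C1", "C2", "C3", "C4", "C5"]
    selems = ["O", "C", "C", "C", "C", "C"]
    sbonds = [[j, (j + 1) % 6] for j in range(6)]
    atoms_xyz = [*ring]
    c6 = ring[5] + np.array([0.0, 0.0, 1.5])
    snames.append("C6")
    selems.append("C")
    sbonds.append([5, 6])
    atoms_xyz.append(c6)
    # hydrogens
    h_id = 7
    for ci, toward_face in [(1, False), (2, False), (3, True), (4, True),
                            (5, True), (6, False)]:
        c = atoms_xyz[ci]
        if toward_face:
            h = c + 1.09 * (-c / np.linalg.norm(c))   # aimed at benzene center
        else:
            h = c + np.array([0.0, 0.0, 1.09])         # pointing away
        snames.append(f"H{ci}")
        selems.append("H")
        sbonds.append([ci, h_id])
        atoms_xyz.append(h)
        h_id += 1
    names = list(bnames) + snames
    elems = list(belems) + selems
    bonds = np.vstack([bbonds, np.array(sbonds) + 6])
    top = trajio.MolecularTopology(names, elems,
                                   np.array([0] * 6 + [1] * len(snames)),
                                   ["BNZ"] * 6 + ["GAL"] * len(snames), bonds)
    coords = np.vstack([bxyz, np.array(atoms_xyz)])
    return top, coords


class TestDetectRings:
    def test_benzene_single_flat_aromatic_ring(self, benzene_system):
        top, coords = benzene_system
        rings = interactions.detect_rings(top, coords)
        assert len(rings) == 1
        r = rings[0]
        assert r.aromatic and r.size == 6
        assert r.planarity == pytest.approx(0.0, abs=1e-12)
        assert np.linalg.norm(r.normal) == pytest.approx(1.0)

    def test_yariv_mimic_ring_census_and_roles(self):
        names, elements, bonds, xyz = synth.build_yariv_mimic(with_sugars=True)
        top = _topology_from_parts(names, elements, bonds, resname="YRV")
        rings = interactions.detect_rings(top, xyz)
        aromatic = [r for r in rings if r.aromatic]
        saccharide = [r for r in rings if r.role == "saccharide"]
        assert len(aromatic) == 4
        assert len(saccharide) == 3
        assert sum(r.role == "central" for r in aromatic) == 1
        assert sum(r.role == "peripheral" for r in aromatic) == 3

    def test_galactose_chair_is_nonaromatic(self):
        ring = synth.build_pyranose_templates()["chair"]
        top = _topology_from_parts(
            ["O5", "C1", "C2", "C3", "C4", "C5"],
            ["O", "C", "C", "C", "C", "C"],
            np.array([[j, (j + 1) % 6] for j in range(6)]), resname="GAL")
        rings = interactions.detect_rings(top, ring)
        assert len(rings) == 1
        assert not rings[0].aromatic
        assert rings[0].role == "saccharide"


class TestClassifyPiPi:
    def _rings(self, offset, rot=None):
        top, coords = _two_benzenes(offset, rot)
        return interactions.detect_rings(top, coords)

    def test_ideal_parallel_stack(self):
        ra, rb = self._rings([0, 0, 3.5])
        label, m = interactions.classify_pi_pi(ra, rb)
        assert label == "pi_pi_parallel"
        assert m["dist_A"] == pytest.approx(3.5)
        assert m["angle_deg"] == pytest.approx(0.0, abs=1e-9)
        assert m["offset_A"] == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_rings_are_tshaped(self):
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("x", 90, degrees=True).as_matrix()
        ra, rb = self._rings([0, 0, 5.0], rot=R)
        label, m = interactions.classify_pi_pi(ra, rb)
        assert label == "pi_pi_tshaped"
        assert m["angle_deg"] == pytest.approx(90.0)

    def test_distant_rings_none(self):
        ra, rb = self._rings([0, 0, 10.0])
        label, _ = interactions.classify_pi_pi(ra, rb)
        assert label == "none"

    def test_symmetric_in_arguments(self):
        ra, rb = self._rings([1.0, 0.5, 3.6])
        la, ma = interactions.classify_pi_pi(ra, rb)
        lb, mb = interactions.classify_pi_pi(rb, ra)
        assert la == lb == "pi_pi_parallel"
        assert ma["dist_A"] == pytest.approx(mb["dist_A"])
        assert ma["offset_A"] == pytest.approx(mb["offset_A"])

    def test_nonaromatic_input_rejected(self):
        ring = synth.build_pyranose_templates()["chair"]
        top = _topology_from_parts(
            ["O5", "C1", "C2", "C3", "C4", "C5"],
            ["O", "C", "C", "C", "C", "C"],
            np.array([[j, (j + 1) % 6] for j in range(6)]))
        sugar = interactions.detect_rings(top, ring)[0]
        ra, _ = self._rings([0, 0, 3.5])
        with pytest.raises(TypeError):
            interactions.classify_pi_pi(ra, sugar)


class TestClassifyChPi:
    def _benzene_ring(self, benzene_system):
        top, coords = benzene_system
        return interactions.detect_rings(top, coords)[0]

    def test_ideal_geometry_accepted(self, benzene_system):
        ring = self._benzene_ring(benzene_system)
        h = np.array([0.0, 0.0, 2.6])
        c = np.array([0.0, 0.0, 3.69])
        label, m = interactions.classify_ch_pi(c, h, ring)
        assert label == "ch_pi"
        assert m["dist_A"] == pytest.approx(2.6)
        assert m["angle_deg"] == pytest.approx(180.0)

    def test_wrong_angle_rejected(self, benzene_system):
        ring = self._benzene_ring(benzene_system)
        h = np.array([0.0, 0.0, 2.6])
        c = h + np.array([1.09, 0.0, 0.0])   # C-H perpendicular to approach
        label, _ = interactions.classify_ch_pi(c, h, ring)
        assert label == "none"

    def test_galactose_face_donors_subset(self):
        """Pose with the C3/C4/C5/C6 face down: every reported donor comes
        from that face."""
        top, coords = _galactose_on_benzene()
        records = interactions.find_ch_pi(top, coords)
        assert len(records) > 0
        assert {r.donor_name for r in records} <= {"C3", "C4", "C5", "C6"}

    def test_reconstructed_hydrogens_when_absent(self):
        """Stripping hydrogens still finds CH/pi contacts via ideal-geometry
        reconstruction (positions differ, the contact face persists)."""
        top, coords = _galactose_on_benzene()
        keep = [i for i in range(top.n_atoms) if top.elements[i] != "H"]
        remap = {a: i for i, a in enumerate(keep)}
        bonds = np.array([[remap[a], remap[b]] for a, b in top.bonds
                          if a in remap and b in remap])
        heavy = trajio.MolecularTopology(
            [top.names[i] for i in keep], [top.elements[i] for i in keep],
            top.resids[keep], [top.resnames[i] for i in keep], bonds)
        records = interactions.find_ch_pi(heavy, coords[keep])
        assert len(records) > 0
        assert all(r.kind == "ch_pi" for r in records)


class TestDetectHbonds:
    def _hydroxyl_pair(self, d_oo, angle_linear=True):
        """Two O-H...O fragments in separate molecules."""
        names = ["O1", "H1", "C1", "O2", "C2"]
        elements = ["O", "H", "C", "O", "C"]
        bonds = np.array([[0, 1], [0, 2], [3, 4]])
        o1 = np.zeros(3)
        h1 = np.array([0.96, 0.0, 0.0]) if angle_linear \
            else np.array([0.0, 0.96, 0.0])
        o2 = np.array([d_oo, 0.0, 0.0])
        coords = np.stack([o1, h1, o1 + np.array([-1.4, 0, 0]), o2,
                           o2 + np.array([1.4, 0, 0])])
        top = trajio.MolecularTopology(names, elements,
                                       np.array([0, 0, 0, 1, 1]),
                                       ["MOA"] * 3 + ["MOB"] * 2, bonds)
        return top, coords

    def test_ideal_linear_hbond(self):
        top, coords = self._hydroxyl_pair(2.8)
        records = interactions.detect_hbonds(top, coords)
        assert len(records) == 1
        assert records[0].metrics["angle_deg"] == pytest.approx(180.0)

    def test_too_long_rejected(self):
        top, coords = self._hydroxyl_pair(4.5)
        assert interactions.detect_hbonds(top, coords) == []

    def test_count_matches_naive_pair_scan(self):
        """Random field of explicit O-H groups: count equals an independent
        O(n^2) scan with its own trigonometry."""
        rng = np.random.default_rng(23)
        n_mol = 25
        names, elements, resids, bonds, coords = [], [], [], [], []
        for m in range(n_mol):
            o = rng.uniform(-8, 8, 3)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            h = o + 0.96 * direction
            c = o - 1.4 * direction
            base = len(names)
            names += [f"O{m}", f"H{m}", f"C{m}"]
            elements += ["O", "H", "C"]
            resids += [m] * 3
            bonds += [[base, base + 1], [base, base + 2]]
            coords += [o, h, c]
        top = trajio.MolecularTopology(names, elements, np.array(resids),
                                       ["MOL"] * len(names), np.array(bonds))
        coords = np.array(coords)
        records = interactions.detect_hbonds(top, coords)
        # independent scan
        expected = 0
        for d in range(n_mol):
            for a in range(n_mol):
                if d == a:
                    continue
                od, hd, oa = coords[3 * d], coords[3 * d + 1], coords[3 * a]
                if np.linalg.norm(oa - od) > 3.5:
                    continue
                v1 = od - hd
                v2 = oa - hd
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1)
                                           * np.linalg.norm(v2))
                theta = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if theta >= 130.0:
                    expected += 1
        assert len(records) == expected
        assert expected > 0


    def test_groove_pose_count_matches_closed_form_scan(self):
        """Hydroxylated galactotriose laid over a Yariv mimic: the detected
        hydrogen-bond count equals an O(n^2) scan that evaluates the
        best-rotamer D-H...A angle by closed-form scalar trigonometry."""
        import math

        ynames, yelems, ybonds, yxyz = synth.build_yariv_mimic()
        gtop, gtraj, gtruth = synth.gen_galactan_chain(
            n_units=3, with_hydroxyls=True)
        gxyz = gtraj.coords[0] + np.array([0.0, 0.0, 2.9])
        ny = len(ynames)
        top = trajio.MolecularTopology(
            list(ynames) + gtop.names, list(yelems) + gtop.elements,
            np.concatenate([np.zeros(ny, int), gtop.resids + 1]),
            ["YRV"] * ny + gtop.resnames,
            np.vstack([ybonds, gtop.bonds + ny]))
        coords = np.vstack([yxyz, gxyz])
        records = interactions.detect_hbonds(top, coords)

        heavy_nbrs = {i: [int(j) for j in top.neighbors(i)
                          if top.elements[j] != "H"]
                      for i in range(top.n_atoms)}
        expected = 0
        for d in range(top.n_atoms):
            if top.elements[d] != "O" or len(heavy_nbrs[d]) != 1:
                continue   # only hydroxyl-like O can donate without H
            c = heavy_nbrs[d][0]
            for a in range(top.n_atoms):
                if a == d or top.elements[a] not in ("O", "N"):
                    continue
                if top.molecule_of[a] == top.molecule_of[d]:
                    continue
                r = np.linalg.norm(coords[a] - coords[d])
                if r > 3.5:
                    continue
                u = coords[d] - coords[c]
                av = coords[a] - coords[d]
                beta = math.degrees(math.acos(
                    np.clip(np.dot(u, av) / (np.linalg.norm(u) * r), -1, 1)))
                gamma = math.radians(abs(beta - (180.0 - 109.5)))
                L = 0.96
                # cos of angle at H between H->D and H->A, scalar form
                ha = math.sqrt(r * r + L * L - 2 * r * L * math.cos(gamma))
                cos_theta = (L - r * math.cos(gamma)) / ha
                theta = 180.0 - math.degrees(math.acos(
                    np.clip(-cos_theta, -1, 1)))
                if theta >= 130.0:
                    expected += 1
        assert len(records) == expected
        assert expected > 0


class TestStackTopology:
    def test_ideal_four_stack_is_a_path_in_generator_order(
            self, yariv_tetramer_twisted):
        top, traj, truth = yariv_tetramer_twisted
        rings = interactions.detect_rings(top, traj.coords[0])
        st = interactions.stack_topology(rings)
        assert sorted(map(tuple, st.graph.edges)) == [(0, 1), (1, 2), (2, 3)]
        assert st.order in ([0, 1, 2, 3], [3, 2, 1, 0])

    def test_two_distant_dimers_two_components(self):
        import networkx as nx
        top1, traj1, _ = synth.gen_rigid_stack(n_units=2, seed=0)
        names, elements, bonds, _ = synth.build_yariv_mimic()
        n1 = top1.n_atoms
        nu = len(names)
        top = trajio.MolecularTopology(
            top1.names + list(names) * 2, top1.elements + list(elements) * 2,
            np.concatenate([top1.resids, [2] * nu, [3] * nu]),
            top1.resnames + ["YRV"] * (2 * nu),
            np.vstack([top1.bonds,
                       np.asarray(bonds) + n1, np.asarray(bonds) + n1 + nu]))
        far = traj1.coords[0] + np.array([60.0, 0.0, 0.0])
        coords = np.vstack([traj1.coords[0], far])
        rings = interactions.detect_rings(top, coords)
        st = interactions.stack_topology(rings)
        assert nx.number_connected_components(
            st.graph.subgraph([n for n in st.graph
                               if st.graph.degree[n] > 0])) == 2

    def test_distant_monomers_no_edges(self):
        top, traj, _ = synth.gen_rigid_stack(n_units=2, rise=20.0, seed=0)
        rings = interactions.detect_rings(top, traj.coords[0])
        st = interactions.stack_topology(rings)
        assert st.graph.number_of_edges() == 0
        assert st.order == []

    def test_single_unit_empty_profile(self):
        top, traj, _ = synth.gen_rigid_stack(n_units=1, seed=0)
        rings = interactions.detect_rings(top, traj.coords[0])
        st = interactions.stack_topology(rings)
        assert interactions.irregularity_profile(st) == []
        assert st.twists == {}

    def test_adjacent_central_rings_parallel_in_ideal_stack(
            self, yariv_dimer):
        top, traj, _ = yariv_dimer
        rings = interactions.detect_rings(top, traj.coords[0])
        centrals = [r for r in rings if r.role == "central"]
        label, _ = interactions.classify_pi_pi(*centrals)
        assert label == "pi_pi_parallel"


class TestStackTwist:
    def test_generated_twist_recovered_on_every_pair(
            self, yariv_tetramer_twisted):
        top, traj, truth = yariv_tetramer_twisted
        rings = interactions.detect_rings(top, traj.coords[0])
        st = interactions.stack_topology(rings)
        assert len(st.twists) == 3
        for t in st.twists.values():
            assert t == pytest.approx(10.0, abs=0.1)

    def test_zero_twist(self, yariv_dimer):
        top, traj, _ = yariv_dimer
        rings = interactions.detect_rings(top, traj.coords[0])
        st = interactions.stack_topology(rings)
        for t in st.twists.values():
            assert t == pytest.approx(0.0, abs=1e-9)

    def test_mirror_reflection_flips_all_twist_signs(
            self, yariv_tetramer_twisted):
        top, traj, _ = yariv_tetramer_twisted
        rings = interactions.detect_rings(top, traj.coords[0])
        t0 = list(interactions.stack_topology(rings).twists.values())
        mirrored = traj.coords[0].copy()
        mirrored[:, 0] *= -1.0
        rings_m = interactions.detect_rings(top, mirrored)
        t1 = list(interactions.stack_topology(rings_m).twists.values())
        np.testing.assert_allclose(sorted(t1), sorted(-t for t in t0),
                                   atol=1e-9)
        assert interactions.handedness(t1) == -interactions.handedness(t0)


class TestIrregularityProfile:
    def test_ideal_stack_profile(self, yariv_tetramer_twisted):
        top, traj, _ = yariv_tetramer_twisted
        rings = interactions.detect_rings(top, traj.coords[0])
        st = interactions.stack_topology(rings)
        for entry in interactions.irregularity_profile(st):
            assert entry["angle_deg"] == pytest.approx(0.0, abs=1e-6)
            assert entry["rise_A"] == pytest.approx(3.5, abs=1e-6)
            assert entry["slip_A"] == pytest.approx(0.0, abs=1e-6)

    def test_jittered_stack_has_larger_mean_angle(self):
        """Orientation jitter of sigma = 10 deg raises the mean interplanar
        angle well above the ideal stack's zero."""
        angles_ideal, angles_jit = [], []
        for seed in range(5):
            for jitter, sink in ((0.0, angles_ideal), (10.0, angles_jit)):
                top, traj, _ = synth.gen_rigid_stack(
                    n_units=4, twist_deg=0.0, jitter_angle_deg=jitter,
                    n_frames=4, seed=seed)
                for f in range(traj.n_frames):
                    rings = interactions.detect_rings(top, traj.coords[f])
                    st = interactions.stack_topology(rings, thresholds=
                        interactions.Thresholds(pi_pi_angle=45.0))
                    sink += [e["angle_deg"] for e in st.profile]
        assert np.mean(angles_jit) > np.mean(angles_ideal) + 2.0


class TestRigidInvariance:
    def test_all_classifier_counts_invariant_under_rigid_motion(self):
        """pi-pi, CH/pi and H-bond counts are unchanged by 20 random global
        rigid transformations."""
        top, coords = _galactose_on_benzene()
        rng = np.random.default_rng(31)

        def census(c):
            rings = interactions.detect_rings(top, c)
            aromatic = [r for r in rings if r.aromatic]
            n_pp = sum(1 for i, ra in enumerate(aromatic)
                       for rb in aromatic[i + 1:]
                       if interactions.classify_pi_pi(ra, rb)[0] != "none")
            n_chpi = len(interactions.find_ch_pi(top, c, rings))
            n_hb = len(interactions.detect_hbonds(top, c))
            return n_pp, n_chpi, n_hb

        base = census(coords)
        assert base[1] > 0
        for _ in range(20):
            R, t = random_rigid(rng)
            assert census(coords @ R.T + t) == base
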