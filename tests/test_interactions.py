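"""Interaction-geometry classifiers against brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import idpens as ip
from idpens import _geometry as g
from idpens.interactions import DEFAULT_CUTOFFS, _pair_within

NM = 0.1


# ---------------------------------------------------------------------------
# Independent brute-force oracles (pure double loops, no shared code paths)
# ---------------------------------------------------------------------------

def oracle_contact(xa, xb, cutoff):
    return any(np.linalg.norm(p - q) <= cutoff for p in xa for q in xb)


def oracle_hbonds(frame, top, cutoffs=DEFAULT_CUTOFFS):
    found = []
    for d in range(top.n_atoms):
        if not top.donor[d]:
            continue
        for h in top.hydrogen_links.get(d, []):
            for a in range(top.n_atoms):
                if not top.acceptor[a] or a == d:
                    continue
                if top.atom_residue[a] == top.atom_residue[d]:
                    continue
                r_ha = np.linalg.norm(frame[a] - frame[h])
                if r_ha > cutoffs.hbond_distance:
                    continue
                v1 = frame[d] - frame[h]
                v2 = frame[a] - frame[h]
                ang = np.degrees(np.arccos(np.clip(
                    v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2),
                    -1, 1)))
                if ang > cutoffs.hbond_angle:
                    found.append((d, h, a))
    return found


def oracle_ring(frame, ids_a, ids_b):
    def plane(ids):
        xyz = frame[np.asarray(ids)]
        c = xyz.mean(0)
        u, s, vt = np.linalg.svd(xyz - c)
        return c, vt[2]
    ca, na = plane(ids_a)
    cb, nb = plane(ids_b)
    r = np.linalg.norm(cb - ca)
    theta = np.degrees(np.arccos(min(abs(na @ nb), 1.0)))
    phi = np.degrees(np.arccos(min(abs(na @ (cb - ca) / r), 1.0)))
    return r, theta, phi


# ---------------------------------------------------------------------------
# Boundary behavior
# ---------------------------------------------------------------------------

def _two_atom_frame(dist_nm):
    return np.array([[0.0, 0, 0], [dist_nm, 0, 0]])


@pytest.mark.parametrize("d_a,expected", [(5.99, True), (6.0, True),
                                          (6.01, False)])
def test_contact_cutoff_inclusive(d_a, expected):
    frame = _two_atom_frame(d_a * NM)
    assert _pair_within(frame[:1], frame[1:], DEFAULT_CUTOFFS.contact) is expected


@pytest.mark.parametrize("angle,expected", [(180.0, True), (160.0, True),
                                            (140.0, False)])
def test_hbond_angle_criterion(angle, expected):
    # donor O, hydrogen, acceptor O with controlled D-H...A angle
    top = ip.Topology(residue_numbers=[1, 2], residue_names=["SER", "SER"],
                      atom_names=["OG", "HG", "OX"],
                      atom_residue=np.array([0, 0, 1]),
                      elements=["O", "H", "O"],
                      donor=np.array([True, False, False]),
                      acceptor=np.array([True, False, True]),
                      hydrophobic=np.zeros(3, bool),
                      hydrogen_links={0: [1]})
    h = np.zeros(3)
    d = np.array([0.1, 0.0, 0.0])
    t = np.deg2rad(180.0 - angle)
    a = 0.2 * np.array([np.cos(np.pi - t) * -1, np.sin(t), 0.0])
    a = np.array([-0.2 * np.cos(t), 0.2 * np.sin(t), 0.0])
    frame = np.stack([d, h, a])
    result = ip.hydrogen_bonds(frame, top)
    assert bool(result) is expected
    assert result == oracle_hbonds(frame, top)


def test_hydrophobic_excludes_non_carbon_pairs(random_frames):
    top = random_frames.topology
    # N-C pair at 3 A must not trigger: construct directly, atoms spread out
    n1 = top.atom_names.index("N1")
    lc = top.atom_names.index("LC7")
    frame = (np.arange(top.n_atoms)[:, None] + 5) * np.array([10.0, 0.0, 0.0])
    frame[n1] = [0, 0, 0]
    frame[lc] = [0.3, 0, 0]
    assert not ip.hydrophobic_contact(frame, top, 0)
    c1 = top.atom_names.index("C1")
    frame[c1] = [0.1, 0, 0]
    assert ip.hydrophobic_contact(frame, top, 0)


class TestRingGeometry:
    @staticmethod
    def _hexagon(radius=0.14):
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        return radius * np.stack([np.cos(ang), np.sin(ang),
                                  np.zeros(6)], axis=1)

    def test_parallel_offset_construction(self):
        a = self._hexagon()
        b = a + np.array([0, 0, 0.35])
        frame = np.concatenate([a, b])
        geom = ip.ring_geometry(frame, np.arange(6), np.arange(6, 12))
        assert geom.theta == pytest.approx(0.0, abs=1e-9)
        assert geom.phi == pytest.approx(0.0, abs=1e-9)
        assert geom.r == pytest.approx(0.35, abs=1e-12)
        assert ip.classify_stacking(geom) == "parallel"

    def test_perpendicular_t_construction(self):
        a = self._hexagon()
        b = self._hexagon() @ np.array([[1.0, 0, 0], [0, 0, -1], [0, 1, 0]])
        b = b + np.array([0, 0, 0.50])
        frame = np.concatenate([a, b])
        geom = ip.ring_geometry(frame, np.arange(6), np.arange(6, 12))
        assert geom.theta == pytest.approx(90.0, abs=1e-6)
        assert geom.phi == pytest.approx(0.0, abs=1e-6)
        assert ip.classify_stacking(geom) == "t_stack"

    def test_far_rings_unclassified(self):
        a = self._hexagon()
        b = a + np.array([0, 0, 1.0])
        frame = np.concatenate([a, b])
        geom = ip.ring_geometry(frame, np.arange(6), np.arange(6, 12))
        assert ip.classify_stacking(geom) == "none"

    @pytest.mark.parametrize("theta,expected", [(59.0, "parallel"),
                                                (60.5, "none"),
                                                (76.0, "t_stack")])
    def test_theta_boundaries(self, theta, expected):
        a = self._hexagon()
        t = np.deg2rad(theta)
        rot = np.array([[1, 0, 0], [0, np.cos(t), -np.sin(t)],
                        [0, np.sin(t), np.cos(t)]])
        b = self._hexagon() @ rot.T + np.array([0, 0, 0.40])
        frame = np.concatenate([a, b])
        geom = ip.ring_geometry(frame, np.arange(6), np.arange(6, 12))
        assert geom.theta == pytest.approx(theta, abs=1e-6)
        assert ip.classify_stacking(geom) == expected

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(12)
        a = self._hexagon()
        b = self._hexagon() + rng.normal(size=3) * 0.3
        frame = np.concatenate([a, b])
        ref = ip.ring_geometry(frame, np.arange(6), np.arange(6, 12))
        R = g.random_rotation(rng)
        moved = frame @ R.T + rng.normal(size=3)
        got = ip.ring_geometry(moved, np.arange(6), np.arange(6, 12))
        assert got.r == pytest.approx(ref.r, abs=1e-9)
        assert got.theta == pytest.approx(ref.theta, abs=1e-7)
        assert got.phi == pytest.approx(ref.phi, abs=1e-7)

    def test_collinear_ring_rejected(self):
        frame = np.stack([[0, 0, 0], [1, 0, 0], [2, 0, 0],
                          [0, 1, 0], [1, 1, 0], [0, 0, 1.0]]).astype(float)
        with pytest.raises(ValueError):
            ip.ring_geometry(frame, np.arange(3), np.arange(3, 6))


class TestOracleEquivalence:
    """Every classifier must agree with an independent all-pairs brute force
    on random annotated frames."""

    def test_contacts_and_hydrophobic(self, random_frames):
        top = random_frames.topology
        elements = np.array(top.elements)
        lig = np.nonzero(top.ligand_mask)[0]
        lig_heavy = lig[top.heavy[lig]]
        lig_ccl = lig[np.isin(elements[lig], ("C", "CL"))]
        for f in range(random_frames.n_frames):
            xyz = random_frames.coordinates[f]
            for r in top.protein_residue_indices():
                res_heavy = np.nonzero((top.atom_residue == r) & top.heavy)[0]
                res_c = np.nonzero((top.atom_residue == r)
                                   & (elements == "C"))[0]
                assert ip.residue_contact(xyz, top, r, lig) == oracle_contact(
                    xyz[res_heavy], xyz[lig_heavy], DEFAULT_CUTOFFS.contact)
                assert ip.hydrophobic_contact(xyz, top, r) == oracle_contact(
                    xyz[res_c], xyz[lig_ccl], DEFAULT_CUTOFFS.hydrophobic)

    def test_hydrogen_bonds(self, random_frames):
        top = random_frames.topology
        for f in range(random_frames.n_frames):
            xyz = random_frames.coordinates[f]
            assert sorted(ip.hydrogen_bonds(xyz, top)) == sorted(
                oracle_hbonds(xyz, top))

    def test_ring_descriptors(self, random_frames):
        top = random_frames.topology
        pring = top.ring_groups["PHE_ring"]
        lring = top.ring_groups["LIG_ring"]
        for f in range(random_frames.n_frames):
            xyz = random_frames.coordinates[f]
            geom = ip.ring_geometry(xyz, pring, lring)
            r, theta, phi = oracle_ring(xyz, pring, lring)
            assert geom.r == pytest.approx(r, abs=1e-9)
            assert geom.theta == pytest.approx(theta, abs=1e-6)
            assert geom.phi == pytest.approx(phi, abs=1e-6)

    def test_bound_fraction_counts(self, random_frames):
        top = random_frames.topology
        lig = np.nonzero(top.ligand_mask & top.heavy)[0]
        prot = np.nonzero(~top.ligand_mask & top.heavy)[0]
        expected = np.mean([
            oracle_contact(random_frames.coordinates[f][lig],
                           random_frames.coordinates[f][prot],
                           DEFAULT_CUTOFFS.contact)
            for f in range(random_frames.n_frames)])
        assert ip.bound_fraction(random_frames) == pytest.approx(expected)


def test_hydrophobic_subset_of_contact(random_frames):
    """A 4 A carbon pair is always within the 6 A contact cutoff."""
    top = random_frames.topology
    for f in range(random_frames.n_frames):
        xyz = random_frames.coordinates[f]
        for r in top.protein_residue_indices():
            if ip.hydrophobic_contact(xyz, top, r):
                lig = np.nonzero(top.ligand_mask)[0]
                assert ip.residue_contact(xyz, top, r, lig)


def test_bound_fraction_hand_count():
    """10 frames, ligand within reach in exactly 4."""
    ens = _toy_liganded(bound_frames_count=4, n_frames=10)
    assert ip.bound_fraction(ens) == pytest.approx(0.4)
    far = _toy_liganded(bound_frames_count=0, n_frames=5)
    assert ip.bound_fraction(far) == 0.0


def _toy_liganded(bound_frames_count, n_frames):
    top = ip.Topology(residue_numbers=[1, 2], residue_names=["ALA", "LIG"],
                      atom_names=["CA", "LC"], atom_residue=np.array([0, 1]),
                      elements=["C", "C"], donor=np.zeros(2, bool),
                      acceptor=np.zeros(2, bool),
                      hydrophobic=np.ones(2, bool), ligand_atoms=[1])
    coords = np.zeros((n_frames, 2, 3))
    for f in range(n_frames):
        coords[f, 1, 0] = 0.5 if f < bound_frames_count else 5.0
    return ip.Ensemble(top, coords)


class TestProfile:
    def test_single_frame_populations_binary(self, liganded_ensemble):
        ens, _ = liganded_ensemble
        prof = ip.interaction_profile(ens, frame_subset=np.array([0]))
        vals = prof.populations.to_numpy()
        assert set(np.round(vals.ravel(), 12)) <= {0.0, 1.0}

    def test_site_neighbors_always_in_contact(self, liganded_ensemble):
        ens, _ = liganded_ensemble
        prof = ip.interaction_profile(ens)
        site_num = ens.topology.residue_numbers[13]
        for rn in (site_num - 1, site_num, site_num + 1):
            assert prof.populations["contact"].loc[rn] == pytest.approx(1.0)

    def test_profile_equals_per_frame_average(self, liganded_ensemble):
        ens, _ = liganded_ensemble
        sub = np.arange(10)
        prof = ip.interaction_profile(ens, frame_subset=sub)
        top = ens.topology
        lig = np.nonzero(top.ligand_mask)[0]
        lig_heavy = lig[top.heavy[lig]]
        for r in list(top.protein_residue_indices())[:8]:
            res_heavy = np.nonzero((top.atom_residue == r) & top.heavy)[0]
            manual = np.mean([
                oracle_contact(ens.coordinates[f][res_heavy],
                               ens.coordinates[f][lig_heavy],
                               DEFAULT_CUTOFFS.contact) for f in sub])
            assert prof.populations["contact"].loc[
                top.residue_numbers[r]] == pytest.approx(manual)

    def test_profile_r2_reference_values(self, liganded_ensemble):
        ens, _ = liganded_ensemble
        prof = ip.interaction_profile(ens)
        assert ip.profile_r2(prof, prof) == pytest.approx(1.0)
        # scale-free: doubling populations leaves squared Pearson at 1
        import copy
        double = copy.deepcopy(prof)
        double.populations = prof.populations * 0.5
        assert ip.profile_r2(prof, double) == pytest.approx(1.0)

    def test_profile_r2_hand_computed(self):
        a = np.array([0.1, 0.4, 0.9, 0.3, 0.5])
        b = np.array([0.2, 0.5, 0.7, 0.2, 0.6])
        r = (np.corrcoef(a, b)[0, 1]) ** 2
        import pandas as pd
        pa = ip.InteractionProfile([1, 2, 3, 4, 5],
                                   pd.DataFrame({"contact": a}), 5)
        pb = ip.InteractionProfile([1, 2, 3, 4, 5],
                                   pd.DataFrame({"contact": b}), 5)
        assert ip.profile_r2(pa, pb) == pytest.approx(r, abs=1e-12)

    def test_zero_variance_profile_warns_nan(self):
        import pandas as pd
        pa = ip.InteractionProfile([1, 2], pd.DataFrame({"contact": [0.5, 0.5]}), 2)
        pb = ip.InteractionProfile([1, 2], pd.DataFrame({"contact": [0.1, 0.9]}), 2)
        with pytest.warns(UserWarning):
            assert np.isnan(ip.profile_r2(pa, pb))


def test_contact_map_excludes_sequence_neighbors(coil_ensemble):
    ens, _ = coil_ensemble
    cm = ip.contact_map(ens, frame_subset=np.arange(3))
    vals = cm.to_numpy()
    n = vals.shape[0]
    for i in range(n):
        for j in range(max(0, i - 2), min(n, i + 3)):
            assert vals[i, j] == 0.0
    assert np.allclose(vals, vals.T)
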