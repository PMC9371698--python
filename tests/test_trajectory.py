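"""Superposition, RMSF, distances, SASA/ΔSASA, and rupture detection."""

import numpy as np
import pytest

import cadforce as cf
from cadforce.structures import Selection, Structure, Trajectory
from cadforce.trajectory import (
    backbone_rmsd,
    com_distance,
    delta_sasa,
    delta_sasa_trace,
    kabsch_superpose,
    min_pair_distance_trace,
    rmsd_timeseries,
    rmsf,
    rupture_frame,
    salt_bridge_formed,
    salt_bridge_trace,
    shrake_rupley_sasa,
)
from tests.conftest import make_structure


def quaternion_rmsd(mobile, reference):
    """Independent superposition oracle via Horn's quaternion method."""
    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(key)[-1]
    n = len(a)
    msd = ((a**2).sum() + (b**2).sum() - 2 * lam) / n
    return np.sqrt(max(msd, 0.0))


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    return rot, rng.normal(0, 10, 3)


class TestKabsch:
    def test_identical_sets_zero_rmsd(self, rng):
        pts = rng.normal(size=(12, 3))
        *_, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_zero_rmsd(self, rng):
        pts = rng.normal(size=(12, 3))
        rot, t = random_rigid_transform(rng)
        *_, rmsd = kabsch_superpose(pts @ rot.T + t, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(10):
            a = rng.normal(size=(20, 3))
            b = a + rng.normal(0, 0.5, (20, 3))
            *_, rmsd = kabsch_superpose(a, b)
            assert rmsd == pytest.approx(quaternion_rmsd(a, b), abs=1e-9)

    def test_rotation_is_proper(self, rng):
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        rot, *_ = kabsch_superpose(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_collinear_degenerate_error(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line + 1.0)


class TestBackboneRMSD:
    def _protein(self, shift=0.0):
        names = ["N", "CA", "C", "O"] * 5
        res = np.repeat(np.arange(1, 6), 4)
        rng = np.random.default_rng(4)
        coords = rng.normal(0, 5, (20, 3)) + shift
        return make_structure(
            coords, atom_name=names, res_ids=res, element="C"
        )

    def test_self_rmsd_zero(self):
        s = self._protein()
        assert backbone_rmsd(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_translation_removed(self):
        s = self._protein()
        t = Structure(
            element=s.element,
            atom_name=s.atom_name,
            res_name=s.res_name,
            res_id=s.res_id,
            chain_id=s.chain_id,
            coords=s.coords + np.array([5.0, 0.0, 0.0]),
        )
        assert backbone_rmsd(s, t) == pytest.approx(0.0, abs=1e-9)

    def test_unmatched_atoms_dropped(self):
        s = self._protein()
        # second structure missing residue 5 entirely
        keep = s.res_id < 5
        t = s.subset(np.flatnonzero(keep))
        assert backbone_rmsd(s, t) == pytest.approx(0.0, abs=1e-12)

    def test_too_few_matched_atoms(self):
        s = self._protein()
        t = s.subset(np.array([0, 1]))
        with pytest.raises(ValueError, match="matched"):
            backbone_rmsd(s, t)


class TestRMSF:
    def test_static_trajectory_all_zero(self, anchor_protein):
        frames = np.repeat(anchor_protein.coords[None], 10, axis=0)
        traj = Trajectory(anchor_protein, frames)
        series = rmsf(traj, selection=Selection(atom_names=("CA",)), window=(0, 9))
        assert np.allclose(series.to_numpy(), 0.0)

    def test_sigma_sqrt3_recovery(self, anchor_protein):
        """One residue fluctuating at σ = 0.1 nm shows RMSF ≈ σ√3."""
        spec = cf.FluctuationSpec(
            reference=anchor_protein,
            per_residue_sd={21: 0.1},
            n_frames=10_000,
            seed=3,
        )
        traj = cf.generate_fluctuation_trajectory(spec)
        series = rmsf(
            traj, selection=Selection(atom_names=("CA",)), window=(0, 9999)
        )
        assert series[21] == pytest.approx(0.1 * 10 * np.sqrt(3), rel=0.05)

    def test_rigid_rotation_invariance(self, anchor_protein, rng):
        spec = cf.FluctuationSpec(
            reference=anchor_protein,
            per_residue_sd={5: 0.05, 30: 0.15},
            n_frames=300,
            seed=9,
        )
        traj = cf.generate_fluctuation_trajectory(spec)
        base = rmsf(traj, selection=Selection(atom_names=("CA",)), window=(0, 299))
        rotated = traj.frames.copy()
        for f in range(rotated.shape[0]):
            rot, t = random_rigid_transform(rng)
            rotated[f] = rotated[f] @ rot.T + t
        series = rmsf(
            Trajectory(anchor_protein, rotated),
            selection=Selection(atom_names=("CA",)),
            window=(0, 299),
        )
        assert np.allclose(series.to_numpy(), base.to_numpy(), atol=1e-6)

    def test_single_frame_window_error(self, anchor_protein):
        traj = Trajectory(anchor_protein, anchor_protein.coords[None])
        with pytest.raises(ValueError):
            rmsf(traj, selection=Selection(atom_names=("CA",)), window=(0, 0))


class TestMinPairDistance:
    def test_three_four_five(self):
        top = make_structure([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]], chain=["A", "B"])
        traj = Trajectory(top, top.coords[None])
        trace = min_pair_distance_trace(traj, np.array([0]), np.array([1]))
        assert trace[0] == pytest.approx(5.0)

    def test_overlapping_groups_rejected(self):
        top = make_structure([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        traj = Trajectory(top, top.coords[None])
        with pytest.raises(ValueError, match="disjoint"):
            min_pair_distance_trace(traj, np.array([0, 1]), np.array([1]))

    def test_brute_force_oracle_agreement(self, rng):
        coords = rng.normal(0, 10, (40, 3))
        top = make_structure(coords)
        frames = coords[None] + rng.normal(0, 1, (7, 40, 3))
        traj = Trajectory(top, frames)
        ia, ib = np.arange(20), np.arange(20, 40)
        trace = min_pair_distance_trace(traj, ia, ib)
        for f in range(7):
            expected = min(
                np.linalg.norm(frames[f, i] - frames[f, j])
                for i in ia
                for j in ib
            )
            assert trace[f] == pytest.approx(expected, abs=1e-9)


class TestSaltBridge:
    def test_median_verdict(self):
        t = salt_bridge_formed(np.array([3.5, 3.6, 5.0]))
        assert t.median == pytest.approx(3.6) and t.formed

    def test_boundary_is_strictly_below(self):
        assert not salt_bridge_formed(np.full(11, 4.0)).formed

    def test_frame_order_invariance(self, rng):
        trace = rng.uniform(2.0, 6.0, 101)
        a = salt_bridge_formed(trace)
        b = salt_bridge_formed(rng.permutation(trace))
        assert a.median == b.median and a.formed == b.formed

    def test_two_of_five_replicas_formed(self):
        """Replica ensemble built with 2/5 medians below 4 Å → 40% formed."""
        medians = [3.2, 3.7, 4.8, 5.5, 6.1]
        verdicts = [
            cf.salt_bridge_formed(
                cf.generate_distance_trace(m, 0.3, 2000, seed=i)
            ).formed
            for i, m in enumerate(medians)
        ]
        assert sum(verdicts) == 2
        assert sum(verdicts) / len(verdicts) == pytest.approx(0.40)

    def test_charged_atom_selection(self, salt_bridge_topology):
        traj = Trajectory(salt_bridge_topology, salt_bridge_topology.coords[None])
        t = salt_bridge_trace(traj, ("A", 13), ("B", 99))
        # closest charged pair: OE1 (0,0,0) vs NH1 (3.5,0,0)
        assert t.median == pytest.approx(3.5)
        assert t.formed and t.label == "A13-B99"

    def test_uncharged_residue_rejected(self):
        top = make_structure([[0.0, 0.0, 0.0]], res_name="GLY", res_ids=[1])
        traj = Trajectory(top, top.coords[None])
        with pytest.raises(ValueError, match="charged"):
            salt_bridge_trace(traj, ("A", 1), ("A", 1))


class TestSASA:
    def test_single_sphere_analytic(self, carbon_sphere):
        result = shrake_rupley_sasa(carbon_sphere)
        assert result.total == pytest.approx(4 * np.pi * 3.3**2, rel=0.01)

    def test_disjoint_additivity(self):
        s = make_structure(
            [[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]], radius=[1.9, 1.9]
        )
        pair = shrake_rupley_sasa(s).total
        single = shrake_rupley_sasa(s.subset(np.array([0]))).total
        assert pair == pytest.approx(2 * single, rel=1e-9)

    def test_overlapping_spheres_cap_formula(self):
        """Two equal spheres at distance d: buried caps of height r − d/2."""
        d, rvdw, probe = 3.0, 1.9, 1.4
        r = rvdw + probe
        s = make_structure(
            [[0.0, 0.0, 0.0], [d, 0.0, 0.0]], radius=[rvdw, rvdw]
        )
        total = shrake_rupley_sasa(s, probe=probe).total
        expected = 2 * (4 * np.pi * r**2 - 2 * np.pi * r * (r - d / 2))
        assert total == pytest.approx(expected, rel=0.02)

    def test_missing_radius_names_atom(self):
        s = make_structure([[0.0, 0.0, 0.0]], element="XX", res_ids=[7])
        with pytest.raises(ValueError, match="7"):
            shrake_rupley_sasa(s)

    def test_quadrature_convergence(self, rng):
        coords = rng.normal(0, 4, (50, 3))
        s = make_structure(coords, radius=np.full(50, 1.7))
        coarse = shrake_rupley_sasa(s, n_points=960).total
        fine = shrake_rupley_sasa(s, n_points=3840).total
        assert abs(fine - coarse) / fine <= 0.005

    def test_rigid_transform_invariance(self, rng):
        coords = rng.normal(0, 4, (20, 3))
        s = make_structure(coords, radius=np.full(20, 1.7))
        rot, t = random_rigid_transform(rng)
        s2 = make_structure(coords @ rot.T + t, radius=np.full(20, 1.7))
        a = shrake_rupley_sasa(s).total
        b = shrake_rupley_sasa(s2).total
        # quadrature grid is fixed in space, so invariance holds only to
        # the quadrature tolerance
        assert b == pytest.approx(a, rel=0.005)


class TestDeltaSASA:
    def test_far_bodies_zero(self):
        a = make_structure([[0.0, 0.0, 0.0]], radius=[1.9], chain="A")
        b = make_structure([[100.0, 0.0, 0.0]], radius=[1.9], chain="B")
        assert delta_sasa(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_coincident_spheres_pathological(self):
        a = make_structure([[0.0, 0.0, 0.0]], radius=[1.9], chain="A")
        b = make_structure([[0.0, 0.0, 0.0]], radius=[1.9], chain="B")
        single = shrake_rupley_sasa(a).total
        assert delta_sasa(a, b) == pytest.approx(single, rel=1e-9)

    def test_contact_pair_matches_cap_oracle(self):
        d, rvdw, probe = 4.0, 1.9, 1.4
        r = rvdw + probe
        a = make_structure([[0.0, 0.0, 0.0]], radius=[rvdw], chain="A")
        b = make_structure([[d, 0.0, 0.0]], radius=[rvdw], chain="B")
        expected = 2 * 2 * np.pi * r * (r - d / 2)  # two buried caps
        assert delta_sasa(a, b, probe=probe) == pytest.approx(expected, rel=0.02)

    def test_duplicate_identifiers_rejected(self):
        a = make_structure([[0.0, 0.0, 0.0]], radius=[1.9])
        with pytest.raises(ValueError, match="disjoint"):
            delta_sasa(a, a)

    def test_nonnegative_on_random_pairs(self, rng):
        for _ in range(3):
            a = make_structure(rng.normal(0, 3, (8, 3)), radius=np.full(8, 1.7), chain="A")
            b = make_structure(
                rng.normal(6, 3, (8, 3)), radius=np.full(8, 1.7), chain="B"
            )
            assert delta_sasa(a, b) >= -1.0  # quadrature tolerance


class TestRuptureFrame:
    def test_first_frame_at_or_below_tolerance(self):
        assert rupture_frame(np.array([50.0, 20.0, 0.0, 0.0]), 0.0) == 3

    def test_none_when_never_ruptures(self):
        assert rupture_frame(np.array([50.0, 40.0, 30.0]), 1.0) is None

    def test_separating_dimer_ground_truth(self):
        a = make_structure([[0.0, 0.0, 0.0]], radius=[1.9], chain="A")
        b = make_structure([[2.5, 0.0, 0.0]], radius=[1.9], chain="B")
        traj = cf.generate_separating_dimer(a, b, 5, 12)
        trace = delta_sasa_trace(traj, np.array([0]), np.array([1]))
        assert rupture_frame(trace, 1.0) == 5


class TestCOMDistance:
    def test_unit_mass_pair(self):
        top = make_structure(
            [[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]], element="H", chain=["A", "B"]
        )
        traj = Trajectory(top, top.coords[None])
        d = com_distance(traj, np.array([0]), np.array([1]))
        assert d[0] == pytest.approx(5.0)

    def test_symmetric_group_vs_midpoint(self):
        top = make_structure(
            [[-1.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]],
            element=["C", "C", "H"],
        )
        traj = Trajectory(top, top.coords[None])
        d = com_distance(traj, np.array([0, 1]), np.array([2]))
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_com_oracle(self, rng):
        from cadforce.constants import ATOMIC_MASSES

        elements = rng.choice(["C", "N", "O", "S"], 12).tolist()
        coords = rng.normal(0, 5, (12, 3))
        top = make_structure(coords, element=elements)
        frames = coords[None] + rng.normal(0, 1, (4, 12, 3))
        traj = Trajectory(top, frames)
        ia, ib = np.arange(6), np.arange(6, 12)
        d = com_distance(traj, ia, ib)
        for f in range(4):
            w = np.array([ATOMIC_MASSES[e] for e in elements])
            ca = (frames[f, ia] * w[ia, None]).sum(0) / w[ia].sum()
            cb = (frames[f, ib] * w[ib, None]).sum(0) / w[ib].sum()
            assert d[f] == pytest.approx(np.linalg.norm(ca - cb), abs=1e-9)

    def test_unknown_element_error(self):
        top = make_structure([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]], element="QQ")
        traj = Trajectory(top, top.coords[None])
        with pytest.raises(KeyError):
            com_distance(traj, np.array([0]), np.array([1]))


class TestRMSDTimeseries:
    def test_reference_frame_zero(self, anchor_protein):
        frames = np.repeat(anchor_protein.coords[None], 5, axis=0)
        frames[2] += 1.0  # pure translation: removed by superposition
        traj = Trajectory(anchor_protein, frames)
        series = rmsd_timeseries(traj, reference_frame=0)
        assert series[0] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(series, 0.0, atol=1e-9)

    def test_fluctuation_plateau_matches_monte_carlo(self, anchor_protein):
        """Plateau RMSD ≈ √6·σ between two noisy frames, MC cross-check."""
        sigma_nm = 0.05
        sds = {int(r): sigma_nm for r in np.unique(anchor_protein.res_id)}
        spec = cf.FluctuationSpec(
            reference=anchor_protein, per_residue_sd=sds, n_frames=400, seed=6
        )
        traj = cf.generate_fluctuation_trajectory(spec)
        plateau = rmsd_timeseries(traj, reference_frame=0)[1:].mean()
        # Monte-Carlo oracle: fresh pairs of noisy frames, same statistic
        rng = np.random.default_rng(1234)
        mc = []
        for _ in range(200):
            f1 = anchor_protein.coords + rng.normal(0, sigma_nm * 10, (41, 3))
            f2 = anchor_protein.coords + rng.normal(0, sigma_nm * 10, (41, 3))
            mc.append(kabsch_superpose(f1, f2)[2])
        assert plateau == pytest.approx(np.mean(mc), rel=0.05)
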