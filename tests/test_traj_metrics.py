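"""Trajectory statistics against closed forms and independent oracles."""

import numpy as np
import pytest

from fkbpscreen.sasa import shrake_rupley
from fkbpscreen.synth import PlantedTrajSpec, gen_trajectory
from fkbpscreen.traj import (
    HbondPair,
    TorsionSpec,
    cluster_frames,
    hbond_occupancy,
    hbond_series,
    kabsch,
    radius_of_gyration,
    rmsd_series,
    rmsf,
    sasa_series,
    superpose,
    torsion_series,
)
from fkbpscreen.traj.metrics import DegenerateGeometryError, dihedral

from conftest import make_trajectory


def quaternion_rmsd(p, q):
    """Independent optimal-superposition RMSD via the Horn quaternion
    eigenvalue method."""
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    m = p.T @ q
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k).max()
    msd = ((p ** 2).sum() + (q ** 2).sum() - 2 * lam) / len(p)
    return float(np.sqrt(max(msd, 0.0)))


def random_rigid(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, rng.normal(scale=10.0, size=3)


class TestSuperpose:
    def test_self_fit_zero(self):
        rng = np.random.default_rng(0)
        p = rng.normal(size=(6, 3))
        assert kabsch(p, p)[2] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_zero(self):
        rng = np.random.default_rng(1)
        p = rng.normal(size=(8, 3))
        rot, t = random_rigid(rng)
        assert kabsch(p, p @ rot.T + t)[2] == pytest.approx(0.0, abs=1e-6)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        # near-planar points invite reflections; det must stay +1
        p = rng.normal(size=(5, 3)) * np.array([1.0, 1.0, 1e-4])
        q = rng.normal(size=(5, 3))
        rot, _, _ = kabsch(p, q)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.normal(size=(4, 3))
        q = rng.normal(size=(4, 3))
        assert kabsch(p, q)[2] == pytest.approx(quaternion_rmsd(p, q),
                                                abs=1e-6)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(9)
        p, q = rng.normal(size=(7, 3)), rng.normal(size=(7, 3))
        assert kabsch(p, q)[2] == pytest.approx(kabsch(q, p)[2], abs=1e-9)

    def test_collinear_selection_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch(line, line)

    def test_too_few_atoms_rejected(self):
        p = np.zeros((2, 3))
        with pytest.raises(DegenerateGeometryError):
            kabsch(p, p)

    def test_selection_argument(self):
        rng = np.random.default_rng(4)
        p = rng.normal(size=(10, 3))
        sel = np.arange(5)
        _, _, r = superpose(p, p + 0.0, selection=sel)
        assert r == pytest.approx(0.0, abs=1e-12)


class TestRmsdSeries:
    def test_static_trajectory_all_zero(self):
        frame = np.random.default_rng(0).normal(size=(6, 3))
        traj = make_trajectory(np.repeat(frame[None], 5, axis=0))
        _, vals = rmsd_series(traj, "all")
        assert np.allclose(vals, 0.0, atol=1e-12)

    def test_translated_ligand_linear_growth(self):
        rng = np.random.default_rng(1)
        protein = rng.normal(size=(8, 3)) * 5
        ligand = rng.normal(size=(3, 3)) + 20.0
        frames = []
        for f in range(4):
            lig = ligand + np.array([f * 1.0, 0.0, 0.0])
            frames.append(np.vstack([protein, lig]))
        traj = make_trajectory(
            np.array(frames),
            resnames=["ALA"] * 8 + ["LIG"] * 3,
            names=["CA"] * 8 + ["L1", "L2", "L3"],
            resids=[1] * 8 + [2] * 3)
        _, vals = rmsd_series(traj, fit_selection="protein",
                              measure_selection="ligand")
        assert np.allclose(vals, [0.0, 1.0, 2.0, 3.0], atol=1e-9)

    def test_rigid_transform_of_every_frame_invariant(self):
        traj, _ = gen_trajectory(PlantedTrajSpec(seed=3, n_frames=10))
        _, base = rmsd_series(traj, "resid 1")
        rng = np.random.default_rng(7)
        coords = traj.coords.copy()
        for f in range(len(coords)):
            rot, t = random_rigid(rng)
            coords[f] = coords[f] @ rot.T + t
        moved = make_trajectory(coords, resids=traj.resids,
                                times=traj.times)
        _, vals = rmsd_series(moved, "resid 1")
        assert np.allclose(vals, base, atol=1e-6)


class TestRmsf:
    def test_static_zero(self):
        frame = np.random.default_rng(0).normal(size=(5, 3))
        traj = make_trajectory(np.repeat(frame[None], 4, axis=0))
        _, vals = rmsf(traj, "all")
        assert np.allclose(vals, 0.0, atol=1e-12)

    def test_single_frame_zeros_with_warning(self, caplog):
        traj = make_trajectory(np.zeros((1, 4, 3)) + np.arange(12).reshape(1, 4, 3))
        _, vals = rmsf(traj, "all")
        assert np.allclose(vals, 0.0)
        assert any("single frame" in r.message for r in caplog.records)

    def test_oscillating_atom_closed_form(self):
        # prealigned frames (align=False): oscillation +/- a -> RMSF = a
        rng = np.random.default_rng(2)
        base = rng.normal(size=(10, 3)) * 10
        a = 0.7
        frames = []
        for f in range(20):
            c = base.copy()
            c[0, 0] += a if f % 2 == 0 else -a
            frames.append(c)
        traj = make_trajectory(np.array(frames))
        _, vals = rmsf(traj, "all", align=False)
        assert vals[0] == pytest.approx(a, abs=1e-12)
        assert np.allclose(vals[1:], 0.0, atol=1e-12)

    def test_isotropic_jitter_matches_sigma_sqrt3(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(50, 3)) * 20
        sigma = 0.2
        frames = base[None] + rng.normal(0, sigma, size=(2000, 50, 3))
        traj = make_trajectory(frames)
        _, vals = rmsf(traj, "all")
        expected = sigma * np.sqrt(3)
        assert np.mean(vals) == pytest.approx(expected, rel=0.05)

    def test_by_residue_averages(self):
        rng = np.random.default_rng(6)
        frames = rng.normal(size=(10, 4, 3))
        traj = make_trajectory(frames, resids=[1, 1, 2, 2],
                               resnames=["ALA"] * 4, names=["CA"] * 4)
        ids, vals = rmsf(traj, "protein", by_residue=True)
        assert list(ids) == [1, 2] and len(vals) == 2


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        traj = make_trajectory(np.zeros((1, 1, 3)))
        assert radius_of_gyration(traj, "all").average == 0.0

    def test_two_unit_masses_closed_form(self):
        coords = np.array([[[0.0, 0, 0], [2.0, 0, 0]]])
        traj = make_trajectory(coords)
        res = radius_of_gyration(traj, "all")
        assert res.average == pytest.approx(0.1)  # 1 Å in nm

    def test_uniform_ring_equals_radius(self):
        theta = np.linspace(0, 2 * np.pi, 36, endpoint=False)
        radius = 4.0
        ring = np.column_stack([radius * np.cos(theta),
                                radius * np.sin(theta),
                                np.zeros_like(theta)])
        res = radius_of_gyration(make_trajectory(ring[None]), "all")
        assert res.values[0] == pytest.approx(radius / 10.0, abs=1e-9)

    def test_matches_direct_definition(self, toy_traj):
        traj, _ = toy_traj
        res = radius_of_gyration(traj, "all")
        m = traj.masses
        for f in (0, traj.n_frames - 1):
            r = traj.coords[f]
            com = (m[:, None] * r).sum(axis=0) / m.sum()
            rg = np.sqrt((m * ((r - com) ** 2).sum(axis=1)).sum() / m.sum())
            assert res.values[f] == pytest.approx(rg / 10.0, abs=1e-9)

    def test_empty_selection_rejected(self, toy_traj):
        with pytest.raises(ValueError):
            radius_of_gyration(toy_traj[0], "protein")


class TestSasa:
    def test_isolated_atom_closed_form(self):
        area = shrake_rupley(np.zeros((1, 3)), np.array([1.7]))
        assert area[0] == pytest.approx(4 * np.pi * 3.1 ** 2, rel=1e-9)

    def test_two_sphere_analytic_cap(self):
        # equal spheres R at distance d: exposed = 4*pi*R^2 - 2*pi*R*(R-d/2)
        r_exp = 1.7 + 1.4
        d = 2.0
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        areas = shrake_rupley(coords, np.array([1.7, 1.7]), n_points=4000)
        expected = 4 * np.pi * r_exp ** 2 - 2 * np.pi * r_exp * (r_exp - d / 2)
        assert areas[0] == pytest.approx(expected, rel=0.02)
        assert areas[1] == pytest.approx(expected, rel=0.02)

    def test_buried_atom_zero(self):
        # central atom caged by 12 tight neighbours
        phi = (1 + np.sqrt(5)) / 2
        verts = []
        for s1 in (1, -1):
            for s2 in (1, -1):
                verts += [[0, s1, s2 * phi], [s1, s2 * phi, 0],
                          [s1 * phi, 0, s2]]
        cage = np.array(verts, dtype=float)
        cage *= 1.2 / np.linalg.norm(cage[0])
        coords = np.vstack([[0.0, 0, 0], cage])
        areas = shrake_rupley(coords, np.full(13, 1.7))
        assert areas[0] == 0.0

    def test_point_count_convergence(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(50, 3)) * 4.0
        radii = np.full(50, 1.7)
        lo = shrake_rupley(coords, radii, n_points=960).sum()
        hi = shrake_rupley(coords, radii, n_points=4000).sum()
        assert abs(lo - hi) / hi < 0.02

    def test_series_units(self):
        coords = np.zeros((2, 1, 3))
        traj = make_trajectory(coords)
        _, totals = sasa_series(traj, "all")
        assert totals[0] == pytest.approx(4 * np.pi * 3.1 ** 2 / 100.0,
                                          rel=1e-6)


class TestHbonds:
    def test_constant_distance_series(self):
        coords = np.zeros((4, 2, 3))
        coords[:, 1, 0] = 3.0
        traj = make_trajectory(coords)
        series = hbond_series(traj, [HbondPair(0, 1, label="p")])["p"]
        assert np.allclose(series, 3.0)
        assert hbond_occupancy(series) == 100.0

    def test_out_of_window_zero_occupancy(self):
        coords = np.zeros((4, 2, 3))
        coords[:, 1, 0] = 5.0
        traj = make_trajectory(coords)
        series = hbond_series(traj, [HbondPair(0, 1, label="p")])["p"]
        assert hbond_occupancy(series) == 0.0

    def test_planted_occupancy_to_frame_quantization(self):
        # mirror of the reported 31.47% occupancy at toy scale
        target = 0.3147
        n = 300
        spec = PlantedTrajSpec(n_frames=n, hbond_fraction=target, seed=2)
        traj, truth = gen_trajectory(spec)
        series = hbond_series(traj, [truth["hbond_pair"]])["planted"]
        occ = hbond_occupancy(series)
        assert abs(occ / 100.0 - target) <= 1.0 / n

    def test_frame_order_invariant(self, toy_traj):
        traj, truth = toy_traj
        series = hbond_series(traj, [truth["hbond_pair"]])["planted"]
        rng = np.random.default_rng(0)
        assert hbond_occupancy(rng.permutation(series)) == \
            hbond_occupancy(series)

    def test_matches_brute_force_distances(self, toy_traj):
        traj, truth = toy_traj
        pair = truth["hbond_pair"]
        series = hbond_series(traj, [pair])["planted"]
        brute = [np.linalg.norm(traj.coords[f, pair.donor]
                                - traj.coords[f, pair.acceptor])
                 for f in range(traj.n_frames)]
        assert np.allclose(series, brute)

    def test_invalid_pair_rejected(self, toy_traj):
        with pytest.raises(ValueError):
            HbondPair(1, 1).validate(toy_traj[0])
        with pytest.raises(IndexError):
            HbondPair(0, 10_000).validate(toy_traj[0])


class TestTorsions:
    def test_planar_cis_zero(self):
        pts = np.array([[[0.0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]]])
        traj = make_trajectory(pts)
        res = torsion_series(traj, TorsionSpec((0, 1, 2, 3)))
        assert res.raw[0] == pytest.approx(0.0, abs=1e-9)
        assert res.unwrapped[0] == pytest.approx(0.0, abs=1e-9)

    def test_negative_angle_rewraps_to_270(self):
        spec = PlantedTrajSpec(n_frames=5, seed=0)
        traj, truth = gen_trajectory(spec)
        res = torsion_series(traj, truth["torsion"])
        assert np.allclose(res.raw, -90.0, atol=1e-6)
        assert np.allclose(res.unwrapped, 270.0, atol=1e-6)

    def test_constant_torsion_zero_delta(self, toy_traj):
        traj, truth = toy_traj
        res = torsion_series(traj, truth["torsion"])
        assert np.allclose(res.delta, 0.0, atol=1e-6)

    def test_scheduled_torsion_tracked(self):
        schedule = np.linspace(-170, 170, 30)
        spec = PlantedTrajSpec(n_frames=30, torsion_schedule=schedule, seed=1)
        traj, truth = gen_trajectory(spec)
        res = torsion_series(traj, truth["torsion"])
        assert np.allclose(res.raw, schedule, atol=1e-6)

    def test_collinear_middle_bond_flagged_nan(self):
        pts = np.array([[[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]]])
        traj = make_trajectory(pts)
        res = torsion_series(traj, TorsionSpec((0, 1, 2, 3)))
        assert np.isnan(res.raw[0])

    def test_four_distinct_atoms_required(self):
        with pytest.raises(ValueError):
            TorsionSpec((0, 1, 2, 2))


class TestClustering:
    def test_all_identical_single_cluster(self):
        frame = np.random.default_rng(0).normal(size=(5, 3))
        traj = make_trajectory(np.repeat(frame[None], 6, axis=0))
        res = cluster_frames(traj, cutoff=0.5)
        assert len(res.clusters) == 1
        assert res.representative == 0

    def test_two_conformations_majority_representative(self):
        rng = np.random.default_rng(1)
        conf_a = rng.normal(size=(5, 3)) * 3
        conf_b = rng.normal(size=(5, 3)) * 3
        frames = [conf_a + rng.normal(0, 0.05, size=(5, 3)) for _ in range(12)]
        frames += [conf_b + rng.normal(0, 0.05, size=(5, 3)) for _ in range(8)]
        traj = make_trajectory(np.array(frames))
        res = cluster_frames(traj, cutoff=1.0)
        assert len(res.clusters) == 2
        assert res.representative in range(12)
        assert len(res.clusters[0]["members"]) == 12

    def test_matches_exhaustive_neighbor_counting(self):
        rng = np.random.default_rng(2)
        frames = rng.normal(size=(15, 6, 3)) * 2.0
        traj = make_trajectory(frames)
        cutoff = 2.5
        res = cluster_frames(traj, cutoff=cutoff)
        # oracle: quaternion RMSD matrix + independent GROMOS loop
        dist = np.zeros((15, 15))
        for a in range(15):
            for b in range(a + 1, 15):
                dist[a, b] = dist[b, a] = quaternion_rmsd(frames[a], frames[b])
        remaining = list(range(15))
        expected = []
        while remaining:
            counts = {f: sum(dist[f, g] <= cutoff for g in remaining)
                      for f in remaining}
            center = max(remaining, key=lambda f: (counts[f], -f))
            members = [g for g in remaining if dist[center, g] <= cutoff]
            expected.append((center, sorted(members)))
            remaining = [g for g in remaining if g not in members]
        expected.sort(key=lambda c: (-len(c[1]), c[0]))
        got = [(c["center"], sorted(c["members"])) for c in res.clusters]
        assert got == expected

    def test_time_window(self):
        frame = np.random.default_rng(0).normal(size=(4, 3))
        traj = make_trajectory(np.repeat(frame[None], 10, axis=0),
                               times=np.arange(10.0))
        res = cluster_frames(traj, cutoff=0.5, window=(5.0, 9.0))
        assert res.clusters[0]["members"] == [5, 6, 7, 8, 9]
        with pytest.raises(ValueError):
            cluster_frames(traj, window=(100.0, 200.0))


class TestDihedralFunction:
    @pytest.mark.parametrize("angle", [-150.0, -90.0, -30.0, 0.0, 45.0,
                                       120.0, 180.0])
    def test_round_trip_constructed_angle(self, angle):
        from fkbpscreen.synth import _place_atom

        a = np.array([0.0, 0.0, 0.0])
        b = np.array([1.5, 0.0, 0.0])
        c = np.array([2.2, 1.3, 0.0])
        d = _place_atom(a, b, c, 1.5, 109.5, angle)
        got = dihedral(a, b, c, d)
        assert got == pytest.approx(angle, abs=1e-8)
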