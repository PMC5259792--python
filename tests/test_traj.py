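"""Kabsch superposition, ligand RMSD series and geometry series."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from halobind.synth import TrajectorySpec, synth_trajectory
from halobind.traj import (
    Trajectory,
    geometry_series,
    kabsch_superpose,
    ligand_rmsd_series,
    read_trajectory,
    write_trajectory,
)

FIT = lambda lab: lab.startswith("A:")
REPORT = lambda lab: lab.startswith("L:")


def quaternion_oracle(mobile, reference):
    """Independent quaternion eigenvalue method for optimal-rotation RMSD."""
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)
    sxx = m.T @ r
    a = np.empty((4, 4))
    a[0, 0] = sxx[0, 0] + sxx[1, 1] + sxx[2, 2]
    a[0, 1] = a[1, 0] = sxx[1, 2] - sxx[2, 1]
    a[0, 2] = a[2, 0] = sxx[2, 0] - sxx[0, 2]
    a[0, 3] = a[3, 0] = sxx[0, 1] - sxx[1, 0]
    a[1, 1] = sxx[0, 0] - sxx[1, 1] - sxx[2, 2]
    a[1, 2] = a[2, 1] = sxx[0, 1] + sxx[1, 0]
    a[1, 3] = a[3, 1] = sxx[0, 2] + sxx[2, 0]
    a[2, 2] = -sxx[0, 0] + sxx[1, 1] - sxx[2, 2]
    a[2, 3] = a[3, 2] = sxx[1, 2] + sxx[2, 1]
    a[3, 3] = -sxx[0, 0] - sxx[1, 1] + sxx[2, 2]
    lam = np.linalg.eigvalsh(a)[-1]
    e0 = (np.sum(m**2) + np.sum(r**2)) / 2.0
    return np.sqrt(max(0.0, 2.0 * (e0 - lam) / len(m)))


def test_kabsch_identity():
    pts = np.random.default_rng(0).normal(size=(8, 3))
    rot, t, rmsd = kabsch_superpose(pts, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(rot, np.eye(3), atol=1e-9)
    assert np.allclose(t, 0.0, atol=1e-9)


def test_kabsch_recovers_applied_transform():
    rng = np.random.default_rng(1)
    ref = rng.normal(size=(10, 3)) * 5
    applied = Rotation.random(rng=rng)
    shift = rng.normal(size=3) * 10
    mobile = applied.apply(ref) + shift
    rot, t, rmsd = kabsch_superpose(mobile, ref)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(mobile @ rot.T + t, ref, atol=1e-9)
    # recovered rotation inverts the applied one and is proper
    assert np.allclose(rot, applied.as_matrix().T, atol=1e-9)
    assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-12)


def test_kabsch_matches_quaternion_oracle():
    rng = np.random.default_rng(2)
    for _ in range(20):
        ref = rng.normal(size=(4, 3)) * 3
        mobile = ref.copy()
        mobile[0] += rng.normal(size=3)  # one displaced point
        _, _, rmsd = kabsch_superpose(mobile, ref)
        assert rmsd == pytest.approx(quaternion_oracle(mobile, ref), abs=1e-9)


def test_kabsch_never_worse_than_no_fit():
    rng = np.random.default_rng(3)
    for _ in range(10):
        ref = rng.normal(size=(6, 3)) * 4
        mobile = ref + rng.normal(size=(6, 3)) * 0.8
        _, _, fitted = kabsch_superpose(mobile, ref)
        raw = np.sqrt(np.mean(np.sum((mobile - ref) ** 2, axis=1)))
        assert fitted <= raw + 1e-12


def test_kabsch_input_validation():
    with pytest.raises(ValueError, match="at least 3"):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(ValueError, match="collinear"):
        kabsch_superpose(line + 0.1, line)


@pytest.fixture(scope="module")
def jitter_traj(probe_complex):
    spec = TrajectorySpec(n_frames=300, sigma_d=0.15, sigma_theta=5.0,
                          drift=0.1, seed=21)
    return synth_trajectory(probe_complex, 8, spec)


def test_ligand_rmsd_matches_generator_truth(jitter_traj):
    traj, truth = jitter_traj
    series = ligand_rmsd_series(traj, FIT, REPORT, reference_frame=0)
    assert np.allclose(series.values, truth.ligand_displacement, atol=1e-9)
    assert series.values[0] == pytest.approx(0.0, abs=1e-12)
    assert series.mean == pytest.approx(truth.ligand_displacement.mean(), abs=1e-9)


def test_rigid_whole_system_motion_removed(probe_complex):
    spec = TrajectorySpec(n_frames=25, sigma_d=0.0, sigma_theta=0.0,
                          rigid_motion=True, seed=4)
    traj, _ = synth_trajectory(probe_complex, 8, spec)
    series = ligand_rmsd_series(traj, FIT, REPORT)
    assert np.all(series.values < 1e-9)


def test_rmsd_series_invariant_under_added_rigid_motion(jitter_traj):
    traj, _ = jitter_traj
    base = ligand_rmsd_series(traj, FIT, REPORT)
    rng = np.random.default_rng(5)
    moved = traj.coords.copy()
    for i in range(traj.n_frames):
        rot = Rotation.random(rng=rng)
        moved[i] = rot.apply(moved[i]) + rng.normal(size=3) * 8
    moved_traj = Trajectory(coords=moved, labels=traj.labels)
    again = ligand_rmsd_series(moved_traj, FIT, REPORT)
    assert np.allclose(again.values, base.values, atol=1e-8)


def test_geometry_series_matches_truth(jitter_traj):
    traj, truth = jitter_traj
    gs = geometry_series(traj, "L:1:C1", "L:1:CL1", "A:8:O")
    assert np.allclose(gs.d, truth.d, atol=1e-9)
    assert np.allclose(gs.theta, truth.theta, atol=1e-7)


def test_geometry_series_single_frame(probe_complex):
    spec = TrajectorySpec(n_frames=1, sigma_d=0.0, sigma_theta=0.0, seed=1)
    traj, _ = synth_trajectory(probe_complex, 8, spec)
    gs = geometry_series(traj, "L:1:C1", "L:1:CL1", "A:8:O")
    assert gs.sd_d == pytest.approx(0.0, abs=1e-9)
    assert gs.sd_theta == pytest.approx(0.0, abs=1e-6)
    assert gs.mean_d == pytest.approx(gs.d[0])


def test_geometry_series_bad_selection(jitter_traj):
    traj, _ = jitter_traj
    with pytest.raises(ValueError, match="exactly one"):
        geometry_series(traj, "A:", "L:1:CL1", "A:8:O")
    with pytest.raises(ValueError, match="matches no atoms"):
        traj.select("Z:99")


def test_trajectory_pdb_roundtrip(tmp_path, probe_complex):
    spec = TrajectorySpec(n_frames=5, seed=2)
    traj, _ = synth_trajectory(probe_complex, 8, spec)
    path = tmp_path / "traj.pdb"
    write_trajectory(traj, path)
    back = read_trajectory(path)
    assert back.n_frames == traj.n_frames
    assert back.labels == traj.labels
    assert np.allclose(back.coords, traj.coords, atol=5.001e-4)  # PDB precision
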