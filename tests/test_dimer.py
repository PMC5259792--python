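"""Reduced rigid-body dimer: energies, minimization and Monte Carlo sampling."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from halobind.dimer import (
    Pose,
    RigidDimer,
    _fast_energy,
    distance_energy_profile,
    minimize,
    sample,
    total_energy,
)
from halobind.fragments import build_chlorobenzene


@pytest.fixture(scope="module")
def dimer():
    return RigidDimer()


def test_long_range_energy_decays(dimer):
    pose = dimer.reference_pose(d=50.0, theta=180.0)
    assert abs(total_energy(dimer, pose)) < 0.01


def test_sigma_hole_angular_preference(dimer):
    """Collinear sigma-hole pose beats a bent one at the same distance."""
    e_collinear = total_energy(dimer, dimer.reference_pose(3.1, 180.0))
    e_bent = total_energy(dimer, dimer.reference_pose(3.1, 120.0))
    assert e_collinear < e_bent


def test_clash_gives_inf_sentinel(dimer):
    pose = dimer.reference_pose(d=1.6, theta=180.0)
    assert total_energy(dimer, pose) == math.inf


def test_fast_energy_matches_composed_route(dimer):
    """The vectorized sampler energy equals the xbond-composed energy."""
    fast = _fast_energy(dimer)
    for d, theta in ((3.1, 180.0), (3.3, 160.0), (4.0, 140.0), (6.0, 120.0)):
        pose = dimer.reference_pose(d, theta)
        assert fast(pose.translation, pose.rotation.as_matrix()) == pytest.approx(
            total_energy(dimer, pose), abs=1e-10
        )


def test_extra_point_rederived_per_pose(dimer):
    """Rotating the probe moves its extra point rigidly with the C-Cl axis."""
    pose = dimer.reference_pose(3.1, 180.0)
    pos, charges, _, _ = dimer.probe_sites(pose)
    ep = pos[-1]
    x = pos[dimer.probe.halogen_index]
    c = pos[dimer.probe.carbon_index]
    u = (x - c) / np.linalg.norm(x - c)
    assert np.allclose(ep, x + 1.9 * u, atol=1e-9)
    assert charges[-1] == pytest.approx(0.04)


def test_minimize_agrees_with_grid_oracle(dimer):
    """6-DOF minimum from the basin edge lands on the (d, theta) grid optimum."""
    ds = np.arange(2.8, 3.65, 0.05)
    thetas = np.arange(150.0, 180.1, 2.0)
    best = (np.inf, None, None)
    for d in ds:
        for th in thetas:
            e = total_energy(dimer, dimer.reference_pose(float(d), float(th)))
            if e < best[0]:
                best = (e, float(d), float(th))
    res = minimize(dimer, dimer.reference_pose(4.0, 150.0))
    g = dimer.geometry(res.pose)
    assert res.energy <= best[0] + 1e-6  # full 6-DOF at least as good as the grid
    assert 2.9 <= g.d <= 3.4
    assert g.theta > 165.0
    assert g.theta >= 150.0  # monotone improvement from the starting angle


def test_minimize_fixed_point(dimer):
    res = minimize(dimer, dimer.reference_pose(4.0, 150.0))
    again = minimize(dimer, res.pose)
    assert again.energy == pytest.approx(res.energy, abs=1e-6)
    g0, g1 = dimer.geometry(res.pose), dimer.geometry(again.pose)
    assert g1.d == pytest.approx(g0.d, abs=1e-3)
    assert g1.theta == pytest.approx(g0.theta, abs=0.1)


def test_minimize_from_clash_rejected(dimer):
    with pytest.raises(ValueError, match="clash"):
        minimize(dimer, dimer.reference_pose(1.6, 180.0))


def test_sampler_determinism(dimer):
    a = sample(dimer, n_steps=2000, seed=5)
    b = sample(dimer, n_steps=2000, seed=5)
    assert np.array_equal(a.d, b.d)
    assert np.array_equal(a.theta, b.theta)
    assert a.acceptance_rate == b.acceptance_rate
    c = sample(dimer, n_steps=2000, seed=6)
    assert not np.array_equal(a.d, c.d)


def test_seed_mandatory(dimer):
    with pytest.raises(ValueError, match="seed"):
        sample(dimer, n_steps=2000)


def test_frozen_sampler_matches_minimum(dimer):
    """At 1 K, started at the minimum, the chain stays at the minimized geometry."""
    res = minimize(dimer, dimer.reference_pose(4.0, 150.0))
    g = dimer.geometry(res.pose)
    frozen = sample(
        dimer, temperature=1.0, n_steps=4000, seed=3, start=res.pose,
        step_translation=0.02, step_rotation_deg=1.0,
    )
    assert frozen.mean_d == pytest.approx(g.d, abs=0.05)
    assert frozen.mean_theta == pytest.approx(g.theta, abs=2.0)


def test_thermal_angle_below_collinear(dimer):
    """T > 0 pulls the mean angle strictly below 180; cooling raises it."""
    warm = sample(dimer, temperature=300.0, n_steps=20000, seed=9)
    cool = sample(dimer, temperature=100.0, n_steps=20000, seed=9)
    assert warm.mean_theta < 180.0
    assert cool.mean_theta > warm.mean_theta


def test_extra_point_ablation_degrades_geometry(dimer):
    """Zeroing the sigma-hole charge (net charge kept) loosens the bond.

    Mirrors the stability contrast between the chlorinated ligand and its
    des-halo analogue: without the extra point the bonded-frame mean
    distance grows and the mean angle drops.
    """
    ablated = RigidDimer(probe=build_chlorobenzene(q_halogen=-0.0325, q_ep=0.0))
    intact = sample(dimer, n_steps=30000, seed=7)
    broken = sample(ablated, n_steps=30000, seed=7)
    assert broken.mean_d > intact.mean_d
    assert broken.mean_theta < intact.mean_theta
    assert broken.fraction_bonded < intact.fraction_bonded


def test_collinear_profile_minimum_near_3_1(dimer):
    ds = np.arange(2.8, 4.01, 0.05)
    es = distance_energy_profile(dimer, ds)
    assert 2.95 <= ds[np.argmin(es)] <= 3.25
    assert es.min() < -1.5


def test_zero_acceptance_burn_in_raises(dimer):
    with pytest.raises(RuntimeError, match="step sizes"):
        sample(dimer, n_steps=1000, seed=1, step_translation=80.0,
               step_rotation_deg=180.0, temperature=1e-6)
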