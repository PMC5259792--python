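"""Sigma-hole extra point, halogen-bond geometry and pair energies."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from halobind.xbond import (
    COULOMB_CONSTANT,
    XBondCriteria,
    XBondGeometry,
    classify_halogen_bond,
    coulomb_energy,
    lj_energy,
    place_sigma_hole,
    repulsive_energy,
    xbond_geometry,
)

coords = st.floats(min_value=-50, max_value=50, allow_nan=False)
point = st.tuples(coords, coords, coords)


def test_extra_point_on_axis():
    site = place_sigma_hole((0, 0, 0), (1.77, 0, 0))
    assert np.allclose(site.extra_point, (3.67, 0, 0))
    site = place_sigma_hole((0, 0, 0), (0, 0, 1.77))
    assert np.allclose(site.extra_point, (0, 0, 3.67))


@given(point, point)
def test_extra_point_constructive_property(c, x):
    c, x = np.asarray(c), np.asarray(x)
    if np.linalg.norm(x - c) < 1e-3:
        return
    site = place_sigma_hole(c, x)
    assert np.linalg.norm(site.extra_point - x) == pytest.approx(1.9, abs=1e-9)
    # collinear: EP on the ray C->X beyond X
    u = (x - c) / np.linalg.norm(x - c)
    assert np.allclose(site.extra_point, x + 1.9 * u, atol=1e-9)
    # the added charge pair is net -0.0325 e regardless of geometry
    assert site.net_charge == pytest.approx(-0.0325)


def test_coincident_carbon_halogen_rejected():
    with pytest.raises(ValueError, match="coincide"):
        place_sigma_hole((1, 1, 1), (1, 1, 1))


def test_xbond_geometry_examples():
    g = xbond_geometry((0, 0, 0), (1.77, 0, 0), (4.87, 0, 0))
    assert g.d == pytest.approx(3.10)
    assert g.theta == pytest.approx(180.0)
    # inverse construction: O at polar angle 20 deg off the axis from X
    x = np.array([1.77, 0, 0])
    o = x + 3.10 * np.array([np.cos(np.radians(20)), np.sin(np.radians(20)), 0])
    g = xbond_geometry((0, 0, 0), x, o)
    assert g.d == pytest.approx(3.10, abs=1e-9)
    assert g.theta == pytest.approx(160.0, abs=1e-9)
    # O coincident with C: back-side placement
    g = xbond_geometry((0, 0, 0), (1.77, 0, 0), (0, 0, 0))
    assert g.theta == pytest.approx(0.0)


def test_coulomb_single_term_closed_form():
    e = coulomb_energy([((0, 0, 0), 0.04)], [((3.0, 0, 0), -0.60)])
    assert e == pytest.approx(332.06 * 0.04 * (-0.60) / 3.0, abs=1e-12)
    assert e == pytest.approx(-2.656, abs=1e-3)


def test_coulomb_zero_charges_and_bilinearity():
    rng = np.random.default_rng(0)
    a = [(rng.normal(size=3) * 5, rng.normal()) for _ in range(4)]
    b = [(rng.normal(size=3) * 5 + 20, rng.normal()) for _ in range(3)]
    zero = [(p, 0.0) for p, _ in a]
    assert coulomb_energy(zero, b) == 0.0
    e1 = coulomb_energy(a, b)
    doubled_a = [(p, 2 * q) for p, q in a]
    doubled_b = [(p, 2 * q) for p, q in b]
    assert coulomb_energy(doubled_a, doubled_b) == pytest.approx(4 * e1, rel=1e-12)
    assert coulomb_energy(b, a) == pytest.approx(e1, rel=1e-12)  # symmetry


def test_coulomb_brute_force_oracle():
    rng = np.random.default_rng(1)
    for _ in range(5):
        a = [(rng.normal(size=3) * 4, rng.normal()) for _ in range(5)]
        b = [(rng.normal(size=3) * 4 + 15, rng.normal()) for _ in range(6)]
        brute = sum(
            COULOMB_CONSTANT * qa * qb / np.linalg.norm(pa - pb)
            for pa, qa in a
            for pb, qb in b
        )
        assert coulomb_energy(a, b) == pytest.approx(brute, abs=1e-10)


def test_coulomb_near_singular_pair_reported():
    with pytest.raises(ValueError, match="near-singular"):
        coulomb_energy([((0, 0, 0), 1.0)], [((0.1, 0, 0), 1.0)])


def test_lj_analytic_landmarks():
    sigma, eps = 3.4, 0.25
    r_min = 2 ** (1 / 6) * sigma
    at = lambda r: lj_energy([((0, 0, 0), sigma, eps)], [((r, 0, 0), sigma, eps)])
    assert at(r_min) == pytest.approx(-eps, rel=1e-12)
    assert at(sigma) == pytest.approx(0.0, abs=1e-12)
    assert at(80.0) == pytest.approx(0.0, abs=1e-8)
    # Lorentz-Berthelot: unlike pair minimum at combined sigma
    e = lj_energy([((0, 0, 0), 3.0, 0.1)],
                  [((2 ** (1 / 6) * 3.5, 0, 0), 4.0, 0.4)])
    assert e == pytest.approx(-np.sqrt(0.1 * 0.4), rel=1e-12)


def test_repulsive_energy_is_wall_only():
    sigma, eps = 4.0, 0.1
    at = lambda r: repulsive_energy([((0, 0, 0), sigma, eps)],
                                    [((r, 0, 0), sigma, eps)])
    assert at(sigma) == pytest.approx(4 * eps)
    assert at(2.0) > at(3.0) > at(8.0) > 0.0  # monotone, never attractive


def test_energies_invariant_under_joint_rigid_transform():
    rng = np.random.default_rng(3)
    a = [(rng.normal(size=3) * 4, rng.normal(), ) for _ in range(4)]
    b = [(rng.normal(size=3) * 4 + 12, rng.normal()) for _ in range(4)]
    lj_a = [(p, 3.4, 0.2) for p, _ in a]
    lj_b = [(p, 3.0, 0.15) for p, _ in b]
    e_c, e_l = coulomb_energy(a, b), lj_energy(lj_a, lj_b)
    rot = Rotation.random(rng=rng)
    shift = rng.normal(size=3) * 30
    move = lambda sites: [(rot.apply(p) + shift, *rest) for p, *rest in sites]
    assert coulomb_energy(move(a), move(b)) == pytest.approx(e_c, abs=1e-9)
    assert lj_energy(move(lj_a), move(lj_b)) == pytest.approx(e_l, abs=1e-9)


@pytest.mark.parametrize(
    "d,theta,bonded",
    [
        (3.1, 170.0, True),   # the bound-state averages satisfy the criteria
        (3.1, 100.0, False),  # angle fails
        (3.5, 140.0, True),   # boundaries inclusive
        (3.51, 170.0, False),
        (4.5, 170.0, False),
    ],
)
def test_classification(d, theta, bonded):
    call = classify_halogen_bond(XBondGeometry(d, theta), XBondCriteria())
    assert call.bonded is bonded
    assert call.distance_ok is (d <= 3.5)
    assert call.angle_ok is (theta >= 140.0)


def test_criteria_validation():
    with pytest.raises(ValueError):
        XBondCriteria(d_max=-1.0)
    with pytest.raises(ValueError):
        XBondCriteria(theta_min=80.0)
    with pytest.raises(ValueError):
        XBondGeometry(d=-0.1, theta=150.0)
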