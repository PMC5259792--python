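"""Rigid-body sampling of a chloroarene-amide dimer under the extra-point model.

A desk-scale surrogate for receptor-context molecular dynamics: the
chlorobenzene probe moves as a rigid body (6 degrees of freedom) relative to
a fixed N-methylacetamide fragment, under a Coulomb + Lennard-Jones energy
that includes the sigma-hole extra point.  Metropolis Monte Carlo at fixed
temperature yields the thermally averaged halogen-bond geometry (mean X...O
distance and mean C-X...O angle over bonded frames), the quantity the
full simulations report; kinetics are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.transform import Rotation

from .fragments import Fragment, build_amide_partner, build_chlorobenzene
from .xbond import (
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

#: Boltzmann constant in kcal/(mol*K).
KB = 0.0019872041

#: Hard-core clash threshold (Angstrom): closer pairs get the +inf sentinel.
CLASH_DISTANCE = 0.5


@dataclass(frozen=True)
class Pose:
    """Rigid placement of the probe: rotation about its body origin, then shift."""

    translation: np.ndarray
    rotation: Rotation

    def apply(self, positions: np.ndarray) -> np.ndarray:
        return self.rotation.apply(positions) + np.asarray(self.translation)


@dataclass
class RigidDimer:
    """Probe + fixed partner; the probe's extra point is re-derived per pose."""

    probe: Fragment = field(default_factory=build_chlorobenzene)
    partner: Fragment = field(default_factory=build_amide_partner)
    criteria: XBondCriteria = field(default_factory=XBondCriteria)

    def __post_init__(self) -> None:
        if self.probe.halogen_index is None or self.probe.carbon_index is None:
            raise ValueError("probe fragment must define a C-X sigma-hole pair")

    def posed_probe(self, pose: Pose) -> np.ndarray:
        return pose.apply(self.probe.positions)

    def probe_sites(self, pose: Pose):
        """Posed probe (positions incl. extra point, charges, sigmas, epsilons)."""
        xyz = self.posed_probe(pose)
        site = place_sigma_hole(
            xyz[self.probe.carbon_index],
            xyz[self.probe.halogen_index],
            q_halogen=self.probe.charges[self.probe.halogen_index],
            q_ep=self.probe.q_ep,
            separation=self.probe.ep_separation,
        )
        positions = np.vstack([xyz, site.extra_point])
        charges = np.append(self.probe.charges, self.probe.q_ep)
        sigmas = np.append(self.probe.sigmas, 0.0)
        epsilons = np.append(self.probe.epsilons, 0.0)
        return positions, charges, sigmas, epsilons

    def geometry(self, pose: Pose) -> XBondGeometry:
        """Halogen-bond geometry of the pose vs the partner carbonyl O."""
        xyz = self.posed_probe(pose)
        o = self.partner.positions[self.partner.atom_index("O")]
        return xbond_geometry(
            xyz[self.probe.carbon_index], xyz[self.probe.halogen_index], o
        )

    def reference_pose(self, d: float = 3.1, theta: float = 180.0) -> Pose:
        """A sigma-hole pose: Cl at distance d from O on the C=O extension.

        theta is the C-Cl...O angle; the probe ring stays in the amide
        plane, tilted about the normal to realize sub-collinear angles.
        """
        o = self.partner.positions[self.partner.atom_index("O")]
        c_amide = self.partner.positions[self.partner.atom_index("C")]
        u = o - c_amide
        u = u / np.linalg.norm(u)
        x_target = o + d * u
        # probe body frame: C1 at (1.39,0,0), Cl on +x at (3.13,0,0)
        body_c = self.probe.positions[self.probe.carbon_index]
        body_x = self.probe.positions[self.probe.halogen_index]
        axis_body = (body_x - body_c) / np.linalg.norm(body_x - body_c)
        # desired Cl->C direction: at angle (180 - theta) from Cl->O = +u
        tilt = np.radians(180.0 - theta)
        normal = np.array([0.0, 0.0, 1.0])
        in_plane = np.cross(normal, u)
        # Cl->C anti-parallel to Cl->O (= -u) at theta=180, tilted in-plane otherwise
        cx_dir = np.cos(tilt) * u + np.sin(tilt) * in_plane
        rot, _ = Rotation.align_vectors(
            [-cx_dir, normal], [axis_body, np.array([0.0, 0.0, 1.0])]
        )
        translation = x_target - rot.apply(body_x)
        return Pose(translation=translation, rotation=rot)


def total_energy(dimer: RigidDimer, pose: Pose) -> float:
    """Coulomb + LJ (+ occluder wall) energy in kcal/mol; +inf on hard clash.

    Composed from the :mod:`halobind.xbond` pair energies: full 12-6 LJ and
    Coulomb against the partner's physical sites, repulsive-only walls
    against its sterics-only sites.
    """
    positions, charges, sigmas, epsilons = dimer.probe_sites(pose)
    p = dimer.partner
    phys = ~p.repulsive
    a_coul = list(zip(positions, charges))
    b_coul = list(zip(p.positions[phys], p.charges[phys]))
    a_lj = list(zip(positions, sigmas, epsilons))
    b_lj = list(zip(p.positions[phys], p.sigmas[phys], p.epsilons[phys]))
    b_wall = list(
        zip(p.positions[p.repulsive], p.sigmas[p.repulsive], p.epsilons[p.repulsive])
    )
    try:
        return (
            coulomb_energy(a_coul, b_coul, min_distance=CLASH_DISTANCE)
            + lj_energy(a_lj, b_lj, min_distance=CLASH_DISTANCE)
            + repulsive_energy(a_lj, b_wall, min_distance=CLASH_DISTANCE)
        )
    except ValueError:
        return math.inf


def _fast_energy(dimer: RigidDimer):
    """Closure computing the same energy as :func:`total_energy`, vectorized.

    Kept numerically identical to the composed route (same combination rules
    and constant); a unit test pins the equality.
    """
    probe, partner = dimer.probe, dimer.partner
    qa = np.append(probe.charges, probe.q_ep)
    qb = partner.charges
    qq = COULOMB_CONSTANT * np.outer(qa, qb)
    sig = 0.5 * (
        np.append(probe.sigmas, 0.0)[:, None] + partner.sigmas[None, :]
    )
    eps4 = 4.0 * np.sqrt(
        np.outer(np.append(probe.epsilons, 0.0), partner.epsilons)
    )
    # sterics-only partner sites keep the r^-12 wall but lose dispersion
    attract = np.where(partner.repulsive[None, :], 0.0, 1.0)
    ci, xi = probe.carbon_index, probe.halogen_index
    sep = probe.ep_separation
    base = probe.positions
    pb = partner.positions

    def energy(translation: np.ndarray, matrix: np.ndarray) -> float:
        xyz = base @ matrix.T + translation
        axis = xyz[xi] - xyz[ci]
        ep = xyz[xi] + sep * axis / np.linalg.norm(axis)
        pos = np.vstack([xyz, ep])
        r = np.linalg.norm(pos[:, None, :] - pb[None, :, :], axis=-1)
        if r.min() < CLASH_DISTANCE:
            return math.inf
        sr6 = (sig / r) ** 6
        return float(np.sum(qq / r) + np.sum(eps4 * sr6 * (sr6 - attract)))

    return energy


@dataclass
class MinimizeResult:
    pose: Pose
    energy: float
    start_energy: float
    n_iterations: int


def minimize(
    dimer: RigidDimer,
    start: Pose,
    tol: float = 1e-8,
    max_iterations: int = 20000,
) -> MinimizeResult:
    """Local 6-DOF minimization (Nelder-Mead over translation + rotation vector)."""
    e0 = total_energy(dimer, start)
    if not math.isfinite(e0):
        raise ValueError("starting pose clashes (infinite energy)")
    energy = _fast_energy(dimer)

    def objective(x: np.ndarray) -> float:
        rot = Rotation.from_rotvec(x[3:]) * start.rotation
        return energy(x[:3], rot.as_matrix())

    x0 = np.concatenate([start.translation, np.zeros(3)])
    res = _scipy_minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"maxiter": max_iterations, "xatol": tol, "fatol": tol},
    )
    if not res.success:
        raise RuntimeError(
            f"minimization did not converge in {max_iterations} iterations: "
            f"{res.message}"
        )
    pose = Pose(
        translation=res.x[:3],
        rotation=Rotation.from_rotvec(res.x[3:]) * start.rotation,
    )
    return MinimizeResult(
        pose=pose, energy=float(res.fun), start_energy=e0, n_iterations=res.nit
    )


@dataclass
class SimResult:
    """Monte-Carlo output: thinned trajectory, geometry series and summary."""

    poses: list[Pose]
    d: np.ndarray
    theta: np.ndarray
    energy: np.ndarray
    bonded: np.ndarray
    mean_d: float
    mean_theta: float
    fraction_bonded: float
    acceptance_rate: float
    seed: int
    n_steps: int
    temperature: float
    bonded_only: bool


def sample(
    dimer: RigidDimer,
    temperature: float = 300.0,
    n_steps: int = 200_000,
    step_translation: float = 0.12,
    step_rotation_deg: float = 6.0,
    seed: int | None = None,
    start: Pose | None = None,
    burn_in_fraction: float = 0.1,
    max_stored_frames: int = 10_000,
    bonded_only: bool = True,
    wall_distance: float = 6.0,
) -> SimResult:
    """Metropolis Monte Carlo over the probe's 6-DOF pose at fixed temperature.

    Each step perturbs the translation by an isotropic Gaussian and the
    orientation by a small rotation about a random axis; moves are accepted
    with the Boltzmann probability min(1, exp(-dE/kT)).  A flat-bottom
    spherical wall rejects poses whose X...O separation exceeds
    ``wall_distance`` — an isolated dimer at finite temperature would
    otherwise dissociate into an unbounded volume (the receptor cavity
    confines the ligand in the full system).  The wall only truncates the
    accessible volume; the Boltzmann distribution inside it, and hence the
    bonded-frame geometry averages, are unaffected by its placement.

    The first ``burn_in_fraction`` of steps is discarded; the remainder is
    thinned to at most ``max_stored_frames`` stored frames, over which the
    summary statistics are computed.  ``mean_d``/``mean_theta`` average the
    frames classified as halogen-bonded (all frames with
    ``bonded_only=False``).  Bit-reproducible for a given seed.
    """
    if seed is None:
        raise ValueError("seed is mandatory for reproducible sampling")
    if n_steps < 100:
        raise ValueError("n_steps too small for meaningful statistics")
    rng = np.random.default_rng(seed)
    kt = KB * temperature
    energy = _fast_energy(dimer)
    pose = start or dimer.reference_pose()
    t = np.asarray(pose.translation, dtype=float)
    rot = pose.rotation
    e = energy(t, rot.as_matrix())
    if not math.isfinite(e):
        raise ValueError("starting pose clashes (infinite energy)")

    burn_in = int(burn_in_fraction * n_steps)
    keep = n_steps - burn_in
    thin = max(1, math.ceil(keep / max_stored_frames))
    step_rot = math.radians(step_rotation_deg)

    o_pos = dimer.partner.positions[dimer.partner.atom_index("O")]
    ci, xi = dimer.probe.carbon_index, dimer.probe.halogen_index
    base = dimer.probe.positions
    base_x = base[xi]

    n_accept = 0
    n_accept_burn = 0
    poses: list[Pose] = []
    d_list: list[float] = []
    theta_list: list[float] = []
    e_list: list[float] = []
    for step in range(n_steps):
        t_new = t + rng.normal(0.0, step_translation, 3)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        dphi = rng.normal(0.0, step_rot)
        rot_new = Rotation.from_rotvec(dphi * axis) * rot
        m_new = rot_new.as_matrix()
        if np.linalg.norm(m_new @ base_x + t_new - o_pos) > wall_distance:
            e_new = math.inf  # outside the flat-bottom wall
        else:
            e_new = energy(t_new, m_new)
        if e_new <= e or rng.random() < math.exp(-(e_new - e) / kt):
            t, rot, e = t_new, rot_new, e_new
            n_accept += 1
            if step < burn_in:
                n_accept_burn += 1
        if step == burn_in - 1 and n_accept_burn == 0:
            raise RuntimeError(
                "no accepted moves during burn-in; reduce step sizes"
            )
        if step >= burn_in and (step - burn_in) % thin == 0:
            xyz = base @ rot.as_matrix().T + t
            g = xbond_geometry(xyz[ci], xyz[xi], o_pos)
            poses.append(Pose(translation=t.copy(), rotation=rot))
            d_list.append(g.d)
            theta_list.append(g.theta)
            e_list.append(e)

    d = np.array(d_list)
    theta = np.array(theta_list)
    bonded = np.array(
        [
            classify_halogen_bond(XBondGeometry(dd, th), dimer.criteria).bonded
            for dd, th in zip(d, theta)
        ]
    )
    subset = bonded if bonded_only else np.ones_like(bonded, dtype=bool)
    if subset.sum() == 0:
        mean_d = mean_theta = float("nan")
    else:
        mean_d = float(d[subset].mean())
        mean_theta = float(theta[subset].mean())
    return SimResult(
        poses=poses,
        d=d,
        theta=theta,
        energy=np.array(e_list),
        bonded=bonded,
        mean_d=mean_d,
        mean_theta=mean_theta,
        fraction_bonded=float(bonded.mean()),
        acceptance_rate=n_accept / n_steps,
        seed=seed,
        n_steps=n_steps,
        temperature=temperature,
        bonded_only=bonded_only,
    )


def distance_energy_profile(dimer: RigidDimer, distances: np.ndarray) -> np.ndarray:
    """E(d) along the collinear sigma-hole approach (theta = 180 deg)."""
    energy = _fast_energy(dimer)
    out = []
    for d in np.asarray(distances, dtype=float):
        pose = dimer.reference_pose(d=float(d), theta=180.0)
        out.append(energy(pose.translation, pose.rotation.as_matrix()))
    return np.array(out)


def sample_distance_1d(
    dimer: RigidDimer,
    temperature: float = 300.0,
    n_steps: int = 50_000,
    d_min: float = 2.7,
    d_max: float = 4.5,
    seed: int | None = None,
    thin: int = 10,
) -> np.ndarray:
    """1-DOF restriction: Metropolis over the collinear X...O distance only.

    Uses an independence sampler (uniform proposals on [d_min, d_max]); the
    chain is thinned by ``thin`` so rejection-induced repeats decorrelate,
    making the retained draws effectively independent for multinomial
    histogram checks against direct quadrature of exp(-E(d)/kT).  Along the
    collinear approach the probe orientation is constant, so the energy is
    evaluated with a cached rotation and a translation linear in d.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    rng = np.random.default_rng(seed)
    kt = KB * temperature
    energy = _fast_energy(dimer)
    ref = dimer.reference_pose(d=d_min, theta=180.0)
    matrix = ref.rotation.as_matrix()
    t0 = np.asarray(ref.translation, dtype=float)
    o = dimer.partner.positions[dimer.partner.atom_index("O")]
    c_amide = dimer.partner.positions[dimer.partner.atom_index("C")]
    u = (o - c_amide) / np.linalg.norm(o - c_amide)

    def e_of(d: float) -> float:
        return energy(t0 + (d - d_min) * u, matrix)

    d = 0.5 * (d_min + d_max)
    e = e_of(d)
    out = np.empty(n_steps // thin)
    kept = 0
    for i in range(n_steps):
        d_new = rng.uniform(d_min, d_max)
        e_new = e_of(d_new)
        if e_new <= e or rng.random() < math.exp(-(e_new - e) / kt):
            d, e = d_new, e_new
        if (i + 1) % thin == 0:
            out[kept] = d
            kept += 1
    return out[:kept]
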