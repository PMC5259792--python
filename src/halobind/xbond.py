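"""Sigma-hole extra-point charge model and halogen-bond geometry.

A carbon-bound halogen carries a belt of negative potential but a small
positive cap (the sigma-hole) on the far side of the C-X axis, letting it
act as a Lewis acid toward a carbonyl oxygen.  Fixed-charge force fields
recover this anisotropy with a positive extra point (EP): the halogen keeps
a negative charge while a massless positive charge sits on the extension of
the C-X axis beyond the halogen.  Defaults are the chlorine parameterization
used here throughout: q_Cl = -0.0725 e, q_EP = +0.04 e, Cl-EP separation
1.9 A.

Geometry of a halogen bond X...O=C is characterized by the X...O distance d
and the C-X...O angle theta (180 deg = sigma-hole pointing straight at O).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import angle as _angle
from .structures import distance as _distance

#: Coulomb constant in kcal*A/(mol*e^2), biomolecular force-field convention.
COULOMB_CONSTANT = 332.06

#: Chlorine extra-point defaults: charges in e, separation in Angstrom.
DEFAULT_Q_HALOGEN = -0.0725
DEFAULT_Q_EP = 0.04
DEFAULT_EP_SEPARATION = 1.9


@dataclass(frozen=True)
class SigmaHoleSite:
    """A halogen with its sigma-hole extra point.

    The extra point lies on the ray from carbon through the halogen, beyond
    the halogen, at exactly ``separation`` Angstrom from it.
    """

    carbon: np.ndarray
    halogen: np.ndarray
    extra_point: np.ndarray
    q_halogen: float = DEFAULT_Q_HALOGEN
    q_ep: float = DEFAULT_Q_EP
    separation: float = DEFAULT_EP_SEPARATION

    @property
    def net_charge(self) -> float:
        return self.q_halogen + self.q_ep


@dataclass(frozen=True)
class XBondGeometry:
    """d = X...O distance (A); theta = C-X...O angle (deg)."""

    d: float
    theta: float

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("X...O distance must be positive")
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError("theta must be within [0, 180] degrees")


@dataclass(frozen=True)
class XBondCriteria:
    """Geometric acceptance window for a halogen bond (inclusive bounds)."""

    d_max: float = 3.5
    theta_min: float = 140.0

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not 90.0 < self.theta_min <= 180.0:
            raise ValueError("theta_min must be in (90, 180]")


def place_sigma_hole(
    carbon,
    halogen,
    q_halogen: float = DEFAULT_Q_HALOGEN,
    q_ep: float = DEFAULT_Q_EP,
    separation: float = DEFAULT_EP_SEPARATION,
) -> SigmaHoleSite:
    """Construct the extra point: EP = X + separation * unit(X - C)."""
    c = np.asarray(carbon, dtype=float)
    x = np.asarray(halogen, dtype=float)
    axis = x - c
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ValueError("carbon and halogen positions coincide")
    ep = x + separation * axis / norm
    return SigmaHoleSite(
        carbon=c, halogen=x, extra_point=ep,
        q_halogen=q_halogen, q_ep=q_ep, separation=separation,
    )


def xbond_geometry(carbon, halogen, oxygen) -> XBondGeometry:
    """Measure (d, theta) of a C-X ... O arrangement.

    theta is the angle at the halogen between the X->C and X->O directions,
    reported as the C-X...O angle: 180 deg means the sigma-hole (anti to C)
    points straight at the acceptor; 0 deg puts O behind the carbon.
    """
    d = _distance(halogen, oxygen)
    theta = _angle(carbon, halogen, oxygen)
    return XBondGeometry(d=d, theta=theta)


def _pair_matrix(sites_a, sites_b):
    pa = np.asarray([s[0] for s in sites_a], dtype=float)
    pb = np.asarray([s[0] for s in sites_b], dtype=float)
    return np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)


def coulomb_energy(sites_a, sites_b, min_distance: float = 0.5) -> float:
    """Coulomb energy (kcal/mol) between two site lists [(position, q_e), ...].

    Inter-list pairs only; symmetric in argument order.  A pair closer than
    ``min_distance`` raises (the point-charge model diverges there).
    """
    if not sites_a or not sites_b:
        return 0.0
    r = _pair_matrix(sites_a, sites_b)
    if np.min(r) < min_distance:
        i, j = np.unravel_index(np.argmin(r), r.shape)
        raise ValueError(
            f"near-singular pair: site {i} of A and site {j} of B at "
            f"{r[i, j]:.3f} A (< {min_distance} A)"
        )
    qa = np.asarray([s[1] for s in sites_a], dtype=float)
    qb = np.asarray([s[1] for s in sites_b], dtype=float)
    return float(COULOMB_CONSTANT * np.sum(np.outer(qa, qb) / r))


def lj_energy(sites_a, sites_b, min_distance: float = 0.5) -> float:
    """12-6 Lennard-Jones energy between [(position, sigma_A, eps), ...] lists.

    Lorentz-Berthelot combination: sigma_ij = (sigma_i + sigma_j)/2,
    eps_ij = sqrt(eps_i * eps_j).  A single pair has its minimum -eps_ij at
    r = 2^(1/6) sigma_ij and crosses zero at r = sigma_ij.
    """
    if not sites_a or not sites_b:
        return 0.0
    r = _pair_matrix(sites_a, sites_b)
    if np.min(r) < min_distance:
        i, j = np.unravel_index(np.argmin(r), r.shape)
        raise ValueError(
            f"near-singular pair: site {i} of A and site {j} of B at "
            f"{r[i, j]:.3f} A (< {min_distance} A)"
        )
    sig_a = np.asarray([s[1] for s in sites_a], dtype=float)
    sig_b = np.asarray([s[1] for s in sites_b], dtype=float)
    eps_a = np.asarray([s[2] for s in sites_a], dtype=float)
    eps_b = np.asarray([s[2] for s in sites_b], dtype=float)
    sig = 0.5 * (sig_a[:, None] + sig_b[None, :])
    eps = np.sqrt(np.outer(eps_a, eps_b))
    sr6 = (sig / r) ** 6
    return float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))


def repulsive_energy(sites_a, sites_b, min_distance: float = 0.5) -> float:
    """Repulsive-only wall energy 4*eps*(sigma/r)^12 between site lists.

    Same [(position, sigma, eps), ...] convention and Lorentz-Berthelot
    combination as :func:`lj_energy`, but without the attractive r^-6 term;
    used for sterics-only pseudo-atoms (e.g. helix-context occluders).
    """
    if not sites_a or not sites_b:
        return 0.0
    r = _pair_matrix(sites_a, sites_b)
    if np.min(r) < min_distance:
        i, j = np.unravel_index(np.argmin(r), r.shape)
        raise ValueError(
            f"near-singular pair: site {i} of A and site {j} of B at "
            f"{r[i, j]:.3f} A (< {min_distance} A)"
        )
    sig_a = np.asarray([s[1] for s in sites_a], dtype=float)
    sig_b = np.asarray([s[1] for s in sites_b], dtype=float)
    eps_a = np.asarray([s[2] for s in sites_a], dtype=float)
    eps_b = np.asarray([s[2] for s in sites_b], dtype=float)
    sig = 0.5 * (sig_a[:, None] + sig_b[None, :])
    eps = np.sqrt(np.outer(eps_a, eps_b))
    return float(np.sum(4.0 * eps * (sig / r) ** 12))


@dataclass(frozen=True)
class XBondCall:
    """Classification record: the verdict plus both comparisons."""

    bonded: bool
    geometry: XBondGeometry
    criteria: XBondCriteria
    distance_ok: bool
    angle_ok: bool


def classify_halogen_bond(
    g: XBondGeometry, criteria: XBondCriteria | None = None
) -> XBondCall:
    """Bonded iff d <= d_max and theta >= theta_min (both inclusive)."""
    criteria = criteria or XBondCriteria()
    distance_ok = g.d <= criteria.d_max
    angle_ok = g.theta >= criteria.theta_min
    return XBondCall(
        bonded=distance_ok and angle_ok,
        geometry=g,
        criteria=criteria,
        distance_ok=distance_ok,
        angle_ok=angle_ok,
    )
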