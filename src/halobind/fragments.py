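"""Rigid molecular fragments for the reduced dimer simulation.

Two fragments stand in for the ligand chloroaryl moiety and the receptor
backbone: chlorobenzene (the minimal sigma-hole donor, analogous to a
chloronaphthyl group) and an N-methylacetamide fragment (trans amide with
united-atom methyls, a backbone carbonyl surrogate).  Geometry is idealized;
charges are RESP/OPLS-flavored with the halogen carrying the extra-point
pair (q_Cl = -0.0725 e, q_EP = +0.04 e at 1.9 A) of the chlorine
parameterization used throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .xbond import DEFAULT_EP_SEPARATION, DEFAULT_Q_EP, DEFAULT_Q_HALOGEN


def load_nonbonded_parameters() -> dict[str, dict[str, float]]:
    """LJ parameters by atom type from the packaged parameter file."""
    text = resources.files("halobind.data").joinpath("nonbonded.json").read_text()
    return json.loads(text)["types"]


@dataclass
class Fragment:
    """A rigid group of charged LJ sites, positions in its body frame."""

    names: list[str]
    elements: list[str]
    positions: np.ndarray
    charges: np.ndarray
    sigmas: np.ndarray
    epsilons: np.ndarray
    # indices of the C-X pair defining a sigma-hole, if the fragment has one
    carbon_index: int | None = None
    halogen_index: int | None = None
    q_ep: float = 0.0
    ep_separation: float = DEFAULT_EP_SEPARATION
    #: mask of sterics-only sites (repulsive r^-12 wall, no dispersion)
    repulsive: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.epsilons = np.asarray(self.epsilons, dtype=float)
        if self.repulsive is None:
            self.repulsive = np.zeros(len(self.names), dtype=bool)
        else:
            self.repulsive = np.asarray(self.repulsive, dtype=bool)
        n = len(self.names)
        for arr, label in (
            (self.positions, "positions"),
            (self.charges, "charges"),
            (self.sigmas, "sigmas"),
            (self.epsilons, "epsilons"),
            (self.repulsive, "repulsive"),
        ):
            if len(arr) != n:
                raise ValueError(f"{label}: expected {n} entries, got {len(arr)}")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom_index(self, name: str) -> int:
        return self.names.index(name)


def build_chlorobenzene(
    q_halogen: float = DEFAULT_Q_HALOGEN,
    q_ep: float = DEFAULT_Q_EP,
    ep_separation: float = DEFAULT_EP_SEPARATION,
) -> Fragment:
    """Idealized chlorobenzene in the xy-plane, Cl on the +x axis.

    Ring C-C 1.39 A, C-H 1.08 A, C-Cl 1.74 A.  The ipso carbon charge
    balances the net halogen+EP charge so the fragment stays neutral; the
    remaining ring carries alternating -0.115/+0.115 C/H pairs.
    """
    params = load_nonbonded_parameters()
    names, elements, positions, charges, types = [], [], [], [], []
    r_ring, r_ch, r_ccl = 1.39, 1.08, 1.74
    for i in range(6):
        ang = np.radians(60.0 * i)
        u = np.array([np.cos(ang), np.sin(ang), 0.0])
        names.append(f"C{i + 1}")
        elements.append("C")
        positions.append(r_ring * u)
        types.append("ca")
        if i == 0:
            charges.append(-(q_halogen + q_ep))
        else:
            charges.append(-0.115)
            names.append(f"H{i + 1}")
            elements.append("H")
            positions.append((r_ring + r_ch) * u)
            charges.append(0.115)
            types.append("ha")
    names.append("CL1")
    elements.append("Cl")
    positions.append(np.array([r_ring + r_ccl, 0.0, 0.0]))
    charges.append(q_halogen)
    types.append("cl")
    return Fragment(
        names=names,
        elements=elements,
        positions=np.array(positions),
        charges=np.array(charges),
        sigmas=np.array([params[t]["sigma"] for t in types]),
        epsilons=np.array([params[t]["epsilon"] for t in types]),
        carbon_index=0,
        halogen_index=names.index("CL1"),
        q_ep=q_ep,
        ep_separation=ep_separation,
    )


def build_nmethylacetamide() -> Fragment:
    """Planar trans N-methylacetamide with united-atom methyls.

    C=O 1.229 A, C-N 1.335 A, N-H 1.01 A; amide H anti to the carbonyl O
    across the C-N bond, methyls trans, all in the z = 0 plane.  Charges are
    AMBER-flavored with the methyl hydrogens collapsed onto their carbons.
    """
    params = load_nonbonded_parameters()
    c = np.array([0.0, 0.0, 0.0])
    n = np.array([1.335, 0.0, 0.0])
    o = 1.229 * np.array([np.cos(np.radians(122.9)), np.sin(np.radians(122.9)), 0.0])
    ch3a = 1.52 * np.array(
        [np.cos(np.radians(-116.6)), np.sin(np.radians(-116.6)), 0.0]
    )
    ch3n = n + 1.45 * np.array(
        [np.cos(np.radians(58.3)), np.sin(np.radians(58.3)), 0.0]
    )
    h = n + 1.01 * np.array(
        [np.cos(np.radians(-58.3)), np.sin(np.radians(-58.3)), 0.0]
    )
    names = ["C", "O", "N", "H", "CH3C", "CH3N"]
    elements = ["C", "O", "N", "H", "C", "C"]
    positions = np.array([c, o, n, h, ch3a, ch3n])
    charges = np.array([0.5973, -0.5679, -0.4157, 0.2719, -0.0293, 0.1437])
    types = ["c", "o", "n", "hn", "c3u", "c3u"]
    return Fragment(
        names=names,
        elements=elements,
        positions=positions,
        charges=charges,
        sigmas=np.array([params[t]["sigma"] for t in types]),
        epsilons=np.array([params[t]["epsilon"] for t in types]),
    )


def build_amide_partner() -> Fragment:
    """N-methylacetamide embedded in a reduced helix context.

    In TM4 the exposed carbonyl is approachable only from the outward
    C=O direction: the peptide-plane faces are packed against the adjacent
    helix turns and the backside against the helix body.  Three sterics-only
    occluder pseudo-atoms (type 'occ': repulsive r^-12 wall, no charge, no
    dispersion) reproduce that occlusion — two flanking the amide plane,
    one behind the carbonyl carbon — leaving the sigma-hole approach funnel
    open.  Without them an isolated amide's faces are free and an aromatic
    probe simply stacks onto them, a pose the receptor forbids.
    """
    base = build_nmethylacetamide()
    params = load_nonbonded_parameters()
    occ = params["occ"]
    c = base.positions[base.atom_index("C")]
    o = base.positions[base.atom_index("O")]
    u = (o - c) / np.linalg.norm(o - c)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, u)  # in-plane, perpendicular to the carbonyl direction
    lateral = np.radians(75.0)
    occluders = [
        c + 4.7 * z,                    # adjacent helix turn above
        c - 4.7 * z,                    # adjacent helix turn below
        c - 4.2 * u,                    # helix body behind the carbonyl
        o + 4.8 * (np.cos(lateral) * u + np.sin(lateral) * v),   # lateral
        o + 4.8 * (np.cos(lateral) * u - np.sin(lateral) * v),   # helix surface
    ]
    names = base.names + [f"OCC{i + 1}" for i in range(len(occluders))]
    elements = base.elements + ["X"] * len(occluders)
    positions = np.vstack([base.positions, occluders])
    charges = np.append(base.charges, np.zeros(len(occluders)))
    sigmas = np.append(base.sigmas, [occ["sigma"]] * len(occluders))
    epsilons = np.append(base.epsilons, [occ["epsilon"]] * len(occluders))
    repulsive = np.append(
        np.zeros(base.n_atoms, dtype=bool), np.ones(len(occluders), dtype=bool)
    )
    return Fragment(
        names=names,
        elements=elements,
        positions=positions,
        charges=charges,
        sigmas=sigmas,
        epsilons=epsilons,
        repulsive=repulsive,
    )
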