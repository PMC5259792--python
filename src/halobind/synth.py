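"""Synthetic fixtures with recorded ground truth.

Generates the inputs the analysis stages consume: ideal alpha-helices with
optional proline substitutions, chlorobenzene probes posed at a controlled
distance/angle from a chosen backbone carbonyl, Gaussian-jitter trajectories
around a specified mean halogen-bond geometry, and toy receptor sequences
with planted Ballesteros-Weinstein anchor motifs.  Every generator returns a
machine-readable truth record so downstream modules can be tested closed-loop.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structures import (
    Atom,
    Residue,
    Structure,
    ONE_TO_THREE,
    _unit,
    place_atom,
)
from .bw import AnchorSpec, EXPOSURE_OFFSET, MOTIF_WINDOW
from .xbond import xbond_geometry

# Standard backbone internal coordinates (Angstrom / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.01
ANGLE_N_CA_C = 109.5  # tetrahedral CA; reproduces 1.5 A rise / 3.6 res per turn
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8


@dataclass
class HelixSpec:
    """Ideal-helix fixture parameters (phi/psi default to alpha-helical)."""

    length: int
    phi: float = -57.0
    psi: float = -47.0
    omega: float = 180.0
    sequence: str | None = None
    proline_positions: Sequence[int] = ()

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("helix length must be >= 1")
        if any(not (1 <= p <= self.length) for p in self.proline_positions):
            raise ValueError("proline positions must lie within [1, length]")
        if self.sequence is None:
            seq = ["A"] * self.length
            for p in self.proline_positions:
                seq[p - 1] = "P"
            self.sequence = "".join(seq)
        elif len(self.sequence) != self.length:
            raise ValueError("sequence length disagrees with spec length")
        else:
            self.proline_positions = tuple(
                i + 1 for i, c in enumerate(self.sequence) if c == "P"
            )


def build_ideal_helix(spec: HelixSpec) -> Structure:
    """Build an N/CA/C/O/H backbone helix from internal coordinates.

    The amide H is placed on the external bisector of the C(prev)-N-CA angle
    for every non-proline residue after the first; prolines carry no H.
    """
    L = spec.length
    n = [np.array([0.0, 0.0, 0.0])]
    ca = [np.array([BOND_N_CA, 0.0, 0.0])]
    c0 = place_atom(
        np.array([0.0, 1.0, 0.0]), n[0], ca[0], BOND_CA_C, ANGLE_N_CA_C, 120.0
    )
    c = [c0]
    for i in range(L - 1):
        n.append(place_atom(n[i], ca[i], c[i], BOND_C_N, ANGLE_CA_C_N, spec.psi))
        ca.append(place_atom(ca[i], c[i], n[i + 1], BOND_N_CA, ANGLE_C_N_CA, spec.omega))
        c.append(place_atom(c[i], n[i + 1], ca[i + 1], BOND_CA_C, ANGLE_N_CA_C, spec.phi))

    residues = []
    for i in range(L):
        code = spec.sequence[i]
        o = place_atom(n[i], ca[i], c[i], BOND_C_O, ANGLE_CA_C_O, spec.psi + 180.0)
        atoms = [
            Atom("N", "N", n[i]),
            Atom("CA", "C", ca[i]),
            Atom("C", "C", c[i]),
            Atom("O", "O", o),
        ]
        if code != "P" and i > 0:
            h = n[i] - BOND_N_H * _unit(_unit(c[i - 1] - n[i]) + _unit(ca[i] - n[i]))
            atoms.append(Atom("H", "H", h))
        residues.append(
            Residue(index=i + 1, code=code, atoms=atoms,
                    name=ONE_TO_THREE.get(code, "UNK"))
        )
    return Structure(chains={"A": residues}, helix_ranges=[("A", 1, L)])


# --- halogen probe placement -------------------------------------------------

PROBE_CHAIN = "L"
PROBE_RESNAME = "CLB"


def _probe_xyz(probe, o: np.ndarray, v: np.ndarray, spin_deg: float,
               d: float, theta: float) -> np.ndarray:
    """Chlorobenzene coordinates with Cl at o + d*v and C-Cl...O angle theta.

    ``v`` is the O->Cl approach direction; ``spin_deg`` selects the tilt
    plane about that axis.
    """
    from scipy.spatial.transform import Rotation

    body_c = probe.positions[probe.carbon_index]
    body_x = probe.positions[probe.halogen_index]
    axis_body = _unit(body_x - body_c)
    x_pos = o + d * v
    w0 = _unit(
        np.cross(v, [0.0, 0.0, 1.0]) if abs(v[2]) < 0.9
        else np.cross(v, [1.0, 0.0, 0.0])
    )
    w = Rotation.from_rotvec(np.radians(spin_deg) * v).apply(w0)
    tilt = np.radians(180.0 - theta)
    cx_dir = np.cos(tilt) * v + np.sin(tilt) * w  # Cl -> C1
    rot, _ = Rotation.align_vectors([-cx_dir], [axis_body])
    return rot.apply(probe.positions) + (x_pos - rot.apply(body_x))


def place_halogen_probe(
    s: Structure,
    carbonyl_residue: int,
    d: float,
    theta: float,
    chain_id: str | None = None,
    clash_cutoff: float = 2.0,
) -> Structure:
    """Append a chlorobenzene probe posed at (d, theta) vs a backbone carbonyl.

    The chlorine sits at distance ``d`` from the carbonyl O with the
    measured C-Cl...O angle equal to ``theta``; those two constraints leave
    the approach direction and the ring spin free, and both are searched
    (a Fibonacci sphere of approach directions, seeded by the C=O axis,
    times 45-deg ring spins) for the pose with maximal clearance from the
    protein.  The returned structure gains a HETATM residue (chain 'L',
    resname CLB) and ``xbond_geometry`` on its C1/CL1 atoms against the
    chosen O round-trips (d, theta) exactly.  A clearance below
    ``clash_cutoff`` in every candidate pose raises.
    """
    from scipy.spatial.transform import Rotation

    from .fragments import build_chlorobenzene

    if d <= 1.5:
        raise ValueError("probe distance must exceed 1.5 A")
    res = s.residue(carbonyl_residue, chain_id)
    c = res.require_atom("C").position
    o = res.require_atom("O").position
    probe = build_chlorobenzene()
    protein_xyz = np.array(
        [a.position for ch in s.chains.values() for r in ch for a in r.atoms]
    )
    # candidate approach directions: C=O axis first, then a Fibonacci sphere
    golden = np.pi * (3.0 - np.sqrt(5.0))
    k = np.arange(64)
    zs = 1.0 - 2.0 * (k + 0.5) / len(k)
    rs = np.sqrt(1.0 - zs**2)
    sphere = np.stack([rs * np.cos(golden * k), rs * np.sin(golden * k), zs], axis=1)
    directions = np.vstack([[_unit(o - c)], sphere])

    best = None
    best_clearance = -np.inf
    for v in directions:
        v = _unit(v)
        for spin_deg in range(0, 360, 45):
            xyz = _probe_xyz(probe, o, v, spin_deg, d, theta)
            dmin = np.min(
                np.linalg.norm(xyz[:, None, :] - protein_xyz[None, :, :], axis=-1)
            )
            if dmin > best_clearance:
                best_clearance = dmin
                best = xyz
    if best_clearance < clash_cutoff:
        raise ValueError(
            f"cannot place probe at (d={d}, theta={theta}) without a clash "
            f"(best clearance {best_clearance:.2f} A)"
        )
    xyz = best
    out = copy.deepcopy(s)
    atoms = [
        Atom(name, el, pos)
        for name, el, pos in zip(probe.names, probe.elements, xyz)
    ]
    out.chains[PROBE_CHAIN] = [
        Residue(index=1, code="X", atoms=atoms, name=PROBE_RESNAME, het=True)
    ]
    return out


def probe_geometry(s: Structure, carbonyl_residue: int,
                   chain_id: str | None = None):
    """Measured (d, theta) of the placed probe against the chosen carbonyl."""
    probe = s.chains[PROBE_CHAIN][0]
    res = s.residue(carbonyl_residue, chain_id)
    return xbond_geometry(
        probe.require_atom("C1").position,
        probe.require_atom("CL1").position,
        res.require_atom("O").position,
    )


# --- jittered trajectories ---------------------------------------------------


@dataclass
class TrajectorySpec:
    """Gaussian-jitter trajectory around a mean halogen-bond geometry."""

    n_frames: int
    mean_d: float = 3.1
    mean_theta: float = 170.0
    sigma_d: float = 0.15
    sigma_theta: float = 5.0
    drift: float = 0.0
    rigid_motion: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.sigma_d < 0 or self.sigma_theta < 0 or self.drift < 0:
            raise ValueError("jitter sigmas must be non-negative")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class TrajectoryTruth:
    """Per-frame ground truth recorded by the generator."""

    d: np.ndarray
    theta: np.ndarray
    ligand_displacement: np.ndarray
    spec: TrajectorySpec


def synth_trajectory(base: Structure, carbonyl_residue: int, spec: TrajectorySpec):
    """Jitter the probe of ``base`` about its mean geometry, frame by frame.

    Frame 0 is the unperturbed base pose (the docking-pose reference for
    ligand-RMSD analysis); each of the following ``spec.n_frames`` frames
    re-poses the probe at (d_i, theta_i) drawn from the spec's Gaussians
    (theta clipped to [90, 180]), optionally adds an isotropic Gaussian
    drift translation, then (optionally) applies a random rigid motion to
    the whole system.  The truth record carries the realized (post-drift)
    geometry and the ligand displacement RMSD relative to the base pose in
    the protein frame.  Returns (Trajectory, TrajectoryTruth).
    """
    from scipy.spatial.transform import Rotation

    from .traj import Trajectory, structure_labels

    if PROBE_CHAIN not in base.chains:
        raise ValueError("base structure has no probe; call place_halogen_probe")
    rng = np.random.default_rng(spec.seed)
    res = base.residue(carbonyl_residue)
    o_pos = res.require_atom("O").position
    probe_res = base.chains[PROBE_CHAIN][0]
    base_probe = np.array([a.position for a in probe_res.atoms])
    protein_atoms = [
        a
        for cid, ch in base.chains.items()
        if cid != PROBE_CHAIN
        for r in ch
        for a in r.atoms
    ]
    protein_xyz = np.array([a.position for a in protein_atoms])

    names = [a.name for a in probe_res.atoms]
    base_cl = base_probe[names.index("CL1")]
    base_c1 = base_probe[names.index("C1")]
    approach = _unit(base_cl - o_pos)  # O -> Cl direction of the base pose
    cx = _unit(base_c1 - base_cl)
    # tilt-plane normal: rotating the probe about it (through Cl) changes theta
    normal = np.cross(approach, cx)
    if np.linalg.norm(normal) < 1e-8:  # collinear base pose: any perpendicular
        normal = np.cross(
            approach,
            [0.0, 0.0, 1.0] if abs(approach[2]) < 0.9 else [1.0, 0.0, 0.0],
        )
    normal = _unit(normal)

    g0 = xbond_geometry(base_c1, base_cl, o_pos)
    frames = [np.vstack([protein_xyz, base_probe])]
    d_true, th_true, disp = [g0.d], [g0.theta], [0.0]
    for _ in range(spec.n_frames):
        d_i = max(1.6, rng.normal(spec.mean_d, spec.sigma_d))
        th_i = float(np.clip(rng.normal(spec.mean_theta, spec.sigma_theta), 90.0, 180.0))
        # rotate the rigid base probe about Cl to realize theta_i, then slide
        # it along the approach axis to realize d_i; zero jitter is the base
        rot = Rotation.from_rotvec(np.radians(g0.theta - th_i) * normal)
        xyz_probe = rot.apply(base_probe - base_cl) + base_cl
        xyz_probe = xyz_probe + (d_i - g0.d) * approach
        if spec.drift > 0:
            xyz_probe = xyz_probe + rng.normal(0.0, spec.drift, 3)
        g = xbond_geometry(
            xyz_probe[names.index("C1")], xyz_probe[names.index("CL1")], o_pos
        )
        d_true.append(g.d)
        th_true.append(g.theta)
        disp.append(
            float(np.sqrt(np.mean(np.sum((xyz_probe - base_probe) ** 2, axis=1))))
        )
        frame = np.vstack([protein_xyz, xyz_probe])
        if spec.rigid_motion:
            rot = Rotation.random(rng=rng)
            shift = rng.normal(0.0, 5.0, 3)
            frame = rot.apply(frame) + shift
        frames.append(frame)

    labels = [
        f"{cid}:{r.index}:{a.name}"
        for cid, ch in base.chains.items()
        if cid != PROBE_CHAIN
        for r in ch
        for a in r.atoms
    ] + [f"{PROBE_CHAIN}:1:{a.name}" for a in probe_res.atoms]
    traj = Trajectory(coords=np.stack(frames), labels=labels, topology=base)
    truth = TrajectoryTruth(
        d=np.array(d_true),
        theta=np.array(th_true),
        ligand_displacement=np.array(disp),
        spec=spec,
    )
    return traj, truth


# --- anchored receptor sequences --------------------------------------------

_AA_NO_P = "ACDEFGHIKLMNQRSTVWY"


@dataclass
class SequenceTruth:
    sequence: str
    anchor: AnchorSpec
    spans: dict
    motif: str
    proline_positions: tuple
    exposed_labels: tuple


def synth_receptor_sequence(motif: str, seed: int, length: int = 60):
    """Random sequence with a planted TM4 anchor (W at 4.50) and proline motif.

    The TM4 span is positions 11..45 with the anchor at 25; motif prolines
    are planted per the classifier's decision table (P and PP end at 4.60,
    PxP at 4.61), and the scan window is otherwise proline-free.  Returns
    (sequence, AnchorSpec, spans, SequenceTruth) with the expected motif
    call and exposed-carbonyl labels.
    """
    if motif not in ("P", "PP", "PxP", "none"):
        raise ValueError(f"unknown motif {motif!r}")
    rng = np.random.default_rng(seed)
    anchor_pos = 25
    span = (11, 45)
    seq = [rng.choice(list(_AA_NO_P + "P")) for _ in range(length)]
    lo, hi = MOTIF_WINDOW
    window = range(anchor_pos + (lo - 50), anchor_pos + (hi - 50) + 1)
    for pos in window:  # keep the scan window proline-free, then plant
        seq[pos - 1] = str(rng.choice(list(_AA_NO_P)))
    plant = {
        "P": (60,),
        "PP": (59, 60),
        "PxP": (59, 61),
        "none": (),
    }[motif]
    positions = tuple(anchor_pos + nn - 50 for nn in plant)
    for pos in positions:
        seq[pos - 1] = "P"
    seq[anchor_pos - 1] = "W"
    sequence = "".join(seq)
    anchor = AnchorSpec(tm=4, position=anchor_pos, expected_aa="W")
    spans = {4: span}
    exposed = tuple(f"4.{nn - EXPOSURE_OFFSET}" for nn in plant)
    truth = SequenceTruth(
        sequence=sequence,
        anchor=anchor,
        spans=spans,
        motif=motif,
        proline_positions=positions,
        exposed_labels=exposed,
    )
    return sequence, anchor, spans, truth
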