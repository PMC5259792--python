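"""Trajectory analysis: Kabsch superposition, ligand RMSD and geometry series.

The standard ligand-stability protocol: superpose every frame on a
reference using a fit selection (receptor backbone), then measure the RMSD
of a report selection (the ligand) without re-fitting, plus per-frame
halogen-bond geometry with summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .structures import Atom, Structure, _from_gemmi_model
from .xbond import XBondCriteria, XBondGeometry, classify_halogen_bond, xbond_geometry


@dataclass
class Trajectory:
    """Frames of coordinates over a fixed atom topology.

    ``coords`` has shape (n_frames, n_atoms, 3); ``labels`` identify atoms
    as "chain:resindex:atomname" strings; ``topology`` is the Structure of
    the first frame (atom order matches).
    """

    coords: np.ndarray
    labels: list[str]
    topology: Structure | None = None
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.labels):
            raise ValueError("labels length must match atom count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, predicate: str | Callable[[str], bool]) -> np.ndarray:
        """Atom indices whose label satisfies the predicate.

        A string predicate is matched as a substring of the label (e.g. a
        residue name fragment like ":12:" or an atom name like ":CL1").
        """
        if callable(predicate):
            idx = [i for i, lab in enumerate(self.labels) if predicate(lab)]
        else:
            idx = [i for i, lab in enumerate(self.labels) if predicate in lab]
        if not idx:
            raise ValueError(f"selection {predicate!r} matches no atoms")
        return np.array(idx)


def structure_labels(s: Structure) -> list[str]:
    return [
        f"{cid}:{res.index}:{atom.name}"
        for cid, residues in s.chains.items()
        for res in residues
        for atom in res.atoms
    ]


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a multi-MODEL PDB as a trajectory (constant topology required)."""
    import gemmi

    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    frames = []
    labels = None
    topology = None
    for model in st:
        s = _from_gemmi_model(model)
        labs = structure_labels(s)
        coords = np.array([a.position for a in s.atoms()])
        if labels is None:
            labels, topology = labs, s
        elif labs != labels:
            raise ValueError(f"{path}: MODELs differ in atom topology")
        frames.append(coords)
    return Trajectory(coords=np.stack(frames), labels=labels, topology=topology)


def write_trajectory(t: Trajectory, path: str | Path) -> None:
    """Write as multi-MODEL PDB using the topology of the first frame."""
    from .structures import _pdb_atom_line

    if t.topology is None:
        raise ValueError("trajectory has no topology to write")
    lines = []
    for i in range(t.n_frames):
        lines.append(f"MODEL     {i + 1:>4}")
        serial = 0
        ai = 0
        for cid, residues in t.topology.chains.items():
            for res in residues:
                for atom in res.atoms:
                    serial += 1
                    moved = Atom(atom.name, atom.element, t.coords[i, ai], res.index)
                    lines.append(_pdb_atom_line(serial, moved, res, cid))
                    ai += 1
            lines.append(f"TER   {serial + 1:>5}")
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of mobile onto reference.

    Returns (rotation matrix R, translation t, post-fit RMSD) such that
    ``mobile @ R.T + t`` best matches ``reference``.  Reflections are
    excluded by the determinant correction, so R is a proper rotation.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a rigid superposition")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    mu_m = w @ mobile
    mu_r = w @ reference
    mc = mobile - mu_m
    rc = reference - mu_r
    # collinearity check: centered reference must span at least a plane
    if np.linalg.matrix_rank(rc, tol=1e-8) < 2:
        raise ValueError("reference points are collinear; rotation underdetermined")
    h = (mc * w[:, None]).T @ rc
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    t = mu_r - rot @ mu_m
    fitted = mc @ rot.T + mu_r
    rmsd = float(np.sqrt(np.sum(w[:, None] * (fitted - reference) ** 2)))
    return rot, t, rmsd


@dataclass
class RMSDSeries:
    """Per-frame RMSD of a report selection after fitting on a fit selection."""

    values: np.ndarray
    reference_frame: int
    mean: float
    sd: float

    @classmethod
    def from_values(cls, values: np.ndarray, reference_frame: int) -> "RMSDSeries":
        values = np.asarray(values, dtype=float)
        return cls(
            values=values,
            reference_frame=reference_frame,
            mean=float(values.mean()),
            sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        )


def ligand_rmsd_series(
    t: Trajectory,
    fit_selection,
    report_selection,
    reference_frame: int = 0,
    weights: np.ndarray | None = None,
) -> RMSDSeries:
    """Ligand RMSD vs a reference frame after superposing on the fit selection.

    Every frame is rigidly superposed on the reference frame using only the
    fit-selection atoms (receptor-backbone analogue); the RMSD is then taken
    over the report selection (the ligand) without re-fitting, so genuine
    ligand motion relative to the receptor is retained while global rigid
    motion is removed.  Uniform weights by default.
    """
    fit_idx = t.select(fit_selection) if not isinstance(
        fit_selection, np.ndarray
    ) else fit_selection
    rep_idx = t.select(report_selection) if not isinstance(
        report_selection, np.ndarray
    ) else report_selection
    ref_fit = t.coords[reference_frame, fit_idx]
    ref_rep = t.coords[reference_frame, rep_idx]
    out = np.empty(t.n_frames)
    for i in range(t.n_frames):
        rot, shift, _ = kabsch_superpose(t.coords[i, fit_idx], ref_fit, weights)
        rep = t.coords[i, rep_idx] @ rot.T + shift
        out[i] = np.sqrt(np.mean(np.sum((rep - ref_rep) ** 2, axis=1)))
    return RMSDSeries.from_values(out, reference_frame)


@dataclass
class GeometrySeries:
    """Per-frame halogen-bond geometry with summary statistics."""

    d: np.ndarray
    theta: np.ndarray
    bonded: np.ndarray
    mean_d: float
    mean_theta: float
    sd_d: float
    sd_theta: float
    bonded_only: bool


def geometry_series(
    t: Trajectory,
    carbon: int | str,
    halogen: int | str,
    oxygen: int | str,
    criteria: XBondCriteria | None = None,
    bonded_only: bool = False,
) -> GeometrySeries:
    """Per-frame (d, theta) of a C-X...O triple plus mean/sd summary.

    Atoms may be given as indices or label substrings resolving to exactly
    one atom.  Summary statistics cover all frames by default, or only the
    frames passing the halogen-bond criteria with ``bonded_only=True``.
    """
    def resolve(a) -> int:
        if isinstance(a, (int, np.integer)):
            if not 0 <= a < t.n_atoms:
                raise ValueError(f"atom index {a} out of range")
            return int(a)
        idx = t.select(a)
        if len(idx) != 1:
            raise ValueError(f"selection {a!r} must resolve to exactly one atom")
        return int(idx[0])

    ci, xi, oi = resolve(carbon), resolve(halogen), resolve(oxygen)
    criteria = criteria or XBondCriteria()
    d = np.empty(t.n_frames)
    theta = np.empty(t.n_frames)
    bonded = np.empty(t.n_frames, dtype=bool)
    for i in range(t.n_frames):
        g = xbond_geometry(t.coords[i, ci], t.coords[i, xi], t.coords[i, oi])
        d[i], theta[i] = g.d, g.theta
        bonded[i] = classify_halogen_bond(g, criteria).bonded
    subset = bonded if bonded_only else np.ones(t.n_frames, dtype=bool)
    if subset.sum() == 0:
        mean_d = mean_theta = sd_d = sd_theta = float("nan")
    else:
        mean_d = float(d[subset].mean())
        mean_theta = float(theta[subset].mean())
        sd_d = float(d[subset].std(ddof=1)) if subset.sum() > 1 else 0.0
        sd_theta = float(theta[subset].std(ddof=1)) if subset.sum() > 1 else 0.0
    return GeometrySeries(
        d=d, theta=theta, bonded=bonded,
        mean_d=mean_d, mean_theta=mean_theta, sd_d=sd_d, sd_theta=sd_theta,
        bonded_only=bonded_only,
    )
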