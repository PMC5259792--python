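"""Structural data model, PDB I/O and geometric primitives.

Coordinates are in Angstrom throughout; residue indices are 1-based per
chain and helix ranges are inclusive, following PDB convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: N-H bond length used when the amide hydrogen has to be rebuilt (Angstrom).
NH_BOND_LENGTH = 1.01


@dataclass
class Atom:
    """A single atom: PDB atom name, element symbol and position in Angstrom."""

    name: str
    element: str
    position: np.ndarray
    residue_index: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: position must be 3 finite floats")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: empty element symbol")


@dataclass
class Residue:
    """One residue: 1-based index, one-letter code and its atoms.

    ``het`` marks HETATM groups (ligands, probes); their ``code`` is 'X'.
    """

    index: int
    code: str
    atoms: list[Atom] = field(default_factory=list)
    name: str = ""
    het: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            self.name = ONE_TO_THREE.get(self.code, "UNK")
        for a in self.atoms:
            a.residue_index = self.index

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def require_atom(self, name: str) -> Atom:
        a = self.atom(name)
        if a is None:
            raise KeyError(f"residue {self.index} ({self.name}): missing atom {name!r}")
        return a

    @property
    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in BACKBONE_ATOMS)

    @property
    def has_backbone_NH(self) -> bool:
        """Whether the backbone N-H donor exists.

        Proline has no amide hydrogen, so it can never donate.  For other
        residues the donor exists as soon as N is present: a missing explicit
        H is rebuilt geometrically by :meth:`amide_h_position`.
        """
        return self.code != "P" and self.atom("N") is not None

    def amide_h_position(self, prev: "Residue | None") -> np.ndarray:
        """Explicit backbone amide H position, rebuilt if the record lacks one.

        The rebuilt H sits on the external bisector of the C(prev)-N-CA
        angle, in that plane, at ``NH_BOND_LENGTH`` from N.  Requires the
        preceding residue's carbonyl C; chain-initial residues therefore have
        no reconstructible amide H.
        """
        if self.code == "P":
            raise ValueError(f"residue {self.index}: proline has no amide H")
        h = self.atom("H")
        if h is not None:
            return h.position
        if prev is None:
            raise ValueError(f"residue {self.index}: chain-initial N-H cannot be rebuilt")
        n = self.require_atom("N").position
        ca = self.require_atom("CA").position
        c_prev = prev.require_atom("C").position
        u = _unit(c_prev - n) + _unit(ca - n)
        return n - NH_BOND_LENGTH * _unit(u)


@dataclass
class Structure:
    """Ordered chains of residues with optional inclusive helix ranges."""

    chains: dict[str, list[Residue]] = field(default_factory=dict)
    helix_ranges: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            idx = [r.index for r in residues]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError(f"chain {cid}: residue indices must strictly increase")
        for cid, start, end in self.helix_ranges:
            self._check_range(cid, start, end)

    def _check_range(self, chain_id: str, start: int, end: int) -> None:
        residues = self.chains.get(chain_id)
        if residues is None:
            raise ValueError(f"no chain {chain_id!r}")
        present = {r.index for r in residues}
        if start > end or start not in present or end not in present:
            raise ValueError(
                f"helix range {chain_id}:{start}-{end} outside chain bounds"
            )

    def chain(self, chain_id: str | None = None) -> list[Residue]:
        if chain_id is None:
            chain_id = next(iter(self.chains))
        return self.chains[chain_id]

    def residue(self, index: int, chain_id: str | None = None) -> Residue:
        for r in self.chain(chain_id):
            if r.index == index:
                return r
        raise KeyError(f"no residue {index} in chain {chain_id or 'first'}")

    def atoms(self) -> list[Atom]:
        return [a for ch in self.chains.values() for r in ch for a in r.atoms]

    @property
    def sequence(self) -> str:
        return "".join(r.code for r in self.chain() if not r.het)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def distance(a, b) -> float:
    """Euclidean distance between two points in Angstrom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.linalg.norm(a - b))


def angle(a, b, c) -> float:
    """Angle a-b-c at vertex b, in degrees, in [0, 180]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("degenerate angle: zero-length arm")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(a, b, c, d) -> float:
    """Torsion angle a-b-c-d in degrees, in (-180, 180]."""
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, theta_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given three predecessors and internal coordinates.

    Natural-extension (NeRF) construction: ``bond`` is |C-D|, ``theta_deg``
    the B-C-D angle and ``torsion_deg`` the A-B-C-D dihedral.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(theta_deg)
    tau = np.radians(torsion_deg)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(tau), np.sin(theta) * np.sin(tau)]
    )
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.stack([bc, np.cross(n, bc), n], axis=1)
    return c + m @ d_local


# --- PDB I/O -----------------------------------------------------------------

def _from_gemmi_model(model, keep_altlocs=("", "A")) -> Structure:
    import gemmi

    chains: dict[str, list[Residue]] = {}
    dropped = 0
    for ch in model:
        residues = []
        for res in ch:
            atoms = []
            for at in res:
                alt = at.altloc if at.altloc != "\x00" else ""
                if alt not in keep_altlocs:
                    dropped += 1
                    continue
                atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name or at.name[:1],
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        residue_index=res.seqid.num,
                    )
                )
            het = res.het_flag == "H"
            code = THREE_TO_ONE.get(res.name, "X")
            residues.append(
                Residue(index=res.seqid.num, code=code, atoms=atoms,
                        name=res.name, het=het)
            )
        if residues:
            chains[ch.name] = residues
    if dropped:
        log.warning("dropped %d non-A altloc atoms", dropped)
    return Structure(chains=chains)


def read_structure(path: str | Path, model: int = 0) -> Structure:
    """Read a PDB file into a :class:`Structure` (first MODEL by default).

    Altloc policy: blank or 'A' kept, others dropped with a logged count.
    Helix ranges are taken from HELIX records when present.  Multi-MODEL
    files are trajectories; use :func:`halobind.traj.read_trajectory` to keep
    every frame (a warning is logged here).
    """
    import gemmi

    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty PDB file")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: PDB parse error: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models / ATOM records")
    if len(st) > 1 and model == 0:
        log.warning("%s has %d MODELs; reading the first (see halobind.traj)",
                    path, len(st))
    structure = _from_gemmi_model(st[model])
    for helix in st.helices:
        cid = helix.start.chain_name
        if cid in structure.chains:
            structure.helix_ranges.append(
                (cid, helix.start.res_id.seqid.num, helix.end.res_id.seqid.num)
            )
    return structure


def _pdb_atom_line(serial: int, atom: Atom, res: Residue, chain_id: str) -> str:
    record = "HETATM" if res.het else "ATOM"
    name = atom.name
    # PDB column rule: 1-letter elements start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    x, y, z = atom.position
    return (
        f"{record:<6}{serial:>5} {name:<4} {res.name:<3} {chain_id}"
        f"{res.index:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2}"
    )


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as PDB (ATOM/HETATM/TER/END), 3-decimal coordinates."""
    lines = []
    serial = 0
    for cid, residues in structure.chains.items():
        for res in residues:
            for atom in res.atoms:
                serial += 1
                lines.append(_pdb_atom_line(serial, atom, res, cid))
        lines.append(f"TER   {serial + 1:>5}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
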