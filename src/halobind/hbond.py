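"""Backbone hydrogen-bond network analysis and exposed-carbonyl detection.

A proline at helix position i lacks the amide hydrogen, breaking the
i-4 -> i backbone hydrogen bond of an alpha-helix and leaving the carbonyl
oxygen of residue i-4 unsatisfied ("exposed") — the structural feature that
lets a ligand halogen atom reach the TM4 backbone in serotonin receptors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .structures import Residue, Structure, distance

log = logging.getLogger(__name__)

#: DSSP electrostatic coupling constant: q1*q2*332 = 0.42*0.20*332 kcal*A/mol.
DSSP_COUPLING = 0.084 * 332.0

#: Default H-bond acceptance threshold (kcal/mol), the DSSP convention.
DEFAULT_CUTOFF = -0.5

#: Donor offsets considered for a local helical network (3_10 / alpha / pi).
DONOR_OFFSETS = (3, 4, 5)


@dataclass(frozen=True)
class BackboneHBond:
    """An accepted backbone N-H(donor) ... O=C(acceptor) hydrogen bond."""

    donor: int
    acceptor: int
    energy: float


@dataclass(frozen=True)
class ExposedCarbonyl:
    """A carbonyl O with no accepted backbone H-bond from donors i+3..i+5.

    ``cause`` is the index of the proline whose missing N-H broke the i+4
    bond, or the string ``"unsatisfied"`` when no proline is responsible.
    """

    residue: int
    cause: int | str
    bw_label: str | None = None


def hbond_energy(donor: Residue, acceptor: Residue, prev: Residue | None) -> float:
    """DSSP electrostatic H-bond energy (kcal/mol) of donor N-H vs acceptor C=O.

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN).  ``prev`` is the
    residue preceding the donor, needed to rebuild a missing amide H.
    Returns +inf when any inter-atom distance drops below 0.5 A (overlapping
    atoms make the point-charge model meaningless).
    """
    if not donor.has_backbone_NH:
        raise ValueError(f"residue {donor.index}: no backbone N-H donor")
    h = donor.amide_h_position(prev)
    n = donor.require_atom("N").position
    c = acceptor.require_atom("C").position
    o = acceptor.require_atom("O").position
    r_on, r_ch = distance(o, n), distance(c, h)
    r_oh, r_cn = distance(o, h), distance(c, n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return math.inf
    return DSSP_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _helix_residues(
    s: Structure, helix_range: tuple[int, int], chain_id: str | None
) -> dict[int, Residue]:
    start, end = helix_range
    if end - start + 1 < 5:
        raise ValueError(
            f"helix range {start}-{end} shorter than 5 residues: no i+3..i+5 "
            "donor network to analyze"
        )
    byindex = {}
    for r in s.chain(chain_id):
        if start <= r.index <= end and not r.het:
            if r.has_backbone:
                byindex[r.index] = r
            else:
                log.warning(
                    "residue %d lacks full backbone; excluded from H-bond analysis",
                    r.index,
                )
    if not byindex:
        raise ValueError(f"helix range {start}-{end} contains no usable residues")
    return byindex


def find_backbone_hbonds(
    s: Structure,
    helix_range: tuple[int, int],
    cutoff: float = DEFAULT_CUTOFF,
    chain_id: str | None = None,
) -> list[BackboneHBond]:
    """All accepted (donor i+k -> acceptor i) bonds, k in {3,4,5}, E <= cutoff.

    Prolines never appear as donors.  Sorted by acceptor index, then donor.
    """
    if cutoff >= 0:
        raise ValueError("cutoff must be negative (attractive H-bond energy)")
    byindex = _helix_residues(s, helix_range, chain_id)
    chainmap = {r.index: r for r in s.chain(chain_id) if not r.het}
    bonds = []
    for i, acceptor in sorted(byindex.items()):
        for k in DONOR_OFFSETS:
            donor = byindex.get(i + k)
            prev = chainmap.get(i + k - 1)
            if donor is None or not donor.has_backbone_NH:
                continue
            if donor.atom("H") is None and prev is None:
                continue  # amide H not rebuildable without preceding carbonyl
            e = hbond_energy(donor, acceptor, prev)
            if e <= cutoff:
                bonds.append(BackboneHBond(donor=i + k, acceptor=i, energy=e))
    return bonds


def exposed_carbonyls(
    s: Structure,
    helix_range: tuple[int, int],
    cutoff: float = DEFAULT_CUTOFF,
    chain_id: str | None = None,
) -> list[ExposedCarbonyl]:
    """Carbonyl oxygens with no accepted local backbone H-bond.

    Residue i (within [start, end-4]; the last four residues of the range
    have no candidate donors and are excluded) is flagged when no donor in
    i+3..i+5 satisfies E <= cutoff.  When the i+4 donor is a proline, that
    proline index is reported as the cause — the i-4 exposure rule.
    """
    bonds = find_backbone_hbonds(s, helix_range, cutoff, chain_id)
    satisfied = {b.acceptor for b in bonds}
    byindex = _helix_residues(s, helix_range, chain_id)
    start, end = helix_range
    out = []
    for i in sorted(byindex):
        if i > end - 4 or i in satisfied:
            continue
        donor4 = byindex.get(i + 4)
        cause: int | str
        if donor4 is not None and donor4.code == "P":
            cause = i + 4
        else:
            cause = "unsatisfied"
        out.append(ExposedCarbonyl(residue=i, cause=cause))
    return out
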