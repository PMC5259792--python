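"""Backbone H-bond network and the proline i-4 exposure rule."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from halobind.hbond import (
    exposed_carbonyls,
    find_backbone_hbonds,
    hbond_energy,
)
from halobind.structures import Atom, Residue, Structure
from halobind.synth import HelixSpec, build_ideal_helix


def dssp_oracle(structure, donor_i, acceptor_i):
    """Direct formula evaluation, independent of the module's bookkeeping."""
    ch = {r.index: r for r in structure.chain()}
    donor, acceptor, prev = ch[donor_i], ch[acceptor_i], ch[donor_i - 1]
    h = donor.amide_h_position(prev)
    n = donor.atom("N").position
    c = acceptor.atom("C").position
    o = acceptor.atom("O").position
    r = lambda a, b: float(np.linalg.norm(a - b))
    return 27.888 * (1 / r(o, n) + 1 / r(c, h) - 1 / r(o, h) - 1 / r(c, n))


def test_ideal_helix_i4_energy(ideal_helix):
    ch = {r.index: r for r in ideal_helix.chain()}
    e = hbond_energy(ch[10], ch[6], ch[9])
    assert e < -0.5
    assert e == pytest.approx(dssp_oracle(ideal_helix, 10, 6), abs=1e-12)


def test_proline_donor_rejected(pro12_helix):
    ch = {r.index: r for r in pro12_helix.chain()}
    with pytest.raises(ValueError, match="N-H donor"):
        hbond_energy(ch[12], ch[8], ch[11])


def test_long_range_energy_vanishes(ideal_helix):
    """1/r terms cancel at long range: 30 A separation gives |E| < 0.05."""
    donor = ideal_helix.residue(10)
    prev = ideal_helix.residue(9)
    far = Residue(
        index=99, code="A",
        atoms=[
            Atom("N", "N", (30.0, 0, 0)),
            Atom("CA", "C", (31.4, 0, 0)),
            Atom("C", "C", (32.0, 1.0, 0)),
            Atom("O", "O", (31.6, 2.2, 0)),
        ],
    )
    assert abs(hbond_energy(donor, far, prev)) < 0.05


def test_overlapping_atoms_get_inf_sentinel(ideal_helix):
    donor = ideal_helix.residue(10)
    prev = ideal_helix.residue(9)
    n_pos = donor.atom("N").position
    clash = Residue(
        index=99, code="A",
        atoms=[
            Atom("N", "N", n_pos + 10.0),
            Atom("CA", "C", n_pos + 11.0),
            Atom("C", "C", n_pos + (0.1, 0, 0)),
            Atom("O", "O", n_pos + (0.2, 0, 0)),
        ],
    )
    assert hbond_energy(donor, clash, prev) == math.inf


def test_ideal_helix_bond_pattern(ideal_helix):
    """Every interior residue accepts from i+4; exhaustive-oracle agreement."""
    bonds = find_backbone_hbonds(ideal_helix, (1, 20), cutoff=-0.5)
    i4 = {(b.donor, b.acceptor) for b in bonds if b.donor - b.acceptor == 4}
    assert i4 == {(i + 4, i) for i in range(1, 17)}
    # oracle: exhaustive pair evaluation over the same donor window
    expected = set()
    for i in range(1, 21):
        for k in (3, 4, 5):
            j = i + k
            if j < 2 or j > 20:
                continue
            if ideal_helix.residue(j).code == "P":
                continue
            if dssp_oracle(ideal_helix, j, i) <= -0.5:
                expected.add((j, i))
    assert {(b.donor, b.acceptor) for b in bonds} == expected


def test_proline_never_donates(pro12_helix):
    bonds = find_backbone_hbonds(pro12_helix, (1, 20), cutoff=-0.5)
    assert all(b.donor != 12 for b in bonds)
    assert all(not (b.acceptor == 8 and b.donor == 12) for b in bonds)


def test_short_range_rejected(ideal_helix):
    with pytest.raises(ValueError, match="shorter than 5"):
        find_backbone_hbonds(ideal_helix, (1, 4), cutoff=-0.5)


def test_nonnegative_cutoff_rejected(ideal_helix):
    with pytest.raises(ValueError, match="negative"):
        find_backbone_hbonds(ideal_helix, (1, 20), cutoff=0.5)


def test_exposed_carbonyl_i4_rule(pro12_helix):
    exposed = exposed_carbonyls(pro12_helix, (1, 20), cutoff=-0.5)
    assert [(e.residue, e.cause) for e in exposed] == [(8, 12)]


def test_ideal_helix_has_no_exposed_carbonyls(ideal_helix):
    assert exposed_carbonyls(ideal_helix, (1, 20), cutoff=-0.5) == []


def test_double_proline_exposes_two_carbonyls():
    s = build_ideal_helix(HelixSpec(20, proline_positions=(12, 13)))
    exposed = exposed_carbonyls(s, (1, 20), cutoff=-0.5)
    assert [(e.residue, e.cause) for e in exposed] == [(8, 12), (9, 13)]


def test_proline_cause_offset_is_always_four():
    for pro in (10, 12, 14):
        s = build_ideal_helix(HelixSpec(20, proline_positions=(pro,)))
        for e in exposed_carbonyls(s, (1, 20), cutoff=-0.5):
            if isinstance(e.cause, int):
                assert e.cause - e.residue == 4


def test_mutating_proline_back_to_ala_empties_exposed_list():
    """Detection is causally tied to the missing donor, not to geometry."""
    with_pro = build_ideal_helix(HelixSpec(20, proline_positions=(12,)))
    without = build_ideal_helix(HelixSpec(20))
    assert exposed_carbonyls(with_pro, (1, 20), -0.5) != []
    assert exposed_carbonyls(without, (1, 20), -0.5) == []


def test_output_invariant_under_rigid_transform(pro12_helix):
    rng = np.random.default_rng(7)
    rot = Rotation.random(rng=rng)
    shift = rng.normal(size=3) * 20
    moved_chains = {}
    for cid, residues in pro12_helix.chains.items():
        moved_chains[cid] = [
            Residue(
                index=r.index, code=r.code, name=r.name, het=r.het,
                atoms=[
                    Atom(a.name, a.element, rot.apply(a.position) + shift)
                    for a in r.atoms
                ],
            )
            for r in residues
        ]
    moved = Structure(chains=moved_chains)
    orig = exposed_carbonyls(pro12_helix, (1, 20), -0.5)
    new = exposed_carbonyls(moved, (1, 20), -0.5)
    assert [(e.residue, e.cause) for e in new] == [(e.residue, e.cause) for e in orig]
    b0 = find_backbone_hbonds(pro12_helix, (1, 20), -0.5)
    b1 = find_backbone_hbonds(moved, (1, 20), -0.5)
    assert [(b.donor, b.acceptor) for b in b0] == [(b.donor, b.acceptor) for b in b1]
    assert np.allclose([b.energy for b in b0], [b.energy for b in b1], atol=1e-9)
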