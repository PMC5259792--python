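"""Five-element antagonist pharmacophore annotation.

Serotonin 5-HT6 receptor antagonists share four structural elements: a
positive ionisable atom (PI, typically a basic amine), a central aromatic
ring (AR), a hydrogen-bond acceptor (HBA, sulfonyl/carbonyl oxygens) and a
hydrophobic site (HYD, a terminal aromatic system).  The extended model
adds a fifth element: a halogen attached to HYD, positioned to halogen-bond
the exposed TM4 backbone carbonyl.  This module detects all five on an
annotated small molecule and reports four-point / five-point matches.

Aromaticity is read from the input annotation (SD-style aromatic flags, or
RDKit perception when a molecule is built from SMILES); it is never
re-perceived from geometry, which keeps the matcher deterministic across
input dialects.  Inter-feature distances are reported but not gated: the
model is topological.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HALOGENS = {"Cl", "Br", "I"}


@dataclass(frozen=True)
class MolAtom:
    element: str
    position: tuple[float, float, float]
    formal_charge: int
    aromatic: bool
    n_h: int


@dataclass(frozen=True)
class MolBond:
    a: int
    b: int
    order: float
    aromatic: bool


@dataclass
class Molecule:
    """Annotated small molecule: atoms with aromatic flags, bonds with orders."""

    atoms: list[MolAtom]
    bonds: list[MolBond]
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.a < n and 0 <= b.b < n) or b.a == b.b:
                raise ValueError(f"bond ({b.a}, {b.b}) has invalid endpoints")
            if b.aromatic and not (
                self.atoms[b.a].aromatic and self.atoms[b.b].aromatic
            ):
                raise ValueError(
                    f"aromatic bond ({b.a}, {b.b}) joins non-aromatic atoms"
                )

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_rdkit(cls, mol, name: str = "") -> "Molecule":
        from rdkit.Chem import AllChem

        if mol.GetNumConformers() == 0:
            AllChem.Compute2DCoords(mol)
        conf = mol.GetConformer()
        atoms = []
        for a in mol.GetAtoms():
            p = conf.GetAtomPosition(a.GetIdx())
            atoms.append(
                MolAtom(
                    element=a.GetSymbol(),
                    position=(p.x, p.y, p.z),
                    formal_charge=a.GetFormalCharge(),
                    aromatic=a.GetIsAromatic(),
                    n_h=a.GetTotalNumHs(),
                )
            )
        bonds = [
            MolBond(
                a=b.GetBeginAtomIdx(),
                b=b.GetEndAtomIdx(),
                order=b.GetBondTypeAsDouble(),
                aromatic=b.GetIsAromatic(),
            )
            for b in mol.GetBonds()
        ]
        return cls(atoms=atoms, bonds=bonds, name=name or mol.GetProp("_Name")
                   if mol.HasProp("_Name") else name)

    @classmethod
    def from_smiles(cls, smiles: str, name: str = "") -> "Molecule":
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        return cls.from_rdkit(mol, name=name)

    @classmethod
    def from_molblock(cls, block: str, name: str = "") -> "Molecule":
        """Parse a V2000 mol block, keeping its aromatic annotation as-is."""
        from rdkit import Chem

        mol = Chem.MolFromMolBlock(block, sanitize=False, removeHs=False)
        if mol is None:
            raise ValueError("unparseable mol block")
        flags = (
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
            ^ Chem.SanitizeFlags.SANITIZE_SETAROMATICITY
        )
        Chem.SanitizeMol(mol, sanitizeOps=flags, catchErrors=True)
        mol.UpdatePropertyCache(strict=False)
        # propagate V2000 order-4 annotation onto the atoms
        for bond in mol.GetBonds():
            if bond.GetBondType() == Chem.BondType.AROMATIC:
                bond.SetIsAromatic(True)
                bond.GetBeginAtom().SetIsAromatic(True)
                bond.GetEndAtom().SetIsAromatic(True)
        mol = Chem.RemoveHs(mol, sanitize=False)
        return cls.from_rdkit(mol, name=name)

    @classmethod
    def from_sdf(cls, path) -> "Molecule":
        text = open(path).read()
        block = text.split("$$$$")[0]
        name = block.splitlines()[0].strip() if block.splitlines() else ""
        return cls.from_molblock(block, name=name)

    # -- graph helpers -------------------------------------------------------

    def neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.a == i:
                out.append(b.b)
            elif b.b == i:
                out.append(b.a)
        return out

    def bond_between(self, i: int, j: int) -> MolBond | None:
        for b in self.bonds:
            if {b.a, b.b} == {i, j}:
                return b
        return None

    def has_cycle(self) -> bool:
        parent = list(range(len(self.atoms)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for b in self.bonds:
            ra, rb = find(b.a), find(b.b)
            if ra == rb:
                return True
            parent[ra] = rb
        return False

    def aromatic_systems(self) -> list[frozenset[int]]:
        """Connected components of aromatic atoms linked by aromatic bonds."""
        adj: dict[int, set[int]] = {}
        for b in self.bonds:
            if b.aromatic:
                adj.setdefault(b.a, set()).add(b.b)
                adj.setdefault(b.b, set()).add(b.a)
        seen: set[int] = set()
        systems = []
        for start in sorted(adj):
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                x = stack.pop()
                for y in adj.get(x, ()):
                    if y not in comp:
                        comp.add(y)
                        stack.append(y)
            seen |= comp
            systems.append(frozenset(comp))
        return systems


@dataclass
class FeatureSet:
    """Pharmacophore annotation: atom ids / atom-id sets per element."""

    pi: list[int] = field(default_factory=list)
    ar: list[frozenset[int]] = field(default_factory=list)
    hba: list[int] = field(default_factory=list)
    hyd: list[frozenset[int]] = field(default_factory=list)
    halogen_on_hyd: list[tuple[int, int]] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (self.pi or self.ar or self.hba or self.hyd)


def _is_basic_amine(m: Molecule, i: int) -> bool:
    a = m.atoms[i]
    if a.element != "N" or a.aromatic or a.formal_charge < 0:
        return False
    for b in m.bonds:
        if i in (b.a, b.b) and (b.order != 1.0 or b.aromatic):
            return False
    # exclude amide / sulfonamide: a neighbor C or S double-bonded to O
    for j in m.neighbors(i):
        nj = m.atoms[j]
        if nj.element in ("C", "S"):
            for k in m.neighbors(j):
                bk = m.bond_between(j, k)
                if m.atoms[k].element == "O" and bk is not None and bk.order == 2.0:
                    return False
    return True


def _ring_count(m: Molecule, system: frozenset[int]) -> int:
    edges = sum(
        1 for b in m.bonds if b.a in system and b.b in system and b.aromatic
    )
    return edges - len(system) + 1


def _substituents_ok(m: Molecule, system: frozenset[int]) -> bool:
    """Only halogen or methyl substituents hang off the aromatic system."""
    for i in system:
        for j in m.neighbors(i):
            if j in system:
                continue
            nj = m.atoms[j]
            if nj.element in HALOGENS:
                continue
            if nj.element == "C" and len(m.neighbors(j)) == 1 and not nj.aromatic:
                continue  # methyl
            return False
    return True


def _pi_bearing_systems(
    m: Molecule, pi_atoms: list[int], systems: list[frozenset[int]]
) -> set[int]:
    """Indices of aromatic systems reached from a PI atom through linker atoms."""
    in_system = {}
    for si, sys_atoms in enumerate(systems):
        for a in sys_atoms:
            in_system[a] = si
    hit: set[int] = set()
    for start in pi_atoms:
        seen = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in m.neighbors(x):
                if y in seen:
                    continue
                if y in in_system:
                    hit.add(in_system[y])  # stop at the first aromatic system
                    continue
                seen.add(y)
                stack.append(y)
    return hit


def detect_features(m: Molecule) -> FeatureSet:
    """Annotate PI, AR, HBA, HYD and halogen-on-HYD sites.

    Rules: PI = basic (non-amide, non-sulfonamide) sp3 amine nitrogen with
    non-negative formal charge; AR = every aromatic ring system; HBA =
    oxygens double-bonded to C or S (carbonyl / sulfonyl); HYD = an aromatic
    system of >= 2 fused rings, or one carrying only halogen/methyl
    substituents, disjoint from the AR system linked to the PI; halogen-on-
    HYD = Cl/Br/I bonded to a HYD atom.  Raises on a cyclic molecule with no
    aromatic annotation (annotated input required; aromaticity is not
    perceived here).
    """
    has_aromatic = any(a.aromatic for a in m.atoms)
    if not has_aromatic and m.has_cycle():
        raise ValueError(
            "molecule has rings but no aromatic annotation; supply annotated "
            "input (SD aromatic flags or an RDKit-perceived molecule)"
        )
    systems = m.aromatic_systems()
    pi = [i for i in range(len(m.atoms)) if _is_basic_amine(m, i)]
    hba = [
        b.a if m.atoms[b.a].element == "O" else b.b
        for b in m.bonds
        if b.order == 2.0
        and {m.atoms[b.a].element, m.atoms[b.b].element} & {"O"}
        and {m.atoms[b.a].element, m.atoms[b.b].element} & {"C", "S"}
    ]
    pi_systems = _pi_bearing_systems(m, pi, systems)
    hyd = []
    for si, system in enumerate(systems):
        if si in pi_systems:
            continue
        if _ring_count(m, system) >= 2 or _substituents_ok(m, system):
            hyd.append(system)
    halogen_on_hyd = []
    for hi, system in enumerate(hyd):
        for i in system:
            for j in m.neighbors(i):
                if m.atoms[j].element in HALOGENS:
                    halogen_on_hyd.append((j, hi))
    return FeatureSet(
        pi=pi, ar=list(systems), hba=sorted(set(hba)),
        hyd=hyd, halogen_on_hyd=halogen_on_hyd,
    )


@dataclass(frozen=True)
class MatchReport:
    """Antagonist-model match: the four-point core and the five-point extension."""

    four_point: bool
    five_point: bool
    evidence: dict


def match_antagonist_model(f: FeatureSet) -> MatchReport:
    """Four-point iff PI, AR, HBA and HYD all present; five-point adds the halogen."""
    four = bool(f.pi) and bool(f.ar) and bool(f.hba) and bool(f.hyd)
    five = four and bool(f.halogen_on_hyd)
    return MatchReport(
        four_point=four,
        five_point=five,
        evidence={
            "PI": list(f.pi),
            "AR": [sorted(s) for s in f.ar],
            "HBA": list(f.hba),
            "HYD": [sorted(s) for s in f.hyd],
            "halogen_on_HYD": list(f.halogen_on_hyd),
            "distance_gating": "not applied (topological model)",
        },
    )


#: Reconstructed scaffolds of the benzimidazole sulfonamide series, built
#: from the systematic names; used as packaged fixtures.  Keys are the
#: series numbers: 7/16 carry 5-chloro/5-bromo-2-naphthyl HYD, 10/17 the
#: chloro/bromo-methyl-benzothiophene HYD, 18/19 their des-halo analogues.
COMPOUND_SMILES = {
    7: "CN(C)CCn1cnc2ccc(NS(=O)(=O)c3ccc4c(Cl)cccc4c3)cc21",
    10: "CN(C)CCn1cnc2ccc(NS(=O)(=O)c3sc4ccc(Cl)cc4c3C)cc21",
    16: "CN(C)CCn1cnc2ccc(NS(=O)(=O)c3ccc4c(Br)cccc4c3)cc21",
    17: "CN(C)CCn1cnc2ccc(NS(=O)(=O)c3sc4ccc(Br)cc4c3C)cc21",
    18: "CN(C)CCn1cnc2ccc(NS(=O)(=O)c3ccc4ccccc4c3)cc21",
    19: "CN(C)CCn1cnc2ccc(NS(=O)(=O)c3sc4ccccc4c3C)cc21",
}


def compound(number: int) -> Molecule:
    """One of the packaged series scaffolds, as an annotated Molecule."""
    try:
        smiles = COMPOUND_SMILES[number]
    except KeyError:
        raise ValueError(
            f"no packaged compound {number}; have {sorted(COMPOUND_SMILES)}"
        ) from None
    return Molecule.from_smiles(smiles, name=f"compound {number}")
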