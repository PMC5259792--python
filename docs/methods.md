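# Methods

## Exposed-carbonyl detection

Backbone hydrogen bonds are scored with the DSSP electrostatic energy

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)  kcal/mol

between an N–H donor and a C=O acceptor, accepted at E ≤ −0.5 kcal/mol
(configurable; −0.5 is the DSSP convention).  Crystal structures usually
lack hydrogens, so a missing amide H is rebuilt at 1.01 Å from N on the
external bisector of the C(prev)–N–CA angle, in that plane.  Prolines have
no amide H and are never donors.

Only the local helical donor window i+3…i+5 is searched (3₁₀/α/π
geometries); the claim being operationalized concerns the helix's own
network, not long-range tertiary contacts.  A carbonyl i is *exposed* when
no donor in that window satisfies the cutoff; when the failed i+4 donor is
a proline, that proline is reported as the cause — the i−4 rule.  The last
four residues of an analyzed range have no candidate donors and are
excluded rather than reported, so helix ends are not trivially "exposed".

On ideal α-helical geometry (φ = −57°, ψ = −47°) the i+4 energy is
≈ −2.7 kcal/mol while i+3 (+0.3) and i+5 (−0.2) fall outside the cutoff,
so a single proline exposes exactly one carbonyl.

## Ballesteros–Weinstein numbering and the TM4 motif

Labels t.nn are assigned by offset from a user-supplied x.50 anchor within
each TM span; no alignment is performed (deterministic, offline).  The TM4
proline motif is read from the window 4.57–4.62: two adjacent prolines →
PP, two separated by one residue → PxP, a lone proline → P.  The package
fixes one indexing convention — PP ends at 4.60 ({4.59, 4.60}) and PxP at
4.61 ({4.59, 4.61}) — chosen to be self-consistent with the lone-proline
case (P at 4.60 exposing 4.56, four BW units below).  The convention is
echoed in every motif record.  Each motif proline at 4.nn predicts an
exposed carbonyl at 4.(nn−4).

The packaged `tm4_windows_synthetic.json` fixtures are constructed window
snippets exemplifying the three motif classes (filename and file header say
so); they are not database-derived sequences.

## The σ-hole extra-point model

A carbon-bound halogen is represented by two point charges 1.9 Å apart: the
halogen itself at −0.0725 e and a massless extra point at +0.04 e on the
extension of the C–X axis beyond the halogen, reproducing the positive
σ-hole cap in a fixed-charge force field.  The extra point is re-derived
from the posed C and X at every energy evaluation; the pair's net charge
(−0.0325 e) is independent of geometry.  Coulomb energies use
332.06 kcal·Å/(mol·e²); Lennard-Jones 12-6 terms use Lorentz–Berthelot
combination with GAFF-flavored parameters stored as data
(`data/nonbonded.json`), not code.

Halogen-bond geometry is (d, θ): d = X···O distance, θ = C–X···O angle
(180° = σ-hole pointing at the acceptor).  Classification is inclusive at
the boundaries, bonded iff d ≤ 3.5 Å and θ ≥ 140° (defaults bracketing the
literature geometry of carbonyl halogen bonds; both configurable).

## The reduced dimer simulation

The receptor-context simulation is replaced at desk scale by a rigid-body
model: a chlorobenzene probe (the minimal σ-hole donor; idealized geometry,
OPLS-flavored ring charges, the ipso carbon balancing the halogen pair so
the fragment is neutral) against a fixed N-methylacetamide fragment (trans
amide, united-atom methyls, AMBER-flavored charges) as the backbone
carbonyl surrogate.

Two features represent the helix environment rather than vacuum:

* **Occluders.**  In TM4 an exposed carbonyl is approachable only through
  the outward funnel along its C=O direction: the peptide-plane faces are
  packed against the adjacent helix turns, the backside against the helix
  body, and the lateral in-plane directions against the helix cylinder
  surface.  Five sterics-only pseudo-atoms (repulsive r⁻¹² walls, no charge,
  no dispersion; positions in `fragments.build_amide_partner`) reproduce
  that occlusion.  Without them the global minimum of an isolated
  aromatic/amide dimer is face-on stacking (≈ −6 kcal/mol), a pose the
  receptor forbids; with them the σ-hole funnel (≈ −2.1 kcal/mol at
  d = 3.1 Å) is the dominant accessible basin.
* **A flat-bottom wall** at X···O = 6 Å rejects dissociated poses.  An
  isolated dimer at 300 K would otherwise escape into unbounded volume (the
  binding cavity plays this role in the full system).  The wall only
  truncates the accessible volume; the Boltzmann distribution inside it —
  and therefore the bonded-frame averages — do not depend on its placement.

Sampling is Metropolis Monte Carlo over the probe's six pose degrees of
freedom: Gaussian translation steps (σ = 0.12 Å) and small random-axis
rotations (σ = 6°), acceptance min(1, exp(−ΔE/k_BT)), k_B = 0.0019872
kcal/(mol·K).  Monte Carlo is used instead of dynamics because the
quantity of interest is a configurational average, not kinetics.  The
first 10 % of steps are burn-in; the remainder is thinned to ≤ 10⁴ stored
frames.  Geometry averages are taken over frames passing the halogen-bond
criteria (the averages describe the bound state; an all-frames variant is a
flag).  Runs are bit-reproducible given a seed.  At the default
2×10⁵ steps the bonded-frame means are stable to ≈ 0.01 Å / 0.5° across
seeds (~30 s on one CPU).

A 1-DOF restriction (collinear approach, distance only) uses an
independence sampler thinned by 10 and is checked against direct
quadrature of exp(−E(d)/k_BT) bin by bin — the sampler-correctness test.

Minimization over the same energy uses Nelder–Mead on
translation + rotation-vector coordinates (robust to the +∞ clash
sentinel).

## Trajectory analysis

Superposition is the Kabsch algorithm (SVD with determinant correction, so
reflections are excluded); an independent quaternion-eigenvalue oracle pins
it in the tests.  Ligand RMSD follows the standard fit/report split: each
frame is superposed on a reference frame using the fit selection (receptor
backbone), then the RMSD is measured over the report selection (ligand)
without re-fitting, so rigid whole-system motion cancels while genuine
ligand motion is retained.  Weights are uniform by default (mass-weighting
is a flag).  Geometry series apply the (d, θ) measurement per frame with
all-frames or bonded-only summaries.

## Pharmacophore annotation

Detection is topological and runs on annotated molecules; aromaticity is
read from the input (SD aromatic flags or an RDKit-perceived molecule) and
never re-perceived, which keeps the matcher deterministic across dialects.
Rules: PI = sp³ amine N with non-negative formal charge, excluding
amide/sulfonamide N (a C/S neighbor double-bonded to O); HBA = carbonyl and
sulfonyl oxygens; AR = every aromatic ring system; HYD = an aromatic system
with ≥ 2 fused rings (or only halogen/methyl substituents) disjoint from
the AR system reached from the PI through the linker; halogen-on-HYD =
Cl/Br/I bonded to a HYD atom.  The four-point match requires PI, AR, HBA
and HYD; the five-point match adds halogen-on-HYD.  Inter-feature distances
are reported but deliberately not gated (the published model is
topological); PI is a structural rule, not a pKa calculation.  The packaged
series fixtures are scaffolds reconstructed from systematic names as
SMILES.

## Mass and PAMPA arithmetic

The isotope table is embedded data (CODATA/AME-derived exact masses, six
decimals); [M+H]+ adds the proton mass (electron subtracted — the 0.0005 Da
difference from the H-atom mass is below reporting precision).  Instrument
values printed at one decimal are matched at ±0.15.

PAMPA: P = −ln(1 − C_A/C_eq) / (A·(1/V_D + 1/V_A)·t) with
C_eq = (C_D·V_D + C_A·V_A)/(V_D + V_A), defaults A = 0.3 cm², V_D = 0.3 mL,
V_A = 0.2 mL.  mL is treated as cm³, under which the formula is
dimensionally consistent and yields cm/s directly.  Duplicate wells are
averaged at the P level with the replicate range reported
(concentration-level averaging is a flag).  P is undefined once C_A reaches
C_eq (error, not a number).

## Synthetic data: what it emulates and what it does not

The helix builder uses standard backbone internal coordinates (N–CA 1.458,
CA–C 1.525, C–N 1.329, C=O 1.231 Å; N–CA–C at the tetrahedral 109.5°, which
reproduces the textbook 1.50 Å rise and 3.6 residues/turn at α-helical
φ/ψ).  Probe placement searches approach directions and ring spins for the
maximal-clearance pose satisfying (d, θ) exactly.  Jitter trajectories
transform the base pose rigidly (rotation about the halogen for θ,
translation along the approach axis for d), so zero jitter reproduces the
base bit-for-bit and every frame carries exact ground truth.

Passing the closed-loop tests therefore shows that the analysis recovers
what the generators plant under ideal geometry with Gaussian noise.  It
does not show robustness to real-structure pathologies — bent or π-bulged
helices, missing density, alternate conformers beyond altloc A, water-
mediated H-bonds, or anharmonic ligand dynamics.

## Known limitations

* The reduced dimer reproduces bound-state *geometry averages*, not binding
  free energies, kinetics, or the receptor-scale ligand RMSD values (those
  require the full receptor simulation; the trajectory machinery is instead
  validated by oracle equivalence, ground-truth recovery, and the
  extra-point ablation property, which reproduces the halogenated vs
  des-halo stability contrast qualitatively).
* Extra-point parameters are fitted for aryl chlorine; bromine/iodine
  values are accepted via configuration but no fitted defaults are shipped.
* The bonded-frame mean distance (≈ 3.23 Å) sits slightly above the energy
  minimum (3.08 Å) because the 300 K ensemble weights the shallow outer
  wall of the well; the mean angle (≈ 163°) sits below collinear for the
  same thermal reason.
* Sequence numbering assumes user-supplied anchors; there is no automatic
  TM detection or alignment.
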