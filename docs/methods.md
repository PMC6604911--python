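# Methods

This note records the models behind `dnapatite`, the parameters that
matter, and what the desk-scale substitutes do and do not establish.

## Apatite crystals

Unit cells are expanded from the asymmetric unit under the twelve P6₃/m
operations, with fractional duplicates merged at 10⁻³ (fractional). The
packaged site tables (`data/hap.json`, `data/fap.json`) use published
single-crystal refinements (Kay–Young–Posner 1964; Hughes–Cameron–Crowley
1989) with lattice constants a = b = 9.42 / 9.40 Å and c = 6.87 / 6.88 Å.
The hydroxyl column is disordered about the mirror plane at z = ¼
(occupancy ½); it is resolved deterministically by keeping the lowest- and
highest-z members of the 4-site orbit, i.e. one O–H pointing up and one
down per cell, which fixes the 44-atom count and cancels the cell's
hydroxyl dipole. Hydrogen partial sites follow their bonded oxygen.

Atom charges are formal-ionic with the phosphate split P +1.300 /
O −1.075 (group total −3) and hydroxyl O −1.400 / H +0.400; every built
cell is exactly neutral. Each PO₄, OH, Ca and F is tagged as an intact
group; carving and growth only ever move or keep whole groups, so
electroneutrality is structural, not corrective.

Pore carving removes the atoms of whole unit cells (a 2×2×7 channel in
the 6×6×7 super-cell: side 18.84 Å, γ = 120°). With a DNA guest present,
any group within 2.0 Å of a guest atom is translated by an integer number
of super-cell lattice vectors to the nearest vacant border site along
±a/±b; the move is logged, and counts and charge are invariant. The
measured internal diagonals of the channel depend on which border groups
were translated and are therefore reported, not asserted exactly.

## Canonical B-DNA

The builder is an idealized fiber model: planar Watson–Crick pairs
stacked at rise 3.4 Å / twist 36° about a common axis, strands related by
the pair dyad, so the duplex is exactly helically symmetric and
reconstruction is bit-reproducible.

Geometry is derived at first use, deterministically:

* base moieties come rigidly from the CCD ideal components (DA, DT, DG,
  DC, 5-methyl-dC); each pair is posed in-plane by least squares against
  literature hydrogen-bond distances (A:T 2.82/2.95 Å plus the 3.65 Å
  minor-groove C2···O2 contact; G:C 2.91/2.95/2.86 Å) with the C1′
  anchors on a 10.8 Å C1′–C1′ axis — the separation the CCD base
  geometries require for a clash-free Watson–Crick pose;
* the deoxyribose is built from internal coordinates at C2′-endo pucker
  (pseudorotation phase 162°, amplitude 36°), with exocyclic
  stereochemistry taken from the CCD reference;
* one inter-residue phosphate is solved under helical symmetry so every
  O3′–P–O5′ linkage is identical; a joint fit of six global parameters
  (pair displacement, sugar spin, glycosidic angle, pucker phase, C1′
  half-separation, attachment tilt) closes the backbone while matching
  the canonical observables — phosphorus radius ≈ 9.6 Å and diametric
  backbones, the values consistent with the 11.7 / 17.2 Å minor/major
  groove phosphate separations.

The resulting helix has adjacent intra-strand P–P = 6.8 Å, minor-groove
P–P = 11.7 Å, anti glycosidic torsions (χ ≈ −125°), and residual strain
confined to the phosphodiester bridge (O3′–P within 0.03 Å of ideal).
5′ termini carry free hydroxyls (no terminal phosphate), giving an n-nt
strand n−1 phosphates; the simplified charge model places −1 e per
internal phosphodiester and leaves sugars and bases neutral, so a
dodecamer duplex carries −22 e, neutralized by ⌈n_P/2⌉ Ca²⁺ counterions.
Minor-groove counterions start on the groove midline between cross-strand
phosphates and are relaxed by steepest descent with the DNA fixed.

**Inter-chain distance.** IC is implemented as twice the mean radial
distance of the backbone phosphate groups (P, OP1, OP2) from the helix
axis (the first principal axis of the phosphate-group centers), i.e. the
separation of the two sugar–phosphate chains across the axis; structures
without a phosphate backbone fall back to the distance between strand
mass centers. A literal whole-strand center-of-mass distance is not
usable for a helix: over a full turn the azimuthal positions average out
and any ~1-turn duplex gives ≈ 2 Å regardless of its width.

## Molecular mechanics

A compact class-I force field (`data/forcefield.dat`): harmonic bonds by
element pair, harmonic angles with equilibrium values from a valence rule
(trigonal 120°, tetrahedral 109.5°, water 104.52°), cosine torsions in
three classes (sp3–sp3 threefold, planarizing twofold between trigonal
centers, mixed), 12-6 Lennard-Jones with Lorentz–Berthelot combining, and
Coulomb electrostatics (C = 332.0636 kcal Å mol⁻¹ e⁻²) with 1-2/1-3
exclusions and 1-4 scaling (electrostatics ÷1.2, LJ ÷2.0). Aqueous Ca²⁺
uses the Åqvist ion values; the hydroxide oxygen carries an enlarged
soft-anion radius; water is a flexible 3-site TIP3P variant. Topology is
perceived from geometry (covalent radii × 1.25, same molecule only).

Energies and analytic forces are verified in the test suite against
independent brute-force loops (10⁻¹⁰ relative) and central-difference
gradients (10⁻⁴ kcal/mol/Å). In cutoff mode both LJ and Coulomb are
rolled off by a CHARMM-style switching function. The minimizer is plain
steepest descent with backtracking step halving (initial step 0.01 Å)
and positional freezing; in encapsulation workflows the mineral is frozen
at its crystallographic coordinates, so its internal bonded terms are
constant and Δτ isolates the DNA's geometric stress.

This parameter set is the package's own: it reproduces the *structure*
of the models exactly and the *sign and ordering* of interaction
energetics, but its absolute energies are not comparable to
production-grade force fields. Relaxed-state strain values are therefore
checked as properties (signs, additivity, oracle equality on synthetic
perturbations), not as numeric reproductions.

## Template growth

The phosphate-plane finder enumerates near-parallelogram 4-tuples of
phosphorus atoms (sides 5–16 Å), scoring by deviation from a target
(u, v, γ) with degrees weighted at 0.1 Å/deg; the search is exhaustive
for closure deviations below the pairing tolerance (0.9 Å for crystals,
where lattice-exact planes exist; 2.2 Å for helical DNA, the smallest
tolerance admitting any near-parallelogram on an exactly symmetric
helix). On the crystal the best plane is spanned by u = c and the a−c
diagonal (v = 11.66 Å, γ = 126°). On the ideal duplex the cross-strand
side is quantized to 11.85 or 15.30 Å by helical symmetry — intermediate
values require the conformational variability of relaxed structures.

Growth rigid-fits (Kabsch) four lattice phosphorus sites onto the DNA
plane and emits whole charged groups within a cutoff radius of the plane
center; with a DNA guest, crystal groups within 2.0 Å of the guest are
omitted (the DNA's own phosphates stand in for the coincident lattice
sites). Profiles use exact no-cutoff energies; the default radius grid is
5–30 Å in 2.5 Å steps, and tests use 6–12 Å shells to stay desk-sized.

## Nucleation dynamics

A declared scaled-down stand-in for production nucleation MD, preserving
concentration and stoichiometry at 1/27 of the full-scale ion counts
(35 Ca²⁺, 21 PO₄³⁻, 7 OH⁻, ≈ 930–1080 waters in a 30.7×30.5×36.0 ų
box). Deliberate simplifications, chosen for single-CPU feasibility and
documented as such: NVT Langevin (BAOAB; velocity Verlet in the zero-
friction limit) instead of weak-coupling NPT; shifted-force Coulomb at
the 12 Å cutoff instead of Ewald summation (long-range structure is
perturbed, first-shell contact peaks are not); flexible stiff-bond water
at 1 fs instead of constraint-rigid water; and the DNA template frozen in
all stages. Boxes are packed at 1.00 g/cm³ water density (closed-form
count over the solute-displaced free volume, 9 ų per heavy atom) with
periodic clash checking at 1.5 Å; short steepest-descent relaxation
precedes dynamics. The staged equilibration schedule (0.5/0.5/0.5/0.15/
0.25/0.5 ns at 500 K then 298 K) is scaled by a single declared factor.

Test-scale runs are 2–3 ps: long enough for counterion–phosphate contact
pairs to form and for first-shell RDF peaks to stabilize, far too short
for cluster-growth kinetics or for ion-exchange equilibrium between
hydroxide and phosphate coordination. Under the formal-ionic hydroxide
charges (O −1.4 e, required for the electroneutral mineral lattice) the
few OH⁻ ions pair strongly with Ca²⁺, so the hydroxide first-shell peak
is sharper at desk scale than production-scale modeling reports; this
limitation is asserted openly in the acceptance tests rather than
papered over.

## Trajectory analysis

g(r) is the minimum-image pair histogram normalized by shell volume,
partner density and frame count (uniform fluid → 1; verified on seeded
ideal-gas and simple-cubic fixtures). Default bins are 0.05 Å out to
10 Å — fine enough to resolve a 3.14/3.82 Å doublet; peaks are local
maxima above a prominence threshold (default 0.1), refined by parabolic
interpolation over three bins. Phosphate–calcium distances are measured
phosphorus-to-calcium. Coordination numbers count partners within a
shell directly, and the suite cross-checks them against 4πρ∫g r² dr.

## Synthetic fixtures

Every fixture (ideal-gas and lattice trajectories, planted RDF curves,
perturbed duplexes with stored displacement fields, attractive/repulsive
mineral–DNA toy complexes, miniature stoichiometric boxes) is seeded,
bit-reproducible, and ships its ground truth computed by plain
brute-force loops kept in `synthetic.py`, separate from the vectorized
production code they check. Passing tests on these fixtures establish
internal correctness of the machinery — histogram normalization, energy
summation, superposition algebra — not the realism of any particular
force-field number; realism rests on the structural observables
(distances, counts, stoichiometry) checked against crystallographic and
fiber-diffraction values.

## Known limitations

* The force field is a transparent stand-in; absolute energies, and any
  quantity that depends on relaxed-ensemble sampling (relaxed Δτ, RMSD
  and IC values, absolute growth-profile energies), are out of scope and
  replaced by sign/ordering properties.
* The idealized duplex is exactly helically symmetric; sequence-dependent
  fine structure (propeller, slide, groove-width modulation) is absent,
  which quantizes the DNA phosphate-plane side v to two registers.
* Nucleation runs probe first-shell ion pairing only; cluster-size
  statistics and hydroxide exchange require production-scale sampling.
* No Ewald electrostatics, no pressure coupling, no quantum-mechanical
  validation of interaction energies.
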