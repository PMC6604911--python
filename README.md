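# dnapatite

Atomistic modeling of DNA/apatite biominerals: hydroxyapatite (HAp,
Ca₁₀(PO₄)₆(OH)₂) and fluoroapatite (FAp, Ca₁₀(PO₄)₆F₂) crystals with
DNA-sized nanopores, canonical B-form DNA built from sequence, the strain
the mineral imposes on an embedded double helix, template-directed crystal
growth from the phosphate plane shared by B-DNA and the apatite lattice,
and desk-scale Langevin dynamics of calcium-phosphate nucleation at a DNA
template.

## Who it is for

Researchers modeling organic–inorganic biominerals who need reproducible,
scriptable building blocks: a P6₃/m apatite builder, a dependency-free
canonical B-DNA generator, a small transparent molecular-mechanics core
with brute-force-verified energies, and radial-distribution-function
analysis of ion-pairing trajectories.

## The models

**Crystals.** Both apatites are hexagonal P6₃/m (HAp: a = b = 9.42 Å,
c = 6.87 Å; FAp: 9.40/6.88 Å). The unit cell is generated from seven
symmetrically independent sites; the disordered hydroxyl column
(occupancy ½) is resolved deterministically into one up- and one
down-pointing OH per cell, giving exactly 44 atoms (HAp) or 42 (FAp) with
zero net charge. Super-cells are exact lattice replications; a rhombic
2×2×7-cell channel (side 18.84 ≈ 19 Å, γ = 120°) is carved by removing
whole neutral cells, and any charged group clashing with an embedded DNA
guest is translated intact to a vacant border site, never deleted.

**B-DNA.** Base pairs are planar Watson–Crick pairs (hydrogen-bond
donor–acceptor distances 2.8–3.0 Å) stacked at rise 3.4 Å and twist 36°
(10 bp per turn); the two strands are exact dyad images. Residue geometry
is derived at run time from Chemical Component Dictionary components plus
a deterministic least-squares calibration that closes the sugar–phosphate
backbone under helical symmetry (C2′-endo sugars, phosphorus radius
9.6 Å, adjacent intra-strand P–P 6.8 Å, minor-groove P–P 11.7 Å).

**Strain metrics.** For a duplex relaxed inside a pore: Δτ = ΔE_str +
ΔE_bnd + ΔE_tor, the change in bonded energy relative to the canonical
starting structure (nonbonded terms excluded by construction); all-atom
RMSD with optional Kabsch superposition; and the inter-chain distance IC,
the cross-axis separation of the two sugar–phosphate chains.

**Template growth.** Four backbone phosphates of B-DNA form a
near-parallelogram that matches an apatite lattice plane spanned by u = c
and the a−c cell diagonal (v = 11.66 Å). The crystal is rigid-fit onto
the DNA plane and grown outward in whole charged groups; energy-vs-
thickness profiles are dominated by the electrostatic term.

**Nucleation.** Stoichiometric Ca²⁺ : PO₄³⁻ : OH⁻ = 10 : 6 : 2 aqueous
boxes (flexible 3-site water at 1.00 g/cm³) are integrated with BAOAB
Langevin dynamics (switched Lennard-Jones, shifted-force Coulomb, frozen
DNA template). First-shell RDF peaks diagnose DNA-phosphate···Ca²⁺ ion
pairing and embryonic cluster formation.

## Worked example

```python
from dnapatite.crystal import CrystalSpec, PoreSpec, build_unit_cell, \
    build_supercell, carve_pore, measure_pore
from dnapatite.dna import build_canonical_duplex, SEQUENCE_I
from dnapatite.strain import interchain_distance
from dnapatite.growth import lattice_plane

cell = build_unit_cell(CrystalSpec.packaged("hap"))
print(len(cell))                      # 44
sc = build_supercell(cell, 6, 6, 7)
carved, pore = carve_pore(sc, PoreSpec((2, 2, 7)))
print(len(carved))                    # 9856
print(measure_pore(carved, pore).side_a)   # 18.84  (~19 Å)

duplex = build_canonical_duplex(SEQUENCE_I)   # 5'-CGCGAATTCGCG-3'
print(round(interchain_distance(duplex.structure), 2))   # 19.77

plane = lattice_plane(CrystalSpec.packaged("hap"))
print(round(plane.u, 2), round(plane.v, 2))   # 6.87 11.66
```

The unit cell holds the full stoichiometric 44 atoms; the pored 6×6×7
super-cell keeps 9856 mineral atoms and a 19 Å channel; the canonical
Dickerson duplex shows an inter-chain (backbone-to-backbone) distance of
19.8 Å; and the crystal's isomorphic phosphate plane repeats at exactly
the lattice constant c along its short side.

A command-line interface mirrors the library:

```bash
dnapatite build-crystal --mineral hap --cells 6 6 7 --pore 2 2 7 -o mineral.pdb
dnapatite build-dna --seq CGCGAATTCGCG --ions minor_groove --seed 1 -o dna.pdb
dnapatite run --workflow growth --outdir out/
```

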