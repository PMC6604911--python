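# dnapatite molecular-mechanics parameter set
#
# A compact class-I parameter table for DNA/apatite biomineral models:
# harmonic bonds and angles, cosine torsions, 12-6 Lennard-Jones with
# Lorentz-Berthelot combining, and fixed partial charges carried on the
# structures themselves.  Values follow the Amber/TIP3P family of force
# fields: nucleic-acid and phosphate/hydroxyl terms after Cornell et al.,
# J. Am. Chem. Soc. 117 (1995) 5179 and Duan et al., J. Comput. Chem. 24
# (2003) 1999; aqueous Ca2+ after Aqvist, J. Phys. Chem. 94 (1990) 8021;
# F- after Dang, Chem. Phys. Lett. 200 (1992) 21; the hydroxide oxygen
# (type OX) carries an enlarged radius reflecting the soft, strongly
# hydrated OH- anion; water is a flexible 3-site TIP3P variant.
# 1-4 scaling: electrostatics /1.2, Lennard-Jones /2.0.
#
# ATOM  type  mass(u)  rmin_half(A)  epsilon(kcal/mol)
ATOM  H    1.008   0.6000  0.0157
ATOM  HO   1.008   0.3000  0.0001
ATOM  HW   1.008   0.3000  0.0001
ATOM  C   12.011   1.9080  0.1094
ATOM  N   14.007   1.8240  0.1700
ATOM  O   15.999   1.6612  0.2100
ATOM  OW  15.999   1.7683  0.1520
ATOM  P   30.974   2.1000  0.2000
ATOM  OX  15.999   2.0500  0.2100
ATOM  CA  40.078   1.3264  0.4497
ATOM  F   18.998   2.2570  0.0074
#
# BOND  elem1 elem2  K(kcal/mol/A^2)  r0(A)     (element-class harmonic bonds)
BOND  C  C   310.0  1.526
BOND  C  N   337.0  1.470
BOND  C  O   320.0  1.420
BOND  C  H   340.0  1.090
BOND  N  H   434.0  1.010
BOND  O  H   553.0  0.960
BOND  P  O   300.0  1.560
BOND  P  C   270.0  1.800
BOND  P  N   250.0  1.700
BOND  P  P   200.0  2.200
BOND  N  O   350.0  1.400
BOND  N  N   400.0  1.350
BOND  O  O   350.0  1.450
BOND  P  H   250.0  1.400
BOND  OW HW  450.0  0.9572
#
# ANGLE: force constant (kcal/mol/rad^2) shared; equilibrium assigned by
# the center atom's element and bonded degree (sp2/sp3 valence rule)
ANGLE_K        70.0
ANGLE_EQ  C 3  120.0
ANGLE_EQ  C 4  109.5
ANGLE_EQ  N 2  118.0
ANGLE_EQ  N 3  120.0
ANGLE_EQ  N 4  109.5
ANGLE_EQ  O 2  108.5
ANGLE_EQ  P 4  109.5
ANGLE_EQ  HW 0 104.52
#
# TORSION by the central-bond atom classes: barrier(kcal/mol) periodicity phase(deg)
# sp3-sp3 threefold; bonds between two trigonal centers (ring/conjugated)
# get a planarizing twofold term
TORSION  sp3   1.40  3    0.0
TORSION  sp2   4.00  2  180.0
TORSION  mixed 1.00  3    0.0
#
# SCALE14  elec  lj
SCALE14  1.2  2.0
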