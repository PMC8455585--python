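# Methods and conventions

This document records the exact formulas and fixed constants the package
implements, in the order of the workflow.

## Units and shared constants

Energies are kcal/mol, distances Å, charges elementary. The electrostatic
conversion constant is 332.0637 kcal·Å/(mol·e²); k_B = 0.0019872041
kcal/(mol·K); solvent dielectric 78.5; water probe radius 1.4 Å.

## Activity scale and dataset bookkeeping

pIC50 = −log10(IC50[nM] · 1e−9). `partition_dataset` splits a series by
explicit id lists and removes named outliers from both partitions; the
bundled reference table holds 54 compounds (43 train / 11 test after three
outliers are removed from the initial 45/12 split of 57).

## CoMFA fields

On a rectangular lattice (default 2 Å spacing, 4 Å margin) an sp³ carbon
probe (radius 1.7 Å, well depth 0.107 kcal/mol, charge +1) is evaluated
against every atom:

- steric: Lennard-Jones 6-12 in rmin form,
  E = ε[(rmin/r)¹² − 2(rmin/r)⁶], summed over atoms with
  ε = √(ε_atom·ε_probe), rmin = r_atom + r_probe; values are capped at
  +30 kcal/mol;
- electrostatic: 332.0637·q/(ε(r)·r) with the distance-dependent
  dielectric ε(r) = r, i.e. 332.0637·q/r². At lattice points where the
  steric field is capped the electrostatic value is replaced by the mean
  of the uncapped points (zero if every point is capped).

## CoMSIA fields

Similarity indices A(j) = −Σ_i w_i exp(−α r_ij²) with α = 0.3 and
per-kind weights w: steric = r_vdw³, electrostatic = partial charge,
hydrophobic = ±1 from the atom-typing table, HBD/HBA = 0/1 flags. No
caps are needed (Gaussian attenuation is finite everywhere).

## Descriptor assembly

Field blocks are stacked per molecule into one row. Columns whose value
range falls below 2.0 (energy/similarity units) are removed before
regression; each retained block is scaled by its pooled standard
deviation so no field dominates by magnitude alone.

## PLS and validation

PLS1 by NIPALS on column-centered data (no per-column scaling beyond the
block scaling above); coefficients via W(PᵀW)⁻¹q; the component count is
capped at min(n−1, p) and selected by leave-one-out q²,

q² = 1 − PRESS/SS_total,  SEP = √(PRESS/(n − a − 1)),

with ties broken toward fewer components. Non-cross-validated r², SEE and
F accompany the fit. External predictions are scored by

r²_pred = 1 − PRES/SD,

where PRES is the squared-error sum of the test predictions and SD the
squared deviation of test observations from the *training* mean. Bootstrap
refits and y-scrambling (identity permutation excluded) provide the
robustness and chance-correlation baselines. Contour maps use the
stdev*coeff convention with 80/20 percentile levels for favored and
disfavored regions.

## Pharmacophore perception and screening

From a protein–ligand complex the package derives:

- HBD/HBA features: donor–acceptor heavy-atom distance ≤ 3.5 Å and
  D–H···A angle ≥ 130°;
- hydrophobic (HY) features: centroids of ≥ 3 apolar ligand carbons
  within 4.5 Å of protein carbons;
- exclusion volumes (radius 1.2 Å) on pocket-lining protein heavy atoms,
  kept only if ≥ 2.0 Å clear of every feature.

Models from multiple complexes merge by consensus: a feature survives if
matched (same kind, within tolerance 1.5 Å) in at least two source
models. A model needs ≥ 3 core features to be screenable. Screening
assigns candidate ligand points (donor parents, acceptors, hydrophobic
centroids) to features of the same kind, superimposes each assignment by
Kabsch least squares, and accepts a pose when every matched pair is
within its tolerance and no heavy atom falls inside an exclusion volume.
The fit score is 10·N − Σ(d_i/tol_i). Screens are evaluated by ROC AUC
(pair-counting), enrichment factors and hit rates.

## MM-GBSA and residue decomposition

Binding energy per frame is E(complex) − E(receptor) − E(ligand), with
E = vdW + Coulomb + GB polar + 0.0072·SASA. GB uses HCT pairwise
descreening radii (an isolated atom's effective radius equals its
intrinsic radius) in the Still expression with prefactor
−(332.0637/2)(1 − 1/78.5). SASA is Shrake–Rupley on a 960-point golden
spiral (translation-exact; rotation-invariant to quadrature error). The
per-residue decomposition assigns each pairwise term half-and-half to its
two owners and adds a ligand self-solvation correction so the residue sum
re-totals the binding free energy exactly (verified to 1e-6).

## Toy water-swap free energies

A bound ligand and a shape-matched cluster of water particles (selected
by identity points: each ligand particle claims its nearest unclaimed
water, ties to the lower index) are exchanged along λ:

E(λ) = E_pb + E_wb + E_lig + E_clu
     + (1−λ)(E_lig:pb + E_clu:wb) + λ(E_clu:pb + E_lig:wb).

The four cross terms use a soft core (reduced r⁶ shifted by α = 0.5; the
Coulomb distance by √(r²+α)) so coincident particles stay finite; since α
does not depend on λ, dE/dλ is exactly the difference of the cross-term
sums. Sampling is Metropolis MC (ligand rigid-body moves, cluster-water,
and bulk-water moves inside a reflection sphere) with neighbour replica
exchange on the default 16-window schedule λ_k = 0.005 + 0.066k. Free
energies come from TI (trapezoid with endpoint extension), double-ended
FEP (averaged forward/backward exponential estimators) and BAR (implicit
equation solved by Brent's method); the reported value averages the three
over independent replicates with the replicate scatter as its error.

## Synthetic-truth generators

- QSAR series: a rigid ring scaffold with randomized substituents at
  three sites; activities are linear in the CoMSIA field values at the
  lattice columns nearest the sites plus Gaussian noise, so sign and
  location of every effect are known.
- Actives/decoys: actives realize every feature within a jitter smaller
  than half the tolerance. Every decoy displaces one feature by 4×
  tolerance away from its nearest neighbour feature — a rigid fit
  preserves pairwise distances, so two features would have to absorb a
  6 Å discrepancy against a 3 Å combined budget, which is impossible —
  and some decoys additionally carry an atom planted in an exclusion
  volume. Note a planted clash atom alone could not guarantee failure: a
  legal match may twist by up to the 1.5 Å feature tolerance, which
  exceeds the 1.2 Å exclusion radius.
- Toy complex: a pocket of pseudo-residues around an apolar ring ligand
  with an exocyclic N–H donor and carbonyl-like acceptor at exactly the
  requested hydrogen-bond distance and angle.
- Swap boxes: periodic single-site water boxes with minimum separation,
  plus either a two-particle dipolar ligand or, in the symmetric null
  case, a single water-like particle whose exchange has ΔG = 0 exactly.
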