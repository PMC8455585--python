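# ligandfield

A desk-scale toolkit for ligand-based and structure-based computer-aided
drug design, built around the workflow used to study ATP-competitive kinase
inhibitors: 3D-QSAR on molecular interaction fields, structure-based
pharmacophore screening, an MM-GBSA energetic decomposition, and a toy
water-swap absolute binding free-energy simulator. Everything runs in
seconds to minutes on a single CPU with no external engines.

## What is in the box

| module | contents |
| --- | --- |
| `ligandfield.chemio` | SDF / MOL2 / PDB reading and writing, atom typing, pIC50 conversions, train/test bookkeeping, the bundled 54-compound activity table |
| `ligandfield.fieldgen` | CoMFA steric (Lennard-Jones 6-12 probe) and electrostatic (distance-dependent dielectric) lattice fields; CoMSIA Gaussian similarity fields (S, E, H, HBD, HBA); block scaling; OpenDX export |
| `ligandfield.qsar` | PLS1 (NIPALS) with leave-one-out q²/SEP model selection, external predictive r², bootstrap and y-scrambling validation, stdev*coeff contour maps — statsmodels-style `FieldPLS` / `FieldPLSResults` objects |
| `ligandfield.pharmacophore` | Feature perception from protein–ligand complexes (H-bond distance/angle gates, hydrophobic clusters, exclusion volumes), multi-complex merging, rigid-fit screening with ROC/enrichment metrics |
| `ligandfield.energetics` | Generalized Born (HCT radii, Still pairwise term), Shrake–Rupley SASA, MM-GBSA binding free energy with an exactly conserving per-residue decomposition |
| `ligandfield.waterswap` | Toy water-swap free-energy method: a ligand and a shape-matched water cluster exchanged along a soft-core λ coordinate, Metropolis MC with replica exchange, TI / FEP / BAR estimators |
| `ligandfield.synthdata` | Planted-truth generators: congeneric QSAR series, labelled actives/decoys, pocket complexes, swap boxes |
| `ligandfield.pipeline` | The virtual-screening funnel: descriptor filters → dedup → pharmacophore → QSAR ranking, with a JSON manifest |
| `ligandfield.cli` | `ligandfield` console command wrapping all of the above |

## Worked example

Generate a synthetic congeneric series with planted field effects and fit
a CoMSIA-style PLS model:

```bash
ligandfield synth-qsar --seed 11 --n 24 --out data
ligandfield qsar-fit --structures data/series.sdf \
    --activities data/activities.csv --method comsia --out model.json
```

Printed output (verbatim):

```
wrote 24 molecules to data
Molecular-field PLS regression
==============================================
n compounds                                 24
n descriptor columns                        90
components (LOO-selected)                   10
q2 (LOO)                                0.9774
SEP                                     1.1910
r2                                      0.9964
SEE                                     0.4747
F                                       361.53
reliable (r2>0.9, q2>0.5)                 True
----------------------------------------------
field contributions:
  S              0.310
  E              0.067
  H              0.432
  HBA            0.191
model saved to model.json
```

The same objects are available from Python, along with the structure-based
half of the workflow:

```python
from ligandfield import synthdata, pharmacophore, energetics

cx = synthdata.make_toy_complex(seed=1, n_frames=3, frame_jitter=0.02)
model = pharmacophore.perceive_features(cx)
mols, labels = synthdata.make_actives_decoys(model, 5, 5, seed=3)
hits = pharmacophore.screen_library(model, mols)
binding = energetics.mmgbsa_binding(cx)
```

which prints, for example:

```
features: ['HBA', 'HBD', 'HY'] | exclusion volumes: 15
act000  fit=29.95  rmsd=0.028
dG_bind = -0.940 +/- 0.266 kcal/mol
```

A symmetric toy water-swap (identical species exchanged, so the exact
answer is 0) runs in seconds:

```bash
ligandfield waterswap --seed 3 --n-waters 8 --steps 300 --replicates 2 --symmetric
```

## Validation strategy

Because every heavy computation here has a closed-form or brute-force
counterpart at desk scale, the test suite leans on oracles rather than
golden numbers:

- the LOO cross-validation in `qsar` is checked against a naive
  double-loop re-fit, and NIPALS against ordinary least squares and
  scikit-learn's `PLSRegression`;
- field generators are checked against single-atom closed forms and
  translation equivariance;
- the generalized Born ion, isolated-sphere SASA and spherical-cap fused
  spheres have analytic references; the residue decomposition must re-sum
  to the total binding free energy to 1e-6;
- the swap energy must reassemble exactly from its eight components, its
  analytic λ-gradient must match finite differences, a symmetric swap must
  give ΔG ≈ 0, and TI/FEP/BAR must all agree with the harmonic-oscillator
  closed form on analytically sampled gradients;
- screening must perfectly separate constructed actives from decoys whose
  failure is geometrically provable (a displaced feature grows a pairwise
  distance beyond what two tolerances can absorb under any rigid fit).

## Reproduction

```bash
pip install --no-build-isolation -e .
python -m pytest -q tests/                    # full suite, ~30 s
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` recomputes the headline quantities (fixture
integrity, dataset bookkeeping, LOO oracle deviation, planted-effect
recovery, screening AUC and hit rates, solvation identities, swap
free-energy identities) and writes them as JSON; all randomness derives
from `--seed`.

See `docs/methods.md` for the scientific conventions and formulas.
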