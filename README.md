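# toxinterface

Quantitative analysis pipeline for studies of a bivalent spider-toxin /
ion-channel / membrane system: contact-pair statistics on structures and
trajectory frames, cryo-EM density-map model scoring and restraint-based
pose ranking, NMR-ensemble geometry (RMSD, greedy clustering, solvent
accessibility), and the thermodynamics of membrane partitioning and
channel activation — including the free-energy additivity analysis for
bivalent toxin constructs.

The package is aimed at structural biologists and biophysicists who need
these bespoke analyses as tested, scriptable building blocks rather than
one-off notebook code. Every stage can run on synthetic inputs produced
by the built-in generators, so the whole pipeline is exercisable without
downloading deposited structures or maps.

## The quantities it computes

**Contact statistic N_p.** For two atom groups A and B, N_p is the
number of heavy-atom pairs (a ∈ A, b ∈ B) within a first interaction
shell of 6 Å (cutoff inclusive), averaged over trajectory frames or
ensemble models. This equals integrating the non-normalized pair
distance distribution g(r) over r ∈ [0, 6]. It drives residue–residue
contact matrices, lipid head/tail contact profiles, hydrophobic-cluster
compactness and neighbor-residue counts.

**Density-map scoring.** Map–model agreement is the Pearson correlation
over voxels of the experimental map and a mass-weighted Gaussian-atom
rendering of the model. Per-atom positional confidence is scored as
−m_a·ρ(x_a, y_a, z_a) with ρ the unit-max-normalized density at the atom
position (trilinear interpolation); the best (most negative) 20% are
flagged well-resolved. Candidate poses (e.g. the two mirror-image lobe
assignments in a symmetric map) are ranked by map correlation, breaking
ties by distance-restraint violations.

**Ensemble geometry.** Kabsch superposition; ensemble RMSD to the
iteratively converged mean; greedy RMSD-neighborhood (Daura/GROMOS)
clustering with the "most representative" model as the center of the
largest cluster; Shrake–Rupley SASA on a deterministic Fibonacci point
set; buried interface area (SASA_A + SASA_B − SASA_AB)/2; per-residue
ΔSASA between bound and free states.

**Thermodynamics.** The mole-fraction partition model for Trp
fluorescence titrations,

    F/F₀([L]) = 1 + (F/F₀ᵐᵃˣ − 1) · Kₓ[L] / ([W] + Kₓ[L]),

with [L] the accessible lipid (60% of total, the outer leaflet) and
[W] = 55.3 M, fitted by nonlinear least squares; ΔG° = −RT ln Kₓ
(T = 293 K default); the Hill dose-response
I = I_min + (I_max − I_min)/(1 + (K_D/[Tx])^s); and the bivalency
report, which compares measured bivalent partitioning free energies
with the additive sum of their lobes.

## Worked example

Fit a simulated titration at the reported DkTx parameters
(Kₓ = 2.3×10⁶, F/F₀ᵐᵃˣ = 2.65, 2% multiplicative noise, 4 replicates):

```python
from toxinterface import synth, thermo

data = synth.simulate_titration(2.3e6, 2.65,
                                noise=synth.NoiseModel(sd=0.02),
                                replicates=4, seed=1)
print(thermo.PartitionModel(data).fit().summary())
```

```
Membrane partition fit
==============================================
observations                                36
Kx                                   2.448e+06
Kx std err                           3.425e+05
F/F0 max                                 2.648
F/F0 max std err                        0.0155
dG (kcal/mol)                            -8.56
temperature (K)                          293.0
residual (SSR)                         0.08063
max bound fraction                       0.977
```

The fitted Kₓ lands within the experimental uncertainty band of the
generating value (2.3 ± 0.7 ×10⁶) and the derived ΔG° of −8.6 kcal/mol
matches the −8.5 kcal/mol obtained from the generating coefficient. The
bivalency ledger built from the monovalent lobes (K1 −7.5, K2 −5.8
kcal/mol):

```python
print(thermo.bivalency_report(thermo.REPORTED_MONO_DG,
                              thermo.REPORTED_BIVALENT_DG,
                              thermo.BIVALENT_COMPOSITION))
```

```
construct  measured  theoretical  penalty
     DkTx      -8.5        -13.3      4.8
     K1K1      -8.7        -15.0      6.3
     K2K2      -6.6        -11.6      5.0
```

i.e. every bivalent construct partitions 4.8–6.3 kcal/mol more weakly
than perfect additivity of its lobes would predict.

The same stages are available from the shell, e.g.

```bash
toxinterface simulate complex --n-res 8 --contacts A:2-B:3 --seed 7 --out toy.pdb
toxinterface contacts --pdb toy.pdb --sel-a "chain A" --sel-b "chain B" --out matrix.csv
toxinterface demo --seed 1 --out-dir demo_out   # end-to-end pipeline run
```

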