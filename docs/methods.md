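# Methods

This note records the models implemented in `toxinterface`, the choices
made where the underlying conventions were genuinely open, and what the
synthetic-data generators do and do not emulate.

## Coordinate model and I/O

Structures are ordered atom lists over 1-based models (NMR ensemble
members or trajectory frames); multi-model structures must share an
atom roster, which is validated on parse. PDB parsing is fixed-width
with line-numbered errors; elements come from columns 77–78 when
present and are otherwise inferred from the atom-name field using
standard column justification (a left-justified two-letter name is a
metal, leading digits mark hydrogens). Atomic masses come from a closed
table (H 1.008, C 12.011, N 14.007, O 15.999, S 32.06, P 30.974, plus
common ions); an element outside the table raises rather than receiving
a default mass. Insertion codes and hybrid-36 numbering are not
supported — the deposited entries and synthetic fixtures this pipeline
targets do not need them.

Density maps are CCP4/MRC 2014 files read through gemmi; axis order is
normalized to (x, y, z) at read time regardless of the header's
MAPC/MAPR/MAPS permutation, and all downstream code assumes canonical
order. Non-orthogonal cells are rejected. Restraint tables use a simple
whitespace-delimited 7-column format (`chainA resA atomA chainB resB
atomB upper`); this is a documented stand-in for refinement-package
restraint dialects, which are not standardized plain text.

## Contact statistic

N_p counts unordered heavy-atom pairs across two disjoint groups with
distance ≤ 6 Å. Decisions:

* **The cutoff is inclusive** — the first-shell integral is closed at
  its upper bound, so a pair at exactly 6.000 Å counts.
* **Hydrogens are excluded** in one place (the contacts module);
  parsers keep them.
* **"Side-chain"** means heavy atoms excluding N, CA, C, O; CB is a
  side-chain atom. The sidechain-only filter is applied symmetrically
  to both selections.
* **Frames are weighted equally** in all time averages.
* **No periodic-boundary handling**: inputs are assumed whole and
  unwrapped. Wrapped trajectories are out of scope.

The production path uses a k-d tree (`scipy.spatial.cKDTree`) for
neighbor search; the test suite pins it against a brute-force O(n²)
double loop on every fixture class.

## Density scoring and pose ranking

"Normalized density" is read as the map scaled to unit maximum
(positive peak = 1); z-scoring is available as an alternative but
unit-max is the default, keeping ρ ≤ 1 and scores comparable across
maps. The per-atom score is −m_a·ρ at the atom position by trilinear
interpolation; *top 20%* means the most favorable (most negative) 20%
of scores, i.e. `round(0.2·N)` atoms, with ties broken toward the lower
serial. Atoms outside the map bounding box read ρ = 0 with a warning,
never an exception, because refinement intermediates may poke out of
the box.

A restraint is violated when the model distance exceeds its upper
bound; the violation RMSD is the root-mean-square *excess* over
violated restraints only, so it is zero exactly when nothing is
violated. Selectors that do not resolve to exactly one atom are
excluded from the count and reported separately.

Pose ranking renders each pose as a sum of mass-weighted isotropic
Gaussians (amplitude m_a, width σ) on the experimental grid and orders
by (higher correlation, fewer violations, lower violation RMSD, input
order). The composite ordering is a package decision: the two criteria
were historically evaluated side by side without a stated combiner, and
correlation-first matches how discriminating mirror-image lobe
assignments actually proceeds (the map dominates; restraints break
near-ties).

## Ensemble geometry

* **Superposition** is closed-form Kabsch via SVD with the determinant
  correction, so reflections are never returned; collinear point sets
  raise.
* **RMSD to mean** iterates superpose-all-on-mean / recompute-mean
  until the mean shifts < 1e-6 Å (cap 100 iterations), then averages
  each model's RMSD to the mean. The wording "deviation to the mean"
  is ambiguous between this and the mean of pairwise RMSDs; the
  alternative is exposed as `method="pairwise_mean"`.
* **Clustering** is the greedy neighbor-count algorithm: repeatedly
  take the model with the most neighbors within the cutoff (ties:
  lowest index), split off that cluster, repeat. The representative is
  the picked center; the "most representative model" is the center of
  the largest cluster. The matrix-level routine is exposed separately
  so memberships can be verified against hand traces.
* **SASA** is Shrake–Rupley with a deterministic Fibonacci-lattice
  point set (default 960 points — lone-sphere quadrature error well
  under 1%, and doubling the count moves areas < 0.5%), probe 1.4 Å,
  and a fixed Bondi-like radius table (C 1.70, N 1.55, O 1.52, S 1.80,
  P 1.80 Å). No RNG, so areas are bit-reproducible. Hydrogens are
  ignored.
* **Interface area** uses the buried-surface-per-complex convention
  (SASA_A + SASA_B − SASA_AB)/2. The convention behind historical
  printed interface areas is unstated, so agreement with such values is
  a soft check only. Per-residue ΔSASA is SASA_free − SASA_bound;
  summed over both partners it equals twice the buried interface area,
  an identity the tests enforce within quadrature tolerance.
* **Residue classes**: hydrophobic {ALA VAL LEU ILE MET PHE TRP PRO},
  basic {LYS ARG HIS} (histidine counted basic, matching the coloring
  convention of the structures this targets), acidic {ASP GLU}, else
  other.

## Thermodynamics

The partition model is F/F₀ = 1 + (F/F₀ᵐᵃˣ−1)·Kₓ[L]/([W]+Kₓ[L]) with
[W] = 55.3 M and [L] = 0.6 × total lipid (the outer leaflet), applied
before fitting. Fits minimize unweighted squared residuals over all
replicate points (replicate weighting conventions for such titrations
are unstated; weighted fitting is a one-line change on the residual).
Kₓ is fitted on a log₁₀ scale for conditioning, with bounds
Kₓ ∈ [1, 10¹⁰], F/F₀ᵐᵃˣ ∈ [1, 20], initialized at Kₓ = [W]/median([L])
and the maximum observed F/F₀. Standard errors come from the Jacobian.
If the best fit implies a maximum bound fraction below 0.3 the result
carries a low-confidence flag — a titration that never approaches
saturation cannot pin Kₓ.

ΔG° = −RT ln Kₓ with R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹ and T = 293 K by
default; this temperature reproduces all five reported free energies
from the reported partition coefficients to one decimal, which is how
the default was fixed (the measurement temperature was not stated).
One reported Kₓ (K2K2) appears in two inconsistent magnitudes in the
source data; the constant table uses 8.1×10⁴, the value consistent with
the reported ΔG° of −6.6 kcal/mol, and records the discrepancy in a
comment.

The Hill equation is I = I_min + (I_max−I_min)/(1+(K_D/[Tx])^s) — the
exponent sits on the ratio, giving increasing response with
concentration and the exact midpoint (I_min+I_max)/2 at [Tx] = K_D.
Initialization: K_D at the concentration nearest half-maximum, s = 1,
I_min/I_max from the extreme observations. If the response never
doubles over its minimum the transition was not spanned and K_D is
flagged as a lower bound rather than an estimate.

The bivalency report takes measured monovalent ΔG° per lobe and
measured bivalent ΔG° per construct, computes the theoretical bivalent
value as the sum of its lobes (complete additivity), and reports the
penalty measured − theoretical (positive = tethering weakens
partitioning).

## Synthetic-data generators

Every generator is a pure function of its arguments and an explicit
seed; zero noise collapses each simulator to its closed-form model.

* **Toy complexes** place compact 4-heavy-atom pseudo-residues
  (N, CA, C, CB + one hydrogen) on well-separated chain rails (12 Å
  residue spacing, 50 Å chain spacing) and relocate one partner residue
  per planted contact to 3.5 Å from its target, guaranteeing ≥1
  heavy-atom pair within 4.5 Å for planted pairs and > 8 Å for every
  other inter-chain pair. The construction is verified geometrically
  before returning and raises when a requested contact density is
  infeasible. This gives exact ground truth for recall/false-positive
  tests but has none of the excluded-volume or secondary structure of
  real proteins.
* **Membrane slabs** are planar two-leaflet grids of labeled head
  (HEA: P, O1, O2) and tail (TAI: C1–C3) residues — enough structure
  for head/tail contact profiling, with no force-field realism.
* **Synthetic maps** are sums of mass-weighted isotropic Gaussians
  (amplitude m_a) at heavy-atom positions; the grid-sum matches the
  analytic Gaussian integral within 1% on padded maps. Real
  experimental maps have resolution-dependent falloff, noise and
  symmetry artifacts that these do not.
* **Titrations** use multiplicative Gaussian noise (fluorescence error
  scales with intensity); **dose-responses** use additive Gaussian
  noise (current noise is roughly signal-independent). Neither noise
  magnitude is stated in the source data; the defaults (2%
  multiplicative; 2% of range additive) are package conventions and
  configurable. The default titration grid is 9 points over 0–1.6 mM
  total lipid, mirroring the experimental range.
* **Perturbed ensembles** displace heavy atoms by isotropic Gaussians;
  hydrogens follow their nearest same-residue heavy atom rigidly.

Passing the recovery tests on these inputs shows the estimators are
correct and well-conditioned under the stated noise models; it does not
show robustness to the systematic errors of real measurements
(scattering correction residuals, rundown, partial toxin activity).

## Problem sizes and scope

The test and demo problem sizes — 50–60-atom contact clouds, 8–10
residue toy chains, ~10³-voxel-scale maps, 50-seed fit sweeps — are
chosen as the smallest sizes at which each property is sharply testable
(exact oracle agreement, planted-contact recall, median-error bands).
Known limitations: no mmCIF, no symmetry expansion, no wrapped-PBC
trajectories, no kinetic (on/off-rate) modeling, and no attempt to
reproduce map correlation coefficients computed by external refinement
packages over unknown masks.
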