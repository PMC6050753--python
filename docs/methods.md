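# Methods

This note records the models, conventions and numerical choices behind
fabscatter, and what the synthetic fixtures do and do not establish.

## Scattering model

The orientationally averaged intensity of a rigid particle is computed by
the exact Debye double sum over scatterer pairs,
I(q) = Σ_ij f_i f_j sin(q·r_ij)/(q·r_ij), with the sinc limit taken as 1 at
q·r = 0. No multipole, spherical-harmonic or coarse-grid approximation is
used: the method's central object is the per-pair decomposition itself,
stored as a full symmetric S×S matrix whose grand sum (not a doubled
half-sum) is the conserved quantity. sin(x)/x is evaluated directly rather
than through `numpy.sinc` so that a brute-force double loop reproduces the
vectorized sum to ~1e-14 relative; the π-rescaling inside `numpy.sinc`
costs ~5e-10 of cancellation error on realistic sums, which matters when
the decomposition is asserted to conserve I(q) to 1e-9.

Two site levels are supported:

* **atomic** — every atom a site, atomic form factors;
* **residue** (default for difference matrices) — one site per residue at
  its C-alpha, with a residue form factor. This is the coarse level at
  which difference matrices are cheap for thousands of frames.

Difference matrices D(A, B) = M_A − M_B are antisymmetric under operand
swap and sum to I_A(q) − I_B(q). They are reported at q ∈ {0.05, 0.1,
0.15, 0.2} Å⁻¹, default 0.1: at low q a local conformational change shows
up as a sharply localized row/column band, while beyond ~0.15 Å⁻¹ the
signal spreads over all residues.

## Form factors

Vacuum atomic form factors use the published Cromer–Mann 4-Gaussian
parameterization, f(q) = Σ_k a_k·exp(−b_k·(q/4π)²) + c, with coefficients
shipped as package data. Every shipped species satisfies f(0) = Z within
0.1%; magnesium (0.11% off at q = 0 in this parameterization) is omitted
from the shipped set rather than shipping a species that violates the
stated f(0) contract.

The optional solvent correction subtracts the scattering of displaced bulk
solvent, ρ_s·V·exp(−q²·V^{2/3}/4π), with ρ_s = 0.334 e/Å³ and per-element
displaced volumes from the standard excluded-volume tables. No hydration
shell is modeled; profiles are "protein in vacuo minus displaced solvent",
which is sufficient for relative comparisons across conformers but will
differ systematically from hydration-shell-aware predictors at higher q.

Residue form factors are plain composition sums over the residue's
in-chain atomic composition (free amino acid minus one water, hydrogens
included, neutral side chains, His protonated at N-epsilon). A
precomputed-grid + linear-interpolation mode reproduces the
tabulate-and-interpolate usage of coarse pipelines and agrees with direct
evaluation to ≤0.5% at a 0.01 Å⁻¹ grid step. Terminal-residue variants
are not distinguished: the difference-matrix signal of interest is an
interior-residue phenomenon, and a one-water perturbation on two termini
is negligible against whole-domain scattering.

## Fit statistic

χ² = 1/(N−1)·Σ[(I_exp − δ − c·I_mod)/σ]², minimized analytically (weighted
linear least squares) over the scale c, and over the offset δ when constant
subtraction is enabled; δ absorbs small buffer-subtraction errors and can
only lower χ². The 1/(N−1) normalization is the reduced-χ² convention of
the standard crystal-vs-SAXS fitting tools. The theoretical curve is
linearly interpolated onto the experimental grid; extrapolation raises.
Fitting defaults to q ≤ 0.2 Å⁻¹ — single rigid conformers of flexible
proteins rarely explain data beyond that, and truncation avoids overfitting
the low-information tail — with full-range fitting available. χ² is *not*
monotone under truncation (removing ill-fitting high-q points can raise the
reduced statistic); both values are simply reported for their point sets.
Categories: good < 3 ≤ fair < 6 ≤ poor < 9 ≤ very poor, half-open on the
left boundary of each upper interval.

Residuals are stored as log10(I_exp) − log10(c·I_mod + δ) and written in
4-column fit files (q, I_exp, σ, fitted model) round-trippable at 6
significant figures.

## Guinier and shape statistics

Guinier Rg comes from a weighted linear fit of ln I vs q² over the largest
low-q window with q·Rg ≤ 1.3, iterated to self-consistency from a 5-point
seed window; a non-negative slope raises (no Guinier decay). Dmax is not
reported from Guinier analysis — it is not observable from the Guinier
region — only from coordinates, where it is the exact maximum pairwise
distance (computed on the convex hull above 2000 atoms). Model Rg uses
electron-count weights by default.

## Ensemble analysis

Superposition is Kabsch (SVD with determinant correction), computed on a
selection and applied to all atoms. PCA aligns all frames to frame 1, then
realigns once to the ensemble mean (single pass, configurable; full
iterative mean convergence changes Cα covariances at far below the
eigenvalue scale and is not worth the second sweep). The covariance of the
analyzed C-alpha coordinates is diagonalized with a dense symmetric
eigensolver; eigenvector signs are fixed by making each vector's
largest-magnitude component positive, so projections are reproducible run
to run. Projection of external structures aligns them to the same reference
used in the final training alignment pass — this, not the post-hoc mean, is
what makes train-frame projections reproduce stored scores to 1e-8.

Clustering is hierarchical agglomerative on pairwise best-fit RMSD over a
selection. The termination threshold ε (default 2 Å) cuts the dendrogram
where inter-cluster linkage distance exceeds ε; linkage defaults to
*average*, the default of the standard trajectory-clustering tools (the
algorithm family and ε are conventionally specified without naming a
linkage, so it is configurable). The cluster representative is the member
frame with minimum mean RMSD to its co-members — a physical frame standing
in for the non-physical mean structure — with ties broken toward the lowest
frame index.

Autocorrelation of scalar series (e.g. per-frame elbow angles) uses the
mean-removed estimator with per-lag 1/(n−k) normalization against the
series variance, so lag 0 is exactly 1 and a strictly alternating series
gives exactly −1 at lag 1.

## Elbow angle

Each F(ab) module (variable VL/VH, constant CL/CH1) is related by an
approximate two-fold. The rotation part of the least-squares superposition
of the light-chain domain onto its heavy-chain partner (residues paired by
rank after truncation to equal length — no sequence aligner dependency; a
custom pairing hook can be layered on top) yields the module's pseudo-dyad
axis. The elbow angle is the angle α between the two axes, disambiguated
onto (0°, 360°): if det[v̂, ĉ, ĥ] < 0, with ĥ the unit vector from the
constant-module centroid to the variable-module centroid, the reported
angle is 360° − α. Reported F(ab) elbow angles span roughly 117–227°, so
the >180° branch is required. A superposition rotation below 90° means the
"pair" is far from a two-fold and the axis is not meaningful; this is
recorded as a warning on the result rather than an error.

Under this handedness convention (centroid vector fixed by module role,
not by chain), relabeling which chain is "heavy" leaves the angle
unchanged — both dyad axes flip sign together and the determinant is
invariant. Domain splits are user-supplied residue numbers (variable =
residues strictly below the split); the CLI ships the conventional
lambda-chain example (heavy 113, light 107). Splits are a property of the
numbering scheme of the structure at hand and are deliberately not guessed.

## Synthetic fixtures: what they emulate and what they don't

The hinge toy builds four helical-lattice C-alpha point clouds (60
pseudo-residues each by default; helix radius 7 Å, rise 1.5 Å, twist 100°,
giving well-conditioned inertia tensors): a fixed constant module whose two
domains are related by an exact 175° rotation about +z, and a variable
module (its own 175° pseudo-dyad) whose axis is placed at the requested
elbow angle with a 45° out-of-plane twist. The twist sign flips across
180° so that the computed, disambiguated elbow angle equals the requested
angle on both branches — the generator is exact ground truth for the
geometry (recovered to ≲0.1° in tests). The module centroid bends in the
x–z plane at half the polar angle, keeping the handedness reference
non-degenerate. Pseudo-residues are glycine-labelled so residue form
factors resolve with the smallest standard composition.

Frames sweep (or draw) the elbow angle over a range, 130–175° by default —
inside the experimentally observed F(ab) band — and a 10-residue loop in
the heavy constant domain independently toggles between "bent" and
"extended" (6 Å radial displacement), reproducing the confound of a global
hinge (PC1) with a local loop change that difference matrices must
localize. Frames with steric clashes (any pair < 1 Å) are regenerated with
0.05 Å jitter, with a hard failure after 100 attempts. Generation is
byte-deterministic under the spec seed.

Synthetic experiments perturb a Debye profile with Gaussian noise
σ(q) = a·I(q) + b, a = 0.01 and b = 1e-4·max I by default — a minimal
counting-statistics-like model (relative noise with a floor where the
signal vanishes). The same σ is stored in the curve, so the reduced χ² of
the generating conformer is ~1 by construction.

What passing tests on these fixtures do **not** show: agreement with
hydration-shell-aware predictors on real proteins; robustness to
correlated or non-Gaussian beamline noise, buffer-subtraction artifacts or
interparticle effects; elbow-angle behavior on real immunoglobulin folds
(imperfect internal symmetry, unequal domain lengths, insertion codes); or
PCA/clustering behavior on solvent-coupled anharmonic MD ensembles. The
fixtures establish algorithmic fidelity — exactness, conservation,
invariances, and recovery of planted parameters — not force-field realism.

## Problem sizes

Default validation sizes are chosen for exactness checks at desk scale: 50
random sites for Debye-oracle comparisons, 200-residue chains for
difference-matrix localization, 100-frame sweeps of 240-site toys (about
two minutes end-to-end including 100 profile fits on 200-point grids) for
pipeline recovery, and 10⁴ points for the uniform-sphere Rg limit.

## Known limitations

* No hydration-shell model: absolute profiles differ from shell-aware
  tools; χ² comparisons between conformers of the same topology are the
  intended use.
* Residue form factors are composition sums, not orientation-averaged
  internal-structure factors; at residue-level the profile is reliable only
  at low q (the difference-matrix regime, q ≤ 0.2 Å⁻¹).
* Guinier fitting assumes a monodisperse decaying curve; aggregation or
  repulsion at very low q will bias Rg.
* The elbow-angle rank pairing assumes the four domains have comparable
  lengths and consistent numbering; heavily engineered constructs may need
  an explicit pairing.
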