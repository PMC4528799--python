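# Methods

## The diffuse-scattering model

A crystal whose unit cells independently adopt conformations drawn from a
common distribution scatters, in addition to the Bragg peaks, a diffuse
intensity equal to the variance of the unit-cell structure factor:

    I_D(q) = N [ ⟨|F_n(q)|²⟩_n − |⟨F_n(q)⟩_n|² ].

The equivalent all-atom covariance formulation expands this variance over
atom pairs; its cost grows with the square of the atom count, whereas the
ensemble form above is linear in atoms and models. We therefore compute the
ensemble form and keep the pair expansion as an independent test oracle:
on small systems both agree to ~1e-15 relative.

Assumptions inherited by everything downstream:

- **No inter-cell correlations.** Each snapshot is one unit cell; disorder
  spanning neighboring cells is representable only through the supercell
  ("copies") expansion mode, where a caller-supplied assignment hook places
  (possibly different) models in adjacent copies.
- **Equal model weights.** Snapshots are equally probable.
- **Per-unit-cell scale.** The lattice-count prefactor N is fixed to 1; all
  comparisons in this package are correlation-based, so a global scale is
  immaterial.
- **P1 content.** No symmetry expansion is performed; Friedel symmetry of
  computed maps is an emergent consequence of real scatterers and is tested,
  not assumed.
- **Protein-only signal.** Waters are dropped on read by default and there
  is no bulk-solvent or anomalous term, so simulated maps isolate the
  correlated motion encoded by the disorder model. Per-atom isotropic B
  factors are likewise excluded from the structure factors by default
  (`use_b=True` retains them as Debye–Waller factors): the ensemble spread
  itself is the disorder model. Hydrogens are dropped by default.

Structure factors use direct summation with IT92 4-Gaussian form factors
(via gemmi's coefficient table). Direct summation is exact at arbitrary —
including fractional — Miller indices, which the subsampling scheme needs;
system sizes here (10²–10³ atoms, 10³–10⁴ reflections, 10³ models) keep it
inexpensive. Reciprocal grids cover the full ±h, ±k, ±l sphere to a
resolution limit d_min, defined as |s| = 1/d ≤ 1/d_min with the boundary
included (tolerance 1e-12 relative).

## TLS sampling

A TLS group models a rigid body whose orientation and position fluctuate:
L (rad²) is the covariance of a small rotation vector ω, T (Å²) the
covariance of a translation u, and S (Å·rad) their cross-covariance, all
about a stated origin. PDB headers carry L in deg² and S in Å·deg; both are
converted to radians on parse and back on write. S is determined only up to
its trace, which is fixed to zero on construction (the standard convention).

Sampling requires decomposing the tensors into independent motional axes:

1. libration axes l_k and variances λ_k: the eigensystem of L;
2. screw pitches c_k = Ŝ_kk/λ_k and axis offset points w_k (read off the
   off-diagonal elements of Ŝ = P S Pᵀ in the libration eigenframe):
   librating about an axis *displaced* from the origin, with a *pitch*
   along it, is what generates rotation–translation coupling;
3. vibration axes and variances: the eigensystem of the residual
   V = T − Σ_k λ_k a_k a_kᵀ, where a_k = c_k l_k − l_k × w_k is the
   translation per radian produced by libration k.

Reassembling (T, L, S) from the decomposition reproduces the inputs exactly
(machine precision; the test contract requires 1e-6), and residual
variances in [−1e-6, 0) Å² are clamped to zero to absorb rounding in parsed
4-decimal tensors; larger negatives mean S is inconsistent with T and
raise. Groups failing eigenvalue validation (negative T or L eigenvalues
beyond 1e-8) are rejected before sampling — such tensors describe negative
variances and have no real-space realization.

Each snapshot draws the six amplitudes as independent zero-mean Gaussians
and applies the three librations as *exact finite rotations* (axis-angle,
composed in fixed axis order) about their offset axes with their screw
translations, then adds the vibration. Finite rotations keep every sampled
model exactly rigid (interatomic distances to machine precision); the
closed-form ADP tensor

    U(r) = T + A L Aᵀ + A S + Sᵀ Aᵀ,   A = skew(r − origin),

is recovered by the sampled displacement covariance in the small-angle
limit, and serves as the statistical oracle (5% + 3 Monte-Carlo standard
errors at 10⁴ draws; finite-angle corrections enter at order λ, well below
that tolerance for librations up to a few degrees).

Randomness: one master seed; per-(model, group) substreams derived by
counter (`SeedSequence(seed, spawn_key=(model, group))`), so ensembles are
reproducible and independent of evaluation order.

### Correlated inter-group motion

Independent sampling assumes no correlation between groups. To model
correlated rigid-body motion of two groups, both are stepped
*deterministically* along all their translation and libration eigenvectors
through a common grid of multiples of the per-axis standard deviation σ —
default step σ/2 over 10 models, i.e. −2.5σ, −2.0σ, …, +2.0σ. (A grid from
−2.5σ to +2.5σ at step σ/2 would contain 11 points; we honor the stated
model count of 10 and keep the stated step, dropping the +2.5σ endpoint.)
"Antiparallel" motion negates the translation steps of the second group
only; librations are stepped identically in both modes, since the screw
coupling already ties them to the translations. These ensembles are
deterministic by construction: the seed argument is accepted and ignored,
so re-runs with any seed are bit-identical.

## Map analytics

Diffuse intensity falls steeply with resolution, and that shared radial
falloff dominates naive map correlations. All meaningful comparisons
therefore use *anisotropic maps*: each intensity minus its resolution-shell
mean. Shells are equal-width in |s| = 1/d (uniform shell population at high
resolution; the binning variable is a convention of this package), default
50 bins for subtraction and 10 for per-shell correlations, both
configurable. Per-shell correlations with fewer than 3 points or zero
variance are reported as missing (NaN), never as 0, to avoid biasing trend
curves. Subtraction is idempotent and leaves exactly zero shell means;
adding any shell-constant radial component to a map does not change its
anisotropic correlation with another map.

## Subsampling between Bragg points

The molecular transform is continuous; integer indices merely sample it.
Growing the cell m-fold in real space with vacuum padding makes the
reciprocal lattice m-fold finer, and F_expanded(mh, mk, ml) equals
F_original(h, k, l) identically (the fractional coordinates rescale
exactly), so integer indices of the expanded cell are fractional indices
h/m of the original lattice. The "copies" mode tiles m³ translated copies
instead, which preserves the total scattering mass and supports cross-cell
correlation schemes through the model-assignment hook; with identical
copies it reproduces the lattice extinctions (F = 0 except at indices
divisible by m), which is tested.

A fractional map is collapsed back onto the Bragg lattice by assigning
each fractional index to its nearest integer triple — component-wise, ties
rounded half away from zero (deterministic and symmetric about the origin)
— and averaging within each 1×1×1 voxel. Total intensity is conserved
exactly, and the voxel around the origin is retained in the collapsed
output so that conservation holds identically (generated grids themselves
never include (0,0,0)).

Cell expansion does not commute with symmetry operations that include
translations. Structures declaring a space group with a screw component —
including screws induced by lattice centering, detected from the symmetry
operations' intrinsic translations rather than from the symbol — trigger a
warning: subsampled maps of such structures are comparable between
simulations but not against experimental data.

## Synthetic test systems

The fixtures module generates random point-cloud "structures" (uniform in
the cell, one atom per residue, chains split evenly so TLS selections
address contiguous blocks) and random TLS groups built *generatively* from
the decomposition itself: positive eigenvalues for L and for the vibration
residual, screw pitches constrained so trace(S) = 0, and T assembled as
vibration covariance plus the libration-induced translation covariance.
Every generated group is therefore physical by construction and
decomposes without clamping — a property swept in the tests.

Default scales (chosen once as representative of modest crystalline
rigid-body disorder, and doubling as the standing study conditions for the
verification runs): 40-atom two-chain systems in a 30 × 34 × 38 Å
monoclinic cell (β = 105°), libration eigenvalues ~(1.5–2.5°)², residual
vibration eigenvalues 0.01–0.03 Å², screw pitches ~N(0, 0.8 Å/rad), axis
offsets ~N(0, 1.5 Å), maps to d_min = 3 Å (~5800 reflections). Ensemble
convergence is assessed exactly as with real systems: the anisotropic-map
correlation between two independently seeded ensembles of n models rises
with n (≈0.65 at n = 16, ≈0.94 at n = 125) and exceeds 0.95 by n = 1000.

What the toys do *not* emulate: bonded geometry, secondary structure,
solvent, realistic packing density, or inter-group chemical restraints.
Passing tests demonstrate the correctness of the sampling and scattering
mathematics under the stated model, not the biological plausibility of any
particular TLS refinement.

## Numerical choices and limitations

- Guinier variance is accumulated as running sums of F and |F|²; the
  subtraction loses ~16 digits' worth of precision relative to |F|², which
  is harmless at the diffuse/Bragg ratios of interest (≥1e-6). Tiny
  negative variances (beyond −1e-9 of the map scale would be a bug and
  raises) are clamped to zero.
- Atom matching across PDB models is by (chain, residue number, atom name),
  robust to renumbered MODEL blocks; mismatched rosters are a hard error
  naming the first offender. Alternate locations other than blank/'A' are
  dropped — the ensemble itself is the disorder model.
- Map comparisons require identical index sets; there is no resampling.
- Ensembles are generated in memory as explicit models; at 10³ models and
  10² atoms this is a few MB. The diffuse accumulation is O(n_hkl) memory
  regardless of ensemble size.
- Refinement of TLS parameters against data, liquid-like-motion and
  normal-mode disorder models, diffraction-image processing, and direct
  evaluation of F at fractional indices without cell expansion are out of
  scope.
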