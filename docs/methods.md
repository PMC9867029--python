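# Methods

This note records the models implemented in `ionshell`, the defaults and
their rationale, the numerical choices, and the limits of what the
synthetic-data tests demonstrate.

## Units and containers

Lengths are nm, times ps (GRO/XTC conventions; PDB ångström values are
divided by 10 on read). A `Topology` is an ordered list of atoms with
0-based contiguous indices and a *role* flag in {protein, water, ion}
assigned from residue-name tables (`HOH/SOL/TIP3/...` → water; `NA/CL/MG/K/
LI/CA/SR/NH4` and common force-field synonyms → ion with a signed valence;
everything else → protein, with a warning for non-standard names). The
tables are extensible via YAML so arbitrary salts can be named. Only
orthorhombic boxes are supported; triclinic input is rejected outright
rather than silently mis-wrapped. Residue numbers are kept as authored
(1-based in files).

The selection mini-language (`name`, `resname`, `resnum`/`resid`, `role`,
`element`, `chain`, combined with `and`/`or`/`not` and parentheses,
multi-value predicates meaning any-of, `a:b` residue ranges) is evaluated
deterministically over the topology arrays; an empty result is a valid
selection, a syntax error reports its character position.

## Essential dynamics

The covariance analysed is the standard 3N×3N Cartesian covariance of the
N selected atoms (Cα by convention), mass-unweighted, about the grand mean
of all concatenated frames — the convention of the common MD tool chains.
All variances are population statistics (ddof = 0) so the PCA identities
hold exactly: Σλ equals the covariance trace, the variance of a training
projection equals its eigenvalue, and reconstruction from all modes returns
the centred coordinates to round-off.

Superposition is a rigid-body least-squares (Kabsch) fit with the proper-
rotation constraint det R = +1; mirror-image conformations therefore retain
a positive RMSD. The default reference is the first frame of the first
trajectory (configurable); fewer than three non-collinear selected atoms is
an error because the rotation is under-determined. Eigenvector signs are
fixed by making each vector's largest-magnitude component positive (ties
break to the lower index) so projections are reproducible across runs.

RMSF along one mode is computed on the mode-filtered trajectory
x_f(t) = mean + p_m(t)·v_m, which reduces analytically to
std(p_m)·|v_m,j| per atom; the peak atoms are those moved most by the
collective motion.

## Ellipsoidal hydration shells

Per frame, the protein selection (all protein atoms by default, not just
Cα) defines a 3×3 geometric covariance whose eigendecomposition gives the
instantaneous protein ellipsoid. Semiaxes are a_i = factor·√λ_i with
factor = 2 by default: the eigenvalue has units of nm² so only the square
root is dimensionally meaningful, and for a Gaussian positional
distribution 2√λ covers ≈95% of atoms per axis. For a **uniform solid**
ellipsoid the axis variance is s_i²/5, so the fitted semiaxis is
(2/√5) ≈ 0.894 of the generating semiaxis — tests of the synthetic
generator compare against the convention, not the generating value.

Shells are bounded by ellipsoids with semiaxes a_i + n·δ_i, where
δ_i = δ₀·λ_i/λ_max and δ₀ = 0.03 nm by default. Note this eigenvalue
(not √eigenvalue) scaling means shells are *not* similar ellipsoids: minor
axes grow much more slowly than the major axis. A config switch
(`increment_scaling = "sqrt_eigenvalue"`) provides the shape-preserving
alternative, but the eigenvalue scaling is the default.

A point in the ellipsoid body frame belongs to layer n iff
E_n(p) = Σ_i (q_i/(a_i+nδ_i))² ≥ 1 and E_{n+1}(p) < 1, so a point exactly
on a shell's inner surface belongs to that shell. Points inside the
innermost ellipsoid are reported as an explicit *inner-core* row and points
beyond the outermost shell as an *outside* row, so solvent counts conserve
exactly in every frame. Negative n probes the protein interior; n_min is
validated so no semiaxis collapses.

Densities are counts/volume with the volume of the full shell,
V_n = (4π/3)[Π(a_i+(n+1)δ_i) − Π(a_i+nδ_i)], deliberately **ignoring** the
volume occupied by protein atoms or other solutes; interior layers
therefore read low in absolute terms and the profile is to be interpreted
comparatively between conditions. Water is counted by one oxygen per
molecule, ions by their single atom. When a frame carries a box, solvent
coordinates are wrapped to the periodic image nearest the ellipsoid centre
before assignment (the protein is assumed whole and centred). The distance
coordinate reported for layer n is a₁ + (n+½)δ₁ along the major semiaxis,
frame-averaged. Frames whose fit degenerates (coplanar selection) are
skipped with a warning.

## Distances, distributions, salt bridges

Residue-pair distances use Cα–Cα by default (the natural choice for a
backbone-level open/close observable); `min-heavy` takes the per-frame
minimum over all heavy-atom pairs, and an explicit atom-pair list averages
those fixed pairs. The minimum-image convention applies whenever a box is
present.

Distance histograms use a uniform bin width (default 0.05 nm) and report
probability mass (frequencies summing to 1). Modes are strict local maxima
with prominence at least 5% of the tallest bin (defaults chosen to resolve
maxima 0.5 nm apart with margin); the histogram is zero-padded so boundary
maxima count, and a constant series yields a single occupied bin with one
mode. Mode detection requires ≥100 samples.

A salt bridge between an acid (Asp OD1/OD2, Glu OE1/OE2) and a base (Arg
NH1/NH2, Lys NZ) is scored as the mean of its one or two O–N atom-pair
distances. For the two-O/two-N case the assignment minimising the summed
distance in the resolving frame is chosen and kept fixed for the rest of
the trajectory; exact ties break to the lower-index (identity) pairing.
For Lys both oxygens pair with the single NZ. Contact enumeration between
two conformers of one sequence scores every acid×base couple in both
structures (pairing resolved per structure) against a cutoff, 0.5 nm by
default — the common literature convention for salt-bridge existence — and
labels each contact `both`, `A-only` (broken going A→B) or `B-only`.

## Binding titrations

The single-site hyperbola ΔAU_obs = ΔAU_max·[L]/(K_D+[L]) is fitted per
wavelength and globally with one shared K_D. The free-ligand concentration
is approximated by the total (analytical) concentration; no tight-binding
quadratic correction is applied (a caveat when K_D approaches the protein
concentration). The global objective is unweighted joint least squares
across wavelengths.

Numerically, the per-wavelength baseline and amplitude enter the model
linearly and are profiled out in closed form for each trial K_D (variable
projection); the scalar K_D is then located by a 121-point log-spaced grid
over [10⁻³·L_min, 10³·L_max] followed by bounded scalar minimisation in
ln K_D (xatol 10⁻¹²). Fitting an explicit per-wavelength baseline — rather
than subtracting the noisy zero-ligand column from every other column —
keeps the residuals independent, which is what makes the reported standard
errors calibrated: in the replicate study (50 wavelengths, 12 points,
0.002 AU noise) the ±2 SE interval covers the true K_D in ≈95% of
replicates and the relative bias is well under 1%. SEs come from the
Gauss–Newton curvature s²(JᵀJ)⁻¹ at the optimum. A flat (all-constant)
response is rejected as unidentifiable, and a fitted K_D above the top
ligand concentration triggers a saturation warning.

Free energies use ΔG = RT ln(K_D/1 M) with R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹
and T = 298 K, the convention consistent with the published per-salt
binding table this package's tests check against (all eight rows reproduce
within ±0.01 kcal/mol); SE(ΔG) = RT·SE(K_D)/K_D to first order.

The high-spin fraction is a constrained two-reference linear decomposition:
min_α ‖s − (α·HS + (1−α)·LS)‖² with α ∈ [0,1], solved in closed form. This
is a documented stand-in for band-fitting spectral procedures used
experimentally, not a claim of equivalence; reference spectra are
user-supplied or synthetic, never shipped as "true" P450 spectra.

Ionic strength is I = ½Σc_i z_i² over fully dissociated species; a small
table maps common 1:1 and 1:2 salts to their compositions (1.17 M and
0.07 M MgCl₂ give 3.51 and 0.21 M, i.e. 3.5 and 0.2 after rounding).

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical* structure the analyses assume,
with all randomness derived from an explicit seed (bit-reproducible):

- **Ellipsoid system**: protein stand-in points uniform in a solid
  ellipsoid (closed-form covariance for validating the fit), sampled once
  and held fixed across frames; water oxygens and ions uniform in the box
  outside the ellipsoid with Poisson-rounded counts, resampled
  independently per frame so per-layer counts are independent Poisson
  draws — exactly what the trajectory-averaged density oracle requires.
  Ion placement ignores electroneutrality by default (densities stay
  controlled); a `neutralize` flag balances the total charge by topping up
  a counter-ion species.
- **Two-state trajectory**: each frame is one of two conformers plus iid
  Gaussian noise; states are iid Bernoulli draws or an optional two-state
  Markov chain with the same stationary occupancy. There is no temporal
  correlation in the noise and no intermediate conformations.
- **Titration spectra**: the hyperbola plus iid Gaussian noise, signed
  amplitudes encoding the 419-decrease/388-increase difference pattern.
- **Salt-bridge fixture**: a minimal Asp+Arg pair whose designated O–N
  distances are exact by construction; with a single requested distance
  both pairs are placed at that distance so any per-pair mean equals it.

None of this reproduces real solvent structure, force-field physics,
correlated protein dynamics or instrument drift. Passing tests demonstrate
the *estimators* are correct and calibrated under their stated assumptions;
they say nothing about force-field accuracy or sampling convergence of any
particular MD study.

## Problem sizes and numerical tolerances

The test suite runs at desk scale by design: uniform-density shell checks
use a ~57 000-water box over 6 frames with shells n ∈ [−5, 100]
(δ₀ = 0.03 nm); the layer-volume closed form is cross-checked against
2×10⁶-point Monte-Carlo integration and an exhaustive per-point layer scan
at 10⁴ points; PCA identities use 10-residue two-state systems at a few
hundred frames; parameter recovery uses 300–500 replicate 50-wavelength
fits. The "3σ Poisson" band for a layer's mean density uses the Poisson σ
of a single frame's expected count, so frame-averaging only tightens the
observed statistic relative to the band.

## Known limitations

- No triclinic PBC, velocities, or trajectory editing.
- Layer volumes are never excluded-volume corrected; interior densities
  are comparative quantities only.
- The free-ligand ≈ total-ligand approximation biases K_D when binding is
  tight relative to the protein concentration.
- The spin decomposition is linear and two-state; intermediate spin or
  baseline drift is not modelled.
- `pair_polar_atoms` fixes the O–N assignment from a single frame; bridges
  that swap pairing mid-trajectory keep the initial assignment.
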