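# ionshell

Analysis tools for studying how the ionic environment shifts a protein's
open/closed conformational equilibrium, built around two workflows:

1. **Trajectory analysis** — post-processing of protein MD trajectories:
   essential-dynamics PCA of the Cα positional covariance, residue-pair
   distance observables and their (possibly bimodal) distributions,
   salt-bridge distances and open-vs-closed ionic-contact comparison, and an
   ellipsoidal hydration-shell model that resolves water and ion number
   densities layer by layer from the protein interior out into bulk solvent.
2. **Titration analysis** — global fitting of multi-wavelength equilibrium
   binding titrations (type-I UV–Vis difference spectra) with one shared
   dissociation constant, free-energy conversion, high-/low-spin spectral
   decomposition, and ionic-strength arithmetic.

The intended users are structural/computational biochemists working on
lid-gated enzymes (e.g. bacterial cytochromes P450, where substrate binding
and closure displace the heme axial water and shift the Soret band from
419 to 388 nm), but every routine is generic.

## The models

**Binding.** At each wavelength *w* the difference absorbance follows the
single-site hyperbola

    ΔAU_obs(w, L) = ΔAU_max(w) · [L] / (K_D + [L])

with one K_D shared across all wavelengths and a signed amplitude per
wavelength. The global fit profiles out the per-wavelength baseline and
amplitude analytically (variable projection) and optimises only the scalar
K_D; standard errors come from the Gauss–Newton curvature. The binding free
energy is ΔG = RT ln(K_D / 1 M) with R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹,
T = 298 K by default.

**Hydration shells.** Per frame the protein is approximated by the
ellipsoid of its 3×3 geometric coordinate covariance: eigenvectors give the
axis directions, and semiaxes are a_i = 2√λ_i. Concentric shells grow as
a_i(n) = a_i + n·δ_i with δ_i = 0.03 nm · λ_i/λ_max, n possibly negative
(interior layers); each shell's water/ion number density is count/volume
with no excluded-volume correction, averaged over frames.

**Essential dynamics.** The 3N×3N covariance of superposed Cα coordinates
is diagonalised; leading eigenvectors span the essential subspace, frames
are projected onto modes, and per-atom RMSF of the mode-filtered trajectory
localises the collective motion (e.g. a lid's helix/loop closure).

Synthetic-data generators (`ionshell.synthetic_data`) produce solvated
ellipsoid systems with known uniform densities, two-state Cα trajectories
with prescribed occupancies, titration spectra obeying the hyperbola, and
exact salt-bridge geometries — so the full pipeline is testable end to end
with known ground truth.

## Worked example

```python
import numpy as np
from ionshell.synthetic_data import TitrationSpec, gen_titration
from ionshell.binding_titration import fit_global

spec = TitrationSpec(
    true_KD=5e-6,                                   # 5 uM
    ligand_concentrations=np.concatenate([[0.0], np.geomspace(5e-7, 9e-5, 11)]),
    wavelengths=np.linspace(360, 450, 50),
    amplitudes=np.linspace(-0.08, 0.07, 50),        # Soret loss/gain across the band
    noise_sigma=0.002,
    seed=7,
)
fit = fit_global(gen_titration(spec), T=298.0)
print(f"KD    = {fit.KD*1e6:.2f} +/- {fit.KD_se*1e6:.2f} uM")
print(f"dG    = {fit.delta_g:.2f} +/- {fit.delta_g_se:.2f} kcal/mol")
print(f"RSS   = {fit.rss:.5f} AU^2 over {fit.n_obs} points")
```

prints

```
KD    = 4.93 +/- 0.11 uM
dG    = -7.24 +/- 0.01 kcal/mol
RSS   = 0.00171 AU^2 over 600 points
```

i.e. a 50-wavelength titration with 0.002 AU noise recovers the 5 µM
dissociation constant within its standard error, and the corresponding
binding free energy of −7.24 kcal/mol.

## Command line

```sh
ionshell pca --top sys.gro --traj low.xtc --traj high.xtc --sel "name CA" --modes 2
ionshell shell-density --top sys.gro --traj sys.xtc --delta0 0.03 --nmin -40 --nmax 60 --ions NA,CL
ionshell distance --top sys.gro --traj sys.xtc --pair 85:185 --rule ca
ionshell tethers --open open.pdb --closed closed.pdb --cutoff 0.5
ionshell titration-fit --csv titration.csv -T 298
ionshell run --config workflow.yaml      # full manifest-tracked workflows
```

## Documentation

See `docs/methods.md` for the modelling assumptions, parameter defaults,
what the synthetic generators do and do not emulate, and known limitations.
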