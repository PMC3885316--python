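# hyperpol

Analysis toolkit for static and dynamic first-order hyperpolarizabilities
(β) of molecules in gas and solution: finite-field response extraction,
tensor invariants, double-harmonic vibrational β, hyperpolarizability-density
grid analysis, IR/Raman spectral simulation, and dispersion / solvent-ratio
bookkeeping. All internal computation is in Hartree atomic units; conversion
to practical units (Debye, cm⁻¹, km/mol, Å⁴/amu, SI) happens only at the
I/O edges through a central unit registry derived from CODATA constants.

## Modules

| Module | What it does |
| --- | --- |
| `hyperpol.tensors` | `Dipole`/`Alpha`/`Beta`/`Gamma` types, the contracted β components and the `beta_vec` invariant, unit conversions |
| `hyperpol.finite_field` | Field stencils, dipole-vs-field samples, central-difference extraction of μ₀/α/β/γ with Romberg (Richardson) refinement |
| `hyperpol.density` | ρ⁽²⁾ hyperpolarizability densities from field-tagged grids, β moments, isosurface mask export |
| `hyperpol.vibrational` | Double-harmonic [μα] bracket, EOPE/SHG infinite-frequency limits, per-mode contributions, IR intensities and Raman activities |
| `hyperpol.spectra` | Area-normalized Lorentzian broadening, dispersion series, percent-dispersion / solvent-ratio / crossing queries |
| `hyperpol.synthetic` | Seeded model molecules with closed-form responses (the test oracles), Gaussian-blob density grids, packaged reference tables |
| `hyperpol.io`, `hyperpol.cli` | Gaussian cube, TSV and JSON interchange; the `hyperpol` command |

## CLI

```sh
hyperpol synth --seed 5 --outdir work/        # reproducible synthetic inputs
hyperpol ffit --samples work/dipole_samples.tsv --out ffit.json
hyperpol vib --modes work/modes.tsv --process EOPE --out vib.json
hyperpol density --cube work/density_0.cube --cube work/density_1.cube \
    --cube work/density_2.cube --j x --k x --out density.json
hyperpol spectra --modes work/modes.tsv --fwhm 10 --out spectra.tsv
hyperpol disperse --process EOPE --out dispersion.json
hyperpol betavec --tensors tensors.json --out report.json
hyperpol repro                                # re-derive the golden values
```

Exit codes: 0 success, 1 golden-check failure (`repro`), 2 usage error,
3 I/O error, 4 validation error.

## Conventions worth knowing

- `beta[i, j, k]` is the pure derivative ∂²μᵢ/∂Fⱼ∂Fₖ at zero field (Taylor
  convention: the 1/2! of the dipole expansion cancels the derivative
  factor). Kleinman symmetrization is the default for table-built tensors;
  finite-field output keeps the raw jk-symmetric tensor.
- The density-route prefactor is fixed by route equivalence with the dipole
  expansion (c = 1 for a derivative-defined ρ⁽²⁾); a `"paper-literal"`
  flag (c = ½) is available for comparison with the conventional −1/2!
  notation.
- Normal-mode derivatives are stored per mass-weighted atomic-unit
  coordinate (electron-mass weighting); the km/mol and Å⁴/amu conversion
  chains are derived from fundamental constants, not hard-coded.
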