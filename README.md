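# lvcdyn

Surface-hopping nonadiabatic dynamics on analytical linear vibronic coupling
(LVC) potentials with spin-orbit coupling: from Wigner-sampled initial
conditions through trajectory propagation to population, charge-transfer,
kinetic, and coherence analyses. A synthetic model generator emulates a
Re-complex/tryptophan-like excited-state manifold (low-lying charge-separated
states with weak SOC, higher metal-to-ligand charge-transfer states with
strong SOC), and a packaged vertical-excitation table serves as an in-repo
fixture.

## What it does

* **`lvcdyn.core`** — the LVC Hamiltonian `V = V0 1 + W` over dimensionless
  mass-frequency-scaled normal coordinates; diabatic → MCH (spin-free
  adiabatic) → diagonal (SOC-including) transforms; analytic gradients and
  nonadiabatic couplings; Löwdin-orthonormalized time overlaps; model
  truncation (frequency cutoff, state removal, ground-state SOC zeroing).
* **`lvcdyn.factory`** — synthetic manifold generation from a `ManifoldSpec`;
  the packaged vertical-excitation fixture; κ/λ parametrization from gradient
  and wave-function-overlap oracles (finite-difference diabatization); exact
  quantum oracles (frozen-nuclei matrix exponential and a split-operator
  wavepacket propagator for ≤ 3 states / ≤ 2 modes).
* **`lvcdyn.initcond`** — ground-state Wigner sampling; vertical excitations
  with oscillator strengths and CT fractions; Gaussian-convolved absorption
  spectra with exact CT-bin decomposition; stochastic initial-state selection
  in an energy window (2.8–3.2 eV by default).
* **`lvcdyn.dynamics`** — fewest-switches surface hopping in the diagonal
  representation: velocity-Verlet nuclear steps (0.5 fs), local-diabatization
  electronic substeps (0.02 fs), stochastic hops with full-velocity
  rescaling, energy-based decoherence, per-trajectory RNG streams, energy
  audits.
* **`lvcdyn.analysis`** — populations in three representations × three
  estimators; CT-number evolution `Ω_AB(t)` including transition CT terms;
  hot/cold biexponential kinetic fits with trajectory bootstrap; state
  character classification (CS/MLCT/LLCT/IL/AMCS/AC/MC); per-mode coherence
  descriptors (shiftEX, cohEX, Δσ) with important-mode flags.
* **`lvcdyn.io`** — a diff-friendly text format for models and CT tables
  (lossless at 17 significant digits), HDF5/JSON ensemble archives (full or
  compact "analysis" mode), YAML run configuration, and the CLI.

## CLI

```bash
lvcdyn generate-model --preset azurin-like --seed 1 --out model.lvc --ct-out ct.txt
lvcdyn sample    --model model.lvc -n 1000 --seed 2 --out samples.tsv
lvcdyn spectrum  --model model.lvc --ct ct.txt --samples samples.tsv --out spectrum.tsv
lvcdyn select    --model model.lvc --samples samples.tsv --window 2.8 3.2 --seed 3 --out sel.tsv
lvcdyn propagate --model model.lvc --samples samples.tsv --selections sel.tsv \
                 --t-final 1000 --seed 4 --out ensemble.h5
lvcdyn analyze populations --ensemble ensemble.h5 --out pops.tsv
lvcdyn analyze ct          --ensemble ensemble.h5 --ct ct.txt --out ct.tsv
lvcdyn analyze kinetics    --ensemble ensemble.h5 --out kinetics.json
lvcdyn analyze coherence   --ensemble ensemble.h5 --out coherence.tsv
```

Every command writes a `<out>.manifest.json` with arguments, seeds, package
version, and input checksums; reruns with identical inputs reproduce output
tables byte-for-byte.

## Conventions worth knowing

* Interfaces use eV, fs, Å, amu, cm⁻¹; `Q` is dimensionless with
  ground-state Wigner variance 1/2 per mode.
* The normal-mode matrix `K` has orthonormal columns (mass-weighted
  convention); the coordinate transform uses the `sqrt(ω/ħ)` prefactor so
  that `V0 = Σ ħω Q²/2`.
* Spin expansion orders singlets first, then triplets grouped by M_S block;
  SOC is supplied as the full Hermitian matrix over that basis.
* The hopping basis is the diagonal (SOC-including) representation; initial
  states are selected in the MCH representation and mapped by maximum
  overlap.
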