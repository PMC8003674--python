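# vibrodyn

Linear vibronic coupling (LVC) models for coupled excited electronic
states: maximum-overlap diabatization of adiabatic scans, numerically
exact quantum wavepacket propagation in a truncated harmonic-oscillator
product basis, vibronic absorption spectra from damped autocorrelation
Fourier transforms, and diabatic population analysis.

## What it does

- **`vibrodyn.lvc`** — the LVC Hamiltonian data model: ground-state normal
  modes (dimensionless coordinates, frequencies in eV), vertical energies,
  state-diagonal gradients, linear inter-state couplings and Condon
  transition dipoles. Evaluates diabatic/adiabatic potentials at arbitrary
  coordinates, provides analytic lineshape moments, a versioned JSON
  schema with bit-exact round trip, and a best-effort plain-text operator
  export.
- **`vibrodyn.diabatization`** — orthogonal-Procrustes (maximum-overlap)
  diabatization: builds the orthogonal transformation closest to a
  wavefunction-overlap matrix, rotates adiabatic energies into the
  diabatic representation, and extracts all λ parameters by central
  differences over ±Δ displaced geometries. Fails loudly on rank-deficient
  overlaps, naming the offending mode/sign.
- **`vibrodyn.propagation`** — sparse Hamiltonian assembly and adaptive
  short-iterative Lanczos propagation; returns autocorrelation,
  per-state populations, norm and energy traces. Includes the closed-form
  displaced-oscillator (vertical-gradient) autocorrelation, used both as a
  feature and as an oracle, and coupling-weight-based mode reduction.
- **`vibrodyn.spectroscopy`** — absorption spectra from autocorrelations
  with quadratic time-domain damping (Gaussian frequency broadening, the
  HWHM↔Γ mapping is `Γ = hwhm²/(4 ln 2)`), |μ|²-weighted sums over doorway
  states, optional cross-correlation terms, broadened stick spectra, and
  shift/weight/normalize/combine utilities. Absolute units (M⁻¹cm⁻¹) for
  dipoles in a.u., or relative units.
- **`vibrodyn.populations`** — mono-exponential decay fits (free baseline,
  multi-start), half-transfer times, and a tabular per-state report.
- **`vibrodyn.fixtures`** — seeded synthetic models, mock adiabatic scans
  generated by diagonalizing a known model (exact round-trip oracle for
  the diabatization), and two bundled presets: a two-state/two-mode
  conical-intersection benchmark and a six-state/six-mode bright/dark
  layout.

Units: energies in eV, time in fs, ħ = 0.6582119569 eV·fs, dipoles in
atomic units.

## CLI

A single `vibrodyn` entry point with subcommands:

```sh
# synthetic model and mock scan, then recover the model by diabatization
vibrodyn synth model --preset nucleobase-like --seed 7 --out model.json
vibrodyn synth scan --model model.json --delta 0.05 --out scan.json
vibrodyn diabatize --scan scan.json --out recovered.json

# propagate a doorway wavepacket, store HDF5 + populations TSV
vibrodyn propagate --model model.json --state bright1 --tfinal 250 \
    --dt 0.1 --nmax 4 --out result.h5 --tsv populations.tsv
vibrodyn populations --input result.h5 --fit state:bright1

# vibronic spectrum (couplings on/off), pure-electronic sticks, combine
vibrodyn spectrum --model model.json --state bright1 --hwhm 0.04 \
    --tfinal 100 --couplings on --out spec.tsv
vibrodyn stick-spectrum --table sticks.tsv --hwhm 0.25 --out stick.tsv
vibrodyn combine --inputs a.tsv,b.tsv --weights 0.5,0.5 \
    --shifts -0.3,-0.3 --out combined.tsv
```

Spectra are written as two-column TSV with a JSON metadata sidecar; scan
files come in JSON and a documented plain-text variant (`.txt`).

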