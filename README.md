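# thiokin

Kinetic analysis of disulfide UV photolysis probed by time-resolved
X-ray absorption at the sulfur K-edge.

When an aliphatic disulfide such as L-cystine absorbs a ~267 nm photon in
aqueous solution, the S–S bond cleaves homolytically into a pair of
geminate thiyl radicals (RS•). Held together by the solvent cage, most
pairs recombine within picoseconds into a vibrationally hot parent, which
either cools back to the ground state or sheds the excess energy by
breaking a C–S bond, producing a perthiyl radical (RSS•). Femtosecond
sulfur K-edge spectroscopy watches all of this at once: an induced
absorption for the thiyl radical (2466.8 eV), one for the perthiyl
radical (2468.2 eV) and the ground-state bleach (2472.0 eV).

`thiokin` turns that experiment into a reusable analysis pipeline:

- **`thiokin.kinetics`** — the branching sequential rate-equation model
  solved in closed form. The excited parent N₁ decays with τ₁ into three
  thiyl sub-ensembles N₂ᵢ (yields q₂ᵢ, time constants τ₂ᵢ, the third
  non-decaying); recombination feeds the vibrationally excited parent
  N₃ⱼ, which relaxes to the ground state N₀ (q₃₁, τ₃₁) or fragments into
  perthiyl N₄ⱼ (q₃₂, τ₃₂); perthiyl partially recombines (q₄₁, τ₄₁).
  Every sub-chain is a Bateman cascade, so populations are sums of
  exponentials; with a Gaussian instrument response of width σ_IRF each
  exponential becomes an exponentially modified Gaussian, making the IRF
  convolution exact. A stiff ODE integrator twin (`ode_oracle`) verifies
  the analytic solver.
- **`thiokin.observables`** — populations → ΔA channels, including the
  8 % spectral admixture of the thiyl line in the perthiyl channel and
  the bleach convention ΔA = −A₀·(1 − N₀).
- **`thiokin.fitting`** — global weighted least squares: shared kinetics
  + IRF across all channels, free per-channel amplitudes, simplex-safe
  yield parameterization, covariance and bootstrap uncertainties, and a
  seeded parameter-recovery simulation study.
- **`thiokin.simulate`** — synthetic experiments (linear-then-log delay
  grid, per-point or shot-level noise, optional drift) so the whole
  pipeline is testable without the measured data.
- **`thiokin.spectra`** — sulfur K-edge lineshape assembly (pseudo-Voigt
  lines + edge jump) and decomposition of differential spectra.
- **`thiokin.cli` / `thiokin.io`** — `thiokin simulate|fit|recover|
  spectra|irf|report`, strict YAML configs, diff-friendly CSV traces.

## Worked example

```python
import numpy as np
from thiokin import (fixture_table1, default_design, generate_traces,
                     global_fit, solve_populations, recombined_fraction,
                     asymptotic_recovery, quadrature_irf_width)

# instrument response from its quadrature budget (ps)
quadrature_irf_width([0.020, 0.045, 0.065, 0.030])   # 0.08689 -> 87 fs

# population dynamics at the published parameter set
params, irf = fixture_table1()
traj = solve_populations(params, np.array([0.3, 20.0, 1000.0]))
traj.N2        # [0.6556, 0.1457, 0.14]   thiyl population
traj.N0        # [0.0259, 0.5713, 0.6874] recovered ground state
recombined_fraction(params, 20.0)   # 0.8543 -> >80 % recombined in 20 ps
asymptotic_recovery(params)         # 0.6904 -> ~70 % recovered at 1 ns

# synthetic three-channel experiment and global fit
traces = generate_traces(params, irf, default_design(seed=42))
fit = global_fit(traces)
fit.success, fit.redchi             # (True, 0.908)
fit.values()["tau1"]                # 0.1171  (truth 0.14, stderr 0.022)
fit.values()["q21"]                 # 0.6737  (truth 0.67)
```

The numbers mean: at 0.3 ps roughly two thirds of the excitation sits in
the thiyl state; by 20 ps 85 % of the thiyl radicals formed have
recombined; by 1 ns 69 % of the dissociated molecules are back in the
ground state. The single-seed fit recovers the generating parameters
within its quoted standard errors; the weakly constrained perthiyl pair
(τ₄₁, q₄₁) shows the expected large uncertainty from a 0.8 ns window.

The same pipeline from the shell:

```sh
echo "seed: 42" > run.yaml
thiokin simulate --config run.yaml --out-dir traces
thiokin fit --config run.yaml --traces traces/trace_2466.8eV.csv \
    --traces traces/trace_2468.2eV.csv --traces traces/trace_2472.0eV.csv \
    --out fit_report.json
thiokin report --fit-report fit_report.json
```

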