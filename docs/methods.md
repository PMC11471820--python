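# Methods

## The kinetic model

The reaction scheme is a branching sequential compartment model for the
photolysis of an aliphatic disulfide in solution. One photon promotes a
parent molecule to a dissociative state; populations are expressed per
unit initial excitation, N₁(0) = 1, everything else 0.

```
N1 --(k1)--> N2i --(k2i)--> N3j --(k31)--> N0          (j = 1, relaxation)
                            N3j --(k32)--> N4j' --(k4j')--> N0   (j = 2)
```

- N₁ — optically excited parent; decays with k₁ = 1/τ₁ into thiyl pairs.
- N₂ — thiyl radicals, split into three sub-ensembles i = 1..3 with
  yields q₂₁ + q₂₂ + q₂₃ = 1. Two recombine (τ₂₁ sub-ps, τ₂₂ a few ps);
  the third represents cage-escaped pairs and does not decay within the
  sub-ns observation window. It is modelled with an exact rate of zero
  (`tau = math.inf` sentinel) rather than a large time constant: the data
  only bound those lifetimes from below (≳10 ns), and a frozen state is
  the cleanest expression of that. The same applies to the persistent
  perthiyl fraction q₄₂ = 1 − q₄₁.
- N₃ — vibrationally excited recombined parent. Every thiyl sub-ensemble
  feeds both N₃ branches with the same yields (q₃₁ relaxation, q₃₂ = 1 −
  q₃₁ C–S fragmentation); the model has no sub-ensemble-dependent hot-
  parent branching, since nothing in the three observed channels could
  distinguish one.
- N₄ — perthiyl radicals; fraction q₄₁ recombines with τ₄₁, the rest
  persists.
- N₀ — recovered cold ground state (absorbing sink).

Because each sub-chain N₁ → N₂ᵢ → N₃ⱼ (→ N₄ⱼ′) → N₀ is linear, its
populations are Bateman solutions: sums of exponentials with partial-
fraction amplitudes. Aggregation applies the branching yields, which
makes total population exactly conserved, N₁+N₂+N₃+N₄+N₀ = 1 at all t ≥ 0.

Useful closed forms exposed by the package:

- `recombined_fraction(params, t)` = (1 − N₁ − N₂)/(1 − N₁): the share of
  thiyl radicals formed by time t that have already recombined (0/0 at
  t = 0 defined as 0; for t beyond a few τ₁ this approaches 1 − N₂(t)).
- `asymptotic_recovery(params)` = (q₂₁+q₂₂)·(q₃₁ + q₃₂·q₄₁): the t → ∞
  ground-state recovery, the product of "thiyl that ever recombines" and
  "hot parent that ever reaches the cold ground state".

## Instrument response

The IRF is a single shared Gaussian (standard deviation σ_IRF, offset
t₀) for all channels; its width budget is the quadrature sum of pulse
durations, group-velocity mismatch and timing jitter
(`quadrature_irf_width`). The model trace is the exact convolution of
the IRF-free solution with that Gaussian: each term c·tᵐ·e^(−kt)·H(t)
maps onto a closed-form profile — the m = 0 case is the exponentially
modified Gaussian
½·exp(σ²k²/2 − k(t−t₀))·erfc((σk − (t−t₀)/σ)/√2), and higher m follow
the derivative recurrence E_{m+1} = (u − σ²k)·E_m + m·σ²·E_{m−1} with
E₁ = (u − σ²k)·E₀ + σ²·g(u). Where the plain erfc expression would lose
precision (σk large relative to u/σ) the scaled complementary error
function (erfcx) form is used, so the profile is stable for arbitrary
σ/τ ratios.

## Numerical choices

- **Term algebra.** Populations are represented symbolically as sums of
  c·tᵐ·e^(−kt) terms; convolution with the next exponential stage,
  integration into the sink and Gaussian convolution are all closed
  under this representation. This keeps every evaluation exact up to
  floating point — no time stepping.
- **Degenerate rates.** When two cascade rates agree to better than
  1e−9 relative, partial-fraction amplitudes diverge; the solver then
  switches to the analytic confluent limit (tᵐ⁺¹/(m+1)·e^(−kt)), which
  is the exact solution at equality and keeps outputs continuous as
  rates cross.
- **ODE twin.** `ode_oracle` integrates the full 25-state sub-ensemble
  system with LSODA at rtol 1e−11/atol 1e−13. It exists to verify the
  analytic solver (the test suite demands agreement <1e−6 over random
  schemes with time constants spanning 0.05–500 ps) and is not used in
  fitting.
- **Optimizer.** Trust-region-reflective least squares (SciPy via
  lmfit), finite-difference Jacobian, ftol 1e−10 / xtol 1e−8. Standard
  errors are Jacobian-covariance based, scaled by the reduced
  chi-square; a residual-resampling bootstrap
  (`bootstrap_uncertainties`) is the cross-check. An optional seeded
  multi-start (`FitSpec.multistart`) guards against local minima in the
  near-degenerate 0.41/0.45/0.63 ps time-constant cluster.
- **Simplex constraint.** The thiyl yields are fitted as q₂₁ ∈ (0,1)
  and the conditional fraction f₂₂ = q₂₂/(1−q₂₁) ∈ (0,1) — a
  stick-breaking parameterization expressed through box bounds rather
  than unconstrained logits. The feasible set is identical; box-bounded
  fractions compose better with the trust-region-reflective bounds and
  keep the printed parameters one algebraic step from the fitted ones.
- **Bounds and starts.** Default bounds put each time constant in the
  decade(s) its signal component occupies (τ₁ ∈ [0.02, 1] ps, τ₂₁ ∈
  [0.05, 2], τ₂₂ ∈ [1, 50], τ₃ ∈ [0.05, 5], τ₄₁ ∈ [20, 2000] ps;
  σ_IRF ∈ [0.02, 0.3] ps; t₀ ∈ ±0.5 ps). Starting values are the
  geometric (scale parameters) or arithmetic (fractions, t₀) midpoints
  of the bounds; amplitudes start at each trace's peak |ΔA|.

## Observable model

The thiyl channel is A₂·N₂, the perthiyl channel A₄·N₄ plus 8 % of the
*predicted* thiyl channel (spectral overlap of the two lines — a fixed
constant by default, optionally fitted), and the bleach −A₀·(1 − N₀),
i.e. every species that is not cold parent depletes the parent
absorption equally. The alternative convention, in which the
vibrationally hot parent already absorbs like cold parent and does not
bleach, is available (`default_channels(hot_parent_absorbs=True)`); it
matters only during the few ps that N₃ carries population. N₁ and N₃
contribute to no product channel. Amplitudes are free per channel
because the experiment prints edge-normalized, not absolute, cross
sections.

## Synthetic data

`ExperimentDesign` emulates the structure of the measured delay scans:
three channels at 2466.8 / 2468.2 / 2472.0 eV, a delay grid linear from
−1 to 5 ps in 50 fs steps and logarithmic from 5 to 800 ps (30 points;
151 points per channel), Gaussian per-point noise, and optionally a
shot-level mode in which n shots per delay are averaged and their sample
standard deviation becomes the reported error bar. A seeded random-walk
drift term can emulate slow variations of experimental conditions (off
by default). Seeds are mandatory for any stochastic output.

The default noise level, per-point σ = 8e−4 with channel amplitudes
0.020 / 0.010 / 0.025 (all parent-edge-normalized), gives a peak thiyl
signal-to-noise around 15, comparable to the visual quality of the
published scans; the experiment's actual per-point uncertainties live
only in its source-data file, so this default is a documented config
constant, not a measured value.

What the generator does **not** emulate: correlated (non-white) noise
beyond the optional random walk, delay-dependent error bars, probe-
energy drift, multi-photon contributions, and any spectral congestion
beyond the single 8 % overlap scalar. Passing recovery tests therefore
demonstrate identifiability of the scheme under clean Gaussian noise on
this grid — not robustness to every systematic a beamline can produce.

## Recovery study and problem sizes

`parameter_recovery_study` runs generate → fit over many deterministic
seeds and reports per-parameter median, mean, bias, RMSE and optional
interval coverage. The shipped study (also behind
`scripts/acceptance.py`) uses 50 replicates of 3 × 151 points — enough
for stable medians while a full study remains a one-minute,
single-CPU run. The weakly identified perthiyl pair (τ₄₁, q₄₁) shows
large single-replicate scatter, consistent with its large printed
uncertainty (±165 ps): the 0.8 ns window barely bounds a 268 ps decay
whose amplitude trades off against its yield.

## Spectra

Lines are area-normalized pseudo-Voigt profiles (Thompson–Cox–Hastings
mixing; exact Voigt behind `exact_voigt=True`): core-excited sulfur 1s
lines are naturally Lorentzian, inhomogeneous (conformer) broadening
adds a Gaussian component, and the ionization continuum is an
error-function edge jump. The default Lorentzian FWHM used in examples
(0.6 eV) is a config value: the experiment only states that its
resolution is well below the natural sulfur 1s linewidth. Two explicit
energy shifts are model fields — a theory-to-experiment calibration
(e.g. +52.09 eV for computed transition energies) and an energy-axis
recalibration (e.g. +0.3 eV). Decomposition of a differential spectrum
solves the (linear) amplitude problem by weighted least squares with
condition-number diagnostics — near-collinear templates are flagged,
not silently inverted — and can refine widths/centers nonlinearly. The
lineshape-analysis protocol used for the original experiment is not
published in enough detail to replicate exactly; this module is a
generic implementation of that kind of decomposition.

## Known limitations

- Area "conservation" of Lorentzian-dominated lines on a finite energy
  window is limited by the 1/x tails (≈0.6 % lost per ±60 eV window for
  a 0.6 eV FWHM line); the Gaussian limit meets 1e−4.
- The ± values printed for the original experiment were reproduced here
  as covariance-based errors; the original error convention is not
  stated, so coverage statements compare spreads, not methods.
- The model window ends where the data do: nothing distinguishes a
  truly frozen sub-ensemble from one decaying with τ ≫ 1 ns.
- No model selection: the scheme topology is fixed; alternative
  topologies (e.g. direct perthiyl formation) are out of scope.
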