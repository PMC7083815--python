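# crnoise

**Coloured extrinsic noise in mass-action reaction–diffusion systems.**

Biological patterning models are usually driven by white noise, because
intrinsic (copy-number) fluctuations are uncorrelated in time. When the
noise is *extrinsic* — a fluctuating inflow of material produced by an
auxiliary network, or an imperfect experimental feed — its temporal
correlations are unconstrained, and the forcing acquires a *colour*.
`crnoise` is a toolkit for studying what that colour does to
spatio-temporal patterns, aimed at modellers of reaction–diffusion
systems and chemical reaction networks. It provides:

1. **Monostationarity certification.** Before adding parameter noise one
   must rule out stochastic switching between coexisting steady states.
   The sign-vector injectivity test decides, from the network structure
   alone (no rate values), whether the mass-action kinetics
   `f(x) = m1 diag(k) x^{m2}` admit at most one positive equilibrium for
   *every* positive rate vector:
   `ker(m2) = {0}` and `σ(ker m1) ∩ σ(im m2) = {0}`,
   decided exactly by sign-pattern enumeration with LP feasibility.
2. **Analytic power spectra.** The system is linearised about its unique
   steady state, compartmentalised on a 1-D Neumann domain, and
   decomposed into cosine modes with matrices
   `A_κ = J + (2D/Δs²)(cos κΔs − 1)`. For forcing with spectral matrix
   `N(ω)` the predicted spectrum per mode is
   `P(κ,ω) = diag(Φ⁻¹ N Φ⁻†)`, `Φ = −[A_κ + iω]`. When every species
   shares one correlation function the colour simply multiplies the white
   spectrum: `P_coloured = P_white · P_corr(ω)`.
3. **Noise colours.** White, Ornstein–Uhlenbeck (`1/(1+ω²τ²)`), power-law
   (`1/ω^α`, red through violet, Timmer–König frequency synthesis),
   predator–prey quasi-cycle input spectra, per-species mixed colours,
   reduced (single-species) inflows, and inflow-positivity truncation.
4. **Stochastic simulation.** Stabilised explicit Euler–Maruyama for the
   linearised and the full nonlinear compartment system, with
   counter-based per-repetition seeding, plus periodogram estimation
   (cosine modes × temporal FFT, averaged over repetitions) and
   analytic-vs-empirical comparison reports.

See `docs/methods.md` for the model, conventions and numerical choices.

## Worked example

The reference system is the Schnakenberg (activator–depleted substrate)
scheme `∅→X1, X1→∅, ∅→X2, 2X1+X2→3X1` with k1 = k2 = 10, k3 = 0.01,
k−1 = 20, D = (1e−4, 1e−2) on L = 0.1 with K = 40 compartments:

```python
import numpy as np
import crnoise as cn
from crnoise.noise import NoiseModel, noise_spectrum_N

preset = cn.schnakenberg_preset()

report = cn.check_injectivity(preset.network)
print("injective:", report.injective)

xstar = cn.schnakenberg_steady_state(preset.params)
print("steady state:", xstar)
J = cn.jacobian(preset.network, preset.params, xstar)
lam = np.linalg.eigvals(cn.mode_matrix(J, preset.diffusion, preset.grid, 0))
print("mode-0 eigenvalues:", np.round(lam, 4))

tau = 100.0
om = cn.omega_grid(200.0, 0.01)
white = NoiseModel(covariance=np.ones((2, 2)), variant="white")
ou = NoiseModel(covariance=np.ones((2, 2)), variant="ou", tau=tau)
Pw = cn.analytic_spectrum(J, preset.diffusion, preset.grid,
                          lambda w: noise_spectrum_N(white, w), om)
Po = cn.analytic_spectrum(J, preset.diffusion, preset.grid,
                          lambda w: noise_spectrum_N(ou, w), om)
pk = np.argmax(Pw.power[0, 0])
print(f"white-noise m=0 peak: omega = {om[pk]:.3f}, power = {Pw.power[0,0,pk]:.1f}")
print(f"OU suppression at the peak: {Po.power[0,0,pk]/Pw.power[0,0,pk]:.2e}")
share_w = Pw.power[0, 1, 1:].sum() / Pw.power[0, :, 1:].sum()
share_o = Po.power[0, 1, 1:].sum() / Po.power[0, :, 1:].sum()
print(f"m=1 share of x1 power: white {share_w:.3f} -> OU {share_o:.3f}")
```

prints

```
injective: True
steady state: [   1. 1000.]
mode-0 eigenvalues: [-0.005+0.4472j -0.005-0.4472j]
white-noise m=0 peak: omega = 0.440, power = 3110.3
OU suppression at the peak: 5.17e-04
m=1 share of x1 power: white 0.082 -> OU 0.720
```

Reading the output: the network is monostationary for all positive rates,
so inflow fluctuations cannot trigger stochastic switching. The
homogeneous mode is a slowly damped spiral (decay 0.005, angular
frequency 0.447), so white noise sustains a sharp temporal oscillation
peak at m = 0, ω ≈ 0.45. Ornstein–Uhlenbeck colouring with τ = 100
suppresses that resonance by ≈ 2000×, and the m = 1 spatial mode's share
of the activator's power rises from 8% to 72% — temporally correlated
noise stabilises a spatial pattern that white noise leaves buried in
oscillations.

Simulation experiments are driven by a YAML config and the CLI:

```bash
crnoise check-injectivity network.json
crnoise run --config experiment.yaml --outdir runs/ou --colour ou --tau 100 --seed 7
```

writing spectra as CSV, comparison metrics and metadata as JSON, with
byte-identical reruns at a fixed seed.

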