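# Methods

`crnoise` studies how *extrinsic* coloured noise — stochastic drift in the
inflow rate constants of a mass-action reaction–diffusion system — shapes
spatio-temporal patterns. This note records the model, the numerical
choices, and what the synthetic experiments do and do not establish.

## Model

A network of n species with M mass-action reactions on a 1-D domain
[0, L] with homogeneous Neumann boundaries obeys

    dx/dt = D d²x/ds² + f(x),     f(x) = m1 diag(k) x^{m2},

where `m1` (n×M) holds the reaction vectors β−α as columns and `m2` (M×n)
the reactant stoichiometries α as rows. Inflow reactions ∅ → X_i model
production by processes outside the system (an auxiliary network, an
experimental feed); their rate constants are promoted to stochastic
processes K(t) = k + Ω^(−1/2) η(t), where Ω is the *subsystem size* (noise
strength): the larger the external subsystem, the weaker its fluctuations.
η is a zero-mean Gaussian process, truncated so the physical inflow stays
non-negative; the truncation is assumed (and verified) to be negligible at
the parameter scales studied.

### Monostationarity certificate

Stochastic parameters must not open the door to stochastic switching
between coexisting steady states, so admissible networks are required to
be *injective*: `f` has at most one positive root for every positive rate
vector. The structural test is

    ker(m2) = {0}   and   σ(ker m1) ∩ σ(im m2) = {0},

where σ maps vectors to sign patterns in {−,0,+}. The implementation
enumerates all 3^M sign patterns up to global sign (both sets are
subspaces, hence symmetric under negation) and decides membership in each
sign-vector set by an LP feasibility problem: strict sign constraints
relax exactly to v_i ≥ 1 / v_i ≤ −1 because sign sets of subspaces are
cones. This is exact and parameter-free but exponential in M; a budget
guard (default 60 000 patterns, i.e. M ≤ 10) keeps it desk-scale. When the
intersection is non-trivial the report carries a verified witness pair.
Zero tolerance for floating sign decisions is 1e−9; integer input is
signed exactly.

### Linearisation and compartments

Writing x = x* + Ω^(−1/2) δx and keeping leading order gives the additive
linear SPDE for the scaled perturbation δx (the Ω^(−1/2) scaling is the
dominant-balance choice: stochastic forcing and linear response enter at
the same order; non-inflow rate noise linearises to the same additive
form). Space is discretised into K compartments of width Δs = L/K.
The compartmental operator, species-major, is

    A = D/Δs² · (discrete Neumann Laplacian) + J ⊗ I_K,

with J the kinetics Jacobian at x*. The Laplacian uses ghost-point
(reflecting) boundary rows — boundary diagonal −D/Δs² instead of the
interior −2D/Δs² — because that stencil is *exactly* diagonalised by the
half-sample cosine modes cos(κ_m Δs (j−1/2)), κ_m = mπ/L, giving the
per-mode matrices

    A_κ = J + (2D/Δs²)(cos κ_m Δs − 1),

and making the spatial transform, the operator and the spectra mutually
consistent to machine precision. A constant-diagonal stencil, or cosine
nodes at (j−1), would each introduce O(1/K) inconsistencies between the
operator and the mode decomposition; the (j−1) node variant is available
behind `convention="literal"` for comparison.

### Analytic spectra

For stationary forcing with Hermitian spectral matrix N(ω), each mode has

    P(κ, ω) = real diag( Φ⁻¹ N(ω) Φ⁻† ),   Φ = −[A_κ + iω].

Validity requires every A_κ Hurwitz-stable (outside the Turing-unstable
regime); the pipeline refuses otherwise (threshold −1e−12 on the largest
real part). When all species share one correlation function, N(ω) =
B · P_corr(ω) and the coloured spectrum is the white spectrum times the
scalar colour factor — the package's central factorisation identity,
asserted to machine precision in the tests.

Implemented colours (P_corr): white 1; Ornstein–Uhlenbeck 1/(1+ω²τ²);
power-law 1/|ω|^α (red α=2 … violet α=−2; singular at ω=0 for α>0, the
zero bin is excluded); auxiliary quasi-cycle (α_pp+β_pp ω²)/((ω²−Ω0²)²+Γ²ω²);
mixed per-species OU times τ_i with N = diag(H) B diag(H)†,
H_i = 1/(1+iωτ_i) and τ_i = 0 meaning white. The quasi-cycle denominator
uses the squared resonant form, which has the interior peak a stochastic
predator–prey subnetwork exhibits; the monotone variant
(ω²+Ω0²)+Γ²ω² is available via `squared_denominator=False`. With the
reference coefficients (α_pp=0.000384, β_pp=Γ=0.04, Ω0²=0.016) the
resonant form peaks near ω ≈ 0.13; no sharper claim about the peak
location is asserted. A per-species mask ("reduced inflows") zeroes rows
and columns of N for species with deterministic inflow only.

Spatial structure of the noise: compartments are statistically
independent, with species covariance B within each compartment. Under the
orthonormal cosine basis this maps to mode noise with the *same*
covariance B at every mode, which is the convention the analytic spectra
assume. The default covariance is the fully correlated rank-one B = ones,
which maximises the visibility of colour effects.

## Samplers

* White: η = b z/√dt per noise step, b the symmetric PSD square root of B
  (negative eigenvalues within −1e−12 clipped), so η·dt is the Itô
  increment b z √dt.
* OU/mixed: Euler–Maruyama on dη = −η/τ dt + (b dW)/τ from the stationary
  law (variance B/(2τ)); autocorrelation e^(−Δ/τ), spectrum Lorentzian.
* Power-law and quasi-cycle: frequency-domain synthesis — independent
  complex Gaussian amplitudes with E|X_q|² = N·S(ω_q)/dt, Hermitian
  symmetry via the inverse real FFT, zero-frequency bin pinned to 0
  (zero-mean noise; the α>0 pole never enters). α = 0 reproduces white
  statistics exactly up to the enforced zero record mean, which fixes the
  normalisation with no free constant.
* Truncation: η_i ← max(η_i, −k_i √Ω) with k_i the species' deterministic
  inflow rate, i.e. non-negativity of the physical inflow, applied on the
  noise grid (see below). The clamped fraction is reported; at the
  reference scales it is 0 for white/OU/red noise.

## Time discretisation

Integration is explicit Euler–Maruyama. Two time scales are separated
deliberately:

* the **noise step** dt (default 0.01): noise is sampled, truncated and
  the state recorded on this grid;
* **sub-steps**: within each noise step the deterministic drift is
  advanced `substeps` times with η held constant. The diffusion block is
  stiff — on the reference grid D₂/Δs² = 1600 gives eigenvalues down to
  ≈ −6.4·10³, so a bare explicit step at dt = 0.01 diverges; sub-stepping
  (auto-chosen so dt_fine·max|Re λ| ≤ 1, i.e. half the explicit stability
  bound, and checked against the bound) stabilises it without inflating
  the noise bookkeeping. Holding η constant within 0.01 time units is
  spectrally neutral for every colour studied (content at ω ≪ 2π/dt);
  for strongly blue/violet noise the synthesised band is limited by the
  noise-step Nyquist, a known limitation.

Truncation on the noise grid (not the sub-step) keeps the clamp physical:
a white-noise sample over an interval Δ has scale 1/√Δ, so clamping at
ever finer sub-steps would clip *any* white noise as Δ→0, while on the
dt = 0.01 grid the reference threshold −k√Ω = −100 sits ten standard
deviations out.

Initial condition: white-noise runs start from the exact stationary
Gaussian law (factor of the algebraic Lyapunov covariance solving
AC + CAᵀ + B⊗I = 0), making records stationary from t = 0 — important
because the slowest mode of the reference system relaxes on 1/|Re λ| =
200 time units, longer than some horizons of interest. Coloured runs
start at rest and discard a burn-in: min(5τ, T/5) generally, the final
fifth of the record for red noise (whose quasi-frozen drift makes the
early record a deterministic transient). Where a linear and a nonlinear
run must share a noise path (weak-noise consistency), both start at rest.

Repetition seeding is counter-based: repetition r of run seed s always
receives stream `SeedSequence(s).spawn(...)[r]`, so batched and
one-at-a-time execution, and linear and nonlinear runs at the same seed,
are bit-identical in their noise.

The nonlinear integrator advances the full mass-action right-hand side
plus Ω^(−1/2) η with the same scheme; negative concentrations are counted
and reported, not clipped (they diagnose breakdown of the linear theory),
unless clipping is requested explicitly.

## Spectral estimation

Per repetition: orthonormal half-sample DCT over compartments per time
point, subtraction of the per-mode time mean (removes the deterministic
ω = 0 offset), temporal transform F(ω) = dt Σ x_t e^(−iωt) over a
half-open stationary window, periodogram |F|²/T_w, then averaging over
repetitions. Windows are half-open so a window of length T_w holds
exactly T_w/dt samples and its frequency grid 2πq/T_w coincides with the
analytic evaluation grid. No taper by default (Hann optional,
power-normalised). Under this convention the estimator is asymptotically
unbiased for the analytic P(κ,ω) with no adjustable constant; the tests
verify it against the closed-form scalar Lorentzian at ~4.6% median error
with 200 repetitions (the Monte-Carlo floor at that repetition count is
0.674/√200 ≈ 4.8%).

Finite windows still impose a resolution limit of Δω = 2π/T_w: a spectral
line narrower than a bin (the reference system's m = 0 resonance has
half-width |Re λ| = 0.005) is smeared by the window kernel, and pointwise
bin-by-bin comparison against the ideal analytic spectrum near such a
line is biased by up to a factor ≈ 2 at T_w = 200 regardless of how many
repetitions are averaged. This is a property of every windowed estimator,
not of the implementation; comparisons at that horizon should use
resolved bands or longer windows (the τ = 100 OU experiment uses
T = 1000, where the relevant structure is resolved).

`compare_spectra` reports the median and maximum relative error at the
top-q highest-power analytic grid points, a log-spectral distance over a
stated band, and per-mode peak offsets.

## Reference configuration

The two-species activator–depleted-substrate (Schnakenberg) scheme
∅→X1, X1→∅, ∅→X2, 2X1+X2→3X1 with k1 = k2 = 10, k3 = 0.01, k−1 = 20
passes the injectivity test for *all* positive rates; the closed-form
steady state is x* = ((k1+k2)/k−1, k2 k−1²/(k3(k1+k2)²)) = (1, 1000).
Diffusion D = (1e−4, 1e−2), L = 0.1, K = 40 (Δs = 0.0025). The Jacobian
at x* is [[0, 0.01], [−20, −0.01]]; its complex pair −0.005 ± 0.4472i
makes the homogeneous mode a slowly decaying spiral, so spectra peak at
m = 0, ω ≈ 0.45 under white noise, and OU colouring (τ = 100) suppresses
that temporal resonance by 1/(1+ω²τ²) ≈ 5·10⁻⁴, letting the m = 1
spatial mode carry a visibly larger share of the power — the
noise-stabilised pattern regime. The parameters sit outside the Turing
space; a variant inside it (k1 = 9, k2 = 11, k3 = 0.005, k−1 = 2,
D₂ = 0.02: mode 1 growth rate +0.047) is used to test that the pipeline
refuses unstable configurations.

## Problem sizes in the test suite

Stochastic checks run at deliberately chosen scales: 20 repetitions at
T = 200 for the white-noise study, 10 repetitions at T = 1000 for the OU
study, 10⁶ recorded steps for the Lyapunov covariance oracle (K = 4),
100 realisations for the synthesis-slope fits, 200 repetitions for the
estimator calibration, and 2 shared-seed repetitions at T = 150 for the
weak-noise consistency check (pathwise, so repetitions barely matter).
Scaled-down grids (K = 8) appear where only qualitative behaviour is at
stake; because per-compartment variance grows as the grid coarsens
(fewer modes share it), such runs use a larger Ω to stay in the same
fluctuation regime.

## What the synthetic experiments do not show

The generator emulates the study conditions: compartmentwise-independent
Gaussian inflow noise with the stated colours on a 1-D Neumann domain.
It does not emulate spatially correlated noise kernels B(s,s′),
multiplicative (non-inflow) noise beyond its additive linearisation,
intrinsic copy-number noise (no chemical master equation), domains in
more than one dimension, or dynamics inside the Turing-unstable regime.
Blue/violet noise is simulated but its linear-theory prediction is known
to fail (truncation becomes material and amplitudes unphysical); no
quantitative claims are tested there.
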