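# Methods

## Scope and model overview

`diffuspect` treats one physical quantity — the translational
self-diffusion coefficient of a small peptide and its aggregates in
solution — measured three ways and interpreted through one hydrodynamic
model:

* from particle trajectories, via the mean-square-displacement (MSD)
  tensor;
* from pulsed-field-gradient stimulated-echo (PFGSTE) NMR decay curves,
  via mono-exponential fitting and regularized multi-exponential
  inversion (the diffusion dimension of a DOSY experiment);
* and through Stokes–Einstein / Perrin hydrodynamics, which converts a
  diffusion coefficient into a hydrodynamic radius and an equivalent
  prolate-ellipsoid shape.

All internal units are SI (m, s, m² s⁻¹, T m⁻¹); radii are reported in nm
and gradient files default to G cm⁻¹ (1 G cm⁻¹ = 0.01 T m⁻¹), with the
unit always explicit — a bare `gradient` column without a unit flag is an
error, never a guess.

## Synthetic data generator

The generator replaces the spectrometer and the MD engine; it emulates
free anisotropic Brownian motion and ideal Stejskal–Tanner attenuation,
nothing else.

**Trajectories.** Euler–Maruyama steps with per-step covariance
2·D_lab·dt, where D_lab = R·diag(D₁,D₂,D₃)·Rᵀ and R is the particle's
body-to-lab rotation. Optional isotropic rotational diffusion composes a
small random rotation per step whose rotation-vector components have
variance 2·D_r·dt per axis. Because the body tensor is diagonal, steps are
drawn in the body frame and rotated, which is exact and fast. The PSD
matrix square root is taken by eigendecomposition so that zero principal
coefficients produce exactly zero displacement. One integer seed is
expanded with `numpy.random.SeedSequence` and split per particle, then per
particle into displacement and rotation streams: enlarging the ensemble
never reshuffles existing particles, and identical seeds give bit-identical
trajectories.

Default study conditions used throughout the tests mirror the regime of
the aqueous-peptide simulations being emulated: D ≈ 2.5·10⁻¹⁰ m² s⁻¹
(small peptide/oligomer in water), dt = 10 ps, ensembles of 200 particles
and trajectories of 2000–5000 frames. These sizes put single-run
statistical errors at the few-percent level, which is what the recovery
tolerances (3% isotropic, 5% anisotropic eigenvalues) reflect.

**Decays.** Intensity at gradient g is Σᵢ wᵢ·exp(−b(g)·Dᵢ) with
b = γ²g²δ²(Δ−δ/3), plus additive zero-mean Gaussian noise of standard
deviation (Σwᵢ)/SNR. Additive Gaussian (not Rician) noise is appropriate
to the high-SNR regime of the experiments modelled. Stimulated-echo
relaxation losses (T₁/T₂ weighting) are absorbed into the component
amplitudes and not modelled separately.

**What passing tests do not show.** The generator has no inter-particle
interactions, no hydrodynamic coupling, no aggregation kinetics, no
chemical-shift dimension and no baseline/phase artifacts. Recovery of an
injected D therefore validates the estimators, not the ability to resolve
real spectra with overlapping resonances or time-dependent aggregation.

## MSD tensor estimation

M_ab(τ) = ⟨Δa(τ)·Δb(τ)⟩ is averaged over **all overlapping time origins**
(standard practice; independent-block averaging would discard most of the
data) and all particles, for the six unique index pairs. The estimator
uses the FFT cross-correlation identity, O(N log N) per pair; positions
are mean-centered per particle first, which leaves displacements unchanged
but makes constant trajectories exactly zero. Lag 0 is included and is
identically zero. A brute-force double-loop oracle in the test suite pins
the estimator to 10⁻¹² relative on small trajectories.

Each D_ab is half the least-squares slope (intercept free) of M_ab versus
lag over a fit window; the isotropic coefficient is one sixth of the
total-MSD slope over the same window, and on noiseless linear inputs the
two agree to machine precision (the total MSD is the trace). The default
window spans 10%–50% of the largest available lag: below that the series
is dominated by the noisy origin, above it by poorly averaged long lags.
The window is a parameter everywhere.

Diagonalization uses the symmetric eigensolver; asymmetry beyond 10⁻¹²
(relative) is rejected. Eigenvalues are sorted descending and their mean
equals trace/3 by construction. Atom/particle selection is the caller's
responsibility: every trajectory row is one particle.

The relation M_ab = 2·D_ab·τ is the per-component Einstein relation (some
sources label the MSD = 2Dt step "Stokes–Einstein"; the Stokes–Einstein
relation proper is the D ↔ R_h conversion in the hydrodynamics module).

## PFGSTE modelling and inversion

The acquisition schedule of the reference experiment — 32 linearly spaced
gradients from 1.77 to 250 G cm⁻¹, δ = 2 ms, Δ = 50 ms, ¹H γ — is built
in (`build_reference_schedule`); the ramp shape is configurable since only the
endpoints and count are specified. At the maximum gradient
b ≈ 8.83·10¹⁰ s m⁻², so a free peptide at 3.4·10⁻¹⁰ m² s⁻¹ decays by
e⁻³⁰: the schedule fully samples the species of interest.

**Mono-exponential fit.** Log-linear regression over positive intensities
initializes a nonlinear least-squares fit of S₀·exp(−b·D). An unattenuated
(constant) curve is flagged degenerate rather than fitted.

**Spectrum inversion.** The multi-exponential inverse problem
min ‖S − K·w‖² + λ²‖w‖², w ≥ 0, K[i,j] = exp(−bᵢ·Dⱼ), is solved by
non-negative least squares on the Tikhonov-augmented system. This is a
generic regularized inversion in the CONTIN tradition, standing in for
proprietary Bayesian DOSY transforms, which are out of scope. The default
grid is 256 log-spaced points over 10⁻¹²…10⁻⁸ m² s⁻¹, covering fibril
seeds (~10⁻¹¹) through free peptide (~3·10⁻¹⁰) with margin.

The default λ is 10⁻³ of the kernel's largest singular value. The choice
balances two failure modes measured on forward-simulated decays under the
built-in schedule: at 10⁻² the noiseless single-species peak broadens to
~0.5 decades FWHM (spilling weight outside ±0.2 decades of the true D),
while at 3·10⁻⁴ the non-negative solution starts splitting one physical
mode into disjoint spikes at realistic noise. At 10⁻³ a noiseless single
species keeps all weight within ±0.2 decades, total spectral weight
matches the zero-gradient amplitude to ~0.2%, and a 22-fold mixture at
SNR 200 resolves reliably. An explicit λ can always be passed.

**Peak extraction.** Contiguous runs of positive weight become candidate
peaks; runs separated by gaps narrower than 0.06 decades are merged first,
because sparse NNLS solutions can represent one mode as adjacent spikes
with interior zeros. The mode is the weight-maximizing grid point, the
fraction is the run's share of total weight, the width is the log₁₀ FWHM,
and peaks under `min_fraction` (default 0.02) are dropped. Measured
resolution limits under the built-in schedule at SNR 200: D ratios ≥ 5
resolve into distinct peaks, ratios ≤ 1.5 merge into one.

## Hydrodynamics

Stokes–Einstein R_h = k_BT/(6πηD) with k_B = 1.380649·10⁻²³ J K⁻¹ (exact).
Default solvent conditions are T = 298.15 K and η = 1.00·10⁻³ Pa·s; the
measurements being reproduced state 25 °C but no viscosity, and this pair
reproduces four of the five reported radii exactly at 2-decimal rounding.
The remaining entry (D = 3.50·10⁻¹⁰ m² s⁻¹, reported 0.61 nm) yields
0.62 nm under any (T, η) consistent with the other rows; the discrepancy
is surfaced in the tests rather than absorbed by tuning, and the
downstream semi-minor axis is still reproduced from the reported radius.

The prolate Perrin friction gives R_h = aξ/ln((1+ξ)/(b/a)),
ξ = √(1−(b/a)²), with the continuous sphere limit R_h → a as b → a. R_h is
strictly increasing in b on (0, a], so the inverse problem (b from a
measured R_h at fixed a) is solved by Brent root-finding on
(10⁻⁶·a, a(1−10⁻⁹)) to machine tolerance. The semi-major axis is fixed at
a = 2.1 nm, the extended length scale of a hexapeptide, following the
semi-axis convention of the reported table (its accompanying text calls
2.1 nm a "long axis"; the column header's semi-axis reading is
implemented). The reference molecular volume V = 0.23 nm³ is an input
constant; (4/3)πab² bookkeeping and its inverse b = √(3V/4πa) are
provided.

The structure-based "theoretical radius" is the solvent-accessible
volume-to-surface ratio V_SAS/A_SAS (0.17 nm for 1.45 nm³ / 8.45 nm²).
This estimator is a compactness length — for a sphere it returns r/3, not
r — and is documented as such; it serves as a lower reference against
which the measured ~0.63 nm radii indicate oligomerization.

**Rounding.** Report parity uses decimal half-up rounding to 2 decimals,
applied only at the presentation layer. The table pipeline feeds the
*rounded* radius into the Perrin inversion by default, matching the
internal consistency of the reported table; `use_rounded_rh=False` chains
at full precision.

## Report and CLI

`build_table1_report` assembles (concentration, D) pairs into rows of
(R_h, a, b, volume check); reports embed the full resolved configuration
(T, η, a, V, λ, grid, seeds) and contain no timestamps, so a fixed config
and seed give byte-identical files. Readers reject malformed rows with
line numbers and refuse ambiguous gradient units. The CLI subcommands are
thin wrappers over these functions.

## Known limitations

* The decay model is ideal Stejskal–Tanner: no convection compensation,
  no gradient non-linearity, no relaxation during δ.
* Only the 1-D diffusion dimension of DOSY is modelled; chemical-shift
  resolution and 2-D rendering are out of scope.
* The ellipsoid model is prolate-only (b = c ≤ a); oblate and triaxial
  friction, and rotational Perrin factors, are not implemented.
* The Brownian generator is non-interacting; aggregation onset, crowding
  and hydrodynamic interactions are deliberately absent.
* The NNLS inversion's weight fractions are amplitude fractions, which
  equal population fractions only when per-species signal amplitudes are
  proportional to concentration (equal proton counts, equal relaxation
  weighting).
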