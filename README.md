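# diffuspect

Diffusion-based characterization of peptide aggregation state.

Short amyloidogenic peptides — the motivating case is IVAGVN, the
steric-zipper hexapeptide of human cystatin C — aggregate in solution, and
their aggregation state can be read off the translational self-diffusion
coefficient *D*. `diffuspect` implements the three measurement routes to
*D* and the hydrodynamic model that interprets it:

1. **MSD tensor analysis** of particle trajectories. The six unique
   displacement products grow linearly with lag time,
   *M*<sub>ab</sub>(τ) = ⟨Δa·Δb⟩ = 2 *D*<sub>ab</sub> τ, and the total MSD
   obeys the Einstein–Smoluchowski law MSD = 6 *D* τ. Fitting the six
   slopes yields the diffusion tensor; its eigenvalues are the principal
   diffusion coefficients and their mean is compared with the isotropic
   6*D*t fit.
2. **PFGSTE / DOSY decay analysis.** In a pulsed-field-gradient
   stimulated-echo NMR experiment a species with diffusion coefficient *D*
   attenuates as the Stejskal–Tanner law
   *S*(g) = *S*₀ exp(−γ²g²δ²(Δ−δ/3)·*D*). A mono-exponential fit handles
   the single-species case; multi-component decays are inverted into a
   diffusion spectrum by Tikhonov-regularized non-negative least squares
   on a log-spaced *D* grid, and peaks are read off per species.
3. **Hydrodynamics.** Stokes–Einstein, *R*<sub>h</sub> = k<sub>B</sub>T /
   (6πη*D*), converts *D* into a hydrodynamic radius; modelling the
   extended peptide as a prolate ellipsoid of revolution with semi-axes
   *a* > *b* = *c*, the exact Perrin friction
   *R*<sub>h</sub> = *a*ξ / ln((1+ξ)/(*b*/*a*)), ξ = √(1−(*b*/*a*)²),
   is inverted by bracketed root-finding to recover the semi-minor axis
   from a measured radius at fixed *a*.

A seeded synthetic-data module generates Brownian trajectories with a
prescribed (possibly anisotropic) diffusion tensor and optional rotational
tumbling, and multi-component PFGSTE decays with controlled noise, so the
whole pipeline is testable against known ground truth without an
instrument or an MD engine.

## Worked example

The concentration-series report (peptide in water, T = 298.15 K,
η = 1.00·10⁻³ Pa·s, semi-major axis fixed at 2.1 nm):

```sh
$ diffuspect --quiet hydro-report --out table.csv
  0.52 mM  D=3.400e-10  Rh=0.64 nm  a=2.10  b=0.16  V=0.23 nm^3
  1.05 mM  D=3.500e-10  Rh=0.62 nm  a=2.10  b=0.14  V=0.17 nm^3
  2.60 mM  D=3.460e-10  Rh=0.63 nm  a=2.10  b=0.15  V=0.20 nm^3
  3.50 mM  D=3.460e-10  Rh=0.63 nm  a=2.10  b=0.15  V=0.20 nm^3
  5.25 mM  D=3.460e-10  Rh=0.63 nm  a=2.10  b=0.15  V=0.20 nm^3
```

Each row converts a measured diffusion coefficient into a hydrodynamic
radius (Rh), then inverts the Perrin formula at a = 2.1 nm for the
semi-minor axis b; V is the ellipsoid volume implied by the reported axes.
Radii of ~0.63 nm are several times larger than the ~0.17 nm
volume-to-surface estimate from the bare molecular structure
(`sas_ratio_rh(1.45, 8.45)`), indicating that the diffusing species are
small oligomers rather than monomers. The first row's axes close the
volume bookkeeping at the reference molecular volume of 0.23 nm³.

A two-species decay — free peptide at 3.40·10⁻¹⁰ m²/s plus slow
fibril-seed material at 1.56·10⁻¹¹ m²/s — simulated at SNR 200 and
inverted:

```python
>>> import diffuspect as dp
>>> sched = dp.build_reference_schedule()   # 32 gradients, 1.77-250 G/cm
>>> decay = dp.simulate_pfgste_decay([(0.5, 3.40e-10), (0.5, 1.56e-11)],
...                                  sched, dp.NoiseSpec(snr=200, seed=1))
>>> print(dp.PFGSTEModel(decay).fit_spectrum().summary())
Regularized DOSY inversion
--------------------------
grid       1.00e-12 .. 1.00e-08 m^2/s (256 pts)
lambda     5.001e-02
resid norm 2.497e-02
total wt   1.00306

  mode D [m^2/s]  fraction  fwhm [dec]
      1.6138e-11     0.501       0.298
      3.3534e-10     0.498       0.235
```

Both injected species are recovered at the right diffusion coefficients
(within a few grid cells) with the injected 50/50 weights.

Trajectory analysis follows the same model/results idiom:

```python
>>> cfg = dp.SimulationConfig(n_particles=200, n_steps=5000, dt=1e-11,
...                           body_tensor=(4e-10, 1e-10, 1e-10), seed=7)
>>> traj = dp.simulate_brownian_trajectory(cfg)
>>> res = dp.MSDDiffusionModel(traj, max_lag=1000).fit()
>>> res.eigenvalues      # principal diffusion coefficients, m^2/s
array([4.05985328e-10, 1.02539611e-10, 9.72928790e-11])
```

## Command-line interface

`diffuspect` exposes `simulate-trajectory`, `msd-fit`, `dosy-simulate`,
`dosy-invert` and `hydro-report`; see `diffuspect --help`. All commands
accept a JSON/YAML run configuration, log their resolved parameters and
seeds, and write outputs atomically and deterministically.

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
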