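# dropmix

Computational companion to **drop-on-drop** sample delivery for
time-resolved serial crystallography. In that method a piezoelectric
injector (PEI) fires a burst of picoliter substrate drops at 1–2 m s⁻¹ onto
a nanoliter crystal-bearing drop deposited on a moving tape by acoustic
droplet ejection (ADE); the merged drop reaches the X-ray beam after a
delay set by the tape speed. Whether this works as a reaction trigger hangs
on one quantitative question: does the substrate equilibrate through the
merged drop much faster than the enzyme turns over?

`dropmix` provides the three computations that answer it:

- **Stochastic mixing simulations** (`lattice_sim`, `drop_geometry`,
  `mixing_pipeline`): an exact Gillespie-direct kinetic Monte Carlo engine
  over compartment lattices, solving the reaction–diffusion master equation
  for three regimes — pure Fickian diffusion from resting PEI drops on the
  voxelised sphere, the post-impact cone-jet partial mix, and a
  proportional mass-flow chain (per-particle transfer rate v/L) that lower-
  bounds the mixing time of the inertial collision. The validation
  chemistry is competitive Ca²⁺ binding by two indicators,
  Ca + Dye ⇌ CaDye with k_off = K_d·k_on, K_d = 400 nM (Fura Red) and
  90 µM (Fluo-5N).
- **Fluorescence analysis** (`spectral_fit`, `synthetic_data`): linear
  unmixing of emission spectra into four max-normalised components over
  510–750 nm, f(λ) = s_d·sc_diode + s_fluo·fl_fluo + s_fura−·fl_fura− +
  s_fura+·fl_fura+ + c, with 1/tape-speed residence correction, and
  exponential rise fits s(t) = a·(1 − e^(−t/τ)) of the calcium-dependent
  amplitudes — plus a generator of synthetic spectra with known ground
  truth, since the raw measurements are not public.
- **Planning arithmetic** (`planner`): merged concentrations
  n·V_drop·C/(V_main + n·V_drop), tape delay times, burst-vs-continuous
  substrate consumption, and the L²/6D crystal-size diffusion heuristic.

See `docs/methods.md` for models, assumptions and parameter defaults.

## Worked example

The three numbered drivers under `analysis/` reproduce the study's
computational narrative. Regime comparison (coarse 20 µm lattice, scaled
particle counts; a few minutes on one CPU):

```bash
$ python analysis/02_simulate_mixing.py --seed 1 --out results
        regime  equilibration_time_s  reached
     mass_flow             0.0001348     True
      cone_jet                 2.506     True
diffusion_only                 3.992     True

mass-flow equilibration: 0.135 ms (<1 ms: inertial mixing is not the bottleneck)
diffusion-only equilibration: 3.99 s (comparable to or slower than a 1-2 s enzymatic turnover)
separation: 2.96e+04x
```

The times are 90%-of-asymptote equilibration of the volume-averaged bound
dye after merging 3 × 60 pL drops of 100 mM CaCl₂ into the 4 nL drop
carrying 1 mM of each indicator: if the drops only rested on the surface
and diffused, mixing would take seconds — slower than a typical 1–2 s
enzymatic reaction — whereas collision-driven flow mixes in ~0.1 ms,
leaving binding kinetics and crystal-interior diffusion as the only
limits.

Planning arithmetic and the synthetic fluorescence re-enactment:

```bash
$ python analysis/01_plan_experiment.py
          experiment  drops  drop_pL  stock_M  main_nL  final_mM
       HEWL + GlcNAc      2      120    0.226        3      16.7
       HEWL + GlcNAc      6      120    0.226        3      43.7
CTX-M-15 + ertapenem      4      120      0.8        3       110
   Ca dye validation      5       60      0.1        4      6.98
...
delay window: 0.1-6 s (600 down to 10 mm/s tape)
burst vs continuous consumption: 20.3-fold saving
ligand per dataset (0.18 mL of 0.226 M): 40.7 µmol

$ python analysis/03_fit_fluorescence.py --seed 1
...
fluo: tau = 156 ms (true 150 ms), a = 1
fura_plus: tau = 106 ms (true 100 ms), a = 0.502
```

The merged concentrations are exactly the operating points of the two
enzyme case studies (16.7–43.7 mM GlcNAc, 110.3 mM ertapenem, 1.5–7 mM
CaCl₂); the rise fit recovers the generating time constants from noisy
synthetic spectra through the full unmix-then-fit pipeline.

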