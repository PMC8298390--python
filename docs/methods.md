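# Methods

`dropmix` models the mixing physics and the fluorescence analysis behind
drop-on-drop sample delivery for time-resolved serial crystallography: a
burst of picoliter substrate drops from a piezoelectric injector (PEI)
collides at 1–2 m s⁻¹ with a nanoliter crystal-bearing drop deposited by
acoustic droplet ejection (ADE) onto a moving tape, and the merged drop is
carried to the X-ray interaction point after a delay set by the tape speed.
The package answers two questions quantitatively: *how fast does the
substrate equilibrate through the merged drop*, and *what do the
fluorescence validation measurements of that mixing look like and how are
they analysed*.

## Chemical model

The validation chemistry is competitive 1:1 calcium binding by two
indicators with well separated affinities:

    Ca + Dye_free ⇌ Dye_bound,   k_off = K_d · k_on

with K_d(Fura Red) = 400 nM and K_d(Fluo-5N) = 90 µM. Published sources
give the dissociation constants but not the individual rate constants, so
the package adopts a diffusion-influenced association rate
k_on = 1×10⁸ M⁻¹ s⁻¹ for both dyes (typical of small-ligand binding in free
solution) and derives k_off from K_d. Both are configurable; absolute
kinetic outputs (not the equilibria) depend on this choice, though in every
regime studied here binding is much faster than transport, so the reported
equilibration times are transport-limited and insensitive to k_on within an
order of magnitude.

The unique non-negative equilibrium of the two-dye system is found from the
free-calcium conservation residual g(x) = x + Σ_d D_d·x/(K_d+x) − Ca_tot,
which is strictly increasing in x; the root is bracketed on [0, Ca_tot] and
solved by Brent's method (a damped fixed-point iteration would converge to
the same root; the bracketed solve is unconditional and was preferred).
Mass balances are then enforced exactly and the K_d relation is verified to
1×10⁻⁶ relative.

## Stochastic engine

Space is discretised into compartments holding integer particle counts per
species; events are elementary reactions within a compartment and
per-particle transfers along couplings. The exact Gillespie direct method
samples the chemical master equation: waiting times are exponential in the
total propensity, and the firing channel is chosen hierarchically — a
Fenwick tree over per-compartment propensity totals (O(log C) selection and
update), then a linear scan of the ~30 channels inside the chosen
compartment. Propensities: k·n for unimolecular, k·n_A·n_B·s/V for
bimolecular (s = moles per simulated particle, V the compartment volume),
r·n for transfers. The loop is numba-compiled; the RNG is numpy's MT19937
seeded once per run, so identical seeds give bit-identical trajectories.

Real drops hold ~10¹² molecules. Simulations use scaled counts — by default
10⁵ particles for the most abundant conserved moiety — which preserves all
concentrations and mean dynamics exactly while inflating relative
fluctuations by √scale. Conserved moieties (total Ca, total of each dye)
are invariant event by event, and the suite checks this exactly on recorded
snapshots.

A deterministic mass-action ODE integrator (scipy LSODA, rtol ≤ 1×10⁻⁸)
over the same network serves as the large-count oracle; the suite verifies
SSA/ODE agreement within three standard errors at ≥10⁴ particles, and the
engine's stationary mean was checked against the exact birth–death
stationary distribution of A+B⇌C during development.

## Geometries and regimes

*Diffusion-only.* The 4 nL ADE drop (diameter ≈197 µm) is voxelised into
cubic compartments of edge h (default 10 µm); boundary voxels keep the
partial volume estimated by 4×4×4 sub-sampling, so the summed volume tracks
the spherical volume to a few tenths of a percent. Six-neighbour couplings
carry per-species Fickian hop rates D/h², corrected by h³/V for partial
voxels so that k_ij·V_i = k_ji·V_j and uniform concentrations are
stationary. The PEI drops rest on the surface at time zero: one cap
compartment per drop is appended at evenly spaced sites on a 45° latitude
ring (the published description says only "distributed across the surface";
the ring is a configurable choice), coupled to the surface voxels under the
contact disc with D·A/(d·V) rates. Diffusion coefficients default to
7.9×10⁻¹⁰ m² s⁻¹ for Ca²⁺ and 4×10⁻¹⁰ m² s⁻¹ for the dyes (literature
free-solution values).

*Cone-jet.* The partial-mix structure formed within milliseconds of impact
is idealised as one cone per PEI drop extending inward from the contact
site, depth 0.5×R and base radius fixed by conserving each drop's volume
(the jet geometry of the original study is not public; both parameters are
configuration defaults and flagged as such). Substrate
starts uniformly distributed over the cone voxels; transport is otherwise
identical to the diffusion-only regime. Cone depth below one voxel
degenerates to a surface distribution.

*Mass-flow.* The opposite extreme — mixing entirely by collision-driven
inertial flow — is a chain of n equal compartments (default 10) spanning
the merged volume, coupled by proportional mass transfer at per-particle
rate v_rel/L_mix with L_mix = drop diameter / n, following the inertial
mixing treatment for droplet collisions; there are no Fickian couplings, so
this is the lower bound on mixing time. v_rel defaults to 1.5 m s⁻¹, the
middle of the observed 1–2 m s⁻¹ impact range. The Weber number
ρv²L/σ ≈ 6 for the 200 µm drop confirms the inertia-dominated collision
regime this model assumes.

## Equilibration time

The monitored observable is the volume-averaged bound-dye concentration
(total moles bound / merged volume). The equilibration time is the first
crossing of threshold × asymptote with linear interpolation between
samples; the threshold defaults to 0.9 (the original criterion is not
stated; the threshold is reported alongside every time). The asymptote is
the mean of the final 10% of samples, with stationarity required as <1%
drift between the last two 10% blocks; a closed-form equilibrium value may
be supplied instead. Runs that fail to reach threshold (or whose tail is
not stationary) are re-run once with a 3× longer horizon. Default horizons
are 10 s for the diffusive regimes and 10 ms for mass flow, recorded on a
400-point uniform grid.

## Fluorescence analysis

Measured spectra are modelled by linear unmixing: four
max-normalised components — residual diode scatter and the emissions of
Fluo-5N (λmax 515 nm), Ca-bound Fura Red (640 nm) and Ca-free Fura Red
(670 nm) — plus a constant offset, fitted by unconstrained ordinary least
squares over 510–750 nm. On any exact linear combination the generating
coefficients are recovered to machine precision; a rank-deficient design
(duplicate components) raises a conditioning error.

Because a drop's residence time in the detection volume is proportional to
1/tape-speed, raw intensities are multiplied by speed/reference-speed
(reference 100 mm s⁻¹, a control speed) before unmixing; the operation is
idempotent via a `speed_corrected` flag.

The calcium-dependent amplitudes versus interaction time t are fitted with
s(t) = a·(1 − e^(−t/τ)) by Levenberg–Marquardt least squares in
(a, log τ), with the initial τ taken from the half-maximum crossing and
five starts spanning a decade around it. Point uncertainties act as inverse
weights when present. An optional pooling step averages the k earliest time
points (used for the weak high-affinity-dye signal). Plateau-only data and
fits whose τ uncertainty exceeds 10× the estimate are flagged unstable
rather than trusted. A single exponential is a deliberate simplification of
three-dimensional mixing plus binding — it is used for comparison, not as a
mechanistic model.

## Synthetic data

The raw validation spectra are not published, so the generator emulates
them: Gaussian surrogate components (FWHM 60 nm at the stated peaks; the
diode profile is a 40 nm Gaussian at 455 nm whose tail reaches into the fit
window — real component spectra can be loaded from CSV to override),
saturating-exponential amplitudes with configurable τ in the observed
<100–150 ms
regime, the 1/speed intensity scaling, and additive Gaussian noise with σ
expressed as a fraction of the window peak (default 2%; the experimental
noise level is unpublished). Ground truth is returned with every dataset.
What passing tests show is therefore that the *analysis pipeline* is
unbiased and convergent under a realistic noise model — not that the
surrogate shapes match the real instrument response, detector nonlinearity,
photobleaching, or drop-to-drop variability, none of which are modelled.

Canned scenarios bundle the in-study parameter sets (dye validation drop
recipe; GlcNAc and ertapenem substrate recipes) with provenance notes on
every number.

## Problem sizes and numerical choices

The default lattice spacing of 10 µm puts ≈20 voxels across the ADE drop.
The regime comparison and the acceptance computation run the diffusive
regimes at h = 20 µm with 10⁴ particles for the most abundant moiety, and
the mass-flow model at the default 10⁵ particles — sizes chosen so a full
comparison completes in minutes on one CPU while leaving the measured
equilibration times comfortably clear of the claimed bounds (the grid-
refinement test in the suite verifies the diffusive equilibration time
moves by <20% when h is halved). Tie-breaking inside a compartment follows
the fixed channel order (reactions, then transfers); record times capture
the state immediately before each requested instant; an exhausted system
(zero total propensity) terminates early and is flagged absorbed.

## Known limitations

- No computational fluid dynamics: coalescence, surface-tension-driven
  shape evolution and the real jet geometry are replaced by the two
  bracketing idealisations (pure diffusion, pure proportional flow) and a
  parameterised cone.
- Absolute simulated times inherit the uncertainty of the adopted k_on and
  diffusion coefficients; only robust order-of-magnitude separations
  between regimes are asserted.
- The exponential rise is phenomenological; no attempt is made at richer
  mixing kinetics.
- Diffusion *inside* crystals (obstruction factors, solvent-channel
  geometry) is out of scope; the crystal-size guidance uses the
  free-solution L²/6D heuristic.
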