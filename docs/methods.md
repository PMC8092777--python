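# Methods

## Body-wave model and estimation

The midline of a steadily swimming subcarangiform fish is modelled as

    h(x, t) = (a e^{bx} + c e^{dx}) · cos{2π(f t − x/λ)},

with `x` in body lengths (BL) from the snout, oriented opposite the
direction of travel. The envelope is the sum of a decaying head term
(`a ≥ 0`, `b < 0`) and a growing tail term (`c, d > 0`); the tail term
carries essentially all of the thrust-producing excursion. Because total
length exceeds body length, stations beyond `x = 1` (tail tip near
1.10–1.13 BL) are legitimate inputs.

Estimation from a track of lateral displacements at fixed stations:

1. **Frequency.** Station-summed, zero-padded periodogram for the initial
   peak; refinement by variable projection — at each candidate frequency
   the per-station cos/sin amplitudes are solved linearly and the pooled
   residual minimized over frequency (bounded scalar minimization within
   ±1 unpadded bin). Requires ≥ 2 periods of data and nonzero variance.
2. **Amplitudes.** Half peak-to-peak excursion, taken as the modulus of
   the best-fit single-frequency sinusoid per station. This estimator is
   exact on model-generated data and robust to sampling phase, unlike a
   max–min range. Whether tracked amplitudes are half or full excursions
   is a convention choice; half peak-to-peak is used throughout.
3. **Wavelength.** Per-station sinusoid phases, unwrapped along the body
   (the phase lag grows tailward for a tailward-traveling wave), are
   regressed on station position; the slope is `2π/λ`. A near-zero slope
   is reported as an infinite wavelength (standing wave) rather than an
   error. At least 3 stations with nonzero amplitude are required.
4. **Envelope.** Two-stage log-linear fit: stations `x > 0.4` give
   `(c, d)`; the tail term is subtracted from stations `x < 0.25` and the
   positive residuals give `(a, b)`. Stations with `0.25 ≤ x ≤ 0.4` are
   used by neither stage. With `iterations = 1` this is the literal
   one-pass procedure; it leaves the tail slope `d` biased slightly low
   because the head term still contaminates the tail region. The default
   mode iterates the two stages as a fixed-point loop (tolerance 1e-10 on
   parameter change), whose fixed point is the exact generating envelope;
   on noiseless synthetic data all six constants are recovered to ~1e-9
   relative. Head-region residuals at rounding level (≤ 1e-9 of the peak
   amplitude) are interpreted as "no measurable head term" (`a = b = 0`);
   genuinely nonpositive residuals raise an error naming the stations.

Goodness of fit `R²` is pooled over all stations and times
(`1 − SSE/SST` about the grand mean), with a single global phase offset
absorbing the arbitrary time origin of the track.

## Synthetic digitized tracks

The generator emulates overhead 60 fps video digitization of a
station-holding fish in a flume: lateral displacement sampled from the
model at fixed stations, plus i.i.d. Gaussian noise per sample. Defaults:
nine landmarks at plausible anatomical fractions (0, 0.05, 0.15, 0.25,
0.45, 0.60, 0.75, 0.85, 1.13 BL — snout, eyes, pectoral base/end, dorsal
root/end, adipose root, caudal root, tail tip), 60 fps, 4 s, zero noise,
fixed seed. The true landmark coordinates of the digitized fish were
never published, so these fractions are assumptions chosen to populate
both fitting regions. The generator does **not** model occlusion,
tracking dropouts, lens distortion, non-uniform frame timing, or axial
drift of a fish failing to hold station; passing round-trip tests
therefore shows the estimators are correct and noise-stable, not that
they are robust to every artifact of real video.

## Body geometry and prescribed motion

The swimmer is a rectangular-planform plate: a symmetric NACA 4-digit
section (closed-trailing-edge thickness polynomial) extruded vertically.
Defaults match the measured animal and its model: total length
L = 0.439 m, height 0.0893 m, maximum thickness 0.0451 m, and body length
BL = 0.397 m for converting kinematic units (the animal's total length,
44.9 cm, differs slightly from the 43.9 cm model; the model dimensions
are used). Kinematic quantities (stations, speeds) are in BL; geometry
and pair separations in L.

Deformation is purely lateral: every node moves by `h(x/BL, t)·BL` metres
with the analytic time derivative as its prescribed velocity; axial and
vertical coordinates are untouched. This is the literal definition of the
wave as displacement perpendicular to travel; an arc-length-preserving
variant (which would shorten the projected body) is a possible extension,
not implemented. The triangulated surface is closed by construction
(Σ area·normal = 0 to rounding), watertight, and exports to OBJ/STL.

## The vortex solver

A full 3-D viscous computation of this problem is cluster-scale; the
package substitutes a 2-D unsteady discrete-vortex (lumped-vortex) panel
method on the horizontal midplane, which captures the phase- and
separation-dependent wake-interference physics of pair swimming at
interactive cost. Design:

- **Discretization.** The deforming midline is split into `n_panels` flat
  panels (cosine-clustered toward both ends), each carrying a point
  vortex at its quarter point with a collocation point at three quarters.
  No-penetration (including prescribed body motion) is enforced at every
  collocation point.
- **Kutta condition and shedding.** One nascent wake vortex per body per
  step, placed behind the trailing edge along the local tangent at 25% of
  the free-stream travel per timestep `0.25·U·Δt` — i.e. inside the wake
  sheet segment it discretizes. Its strength is an unknown of the linear
  system, closed by Kelvin's theorem per body (total bound + shed + wake
  + truncated circulation stays at its initial zero). Circulation is
  conserved to solver precision (~1e-16 relative) at every step.
- **Wake.** Free point vortices advected by free stream plus all induced
  velocities (forward Euler). Induced velocities use a Lamb-type core of
  radius 2% of the model length (`vortex_core_L`), a *physical*
  regularization scale: tying the core to panel size would change the
  wake dynamics under mesh refinement, which is exactly what a
  convergence study must hold fixed. Bound-to-collocation influences use
  the singular kernel (the ¼–¾ arrangement requires it). The wake is
  truncated beyond `wake_cap_L` model lengths downstream; removed
  circulation is tallied per body so the Kelvin ledger stays closed.
- **Pressure.** Unsteady Bernoulli across the sheet:
  `Δp_j = ρ [V_t,j γ_j/Δc_j + d/dt Σ_{k≤j} γ_k]`, with `V_t,j` the
  tangential component of free stream + wake + other-body induction
  relative to the moving panel, and a backward difference in time for the
  potential-jump term. Panel force is `Δp·Δc·n̂` per unit span, scaled by
  the body height (strip approximation, no tip loss).
- **Friction.** Per panel, turbulent flat-plate
  `C_f = 0.074·Re^{−1/5}` at the body Reynolds number
  `Re = ρ(U·BL)L/μ`, applied to the local tangential relative velocity
  over both wetted sides. This stands in for the resolved viscous stress;
  it is what makes the rigid-body drag nonzero and the self-propelled
  balance well-posed.
- **Stability guard.** Any wake-induced speed above 50× the inlet speed
  aborts with a diagnostic; a singular panel system raises immediately.

Defaults: 40 panels, 100 steps per tail-beat period, 8 periods with the
first 2 discarded as impulsive-start transient, wake cap 6 L. The test
suite and sweeps run a scaled-down 24-panel / 50-step / 4-period setup;
at the measured 1.52 BL/s kinematics, jointly doubling panels and halving
the timestep from that setup changes mean thrust by ~2%, and the net
axial pressure force agrees with the rate of change of total vortex
impulse (momentum oracle) within ~8%.

Coordinates: inlet flow along +x (the fish swims toward −x, held at
station), y lateral, circulation positive counterclockwise. Antiphase
pairs are realized by a π wave-phase offset of the second body, which
makes the configuration exactly mirror-symmetric about the mid-plane;
inphase pairs map onto themselves under mirror + half-period time shift,
which is the form in which "both bodies experience the same forces" is
exact (instantaneously, up to the decaying start-up transient).

## Forces, efficiency, transects, sweep

Per element and timestep, the axial pressure force is split into thrust
(−x part, on thrust-directed elements) and pressure drag (+x part); total
drag adds friction. Averages use the longest post-transient window
spanning whole periods. The thrust series is dominated by twice the
tail-beat frequency and the lateral force by the tail-beat frequency
itself — a consequence of the wave's sign reversal after half a period.

Froude efficiency: `η = P_T/(P_T+P_S)` with
`P_T = ⟨Σ F_Ti·u_i⟩` and `P_S = ⟨Σ F_Si·v_i⟩`. Two sign/velocity
conventions deserve note. First, `u_i` is each element's speed along the
direction of travel in the ground frame — the swimming speed `U` — since
the prescribed wave has no axial component (a purely body-frame reading
would make `u_i ≡ 0` and `η ≡ 0` for any station-holding swimmer).
Second, `F_Si` is the lateral force the element exerts **on the fluid**
(the sign-flipped surface force), so `P_S` is the positive power spent
driving the recoil and `η ∈ [0, 1]` for every converged run. Pair runs
report per-body triples and the pooled value.

The self-propelled state is found by bisecting the tail-beat frequency
until `|F_T/F_D − 1| ≤ 0.05` ("largely balanced"); mean thrust is
monotone in frequency over any sensible bracket while drag is
friction-dominated, so the imbalance has a single sign change.

Wake transects sample the time-averaged velocity magnitude (final 2
periods) along the line through the midpoint of the two snouts, reported
in BL/s and as a ratio to the inlet speed; a solitary variant samples
behind a single body. The sweep driver covers separation × phase grids,
rebalancing the frequency per cell by default, records per-cell failures
without aborting, and appends the solitary reference row.

## Known limitations

- Absolute force and power levels are 2-D inviscid-plus-friction strip
  values; they are the right order of magnitude but are not substitutes
  for 3-D viscous computations, and no acceptance is claimed for them.
- The near-field between two bodies closer than ~0.5 L is where the 2-D
  midplane abstraction is weakest: at 0.4 L separation the solver places
  a velocity deficit on the mid-line where a 3-D computation reports
  accelerated flow. Mid-range separations (0.8–1.2 L) reproduce reported
  deficit ratios closely (e.g. ~0.98 vs ~0.97 at 0.8 L, antiphase,
  1–2 L behind the snouts, balanced kinematics).
- Leading-edge suction is represented only through the pressure integral
  on the discretized surface; no separate suction-force model is added.
- Forward Euler wake advection is first-order; with the default timestep
  the induced error in mean thrust is at the few-percent level.
- Burst-and-glide, acceleration manoeuvres, free-surface and wall
  effects, and 3-D tip effects are out of scope.
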