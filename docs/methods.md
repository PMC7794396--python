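# Methods

`cochstream` simulates how sound-evoked travelling waves on the basilar
membrane drive a slow, steady fluid circulation (acoustic steady
streaming) in the cochlear chambers, and how that circulation transports
drug particles from the base of the cochlea towards the apex. This note
documents the model, its assumptions, the numerical choices, and the
limits of what the test suite demonstrates.

## 1. Membrane model and travelling wave

The uncoiled cochlea is two fluid chambers of height `h = 0.5 mm`
separated by the basilar membrane along `y = 0`, connected at the apex
through the helicotrema. The membrane is an array of independent
transverse strips of area `A = 8 um x 186 um` (one hair-cell width times
the membrane breadth), each a damped oscillator with specific acoustic
impedance

    Z(x) = [ i w m(x) + xi - i K(x)/w ] / A .

Stiffness and mass follow gerbil measurements and vary exponentially:
`K = K0 exp(-x/l_K)` with `K0 = 1 N/m`, and `m = m0 exp(+x/l_m)` with
`m0 = 32 ng`; the length scales are fitted to the 7 mm samples
(`0.03 N/m`, `65 ng`), giving `l_K = 2.00 mm` and `l_m = 9.88 mm`. These
fits reproduce the tonotopic constant: the undamped resonance condition
`w^2 = K/m` yields a logarithmic place-frequency map with
`slope = 2/(1/l_K + 1/l_m) = 3.32 mm` of distance per natural-log
frequency, matching the printed 3.3 mm. (Quoted nm-scale length values
for `l_K`, `l_m` circulating with this parameter set are dimensionally
inconsistent with both the endpoint data and the 3.3 mm constant and are
treated as a units typo; the endpoint fits are authoritative here.)

The trans-membrane pressure obeys a 1-D wave equation with local
wavenumber `k(x) = sqrt(2 w rho0 / (i Z h))`, square root taken on the
branch with `Im k <= 0`. The WKB (Liouville-Green) solution gives the
pressure envelope `p_hat = p0 (Z/Z0)^(1/4)` and membrane velocity
`V_hat = (p0/Z0) (Z0/Z)^(3/4) exp(-i Phi)`.

**Amplitude convention.** Physical signals are `Re[q_hat e^{iwt}]`:
`q_hat` is the full (peak) amplitude, and `p0 = sqrt(2) * 20 uPa *
10^(SPL/20)`. Every quadratic time average is then
`<ab> = Re[a_hat conj(b_hat)]/2`. Conventions in which `p0` is the
coefficient of a `+ c.c.` expansion double every physical first-order
amplitude and quadruple the streaming; see section 7.

**Damping and the envelope mode.** The drag `xi` is spatially constant
but level dependent — `{60, 80, 100} dB -> {10, 500, 2000} nN s/m` — a
calibrated stand-in for the cochlear amplifier, whose gain shrinks with
level. Two envelope modes are implemented:

* `attenuation="full"` evaluates `Phi = int k dx` with the damped `k`
  exactly. With the calibrated drag values this attenuates the wave to
  under 1% of its basal amplitude *before* it reaches the 20 kHz
  resonance place at 80/100 dB: the envelope then peaks at `x = 0` and no
  level produces a peak at the characteristic place.
* `attenuation="compensated"` (default) takes the physical position that
  the active process cancels viscous propagation loss basal to the peak
  (the same assumption under which the drag table can represent peak
  width at all): the phase comes from `Re k`, the amplitude follows the
  local-impedance law `|Z|^{-3/4}`, and the only decay in the exponent is
  the evanescent decay of the *lossless* (`xi = 0`) wavenumber apical to
  the resonance place. Its integrable inverse-square-root singularity at
  the resonance is handled by the trapezoid rule on a grid with at least
  20 points per local wavelength.

Only the compensated mode reproduces the calibrated behaviour (envelope
peak at the place at every level, level-ordered sensitivity, peak
broadening with level) and it is the default throughout.

## 2. Oscillatory flow

At these amplitudes the Reynolds number is tiny while the Womersley
number is large, so the first-order flow obeys the unsteady Stokes
equations and oscillates as a single harmonic per tone:

    i w rho0 u_hat = -grad p_hat + mu lap u_hat ,   div u_hat = 0 .

Membrane displacements (nm-um) are far smaller than the chamber height,
so the membrane enters as a transpiration condition on its *mean* (flat)
line: both chamber faces move vertically with `V_hat(x)`, with no slip
tangentially; all outer walls are rigid no-slip; continuity closes
through the helicotrema. The moving-boundary effect that this
linearisation drops re-enters at second order as a boundary slip
(section 3).

Discretisation: a marker-and-cell staggered grid on a rectilinear tensor
mesh, complex sparse direct solve (SuperLU) of the saddle-point system
with the pressure pinned in one apical helicotrema cell. The
longitudinal spacing follows the local wavelength (12 cells per
wavelength by default, graded transitions); the vertical spacing is
stretched from `delta_nu/3.5` at the membrane (with
`delta_nu = sqrt(2 nu / w)` of the highest tone) to `h/8` in the bulk
and back down near the outer walls, whose own Stokes layers otherwise
dominate the dissipation error. Verified invariants: machine-precision
linearity, per-chamber flux balance between membrane and helicotrema to
1e-10, upper/lower chamber mirror symmetry, the Stokes second-problem
boundary layer against its closed form (<3% on a coarse grid), and
global power input = viscous dissipation to <1% on a resolved grid.

## 3. Steady streaming

With `Q = (conj(u_hat) . grad) u_hat`, the time-averaged second-order
ingredients are

* Reynolds-stress force      `F = -(rho0/2) Re Q`,
* Stokes drift               `u_sd = -Im Q / (2 w)`,
* membrane boundary slip     `u_slip = -(1/2) Re[conj(xi_bm) d_y u_hat]`
  per chamber face, with `xi_bm = V_hat/(i w)` the membrane excursion,
  from Taylor-expanding no-slip on the moving membrane about its mean
  line (evaluated with one-sided second-order stencils per face; the two
  faces carry independent values in the steady problem).

The Eulerian mean solves steady Stokes flow with forcing `F` and the
slip as membrane boundary values (streaming Reynolds number << 1 at
nm/s-um/s speeds, so the mean flow does not advect itself); the
Lagrangian mean `u_ss = u_euler + u_sd` is the transport velocity and
the primary observable. The drift sign convention is fixed by the
progressive-wave limit (`u = U cos(wt - kx)` drifts forward at
`U^2 k / 2w`), verified against brute-force trajectory averaging, not
taken from notation.

Because the formulation is perturbative, streaming is *exactly*
quadratic in the drive (the historical trick of amplifying the drive by
300 and dividing the streaming by 300^2 returns the identical field to
round-off) and multi-tone fields superpose exactly — distinct
frequencies cannot beat into DC. Combs therefore cost one oscillatory
and one steady solve per tone on a shared grid.

Two structural consequences worth knowing:

* **The Lagrangian mean vanishes on the membrane.** A particle sitting
  on a wall that oscillates with zero mean cannot drift, so the slip and
  the drift cancel at `y -> 0`. Immediately above/below the membrane
  there is a thin *base-ward* sub-layer (within ~`delta_nu`), then the
  apex-ward lane, then the base-ward far-field return flow — matching
  the reported particle behaviour (near-membrane particles drift
  base-ward; others are captured and carried apex-ward).
* **Net mean transpiration recirculates around the membrane tip.** The
  steady slip's integral over the membrane is nonzero, and that mean
  flux returns between the chambers around the membrane end as a
  localised jet. At 100 dB this tip jet exceeds the wave-peak streaming
  and even reverses the local profile at the characteristic place. This
  is a genuine feature of the flattened-boundary formulation, not a
  solver artifact (it scales exactly quadratically and converges under
  refinement).

## 4. Particle transport

Drug carriers are dilute rigid spheres (200 nm, neutrally buoyant by
default, 5000 per ensemble, seeded on a uniform grid over the basal
region of each chamber) under Stokes drag, with wall collisions that
reverse the normal velocity times the restitution (0.95) and shave the
friction fraction (1e-3) off the tangential velocity. The quoted
friction coefficient is interpreted as this collision-tangential loss —
it is listed alongside the collision model — not as a fluid drag
modifier. The drag relaxation time is `tau_p ~ 2.2 ns`, making the ODE
stiff at any usable timestep; the drag is therefore integrated exactly
over each step (exponential integrator, carrier flow evaluated at the
midpoint), which also reproduces the closed-form approach to terminal
velocity to 1e-6. With Stokes number `w tau_p ~ 3e-4` even at 20 kHz,
finite-mass paths track passive tracers to <0.1% of path length, so the
default "fast mode" advects particles in the Lagrangian mean field only,
with steps spanning many acoustic cycles; full oscillatory stepping
(>=10 steps per cycle of the highest tone, Courant number held below 1)
exists for validation and agrees with fast mode to <10% in mean drift.

Transport times integrate `dx / u_lane` along the lane of fastest
apex-ward Lagrangian flow at each `x` (interpolated continuously along
the duct); a non-positive lane speed reports the blocking position
instead of a time. The lane is only defined inside the comb's place
span — beyond the apical-most tone the flow reverses, which is exactly
why extending the reach requires adding lower-frequency tones.

## 5. Multi-frequency stimulus design

A comb is a set of `n` tones with fixed ratio `R`; the log map turns it
into equally spaced wave peaks, `delta = slope * ln R`. Defaults follow
the published setup: `n = 10`, `delta = 330 um`, one common SPL, zero
phases (streaming from distinct tones is phase-independent after
averaging — asserted by test), and the highest tone anchored so its
place is 0.25 mm, since the source experiments leave the absolute frequency anchor
unstated. Spacings `<= 100 um` are refused by default: overlapping
nonlinear response regions would need two-tone suppression, which this
model does not contain. Each tone carries the damping of its own SPL
(no cross-tone interaction).

## 6. Time-domain oracle

An independent, deliberately simple solver cross-checks the perturbative
pipeline at desk scale: semi-implicit incompressible Navier-Stokes
(implicit Euler viscosity, explicit advection, incremental pressure
projection) on a coarse instance of the same grid family, with the fixed
flat transpiration membrane, passive tracers advanced by RK4 in the
time-interpolated field, and the Lagrangian drift measured from
cycle-boundary positions after discarding a startup transient long
compared to the chamber's viscous time `h^2/nu ~ 0.25 s`. Because its
membrane does not move, it validates the Reynolds-force and Stokes-drift
channels but *not* the boundary-slip term — a stated limitation; the
slip is instead pinned analytically by the wall-cancellation identity
above. Drift on both sides of the comparison is extracted with the same
trajectory functional (tracers in the bilinearly interpolated staggered
fields); with sub-cell oscillation excursions, trajectory averaging
samples the interpolant's one-sided cell gradients, so comparing a
stencil-based drift against a trajectory-based one would measure the
drift-extraction operators, not the physics. Agreement at mid-domain
probes is 4-8% on the standard coarse benchmark (tolerance 10%);
halving the (already fine) timestep moves the drift by <2%, and the
measured drift is quadratic in the drive to 2%. The oracle configuration
is a 150 Hz Gaussian wave packet on a 3 mm domain at an amplitude chosen
so the streaming Reynolds number stays well below 1 — at larger
amplitudes the oracle's mean-flow self-advection (absent by construction
from the linear steady solve) visibly bends the square law. The oracle
is never used for headline numbers.

## 7. Known limitations and departures from the published description

* **Streaming magnitude.** The converged Lagrangian maximum for 20 kHz
  at 80 dB is ~70 nm/s (grid-refinement checked), against the reported
  "about 300 nm/s". The factor ~4 is exactly what the amplitude
  convention is worth: reading `p0 = sqrt(2) p_rms` as the coefficient
  of a `+ c.c.` expansion doubles the physical drive (+6 dB) and
  quadruples the streaming. This package keeps the standard acoustic
  convention (peak amplitude = `sqrt(2) p_rms`) and reports the smaller
  number rather than adopting the convention that reproduces the quote.
* **Pressure power law.** With the calibrated drag table, the WKB
  amplitude law makes peak sensitivity scale as `xi^{-3/4}`, so the
  60 dB (`xi = 10 nN s/m`) response is large enough that the absolute
  membrane response is non-monotone in level, and the log-log slope of
  peak streaming vs pressure across all three levels computes to ~0.03
  (`u_ss`) and ~0.31 (`v_ss`) rather than the reported 1.3. The
  80->100 dB segment alone gives 1.1-1.4. The 60 dB peak has a ~29 um
  wavelength — about 2.6 cells of the reference solver's 11.2 um
  membrane mesh — so the reference 60 dB response was necessarily
  smoothed toward the printed law; this package resolves it instead and
  reports what the stated model actually produces.
* **Profile shape vs level.** The near-membrane streaming profile scale
  is the penetration depth `1/|k_peak| ~ sqrt(xi)` (3.7-52 um across the
  table), so normalized profiles at the place are *not* level-invariant
  in a resolved computation; what is invariant is the qualitative
  structure, and the vertical extent grows with level (as also stated in
  the published description). At 100 dB the tip-recirculation jet
  additionally reverses the local profile.
* No fluid-structure interaction (oval/round windows are rigid; membrane
  motion is prescribed), no active-process dynamics beyond the
  level-dependent drag, no two-tone suppression (hence the 100 um
  spacing guard), no longitudinal membrane motion, no Brownian motion or
  particle-particle interaction, 2-D planar geometry only.
* Synthetic-data realism: the wave-packet oracle benchmark emulates the
  *structure* of a membrane wave (travelling phase, localised envelope)
  at low frequency where a coarse grid is honest; it does not emulate
  cochlear amplitudes or frequencies, so oracle agreement demonstrates
  correctness of the second-order machinery, not clinical magnitudes.

## 8. Default problem sizes

Default production grids are ~150-190 x 60 cells (refined to 12 cells
per local wavelength and 3.5 cells per Stokes layer), solving in a few
seconds per tone; the oracle benchmark uses ~90 x 28 cells, 48 steps per
cycle and 160 cycles (~30 s). The test suite and the acceptance script
run the full pipeline at these sizes.
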