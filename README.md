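# cochstream

Sound-evoked steady streaming and drug-particle transport in a
two-chamber model of the cochlea.

## The problem

Drugs against sensorineural hearing loss must reach hair cells deep in
the cochlea, but the organ can only be accessed at its basal end and
passive diffusion along the 7+ mm duct is hopelessly slow. Sound itself
offers a pump: a tone evokes a travelling wave on the basilar membrane
that peaks at a frequency-dependent place, and the oscillatory flow it
drives rectifies — at second order — into a steady circulation
("acoustic steady streaming"). A single tone only stirs a local vortex
pair, but a comb of tones whose wave peaks are spaced a few hundred
micrometres apart merges the vortices into a continuous near-membrane
*streaming channel* that carries suspended drug particles from the base
towards the apex. `cochstream` is a simulator for designing and
quantifying such stimuli, for researchers in cochlear mechanics and
inner-ear drug delivery.

## The model

* **Membrane wave (WKB).** The basilar membrane is a strip-impedance
  model `Z(x) = [i w m(x) + xi - i K(x)/w]/A` with exponential gerbil
  stiffness/mass profiles (`K0 = 1 N/m`, `m0 = 32 ng`, fitted length
  scales `l_K = 2.0 mm`, `l_m = 9.9 mm`) and a level-dependent drag
  `xi(SPL)` standing in for the cochlear amplifier. The trans-membrane
  pressure wave `p ~ p_hat exp(-i int k dx')` has local wavenumber
  `k = sqrt(2 w rho0/(i Z h))`; the membrane velocity envelope
  `|V_hat| = |p0/Z0| |Z0/Z|^{3/4}` peaks at the characteristic place of
  the tonotopic map `x(f) = -3.32 mm * ln(f/f_base)`.
* **Oscillatory flow.** Per tone, the unsteady Stokes equations in the
  two chambers on a staggered grid, driven by membrane transpiration.
* **Steady streaming.** Reynolds-stress forcing
  `-(rho0/2) Re[(u* . grad)u]`, the moving-membrane boundary slip, and
  the Stokes drift `-Im[(u* . grad)u]/(2w)` combine into the Lagrangian
  mean flow `u_ss` — the transport velocity. Exactly quadratic in the
  stimulus; tones superpose exactly.
* **Particles.** 200 nm finite-mass carriers under Stokes drag with an
  almost-elastic wall-collision model (restitution 0.95, friction 1e-3),
  advected in the mean flow; transport times along the channel lane.
* **Oracle.** An independent time-domain Navier-Stokes solver with
  tracer particles cross-checks the perturbative streaming at desk scale.

See `docs/methods.md` for assumptions, numerics and known limitations.

## Worked example

Design a ten-tone comb whose wave peaks are 330 um apart, anchored so
the highest tone peaks 0.25 mm from the base:

```
$ cochstream design --out out_design
comb: n=10  R=1.1045  delta=330 um
    10670.8 Hz @  80.0 dB -> x =  3.220 mm
    11785.5 Hz @  80.0 dB -> x =  2.890 mm
    ...
    26094.9 Hz @  80.0 dB -> x =  0.250 mm
place span: 2.970 mm
```

`R = exp(delta/slope) = 1.1045` is the frequency ratio that yields the
requested 330 um spacing under the 3.32 mm tonotopic constant, and the
ten places span `9 x 0.33 = 2.97 mm` — the reach of the streaming
channel this comb creates.

Solve the streaming for a single 5 kHz tone at 80 dB SPL:

```
$ cochstream streaming --config run.toml --out out_streaming
max |u_ss| = 117.0 nm/s
```

(`run.toml` sets `[stimulus] kind='tone', f=5000.0, spl=80.0` and
`[solver] resolution='coarse'`.) The number is the largest Lagrangian
mean speed in the domain; the output directory contains the mean-flow
field as VTK (`streaming.vtk`), vertical profiles at the wave peak as
CSV, and a JSON manifest of the exact resolved configuration. The other
subcommands are `wkb` (membrane wave and sensitivity tables), `flow`
(oscillatory field), `particles` (ensemble transport and transit time)
and `validate` (invariant suite).

Everything is also available as a library:

```python
from cochstream import MembraneProperties, FluidProperties, Tone
from cochstream import single_tone_streaming

run = single_tone_streaming(MembraneProperties(), FluidProperties(),
                            Tone(f=20000.0, spl=80.0))
print(run.wkbs[0].peak_place())        # 0.00113  (m) - the 20 kHz place
print(run.streaming.max_speed())       # 7.0e-08  (m/s)
```

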