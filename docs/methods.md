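# Methods

## The physical model

A monoflagellate *C. reinhardtii* cell is modelled as a sphere of radius
*r* in creeping flow. The single beating flagellum exerts a beat-averaged
force *F* at angle *θ* from the surface normal at its base. Decomposed at
the base, the normal component translates the centre around a circle
(revolution, radius *R*, angular velocity *ω*) and the tangential component
spins the body; in the observed motion the spin is phase-locked to the
revolution, so one *ω* governs both. Balancing each component against the
Stokes drag force `6πηrv` (with `v = Rω`) and drag torque `8πηr³ω` gives

    F cos θ = 6πηrRω,        r F sin θ = 8πηr³ω,

so `tan θ = 4r/(3R)` and the input power `F cosθ·Rω + F sinθ·rω` equals
the dissipation `6πηr(Rω)² + 8πηr³ω²` identically — the implementation
exposes this residual as a self-check, and a property test holds it below
10⁻¹² over random parameter draws.

For the intact biflagellate cell the two flagellar bases sit a central
angle *α* apart on the equator (default 20°, a value measured from cell
micrographs); by symmetry the two beat-averaged forces combine along the
body axis with projection `cos(θ − α/2)` each, giving the predicted speed
`v = 2F cos(θ − α/2)/(6πηr)`. The force model is beat-averaged throughout:
the ~49 Hz beat ripple is estimated as a kinematic observable but does not
feed back into *F*.

Assumptions worth keeping in mind: the sphere is rigid and far from
boundaries (cells actually revolve near the microwell floor; no wall
correction is applied), the fluid is water at the recording temperature
(η = 1.002×10⁻³ Pa·s), and the flagellar force is reduced to a single
constant vector per flagellum.

### Known inconsistency in the published figures

Exact arithmetic on the reference inputs gives F·cos(θ − α/2) = 4.94 pN
and propulsion 2F·cos(θ − α/2) = 9.88 pN, where the published text prints
5.0 pN and 10 pN after rounding *F* and *θ* first; the published speed
(105 μm/s) agrees with the exact chain (104.65 → 105 at 3 s.f.). The
package always reports the exact values.

## Estimators

**Circle fit.** Kåsa's algebraic least squares gives a closed-form centre
and radius (rank-deficiency of its normal system detects collinear tracks);
a geometric least-squares refinement (Levenberg–Marquardt on the radial
residuals) then removes the algebraic fit's small-arc bias. The RMS radial
residual is reported per cell.

**Angular velocity.** The polar angle about the fitted centre is unwrapped
and regressed linearly against time. This uses every sample, needs no
frequency initialisation, and its slope sign gives the rotation direction
(ccw = increasing `atan2(y−cy, x−cx)`; note that in the y-down image frame
this appears clockwise on screen). Estimation requires ≥ 8 samples spanning
≥ 1 full revolution.

**Beat frequency.** The radial residual `|p(t) − c| − R` of an orbit with a
radial beat modulation is a pure sinusoid at the beat frequency; its
periodogram is searched above twice the revolution frequency `ω/2π` so the
orbit fundamental (and circle-fit leakage at it) cannot be selected. A peak
is accepted only if its power exceeds 30× the median band power: for white
noise the band maximum is ~8–12× the median over the few hundred bins of a
half-second record (exponential order statistics), so 30 keeps false alarms
negligible, while a genuine beat — amplitude a few times the localisation
noise, coherent over the record — sits orders of magnitude above the
median. The returned frequency is quantised to the periodogram grid
(1/duration Hz).

**Motion classification.** A track is *immotile* when the path length of
its boxcar-smoothed, decimated trajectory (20 ms scale) is below 2 μm over
the analysed window. Smoothing is essential: raw path length integrates
centroid noise (σ√2 per frame, tens of μm/s of spurious "motion" at 1 kHz),
whereas real swimming (≥100 μm/s) or orbiting (ωR ≥ ~15 μm/s) survives
averaging at the 20 ms scale. A non-immotile track is *revolving* when the
circle fit converges over ≥1 revolution with relative RMS residual
`fit_residual/R < 0.35`, else *translating*. All three thresholds are
config-exposed and echoed in the JSON outputs.

## Synthetic data

The generator emulates the statistical structure the estimators assume:

* orbits `center + (R + a·sin(2πf_b t))·(cosφ(t), sinφ(t))` with
  `φ(t) = ωt + φ₀` — the beat is applied as a radial modulation, matching
  the displacement ripple superimposed on the revolution sinusoid in the
  recordings (the true modulation geometry is not known);
* straight swimmers at constant velocity, and immotile cells;
* i.i.d. isotropic Gaussian centroid noise (the standard localisation-error
  model), default σ = 0.05 μm;
* defaults R = 1.16 μm, ω = 22.75 rad/s (the reference population means),
  beat 49 Hz, 1 kHz sampling (high-speed-camera regime; the original
  recordings' frame rate and calibration are not published, so these are
  declared stand-ins, not reconstructions).

The renderer draws each cell as a disk (radius 5 μm) with fractional-
coverage edges and optional Gaussian blur into uint8 frames, and emits the
true centroid per cell per frame in pixel coordinates, flagging frames
where two centres come closer than one cell diameter. What it does **not**
emulate: phase-contrast halos, intensity flicker, cell shape and flagella,
out-of-focus drift, or cells entering/leaving the field. Passing tests on
this material therefore demonstrate correctness of the estimators under
the stated noise model, not robustness to every real-microscopy artefact.

## Tracking

Frames are thresholded (Otsu by default, fixed threshold available) after
polarity normalisation, so an image and its inverse give identical masks
under opposite polarity flags. Connected components within an area window
become detections; centroids are intensity-weighted means over the
component after subtracting the background level (median intensity outside
the mask), which recovers subpixel positions on blurred disks (<0.1 px on
rendered data). Linking is greedy nearest-neighbour in ascending distance
order with a displacement gate of 5 μm per elapsed frame and gap bridging
up to 2 frames; exact distance ties break by lower track id, then by
detection position, making the result invariant to detection order. At
microwell densities (cells tens of μm apart moving ≪ the gate per frame)
greedy assignment coincides with globally optimal matching.

## Numerical and reporting choices

* SI units inside the force model; reporting converts to pN and μm/s.
* Population means are plain arithmetic means of the per-cell estimates.
* Degenerate model inputs are errors, not silent zeros: R = 0 leaves θ
  undefined, ω = 0 carries no force information.
* Pipeline artifacts are deterministic for a fixed seed (per-cell seeds are
  spawned from the config seed via `SeedSequence`), and every JSON artifact
  embeds a provenance block (config hash, package version, seed,
  thresholds).
* Problem sizes in the test suite — e.g. 100 synthetic orbits of 2 s at
  1 kHz for parameter recovery, a 5-cell 500-frame stack for tracking
  fidelity, a 3-cell rendered population at 250 Hz for the end-to-end round
  trip — were chosen so each check exercises several revolutions per cell
  and a few hundred periodogram bins while completing in seconds.

## Limitations

* No hydrodynamic simulation: trajectories are kinematic, so the synthetic
  data cannot probe failures of the Stokes model itself.
* No near-wall drag correction; forces are underestimated to the extent
  the microwell floor matters.
* The beat-frequency estimator assumes an evenly sampled track and reports
  a single dominant peak; amplitude-modulated or drifting beats would need
  a spectrogram approach.
* The motion classifier's thresholds were set for the microwell geometry
  and default noise scale; substantially different magnifications or noise
  levels may need retuning via the config.
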