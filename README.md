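# chlamyorbit

Analysis pipeline for the orbital (revolution) motion of **monoflagellate
*Chlamydomonas reinhardtii***. When one of the two flagella of this
breaststroke-swimming alga is removed, the remaining flagellum drives the
cell centre around a small circle instead of forward. From video of such
cells, this package measures the per-cell revolution radius *R* and angular
velocity *ω*, extracts the flagellar beat frequency, and solves a
creeping-flow force balance for the beat-averaged driving force per
flagellum — from which the swimming speed of the intact biflagellate cell
is predicted.

It is intended for microswimmer labs analysing high-speed phase-contrast
recordings of cells in microwells, and ships a synthetic-data module so the
whole chain is testable without any recording.

## Model

The cell body is a sphere of radius *r* in Stokes flow (viscosity *η*). The
flagellum applies a beat-averaged force of magnitude *F* at angle *θ* from
the surface normal at its base. The normal component drives the revolution
(circle of radius *R* at angular velocity *ω*), the tangential component
drives the body spin, phase-locked to the revolution:

    F cos θ = 6πηrRω              (translation ↔ Stokes drag)
    r F sin θ = 8πηr³ω            (rotation ↔ Stokes torque)

hence `tan θ = 4r/(3R)` independent of *η* and *ω*, and the power input
`F cosθ·Rω + F sinθ·rω` equals the viscous dissipation identically. For the
intact biflagellate cell, whose two flagella sit a central angle *α*
(default 20°) apart on the equator, each flagellum contributes
`F cos(θ − α/2)` along the swimming direction:

    v = 2 F cos(θ − α/2) / (6πηr)

Defaults: *r* = 5 μm, *η* = 1.002×10⁻³ Pa·s, *α* = 20°, all configurable.

## Pipeline stages

| stage      | in → out | what it does |
|------------|----------|--------------|
| `simulate` | config → tracks (+ TIFF stack) | synthetic orbiting / swimming / immotile cells with known ground truth |
| `track`    | image stack → `tracks.csv` | Otsu (or fixed) thresholding, connected components with intensity-weighted centroids, greedy nearest-neighbour linking with gap bridging |
| `analyze`  | tracks → `kinematics.csv`, `summary.json` | motion classification; per-cell circle fit (Kåsa + geometric refinement), *ω* by unwrapped-phase regression, beat frequency by periodogram peak |
| `model`    | kinematics → `report.json` | population mean (R, ω) → force balances → biflagellate prediction |

All stages share one CSV dialect (`track_id,frame,t_s,x_um,y_um`) and are
available as a library (`import chlamyorbit`) and as a CLI.

## Worked example

Full synthetic round trip (6 cells: 3 revolving at R = 1.16 μm,
ω = 22.75 rad/s, 2 swimming, 1 immotile, with 0.05 μm centroid noise):

```sh
$ chlamyorbit run --seed 42 --out-dir demo
[chlamyorbit] simulate: wrote 6 ground-truth tracks
[chlamyorbit] analyze: 3 revolving cells analysed
[chlamyorbit] model: wrote force-model report
```

`demo/report.json` then contains (abridged):

```json
{
  "population": {"n_cells": 3, "mean_R_um": 1.1603, "mean_omega_rad_s": 22.7502},
  "force_solution": {
    "F_cos_pN": 2.4927, "F_sin_pN": 14.3230, "tan_theta": 5.7459,
    "theta_deg": 80.127, "F_pN": 14.5383,
    "projected_force_pN": 4.9420, "v_biflagellate_um_s": 104.66
  }
}
```

Reading: the three noisy orbits were re-estimated to within 0.03% of their
generated kinematics; the flagellum pushes with ≈14.5 pN, almost
tangentially (θ ≈ 80°, so most of the force spins the body), and two such
flagella would propel the intact cell at ≈105 μm/s — inside the 100–200 μm/s
range observed for swimming *C. reinhardtii*.

The model alone, at the reference population mean:

```sh
$ chlamyorbit model --R 1.16 --omega 22.75 --out report.json
F = 14.5 pN, theta = 80.1 deg, v = 104.7 um/s
```

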