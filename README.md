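# boecyto

Computational toolkit for a micro flow cytometer whose illumination comes
from **binary optical elements (BOEs)** — multilevel diffractive phase masks
that reshape a laser into rectangular, quasi-flat-top focal spots — and whose
sample stream is confined by a **3D hydrodynamic-focusing chip**. It is aimed
at instrument builders and students of cytometer design who want to explore,
end to end and entirely in software: how such spots are designed, how the
chip's channel resistances set its sheath split and core velocity, and how
spot geometry and uniformity propagate into fluorescence-pulse statistics.

## What it computes

**Mask design.** With a lens of focal length *f* behind the BOE, the focal
field is the scaled Fourier transform of the aperture field,
*U(u,v) = (1/λf)·FT[A·e^{iΦ₀+iΦ_B}]*, so finding the BOE phase Φ_B that
produces a prescribed flat-top amplitude |U| is phase retrieval. `boecyto`
solves it with a modified Gerchberg–Saxton iteration (signal-window /
freedom-region separation, adaptive amplitude feedback, progressive
quantization 64→32→16 levels) and converts the phase to an etched relief
*h = λΦ_B / 2π(n−1)*. Three stock targets: **R1** a 50 μm × 10 μm rectangle,
**R2** two such rectangles with 110 μm leading-edge pitch (time-of-flight
velocimetry), **R3** adds a 50 μm square between them (longer exposure).

**Spot metrics.** Diffraction efficiency η (signal-region energy over input
energy), relative RMS amplitude/intensity errors (RMSA/RMSI) over the spot
region, and half-maximum dimension measurement.

**Chip hydraulics.** Laminar resistance network
*ΔP = Σ 32υρK_P (l/d²)(Q/A)* with hydraulic diameter *d = 2ab/(a+b)*, the
resulting sheath split Q_HS/Q_VS, and the rectangular-duct velocity series
whose centerline-to-mean ratio runs from 2.096 (square) to 1.5 (parallel
plates).

**Signal simulation & pulse analysis.** Poisson bead arrivals, disc-kernel
transit profiles, shot + Gaussian detector noise; threshold pulse detection,
per-bead event grouping (1/2/3 sub-pulses for R1/R2/R3), dual-edge
time-of-flight velocity *(L/T₁ + L/T₂)/2* with *L* = 110 μm, and the
90-percent-gated CV of pulse areas.

## Worked example

Design the R1 mask at the reference parameters (488 nm, f = 10 mm, 3 mm
aperture, 128 × 128 zones, 16 levels) and score the spot:

```python
from boecyto import beam_shaping as bs, spot_metrics as sm

optics = bs.OpticalConfig()                       # the reference design
target = bs.make_target("R1", bs.focal_grid_for(optics))
mask, focal, log = bs.gs_design(target, optics, bs.GSOptions(rng_seed=0))
m = sm.evaluate_spot(focal, bs.aperture_field(optics), target)
print(f"eta {m.eta:.3f}  rmsa {m.rmsa:.3f}  rmsi {m.rmsi:.3f}")
print(f"dims {m.measured_dims[0][0]*1e6:.2f} x {m.measured_dims[0][1]*1e6:.2f} um")
```

prints

```
eta 0.752  rmsa 0.211  rmsi 0.369
dims 50.11 x 9.98 um
```

i.e. 75% of the laser power lands in the spot, the residual flat-top ripple
is ~21% in amplitude, and the half-maximum dimensions miss the 50 μm × 10 μm
target by about 0.2% — the familiar trade-off of multilevel diffractive
homogenizers: sharp, accurate boundaries with some residual ripple.

The chip hydraulics at the stock operating point (60 μl/min sample,
7.2 ml/min sheath, water):

```sh
boecyto flow --out flowdemo
```

```json
{
  "centerline_velocity_m_s": 4.802596848302138,
  "mean_velocity_m_s": 2.3946170591727682,
  "split_ratio_qhs_qvs": 8.022532974681141,
  "vmax_over_vavr": 2.005580320204191,
  ...
}
```

The resistance-set sheath split lands near the design optimum of 8, and the
centerline (focused-core) velocity in the 310 μm × 163 μm straight channel
is 4.8 m/s — the system's operating velocity.

A full reproducible run (design → evaluate → flow → simulate → analyze) from
one YAML config:

```sh
boecyto init-config --out run.yaml
boecyto run --config run.yaml --seed 0 --out out/
```

which leaves per-stage CSV/JSON outputs and a `manifest.json` with seeds and
checksums; rerunning with the same seed reproduces every file bit-for-bit.

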