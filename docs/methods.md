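# Methods

This note records the models behind `boecyto`, the defaults and why they
were chosen, the numerical choices that affect results, and what the
synthetic data can and cannot say about a physical instrument.

## Optical model and mask design

The BOE is treated as a thin phase screen against an ideal lens, so the
focal field is the Fraunhofer transform of the aperture field,
U = (1/λf)·FT[G]. The discrete implementation is a centered FFT scaled by
dx²/λf; with focal pitch λf/(n·dx) this transform is exactly unitary in the
pitch²-weighted energy norm, which the test suite checks to 1e−10 and which
makes diffraction efficiency well defined without renormalisation. The
incident beam is uniform over the square aperture by default — consistent
with identifying the aperture side D with the beam diameter in the sampling
relation λf/D — with an optional truncated Gaussian (1/e² diameter = D) for
sensitivity studies.

Design uses a modified Gerchberg–Saxton iteration. The focal constraint is
applied only on the *signal region* (the rasterized target support); the
rest of the plane is a freedom region that absorbs the mismatch. The
imposed amplitude is reinforced adaptively, t + α(t − |U|) with feedback
strength α = 0.5 by default, which speeds flattening of the top. After the
continuous-phase stage (up to 100 iterations, early exit when the RMSI
change per iteration falls below 1e−6), the phase is quantized
progressively — 64, then 32, then 16 levels, 25 re-optimization iterations
each — so the final mask is directly expressible as 2⁴-mask lithography
with height interval λ/(2⁴(n−1)) ≈ 66 nm on quartz at 488 nm. The initial
phase is uniform random from a caller-supplied seed; runs are bit
reproducible. With feedback off and quantization disabled the iteration
reduces to plain alternating projections, for which the signal-region
amplitude mismatch is non-increasing (the classical error-reduction
argument); this is asserted as a property test. With feedback on,
monotonicity is *not* guaranteed and is not claimed.

Grid choices: the simulation grid is the zone grid zero-padded ×4, giving a
focal pitch of λf/4D ≈ 0.41 μm for the reference design. Targets are
rasterized with exact per-pixel area coverage (separable axis overlap
products) and amplitude √coverage, so the raster carries the exact
geometric area and the half-maximum edges sit within ~0.1 μm of the true
boundary. A center-in binary raster on a coarser ×2 grid would by itself
bias the 10 μm dimension by several percent — more than the design error
being measured — which is why the finer grid and coverage weighting are the
defaults, and why metrics are evaluated directly on this grid rather than
being resampled to the λf/D grid first.

Dimension measurement takes the intensity profile through each sub-spot's
centroid, finds the outermost in-rectangle samples above half maximum, and
walks outward to the interpolated half-max crossings. Anchoring the peak
and the starting samples inside the hinted rectangle keeps freedom-region
speckle adjacent to the spot from hijacking the edges; interior ripple dips
below half maximum (possible in low-iteration designs) are treated as part
of the spot, not as edges. Quantization ties round toward the lower level,
for determinism.

R2/R3 geometry: only the 50 μm × 10 μm rectangle, the 50 μm square and the
110 μm leading-edge pitch are fixed by the design; the R3 layout fills the
span symmetrically, leaving 25 μm gaps between the square and each
rectangle. All rectangle layouts are overrideable.

## Chip hydraulics

Each channel segment contributes a laminar resistance term
32υρK_P(l/d²)(Q/A), with hydraulic diameter d = 2ab/(a+b); the vertical
sheath feed splits over 4 identical branches and the horizontal over 2.
Equal pressure drop across the vertical and horizontal sheath paths fixes
the split ratio Q_HS/Q_VS as a ratio of geometric resistance sums plus a
junction offset: the high-aspect correction K_P = 1.4 and offset
K_Q = 0.75 are injected constants (originally CFD-calibrated); no CFD is
performed here. The segments shared with the sample stream can carry
Q_VS + Q_S exactly (default) or drop Q_S as an approximation, a config
toggle. The per-segment lengths of the physical chip are not published
numerically, so `example_network()` ships an illustrative set of
150 μm-layer channels whose split lands near the design optimum of 8; it is
a demonstration config, not a measured geometry.

The straight-channel velocity profile is the classical Fourier series for a
rectangular duct, with coordinates centered on the axis (y across the width
a, z across the height b). Both the series flow rate and the profile are
evaluated with 100 terms by default; the 1/(2n+1)³ tail puts the truncation
error below 1e−6 relative at 25 terms already, and the cosh ratio is
computed in an exponent-capped form that cannot overflow at extreme aspect
ratios. The implementation is validated against the two analytic anchors
that pin the form uniquely — V_MAX/V_AVR = 2.0962 for a square duct and
→ 1.5 in the parallel-plate limit — plus recovery of the flow rate by
quadrature. For the fabricated 310 μm × 163 μm channel the computed ratio
is 2.0056; at the stock rates (7.2 ml/min sheath + 60 μl/min sample) this
gives a centerline velocity of 4.80 m/s, the system operating point.
Fluid defaults are water at 20 °C (υ = 1.004e−6 m²/s, ρ = 998 kg/m³).

## Signal simulation

A bead is modeled as a uniform disc of its projected area (5 μm default);
its instantaneous emission is the spot intensity integrated over the disc,
so the transit profile is one column of spot ⊛ disc, precomputed once per
run and sliced per bead with linear interpolation in the lateral offset.
No photobleaching, saturation or refraction is modeled; "longer exposure"
manifests purely as larger integrated area.

Arrivals are a Poisson process at concentration × volumetric sample rate —
5 × 10⁶ /ml at 60 μl/min gives mean 5000 events/s. Per-bead brightness is
log-normal with unit mean and configurable CV; lateral offset is Gaussian
(sd = stream width/4) truncated at the stream edge, with the 15 μm default
width in the middle of the chip's focused-stream range (10–23 μm).
Overlapping transits sum on the shared timeline and are *recorded*, not
suppressed. Arrival times are quantized to the digitizer clock before
rendering: at the 10 MHz default the sub-sample phase carries no
information usable by the analysis, and snapping makes the noise-free
contract exact — identical transits produce identical samples, hence
exactly zero area CV when all spread sources are off. Detector noise is
Poisson shot noise at 400 counts per calibrated signal unit (SNR = 20 at
the R1 plateau) plus additive Gaussian noise of sd 0.01 and a 0.02
baseline; the gain auto-calibrates so a centered noise-free transit peaks
at 1.0, mirroring the practice of raising PMT gain for the dimmer
multi-rectangle spots. The 10 MHz sampling default keeps ≥ 30 samples
across the shortest pulse at the highest chip velocity; a
1 GSa/s-oscilloscope rate is configurable but wasteful for simulation.

What the generator does *not* emulate: defocus or spot deformation away
from the focal plane, scatter channels, spectral overlap, bead refraction,
and real fabrication errors in the masks. Consequently, passing tests show
that the *analysis chain* is correct and that the uniformity→CV mechanism
behaves as designed; they do not reproduce any experimentally measured CV.

## Pulse analysis

Detection is threshold crossing with hysteresis; per-pulse baseline is the
median of nearby sub-threshold samples; rise/fall times interpolate the
threshold crossing; width is at half height; area is the
baseline-subtracted trapezoid extended past the threshold crossings down to
10% of the threshold-over-baseline rise, so the sub-threshold edge ramps
are not clipped (keeps summed sub-pulse areas within 0.5% of the whole-span
integral). Pulses whose rising edges fall within 1.5 × (sub-spot
pitch/velocity) group into one event; groups with the expected 1/2/3
sub-pulses are clean, larger ones are flagged coincident, smaller ones
incomplete, and flagged events are excluded from CV and velocity statistics
by default.

Velocity uses both edges: (L/T₁ + L/T₂)/2 with T₁/T₂ the first-to-last
rising/falling edge intervals and L = 110 μm the leading-edge separation of
the outer sub-spots — for R3's three pulses the outer pair spans the same
110 μm, so the definition is consistent across R2 and R3.

The 90-percent gate retains the ⌊0.9n⌋ events closest to the *median* area
(ties to the smaller area, then input order). A median center was chosen
over the mean because a mean-centered window is circular under the very
outliers the gate exists to remove; a mean-centered variant is available.
CV is the n−1 sample standard deviation over the mean of the retained
areas. For Gaussian areas the gate converges to the central-90%
truncated-normal CV, σ√(1 − 2zφ(z)/0.9)/μ with z = 1.645, which the suite
checks at n = 10⁴.

## Problem sizes used in tests

Design-quality checks run the full 128-zone reference design once (about
200 iterations of 512² FFTs, a few seconds); iteration-property tests use
32-zone toy grids. Simulation tests use 0.02–0.1 s acquisitions at reduced
concentrations (hundreds of events), except the throughput check, which
runs the full 1 s at the stock concentration; the acceptance script does
the same. Velocity-recovery checks span 0.7–9.0 m/s with ~60 ms runs per
velocity. These sizes were chosen so each statistic has enough events to be
stable at its stated tolerance.

## Known limitations

- Scalar diffraction only; no vector effects, aberrations, chromatic
  spread, or etch-depth error models, so simulated spots are systematically
  cleaner than fabricated ones.
- K_P and K_Q are taken as given; outside the calibrated geometry class the
  split-ratio formula is only as good as those constants.
- The example channel network is illustrative, not the physical chip's
  drawing.
- Coincidence handling stops at flagging; no doublet deconvolution.
- The spot-ripple generator produces stationary Gaussian-filtered noise,
  which approximates but does not reproduce the structured ripple of real
  quantized designs (those are available directly via the design pipeline).
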