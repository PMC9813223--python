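# Methods

## The imaging model

`lissavol` simulates a point-scanning multiphoton microscope in which two
resonant devices sweep the focus simultaneously: a resonant mirror (RM)
scans x sinusoidally at `f_rm` (default 7834 Hz) and an ultrasound-driven
tunable acoustic gradient (TAG) lens sweeps the focal plane in z at
`f_tag` (default 456 kHz).  A non-resonant galvanometer steps y one line
per mirror period, so a volume of `n_y` frames is acquired in
`n_y / f_rm` seconds.  Acquisition is clocked by the pulsed laser: one
intensity sample per pulse, at `t_k = k / f_rep` exactly (default
`f_rep` = 80 MHz), with no pulse jitter and no detector impulse response.

The instantaneous focus position is

```
x(t) = A sin(2π f_rm t)
φ(t) = (2π f_tag t + φ0) mod 2π,   z(t) = (Z/2) sin(φ(t))
y(t) = y line of the current frame (constant within a frame)
```

with `A` the mirror half-swing in sample space and `Z` the peak-to-peak
axial scan range (default 120 µm).  Because `f_tag / f_rm` is in general
irrational-looking (58.2 at the defaults), the x–z trajectory is a
Lissajous figure whose pattern differs from frame to frame.  All the
information needed to predict frame `i`'s pattern is the TAG phase at the
moment its pixel-enable window opens — the phase delay `Δφ` — which the
simulator records in each frame's metadata exactly as the real
instrument derives it from the TAG TTL vs pixel-enable timing.

### Enable windows and time conventions

Only the near-linear part of the sinusoidal mirror sweep is sampled.  The
enable windows are centered on the zero crossings of the swing, where the
mirror moves fastest:

* bidirectional gating (default): two windows per period, each
  `duty/2` periods long, centered on the down-crossing at `iT + T/2` and
  the up-crossing at `(i+1)T` (`T = 1/f_rm`);
* unidirectional gating: one window of `duty` periods centered on the
  down-crossing.

Total enabled time is exactly `duty / f_rm` for every frame.  The default
duty of 0.65 was fixed once, from the published pulse budget (10,000
pulses per 0.125 ms frame, of which the near-linear region is kept) and
the requirement that the gated sweep reproduce the observed voxel fill
ratios; it is an ordinary configuration knob.

Time zero is the mirror zero crossing of frame 0; the laser emits pulse 0
at `t = 0` and the first *enabled* pulse arrives a fraction of a mirror
period later, when frame 0's first window opens.  The TAG TTL rising edge
defines phase zero and `z = 0` is mid-range.

The mirror amplitude is derived from the field of view rather than
specified: `A = (fov_x/2) / sin(θ_h)` with `θ_h` the mirror phase
half-width of one enable window (`π·duty/2` bidirectional, capped at
`π/2`).  The window edges therefore land exactly on ±`fov_x/2`, closing
the otherwise under-determined link between mechanical swing and imaged
field.

### Why 7834 Hz

The nominal mirror clock of this class of instrument is 8 kHz, and the
design calculators (`pulses_per_frame`, `tag_lines_per_frame`, …) use it
for the printed budget numbers.  The *working* default is 7834 Hz so that
the volume rate is `7834/256 ≈ 30.6` vps — the measured operating rate —
and so that `f_tag/f_rm` is non-integer, which makes the Lissajous
pattern drift between frames as observed.  The exact mirror frequency of
the physical instrument is not published; 7834 Hz is a reconstruction
consistent with the reported rate, exposed as an ordinary config value.

## Phantoms

A phantom is a sum of primitives — spheres (beads) and laterally infinite
slabs (thin films) — blurred by an anisotropic Gaussian PSF and carried
by a rigid motion law (static; harmonic in z; linear ramp in x with a
travel stop).  Default PSF FWHMs are 1.02 / 1.18 / 10.72 µm (x/y/z), the
measured resolutions of the underfilled-aperture configuration; they are
inputs, never outputs, of the simulation.

* Spheres with diameter ≤ min PSF sigma are treated as point emitters:
  the blurred image is the PSF itself, peak-normalized to the brightness
  (width error from the neglected radius < 3 %).
* Larger spheres are evaluated as the ball indicator sampled on a local
  grid (≥ 3 samples per sigma and ≥ 20 per diameter, capped at 300 per
  axis), blurred with a separable Gaussian filter and queried by
  trilinear interpolation; beyond 4.5 sigma outside the ball the field is
  zero.  Deep inside a large sphere the value approaches the brightness.
* Slabs use the closed-form erf profile of a 1D Gaussian-blurred
  indicator.

Photon noise is Poisson per pulse with mean
`intensity × photons_per_pulse`.  The default of 5 photons per pulse at
unit brightness encodes a single-pulse SNR of ~7 dB, interpreting the dB
figure as `10·log10(mean photons)`; the published measurement conditions
behind that figure are not stated, so only the dB value is honored.

What the phantoms deliberately omit: nonlinear (squared) excitation,
scattering, photobleaching, depth-dependent attenuation, mirror
turnaround distortion beyond gating, and TAG diopter-vs-frequency
physics (the range/resolution trade-off enters only through configurable
`z_range` and PSF widths).  Passing tests therefore demonstrate the
correctness of the synchronization/reconstruction logic, not robustness
to those real-world effects.

## Reconstruction

Each enabled sample is assigned to the voxel whose center is nearest the
*predicted* position: x from the mirror closed form, z re-derived from
the frame's recorded `Δφ` plus the elapsed time — the same phase-based
prediction route the instrument uses, never stored coordinates.  Nearest
mapping is implemented as half-open binning of the continuous position
(ties at bin edges go to the lower bin), which a test checks against a
brute-force nearest-center search.

Voxels receiving several samples store their arithmetic mean, so voxel
intensity is independent of dwell density (the arcsine-distributed dwell
of harmonic scanning would otherwise brighten the turning regions).
Voxels receiving none are *missing*: NaN-valued, excluded from all
statistics, zero-filled only at TIFF export for visual parity with raw
instrument images.  The fill ratio — the fraction of voxels hit at least
once — is the headline sparsity metric; it is reported volume-wide by
default, with per-z-slice values available since the instrument's
"pixel ratio" refers to a 2D cross-section (the two agree to within a few
percent at the default grid).

`rebin_grid` maps the same raw stream onto an alternate grid (fill is
monotone in voxel count by pigeonhole); `accumulate` merges consecutive
volumes with hit-weighted means, trading temporal resolution for fill.
Because consecutive Lissajous patterns are highly correlated, accumulated
fill saturates well below the independent-sampling prediction
`1 − (1−p)^N`.

## Dynamic imaging analytics

Centroid tracks use the signal-weighted centroid (voxel mean × hit
count) over non-missing voxels, stamped at mid-volume time so harmonic
motions incur symmetric phase error.  Spectra are magnitude rFFTs of the
mean-subtracted displacement, normalized to unit peak, with the DC bin
excluded from peak search; no window is applied by default (≈ 92-point
records, leakage acceptable; a Hann option exists).  The FWHM estimator
interpolates the half-max crossings linearly and is exact on
piecewise-linear profiles.

## Problem sizes and numerics

The acceptance computations run the documented conditions end to end:
fill ratios from full 2.6-million-sample volumes on the 256 × 256 × 80
grid (three runs starting at seed-derived TAG phases, since the sampling
geometry — not photon noise — decides which voxels are hit), and the
aliasing experiment as 92 volumes (~3 s at 30.6 vps) through the complete
phantom → acquisition → reconstruction → tracking chain.  Unit tests
exercising the same chains use a reduced pulse rate (8 MHz) and/or fewer
y lines; this scales sample counts, not the scan geometry or rates, and
none of the checked properties get easier with fewer pulses.  Binning is
exact integer arithmetic after one `floor`; window-edge pulse selection
uses a half-pulse tolerance so edge pulses are classified stably.

## Known limitations

* The 64 × 64-pixel fill ratio saturates near 1.0 in simulation
  (~26,000 samples shared by 5,120 voxels per y slab); reported
  instrument values below that are not reproducible by any sampling
  pattern consistent with the other grid sizes.
* Constant pulse-to-fluorescence delay is absorbed into the phase
  conventions (set to zero); only relative timing matters here.
* Whether the physical system bins both sweep directions into one frame
  is not documented; both modes exist behind the `bidirectional` flag
  (default on).
* No inpainting/denoising of missing voxels is provided; exports keep
  the raw sparse volumes.
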