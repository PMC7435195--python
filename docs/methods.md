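# Methods

## The problem

Quantitative phase imaging encodes the optical path delay of a transparent
specimen in a two-beam interferogram

    I(x, y) = a(x, y) + b(x, y) · cos θ(x, y) + n(x, y),

where `a` is the incoherent background, `b` the fringe amplitude, `θ` the
total phase (sample phase plus the carrier set by the beam tilt) and `n`
noise.  Off-axis recordings put the fringe term's Fourier lobes far from
DC and can be demodulated by spectral filtering; the interesting regime is
the slightly-off-axis to quasi on-axis one, where the lobes overlap and a
fully two-dimensional, single-shot demodulator is needed.  This package
implements such a demodulator: variational decomposition of the
interferogram, local fringe direction estimation, Hilbert spiral transform
quadrature, 2D phase unwrapping and plane removal, with an optional
variational aberration-correction step applied to the unwrapped phase.

## Pipeline stages

### Variational decomposition (uVID)

The interferogram is split into noise, background (structure) and fringes
(texture) with no user-set parameters.

* Noise is removed by a pluggable denoiser.  The default is BayesShrink
  wavelet soft-thresholding with the noise level estimated from the median
  absolute deviation of the finest wavelet detail; BM3D is used
  automatically when the optional `bm3d` package is importable.  The noise
  raster is defined as input minus denoised, so additivity is exact by
  construction.
* Structure and texture come from the TV-L2 (ROF) problem
  `min_u TV(u) + ‖u − f‖² / (2µ)` solved in the dual by Chambolle's
  projection with `µ = 100` and, for the classical iteration, step
  `τ = 0.25`.  The default iteration carries FISTA momentum (fast gradient
  projection), which reaches the same fixed point in roughly the square
  root of the iterations; the plain `τ`-step iteration is available with
  `accelerate=False`.
* The number of projections is not a free parameter: iteration stops when
  the maximum relative change of the structure drops below `tol = 1e-3`.
  This early, data-driven stop is part of the model.  The oscillatory
  fringe content enters the texture within the first projections, while a
  fully converged dual at `µ = 100` would slowly erode large compact
  features (the cell itself, the Gaussian background) into the texture as
  well; on the synthetic phantom the fringe-fidelity error roughly
  quintuples if the projection is run to convergence.

Boundary handling for all gradient/divergence operators is
Neumann/replicate.  Fringes are re-centred so that any residual mean is
assigned to the background; the three terms always sum to the input to
machine precision.

### Fringe direction

The spiral transform needs the local fringe direction β (modulo 2π, the
angle of the fringe normal against +x).  It is built in stages:

1. **Orientation (mod π).**  A plane is least-squares fitted to the
   intensities of every w×w neighbourhood (w odd, 3–13); the plane's
   gradient is reduced through a structure tensor averaged over the same
   window, whose principal axis gives the orientation in [0, π).  The
   tensor's coherence times the gradient magnitude serves as a quality
   map; pixels with degenerate gradients (< 1e-6 of the dynamic range) are
   flagged invalid and filled from their nearest valid neighbour.
2. **Disambiguation (mod π → mod 2π).**  Classical angle doubling:
   `2·orientation` is a continuous mod-2π field, which is 2D-unwrapped and
   halved.  Doubling is applied to a quality-weighted complex smoothing of
   `exp(2iθ)` (Gaussian, 8 px by default) rather than to raw per-pixel
   angles: fringe crests are bands of near-zero gradient whose orientation
   is noise, and unwrapping the raw doubled field across them seeds large
   spurious half-turn domains.  The half-turn decisions of the smoothed
   field are transferred back to the full-resolution orientation.
3. **Sine–cosine filtering.**  `sin β` and `cos β` are filtered by
   removing their locally highest-frequency detail component (the residual
   of a 3×3 median followed by a unit Gaussian) `n_modes = 3` times, then
   recombined with `atan2`.  Filtering the sine/cosine pair avoids smearing
   across the 0/2π seam and is half-turn equivariant.
4. **Global sign.**  A cosine fringe pattern is even in θ, so β and β+π
   demodulate to conjugate phases; the ambiguity is physical.  The package
   anchors the sign by requiring the demodulated carrier ramp to increase
   along +x; carrier-free inputs keep the ambiguity and warn.  Evaluation
   routines align sign and piston before scoring for the same reason.

### Hilbert spiral transform

For a zero-mean fringe field `f` the quadrature is

    q = Re[ −i · exp(−iβ) · F⁻¹{ SPF · F[f] } ],

with the spiral phase function `SPF(u, v) = (u + iv)/√(u²+v²)` (unit
modulus, DC nulled; Nyquist placed in the negative half for even sizes).
The analytic fringe pattern `f + i q` has the wrapped phase as its angle.
The raster is mirror-padded to twice its size before the FFT and cropped
afterwards to suppress periodic-extension ringing.  Taking the real part
of the complex quadrature is the vortex-demodulation convention: for
locally monochromatic fringes obeying the Bedrosian condition (amplitude
low-pass relative to the carrier) the imaginary remainder is negligible.
Amplitude-detailed objects violating that condition are out of scope.

### Phase unwrapping

The default unwrapper solves the weighted-least-squares Poisson problem of
the wrapped phase gradients with a cosine transform (Neumann boundaries),
then snaps the smooth solution back onto the input modulo 2π
("congruence") and repairs isolated 2π-outlier patches against a 13×13
median of the result.  All corrections are exact 2π multiples, so
rewrapping the output reproduces the input everywhere; on residue-free
inputs the unwrap is exact up to a constant.  The ecosystem's
quality-guided network unwrapper remains available (`method="quality"`),
but on folded-fringe phantoms its branch cuts tend to follow the whole
low-quality cell rim, displacing the entire cell interior by 2π — the
least-squares route confines such errors to the defect itself.

### Window search and direction refinement

The direction chain runs for every plane-fit window w ∈ {3, 5, …, 13};
each window's phase is demodulated and unwrapped and its mean gradient
magnitude recorded.  Direction errors inject phase jumps that raise the
mean gradient, so the window with the minimal value wins (ties to the
smaller window, which preserves resolution).

After window selection the direction map is refined: β is re-derived from
the gradient of the Gaussian-smoothed, non-congruent least-squares unwrap
of the provisional phase and the fringes demodulated again, keeping the
iterate with the smallest mean gradient.  This extends the same
gradient-minimisation principle from a discrete window sweep to the
direction field itself, and is what recovers fringe *folds* — closed
contours where the object's phase gradient locally cancels the carrier and
the fringe direction reverses.  Local orientation estimators cannot see a
fold (cosine fringes look identical under conjugation); the provisional
phase surface can.

### Aberration correction

Instrumental backgrounds (defocus, astigmatism) survive demodulation as a
slowly varying additive phase.  The same structure–texture decomposition
is applied to the unwrapped phase raster; the structure (background) is
discarded, the texture re-centred to zero mean.  The denoising stage is
skipped — an unwrapped phase map has no separable high-frequency noise
term worth splitting off.  Plane removal runs before this correction.

## Synthetic data

The generator emulates a single-shot QPI measurement of an unstressed red
blood cell:

* Height profile `z(x, y)` — the Evans–Skalak biconcave-disc model with
  `D0 = 7.82 µm`, `a0 = 0.0518`, `a1 = 2.0026`, `a2 = −4.491`; zero
  outside the support disc (cell on a flat substrate).  At the centre
  `z = D0·a0 ≈ 0.405 µm`; the rim torus is thicker (≈ 1.28 µm), so the
  5× phase object spans ≈ 6.4 rad.
* Phase object `5·z` sampled on the pixel grid.  The pixel pitch is
  configurable; by default the cell spans one third of the field, making
  the object's phase gradient reach ≈ 0.8 rad/px at the rim.
* Interferogram `I = a + cos(5z + 2πx/T) + 0.05·G`, with carrier period
  `T ∈ [4, ∞]` px along x, a centred Gaussian background (amplitude 1,
  σ = size/3) and seeded standard-normal noise `G`
  (`numpy.random.default_rng`).  The same seed reproduces the raster
  bitwise.
* Ground truth: the additive three-term decomposition, the phase raster,
  and the ideal direction map `β = atan2(∂θ/∂y, ∂θ/∂x) mod 2π` from
  finite differences of the total phase.

What the generator does **not** emulate: partially coherent illumination,
speckle, amplitude objects, parasitic interferences, camera quantisation
and shot noise, field-dependent fringe contrast.  Passing tests therefore
demonstrate the numerical chain on an idealised but adversarial phantom
(strong background, overlapped spectra, folded fringes), not performance
on any particular instrument.

## Numerical choices

* Coordinates: origin at the raster corner, x = column, y = row, 0-based;
  phantom centred on the grid.
* Interior scoring masks exclude a 16-px border and, for closed-fringe
  objects, a 10-px disc at the direction vortex — acknowledged singular
  areas of single-shot demodulation.
* RMS scoring aligns the global sign and piston first; these are exact
  invariances of the problem, not of the implementation.
* `background_std` uses the population convention (ddof = 0) so that it
  equals the RMS of the region about its own mean exactly.
* Degenerate-gradient threshold for orientation validity: 1e-6 of the
  fringe dynamic range.
* All randomness flows through one seeded `default_rng` stream per
  generated raster.

## Known limitations

* **Fringe folds at low carrier.**  When the object's phase gradient
  exceeds the carrier frequency (here for carrier periods T ≳ 30 px),
  fringes fold along closed contours.  A fold misplaced by even one pixel
  in the estimated direction map miscounts one fringe across it, shifting
  an extended region of the unwrapped phase by 2π.  With the *ideal*
  direction map the pipeline recovers the phantom to ≈ 0.04–0.30 rad RMS
  at every carrier period tested (8–150 px); with the *estimated* map the
  recovery is sub-0.12 rad for T ≤ 20 px but degrades to ~1.3–2.9 rad RMS
  in the strongly folded regime (T ∈ {30, 60, 100, 150} on the default
  phantom), where it beats the direction-free variant at some periods and
  loses at others — which fold arcs get captured is effectively chaotic
  with respect to small perturbations of the chain.  This fragility is
  intrinsic to guiding a spiral-transform quadrature with a locally
  estimated direction; the direction-refinement stage recovers thin fold
  slivers but not every extended fold arc.
* The mean-gradient selection criterion is a proxy: differences of a few
  percent in mean gradient can correspond to large RMS differences between
  demodulation basins, so the search can occasionally prefer a smooth but
  sheet-shifted solution.
* Processing time is dominated by the per-window direction chain and the
  refinement passes (~20–60 s for a 512² interferogram on one CPU).

## Problem sizes used in tests

Unit tests run on 64²–256² rasters; the end-to-end acceptance checks use
the 512² phantom at carrier periods {8, 16, 30, 60, 100, 150} px with
noise amplitude 0.05, matching the synthetic study conditions, and the
acceptance script reproduces the same quantities from scratch.
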