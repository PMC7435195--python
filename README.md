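# vhqpi — single-shot quantitative phase imaging by variational decomposition and spiral-transform demodulation

Quantitative phase imaging (QPI) measures the optical path delay a
transparent specimen — a live cell, typically — imprints on a light wave,
by recording a two-beam interferogram

```
I(x, y) = a(x, y) + b(x, y)·cos θ(x, y) + n(x, y)
```

and decoding the phase `θ`.  Off-axis systems separate the fringe term
spectrally and are easy to demodulate but waste space–bandwidth; on-axis
systems need multi-frame phase shifting and lose time resolution.  This
package demodulates a **single** interferogram anywhere between those
regimes, including quasi on-axis recordings whose spectral lobes overlap:

1. **uVID** — unsupervised variational image decomposition: a pluggable
   denoiser (wavelet by default, BM3D when installed) splits off the
   noise; an (accelerated) Chambolle dual projection for the TV-L2 problem
   with fixed `µ = 100`, `τ = 0.25` and a data-driven stopping rule splits
   the rest into a smooth background and zero-mean fringes.
2. **Fringe direction** — local fringe orientation (mod π) from a combined
   gradient/plane-fit estimator with window `w`, disambiguated to a
   direction map β (mod 2π) by angle doubling + 2D unwrapping, smoothed by
   sine–cosine filtering.  The window is chosen automatically by sweeping
   `w ∈ {3, 5, …, 13}` and keeping the demodulated phase with the smallest
   mean gradient; a refinement stage then re-derives β from the
   provisional phase surface.
3. **Hilbert spiral transform** — the quadrature
   `q = Re[−i·e^{−iβ}·F⁻¹{SPF·F[f]}]` with the spiral Fourier multiplier
   `SPF = (u+iv)/√(u²+v²)`; the angle of `f + iq` is the wrapped phase,
   which is unwrapped (congruent least-squares) and plane-corrected.
   An optional post-step removes instrumental aberrations by decomposing
   the unwrapped phase itself and discarding its structure.

A synthetic-data module generates fully ground-truthed test interferograms
— the Evans–Skalak red-blood-cell thickness profile as the phase object,
a straight carrier of period `T`, a Gaussian background and seeded noise —
so every stage is testable without experimental data.  A classical
Fourier-transform demodulator is included as the off-axis reference.

## Worked example

```python
import numpy as np
import vhqpi as v

# a 512x512 interferogram of a red blood cell, carrier period 20 px,
# Gaussian background and 0.05 additive noise, fully seeded
spec = v.SyntheticSpec(size=512, period=20.0, noise_amp=0.05,
                       background="gaussian", seed=1)
truth = v.rbc_phase(512, spec)                      # 5*z, radians
interferogram, model = v.generate_interferogram(spec, truth)

phase, decomposition, search = v.vhqpi(interferogram)

mask = v.interior_mask(phase.shape, border=16, exclude_disk=10)
print("selected window:", search.selected_w)
print("uVID projections:", decomposition.iterations_used)
print("RMS vs ground truth [rad]:", round(v.rms_error(phase, truth, mask=mask), 3))
```

Output:

```
selected window: 13
uVID projections: 118
RMS vs ground truth [rad]: 0.111
```

The recovered phase map matches the 6.4-rad-deep cell profile to about a
tenth of a radian over the interior (border and central direction-vortex
disc excluded); the same phantom demodulated with the *ideal* direction
map differs by less than 0.1 rad RMS, i.e. the direction estimation is
not the accuracy bottleneck at this carrier.

## Command line

```bash
vhqpi simulate --size 512 --period 20 --noise 0.05 --seed 1 \
      --out interferogram.tif --truth truth/
vhqpi run interferogram.tif --out phase.tif --report report.json
vhqpi evaluate phase.tif --reference truth/phase.tif --json metrics.json
```

Subcommands: `simulate`, `decompose`, `direction`, `demodulate`,
`ft-demodulate`, `run`, `evaluate`.  Rasters travel as float32 TIFF
(radians for phase); 8/16-bit PNG input is rescaled to [0, 1].

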