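# Methods

## Model

The FGI filter treats denoising as iterated, locally adaptive averaging.
For a pixel `x_i` with (border-truncated) `n x n` window `W`, the window is
ordered by absolute intensity difference to the centre — the centre first,
ties broken stably by raster index — and the `q` closest pixels enter a
weighted average `x_hat_i = sum w_j x_j / sum w_j`. Two fuzzy degrees drive
the weights.

**Impulsivity.** `ROAD_r(x_i)` is the sum of the `r` smallest absolute
differences between `x_i` and its window neighbours (the centre's
self-distance ranks zeroth and contributes nothing; at truncated borders all
available neighbours are used when fewer than `r` exist). The impulsivity
degree is a ramp: `delta = 0` for `ROAD <= p1`, `1` for `ROAD >= p2`, linear
between. A genuine impulse differs from most of its neighbours, so even its
*smallest* `r` differences are large.

**Similarity.** For the absolute difference `L1` between centre and
neighbour: `mu_high = 1` up to `p3`, ramping to 0 at `4*p3`;
`mu_low = 1 - mu_high`; `mu_moderate` is a trapezoid supported on
`(p3, 4*p3)` with plateau on `[2*p3, 3*p3]`.

**Rules and defuzzification.** Three Mamdani rules (AND = min, OR = max,
NOT = 1-x) map `(delta_i, delta_j, mu)` to truncation levels of three
triangular weight consequents on [0, 1]: "low" supported on `[0, 1-p4]`,
"moderate" on `[1-p4, p4]` with apex 0.5, "high" on `[p4, 1]`. The crisp
weight is the centre of gravity of the union of the truncated consequents.
Because `p4 > 0.5` the three supports have disjoint interiors, so the
aggregate integrates as a sum of per-triangle closed forms — exact and cheap
inside the hot loop. An independent implementation
(`fgict.reference.defuzzify_weight_polygon`) integrates the aggregated
polygon from its breakpoints instead; the two routes agree to ~1e-12 and
both are cross-checked against adaptive quadrature in the tests.

**Iteration.** Each iteration runs two passes per slice: pass A computes the
impulsivity degree of every pixel from the current image; pass B computes
windows, rules, weights and updates. This guarantees every weight reads a
fully defined impulsivity map. `base`/`skip_q` write into a fresh buffer
swapped per iteration; the `chaotic` variants update in place in raster-scan
order — a deterministic, reproducible member of the unordered-update family
that parallel implementations realize, and it must (and does) preserve the
range bound. The engine kernels are numba-compiled scalar loops (the
stable partial sort and the per-neighbour rule evaluation do not map onto
whole-array primitives); a plain-Python per-pixel reference implementation
with no shared internals serves as the verification oracle, and the engine
must reproduce it to 1e-12 on random images.

**Update arithmetic.** The average is evaluated in the difference form
`x_hat = x_i + sum(w_j (x_j - x_i)) / sum(w_j)`, which makes constant
windows exact fixed points in floating point. A zero weight sum (impossible
under the rules, which always activate at least one consequent, but kept as
a guard) leaves the pixel unchanged. Arithmetic is float64 by default with
a float32 switch; the two agree to ~1e-6 per iteration and the choice has
no visible effect on image quality.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n` | 3 | window side (odd); windows are 2-D within each slice |
| `q` | 9 | pixels averaged: the full 3x3 window, centre included (`skip_q` drops the centre from the sums; at borders `q` caps at the truncated window size) |
| `r` | 4 | ROAD order, the classical choice for 3x3 windows |
| `p1, p2` | 40/255, 220/255 | impulsivity ramp, on the working intensity scale |
| `p3` | 1.96/255 | similarity scale for attenuation-coefficient / [0,1] data |
| `p4` | 0.9 | weight-consequent shape: high weights live in [0.9, 1], low in [0, 0.1] |
| `max_iterations` | 15 | fixed iteration count (11 for the Poisson benchmark row); metric stops (`max_psnr`/`max_ssim`) return the best logged iterate instead |

All thresholds are expressed on the [0, 1] working scale; values quoted on
the 8-bit scale divide by 255. `p1/p2` are scan-scale-dependent and not
fixed by theory: `scripts/calibrate_p1p2.py` selects them by grid search
maximizing filtered SSIM of a mixed-noise phantom. The selection surface is
flat — SSIM varies by only ~0.02 across p1 in [10/255, 80/255] x p2 in
[120/255, 240/255] — so the shipped 40/255, 220/255 sit on a plateau; any
value that keeps Gaussian-noise ROAD below `p1` and impulse ROAD above `p2`
behaves equivalently. Under pure Gaussian noise at the benchmark variances
the ROAD never reaches `p1`, so `delta = 0` and the thresholds are inert.

## Units and I/O

Volumes are (slice, row, col), 0-based. CT data in Hounsfield Units converts
to linear attenuation via `mu = mu_water (1 + HU/1000)`, using the per-scan
water coefficient (default 0.0192 mm^-1 for phantom-derived volumes, since
no standard public DICOM tag carries it). HU below -1000 (below air) clamp
to zero attenuation: the conversion is exactly invertible on the physical
range and many-to-one below it. Raw binary volumes are little-endian
float64, C-order, no header, with a YAML sidecar holding shape and
calibration — a repository convention, documented rather than assumed
portable. PGM export quantizes [0, max] onto {0..255} with
round-half-away-from-zero.

## Synthetic data

The 3-D Shepp-Logan phantom uses the classical ten-ellipsoid head geometry
with the standard "modified" gray levels (outer shell 1.0, brain interior
0.2, ventricle-like ellipsoids 0.0, small features 0.3), which lie natively
in [0, 1]; the original low-contrast density set sums above 1 inside the
skull and would saturate under a bounded image model, so it is not used.
Intensities are additive over ellipsoids and clipped to [0, 1] as a
safeguard. Slices beyond the outer ellipsoid's z-extent (|z| > 0.81) are
exact zeros; a slice is "air-only" when every reference voxel is below 1e-6,
and such slices are excluded from volume-mean metrics. The default
benchmark size is 256 x 256 x 64 (12 air cap slices).

Noise models (all driven by one seed; identical specs give bit-identical
volumes): additive Gaussian with stated variance, clipped to [0, 1] —
clipping is required by the bounded image model and roughly halves the noise
power in the zero-valued air background, which is why the noisy-phantom PSNR
exceeds the unclipped bound `10 log10(1/sigma^2)` by ~2 dB; fixed-value
salt-and-pepper replacing a `density` fraction (default 0.10) of voxels by 0
or 1 equiprobably; their composition (Gaussian first); and Poisson with
`peak` photons (default 1000) at intensity 1. The phantom emulates the
geometry/statistics side of the benchmark only: it has no scanner blur, no
reconstruction-correlated noise, no anatomy, and its noise is i.i.d. —
passing tests demonstrate the filter's behaviour under the stated noise
models, not clinical performance.

## Metrics

PSNR defaults to the standard `10 log10(MAX^2 / MSE)` (identical inputs
report +inf). A `paper_eq11` variant dividing `MAX^2` by the *root* of the
MSE is kept behind a flag because that form appears in print in this
literature; it is non-standard and inconsistent with the magnitudes the
standard form reproduces (the noisy-phantom rows match the standard form to
within 0.05 dB), so it is not the default. SSIM follows Wang et al.
(Gaussian 11x11 window, sigma 1.5, K1 = 0.01, K2 = 0.03, unit exponents,
data range 1 after normalization), delegated to scikit-image for unit
exponents, with an in-package path for general luminance/contrast/structure
exponents. Volume scores normalize both volumes by the reference maximum
(preserving relative values), score each non-air slice, and average. ROI
standard deviation (population SD over a per-slice rectangle) serves as the
no-reference noise measure for real scans.

## Benchmark behaviour and known limitations

At the default benchmark scale the filter reproduces the intended qualitative
profile: impulses are removed almost completely (10% salt-and-pepper:
SSIM 0.13 -> 0.93 after 15 iterations), mixed noise is handled nearly as
well, and heavy Gaussian noise (variance 0.005) gains ~0.28 SSIM. The
filter restores structure rather than gray values: PSNR routinely *drops*
under prolonged iteration while SSIM rises, because dissimilar neighbours
retain a floor weight of `(1-p4)/3 ~ 0.033` and thin high-contrast
structures therefore erode slowly — on the 256^2 phantom, essentially all
of the filtered-volume MSE is concentrated on the few-pixel-wide skull
shell. This erosion is resolution-dependent: the same experiment at 512^2
in-plane leaves the unfiltered metrics unchanged (to 3 decimals) but raises
the filtered PSNR by ~2.5 dB, since structures are wider relative to the
3x3 window. Mean-SSIM for mild Gaussian noise consequently peaks after ~5
iterations at this scale; running the full 15-iteration schedule trades
PSNR for flatness. The metric stop criteria exist precisely for this:
with a reference volume, `stop="max_ssim"` returns the best iterate.

Other limitations: windows are strictly 2-D (no through-slice support);
the chaotic variant is a deterministic stand-in for genuinely unordered
parallel updates, so bit-exact agreement with a parallel run is not
expected; Poisson and impulsive benchmark strengths (peak, density) are
package conventions, chosen once and documented above rather than fitted;
and complexity is O(pixels * n^2 log n^2) per iteration — a 256x256x64
volume filters at roughly 1.5 s per iteration per volume on one CPU.
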