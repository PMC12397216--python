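# Methods

## The model

`devatlas` operates on a *template chain*: population-averaged brain
templates at a handful of postnatal anchor ages (P4, P7, P14, P21, P28,
P56 by default), all resampled onto one standardized isotropic grid
(20 µm by default), and linked by one dense displacement field per
adjacent anchor pair. The stored field for a pair (older, younger) is the
*backward* transform: indexed on the younger grid, it gives for each
voxel `x` the offset `U(x)` such that resampling reads the older volume
at `x + U(x)`. This is a pull field; its dual point map `x ↦ x + U(x)`
carries coordinates from the younger space into the older one.

Everything else is derived:

- **Forward transforms** come from numerical inversion of the backward
  field: the fixed-point iteration `V_{k+1}(x) = −U(x + V_k(x))`,
  `V₀ = −U`, stopped when the largest per-voxel update drops below a
  tolerance (default 0.05 voxel = 1 µm at 20 µm, well under the
  resolution of the landmark statistics) or after 50 sweeps. The
  returned field carries the residual `max |U(x + V(x)) + V(x)|` as a
  quality metric; a residual above 10× tolerance attaches a warning
  rather than failing, because measured fields are never exactly
  invertible near domain boundaries. The iteration is a contraction only
  where the displacement Jacobian is below 1 in norm — fields that fold
  (e.g. a self-coupled sinusoid with amplitude × frequency ≥ 1) have no
  inverse and are reported through the residual, not silently accepted.
- **Multi-step routes** between non-adjacent ages are compositions:
  `K(x) = W(x) + U(x + W(x))`, with the outer field evaluated by
  trilinear, edge-clamped interpolation. Composition is exact for the
  affine part of the fields and accurate to trilinear interpolation
  error otherwise (associativity holds to the same order).
- **Fractional-age transforms** scale the displacement linearly:
  carrying data from an anchor partway into a bracket uses the pair's
  field multiplied by the age fraction, reinterpreted on the
  intermediate grid (well defined because all spaces in the chain share
  one grid). Linear scaling is exact for translations and the affine
  part of a deformation and is a first-order stand-in for geodesic
  (stationary-velocity) interpolation, which is deliberately out of
  scope. Both the route builder and the template synthesizer use this
  one rule, so fractional steps appear only at non-anchor endpoints of
  a route.

An **intermediate-age model** at age `t` inside bracket `(y, o)` with
fraction `f = (t − y)/(o − y)` is

    model = (1 − f) · warp(T_y, f · F_{y→o}) + f · warp(T_o, (1 − f) · B_{o→y})

where `B` is the stored backward field and `F` its inverse: both
bracketing templates are carried partway into the intermediate space and
averaged with temporal-proximity weights (the nearer template weighs
more, e.g. P7 gets 6/7 against P14's 1/7 for a P8 model). Only the two
bracketing anchors ever contribute. At an anchor the stored template is
returned verbatim. Enumerating every integer age over the default span
gives 6 anchor + 47 interpolated = 53 volumes; the compiled series can
be split into contiguous subsets (conventionally P4–20 / P21–37 /
P38–56) to keep file sizes manageable.

**Segmentations** travel only *down* in age from the adult (oldest)
anchor, through stored backward fields alone, with nearest-neighbour
sampling. This keeps label boundaries independent of the numerically
inverted forward fields, and guarantees (testably, as an exact set
assertion) that no label id is ever invented.

## Coordinate conventions and numerics

- Coordinates are 0-based continuous voxel indices, axis order
  anterior→posterior, superior→inferior, left→right. Physical units
  (µm in memory, mm on disk per the NIfTI standard) enter only at I/O
  and distance reporting.
- Displacements are stored in voxel units of the shared grid, making
  composition and temporal scaling spacing-free.
- Off-grid displacement lookups: trilinear with edge clamping (no
  extrapolation). Off-grid volume samples: trilinear with zero fill
  beyond the grid (`grid-constant`), matching zero-padded backgrounds;
  intensity warps therefore taper rather than cut at the boundary.
- Nearest-neighbour rounding ties (coordinate exactly at .5) round
  toward the smaller index, everywhere (label warps, section placement,
  region lookup).
- Same-age translations return their input bit-identically; no
  resampling is performed when none is needed.

## Landmark validation statistics

A panel of R raters records named landmarks in each template age; the
automated transform ("matrix") places the same landmarks by warping
adult coordinates. A subject's error at a landmark is its Euclidean
distance, in µm, to the componentwise median of the other raters'
coordinates; the median is used for robustness against occasional gross
outliers (e.g. transcription errors). Because each rater is scored
against the R−1 others, the matrix is scored against the median of every
size-(R−1) rater subset, averaged over subsets — with R = 4, every
unique combination of 3 raters. A landmark not identified by all raters
at an age is excluded from that age's statistics. The per-age
matrix-vs-average-rater comparison is a two-tailed t test, *paired* over
landmarks by default since both subjects are scored on the same landmark
set; an unpaired Welch variant is exposed for the alternative reading.
Zero-variance differences report t = 0, p = 1 with a degenerate flag
rather than NaN. "Median coordinate" is taken per axis; a geometric
(spatial) median is a defensible alternative and is noted, not
implemented. Error heatmaps assign every voxel the error of its nearest
assessed landmark (ties toward the smaller landmark index).

## Reconstruction and quantification

Registered 2D sections are rasterized at their anchored voxel positions
(orthogonal plane + slice index, or a full affine pixel→voxel map);
colliding pixels average. Gaps are filled by inverse-distance-weighted
K nearest neighbours in unrestricted 3D (not per-column along the
sectioning axis): each unknown voxel gets `Σ wᵢvᵢ/Σwᵢ` over its k nearest
known voxels, `wᵢ = 1/dᵢ`. Neither k nor the weight exponent is a
standard in the field; the defaults are k = 4 and exponent 1, both
exposed. On integer grids equidistant neighbours are common, so ties at
the k-th distance break toward the lexicographically smaller voxel
index, making the fill deterministic. Known voxels are never modified,
so the fill is idempotent and bounded by the known value range. Region
"load" is the area fraction of feature-positive pixels per atlas region;
excluded regions (conventionally white-matter tracts and the ventricular
system) are a configuration list of label ids, never hard-coded names.
Expression time series interpolate sparse-age data volumes with the same
bracketing-and-linear-weights rule as templates, after translating both
bracketing volumes into the target age's space.

## Preprocessing operators

Block-mean down-sampling (labels: block mode, ties toward the smaller
id); posterior zero-padding of the AP axis (the standard adult template
is 45 voxels shorter rostrocaudally than the developmental templates);
linear resampling of anisotropic acquisitions (20 × 20 × 50 µm serial
stacks) to isotropic voxels at voxel-center alignment — exact on linear
ramps wherever the output sample lies within the input span; integer
origin alignment with zero fill; 3D CLAHE with per-tile clipped
histogram equalization and trilinear blending between tile mappings
(clip limit expressed as a multiple of the uniform bin height; a tile
larger than the volume falls back to one global tile with a warning);
and multiplicative matching of foreground (> 0) means across volumes.
Tilt removal is deliberately absent: it is a manual, per-volume
judgement, and inputs are assumed de-tilted. All operators are
deterministic.

## What the synthetic fixtures emulate — and what they do not

The phantom generator produces nested-ellipsoid "brains" whose semi-axes
grow affinely with age, optionally Gaussian-smoothed (band-limited) and
with seeded noise. Analytic warp fields (translation, centred scaling,
sinusoidal shear) have closed-form inverses or documented invertibility
bounds. Simulated raters are truth plus isotropic Gaussian noise (a
Student-t option exercises the median's robustness claim). These
fixtures give exact oracles for every operator, but they do **not**
carry real anatomy: no tissue texture, no inter-template acquisition
differences (such as apparent shrinking between independently sourced
adult and developmental templates), no registration error beyond the
analytic fields themselves. Passing tests therefore demonstrate the
correctness of the transformation machinery, not the anatomical accuracy
of any particular registration — the latter requires measured
deformation fields and expert rater data, which are inputs to this
package, not products of it.

## Problem sizes

The test suite and the acceptance script run the field-algebra oracles
on 64³ grids, chain/translation recovery on 32³ chains over the full
P4–P56 span, KNN reconstruction oracles on 12³–24³ grids, and the rater
noise study at 200 replicates per noise level — sizes chosen so every
oracle remains exhaustively checkable while exercising the same code
paths as production-scale volumes.

## Known limitations

- Linear displacement scaling is not geodesic interpolation; strongly
  non-affine deformations accumulate first-order error at fractional
  ages.
- Inversion assumes diffeomorphic-scale fields; folding is detected via
  the residual, not prevented.
- The runtime grid is isotropic; anisotropy is handled only by the
  preprocessing resampler.
- No registration is estimated anywhere: displacement fields are inputs
  (or synthetic), and no smoothing or regularization is applied to them.
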