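# devatlas

Translate coordinates and image volumes across postnatal ages of a 4D
developmental mouse brain atlas.

Three-dimensional mouse brain atlases are overwhelmingly adult-only, and
the few developmental ones cover a handful of discrete ages with no
spatial correspondence between them. When templates at anchor ages
(P4, P7, P14, P21, P28, P56) have been co-registered pairwise, the
resulting displacement fields define a *traversable* time axis: data
registered at any age can be carried to any other age, and model
volumes can be synthesized for every postnatal day in between. This
package implements that machinery for researchers integrating
developmental neuroscience data — image volumes, segmentations, point
annotations, and sparse section data — across ages.

## What it does

Given a **template chain** — anchor-age templates on one standardized
isotropic grid plus one *backward* displacement field per adjacent pair
(target = younger age, source = older age; a pull field `U` such that
resampling reads the older volume at `x + U(x)`) — the package provides:

- **Field algebra** (`devatlas.fields`): warp volumes (trilinear, or
  nearest-neighbour for labels), map points by the pull-field duality,
  invert fields by fixed-point iteration
  `V_{k+1}(x) = −U(x + V_k(x))`, compose fields
  `K(x) = W(x) + U(x + W(x))`, and scale displacements linearly for
  fractional ages.
- **Temporal translation** (`devatlas.translator`): route any
  source→target age pair through the intervening anchors; synthesize an
  intermediate-age model at age `t` in bracket `(y, o)`,
  `f = (t−y)/(o−y)`, as

      model = (1−f)·warp(T_y, f·F_{y→o}) + f·warp(T_o, (1−f)·B_{o→y})

  (the nearer template weighs more); transform segmentations *down*
  from the adult anchor only, so label sets are provably preserved;
  compile one model per integer day (6 templates + 47 interpolated =
  53 volumes over P4–P56, splittable into P4–20 / P21–37 / P38–56).
- **Preprocessing** (`devatlas.preprocessing`): block down-sampling,
  posterior padding, anisotropic→isotropic resampling
  (20 × 20 × 50 µm → 20 µm), origin alignment, 3D CLAHE, foreground
  mean-intensity matching.
- **Landmark validation** (`devatlas.landmarks`): per-rater and
  automated-transform errors against the componentwise median of the
  other raters (the transform is scored against every (R−1)-rater
  subset, averaged), paired t tests per age, nearest-landmark error
  heatmaps, and per-region error grouping.
- **Reconstruction & quantification** (`devatlas.reconstruction`):
  place registered 2D sections into an empty atlas volume and fill the
  gaps with inverse-distance-weighted K nearest neighbours; per-region
  feature load (area fraction) with configurable exclusions.
- **Synthetic fixtures** (`devatlas.synthetic`): growth-law ellipsoid
  phantoms, analytic warp fields with closed-form inverses, simulated
  rater panels, sparse section stacks — so everything above is testable
  against exact oracles with no downloads.
- **I/O and CLI** (`devatlas.io`, `devatlas.cli`): NIfTI volumes and
  4D displacement fields with JSON sidecars, landmark CSVs, ITK-SNAP
  label tables, a JSON chain manifest, and a `devatlas` command with
  `translate`, `interpolate-template`, `compile-4d`, `invert-field`,
  `compose-fields`, `preprocess`, `validate-landmarks`, `reconstruct`,
  `quantify`, and `simulate` subcommands.

See `docs/methods.md` for conventions, numerics, and limitations.

## Worked example

Build a synthetic two-anchor chain whose backward field is a pure
translation, then move a point and a model across ages:

```python
import numpy as np
import devatlas as da
from devatlas.synthetic import make_analytic_field, make_phantom, PhantomSpec

shape = (32, 32, 32)
t4, _ = make_phantom(PhantomSpec(age=4, shape=shape))
t56 = da.IntensityVolume(space=da.make_space(56, shape),
                         values=np.roll(t4.values, 3, axis=0))
backward = make_analytic_field(          # pulls P56 data into P4 space
    "translation", {"offset": (3.0, 0.0, 0.0)},
    source=t56.space, target=t4.space)
chain = da.TemplateChain(anchor_ages=(4, 56),
                         backward_fields={(56, 4): backward},
                         templates={4: t4, 56: t56})

pts = da.PointSet(space=chain.space(4), points=np.array([[10., 12., 14.]]))
print(da.translate_points(pts, 4, 56, chain).points)
# [[13. 12. 14.]]            <- +3 voxels AP: the P56 correspondence

model = da.make_intermediate_template(30, chain)
plan = da.plan_interpolation(30, chain)
print(round(plan.weight_younger, 3), round(plan.weight_older, 3))
# 0.5 0.5                    <- P30 sits at the temporal midpoint
```

The printed point is the P4 coordinate carried to P56 (the exact inverse
of the stored translation), and the weights show how the P30 model mixes
the warped P4 and P56 templates.

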