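"""Template-conditioning operators applied before registration.

Covers the standardization pipeline for heterogeneous source templates:
block down-sampling to the 20 µm working resolution, posterior zero-padding
to equalize the rostrocaudal extent, resampling anisotropic acquisitions
(20 × 20 × 50 µm serial-section stacks) to isotropic voxels, integer-voxel
origin alignment, 3D CLAHE contrast enhancement, and multiplicative
matching of foreground mean intensities across templates.

Tilt removal is deliberately absent: it is a manual, per-volume judgement
and inputs are assumed already de-tilted. All operators are deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.stats import mode as _mode

from .core import AtlasSpace, IntensityVolume, LabelVolume

__all__ = [
    "downsample",
    "pad_posterior",
    "resample_to_isotropic",
    "align_origin",
    "clahe3d",
    "match_mean_intensity",
]


def downsample(vol: IntensityVolume | LabelVolume, factor: int):
    """Integer block down-sampling: mean pooling for intensities, block
    mode for labels (ties broken toward the smaller id). Trailing voxels on
    axes not divisible by ``factor`` are dropped. Spacing is multiplied by
    ``factor``."""
    factor = int(factor)
    if factor < 2:
        raise ValueError(f"downsample factor must be >= 2, got {factor}")
    is_labels = isinstance(vol, LabelVolume)
    data = vol.labels if is_labels else vol.values
    new_shape = tuple(s // factor for s in data.shape)
    if any(s < 1 for s in new_shape):
        raise ValueError(f"factor {factor} larger than volume extent")
    crop = data[: new_shape[0] * factor,
                : new_shape[1] * factor,
                : new_shape[2] * factor]
    blocks = crop.reshape(new_shape[0], factor, new_shape[1], factor,
                          new_shape[2], factor)
    blocks = blocks.transpose(0, 2, 4, 1, 3, 5).reshape(*new_shape, -1)
    space = AtlasSpace(
        age=vol.space.age, shape=new_shape,
        spacing=vol.space.spacing * factor,
        origin=tuple(o / factor for o in vol.space.origin),
    )
    if is_labels:
        # scipy's mode returns the smallest value among ties
        pooled = _mode(blocks, axis=-1, keepdims=False).mode
        return LabelVolume(space=space, labels=pooled.astype(vol.labels.dtype),
                           table=vol.table)
    return IntensityVolume(space=space,
                           values=blocks.astype(float).mean(axis=-1))


def pad_posterior(vol: IntensityVolume | LabelVolume, n_voxels: int):
    """Append ``n_voxels`` zero slices at the posterior (high-index) end of
    the AP axis. The origin is unchanged; total intensity is conserved."""
    n = int(n_voxels)
    if n < 0:
        raise ValueError(f"pad count must be >= 0, got {n}")
    is_labels = isinstance(vol, LabelVolume)
    data = vol.labels if is_labels else vol.values
    padded = np.pad(data, ((0, n), (0, 0), (0, 0)))
    space = AtlasSpace(age=vol.space.age,
                       shape=(vol.space.shape[0] + n,) + vol.space.shape[1:],
                       spacing=vol.space.spacing, origin=vol.space.origin)
    if is_labels:
        return LabelVolume(space=space, labels=padded, table=vol.table)
    return IntensityVolume(space=space, values=padded)


def resample_to_isotropic(
    vol: IntensityVolume,
    in_spacing: tuple[float, float, float],
    out_spacing: float,
) -> IntensityVolume:
    """Linearly resample an anisotropic acquisition to isotropic voxels.

    Output extent per axis is ``round(extent_phys / out_spacing)``; samples
    are taken at voxel centres with edge clamping, so a linear ramp is
    reproduced exactly wherever the output centre lies within the input
    centre span.
    """
    in_sp = tuple(float(s) for s in in_spacing)
    if any(s <= 0 for s in in_sp) or not (float(out_spacing) > 0):
        raise ValueError("spacings must be positive")
    out_sp = float(out_spacing)
    if in_sp == (out_sp, out_sp, out_sp):
        return IntensityVolume(space=vol.space, values=vol.values.copy())
    shape = vol.values.shape
    out_shape = tuple(int(round(n * s / out_sp)) for n, s in zip(shape, in_sp))
    axes = [
        ((np.arange(n_out) + 0.5) * out_sp / s_in) - 0.5
        for n_out, s_in in zip(out_shape, in_sp)
    ]
    coords = np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)
    values = map_coordinates(np.asarray(vol.values, dtype=float), coords,
                             order=1, mode="nearest")
    space = AtlasSpace(age=vol.space.age, shape=out_shape, spacing=out_sp,
                       origin=vol.space.origin)
    return IntensityVolume(space=space, values=values)


def align_origin(
    vol: IntensityVolume | LabelVolume,
    origin_voxel: tuple[int, int, int],
    target_origin_voxel: tuple[int, int, int],
):
    """Integer-voxel translation bringing ``origin_voxel`` onto
    ``target_origin_voxel``, with zero fill; content shifted past an edge is
    clipped. Origin metadata is updated to the target."""
    shift = tuple(int(t) - int(o)
                  for o, t in zip(origin_voxel, target_origin_voxel))
    for name, ov in (("origin", origin_voxel), ("target", target_origin_voxel)):
        for c, s in zip(ov, vol.space.shape):
            if not (0 <= int(c) < s):
                raise ValueError(f"{name} voxel {ov} outside grid {vol.space.shape}")
    is_labels = isinstance(vol, LabelVolume)
    data = vol.labels if is_labels else vol.values
    out = np.zeros_like(data)
    src = [slice(max(0, -d), min(s, s - d)) for d, s in zip(shift, data.shape)]
    dst = [slice(max(0, d), min(s, s + d)) for d, s in zip(shift, data.shape)]
    out[tuple(dst)] = data[tuple(src)]
    space = AtlasSpace(age=vol.space.age, shape=vol.space.shape,
                       spacing=vol.space.spacing,
                       origin=tuple(float(t) for t in target_origin_voxel))
    if is_labels:
        return LabelVolume(space=space, labels=out, table=vol.table)
    return IntensityVolume(space=space, values=out)


def _clahe_tile_mapping(bins: np.ndarray, nbins: int, clip_limit: float,
                        vmin: float, vmax: float) -> np.ndarray:
    """Clipped-histogram equalization mapping for one tile: bin index →
    output intensity in [vmin, vmax]."""
    hist = np.bincount(bins.ravel(), minlength=nbins).astype(float)
    n = hist.sum()
    clip = clip_limit * n / nbins  # clip limit in multiples of uniform height
    excess = np.maximum(hist - clip, 0.0).sum()
    hist = np.minimum(hist, clip) + excess / nbins
    cdf = np.cumsum(hist) / n
    return vmin + cdf * (vmax - vmin)


def clahe3d(
    vol: IntensityVolume,
    clip_limit: float = 4.0,
    tile_shape: tuple[int, int, int] = (8, 8, 8),
    nbins: int = 256,
) -> IntensityVolume:
    """Contrast-limited adaptive histogram equalization in 3D.

    The volume is partitioned into tiles of ``tile_shape`` voxels; each tile
    gets an equalization mapping from its clipped histogram (``clip_limit``
    expressed as a multiple of the uniform bin height), and every voxel is
    mapped by trilinear blending of the mappings of its neighbouring tile
    centres. Output stays within the input intensity range. A tile larger
    than the volume falls back to a single global tile with a warning.
    """
    if clip_limit <= 0 or any(t < 1 for t in tile_shape):
        raise ValueError("clip limit and tile extents must be positive")
    data = np.asarray(vol.values, dtype=float)
    vmin, vmax = float(data.min()), float(data.max())
    if vmax == vmin:
        return IntensityVolume(space=vol.space, values=data.copy())
    tile_shape = tuple(int(t) for t in tile_shape)
    if any(t > s for t, s in zip(tile_shape, data.shape)):
        warnings.warn(
            f"tile {tile_shape} exceeds volume {data.shape}; "
            "falling back to a single global tile", RuntimeWarning,
        )
        tile_shape = data.shape

    nbins = int(nbins)
    bins = np.minimum(((data - vmin) / (vmax - vmin) * nbins).astype(int),
                      nbins - 1)
    n_tiles = tuple(int(np.ceil(s / t)) for s, t in zip(data.shape, tile_shape))
    mappings = np.empty(n_tiles + (nbins,), dtype=float)
    for i in range(n_tiles[0]):
        for j in range(n_tiles[1]):
            for k in range(n_tiles[2]):
                sl = tuple(slice(idx * t, min((idx + 1) * t, s))
                           for idx, t, s in zip((i, j, k), tile_shape,
                                                data.shape))
                mappings[i, j, k] = _clahe_tile_mapping(
                    bins[sl], nbins, clip_limit, vmin, vmax)

    # fractional tile-centre coordinate of every voxel, clamped
    grid = np.indices(data.shape, dtype=float)
    tc = [np.clip((grid[a] - (tile_shape[a] - 1) / 2.0) / tile_shape[a],
                  0.0, n_tiles[a] - 1.0) for a in range(3)]
    lo = [np.floor(t).astype(int) for t in tc]
    hi = [np.minimum(l + 1, n - 1) for l, n in zip(lo, n_tiles)]
    w = [t - l for t, l in zip(tc, lo)]

    out = np.zeros_like(data)
    for ci in (0, 1):
        for cj in (0, 1):
            for ck in (0, 1):
                ti = hi[0] if ci else lo[0]
                tj = hi[1] if cj else lo[1]
                tk = hi[2] if ck else lo[2]
                weight = ((w[0] if ci else 1 - w[0])
                          * (w[1] if cj else 1 - w[1])
                          * (w[2] if ck else 1 - w[2]))
                out += weight * mappings[ti, tj, tk, bins]
    return IntensityVolume(space=vol.space, values=out)


def match_mean_intensity(vols: list[IntensityVolume]) -> list[IntensityVolume]:
    """Multiplicatively rescale each volume so its foreground mean (voxels
    strictly > 0; backgrounds are zero-padded) equals the grand mean of the
    foreground means. Zero voxels stay zero."""
    means = []
    for i, v in enumerate(vols):
        fg = v.values[v.values > 0]
        if fg.size == 0:
            raise ValueError(f"volume {i} has no positive foreground voxels")
        means.append(float(fg.mean()))
    grand = float(np.mean(means))
    return [
        IntensityVolume(space=v.space, values=v.values * (grand / m))
        for v, m in zip(vols, means)
    ]
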