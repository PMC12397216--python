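"""Displacement-field algebra: warp, map, invert, compose, scale.

All fields are pull fields (see :mod:`devatlas.core`). Off-grid displacement
lookups use trilinear interpolation with edge clamping; off-grid *volume*
samples outside the source domain read as 0 (the padded volumes used in
practice are background-0 outside the brain).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import map_coordinates

from .core import (
    AtlasSpace,
    DisplacementField,
    IntensityVolume,
    LabelVolume,
    PointSet,
    SpaceMismatchError,
)

__all__ = [
    "warp_volume",
    "map_points",
    "invert_field",
    "compose_fields",
    "scale_field",
    "zero_field",
    "round_half_down",
]


def round_half_down(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties (exact .5) toward the smaller index.

    Deterministic tie rule for nearest-neighbour label sampling.
    """
    return np.ceil(np.asarray(x) - 0.5).astype(np.int64)


def zero_field(source: AtlasSpace, target: AtlasSpace) -> DisplacementField:
    """The identity pull field on ``target``'s grid."""
    return DisplacementField(
        source=source,
        target=target,
        displacement=np.zeros(target.shape + (3,), dtype=float),
    )


def _interp_displacement_at(disp: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Trilinear, edge-clamped evaluation of a field at (N, 3) points."""
    pts = np.asarray(points, dtype=float)
    coords = pts.T  # (3, N)
    out = np.empty_like(pts)
    for c in range(3):
        out[:, c] = map_coordinates(disp[..., c], coords, order=1, mode="nearest")
    return out


def _interp_displacement_grid(disp: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Edge-clamped trilinear sampling of a field at a (3, X, Y, Z) coordinate
    grid; returns (X, Y, Z, 3)."""
    out = np.empty(coords.shape[1:] + (3,), dtype=float)
    for c in range(3):
        out[..., c] = map_coordinates(disp[..., c], coords, order=1, mode="nearest")
    return out


def _grid(shape: tuple[int, int, int]) -> np.ndarray:
    return np.indices(shape, dtype=float)


def _check_space(vol_space: AtlasSpace, field_space: AtlasSpace, what: str) -> None:
    if vol_space.shape != field_space.shape or vol_space.age != field_space.age:
        raise SpaceMismatchError(
            f"{what}: volume/point space (age P{vol_space.age}, shape "
            f"{vol_space.shape}) does not match field space (age "
            f"P{field_space.age}, shape {field_space.shape})"
        )


def warp_volume(
    vol: IntensityVolume | LabelVolume,
    field: DisplacementField,
    mode: str | None = None,
) -> IntensityVolume | LabelVolume:
    """Resample ``vol`` (in ``field.source`` space) onto ``field.target``.

    ``mode`` is ``"linear"`` (default for intensities) or ``"nearest"``
    (required for labels). Samples that fall outside the source domain
    become 0 (background). Nearest mode can only emit label values present
    in the input.
    """
    is_labels = isinstance(vol, LabelVolume)
    if mode is None:
        mode = "nearest" if is_labels else "linear"
    if is_labels and mode != "nearest":
        raise ValueError("label volumes must be warped with mode='nearest'")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_space(vol.space, field.source, "warp_volume")

    coords = _grid(field.target.shape) + np.moveaxis(field.displacement, -1, 0)

    if is_labels:
        idx = round_half_down(coords)
        shape = np.asarray(vol.labels.shape).reshape(3, 1, 1, 1)
        inside = np.all((idx >= 0) & (idx < shape), axis=0)
        out = np.zeros(field.target.shape, dtype=vol.labels.dtype)
        ii = tuple(np.clip(idx[c], 0, vol.labels.shape[c] - 1) for c in range(3))
        out[inside] = vol.labels[ii[0][inside], ii[1][inside], ii[2][inside]]
        return LabelVolume(space=field.target, labels=out, table=vol.table)

    if mode == "nearest":
        idx = round_half_down(coords)
        shape = np.asarray(vol.values.shape).reshape(3, 1, 1, 1)
        inside = np.all((idx >= 0) & (idx < shape), axis=0)
        out = np.zeros(field.target.shape, dtype=float)
        ii = tuple(np.clip(idx[c], 0, vol.values.shape[c] - 1) for c in range(3))
        out[inside] = vol.values[ii[0][inside], ii[1][inside], ii[2][inside]]
        return IntensityVolume(space=field.target, values=out)

    values = map_coordinates(
        np.asarray(vol.values, dtype=float), coords, order=1,
        mode="grid-constant", cval=0.0,
    )
    return IntensityVolume(space=field.target, values=values)


def map_points(points: PointSet, field: DisplacementField) -> PointSet:
    """Map points from ``field.target`` space into ``field.source`` space.

    Uses the pull field's dual point map ``p ↦ p + U(p)`` with trilinear,
    edge-clamped interpolation of ``U``. Out-of-domain results are flagged
    by :meth:`PointSet.out_of_domain`, never dropped.
    """
    _check_space(points.space, field.target, "map_points")
    shifted = points.points + _interp_displacement_at(field.displacement,
                                                      points.points)
    return PointSet(space=field.source, points=shifted)


def invert_field(
    field: DisplacementField, tol: float = 0.05, max_iter: int = 50
) -> DisplacementField:
    """Numerically invert a displacement field (swap source and target).

    Fixed-point iteration ``V_{k+1}(x) = -U(x + V_k(x))`` starting from
    ``V_0 = -U``, stopping when the max per-voxel update drops below ``tol``
    voxels or after ``max_iter`` sweeps. The returned field's metadata holds
    ``inverse_residual`` = max ``|U(x + V(x)) + V(x)|``; a residual above
    ``10 * tol`` attaches a warning flag rather than failing — real fields
    are never exactly invertible at domain boundaries.

    The default ``tol`` of 0.05 voxel is 1 µm on the 20 µm standard grid,
    well below the resolution of the landmark validation statistic.
    """
    U = field.displacement
    coords0 = _grid(field.target.shape)
    V = -U.copy()
    for _ in range(max_iter):
        coords = coords0 + np.moveaxis(V, -1, 0)
        U_at = _interp_displacement_grid(U, coords)
        V_new = -U_at
        step = float(np.max(np.abs(V_new - V)))
        V = V_new
        if step < tol:
            break
    coords = coords0 + np.moveaxis(V, -1, 0)
    residual = float(np.max(np.abs(_interp_displacement_grid(U, coords) + V)))
    meta = {"inverse_residual": residual, "inverse_tol": tol}
    if residual > 10 * tol:
        meta["inverse_warning"] = (
            f"inversion residual {residual:.3g} voxels exceeds 10×tol"
        )
        warnings.warn(meta["inverse_warning"], RuntimeWarning, stacklevel=2)
    return DisplacementField(
        source=field.target, target=field.source, displacement=V, metadata=meta
    )


def compose_fields(
    outer: DisplacementField, inner: DisplacementField
) -> DisplacementField:
    """Compose two pull fields into one.

    ``inner`` pulls from its source into the final target grid; ``outer``
    pulls from the overall source into ``inner.source``'s space. The result,
    indexed on ``inner.target`` and sampling ``outer.source``, is

        K(x) = W(x) + U(x + W(x))

    with ``W`` = inner's displacement and ``U`` = outer's (trilinear,
    edge-clamped). Warping once with the composite equals warping with
    ``outer`` then ``inner``, up to interpolation error.
    """
    if (inner.source.age != outer.target.age
            or inner.source.shape != outer.target.shape):
        raise SpaceMismatchError(
            "compose_fields: chain mismatch — inner field pulls from "
            f"P{inner.source.age} into P{inner.target.age}, but outer field "
            f"lands in P{outer.target.age} (sampling P{outer.source.age})"
        )
    W = inner.displacement
    coords = _grid(inner.target.shape) + np.moveaxis(W, -1, 0)
    K = W + _interp_displacement_grid(outer.displacement, coords)
    return DisplacementField(source=outer.source, target=inner.target,
                             displacement=K)


def scale_field(
    field: DisplacementField,
    fraction: float,
    source: AtlasSpace | None = None,
    target: AtlasSpace | None = None,
) -> DisplacementField:
    """Scale displacements by ``fraction`` in [0, 1].

    Linear scaling is the fractional-age transform: it is exact for the
    translation/affine part of a deformation and a first-order approximation
    of geodesic interpolation otherwise. ``source``/``target`` let the
    caller reinterpret the scaled field on an intermediate-age grid.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    return DisplacementField(
        source=source if source is not None else field.source,
        target=target if target is not None else field.target,
        displacement=field.displacement * float(fraction),
        metadata=dict(field.metadata, scaled_by=float(fraction)),
    )
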