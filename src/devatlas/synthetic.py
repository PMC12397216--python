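"""Synthetic phantoms, analytic warp fields, simulated raters, and sparse
section stacks.

Everything here is a pure function of its parameters and seed, so the whole
package is testable without downloading atlas data. The phantoms are nested
ellipsoid shells whose semi-axes grow affinely with age — a stand-in for
templates whose brains grow monotonically across postnatal development, not
a claim of biological realism. The analytic fields (translation, centred
scaling, sinusoidal) have closed-form inverses or documented invertibility
bounds and serve as ground truth for the field algebra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import (
    AtlasSpace,
    DisplacementField,
    IntensityVolume,
    LabelTable,
    LabelVolume,
    PointSet,
)
from .landmarks import MATRIX_ID, LandmarkTable
from .reconstruction import OrthogonalAnchor, Section, SectionStack

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "make_analytic_field",
    "simulate_raters",
    "make_sparse_sections",
    "expected_noise_distance",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a deterministic nested-ellipsoid phantom.

    Semi-axes follow the affine growth law ``base + rate * age`` (voxels),
    monotone in age. ``shell_fractions`` are relative radii of the nested
    label shells (outermost first); each shell gets a constant intensity
    from ``shell_intensities`` before optional Gaussian smoothing
    (``smooth_sigma`` voxels) makes the volume band-limited. ``noise_sd``
    adds seeded Gaussian texture (default off).
    """

    age: float
    shape: tuple[int, int, int] = (64, 64, 64)
    base_semi_axes: tuple[float, float, float] = (6.0, 5.0, 5.0)
    growth_per_day: tuple[float, float, float] = (0.15, 0.12, 0.12)
    shell_fractions: tuple[float, ...] = (1.0, 0.6, 0.3)
    shell_intensities: tuple[float, ...] = (0.3, 0.6, 1.0)
    smooth_sigma: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def semi_axes(self) -> tuple[float, float, float]:
        return tuple(b + g * self.age
                     for b, g in zip(self.base_semi_axes, self.growth_per_day))


def make_phantom(spec: PhantomSpec) -> tuple[IntensityVolume, LabelVolume]:
    """Build the (intensity, label) phantom pair described by ``spec``.

    Labels are 1..n_shells from outermost to innermost (nested), background
    0. Raises if the outer shell does not fit inside the grid.
    """
    if len(spec.shell_fractions) != len(spec.shell_intensities):
        raise ValueError("one intensity per shell required")
    if any(f2 >= f1 for f1, f2 in zip(spec.shell_fractions,
                                      spec.shell_fractions[1:])):
        raise ValueError("shell fractions must strictly decrease (nesting)")
    axes = spec.semi_axes()
    centre = [(s - 1) / 2.0 for s in spec.shape]
    if any(a >= c for a, c in zip(axes, centre)):
        raise ValueError(
            f"semi-axes {axes} exceed the grid {spec.shape} at age {spec.age}"
        )
    grid = np.indices(spec.shape, dtype=float)
    rho = np.sqrt(sum(((grid[i] - centre[i]) / axes[i]) ** 2
                      for i in range(3)))
    labels = np.zeros(spec.shape, dtype=np.int32)
    intensity = np.zeros(spec.shape, dtype=float)
    for k, (frac, level) in enumerate(zip(spec.shell_fractions,
                                          spec.shell_intensities), start=1):
        inside = rho <= frac
        labels[inside] = k
        intensity[inside] = level
    if spec.smooth_sigma > 0:
        intensity = gaussian_filter(intensity, spec.smooth_sigma)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = np.abs(intensity + rng.normal(0, spec.noise_sd, spec.shape))
    space = AtlasSpace(age=spec.age, shape=spec.shape)
    table = LabelTable.from_mapping(
        {k: f"shell_{k}" for k in range(1, len(spec.shell_fractions) + 1)}
    )
    return (IntensityVolume(space=space, values=intensity),
            LabelVolume(space=space, labels=labels, table=table))


def make_analytic_field(
    kind: str,
    params: dict,
    source: AtlasSpace,
    target: AtlasSpace,
) -> DisplacementField:
    """Closed-form warp fields for oracle tests.

    kinds:
      - ``translation``: constant ``U = offset``; exact inverse ``-offset``.
      - ``centred_scaling``: ``U(x) = (a - 1)(x - c)`` (pull field of a
        scaling by ``a`` about ``c``, default grid centre); exact inverse is
        the scaling by ``1/a``.
      - ``sinusoidal``: ``U_i(x) = A sin(k x_j + φ)`` with ``j = (i+1) mod
        3``; invertible (a diffeomorphism) when ``A·k < 1``, enforced.

    For translation and scaling the analytic inverse field is attached in
    ``metadata["analytic_inverse"]``.
    """
    grid = np.indices(target.shape, dtype=float)
    meta: dict = {"kind": kind, "params": dict(params)}
    if kind == "translation":
        offset = np.asarray(params["offset"], dtype=float)
        U = np.broadcast_to(offset, target.shape + (3,)).copy()
        inv = DisplacementField(
            source=target, target=source,
            displacement=np.broadcast_to(-offset, source.shape + (3,)).copy(),
        )
        meta["analytic_inverse"] = inv
    elif kind == "centred_scaling":
        a = float(params["factor"])
        if a <= 0:
            raise ValueError("scaling factor must be positive")
        centre = np.asarray(
            params.get("centre", [(s - 1) / 2.0 for s in target.shape]),
            dtype=float)
        U = np.stack([(a - 1.0) * (grid[i] - centre[i]) for i in range(3)],
                     axis=-1)
        grid_s = np.indices(source.shape, dtype=float)
        Uinv = np.stack(
            [(1.0 / a - 1.0) * (grid_s[i] - centre[i]) for i in range(3)],
            axis=-1)
        meta["analytic_inverse"] = DisplacementField(
            source=target, target=source, displacement=Uinv)
    elif kind == "sinusoidal":
        A = float(params["amplitude"])
        k = float(params["frequency"])  # radians per voxel
        phase = float(params.get("phase", 0.0))
        if A * k >= 1.0:
            raise ValueError(
                f"amplitude × frequency = {A * k:.3g} >= 1 breaks invertibility"
            )
        U = np.stack(
            [A * np.sin(k * grid[(i + 1) % 3] + phase) for i in range(3)],
            axis=-1)
    else:
        raise ValueError(f"unknown analytic field kind {kind!r}")
    return DisplacementField(source=source, target=target, displacement=U,
                             metadata=meta)


def simulate_raters(
    true_landmarks: PointSet,
    n_raters: int,
    noise_sd: float,
    seed: int,
    noise: str = "gaussian",
    t_dof: float = 3.0,
    include_matrix: bool = False,
    matrix_noise_sd: float | None = None,
) -> LandmarkTable:
    """Simulated rater panel: each rater records truth + isotropic noise.

    ``noise`` is ``"gaussian"`` or ``"student_t"`` (heavier tails, to
    exercise the median's robustness). With ``include_matrix``, an
    automated-transform subject is added with its own noise level
    (``matrix_noise_sd``, default ``noise_sd``). Seed-reproducible.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_raters < 1:
        raise ValueError("need at least one rater")
    rng = np.random.default_rng(seed)
    pts = true_landmarks.points
    age = true_landmarks.space.age
    rows = []

    def _noise(sd: float) -> np.ndarray:
        if sd == 0:
            return np.zeros_like(pts)
        if noise == "gaussian":
            return rng.normal(0.0, sd, pts.shape)
        if noise == "student_t":
            return sd * rng.standard_t(t_dof, pts.shape)
        raise ValueError(f"unknown noise model {noise!r}")

    subjects = [f"rater_{i + 1}" for i in range(n_raters)]
    sds = [noise_sd] * n_raters
    if include_matrix:
        subjects.append(MATRIX_ID)
        sds.append(matrix_noise_sd if matrix_noise_sd is not None else noise_sd)
    for subject, sd in zip(subjects, sds):
        noisy = pts + _noise(sd)
        rows.extend(
            {"landmark_id": lm, "rater_id": subject, "age": age,
             "x": p[0], "y": p[1], "z": p[2]}
            for lm, p in enumerate(noisy)
        )
    return LandmarkTable(df=pd.DataFrame(rows),
                         spacing=true_landmarks.space.spacing)


def expected_noise_distance(noise_sd: float) -> float:
    """Mean Euclidean norm of an isotropic 3D Gaussian displacement,
    E‖N(0, σ²I₃)‖ = σ·√2·Γ(2)/Γ(3/2) ≈ 1.5958 σ (chi distribution, 3 df)."""
    return noise_sd * math.sqrt(2.0) * math.gamma(2.0) / math.gamma(1.5)


def make_sparse_sections(volume: IntensityVolume, axis: int,
                         step: int) -> SectionStack:
    """Extract every ``step``-th orthogonal slice as an exactly anchored
    section — an emulation of serial sectioning. Section count is
    ``ceil(extent / step)``."""
    if not (0 <= int(axis) <= 2):
        raise ValueError(f"invalid axis {axis}")
    if int(step) < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    axis, step = int(axis), int(step)
    sections = []
    for idx in range(0, volume.space.shape[axis], step):
        sl = [slice(None)] * 3
        sl[axis] = idx
        sections.append(Section(values=np.asarray(volume.values[tuple(sl)]),
                                anchor=OrthogonalAnchor(axis=axis, index=idx)))
    return SectionStack(sections=tuple(sections))
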