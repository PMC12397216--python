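"""Shared coordinate conventions and container types.

Every object in the package lives on a regular, isotropic voxel grid.
Coordinates are 0-based, continuous voxel indices with a fixed axis order:
axis 0 = anterior→posterior (AP), axis 1 = superior→inferior (SI),
axis 2 = left→right (LR) — the serial-section ordering used by the Allen
mouse brain Common Coordinate Framework. Physical units enter only through
:func:`voxel_to_micron` and the I/O layer; all internal math is in voxels.

Displacement fields follow the *pull* convention: a field indexed on its
target grid stores, for each target voxel ``x``, the offset ``U(x)`` such
that resampling reads the source volume at ``x + U(x)``. Dually, the map
``x ↦ x + U(x)`` sends target-space points into source-space coordinates.
In the developmental-atlas chain the stored fields are the *backward*
transforms (target = younger age, source = older age); *forward* transforms
are obtained by numerical inversion (:func:`devatlas.fields.invert_field`).
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dcfield
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AGE_MIN",
    "AGE_MAX",
    "DEFAULT_ANCHOR_AGES",
    "DEFAULT_SPACING_UM",
    "AgeRangeError",
    "SpaceMismatchError",
    "ChainError",
    "AtlasSpace",
    "IntensityVolume",
    "LabelVolume",
    "LabelEntry",
    "LabelTable",
    "DisplacementField",
    "PointSet",
    "TemplateChain",
    "make_space",
    "voxel_to_micron",
    "micron_to_voxel",
]

#: Supported postnatal-age span in days.
AGE_MIN, AGE_MAX = 4, 56

#: Anchor ages of the template chain: the postnatal days for which
#: population-averaged STPT templates exist.
DEFAULT_ANCHOR_AGES = (4, 7, 14, 21, 28, 56)

#: Standard isotropic grid spacing in micrometres.
DEFAULT_SPACING_UM = 20.0


class AgeRangeError(ValueError):
    """Raised for a postnatal age outside the supported P4–P56 span."""


class SpaceMismatchError(ValueError):
    """Raised when two objects that must share a coordinate space do not."""


class ChainError(ValueError):
    """Raised for an inconsistent or incomplete template chain."""


def _as_shape(shape: Sequence[int]) -> tuple[int, int, int]:
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValueError(f"shape must be three positive extents, got {shape!r}")
    return shape


@dataclass(frozen=True)
class AtlasSpace:
    """Geometry of one postnatal-age coordinate space.

    Parameters
    ----------
    age
        Postnatal day. Integer days are the atlas grid, but fractional ages
        are accepted programmatically (intermediate spaces).
    shape
        Voxel counts per axis (AP, SI, LR).
    spacing
        Isotropic voxel edge length in micrometres.
    origin
        Voxel index of the anatomical reference origin.
    """

    age: float
    shape: tuple[int, int, int]
    spacing: float = DEFAULT_SPACING_UM
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", _as_shape(self.shape))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if not np.isfinite(self.age) or not (AGE_MIN <= self.age <= AGE_MAX):
            raise AgeRangeError(
                f"age {self.age} outside supported span P{AGE_MIN}–P{AGE_MAX}"
            )
        if not (self.spacing > 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    def with_age(self, age: float) -> "AtlasSpace":
        """Same grid reinterpreted at another age."""
        return AtlasSpace(age=age, shape=self.shape, spacing=self.spacing,
                          origin=self.origin)

    def same_grid(self, other: "AtlasSpace") -> bool:
        return self.shape == other.shape and self.spacing == other.spacing


def make_space(
    age: float,
    shape: Sequence[int],
    spacing: float = DEFAULT_SPACING_UM,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> AtlasSpace:
    """Validated :class:`AtlasSpace` constructor."""
    return AtlasSpace(age=float(age), shape=_as_shape(shape),
                      spacing=float(spacing), origin=tuple(origin))


def voxel_to_micron(points: np.ndarray, space: AtlasSpace) -> np.ndarray:
    """Convert voxel coordinates to physical micrometres.

    Works on a single ``(3,)`` coordinate or an ``(N, 3)`` array.
    """
    pts = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinate")
    return pts * space.spacing


def micron_to_voxel(points: np.ndarray, space: AtlasSpace) -> np.ndarray:
    """Inverse of :func:`voxel_to_micron`."""
    pts = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinate")
    return pts / space.spacing


@dataclass(frozen=True)
class LabelEntry:
    id: int
    name: str
    acronym: str = ""
    color: tuple[int, int, int] = (255, 255, 255)


class LabelTable:
    """Ontology metadata carrier: id → (name, acronym, RGB colour).

    Label id 0 is reserved for background and may be absent.
    """

    def __init__(self, entries: Iterable[LabelEntry]):
        self.entries: tuple[LabelEntry, ...] = tuple(entries)
        ids = [e.id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate label ids in table")
        self._by_id = {e.id: e for e in self.entries}
        bg = self._by_id.get(0)
        if bg is not None and bg.name.lower() != "background":
            raise ValueError('label id 0 is reserved and must be named "background"')

    @classmethod
    def from_mapping(cls, names: Mapping[int, str]) -> "LabelTable":
        return cls(LabelEntry(id=int(i), name=str(n)) for i, n in names.items())

    def ids(self) -> set[int]:
        return set(self._by_id)

    def __contains__(self, label_id: int) -> bool:
        return int(label_id) in self._by_id

    def __getitem__(self, label_id: int) -> LabelEntry:
        return self._by_id[int(label_id)]

    def name(self, label_id: int, default: str = "") -> str:
        e = self._by_id.get(int(label_id))
        return e.name if e is not None else default

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, LabelTable) and self.entries == other.entries


@dataclass
class IntensityVolume:
    """A scalar image on an :class:`AtlasSpace` grid."""

    space: AtlasSpace
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.space.shape:
            raise SpaceMismatchError(
                f"values shape {self.values.shape} != space shape {self.space.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity values must be finite")


@dataclass
class LabelVolume:
    """An integer segmentation image; 0 is background."""

    space: AtlasSpace
    labels: np.ndarray
    table: LabelTable | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError(
                f"label volume must have an integer dtype, got {self.labels.dtype}"
            )
        if self.labels.shape != self.space.shape:
            raise SpaceMismatchError(
                f"labels shape {self.labels.shape} != space shape {self.space.shape}"
            )
        if self.table is not None:
            present = set(np.unique(self.labels).tolist()) - {0}
            missing = present - self.table.ids()
            if missing:
                raise ValueError(f"labels {sorted(missing)} absent from label table")

    def label_set(self) -> set[int]:
        return set(np.unique(self.labels).tolist())


@dataclass
class DisplacementField:
    """A dense pull field resampling ``source`` volumes into ``target`` space.

    ``displacement`` has shape ``target.shape + (3,)``, in voxel units of the
    shared grid. ``metadata`` carries diagnostics such as the inversion
    residual.
    """

    source: AtlasSpace
    target: AtlasSpace
    displacement: np.ndarray
    metadata: dict = _dcfield(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        expected = self.target.shape + (3,)
        if self.displacement.shape != expected:
            raise SpaceMismatchError(
                f"displacement shape {self.displacement.shape} != {expected}"
            )
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement values must be finite")

    def point_targets(self, points: np.ndarray) -> np.ndarray:
        """Dual point map ``x ↦ x + U(x)`` (target → source coordinates)."""
        from .fields import _interp_displacement_at  # local: avoid cycle

        pts = np.asarray(points, dtype=float)
        return pts + _interp_displacement_at(self.displacement, pts)


@dataclass
class PointSet:
    """Continuous 0-based voxel coordinates in one space."""

    space: AtlasSpace
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")

    def out_of_domain(self) -> np.ndarray:
        """Boolean flag per point: outside ``[0, shape - 1]`` on any axis."""
        hi = np.asarray(self.space.shape, dtype=float) - 1.0
        return np.any((self.points < 0) | (self.points > hi), axis=1)

    def __len__(self) -> int:
        return self.points.shape[0]


class TemplateChain:
    """The anchor ages, their templates, and the pairwise backward fields.

    ``backward_fields`` maps each adjacent anchor pair ``(older, younger)``
    to the :class:`DisplacementField` whose target is the younger space and
    whose source is the older one (it transforms data *backwards* in age).
    All spaces in a chain share one standardized grid (shape and spacing),
    which is what makes temporal scaling and reinterpretation of fields on
    intermediate grids well defined.
    """

    def __init__(
        self,
        anchor_ages: Sequence[float] = DEFAULT_ANCHOR_AGES,
        backward_fields: Mapping[tuple[float, float], DisplacementField] | None = None,
        templates: Mapping[float, IntensityVolume] | None = None,
    ):
        ages = tuple(float(a) for a in anchor_ages)
        if len(ages) < 2 or any(b <= a for a, b in zip(ages, ages[1:])):
            raise ChainError(f"anchor ages must be strictly increasing, got {ages}")
        if not (AGE_MIN <= ages[0] and ages[-1] <= AGE_MAX):
            raise AgeRangeError(
                f"anchor ages {ages} outside supported span P{AGE_MIN}–P{AGE_MAX}"
            )
        self.anchor_ages = ages
        self.backward_fields = {
            (float(o), float(y)): f
            for (o, y), f in (backward_fields or {}).items()
        }
        self.templates = {float(a): t for a, t in (templates or {}).items()}
        self._forward_cache: dict[tuple, DisplacementField] = {}
        self._route_cache: dict[tuple, object] = {}

        pairs = self.adjacent_pairs()
        missing = [p for p in pairs if p not in self.backward_fields]
        extra = [p for p in self.backward_fields if p not in pairs]
        if missing:
            raise ChainError(f"missing backward fields for pairs {missing}")
        if extra:
            raise ChainError(f"backward fields for non-adjacent pairs {extra}")

        grids = [f.target for f in self.backward_fields.values()]
        grids += [t.space for t in self.templates.values()]
        ref = grids[0]
        for g in grids[1:]:
            if not ref.same_grid(g):
                raise ChainError(
                    "all spaces in a chain must share shape and spacing "
                    f"({ref.shape}@{ref.spacing}µm vs {g.shape}@{g.spacing}µm)"
                )
        self.grid_shape = ref.shape
        self.spacing = ref.spacing
        self.origin = ref.origin

        for (older, younger), f in self.backward_fields.items():
            if f.source.age != older or f.target.age != younger:
                raise ChainError(
                    f"field for pair ({older}, {younger}) has ages "
                    f"source={f.source.age}, target={f.target.age}"
                )
        for age, t in self.templates.items():
            if t.space.age != age:
                raise ChainError(f"template keyed {age} has space age {t.space.age}")

    def adjacent_pairs(self) -> list[tuple[float, float]]:
        """Adjacent ``(older, younger)`` anchor pairs, oldest first."""
        ages = self.anchor_ages
        return [(ages[i + 1], ages[i]) for i in range(len(ages) - 1)][::-1]

    @property
    def span(self) -> tuple[float, float]:
        return self.anchor_ages[0], self.anchor_ages[-1]

    def contains_age(self, age: float) -> bool:
        lo, hi = self.span
        return lo <= age <= hi

    def space(self, age: float) -> AtlasSpace:
        """The shared standardized grid reinterpreted at ``age``."""
        return AtlasSpace(age=age, shape=self.grid_shape, spacing=self.spacing,
                          origin=self.origin)

    def forward_field(self, pair: tuple[float, float], tol: float = 0.05,
                      max_iter: int = 50) -> DisplacementField:
        """Forward (younger→older) field for an adjacent ``(older, younger)``
        pair, obtained by inverting the stored backward field. Cached."""
        key = (pair, tol)
        if key not in self._forward_cache:
            from .fields import invert_field

            self._forward_cache[key] = invert_field(
                self.backward_fields[pair], tol=tol, max_iter=max_iter
            )
        return self._forward_cache[key]
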