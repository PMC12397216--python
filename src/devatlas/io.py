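"""Readers and writers for on-disk formats.

Volumes and displacement fields are NIfTI-1 (plain ``.nii`` or ``.nii.gz``)
with spatial units in millimetres on disk (the NIfTI standard, for viewer
interoperability) and micrometres in memory — the conversion lives only
here. Atlas metadata that NIfTI cannot carry (postnatal age, origin voxel,
field source/target ages) travels in a JSON sidecar next to the file.
Landmark tables are CSV; label tables use the ITK-SNAP label description
text format; a chain manifest is a JSON file listing anchor ages and the
template/field paths.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import (
    AtlasSpace,
    DisplacementField,
    IntensityVolume,
    LabelEntry,
    LabelTable,
    LabelVolume,
    TemplateChain,
    make_space,
)

__all__ = [
    "VolumeFormatError",
    "LabelDtypeError",
    "SidecarError",
    "read_volume",
    "write_volume",
    "read_field",
    "write_field",
    "read_landmarks",
    "write_landmarks",
    "write_report",
    "read_label_table",
    "write_label_table",
    "load_chain",
    "save_chain",
]

MM_PER_UM = 1e-3


class VolumeFormatError(ValueError):
    """Not a readable NIfTI-1 file."""


class LabelDtypeError(TypeError):
    """A label volume stored with a floating-point dtype."""


class SidecarError(ValueError):
    """Missing or invalid JSON sidecar."""


def _sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def _load_nifti(path: str | Path):
    try:
        img = nib.load(str(path))
    except Exception as e:  # nibabel raises several unrelated classes
        raise VolumeFormatError(f"cannot read {path} as NIfTI: {e}") from e
    return img


def _spacing_um(img) -> float:
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise VolumeFormatError(f"anisotropic on-disk spacing {zooms}")
    return float(zooms[0]) / MM_PER_UM


def _read_sidecar(path: str | Path, required: bool = False) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        if required:
            raise SidecarError(
                f"missing sidecar {sc}; create a JSON file with the needed "
                'keys (e.g. {"source_age": 56, "target_age": 28})'
            )
        return {}
    with open(sc) as f:
        return json.load(f)


def _write_sidecar(path: str | Path, payload: dict) -> None:
    with open(_sidecar_path(path), "w") as f:
        json.dump(payload, f, indent=2)


def read_volume(path: str | Path, kind: str = "auto",
                age: float | None = None):
    """Read a NIfTI volume as an :class:`IntensityVolume` or
    :class:`LabelVolume`.

    ``kind`` is ``"auto"`` (labels iff integer dtype), ``"intensity"`` or
    ``"labels"``. Age and origin come from the sidecar unless overridden.
    """
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D volume, got {data.ndim}D")
    meta = _read_sidecar(path)
    if age is None:
        age = meta.get("age")
    if age is None:
        raise SidecarError(
            f"no age for {path}: pass age= or provide a sidecar with an "
            '"age" key'
        )
    space = make_space(age=age, shape=data.shape, spacing=_spacing_um(img),
                       origin=meta.get("origin", (0.0, 0.0, 0.0)))
    is_int = np.issubdtype(data.dtype, np.integer)
    if kind == "auto":
        kind = "labels" if is_int else "intensity"
    if kind == "labels":
        if not is_int:
            raise LabelDtypeError(
                f"{path}: label volume stored as {data.dtype}; re-save with "
                "an integer dtype"
            )
        return LabelVolume(space=space, labels=data)
    return IntensityVolume(space=space, values=data.astype(float))


def write_volume(vol: IntensityVolume | LabelVolume, path: str | Path) -> None:
    """Write a volume as NIfTI plus its metadata sidecar; value round trips
    are bit-exact."""
    is_labels = isinstance(vol, LabelVolume)
    data = vol.labels if is_labels else vol.values
    if is_labels and data.dtype == np.int64:  # NIfTI-1 has no 64-bit int
        data = data.astype(np.int32)
    affine = np.diag([vol.space.spacing * MM_PER_UM] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms((vol.space.spacing * MM_PER_UM,) * 3)
    nib.save(img, str(path))
    _write_sidecar(path, {
        "age": vol.space.age,
        "origin": list(vol.space.origin),
        "kind": "labels" if is_labels else "intensity",
    })


def read_field(path: str | Path) -> DisplacementField:
    """Read a displacement field from a 4D NIfTI (component axis last,
    length 3) plus a sidecar giving source/target ages."""
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise VolumeFormatError(
            f"{path}: displacement field must be 4D with a trailing "
            f"component axis of length 3, got shape {data.shape}"
        )
    meta = _read_sidecar(path, required=True)
    for key in ("source_age", "target_age"):
        if key not in meta:
            raise SidecarError(f"sidecar for {path} lacks {key!r}")
    spacing = _spacing_um(img)
    shape = data.shape[:3]
    source = make_space(meta["source_age"], shape, spacing,
                        meta.get("origin", (0.0, 0.0, 0.0)))
    target = make_space(meta["target_age"], shape, spacing,
                        meta.get("origin", (0.0, 0.0, 0.0)))
    return DisplacementField(source=source, target=target, displacement=data)


def write_field(field: DisplacementField, path: str | Path) -> None:
    affine = np.diag([field.target.spacing * MM_PER_UM] * 3 + [1.0])
    img = nib.Nifti1Image(field.displacement, affine)
    img.header.set_zooms((field.target.spacing * MM_PER_UM,) * 3 + (1.0,))
    nib.save(img, str(path))
    _write_sidecar(path, {
        "source_age": field.source.age,
        "target_age": field.target.age,
        "origin": list(field.target.origin),
    })


def read_landmarks(path: str | Path, spacing: float = 20.0):
    """Read a landmark CSV (columns landmark_id, rater_id, age, x, y, z)."""
    from .landmarks import LandmarkTable, _REQUIRED_COLUMNS

    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return LandmarkTable(df=df, spacing=spacing)


def write_landmarks(table, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def write_report(report, path_prefix: str | Path) -> None:
    """Write a :class:`~devatlas.landmarks.ConcordanceReport` as CSV files
    plus a JSON summary under ``<prefix>_*.csv`` / ``<prefix>.json``."""
    prefix = Path(path_prefix)
    report.mean_errors.to_csv(prefix.with_name(prefix.name + "_means.csv"),
                              index=False)
    report.per_landmark.to_csv(
        prefix.with_name(prefix.name + "_per_landmark.csv"), index=False)
    report.tests.to_csv(prefix.with_name(prefix.name + "_tests.csv"),
                        index=False)
    with open(prefix.with_name(prefix.name + ".json"), "w") as f:
        json.dump({
            "mean_errors": report.mean_errors.to_dict(orient="records"),
            "tests": report.tests.to_dict(orient="records"),
        }, f, indent=2, default=float)


def read_label_table(path: str | Path) -> LabelTable:
    """Read an ITK-SNAP label description file
    (``id R G B A VIS MSHVIS "name"`` per line, # comments)."""
    entries = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 7)
            if len(parts) < 8:
                raise ValueError(f"{path}: malformed label line {line!r}")
            lid = int(parts[0])
            rgb = tuple(int(p) for p in parts[1:4])
            name = parts[7].strip().strip('"')
            entries.append(LabelEntry(id=lid, name=name, color=rgb))
    return LabelTable(entries)


def write_label_table(table: LabelTable, path: str | Path) -> None:
    with open(path, "w") as f:
        f.write("# ITK-SNAP label description file\n")
        f.write("# id R G B A VIS MSHVIS name\n")
        for e in table.entries:
            r, g, b = e.color
            f.write(f'{e.id} {r} {g} {b} 1 1 1 "{e.name}"\n')


def load_chain(manifest_path: str | Path) -> TemplateChain:
    """Load a template chain from a JSON manifest.

    Manifest keys: ``anchor_ages`` (sorted list), ``templates`` (age →
    path), ``backward_fields`` ("older-younger" → path), optional
    ``version``. Paths are resolved relative to the manifest. Referenced
    files must exist.
    """
    mpath = Path(manifest_path)
    with open(mpath) as f:
        manifest = json.load(f)
    base = mpath.parent
    templates = {}
    for age, rel in manifest.get("templates", {}).items():
        p = base / rel
        if not p.exists():
            raise FileNotFoundError(f"manifest references missing file {p}")
        templates[float(age)] = read_volume(p, kind="intensity",
                                            age=float(age))
    fields = {}
    for pair, rel in manifest.get("backward_fields", {}).items():
        older, younger = (float(a) for a in pair.split("-"))
        p = base / rel
        if not p.exists():
            raise FileNotFoundError(f"manifest references missing file {p}")
        fields[(older, younger)] = read_field(p)
    return TemplateChain(anchor_ages=manifest["anchor_ages"],
                         backward_fields=fields, templates=templates)


def save_chain(chain: TemplateChain, directory: str | Path,
               version: str = "1") -> Path:
    """Write a chain's templates, fields, and manifest into a directory;
    returns the manifest path."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": version,
        "spacing": chain.spacing,
        "shape": list(chain.grid_shape),
        "anchor_ages": list(chain.anchor_ages),
        "templates": {},
        "backward_fields": {},
    }
    for age, vol in chain.templates.items():
        rel = f"template_P{age:g}.nii.gz"
        write_volume(vol, d / rel)
        manifest["templates"][f"{age:g}"] = rel
    for (older, younger), field in chain.backward_fields.items():
        rel = f"backward_P{older:g}_to_P{younger:g}.nii.gz"
        write_field(field, d / rel)
        manifest["backward_fields"][f"{older:g}-{younger:g}"] = rel
    mpath = d / "chain.json"
    with open(mpath, "w") as f:
        json.dump(manifest, f, indent=2)
    return mpath
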