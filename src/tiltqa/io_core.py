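"""Domain data model and on-disk formats.

All physical coordinates in this package are LPS (x: right->left,
y: anterior->posterior, z: inferior->superior), axis-aligned, in mm,
with 0-based voxel indices and voxel-center semantics: the physical
center of voxel (i, j, k) is ``origin + (i*sx, j*sy, k*sz)``.

Volumes are stored as NIfTI-1 files. Files whose affine is axis-aligned
up to axis permutations and sign flips are reoriented to the convention
above on read; oblique (rotated/sheared) affines are rejected outright
rather than resampled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import nibabel as nib
import numpy as np
from nibabel import orientations as nio

__all__ = [
    "VolumeGrid",
    "BinaryMask",
    "DoseGrid",
    "PatientEntry",
    "CohortManifest",
    "read_volume",
    "write_volume",
    "read_mask",
    "read_dose",
    "load_manifest",
    "TiltQAError",
    "UnsupportedOrientationError",
    "GridMismatchError",
    "ManifestError",
    "UndefinedMetricError",
    "OutOfExtentError",
    "DegenerateGeometryError",
    "NoOverlapError",
    "SPINE_STRUCTURES",
    "GOLD_SOURCE",
]

#: structures required for the tilt stage
SPINE_STRUCTURES = ("cord", "C1", "C2", "C3", "C4")
#: provenance tag of reference (manually curated / generator truth) contours
GOLD_SOURCE = "gold"


class TiltQAError(Exception):
    """Base class for all package errors."""


class UnsupportedOrientationError(TiltQAError):
    """NIfTI affine is oblique (rotation/shear) and cannot be interpreted."""


class GridMismatchError(TiltQAError):
    """Two volumes expected on one grid have different geometry."""


class ManifestError(TiltQAError):
    """Cohort manifest fails validation."""


class UndefinedMetricError(TiltQAError):
    """A comparison metric is undefined for the given operands."""


class OutOfExtentError(TiltQAError):
    """A mask voxel falls outside the physical extent of a dose grid."""


class DegenerateGeometryError(TiltQAError):
    """Input geometry does not determine the requested quantity."""


class NoOverlapError(TiltQAError):
    """Cord and vertebrae do not overlap longitudinally."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VolumeGrid:
    """Axis-aligned 3D scalar field with physical geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar samples, ordered so that index i runs along +x (left),
        j along +y (posterior), k along +z (superior).
    spacing : tuple of float
        Voxel spacing (sx, sy, sz) in mm; strictly positive.
    origin : tuple of float
        Physical LPS center of voxel (0, 0, 0), in mm.
    """

    values: np.ndarray
    spacing: tuple
    origin: tuple

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError(f"values must be a 3D array, got shape {v.shape}")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        og = tuple(float(o) for o in self.origin)
        if len(og) != 3:
            raise ValueError(f"origin must have three components, got {self.origin}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", og)

    @property
    def shape(self):
        return self.values.shape

    def same_geometry(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def index_to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Physical LPS centers (mm) of voxel indices, shape (n, 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def physical_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of physical LPS points, shape (n, 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} VolumeGrid tagged with a structure label and a source."""

    grid: VolumeGrid
    label: str
    source: str = GOLD_SOURCE

    def __post_init__(self):
        v = self.grid.values
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"mask {self.label!r} has values outside {{0,1}}")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    @property
    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.grid.values))

    def foreground_indices(self) -> np.ndarray:
        """Integer voxel indices of foreground voxels, shape (n, 3)."""
        return np.argwhere(self.grid.values != 0)

    def foreground_coords_mm(self) -> np.ndarray:
        """Physical LPS centers (mm) of foreground voxels, shape (n, 3)."""
        return self.grid.index_to_physical(self.foreground_indices())


@dataclass(frozen=True)
class DoseGrid:
    """Absorbed-dose scalar field in Gy. Values must be finite and >= 0."""

    grid: VolumeGrid
    units: str = "Gy"

    def __post_init__(self):
        v = self.grid.values
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("dose values must be finite and non-negative")


@dataclass
class PatientEntry:
    """One cohort member: structure->source->path mapping plus dose path."""

    patient_id: str
    structures: Dict[str, Dict[str, str]]
    dose: Optional[str] = None
    tilt_deg: Optional[float] = None

    def sources_for(self, structure: str) -> List[str]:
        return sorted(self.structures.get(structure, {}))

    def path(self, structure: str, source: str) -> str:
        try:
            return self.structures[structure][source]
        except KeyError:
            raise ManifestError(
                f"patient {self.patient_id!r} has no {structure!r} from source {source!r}"
            ) from None


@dataclass
class CohortManifest:
    """Validated collection of PatientEntry records."""

    patients: List[PatientEntry]
    root: Path = field(default_factory=Path)

    def __post_init__(self):
        ids = [p.patient_id for p in self.patients]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ManifestError(f"duplicate patient ids in manifest: {dupes}")

    def __iter__(self):
        return iter(self.patients)

    def __len__(self):
        return len(self.patients)

    def entry(self, patient_id: str) -> PatientEntry:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise ManifestError(f"unknown patient id {patient_id!r}")

    def resolve(self, relpath: str) -> Path:
        p = Path(relpath)
        return p if p.is_absolute() else self.root / p

    def test_sources(self) -> List[str]:
        """All non-gold sources appearing anywhere in the manifest."""
        out = set()
        for pat in self.patients:
            for srcmap in pat.structures.values():
                out.update(srcmap)
        out.discard(GOLD_SOURCE)
        return sorted(out)

    def organ_structures(self) -> List[str]:
        """Structures other than the spine set (candidate OARs)."""
        out = set()
        for pat in self.patients:
            out.update(pat.structures)
        return sorted(out - set(SPINE_STRUCTURES))


# ---------------------------------------------------------------------------
# NIfTI reading / writing
# ---------------------------------------------------------------------------

_LPS_AXCODES = ("L", "P", "S")


def _check_axis_aligned(affine: np.ndarray) -> None:
    rot = np.asarray(affine)[:3, :3]
    for j in range(3):
        col = rot[:, j]
        norm = np.linalg.norm(col)
        if norm == 0:
            raise UnsupportedOrientationError("affine has a zero column")
        significant = int(np.sum(np.abs(col) > 1e-4 * norm))
        if significant != 1:
            raise UnsupportedOrientationError(
                "oblique NIfTI affine (rotation/shear) is not supported; "
                "resample the volume to an axis-aligned grid first"
            )


def read_volume(path) -> VolumeGrid:
    """Read a NIfTI volume and return it in the package LPS convention.

    Axis permutations and sign flips in the affine are normalized so the
    returned array always runs x: right->left, y: anterior->posterior,
    z: inferior->superior; physical voxel positions are unchanged.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    UnsupportedOrientationError
        If the affine contains rotation or shear terms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    affine = img.affine
    _check_axis_aligned(affine)

    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:  # tolerate singleton time axis
        data = data[..., 0]
    if data.ndim != 3:
        raise TiltQAError(f"{path}: expected a 3D volume, got shape {data.shape}")

    src_ornt = nio.io_orientation(affine)
    dst_ornt = nio.axcodes2ornt(_LPS_AXCODES)
    xform = nio.ornt_transform(src_ornt, dst_ornt)
    data = nio.apply_orientation(data, xform)
    affine = affine @ nio.inv_ornt_aff(xform, data.shape)

    # affine now maps our index order to RAS; LPS negates x and y
    diag = np.diag(affine)[:3]
    spacing = (abs(diag[0]), abs(diag[1]), abs(diag[2]))
    origin = (-affine[0, 3], -affine[1, 3], affine[2, 3])
    return VolumeGrid(values=data, spacing=spacing, origin=origin)


def write_volume(grid: VolumeGrid, path) -> Path:
    """Write a VolumeGrid as NIfTI-1; inverse of :func:`read_volume`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sx, sy, sz = grid.spacing
    ox, oy, oz = grid.origin
    # our indices run toward L, P, S; NIfTI affines are index -> RAS
    affine = np.array(
        [
            [-sx, 0.0, 0.0, -ox],
            [0.0, -sy, 0.0, -oy],
            [0.0, 0.0, sz, oz],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    img = nib.Nifti1Image(np.asarray(grid.values), affine)
    img.set_data_dtype(np.asarray(grid.values).dtype)
    nib.save(img, str(path))
    return path


def read_mask(path, label: str, source: str = GOLD_SOURCE) -> BinaryMask:
    """Read a NIfTI file as a binary mask (nonzero -> foreground)."""
    grid = read_volume(path)
    values = (np.asarray(grid.values) != 0).astype(np.uint8)
    return BinaryMask(
        grid=VolumeGrid(values, grid.spacing, grid.origin), label=label, source=source
    )


def read_dose(path) -> DoseGrid:
    grid = read_volume(path)
    return DoseGrid(grid=VolumeGrid(np.asarray(grid.values, dtype=float), grid.spacing, grid.origin))


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


def load_manifest(path) -> CohortManifest:
    """Load and eagerly validate a JSON cohort manifest.

    Schema: ``{"patients": [{"id": str,
    "structures": {name: {source: path}}, "dose": path|null}, ...]}``.
    Relative paths are resolved against the manifest's directory.

    Raises
    ------
    ManifestError
        On schema violations, duplicate patient ids, or dangling paths.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"no such manifest: {path}")
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "patients" not in doc:
        raise ManifestError(f"{path}: manifest must be an object with a 'patients' array")
    root = path.parent
    entries = []
    for raw in doc["patients"]:
        try:
            entry = PatientEntry(
                patient_id=str(raw["id"]),
                structures={
                    str(s): {str(src): str(p) for src, p in srcmap.items()}
                    for s, srcmap in raw.get("structures", {}).items()
                },
                dose=raw.get("dose"),
                tilt_deg=raw.get("tilt_deg"),
            )
        except (KeyError, AttributeError, TypeError) as exc:
            raise ManifestError(f"{path}: malformed patient entry {raw!r}") from exc
        entries.append(entry)
    manifest = CohortManifest(patients=entries, root=root)
    missing = []
    for pat in manifest:
        for structure, srcmap in pat.structures.items():
            for source, rel in srcmap.items():
                if not manifest.resolve(rel).exists():
                    missing.append(f"{pat.patient_id}/{structure}/{source}: {rel}")
        if pat.dose is not None and not manifest.resolve(pat.dose).exists():
            missing.append(f"{pat.patient_id}/dose: {pat.dose}")
    if missing:
        raise ManifestError("dangling paths in manifest:\n  " + "\n  ".join(missing))
    return manifest
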