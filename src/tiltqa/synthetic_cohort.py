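"""Phantom cohort generator.

Emulates the study population the pipeline is designed for: head-and-neck
patients whose upper cervical spine is tilted in the sagittal plane, with
laterally placed parotid-like organs whose auto-contour error grows once
the tilt deviates from the cohort median, a midline control organ
(brainstem-like) whose error does not depend on tilt, and a Gaussian
photon-dose bath centered near the superior cord.

Every patient consists of:

* a solid cylindrical cord of length L tilted by its true angle theta
  (direction ``(0, -sin theta, cos theta)`` in LPS, flexion positive);
* four vertebra boxes C1-C4 stacked along the cord axis covering the
  cord's superior ``4 * vertebra_height`` mm (C1 most superior);
* gold organ ellipsoids placed relative to the superior cord end;
* per simulated vendor, a test contour per organ: the gold ellipsoid
  translated by a random vector with per-axis sd ``perturbation_sd(theta)``
  and then dilated or eroded by a random radius of 0 or 1 voxels
  (the control organ always uses the baseline sd ``sigma0``);
* a dose grid ``D(p) = Dmax * exp(-|p - c|^2 / (2 sigma_d^2))`` whose
  center c sits at the superior cord end, jittered per patient.

Masks for one (patient, structure) pair share a tight bounding grid at CT
spacing; the spine structures share one grid; the dose grid is coarser.
Downstream code never assumes a single grid per patient.

The whole cohort is a pure function of ``(GeneratorConfig, seed)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .io_core import (
    BinaryMask,
    CohortManifest,
    DoseGrid,
    GOLD_SOURCE,
    PatientEntry,
    VolumeGrid,
    write_volume,
)

__all__ = [
    "GeneratorConfig",
    "OrganPerturbation",
    "PatientTruth",
    "PhantomTruth",
    "PatientData",
    "CohortData",
    "perturbation_sd",
    "build_cohort",
    "simulate_cohort",
    "TILT_SENSITIVE_ORGANS",
    "CONTROL_ORGANS",
]

TILT_SENSITIVE_ORGANS = ("parotid_l", "parotid_r")
CONTROL_ORGANS = ("brainstem",)
ALL_ORGANS = TILT_SENSITIVE_ORGANS + CONTROL_ORGANS


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level knobs. Lengths in mm, angles in degrees, dose in Gy."""

    n_patients: int = 35
    n_vendors: int = 1
    # sagittal tilt distribution: Normal truncated to [lo, hi]
    tilt_mean_deg: float = 12.0
    tilt_sd_deg: float = 15.0
    tilt_bounds_deg: Tuple[float, float] = (-25.0, 70.0)
    # anatomy
    cord_radius_mm: float = 5.0
    cord_length_mm: float = 60.0
    vertebra_height_mm: float = 15.0
    vertebra_halfwidth_mm: float = 10.0
    parotid_semiaxes_mm: Tuple[float, float, float] = (12.0, 18.0, 22.0)
    parotid_offset_mm: float = 35.0
    control_semiaxes_mm: Tuple[float, float, float] = (10.0, 10.0, 20.0)
    spacing_mm: Tuple[float, float, float] = (1.27, 1.27, 2.0)
    # tilt-dependent contour perturbation
    sigma0_mm: float = 1.0
    k_mm_per_deg: float = 0.15
    deadband_deg: float = 15.0
    # dose model
    dose_max_gy: float = 70.0
    dose_sigma_mm: float = 30.0
    dose_center_jitter_mm: float = 10.0
    dose_spacing_mm: Tuple[float, float, float] = (3.0, 3.0, 3.0)
    grid_pad_mm: float = 6.0

    def __post_init__(self):
        lo, hi = self.tilt_bounds_deg
        if not lo <= self.tilt_mean_deg <= hi:
            raise ValueError("tilt truncation bounds must contain the mean")
        positive = (
            self.n_patients,
            self.n_vendors,
            self.cord_radius_mm,
            self.cord_length_mm,
            self.vertebra_height_mm,
            self.vertebra_halfwidth_mm,
            *self.parotid_semiaxes_mm,
            self.parotid_offset_mm,
            *self.control_semiaxes_mm,
            *self.spacing_mm,
            self.sigma0_mm,
            self.dose_max_gy,
            self.dose_sigma_mm,
            *self.dose_spacing_mm,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("all sizes, counts and scales must be positive")
        if self.k_mm_per_deg < 0 or self.deadband_deg < 0:
            raise ValueError("perturbation slope and deadband must be non-negative")


@dataclass
class OrganPerturbation:
    shift_mm: Tuple[float, float, float]
    morph_voxels: int  # +1 dilate, -1 erode, 0 none


@dataclass
class PatientTruth:
    patient_id: str
    tilt_deg: float
    dose_center_mm: Tuple[float, float, float]
    perturbations: Dict[str, Dict[str, OrganPerturbation]]  # vendor -> organ


@dataclass
class PhantomTruth:
    """Everything needed to recompute every expected downstream value."""

    median_tilt_deg: float
    patients: List[PatientTruth]
    config: GeneratorConfig = field(default_factory=GeneratorConfig)

    def tilt_of(self, patient_id: str) -> float:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p.tilt_deg
        raise KeyError(patient_id)

    def to_json(self, path) -> None:
        doc = {
            "median_tilt_deg": self.median_tilt_deg,
            "config": asdict(self.config),
            "patients": [asdict(p) for p in self.patients],
        }
        Path(path).write_text(json.dumps(doc, indent=1))


@dataclass
class PatientData:
    """In-memory phantom patient: masks keyed by (structure, source)."""

    patient_id: str
    masks: Dict[Tuple[str, str], BinaryMask]
    dose: DoseGrid

    def mask(self, structure: str, source: str = GOLD_SOURCE) -> BinaryMask:
        return self.masks[(structure, source)]


@dataclass
class CohortData:
    patients: List[PatientData]
    truth: PhantomTruth

    def __iter__(self):
        return iter(self.patients)

    def __len__(self):
        return len(self.patients)

    def vendors(self) -> List[str]:
        out = set()
        for p in self.patients:
            out.update(src for (_, src) in p.masks if src != GOLD_SOURCE)
        return sorted(out)


# ---------------------------------------------------------------------------
# Perturbation model
# ---------------------------------------------------------------------------


def perturbation_sd(
    theta_deg: float, config: GeneratorConfig, median_deg: Optional[float] = None
) -> float:
    """Per-axis sd (mm) of the vendor contour translation at tilt theta.

    ``sigma0 + k * max(0, |theta - median| - deadband)``: flat across the
    normal tilt range, growing linearly once the deviation from the cohort
    median exceeds the deadband. ``median_deg`` defaults to the configured
    tilt-distribution mean when no cohort median is supplied.
    """
    if not math.isfinite(theta_deg):
        raise ValueError("tilt angle must be finite")
    med = config.tilt_mean_deg if median_deg is None else median_deg
    excess = max(0.0, abs(theta_deg - med) - config.deadband_deg)
    return config.sigma0_mm + config.k_mm_per_deg * excess


def _sample_truncated_normal(rng, mean, sd, bounds, size):
    lo, hi = bounds
    out = np.empty(size)
    need = np.ones(size, dtype=bool)
    while need.any():
        draw = rng.normal(mean, sd, size=int(need.sum()))
        out[need] = draw
        need = (out < lo) | (out > hi)
    return out


# ---------------------------------------------------------------------------
# Rasterization helpers
# ---------------------------------------------------------------------------


def _make_grid_box(lo, hi, spacing):
    """Grid whose voxel centers cover the physical box [lo, hi]."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    spacing = np.asarray(spacing, float)
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 1)
    return tuple(lo), tuple(shape)


def _grid_axes(origin, shape, spacing):
    return [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]


def _rasterize_ellipsoid(origin, shape, spacing, center, semiaxes):
    ax = _grid_axes(origin, shape, spacing)
    x = (ax[0][:, None, None] - center[0]) / semiaxes[0]
    y = (ax[1][None, :, None] - center[1]) / semiaxes[1]
    z = (ax[2][None, None, :] - center[2]) / semiaxes[2]
    return (x * x + y * y + z * z <= 1.0).astype(np.uint8)


def _spine_arrays(origin, shape, spacing, p0, direction, config):
    """Cord cylinder plus four vertebra boxes, all on one grid."""
    ax = _grid_axes(origin, shape, spacing)
    dx = ax[0][:, None, None] - p0[0]
    dy = ax[1][None, :, None] - p0[1]
    dz = ax[2][None, None, :] - p0[2]
    d = np.asarray(direction, float)
    t = dx * d[0] + dy * d[1] + dz * d[2]  # coordinate along cord axis
    perp2 = (dx - t * d[0]) ** 2 + (dy - t * d[1]) ** 2 + (dz - t * d[2]) ** 2
    L = config.cord_length_mm
    cord = (t >= 0.0) & (t <= L) & (perp2 <= config.cord_radius_mm**2)
    # box cross-section axes: u lateral (x), v = d x u in the sagittal plane
    v = np.array([0.0, d[2], -d[1]])  # unit, orthogonal to d and to x
    v /= np.linalg.norm(v)
    ucoord = np.abs(dx + 0.0 * t)
    vcoord = np.abs(dx * v[0] + dy * v[1] + dz * v[2])
    hw = config.vertebra_halfwidth_mm
    h = config.vertebra_height_mm
    boxes = []
    for i in range(4):  # C1 most superior
        t_hi = L - i * h
        t_lo = L - (i + 1) * h
        boxes.append(
            (t >= t_lo) & (t < t_hi) & (ucoord <= hw) & (vcoord <= hw)
        )
    return cord.astype(np.uint8), [b.astype(np.uint8) for b in boxes]


_MORPH_STRUCT = ndimage.generate_binary_structure(3, 1)


def _apply_morphology(values: np.ndarray, morph: int) -> np.ndarray:
    if morph > 0:
        return ndimage.binary_dilation(values, _MORPH_STRUCT).astype(np.uint8)
    if morph < 0:
        return ndimage.binary_erosion(values, _MORPH_STRUCT).astype(np.uint8)
    return values


# ---------------------------------------------------------------------------
# Cohort construction
# ---------------------------------------------------------------------------


def _organ_layout(p1, config) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Gold (center, semiaxes) per organ, relative to superior cord end p1."""
    par = np.asarray(config.parotid_semiaxes_mm)
    ctl = np.asarray(config.control_semiaxes_mm)
    off = config.parotid_offset_mm
    return {
        "parotid_l": (p1 + np.array([off, 0.0, 0.0]), par),
        "parotid_r": (p1 + np.array([-off, 0.0, 0.0]), par),
        "brainstem": (p1 + np.array([0.0, 0.0, 10.0]), ctl),
    }


def build_cohort(config: GeneratorConfig = GeneratorConfig(), seed: int = 0) -> CohortData:
    """Generate a full in-memory phantom cohort, deterministically in seed."""
    rng = np.random.default_rng(seed)
    n = config.n_patients
    tilts = _sample_truncated_normal(
        rng, config.tilt_mean_deg, config.tilt_sd_deg, config.tilt_bounds_deg, n
    )
    median_tilt = float(np.median(tilts))
    dose_jitter = rng.normal(0.0, config.dose_center_jitter_mm, size=(n, 3))

    spacing = config.spacing_mm
    pad = config.grid_pad_mm
    vendors = [f"vendor{v + 1}" for v in range(config.n_vendors)]

    patients: List[PatientData] = []
    truths: List[PatientTruth] = []
    p0 = np.array([0.0, 10.0, 0.0])  # cord inferior end, fixed for all patients
    for i in range(n):
        pid = f"P{i + 1:03d}"
        theta = float(tilts[i])
        rad = math.radians(theta)
        d = np.array([0.0, -math.sin(rad), math.cos(rad)])
        p1 = p0 + config.cord_length_mm * d

        masks: Dict[Tuple[str, str], BinaryMask] = {}

        # --- spine on one grid -------------------------------------------
        margin = max(config.cord_radius_mm, config.vertebra_halfwidth_mm * math.sqrt(2)) + pad
        lo = np.minimum(p0, p1) - margin
        hi = np.maximum(p0, p1) + margin
        origin, shape = _make_grid_box(lo, hi, spacing)
        cord, boxes = _spine_arrays(origin, shape, spacing, p0, d, config)
        masks[("cord", GOLD_SOURCE)] = BinaryMask(
            VolumeGrid(cord, spacing, origin), "cord", GOLD_SOURCE
        )
        for ci, box in enumerate(boxes):
            name = f"C{ci + 1}"
            masks[(name, GOLD_SOURCE)] = BinaryMask(
                VolumeGrid(box, spacing, origin), name, GOLD_SOURCE
            )

        # --- organs: gold + one test mask per vendor ----------------------
        layout = _organ_layout(p1, config)
        sd_tilt = perturbation_sd(theta, config, median_tilt)
        perturbs: Dict[str, Dict[str, OrganPerturbation]] = {v: {} for v in vendors}
        organ_boxes = []
        for organ in ALL_ORGANS:
            center, semi = layout[organ]
            sd = config.sigma0_mm if organ in CONTROL_ORGANS else sd_tilt
            shifts = {}
            for v in vendors:
                shift = rng.normal(0.0, sd, size=3)
                radius = int(rng.integers(0, 2))
                sign = 1 if rng.integers(0, 2) == 1 else -1
                morph = sign * radius
                shifts[v] = (shift, morph)
                perturbs[v][organ] = OrganPerturbation(tuple(map(float, shift)), morph)
            # one grid covering gold + every vendor's shifted ellipsoid
            morph_margin = np.asarray(spacing)
            lo = center - semi - morph_margin - pad
            hi = center + semi + morph_margin + pad
            for shift, _ in shifts.values():
                lo = np.minimum(lo, center + shift - semi - morph_margin - pad)
                hi = np.maximum(hi, center + shift + semi + morph_margin + pad)
            origin, shape = _make_grid_box(lo, hi, spacing)
            organ_boxes.append((np.asarray(origin), np.asarray(origin) + (np.asarray(shape) - 1) * np.asarray(spacing)))
            gold_vals = _rasterize_ellipsoid(origin, shape, spacing, center, semi)
            masks[(organ, GOLD_SOURCE)] = BinaryMask(
                VolumeGrid(gold_vals, spacing, origin), organ, GOLD_SOURCE
            )
            for v in vendors:
                shift, morph = shifts[v]
                vals = _rasterize_ellipsoid(origin, shape, spacing, center + shift, semi)
                vals = _apply_morphology(vals, morph)
                masks[(organ, v)] = BinaryMask(VolumeGrid(vals, spacing, origin), organ, v)

        # --- dose ----------------------------------------------------------
        c = p1 + dose_jitter[i]
        lo = np.min([b[0] for b in organ_boxes], axis=0) - pad
        hi = np.max([b[1] for b in organ_boxes], axis=0) + pad
        dorigin, dshape = _make_grid_box(lo, hi, config.dose_spacing_mm)
        ax = _grid_axes(dorigin, dshape, config.dose_spacing_mm)
        r2 = (
            (ax[0][:, None, None] - c[0]) ** 2
            + (ax[1][None, :, None] - c[1]) ** 2
            + (ax[2][None, None, :] - c[2]) ** 2
        )
        dose_vals = config.dose_max_gy * np.exp(-r2 / (2.0 * config.dose_sigma_mm**2))
        dose = DoseGrid(VolumeGrid(dose_vals, config.dose_spacing_mm, dorigin))

        patients.append(PatientData(pid, masks, dose))
        truths.append(PatientTruth(pid, theta, tuple(map(float, c)), perturbs))

    return CohortData(patients, PhantomTruth(median_tilt, truths, config))


# ---------------------------------------------------------------------------
# Disk output
# ---------------------------------------------------------------------------


def simulate_cohort(
    config: GeneratorConfig = GeneratorConfig(), seed: int = 0, out_dir=None
):
    """Generate a cohort and write it to disk as NIfTI volumes + manifest.

    Returns ``(CohortManifest, PhantomTruth)``. ``manifest.json`` and
    ``truth.json`` land in ``out_dir`` with volume paths relative to it.
    """
    if out_dir is None:
        raise ValueError("out_dir is required to write a cohort")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = build_cohort(config, seed)

    entries = []
    for pat in cohort:
        structures: Dict[str, Dict[str, str]] = {}
        for (structure, source), mask in sorted(pat.masks.items()):
            rel = f"{pat.patient_id}/{structure}__{source}.nii"
            write_volume(mask.grid, out_dir / rel)
            structures.setdefault(structure, {})[source] = rel
        dose_rel = f"{pat.patient_id}/dose.nii"
        write_volume(pat.dose.grid, out_dir / dose_rel)
        entries.append(
            PatientEntry(
                patient_id=pat.patient_id,
                structures=structures,
                dose=dose_rel,
                tilt_deg=cohort.truth.tilt_of(pat.patient_id),
            )
        )
    manifest = CohortManifest(patients=entries, root=out_dir)
    doc = {
        "patients": [
            {
                "id": e.patient_id,
                "structures": e.structures,
                "dose": e.dose,
                "tilt_deg": e.tilt_deg,
            }
            for e in entries
        ]
    }
    (out_dir / "manifest.json").write_text(json.dumps(doc, indent=1))
    cohort.truth.to_json(out_dir / "truth.json")
    return manifest, cohort.truth
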