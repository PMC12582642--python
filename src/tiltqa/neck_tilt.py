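"""Sagittal neck-tilt measurement and cohort stratification.

The tilt angle is the angle between the upper cervical cord and the
longitudinal (z) axis, measured in the sagittal (y-z) plane. The cord is
restricted to the longitudinal extent of the C1-C4 vertebrae, PCA is run
on the physical coordinates of the remaining cord voxels, and the first
principal component is projected to (y, z). With flexion (chin toward
chest) the superior cord leans anterior, which is -y in LPS, so

    tilt_deg = degrees(atan2(-v_y, v_z)),   v oriented so v_z >= 0,

makes flexion positive and extension negative. A linear fit through the
four vertebra centroids in the sagittal plane provides an independent
slope-based estimate of the same angle and serves as a per-patient
cross-check on the PCA value.

A cohort is stratified by nearest-rank percentiles of the tilt sample
(default 12th/88th): tilts strictly below the lower threshold or strictly
above the upper one are labelled abnormal, everything else normal. For 35
distinct tilts this convention yields exactly 8 abnormal patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .io_core import (
    BinaryMask,
    DegenerateGeometryError,
    GridMismatchError,
    NoOverlapError,
)

__all__ = [
    "TiltResult",
    "CohortStratification",
    "cord_c1c4_voxels",
    "pca_tilt_angle",
    "centroid_slope_angle",
    "stratify",
    "measure_patient",
    "MIN_PCA_VOXELS",
    "AGREEMENT_TOL_DEG",
]

#: below this many cord voxels the covariance is unreliable on 2 mm slices
MIN_PCA_VOXELS = 20
#: |PCA - centroid-slope| tolerance for the per-patient agreement flag
AGREEMENT_TOL_DEG = 2.0


@dataclass(frozen=True)
class TiltResult:
    patient_id: str
    tilt_deg: float
    principal_vector: Tuple[float, float, float]
    n_voxels: int
    centroid_slope_deg: float
    agreement_flag: bool
    degenerate_pca: bool = False  # equal leading eigenvalues; ordering tie-broken


@dataclass(frozen=True)
class CohortStratification:
    lower_threshold_deg: float
    upper_threshold_deg: float
    labels: Dict[str, str]  # patient id -> "normal" | "abnormal"
    lower_pct: float = 12.0
    upper_pct: float = 88.0

    @property
    def n_abnormal(self) -> int:
        return sum(1 for v in self.labels.values() if v == "abnormal")

    @property
    def n_normal(self) -> int:
        return sum(1 for v in self.labels.values() if v == "normal")


def _require_shared_grid(masks: Sequence[BinaryMask]) -> None:
    ref = masks[0].grid
    for m in masks[1:]:
        if not ref.same_geometry(m.grid):
            raise GridMismatchError(
                f"masks {masks[0].label!r} and {m.label!r} are not on one grid"
            )


def cord_c1c4_voxels(cord: BinaryMask, vertebrae: Sequence[BinaryMask]) -> np.ndarray:
    """Physical centers (mm) of cord voxels within the C1-C4 z-extent.

    The longitudinal extent is taken as the set of z-slices in which the
    union of the four vertebra masks has at least one foreground voxel.

    Returns an (n, 3) array of LPS coordinates; raises
    :class:`NoOverlapError` if no cord voxel falls in those slices.
    """
    if len(vertebrae) != 4:
        raise ValueError(f"expected four vertebra masks, got {len(vertebrae)}")
    _require_shared_grid([cord, *vertebrae])
    if cord.foreground_count == 0:
        raise DegenerateGeometryError("cord mask is empty")
    union = np.zeros(cord.grid.shape[2], dtype=bool)
    for v in vertebrae:
        if v.foreground_count == 0:
            raise DegenerateGeometryError(f"vertebra mask {v.label!r} is empty")
        union |= v.values.any(axis=(0, 1))
    idx = cord.foreground_indices()
    keep = union[idx[:, 2]]
    if not keep.any():
        raise NoOverlapError("cord does not overlap the C1-C4 longitudinal extent")
    return cord.grid.index_to_physical(idx[keep])


def pca_tilt_angle(coords: np.ndarray, patient_id: str = "") -> TiltResult:
    """Tilt angle from PCA of cord voxel coordinates.

    3D PCA is run on the coordinates; the leading eigenvector is oriented
    superiorly (v_z >= 0) and its (y, z) components give the signed
    sagittal angle. The result is independent of point ordering.

    The returned :class:`TiltResult` has ``centroid_slope_deg`` NaN and
    ``agreement_flag`` False; :func:`measure_patient` fills them in.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("coords must be an (n, 3) array of mm positions")
    n = pts.shape[0]
    if n < MIN_PCA_VOXELS:
        raise DegenerateGeometryError(
            f"need at least {MIN_PCA_VOXELS} cord voxels for PCA, got {n}"
        )
    centered = pts - pts.mean(axis=0)
    if not centered.any():
        raise DegenerateGeometryError("all cord coordinates identical")
    cov = centered.T @ centered / (n - 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    order = np.argsort(evals, kind="stable")
    v = evecs[:, order[-1]]
    degenerate = bool(np.isclose(evals[order[-1]], evals[order[-2]], rtol=1e-9, atol=0.0))
    if degenerate:
        # deterministic tie-break: among tied leading eigenvectors pick the
        # lexicographically largest absolute-component representative
        tied = [i for i in order if np.isclose(evals[i], evals[order[-1]], rtol=1e-9, atol=0.0)]
        cand = sorted((tuple(np.round(np.abs(evecs[:, i]), 12)), i) for i in tied)
        v = evecs[:, cand[-1][1]]
    if v[2] < 0 or (v[2] == 0 and (v[1] > 0 or (v[1] == 0 and v[0] < 0))):
        v = -v
    tilt = math.degrees(math.atan2(-v[1], v[2]))
    return TiltResult(
        patient_id=patient_id,
        tilt_deg=tilt,
        principal_vector=tuple(map(float, v)),
        n_voxels=n,
        centroid_slope_deg=float("nan"),
        agreement_flag=False,
        degenerate_pca=degenerate,
    )


def centroid_slope_angle(vertebrae: Sequence[BinaryMask]) -> float:
    """Sagittal angle from a line fit through the C1-C4 centroids.

    Each vertebra's foreground centroid is projected to (y, z) mm and a
    least-squares line ``y = a*z + b`` is fit over the four centroids;
    the returned angle is ``degrees(atan(-a))``, matching the PCA sign
    convention (flexion positive).
    """
    if len(vertebrae) != 4:
        raise ValueError(f"expected four vertebra masks, got {len(vertebrae)}")
    _require_shared_grid(list(vertebrae))
    ys, zs = [], []
    for v in vertebrae:
        if v.foreground_count == 0:
            raise DegenerateGeometryError(f"vertebra mask {v.label!r} is empty")
        c = v.foreground_coords_mm().mean(axis=0)
        ys.append(c[1])
        zs.append(c[2])
    zs = np.asarray(zs)
    ys = np.asarray(ys)
    if np.ptp(zs) < 1e-9:
        raise DegenerateGeometryError(
            "vertebra centroids share one z position; sagittal slope undefined"
        )
    a, _ = np.polyfit(zs, ys, 1)
    return math.degrees(math.atan(-a))


def measure_patient(
    cord: BinaryMask, vertebrae: Sequence[BinaryMask], patient_id: str = ""
) -> TiltResult:
    """PCA tilt plus centroid-slope cross-check for one patient."""
    coords = cord_c1c4_voxels(cord, vertebrae)
    res = pca_tilt_angle(coords, patient_id=patient_id)
    slope = centroid_slope_angle(vertebrae)
    return TiltResult(
        patient_id=res.patient_id,
        tilt_deg=res.tilt_deg,
        principal_vector=res.principal_vector,
        n_voxels=res.n_voxels,
        centroid_slope_deg=slope,
        agreement_flag=abs(res.tilt_deg - slope) <= AGREEMENT_TOL_DEG,
        degenerate_pca=res.degenerate_pca,
    )


def _nearest_rank(sorted_vals: np.ndarray, pct: float) -> float:
    n = len(sorted_vals)
    rank = max(1, math.ceil(pct / 100.0 * n))
    return float(sorted_vals[min(rank, n) - 1])


def stratify(
    tilts: Sequence[Tuple[str, float]],
    lower_pct: float = 12.0,
    upper_pct: float = 88.0,
) -> CohortStratification:
    """Label each patient normal/abnormal by percentile cutoffs on tilt.

    Thresholds are nearest-rank percentiles (the value at rank
    ``ceil(p/100 * n)`` of the sorted sample). A tilt is abnormal iff it
    lies strictly below the lower threshold or strictly above the upper
    one; both thresholds themselves are normal.
    """
    tilts = list(tilts)
    if len(tilts) < 3:
        raise ValueError("need at least 3 patients to stratify")
    if not (0 < lower_pct < upper_pct < 100):
        raise ValueError("percentiles must satisfy 0 < lower < upper < 100")
    values = np.asarray([t for _, t in tilts], dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("tilt values must be finite")
    s = np.sort(values)
    lo = _nearest_rank(s, lower_pct)
    hi = _nearest_rank(s, upper_pct)
    labels = {
        pid: ("abnormal" if (t < lo or t > hi) else "normal") for pid, t in tilts
    }
    return CohortStratification(lo, hi, labels, lower_pct, upper_pct)
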