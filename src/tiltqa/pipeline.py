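"""End-to-end orchestration: simulate -> tilt -> stratify -> metrics -> dose -> analyze.

Stages exchange plain pandas DataFrames and are written to CSV between
steps, so each stage can be re-run, inspected or replaced in isolation.
Every constant that shapes the analysis (surface tolerance, percentile
cutoffs, dose exclusion threshold, significance tiers, seed) lives in
:class:`RunConfig` and is echoed into the machine-readable run log.

Stages accept either an on-disk cohort (a :class:`~tiltqa.io_core.CohortManifest`,
volumes loaded lazily per patient) or an in-memory
:class:`~tiltqa.synthetic_cohort.CohortData` phantom cohort.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import contour_metrics, dose_analysis, group_stats, neck_tilt
from .io_core import (
    BinaryMask,
    CohortManifest,
    DoseGrid,
    GOLD_SOURCE,
    ManifestError,
    SPINE_STRUCTURES,
    UndefinedMetricError,
    load_manifest,
    read_dose,
    read_mask,
)
from .synthetic_cohort import CohortData, GeneratorConfig, simulate_cohort

logger = logging.getLogger("tiltqa")

__all__ = [
    "RunConfig",
    "RunResult",
    "tilt_stage",
    "stratify_stage",
    "metrics_stage",
    "dose_stage",
    "analyze_stage",
    "melt_records",
    "box_summary",
    "plot_tilt_histogram",
    "run_all",
]

MetricFrameCols = ["patient", "structure", "source", "dsc", "sdsc", "mda_mm", "tau_mm", "status"]


@dataclass(frozen=True)
class RunConfig:
    """All run-level constants in one place."""

    manifest_path: Optional[str] = None
    out_dir: str = "tiltqa_out"
    tau_mm: float = 2.0
    lower_pct: float = 12.0
    upper_pct: float = 88.0
    exclusion_gy: float = 5.0
    tiers: Tuple[float, float] = (0.05, 0.01)
    structures: Optional[Tuple[str, ...]] = None  # None -> all non-spine structures
    seed: int = 0
    simulate: bool = False
    simulate_n: int = 35
    simulate_vendors: int = 1

    def __post_init__(self):
        if not (0 < self.lower_pct < self.upper_pct < 100):
            raise ValueError("percentiles must satisfy 0 < lower < upper < 100")
        if self.tau_mm <= 0:
            raise ValueError("surface tolerance must be positive")
        if self.exclusion_gy < 0:
            raise ValueError("dose exclusion threshold must be non-negative")
        if not self.simulate and self.manifest_path is None:
            raise ValueError("either a manifest path or --simulate is required")


@dataclass
class RunResult:
    tilt: pd.DataFrame
    cohort: pd.DataFrame
    stratification: neck_tilt.CohortStratification
    metrics: pd.DataFrame
    dose: pd.DataFrame
    results: pd.DataFrame
    summary: pd.DataFrame
    paths: Dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Cohort access (disk or memory)
# ---------------------------------------------------------------------------


class _CohortAccess:
    """Uniform lazy access to masks and dose for either cohort kind."""

    def __init__(self, cohort: Union[CohortManifest, CohortData]):
        self._c = cohort
        self._disk = isinstance(cohort, CohortManifest)

    def patient_ids(self) -> List[str]:
        if self._disk:
            return [p.patient_id for p in self._c]
        return [p.patient_id for p in self._c.patients]

    def structures(self, pid: str) -> Dict[str, List[str]]:
        """structure -> sorted list of sources available for this patient."""
        if self._disk:
            entry = self._c.entry(pid)
            return {s: sorted(m) for s, m in entry.structures.items()}
        pat = next(p for p in self._c.patients if p.patient_id == pid)
        out: Dict[str, List[str]] = {}
        for (structure, source) in pat.masks:
            out.setdefault(structure, []).append(source)
        return {s: sorted(v) for s, v in out.items()}

    def mask(self, pid: str, structure: str, source: str) -> BinaryMask:
        if self._disk:
            entry = self._c.entry(pid)
            path = self._c.resolve(entry.path(structure, source))
            return read_mask(path, label=structure, source=source)
        pat = next(p for p in self._c.patients if p.patient_id == pid)
        return pat.masks[(structure, source)]

    def dose(self, pid: str) -> Optional[DoseGrid]:
        if self._disk:
            entry = self._c.entry(pid)
            if entry.dose is None:
                return None
            return read_dose(self._c.resolve(entry.dose))
        pat = next(p for p in self._c.patients if p.patient_id == pid)
        return pat.dose

    def organ_structures(self) -> List[str]:
        out = set()
        for pid in self.patient_ids():
            out.update(self.structures(pid))
        return sorted(out - set(SPINE_STRUCTURES))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def tilt_stage(cohort: Union[CohortManifest, CohortData]) -> pd.DataFrame:
    """Per-patient PCA tilt with centroid-slope cross-check.

    Requires cord and C1-C4 (gold source) for every patient; a missing
    spine structure raises :class:`ManifestError` naming the patient.
    """
    acc = _CohortAccess(cohort)
    rows = []
    for pid in acc.patient_ids():
        avail = acc.structures(pid)
        for s in SPINE_STRUCTURES:
            if s not in avail or GOLD_SOURCE not in avail[s]:
                raise ManifestError(
                    f"patient {pid!r} lacks structure {s!r} (source {GOLD_SOURCE!r}) "
                    "required for tilt analysis"
                )
        cord = acc.mask(pid, "cord", GOLD_SOURCE)
        vertebrae = [acc.mask(pid, f"C{i}", GOLD_SOURCE) for i in (1, 2, 3, 4)]
        res = neck_tilt.measure_patient(cord, vertebrae, patient_id=pid)
        rows.append(
            {
                "patient": pid,
                "tilt_deg": res.tilt_deg,
                "centroid_slope_deg": res.centroid_slope_deg,
                "n_voxels": res.n_voxels,
                "agreement_flag": res.agreement_flag,
            }
        )
        logger.debug("tilt %s: %.2f deg (%d voxels)", pid, res.tilt_deg, res.n_voxels)
    return pd.DataFrame(rows)


def stratify_stage(
    tilt: pd.DataFrame, lower_pct: float = 12.0, upper_pct: float = 88.0
):
    """Label patients normal/abnormal; returns (frame, CohortStratification)."""
    pairs = list(zip(tilt["patient"], tilt["tilt_deg"]))
    strat = neck_tilt.stratify(pairs, lower_pct, upper_pct)
    frame = tilt[["patient", "tilt_deg"]].copy()
    frame["label"] = frame["patient"].map(strat.labels)
    logger.info(
        "stratified %d patients: %d normal, %d abnormal (thresholds %.2f / %.2f deg)",
        len(frame), strat.n_normal, strat.n_abnormal,
        strat.lower_threshold_deg, strat.upper_threshold_deg,
    )
    return frame, strat


def metrics_stage(
    cohort: Union[CohortManifest, CohortData],
    structures: Optional[Sequence[str]] = None,
    tau_mm: float = 2.0,
) -> pd.DataFrame:
    """Geometric metrics for every (patient, structure, non-gold source).

    Pairs where either mask is empty yield a row with NaN metrics and a
    non-'ok' status instead of aborting the run.
    """
    acc = _CohortAccess(cohort)
    wanted = list(structures) if structures is not None else acc.organ_structures()
    rows = []
    for pid in acc.patient_ids():
        avail = acc.structures(pid)
        for structure in wanted:
            sources = avail.get(structure, [])
            if GOLD_SOURCE not in sources:
                continue
            gold = acc.mask(pid, structure, GOLD_SOURCE)
            for source in sources:
                if source == GOLD_SOURCE:
                    continue
                test = acc.mask(pid, structure, source)
                row = {
                    "patient": pid, "structure": structure, "source": source,
                    "dsc": np.nan, "sdsc": np.nan, "mda_mm": np.nan,
                    "tau_mm": tau_mm, "status": "ok",
                }
                try:
                    rec = contour_metrics.score_pair(gold, test, tau_mm, patient_id=pid)
                    row.update(dsc=rec.dsc, sdsc=rec.sdsc, mda_mm=rec.mda_mm)
                except UndefinedMetricError as exc:
                    row["status"] = "missing"
                    logger.warning("metrics %s/%s/%s undefined: %s", pid, structure, source, exc)
                rows.append(row)
    return pd.DataFrame(rows, columns=MetricFrameCols)


def dose_stage(
    cohort: Union[CohortManifest, CohortData],
    structures: Optional[Sequence[str]] = None,
    exclusion_gy: float = 5.0,
) -> pd.DataFrame:
    """Mean-dose differences for every (patient, structure, source) triple."""
    acc = _CohortAccess(cohort)
    wanted = list(structures) if structures is not None else acc.organ_structures()
    rows = []
    for pid in acc.patient_ids():
        dose = acc.dose(pid)
        if dose is None:
            logger.warning("patient %s has no dose grid; skipped in dose stage", pid)
            continue
        avail = acc.structures(pid)
        for structure in wanted:
            sources = avail.get(structure, [])
            if GOLD_SOURCE not in sources:
                continue
            gold = acc.mask(pid, structure, GOLD_SOURCE)
            for source in sources:
                if source == GOLD_SOURCE:
                    continue
                test = acc.mask(pid, structure, source)
                try:
                    rec = dose_analysis.dose_difference(
                        dose, gold, test, exclusion_gy, patient_id=pid
                    )
                except UndefinedMetricError as exc:
                    logger.warning("dose %s/%s/%s undefined: %s", pid, structure, source, exc)
                    continue
                rows.append(
                    {
                        "patient": pid, "structure": structure, "source": source,
                        "mean_gold_gy": rec.mean_dose_gold_gy,
                        "mean_test_gy": rec.mean_dose_test_gy,
                        "signed_diff_gy": rec.signed_diff_gy,
                        "abs_diff_gy": rec.abs_diff_gy,
                        "excluded": rec.excluded,
                        "reason": rec.reason,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "patient", "structure", "source", "mean_gold_gy", "mean_test_gy",
            "signed_diff_gy", "abs_diff_gy", "excluded", "reason",
        ],
    )


def melt_records(metrics: pd.DataFrame, dose: pd.DataFrame) -> pd.DataFrame:
    """Long-form (patient, structure, source, metric, value, usable) frame."""
    parts = []
    if len(metrics):
        for col in ("dsc", "sdsc", "mda_mm"):
            part = metrics[["patient", "structure", "source", col, "status"]].copy()
            part["metric"] = col
            part["value"] = part.pop(col)
            part["usable"] = (part.pop("status") == "ok") & part["value"].notna()
            parts.append(part)
    if len(dose):
        for col, name in (("abs_diff_gy", "abs_dose_diff_gy"), ("signed_diff_gy", "signed_dose_diff_gy")):
            part = dose[["patient", "structure", "source", col, "excluded"]].copy()
            part["metric"] = name
            part["value"] = part.pop(col)
            part["usable"] = ~part.pop("excluded").astype(bool)
            parts.append(part)
    if not parts:
        return pd.DataFrame(
            columns=["patient", "structure", "source", "metric", "value", "usable"]
        )
    return pd.concat(parts, ignore_index=True)[
        ["patient", "structure", "source", "metric", "value", "usable"]
    ]


def analyze_stage(
    metrics: pd.DataFrame,
    dose: pd.DataFrame,
    strat: neck_tilt.CohortStratification,
) -> pd.DataFrame:
    """Cohort rank-sum tests over all metrics; one row per test."""
    long = melt_records(metrics, dose)
    results = group_stats.compare_cohorts(long, strat)
    return pd.DataFrame([asdict(r) for r in results])


def box_summary(
    metrics: pd.DataFrame,
    dose: pd.DataFrame,
    strat: neck_tilt.CohortStratification,
) -> pd.DataFrame:
    """Per-group box-plot statistics (1.5*IQR whisker convention)."""
    long = melt_records(metrics, dose)
    long = long[long["usable"]]
    long = long.assign(group=long["patient"].map(strat.labels))
    rows = []
    for (structure, source, metric, group), sub in long.groupby(
        ["structure", "source", "metric", "group"], sort=True
    ):
        v = sub["value"].to_numpy(float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        rows.append(
            {
                "structure": structure, "source": source, "metric": metric,
                "group": group, "n": len(v), "median": med, "q1": q1, "q3": q3,
                "whisker_low": inside.min() if len(inside) else np.nan,
                "whisker_high": inside.max() if len(inside) else np.nan,
                "n_outliers": int(len(v) - len(inside)),
            }
        )
    return pd.DataFrame(rows)


def plot_tilt_histogram(
    tilts: Sequence[float],
    strat: neck_tilt.CohortStratification,
    path,
) -> None:
    """Cohort tilt histogram with percentile cutoffs and median marked."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(list(tilts), bins=15, color="0.7", edgecolor="0.3")
    ax.axvline(strat.lower_threshold_deg, color="red", label="percentile cutoffs")
    ax.axvline(strat.upper_threshold_deg, color="red")
    ax.axvline(float(np.median(list(tilts))), color="cyan", label="median")
    ax.set_xlabel("neck tilt (deg, flexion positive)")
    ax.set_ylabel("patients")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def run_all(config: RunConfig) -> RunResult:
    """Execute the whole pipeline and write every artifact under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        gen = GeneratorConfig(
            n_patients=config.simulate_n, n_vendors=config.simulate_vendors
        )
        manifest, _ = simulate_cohort(gen, seed=config.seed, out_dir=out / "phantom")
        logger.info("simulated %d-patient cohort into %s", len(manifest), out / "phantom")
    else:
        manifest = load_manifest(config.manifest_path)

    tilt = tilt_stage(manifest)
    cohort_frame, strat = stratify_stage(tilt, config.lower_pct, config.upper_pct)
    metrics = metrics_stage(manifest, config.structures, config.tau_mm)
    dose = dose_stage(manifest, config.structures, config.exclusion_gy)
    results = analyze_stage(metrics, dose, strat)
    summary = box_summary(metrics, dose, strat)

    paths = {}
    for name, frame in (
        ("tilt", tilt), ("cohort", cohort_frame), ("metrics", metrics),
        ("dose", dose), ("results", results), ("box_summary", summary),
    ):
        p = out / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = str(p)
    hist_path = out / "tilt_histogram.png"
    plot_tilt_histogram(tilt["tilt_deg"], strat, hist_path)
    paths["tilt_histogram"] = str(hist_path)

    log = {
        "config": asdict(config),
        "n_patients": int(len(tilt)),
        "n_normal": strat.n_normal,
        "n_abnormal": strat.n_abnormal,
        "lower_threshold_deg": strat.lower_threshold_deg,
        "upper_threshold_deg": strat.upper_threshold_deg,
        "signed_dose_diff_convention": "test_minus_gold",
        "whisker_convention": "1.5*IQR",
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=1))
    paths["run_log"] = str(log_path)

    return RunResult(tilt, cohort_frame, strat, metrics, dose, results, summary, paths)
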