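"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from tiltqa import BinaryMask, GeneratorConfig, VolumeGrid, build_cohort
from tiltqa.pipeline import dose_stage, metrics_stage, stratify_stage, tilt_stage


# ---------------------------------------------------------------------------
# Mask construction helpers
# ---------------------------------------------------------------------------


def make_mask(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
              label="organ", source="test"):
    values = np.asarray(values, dtype=np.uint8)
    return BinaryMask(VolumeGrid(values, spacing, origin), label=label, source=source)


def random_mask(rng, shape, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                p=0.3, label="organ", source="test"):
    """Random non-empty Bernoulli mask (re-draws until non-empty)."""
    while True:
        vals = (rng.random(shape) < p).astype(np.uint8)
        if vals.any():
            return make_mask(vals, spacing, origin, label, source)


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation paths they check)
# ---------------------------------------------------------------------------


def brute_surface_elements(mask: BinaryMask):
    """All exposed voxel faces by explicit per-voxel neighbour loops."""
    vals = np.asarray(mask.values, dtype=bool)
    spacing = np.asarray(mask.grid.spacing)
    origin = np.asarray(mask.grid.origin)
    pts, areas = [], []
    for i, j, k in np.argwhere(vals):
        for axis, step in ((0, -1), (0, 1), (1, -1), (1, 1), (2, -1), (2, 1)):
            nb = [i, j, k]
            nb[axis] += step
            inside = 0 <= nb[axis] < vals.shape[axis]
            if inside and vals[tuple(nb)]:
                continue
            center = origin + np.array([i, j, k]) * spacing
            center[axis] += 0.5 * step * spacing[axis]
            pts.append(center)
            areas.append(spacing.prod() / spacing[axis])
    return np.asarray(pts), np.asarray(areas)


def brute_nearest_distances(pts_a, pts_b):
    """All-pairs Euclidean nearest distances, O(n^2)."""
    d = cdist(pts_a, pts_b)
    return d.min(axis=1), d.min(axis=0)


def brute_surface_dice(mask_a, mask_b, tau_mm):
    pa, aa = brute_surface_elements(mask_a)
    pb, ab = brute_surface_elements(mask_b)
    da, db = brute_nearest_distances(pa, pb)
    return (aa[da <= tau_mm].sum() + ab[db <= tau_mm].sum()) / (aa.sum() + ab.sum())


def brute_mda(mask_a, mask_b):
    pa, aa = brute_surface_elements(mask_a)
    pb, ab = brute_surface_elements(mask_b)
    da, db = brute_nearest_distances(pa, pb)
    return ((aa * da).sum() + (ab * db).sum()) / (aa.sum() + ab.sum())


def enumeration_ranksum(x, y):
    """Exact two-tailed Mann-Whitney p by full enumeration of rank splits.

    Valid only for tie-free pooled samples. Returns (U_x, p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    pooled = np.sort(np.concatenate([x, y]))
    assert len(np.unique(pooled)) == nx + ny, "oracle requires no ties"
    ranks = {v: r + 1 for r, v in enumerate(pooled)}
    rx = sum(ranks[v] for v in x)
    u_obs = rx - nx * (nx + 1) / 2
    mid = nx * ny / 2.0
    dev = abs(u_obs - mid)
    count = 0
    total = 0
    all_ranks = range(1, nx + ny + 1)
    for combo in combinations(all_ranks, nx):
        total += 1
        u = sum(combo) - nx * (nx + 1) / 2
        if abs(u - mid) >= dev - 1e-12:
            count += 1
    return u_obs, count / total


def u_distribution_enumeration(nx, ny):
    """Oracle U null distribution and a representative rank split per U."""
    counts = {}
    rep = {}
    for combo in combinations(range(1, nx + ny + 1), nx):
        u = int(sum(combo) - nx * (nx + 1) // 2)
        counts[u] = counts.get(u, 0) + 1
        rep.setdefault(u, combo)
    return counts, rep


# ---------------------------------------------------------------------------
# Phantom cohort fixtures (session-scoped; expensive stages computed once)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def cohort35():
    """Default 35-patient phantom cohort, seed 1."""
    return build_cohort(GeneratorConfig(), seed=1)


@pytest.fixture(scope="session")
def cohort35_tilt(cohort35):
    return tilt_stage(cohort35)


@pytest.fixture(scope="session")
def cohort35_strat(cohort35_tilt):
    return stratify_stage(cohort35_tilt)


@pytest.fixture(scope="session")
def cohort35_metrics(cohort35):
    return metrics_stage(cohort35)


@pytest.fixture(scope="session")
def cohort35_dose(cohort35):
    return dose_stage(cohort35)
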