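"""PCA tilt angle, centroid-slope cross-check, percentile stratification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_mask
from tiltqa import (
    centroid_slope_angle,
    cord_c1c4_voxels,
    measure_patient,
    pca_tilt_angle,
    stratify,
)
from tiltqa.io_core import DegenerateGeometryError, GridMismatchError, NoOverlapError


def cylinder_points(theta_deg, n=5000, radius=5.0, length=60.0, seed=7):
    """Uniform points in a tilted cylinder (axis in the sagittal plane)."""
    rng = np.random.default_rng(seed)
    t = rng.uniform(0, length, n)
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    phi = rng.uniform(0, 2 * np.pi, n)
    rad = math.radians(theta_deg)
    d = np.array([0.0, -math.sin(rad), math.cos(rad)])
    u = np.array([1.0, 0.0, 0.0])
    v = np.cross(d, u)
    return (
        t[:, None] * d
        + (r * np.cos(phi))[:, None] * u
        + (r * np.sin(phi))[:, None] * v
    )


class TestPcaTiltAngle:
    def test_axis_aligned_points_zero_tilt(self):
        pts = np.array([[0.0, 0.0, z] for z in range(0, 60, 2)], float)
        pts[::2, 0] = 0.3  # break exact collinearity laterally
        res = pca_tilt_angle(pts)
        assert res.tilt_deg == pytest.approx(0.0, abs=1e-6)
        assert res.principal_vector[2] >= 0

    def test_forty_five_degree_flexion_sign(self):
        t = np.linspace(0, 60, 40)
        pts = np.stack([np.zeros_like(t), -t / np.sqrt(2), t / np.sqrt(2)], axis=1)
        res = pca_tilt_angle(pts)
        assert res.tilt_deg == pytest.approx(45.0, abs=1e-9)

    def test_cylinder_recovers_true_angle(self):
        res = pca_tilt_angle(cylinder_points(20.0))
        assert res.tilt_deg == pytest.approx(20.0, abs=0.5)

    def test_permutation_invariance(self):
        pts = cylinder_points(33.0, n=800)
        rng = np.random.default_rng(1)
        shuffled = pts[rng.permutation(len(pts))]
        assert pca_tilt_angle(pts).tilt_deg == pytest.approx(
            pca_tilt_angle(shuffled).tilt_deg, abs=1e-12
        )

    @pytest.mark.parametrize("theta", [-40.0, -5.0, 0.0, 17.0, 62.0])
    def test_mirror_antisymmetry(self, theta):
        """Negating all y coordinates negates the tilt exactly."""
        pts = cylinder_points(theta, n=1500)
        mirrored = pts * np.array([1.0, -1.0, 1.0])
        assert pca_tilt_angle(mirrored).tilt_deg == pytest.approx(
            -pca_tilt_angle(pts).tilt_deg, abs=1e-9
        )

    @pytest.mark.parametrize("phi", [-30.0, -10.0, 15.0, 40.0])
    def test_rotation_consistency(self, phi):
        """Rotating points by phi about the x axis shifts the tilt by phi."""
        base = cylinder_points(10.0, n=4000)
        c, s = math.cos(math.radians(phi)), math.sin(math.radians(phi))
        # rotation that advances flexion by phi in the (y, z) plane
        rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]], float)
        rotated = base @ rot.T
        t0 = pca_tilt_angle(base).tilt_deg
        t1 = pca_tilt_angle(rotated).tilt_deg
        assert t1 - t0 == pytest.approx(phi, abs=0.1)

    def test_density_invariance_on_phantom(self, cohort35):
        pat = cohort35.patients[0]
        coords = cord_c1c4_voxels(
            pat.mask("cord"), [pat.mask(f"C{i}") for i in (1, 2, 3, 4)]
        )
        full = pca_tilt_angle(coords).tilt_deg
        half = pca_tilt_angle(coords[::2]).tilt_deg
        assert abs(full - half) < 0.5

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            pca_tilt_angle(np.zeros((5, 3)))  # too few points
        with pytest.raises(DegenerateGeometryError):
            pca_tilt_angle(np.tile([1.0, 2.0, 3.0], (30, 1)))  # identical points


class TestCordC1C4Selection:
    def _spine(self, cord_slices, vert_slices):
        shape = (4, 4, 50)
        cord = np.zeros(shape, np.uint8)
        cord[1:3, 1:3, cord_slices] = 1
        verts = []
        n = len(range(*vert_slices.indices(50)))
        quarter = max(1, n // 4)
        sl = list(range(*vert_slices.indices(50)))
        for i in range(4):
            v = np.zeros(shape, np.uint8)
            chunk = sl[i * quarter: (i + 1) * quarter] or sl[-1:]
            v[:, :, chunk] = 1
            verts.append(make_mask(v, label=f"C{i+1}"))
        return make_mask(cord, label="cord"), verts

    def test_slice_overlap_selection(self):
        cord, verts = self._spine(slice(0, 50), slice(20, 50))
        coords = cord_c1c4_voxels(cord, verts)
        # cord has 4 voxels per slice; only slices hosting vertebrae remain
        covered = set()
        for v in verts:
            covered |= {k for k in range(50) if v.values[:, :, k].any()}
        assert len(coords) == 4 * len(covered)
        assert coords[:, 2].min() == pytest.approx(min(covered))  # unit z spacing

    def test_disjoint_extent_raises(self):
        cord, verts = self._spine(slice(0, 15), slice(30, 50))
        with pytest.raises(NoOverlapError):
            cord_c1c4_voxels(cord, verts)

    def test_grid_mismatch_raises(self):
        cord, verts = self._spine(slice(0, 50), slice(20, 50))
        shifted = make_mask(verts[0].values, origin=(5, 0, 0), label="C1")
        with pytest.raises(GridMismatchError):
            cord_c1c4_voxels(cord, [shifted, *verts[1:]])

    def test_matches_brute_force_on_phantom(self, cohort35):
        pat = cohort35.patients[3]
        cord = pat.mask("cord")
        verts = [pat.mask(f"C{i}") for i in (1, 2, 3, 4)]
        coords = cord_c1c4_voxels(cord, verts)
        # independent slice filter: loop over every z slice
        union = np.zeros(cord.grid.shape[2], bool)
        for v in verts:
            for k in range(cord.grid.shape[2]):
                union[k] |= bool(v.values[:, :, k].any())
        count = sum(
            int(cord.values[:, :, k].sum()) for k in range(cord.grid.shape[2]) if union[k]
        )
        assert len(coords) == count


class TestCentroidSlope:
    def test_exact_line_thirty_degrees(self):
        """Vertebra cubes whose centroids lie exactly on a 30-degree flexion
        line: y spacing chosen so one index step per vertebra gives slope
        -tan(30 deg) in physical mm."""
        spacing = (1.0, 8.0 * math.tan(math.radians(30.0)), 1.0)
        shape = (5, 40, 40)
        masks = []
        for i in range(4):
            z = 5 + 8 * i  # centroid z advances 8 mm per vertebra
            y = 30 - i     # centroid y index drops by one -> flexion
            v = np.zeros(shape, np.uint8)
            v[1:4, y - 1: y + 2, z - 1: z + 2] = 1  # symmetric cube centred at (y, z)
            masks.append(make_mask(v, spacing, label=f"C{i+1}"))
        assert centroid_slope_angle(masks) == pytest.approx(30.0, abs=1e-9)

    def test_identical_z_centroids_degenerate(self):
        shape = (4, 20, 8)
        masks = []
        for i in range(4):
            v = np.zeros(shape, np.uint8)
            v[1:3, 2 + 4 * i: 4 + 4 * i, 3:5] = 1  # all share one z centroid
            masks.append(make_mask(v, label=f"C{i+1}"))
        with pytest.raises(DegenerateGeometryError):
            centroid_slope_angle(masks)

    def test_agrees_with_pca_on_phantom(self, cohort35, cohort35_tilt):
        diff = (cohort35_tilt["tilt_deg"] - cohort35_tilt["centroid_slope_deg"]).abs()
        assert diff.max() < 2.0
        assert cohort35_tilt["agreement_flag"].all()
        r = np.corrcoef(cohort35_tilt["tilt_deg"], cohort35_tilt["centroid_slope_deg"])[0, 1]
        assert r > 0.99


class TestStratify:
    def test_thirty_five_distinct_gives_eight_abnormal(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(12, 15, 35)
        strat = stratify([(f"p{i}", v) for i, v in enumerate(vals)])
        assert strat.n_abnormal == 8
        below = sum(v < strat.lower_threshold_deg for v in vals)
        above = sum(v > strat.upper_threshold_deg for v in vals)
        assert (below, above) == (4, 4)

    def test_all_equal_values_all_normal(self):
        strat = stratify([(f"p{i}", 5.0) for i in range(35)])
        assert strat.lower_threshold_deg == strat.upper_threshold_deg == 5.0
        assert strat.n_abnormal == 0

    def test_values_1_to_100(self):
        strat = stratify([(f"p{i}", float(i)) for i in range(1, 101)])
        assert strat.lower_threshold_deg == 12.0
        assert strat.upper_threshold_deg == 88.0
        assert strat.n_abnormal == 11 + 12

    def test_conservation_and_order_invariance(self):
        rng = np.random.default_rng(3)
        pairs = [(f"p{i}", float(v)) for i, v in enumerate(rng.normal(0, 10, 21))]
        strat = stratify(pairs)
        assert strat.n_normal + strat.n_abnormal == 21
        shuffled = [pairs[i] for i in rng.permutation(21)]
        assert stratify(shuffled).labels == strat.labels

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-80, max_value=80, allow_nan=False, width=32),
            min_size=3,
            max_size=60,
        )
    )
    def test_invariants_hold_for_arbitrary_samples(self, values):
        """Thresholds ordered, labels conserved, threshold values normal,
        for any finite tilt sample."""
        pairs = [(f"p{i}", float(v)) for i, v in enumerate(values)]
        strat = stratify(pairs)
        assert strat.lower_threshold_deg <= strat.upper_threshold_deg
        assert strat.n_normal + strat.n_abnormal == len(pairs)
        for pid, v in pairs:
            if v in (strat.lower_threshold_deg, strat.upper_threshold_deg):
                assert strat.labels[pid] == "normal"

    def test_validation(self):
        with pytest.raises(ValueError):
            stratify([("a", 1.0), ("b", 2.0)])
        with pytest.raises(ValueError):
            stratify([("a", 1.0), ("b", 2.0), ("c", 3.0)], lower_pct=90, upper_pct=10)


def test_measure_patient_recovers_truth(cohort35):
    pat = cohort35.patients[7]
    res = measure_patient(
        pat.mask("cord"), [pat.mask(f"C{i}") for i in (1, 2, 3, 4)], pat.patient_id
    )
    assert res.tilt_deg == pytest.approx(cohort35.truth.tilt_of(pat.patient_id), abs=1.0)
    assert res.agreement_flag
    assert res.n_voxels >= 20
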