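"""Counting procedures: thresholding, components, Z-center, doubling rule."""

import numpy as np
import pytest

from conftest import flood_fill_count, oracle_ols
from titerkit import fixtures, image_titer as it
from titerkit.errors import NoSampleError, ShallowStackError, UndefinedRedundancyError


def _stack_from(arr):
    return it.ImageStack(np.asarray(arr, dtype=float))


class TestBinarize:
    def test_constant_zero_stack_warns_and_is_empty(self):
        stack = _stack_from(np.zeros((3, 10, 10)))
        with pytest.warns(UserWarning, match="constant image"):
            binary, thr = it.binarize_stack(stack, policy="otsu")
        assert not binary.any()

    def test_fixed_threshold_out_of_range(self):
        stack = _stack_from(np.full((2, 5, 5), 10.0))
        with pytest.raises(ValueError, match="outside intensity range"):
            it.binarize_stack(stack, policy="fixed:99")

    def test_mask_excludes_punctum(self):
        stack, truth = fixtures.make_stack(n_puncta=20, seed=4)
        binary, _ = it.binarize_stack(stack, policy="fixed:600")
        n_all = it.count_puncta_3d(binary)
        z, y, x = truth.punctum_centers[0]
        mask = np.zeros(stack.shape, dtype=np.uint8)
        mask[z, int(y) - 6:int(y) + 7, int(x) - 6:int(x) + 7] = 1
        binary_m, _ = it.binarize_stack(stack, it.RoiMaskSet(mask), "fixed:600")
        assert it.count_puncta_3d(binary_m) == n_all - 1

    def test_percentile_policy_selects_punctum_voxels(self):
        """With amplitude-separated puncta over dim nuclei, a high percentile
        threshold keeps only voxels near punctum centers."""
        stack, truth = fixtures.make_stack(
            n_puncta=30, nuclei_spec=(3, 14.0), seed=9
        )
        binary, thr = it.binarize_stack(stack, policy="pct:99.9")
        assert thr > 400  # above nucleus peak intensity (300 over background)
        assert it.count_puncta_3d(binary) == 30
        centers = np.array([(z, y, x) for z, y, x in truth.punctum_centers])
        for idx in zip(*np.nonzero(binary)):
            d = np.abs(centers - np.array(idx))
            same_plane = d[:, 0] == 0
            assert (np.maximum(d[:, 1], d[:, 2])[same_plane] <= 3).any()

    def test_threshold_monotonicity(self, rng):
        stack = _stack_from(rng.uniform(0, 100, (4, 30, 30)))
        areas = []
        for t in (20, 40, 60, 80):
            binary, _ = it.binarize_stack(stack, policy=f"fixed:{t}")
            areas.append(binary.sum())
        assert areas == sorted(areas, reverse=True)

    def test_mask_never_increases_count_or_area(self, rng):
        """Exclusion masks that blanket whole objects (the practical case:
        follicle cells, host nuclei) can only remove counts; any mask can
        only shrink foreground area."""
        for seed in range(5):
            stack, truth = fixtures.make_stack(n_puncta=30, seed=seed)
            binary, _ = it.binarize_stack(stack, policy="fixed:600")
            base = it.count_puncta_3d(binary)
            mask = np.zeros(stack.shape, dtype=np.uint8)
            hidden = rng.choice(30, size=rng.integers(1, 10), replace=False)
            for i in hidden:
                z, y, x = truth.punctum_centers[i]
                mask[z, int(y) - 6:int(y) + 7, int(x) - 6:int(x) + 7] = 1
            binary_m, _ = it.binarize_stack(stack, it.RoiMaskSet(mask), "fixed:600")
            assert it.count_puncta_3d(binary_m) <= base
            speckle = (rng.uniform(size=stack.shape) < 0.2).astype(np.uint8)
            binary_s, _ = it.binarize_stack(stack, it.RoiMaskSet(speckle), "fixed:600")
            assert binary_s.sum() <= binary.sum()


class TestComponentCounts:
    def test_diagonal_touch_connectivity(self):
        plane = np.zeros((6, 6), dtype=bool)
        plane[1, 1] = plane[1, 2] = True
        plane[2, 3] = plane[2, 4] = True  # touches first blob only diagonally
        assert it.count_particles_2d(plane, connectivity=8, min_size_px=1) == 1
        assert it.count_particles_2d(plane, connectivity=4, min_size_px=1) == 2

    def test_min_size_filter(self):
        plane = np.zeros((8, 8), dtype=bool)
        plane[1, 1] = True            # area 1
        plane[4, 4] = plane[4, 5] = True  # area 2
        assert it.count_particles_2d(plane, min_size_px=2) == 1
        assert it.count_particles_2d(plane, min_size_px=1) == 2
        assert it.count_particles_2d(plane, min_size_px=3) == 0

    @pytest.mark.parametrize("connectivity,full", [(4, False), (8, True)])
    def test_2d_counts_match_flood_fill(self, rng, connectivity, full):
        for _ in range(10):
            plane = rng.uniform(size=(40, 40)) < 0.25
            assert it.count_particles_2d(plane, connectivity, 1) == \
                flood_fill_count(plane, full, 1)

    @pytest.mark.parametrize("connectivity,full", [(6, False), (26, True)])
    def test_3d_counts_match_flood_fill(self, rng, connectivity, full):
        for _ in range(5):
            vol = rng.uniform(size=(6, 20, 20)) < 0.2
            assert it.count_puncta_3d(vol, connectivity, 1) == \
                flood_fill_count(vol, full, 1)

    def test_plane_sum_at_least_3d_count(self, rng):
        """Components split across planes: summed 2D counts can only
        overcount relative to 3D components."""
        for seed in range(5):
            stack, _ = fixtures.make_stack(
                n_puncta=60, straddle_fraction=0.3, seed=seed
            )
            binary, _ = it.binarize_stack(stack, policy="fixed:450")
            n3 = it.count_puncta_3d(binary, min_size_vox=1)
            n2 = sum(it.count_particles_2d(p, min_size_px=1) for p in binary)
            assert n2 >= n3

    def test_empty_returns_zero(self):
        assert it.count_puncta_3d(np.zeros((3, 5, 5), dtype=bool)) == 0
        assert it.count_particles_2d(np.zeros((5, 5), dtype=bool)) == 0


class TestZCenter:
    def test_symmetric_ellipsoid(self):
        z, y, x = np.mgrid[0:21, 0:41, 0:41]
        ellipsoid = (((z - 10) / 9.0) ** 2 + ((y - 20) / 15.0) ** 2
                     + ((x - 20) / 15.0) ** 2) <= 1
        assert it.find_z_center(ellipsoid) == 10

    def test_single_plane(self):
        vol = np.zeros((1, 5, 5), dtype=bool)
        vol[0, 2, 2] = True
        assert it.find_z_center(vol) == 0

    def test_empty_raises(self):
        with pytest.raises(NoSampleError):
            it.find_z_center(np.zeros((4, 5, 5), dtype=bool))

    def test_matches_exhaustive_area_scan(self, rng):
        for _ in range(10):
            vol = rng.uniform(size=(8, 15, 15)) < rng.uniform(0.05, 0.4)
            if not vol.any():
                continue
            areas = [p.sum() for p in vol]
            assert it.find_z_center(vol) == int(np.argmax(areas))


class TestStage10:
    def test_doubling_arithmetic(self):
        """Per-plane counts [10, 12, 8] from the Z-center down give a
        reported total of 2 * 30 = 60."""
        vol = np.zeros((3, 64, 64))
        grid = [(y, x) for y in range(2, 62, 6) for x in range(2, 62, 6)]

        def scatter(plane, n, size):
            for y, x in grid[:n]:
                plane[y:y + size, x:x + size] = 1000.0

        scatter(vol[0], 10, 3)  # largest area -> Z-center
        scatter(vol[1], 12, 2)
        scatter(vol[2], 8, 2)
        res = it.quantify_stage10_cyst(_stack_from(vol), policy="fixed:500")
        assert res.per_plane_counts == [10, 12, 8]
        assert res.total_raw == 30
        assert res.total_reported == 60
        assert res.planes_used == (0, 2)
        assert res.method == "semi_auto_2d"

    def test_fixture_recovery_is_exact(self):
        stack, truth = fixtures.make_stage10_stack(n_puncta=300, seed=2)
        res = it.quantify_stage10_cyst(stack, policy="fixed:600")
        assert res.total_reported == truth.n_puncta

    def test_empty_after_masking_is_zero(self):
        stack, _ = fixtures.make_stack(n_puncta=10, seed=0)
        mask = np.ones((1,) + stack.shape[1:], dtype=np.uint8)
        res = it.quantify_stage10_cyst(stack, it.RoiMaskSet(mask), "fixed:600")
        assert res.total_reported == 0 and res.per_plane_counts == []

    def test_shallow_stack_raises(self):
        vol = np.zeros((4, 10, 10))
        vol[1, 3:6, 3:6] = 1000.0  # single foreground plane
        with pytest.raises(ShallowStackError):
            it.quantify_stage10_cyst(_stack_from(vol), policy="fixed:500")

    def test_redundancy_correction_scales_total(self):
        stack, truth = fixtures.make_stage10_stack(
            n_puncta=200, seed=3, straddle_fraction=0.1, strict=True
        )
        plain = it.quantify_stage10_cyst(stack, policy="fixed:450",
                                         estimate_redundancy=True)
        corrected = it.quantify_stage10_cyst(stack, policy="fixed:450",
                                             redundancy_correct=True)
        assert plain.redundancy_fraction is not None
        assert corrected.total_reported == int(round(
            plain.total_reported * (1 - plain.redundancy_fraction)
        ))


class TestRedundancy:
    def test_identical_planes_full_overlap(self):
        plane = np.zeros((10, 10), dtype=bool)
        plane[2:5, 2:5] = True
        plane[7:9, 7:9] = True
        vol = np.stack([plane, plane])
        assert it.estimate_plane_redundancy(vol, [(0, 1)]) == 1.0

    def test_disjoint_planes_zero(self):
        a = np.zeros((10, 10), dtype=bool)
        b = np.zeros((10, 10), dtype=bool)
        a[1:3, 1:3] = True
        b[6:8, 6:8] = True
        assert it.estimate_plane_redundancy(np.stack([a, b]), [(0, 1)]) == 0.0

    def test_overlap_pixel_threshold(self):
        """One shared pixel does not count as redundancy; two do."""
        first = np.zeros((8, 8), dtype=bool)
        first[2, 2:5] = True
        one_px = np.zeros((8, 8), dtype=bool)
        one_px[2, 4:7] = True  # shares only (2,4)
        two_px = np.zeros((8, 8), dtype=bool)
        two_px[2, 3:6] = True  # shares (2,3) and (2,4)
        assert it.estimate_plane_redundancy(np.stack([first, one_px]), [(0, 1)]) == 0.0
        assert it.estimate_plane_redundancy(np.stack([first, two_px]), [(0, 1)]) == 1.0

    def test_no_components_is_undefined(self):
        with pytest.raises(UndefinedRedundancyError):
            it.estimate_plane_redundancy(np.zeros((3, 5, 5), dtype=bool))

    def test_non_adjacent_pair_rejected(self):
        vol = np.ones((4, 5, 5), dtype=bool)
        with pytest.raises(ValueError, match="not adjacent"):
            it.estimate_plane_redundancy(vol, [(0, 2)])

    def test_straddle_fixture_matches_designed_fraction(self):
        stack, truth = fixtures.make_stack(
            n_puncta=400, shape=(16, 256, 256), straddle_fraction=0.05, seed=6
        )
        binary, _ = it.binarize_stack(stack, policy="fixed:450")
        est = it.estimate_plane_redundancy(binary)
        assert est == pytest.approx(truth.straddle_fraction(), abs=0.02)


class TestMethodComparison:
    def test_identity(self, rng):
        manual = rng.normal(400, 100, 30)
        res = it.compare_counting_methods(manual, manual.copy())
        assert res.slope == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.test.p_two_tailed == pytest.approx(1.0)

    def test_matches_normal_equations(self, rng):
        manual = rng.normal(400, 120, 40)
        auto = manual + rng.normal(0, 40, 40)
        res = it.compare_counting_methods(manual, auto)
        slope, intercept, r2 = oracle_ols(manual, auto)
        assert res.slope == pytest.approx(slope, abs=1e-9)
        assert res.intercept == pytest.approx(intercept, abs=1e-9)
        assert res.r_squared == pytest.approx(r2, abs=1e-9)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            it.compare_counting_methods([5, 5, 5, 5], [4, 5, 6, 7])
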