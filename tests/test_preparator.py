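"""Preprocessing and segmentation: oracles and contracts."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.filters import (
    threshold_isodata,
    threshold_li,
    threshold_mean,
    threshold_otsu,
    threshold_triangle,
)

from ciliametry.preparator import (
    Canny3DSpec,
    ThresholdSpec,
    VoxelMask,
    apply_segmentation,
    auto_threshold,
    auto_threshold_array,
    divide_by_background,
    fill_holes_3d,
    histogram_256,
    segment_canny3d,
    segment_hysteresis,
    segment_threshold,
    smooth_gaussian,
    subtract_background,
)


def _as_tzyx(arr3d):
    return np.asarray(arr3d)[np.newaxis]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

class TestBackground:
    def test_flat_background_fully_removed(self):
        out = subtract_background(np.full((1, 1, 32, 32), 50.0), radius=5)
        assert np.allclose(out, 0.0)

    def test_bright_spot_survives_rolling_ball(self):
        plane = np.full((64, 64), 10.0)
        plane[30:33, 30:33] += 100.0
        out = subtract_background(plane[None, None], radius=15)[0, 0]
        # spot excess retained within 10%, surroundings near zero
        assert abs(out[31, 31] - 100.0) <= 10.0
        assert out[5, 5] == pytest.approx(0.0, abs=1.0)

    def test_never_negative(self):
        rng = np.random.default_rng(0)
        out = subtract_background(rng.random((1, 2, 20, 20)) * 100, radius=4)
        assert (out >= 0).all()

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros((1, 1, 4, 4)), radius=0)

    def test_divide_constant_is_one(self):
        out = divide_by_background(np.full((1, 1, 32, 32), 40.0), sigma=3)
        assert np.allclose(out, 1.0, atol=1e-6)

    def test_divide_flattens_illumination_gradient(self):
        yy, xx = np.mgrid[0:64, 0:64]
        illum = 50.0 + 0.8 * xx  # slow gradient
        tube = np.zeros((64, 64))
        tube[30:34, 8:56] = 150.0
        img = (illum + tube)[None, None]
        out = divide_by_background(img, sigma=12)[0, 0]
        bg_in = img[0, 0][:20]
        bg_out = out[:20]
        cv_in = bg_in.std() / bg_in.mean()
        cv_out = bg_out.std() / bg_out.mean()
        assert cv_out * 2 <= cv_in
        assert out[31, 30] > 1.5  # tube contrast preserved

    def test_divide_zero_image_guarded(self):
        out = divide_by_background(np.zeros((1, 1, 8, 8)), sigma=2)
        assert np.isfinite(out).all()


class TestSmooth:
    def test_sigma_zero_identity(self):
        rng = np.random.default_rng(1)
        img = rng.random((1, 3, 8, 8))
        np.testing.assert_array_equal(smooth_gaussian(img, 0), img)

    def test_impulse_mass_conserved(self):
        img = np.zeros((1, 1, 41, 41))
        img[0, 0, 20, 20] = 1.0
        out = smooth_gaussian(img, 2.0)
        assert out.sum() == pytest.approx(1.0, rel=0.01)

    def test_no_mixing_across_z(self):
        img = np.zeros((1, 3, 21, 21))
        img[0, 1, 10, 10] = 1.0
        out = smooth_gaussian(img, 2.0)
        assert out[0, 0].sum() == 0.0
        assert out[0, 2].sum() == 0.0


# ---------------------------------------------------------------------------
# auto thresholds
# ---------------------------------------------------------------------------

def _otsu_objective(counts, edges):
    """Between-class variance at every cut point (exhaustive scan)."""
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()
    out = np.full(256, -1.0)
    for k in range(256):
        w0 = counts[: k + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[: k + 1] * centers[: k + 1]).sum() / w0
        m1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / w1
        out[k] = w0 * w1 * (m0 - m1) ** 2
    return out


def _cut_bin(thr, edges):
    """Invert the threshold-to-bin mapping (threshold = lower edge of k+1)."""
    return int(np.argmin(np.abs(edges[1:-1] - thr)))


class TestAutoThreshold:
    def test_otsu_two_point_histogram(self):
        values = np.concatenate([np.full(500, 10.0), np.full(500, 200.0)])
        counts, edges = histogram_256(values)
        thr = auto_threshold(counts, edges, "otsu")
        assert 10.0 < thr <= 200.0
        obj = _otsu_objective(counts, edges)
        assert obj[_cut_bin(thr, edges)] == pytest.approx(obj.max(), rel=1e-9)

    def test_otsu_maximizes_bruteforce_objective_on_random_data(self):
        """The chosen cut attains the exhaustive-scan between-class
        variance maximum (empty bins between the modes create exact
        ties, so the objective is compared, not the bin index)."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            vals = np.concatenate(
                [rng.normal(40, 8, 300).clip(0), rng.normal(150, 20, 120).clip(0)]
            )
            counts, edges = histogram_256(vals)
            thr = auto_threshold(counts, edges, "otsu")
            obj = _otsu_objective(counts, edges)
            assert obj[_cut_bin(thr, edges)] == pytest.approx(obj.max(), rel=1e-9)

    def test_mean_rule_uniform(self):
        vals = np.arange(256, dtype=float)
        thr = auto_threshold_array(vals, "mean")
        assert thr == pytest.approx(127.5, abs=0.5)

    def test_degenerate_single_value(self):
        with pytest.warns(UserWarning, match="degenerate"):
            thr = auto_threshold_array(np.full(100, 42.0), "mean")
        assert thr == pytest.approx(42.0, abs=0.5)

    def test_unknown_method_rejected(self):
        counts, edges = histogram_256(np.arange(10.0))
        with pytest.raises(ValueError):
            auto_threshold(counts, edges, "huang")

    @pytest.mark.parametrize(
        "method,skimage_fn",
        [
            ("otsu", threshold_otsu),
            ("mean", threshold_mean),
            ("triangle", threshold_triangle),
            ("li", threshold_li),
            ("isodata", threshold_isodata),
        ],
    )
    def test_cross_check_against_skimage(self, method, skimage_fn):
        """Binned-histogram thresholds agree with the skimage equivalents
        to within a few histogram bins on bimodal data."""
        rng = np.random.default_rng(9)
        vals = np.concatenate(
            [rng.normal(30, 6, 4000).clip(0), rng.normal(180, 15, 1500)]
        )
        ours = auto_threshold_array(vals, method)
        theirs = float(skimage_fn(vals))
        bin_width = (vals.max() - vals.min()) / 256
        assert abs(ours - theirs) <= 5 * bin_width

    def test_renyi_entropy_separates_bimodal(self):
        """Entropic thresholds land between the modes (at the edge of the
        dominant background mode, as entropy methods do): all foreground
        values pass, nearly all background values fail."""
        rng = np.random.default_rng(5)
        bg = rng.normal(20, 4, 5000).clip(0)
        fg = rng.normal(200, 10, 300)
        thr = auto_threshold_array(np.concatenate([bg, fg]), "renyi_entropy")
        assert (fg >= thr).all()
        assert (bg >= thr).mean() < 0.01


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

class TestSegmentThreshold:
    def test_custom_threshold_ge_rule(self):
        ch = _as_tzyx(np.array([[[50.0, 150.0], [100.0, 99.0]]]))
        spec = ThresholdSpec(method="custom", custom_value=100.0)
        mask = segment_threshold(ch, spec).mask
        np.testing.assert_array_equal(mask[0, 0], [[False, True], [True, False]])

    def test_per_timepoint_vs_global(self):
        rng = np.random.default_rng(0)
        frame = np.concatenate(
            [rng.normal(20, 3, 2000).clip(0), rng.normal(120, 10, 500)]
        ).reshape(1, 50, 50)
        ch = np.stack([frame, frame * 2.0])  # second frame twice as bright
        per_t = ThresholdSpec(method="otsu", per_timepoint=True)
        thr_masks = segment_threshold(ch, per_t).mask
        # per-frame thresholds adapt: both frames segment the same voxels
        np.testing.assert_array_equal(thr_masks[0], thr_masks[1])
        global_spec = ThresholdSpec(method="otsu", per_timepoint=False)
        global_masks = segment_threshold(ch, global_spec).mask
        assert global_masks[1].sum() > global_masks[0].sum()

    def test_phantom_recall_with_otsu_on_max_projection(self, straight_tube_scene):
        image = straight_tube_scene["image"]
        gt = straight_tube_scene["gt_masks"][0]
        spec = ThresholdSpec(method="otsu", histogram_source="max_projection")
        mask = segment_threshold(image.channel(0), spec).mask[0]
        recall = (mask & gt).sum() / gt.sum()
        assert recall >= 0.9


def _hysteresis_oracle(vol, low, high, connectivity):
    """Label components of (>= low); keep those containing a (>= high) voxel."""
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    labels, n = ndimage.label(vol >= low, structure=structure)
    out = np.zeros(vol.shape, dtype=bool)
    for lbl in range(1, n + 1):
        comp = labels == lbl
        if (vol[comp] >= high).any():
            out |= comp
    return out


def _bfs_hysteresis_oracle(vol, low, high):
    """Brute-force BFS under 26-connectivity, independent of scipy labeling."""
    from collections import deque

    shape = vol.shape
    weak = vol >= low
    visited = np.zeros(shape, dtype=bool)
    out = np.zeros(shape, dtype=bool)
    for seed in np.argwhere(vol >= high):
        seed = tuple(seed)
        if visited[seed]:
            continue
        comp = []
        dq = deque([seed])
        visited[seed] = True
        while dq:
            cur = dq.popleft()
            comp.append(cur)
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        nb = (cur[0] + dz, cur[1] + dy, cur[2] + dx)
                        if nb == cur or any(
                            c < 0 or c >= s for c, s in zip(nb, shape)
                        ):
                            continue
                        if weak[nb] and not visited[nb]:
                            visited[nb] = True
                            dq.append(nb)
        for c in comp:
            out[c] = True
    return out


class TestHysteresis:
    def test_line_profile(self):
        line = np.array([0.0, 120.0, 180.0, 120.0, 0.0]).reshape(1, 1, 1, 5)
        mask = segment_hysteresis(line, 100.0, 150.0).mask
        np.testing.assert_array_equal(mask[0, 0, 0], [False, True, True, True, False])

    def test_no_seed_empty(self):
        line = np.array([0.0, 120.0, 180.0, 120.0, 0.0]).reshape(1, 1, 1, 5)
        assert segment_hysteresis(line, 100.0, 200.0).mask.sum() == 0

    def test_low_above_high_rejected(self):
        with pytest.raises(ValueError):
            segment_hysteresis(np.zeros((1, 2, 2, 2)), 10.0, 5.0)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_oracle_equivalence_random_volumes(self, connectivity):
        rng = np.random.default_rng(17)
        for _ in range(30):
            vol = rng.random((12, 12, 12)) * 255
            low, high = sorted(rng.uniform(50, 220, 2))
            ours = segment_hysteresis(vol[None], low, high, connectivity).mask[0]
            np.testing.assert_array_equal(
                ours, _hysteresis_oracle(vol, low, high, connectivity)
            )

    def test_equals_threshold_when_low_equals_high(self):
        rng = np.random.default_rng(2)
        vol = rng.random((1, 8, 8, 8)) * 200
        t = 90.0
        hyst = segment_hysteresis(vol, t, t).mask
        thr = segment_threshold(vol, ThresholdSpec(method="custom", custom_value=t)).mask
        np.testing.assert_array_equal(hyst, thr)

    def test_monotone_in_low_threshold(self):
        rng = np.random.default_rng(4)
        vol = rng.random((1, 10, 10, 10)) * 255
        high = 200.0
        wide = segment_hysteresis(vol, 80.0, high).mask
        narrow = segment_hysteresis(vol, 120.0, high).mask
        assert (narrow & ~wide).sum() == 0  # narrow ⊆ wide


class TestCanny3D:
    def test_constant_image_empty(self):
        spec = Canny3DSpec(
            gaussian_sigma=1.0,
            low_spec=ThresholdSpec(method="custom", custom_value=1.0),
            high_spec=ThresholdSpec(method="custom", custom_value=2.0),
        )
        mask = segment_canny3d(np.full((1, 5, 16, 16), 80.0), spec).mask
        assert mask.sum() == 0

    def test_step_edge_maximal_gradient_on_step(self):
        from ciliametry.preparator import _sobel_gradient_magnitude

        vol = np.zeros((7, 9, 16))
        vol[:, :, 8:] = 100.0
        grad = _sobel_gradient_magnitude(vol)
        interior = grad[3, 4]
        assert interior.argmax() in (7, 8)

    def test_covers_tube_after_hole_fill(self, straight_tube_scene):
        """Edge-based segmentation yields a closed, larger reconstruction
        covering the full ground-truth tube."""
        image = straight_tube_scene["image"]
        gt = straight_tube_scene["gt_masks"][0]
        spec = Canny3DSpec(
            gaussian_sigma=1.0,
            low_spec=ThresholdSpec(method="triangle", histogram_source="max_projection"),
            high_spec=ThresholdSpec(method="otsu", histogram_source="max_projection"),
            fill_holes=True,
        )
        canny = segment_canny3d(image.channel(0), spec).mask[0]
        coverage = (canny & gt).sum() / gt.sum()
        assert coverage >= 0.99
        thr_mask = segment_threshold(
            image.channel(0), ThresholdSpec(method="otsu", histogram_source="max_projection")
        ).mask[0]
        assert canny.sum() >= thr_mask.sum()  # "bigger segmentations"


class TestFillHoles:
    def test_hollow_box_filled(self):
        vol = np.zeros((1, 7, 7, 7), dtype=bool)
        vol[0, 1:6, 1:6, 1:6] = True
        vol[0, 2:5, 2:5, 2:5] = False
        filled = fill_holes_3d(VoxelMask(vol)).mask
        assert filled[0, 1:6, 1:6, 1:6].all()

    def test_open_tube_unchanged(self):
        vol = np.zeros((1, 7, 7, 7), dtype=bool)
        vol[0, :, 2:5, 2:5] = True
        vol[0, :, 3, 3] = False  # hole open to both z borders
        out = fill_holes_3d(VoxelMask(vol)).mask
        np.testing.assert_array_equal(out, vol)

    def test_matches_border_floodfill_oracle_and_idempotent(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            vol = rng.random((10, 10, 10)) < 0.45
            ours = fill_holes_3d(VoxelMask(vol[None])).mask[0]
            # oracle: flood background from the border, complement
            bg = ~vol
            labels, n = ndimage.label(bg, ndimage.generate_binary_structure(3, 1))
            border_labels = set(np.unique(labels[0])) | set(np.unique(labels[-1]))
            border_labels |= set(np.unique(labels[:, 0])) | set(np.unique(labels[:, -1]))
            border_labels |= set(np.unique(labels[:, :, 0])) | set(
                np.unique(labels[:, :, -1])
            )
            reachable = np.isin(labels, sorted(border_labels - {0}))
            oracle = ~(bg & reachable)
            np.testing.assert_array_equal(ours, oracle)
            np.testing.assert_array_equal(
                fill_holes_3d(fill_holes_3d(VoxelMask(vol[None]))).mask[0], ours
            )


class TestApplySegmentation:
    def test_binary_uint8(self):
        ch = np.array([[[[10, 20], [30, 40]]]], dtype=np.uint8)
        mask = VoxelMask(ch >= 30)
        out = apply_segmentation(ch, mask, "binary")
        assert set(np.unique(out)) <= {0, 255}
        assert out.dtype == np.uint8

    def test_background_removed_identity_on_foreground(self):
        ch = np.array([[[[10.0, 20.0], [30.0, 40.0]]]])
        mask = VoxelMask(ch >= 25)
        out = apply_segmentation(ch, mask, "background_removed")
        assert out[0, 0, 1, 0] == 30.0 and out[0, 0, 0, 0] == 0.0
        assert out[mask.mask].sum() == ch[mask.mask].sum()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            apply_segmentation(
                np.zeros((1, 1, 2, 2)), VoxelMask(np.zeros((1, 1, 3, 3), bool)), "binary"
            )
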