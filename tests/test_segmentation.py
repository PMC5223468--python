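"""Per-slice segmentation: Intermodes thresholding, cleanup, watershed, ROIs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipidstack import (
    ImageStack,
    NotBimodalError,
    SegmentationParams,
    binarize_slice,
    intermodes_threshold,
    register_particles,
    segment_stack,
    watershed_split,
)


# ---------------------------------------------------------------------------
# Independent Intermodes oracle: literal step-by-step reimplementation.
# ---------------------------------------------------------------------------

def intermodes_oracle(hist, max_iter=10_000):
    h = [float(v) for v in hist]

    def maxima(y):
        # interior local-maximum plateaus, each reported at its centre
        out = []
        k = 1
        while k < 255:
            end = k
            while end + 1 < 256 and y[end + 1] == y[k]:
                end += 1
            if end < 255 and y[k - 1] < y[k] and y[end + 1] < y[k]:
                out.append((k + end) / 2.0)
            k = end + 1
        return out

    it = 0
    while len(maxima(h)) != 2:
        if it >= max_iter:
            raise RuntimeError("not bimodal")
        padded = [0.0] + h + [0.0]
        h = [(padded[k] + padded[k + 1] + padded[k + 2]) / 3.0 for k in range(256)]
        it += 1
    p1, p2 = maxima(h)
    return math.floor((p1 + p2) / 2)


def mixture_histogram(rng, mu1=60, mu2=180, sd=10, n1=4000, n2=1000):
    values = np.concatenate(
        [rng.normal(mu1, sd, n1), rng.normal(mu2, sd, n2)]
    )
    values = np.clip(np.rint(values), 0, 255).astype(int)
    return np.bincount(values, minlength=256)[:256]


class TestIntermodes:
    def test_two_delta_peaks_midpoint(self):
        h = np.zeros(256)
        h[50] = h[150] = 1000
        assert intermodes_threshold(h) == 100

    def test_already_bimodal_no_smoothing(self):
        h = np.zeros(256)
        h[10], h[20] = 500, 300
        assert intermodes_threshold(h) == 15

    def test_matches_oracle_on_gaussian_mixture(self):
        h = mixture_histogram(np.random.default_rng(1))
        assert intermodes_threshold(h) == intermodes_oracle(h)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_on_varied_mixtures(self, seed):
        rng = np.random.default_rng(seed)
        mu1 = rng.integers(20, 90)
        mu2 = rng.integers(120, 230)
        h = mixture_histogram(rng, mu1=mu1, mu2=mu2, sd=rng.integers(5, 20))
        assert intermodes_threshold(h) == intermodes_oracle(h)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        mu1=st.integers(10, 100),
        gap=st.integers(40, 150),
        sd=st.integers(3, 25),
        seed=st.integers(0, 2**16),
    )
    def test_oracle_equivalence_property(self, mu1, gap, sd, seed):
        h = mixture_histogram(
            np.random.default_rng(seed), mu1=mu1, mu2=min(mu1 + gap, 255), sd=sd
        )
        try:
            expected = intermodes_oracle(h)
        except RuntimeError:
            with pytest.raises(NotBimodalError):
                intermodes_threshold(h)
            return
        assert intermodes_threshold(h) == expected

    def test_single_bin_rejected(self):
        h = np.zeros(256)
        h[100] = 1000
        with pytest.raises(NotBimodalError):
            intermodes_threshold(h)

    def test_iteration_cap(self):
        h = np.zeros(256)
        h[40], h[50], h[60] = 100, 100, 100
        with pytest.raises(NotBimodalError):
            intermodes_threshold(h, max_iter=1)


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestBinarize:
    def test_uniform_background_empty(self):
        img = np.full((32, 32), 10, dtype=np.uint8)
        assert not binarize_slice(img, 100).any()

    def test_bright_disk_pixel_count(self):
        img = np.full((64, 64), 10, dtype=np.uint8)
        disk = disk_mask((64, 64), (32, 32), 10)
        img[disk] = 200
        mask = binarize_slice(img, 100, pixel_size=(1.0, 1.0))
        assert mask.sum() == disk.sum()  # oracle: direct rasterized-disk count

    def test_min_area_filter_removes_speck(self):
        img = np.full((32, 32), 10, dtype=np.uint8)
        img[5, 5] = 200
        params = SegmentationParams(min_droplet_area=20.0)
        assert not binarize_slice(img, 100, params, pixel_size=(1.0, 1.0)).any()

    def test_holes_filled(self):
        img = np.full((32, 32), 10, dtype=np.uint8)
        disk = disk_mask((32, 32), (16, 16), 8)
        img[disk] = 200
        img[16, 16] = 10  # hole
        mask = binarize_slice(img, 100)
        assert mask[16, 16]


class TestWatershed:
    def test_two_overlapping_disks_split(self):
        mask = disk_mask((64, 64), (32, 24), 10) | disk_mask((64, 64), (32, 39), 10)
        labels = watershed_split(mask)
        assert labels.max() == 2
        assert (labels > 0).sum() == mask.sum()

    def test_single_disk_is_noop(self):
        mask = disk_mask((64, 64), (32, 32), 12)
        labels = watershed_split(mask)
        assert labels.max() == 1
        np.testing.assert_array_equal(labels > 0, mask)

    def test_empty_mask(self):
        assert watershed_split(np.zeros((16, 16), bool)).max() == 0


class TestRegisterParticles:
    spacing = (10.0, 1.0, 1.0)

    def test_solid_square(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[10:13, 10:13] = 1
        img = np.full((32, 32), 50, dtype=np.uint8)
        (roi,) = register_particles(labels, img, 4, self.spacing)
        assert roi.area == pytest.approx(9.0)
        assert roi.pixel_count == 9
        assert roi.centroid == pytest.approx((11.5, 11.5))  # pixel center of (11, 11)
        assert roi.slice_index == 4

    def test_area_equals_pixel_count_times_pixel_area(self):
        labels = disk_mask((64, 64), (30, 30), 9).astype(np.int32)
        img = np.zeros((64, 64), dtype=np.uint8)
        (roi,) = register_particles(labels, img, 0, (10.0, 0.5, 0.5))
        assert roi.area == pytest.approx(roi.pixel_count * 0.25)

    def test_ellipse_axes_and_orientation(self):
        yy, xx = np.mgrid[:64, :128]
        ellipse = ((xx - 64) / 20.0) ** 2 + ((yy - 32) / 10.0) ** 2 <= 1.0
        img = np.zeros((64, 128), dtype=np.uint8)
        (roi,) = register_particles(ellipse.astype(np.int32), img, 0, self.spacing)
        assert roi.semi_major == pytest.approx(20.0, rel=0.05)
        assert roi.semi_minor == pytest.approx(10.0, rel=0.05)
        assert abs(roi.orientation) < 5.0

    def test_mean_intensity_of_constant_label(self):
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[4:8, 4:8] = 1
        img = np.full((16, 16), 77, dtype=np.uint8)
        (roi,) = register_particles(labels, img, 0, self.spacing)
        assert roi.mean_intensity == pytest.approx(77.0)


class TestSegmentStack:
    def test_blank_stack_yields_empty_lists(self):
        stack = ImageStack(np.zeros((10, 32, 32), np.uint8), (10, 1, 1), 8)
        rois = segment_stack(stack)
        assert len(rois) == 10
        assert all(r == [] for r in rois)

    def test_deterministic(self, noisy_stack):
        stack, _ = noisy_stack
        assert segment_stack(stack) == segment_stack(stack)

    def test_roi_count_matches_rasterized_cross_sections(self, clean_sphere_stack):
        """On a noiseless stack, per-slice ROI counts equal the number of
        ground-truth cross-sections whose rasterization survives the area filter
        (independent oracle: count pixel centres inside each analytic section)."""
        stack, truth = clean_sphere_stack
        params = SegmentationParams()
        rois = segment_stack(stack, params)
        dz, dy, dx = stack.spacing
        ny, nx = stack.shape[1:]
        yc = (np.arange(ny) + 0.5) * dy
        xc = (np.arange(nx) + 0.5) * dx
        for z in range(stack.n_slices):
            expected = 0
            for t in truth.droplets.itertuples():
                h = abs((z + 0.5) * dz - t.z)
                if h >= t.az:
                    continue
                s2 = 1.0 - (h / t.az) ** 2
                inside = (
                    ((xc[None, :] - t.x) / t.ax) ** 2
                    + ((yc[:, None] - t.y) / t.ay) ** 2
                ) <= s2
                if inside.sum() * dy * dx >= params.min_droplet_area:
                    expected += 1
            assert len(rois[z]) == expected, f"slice {z}"

    def test_recall_one_roi_per_section(self, clean_sphere_stack):
        """Non-touching droplets: no section is split, none missed (recall 1)."""
        stack, truth = clean_sphere_stack
        rois = segment_stack(stack)
        total_sections = sum(len(r) for r in rois)
        big_sections = sum(
            1
            for t in truth.cross_sections.itertuples()
            if t.area >= 30.0  # comfortably above filter + rasterization jitter
        )
        assert total_sections >= big_sections
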