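"""Cross-slice deduplication, volume conversion, manual-ROI merging."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipidstack import (
    DropletSet,
    ImageStack,
    LinkParams,
    ManualROI,
    ROI2D,
    build_droplet_set,
    collapse_chain,
    link_across_slices,
    merge_manual,
    roi_to_volume,
    write_droplet_table,
)

SPACING = (10.0, 1.0, 1.0)


def make_roi(slice_index, x, y, area=100.0, mean=100.0, aspect=1.0, pixels=None):
    r = math.sqrt(area / math.pi)
    return ROI2D(
        slice_index=slice_index,
        pixel_count=pixels if pixels is not None else max(int(round(area)), 1),
        area=area,
        centroid=(x, y),
        semi_major=r * math.sqrt(aspect),
        semi_minor=r / math.sqrt(aspect),
        orientation=0.0,
        mean_intensity=mean,
        origin="auto",
    )


class TestRoiToVolume:
    def test_circular_roi_sphere(self):
        roi = make_roi(0, 50, 50, area=math.pi * 25.0)  # r = 5 um
        volume, shape, axes = roi_to_volume(roi)
        assert shape == "sphere"
        assert volume == pytest.approx(4 / 3 * math.pi * 125.0)  # ~523.60
        assert axes == pytest.approx((5.0, 5.0, 5.0))

    def test_elongated_roi_ellipsoid(self):
        roi = ROI2D(0, 100, math.pi * 50, (0, 0), 10.0, 5.0, 0.0, 100.0)
        volume, shape, axes = roi_to_volume(roi)
        assert shape == "ellipsoid"
        assert volume == pytest.approx(4 / 3 * math.pi * 10 * 25)  # ~1047.20
        assert axes == (10.0, 5.0, 5.0)

    def test_aspect_at_cutoff_is_sphere(self):
        roi = ROI2D(0, 100, 80.0, (0, 0), 10.5, 10.0, 0.0, 100.0)  # aspect 1.05
        _, shape, _ = roi_to_volume(roi, sphere_aspect_cutoff=1.1)
        assert shape == "sphere"

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        area=st.floats(10.0, 1e4),
        aspect=st.floats(1.0, 3.0),
    )
    def test_volume_identity_property(self, area, aspect):
        roi = make_roi(0, 0, 0, area=area, aspect=aspect)
        volume, shape, (a, b, c) = roi_to_volume(roi)
        assert volume == pytest.approx(4 / 3 * math.pi * a * b * c, rel=1e-12)
        assert a >= b >= c > 0
        assert (shape == "sphere") == (a == b == c)


class TestCollapseChain:
    def test_max_signal_member_wins(self):
        chain = [
            make_roi(3, 10, 10, mean=80.0, pixels=100),
            make_roi(4, 10, 10, mean=120.0, pixels=100),
            make_roi(5, 10, 10, mean=95.0, pixels=100),
        ]
        d = collapse_chain(chain, SPACING)
        assert d.source_slice == 4
        assert d.centroid[2] == pytest.approx(45.0)  # centre of slice 4, dz = 10

    def test_single_roi_identity(self):
        roi = make_roi(7, 30, 40, area=math.pi * 25)
        d = collapse_chain([roi], SPACING)
        assert d.source_slice == 7
        assert d.centroid == pytest.approx((30.0, 40.0, 75.0))
        assert d.volume == pytest.approx(4 / 3 * math.pi * 125)

    def test_signal_tie_breaks_to_larger_area(self):
        chain = [
            make_roi(1, 10, 10, area=50.0, mean=100.0, pixels=10),
            make_roi(2, 10, 10, area=60.0, mean=100.0, pixels=10),
        ]
        d = collapse_chain(chain, SPACING)
        assert d.source_slice == 2

    def test_empty_chain_errors(self):
        with pytest.raises(ValueError, match="empty"):
            collapse_chain([], SPACING)


class TestLinkAcrossSlices:
    def test_concentric_rois_form_one_chain(self):
        rois = [[make_roi(s, 100, 100)] for s in range(3, 8)]
        chains = link_across_slices(rois)
        assert len(chains) == 1
        assert len(chains[0]) == 5

    def test_distant_rois_stay_separate(self):
        rois = [[make_roi(3, 0, 0, area=math.pi * 25)], [make_roi(4, 100, 0, area=math.pi * 25)]]
        assert len(link_across_slices(rois)) == 2

    def test_slice_gap_respected(self):
        rois = [[make_roi(3, 50, 50)], [make_roi(5, 50, 50)]]  # gap of 2
        assert len(link_across_slices(rois, LinkParams(max_slice_gap=1))) == 2
        assert len(link_across_slices(rois, LinkParams(max_slice_gap=2))) == 1

    def test_idempotent_on_collapsed_representatives(self, clean_sphere_stack):
        stack, _ = clean_sphere_stack
        ds = build_droplet_set(stack)
        reps = [
            [
                make_roi(
                    d.source_slice,
                    d.centroid[0],
                    d.centroid[1],
                    area=math.pi * d.semi_axes[0] * d.semi_axes[1],
                )
            ]
            for d in ds.droplets
        ]
        chains = link_across_slices(reps)
        assert len(chains) == len(ds)
        assert all(len(c) == 1 for c in chains)

    def test_simulator_chain_count(self, clean_sphere_stack):
        """Spheres spanning several slices each yield exactly one chain."""
        stack, truth = clean_sphere_stack
        from lipidstack import segment_stack

        chains = link_across_slices(segment_stack(stack))
        assert len(chains) == truth.n_droplets


class TestMergeManual:
    def _auto_set(self):
        roi = make_roi(5, 100, 100, area=math.pi * 100)  # r = 10 at (100, 100)
        return DropletSet([collapse_chain([roi], SPACING, droplet_id=1)])

    def test_distant_manual_added(self):
        ds = self._auto_set()
        manual = [ManualROI(5, (299.5, 299.5), 15.0, 15.0)]
        merged = merge_manual(ds, manual, spacing=SPACING)
        assert len(merged) == 2
        added = merged.droplets[-1]
        assert added.origin == "manual"
        assert added.volume == pytest.approx(4 / 3 * math.pi * 15**3)  # ~14137.17

    def test_concentric_manual_rejected_with_warning(self):
        ds = self._auto_set()
        manual = [ManualROI(5, (99.5, 99.5), 10.0, 10.0)]
        with pytest.warns(UserWarning, match="duplicate"):
            merged = merge_manual(ds, manual, spacing=SPACING)
        assert len(merged) == 1

    def test_empty_manual_is_identity(self):
        ds = self._auto_set()
        merged = merge_manual(ds, [], spacing=SPACING)
        assert [d.centroid for d in merged.droplets] == [d.centroid for d in ds.droplets]

    def test_manual_slice_outside_stack_errors(self):
        ds = self._auto_set()
        with pytest.raises(ValueError, match="outside stack"):
            merge_manual(ds, [ManualROI(50, (0, 0), 5, 5)], spacing=SPACING, n_slices=10)


class TestBuildDropletSet:
    def test_recovers_every_sphere(self, clean_sphere_stack):
        stack, truth = clean_sphere_stack
        ds = build_droplet_set(stack)
        assert len(ds) == truth.n_droplets

    def test_blank_stack_with_manual_rois(self):
        stack = ImageStack(np.zeros((10, 64, 64), np.uint8), SPACING, 8)
        manual = [ManualROI(s, (20.0 * s, 20.0), 8.0, 8.0) for s in (1, 4, 7)]
        ds = build_droplet_set(stack, manual=manual)
        assert len(ds) == 3
        assert all(d.origin == "manual" for d in ds.droplets)

    def test_rerun_is_byte_identical(self, tmp_path, noisy_stack):
        stack, _ = noisy_stack
        paths = []
        for run in range(2):
            ds = build_droplet_set(stack)
            p = tmp_path / f"run{run}.csv"
            write_droplet_table(ds, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_source_slice_holds_chain_maximum_signal(self, clean_sphere_stack):
        """Post-hoc invariant: the registered slice carries the chain's
        maximal integrated intensity."""
        from lipidstack import segment_stack

        stack, _ = clean_sphere_stack
        rois_per_slice = segment_stack(stack)
        chains = link_across_slices(rois_per_slice)
        for chain in chains:
            best = max(chain, key=lambda r: (r.mean_intensity * r.pixel_count, r.area))
            d = collapse_chain(chain, stack.spacing)
            assert d.source_slice == best.slice_index

    def test_recovered_volumes_close_to_truth(self, clean_sphere_stack):
        """Noiseless non-touching spheres: volumes discretization-limited."""
        from scipy.spatial import cKDTree

        stack, truth = clean_sphere_stack
        ds = build_droplet_set(stack)
        tree = cKDTree(truth.droplets[["x", "y", "z"]].to_numpy())
        errors = []
        for d in ds.droplets:
            _, i = tree.query(d.centroid)
            true_vol = truth.droplets["volume"].iloc[i]
            errors.append((d.volume - true_vol) / true_vol)
        errors = np.asarray(errors)
        assert np.all(np.abs(errors) <= 0.15)
        assert abs(np.median(errors)) <= 0.05
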