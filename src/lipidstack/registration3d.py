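"""Cross-slice deduplication of per-slice ROIs into 3D droplets.

A lipid droplet larger than the Z step appears in several consecutive slices.
ROIs are chained across slices when their XY centroids are closer than the
larger of the two equivalent radii (successive cross-sections of a sphere are
concentric, so centroid containment is the minimal correct criterion). Each
chain is collapsed to a single droplet: the representative ROI is the chain
member with maximal mean intensity (the in-focus slice), its XY centroid and
slice give the 3D centroid, and its area/ellipse give the volume — a
near-circular ROI becomes a sphere of the area-equivalent radius, an
elongated one an ellipsoid whose Z semi-axis equals the in-plane semi-minor
axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .segmentation import ROI2D, SegmentationParams, segment_stack
from .stacks_io import ImageStack, ManualROI

__all__ = [
    "Droplet3D",
    "DropletSet",
    "LinkParams",
    "link_across_slices",
    "collapse_chain",
    "roi_to_volume",
    "merge_manual",
    "build_droplet_set",
]

_VOL = 4.0 / 3.0 * math.pi


@dataclass(frozen=True)
class LinkParams:
    """Chaining and shape-model parameters.

    max_centroid_gap
        Two ROIs in nearby slices belong to the same droplet when their XY
        centroid distance is below this fraction of the larger equivalent
        radius. 1.0 = centroid containment.
    max_slice_gap
        Maximum slice separation for chaining. With a 10 um Z step a droplet
        above the size filter cannot vanish for a whole slice, so 1.
    sphere_aspect_cutoff
        ROIs with major/minor axis ratio at or below this are modelled as
        spheres; above it, as ellipsoids.
    """

    max_centroid_gap: float = 1.0
    max_slice_gap: int = 1
    sphere_aspect_cutoff: float = 1.1

    def __post_init__(self) -> None:
        if self.max_centroid_gap <= 0 or self.max_slice_gap <= 0:
            raise ValueError("link parameters must be strictly positive")
        if self.sphere_aspect_cutoff <= 0:
            raise ValueError("sphere_aspect_cutoff must be strictly positive")


@dataclass(frozen=True)
class Droplet3D:
    """One deduplicated droplet: centroid (x, y, z) um, volume um^3, shape model."""

    id: int
    centroid: tuple[float, float, float]
    volume: float
    shape: str
    source_slice: int
    semi_axes: tuple[float, float, float]
    origin: str = "auto"
    check_volume: bool = True

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes
        if not (a >= b >= c > 0):
            raise ValueError(f"need semi_axes a >= b >= c > 0, got {self.semi_axes}")
        if self.shape not in ("sphere", "ellipsoid"):
            raise ValueError(f"shape must be sphere|ellipsoid, got {self.shape}")
        if self.shape == "sphere" and not (a == b == c):
            raise ValueError("sphere requires equal semi-axes")
        if self.check_volume and not math.isclose(
            self.volume, _VOL * a * b * c, rel_tol=1e-9
        ):
            raise ValueError("volume inconsistent with (4/3)*pi*a*b*c")


@dataclass
class DropletSet:
    """All droplets of one muscle plus provenance references."""

    droplets: list[Droplet3D]
    stack_ref: str = ""
    params_ref: str = ""

    def __post_init__(self) -> None:
        ids = [d.id for d in self.droplets]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("droplet ids must be unique and consecutive from 1")

    def __len__(self) -> int:
        return len(self.droplets)

    @property
    def total_volume(self) -> float:
        return float(sum(d.volume for d in self.droplets))

    def points(self):
        """(n, 3) array of droplet centroids in um."""
        import numpy as np

        return np.array([d.centroid for d in self.droplets], dtype=float).reshape(-1, 3)


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

def _linkable(a: ROI2D, b: ROI2D, params: LinkParams) -> tuple[bool, float]:
    dx = a.centroid[0] - b.centroid[0]
    dy = a.centroid[1] - b.centroid[1]
    dist = math.hypot(dx, dy)
    limit = params.max_centroid_gap * max(a.equivalent_radius, b.equivalent_radius)
    return dist < limit, dist


def link_across_slices(
    rois_per_slice: list[list[ROI2D]], params: LinkParams | None = None
) -> list[list[ROI2D]]:
    """Group per-slice ROIs into chains, one chain per physical droplet.

    Greedy nearest-centroid matching slice by slice; candidate (chain, ROI)
    pairs are ranked by centroid distance, then smaller area difference, then
    lower x, then lower y of the incoming ROI. Chaining is transitive through
    the chain's most recent member.
    """
    params = params or LinkParams()
    chains: list[list[ROI2D]] = []
    slices = sorted({roi.slice_index for rois in rois_per_slice for roi in rois})
    by_slice: dict[int, list[ROI2D]] = {}
    for rois in rois_per_slice:
        for roi in rois:
            by_slice.setdefault(roi.slice_index, []).append(roi)

    for s in slices:
        incoming = by_slice[s]
        open_chains = [
            ch for ch in chains if 0 < s - ch[-1].slice_index <= params.max_slice_gap
        ]
        candidates = []
        for ci, ch in enumerate(open_chains):
            last = ch[-1]
            for ri, roi in enumerate(incoming):
                ok, dist = _linkable(last, roi, params)
                if ok:
                    candidates.append(
                        (
                            dist,
                            abs(last.area - roi.area),
                            roi.centroid[0],
                            roi.centroid[1],
                            ci,
                            ri,
                        )
                    )
        candidates.sort()
        used_chains: set[int] = set()
        used_rois: set[int] = set()
        for _, _, _, _, ci, ri in candidates:
            if ci in used_chains or ri in used_rois:
                continue
            open_chains[ci].append(incoming[ri])
            used_chains.add(ci)
            used_rois.add(ri)
        for ri, roi in enumerate(incoming):
            if ri not in used_rois:
                chains.append([roi])
    return chains


def roi_to_volume(
    roi: ROI2D, sphere_aspect_cutoff: float = 1.1
) -> tuple[float, str, tuple[float, float, float]]:
    """Convert a single ROI to a sphere or ellipsoid volume.

    Near-circular ROIs (aspect <= cutoff) become spheres with
    ``r = sqrt(area / pi)`` so a circle's volume is exactly reproducible from
    its area. Elongated ROIs become ellipsoids with the in-plane semi-axes
    and the semi-minor axis reused as the Z semi-axis:
    ``V = (4/3) * pi * a * b^2``.
    """
    if roi.semi_minor <= 0 or roi.semi_major <= 0:
        raise ValueError("non-positive ellipse axes")
    if roi.semi_major / roi.semi_minor <= sphere_aspect_cutoff:
        r = math.sqrt(roi.area / math.pi)
        return _VOL * r**3, "sphere", (r, r, r)
    a, b = roi.semi_major, roi.semi_minor
    return _VOL * a * b * b, "ellipsoid", (a, b, b)


def collapse_chain(
    chain: list[ROI2D],
    spacing: tuple[float, float, float],
    sphere_aspect_cutoff: float = 1.1,
    droplet_id: int = 1,
) -> Droplet3D:
    """Collapse a chain to one droplet at its slice of maximum signal.

    The representative ROI is the member with the maximal signal: the
    integrated intensity over its support (mean intensity x pixel count, or
    mean intensity alone where no pixel support exists). Ties go to the larger
    area, then the lower slice index. Maximal *mean* intensity is not used
    because axial bleed can leave a tiny out-of-focus cap whose few pixels
    out-average the in-focus cross-section. The droplet's XY centroid is the
    representative's centroid and its Z is the physical centre of that slice.
    """
    if not chain:
        raise ValueError("empty chain")

    def signal(r: ROI2D) -> float:
        return r.mean_intensity * r.pixel_count if r.pixel_count > 0 else r.mean_intensity

    rep = max(chain, key=lambda r: (signal(r), r.area, -r.slice_index))
    volume, shape, semi_axes = roi_to_volume(rep, sphere_aspect_cutoff)
    dz = spacing[0]
    return Droplet3D(
        id=droplet_id,
        centroid=(rep.centroid[0], rep.centroid[1], (rep.slice_index + 0.5) * dz),
        volume=volume,
        shape=shape,
        source_slice=rep.slice_index,
        semi_axes=semi_axes,
        origin=rep.origin,
    )


# ---------------------------------------------------------------------------
# Manual ROI merge
# ---------------------------------------------------------------------------

def _manual_to_roi2d(m: ManualROI, spacing: tuple[float, float, float]) -> ROI2D:
    _, dy, dx = spacing
    return ROI2D(
        slice_index=m.slice_index,
        pixel_count=0,
        area=math.pi * m.semi_major * m.semi_minor,
        centroid=((m.center[0] + 0.5) * dx, (m.center[1] + 0.5) * dy),
        semi_major=m.semi_major,
        semi_minor=m.semi_minor,
        orientation=m.angle,
        mean_intensity=float("nan"),
        origin="manual",
    )


def merge_manual(
    auto_set: DropletSet,
    manual: list[ManualROI],
    params: LinkParams | None = None,
    spacing: tuple[float, float, float] = (10.0, 1.0, 1.0),
    n_slices: int | None = None,
) -> DropletSet:
    """Add hand-fitted ROIs for droplets the automatic pass missed.

    A manual ROI whose centroid falls within the chaining criterion of an
    existing automatic droplet in the same or an adjacent slice (within
    ``max_slice_gap``) is rejected as a duplicate registration: a warning is
    emitted and the set is unchanged. Ids are reassigned consecutively.
    """
    params = params or LinkParams()
    dz, dy, dx = spacing
    kept = list(auto_set.droplets)
    for m in manual:
        if n_slices is not None and m.slice_index >= n_slices:
            raise ValueError(
                f"manual ROI slice {m.slice_index} outside stack of {n_slices} slices"
            )
        roi = _manual_to_roi2d(m, spacing)
        r_m = roi.equivalent_radius
        duplicate = None
        for d in kept:
            if abs(d.source_slice - m.slice_index) > params.max_slice_gap:
                continue
            r_d = math.sqrt(d.semi_axes[0] * d.semi_axes[1])
            dist = math.hypot(
                d.centroid[0] - roi.centroid[0], d.centroid[1] - roi.centroid[1]
            )
            if dist < params.max_centroid_gap * max(r_m, r_d):
                duplicate = d
                break
        if duplicate is not None:
            warnings.warn(
                f"manual ROI at slice {m.slice_index}, centroid "
                f"({roi.centroid[0]:.1f}, {roi.centroid[1]:.1f}) um duplicates "
                f"auto droplet {duplicate.id}; rejected",
                stacklevel=2,
            )
            continue
        volume, shape, semi_axes = roi_to_volume(roi, params.sphere_aspect_cutoff)
        kept.append(
            Droplet3D(
                id=len(kept) + 1,
                centroid=(roi.centroid[0], roi.centroid[1], (m.slice_index + 0.5) * dz),
                volume=volume,
                shape=shape,
                source_slice=m.slice_index,
                semi_axes=semi_axes,
                origin="manual",
            )
        )
    renumbered = [
        Droplet3D(
            id=i,
            centroid=d.centroid,
            volume=d.volume,
            shape=d.shape,
            source_slice=d.source_slice,
            semi_axes=d.semi_axes,
            origin=d.origin,
            check_volume=d.check_volume,
        )
        for i, d in enumerate(kept, start=1)
    ]
    return DropletSet(
        droplets=renumbered, stack_ref=auto_set.stack_ref, params_ref=auto_set.params_ref
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def build_droplet_set(
    stack: ImageStack,
    params: SegmentationParams | None = None,
    link_params: LinkParams | None = None,
    manual: list[ManualROI] | None = None,
) -> DropletSet:
    """Segment -> chain -> collapse -> merge manual ROIs. Fully deterministic."""
    params = params or SegmentationParams()
    link_params = link_params or LinkParams()
    rois_per_slice = segment_stack(stack, params)
    chains = link_across_slices(rois_per_slice, link_params)
    droplets = [
        collapse_chain(ch, stack.spacing, link_params.sphere_aspect_cutoff, i)
        for i, ch in enumerate(chains, start=1)
    ]
    auto_set = DropletSet(
        droplets=droplets,
        stack_ref=stack.source_id,
        params_ref=f"{params!r}|{link_params!r}",
    )
    if manual:
        return merge_manual(
            auto_set, manual, link_params, stack.spacing, n_slices=stack.n_slices
        )
    return auto_set
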