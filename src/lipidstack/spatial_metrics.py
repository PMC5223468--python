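"""Whole-muscle summaries and spatial statistics.

Totals (total lipid volume = sum of droplet volumes, droplet count, mean
volume, volume histogram), the nearest-neighbor clustering index, and
serial-section histology volume estimation.

The nearest-neighbor index is the mean observed distance from each droplet
to its nearest neighbour divided by the mean of the same statistic under
complete spatial randomness (CSR) in a bounding domain. Values below 1
indicate clustering, above 1 dispersion. The CSR expectation is evaluated by
Monte Carlo inside the chosen domain (bounding box, convex hull of the
points, or an explicit muscle mask) rather than by the unbounded-Poisson
closed form 0.554 * lambda**(-1/3), because muscle volumes are strongly
bounded and anisotropic so edge effects matter; the closed form is reported
alongside for reference.

One caveat applies to absolute distances in decellularized tissue: the
extracellular matrix contracts during processing, so inter-droplet distances
are relative, not anatomical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, cKDTree
from scipy.stats import ks_2samp

from .registration3d import DropletSet
from .stacks_io import MaskVolume

__all__ = [
    "MetricsReport",
    "NNResult",
    "SectionTrack",
    "HistogramComparison",
    "summarize",
    "nearest_neighbor_index",
    "serial_section_volume",
    "compare_volume_histograms",
    "metrics_report",
]

#: 3D Clark–Evans constant: E[NN] = GAMMA(4/3) * (3 / (4 pi lambda))**(1/3).
_CE3 = math.gamma(4.0 / 3.0) * (3.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
#: 2D constant: E[NN] = 0.5 / sqrt(lambda).
_CE2 = 0.5


@dataclass(frozen=True)
class NNResult:
    """Nearest-neighbor clustering index and its ingredients (um)."""

    nn_index: float
    nn_mean_observed: float
    nn_mean_expected: float
    nn_expected_poisson: float
    domain: str
    mc_reps: int
    seed: int
    n_points: int


@dataclass(frozen=True)
class MetricsReport:
    """Totals, volume histogram and (optionally) the NN clustering index."""

    total_volume: float
    n_droplets: int
    mean_volume: Optional[float]
    volume_histogram: tuple[np.ndarray, np.ndarray]  # (bin_edges um^3, counts)
    nn: Optional[NNResult] = None

    def to_dict(self) -> dict:
        edges, counts = self.volume_histogram
        out = {
            "total_volume_um3": self.total_volume,
            "n_droplets": self.n_droplets,
            "mean_volume_um3": self.mean_volume,
            "volume_histogram": {
                "bin_edges_um3": list(map(float, edges)),
                "counts": list(map(int, counts)),
            },
        }
        if self.nn is not None:
            out["nearest_neighbor"] = {
                "index": self.nn.nn_index,
                "mean_observed_um": self.nn.nn_mean_observed,
                "mean_expected_um": self.nn.nn_mean_expected,
                "expected_poisson_um": self.nn.nn_expected_poisson,
                "domain": self.nn.domain,
                "mc_reps": self.nn.mc_reps,
                "seed": self.nn.seed,
            }
        return out


@dataclass(frozen=True)
class SectionTrack:
    """One adipocyte tracked through consecutive histological sections."""

    track_id: int
    areas: tuple[float, ...]  # um^2, one per consecutive section
    section_thickness: float  # um

    def __post_init__(self) -> None:
        if len(self.areas) == 0:
            raise ValueError("empty track")
        if any(a <= 0 for a in self.areas):
            raise ValueError("all section areas must be > 0")
        if self.section_thickness <= 0:
            raise ValueError("section thickness must be > 0")


@dataclass(frozen=True)
class HistogramComparison:
    bin_edges: np.ndarray
    counts_a: np.ndarray
    counts_b: np.ndarray
    ks_statistic: float


# ---------------------------------------------------------------------------
# Totals
# ---------------------------------------------------------------------------

def _volume_bins(volumes: np.ndarray, bins) -> np.ndarray:
    if not np.isscalar(bins):
        return np.asarray(bins, dtype=float)
    lo, hi = float(volumes.min()), float(volumes.max())
    if lo == hi:
        return np.array([lo * 0.999 if lo > 0 else -0.5, hi * 1.001 if hi > 0 else 0.5])
    if lo > 0:
        return np.geomspace(lo, hi, int(bins) + 1)
    return np.linspace(lo, hi, int(bins) + 1)


def summarize(droplets: Union[DropletSet, Sequence[float]], histogram_bins=20) -> MetricsReport:
    """Exact totals and a volume histogram (default: 20 log-spaced bins).

    Accepts a DropletSet or a bare sequence of volumes. An empty set yields
    zero totals and an absent mean.
    """
    if isinstance(droplets, DropletSet):
        volumes = np.array([d.volume for d in droplets.droplets], dtype=float)
    else:
        volumes = np.asarray(droplets, dtype=float)
    n = len(volumes)
    if n == 0:
        return MetricsReport(0.0, 0, None, (np.array([0.0, 1.0]), np.array([0])))
    edges = _volume_bins(volumes, histogram_bins)
    counts, edges = np.histogram(volumes, bins=edges)
    return MetricsReport(
        total_volume=float(volumes.sum()),
        n_droplets=n,
        mean_volume=float(volumes.mean()),
        volume_histogram=(edges, counts),
    )


# ---------------------------------------------------------------------------
# Nearest-neighbor index
# ---------------------------------------------------------------------------

class _Domain:
    """Uniform sampler over the null domain, reduced to non-degenerate axes."""

    def __init__(self, kind: str, points: np.ndarray, spec):
        self.kind = kind
        self.hull = None
        self.mask_coords = None
        self.mask_step = None
        if kind == "mask":
            mask: MaskVolume = spec
            dz, dy, dx = mask.spacing
            zz, yy, xx = np.nonzero(mask.voxels)
            self.mask_coords = np.column_stack(
                [(xx + 0.5) * dx, (yy + 0.5) * dy, (zz + 0.5) * dz]
            )
            if len(self.mask_coords) == 0:
                raise ValueError("mask domain is empty")
            self.mask_step = np.array([dx, dy, dz])
            self.lo = self.mask_coords.min(axis=0) - self.mask_step / 2
            self.hi = self.mask_coords.max(axis=0) + self.mask_step / 2
        elif kind == "bounding_box":
            if spec is None:
                self.lo = points.min(axis=0)
                self.hi = points.max(axis=0)
            else:
                bounds = np.asarray(spec, dtype=float)
                if bounds.shape != (3, 2):
                    raise ValueError("explicit box must be ((x0,x1),(y0,y1),(z0,z1))")
                self.lo = bounds[:, 0]
                self.hi = bounds[:, 1]
        elif kind == "convex_hull":
            self.lo = points.min(axis=0)
            self.hi = points.max(axis=0)
        else:
            raise ValueError(f"unknown domain kind {kind!r}")

        extent = self.hi - self.lo
        self.active = extent > 0
        if not self.active.any():
            raise ValueError("domain has zero extent in every axis")
        degenerate = ~self.active
        if degenerate.any():
            # Zero extent is allowed only when all points share that coordinate.
            for ax in np.nonzero(degenerate)[0]:
                if not np.allclose(points[:, ax], points[0, ax]):
                    raise ValueError(
                        f"domain has zero extent along axis {'xyz'[ax]} but the "
                        "points do not share that coordinate"
                    )
        self.ndim = int(self.active.sum())
        if kind == "convex_hull":
            reduced = points[:, self.active]
            if self.ndim < 2:
                raise ValueError("convex hull domain needs >= 2 non-degenerate axes")
            hull = ConvexHull(reduced)
            self.hull = Delaunay(reduced[hull.vertices])
            self.volume = float(hull.volume)
        elif kind == "mask":
            self.volume = float(len(self.mask_coords) * np.prod(self.mask_step))
        else:
            self.volume = float(np.prod(extent[self.active]))

    def reduce(self, points: np.ndarray) -> np.ndarray:
        return points[:, self.active]

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        lo = self.lo[self.active]
        hi = self.hi[self.active]
        if self.kind == "bounding_box":
            return rng.uniform(lo, hi, size=(n, self.ndim))
        if self.kind == "mask":
            idx = rng.integers(0, len(self.mask_coords), size=n)
            jitter = rng.uniform(-0.5, 0.5, size=(n, 3)) * self.mask_step
            return (self.mask_coords[idx] + jitter)[:, self.active]
        # convex hull: rejection sampling in the bounding box
        out = np.empty((0, self.ndim))
        while len(out) < n:
            cand = rng.uniform(lo, hi, size=(max(n, 64), self.ndim))
            inside = self.hull.find_simplex(cand) >= 0
            out = np.vstack([out, cand[inside]])
        return out[:n]


def _mean_nn_distance(points: np.ndarray) -> float:
    dists, _ = cKDTree(points).query(points, k=2)
    return float(dists[:, 1].mean())


def nearest_neighbor_index(
    points: Sequence[Sequence[float]],
    domain: Union[str, MaskVolume, Sequence] = "bounding_box",
    mc_reps: int = 999,
    seed: int = 0,
    bounds: Optional[Sequence] = None,
) -> NNResult:
    """Nearest-neighbor clustering index with a Monte Carlo CSR null.

    Parameters
    ----------
    points
        (n, 3) droplet centroids in um, n >= 2.
    domain
        ``"bounding_box"`` (of the points, or of explicit ``bounds``),
        ``"convex_hull"`` of the points, or a :class:`MaskVolume`.
    mc_reps
        CSR realizations used for the expectation (each of the same n).
    seed
        RNG seed for the null; recorded in the result for provenance.
    bounds
        Optional explicit box ``((x0, x1), (y0, y1), (z0, z1))`` um.

    Index < 1 indicates clustering; an axis of zero extent is tolerated when
    every point shares that coordinate (distances fall back to the remaining
    dimensions).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array of um coordinates")
    n = len(pts)
    if n < 2:
        raise ValueError("nearest-neighbor index needs >= 2 points")
    if isinstance(domain, MaskVolume):
        dom = _Domain("mask", pts, domain)
        domain_name = "mask"
    else:
        dom = _Domain(str(domain), pts, bounds)
        domain_name = str(domain)

    reduced = dom.reduce(pts)
    observed = _mean_nn_distance(reduced)

    rng = np.random.default_rng(seed)
    expected = float(
        np.mean([_mean_nn_distance(dom.sample(n, rng)) for _ in range(mc_reps)])
    )
    lam = n / dom.volume
    if dom.ndim == 3:
        poisson = _CE3 * lam ** (-1.0 / 3.0)
    elif dom.ndim == 2:
        poisson = _CE2 * lam ** (-0.5)
    else:
        poisson = 1.0 / (2.0 * lam)
    return NNResult(
        nn_index=observed / expected,
        nn_mean_observed=observed,
        nn_mean_expected=expected,
        nn_expected_poisson=poisson,
        domain=domain_name,
        mc_reps=mc_reps,
        seed=seed,
        n_points=n,
    )


def metrics_report(
    droplets: DropletSet,
    histogram_bins=20,
    domain: Union[str, MaskVolume, Sequence] = "bounding_box",
    mc_reps: int = 999,
    seed: int = 0,
    bounds: Optional[Sequence] = None,
) -> MetricsReport:
    """Full report: totals plus the NN index when the set has >= 2 droplets."""
    report = summarize(droplets, histogram_bins)
    if len(droplets) >= 2:
        nn = nearest_neighbor_index(
            droplets.points(), domain=domain, mc_reps=mc_reps, seed=seed, bounds=bounds
        )
        report = MetricsReport(
            report.total_volume,
            report.n_droplets,
            report.mean_volume,
            report.volume_histogram,
            nn=nn,
        )
    return report


# ---------------------------------------------------------------------------
# Serial-section histology
# ---------------------------------------------------------------------------

def serial_section_volume(track: SectionTrack, method: str = "slab") -> float:
    """Volume of one tracked adipocyte from consecutive section areas.

    ``slab``: sum(area_i) * thickness — each section contributes a slab.
    ``ellipsoid_max_section``: sphere of the area-equivalent radius of the
    largest section, mirroring the confocal single-ROI conversion.
    """
    if method == "slab":
        return float(sum(track.areas) * track.section_thickness)
    if method == "ellipsoid_max_section":
        r = math.sqrt(max(track.areas) / math.pi)
        return 4.0 / 3.0 * math.pi * r**3
    raise ValueError(f"unknown method {method!r}")


def compare_volume_histograms(
    volumes_a: Sequence[float], volumes_b: Sequence[float], bins=20
) -> HistogramComparison:
    """Histograms of two volume samples on shared bins plus the two-sample KS
    statistic (descriptive; no p-value)."""
    a = np.asarray(volumes_a, dtype=float)
    b = np.asarray(volumes_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both volume samples must be non-empty")
    combined = np.concatenate([a, b])
    edges = _volume_bins(combined, bins)
    counts_a, _ = np.histogram(a, bins=edges)
    counts_b, _ = np.histogram(b, bins=edges)
    ks = float(ks_2samp(a, b, method="asymp").statistic)
    return HistogramComparison(edges, counts_a, counts_b, ks)
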