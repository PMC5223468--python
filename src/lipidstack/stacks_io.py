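"""Image stack, mask, and table I/O with the package's coordinate conventions.

Conventions (global to the package):

* Voxel grids are indexed ``(z, y, x)``: slice, row, column.
* Physical spacing is ``(dz, dy, dx)`` in micrometres; anisotropy is
  first-class (confocal stacks typically have dz much larger than dx = dy).
* The physical coordinate of voxel ``(z, y, x)`` is its *centre*:
  ``((z + 0.5) * dz, (y + 0.5) * dy, (x + 0.5) * dx)`` relative to the stack
  origin, reported as ``(x_um, y_um, z_um)``.
* All distances, areas and volumes are in micrometres and powers thereof,
  never in voxel units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "MaskVolume",
    "ManualROI",
    "read_stack",
    "write_stack",
    "read_mask",
    "read_manual_rois",
    "write_droplet_table",
    "read_droplet_table",
    "write_provenance",
    "voxel_centers",
]

#: CSV columns of the droplet table, in export order.
DROPLET_COLUMNS = [
    "id",
    "x_um",
    "y_um",
    "z_um",
    "volume_um3",
    "shape",
    "source_slice",
    "semi_a_um",
    "semi_b_um",
    "semi_c_um",
    "origin",
]

MANUAL_ROI_COLUMNS = ["slice", "x", "y", "semi_major_um", "semi_minor_um", "angle_deg"]


@dataclass(frozen=True)
class ImageStack:
    """A 3D grayscale intensity grid with physical voxel spacing.

    Parameters
    ----------
    voxels
        Integer intensity array of shape ``(n_slices, n_rows, n_cols)``.
    spacing
        ``(dz, dy, dx)`` voxel spacing in micrometres, all strictly positive.
    bit_depth
        8 or 16; all intensities must lie in ``[0, 2**bit_depth - 1]``.
    source_id
        Free-text provenance (file path, simulation seed, ...).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    bit_depth: int
    source_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim == 2:
            v = v[np.newaxis]
        if v.ndim != 3 or v.shape[0] < 1:
            raise ValueError("voxels must be a 3D (z, y, x) array with >= 1 slice")
        if not np.issubdtype(v.dtype, np.integer):
            raise ValueError("voxels must be an integer array")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if v.min() < 0 or v.max() > 2**self.bit_depth - 1:
            raise ValueError("intensities outside [0, 2**bit_depth - 1]")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", sp)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class MaskVolume:
    """Binary volume congruent with an :class:`ImageStack` (muscle boundary etc.)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels).astype(bool)
        if v.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")
        sp = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in sp):
            raise ValueError("spacing must be strictly positive")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", sp)

    def validate_against(self, stack: ImageStack) -> None:
        if self.voxels.shape != stack.shape:
            raise ValueError(
                f"mask shape {self.voxels.shape} != stack shape {stack.shape}"
            )
        if not np.allclose(self.spacing, stack.spacing):
            raise ValueError("mask spacing differs from stack spacing")


@dataclass(frozen=True)
class ManualROI:
    """A hand-fitted circular/elliptical ROI at the slice of maximum signal.

    ``center`` is in pixel units ``(x, y)`` of the slice; the semi-axes are in
    micrometres; ``angle`` in degrees from the +x axis.
    """

    slice_index: int
    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    angle: float = 0.0

    def __post_init__(self) -> None:
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError(
                f"need semi_major >= semi_minor > 0, got "
                f"({self.semi_major}, {self.semi_minor})"
            )


def voxel_centers(n: int, step: float) -> np.ndarray:
    """Physical centre coordinates of ``n`` voxels of size ``step`` (pixel-center)."""
    return (np.arange(n) + 0.5) * step


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def _spacing_from_tiff(tif: tifffile.TiffFile) -> list[Optional[float]]:
    """Extract (dz, dy, dx) in um from TIFF metadata; None for unavailable axes."""
    dz = dy = dx = None
    page = tif.pages[0]
    # ImageJ-style metadata: XY from resolution tags, Z from 'spacing'.
    ij = tif.imagej_metadata or {}
    unit = str(ij.get("unit", "")).lower()
    scale = 1.0
    if unit in ("um", "micron", "micrometer", "µm", "µm"):
        scale = 1.0
    elif unit in ("mm", "millimeter"):
        scale = 1000.0
    res_unit = page.tags.get("ResolutionUnit")
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    # Resolution tags are pixels per unit as a rational.
    if res_unit is not None and not ij:
        ru = int(res_unit.value)
        if ru == 2:  # inch
            scale = 25400.0
        elif ru == 3:  # centimetre
            scale = 10000.0
        else:
            scale = None  # unit-less resolution: not trustworthy
    if scale is not None:
        if xres is not None and xres.value[0] > 0:
            num, den = xres.value
            if num > 0:
                dx = den / num * scale
        if yres is not None and yres.value[0] > 0:
            num, den = yres.value
            if num > 0:
                dy = den / num * scale
    if "spacing" in ij:
        dz = float(ij["spacing"]) * (scale if scale else 1.0)
    return [dz, dy, dx]


def read_stack(
    path: str | Path,
    spacing_override: Optional[Sequence[float]] = None,
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF into an :class:`ImageStack`.

    Spacing is taken from TIFF/ImageJ metadata where present; any component
    the file does not provide is filled from ``spacing_override`` ``(dz, dy,
    dx)``. If a component is available from neither source the read fails —
    results must never depend on a silent default.

    Raises
    ------
    FileNotFoundError
        Missing file.
    ValueError
        RGB or floating-point TIFF, or spacing unavailable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(str(path)) as tif:
        if tif.pages[0].samplesperpixel != 1:
            raise ValueError(
                "RGB/multi-sample TIFF not supported: expected grayscale"
            )
        data = tif.asarray()
        spacing = _spacing_from_tiff(tif)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(
            f"unsupported TIFF layout with shape {data.shape}: expected a "
            "single- or multi-page grayscale image (RGB is not supported)"
        )
    if np.issubdtype(data.dtype, np.floating):
        raise ValueError("floating-point TIFF not supported; expected 8/16-bit grayscale")
    if data.dtype.itemsize > 2:
        raise ValueError(f"unsupported sample depth {data.dtype}")
    bit_depth = 8 if data.dtype.itemsize == 1 else 16

    if spacing_override is not None:
        ov = [float(s) for s in spacing_override]
        if len(ov) != 3:
            raise ValueError("spacing_override must be (dz, dy, dx)")
        spacing = [m if m is not None else o for m, o in zip(spacing, ov)]
    if any(s is None for s in spacing):
        missing = [ax for ax, s in zip("zyx", spacing) if s is None]
        raise ValueError(
            f"spacing unavailable for axis/axes {missing}: the TIFF carries no "
            "usable resolution metadata and no spacing_override was given"
        )
    return ImageStack(
        voxels=data,
        spacing=tuple(spacing),  # type: ignore[arg-type]
        bit_depth=bit_depth,
        source_id=str(path),
    )


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as an ImageJ-compatible multi-page TIFF.

    Stores spacing so that :func:`read_stack` round-trips without an override.
    """
    dz, dy, dx = stack.spacing
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    tifffile.imwrite(
        str(path),
        stack.voxels.astype(dtype),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )


def read_mask(path: str | Path, spacing: Sequence[float]) -> MaskVolume:
    """Read a binary TIFF volume (nonzero = inside) with the stack's spacing."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[np.newaxis]
    return MaskVolume(voxels=data > 0, spacing=tuple(float(s) for s in spacing))


# ---------------------------------------------------------------------------
# Manual ROI tables
# ---------------------------------------------------------------------------

def read_manual_rois(path: str | Path) -> list[ManualROI]:
    """Read hand-fitted ROIs from CSV.

    Expected header: ``slice,x,y,semi_major_um,semi_minor_um,angle_deg``.
    Invalid rows are reported with 1-based file line numbers (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != MANUAL_ROI_COLUMNS:
        raise ValueError(
            f"malformed manual-ROI header in {path}: expected "
            f"{','.join(MANUAL_ROI_COLUMNS)}, got {','.join(map(str, df.columns))}"
        )
    rois: list[ManualROI] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        line = int(i) + 2  # header is line 1
        try:
            vals = [float(row[c]) for c in MANUAL_ROI_COLUMNS]
        except (TypeError, ValueError):
            errors.append(f"line {line}: non-numeric field")
            continue
        sl, x, y, a, b, ang = vals
        if not float(sl).is_integer() or sl < 0:
            errors.append(f"line {line}: slice must be a non-negative integer, got {sl}")
            continue
        try:
            rois.append(ManualROI(int(sl), (x, y), a, b, ang))
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValueError("invalid manual ROI rows:\n" + "\n".join(errors))
    return rois


# ---------------------------------------------------------------------------
# Droplet tables
# ---------------------------------------------------------------------------

def write_droplet_table(droplets, path: str | Path) -> None:
    """Write a DropletSet to CSV (physical um coordinates, 3 decimals).

    The table round-trips losslessly at the stated precision through
    :func:`read_droplet_table`.
    """
    rows = []
    for d in droplets.droplets:
        rows.append(
            {
                "id": d.id,
                "x_um": d.centroid[0],
                "y_um": d.centroid[1],
                "z_um": d.centroid[2],
                "volume_um3": d.volume,
                "shape": d.shape,
                "source_slice": d.source_slice,
                "semi_a_um": d.semi_axes[0],
                "semi_b_um": d.semi_axes[1],
                "semi_c_um": d.semi_axes[2],
                "origin": d.origin,
            }
        )
    df = pd.DataFrame(rows, columns=DROPLET_COLUMNS)
    df.to_csv(path, index=False, float_format="%.3f")


def read_droplet_table(path: str | Path):
    """Read a droplet CSV written by :func:`write_droplet_table` back into a DropletSet."""
    from .registration3d import Droplet3D, DropletSet

    df = pd.read_csv(path)
    missing = [c for c in DROPLET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"droplet table missing columns: {missing}")
    droplets = [
        Droplet3D(
            id=int(r.id),
            centroid=(float(r.x_um), float(r.y_um), float(r.z_um)),
            volume=float(r.volume_um3),
            shape=str(r.shape),
            source_slice=int(r.source_slice),
            semi_axes=(float(r.semi_a_um), float(r.semi_b_um), float(r.semi_c_um)),
            origin=str(r.origin),
            check_volume=False,  # 3-decimal rounding breaks the exact identity
        )
        for r in df.itertuples()
    ]
    return DropletSet(droplets=droplets, stack_ref=str(path), params_ref="")


def write_provenance(path: str | Path, payload: dict) -> None:
    """Write a JSON run-provenance sidecar (parameters, seed, version)."""
    from . import __version__

    payload = dict(payload)
    payload.setdefault("software", {"name": "lipidstack", "version": __version__})
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
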