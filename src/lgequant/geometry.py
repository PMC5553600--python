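"""Contours, masks, LV mass and infarct-size bookkeeping.

Every quantification method in this package reduces to the same final
step: a per-voxel infarct weight map in [0, 1] over a myocardium mask,
converted to infarct size as a percentage of LV myocardium (%LV) and in
grams.  This module owns that conversion, plus the rasterization of
endocardial/epicardial contours into myocardium masks.

Conventions
-----------
* Image arrays are indexed (slice, row, col); physical coordinates are
  x = (col + 0.5) * pixel_spacing_x, y = (row + 0.5) * pixel_spacing_y,
  i.e. voxel centers sit at half-integer pixel positions.
* A voxel belongs to the myocardium iff its center lies inside (or on)
  the epicardial polygon and strictly outside the endocardial polygon.
* Voxel depth is slice_thickness + slice_gap (contiguous-coverage
  convention), so gapped acquisitions do not under-count mass.
* Myocardial density is 1.05 g/mL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


class GeometryError(ValueError):
    """Raised for invalid or degenerate contour geometry."""


class MetadataError(ValueError):
    """Raised when required spacing metadata is missing or invalid."""


@dataclass
class ImageStack:
    """A short-axis grayscale stack with spacing metadata.

    Parameters
    ----------
    intensities : ndarray, shape (n_slices, n_rows, n_cols)
        Voxel intensities in arbitrary units, finite and non-negative.
    pixel_spacing : (float, float)
        In-plane spacing (x, y) in mm.
    slice_thickness, slice_gap : float
        Through-plane geometry in mm.
    """

    intensities: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    slice_gap: float = 0.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise MetadataError("intensities must be a 3-D (slice, row, col) array")
        if not np.all(np.isfinite(self.intensities)):
            raise MetadataError("intensities must be finite")
        sx, sy = self.pixel_spacing
        if sx <= 0 or sy <= 0 or self.slice_thickness <= 0 or self.slice_gap < 0:
            raise MetadataError("spacings must be positive (gap non-negative)")

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in mL, including the slice gap."""
        sx, sy = self.pixel_spacing
        return sx * sy * (self.slice_thickness + self.slice_gap) / 1000.0

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates in mm for one slice, shape (rows, cols)."""
        _, n_rows, n_cols = self.intensities.shape
        sx, sy = self.pixel_spacing
        x = (np.arange(n_cols) + 0.5) * sx
        y = (np.arange(n_rows) + 0.5) * sy
        return np.meshgrid(x, y)


@dataclass
class ContourSet:
    """Per-slice closed endocardial and epicardial polygons in mm.

    ``endo[s]`` and ``epi[s]`` are (N, 2) arrays of [x, y] vertices for
    slice ``s``; the polygon is implicitly closed (last vertex connects
    back to the first).  ``provenance`` records whether the contours are
    simulation ground truth or a (simulated) reader's tracing.
    """

    endo: list[np.ndarray]
    epi: list[np.ndarray]
    provenance: str = "truth"

    def __post_init__(self) -> None:
        if len(self.endo) != len(self.epi):
            raise GeometryError("endo and epi must cover the same slices")
        self.endo = [np.asarray(c, dtype=float) for c in self.endo]
        self.epi = [np.asarray(c, dtype=float) for c in self.epi]

    @property
    def n_slices(self) -> int:
        return len(self.endo)

    def validate(self) -> None:
        """Check closedness/simplicity and endo-inside-epi on every slice."""
        for s, (en, ep) in enumerate(zip(self.endo, self.epi)):
            for name, poly in (("endocardial", en), ("epicardial", ep)):
                if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                    raise GeometryError(
                        f"slice {s}: {name} contour needs >=3 [x, y] vertices"
                    )
                if not shapely.Polygon(poly).is_valid:
                    raise GeometryError(
                        f"slice {s}: {name} contour is self-intersecting"
                    )
            if not shapely.Polygon(ep).contains(shapely.Polygon(en)):
                raise GeometryError(
                    f"slice {s}: endocardial contour not strictly inside epicardial"
                )


@dataclass
class MyocardiumMask:
    """Boolean myocardium volume aligned to an ImageStack."""

    mask: np.ndarray
    source: ContourSet | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class InfarctMap:
    """Per-voxel infarct weight in [0, 1]; dichotomous methods use {0, 1}."""

    weights: np.ndarray
    method: str = ""
    status: str = "ok"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size and (
            self.weights.min() < 0.0 or self.weights.max() > 1.0
        ):
            raise ValueError("infarct weights must lie in [0, 1]")


@dataclass
class InfarctSizeResult:
    """Infarct size of one (patient, reader, method) measurement."""

    percent_lv: float
    mass_g: float
    lv_mass_g: float
    method: str = ""
    reader: str = ""
    patient: str = ""

    def as_row(self) -> dict:
        return {
            "patient": self.patient,
            "reader": self.reader,
            "method": self.method,
            "percent_lv": self.percent_lv,
            "mass_g": self.mass_g,
            "lv_mass_g": self.lv_mass_g,
        }


def rasterize_contours(contours: ContourSet, stack: ImageStack) -> MyocardiumMask:
    """Rasterize endo/epi contours into a myocardium mask.

    A voxel is myocardium iff its center is covered by the epicardial
    polygon (boundary inclusive) and not strictly inside the endocardial
    polygon.  Raises :class:`GeometryError`, naming the slice, when the
    contours cross or produce an empty slice mask.
    """
    contours.validate()
    if contours.n_slices != stack.n_slices:
        raise GeometryError(
            f"contour set covers {contours.n_slices} slices, stack has {stack.n_slices}"
        )
    xx, yy = stack.voxel_centers_mm()
    xf, yf = xx.ravel(), yy.ravel()
    mask = np.zeros(stack.intensities.shape, dtype=bool)
    for s in range(stack.n_slices):
        epi_poly = shapely.Polygon(contours.epi[s])
        endo_poly = shapely.Polygon(contours.endo[s])
        inside_epi = shapely.intersects_xy(epi_poly, xf, yf)
        inside_endo = shapely.contains_xy(endo_poly, xf, yf)
        slice_mask = inside_epi & ~inside_endo
        if not slice_mask.any():
            raise GeometryError(f"slice {s}: contours rasterize to an empty mask")
        mask[s] = slice_mask.reshape(xx.shape)
    return MyocardiumMask(mask=mask, source=contours)


def lv_mass(mask: MyocardiumMask, stack: ImageStack) -> float:
    """LV myocardial mass in grams: voxel count x voxel volume x density."""
    n = mask.voxel_count
    if n == 0:
        warnings.warn("empty myocardium mask: LV mass is 0 g", stacklevel=2)
        return 0.0
    return n * stack.voxel_volume_ml * MYOCARDIAL_DENSITY_G_PER_ML


def infarct_size(
    infarct: InfarctMap,
    mask: MyocardiumMask,
    stack: ImageStack,
    *,
    method: str = "",
    reader: str = "",
    patient: str = "",
) -> InfarctSizeResult:
    """Convert a weight map to %LV and grams over a myocardium mask."""
    if infarct.weights.shape != mask.mask.shape:
        raise ValueError("infarct map and myocardium mask are misaligned")
    n_myo = mask.voxel_count
    if n_myo == 0:
        raise GeometryError("cannot compute infarct size on an empty myocardium")
    weight_sum = float(infarct.weights.sum())
    percent = 100.0 * weight_sum / n_myo
    mass = weight_sum * stack.voxel_volume_ml * MYOCARDIAL_DENSITY_G_PER_ML
    return InfarctSizeResult(
        percent_lv=percent,
        mass_g=mass,
        lv_mass_g=lv_mass(mask, stack),
        method=method or infarct.method,
        reader=reader,
        patient=patient,
    )
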