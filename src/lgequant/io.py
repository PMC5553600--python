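"""File formats: NIfTI volumes, JSON contours/scores, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import ContourSet, ImageStack

MEASUREMENT_COLUMNS = ["patient", "reader", "method", "percent_lv", "mass_g", "lv_mass_g"]


def _affine(stack: ImageStack) -> np.ndarray:
    sx, sy = stack.pixel_spacing
    sz = stack.slice_thickness + stack.slice_gap
    # array axes are (slice, row, col) -> world (z, y, x)
    return np.diag([sz, sy, sx, 1.0])


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an image stack as a NIfTI volume with spacing in the header."""
    img = nib.Nifti1Image(stack.intensities.astype(np.float32), _affine(stack))
    nib.save(img, str(path))


def read_stack(path: str | Path, slice_gap: float = 0.0) -> ImageStack:
    """Read a NIfTI volume written by :func:`write_stack`.

    The NIfTI header stores only the total slice spacing; ``slice_gap``
    splits it back into thickness + gap if nonzero.
    """
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    sz, sy, sx = float(zooms[0]), float(zooms[1]), float(zooms[2])
    return ImageStack(
        intensities=np.asarray(img.dataobj, dtype=float),
        pixel_spacing=(sx, sy),
        slice_thickness=sz - slice_gap,
        slice_gap=slice_gap,
    )


def write_mask(mask: np.ndarray, stack: ImageStack, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(stack))
    nib.save(img, str(path))


def write_contours(contours: ContourSet, path: str | Path) -> None:
    """Contours as JSON: per-slice arrays of [x_mm, y_mm], 0-based slices."""
    payload = {
        "provenance": contours.provenance,
        "slices": [
            {
                "slice": s,
                "endo": contours.endo[s].tolist(),
                "epi": contours.epi[s].tolist(),
            }
            for s in range(contours.n_slices)
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_contours(path: str | Path) -> ContourSet:
    payload = json.loads(Path(path).read_text())
    slices = sorted(payload["slices"], key=lambda d: d["slice"])
    return ContourSet(
        endo=[np.asarray(d["endo"], dtype=float) for d in slices],
        epi=[np.asarray(d["epi"], dtype=float) for d in slices],
        provenance=payload.get("provenance", "truth"),
    )


def write_measurements(table: pd.DataFrame, path: str | Path) -> None:
    """Measurement table CSV with fixed columns and stable float format."""
    table[MEASUREMENT_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
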