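"""Automated infarct-border determination and the user-correction step.

Two algorithm families are implemented:

* a weighted-threshold ("Segment-style") algorithm that assigns each
  myocardial voxel a continuous infarct fraction according to how far
  its signal intensity lies above a remote-myocardium-based detection
  threshold, so partial-volume / intermediate-signal voxels contribute
  fractionally rather than dichotomously; and
* the full-width-at-half-maximum (FWHM) algorithm, which classifies a
  voxel as infarcted iff its intensity exceeds half the maximal infarct
  signal.

Both run with no user input given a myocardium mask; the user-corrected
(AUTO-UC) variants additionally apply a :class:`CorrectionSet` adding
no-reflow zones at full weight and removing blood-pool / artifact
voxels.  ``simulate_corrections`` generates such a set from ground
truth under a reader's diligence model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from skimage import measure

from .geometry import ImageStack, InfarctMap, MyocardiumMask
from .phantom import GroundTruth, ReaderModel


@dataclass
class WeightedThresholdParams:
    """Parameters of the weighted-threshold algorithm.

    ``k`` sets the detection threshold at k remote SDs above the remote
    mean; ``remote_window`` is the angular width of the sector searched
    for remote myocardium; ``plateau_quantile`` defines the fully
    infarcted intensity level as the mean of the supra-threshold voxels
    at or above that quantile (robust to single hot voxels).
    """

    k: float = 1.8
    remote_window: float = 60.0
    plateau_quantile: float = 0.75

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if not 0 < self.remote_window <= 360:
            raise ValueError("remote_window must lie in (0, 360]")
        if not 0 < self.plateau_quantile <= 1:
            raise ValueError("plateau_quantile must lie in (0, 1]")


@dataclass
class FWHMParams:
    """Parameters of the FWHM algorithm.

    ``reference='half_max'`` thresholds at M/2; ``'half_range'`` at
    remote mean + (M - remote mean)/2, which is additionally invariant
    to intensity offsets.  The maximum M is estimated per volume as the
    ``max_percentile`` of myocardial intensities (99 by default) or the
    global maximum.
    """

    reference: str = "half_max"
    max_estimator: str = "top_percentile"
    max_percentile: float = 99.0

    def __post_init__(self) -> None:
        if self.reference not in ("half_max", "half_range"):
            raise ValueError(f"unknown reference {self.reference!r}")
        if self.max_estimator not in ("global_max", "top_percentile"):
            raise ValueError(f"unknown max estimator {self.max_estimator!r}")
        if not 0 < self.max_percentile <= 100:
            raise ValueError("percentile must lie in (0, 100]")


@dataclass
class CorrectionSet:
    """Manual corrections: per-slice polygons to add (weight 1) or remove.

    ``add_regions`` / ``remove_regions`` are lists of
    ``(slice_index, vertices)`` with vertices as (N, 2) arrays of
    [x_mm, y_mm].  Add and remove regions may not overlap.
    """

    add_regions: list[tuple[int, np.ndarray]] = field(default_factory=list)
    remove_regions: list[tuple[int, np.ndarray]] = field(default_factory=list)
    reader: str = ""


def remote_statistics(
    stack: ImageStack,
    mask: MyocardiumMask,
    window_deg: float = 60.0,
    step_deg: float = 5.0,
    center_mm: tuple[float, float] | None = None,
) -> tuple[float, float, np.ndarray]:
    """Locate remote myocardium and return (mean, SD, remote voxel mask).

    Remote myocardium is found with no user input as the angular sector
    (default 60 degrees, pooled across slices) of minimal mean
    intensity about the LV center.  SD uses the n-1 denominator.
    """
    if mask.voxel_count == 0:
        raise ValueError("empty myocardium mask")
    xx, yy = stack.voxel_centers_mm()
    if center_mm is None:
        # centroid of the myocardium itself
        m_any = mask.mask.any(axis=0)
        center_mm = (float(xx[m_any].mean()), float(yy[m_any].mean()))
    theta = np.degrees(np.arctan2(yy - center_mm[1], xx - center_mm[0])) % 360.0
    theta3 = np.broadcast_to(theta, stack.intensities.shape)

    starts = np.arange(0.0, 360.0, step_deg)
    best_mean, best_sector = np.inf, None
    myo_theta = theta3[mask.mask]
    myo_si = stack.intensities[mask.mask]
    for a in starts:
        in_sector = (myo_theta - a) % 360.0 <= window_deg
        if in_sector.sum() < 10:
            continue
        m = myo_si[in_sector].mean()
        if m < best_mean:
            best_mean, best_sector = m, a
    if best_sector is None:
        raise ValueError("no angular sector with enough myocardial voxels")
    remote = np.zeros_like(mask.mask)
    remote[mask.mask] = (myo_theta - best_sector) % 360.0 <= window_deg
    vals = stack.intensities[remote]
    return float(vals.mean()), float(vals.std(ddof=1)), remote


def weighted_infarct(
    stack: ImageStack,
    mask: MyocardiumMask,
    params: WeightedThresholdParams | None = None,
) -> InfarctMap:
    """Weighted-threshold infarct map.

    threshold t = remote mean + k * remote SD; plateau F = mean of the
    supra-threshold intensities at or above the plateau quantile;
    weight(v) = 0 for SI <= t, else min(1, (SI - t)/(F - t)).
    """
    params = params or WeightedThresholdParams()
    mu_r, sd_r, _ = remote_statistics(stack, mask, params.remote_window)
    t = mu_r + params.k * sd_r
    si = stack.intensities
    supra = mask.mask & (si > t)
    weights = np.zeros_like(si)
    if not supra.any():
        return InfarctMap(weights, method="AUTO_SEGMENT", status="no infarct detected")
    supra_vals = si[supra]
    q = np.quantile(supra_vals, params.plateau_quantile)
    plateau = float(supra_vals[supra_vals >= q].mean())
    if plateau <= t:
        warnings.warn(
            "degenerate contrast: plateau <= threshold; supra-threshold "
            "voxels set to weight 1",
            stacklevel=2,
        )
        weights[supra] = 1.0
    else:
        weights[supra] = np.clip((si[supra] - t) / (plateau - t), 0.0, 1.0)
    return InfarctMap(weights, method="AUTO_SEGMENT")


def fwhm_infarct(
    stack: ImageStack,
    mask: MyocardiumMask,
    params: FWHMParams | None = None,
) -> InfarctMap:
    """FWHM infarct map: dichotomous classification above half-maximum.

    A credibility guard returns an all-zero map when the half-maximum
    threshold does not clear remote mean + 2 SD, preventing the
    pathological all-infarct output on infarct-free stacks (readers in
    core laboratories pre-screen for the presence of infarction).
    """
    params = params or FWHMParams()
    if mask.voxel_count == 0:
        raise ValueError("empty myocardium mask")
    myo_si = stack.intensities[mask.mask]
    if params.max_estimator == "global_max":
        m_est = float(myo_si.max())
    else:
        m_est = float(np.percentile(myo_si, params.max_percentile))
    mu_r, sd_r, _ = remote_statistics(stack, mask)
    if params.reference == "half_max":
        thresh = m_est / 2.0
    else:
        thresh = mu_r + (m_est - mu_r) / 2.0
    weights = np.zeros_like(stack.intensities)
    if m_est / 2.0 < mu_r + 2.0 * sd_r and params.reference == "half_max":
        warnings.warn("no credible hyperenhancement: zero map", stacklevel=2)
        return InfarctMap(weights, method="AUTO_FWHM", status="no infarct detected")
    if params.reference == "half_range" and thresh < mu_r + 2.0 * sd_r:
        warnings.warn("no credible hyperenhancement: zero map", stacklevel=2)
        return InfarctMap(weights, method="AUTO_FWHM", status="no infarct detected")
    weights[mask.mask & (stack.intensities > thresh)] = 1.0
    return InfarctMap(weights, method="AUTO_FWHM")


# ---------------------------------------------------------------------------
# user corrections


def _rasterize_region(
    slice_index: int, vertices: np.ndarray, stack: ImageStack
) -> np.ndarray:
    poly = shapely.Polygon(np.asarray(vertices, dtype=float))
    xx, yy = stack.voxel_centers_mm()
    return shapely.intersects_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)


def apply_corrections(
    infarct: InfarctMap,
    corrections: CorrectionSet,
    stack: ImageStack,
    mask: MyocardiumMask | None = None,
) -> InfarctMap:
    """Apply manual add/remove corrections to an automated infarct map.

    Voxels inside add regions (restricted to the myocardial contours if
    a mask is given) are set to weight 1; voxels inside remove regions
    to 0; everything else is unchanged.  Overlapping add/remove regions
    raise a validation error.
    """
    weights = infarct.weights.copy()
    add = np.zeros_like(weights, dtype=bool)
    rem = np.zeros_like(weights, dtype=bool)
    for s, verts in corrections.add_regions:
        add[s] |= _rasterize_region(s, verts, stack)
    for s, verts in corrections.remove_regions:
        rem[s] |= _rasterize_region(s, verts, stack)
    if (add & rem).any():
        raise ValueError("add and remove correction regions overlap")
    if mask is not None:
        add &= mask.mask
    weights[add] = 1.0
    weights[rem] = 0.0
    return InfarctMap(weights, method=infarct.method + "_UC", status=infarct.status)


def _mask_to_polygons(mask2d: np.ndarray, stack: ImageStack) -> list[np.ndarray]:
    """Trace a 2-D boolean mask into closed polygons in mm coordinates."""
    padded = np.pad(mask2d.astype(float), 1)
    sx, sy = stack.pixel_spacing
    polys = []
    for contour in measure.find_contours(padded, 0.5):
        rows = contour[:, 0] - 1.0
        cols = contour[:, 1] - 1.0
        verts = np.column_stack(((cols + 0.5) * sx, (rows + 0.5) * sy))
        if len(verts) >= 3:
            polys.append(verts)
    return polys


def simulate_corrections(
    truth: GroundTruth,
    auto_map: InfarctMap,
    reader: ReaderModel,
    seed: int,
    stack: ImageStack,
) -> CorrectionSet:
    """Simulated stand-in for the human correction pass.

    With probability ``correction_completeness`` per region the reader
    (a) adds the true no-reflow zone at full weight and (b) removes any
    connected supra-threshold blob that does not overlap true infarcted
    tissue (bright blood-pool or artifact voxels caught inside the
    myocardial contour).
    """
    if auto_map.weights.shape != truth.myocardium_mask.shape:
        raise ValueError("infarct map and ground truth are misaligned")
    rng = np.random.default_rng(seed)
    corr = CorrectionSet(reader=reader.reader_id)
    p = reader.correction_completeness
    true_infarct = (
        truth.infarct_core_mask | truth.grey_zone_mask | truth.no_reflow_mask
    )
    for s in range(truth.myocardium_mask.shape[0]):
        # no-reflow additions
        nr = truth.no_reflow_mask[s]
        if nr.any():
            labels, n = ndimage.label(nr)
            for lab in range(1, n + 1):
                if rng.random() < p:
                    for verts in _mask_to_polygons(labels == lab, stack):
                        corr.add_regions.append((s, verts))
        # false-positive removals
        pos = auto_map.weights[s] > 0
        fp = pos & ~true_infarct[s]
        if fp.any():
            labels, n = ndimage.label(pos)
            for lab in range(1, n + 1):
                blob = labels == lab
                overlap = (blob & true_infarct[s]).sum() / blob.sum()
                if overlap < 0.1 and rng.random() < p:
                    for verts in _mask_to_polygons(blob, stack):
                        corr.remove_regions.append((s, verts))
    return corr
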