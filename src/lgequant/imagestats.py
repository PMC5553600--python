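"""Signal-to-noise and contrast-to-noise ratios from regions of interest.

SNR of a tissue is the mean signal intensity over its ROI divided by
the SD of the signal in an air ("noise") ROI; infarct-to-remote CNR is
the difference of the two tissue SNRs.  SDs use the sample (n-1)
denominator since ROIs are small.  No Rician noise-floor correction is
applied: the statistic is the plain ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import ImageStack
from .phantom import GroundTruth


@dataclass
class ROISet:
    """Voxel-index ROIs for infarct, remote myocardium and air.

    Each ROI is a tuple of integer index arrays (slice, row, col), as
    produced by ``numpy.nonzero``; the three ROIs must be pairwise
    disjoint and nonempty.
    """

    infarct_roi: tuple[np.ndarray, ...]
    remote_roi: tuple[np.ndarray, ...]
    air_roi: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        sets = []
        for name in ("infarct_roi", "remote_roi", "air_roi"):
            idx = getattr(self, name)
            if len(idx[0]) == 0:
                raise ValueError(f"{name} is empty")
            sets.append(set(zip(*(a.tolist() for a in idx))))
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("ROIs must be pairwise disjoint")


def snr(stack: ImageStack, tissue_roi, air_roi) -> float:
    """mean(tissue SI) / SD(air SI), sample SD with n-1 denominator."""
    air = stack.intensities[air_roi]
    if len(air) < 2:
        raise ValueError("air ROI needs at least 2 voxels")
    sd = float(air.std(ddof=1))
    if sd == 0:
        raise ValueError("zero air SD: degenerate noiseless input")
    return float(stack.intensities[tissue_roi].mean()) / sd


def cnr(stack: ImageStack, infarct_roi, remote_roi, air_roi) -> float:
    """Infarct SNR minus remote-myocardium SNR."""
    return snr(stack, infarct_roi, air_roi) - snr(stack, remote_roi, air_roi)


def phantom_rois(
    truth: GroundTruth, stack: ImageStack, radius_mm: float = 4.0
) -> ROISet:
    """Centroid-anchored disk ROIs for a phantom.

    Disks of ``radius_mm`` are placed at the infarct-core centroid and
    at the remote-myocardium centroid of the slice with the most core
    voxels; the air ROI is a disk in the image corner, outside the
    epicardial region.
    """
    core = truth.infarct_core_mask
    if not core.any():
        raise ValueError("phantom has no infarct core")
    s = int(core.sum(axis=(1, 2)).argmax())
    sx, sy = stack.pixel_spacing
    rows, cols = np.nonzero(core[s])
    remote = truth.myocardium_mask[s] & ~core[s] & ~truth.grey_zone_mask[s] & ~truth.no_reflow_mask[s]
    r_rows, r_cols = np.nonzero(remote)

    def disk(cr, cc, allowed=None):
        rr, cc_grid = np.mgrid[0 : core.shape[1], 0 : core.shape[2]]
        d = np.hypot((rr - cr) * sy, (cc_grid - cc) * sx)
        m = d <= radius_mm
        if allowed is not None:
            m &= allowed
        return m

    inf_m = disk(rows.mean(), cols.mean(), allowed=core[s])
    # remote centroid of an annulus can fall in the cavity; anchor on the
    # remote voxel closest to the centroid instead
    cr, cc = r_rows.mean(), r_cols.mean()
    j = int(np.argmin((r_rows - cr) ** 2 + (r_cols - cc) ** 2))
    rem_m = disk(r_rows[j], r_cols[j], allowed=remote)
    body = ndimage.binary_dilation(
        truth.myocardium_mask[s] | truth.blood_pool_mask[s], iterations=3
    )
    air_m = disk(3, 3, allowed=~body)

    def to_idx(m):
        r, c = np.nonzero(m)
        return (np.full_like(r, s), r, c)

    return ROISet(
        infarct_roi=to_idx(inf_m), remote_roi=to_idx(rem_m), air_roi=to_idx(air_m)
    )
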