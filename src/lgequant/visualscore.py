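"""17-segment visual scoring: VISUAL and VISUAL-ISI.

Myocardium is partitioned into the standard AHA 17-segment model
(6 basal, 6 mid-cavity, 4 apical segments plus the apical cap).  Each
segment receives a 5-point hyperenhancement extent score
(0 = none, 1 = 1-25%, 2 = 26-50%, 3 = 51-75%, 4 = 76-100%) and,
optionally, a 4-point signal-intensity score from the mean intensity of
the hyperenhanced tissue relative to the brighter of the brightest
infarct voxel and the LV blood pool.

VISUAL infarct size sums the midpoint of each extent bin
(1 -> 13%, 2 -> 38%, 3 -> 63%, 4 -> 88%) over segments and divides by
17.  VISUAL-ISI additionally multiplies each segment's midpoint by a
signal-intensity weight before summing; the weight mapping reuses the
extent midpoints as fractions (1 -> 0.13, ... 4 -> 0.88) and is
configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import ImageStack, MyocardiumMask
from .manualquant import RegionClassification

EXTENT_MIDPOINTS = {0: 0.0, 1: 13.0, 2: 38.0, 3: 63.0, 4: 88.0}
SI_WEIGHTS = {0: 0.0, 1: 0.13, 2: 0.38, 3: 0.63, 4: 0.88}


@dataclass
class SegmentLabelMap:
    """Per-voxel AHA segment label in {1..17}, 0 where unassigned."""

    labels: np.ndarray
    rv_insertion_angle: float


@dataclass
class SegmentScores:
    """Extent scores (0-4) and optional signal-intensity scores per segment."""

    extent: np.ndarray  # 17 ints in {0..4}
    si: np.ndarray | None = None  # 17 ints, 0 only where extent == 0
    patient: str = ""
    reader: str = ""

    def __post_init__(self) -> None:
        self.extent = np.asarray(self.extent, dtype=int)
        if self.extent.shape != (17,):
            raise ValueError("need exactly 17 extent scores")
        if np.any((self.extent < 0) | (self.extent > 4)):
            raise ValueError("extent scores must lie in 0..4")
        if self.si is not None:
            self.si = np.asarray(self.si, dtype=int)
            if self.si.shape != (17,):
                raise ValueError("need exactly 17 SI scores")
            if np.any((self.si == 0) & (self.extent > 0)):
                raise ValueError("SI score missing for a hyperenhanced segment")
            if np.any((self.si > 0) & (self.extent == 0)):
                raise ValueError("SI score present for an unenhanced segment")


def assign_segments(
    mask: MyocardiumMask,
    stack: ImageStack,
    rv_insertion_angle: float = 0.0,
    center_mm: tuple[float, float] | None = None,
) -> SegmentLabelMap:
    """Assign every myocardial voxel to an AHA segment.

    Slices (ordered base to apex) are split into basal/mid/apical
    thirds by slice count, remainders going to the basal then mid
    rings.  Basal and mid rings are divided into 6 sectors of 60
    degrees, the apical ring into 4 sectors of 90 degrees, measured
    from ``rv_insertion_angle``.  The apical-most slice becomes the
    apical cap (segment 17) when its endocardial cavity area is below
    10% of its epicardial area; otherwise no cap segment is assigned
    and a warning is issued.
    """
    n_slices = mask.mask.shape[0]
    if n_slices < 3:
        raise ValueError("need at least 3 slices for the 17-segment model")
    xx, yy = stack.voxel_centers_mm()
    if center_mm is None:
        m_any = mask.mask.any(axis=0)
        center_mm = (float(xx[m_any].mean()), float(yy[m_any].mean()))
    theta = (
        np.degrees(np.arctan2(yy - center_mm[1], xx - center_mm[0]))
        - rv_insertion_angle
    ) % 360.0

    base = n_slices // 3
    rem = n_slices % 3
    n_basal = base + (1 if rem >= 1 else 0)
    n_mid = base + (1 if rem == 2 else 0)
    ring_of_slice = (
        ["basal"] * n_basal + ["mid"] * n_mid + ["apical"] * (n_slices - n_basal - n_mid)
    )

    # apical cap: last slice with nearly obliterated cavity
    cap_slice = None
    last = n_slices - 1
    myo_last = mask.mask[last]
    if myo_last.any():
        # cavity = pixels inside the myocardial ring
        from scipy import ndimage

        filled = ndimage.binary_fill_holes(myo_last)
        cavity = filled & ~myo_last
        if cavity.sum() < 0.10 * filled.sum():
            cap_slice = last
    if cap_slice is None:
        warnings.warn(
            "no apical-cap slice detected (cavity present on the apical-most "
            "slice); segment 17 left unassigned",
            stacklevel=2,
        )

    labels = np.zeros(mask.mask.shape, dtype=int)
    for s in range(n_slices):
        myo = mask.mask[s]
        if not myo.any():
            continue
        if s == cap_slice:
            labels[s][myo] = 17
            continue
        ring = ring_of_slice[s]
        if ring == "basal":
            sector = np.floor_divide(theta, 60.0).astype(int) % 6
            labels[s][myo] = 1 + sector[myo]
        elif ring == "mid":
            sector = np.floor_divide(theta, 60.0).astype(int) % 6
            labels[s][myo] = 7 + sector[myo]
        else:
            sector = np.floor_divide(theta, 90.0).astype(int) % 4
            labels[s][myo] = 13 + sector[myo]
    return SegmentLabelMap(labels=labels, rv_insertion_angle=rv_insertion_angle)


def extent_score(hyper_fraction: float) -> int:
    """5-point extent score: 0 none, 1 = 1-25%, 2 = 26-50%, 3 = 51-75%, 4 = 76-100%."""
    if not 0.0 <= hyper_fraction <= 1.0:
        raise ValueError("hyperenhancement fraction must lie in [0, 1]")
    if hyper_fraction == 0.0:
        return 0
    return min(4, int(np.ceil(hyper_fraction / 0.25)))


def si_score(mean_hyper_si: float, reference_si: float) -> int:
    """4-point signal-intensity score from the ratio to the reference.

    The reference is the brightest infarct voxel or the LV blood pool,
    whichever is higher; quartile bins (0, 0.25] -> 1 ... (0.75, 1] -> 4.
    """
    if reference_si <= 0:
        raise ValueError("reference intensity must be positive")
    if mean_hyper_si > reference_si:
        raise ValueError("mean hyperenhanced intensity exceeds the reference")
    r = mean_hyper_si / reference_si
    return max(1, min(4, int(np.ceil(r / 0.25))))


def visual_size(scores: SegmentScores) -> float:
    """VISUAL %LV: sum of extent-bin midpoints over 17 segments / 17."""
    return float(sum(EXTENT_MIDPOINTS[int(e)] for e in scores.extent) / 17.0)


def visual_isi_size(
    scores: SegmentScores, si_weights: dict[int, float] | None = None
) -> float:
    """VISUAL-ISI %LV: extent midpoints weighted by the SI score, / 17."""
    if scores.si is None:
        raise ValueError("SI scores required for VISUAL-ISI")
    w = si_weights or SI_WEIGHTS
    return float(
        sum(
            EXTENT_MIDPOINTS[int(e)] * w[int(s)]
            for e, s in zip(scores.extent, scores.si)
        )
        / 17.0
    )


def score_stack(
    cls: RegionClassification,
    labels: SegmentLabelMap,
    stack: ImageStack,
    mask: MyocardiumMask,
    blood_pool_reference: float | None = None,
    *,
    patient: str = "",
    reader: str = "",
) -> SegmentScores:
    """Score every segment from a tissue classification.

    Hyperenhanced tissue is bright plus the grey the reader judged
    hyperenhanced plus no-reflow; no-reflow voxels count as fully
    bright (reference intensity) in the SI average.  The SI reference
    is the brighter of the brightest hyperenhanced voxel and the
    blood-pool level.
    """
    if labels.labels.shape != stack.intensities.shape:
        raise ValueError("segment labels and stack are misaligned")
    hyper = (cls.bright_mask | cls.grey_included_mask | cls.no_reflow_mask) & mask.mask
    si = stack.intensities

    brightest = float(si[hyper].max()) if hyper.any() else 0.0
    if blood_pool_reference is None:
        from scipy import ndimage

        cavity = np.zeros_like(mask.mask)
        for s in range(mask.mask.shape[0]):
            filled = ndimage.binary_fill_holes(mask.mask[s])
            cavity[s] = filled & ~mask.mask[s]
        blood_pool_reference = float(si[cavity].mean()) if cavity.any() else 0.0
    reference = max(brightest, blood_pool_reference)

    extent = np.zeros(17, dtype=int)
    si_scores = np.zeros(17, dtype=int)
    for seg in range(1, 18):
        in_seg = labels.labels == seg
        n_seg = int(in_seg.sum())
        if n_seg == 0:
            continue
        frac = float((hyper & in_seg).sum()) / n_seg
        extent[seg - 1] = extent_score(frac)
        if extent[seg - 1] > 0:
            vals = np.where(cls.no_reflow_mask & in_seg, reference, si)[hyper & in_seg]
            mean_si = min(float(vals.mean()), reference)
            si_scores[seg - 1] = si_score(mean_si, reference)
    return SegmentScores(extent=extent, si=si_scores, patient=patient, reader=reader)
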