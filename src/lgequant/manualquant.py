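"""Manual planimetry emulation: MANUAL and MANUAL-ISI.

Readers classify myocardium into fully bright, intermediate-signal
("grey") and dark no-reflow tissue.  MANUAL includes every voxel that
appears hyperenhanced, bright or grey; MANUAL-ISI includes 100% of
bright regions but only 50% of grey regions.  No-reflow zones count as
100% infarcted in both.

Two classification routes exist:

* threshold mode — fixed display-reference thresholds standing in for
  the preset window/level (bright: SI >= 0.7 R, grey: 0.35 R <= SI
  < 0.7 R, with R the maximal myocardial intensity); deterministic.
* simulated-reader mode — ground-truth tissue masks with the
  bright/grey boundaries jittered per the reader model.  Reader
  inconsistency in deciding how much of the ambiguous grey shell
  "appears hyperenhanced" is modelled as a per-reader random inclusion
  depth of the shell; this inclusion only affects MANUAL (and the
  visual extent scores), whereas MANUAL-ISI applies its fixed 50% rule
  to the reader's full (jittered) grey region.  That asymmetry is the
  mechanism by which explicit intermediate-signal instructions improve
  reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import ImageStack, InfarctMap, InfarctSizeResult, MyocardiumMask, infarct_size
from .phantom import GroundTruth, ReaderModel


@dataclass
class RegionClassification:
    """Bright / grey / no-reflow tissue masks for one (patient, reader).

    ``grey_included_mask`` is the part of the grey shell the reader
    chose to treat as hyperenhanced when tracing the MANUAL (all
    hyperenhanced tissue) border; it defaults to the full grey mask for
    deterministic classifications.
    """

    bright_mask: np.ndarray
    grey_mask: np.ndarray
    no_reflow_mask: np.ndarray
    grey_included_mask: np.ndarray | None = None
    provenance: str = "threshold"

    def __post_init__(self) -> None:
        if self.grey_included_mask is None:
            self.grey_included_mask = self.grey_mask
        if (self.bright_mask & self.grey_mask).any():
            raise ValueError("bright and grey masks must be disjoint")


def classify_regions(
    stack: ImageStack,
    mask: MyocardiumMask,
    truth: GroundTruth | None = None,
    reader: ReaderModel | None = None,
    seed: int | None = None,
    grey_threshold: float = 0.35,
    bright_threshold: float = 0.7,
) -> RegionClassification:
    """Classify myocardium into bright / grey / no-reflow tissue.

    With ``truth`` (and optionally a reader model + seed) the
    classification derives from the ground-truth masks, restricted to
    the supplied myocardium mask, with boundary jitter; otherwise fixed
    display-reference thresholds are applied to the intensities.
    """
    myo = mask.mask
    if truth is not None:
        return _classify_from_truth(stack, myo, truth, reader, seed)

    si = stack.intensities
    if not myo.any():
        raise ValueError("empty myocardium mask")
    ref = float(si[myo].max())
    bright = myo & (si >= bright_threshold * ref)
    grey = myo & (si >= grey_threshold * ref) & ~bright
    # no-reflow: dark voxels fully enclosed by bright tissue, per slice
    remote_level = float(np.median(si[myo]))
    no_reflow = np.zeros_like(myo)
    for s in range(si.shape[0]):
        filled = ndimage.binary_fill_holes(bright[s])
        no_reflow[s] = filled & ~bright[s] & (si[s] < remote_level) & myo[s]
    grey &= ~no_reflow
    return RegionClassification(
        bright_mask=bright,
        grey_mask=grey,
        no_reflow_mask=no_reflow,
        provenance="threshold",
    )


def _classify_from_truth(
    stack: ImageStack,
    myo: np.ndarray,
    truth: GroundTruth,
    reader: ReaderModel | None,
    seed: int | None,
) -> RegionClassification:
    """Ground-truth classification with reader boundary jitter.

    The perceived extent of the grey shell is shifted by a per-reader
    Gaussian offset (SD ``grey_boundary_jitter_sd``, mm) of its outer
    boundary, measured as Euclidean distance from the bright core.  The
    fraction of perceived grey the reader treats as hyperenhanced when
    tracing the MANUAL border is a per-reader uniform draw on
    [0.5, 1] of the shell volume (innermost first): readers instructed
    to include "any hyperenhanced tissue" include at least as much grey
    as the fixed 50% rule, but disagree on how far out the shell
    extends.  With zero jitter the classification equals ground truth
    and the full shell is included.
    """
    sx, sy = stack.pixel_spacing
    core_plus_nr = truth.infarct_core_mask | truth.no_reflow_mask
    jitter_sd = reader.grey_boundary_jitter_sd if reader is not None else 0.0
    rng = np.random.default_rng(seed if seed is not None else 0)
    nr = truth.no_reflow_mask & myo
    bright = core_plus_nr & myo & ~truth.no_reflow_mask

    if jitter_sd == 0:
        grey = truth.grey_zone_mask & myo
        return RegionClassification(
            bright_mask=bright,
            grey_mask=grey,
            no_reflow_mask=nr,
            provenance="reader",
        )

    grey_full = truth.grey_zone_mask
    g_off = rng.normal(0.0, jitter_sd)  # outer grey boundary shift, mm
    u = rng.uniform(0.5, 1.0)  # MANUAL inclusion fraction of the shell

    # distance (mm) from the bright core, per slice
    dist = np.full(myo.shape, np.inf)
    for s in range(myo.shape[0]):
        if core_plus_nr[s].any():
            dist[s] = ndimage.distance_transform_edt(
                ~core_plus_nr[s], sampling=(sy, sx)
            )
    # slices whose infarct is entirely grey have no core to measure from
    finite = np.isfinite(dist)
    in_shell = grey_full & finite
    shell_width = float(dist[in_shell].max()) if in_shell.any() else 0.0
    outer = max(shell_width + g_off, 0.0)
    grey = myo & ~core_plus_nr & finite & (dist > 0) & (dist <= outer)
    grey |= grey_full & ~finite & myo  # keep core-free grey slices as drawn

    grey_incl = np.zeros_like(myo)
    if grey.any():
        d = np.where(finite, dist, np.finfo(float).max)  # rank core-free slices last
        cutoff = np.quantile(d[grey], u)
        grey_incl = grey & (d <= cutoff)
    return RegionClassification(
        bright_mask=bright,
        grey_mask=grey,
        no_reflow_mask=nr,
        grey_included_mask=grey_incl,
        provenance="reader",
    )


def manual_size(
    cls: RegionClassification,
    mask: MyocardiumMask,
    stack: ImageStack,
    *,
    reader: str = "",
    patient: str = "",
) -> InfarctSizeResult:
    """MANUAL planimetry: all hyperenhanced tissue at weight 1.

    Includes bright tissue, the grey tissue the reader judged
    hyperenhanced, and no-reflow zones (100% infarcted).
    """
    weights = np.zeros_like(mask.mask, dtype=float)
    included = cls.bright_mask | cls.grey_included_mask | cls.no_reflow_mask
    weights[included & mask.mask] = 1.0
    return infarct_size(
        InfarctMap(weights, method="MANUAL"),
        mask,
        stack,
        method="MANUAL",
        reader=reader,
        patient=patient,
    )


def manual_isi_size(
    cls: RegionClassification,
    mask: MyocardiumMask,
    stack: ImageStack,
    *,
    reader: str = "",
    patient: str = "",
) -> InfarctSizeResult:
    """MANUAL-ISI: bright and no-reflow at weight 1, grey at weight 0.5."""
    weights = np.zeros_like(mask.mask, dtype=float)
    weights[(cls.bright_mask | cls.no_reflow_mask) & mask.mask] = 1.0
    weights[cls.grey_mask & mask.mask & ~cls.bright_mask & ~cls.no_reflow_mask] = 0.5
    return infarct_size(
        InfarctMap(weights, method="MANUAL_ISI"),
        mask,
        stack,
        method="MANUAL_ISI",
        reader=reader,
        patient=patient,
    )
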