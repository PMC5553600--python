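"""Synthetic short-axis LGE phantom cohort with a simulated-reader model.

The phantom is an annular LV myocardium across 8-12 short-axis slices
with a bright blood pool, an infarcted sector whose core is fully
hyperenhanced, an intermediate-signal ("grey") border shell at the
infarct rim standing in for partial-volume effects, and an optional
dark no-reflow core (microvascular obstruction).  Rician noise models
the magnitude-MR background; a Gaussian option exists for analytic
tests.

The simulated reader perturbs the true endocardial/epicardial contours
with a smooth periodic random radial field (correlated Gaussian over
contour angle) plus an optional signed bias.  This embodies the
dominant source of between-laboratory variability in infarct sizing:
even fully automated infarct-border algorithms inherit variability from
the manual tracing of myocardial borders that precedes them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import shapely
from scipy import ndimage

from .geometry import (
    ContourSet,
    GeometryError,
    ImageStack,
    MYOCARDIAL_DENSITY_G_PER_ML,
)

_N_CONTOUR_VERTICES = 360


class ConfigurationError(ValueError):
    """Raised for invalid cohort/phantom configuration."""


@dataclass
class PhantomSpec:
    """Geometry and tissue-intensity model of one synthetic LGE stack.

    Defaults emulate a typical acute-infarct LGE acquisition: ~1.5 mm
    in-plane resolution, 8 mm effective slice coverage, a mid-wall
    annulus of 25/35 mm endo/epi radius, and an anterior infarct of 90
    degrees extent with 60% transmurality.
    """

    grid: tuple[int, int, int] = (128, 128, 10)  # (rows, cols, slices)
    pixel_spacing: tuple[float, float] = (1.5, 1.5)
    slice_thickness: float = 8.0
    slice_gap: float = 0.0
    endo_radius_by_slice: list[float] | None = None
    epi_radius_by_slice: list[float] | None = None
    infarct_angular_extent: float = 90.0
    infarct_angular_center: float = 90.0
    transmural_fraction: float = 0.6
    grey_zone_width: float = 0.25  # fraction of infarct wall thickness
    no_reflow_fraction: float = 0.0  # fraction of infarct core volume
    intensity_remote_mean: float = 100.0
    intensity_remote_sd: float = 0.0
    intensity_infarct_plateau: float = 1000.0
    intensity_blood_pool: float = 800.0
    intensity_no_reflow: float = 50.0
    noise_sd: float = 20.0
    noise_model: str = "rician"

    def __post_init__(self) -> None:
        n_rows, n_cols, n_slices = self.grid
        if self.endo_radius_by_slice is None:
            # base-to-apex taper; the cavity nearly obliterates on the
            # apical-most slice (the apical cap of visual scoring)
            self.endo_radius_by_slice = list(np.linspace(25.0, 7.0, n_slices))
        if self.epi_radius_by_slice is None:
            self.epi_radius_by_slice = list(np.linspace(35.0, 27.0, n_slices))
        if len(self.endo_radius_by_slice) != n_slices or len(
            self.epi_radius_by_slice
        ) != n_slices:
            raise ConfigurationError("per-slice radii must match slice count")
        for en, ep in zip(self.endo_radius_by_slice, self.epi_radius_by_slice):
            if not en < ep:
                raise GeometryError("endo radius must be < epi radius on every slice")
        for frac in (
            self.transmural_fraction,
            self.grey_zone_width,
            self.no_reflow_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError("fractions must lie in [0, 1]")
        if not self.intensity_infarct_plateau > self.intensity_remote_mean:
            raise ConfigurationError("infarct plateau must exceed remote mean")
        if self.noise_model not in ("gaussian", "rician"):
            raise ConfigurationError(f"unknown noise model {self.noise_model!r}")
        sx, sy = self.pixel_spacing
        half_x, half_y = n_cols * sx / 2.0, n_rows * sy / 2.0
        if max(self.epi_radius_by_slice) >= min(half_x, half_y):
            raise GeometryError("epicardium exceeds the image grid")


@dataclass
class ReaderModel:
    """Statistical model of one simulated reader (core laboratory).

    ``contour_error_sd`` is the radial SD (mm) of the smooth tracing
    error applied to endo/epi borders; ``contour_error_correlation_length``
    its angular correlation scale (degrees).  ``grey_boundary_jitter_sd``
    perturbs the bright/grey tissue boundaries during manual/visual
    classification, and ``correction_completeness`` is the probability
    that each correctable region is actually corrected in the
    user-corrected automated methods.
    """

    contour_error_sd: float = 1.0
    contour_error_correlation_length: float = 40.0
    contour_bias: float = 0.0
    grey_boundary_jitter_sd: float = 0.5
    correction_completeness: float = 1.0
    reader_id: str = "reader1"

    def __post_init__(self) -> None:
        if self.contour_error_sd < 0:
            raise ConfigurationError("contour_error_sd must be >= 0")
        if not 0.0 <= self.correction_completeness <= 1.0:
            raise ConfigurationError("correction_completeness must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Simulation ground truth for one phantom.

    ``infarct_core_mask``, ``grey_zone_mask`` and ``no_reflow_mask`` are
    mutually disjoint subsets of ``myocardium_mask``.  The true infarct
    size counts core and no-reflow voxels at weight 1 and grey-zone
    voxels at weight 0.5 (the convention the intermediate-signal-
    intensity methods implement); alternative conventions can be
    recomputed from the masks.
    """

    myocardium_mask: np.ndarray
    infarct_core_mask: np.ndarray
    grey_zone_mask: np.ndarray
    no_reflow_mask: np.ndarray
    blood_pool_mask: np.ndarray
    true_contours: ContourSet
    true_infarct_percent_lv: float
    true_infarct_grams: float
    lv_center_mm: tuple[float, float] = (0.0, 0.0)

    def weighted_infarct_voxels(self) -> float:
        return float(
            self.infarct_core_mask.sum()
            + self.no_reflow_mask.sum()
            + 0.5 * self.grey_zone_mask.sum()
        )


@dataclass
class CohortSpec:
    """Design of a synthetic multi-patient, multi-reader study."""

    n_patients: int = 30
    n_readers: int = 3
    infarct_size_distribution: tuple[str, float, float] = ("normal", 20.0, 10.0)
    size_truncation: tuple[float, float] = (2.0, 60.0)
    reader_models: list[ReaderModel] | None = None
    master_seed: int = 0
    phantom_template: PhantomSpec | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.infarct_size_distribution[2] < 0:
            raise ConfigurationError("infarct size SD must be >= 0")
        if self.reader_models is None:
            self.reader_models = [
                ReaderModel(reader_id=f"reader{i + 1}") for i in range(self.n_readers)
            ]
        if len(self.reader_models) != self.n_readers:
            raise ConfigurationError("need exactly one ReaderModel per reader")


@dataclass
class PatientData:
    patient_id: str
    stack: ImageStack
    truth: GroundTruth
    reader_contours: dict[str, ContourSet]
    target_percent_lv: float
    seed: int


@dataclass
class CohortDataset:
    spec: CohortSpec
    patients: list[PatientData]

    def __len__(self) -> int:
        return len(self.patients)


# ---------------------------------------------------------------------------
# phantom generation


def _circle_contour(center: tuple[float, float], radius: float) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, _N_CONTOUR_VERTICES, endpoint=False)
    return np.column_stack(
        (center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta))
    )


def _angular_distance_deg(theta_deg: np.ndarray, center_deg: float) -> np.ndarray:
    d = (theta_deg - center_deg + 180.0) % 360.0 - 180.0
    return np.abs(d)


def generate_phantom(
    spec: PhantomSpec, seed: int
) -> tuple[ImageStack, GroundTruth]:
    """Generate one synthetic LGE stack with its ground truth.

    The tissue model assigns each voxel a plateau intensity (remote
    myocardium, infarct core, grey shell at the midpoint of remote and
    core, dark no-reflow, blood pool, zero-signal background) and adds
    noise per ``spec.noise_model``.  Identical (spec, seed) pairs
    reproduce bit-identical output.
    """
    rng = np.random.default_rng(seed)
    n_rows, n_cols, n_slices = spec.grid
    sx, sy = spec.pixel_spacing
    cx, cy = n_cols * sx / 2.0, n_rows * sy / 2.0

    x = (np.arange(n_cols) + 0.5) * sx - cx
    y = (np.arange(n_rows) + 0.5) * sy - cy
    xx, yy = np.meshgrid(x, y)
    rr = np.hypot(xx, yy)
    theta = np.degrees(np.arctan2(yy, xx)) % 360.0
    ang_dist = _angular_distance_deg(theta, spec.infarct_angular_center)

    shape = (n_slices, n_rows, n_cols)
    myo = np.zeros(shape, dtype=bool)
    infarct = np.zeros(shape, dtype=bool)
    blood = np.zeros(shape, dtype=bool)

    for s in range(n_slices):
        r_en = spec.endo_radius_by_slice[s]
        r_ep = spec.epi_radius_by_slice[s]
        myo[s] = (rr >= r_en) & (rr <= r_ep)
        blood[s] = rr < r_en
        if spec.transmural_fraction > 0 and spec.infarct_angular_extent > 0:
            r_inf = r_en + spec.transmural_fraction * (r_ep - r_en)
            infarct[s] = (
                myo[s]
                & (rr <= r_inf)
                & (ang_dist <= spec.infarct_angular_extent / 2.0)
            )

    # grey shell: infarct voxels within a set distance of remote myocardium
    grey = np.zeros(shape, dtype=bool)
    if spec.grey_zone_width > 0 and infarct.any():
        for s in range(n_slices):
            if not infarct[s].any():
                continue
            wall = spec.transmural_fraction * (
                spec.epi_radius_by_slice[s] - spec.endo_radius_by_slice[s]
            )
            depth = spec.grey_zone_width * wall
            remote = myo[s] & ~infarct[s]
            if not remote.any():
                continue
            dist_to_remote = ndimage.distance_transform_edt(
                ~remote, sampling=(sy, sx)
            )
            grey[s] = infarct[s] & (dist_to_remote <= depth)
    core = infarct & ~grey

    # no-reflow: innermost fraction of the core, by radius
    no_reflow = np.zeros(shape, dtype=bool)
    if spec.no_reflow_fraction > 0 and core.any():
        radii = np.broadcast_to(rr, shape)[core]
        cutoff = np.quantile(radii, spec.no_reflow_fraction)
        nr = core & (np.broadcast_to(rr, shape) <= cutoff)
        no_reflow = nr
        core = core & ~nr

    signal = np.zeros(shape, dtype=float)
    signal[blood] = spec.intensity_blood_pool
    signal[myo] = spec.intensity_remote_mean
    if spec.intensity_remote_sd > 0:
        remote_mask = myo & ~infarct
        signal[remote_mask] += rng.normal(
            0.0, spec.intensity_remote_sd, int(remote_mask.sum())
        )
    grey_level = 0.5 * (spec.intensity_remote_mean + spec.intensity_infarct_plateau)
    signal[grey] = grey_level
    signal[core] = spec.intensity_infarct_plateau
    signal[no_reflow] = spec.intensity_no_reflow

    if spec.noise_sd > 0:
        if spec.noise_model == "gaussian":
            intens = signal + rng.normal(0.0, spec.noise_sd, shape)
        else:  # rician: magnitude of complex signal with iid gaussian channels
            re = signal + rng.normal(0.0, spec.noise_sd, shape)
            im = rng.normal(0.0, spec.noise_sd, shape)
            intens = np.hypot(re, im)
    else:
        intens = signal
    intens = np.clip(intens, 0.0, None)

    contours = ContourSet(
        endo=[
            _circle_contour((cx, cy), r) for r in spec.endo_radius_by_slice
        ],
        epi=[_circle_contour((cx, cy), r) for r in spec.epi_radius_by_slice],
        provenance="truth",
    )

    stack = ImageStack(
        intensities=intens,
        pixel_spacing=spec.pixel_spacing,
        slice_thickness=spec.slice_thickness,
        slice_gap=spec.slice_gap,
    )
    n_myo = int(myo.sum())
    weighted = float(core.sum() + no_reflow.sum() + 0.5 * grey.sum())
    percent = 100.0 * weighted / n_myo if n_myo else 0.0
    grams = weighted * stack.voxel_volume_ml * MYOCARDIAL_DENSITY_G_PER_ML
    truth = GroundTruth(
        myocardium_mask=myo,
        infarct_core_mask=core,
        grey_zone_mask=grey,
        no_reflow_mask=no_reflow,
        blood_pool_mask=blood,
        true_contours=contours,
        true_infarct_percent_lv=percent,
        true_infarct_grams=grams,
        lv_center_mm=(cx, cy),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# reader contour perturbation


def _smooth_periodic_field(
    rng: np.random.Generator, n: int, sd: float, correlation_length_deg: float
) -> np.ndarray:
    """Correlated Gaussian field over n equally spaced contour angles.

    White noise circularly convolved with a Gaussian kernel whose width
    is the correlation length; normalized so the marginal SD is ``sd``
    exactly.
    """
    if sd == 0:
        return np.zeros(n)
    white = rng.normal(0.0, 1.0, n)
    sigma_samples = max(correlation_length_deg / 360.0 * n, 1e-6)
    half = n // 2
    lags = np.arange(-half, n - half)
    kernel = np.exp(-0.5 * (lags / sigma_samples) ** 2)
    # circular convolution via FFT
    smoothed = np.real(np.fft.ifft(np.fft.fft(white) * np.fft.fft(np.roll(kernel, half))))
    norm = np.sqrt(np.sum(kernel**2))
    return sd * smoothed / norm


def perturb_contours(
    truth: ContourSet, reader: ReaderModel, seed: int, max_retries: int = 10
) -> ContourSet:
    """Apply a smooth radial tracing error to every contour.

    Each contour is displaced radially about its centroid by a periodic
    correlated Gaussian field (SD ``contour_error_sd``, angular scale
    ``contour_error_correlation_length``) plus the signed
    ``contour_bias`` (positive = outward).  Perturbations that invert
    the endo/epi ordering anywhere are resampled a bounded number of
    times before raising :class:`GeometryError`.
    """
    rng = np.random.default_rng(seed)
    if reader.contour_error_sd == 0 and reader.contour_bias == 0:
        return ContourSet(
            endo=[c.copy() for c in truth.endo],
            epi=[c.copy() for c in truth.epi],
            provenance="reader",
        )
    endo_out, epi_out = [], []
    for s in range(truth.n_slices):
        for attempt in range(max_retries):
            new = {}
            for name, poly in (("endo", truth.endo[s]), ("epi", truth.epi[s])):
                center = poly.mean(axis=0)
                rel = poly - center
                radii = np.hypot(rel[:, 0], rel[:, 1])
                angles = np.arctan2(rel[:, 1], rel[:, 0])
                order = np.argsort(angles)
                fld = np.empty_like(radii)
                fld[order] = _smooth_periodic_field(
                    rng,
                    len(radii),
                    reader.contour_error_sd,
                    reader.contour_error_correlation_length,
                )
                new_r = radii + reader.contour_bias + fld
                if np.any(new_r <= 0):
                    new = None
                    break
                new[name] = center + rel / radii[:, None] * new_r[:, None]
            if new is None:
                continue
            en_poly = shapely.Polygon(new["endo"])
            ep_poly = shapely.Polygon(new["epi"])
            if (
                en_poly.is_valid
                and ep_poly.is_valid
                and ep_poly.contains(en_poly)
            ):
                endo_out.append(new["endo"])
                epi_out.append(new["epi"])
                break
        else:
            raise GeometryError(
                f"slice {s}: could not sample a valid contour perturbation "
                f"in {max_retries} attempts"
            )
    return ContourSet(endo=endo_out, epi=epi_out, provenance="reader")


# ---------------------------------------------------------------------------
# cohort generation


def draw_infarct_sizes(cohort: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw per-patient true infarct sizes (%LV) from the cohort model.

    The default is normal(20, 10) truncated to [2, 60] %LV, matching the
    between-patient spread of an acute STEMI population (method means
    ~17-27 %LV, SDs ~8-13 %LV).  Truncation is by resampling so the
    shape inside the bounds stays normal.
    """
    family, mean, sd = cohort.infarct_size_distribution
    if family != "normal":
        raise ConfigurationError(f"unknown infarct size distribution {family!r}")
    lo, hi = cohort.size_truncation
    out = np.empty(cohort.n_patients)
    for i in range(cohort.n_patients):
        for _ in range(10_000):
            v = rng.normal(mean, sd)
            if lo <= v <= hi:
                out[i] = v
                break
        else:
            raise ConfigurationError("infarct size truncation bounds too narrow")
    return out


def _spec_for_target_size(
    template: PhantomSpec, target_percent: float, rng: np.random.Generator
) -> PhantomSpec:
    """Choose infarct geometry so ground-truth size lands near the target.

    For an annulus, the myocardial volume fraction of the sub-sector
    band from the endocardium to transmural depth f is
    extent/360 * (r_f^2 - r_en^2)/(r_ep^2 - r_en^2) per slice; the
    angular extent is solved from that, raising transmurality when a
    full circle would not suffice.
    """
    tf = rng.uniform(0.5, 0.8)
    center = rng.uniform(0.0, 360.0)
    en = np.asarray(template.endo_radius_by_slice)
    ep = np.asarray(template.epi_radius_by_slice)
    for _ in range(20):
        r_f = en + tf * (ep - en)
        band_frac = float(np.sum(r_f**2 - en**2) / np.sum(ep**2 - en**2))
        extent = 360.0 * (target_percent / 100.0) / band_frac
        if extent <= 330.0:
            break
        tf = min(1.0, tf + 0.1)
    extent = min(extent, 355.0)
    return replace(
        template,
        transmural_fraction=tf,
        infarct_angular_extent=extent,
        infarct_angular_center=center,
    )


def generate_cohort(cohort: CohortSpec) -> CohortDataset:
    """Simulate a full multi-reader cohort, deterministically from master_seed.

    Each patient gets one stack + ground truth and one perturbed contour
    set per reader; all randomness derives from ``master_seed`` via a
    seed sequence so the cohort is exactly reproducible.
    """
    root = np.random.SeedSequence(cohort.master_seed)
    size_rng = np.random.default_rng(root.spawn(1)[0])
    targets = draw_infarct_sizes(cohort, size_rng)
    template = cohort.phantom_template or PhantomSpec()

    patients = []
    patient_seqs = root.spawn(cohort.n_patients + 1)[1:]
    for i, (target, seq) in enumerate(zip(targets, patient_seqs)):
        sub = seq.spawn(2 + cohort.n_readers)
        geom_rng = np.random.default_rng(sub[0])
        spec = _spec_for_target_size(template, float(target), geom_rng)
        phantom_seed = int(np.random.default_rng(sub[1]).integers(2**31))
        stack, truth = generate_phantom(spec, phantom_seed)
        reader_contours = {}
        for j, reader in enumerate(cohort.reader_models):
            r_seed = int(np.random.default_rng(sub[2 + j]).integers(2**31))
            reader_contours[reader.reader_id] = perturb_contours(
                truth.true_contours, reader, r_seed
            )
        patients.append(
            PatientData(
                patient_id=f"P{i + 1:03d}",
                stack=stack,
                truth=truth,
                reader_contours=reader_contours,
                target_percent_lv=float(target),
                seed=phantom_seed,
            )
        )
    return CohortDataset(spec=cohort, patients=patients)
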