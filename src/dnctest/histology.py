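"""TH+ histology quantification: DAB cell counting and terminal density.

Counting reproduces a standard particle-analysis recipe for DAB-stained
somata in coronal midbrain sections: green channel of the RGB scan,
inversion (stained cells become bright), removal of small bright maxima
by grayscale opening, Gaussian blur, rolling-ball background
subtraction, automatic (isodata) thresholding, distance-transform
watershed to split touching somata, and a strict particle-area filter.

Terminal density inverts the grayscale so that denser DAB staining maps
to higher values, restricts to an ROI and an intensity band, and reports
the mean (optionally through a monotone optical-density calibration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_isodata
from skimage.measure import label, regionprops
from skimage.morphology import disk, opening
from skimage.restoration import rolling_ball
from skimage.segmentation import watershed

__all__ = [
    "HistologyImage",
    "CountingParams",
    "DensityParams",
    "SectionResult",
    "PercentLoss",
    "count_cells",
    "terminal_density",
    "percent_loss",
    "bilateral_total_loss",
    "round_half_up",
]


@dataclass(frozen=True)
class HistologyImage:
    """2-D grayscale or RGB pixel array with optional pixel size (um)."""

    pixels: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] not in (3, 4)):
            raise ValueError("image must be 2-D grayscale or (H, W, 3|4) RGB(A)")
        if px.ndim == 2 and (px.shape[0] == 0 or px.shape[1] == 0):
            raise ValueError("zero-size image")
        object.__setattr__(self, "pixels", px)

    @property
    def dtype_max(self) -> float:
        if np.issubdtype(self.pixels.dtype, np.integer):
            return float(np.iinfo(self.pixels.dtype).max)
        return 255.0  # float images are treated on the 8-bit scale

    def grayscale(self) -> np.ndarray:
        """Green channel for RGB input (highest DAB contrast), else as-is."""
        if self.pixels.ndim == 3:
            return np.asarray(self.pixels[:, :, 1], dtype=float)
        return np.asarray(self.pixels, dtype=float)


@dataclass(frozen=True)
class CountingParams:
    """Knobs of the cell-counting pipeline (pixel units).

    ``maxima_filter_size`` is the disk radius of the grayscale opening
    that removes bright maxima smaller than the element.  ``blur_size``
    is the half-width of the Gaussian kernel (sigma = blur_size / 3,
    truncated at blur_size).  ``min_particle_area`` is exclusive: a
    particle counts only if its area is strictly greater.
    ``min_contrast`` (gray levels after background subtraction) guards
    against thresholding pure background texture.
    """

    maxima_filter_size: int = 7
    blur_size: float = 7.0
    background_radius: int = 60
    min_particle_area: int = 100
    threshold_method: str = "isodata"
    marker_min_distance: int = 7
    min_contrast: float = 10.0

    def __post_init__(self):
        if min(self.maxima_filter_size, self.blur_size, self.background_radius) <= 0:
            raise ValueError("all filter sizes must be positive")
        if self.min_particle_area < 1:
            raise ValueError("min_particle_area must be >= 1")
        if self.threshold_method != "isodata":
            raise ValueError("only the isodata automatic threshold is implemented")


@dataclass(frozen=True)
class DensityParams:
    """Intensity band and optional OD calibration for terminal density."""

    threshold_range: tuple[float, float] = (45.0, 255.0)
    od_calibration: tuple[tuple[float, float], ...] | None = None
    thresholded_pixels_only: bool = True

    def calibrate(self, gray: np.ndarray) -> np.ndarray:
        """Map inverted gray values through the monotone OD lookup (identity default)."""
        if self.od_calibration is None:
            return gray
        xs = np.array([p[0] for p in self.od_calibration], dtype=float)
        ys = np.array([p[1] for p in self.od_calibration], dtype=float)
        order = np.argsort(xs)
        return np.interp(gray, xs[order], ys[order])


@dataclass(frozen=True)
class SectionResult:
    """Per-section readout: a cell count or a mean optical density."""

    section_id: str
    cell_count: int | None = None
    mean_od: float | None = None
    labeled_mask: np.ndarray | None = field(default=None, compare=False)
    n_candidates: int = 0


def _invert(gray: np.ndarray, dtype_max: float) -> np.ndarray:
    return dtype_max - gray


def count_cells(
    image: HistologyImage,
    params: CountingParams = CountingParams(),
    section_id: str = "section",
) -> SectionResult:
    """Count DAB-stained somata in one section.

    Pipeline order: grayscale (green channel) -> inversion -> grayscale
    opening (disk radius ``maxima_filter_size``) -> Gaussian blur ->
    rolling-ball background subtraction -> isodata threshold ->
    distance-transform watershed -> connected components -> keep
    particles with area strictly greater than ``min_particle_area``.
    The labelled mask of counted particles is returned for audit
    overlays.
    """
    gray = image.grayscale()
    if min(gray.shape) < 3 * params.blur_size:
        raise ValueError(
            f"image {gray.shape} smaller than 3x the blur size {params.blur_size}"
        )
    inv = _invert(gray, image.dtype_max)
    opened = opening(inv, disk(params.maxima_filter_size))
    sigma = params.blur_size / 3.0
    blurred = gaussian(opened, sigma=sigma, truncate=params.blur_size / sigma, preserve_range=True)
    background = rolling_ball(blurred, radius=params.background_radius)
    subtracted = blurred - background

    if float(subtracted.max()) < params.min_contrast:
        # nothing brighter than background texture: no stained somata
        return SectionResult(
            section_id=section_id,
            cell_count=0,
            labeled_mask=np.zeros(gray.shape, dtype=np.int32),
        )
    thresh = threshold_isodata(subtracted)
    mask = subtracted > thresh

    # split touching somata: watershed on the Euclidean distance transform
    # with local-maxima markers
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance,
        min_distance=params.marker_min_distance,
        labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, peaks.shape[0] + 1)
    if peaks.shape[0] == 0:
        segmented = label(mask)
    else:
        segmented = watershed(-distance, markers, mask=mask)

    labeled = label(segmented > 0) if peaks.shape[0] == 0 else segmented
    props = regionprops(labeled)
    kept = np.zeros_like(labeled)
    count = 0
    for p in props:
        if p.area > params.min_particle_area:
            count += 1
            kept[labeled == p.label] = count
    return SectionResult(
        section_id=section_id,
        cell_count=count,
        labeled_mask=kept,
        n_candidates=len(props),
    )


def terminal_density(
    image: HistologyImage,
    roi: np.ndarray,
    params: DensityParams = DensityParams(),
    section_id: str = "section",
) -> SectionResult:
    """Mean optical density of TH+ terminal staining within an ROI.

    The grayscale image is inverted (denser staining -> higher value);
    ROI pixels whose inverted gray value lies within ``threshold_range``
    are mapped through the OD calibration and averaged.  Pixels outside
    the band never contribute, so the measure is invariant to them.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != image.grayscale().shape:
        raise ValueError("ROI mask shape must match the image")
    if not roi.any():
        raise ValueError("ROI is empty")
    inv = _invert(image.grayscale(), image.dtype_max)
    lo, hi = params.threshold_range
    selected = roi & (inv >= lo) & (inv <= hi)
    if params.thresholded_pixels_only:
        if not selected.any():
            raise ValueError(
                "no ROI pixels fall within the intensity band "
                f"[{lo}, {hi}]; empty density measurement"
            )
        values = inv[selected]
    else:
        values = inv[roi]
    return SectionResult(
        section_id=section_id,
        mean_od=float(np.mean(params.calibrate(values))),
    )


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going up (reporting convention)."""
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class PercentLoss:
    """Percent loss with both the unrounded value and the reported integer."""

    percent: float

    @property
    def rounded(self) -> int:
        return round_half_up(self.percent)

    def __float__(self) -> float:
        return self.percent


def percent_loss(reference: float, test: float) -> PercentLoss:
    """Loss of the test measurement relative to a reference, in percent.

    E.g. nigral cell counts 8252 (control) vs 5914 (PD model) give 28%
    loss of dopamine neurons.
    """
    if reference <= 0:
        raise ValueError("reference must be positive")
    return PercentLoss(percent=(reference - test) / reference * 100.0)


def bilateral_total_loss(intact_side: float, lesioned_side: float) -> PercentLoss:
    """Whole-animal loss after a unilateral lesion.

    Assumes the intact hemisphere equals the pre-lesion count of either
    side, so the whole-animal loss is (intact - lesioned) / (2 * intact)
    * 100 — e.g. a 57% unilateral loss corresponds to 29% total loss of
    striatum-projecting neurons.
    """
    if intact_side <= 0:
        raise ValueError("intact-side count must be positive")
    return PercentLoss(percent=(intact_side - lesioned_side) / (2.0 * intact_side) * 100.0)
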