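"""Standardized image analysis for thrombus-formation parameters.

Operators here turn end-stage brightfield/fluorescence images, differential
time series and confocal z-stacks into the eight per-microspot outcome
parameters: morphological score, integrated feature size, platelet deposition
(% surface-area coverage), stable platelet adhesion, fibrinogen binding,
P-selectin expression, thrombus volume (μm³/μm²) and procoagulant activity.

The segmentation pipeline is fixed in order: contrast auto-enhancement
(1st–99th percentile linear stretch), separable horizontal + vertical median
filtering (length 3), thresholding (Otsu by default, fixed override), then a
binary close followed by open with a 3×3 square structuring element.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label
from skimage.morphology import closing as _closing
from skimage.morphology import opening as _opening

__all__ = [
    "FeatureSet",
    "ThrombusParameterSet",
    "ScoreCalibration",
    "segment_coverage",
    "feature_areas",
    "integrated_feature_size",
    "morphological_score",
    "stable_adhesion",
    "thrombus_volume",
    "marker_coverage",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass
class FeatureSet:
    """Connected-component areas of a segmented platelet field.

    Areas are sorted ascending (ranked from small to large); the unit of area
    (pixels or μm²) is recorded, not converted.
    """

    areas: np.ndarray
    unit: str = "px"

    def __post_init__(self) -> None:
        self.areas = np.sort(np.asarray(self.areas, dtype=float))
        if self.areas.size and self.areas[0] <= 0:
            raise ValueError("feature areas must be positive")

    @property
    def n(self) -> int:
        return int(self.areas.size)

    @property
    def total(self) -> float:
        return float(self.areas.sum())


@dataclass
class ThrombusParameterSet:
    """The eight outcome parameters measured for one microspot."""

    morphological_score: int
    integrated_feature_size: float
    platelet_deposition: float
    stable_adhesion: float
    fibrinogen_binding: float
    pselectin_expression: float
    thrombus_volume: float
    procoagulant_activity: float

    def __post_init__(self) -> None:
        if self.morphological_score not in range(6):
            raise ValueError("morphological score must be an integer 0–5")
        for name in (
            "platelet_deposition",
            "stable_adhesion",
            "fibrinogen_binding",
            "pselectin_expression",
            "procoagulant_activity",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")
        if self.thrombus_volume < 0 or self.integrated_feature_size < 0:
            raise ValueError("volume and integrated feature size must be ≥ 0")


def _check_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty single-channel 2-D image")
    return img.astype(float)


def _stretch(img: np.ndarray) -> np.ndarray:
    """Linear 1st–99th percentile contrast stretch (the auto-enhance step)."""
    lo, hi = np.percentile(img, (1, 99))
    if hi <= lo:
        return img.copy()
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0) * 255.0


def _threshold(img: np.ndarray, method) -> np.ndarray | None:
    """Apply the threshold policy; None signals a constant image under Otsu."""
    if method == "otsu":
        if np.ptp(img) == 0:
            return None
        return img > threshold_otsu(img)
    if isinstance(method, tuple) and len(method) == 2 and method[0] == "fixed":
        return img > float(method[1])
    raise ValueError(f"unknown threshold method {method!r}; use 'otsu' or ('fixed', t)")


def segment_coverage(
    image: np.ndarray, method="otsu"
) -> tuple[np.ndarray, float]:
    """Segment adhered platelets and return (binary mask, % coverage).

    Pipeline order is fixed: percentile auto-enhance → length-3 median filter
    along rows then columns → threshold → binary close then open (3×3 square).
    A constant image under Otsu yields an empty mask and 0% coverage by
    convention.
    """
    img = _check_image(image)
    img = _stretch(img)
    img = ndimage.median_filter(img, size=(1, 3), mode="nearest")
    img = ndimage.median_filter(img, size=(3, 1), mode="nearest")
    mask = _threshold(img, method)
    if mask is None:
        return np.zeros(img.shape, dtype=bool), 0.0
    mask = _opening(_closing(mask, _SQUARE3), _SQUARE3)
    coverage = 100.0 * mask.sum() / mask.size
    return mask, float(coverage)


def feature_areas(mask: np.ndarray, connectivity: int = 8) -> FeatureSet:
    """Connected-component areas of a binary mask, sorted ascending."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labelled = _cc_label(mask.astype(bool), connectivity=1 if connectivity == 4 else 2)
    areas = np.bincount(labelled.ravel())[1:]
    return FeatureSet(areas=areas[areas > 0])


def integrated_feature_size(fs: FeatureSet) -> float:
    """Size-weighted mean feature area, Σf² / Σf.

    The statistic weighs each feature by its own area, so large aggregates
    dominate: a single feature of area A gives exactly A, and the value always
    lies between the smallest and largest feature area. Empty fields give 0
    by convention.
    """
    if fs.n == 0:
        return 0.0
    f = fs.areas
    return float(np.sum(f * f) / np.sum(f))


@dataclass
class ScoreCalibration:
    """Cut-offs for the 0–5 morphological score proxy rubric.

    ``coverage_floor_pct``: below this coverage the field scores 0 (no or
    hardly any adhered platelets). ``dense_coverage_pct`` splits sparse (1)
    from extensive (2) single-platelet coverage. ``single_platelet_area_px``
    is the largest area still counted as a single platelet;
    ``aggregate_cuts_px`` split small (3) / intermediate (4) / large (5)
    aggregates on the largest feature. ``full_thrombus_coverage_pct`` also
    promotes to 5 on coverage alone.
    """

    coverage_floor_pct: float = 0.5
    dense_coverage_pct: float = 10.0
    single_platelet_area_px: float = 50.0
    aggregate_cuts_px: tuple[float, float] = (500.0, 2000.0)
    full_thrombus_coverage_pct: float = 25.0

    def __post_init__(self) -> None:
        cov = (self.coverage_floor_pct, self.dense_coverage_pct, self.full_thrombus_coverage_pct)
        area = (self.single_platelet_area_px, *self.aggregate_cuts_px)
        if any(a >= b for a, b in zip(cov, cov[1:])) or any(
            a >= b for a, b in zip(area, area[1:])
        ):
            raise ValueError("score calibration cut-offs must be strictly increasing")


def morphological_score(
    mask: np.ndarray,
    fs: FeatureSet | None = None,
    calibration: ScoreCalibration | None = None,
) -> int:
    """Deterministic proxy for the visual 0–5 morphology rubric.

    0 = no/hardly any platelets, 1 = multiple single platelets, 2 = extensive
    single-platelet coverage, 3/4/5 = small/intermediate/large aggregates,
    judged from coverage and the largest feature area against the calibration.
    """
    cal = calibration or ScoreCalibration()
    mask = np.asarray(mask).astype(bool)
    if fs is None:
        fs = feature_areas(mask)
    coverage = 100.0 * mask.sum() / mask.size
    if coverage < cal.coverage_floor_pct or fs.n == 0:
        return 0
    largest = float(fs.areas[-1])
    if largest < cal.single_platelet_area_px:
        return 2 if coverage >= cal.dense_coverage_pct else 1
    lo, hi = cal.aggregate_cuts_px
    if largest >= hi or coverage >= cal.full_thrombus_coverage_pct:
        return 5
    return 4 if largest >= lo else 3


def stable_adhesion(
    frames,
    background: float | None = None,
    persistence: float = 1.0,
    change_threshold: float = 30.0,
) -> float:
    """Stable platelet adhesion (%) from a differential image time series.

    A pixel counts as stably adhered when it is above background in at least
    ``persistence`` fraction of frames and its mean absolute frame-to-frame
    intensity change stays below ``change_threshold``. ``background`` defaults
    to an Otsu threshold on the temporal mean image.
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("all frames must share one shape")
    stack = np.stack(frames)
    if background is None:
        mean_img = stack.mean(axis=0)
        background = float(threshold_otsu(mean_img)) if np.ptp(mean_img) > 0 else np.inf
    above = (stack > background).mean(axis=0) >= persistence
    diffs = np.abs(np.diff(stack, axis=0)).mean(axis=0)
    stable = above & (diffs < change_threshold)
    return float(100.0 * stable.sum() / stable.size)


def thrombus_volume(
    stack,
    slice_spacing: float,
    pixel_size: float,
    method="otsu",
    min_contrast: float = 10.0,
) -> float:
    """Summed thrombus volume per surface area (μm³/μm²) from a z-stack.

    Each slice is thresholded with the shared policy; the volume is the count
    of occupied voxels × voxel volume, divided by the field area — i.e. the
    mean occupied height. With Otsu, one global threshold is computed over
    the whole stack, and a stack whose foreground/background separation is
    below ``min_contrast`` grey levels is treated as empty.
    """
    if slice_spacing <= 0 or pixel_size <= 0:
        raise ValueError("slice spacing and pixel size must be positive")
    slices = [np.asarray(s, dtype=float) for s in stack]
    if len(slices) < 2:
        raise ValueError("need at least 2 slices")
    vol = np.stack(slices)
    if method == "otsu":
        if np.ptp(vol) == 0:
            return 0.0
        t = threshold_otsu(vol)
        occupied = vol > t
        if not occupied.any() or occupied.all():
            return 0.0 if not occupied.any() else float(len(slices) * slice_spacing)
        if vol[occupied].mean() - vol[~occupied].mean() < min_contrast:
            return 0.0
    else:
        occ = _threshold(vol.reshape(-1), method)
        occupied = occ.reshape(vol.shape)
    field_px = slices[0].size
    return float(occupied.sum() * slice_spacing / field_px)


def marker_coverage(
    fluor_image: np.ndarray,
    method="otsu",
    nonspecific_control: np.ndarray | float | None = None,
) -> float:
    """Fluorescence marker coverage (%), corrected for non-specific labelling.

    The control may be a matched control image (its own coverage is measured
    with the same threshold policy) or a scalar coverage %; the corrected
    value is floored at 0.
    """
    _, cov = segment_coverage(fluor_image, method)
    if nonspecific_control is None:
        return cov
    if np.isscalar(nonspecific_control):
        ctrl = float(nonspecific_control)
    else:
        _, ctrl = segment_coverage(np.asarray(nonspecific_control), method)
    if ctrl > 100.0:
        raise ValueError("control coverage cannot exceed 100%")
    return max(0.0, cov - ctrl)
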