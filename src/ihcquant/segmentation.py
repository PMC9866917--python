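"""Threshold + marker-controlled watershed segmentation of positive nuclei.

A pixel is a foreground candidate when its luma lies inside the biomarker's
inclusive threshold band [T_L, T_H].  Candidates are cleaned by morphological
opening, markers are grown from distance-transform peaks, and a watershed
flood on the image gradient splits touching nuclei.  Ridge (watershed-line)
pixels count as background, giving a conservative positive area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters as skfilters
from skimage import segmentation as skseg

from ihcquant.core_io import BiomarkerKind, ensure_rgb_image
from ihcquant.preprocessing import luma_image

#: 4-connected structuring element (3x3 elliptical)
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class ThresholdPair:
    """Lower/upper segmentation thresholds bound to a biomarker kind."""

    lower: int
    upper: int
    biomarker: BiomarkerKind | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.lower <= self.upper <= 255:
            raise ValueError(
                f"thresholds must satisfy 0 <= lower <= upper <= 255, "
                f"got ({self.lower}, {self.upper})"
            )

    def to_dict(self) -> dict:
        return {
            "lower": int(self.lower),
            "upper": int(self.upper),
            "biomarker": self.biomarker.value if self.biomarker else None,
        }


#: published per-biomarker threshold table
DEFAULT_THRESHOLDS = {
    BiomarkerKind.PR: (160, 180),
    BiomarkerKind.ER: (180, 210),
    BiomarkerKind.HER2: (40, 230),
    BiomarkerKind.KI67: (160, 180),
}


@dataclass(frozen=True)
class MorphologySettings:
    """Marker-recipe parameters (values are defaults, not published)."""

    opening_iterations: int = 2
    background_dilation_iterations: int = 3
    distance_fraction: float = 0.4
    min_object_px: int = 30

    def to_dict(self) -> dict:
        return {
            "opening_iterations": self.opening_iterations,
            "background_dilation_iterations": self.background_dilation_iterations,
            "distance_fraction": self.distance_fraction,
            "min_object_px": self.min_object_px,
        }


@dataclass
class SegmentationResult:
    foreground_mask: np.ndarray
    labels: np.ndarray
    positive_area_sp: int
    window_area_sw: int
    params_used: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.positive_area_sp > self.window_area_sw:
            raise ValueError("positive area cannot exceed window area")


def select_thresholds(biomarker: BiomarkerKind) -> ThresholdPair:
    """Published threshold pair for a biomarker kind."""
    if not isinstance(biomarker, BiomarkerKind):
        biomarker = BiomarkerKind.parse(biomarker)
    lower, upper = DEFAULT_THRESHOLDS[biomarker]
    return ThresholdPair(lower=lower, upper=upper, biomarker=biomarker)


def threshold_band(img: np.ndarray, thresholds: ThresholdPair) -> np.ndarray:
    """Boolean candidate mask: T_L <= luma <= T_H (inclusive band)."""
    y = luma_image(img)
    return (y >= thresholds.lower) & (y <= thresholds.upper)


def _erode(mask: np.ndarray, iterations: int) -> np.ndarray:
    if iterations <= 0:
        return mask
    return ndi.binary_erosion(mask, structure=_CROSS, iterations=iterations)


def _dilate(mask: np.ndarray, iterations: int) -> np.ndarray:
    if iterations <= 0:
        return mask
    return ndi.binary_dilation(mask, structure=_CROSS, iterations=iterations)


def watershed_segment(
    img: np.ndarray,
    candidate: np.ndarray,
    morphology: MorphologySettings | None = None,
) -> SegmentationResult:
    """Split the candidate mask into labeled nuclei via marker-controlled watershed.

    Steps: open the candidate mask; dilate it to bound the uncertain region;
    threshold the distance transform at ``distance_fraction`` of its maximum
    for sure-foreground markers; flood the luma gradient from the markers;
    drop ridge pixels and components below ``min_object_px``.
    """
    arr = ensure_rgb_image(img)
    cand = np.asarray(candidate).astype(bool)
    if cand.shape != arr.shape[:2]:
        raise ValueError(f"candidate mask shape {cand.shape} != image {arr.shape[:2]}")
    m = morphology or MorphologySettings()
    sw = int(arr.shape[0] * arr.shape[1])
    params = {"morphology": m.to_dict()}

    def empty_result() -> SegmentationResult:
        return SegmentationResult(
            foreground_mask=np.zeros_like(cand),
            labels=np.zeros(cand.shape, dtype=np.int32),
            positive_area_sp=0,
            window_area_sw=sw,
            params_used=params,
        )

    if not cand.any():
        return empty_result()

    opened = _dilate(_erode(cand, m.opening_iterations), m.opening_iterations)
    if not opened.any():
        return empty_result()

    not_sure_bg = _dilate(opened, m.background_dilation_iterations)
    distance = ndi.distance_transform_edt(opened)
    sure_fg = distance > m.distance_fraction * distance.max()
    if not sure_fg.any():
        return empty_result()

    marker_labels, n_markers = ndi.label(sure_fg, structure=_CROSS)
    markers = marker_labels.astype(np.int32) + 1  # background = 1, objects >= 2
    unknown = not_sure_bg & ~sure_fg
    markers[unknown] = 0

    gradient = skfilters.sobel(luma_image(arr))
    flooded = skseg.watershed(gradient, markers, watershed_line=True)
    foreground = flooded >= 2  # ridge (0) and background (1) excluded

    labels, _ = ndi.label(foreground, structure=_CROSS)
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < m.min_object_px)
    if small.size:
        labels[np.isin(labels, small[small > 0])] = 0
    # relabel consecutively (0 stays background even if absent from the array)
    kept = np.unique(labels)
    if kept.size == 0 or kept[0] != 0:
        kept = np.insert(kept, 0, 0)
    remap = np.zeros(kept.max() + 1, dtype=np.int32)
    remap[kept] = np.arange(kept.size, dtype=np.int32)
    labels = remap[labels]

    mask = labels > 0
    return SegmentationResult(
        foreground_mask=mask,
        labels=labels,
        positive_area_sp=int(mask.sum()),
        window_area_sw=sw,
        params_used=params,
    )


def segment(
    img: np.ndarray,
    biomarker: BiomarkerKind,
    morphology: MorphologySettings | None = None,
    thresholds: ThresholdPair | None = None,
) -> SegmentationResult:
    """Full segmentation of a (preprocessed) biomarker image."""
    tp = thresholds or select_thresholds(biomarker)
    candidate = threshold_band(img, tp)
    result = watershed_segment(img, candidate, morphology=morphology)
    result.params_used["thresholds"] = tp.to_dict()
    return result
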