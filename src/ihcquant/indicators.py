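"""Per-biomarker diagnostic indicators: relative positive area and intensity.

``relative_area`` is exact rational arithmetic on pixel counts.  The
intensity coefficient is an ordinal 1-3 score binned from the mean brightness
of segmented pixels measured, by default, on the original (pre-gain) image so
that it stays independent of the brightness correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from ihcquant.config import PipelineConfig
from ihcquant.core_io import BiomarkerKind, ProvenanceRecord, ensure_rgb_image
from ihcquant.preprocessing import luma_image, preprocess_stages
from ihcquant.segmentation import (
    MorphologySettings,
    SegmentationResult,
    segment,
)


class NoPositiveCellsError(ValueError):
    """Raised when an intensity is requested over an empty positive mask."""


@dataclass(frozen=True)
class AreaIndicator:
    """Relative positive area delta_S = Sp / Sw, held exactly as a rational."""

    sp: int
    sw: int

    def __post_init__(self) -> None:
        if self.sw <= 0:
            raise ValueError("window area Sw must be positive")
        if not 0 <= self.sp <= self.sw:
            raise ValueError("Sp must lie in [0, Sw]")

    @property
    def delta_s(self) -> Fraction:
        return Fraction(self.sp, self.sw)


@dataclass(frozen=True)
class IntensityCoefficient:
    ki: int
    mean_brightness: float

    def __post_init__(self) -> None:
        if self.ki not in (1, 2, 3):
            raise ValueError(f"ki must be 1, 2 or 3, got {self.ki}")


def relative_area(result: SegmentationResult) -> AreaIndicator:
    if result.window_area_sw <= 0:
        raise ValueError("window area Sw must be positive")
    return AreaIndicator(sp=result.positive_area_sp, sw=result.window_area_sw)


def masked_mean_brightness(original: np.ndarray, mask: np.ndarray) -> float:
    """Mean luma of the original image over the mask's foreground pixels."""
    arr = ensure_rgb_image(original)
    m = np.asarray(mask).astype(bool)
    if m.shape != arr.shape[:2]:
        raise ValueError(f"mask shape {m.shape} != image {arr.shape[:2]}")
    if not m.any():
        raise NoPositiveCellsError("no positive cells: mask is empty")
    return float(luma_image(arr)[m].mean())


def intensity_coefficient(mean_brightness: float) -> IntensityCoefficient:
    """Ordinal staining intensity: 1 if Y <= 15, 2 if 15 < Y <= 30, 3 if Y > 30."""
    y = float(mean_brightness)
    if not 0.0 <= y <= 255.0:
        raise ValueError(f"mean brightness must be in [0, 255], got {y}")
    if y <= 15.0:
        ki = 1
    elif y <= 30.0:
        ki = 2
    else:
        ki = 3
    return IntensityCoefficient(ki=ki, mean_brightness=y)


@dataclass
class BiomarkerIndicators:
    """Everything measured for one biomarker image."""

    biomarker: BiomarkerKind
    sp: int
    sw: int
    mean_brightness: float | None
    ki: int | None
    no_positive_cells: bool
    provenance: ProvenanceRecord | None = None
    thresholds: dict | None = None

    @property
    def sigma_s(self) -> Fraction:
        return Fraction(self.sp, self.sw)

    def to_dict(self) -> dict:
        return {
            "biomarker": self.biomarker.value,
            "sigma_s": float(self.sigma_s),
            "sp": self.sp,
            "sw": self.sw,
            "mean_brightness": self.mean_brightness,
            "ki": self.ki,
            "no_positive_cells": self.no_positive_cells,
            "thresholds": self.thresholds,
            "provenance": self.provenance.to_dict() if self.provenance else None,
        }


@dataclass
class IndicatorSet:
    """Per-biomarker indicators; complete (all four biomarkers) by construction."""

    entries: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [k.value for k in BiomarkerKind if k not in self.entries]
        if missing:
            raise ValueError(f"incomplete indicator set, missing biomarkers: {missing}")

    def __getitem__(self, kind: BiomarkerKind) -> BiomarkerIndicators:
        return self.entries[kind]

    def sigma_s(self, kind: BiomarkerKind):
        return self.entries[kind].sigma_s

    def ki(self, kind: BiomarkerKind):
        return self.entries[kind].ki

    @classmethod
    def from_values(
        cls,
        er_sigma,
        pr_sigma,
        her2_sigma,
        ki67_sigma,
        er_ki=None,
        pr_ki=None,
        her2_ki=None,
        ki67_ki=None,
    ) -> "IndicatorSet":
        """Build a set directly from indicator values (for rules and tests).

        Float sigmas are interpreted through their decimal representation, so
        ``0.66`` means the exact rational 66/100 (boundary comparisons against
        the rule constants are then exact).
        """
        entries = {}
        for kind, sigma, ki in (
            (BiomarkerKind.ER, er_sigma, er_ki),
            (BiomarkerKind.PR, pr_sigma, pr_ki),
            (BiomarkerKind.HER2, her2_sigma, her2_ki),
            (BiomarkerKind.KI67, ki67_sigma, ki67_ki),
        ):
            frac = Fraction(str(sigma)) if isinstance(sigma, float) else Fraction(sigma)
            if not 0 <= frac <= 1:
                raise ValueError(f"sigma for {kind.value} must be in [0, 1], got {sigma}")
            entries[kind] = BiomarkerIndicators(
                biomarker=kind,
                sp=frac.numerator,
                sw=frac.denominator,
                mean_brightness=None,
                ki=ki,
                no_positive_cells=ki is None,
            )
        return cls(entries=entries)

    def to_dict(self) -> dict:
        return {k.value: v.to_dict() for k, v in self.entries.items()}


def compute_biomarker_indicators(
    img: np.ndarray,
    biomarker: BiomarkerKind,
    config: PipelineConfig | None = None,
    rules=None,
) -> tuple[BiomarkerIndicators, SegmentationResult]:
    """Preprocess, segment and measure one biomarker image.

    When a knowledge-base :class:`~ihcquant.knowledge_base.RuleStore` is
    given, the window/alpha/threshold parameters are fired through it (and
    logged); the defaults are equivalent to the built-in selectors.
    """
    cfg = config or PipelineConfig()
    if rules is not None:
        stages = preprocess_stages(
            img,
            probe_window=cfg.probe_window,
            window_rule=lambda psnr: rules.fire("window", psnr_db=psnr)["window_side"],
            alpha_rule=lambda y: rules.fire("alpha", y=y)["alpha"],
        )
    else:
        stages = preprocess_stages(img, probe_window=cfg.probe_window)
    seg_input = stages.output if cfg.segment_on == "amplified" else stages.filtered
    morphology = MorphologySettings(
        opening_iterations=cfg.opening_iterations,
        background_dilation_iterations=cfg.background_dilation_iterations,
        distance_fraction=cfg.distance_fraction,
        min_object_px=cfg.min_object_px,
    )
    thresholds = None
    if rules is not None:
        from ihcquant.segmentation import ThresholdPair

        action = rules.fire("threshold", image_type=biomarker)
        thresholds = ThresholdPair(
            lower=action["t_low"], upper=action["t_high"], biomarker=biomarker
        )
    seg = segment(seg_input, biomarker, morphology=morphology, thresholds=thresholds)

    intensity_img = img if cfg.intensity_source == "original" else stages.output
    try:
        mean_y = masked_mean_brightness(intensity_img, seg.foreground_mask)
        if cfg.intensity_channel == "inverted_luma":
            mean_y = 255.0 - mean_y
        ki = intensity_coefficient(mean_y).ki
        no_positive = False
    except NoPositiveCellsError:
        mean_y = None
        ki = None
        no_positive = True

    ind = BiomarkerIndicators(
        biomarker=biomarker,
        sp=seg.positive_area_sp,
        sw=seg.window_area_sw,
        mean_brightness=mean_y,
        ki=ki,
        no_positive_cells=no_positive,
        provenance=stages.record,
        thresholds=seg.params_used.get("thresholds"),
    )
    return ind, seg


def compute_indicator_set(
    stack: dict, config: PipelineConfig | None = None, rules=None
) -> IndicatorSet:
    """Run the full measurement chain on a four-biomarker image stack.

    ``stack`` maps :class:`BiomarkerKind` (or any parseable alias) to an RGB
    image.  All four biomarkers must be present.
    """
    normalized = {}
    for key, img in stack.items():
        kind = key if isinstance(key, BiomarkerKind) else BiomarkerKind.parse(key)
        normalized[kind] = img
    missing = [k.value for k in BiomarkerKind if k not in normalized]
    if missing:
        raise ValueError(f"missing biomarker images: {missing}")

    entries = {}
    for kind in BiomarkerKind:
        ind, _ = compute_biomarker_indicators(normalized[kind], kind, config=config, rules=rules)
        entries[kind] = ind
    return IndicatorSet(entries=entries)
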