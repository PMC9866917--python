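"""Seeded generator of IHC-like images with ground truth.

Images have a light, uniform background; positive (stained) nuclei are warm
brown ellipses whose mean luma is controlled; counter-stained negative nuclei
are cool blue ellipses.  Impulse (salt-and-pepper) noise is added separately
with an exact corrupted-pixel count.  Everything is driven by a single seed
and is bit-exact reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from ihcquant.core_io import ensure_rgb_image
from ihcquant.preprocessing import LUMA_WEIGHTS, luma_image

#: unit color directions (R, G, B); scaled so that luma hits the target
POSITIVE_DIRECTION = (1.0, 0.85, 0.60)   # warm DAB-like brown
NEGATIVE_DIRECTION = (0.55, 0.65, 1.0)   # cool hematoxylin-like blue

#: uniform background color (luma ~233, above every published threshold band)
BACKGROUND_RGB = (235, 233, 228)


class FixturePlacementError(RuntimeError):
    """Raised when the requested coverage cannot be placed."""


def _direction_luma(direction) -> float:
    return sum(w * d for w, d in zip(LUMA_WEIGHTS, direction))


def color_for_luma(luma: float, direction=POSITIVE_DIRECTION) -> tuple[int, int, int]:
    """RGB triple along ``direction`` whose luma is (approximately) ``luma``."""
    scale = luma / _direction_luma(direction)
    channels = [scale * d for d in direction]
    if any(c > 255.5 for c in channels):
        raise ValueError(f"luma {luma} is not reachable along direction {direction}")
    return tuple(int(min(255, math.floor(c + 0.5))) for c in channels)


@dataclass(frozen=True)
class FixtureSpec:
    height: int = 512
    width: int = 512
    positive_fraction: float = 0.25
    positive_luma: float = 195.0
    negative_count: int = 12
    nucleus_radius_px: tuple = (16.0, 4.0)   # (mean, spread)
    impulse_noise_density: float = 0.0
    seed: int = 0
    negative_luma: float = 110.0
    luma_jitter: float = 2.0
    allow_overlap: bool = False
    fraction_tolerance: float = 0.01
    max_attempts: int = 20_000

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("fixture dimensions must be positive")
        if not 0.0 <= self.positive_fraction <= 0.9:
            raise ValueError("positive_fraction must be in [0, 0.9]")
        if not 0.0 <= self.positive_luma <= 255.0:
            raise ValueError("positive_luma must be in [0, 255]")
        if not 0.0 <= self.impulse_noise_density <= 0.5:
            raise ValueError("impulse_noise_density must be in [0, 0.5]")
        if self.negative_count < 0:
            raise ValueError("negative_count must be non-negative")
        if self.nucleus_radius_px[0] < 1.5:
            raise ValueError("mean nucleus radius must be at least 1.5 px")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    positive_mask: np.ndarray
    nucleus_table: list = field(default_factory=list)
    true_delta_s: float = 0.0
    true_mean_luma: float = 0.0


def _sample_nucleus(rng, spec: FixtureSpec, shrink: float = 1.0):
    mean_r, spread = spec.nucleus_radius_px
    a = max(2.0, rng.normal(mean_r, spread) * shrink)
    b = max(2.0, a * rng.uniform(0.6, 1.0))
    row = rng.uniform(0, spec.height)
    col = rng.uniform(0, spec.width)
    rot = rng.uniform(0, math.pi)
    return row, col, a, b, rot


def make_ihc_image(spec: FixtureSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a fixture and its ground truth (recorded before noise).

    Positive nuclei are placed (non-overlapping by default) until the covered
    fraction is within ``fraction_tolerance`` of ``positive_fraction``; if the
    attempt cap is hit first a :class:`FixturePlacementError` is raised.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:, :] = BACKGROUND_RGB

    total = h * w
    target_px = int(round(spec.positive_fraction * total))
    tol_px = max(1, int(round(spec.fraction_tolerance * total)))

    positive_mask = np.zeros((h, w), dtype=bool)
    occupied = np.zeros((h, w), dtype=bool)
    table: list[dict] = []

    attempts = 0
    covered = 0
    shrink = 1.0
    while target_px > 0 and abs(covered - target_px) > tol_px:
        if covered > target_px:
            break  # inside tolerance is handled above; overshoot beyond tol cannot shrink
        attempts += 1
        if attempts > spec.max_attempts:
            raise FixturePlacementError(
                f"could not reach positive fraction {spec.positive_fraction} "
                f"within {spec.max_attempts} attempts (covered {covered / total:.3f})"
            )
        # shrink radii near the target so a single nucleus cannot overshoot
        remaining = target_px - covered
        mean_area = math.pi * spec.nucleus_radius_px[0] ** 2 * 0.8
        shrink = min(1.0, math.sqrt(max(remaining + tol_px, 16) / mean_area)) if mean_area else 1.0
        row, col, a, b, rot = _sample_nucleus(rng, spec, shrink=shrink)
        rr, cc = draw_ellipse(row, col, a, b, shape=(h, w), rotation=rot)
        if rr.size == 0:
            continue
        new = ~occupied[rr, cc] if spec.allow_overlap else None
        if not spec.allow_overlap and occupied[rr, cc].any():
            continue
        gain = covered + (int(new.sum()) if spec.allow_overlap else rr.size)
        if gain > target_px + tol_px:
            continue
        nucleus_luma = float(np.clip(spec.positive_luma + rng.normal(0.0, spec.luma_jitter), 0, 220))
        color = color_for_luma(nucleus_luma, POSITIVE_DIRECTION)
        img[rr, cc] = color
        positive_mask[rr, cc] = True
        occupied[rr, cc] = True
        covered = int(positive_mask.sum())
        table.append(
            {"row": row, "col": col, "radius_a": a, "radius_b": b, "rotation": rot,
             "cls": "positive", "luma": nucleus_luma}
        )

    # counter-stained (negative) nuclei never overlap positive ones
    placed_neg = 0
    neg_attempts = 0
    while placed_neg < spec.negative_count and neg_attempts < spec.max_attempts:
        neg_attempts += 1
        row, col, a, b, rot = _sample_nucleus(rng, spec)
        rr, cc = draw_ellipse(row, col, a, b, shape=(h, w), rotation=rot)
        if rr.size == 0 or occupied[rr, cc].any():
            continue
        nucleus_luma = float(np.clip(spec.negative_luma + rng.normal(0.0, spec.luma_jitter), 0, 160))
        img[rr, cc] = color_for_luma(nucleus_luma, NEGATIVE_DIRECTION)
        occupied[rr, cc] = True
        placed_neg += 1
        table.append(
            {"row": row, "col": col, "radius_a": a, "radius_b": b, "rotation": rot,
             "cls": "negative", "luma": nucleus_luma}
        )

    true_delta_s = positive_mask.sum() / total
    true_mean_luma = float(luma_image(img)[positive_mask].mean()) if positive_mask.any() else 0.0
    truth = GroundTruth(
        positive_mask=positive_mask,
        nucleus_table=table,
        true_delta_s=true_delta_s,
        true_mean_luma=true_mean_luma,
    )
    if spec.impulse_noise_density > 0:
        img = add_impulse_noise(img, spec.impulse_noise_density, seed=int(rng.integers(2**31)))
    return img, truth


def add_impulse_noise(img: np.ndarray, density: float, seed: int) -> np.ndarray:
    """Corrupt an exact ``round(density * H * W)`` count of whole pixels.

    Each corrupted pixel is set to black or white (equal probability) on all
    three channels jointly, sampled without replacement.
    """
    arr = ensure_rgb_image(img).copy()
    if not 0.0 <= density <= 0.5:
        raise ValueError(f"impulse noise density must be in [0, 0.5], got {density}")
    h, w = arr.shape[:2]
    n = int(round(density * h * w))
    if n == 0:
        return arr
    rng = np.random.default_rng(seed)
    flat = rng.choice(h * w, size=n, replace=False)
    values = rng.integers(0, 2, size=n, dtype=np.uint8) * 255
    rows, cols = np.unravel_index(flat, (h, w))
    arr[rows, cols] = values[:, None]
    return arr
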