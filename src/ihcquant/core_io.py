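"""Image I/O and core domain types.

Images are plain ``numpy.ndarray`` of shape ``(H, W, 3)`` and dtype ``uint8``,
row-major with the origin at the top-left and ``(row, col)`` indexing.  The
channel order is fixed RGB internally regardless of the source library.
"""

from __future__ import annotations

import enum
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger(__name__)

#: dtype of all pipeline images
IMAGE_DTYPE = np.uint8

_SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}

# PIL modes that carry more (or fewer) than 8 bits per channel
_UNSUPPORTED_MODES = {"I", "I;16", "I;16B", "I;16L", "I;16N", "F", "LAB", "CMYK"}


class UnsupportedBitDepthError(ValueError):
    """Raised for sources that are not 8 bits per channel (no silent rescale)."""


class BiomarkerKind(enum.Enum):
    """The four immunohistochemical biomarkers driving the diagnosis."""

    PR = "PR"
    ER = "ER"
    HER2 = "HER2"
    KI67 = "KI67"

    @classmethod
    def parse(cls, name: str) -> "BiomarkerKind":
        """Parse a case-insensitive alias ("er", "estrogen", "her2/neu", ...)."""
        key = str(name).strip().lower().replace("-", "").replace("_", "").replace(" ", "")
        aliases = {
            "pr": cls.PR,
            "progesterone": cls.PR,
            "er": cls.ER,
            "estrogen": cls.ER,
            "her2": cls.HER2,
            "her2/neu": cls.HER2,
            "her2neu": cls.HER2,
            "oncoprotein": cls.HER2,
            "ki67": cls.KI67,
            "cellproliferationbiomarker": cls.KI67,
            "proliferation": cls.KI67,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown biomarker kind: {name!r}") from None


class Grade(enum.Enum):
    """Histological tumor differentiation grade, supplied by the diagnostician."""

    G1 = "G1"
    G2 = "G2"
    G3 = "G3"

    @classmethod
    def parse(cls, name: str) -> "Grade":
        key = str(name).strip().upper()
        try:
            return cls[key]
        except KeyError:
            raise ValueError(f"unknown grade: {name!r} (expected G1/G2/G3)") from None


@dataclass
class ProvenanceRecord:
    """State recorded while running the preprocessing chain.

    ``stage_checksums`` holds digests of the four stage images (input,
    probe-filtered, filtered, gain-adjusted) keyed ``"I"``, ``"II"``,
    ``"III"``, ``"IIII"``.
    """

    probe_psnr_db: float
    selected_window: int
    mean_brightness_y: float
    selected_alpha: float
    stage_checksums: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.selected_window not in (3, 5):
            raise ValueError(f"selected_window must be 3 or 5, got {self.selected_window}")

    def to_dict(self) -> dict:
        return {
            "probe_psnr_db": None if np.isinf(self.probe_psnr_db) else float(self.probe_psnr_db),
            "probe_psnr_infinite": bool(np.isinf(self.probe_psnr_db)),
            "selected_window": int(self.selected_window),
            "mean_brightness_y": float(self.mean_brightness_y),
            "selected_alpha": float(self.selected_alpha),
            "stage_checksums": dict(self.stage_checksums),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def ensure_rgb_image(img: np.ndarray, name: str = "image") -> np.ndarray:
    """Validate an (H, W, 3) uint8 array and return it."""
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{name} must have shape (H, W, 3), got {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{name} must be at least 1x1, got {arr.shape}")
    if arr.dtype != IMAGE_DTYPE:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(IMAGE_DTYPE)
        else:
            raise ValueError(f"{name} must be uint8 in [0, 255], got dtype {arr.dtype}")
    return arr


def image_checksum(img: np.ndarray) -> str:
    """SHA-256 digest over shape and raw pixel bytes."""
    arr = np.ascontiguousarray(img)
    h = hashlib.sha256()
    h.update(str(arr.shape).encode())
    h.update(arr.tobytes())
    return h.hexdigest()


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG file as an (H, W, 3) uint8 RGB array.

    Grayscale sources are replicated to three channels; an alpha channel is
    dropped.  Bit depths other than 8 per channel raise
    :class:`UnsupportedBitDepthError` rather than rescaling silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ValueError(f"unsupported image format {path.suffix!r}: {path}")
    try:
        with Image.open(path) as im:
            if im.mode in _UNSUPPORTED_MODES:
                raise UnsupportedBitDepthError(
                    f"unsupported bit depth (mode {im.mode!r}) in {path}; "
                    "only 8-bit-per-channel images are accepted"
                )
            if im.format == "JPEG":
                logger.warning("reading lossy JPEG input: %s", path)
            if im.mode in ("L", "1"):
                im = im.convert("L")
                arr = np.asarray(im, dtype=IMAGE_DTYPE)
                return np.repeat(arr[:, :, None], 3, axis=2)
            im = im.convert("RGB")
            return np.asarray(im, dtype=IMAGE_DTYPE)
    except UnidentifiedImageError as exc:
        raise OSError(f"unreadable or corrupt image file: {path}") from exc


def write_image(path, img: np.ndarray) -> None:
    """Write an RGB image as PNG or uncompressed-pixel TIFF/JPEG by extension."""
    arr = ensure_rgb_image(img)
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ValueError(f"unsupported image format {path.suffix!r}: {path}")
    Image.fromarray(arr, mode="RGB").save(path)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit single-channel PNG (foreground=255)."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
    out = np.where(arr.astype(bool), 255, 0).astype(IMAGE_DTYPE)
    try:
        Image.fromarray(out, mode="L").save(Path(path))
    except OSError as exc:
        raise OSError(f"cannot write mask to {path}: {exc}") from exc


def read_mask(path) -> np.ndarray:
    """Read a mask PNG back as a boolean array (nonzero = foreground)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 0


def write_labels(path, labels: np.ndarray) -> None:
    """Write an integer label image as 16-bit PNG (labels above 65535 rejected)."""
    arr = np.asarray(labels)
    if arr.ndim != 2:
        raise ValueError(f"labels must be 2-D, got shape {arr.shape}")
    if arr.max(initial=0) > 65535:
        raise ValueError("label image exceeds 16-bit range")
    Image.fromarray(arr.astype(np.uint16)).save(Path(path))
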