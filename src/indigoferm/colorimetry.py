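"""Colorimetric scoring of dyed-cloth swatches.

The dyeing phenotype of an indigo fermentation vat is assessed by dipping a
small piece of cotton cloth into the fluid, oxidising it in air, and scanning
the dyed cloth.  The scan is summarised as a single dyeing-intensity score:
the Euclidean norm sqrt(L*^2 + a*^2 + b*^2) of the mean CIELAB colour of the
swatch.  L* is lightness, a* red-green chromaticity, b* yellow-blue
chromaticity; -b* is the blue direction indigo pulls the cloth towards.

Conversions between sRGB and CIELAB use the standard scanner assumptions:
IEC 61966-2-1 sRGB gamma, D65 white point, 2 degree observer (the defaults of
``skimage.color``).  Averaging is done in Lab space by default, because the
score is defined on L*, a*, b* values; averaging in sRGB space is available
for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "LabColor",
    "RGBImage",
    "DyeScore",
    "srgb_to_lab",
    "lab_to_srgb",
    "intensity",
    "extract_swatch_mask",
    "score_image",
    "delta_e",
]


@dataclass(frozen=True)
class LabColor:
    """A CIELAB colour. L in [0, 100]; a and b unbounded but finite."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        for name in ("L", "a", "b"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"LabColor.{name} must be finite, got {v!r}")
        if not (0.0 <= self.L <= 100.0):
            raise ValueError(f"LabColor.L must lie in [0, 100], got {self.L!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


@dataclass
class RGBImage:
    """An 8-bit sRGB image (H x W x 3, integer values in [0, 255])."""

    pixels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 pixel array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("sRGB channel values must lie in [0, 255]")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.allclose(px, np.round(px)):
                raise ValueError("sRGB channel values must be integral")
            px = np.round(px).astype(np.uint8)
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class DyeScore:
    """Mean swatch colour and its intensity norm."""

    mean_lab: LabColor
    intensity: float
    n_pixels_used: int
    mask_fraction: float = field(default=1.0)

    def __post_init__(self) -> None:
        if self.n_pixels_used < 1:
            raise ValueError("n_pixels_used must be >= 1")
        expected = float(np.linalg.norm(self.mean_lab.as_array()))
        if abs(expected - self.intensity) > 1e-9:
            raise ValueError(
                f"intensity {self.intensity!r} is not the norm of mean_lab ({expected!r})"
            )


def srgb_to_lab(rgb) -> LabColor:
    """Convert one 8-bit sRGB triplet to CIELAB (D65, 2 degree observer)."""
    arr = np.asarray(rgb, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"expected an (r, g, b) triplet, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError(f"sRGB channels must lie in [0, 255], got {tuple(arr)}")
    lab = _skcolor.rgb2lab(arr.reshape(1, 1, 3) / 255.0)[0, 0]
    return LabColor(float(lab[0]), float(lab[1]), float(lab[2]))


def lab_to_srgb(lab: LabColor) -> tuple[np.ndarray, bool]:
    """Convert CIELAB to the nearest 8-bit sRGB triplet.

    Returns ``(rgb, in_gamut)``; out-of-gamut colours are clipped to the cube
    and flagged ``in_gamut=False``.
    """
    rgb = _skcolor.lab2rgb(lab.as_array().reshape(1, 1, 3))[0, 0]
    in_gamut = bool(np.all(rgb >= -1e-9) and np.all(rgb <= 1 + 1e-9))
    rgb8 = np.clip(np.round(np.clip(rgb, 0.0, 1.0) * 255.0), 0, 255).astype(np.uint8)
    return rgb8, in_gamut


def intensity(lab: LabColor) -> float:
    """Dyeing intensity: sqrt(L*^2 + a*^2 + b*^2)."""
    return float(np.linalg.norm(lab.as_array()))


def delta_e(a: LabColor, b: LabColor) -> float:
    """CIE76 colour difference (Euclidean distance in Lab space)."""
    return float(np.linalg.norm(a.as_array() - b.as_array()))


def extract_swatch_mask(image: RGBImage, border_fraction: float = 0.15) -> np.ndarray:
    """Boolean mask selecting the central crop of a swatch image.

    ``border_fraction`` of the height and width is discarded on every side,
    excluding the undyed margin of the cloth.  The default central-crop
    strategy assumes the swatch fills the scan; no segmentation is attempted.
    """
    if not (0.0 <= border_fraction < 0.5):
        raise ValueError(f"border_fraction must lie in [0, 0.5), got {border_fraction!r}")
    h, w = image.shape
    top = int(np.floor(h * border_fraction))
    left = int(np.floor(w * border_fraction))
    mask = np.zeros((h, w), dtype=bool)
    mask[top : h - top, left : w - left] = True
    if not mask.any():
        raise ValueError(
            f"border_fraction {border_fraction} leaves no interior pixels in a {h}x{w} image"
        )
    return mask


def score_image(
    image: RGBImage,
    border_fraction: float = 0.15,
    average_in: str = "lab",
) -> DyeScore:
    """Score a swatch image: masked per-pixel sRGB->Lab, mean, Euclidean norm.

    ``average_in='lab'`` (default) averages after conversion to Lab;
    ``'srgb'`` averages raw channels first and converts the mean colour.
    """
    mask = extract_swatch_mask(image, border_fraction)
    pixels = image.pixels[mask]
    if average_in == "lab":
        lab = _skcolor.rgb2lab(pixels.reshape(-1, 1, 3) / 255.0).reshape(-1, 3)
        mean = lab.mean(axis=0)
    elif average_in == "srgb":
        mean_rgb = pixels.mean(axis=0)
        mean = _skcolor.rgb2lab(mean_rgb.reshape(1, 1, 3) / 255.0)[0, 0]
    else:
        raise ValueError(f"average_in must be 'lab' or 'srgb', got {average_in!r}")
    mean_lab = LabColor(float(np.clip(mean[0], 0.0, 100.0)), float(mean[1]), float(mean[2]))
    return DyeScore(
        mean_lab=mean_lab,
        intensity=intensity(mean_lab),
        n_pixels_used=int(pixels.shape[0]),
        mask_fraction=float(mask.mean()),
    )
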