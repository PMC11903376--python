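"""High-voltage surface-area quantification from bipolar voltage-map images.

Clinical voltage maps paint bipolar amplitude > 0.5 mV purple (healthy
tissue), < 0.1 mV grey (scar), and the range in between as a blue-to-red
spectrum.  Pixels of a map screenshot are classified into those classes by
hue/saturation/value rules, and the healthy-voltage percentage is computed
from the class counts.

The default denominator excludes grey scar pixels — healthy % =
100 * purple / (purple + intermediate) — so the output is a true percentage
of viable mapped surface; the literal ratio purple / intermediate is also
reported, and a config flag can include grey in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PaletteConfig:
    """HSV class boundaries (hue in degrees).  Defaults match common
    electroanatomic color scales; the clinical palette is not standardized,
    so these are configurable."""

    purple_hue: tuple[float, float] = (255.0, 325.0)
    intermediate_hue: tuple[float, float] = (0.0, 250.0)  # red .. blue
    min_saturation: float = 0.20  # below: grey
    min_value: float = 0.12  # below: background
    include_grey_in_denominator: bool = False


@dataclass
class VoltageImageResult:
    counts: dict[str, int]
    healthy_percent: float | None  # default rule, None if undefined
    literal_ratio_percent: float | None  # 100 * purple / intermediate
    flags: list[str] = field(default_factory=list)


def classify_pixels(image: np.ndarray, palette: PaletteConfig | None = None) -> dict[str, int]:
    """Count pixels per class {purple, grey, intermediate, background}."""
    from skimage.color import rgb2hsv

    palette = palette or PaletteConfig()
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.dtype == np.uint8:
        img = img / 255.0
    hsv = rgb2hsv(img[..., :3])
    h = hsv[..., 0] * 360.0
    s = hsv[..., 1]
    v = hsv[..., 2]

    background = v < palette.min_value
    grey = (~background) & (s < palette.min_saturation)
    colored = (~background) & (~grey)
    lo, hi = palette.purple_hue
    purple = colored & (h >= lo) & (h <= hi)
    ilo, ihi = palette.intermediate_hue
    intermediate = colored & (~purple) & (h >= ilo) & (h <= ihi)
    other = colored & ~purple & ~intermediate
    counts = {
        "purple": int(purple.sum()),
        "grey": int(grey.sum()),
        "intermediate": int(intermediate.sum() + other.sum()),
        "background": int(background.sum()),
    }
    return counts


def healthy_percent(counts: dict[str, int],
                    palette: PaletteConfig | None = None) -> VoltageImageResult:
    """Healthy-voltage percentage from class counts; both denominator rules
    are always reported."""
    palette = palette or PaletteConfig()
    p = counts["purple"]
    inter = counts["intermediate"]
    grey = counts["grey"]
    flags: list[str] = []
    denom = p + inter + (grey if palette.include_grey_in_denominator else 0)
    if p + inter + grey == 0:
        return VoltageImageResult(counts=counts, healthy_percent=None,
                                  literal_ratio_percent=None,
                                  flags=["no colored pixels; healthy % undefined"])
    healthy = 100.0 * p / denom if denom > 0 else None
    if denom == 0:
        flags.append("zero denominator under default rule")
    literal = 100.0 * p / inter if inter > 0 else None
    if inter == 0:
        flags.append("zero intermediate count; literal ratio undefined")
    return VoltageImageResult(counts=counts, healthy_percent=healthy,
                              literal_ratio_percent=literal, flags=flags)


def analyze_image(image: np.ndarray, palette: PaletteConfig | None = None) -> VoltageImageResult:
    return healthy_percent(classify_pixels(image, palette), palette)


def load_image(path: str) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))
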