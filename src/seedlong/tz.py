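"""Tetrazolium stained-area quantification on seed cross-section images.

Viable (respiring) tissue reduces 2,3,5-triphenyltetrazolium chloride to
red formazan; dead tissue stays unstained.  Given an RGB image of a cut
seed on a light background, this module segments the section, counts the
pixels falling inside a red hue/saturation/brightness window, and applies
the standard area rule: a seed is viable when the stained fraction of its
section is at least 50%.

The thresholds mirror an interactive colour-threshold workflow and are
fully overridable; the defaults target saturated red staining.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.color import rgb2hsv

from .errors import DataError

__all__ = ["StainThresholds", "StainResult", "stained_fraction", "classify_viability", "batch_viability"]


@dataclass(frozen=True)
class StainThresholds:
    """Colour windows defining "stained" pixels and the background cut.

    Hue windows are in degrees with wrap-around support for red (the
    default covers [0, 20] plus [340, 360)); saturation and brightness are
    fractions in [0, 1].  Pixels at least ``bg_value_min`` bright and at
    most ``bg_sat_max`` saturated count as background; everything else is
    section.
    """

    hue_windows: tuple = ((0.0, 20.0), (340.0, 360.0))
    sat_min: float = 0.35
    value_min: float = 0.15
    value_max: float = 0.95
    bg_value_min: float = 0.92
    bg_sat_max: float = 0.10

    def __post_init__(self):
        for lo, hi in self.hue_windows:
            if not (0.0 <= lo <= hi <= 360.0):
                raise DataError(f"malformed hue window ({lo}, {hi})")
        for name in ("sat_min", "value_min", "value_max", "bg_value_min", "bg_sat_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DataError(f"{name} must be in [0, 1], got {v}")
        if self.value_min > self.value_max:
            raise DataError("value_min must not exceed value_max")


@dataclass(frozen=True)
class StainResult:
    """Pixel counts and viability call for one section image."""

    stained_pixels: int
    section_pixels: int

    @property
    def stained_fraction(self) -> float:
        return self.stained_pixels / self.section_pixels

    @property
    def viable(self) -> bool:
        return classify_viability(self.stained_fraction)

    def to_dict(self) -> dict:
        return {
            "stained_pixels": self.stained_pixels,
            "section_pixels": self.section_pixels,
            "stained_fraction": self.stained_fraction,
            "viable": self.viable,
        }


def stained_fraction(image, thresholds: StainThresholds = StainThresholds()) -> StainResult:
    """Count section pixels and the stained subset of an RGB raster.

    Parameters
    ----------
    image : ndarray, HxWx3
        RGB image (uint8 or float in [0, 1]).
    thresholds : StainThresholds
        Colour windows; defaults target red formazan staining on a white
        background.

    Raises
    ------
    DataError
        If the image is empty, not RGB, or no section pixels are found.
    """
    arr = np.asarray(image)
    if arr.size == 0 or arr.ndim != 3 or arr.shape[2] < 3:
        raise DataError("expected a non-empty HxWx3 RGB image")
    hsv = rgb2hsv(arr[..., :3])
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    val = hsv[..., 2]

    background = (val >= thresholds.bg_value_min) & (sat <= thresholds.bg_sat_max)
    section = ~background
    n_section = int(section.sum())
    if n_section == 0:
        raise DataError("no section detected (image is all background)")

    in_hue = np.zeros_like(hue, dtype=bool)
    for lo, hi in thresholds.hue_windows:
        in_hue |= (hue >= lo) & (hue < hi) if hi < 360.0 else (hue >= lo) & (hue <= hi)
    stained = (
        section
        & in_hue
        & (sat >= thresholds.sat_min)
        & (val >= thresholds.value_min)
        & (val <= thresholds.value_max)
    )
    return StainResult(stained_pixels=int(stained.sum()), section_pixels=n_section)


def classify_viability(fraction: float) -> bool:
    """Area rule: viable iff the stained fraction is >= 0.5 (boundary viable)."""
    if not (0.0 <= fraction <= 1.0):
        raise DataError(f"stained fraction must be in [0, 1], got {fraction}")
    return fraction >= 0.5


def batch_viability(images: Sequence, thresholds: StainThresholds = StainThresholds()):
    """Quantify a batch of section images and aggregate percent viability.

    Returns
    -------
    (percent_viable, rows) : (float, list of dict)
        ``rows`` holds one record per image (counts, fraction, viability,
        or an ``error`` field for images that failed); the aggregate is
        ``100 * viable / scored`` over successfully scored images.
    """
    images = list(images)
    if not images:
        raise DataError("empty image batch")
    rows = []
    n_viable = 0
    n_scored = 0
    for i, img in enumerate(images):
        try:
            res = stained_fraction(img, thresholds)
        except DataError as exc:
            rows.append({"image": i, "error": str(exc)})
            continue
        rec = {"image": i, **res.to_dict(), "error": ""}
        rows.append(rec)
        n_scored += 1
        n_viable += int(res.viable)
    if n_scored == 0:
        raise DataError("no image in the batch could be scored")
    return 100.0 * n_viable / n_scored, rows
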