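"""Picro-Sirius red image quantification by HSI reference-color scoring.

Under polarized light, Picro-Sirius red renders thick type I collagen
fibers red/yellow birefringent and thin type III fibers weakly green.
Each image pixel is converted from RGB to the classical HSI
(hue-saturation-intensity) space and scored against user-defined reference
colors: a pixel exactly at the reference hue scores 1, the score falls off
linearly with circular hue distance, and pixels outside the hue tolerance
— or too unsaturated / too dark / too bright to be a stained fiber —
score 0.  Per class (red, yellow, green) the pixel scores are summed and
expressed as a percentage of the image's pixel count; total collagen is
the sum of the three class percentages, with each pixel counted in at most
one class (highest score wins).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

CLASS_NAMES = ("red", "yellow", "green")
#: tie-break priority for per-pixel class assignment
CLASS_PRIORITY = {"red": 0, "yellow": 1, "green": 2}


class HistologyError(ValueError):
    pass


@dataclass
class HSIImage:
    """Per-pixel hue (deg, [0,360)), saturation [0,1], intensity [0,1]."""

    hue: np.ndarray
    saturation: np.ndarray
    intensity: np.ndarray
    chromatic: np.ndarray  # bool; False for achromatic (gray) pixels

    @property
    def shape(self) -> tuple[int, int]:
        return self.hue.shape


@dataclass(frozen=True)
class ReferenceColor:
    """An HSI target with tolerances defining one fiber-color class."""

    name: str
    hue_center: float  # degrees
    hue_tol: float = 20.0  # degrees; score hits 0 at this distance
    sat_min: float = 0.2
    int_range: tuple[float, float] = (0.05, 0.95)
    falloff: str = "linear"

    def __post_init__(self) -> None:
        if self.hue_tol <= 0:
            raise HistologyError("hue_tol must be positive")
        if not 0 <= self.sat_min < 1:
            raise HistologyError("sat_min must be in [0, 1)")
        if self.falloff != "linear":
            raise HistologyError("only linear falloff is defined")

    @classmethod
    def from_rgb(
        cls,
        name: str,
        rgb: tuple[int, int, int],
        hue_tol: float = 20.0,
        sat_min: float = 0.2,
        int_range: tuple[float, float] = (0.05, 0.95),
    ) -> "ReferenceColor":
        """Build a reference whose hue_center is the HSI hue of an RGB anchor."""
        px = np.array(rgb, dtype=np.uint8).reshape(1, 1, 3)
        hsi = rgb_to_hsi(px)
        if not hsi.chromatic[0, 0]:
            raise HistologyError(f"anchor color {rgb} is achromatic")
        return cls(name=name, hue_center=float(hsi.hue[0, 0]),
                   hue_tol=hue_tol, sat_min=sat_min, int_range=int_range)


#: Default fiber-class references (engineering defaults, overridable in config).
DEFAULT_REFERENCES = (
    ReferenceColor("red", hue_center=0.0, hue_tol=20.0),
    ReferenceColor("yellow", hue_center=50.0, hue_tol=20.0),
    ReferenceColor("green", hue_center=120.0, hue_tol=30.0),
)


@dataclass(frozen=True)
class CollagenScores:
    """Per-class aggregates and percentage total collagen for one image."""

    score_sum: dict[str, float]
    area_px: dict[str, int]
    pct_score: dict[str, float]
    total_collagen_pct: float
    n_pixels: int

    def type_i_pct(self) -> float:
        return self.pct_score["red"] + self.pct_score["yellow"]

    def type_iii_pct(self) -> float:
        return self.pct_score["green"]


def read_image(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF image as an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    if arr.size == 0:
        raise HistologyError(f"empty image {path}")
    return arr


def rgb_to_hsi(image: np.ndarray) -> HSIImage:
    """Classical arccos HSI conversion of an 8-bit RGB image.

    I = (R+G+B)/3 scaled to [0,1]; S = 1 - min/mean; H from the arccos
    formulation with H <- 360 - H when B > G.  Achromatic pixels (R=G=B,
    including black) get H=0, S=0 and chromatic=False.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise HistologyError("expected an (H, W, 3) RGB array")
    rgb = image.astype(np.float64) / 255.0
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    total = r + g + b
    intensity = total / 3.0
    minc = np.minimum(np.minimum(r, g), b)
    with np.errstate(invalid="ignore", divide="ignore"):
        saturation = np.where(total > 0, 1.0 - 3.0 * minc / np.where(total > 0, total, 1.0), 0.0)
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    chromatic = den > 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(num / np.where(chromatic, den, 1.0), -1.0, 1.0)
    theta = np.degrees(np.arccos(cosang))
    hue = np.where(b > g, 360.0 - theta, theta)
    hue = np.where(chromatic, hue, 0.0)
    hue = np.where(hue >= 360.0, hue - 360.0, hue)
    saturation = np.where(chromatic, saturation, 0.0)
    return HSIImage(hue=hue, saturation=np.clip(saturation, 0.0, 1.0),
                    intensity=np.clip(intensity, 0.0, 1.0), chromatic=chromatic)


def circular_hue_distance(h: np.ndarray, center: float) -> np.ndarray:
    d = np.abs(h - center) % 360.0
    return np.minimum(d, 360.0 - d)


def pixel_scores(hsi: HSIImage, ref: ReferenceColor) -> np.ndarray:
    """Per-pixel closeness score in [0, 1] against one reference color.

    score = max(0, 1 - d_hue/hue_tol), gated to 0 for achromatic pixels,
    saturation below ``sat_min`` or intensity outside ``int_range``.
    """
    d = circular_hue_distance(hsi.hue, ref.hue_center)
    score = np.maximum(0.0, 1.0 - d / ref.hue_tol)
    admissible = (
        hsi.chromatic
        & (hsi.saturation >= ref.sat_min)
        & (hsi.intensity >= ref.int_range[0])
        & (hsi.intensity <= ref.int_range[1])
    )
    return np.where(admissible, score, 0.0)


def quantify_collagen(
    image: np.ndarray, refs: tuple[ReferenceColor, ...] = DEFAULT_REFERENCES
) -> CollagenScores:
    """Score an RGB image against the three fiber-class references.

    Each pixel contributes to at most one class: the class with the highest
    positive score, ties broken by the fixed priority red > yellow > green.
    ``pct_score`` uses the full pixel count as denominator, so an image of
    nothing but exact-reference pixels scores 100.
    """
    names = [r.name for r in refs]
    if len(set(names)) != len(names):
        raise HistologyError("reference color names must be distinct")
    hsi = rgb_to_hsi(image)
    stack = np.stack([pixel_scores(hsi, r) for r in refs])  # (C, H, W)
    order = np.argsort([CLASS_PRIORITY.get(r.name, 99) for r in refs])
    best = np.zeros(hsi.shape, dtype=int) - 1
    best_score = np.zeros(hsi.shape)
    for c in order:  # priority order; strict > keeps earlier (higher-priority) winner
        s = stack[c]
        take = s > best_score
        best[take] = c
        best_score[take] = s[take]
    n_pixels = int(np.prod(hsi.shape))
    score_sum: dict[str, float] = {}
    area_px: dict[str, int] = {}
    pct: dict[str, float] = {}
    for c, ref in enumerate(refs):
        mask = (best == c) & (best_score > 0)
        score_sum[ref.name] = float(best_score[mask].sum())
        area_px[ref.name] = int(mask.sum())
        pct[ref.name] = 100.0 * score_sum[ref.name] / n_pixels
    return CollagenScores(
        score_sum=score_sum,
        area_px=area_px,
        pct_score=pct,
        total_collagen_pct=float(sum(pct.values())),
        n_pixels=n_pixels,
    )


def score_image_file(
    path: str | Path, refs: tuple[ReferenceColor, ...] = DEFAULT_REFERENCES
) -> CollagenScores:
    return quantify_collagen(read_image(path), refs)


# ---------------------------------------------------------------------------
# qualitative (pathologist) scoring records

QUALITATIVE_COLUMNS = {
    "fiber_color": {"Yellow", "Red", "Green"},
    "thick": {"+", "-"},
    "thin": {"+", "-"},
    "papillary_dermis": {"+", "-"},
    "mid_dermis": {"+", "-"},
    "deep_dermis": {"+", "-"},
    "horizontal": {"+", "-"},
    "vertical": {"+", "-"},
}


def read_qualitative_scores(path: str | Path) -> pd.DataFrame:
    """Read a CSV of qualitative fiber-scoring records (no computation).

    Expected columns: group, day, fiber_color (Yellow/Red/Green), then
    presence/absence (+/-) for thick, thin, papillary_dermis, mid_dermis,
    deep_dermis, horizontal, vertical.  The records mirror the blinded
    pathologist scoring sheet and are only validated and passed through for
    joint reporting with the quantitative scores.
    """
    table = pd.read_csv(path)
    if table.empty:
        return table
    for col, allowed in QUALITATIVE_COLUMNS.items():
        if col not in table.columns:
            raise HistologyError(f"qualitative scores missing column {col!r}")
        vals = set(table[col].astype(str).str.strip())
        # tolerate the underscore variant of the minus used in print
        vals = {"-" if v == "_" else v for v in vals}
        bad = vals - allowed
        if bad:
            raise HistologyError(f"column {col!r} has unknown values {sorted(bad)}")
    return table
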