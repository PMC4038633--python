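"""Seeded synthetic data with the statistical structure the analysis assumes.

Three generators:

* :func:`simulate_spectrum` — a two-Gaussian autofluorescence spectrum
  (collagen band at 405 nm, NADH band at 455 nm with the larger amplitude,
  so the global maximum is the NADH peak), on top of a linear baseline,
  optionally multiplied by a hemoglobin-reabsorption dip near 420 nm, plus
  additive Gaussian noise.
* :func:`simulate_study` — a full factorial study (groups x animals x days
  x sites x replicates) whose per-animal-per-day collagen level is drawn
  from a group/day trajectory.  The bundled ``healing`` trajectory preset
  emulates the published wound-healing time course: un-wounded skin flat
  near 0.56, wounded groups starting near 0.31 at day 0 and rising, the
  laser-treated group rising faster and plateauing by day 30.
* :func:`simulate_histology` — a fiber image with known per-class (red /
  yellow / green) pixel fractions for validating the HSI scorer against a
  pixel-counting oracle.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .histology import ReferenceColor
from .metrics import collagen_intensity
from .preprocess import PreprocessConfig, preprocess
from .spectra import (
    DAYS,
    GROUPS,
    Spectrum,
    SpectrumMeta,
    StudyDataset,
    StudyDesign,
    write_spectrum,
)


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# spectra

DEFAULT_GRID = np.arange(320.0, 550.0 + 1e-9, 1.0)  # 1-nm step, 231 samples


@dataclass(frozen=True)
class SpectrumParams:
    """Generative parameters of one synthetic autofluorescence spectrum.

    Amplitudes are in arbitrary units; peak widths are Gaussian sigmas in
    nm.  The defaults put the noiseless normalized collagen intensity near
    the un-wounded-skin level (~0.56).  The hemoglobin dip defaults to off,
    matching in vivo spectra where reabsorption is weak.
    """

    collagen_center: float = 405.0
    collagen_sigma: float = 18.0
    nadh_center: float = 455.0
    nadh_sigma: float = 28.0
    collagen_amp: float = 0.36
    nadh_amp: float = 1.0
    baseline_slope: float = 0.0  # a.u. per nm
    baseline_offset: float = 0.0
    noise_sd: float = 0.0
    hb_dip_depth: float = 0.0  # fraction removed at 420 nm, in [0, 1]
    hb_dip_sigma: float = 10.0

    def __post_init__(self) -> None:
        if self.nadh_amp <= self.collagen_amp:
            raise SimulationError(
                "nadh_amp must exceed collagen_amp (NADH is the global maximum)"
            )
        if self.collagen_amp <= 0 or self.noise_sd < 0:
            raise SimulationError("amplitudes must be positive, noise_sd >= 0")
        if not 0.0 <= self.hb_dip_depth <= 1.0:
            raise SimulationError("hb_dip_depth must be in [0, 1]")


def _gauss(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def model_intensity(params: SpectrumParams, grid: np.ndarray) -> np.ndarray:
    """Noiseless model: (baseline + peaks) * (1 - hemoglobin dip)."""
    y = (
        params.baseline_offset
        + params.baseline_slope * (grid - grid[0])
        + params.collagen_amp * _gauss(grid, params.collagen_center, params.collagen_sigma)
        + params.nadh_amp * _gauss(grid, params.nadh_center, params.nadh_sigma)
    )
    if params.hb_dip_depth > 0:
        y = y * (1.0 - params.hb_dip_depth * _gauss(grid, 420.0, params.hb_dip_sigma))
    return y


def noiseless_collagen_intensity(
    params: SpectrumParams,
    grid: np.ndarray = DEFAULT_GRID,
    config: PreprocessConfig | None = None,
) -> float:
    """Ground-truth normalized 405 nm intensity of the noiseless spectrum,
    computed through the same preprocessing chain the pipeline applies."""
    spec = Spectrum(grid.copy(), model_intensity(params, grid))
    return collagen_intensity(preprocess(spec, config))


def _analytic_normalized_405(collagen_amp: float, template: SpectrumParams,
                             grid: np.ndarray) -> float:
    """Normalized 405 nm value of the noiseless model after two-point
    baseline removal (no smoothing) — the invertible map used to solve
    amplitudes for trajectory targets."""
    p = replace(template, collagen_amp=collagen_amp)
    y = model_intensity(p, grid)
    line = y[0] + (y[-1] - y[0]) * (grid - grid[0]) / (grid[-1] - grid[0])
    y = y - line
    i405 = int(np.argmin(np.abs(grid - 405.0)))
    return float(y[i405] / y.max())


#: Range of normalized collagen targets the two-Gaussian model can realize:
#: the NADH tail alone contributes ~0.20 at 405 nm, setting the floor.
TARGET_RANGE = (0.22, 0.92)


def amp_for_target(
    target: float, template: SpectrumParams | None = None,
    grid: np.ndarray = DEFAULT_GRID,
) -> float:
    """Solve the collagen amplitude whose noiseless normalized 405 nm
    intensity equals ``target`` (Brent's method on the analytic model)."""
    template = template or SpectrumParams()
    lo, hi = TARGET_RANGE
    if not lo <= target <= hi:
        raise SimulationError(f"target {target} outside realizable {TARGET_RANGE}")
    f = lambda a: _analytic_normalized_405(a, template, grid) - target
    amp = brentq(f, 1e-9, 0.999 * template.nadh_amp, xtol=1e-10)
    return float(amp)


def simulate_spectrum(
    params: SpectrumParams,
    seed: int | np.random.Generator,
    grid: np.ndarray = DEFAULT_GRID,
    meta: SpectrumMeta | None = None,
    config: PreprocessConfig | None = None,
) -> Spectrum:
    """One noisy spectrum; deterministic per seed.

    The returned spectrum carries ``ground_truth['collagen_intensity']``,
    the noiseless post-preprocessing normalized 405 nm value.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y = model_intensity(params, grid)
    if params.noise_sd > 0:
        y = y + rng.normal(0.0, params.noise_sd, size=len(grid))
    truth = {"collagen_intensity": noiseless_collagen_intensity(params, grid, config)}
    return Spectrum(grid.copy(), y, meta or SpectrumMeta(), ground_truth=truth)


# ---------------------------------------------------------------------------
# study-level trajectories

@dataclass(frozen=True)
class TrajectoryParams:
    """Per (group, day): target normalized collagen mean and between-animal sd."""

    means: dict = field(default_factory=dict)  # (group, day) -> mean
    sds: dict = field(default_factory=dict)  # (group, day) -> between-animal sd

    def __post_init__(self) -> None:
        for k, m in self.means.items():
            if not 0.0 < m < 1.0:
                raise SimulationError(f"trajectory mean {m} for {k} outside (0, 1)")


def healing_trajectory(n_per_group: int = 15) -> TrajectoryParams:
    """The default wound-healing time-course preset.

    Group/day means follow the published collagen-intensity table for
    un-wounded control, un-illuminated control and laser-treated animals on
    days 0-60; between-animal sds are back-computed from the printed SEMs
    (sd = SEM * sqrt(n)).  This is an emulation of the reported curve
    shapes, not a re-release of the data.
    """
    sq = math.sqrt(n_per_group)
    mean_sem = {
        "unwounded_control": {
            0: (0.5600, 0.0058), 5: (0.5614, 0.0026), 10: (0.5614, 0.0050),
            30: (0.5514, 0.0070), 45: (0.5589, 0.0040), 60: (0.5580, 0.0061),
        },
        "unilluminated_control": {
            0: (0.3200, 0.0299), 5: (0.4615, 0.0241), 10: (0.4890, 0.0148),
            30: (0.5042, 0.0081), 45: (0.5496, 0.0097), 60: (0.5491, 0.0066),
        },
        "laser_treated": {
            0: (0.3092, 0.0299), 5: (0.5404, 0.0120), 10: (0.5698, 0.0103),
            30: (0.5675, 0.0123), 45: (0.5596, 0.0124), 60: (0.5562, 0.0096),
        },
    }
    means, sds = {}, {}
    for g, by_day in mean_sem.items():
        for d, (m, sem) in by_day.items():
            means[(g, d)] = m
            sds[(g, d)] = sem * sq
    return TrajectoryParams(means=means, sds=sds)


def simulate_study(
    design: StudyDesign | None = None,
    traj: TrajectoryParams | None = None,
    seed: int = 0,
    noise_sd: float = 0.01,
    out_dir: str | Path | None = None,
    template: SpectrumParams | None = None,
) -> StudyDataset:
    """Generate a full factorial study of synthetic spectra.

    One collagen level is drawn per animal x day from the trajectory
    (clipped to the model's realizable range) and shared by that animal's
    16 replicates, which differ only by additive recording noise and a
    small per-site baseline offset.  With ``out_dir`` set, spectrum files
    and a ``manifest.csv`` are written there.
    """
    design = design or StudyDesign()
    traj = traj or healing_trajectory(design.animals_per_group)
    template = template or SpectrumParams()
    rng = np.random.default_rng(seed)
    grid = DEFAULT_GRID
    spectra: list[Spectrum] = []
    manifest_rows = []
    prefixes = {"unwounded_control": "uw", "unilluminated_control": "uc",
                "laser_treated": "lt"}
    for group in design.groups:
        prefix = prefixes.get(group, group[:3])
        for a in range(1, design.animals_per_group + 1):
            animal_id = f"{prefix}{a:02d}"
            for day in design.days:
                mean = traj.means[(group, day)]
                sd = traj.sds.get((group, day), 0.0)
                target = float(np.clip(rng.normal(mean, sd), *TARGET_RANGE))
                amp = amp_for_target(target, template, grid)
                params = replace(template, collagen_amp=amp, noise_sd=noise_sd)
                clean = model_intensity(params, grid)
                truth = {
                    "collagen_intensity": noiseless_collagen_intensity(params, grid),
                    "target": target,
                }
                for site in range(1, design.sites + 1):
                    site_offset = rng.normal(0.0, 0.2 * noise_sd)
                    for rep in range(1, design.replicates + 1):
                        y = clean + site_offset
                        if noise_sd > 0:
                            y = y + rng.normal(0.0, noise_sd, size=len(grid))
                        meta = SpectrumMeta(
                            animal_id=animal_id, group=group, day=day,
                            site=site, replicate=rep,
                        )
                        spectra.append(
                            Spectrum(grid.copy(), y, meta, ground_truth=truth)
                        )
    dataset = StudyDataset(spectra, design)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in dataset.spectra:
            m = s.meta
            name = f"{m.animal_id}_d{m.day:02d}_s{m.site}_r{m.replicate}.csv"
            write_spectrum(s, out_dir / name)
            manifest_rows.append(
                dict(file=name, animal_id=m.animal_id, group=m.group,
                     day=m.day, site=m.site, replicate=m.replicate)
            )
        pd.DataFrame(manifest_rows).to_csv(out_dir / "manifest.csv", index=False)
    return dataset


# ---------------------------------------------------------------------------
# histology images

#: Pure RGB anchors per fiber class; their HSI hues are exactly 0/60/120 deg.
CLASS_COLORS = {
    "red": (255, 0, 0),
    "yellow": (255, 255, 0),
    "green": (0, 255, 0),
}


@dataclass(frozen=True)
class ImageParams:
    """Layout of a synthetic Picro-Sirius-like fiber image."""

    width: int = 512
    height: int = 512
    background: tuple[int, int, int] = (0, 0, 0)
    class_fractions: tuple[tuple[str, float], ...] = (
        ("red", 0.10), ("yellow", 0.05), ("green", 0.03),
    )
    class_colors: tuple[tuple[str, tuple[int, int, int]], ...] = tuple(
        CLASS_COLORS.items()
    )
    thickness_range: tuple[int, int] = (3, 9)
    hue_jitter_sd: float = 0.0  # degrees, applied in HSV hue

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.class_fractions)
        if total > 1.0:
            raise SimulationError(f"class fractions sum to {total} > 1")
        if any(f < 0 for _, f in self.class_fractions):
            raise SimulationError("negative class fraction")

    def references(self, hue_tol: float = 20.0) -> tuple[ReferenceColor, ...]:
        """Reference colors anchored at this image's exact class colors."""
        colors = dict(self.class_colors)
        return tuple(
            ReferenceColor.from_rgb(name, colors[name], hue_tol=hue_tol)
            for name, _ in self.class_fractions
        )


@dataclass
class HistologySample:
    image: np.ndarray  # (H, W, 3) uint8
    fractions: dict  # class -> achieved pixel fraction (exact)
    params: ImageParams


def _segment_mask(h: int, w: int, p0, p1, thickness: float,
                  yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    """Boolean mask of pixels within thickness/2 of segment p0-p1."""
    (y0, x0), (y1, x1) = p0, p1
    dy, dx = y1 - y0, x1 - x0
    L2 = dy * dy + dx * dx
    if L2 == 0:
        d2 = (yy - y0) ** 2 + (xx - x0) ** 2
    else:
        t = np.clip(((yy - y0) * dy + (xx - x0) * dx) / L2, 0.0, 1.0)
        d2 = (yy - (y0 + t * dy)) ** 2 + (xx - (x0 + t * dx)) ** 2
    return d2 <= (thickness / 2.0) ** 2


def simulate_histology(params: ImageParams, seed: int = 0) -> HistologySample:
    """Paint hue-jittered fiber strokes per class onto the background.

    Strokes are random thick line segments; painting stops for a class the
    moment its target pixel count is reached (the final stroke is truncated
    pixel-by-pixel along its extent), so the achieved fraction matches the
    target to within one pixel.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    h, w = params.height, params.width
    total = h * w
    labels = np.full((h, w), -1, dtype=int)  # -1 background
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    class_list = list(params.class_fractions)
    for ci, (name, frac) in enumerate(class_list):
        target_px = int(round(frac * total))
        assigned = 0
        guard = 0
        while assigned < target_px:
            guard += 1
            if guard > 10000:
                raise SimulationError(
                    f"could not reach fraction {frac} for class {name!r}"
                )
            p0 = rng.uniform(0, h - 1), rng.uniform(0, w - 1)
            angle = rng.uniform(0, 2 * np.pi)
            length = rng.uniform(0.15, 0.5) * min(h, w)
            p1 = (p0[0] + length * np.sin(angle), p0[1] + length * np.cos(angle))
            thickness = rng.uniform(*params.thickness_range)
            mask = _segment_mask(h, w, p0, p1, thickness, yy, xx) & (labels == -1)
            n_new = int(mask.sum())
            if n_new == 0:
                continue
            if assigned + n_new > target_px:
                need = target_px - assigned
                idx = np.flatnonzero(mask.ravel())[:need]
                mask = np.zeros(total, dtype=bool)
                mask[idx] = True
                mask = mask.reshape(h, w)
                n_new = need
            labels[mask] = ci
            assigned += n_new
    image = np.empty((h, w, 3), dtype=np.uint8)
    image[...] = np.array(params.background, dtype=np.uint8)
    colors = dict(params.class_colors)
    for ci, (name, _) in enumerate(class_list):
        mask = labels == ci
        if not mask.any():
            continue
        if params.hue_jitter_sd > 0:
            image[mask] = _jitter_color(
                colors[name], int(mask.sum()), params.hue_jitter_sd, rng
            )
        else:
            image[mask] = np.array(colors[name], dtype=np.uint8)
    fractions = {
        name: float((labels == ci).sum()) / total
        for ci, (name, _) in enumerate(class_list)
    }
    return HistologySample(image=image, fractions=fractions, params=params)


def _jitter_color(rgb: tuple[int, int, int], n: int, sd_deg: float,
                  rng: np.random.Generator) -> np.ndarray:
    """n copies of rgb with Gaussian hue jitter (degrees) in HSV space."""
    from matplotlib.colors import hsv_to_rgb, rgb_to_hsv

    hsv = rgb_to_hsv(np.array(rgb, dtype=float) / 255.0)
    hues = (hsv[0] + rng.normal(0.0, sd_deg / 360.0, size=n)) % 1.0
    out = hsv_to_rgb(
        np.stack([hues, np.full(n, hsv[1]), np.full(n, hsv[2])], axis=-1)
    )
    return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)


def histology_targets() -> dict:
    """Total-collagen percentage targets per (group, day) for image runs.

    Emulates the published image-analysis time course: un-wounded skin flat
    near 15%, un-illuminated control rising from ~0.3% at day 5, laser
    group rising faster.  Split across classes following the qualitative
    fiber-color pattern (early green/yellow, later red).
    """
    totals = {
        "unwounded_control": {5: 15.33, 10: 14.77, 30: 16.21, 45: 15.01, 60: 16.18},
        "unilluminated_control": {5: 0.30, 10: 1.21, 30: 8.24, 45: 11.06, 60: 13.67},
        "laser_treated": {5: 1.76, 10: 7.16, 30: 14.28, 45: 15.88, 60: 14.98},
    }
    # class split (red, yellow, green) by healing stage
    split_by_day = {5: (0.1, 0.3, 0.6), 10: (0.3, 0.5, 0.2),
                    30: (0.5, 0.4, 0.1), 45: (0.7, 0.3, 0.0), 60: (0.8, 0.2, 0.0)}
    out = {}
    for g, by_day in totals.items():
        for d, tot in by_day.items():
            r, y, gr = split_by_day[d]
            if g == "unwounded_control":
                r, y, gr = 0.6, 0.4, 0.0
            out[(g, d)] = {
                "red": tot * r / 100.0,
                "yellow": tot * y / 100.0,
                "green": tot * gr / 100.0,
            }
    return out
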