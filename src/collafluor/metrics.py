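"""Collagen quantities from normalized spectra and their group summaries.

Two per-spectrum collagen metrics are used, both computed on an
NADH-normalized spectrum (global maximum = 1):

* ``collagen_intensity`` — the intensity read at the fixed wavelength
  405 nm, the collagen emission peak.  The wavelength is fixed rather than
  searched: a per-spectrum peak search would change the statistic.
* ``collagen_auc`` — the trapezoidal integral of the normalized intensity
  over the collagen band 350-405 nm.

Per-animal values (after two-stage replicate averaging) are summarized to
group/day mean +/- SEM, and treated-vs-control ratios are reported as fold
changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import NormalizedSpectrum
from .spectra import SpectrumMeta


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class CollagenMetrics:
    collagen_intensity: float
    collagen_auc: float
    meta: SpectrumMeta


@dataclass(frozen=True)
class GroupSummary:
    group: str
    day: int
    n: int
    mean: float
    sem: float
    metric_name: str


def collagen_intensity(nspec: NormalizedSpectrum, target_nm: float = 405.0) -> float:
    """Normalized intensity at the grid point nearest ``target_nm``.

    Ties between two equally near grid points resolve to the lower
    wavelength.
    """
    wl = nspec.wavelengths
    if target_nm < wl[0] or target_nm > wl[-1]:
        raise MetricError(
            f"target {target_nm} nm outside coverage {nspec.coverage}"
        )
    dist = np.abs(wl - target_nm)
    return float(nspec.intensities[int(np.argmin(dist))])


def collagen_auc(
    nspec: NormalizedSpectrum, lo: float = 350.0, hi: float = 405.0
) -> float:
    """Trapezoidal integral of normalized intensity over [lo, hi] nm.

    Band edges falling between grid points contribute linearly interpolated
    endpoint values, so the integral is exact for piecewise-linear signals
    regardless of edge alignment.
    """
    if lo >= hi:
        raise MetricError("band lo must be < hi")
    wl, y = nspec.wavelengths, nspec.intensities
    if lo < wl[0] or hi > wl[-1]:
        raise MetricError(f"band [{lo}, {hi}] outside coverage {nspec.coverage}")
    inside = (wl > lo) & (wl < hi)
    xs = np.concatenate(([lo], wl[inside], [hi]))
    ys = np.concatenate(
        ([np.interp(lo, wl, y)], y[inside], [np.interp(hi, wl, y)])
    )
    return float(np.trapezoid(ys, xs))


def compute_metrics(nspec: NormalizedSpectrum, target_nm: float = 405.0,
                    band: tuple[float, float] = (350.0, 405.0)) -> CollagenMetrics:
    return CollagenMetrics(
        collagen_intensity=collagen_intensity(nspec, target_nm),
        collagen_auc=collagen_auc(nspec, *band),
        meta=nspec.meta,
    )


def metrics_table(metrics: list[CollagenMetrics]) -> pd.DataFrame:
    """Tidy per-spectrum table: one row per metric value."""
    rows = []
    for m in metrics:
        base = dict(
            animal_id=m.meta.animal_id,
            group=m.meta.group,
            day=m.meta.day,
            site=m.meta.site,
            replicate=m.meta.replicate,
        )
        rows.append(dict(base, metric="intensity", value=m.collagen_intensity))
        rows.append(dict(base, metric="auc", value=m.collagen_auc))
    return pd.DataFrame(rows)


def summarize(
    metrics: list[CollagenMetrics] | pd.DataFrame,
    metric_name: str = "intensity",
) -> list[GroupSummary]:
    """Group/day mean and SEM, with the animal as the statistical unit.

    Accepts either CollagenMetrics (already one per animal per day after
    averaging) or a tidy table with columns animal_id, group, day, metric,
    value.  If several rows per animal remain they are averaged to one
    animal value first, so n always counts distinct animals.
    """
    table = metrics if isinstance(metrics, pd.DataFrame) else metrics_table(metrics)
    sub = table[table.metric == metric_name]
    if sub.empty:
        warnings.warn(f"no values for metric {metric_name!r}", stacklevel=2)
        return []
    per_animal = (
        sub.groupby(["group", "day", "animal_id"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    out = []
    for (group, day), cell in per_animal.groupby(["group", "day"], sort=True):
        vals = cell["value"].to_numpy()
        n = len(vals)
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out.append(
            GroupSummary(
                group=group, day=int(day), n=n,
                mean=float(vals.mean()), sem=sem, metric_name=metric_name,
            )
        )
    return out


def summary_table(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(group=s.group, day=s.day, n=s.n, metric=s.metric_name,
                 mean=s.mean, sem=s.sem)
            for s in summaries
        ]
    )


def fold_change(test_mean: float, control_mean: float, digits: int = 3) -> float:
    """Ratio of a treated-group mean to the control mean at the same day.

    Rounded to 3 decimals for spectral metrics and 2 for image percentage
    scores, mirroring the precision these quantities are conventionally
    reported at.
    """
    if control_mean <= 0:
        raise MetricError("fold change undefined for control mean <= 0")
    return round(test_mean / control_mean, digits)
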