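"""Group comparisons: pooled t-test, mixed repeated-measures ANOVA, Bonferroni.

The study design is 3 groups (between-subjects) x 6 post-wounding days
(within-subjects, every animal measured at every day).  The spectral
metrics are compared with a mixed two-factor ANOVA followed by per-day
treated-vs-control contrasts with a Bonferroni multiplier equal to the
number of days tested; image percentage scores use the unpaired two-tailed
Student's (pooled-variance) t-test.  Significance is labeled at the
conventional 0.05 / 0.01 / 0.001 thresholds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    adjusted_p: float | None = None
    label: str = "ns"

    @property
    def effective_p(self) -> float:
        return self.p_value if self.adjusted_p is None else self.adjusted_p


def significance_label(p: float) -> str:
    """Conventional label: thresholds 0.05 / 0.01 / 0.001, strict '<'."""
    if not 0.0 <= p <= 1.0:
        raise StatsError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "P<0.001"
    if p < 0.01:
        return "P<0.01"
    if p < 0.05:
        return "P<0.05"
    return "ns"


def bonferroni(p: float, m: int) -> float:
    """Adjusted p = min(1, m * p)."""
    if m < 1:
        raise StatsError("Bonferroni multiplier must be >= 1")
    return min(1.0, m * p)


def students_t_unpaired(a, b) -> TestResult:
    """Student's unpaired two-tailed t-test (pooled variance).

    Degenerate samples follow the documented conventions: zero pooled
    variance with equal means -> t=0, p=1; zero variance with unequal
    means -> p -> 0 limit, reported with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each sample needs n >= 2")
    na, nb = len(a), len(b)
    df = na + nb - 2
    pooled_var = (
        (na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)
    ) / df
    diff = a.mean() - b.mean()
    if pooled_var == 0.0:
        if diff == 0.0:
            t, p = 0.0, 1.0
        else:
            warnings.warn(
                "zero pooled variance with unequal means; p -> 0 limit",
                stacklevel=2,
            )
            t, p = math.copysign(math.inf, diff), 0.0
    else:
        t = diff / math.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
        p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p_value=float(p),
                      label=significance_label(p))


def rm_anova_bonferroni(
    table: pd.DataFrame,
    groups: tuple[str, str] | None = None,
    dv: str = "value",
) -> tuple[pd.DataFrame, dict[int, TestResult]]:
    """Mixed ANOVA (group between, day within) + Bonferroni per-day contrasts.

    ``table`` is tidy per-animal data with columns animal_id, group, day and
    the dependent variable ``dv`` — one value per animal per day.  Animals
    missing any day are dropped (complete-case) with a warning.  The per-day
    contrasts compare the two groups in ``groups`` (default: the last two in
    sorted order, i.e. treated vs un-illuminated control in the standard
    naming) with a pooled t-test; the Bonferroni multiplier is the number of
    days tested.  No sphericity correction is applied.

    Returns (anova_table, {day: TestResult}).
    """
    required = {"animal_id", "group", "day", dv}
    if not required <= set(table.columns):
        raise StatsError(f"table must have columns {sorted(required)}")
    days = sorted(table["day"].unique())
    if len(days) < 2 or table["group"].nunique() < 2:
        raise StatsError("need >= 2 groups and >= 2 days")
    # complete cases only
    counts = table.groupby("animal_id")["day"].nunique()
    complete = counts[counts == len(days)].index
    dropped = set(table["animal_id"]) - set(complete)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} incomplete animals: {sorted(dropped)[:5]}...",
            stacklevel=2,
        )
    data = table[table["animal_id"].isin(complete)].copy()
    for g, sub in data.groupby("group"):
        if sub["animal_id"].nunique() < 2:
            raise StatsError(f"group {g!r} has < 2 complete animals")

    if np.var(data[dv].to_numpy()) == 0.0:
        # degenerate: no variance anywhere -> F = 0 by convention
        aov = pd.DataFrame(
            {"Source": ["group", "day", "Interaction"],
             "F": [0.0, 0.0, 0.0], "p_unc": [1.0, 1.0, 1.0]}
        )
    else:
        import pingouin as pg  # deferred: heavy import

        aov = pg.mixed_anova(
            data=data, dv=dv, within="day", subject="animal_id", between="group"
        )
        if "p-unc" in aov.columns:  # older pingouin naming
            aov = aov.rename(columns={"p-unc": "p_unc"})

    if groups is None:
        gs = sorted(data["group"].unique())
        groups = (gs[-1], gs[-2]) if "laser_treated" not in gs else (
            "laser_treated",
            "unilluminated_control" if "unilluminated_control" in gs else gs[0],
        )
    m = len(days)
    contrasts: dict[int, TestResult] = {}
    for day in days:
        cell = data[data["day"] == day]
        a = cell[cell["group"] == groups[0]][dv].to_numpy()
        b = cell[cell["group"] == groups[1]][dv].to_numpy()
        raw = students_t_unpaired(a, b)
        adj = bonferroni(raw.p_value, m)
        contrasts[int(day)] = TestResult(
            statistic=raw.statistic, df=raw.df, p_value=raw.p_value,
            adjusted_p=adj, label=significance_label(adj),
        )
    return aov, contrasts


def contrasts_table(contrasts: dict[int, TestResult],
                    contrast_name: str = "laser_treated vs unilluminated_control"
                    ) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(day=day, contrast=contrast_name, statistic=r.statistic,
                 df=r.df, p=r.p_value, p_adj=r.adjusted_p, label=r.label)
            for day, r in sorted(contrasts.items())
        ]
    )
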