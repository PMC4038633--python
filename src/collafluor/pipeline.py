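"""End-to-end orchestration: spectra -> metrics -> statistics -> report.

Two entry points mirror the two measurement arms of the study:

* :func:`run_spectral_pipeline` — load (or receive) a study of raw
  spectra, apply two-stage replicate averaging (replicates within site,
  sites within animal), preprocess each animal/day spectrum, compute the
  collagen intensity and AUC metrics, summarize per group/day, run the
  mixed repeated-measures ANOVA with Bonferroni per-day contrasts, and
  report treated-vs-control fold changes.
* :func:`run_histology_pipeline` — score every Picro-Sirius red image
  against the reference colors, summarize total-collagen percentages per
  group/day, run per-day unpaired t-tests and fold changes.

Both are deterministic given data + config and write tidy CSV tables plus
a run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .histology import DEFAULT_REFERENCES, ReferenceColor, score_image_file
from .metrics import (
    compute_metrics,
    fold_change,
    metrics_table,
    summarize,
    summary_table,
)
from .preprocess import PreprocessConfig, preprocess
from .spectra import StudyDataset, average_study, load_study
from .stats import contrasts_table, rm_anova_bonferroni, students_t_unpaired, bonferroni, significance_label, TestResult

logger = logging.getLogger(__name__)

TEST_GROUP = "laser_treated"
CONTROL_GROUP = "unilluminated_control"


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    manifest: str | None = None
    image_manifest: str | None = None
    out_dir: str = "collafluor_out"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    metric_target_nm: float = 405.0
    metric_band: tuple[float, float] = (350.0, 405.0)
    references: tuple[ReferenceColor, ...] = DEFAULT_REFERENCES
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        pp = raw.get("preprocess", {})
        anchors = pp.get("baseline_anchors") or [None, None]
        ppcfg = PreprocessConfig(
            smoothing_fraction=pp.get("smoothing_fraction", 0.80),
            baseline_anchor_lo=anchors[0],
            baseline_anchor_hi=anchors[1],
            nadh_window=tuple(pp.get("nadh_window", (440.0, 470.0))),
        )
        refs = []
        for r in raw.get("histoquant", {}).get("references", []):
            refs.append(
                ReferenceColor(
                    name=r["name"], hue_center=r["hue_center"],
                    hue_tol=r.get("hue_tol", 20.0),
                    sat_min=r.get("sat_min", 0.2),
                    int_range=tuple(r.get("int_range", (0.05, 0.95))),
                )
            )
        band = raw.get("metrics", {}).get("band", (350.0, 405.0))
        return cls(
            manifest=raw.get("paths", {}).get("manifest"),
            image_manifest=raw.get("paths", {}).get("image_manifest"),
            out_dir=raw.get("paths", {}).get("out_dir", "collafluor_out"),
            preprocess=ppcfg,
            metric_target_nm=raw.get("metrics", {}).get("target_nm", 405.0),
            metric_band=tuple(band),
            references=tuple(refs) if refs else DEFAULT_REFERENCES,
            seed=raw.get("seed", 0),
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "paths": {
                "manifest": self.manifest,
                "image_manifest": self.image_manifest,
                "out_dir": self.out_dir,
            },
            "preprocess": {
                "smoothing_fraction": self.preprocess.smoothing_fraction,
                "baseline_anchors": [
                    self.preprocess.baseline_anchor_lo,
                    self.preprocess.baseline_anchor_hi,
                ],
                "nadh_window": list(self.preprocess.nadh_window),
            },
            "metrics": {
                "target_nm": self.metric_target_nm,
                "band": list(self.metric_band),
            },
            "histoquant": {
                "references": [
                    {
                        "name": r.name, "hue_center": r.hue_center,
                        "hue_tol": r.hue_tol, "sat_min": r.sat_min,
                        "int_range": list(r.int_range),
                    }
                    for r in self.references
                ]
            },
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def fold_table(
    summary: pd.DataFrame,
    test_group: str = TEST_GROUP,
    control_group: str = CONTROL_GROUP,
    digits: int = 3,
) -> pd.DataFrame:
    """Per-day fold change of the test-group mean over the control mean.

    ``summary`` is a tidy table with columns group, day, metric, mean (as
    produced by the pipeline, or assembled from published group means).
    """
    rows = []
    for metric, sub in summary.groupby("metric"):
        wide = sub.pivot_table(index="day", columns="group", values="mean")
        for day, row in wide.iterrows():
            if test_group in row and control_group in row:
                t, c = row[test_group], row[control_group]
                if pd.notna(t) and pd.notna(c) and c > 0:
                    rows.append(
                        dict(day=int(day), metric=metric,
                             test_mean=float(t), control_mean=float(c),
                             fold_change=fold_change(float(t), float(c), digits))
                    )
    return pd.DataFrame(rows).sort_values(["metric", "day"]).reset_index(drop=True)


def run_spectral_pipeline(
    config: RunConfig | None = None,
    dataset: StudyDataset | None = None,
    write: bool = True,
) -> dict[str, pd.DataFrame]:
    """Full spectral arm. Returns {summary, contrasts, folds, anova, per_animal}."""
    cfg = config or RunConfig()
    if dataset is None:
        if cfg.manifest is None:
            raise PipelineError("no dataset and no manifest configured")
        dataset = load_study(cfg.manifest)
    if len(dataset) == 0:
        raise PipelineError("empty study dataset")

    animal_spectra = average_study(dataset, level="animal")
    metrics = []
    nadh_warnings = []
    for spec in animal_spectra:
        try:
            nspec = preprocess(spec, cfg.preprocess)
        except Exception as exc:
            raise PipelineError(
                f"preprocessing failed for animal {spec.meta.animal_id} "
                f"day {spec.meta.day}: {exc}"
            ) from exc
        for w in nspec.warnings:
            nadh_warnings.append(f"{spec.meta.animal_id} d{spec.meta.day}: {w}")
        metrics.append(
            compute_metrics(nspec, cfg.metric_target_nm, cfg.metric_band)
        )
    per_animal = metrics_table(metrics)
    summaries = summarize(per_animal, "intensity") + summarize(per_animal, "auc")
    summary = summary_table(summaries)

    contrasts_frames = []
    anova_frames = []
    groups_present = set(per_animal.group)
    if {TEST_GROUP, CONTROL_GROUP} <= groups_present:
        for metric in ("intensity", "auc"):
            sub = per_animal[
                (per_animal.metric == metric)
                & per_animal.group.isin([TEST_GROUP, CONTROL_GROUP])
            ]
            aov, contrasts = rm_anova_bonferroni(
                sub, groups=(TEST_GROUP, CONTROL_GROUP)
            )
            ct = contrasts_table(contrasts)
            ct.insert(0, "metric", metric)
            contrasts_frames.append(ct)
            aov = aov.copy()
            aov.insert(0, "metric", metric)
            anova_frames.append(aov)
    contrasts_df = (
        pd.concat(contrasts_frames, ignore_index=True)
        if contrasts_frames else pd.DataFrame()
    )
    anova_df = (
        pd.concat(anova_frames, ignore_index=True)
        if anova_frames else pd.DataFrame()
    )
    folds = fold_table(summary) if len(summary) else pd.DataFrame()

    tables = {
        "summary": summary,
        "contrasts": contrasts_df,
        "anova": anova_df,
        "folds": folds,
        "per_animal": per_animal,
    }
    if write:
        _write_tables(cfg, tables, prefix="spectral", extra_log=nadh_warnings)
    return tables


def run_histology_pipeline(
    config: RunConfig | None = None,
    image_table: pd.DataFrame | None = None,
    write: bool = True,
) -> dict[str, pd.DataFrame]:
    """Full image arm.

    ``image_table`` needs columns image (path), group, day and optionally
    animal_id; when absent it is read from ``config.image_manifest``.
    Returns {scores, summary, contrasts, folds}.
    """
    cfg = config or RunConfig()
    if image_table is None:
        if cfg.image_manifest is None:
            raise PipelineError("no image table and no image manifest configured")
        mpath = Path(cfg.image_manifest)
        if not mpath.exists():
            raise PipelineError(f"image manifest not found: {mpath}")
        image_table = pd.read_csv(mpath)
        rel = image_table["image"].map(lambda p: str((mpath.parent / p)))
        image_table = image_table.assign(image=rel)
    if image_table.empty:
        raise PipelineError("no images listed")

    skipped = []
    rows = []
    for _, rec in image_table.iterrows():
        try:
            sc = score_image_file(rec["image"], cfg.references)
        except Exception as exc:  # unreadable image: skip with warning
            logger.warning("skipping unreadable image %s: %s", rec["image"], exc)
            skipped.append(str(rec["image"]))
            continue
        base = dict(image=str(rec["image"]), group=rec["group"], day=int(rec["day"]))
        if "animal_id" in image_table.columns:
            base["animal_id"] = rec["animal_id"]
        for cls in sc.pct_score:
            rows.append(
                dict(base, **{"class": cls}, score_sum=sc.score_sum[cls],
                     area_px=sc.area_px[cls], pct_score=sc.pct_score[cls],
                     total_collagen_pct=sc.total_collagen_pct)
            )
    scores = pd.DataFrame(rows)
    if scores.empty:
        raise PipelineError("all images failed to score")

    per_image = scores.drop_duplicates(subset=["image"])[
        [c for c in ("image", "group", "day", "animal_id", "total_collagen_pct")
         if c in scores.columns]
    ]
    summ_rows = []
    for (group, day), cell in per_image.groupby(["group", "day"], sort=True):
        vals = cell["total_collagen_pct"].to_numpy()
        n = len(vals)
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        summ_rows.append(
            dict(group=group, day=int(day), n=n, metric="total_collagen_pct",
                 mean=float(vals.mean()), sem=sem)
        )
    summary = pd.DataFrame(summ_rows)

    contrast_rows = []
    for day in sorted(per_image["day"].unique()):
        cell = per_image[per_image["day"] == day]
        a = cell[cell.group == TEST_GROUP]["total_collagen_pct"].to_numpy()
        b = cell[cell.group == CONTROL_GROUP]["total_collagen_pct"].to_numpy()
        if len(a) >= 2 and len(b) >= 2:
            r = students_t_unpaired(a, b)
            contrast_rows.append(
                dict(day=int(day), contrast=f"{TEST_GROUP} vs {CONTROL_GROUP}",
                     statistic=r.statistic, df=r.df, p=r.p_value,
                     p_adj=None, label=r.label)
            )
    contrasts = pd.DataFrame(contrast_rows)
    folds = fold_table(summary, digits=2) if len(summary) else pd.DataFrame()

    tables = {"scores": scores, "summary": summary,
              "contrasts": contrasts, "folds": folds}
    if write:
        _write_tables(cfg, tables, prefix="histo",
                      extra_log=[f"skipped: {p}" for p in skipped])
    return tables


def joint_report(spectral_summary: pd.DataFrame,
                 histo_summary: pd.DataFrame) -> pd.DataFrame:
    """Outer-merge the two arms by (group, day); no cell is dropped."""
    s = spectral_summary.rename(
        columns={"mean": "spectral_mean", "sem": "spectral_sem", "n": "spectral_n"}
    )
    h = histo_summary.rename(
        columns={"mean": "histo_mean", "sem": "histo_sem", "n": "histo_n"}
    )
    s = s[s.metric == "intensity"].drop(columns="metric")
    h = h.drop(columns="metric")
    return s.merge(h, on=["group", "day"], how="outer").sort_values(
        ["group", "day"]
    ).reset_index(drop=True)


def _write_tables(cfg: RunConfig, tables: dict[str, pd.DataFrame],
                  prefix: str, extra_log: list[str] | None = None) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{prefix}_{name}.csv", index=False)
    log = {
        "collafluor_version": __version__,
        "seed": cfg.seed,
        "preprocess": {
            "smoothing_fraction": cfg.preprocess.smoothing_fraction,
            "nadh_window": list(cfg.preprocess.nadh_window),
        },
        "metric_target_nm": cfg.metric_target_nm,
        "metric_band": list(cfg.metric_band),
        "notes": extra_log or [],
    }
    with open(out / f"{prefix}_run.log", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
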