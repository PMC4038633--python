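"""Spectrum containers, file I/O and replicate averaging.

An autofluorescence spectrum is a wavelength grid (nm) with intensities in
arbitrary units plus acquisition metadata identifying where in the study
design it was recorded (group, animal, post-wounding day, site on the wound,
replicate at that site).  The native file dialect is two-column delimited
text with a ``#``-prefixed metadata header; a study is described by a CSV
manifest pointing at one file per spectrum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("unwounded_control", "unilluminated_control", "laser_treated")
DAYS = (0, 5, 10, 30, 45, 60)
SITES = (1, 2, 3, 4)
REPLICATES = (1, 2, 3, 4)
SEXES = ("male", "female")

#: Wavelength coverage (nm) required by the downstream collagen/NADH metrics.
REQUIRED_COVERAGE = (350.0, 460.0)

MIN_GRID_LENGTH = 16

#: replicate/site value marking an averaged (aggregate) spectrum.
AGGREGATE = 0


class SpectrumError(ValueError):
    """Raised for malformed or inconsistent spectra / manifests."""


@dataclass(frozen=True)
class SpectrumMeta:
    """Acquisition metadata for one recorded spectrum.

    ``site`` and ``replicate`` use :data:`AGGREGATE` (0) to mark spectra
    produced by averaging over that level.
    """

    animal_id: str = "unknown"
    group: str = "unwounded_control"
    day: int = 0
    site: int = 1
    replicate: int = 1
    sex: str | None = None
    age_weeks: int | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SpectrumError(
                f"unknown group {self.group!r}; expected one of {GROUPS}"
            )
        if self.day not in DAYS:
            raise SpectrumError(f"day {self.day} not in study days {DAYS}")
        if self.site not in SITES and self.site != AGGREGATE:
            raise SpectrumError(f"site {self.site} outside 1-4")
        if self.replicate not in REPLICATES and self.replicate != AGGREGATE:
            raise SpectrumError(f"replicate {self.replicate} outside 1-4")
        if self.sex is not None and self.sex not in SEXES:
            raise SpectrumError(f"sex {self.sex!r} not in {SEXES}")
        if self.age_weeks is not None and self.age_weeks <= 0:
            raise SpectrumError("age_weeks must be positive")

    @property
    def key(self) -> tuple:
        return (self.animal_id, self.day, self.site, self.replicate)


@dataclass
class Spectrum:
    """A single spectrum: strictly increasing wavelength grid + intensities."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)
    #: simulator-attached ground truth (e.g. noiseless collagen intensity).
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.ndim != 1 or self.intensities.ndim != 1:
            raise SpectrumError("wavelengths and intensities must be 1-D")
        if len(self.wavelengths) != len(self.intensities):
            raise SpectrumError(
                f"length mismatch: {len(self.wavelengths)} wavelengths vs "
                f"{len(self.intensities)} intensities"
            )
        if len(self.wavelengths) < MIN_GRID_LENGTH:
            raise SpectrumError(
                f"grid too short ({len(self.wavelengths)} < {MIN_GRID_LENGTH})"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise SpectrumError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return len(self.wavelengths)

    @property
    def coverage(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavelengths[0] <= lo and self.wavelengths[-1] >= hi

    def validate(self) -> list[str]:
        """Return a list of data-quality warnings (empty when clean)."""
        issues: list[str] = []
        if np.any(self.intensities < 0):
            issues.append("negative intensities present")
        if not self.covers(*REQUIRED_COVERAGE):
            issues.append(
                f"coverage {self.coverage} misses required "
                f"{REQUIRED_COVERAGE} nm for collagen/NADH metrics"
            )
        return issues

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        steps = np.diff(self.wavelengths)
        return bool(np.all(np.abs(steps - steps[0]) <= rtol * steps[0]))


# ---------------------------------------------------------------------------
# file I/O

_META_FIELDS = ("animal_id", "group", "day", "site", "replicate", "sex", "age_weeks")
_DELIMS = {"csv": ",", "tsv": "\t", "two_column_text": None}


def read_spectrum(path: str | Path, dialect: str = "csv") -> Spectrum:
    """Read a two-column (wavelength_nm, intensity_au) spectrum file.

    Lines starting with ``#`` carry ``key = value`` metadata; a single
    non-numeric header row is tolerated.  Non-monotone wavelength rows are
    rejected rather than sorted, because out-of-order rows usually indicate
    a corrupted export rather than a permutation.
    """
    path = Path(path)
    if dialect not in _DELIMS:
        raise SpectrumError(f"unknown dialect {dialect!r}")
    delim = _DELIMS[dialect]
    meta_kv: dict[str, str] = {}
    wl: list[float] = []
    inten: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta_kv[k.strip()] = v.strip()
                continue
            parts = line.split(delim) if delim else line.split()
            parts = [p for p in (q.strip() for q in parts) if p]
            if len(parts) < 2:
                raise SpectrumError(f"{path}:{lineno}: expected >=2 columns")
            try:
                w, x = float(parts[0]), float(parts[1])
            except ValueError:
                if not wl and lineno <= len(meta_kv) + 1:
                    continue  # single header row
                raise SpectrumError(
                    f"{path}:{lineno}: malformed numeric row {line!r}"
                ) from None
            wl.append(w)
            inten.append(x)
    meta = _meta_from_strings(meta_kv) if meta_kv else SpectrumMeta()
    try:
        return Spectrum(np.array(wl), np.array(inten), meta)
    except SpectrumError as exc:
        raise SpectrumError(f"{path}: {exc}") from None


def write_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a spectrum as two-column CSV with a ``#`` metadata header.

    Values are printed with 9 significant digits, lossless well beyond the
    6-significant-digit round-trip contract.
    """
    path = Path(path)
    m = spectrum.meta
    with open(path, "w") as fh:
        for name in _META_FIELDS:
            value = getattr(m, name)
            if value is not None:
                fh.write(f"# {name} = {value}\n")
        fh.write("# wavelength_nm,intensity_au\n")
        for w, x in zip(spectrum.wavelengths, spectrum.intensities):
            fh.write(f"{w:.9g},{x:.9g}\n")
    return path


def _meta_from_strings(kv: dict[str, str]) -> SpectrumMeta:
    def _opt_int(v: str | None) -> int | None:
        return None if v in (None, "", "None") else int(v)

    return SpectrumMeta(
        animal_id=kv.get("animal_id", "unknown"),
        group=kv.get("group", "unwounded_control"),
        day=int(kv.get("day", 0)),
        site=int(kv.get("site", 1)),
        replicate=int(kv.get("replicate", 1)),
        sex=kv.get("sex") if kv.get("sex") not in (None, "", "None") else None,
        age_weeks=_opt_int(kv.get("age_weeks")),
    )


# ---------------------------------------------------------------------------
# study-level organization

@dataclass(frozen=True)
class StudyDesign:
    """The factorial layout group x animal x day x site x replicate."""

    groups: tuple[str, ...] = GROUPS
    animals_per_group: int = 15
    days: tuple[int, ...] = DAYS
    sites: int = 4
    replicates: int = 4

    @property
    def n_spectra(self) -> int:
        return (
            len(self.groups)
            * self.animals_per_group
            * len(self.days)
            * self.sites
            * self.replicates
        )

    @property
    def spectra_per_animal_day(self) -> int:
        return self.sites * self.replicates


@dataclass
class StudyDataset:
    """All spectra of a study plus the design they are expected to fill."""

    spectra: list[Spectrum]
    design: StudyDesign = field(default_factory=StudyDesign)

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for s in self.spectra:
            k = s.meta.key
            if k in seen:
                raise SpectrumError(f"duplicate (animal, day, site, replicate) {k}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.spectra)

    def cell_counts(self) -> pd.DataFrame:
        """Spectrum counts per (group, day) with the expected count."""
        rows = [
            {"group": s.meta.group, "day": s.meta.day} for s in self.spectra
        ]
        expected = (
            self.design.animals_per_group
            * self.design.sites
            * self.design.replicates
        )
        idx = pd.MultiIndex.from_product(
            [self.design.groups, self.design.days], names=["group", "day"]
        )
        if rows:
            counts = (
                pd.DataFrame(rows).value_counts(["group", "day"]).reindex(idx)
            ).fillna(0).astype(int)
        else:
            counts = pd.Series(0, index=idx, dtype=int)
        out = counts.rename("n_spectra").reset_index()
        out["n_expected"] = expected
        return out

    def missing_cells(self) -> pd.DataFrame:
        cc = self.cell_counts()
        return cc[cc.n_spectra < cc.n_expected].reset_index(drop=True)

    def groupby_animal_day(self) -> dict[tuple, list[Spectrum]]:
        out: dict[tuple, list[Spectrum]] = {}
        for s in self.spectra:
            out.setdefault((s.meta.group, s.meta.animal_id, s.meta.day), []).append(s)
        return out


MANIFEST_COLUMNS = ("file", "animal_id", "group", "day", "site", "replicate")


def load_study(
    manifest: str | Path, design: StudyDesign | None = None
) -> StudyDataset:
    """Load every spectrum listed in a manifest CSV into a StudyDataset.

    The manifest must carry the columns ``file, animal_id, group, day, site,
    replicate`` (optionally ``sex, age_weeks``); ``file`` paths are resolved
    relative to the manifest's directory.  Metadata in the manifest overrides
    any header metadata in the spectrum files.
    """
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    missing = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing:
        raise SpectrumError(f"manifest missing columns {sorted(missing)}")
    if table.empty:
        warnings.warn(f"empty manifest {manifest}", stacklevel=2)
        return StudyDataset([], design or StudyDesign())
    spectra = []
    for _, row in table.iterrows():
        meta = SpectrumMeta(
            animal_id=str(row["animal_id"]),
            group=str(row["group"]),
            day=int(row["day"]),
            site=int(row["site"]),
            replicate=int(row["replicate"]),
            sex=(str(row["sex"]) if "sex" in table.columns and pd.notna(row.get("sex")) else None),
            age_weeks=(
                int(row["age_weeks"])
                if "age_weeks" in table.columns and pd.notna(row.get("age_weeks"))
                else None
            ),
        )
        fpath = Path(row["file"])
        if not fpath.is_absolute():
            fpath = manifest.parent / fpath
        spec = read_spectrum(fpath)
        spec.meta = meta
        spectra.append(spec)
    dataset = StudyDataset(spectra, design or StudyDesign())
    n_missing = len(dataset.missing_cells())
    if n_missing:
        logger.info("study has %d incomplete (group, day) cells", n_missing)
    return dataset


# ---------------------------------------------------------------------------
# averaging

def _common_meta(metas: Sequence[SpectrumMeta], level: str) -> SpectrumMeta:
    first = metas[0]
    kwargs = dict(
        animal_id=first.animal_id,
        group=first.group,
        day=first.day,
        site=first.site,
        replicate=AGGREGATE,
        sex=first.sex if all(m.sex == first.sex for m in metas) else None,
        age_weeks=first.age_weeks
        if all(m.age_weeks == first.age_weeks for m in metas)
        else None,
    )
    if level == "animal" or any(m.site != first.site for m in metas):
        kwargs["site"] = AGGREGATE
    return SpectrumMeta(**kwargs)


def average_replicates(spectra: Sequence[Spectrum], level: str = "site") -> Spectrum:
    """Pointwise arithmetic mean of spectra sharing an identical grid.

    Grids must match exactly; averaging across different grids silently
    mixed by interpolation could bias peak metrics, so resample explicitly
    with :func:`resample` first if needed.
    """
    if not spectra:
        raise SpectrumError("cannot average zero spectra")
    grid = spectra[0].wavelengths
    for s in spectra[1:]:
        if len(s.wavelengths) != len(grid) or not np.array_equal(s.wavelengths, grid):
            raise SpectrumError("wavelength grids differ; resample explicitly first")
    mean = np.mean([s.intensities for s in spectra], axis=0)
    return Spectrum(grid.copy(), mean, _common_meta([s.meta for s in spectra], level))


def average_study(dataset: StudyDataset, level: str = "animal") -> list[Spectrum]:
    """Two-stage averaging: replicates within site, then sites within animal.

    With ``level='site'`` only the first stage is applied (one spectrum per
    animal/day/site); with ``level='animal'`` the site averages are averaged
    again so the animal is the statistical unit.
    """
    if level not in ("site", "animal"):
        raise SpectrumError(f"unknown averaging level {level!r}")
    by_site: dict[tuple, list[Spectrum]] = {}
    for s in dataset.spectra:
        m = s.meta
        by_site.setdefault((m.group, m.animal_id, m.day, m.site), []).append(s)
    site_means = [average_replicates(v, level="site") for v in by_site.values()]
    if level == "site":
        return site_means
    by_animal: dict[tuple, list[Spectrum]] = {}
    for s in site_means:
        m = s.meta
        by_animal.setdefault((m.group, m.animal_id, m.day), []).append(s)
    return [average_replicates(v, level="animal") for v in by_animal.values()]


def resample(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear-interpolation resampling onto a new grid (opt-in utility)."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = spectrum.coverage
    if grid[0] < lo or grid[-1] > hi:
        raise SpectrumError("target grid extends beyond spectrum coverage")
    new = np.interp(grid, spectrum.wavelengths, spectrum.intensities)
    return Spectrum(grid, new, spectrum.meta)
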