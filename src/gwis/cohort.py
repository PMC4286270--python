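"""Derivation of analysis-ready variables from raw cohort inputs.

This module turns raw tables — two-visit spirometry, residential histories,
an annual exposure grid, and covariates — into the quantities the interaction
scan consumes: the annual lung-function decline outcome, residence-weighted
cumulative exposure, seasonal terms, and the regression design matrix for the
various covariate-adjustment variants.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Period (days) of the seasonal sine/cosine terms.  Any annual period is
#: equivalent up to reparameterization of the two coefficients.
SEASON_PERIOD_DAYS = 365.25


class HistoryError(ValueError):
    """Residential history violates its contract (gap, overlap, bad span)."""


class GridLookupError(LookupError):
    """A referenced (cell, year) combination is absent from the exposure grid."""


@dataclass(frozen=True)
class ResidencePeriod:
    """One residence spell, half-open in days: [start, end)."""

    subject_id: str
    start: datetime.date
    end: datetime.date
    cell: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise HistoryError(
                f"residence period for {self.subject_id} has start >= end "
                f"({self.start} >= {self.end})"
            )


class ExposureGrid:
    """Annual mean exposure (μg/m³) per grid cell per calendar year.

    Internally a dense (n_cells, n_years) array over a contiguous year range;
    convertible to/from a long-format table with columns ``cell``, ``year``,
    ``mean``.
    """

    def __init__(self, values: np.ndarray, cells: Sequence[str], years: Sequence[int]):
        values = np.asarray(values, dtype=float)
        years = np.asarray(years, dtype=int)
        if values.shape != (len(cells), len(years)):
            raise ValueError("grid values shape must be (n_cells, n_years)")
        if len(years) == 0 or np.any(np.diff(years) != 1):
            raise ValueError("grid years must be a non-empty contiguous range")
        if np.any(values < 0):
            raise ValueError("grid exposure means must be non-negative")
        self.values = values
        self.cells = list(cells)
        self.years = years
        self._cell_index = {c: i for i, c in enumerate(self.cells)}

    @property
    def year_start(self) -> int:
        return int(self.years[0])

    def cell_idx(self, cell: str) -> int:
        try:
            return self._cell_index[cell]
        except KeyError:
            raise GridLookupError(f"unknown grid cell {cell!r}") from None

    def mean(self, cell: str, year: int) -> float:
        """Annual mean for one cell-year; raises GridLookupError if absent."""
        ci = self.cell_idx(cell)
        yi = year - self.year_start
        if yi < 0 or yi >= len(self.years):
            raise GridLookupError(f"year {year} not covered by exposure grid")
        return float(self.values[ci, yi])

    def to_frame(self) -> pd.DataFrame:
        cells = np.repeat(self.cells, len(self.years))
        years = np.tile(self.years, len(self.cells))
        return pd.DataFrame(
            {"cell": cells, "year": years, "mean": self.values.ravel()}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExposureGrid":
        piv = frame.pivot(index="cell", columns="year", values="mean").sort_index()
        years = np.sort(piv.columns.to_numpy(dtype=int))
        return cls(piv[years].to_numpy(dtype=float), list(piv.index), years)


def season_terms(exam_day: float) -> tuple[float, float]:
    """Seasonal (sine, cosine) pair for a day-of-year in [0, 366)."""
    if not (0 <= exam_day < 366):
        raise ValueError(f"exam_day must be in [0, 366), got {exam_day}")
    angle = 2.0 * math.pi * exam_day / SEASON_PERIOD_DAYS
    return math.sin(angle), math.cos(angle)


def annual_decline(
    baseline_value: float, followup_value: float, followup_years: float
) -> float:
    """Annual change (mL/sec per year); negative values mean decline."""
    if followup_years <= 0:
        raise ValueError(f"followup_years must be positive, got {followup_years}")
    return (followup_value - baseline_value) / followup_years


def _validate_contiguous(periods: list[ResidencePeriod]) -> None:
    for prev, nxt in zip(periods, periods[1:]):
        if nxt.start < prev.end:
            raise HistoryError(
                f"overlapping residence periods for {prev.subject_id}: "
                f"{prev.end} > {nxt.start}"
            )
        if nxt.start > prev.end:
            raise HistoryError(
                f"gap in residence history for {prev.subject_id}: "
                f"{prev.end} .. {nxt.start}"
            )


def cumulative_exposure(
    history: Iterable[ResidencePeriod], grid: ExposureGrid
) -> float:
    """Residence-weighted sum of annual grid means over the follow-up window.

    Each calendar year contributes the day-weighted average of the annual cell
    means of that year's residences, with weights = days resided / days in the
    calendar year.  A year fully spent in one cell therefore contributes
    exactly that cell-year's mean; partial years at the window edges contribute
    proportionally.
    """
    periods = sorted(history, key=lambda p: p.start)
    if not periods:
        raise HistoryError("empty residence history")
    _validate_contiguous(periods)
    total = 0.0
    for p in periods:
        s, e = p.start.toordinal(), p.end.toordinal()
        year = p.start.year
        while True:
            ys = datetime.date(year, 1, 1).toordinal()
            ye = datetime.date(year + 1, 1, 1).toordinal()
            overlap = min(e, ye) - max(s, ys)
            if overlap > 0:
                total += overlap / (ye - ys) * grid.mean(p.cell, year)
            if ye >= e:
                break
            year += 1
    return total


def assign_cumulative_exposure(
    history: pd.DataFrame, grid: ExposureGrid
) -> pd.Series:
    """Vectorized cumulative exposure for a whole cohort.

    ``history`` holds one row per residence period with columns ``subject_id``,
    ``start_date``, ``end_date`` (datetime.date or ISO strings), ``cell``.
    Returns a Series indexed by subject_id, in order of first appearance.
    Agrees with :func:`cumulative_exposure` applied per subject.
    """
    subj = history["subject_id"].to_numpy()
    subjects = pd.unique(subj)
    sidx = pd.Series(np.arange(len(subjects)), index=subjects)[subj].to_numpy()

    def _ord(col: pd.Series) -> np.ndarray:
        return np.array(
            [pd.Timestamp(v).date().toordinal() for v in col], dtype=np.int64
        )

    start = _ord(history["start_date"])
    end = _ord(history["end_date"])
    if np.any(start >= end):
        raise HistoryError("residence period with start >= end")
    order = np.lexsort((start, sidx))
    same = sidx[order][1:] == sidx[order][:-1]
    prev_end, nxt_start = end[order][:-1], start[order][1:]
    if np.any(same & (nxt_start < prev_end)):
        raise HistoryError("overlapping residence periods")
    if np.any(same & (nxt_start > prev_end)):
        raise HistoryError("gap in residence history")

    cell_idx = np.array([grid.cell_idx(c) for c in history["cell"]])
    y_lo = datetime.date.fromordinal(int(start.min())).year
    y_hi = datetime.date.fromordinal(int(end.max()) - 1).year
    if y_lo < grid.year_start or y_hi > int(grid.years[-1]):
        raise GridLookupError(
            f"history years {y_lo}..{y_hi} exceed grid coverage "
            f"{grid.year_start}..{int(grid.years[-1])}"
        )
    out = np.zeros(len(subjects))
    for year in range(y_lo, y_hi + 1):
        ys = datetime.date(year, 1, 1).toordinal()
        ye = datetime.date(year + 1, 1, 1).toordinal()
        days = np.clip(np.minimum(end, ye) - np.maximum(start, ys), 0, None)
        if not days.any():
            continue
        w = days / (ye - ys)
        np.add.at(out, sidx, w * grid.values[cell_idx, year - grid.year_start])
    return pd.Series(out, index=pd.Index(subjects, name="subject_id"))


# ---------------------------------------------------------------------------
# Design matrix construction
# ---------------------------------------------------------------------------

#: Covariate-adjustment variants.  "full" is the discovery adjustment set;
#: the others mirror the replication sensitivity models (added or omitted
#: covariates relative to "full"), and "minimal" keeps only center, age, sex.
MODEL_VARIANTS = (
    "full",
    "smoking_history",
    "age_squared",
    "no_smoking_status",
    "no_weight_interaction",
    "no_weight_change",
    "no_weight_baseline",
    "minimal",
)

_BASE_REQUIRED = (
    "center",
    "age",
    "sex",
    "height",
    "never_smoker",
    "exam_day_baseline",
    "exam_day_followup",
    "weight_baseline",
    "weight_change",
    "cumulative_exposure",
)


def _require(cohort: pd.DataFrame, columns: Iterable[str]) -> None:
    for col in columns:
        if col not in cohort.columns:
            raise ValueError(f"cohort table is missing required column '{col}'")
        if cohort[col].isna().any():
            raise ValueError(f"missing values in required column '{col}'")


def build_design(
    cohort: pd.DataFrame,
    dosage: np.ndarray | None = None,
    model_variant: str = "full",
    extra_covariates: Sequence[str] = (),
    season: str = "both",
) -> tuple[np.ndarray, list[str]]:
    """Regression design for one SNP under a covariate-adjustment variant.

    Returns ``(X, names)``.  With ``dosage=None`` the SNP and SNP×exposure
    columns are omitted (the covariate-only block used for pre-factorization
    and for stratified exposure-slope models).  ``extra_covariates`` names
    numeric cohort columns entered as-is (e.g. population-stratification
    components or a pooled-sample indicator); they are ignored by "minimal".
    ``season`` is "both" (baseline and follow-up examination dates) or
    "baseline".
    """
    if model_variant not in MODEL_VARIANTS:
        raise ValueError(
            f"unknown model variant {model_variant!r}; expected one of {MODEL_VARIANTS}"
        )
    if season not in ("both", "baseline"):
        raise ValueError("season must be 'both' or 'baseline'")

    minimal = model_variant == "minimal"
    required = ["center", "age", "sex", "cumulative_exposure"]
    if not minimal:
        required = list(_BASE_REQUIRED)
        if model_variant == "smoking_history":
            required += ["pack_years_baseline", "pack_years_followup"]
        required += list(extra_covariates)
    _require(cohort, required)

    n = len(cohort)
    cols: list[tuple[str, np.ndarray]] = [("intercept", np.ones(n))]

    centers = sorted(pd.unique(cohort["center"].astype(str)))
    for lab in centers[1:]:  # reference = lexicographically first label
        cols.append((f"center_{lab}", (cohort["center"].astype(str) == lab).to_numpy(float)))

    cols.append(("age", cohort["age"].to_numpy(float)))
    if model_variant == "age_squared":
        cols.append(("age_squared", cohort["age"].to_numpy(float) ** 2))
    cols.append(("sex", cohort["sex"].to_numpy(float)))

    if not minimal:
        cols.append(("height", cohort["height"].to_numpy(float)))
        if model_variant != "no_smoking_status":
            cols.append(("never_smoker", cohort["never_smoker"].to_numpy(float)))
        if model_variant == "smoking_history":
            cols.append(("pack_years_baseline", cohort["pack_years_baseline"].to_numpy(float)))
            cols.append(("pack_years_followup", cohort["pack_years_followup"].to_numpy(float)))
        exam_cols = ["exam_day_baseline"] + (
            ["exam_day_followup"] if season == "both" else []
        )
        for ec in exam_cols:
            tag = ec.replace("exam_day_", "")
            terms = np.array([season_terms(d) for d in cohort[ec].to_numpy(float)])
            cols.append((f"sin_day_{tag}", terms[:, 0]))
            cols.append((f"cos_day_{tag}", terms[:, 1]))
        wb = cohort["weight_baseline"].to_numpy(float)
        wc = cohort["weight_change"].to_numpy(float)
        if model_variant != "no_weight_baseline":
            cols.append(("weight_baseline", wb))
        if model_variant not in ("no_weight_change",):
            cols.append(("weight_change", wc))
        if model_variant not in (
            "no_weight_interaction",
            "no_weight_change",
            "no_weight_baseline",
        ):
            cols.append(("weight_baseline_x_change", wb * wc))
        for name in extra_covariates:
            cols.append((name, cohort[name].to_numpy(float)))

    exposure = cohort["cumulative_exposure"].to_numpy(float)
    cols.append(("cumulative_exposure", exposure))

    if dosage is not None:
        d = np.asarray(dosage, dtype=float)
        if d.shape != (n,):
            raise ValueError(f"dosage length {d.shape} does not match cohort size {n}")
        cols.append(("dosage", d))
        cols.append(("dosage_x_exposure", d * exposure))

    names = [c[0] for c in cols]
    X = np.column_stack([c[1] for c in cols])
    return X, names
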