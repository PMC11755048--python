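"""Cohort-level fetal-fraction analytics.

Summaries of the FF distribution, comparison of the low-FF (< 5%) group
against samples near the cohort median, mean FF per gestational-week bin,
per-stratum ordinary-least-squares regression of FF on maternal weight, and
inverse prediction of the maternal weight at which the fitted line crosses a
target FF (5% by default — the detection-limit-relevant threshold).

FF is handled in *percent* throughout this module, matching how the
quantities are reported clinically; ``SampleRecord.ff`` fractions are
converted on entry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .synthetic import SampleRecord

__all__ = [
    "FFSummary",
    "GroupComparison",
    "RegressionFit",
    "DEFAULT_GA_STRATA",
    "summarize_ff",
    "compare_low_ff_group",
    "ga_trend",
    "weight_ff_regression",
    "weight_at_ff",
    "nonpregnant_correlations",
]

# Gestational-age strata (weeks, half-open) used for the weight-FF regressions.
DEFAULT_GA_STRATA: tuple[tuple[float, float], ...] = (
    (12.0, 20.0),
    (20.0, 23.0),
    (23.0, math.inf),
)


@dataclass(frozen=True)
class FFSummary:
    n: int
    median_ff_pct: float
    threshold_pct: float
    n_below: int

    @property
    def pct_below(self) -> float:
        return 100.0 * self.n_below / self.n


def summarize_ff(records: Sequence[SampleRecord], threshold: float = 0.05) -> FFSummary:
    """Median FF and the share of samples below ``threshold`` (fraction units in,
    percent units out), with the raw counts."""
    if not records:
        raise ConfigurationError("empty cohort")
    ffs = np.array([r.ff for r in records])
    return FFSummary(
        n=len(records),
        median_ff_pct=float(np.median(ffs)) * 100.0,
        threshold_pct=threshold * 100.0,
        n_below=int(np.sum(ffs < threshold)),
    )


@dataclass(frozen=True)
class GroupComparison:
    """Unpaired t-test of one covariate between the low-FF group and the
    near-median group."""

    variable: str
    mean_low_ff: float
    mean_near_median: float
    n_low_ff: int
    n_near_median: int
    t_statistic: float
    p_value: float

    @property
    def significance_mark(self) -> str:
        if self.p_value < 0.0001:
            return "****"
        if self.p_value < 0.05:
            return "*"
        return "ns"


_COMPARED_VARIABLES = {
    "gestational_age": "gestational_age_weeks",
    "maternal_age": "maternal_age_years",
    "maternal_weight": "maternal_weight_kg",
}


def compare_low_ff_group(
    records: Sequence[SampleRecord],
    threshold: float = 0.05,
    median_window: float = 0.01,
    equal_var: bool = False,
) -> list[GroupComparison]:
    """Compare GA, maternal age and weight between FF < threshold and FF within
    ``median_window`` of the cohort median.

    Welch's t-test by default (``equal_var=True`` switches to the pooled-
    variance test). Both groups need >= 2 members.
    """
    ffs = np.array([r.ff for r in records])
    if ffs.size == 0:
        raise ConfigurationError("empty cohort")
    median = float(np.median(ffs))
    low_idx = ffs < threshold
    near_idx = np.abs(ffs - median) <= median_window
    if low_idx.sum() < 2 or near_idx.sum() < 2:
        raise ConfigurationError(
            f"degenerate groups: {int(low_idx.sum())} low-FF, {int(near_idx.sum())} near-median"
        )
    out = []
    for name, attr in _COMPARED_VARIABLES.items():
        values = np.array([getattr(r, attr) for r in records])
        low, near = values[low_idx], values[near_idx]
        t, p = stats.ttest_ind(low, near, equal_var=equal_var)
        out.append(
            GroupComparison(
                variable=name,
                mean_low_ff=float(low.mean()),
                mean_near_median=float(near.mean()),
                n_low_ff=int(low.size),
                n_near_median=int(near.size),
                t_statistic=float(t),
                p_value=float(p),
            )
        )
    return out


def ga_trend(
    records: Sequence[SampleRecord],
    week_edges: Sequence[float] = (12.0, 20.0, 23.0, math.inf),
) -> pd.DataFrame:
    """Mean/SD FF (%) per gestational-week bin (half-open [lo, hi) intervals).

    Empty bins are reported with n = 0 and NaN statistics, not dropped.
    """
    if len(week_edges) < 2:
        raise ConfigurationError("need at least two bin edges")
    edges = list(week_edges)
    if edges != sorted(edges):
        raise ConfigurationError("bin edges must be increasing")
    ga = np.array([r.gestational_age_weeks for r in records])
    ff_pct = np.array([r.ff for r in records]) * 100.0
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (ga >= lo) & (ga < hi)
        n = int(mask.sum())
        rows.append(
            {
                "ga_lo_weeks": lo,
                "ga_hi_weeks": hi,
                "n": n,
                "mean_ff_pct": float(ff_pct[mask].mean()) if n else float("nan"),
                "sd_ff_pct": float(ff_pct[mask].std(ddof=1)) if n > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of FF (%) on maternal weight (kg) within one GA stratum."""

    ga_lo_weeks: float
    ga_hi_weeks: float
    intercept_pct: float
    slope_pct_per_kg: float
    pearson_r: float
    p_value: float
    n: int
    residual_sd_pct: float
    weight_min_kg: float
    weight_max_kg: float

    def predict_ff_pct(self, weight_kg: float) -> float:
        return self.intercept_pct + self.slope_pct_per_kg * weight_kg


def weight_ff_regression(
    records: Sequence[SampleRecord],
    stratum: tuple[float, float] = (12.0, 20.0),
) -> RegressionFit:
    """Least-squares line FF(%) = a + b * weight within a GA stratum, with
    Pearson correlation attached."""
    lo, hi = stratum
    sub = [r for r in records if lo <= r.gestational_age_weeks < hi]
    if len(sub) < 3:
        raise ConfigurationError(f"stratum [{lo}, {hi}) has fewer than 3 samples")
    w = np.array([r.maternal_weight_kg for r in sub])
    ff_pct = np.array([r.ff for r in sub]) * 100.0
    if np.ptp(w) == 0:
        raise ConfigurationError("all weights identical; regression undefined")
    res = stats.linregress(w, ff_pct)
    resid = ff_pct - (res.intercept + res.slope * w)
    dof = max(len(sub) - 2, 1)
    return RegressionFit(
        ga_lo_weeks=lo,
        ga_hi_weeks=hi,
        intercept_pct=float(res.intercept),
        slope_pct_per_kg=float(res.slope),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=len(sub),
        residual_sd_pct=float(np.sqrt(np.sum(resid**2) / dof)),
        weight_min_kg=float(w.min()),
        weight_max_kg=float(w.max()),
    )


def weight_at_ff(fit: RegressionFit, target_ff: float = 0.05) -> float:
    """Maternal weight at which the fitted line crosses ``target_ff``.

    Inverse prediction: weight = (target% - intercept) / slope. Warns when the
    crossing lies outside the observed weight range (extrapolation) or the
    slope is positive (direction inconsistent with the expected negative
    weight-FF relationship).
    """
    if fit.slope_pct_per_kg == 0:
        raise ConfigurationError("zero slope: no finite crossing weight")
    target_pct = target_ff * 100.0
    weight = (target_pct - fit.intercept_pct) / fit.slope_pct_per_kg
    if fit.slope_pct_per_kg > 0:
        warnings.warn(
            "positive weight-FF slope; crossing computed but direction is "
            "inconsistent with the expected negative correlation",
            stacklevel=2,
        )
    if not fit.weight_min_kg <= weight <= fit.weight_max_kg:
        warnings.warn(
            f"crossing weight {weight:.1f} kg lies outside the observed range "
            f"[{fit.weight_min_kg:.1f}, {fit.weight_max_kg:.1f}] kg (extrapolation)",
            stacklevel=2,
        )
    return weight


def nonpregnant_correlations(
    frame: pd.DataFrame,
    response: str = "cfdna_ng_ml",
    covariates: Iterable[str] = (
        "age_years",
        "height_cm",
        "weight_kg",
        "bmi",
        "body_fat_pct",
        "basal_metabolism_kcal",
    ),
) -> pd.DataFrame:
    """Pearson correlation (with two-sided p) of cfDNA level against each
    covariate; constant covariates are skipped with a warning."""
    if len(frame) < 3:
        raise ConfigurationError("need >= 3 records for correlation")
    y = frame[response].to_numpy(dtype=float)
    rows = []
    for cov in covariates:
        x = frame[cov].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"covariate {cov!r} is constant; skipped", stacklevel=2)
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"covariate": cov, "pearson_r": float(r), "p_value": float(p), "n": len(x)})
    return pd.DataFrame(rows)
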