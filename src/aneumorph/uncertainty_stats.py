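"""Uncertainty quantification across repeated reconstructions.

For each parameter and aneurysm the central value is the median over
groups and the absolute uncertainty is the middle 68.3% range, i.e. the
difference between the 84.13th and 15.87th percentile (equal to +/- one
SD for normal data).  The relative uncertainty is the range divided by
the median, in percent.  Cross-aneurysm aggregation uses medians and
interquartile ranges throughout; means are never used.

The default percentile estimator is the weighted average at position
(n+1)p with clamping at the extremes (the SPSS default); ordinary
linear interpolation is selectable because published uncertainty tables
are sensitive to this choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import PARAMETER_NAMES, ParameterRecord

__all__ = [
    "CohortTable",
    "UncertaintySummary",
    "percentile",
    "uq_summary",
    "absolute_relative_deviations",
    "deviation_boxplot_summary",
    "kendall_tau_b",
    "wilcoxon_signed_rank",
    "normality_test",
    "regression_range_vs_median",
]

_PCTL_METHODS = {"spss": "weibull", "linear": "linear"}


def percentile(x, q: float, method: str = "spss") -> float:
    """Order-statistic percentile of ``x`` at fraction ``q`` in (0, 1).

    ``method='spss'`` interpolates at position (n+1)q, clamped to the
    extremes; ``method='linear'`` uses ordinary linear interpolation on
    positions 1..n.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("percentile of empty data is undefined")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be strictly between 0 and 1")
    if method not in _PCTL_METHODS:
        raise ValueError(f"unknown percentile method {method!r}")
    return float(np.quantile(x, q, method=_PCTL_METHODS[method]))


def range68(x, method: str = "spss") -> float:
    """Middle 68.3% range: P84.13 - P15.87."""
    return percentile(x, 0.8413, method) - percentile(x, 0.1587, method)


class CohortTable:
    """Long-format table of parameter records across aneurysms x groups."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in ("aneurysm", "group") if c not in frame.columns]
        if missing:
            raise ValueError(f"cohort table lacks column(s) {missing}")
        dup = frame.duplicated(subset=["aneurysm", "group"])
        if dup.any():
            raise ValueError("duplicate (aneurysm, group) pairs in cohort table")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[ParameterRecord]) -> "CohortTable":
        rows = [r.as_series() for r in records]
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path, comment="#", dtype={"aneurysm": str, "group": str}))

    def to_csv(self, path, header_comment: Optional[str] = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.frame.to_csv(fh, index=False)

    @property
    def parameters(self) -> list[str]:
        return [c for c in self.frame.columns if c in PARAMETER_NAMES]

    @property
    def aneurysms(self) -> list[str]:
        return sorted(self.frame["aneurysm"].astype(str).unique())

    def groups_per_aneurysm(self) -> pd.Series:
        return self.frame.groupby("aneurysm").size()

    def __len__(self):
        return len(self.frame)


@dataclass
class UncertaintySummary:
    """Per-aneurysm and per-parameter uncertainty tables.

    ``per_aneurysm`` has one row per (parameter, aneurysm) with the
    median, absolute 68.3% range and relative uncertainty (%);
    ``per_parameter`` aggregates across aneurysms (median [IQR] of the
    medians and of the relative uncertainties, plus the Kendall tau
    between them); ``regressions`` holds the OLS fit of the absolute
    range on the median across aneurysms.
    """

    per_aneurysm: pd.DataFrame
    per_parameter: pd.DataFrame
    regressions: pd.DataFrame
    percentile_method: str = "spss"


def _median(x, method):
    return percentile(x, 0.5, method)


def uq_summary(table: CohortTable, method: str = "spss") -> UncertaintySummary:
    """Full uncertainty summary of a cohort (Tables 2-5 shape)."""
    frame = table.frame
    n_groups = table.groups_per_aneurysm()
    if len(n_groups) < 2:
        raise ValueError("uncertainty summary requires at least 2 aneurysms")
    if (n_groups < 3).any():
        raise ValueError("every aneurysm needs at least 3 group reconstructions")

    rows = []
    for param in table.parameters:
        for aneurysm, sub in frame.groupby("aneurysm", sort=True):
            x = sub[param].dropna().to_numpy(dtype=float)
            if len(x) == 0:
                continue
            med = _median(x, method)
            rng = range68(x, method)
            rel = 100.0 * rng / med if med != 0 else np.nan
            rows.append(
                {
                    "parameter": param,
                    "aneurysm": aneurysm,
                    "n_groups": len(x),
                    "median": med,
                    "range68": rng,
                    "rel_uncertainty": rel,
                    "median_zero": med == 0,
                }
            )
    per_aneurysm = pd.DataFrame(rows)

    prows, rrows = [], []
    for param, sub in per_aneurysm.groupby("parameter", sort=False):
        med = sub["median"].to_numpy()
        rel = sub["rel_uncertainty"].to_numpy()
        rng = sub["range68"].to_numpy()
        ok = ~np.isnan(rel)
        try:
            tau = kendall_tau_b(med[ok], rel[ok]) if ok.sum() >= 2 else np.nan
        except ValueError:
            tau = np.nan
        prows.append(
            {
                "parameter": param,
                "value_median": _median(med, method),
                "value_iqr": percentile(med, 0.75, method)
                - percentile(med, 0.25, method),
                "rel_uncertainty_median": _median(rel[ok], method) if ok.any() else np.nan,
                "rel_uncertainty_iqr": (
                    percentile(rel[ok], 0.75, method)
                    - percentile(rel[ok], 0.25, method)
                    if ok.any()
                    else np.nan
                ),
                "tau": tau,
            }
        )
        if len(med) >= 3 and np.ptp(med) > 0:
            res = stats.linregress(med, rng)
            rrows.append(
                {
                    "parameter": param,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "r_squared": res.rvalue**2,
                }
            )
    per_parameter = pd.DataFrame(prows).set_index("parameter")
    regressions = (
        pd.DataFrame(rrows).set_index("parameter")
        if rrows
        else pd.DataFrame(columns=["slope", "intercept", "r_squared"])
    )
    return UncertaintySummary(
        per_aneurysm=per_aneurysm,
        per_parameter=per_parameter,
        regressions=regressions,
        percentile_method=method,
    )


def absolute_relative_deviations(
    table: CohortTable, method: str = "spss"
) -> pd.DataFrame:
    """|x - median| / median per record and parameter (long format)."""
    frame = table.frame
    rows = []
    for param in table.parameters:
        for aneurysm, sub in frame.groupby("aneurysm", sort=True):
            x = sub[param].to_numpy(dtype=float)
            ok = ~np.isnan(x)
            if ok.sum() == 0:
                continue
            med = _median(x[ok], method)
            for group, xi in zip(sub["group"], x):
                if np.isnan(xi):
                    continue
                dev = np.abs(xi - med) / med if med != 0 else np.nan
                rows.append(
                    {
                        "parameter": param,
                        "aneurysm": aneurysm,
                        "group": group,
                        "deviation": dev,
                        "median_zero": med == 0,
                    }
                )
    return pd.DataFrame(rows)


def deviation_boxplot_summary(
    deviations: pd.DataFrame, crop: float = 1.0, method: str = "spss"
) -> pd.DataFrame:
    """Boxplot data per parameter: quartiles, whiskers (1.5 IQR rule) and
    the count of deviations beyond ``crop`` (default 100%)."""
    rows = []
    for param, sub in deviations.groupby("parameter", sort=False):
        d = sub["deviation"].dropna().to_numpy()
        if len(d) == 0:
            continue
        q1 = percentile(d, 0.25, method)
        q2 = percentile(d, 0.5, method)
        q3 = percentile(d, 0.75, method)
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = d[(d >= lo_fence) & (d <= hi_fence)]
        rows.append(
            {
                "parameter": param,
                "q1": q1,
                "median": q2,
                "q3": q3,
                "whisker_low": float(inside.min()) if len(inside) else np.nan,
                "whisker_high": float(inside.max()) if len(inside) else np.nan,
                "n": len(d),
                "n_above_crop": int((d > crop).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall tau-b rank correlation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("kendall_tau_b needs two equal-length lists (n >= 2)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("kendall_tau_b undefined for all-tied input")
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def wilcoxon_signed_rank(d1, d2) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon convention); the exact null
    distribution is enumerated for n <= 25, otherwise the normal
    approximation with continuity correction is used.  Identical inputs
    are a degenerate case reported as (0, p=1).
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if len(d1) != len(d2):
        raise ValueError("paired samples must have equal length")
    diff = d1 - d2
    diff = diff[diff != 0]
    if len(diff) == 0:
        return 0.0, 1.0
    if len(diff) < 6:
        raise ValueError("need at least 6 non-zero differences")
    exact = len(diff) <= 25
    res = stats.wilcoxon(diff, zero_method="wilcox", correction=not exact,
                         alternative="two-sided",
                         method="exact" if exact else "approx")
    return float(res.statistic), float(res.pvalue)


def normality_test(x) -> tuple[float, float]:
    """Shapiro-Wilk W and p-value."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for constant input")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def regression_range_vs_median(
    summary: UncertaintySummary, parameter: str
) -> tuple[float, float, float]:
    """OLS of the absolute 68.3% range on the median across aneurysms."""
    sub = summary.per_aneurysm[summary.per_aneurysm["parameter"] == parameter]
    if len(sub) < 3:
        raise ValueError("regression needs at least 3 aneurysms")
    med = sub["median"].to_numpy()
    rng = sub["range68"].to_numpy()
    if np.ptp(med) == 0:
        raise ValueError("zero variance in medians; regression undefined")
    res = stats.linregress(med, rng)
    # constant response: slope 0 and, by convention, R^2 = 0 (not NaN)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return float(res.slope), float(res.intercept), r2
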