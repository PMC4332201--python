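"""Population statistics for per-cell cytotoxicity data.

Covers the whole quantitative tail of the assay: tertile stratification of
cells by initial FBA accumulation, death fractions per stratum, the
fold-difference in initial FBA between dying and surviving cells, the
coefficient of variation of cell-to-cell intensities, per-cell Pearson
correlations (immunofluorescence vs FBA), time-course condition summaries
with SEM and Student's t-tests, and the power-law fit y = a·x^b used for
nuclear diameter / Hoechst trends versus time in culture.

Conventions: sample (n−1) standard deviations throughout; percentages on
the 0–100 scale; experiments (not cells) are the unit of replication in
time-course summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import EmptyInputError, InvalidParameterError

__all__ = [
    "GroupSummary",
    "PowerLawFit",
    "stratify_by_fba",
    "death_fraction",
    "fold_fba_dying_vs_surviving",
    "coefficient_of_variation",
    "correlate_per_cell",
    "summarize_timecourse",
    "fit_power_law",
    "group_summaries",
]

TERTILES = ("low", "mid", "high")


@dataclass
class GroupSummary:
    """Death and accumulation summary for one FBA stratum (or the whole)."""

    group: str
    n: int
    death_pct: float
    mean_fba: float
    sem: float
    cv_pct: float


@dataclass
class PowerLawFit:
    """Least-squares power-law fit y = a·x^b (log–log space).

    ``rss`` is the residual sum of squares on the log scale.
    """

    a: float
    b: float
    rss: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(x, dtype=float) ** self.b


def stratify_by_fba(values: Sequence[float]) -> np.ndarray:
    """Split cells into low/mid/high tertiles of initial FBA.

    Cells are sorted ascending by value (stable, so ties keep original
    order) and cut into three contiguous groups of equal size; when n is
    not divisible by 3 the extra cells go to the low, then the mid group,
    so group sizes never differ by more than one.  Returns an object array
    of labels aligned with the input order.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise InvalidParameterError("tertile stratification needs n >= 3")
    order = np.argsort(values, kind="stable")
    q, r = divmod(n, 3)
    sizes = (q + (r >= 1), q + (r >= 2), q)
    labels = np.empty(n, dtype=object)
    start = 0
    for name, size in zip(TERTILES, sizes):
        labels[order[start : start + size]] = name
        start += size
    return labels


def death_fraction(died: Sequence[bool], labels=None, group: str | None = None) -> float:
    """Percentage of cells that died, optionally within one stratum."""
    died = np.asarray(died, dtype=bool)
    if labels is not None and group is not None and group != "whole":
        died = died[np.asarray(labels) == group]
    if died.size == 0:
        raise EmptyInputError("death fraction of an empty group")
    return 100.0 * float(died.mean())


def fold_fba_dying_vs_surviving(
    fba: Sequence[float], died: Sequence[bool]
) -> float:
    """Mean initial FBA of dying cells over mean of surviving cells."""
    fba = np.asarray(fba, dtype=float)
    died = np.asarray(died, dtype=bool)
    if not died.any() or died.all():
        raise EmptyInputError("need at least one dying and one surviving cell")
    m_s = fba[~died].mean()
    if m_s == 0:
        raise InvalidParameterError("surviving-cell mean FBA is zero")
    return float(fba[died].mean() / m_s)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Cell-to-cell CV: 100 × sample SD (n−1) / mean, in percent."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise InvalidParameterError("CV needs n >= 2")
    m = values.mean()
    if m <= 0:
        raise InvalidParameterError("CV undefined for non-positive mean")
    return 100.0 * float(values.std(ddof=1) / m)


def correlate_per_cell(
    x_values: Sequence[float], y_values: Sequence[float]
) -> tuple[float, int]:
    """Pearson product-moment correlation and n over paired cells."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if len(x) != len(y):
        raise InvalidParameterError("x and y must have equal length")
    if len(x) < 3:
        raise InvalidParameterError("correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise InvalidParameterError("correlation undefined for zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, len(x)


def group_summaries(
    fba: Sequence[float], died: Sequence[bool], labels: Sequence[str] | None = None
) -> list[GroupSummary]:
    """Low/mid/high/whole summaries of death and FBA accumulation."""
    fba = np.asarray(fba, dtype=float)
    died = np.asarray(died, dtype=bool)
    if labels is None:
        labels = stratify_by_fba(fba)
    labels = np.asarray(labels)
    out = []
    for g in (*TERTILES, "whole"):
        sel = np.ones(len(fba), bool) if g == "whole" else labels == g
        vals, d = fba[sel], died[sel]
        out.append(
            GroupSummary(
                group=g,
                n=int(sel.sum()),
                death_pct=100.0 * float(d.mean()),
                mean_fba=float(vals.mean()),
                sem=float(vals.std(ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1
                else float("nan"),
                cv_pct=coefficient_of_variation(vals) if len(vals) > 1 else float("nan"),
            )
        )
    return out


def summarize_timecourse(
    per_experiment_means: pd.DataFrame,
    fold_between: Iterable[tuple[float, float]] = (),
    compare_conditions: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condition × time summaries from per-experiment means.

    Parameters
    ----------
    per_experiment_means
        Tidy frame with columns ``condition``, ``time_h``, ``experiment``,
        ``value`` — one row per experiment replicate (experiments, not
        cells, are the unit of replication).
    fold_between
        Pairs of time points ``(t_num, t_den)``; per condition the ratio
        of the condition means at those times is reported.
    compare_conditions
        If true, two-sided equal-variance Student's t-tests between every
        pair of conditions at each shared time point.

    Returns
    -------
    summary : DataFrame with condition, time_h, n_experiments, mean, sem
        (sem is NaN for a single experiment) and rows of fold-changes.
    comparisons : DataFrame with condition_a, condition_b, time_h, p_value.
    """
    df = per_experiment_means
    required = {"condition", "time_h", "experiment", "value"}
    if not required.issubset(df.columns):
        raise InvalidParameterError(f"need columns {sorted(required)}")
    rows = []
    for (cond, t), grp in df.groupby(["condition", "time_h"], sort=True):
        v = grp["value"].to_numpy(dtype=float)
        rows.append(
            {
                "condition": cond,
                "time_h": t,
                "n_experiments": len(v),
                "mean": v.mean(),
                "sem": v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
            }
        )
    summary = pd.DataFrame(rows)
    folds = []
    for t_num, t_den in fold_between:
        for cond in summary["condition"].unique():
            sub = summary[summary["condition"] == cond].set_index("time_h")
            if t_num in sub.index and t_den in sub.index:
                denom = sub.loc[t_den, "mean"]
                folds.append(
                    {
                        "condition": cond,
                        "fold_change": sub.loc[t_num, "mean"] / denom
                        if denom != 0
                        else np.nan,
                        "time_num_h": t_num,
                        "time_den_h": t_den,
                    }
                )
    summary.attrs["fold_changes"] = pd.DataFrame(folds)
    comps = []
    if compare_conditions:
        conds = sorted(df["condition"].unique())
        for i, a in enumerate(conds):
            for b in conds[i + 1 :]:
                for t in sorted(df["time_h"].unique()):
                    va = df.query("condition == @a and time_h == @t")["value"]
                    vb = df.query("condition == @b and time_h == @t")["value"]
                    if len(va) >= 2 and len(vb) >= 2:
                        p = float(
                            sps.ttest_ind(va, vb, equal_var=True).pvalue
                        )
                        comps.append(
                            {
                                "condition_a": a,
                                "condition_b": b,
                                "time_h": t,
                                "p_value": p,
                            }
                        )
    return summary, pd.DataFrame(comps)


def fit_power_law(
    x_values: Sequence[float],
    y_values: Sequence[float],
    refine_raw_scale: bool = False,
) -> PowerLawFit:
    """Fit y = a·x^b by least squares on log y vs log x.

    Linearising in log–log space is deterministic and exact on noiseless
    power-law data; ``refine_raw_scale=True`` follows up with nonlinear
    least squares on the raw scale starting from the log–log solution.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise InvalidParameterError("need n >= 2 paired observations")
    if np.any(x <= 0) or np.any(y <= 0):
        raise InvalidParameterError("power-law fit needs strictly positive data")
    lx, ly = np.log(x), np.log(y)
    b, loga = np.polyfit(lx, ly, 1)
    a = float(np.exp(loga))
    b = float(b)
    if refine_raw_scale:
        from scipy.optimize import curve_fit

        (a, b), _ = curve_fit(
            lambda xx, aa, bb: aa * xx**bb, x, y, p0=(a, b), maxfev=10000
        )
        a, b = float(a), float(b)
    rss = float(np.sum((ly - (np.log(a) + b * lx)) ** 2))
    return PowerLawFit(a=a, b=b, rss=rss)
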