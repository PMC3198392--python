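"""Case-control descriptive statistics: contingency chi-square tests,
summary-statistic t-tests, and control-based tertile construction."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateTableError(ValueError):
    pass


class DegenerateTertileWarning(UserWarning):
    pass


def pearson_chi2(table: np.ndarray | Sequence[Sequence[int]],
                 ) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square test of independence.

    ``table`` is categories x groups (typically rows = levels, columns =
    cases/controls).  Returns (statistic, df, p).  No continuity correction
    is applied (the Yates correction would not reproduce the conventional
    large-sample test this mirrors).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise DegenerateTableError("need at least a 2x2 table")
    if (t < 0).any():
        raise DegenerateTableError("negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero row or column margin")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


def two_sample_t(mean1: float, sd1: float, n1: int,
                 mean2: float, sd2: float, n2: int) -> tuple[float, float, float]:
    """Two-sided pooled-variance t-test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=True)
    return float(res.statistic), float(n1 + n2 - 2), float(res.pvalue)


@dataclass(frozen=True)
class TertileCutpoints:
    """Cut-points at the 1/3 and 2/3 empirical quantiles of control values.

    Values <= ``lower`` are "low", <= ``upper`` "medium", else "high"
    (ties go to the lower stratum)."""

    lower: float
    upper: float

    def assign(self, values: np.ndarray | Sequence[float]) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        out = np.where(v <= self.lower, "low",
                       np.where(v <= self.upper, "medium", "high"))
        return np.where(np.isnan(v), None, out)


TERTILE_LEVELS = ["low", "medium", "high"]


def control_tertiles(values_controls: Sequence[float],
                     values_all: Sequence[float] | None = None,
                     ) -> tuple[TertileCutpoints, np.ndarray]:
    """Tertile cut-points from controls; labels for every subject.

    Cut-points are the empirical 1/3 and 2/3 quantiles among controls
    (cases included in the labelling but not the cut-point estimation).
    Fewer than 3 distinct control values yields a
    :class:`DegenerateTertileWarning`; labels are still produced.
    """
    vc = np.asarray(values_controls, dtype=float)
    vc = vc[~np.isnan(vc)]
    if vc.size == 0:
        raise ValueError("no control values")
    if len(np.unique(vc)) < 3:
        warnings.warn("fewer than 3 distinct control values; tertiles degenerate",
                      DegenerateTertileWarning, stacklevel=2)
    lo, hi = np.quantile(vc, [1 / 3, 2 / 3])
    cut = TertileCutpoints(float(lo), float(hi))
    target = values_all if values_all is not None else values_controls
    return cut, cut.assign(target)


def assign_tertiles(subjects: pd.DataFrame,
                    columns: Sequence[str] = ("vegetable_freq", "alcohol_freq"),
                    ) -> pd.DataFrame:
    """Derive <column-root>_tertile labels using control-based cut-points."""
    out = subjects.copy()
    ctrl = out["status"] == 0
    for col in columns:
        _, labels = control_tertiles(out.loc[ctrl, col].to_numpy(),
                                     out[col].to_numpy())
        out[col.replace("_freq", "_tertile")] = pd.Categorical(
            labels, categories=TERTILE_LEVELS)
    return out


# ---------------------------------------------------------------------------
# Table-2 style report
# ---------------------------------------------------------------------------

_CATEGORICALS = [
    ("center", None), ("sex", None), ("bmi_class", None), ("smoking", None),
    ("hypertension", None), ("family_history", None),
    ("vegetable_tertile", None), ("alcohol_tertile", None),
]


def descriptive_table(subjects: pd.DataFrame) -> pd.DataFrame:
    """Categories x (cases n, %, controls n, %, p) descriptive summary."""
    rows = []
    cases = subjects[subjects["status"] == 1]
    ctrls = subjects[subjects["status"] == 0]
    for var, _ in _CATEGORICALS:
        if var not in subjects.columns:
            continue
        levels = (list(subjects[var].cat.categories)
                  if isinstance(subjects[var].dtype, pd.CategoricalDtype)
                  else sorted(subjects[var].dropna().unique()))
        counts = np.array([[int((cases[var] == lv).sum()),
                            int((ctrls[var] == lv).sum())] for lv in levels])
        if counts.shape[0] >= 2 and (counts.sum(0) > 0).all() \
                and not (counts.sum(1) == 0).any():
            _, _, p = pearson_chi2(counts)
        else:
            p = np.nan
        for i, lv in enumerate(levels):
            rows.append({
                "variable": var, "level": str(lv),
                "cases_n": counts[i, 0],
                "cases_pct": 100.0 * counts[i, 0] / max(counts[:, 0].sum(), 1),
                "controls_n": counts[i, 1],
                "controls_pct": 100.0 * counts[i, 1] / max(counts[:, 1].sum(), 1),
                "p": p if i == 0 else np.nan,
            })
    t, _, p = (np.nan, np.nan, np.nan) if len(cases) < 2 or len(ctrls) < 2 else \
        two_sample_t(cases["age"].mean(), cases["age"].std(), len(cases),
                     ctrls["age"].mean(), ctrls["age"].std(), len(ctrls))
    rows.append({"variable": "age", "level": "mean",
                 "cases_n": len(cases), "cases_pct": cases["age"].mean(),
                 "controls_n": len(ctrls), "controls_pct": ctrls["age"].mean(),
                 "p": p})
    return pd.DataFrame(rows)


def write_descriptive_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.4g")
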