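"""Group-comparison and correlation statistics for the study variables.

The analysis layer mirrors a small-animal crossover design: each subject
contributes one row per analysis window (baseline, phenylephrine) with a
flat map of named variables.  Within-group baseline-vs-stimulus contrasts
use a paired t-test; between-group contrasts use an unpaired (equal
variance by default) t-test; associations use Pearson's r with a relevance
rule (p <= 0.05 and |r| > 0.5).  A Shapiro-Wilk normality gate flags, but
does not exclude, non-normal variables.  No multiple-testing correction is
applied; reports carry the number of tests performed so users can apply
their own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "NormalityResult",
    "ComparisonResult",
    "CorrelationResult",
    "normality_gate",
    "compare",
    "correlate",
    "summarise",
]

_META_COLS = ("subject", "group", "window")


@dataclass(frozen=True)
class NormalityResult:
    variable: str
    n: int
    W: float
    p: float
    non_normal: bool
    untestable: bool = False


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    contrast: str  # "within" (paired baseline vs pe) | "between" (unpaired groups)
    groups: tuple[str, ...]
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    p: float

    @property
    def significant(self) -> bool:
        return bool(self.p < 0.05)


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    subgroup: str  # "pooled" | "baseline" | "pe"
    n: int
    r: float
    p: float

    @property
    def relevant(self) -> bool:
        return bool(self.p <= 0.05 and abs(self.r) > 0.5)


def _variables(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in _META_COLS]


def normality_gate(df: pd.DataFrame, variables: list[str] | None = None) -> list[NormalityResult]:
    """Shapiro-Wilk W and p per variable (pooled over rows).

    Variables with fewer than 3 finite values or zero variance are marked
    untestable; non-normal variables (p < 0.05) are flagged, not excluded.
    """
    out = []
    for var in variables or _variables(df):
        x = pd.to_numeric(df[var], errors="coerce").dropna().to_numpy()
        if x.size < 3 or np.ptp(x) == 0:
            out.append(NormalityResult(var, int(x.size), np.nan, np.nan, False, untestable=True))
            continue
        with warnings.catch_warnings():
            # near-identical values (e.g. grid-quantised peak frequencies)
            # are expected; the W statistic is still reported
            warnings.simplefilter("ignore", RuntimeWarning)
            w, p = sps.shapiro(x)
        out.append(NormalityResult(var, int(x.size), float(w), float(p), bool(p < 0.05)))
    return out


def compare(
    df: pd.DataFrame,
    variable: str,
    contrast: str,
    group: str | None = None,
    window: str = "baseline",
    windows: tuple[str, str] = ("baseline", "pe"),
    equal_var: bool = True,
) -> ComparisonResult:
    """Two-sided t-test on one variable.

    ``contrast='within'``: paired test of ``windows[0]`` vs ``windows[1]``
    inside ``group`` (subjects matched by id).  ``contrast='between'``:
    unpaired test between the two groups at ``window`` (Student by default;
    ``equal_var=False`` for Welch).
    """
    if contrast == "within":
        if group is None:
            raise ValueError("within-group contrast requires a group")
        sub = df[df["group"] == group]
        a = sub[sub["window"] == windows[0]].set_index("subject")[variable]
        b = sub[sub["window"] == windows[1]].set_index("subject")[variable]
        common = a.index.intersection(b.index)
        if len(common) != len(a) or len(common) != len(b):
            raise ValueError("paired contrast requires matched subjects in both windows")
        a, b = a.loc[common].to_numpy(float), b.loc[common].to_numpy(float)
        if a.size < 2:
            raise ValueError("paired contrast needs at least 2 subjects")
        diffs = a - b
        if np.allclose(diffs, 0):
            t_stat, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                t_stat, p = sps.ttest_rel(a, b)
        return ComparisonResult(
            variable, "within", (group,),
            float(a.mean()), float(a.std(ddof=1)), a.size,
            float(b.mean()), float(b.std(ddof=1)), b.size,
            float(t_stat), float(p),
        )
    if contrast == "between":
        labels = tuple(pd.unique(df["group"]))
        if len(labels) != 2:
            raise ValueError("between-group contrast requires exactly 2 groups")
        sub = df[df["window"] == window]
        a = sub[sub["group"] == labels[0]][variable].to_numpy(float)
        b = sub[sub["group"] == labels[1]][variable].to_numpy(float)
        if a.size < 2 or b.size < 2:
            raise ValueError("between-group contrast needs >=2 subjects per group")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t_stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
        return ComparisonResult(
            variable, "between", labels,
            float(a.mean()), float(a.std(ddof=1)), a.size,
            float(b.mean()), float(b.std(ddof=1)), b.size,
            float(t_stat), float(p),
        )
    raise ValueError("contrast must be 'within' or 'between'")


def correlate(
    df: pd.DataFrame,
    var_x: str,
    var_y: str,
    subgroup: str = "pooled",
    group: str | None = None,
) -> CorrelationResult:
    """Pearson correlation between two variables.

    ``subgroup='pooled'`` concatenates each subject's baseline and stimulus
    rows (n = 2 x subjects); 'baseline'/'pe' restrict to one window.
    """
    sub = df if group is None else df[df["group"] == group]
    if subgroup != "pooled":
        sub = sub[sub["window"] == subgroup]
    x = sub[var_x].to_numpy(float)
    y = sub[var_y].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("correlation needs at least 3 paired finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sps.NearConstantInputWarning)
        r, p = sps.pearsonr(x, y)
    return CorrelationResult(var_x, var_y, subgroup, int(x.size), float(r), float(p))


def summarise(df: pd.DataFrame, variables: list[str] | None = None) -> pd.DataFrame:
    """Mean +/- SD per variable x group x window, study-table shaped.

    Returns a DataFrame indexed by variable with one (group, window) column
    pair holding mean and SD; SD is NaN for single-subject cells.
    """
    variables = variables or _variables(df)
    rows = {}
    for var in variables:
        row = {}
        for (grp, win), cell in df.groupby(["group", "window"], sort=False):
            vals = pd.to_numeric(cell[var], errors="coerce").dropna()
            row[(grp, win, "mean")] = vals.mean() if len(vals) else np.nan
            row[(grp, win, "sd")] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        rows[var] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["group", "window", "stat"])
    out.index.name = "variable"
    return out
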