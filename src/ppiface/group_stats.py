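"""Group-wise statistics: size-energy regressions and percentage summaries.

For each functional group (or polarity class) and each energy component
(total, vdW, H-bond, electrostatic) an ordinary least-squares fit of the
component's favourable energy magnitude on interface size gives the
coefficient of determination r^2, the ANOVA F statistic and its p-value
(1 and n-2 degrees of freedom, the 95%-confidence significance test).

Percentage summaries report the arithmetic mean and population SD of each
channel's percentage contribution per group, plus the class-B / class-A
ratio of mean electrostatic percentages.

The regression response defaults to magnitudes of favourable energies —
a complex whose net electrostatics is repulsive contributes 0 to the
electrostatic fit — matching the decomposition caveat.  Signed-energy and
exclusion modes are available.  An optional joint multivariate fit
(all three channels as predictors of size) is provided for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

COMPONENTS = ("total", "vdw", "hbond", "elec")
_ENERGY_COL = {"total": "e_total", "vdw": "e_vdw", "hbond": "e_hbond",
               "elec": "e_elec"}


@dataclass
class GroupRegression:
    group: str
    component: str
    n: int
    slope: float
    intercept: float
    r2: float
    f_stat: float
    p_value: float


@dataclass
class GroupSummary:
    group: str
    n: int
    mean_pct_vdw: float
    sd_pct_vdw: float
    mean_pct_hbond: float
    sd_pct_hbond: float
    mean_pct_elec: float
    sd_pct_elec: float


def favorable_magnitude(df: pd.DataFrame, component: str,
                        caveat: str = "zero") -> pd.Series:
    """Regression response for one component.

    ``caveat='zero'``: net-repulsive channel totals contribute 0 (default);
    ``caveat='exclude'``: such complexes are dropped from the fit;
    ``caveat='signed'``: raw signed totals are used.
    'total' is the sum of favourable channel magnitudes.
    """
    if component == "total":
        cols = [favorable_magnitude(df, c, caveat) for c in ("vdw", "hbond", "elec")]
        return sum(cols)
    e = df[_ENERGY_COL[component]].astype(float)
    if caveat == "signed":
        return e
    mag = (-e).clip(lower=0.0)
    if caveat == "exclude":
        mag = mag.where(e <= 0, np.nan)
    return mag


def regress(df: pd.DataFrame, group: str = "all", component: str = "vdw",
            group_col: str | None = None, caveat: str = "zero") -> GroupRegression:
    """OLS of one energy component's magnitude on interface size.

    ``group_col``/``group`` select the subset (``group='all'`` with
    ``group_col=None`` fits the whole table).  Requires >= 3 complexes and a
    non-degenerate predictor.
    """
    if component not in COMPONENTS:
        raise ValueError(f"component must be one of {COMPONENTS}")
    sub = df if group_col is None else df[df[group_col] == group]
    y = favorable_magnitude(sub, component, caveat)
    x = sub["interface_size"].astype(float)
    keep = y.notna() & x.notna()
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"group {group!r}: need >= 3 complexes to fit, got {n}")
    if float(np.var(x)) == 0.0:
        raise ValueError(f"group {group!r}: interface size has zero variance")
    model = sm.OLS(y.to_numpy(), sm.add_constant(x.to_numpy())).fit()
    return GroupRegression(
        group=group, component=component, n=n,
        slope=float(model.params[1]), intercept=float(model.params[0]),
        r2=float(model.rsquared), f_stat=float(model.fvalue),
        p_value=float(model.f_pvalue),
    )


def regress_multivariate(df: pd.DataFrame, caveat: str = "zero") -> dict:
    """Joint fit of interface size on all three channel magnitudes."""
    X = pd.DataFrame({c: favorable_magnitude(df, c, caveat)
                      for c in ("vdw", "hbond", "elec")})
    keep = X.notna().all(axis=1)
    model = sm.OLS(df.loc[keep, "interface_size"].astype(float).to_numpy(),
                   sm.add_constant(X[keep].to_numpy())).fit()
    return {"r2": float(model.rsquared), "f_stat": float(model.fvalue),
            "p_value": float(model.f_pvalue),
            "coef": dict(zip(("const", "vdw", "hbond", "elec"),
                             map(float, model.params)))}


def regression_table(df: pd.DataFrame, group_col: str,
                     caveat: str = "zero") -> pd.DataFrame:
    """r^2/p per group x component (one row per group, as in the headline
    per-function and per-class tables); groups with < 3 complexes are
    skipped."""
    rows = []
    for group in df[group_col].dropna().unique():
        row = {"group": group, "n": int((df[group_col] == group).sum())}
        try:
            for comp in COMPONENTS:
                fit = regress(df, group, comp, group_col, caveat)
                row[f"r2_{comp}"] = round(fit.r2, 3)
                row[f"p_{comp}"] = fit.p_value
        except ValueError:
            continue
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(df: pd.DataFrame, group_col: str | None = None,
              ddof: int = 0) -> list[GroupSummary]:
    """Mean and SD of percentage contributions per group.

    SD is population (ddof=0) by default; undefined-percentage complexes
    (no favourable energy) are excluded.  Empty groups are omitted.
    """
    usable = df[df["pct_vdw"].notna()]
    groups = ([("all", usable)] if group_col is None
              else list(usable.groupby(group_col)))
    out = []
    for name, sub in groups:
        if len(sub) == 0:
            continue
        vals = {}
        for comp in ("vdw", "hbond", "elec"):
            col = sub[f"pct_{comp}"].astype(float)
            vals[f"mean_pct_{comp}"] = float(col.mean())
            vals[f"sd_pct_{comp}"] = float(col.std(ddof=ddof))
        out.append(GroupSummary(group=str(name), n=len(sub), **vals))
    return out


def summary_table(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "group": s.group, "n": s.n,
        "mean_pct_elec": round(s.mean_pct_elec, 2), "sd_pct_elec": round(s.sd_pct_elec, 2),
        "mean_pct_hbond": round(s.mean_pct_hbond, 2), "sd_pct_hbond": round(s.sd_pct_hbond, 2),
        "mean_pct_vdw": round(s.mean_pct_vdw, 2), "sd_pct_vdw": round(s.sd_pct_vdw, 2),
    } for s in summaries])


def class_elec_ratio(df: pd.DataFrame,
                     class_col: str = "polarity_class") -> float:
    """Class-B over class-A ratio of mean electrostatic percentage."""
    by = {s.group: s for s in summarize(df, class_col)}
    if "A" not in by or "B" not in by:
        raise ValueError("both polarity classes required for the ratio")
    if by["A"].mean_pct_elec == 0:
        raise ValueError("class A mean electrostatic percentage is zero")
    return by["B"].mean_pct_elec / by["A"].mean_pct_elec
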