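"""Storage-stability screening: one-way ANOVA, linear time regressions and
Beer--Lambert anthocyanin quantification.

The screening protocol: for each formulation and property, compare the
replicate groups at the sampled storage times by a one-way F test at the
5% level; properties whose F exceeds the critical value are then fitted
with an ordinary least-squares linear model in time, reported with R^2.
Low-R^2 fits are reported, never filtered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PropertySeries",
    "AnovaResult",
    "RegressionModel",
    "AssayConstants",
    "one_way_anova",
    "f_critical",
    "fit_linear",
    "predict_linear",
    "anthocyanin_content",
    "anova_table",
    "regression_table",
]


@dataclass(frozen=True)
class PropertySeries:
    """Replicate groups of one property over storage times."""

    name: str
    groups: tuple[tuple[float, tuple[float, ...]], ...]  # (time, replicates)

    def __post_init__(self):
        if len(self.groups) < 2:
            raise ValueError("ANOVA needs at least two time groups")
        if any(len(reps) < 2 for _, reps in self.groups):
            raise ValueError("every time group needs at least two replicates")


@dataclass(frozen=True)
class AnovaResult:
    F_calc: float
    df_factor: int
    df_error: int
    F_crit: float
    significant: bool


@dataclass(frozen=True)
class RegressionModel:
    """Linear time model y = a + b*x with coefficient of determination."""

    intercept: float
    slope: float
    r_squared: float


@dataclass(frozen=True)
class AssayConstants:
    """Beer--Lambert constants for anthocyanin quantification
    (cyanidin-3-glucoside equivalents at 532 nm)."""

    molar_absorptivity: float = 26_900.0  # L / (mol cm)
    molecular_weight: float = 449.2       # g / mol
    path_length_cm: float = 1.0
    extract_volume_l: float = 0.1
    sample_mass_g: float = 10.0
    dilution_factor: float = 1.0

    def __post_init__(self):
        for f in (
            self.molar_absorptivity, self.molecular_weight, self.path_length_cm,
            self.extract_volume_l, self.sample_mass_g, self.dilution_factor,
        ):
            if f <= 0:
                raise ValueError("assay constants must all be positive")


def one_way_anova(series: PropertySeries, alpha: float = 0.05) -> AnovaResult:
    """One-way fixed-effects ANOVA of a property against storage time.

    F = MS_between / MS_within with df (k-1, N-k); significance is the
    strict comparison F_calc > F_crit at the given alpha.
    """
    groups = [np.asarray(reps, float) for _, reps in series.groups]
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_factor, df_error = k - 1, n_total - k
    if df_error < 1:
        raise ValueError("not enough error degrees of freedom")
    ms_within = ss_within / df_error
    if ms_within == 0:
        if ss_between > 0:
            raise FloatingPointError(
                f"{series.name}: zero within-group variance with nonzero "
                "between-group variance (infinite F)"
            )
        f_calc = 0.0
    else:
        f_calc = (ss_between / df_factor) / ms_within
    f_crit = f_critical(df_factor, df_error, alpha)
    return AnovaResult(
        F_calc=float(f_calc),
        df_factor=df_factor,
        df_error=df_error,
        F_crit=f_crit,
        significant=f_calc > f_crit,
    )


def f_critical(df1: int, df2: int, alpha: float = 0.05) -> float:
    """Upper-alpha quantile of the F(df1, df2) distribution."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return float(sps.f.ppf(1.0 - alpha, df1, df2))


def fit_linear(times: Sequence[float], values: Sequence[float]) -> RegressionModel:
    """Ordinary least squares y = a + b*x with R^2 = 1 - SSE/SST."""
    x = np.asarray(times, float)
    y = np.asarray(values, float)
    if x.size < 3:
        raise ValueError("need at least three points")
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct times")
    b, a = np.polyfit(x, y, 1)
    resid = y - (a + b * x)
    sst = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / sst if sst > 0 else 0.0
    return RegressionModel(intercept=float(a), slope=float(b), r_squared=float(max(r2, 0.0)))


def predict_linear(model: RegressionModel, time: float):
    """Evaluate a fitted linear time model."""
    return model.intercept + model.slope * np.asarray(time, float)


def anthocyanin_content(absorbance: float, k: AssayConstants = AssayConstants()) -> float:
    """Total monomeric anthocyanins, mg per 100 g of sample.

    content = A / (eps * l) * MW * V * dilution / m * 1000 mg/g * 100 g
    """
    if absorbance < 0:
        raise ValueError("absorbance must be non-negative")
    moles_per_l = absorbance / (k.molar_absorptivity * k.path_length_cm)
    grams = moles_per_l * k.molecular_weight * k.extract_volume_l * k.dilution_factor
    return grams / k.sample_mass_g * 100.0 * 1000.0  # mg / 100 g


# ---------------------------------------------------------------------------
# Screening tables over a record DataFrame
# ---------------------------------------------------------------------------

def _series_from_frame(df: pd.DataFrame, prop: str) -> PropertySeries:
    groups = tuple(
        (float(t), tuple(sub[prop].tolist()))
        for t, sub in df.groupby("time")
        if len(sub) >= 2
    )
    return PropertySeries(name=prop, groups=groups)


def anova_table(
    records: pd.DataFrame,
    properties: Iterable[str],
    alpha: float = 0.05,
    fixed_f_crit: float | None = None,
) -> pd.DataFrame:
    """Per-formulation F-screen shaped like the classic summary tables.

    ``fixed_f_crit`` reproduces published comparisons that quote a single
    tabulated critical value regardless of the data's actual degrees of
    freedom; by default the critical value is computed from the data.
    """
    rows = []
    for form, sub in records.groupby("formulation"):
        row: dict = {"formulation": form}
        for prop in properties:
            res = one_way_anova(_series_from_frame(sub, prop), alpha=alpha)
            f_crit = fixed_f_crit if fixed_f_crit is not None else res.F_crit
            star = "*" if res.F_calc > f_crit else ""
            row["F_tab"] = round(f_crit, 3)
            row[prop] = f"{res.F_calc:.3f}{star}"
        rows.append(row)
    return pd.DataFrame(rows).set_index("formulation")


def regression_table(
    records: pd.DataFrame,
    properties: Iterable[str],
    alpha: float = 0.05,
    on_replicate_means: bool = True,
    only_significant: bool = True,
) -> pd.DataFrame:
    """Linear time models per (property, formulation), with R^2.

    By default fits use replicate means per time (the screening convention)
    and only time-significant series get a model row; all fits are reported
    regardless of R^2.
    """
    rows = []
    for prop in properties:
        for form, sub in records.groupby("formulation"):
            if only_significant:
                res = one_way_anova(_series_from_frame(sub, prop), alpha=alpha)
                if not res.significant:
                    continue
            if on_replicate_means:
                means = sub.groupby("time")[prop].mean()
                x, y = means.index.to_numpy(), means.to_numpy()
            else:
                x, y = sub["time"].to_numpy(), sub[prop].to_numpy()
            m = fit_linear(x, y)
            sign = "+" if m.slope >= 0 else "-"
            rows.append(
                {
                    "property": prop,
                    "formulation": form,
                    "model": f"y={m.intercept:.2f}{sign}{abs(m.slope):.3f}x",
                    "intercept": m.intercept,
                    "slope": m.slope,
                    "R2": round(m.r_squared, 2),
                }
            )
    return pd.DataFrame(rows)
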