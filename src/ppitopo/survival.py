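"""Mapping network complexity onto 5-year survival.

Across a panel of cancer types, the complexity score β_1^{1,1} of the
KEGG-derived PPI network correlates inversely with the SEER percent 5-year
survival.  An ordinary least-squares line through the (Betti, survival)
points lets the drop in complexity achieved by a knockout be interpolated
into a predicted survival change.  The interpolation is on a population-level
fit across cancer types — it is a screening heuristic, not a patient-level
prediction, and every predicted gain carries that caveat.

The 11-cancer reference panel (cancer label, percent 5-year survival,
degree-entropy, cycle-basis dimension, nominal and best Betti) ships with
the package so the correlation is reproducible without any download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalModel",
    "PredictedGain",
    "load_reference_table",
    "read_survival_csv",
    "pearson",
    "fit_survival_model",
    "predict_survival_gain",
]

INTERPOLATION_CAVEAT = (
    "interpolated on a population-level linear fit across cancer types; "
    "not a patient-level survival prediction"
)


def load_reference_table() -> pd.DataFrame:
    """The packaged 11-cancer panel: survival, entropy, cycle-basis and
    Betti columns, one row per cancer type."""
    with resources.files("ppitopo.data").joinpath("cancer_survival.csv").open() as fh:
        return pd.read_csv(fh)


def read_survival_csv(path) -> pd.DataFrame:
    """Read a user survival table: CSV with header cancer,survival_pct[,betti]."""
    df = pd.read_csv(path)
    missing = {"cancer", "survival_pct"} - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    if df["cancer"].duplicated().any():
        dups = df.loc[df["cancer"].duplicated(), "cancer"].tolist()
        raise ValueError(f"duplicate cancer labels: {dups}")
    out_of_range = df[(df["survival_pct"] < 0) | (df["survival_pct"] > 100)]
    if len(out_of_range):
        raise ValueError(
            f"survival_pct outside [0, 100] for: {out_of_range['cancer'].tolist()}"
        )
    return df


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation r and two-sided p-value.

    The p-value comes from the t statistic with n - 2 degrees of freedom.
    Constant input makes the correlation undefined and is an error.
    """
    x = pd.Series(x, dtype=float)
    y = pd.Series(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError("need at least 3 points for a correlation p-value")
    if x.nunique() == 1 or y.nunique() == 1:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class SurvivalModel:
    """OLS line survival = slope * betti + intercept, with its correlation."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int

    def predict(self, betti: float) -> float:
        return self.slope * betti + self.intercept

    def summary(self) -> str:
        return (
            f"survival = {self.slope:+.4f} * betti {self.intercept:+.2f}  "
            f"(r = {self.pearson_r:.3f}, p = {self.p_value:.4f}, n = {self.n})"
        )


@dataclass(frozen=True)
class PredictedGain:
    """A knockout's interpolated survival change, flagged as such."""

    gain_pct: float
    caveat: str = INTERPOLATION_CAVEAT


def fit_survival_model(
    table: pd.DataFrame,
    betti_col: str = "nominal_betti",
    survival_col: str = "survival_pct",
) -> SurvivalModel:
    """Fit the linear Betti-survival model to a panel of cancers."""
    if len(table) < 3:
        raise ValueError(
            f"need at least 3 cancers to fit a survival model, got {len(table)}"
        )
    x = table[betti_col].astype(float)
    y = table[survival_col].astype(float)
    fit = stats.linregress(x, y)
    r, p = pearson(x, y)
    if not math.isclose(fit.rvalue, r, rel_tol=0, abs_tol=1e-12):
        raise AssertionError("linregress r inconsistent with pearson")
    return SurvivalModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=r,
        p_value=p,
        n=len(table),
    )


def predict_survival_gain(
    model: SurvivalModel, betti_before: int, betti_after: int
) -> PredictedGain:
    """Interpolated change in percent survival for a Betti drop.

    Returns slope * (betti_after - betti_before): positive when the
    knockout lowers complexity under the fitted negative slope.
    """
    return PredictedGain(gain_pct=model.slope * (betti_after - betti_before))
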