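"""Method-comparison statistics for paired infarct-size measurements.

Bland–Altman bias and 1.96-SD limits of agreement, ordinary-least-squares
correlation, and a balanced two-factor fixed-effects ANOVA (the omnibus test
used to compare regions/methods at the 5% level).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

LOA_MULTIPLIER = 1.96


@dataclass
class AgreementResult:
    """Bland–Altman summary for methods a − b, plus the OLS fit of a on b."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    r_squared: float | None = None
    slope: float | None = None
    intercept: float | None = None
    means: np.ndarray = field(default=None, repr=False)
    differences: np.ndarray = field(default=None, repr=False)


@dataclass
class AnovaResult:
    """Two-factor fixed-effects decomposition.

    ``factors`` maps each term (factor A, factor B, optionally the
    interaction) to (sum of squares, degrees of freedom, F, p).
    """

    factors: dict[str, tuple[float, int, float, float]]
    ss_error: float
    df_error: int
    ss_total: float
    alpha: float = 0.05

    def significant(self, term: str) -> bool:
        return self.factors[term][3] < self.alpha


def _paired_columns(table: pd.DataFrame, method_a: str,
                    method_b: str) -> tuple[np.ndarray, np.ndarray]:
    """Extract paired per-subject sizes from a long (subject, method, size)
    table or directly from a wide table with method columns."""
    if {"subject", "method", "size_percent"}.issubset(table.columns):
        wide = table.pivot(index="subject", columns="method",
                           values="size_percent")
    else:
        wide = table
    for m in (method_a, method_b):
        if m not in wide.columns:
            raise ValueError(f"method {m!r} not present in table")
    wide = wide[[method_a, method_b]].dropna()
    return wide[method_a].to_numpy(float), wide[method_b].to_numpy(float)


def bland_altman(table: pd.DataFrame, method_a: str,
                 method_b: str) -> AgreementResult:
    """Bland–Altman agreement between two methods (differences a − b).

    Returns the mean difference (bias), its sample SD, and the 1.96-SD
    limits of agreement, with the mean-vs-difference pairs for plotting.
    """
    a, b = _paired_columns(table, method_a, method_b)
    if len(a) < 2:
        raise ValueError("Bland–Altman needs >= 2 paired observations")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementResult(
        bias=bias,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        sd_diff=sd,
        means=(a + b) / 2.0,
        differences=diff,
    )


def correlation_r2(table: pd.DataFrame, method_a: str,
                   method_b: str) -> tuple[float, float, float]:
    """Squared Pearson correlation and the OLS line of method_a on method_b."""
    a, b = _paired_columns(table, method_a, method_b)
    if len(a) < 3:
        raise ValueError("correlation needs >= 3 paired observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in one method's sizes")
    fit = stats.linregress(b, a)
    return float(fit.rvalue ** 2), float(fit.slope), float(fit.intercept)


def two_way_anova(values: np.ndarray, factor_a: np.ndarray,
                  factor_b: np.ndarray, alpha: float = 0.05) -> AnovaResult:
    """Balanced two-factor fixed-effects ANOVA.

    Requires a complete balanced layout (every (a, b) cell with the same
    number of replicates); the interaction term is included when cells hold
    more than one replicate.  F = MS_factor / MS_error, p from the F
    distribution.
    """
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "a": np.asarray(factor_a),
        "b": np.asarray(factor_b),
    })
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise ValueError("each factor needs >= 2 levels")
    cells = df.groupby(["a", "b"]).size()
    n_cells_expected = df["a"].nunique() * df["b"].nunique()
    if len(cells) != n_cells_expected or cells.nunique() != 1:
        raise ValueError("unbalanced or incomplete two-way layout")
    replicates = int(cells.iloc[0])

    formula = ("value ~ C(a) + C(b) + C(a):C(b)" if replicates > 1
               else "value ~ C(a) + C(b)")
    model = ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    rename = {"C(a)": "a", "C(b)": "b", "C(a):C(b)": "a:b"}
    factors = {}
    for term, row in table.iterrows():
        if term == "Residual":
            continue
        factors[rename.get(term, term)] = (
            float(row["sum_sq"]), int(row["df"]),
            float(row["F"]), float(row["PR(>F)"]),
        )
    resid = table.loc["Residual"]
    ss_error = float(resid["sum_sq"])
    df_error = int(resid["df"])
    grand = df["value"].mean()
    ss_total = float(np.sum((df["value"] - grand) ** 2))
    return AnovaResult(factors=factors, ss_error=ss_error, df_error=df_error,
                       ss_total=ss_total, alpha=alpha)
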