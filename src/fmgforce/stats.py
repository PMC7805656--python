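"""Two-way fixed-effects ANOVA and Tukey HSD post-hoc comparisons.

The factorial comparison asks whether band combination (15 levels) and
stage-1 algorithm (3 levels) affect the per-subject mean R^2.  The model
is the standard two-way fixed-effects ANOVA with interaction, fit by OLS
(statsmodels) with type-II sums of squares, at alpha = 0.05.  Pairwise
level comparisons use the Tukey HSD studentized-range statistic computed
from the cell means and the residual mean square.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import studentized_range
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .errors import DataError

ALPHA = 0.05


@dataclass
class AnovaResult:
    """ANOVA table plus the pieces Tukey HSD needs."""

    table: pd.DataFrame  # index: factor_a, factor_b, interaction, residual
    mse: float
    df_resid: float
    degenerate: bool = False  # all observations equal; F undefined
    alpha: float = ALPHA

    def f(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])

    def significant(self, effect: str) -> bool:
        return bool(self.p(effect) < self.alpha)


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
) -> AnovaResult:
    """Fixed-effects two-way ANOVA with interaction.

    ``values`` is one observation per row (e.g. per-subject mean R^2);
    every (A, B) cell must be nonempty.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "a": [str(x) for x in factor_a],
            "b": [str(x) for x in factor_b],
        }
    )
    if df.isna().any().any():
        raise DataError("ANOVA input contains missing values")
    cells = df.groupby(["a", "b"], observed=True).size()
    n_a, n_b = df["a"].nunique(), df["b"].nunique()
    if len(cells) < n_a * n_b:
        raise DataError("every factor-level cell must be nonempty")
    sst = float(np.sum((df["value"] - df["value"].mean()) ** 2))
    if sst == 0:
        table = pd.DataFrame(
            {
                "sum_sq": [0.0, 0.0, 0.0, 0.0],
                "df": [n_a - 1, n_b - 1, (n_a - 1) * (n_b - 1), len(df) - n_a * n_b],
                "F": [np.nan] * 4,
                "p": [np.nan] * 4,
            },
            index=["factor_a", "factor_b", "interaction", "residual"],
        )
        return AnovaResult(table=table, mse=0.0, df_resid=len(df) - n_a * n_b, degenerate=True)
    # one observation per cell saturates the interaction model; fall back
    # to the standard additive two-way ANOVA without replication
    formula = "value ~ C(a) * C(b)" if cells.max() > 1 else "value ~ C(a) + C(b)"
    model = ols(formula, data=df).fit()
    raw = anova_lm(model, typ=2)
    table = raw.rename(
        index={
            "C(a)": "factor_a",
            "C(b)": "factor_b",
            "C(a):C(b)": "interaction",
            "Residual": "residual",
        },
        columns={"PR(>F)": "p"},
    )
    mse = float(table.loc["residual", "sum_sq"] / table.loc["residual", "df"])
    return AnovaResult(table=table, mse=mse, df_resid=float(table.loc["residual", "df"]))


def tukey_hsd(
    cell_means: Mapping[str, float],
    mse: float,
    n_per_level: int,
    df_resid: float,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Studentized-range pairwise comparisons across factor levels.

    ``cell_means`` maps each level to its mean; ``mse`` and ``df_resid``
    come from the ANOVA; ``n_per_level`` is the (balanced) per-level
    observation count.  Returns one row per unordered level pair with the
    range statistic q, the Tukey p-value, and a significance flag.
    """
    if len(cell_means) < 2:
        raise DataError("Tukey HSD requires at least 2 levels")
    if n_per_level < 2:
        raise DataError("Tukey HSD requires at least 2 observations per level")
    if mse < 0 or df_resid <= 0:
        raise DataError("invalid residual mean square or df")
    levels = list(cell_means)
    k = len(levels)
    se = np.sqrt(mse / n_per_level)
    rows = []
    for la, lb in itertools.combinations(levels, 2):
        diff = float(cell_means[la] - cell_means[lb])
        if se == 0:
            q = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            q = abs(diff) / se
            p = float(studentized_range.sf(q, k, df_resid))
        rows.append(
            {
                "level_a": la,
                "level_b": lb,
                "diff": diff,
                "q": q,
                "p": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def tukey_from_anova(
    df: pd.DataFrame,
    value_col: str,
    level_col: str,
    anova: AnovaResult,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Tukey HSD over the levels of one factor, using the ANOVA residuals."""
    counts = df.groupby(level_col, observed=True)[value_col].count()
    means = df.groupby(level_col, observed=True)[value_col].mean().to_dict()
    return tukey_hsd(means, anova.mse, int(counts.min()), anova.df_resid, alpha)
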