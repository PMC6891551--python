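"""Cohort-level association analysis of gait features and GHQ-12 totals.

One row per included subject: the GHQ-12 total and the 16 gait features
(4 parameters × {pooled mean, pooled SD, SI mean, SI SD}), plus optional
covariates.  Three classical procedures operate on this table: Pearson
correlations of every feature with the GHQ total, ordinary least squares
regression of the total on a configurable predictor set, and Welch's
unequal-variance t-test for group contrasts.  p-values are two-sided and
uncorrected by default (Benjamini–Hochberg is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import CollinearityError, DegenerateInputError
from .parameters import PARAMETERS

__all__ = [
    "FEATURE_COLUMNS", "CorrelationReport", "RegressionReport",
    "pearson_correlation", "correlation_table", "fit_ols", "welch_ttest",
]

#: The 16 gait features in canonical report order (per parameter:
#: mean, SI of means, SD, SI of SDs — mirroring the correlation table).
FEATURE_COLUMNS = tuple(
    f"{p}_{suffix}" for p in PARAMETERS
    for suffix in ("mean", "si_mean", "sd", "si_sd")
)

#: Default regression predictors: all 16 gait features plus age.
DEFAULT_PREDICTORS = FEATURE_COLUMNS + ("age",)


@dataclass
class CorrelationReport:
    """Per-feature Pearson correlation with the GHQ-12 total."""

    table: pd.DataFrame  # feature, r, p, n, significant
    alpha: float = 0.05

    def __str__(self) -> str:
        lines = [f"{'feature':<28}{'r':>8}{'p':>10}"]
        for _, row in self.table.iterrows():
            star = " *" if row["significant"] else ""
            lines.append(f"{row['feature']:<28}{row['r']:>8.3f}"
                         f"{row['p']:>10.3g}{star}")
        return "\n".join(lines)


@dataclass
class RegressionReport:
    """OLS fit of the GHQ total on the gait feature set."""

    r: float
    r2: float
    f_stat: float
    df1: int
    df2: int
    f_pvalue: float
    coefficients: pd.DataFrame  # predictor, coef, t, p
    n: int

    def __str__(self) -> str:
        head = (f"overall r = {self.r:.3f} / r^2 = {self.r2:.3f}, "
                f"F{self.df1},{self.df2} = {self.f_stat:.3f} "
                f"(p = {self.f_pvalue:.3g}), n = {self.n}")
        lines = [head, f"{'predictor':<28}{'coef':>10}{'t':>8}{'p':>10}"]
        for _, row in self.coefficients.iterrows():
            lines.append(f"{row['predictor']:<28}{row['coef']:>10.4f}"
                         f"{row['t']:>8.3f}{row['p']:>10.3g}")
        return "\n".join(lines)


def _check_vector(x: np.ndarray, name: str, min_n: int = 3) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size < min_n:
        raise DegenerateInputError(f"{name}: need >= {min_n} values, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError(f"{name}: zero variance")
    return x


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with the classical two-sided t-test p.

    Raises
    ------
    DegenerateInputError
        On unequal lengths, n < 3, or zero variance in either vector.
    """
    x = _check_vector(x, "x")
    y = _check_vector(y, "y")
    if x.size != y.size:
        raise DegenerateInputError(f"length mismatch: {x.size} vs {y.size}")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlation_table(cohort: pd.DataFrame, target: str = "ghq_total",
                      features: tuple[str, ...] = FEATURE_COLUMNS,
                      alpha: float = 0.05,
                      fdr: bool = False) -> CorrelationReport:
    """Pearson r of every gait feature against the GHQ-12 total.

    ``fdr=True`` adds Benjamini–Hochberg-adjusted significance instead of
    raw ``p < alpha`` flags.

    Raises
    ------
    DegenerateInputError
        Naming the offending feature column.
    """
    rows = []
    y = cohort[target].to_numpy(dtype=float)
    for feat in features:
        if feat not in cohort.columns:
            raise DegenerateInputError(f"feature column {feat!r} missing")
        try:
            r, p = pearson_correlation(cohort[feat].to_numpy(dtype=float), y)
        except DegenerateInputError as exc:
            raise DegenerateInputError(f"{feat}: {exc}") from exc
        rows.append({"feature": feat, "r": r, "p": p, "n": len(cohort)})
    table = pd.DataFrame(rows)
    if fdr:
        table["significant"] = multipletests(table["p"], alpha=alpha,
                                             method="fdr_bh")[0]
    else:
        table["significant"] = table["p"] < alpha
    return CorrelationReport(table=table, alpha=alpha)


def fit_ols(cohort: pd.DataFrame, predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
            target: str = "ghq_total") -> RegressionReport:
    """OLS of the GHQ total on the predictor set, with intercept.

    Reports overall r/r², the model F on (p, n−p−1) df, and per-predictor
    unstandardized coefficients with t statistics and two-sided p-values.

    Raises
    ------
    DegenerateInputError
        If n <= p + 1.
    CollinearityError
        If the design matrix is rank deficient, naming dependent columns.
    """
    missing = [c for c in predictors if c not in cohort.columns]
    if missing:
        raise DegenerateInputError(f"predictor columns missing: {missing}")
    X = cohort[list(predictors)].to_numpy(dtype=float)
    y = cohort[target].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise DegenerateInputError(f"n={n} too small for {p} predictors")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name columns whose removal restores full rank
        offenders = []
        for j, name in enumerate(predictors):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                offenders.append(name)
        raise CollinearityError(
            "design matrix rank deficient; dependent columns: "
            + ", ".join(offenders)
        )
    fit = sm.OLS(y, design).fit()
    coeffs = pd.DataFrame({
        "predictor": ("intercept",) + tuple(predictors),
        "coef": fit.params,
        "t": fit.tvalues,
        "p": fit.pvalues,
    })
    return RegressionReport(
        r=float(np.sqrt(fit.rsquared)), r2=float(fit.rsquared),
        f_stat=float(fit.fvalue), df1=int(fit.df_model),
        df2=int(fit.df_resid), f_pvalue=float(fit.f_pvalue),
        coefficients=coeffs, n=n,
    )


def welch_ttest(group_a: np.ndarray, group_b: np.ndarray
                ) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test (Satterthwaite df), two-sided.

    Returns ``(t, p, mean_a - mean_b)``.

    Raises
    ------
    DegenerateInputError
        If either group has fewer than 2 values.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each group needs >= 2 values")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue), float(a.mean() - b.mean())
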