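"""Inferential layer: composition chi-squares, factorial ANOVA, t-tests.

Conventions follow the SPSS-style "univariate general linear modeling"
reporting that dominates survey-methods work:

* Pearson chi-square without continuity correction, after dropping
  non-substantive categories ("did not specify") from the table.
* Between-subjects fixed-effects ANOVA with Type-III sums of squares under
  effects (sum-to-zero) coding, so unbalanced cells are handled the way SPSS
  UNIANOVA handles them.
* Effect size is partial eta-squared, recoverable from an F statistic via
  the identity η²_p = F·df1 / (F·df1 + df2).
* Observed (post-hoc) power evaluates the noncentral-F tail beyond the
  central-F critical value, with noncentrality λ = F·df1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "Chi2Result",
    "FactorialEffect",
    "TTestResult",
    "pearson_chi2",
    "partial_eta_sq",
    "observed_power",
    "anova_between",
    "two_sample_t",
]


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p_value: float
    table_used: pd.DataFrame  # contingency counts after exclusions


@dataclass(frozen=True)
class FactorialEffect:
    effect: str
    F: float
    df1: int
    df2: int
    p_value: float
    partial_eta_sq: float
    observed_power: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_value: float
    mean_x: float
    mean_y: float


def pearson_chi2(
    table: pd.DataFrame | Sequence[Sequence[float]],
    drop_labels: Sequence[str] = (),
) -> Chi2Result:
    """Pearson chi-square of independence, no continuity correction.

    ``drop_labels`` removes matching row/column labels (e.g. "did_not_specify")
    before testing.  A zero row/column margin raises, naming the offender.
    """
    df = pd.DataFrame(table).astype(float)
    if drop_labels:
        df = df.drop(index=[l for l in drop_labels if l in df.index], errors="ignore")
        df = df.drop(columns=[l for l in drop_labels if l in df.columns], errors="ignore")
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need at least a 2x2 table after dropping labels")
    if (df.to_numpy() < 0).any():
        raise ValueError("contingency counts must be non-negative")
    row_sums = df.sum(axis=1)
    col_sums = df.sum(axis=0)
    for label, s in row_sums.items():
        if s == 0:
            raise ValueError(f"degenerate contingency table: row {label!r} sums to 0")
    for label, s in col_sums.items():
        if s == 0:
            raise ValueError(f"degenerate contingency table: column {label!r} sums to 0")
    chi2, p, dof, _ = _st.chi2_contingency(df.to_numpy(), correction=False)
    return Chi2Result(chi2=float(chi2), df=int(dof), p_value=float(p), table_used=df)


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """Partial eta-squared from an F statistic: F·df1 / (F·df1 + df2)."""
    if F < 0:
        raise ValueError("F must be non-negative")
    return F * df1 / (F * df1 + df2)


def observed_power(F: float, df1: int, df2: int, alpha: float = 0.05) -> float:
    """Post-hoc power: P[F' > F_crit(α)] with F' ~ noncentral F(df1, df2, λ=F·df1)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if F < 0:
        raise ValueError("F must be non-negative")
    f_crit = _st.f.isf(alpha, df1, df2)
    if F == 0:
        return float(alpha)
    return float(_st.ncf.sf(f_crit, df1, df2, F * df1))


def anova_between(
    outcome: Sequence[float],
    factors: Mapping[str, Sequence],
    include_interactions: bool = True,
    alpha: float = 0.05,
) -> dict[str, FactorialEffect]:
    """Between-subjects fixed-effects ANOVA, Type-III SS, effects coding.

    ``outcome`` and each factor are parallel per-respondent sequences;
    incomplete cases (NaN/None anywhere) are dropped listwise.  By default
    the full factorial (all interactions) is fitted, the SPSS UNIANOVA
    convention; ``include_interactions=False`` fits main effects only.
    Returns one :class:`FactorialEffect` per model term, keyed by the factor
    name (interaction terms keyed ``"a:b"``).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    names = list(factors)
    if not names:
        raise ValueError("at least one factor is required")
    data = pd.DataFrame({"_y": pd.to_numeric(outcome)})
    for name, values in factors.items():
        data[name] = pd.Series(list(values), dtype=object)
    data = data.dropna()
    for name in names:
        if data[name].nunique() < 2:
            raise ValueError(f"factor {name!r} has fewer than 2 levels after listwise deletion")
    cells = data.groupby(names, observed=True).size()
    full = int(np.prod([data[n].nunique() for n in names]))
    if include_interactions and len(cells) < full:
        import warnings

        warnings.warn(
            f"empty cell(s) in the full design ({len(cells)}/{full} occupied)",
            stacklevel=2,
        )
    terms = [f"C({n}, Sum)" for n in names]
    op = "*" if include_interactions else "+"
    formula = "_y ~ " + op.join(terms)
    try:
        fit = smf.ols(formula, data=data).fit()
    except Exception as exc:  # pragma: no cover - singular designs are rare
        raise ValueError(f"singular design: {exc}") from exc
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("singular design matrix (aliased factorial terms)")
    table = sm.stats.anova_lm(fit, typ=3)
    df2 = int(table.loc["Residual", "df"])
    out: dict[str, FactorialEffect] = {}
    for term in table.index:
        if term in ("Intercept", "Residual"):
            continue
        # strip the coding decoration back to plain factor names
        clean = term.replace("C(", "").replace(", Sum)", "")
        F = float(table.loc[term, "F"])
        df1 = int(table.loc[term, "df"])
        out[clean] = FactorialEffect(
            effect=clean,
            F=F,
            df1=df1,
            df2=df2,
            p_value=float(table.loc[term, "PR(>F)"]),
            partial_eta_sq=partial_eta_sq(F, df1, df2),
            observed_power=observed_power(F, df1, df2, alpha),
        )
    return out


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Pooled-variance Student t on complete cases; df = n1 + n2 − 2."""
    xa = np.asarray(pd.to_numeric(pd.Series(list(x)), errors="coerce").dropna(), dtype=float)
    ya = np.asarray(pd.to_numeric(pd.Series(list(y)), errors="coerce").dropna(), dtype=float)
    if len(xa) < 2 or len(ya) < 2:
        raise ValueError("each sample needs at least 2 complete cases")
    if np.var(xa, ddof=1) == 0 and np.var(ya, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    t, p = _st.ttest_ind(xa, ya, equal_var=True)
    return TTestResult(
        t=float(t),
        df=len(xa) + len(ya) - 2,
        p_value=float(p),
        mean_x=float(xa.mean()),
        mean_y=float(ya.mean()),
    )
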