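"""Bioassay survival statistics.

The hazard ratio is the observed/expected-ratio (Mantel-Haenszel style)
log-rank estimator — at each distinct event time groups are pooled and
expected deaths computed from the at-risk proportions — not the Cox
model estimate.  The accompanying chi-square is the sum((O-E)^2/E)
form on 1 df.  Cox fitting (Efron ties) and OLS delegate to
established statistics backends.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "SurvivalRecord",
    "read_survival_table",
    "logrank_hazard_ratio",
    "LogrankResult",
    "cox_ph_fit",
    "CoxResult",
    "hazard_regression",
    "RegressionResult",
    "paired_t",
]


@dataclass(frozen=True)
class SurvivalRecord:
    subject: str
    group: str
    time: int  # days, >= 1
    event: int  # 1 death observed, 0 censored

    def __post_init__(self) -> None:
        if self.time < 1:
            raise ValueError("time must be >= 1 day")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def read_survival_table(path, sep: Optional[str] = None) -> list[SurvivalRecord]:
    """Delimited text with columns subject, group, day, event."""
    df = pd.read_csv(path, sep=sep, engine="python")
    cols = {c.lower(): c for c in df.columns}
    needed = ["subject", "group", "day", "event"]
    missing = [c for c in needed if c not in cols]
    if missing:
        raise ValueError(f"missing column(s): {missing}")
    return [
        SurvivalRecord(
            subject=str(r[cols["subject"]]),
            group=str(r[cols["group"]]),
            time=int(r[cols["day"]]),
            event=int(r[cols["event"]]),
        )
        for _, r in df.iterrows()
    ]


@dataclass(frozen=True)
class LogrankResult:
    hazard_ratio: float
    chi_square: float
    p_value: float
    observed: tuple[float, float]  # treated, control
    expected: tuple[float, float]


def logrank_hazard_ratio(
    treated: Sequence[SurvivalRecord],
    control: Sequence[SurvivalRecord],
    one_tailed: bool = False,
) -> LogrankResult:
    """Observed/expected log-rank hazard ratio of treated vs control.

    HR = (O_t/E_t)/(O_c/E_c); chi-square = sum((O-E)^2/E) on 1 df.
    ``one_tailed`` halves the p when the treated group is the riskier
    one (the planned direction), else reports 1 - p/2.
    """
    if not treated or not control:
        raise ValueError("both groups must be non-empty")
    times_t = np.array([r.time for r in treated])
    events_t = np.array([r.event for r in treated])
    times_c = np.array([r.time for r in control])
    events_c = np.array([r.event for r in control])
    if events_t.sum() + events_c.sum() == 0:
        raise ValueError("no events in either group")

    event_times = np.unique(
        np.concatenate([times_t[events_t == 1], times_c[events_c == 1]])
    )
    O_t = float(events_t.sum())
    O_c = float(events_c.sum())
    E_t = E_c = 0.0
    for t in event_times:
        n_t = float((times_t >= t).sum())
        n_c = float((times_c >= t).sum())
        d = float(((times_t == t) & (events_t == 1)).sum()) + float(
            ((times_c == t) & (events_c == 1)).sum()
        )
        n = n_t + n_c
        E_t += d * n_t / n
        E_c += d * n_c / n
    if E_t == 0:
        raise ValueError("zero expected deaths in treated group")
    if E_c == 0:
        raise ValueError("zero expected deaths in control group")
    if O_c == 0:
        hr = math.inf
    else:
        hr = (O_t / E_t) / (O_c / E_c)
    chi2 = (O_t - E_t) ** 2 / E_t + (O_c - E_c) ** 2 / E_c
    p_two = float(_stats.chi2.sf(chi2, df=1))
    if one_tailed:
        p = p_two / 2 if hr >= 1 else 1 - p_two / 2
    else:
        p = p_two
    return LogrankResult(
        hazard_ratio=hr,
        chi_square=float(chi2),
        p_value=p,
        observed=(O_t, O_c),
        expected=(E_t, E_c),
    )


@dataclass
class CoxResult:
    coefficients: pd.Series  # log-hazard per covariate
    z_scores: pd.Series
    p_values: pd.Series
    concordance: float
    concordance_ci: tuple[float, float]
    dropped: list[str]  # constant covariates, reported as 0 with flag


def cox_ph_fit(
    df: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
    n_boot: int = 200,
    seed: int = 0,
) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) with Harrell's C.

    Constant covariates are dropped with a warning and reported as 0.
    The concordance CI is a subject-level bootstrap percentile interval.
    """
    from lifelines import CoxPHFitter
    from lifelines.utils import concordance_index

    data = df[[duration_col, event_col, *covariates]].copy()
    if (data[event_col].sum()) < 1:
        raise ValueError("no events")
    dropped = [c for c in covariates if data[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"constant covariate(s) dropped: {dropped}", stacklevel=2)
    used = [c for c in covariates if c not in dropped]
    if not used:
        raise ValueError("no informative covariates")
    cph = CoxPHFitter()
    try:
        cph.fit(
            data[[duration_col, event_col, *used]],
            duration_col=duration_col,
            event_col=event_col,
        )
    except Exception as exc:  # pragma: no cover - backend specific
        raise RuntimeError(f"Cox fit did not converge: {exc}") from exc

    coeffs = cph.params_.reindex(covariates).fillna(0.0)
    z = (cph.params_ / cph.standard_errors_).reindex(covariates).fillna(0.0)
    pvals = cph.summary["p"].reindex(covariates).fillna(1.0)

    risk = -cph.predict_partial_hazard(data)  # higher risk = shorter survival
    c_hat = concordance_index(data[duration_col], risk, data[event_col])

    rng = np.random.default_rng(seed)
    n = len(data)
    boots = []
    times = data[duration_col].to_numpy()
    events = data[event_col].to_numpy()
    riskv = np.asarray(risk).ravel()
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if events[idx].sum() == 0:
            continue
        try:
            boots.append(concordance_index(times[idx], riskv[idx], events[idx]))
        except ZeroDivisionError:
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:  # pragma: no cover
        lo = hi = c_hat
    return CoxResult(
        coefficients=coeffs,
        z_scores=z,
        p_values=pvals,
        concordance=float(c_hat),
        concordance_ci=(float(lo), float(hi)),
        dropped=dropped,
    )


@dataclass
class RegressionResult:
    coefficients: pd.Series
    p_values: pd.Series
    multiple_r: float
    shapiro_p: float


def hazard_regression(
    df: pd.DataFrame,
    response: str,
    numeric: Sequence[str],
    categorical: Optional[dict[str, str]] = None,
) -> RegressionResult:
    """OLS of a hazard ratio on numeric and categorical predictors.

    ``categorical`` maps column name -> reference level.  Returns the
    coefficient table, multiple R (sqrt of R^2) and the Shapiro-Wilk
    residual-normality p.
    """
    import statsmodels.api as sm

    categorical = categorical or {}
    n_params = 1 + len(numeric) + sum(df[c].nunique() - 1 for c in categorical)
    if len(df) < n_params + 1:
        raise ValueError("too few observations for the requested model")
    X = df[list(numeric)].astype(float).copy()
    for col, ref in categorical.items():
        levels = [lv for lv in df[col].unique() if lv != ref]
        if ref not in set(df[col]):
            raise ValueError(f"reference level {ref!r} absent from {col!r}")
        for lv in sorted(map(str, levels)):
            X[f"{col}[{lv}]"] = (df[col].astype(str) == lv).astype(float)
    X = sm.add_constant(X)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(f"design matrix rank deficient ({rank} < {X.shape[1]})")
    model = sm.OLS(df[response].astype(float), X).fit()
    resid = model.resid
    shapiro_p = float(_stats.shapiro(resid).pvalue) if len(resid) >= 3 else float("nan")
    return RegressionResult(
        coefficients=model.params,
        p_values=model.pvalues,
        multiple_r=float(np.sqrt(model.rsquared)),
        shapiro_p=shapiro_p,
    )


def paired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, int, float]:
    """Classical paired t on differences; returns (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0):
        if np.allclose(d, 0):
            return 0.0, len(d) - 1, 1.0
        raise ValueError("zero difference variance")
    res = _stats.ttest_rel(a, b)
    return float(res.statistic), len(a) - 1, float(res.pvalue)
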