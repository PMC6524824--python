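"""Expression-quartile survival stratification.

Patients are split on the 25th/75th percentiles of a signature gene's
expression into low / high / excluded classes; follow-up is
administratively censored at a horizon (10 years by default, so deaths
beyond the horizon count as survivors); the two classes are compared with
an in-house Kaplan-Meier product-limit estimate and two-group log-rank
test, and a multivariate Cox proportional-hazards model (Efron ties,
delegated to lifelines) reports adjusted hazard ratios.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "administrative_censor",
    "quartile_groups",
    "stage_class",
    "km_estimate",
    "KMCurve",
    "logrank_test",
    "cox_multivariate",
    "CoxResult",
]


def administrative_censor(records: pd.DataFrame, horizon: float = 10.0) -> pd.DataFrame:
    """Censor every record at ``horizon`` years: any time beyond it becomes
    (horizon, event=0); earlier records are unchanged.  Idempotent."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if (records["time"] < 0).any():
        raise ValueError("negative survival times")
    out = records.copy()
    late = out["time"] > horizon
    out.loc[late, "time"] = horizon
    out.loc[late, "event"] = 0
    return out


def quartile_groups(expression: pd.Series) -> pd.Series:
    """Class each patient as 'low' (<= 25th percentile), 'high' (>= 75th)
    or 'excluded' (strictly between).

    Percentiles use linear interpolation between order statistics.  A
    constant expression vector excludes everyone (logged).
    """
    vals = expression.astype(float)
    if vals.isna().any():
        raise ValueError("missing expression values")
    if len(vals) < 4:
        raise ValueError("need at least 4 patients to form quartile groups")
    q25, q75 = np.percentile(vals.to_numpy(), [25, 75])
    if q25 == q75:
        logger.warning("constant expression: all patients excluded")
        return pd.Series("excluded", index=vals.index, name="group")
    out = pd.Series("excluded", index=vals.index, name="group")
    out[vals <= q25] = "low"
    out[vals >= q75] = "high"
    return out


def stage_class(pathologic_stage: pd.Series) -> pd.Series:
    """Map pathologic stage I/II -> 'early' and III/IV -> 'late'."""
    def classify(s):
        if pd.isna(s):
            return pd.NA
        token = str(s).upper().replace("STAGE", "").strip()
        token = token.rstrip("ABC")
        if token in ("I", "II", "1", "2"):
            return "early"
        if token in ("III", "IV", "3", "4"):
            return "late"
        return pd.NA
    return pathologic_stage.map(classify)


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate over distinct event times."""

    times: np.ndarray      # distinct times with at least one death
    at_risk: np.ndarray    # n_i just before each event time
    deaths: np.ndarray     # d_i at each event time
    survival: np.ndarray   # S(t_i) = prod_{t_j <= t_i} (1 - d_j / n_j)

    def survival_at(self, t: float) -> float:
        """S(t); 1 before the first event, right-continuous step function."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Product-limit estimate from one group's (time, event) records.

    Censored times reduce the risk set but contribute no factor; by the
    usual convention a censoring tied with a death stays at risk for it.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("no records")
    if (t < 0).any():
        raise ValueError("negative survival times")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    out_t, out_n, out_d, out_s = [], [], [], []
    s = 1.0
    n = t.size
    i = 0
    while i < t.size:
        j = i
        while j < t.size and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        if d > 0:
            s *= 1.0 - d / n
            out_t.append(t[i]); out_n.append(n); out_d.append(d); out_s.append(s)
        n -= j - i
        i = j
    return KMCurve(
        times=np.array(out_t), at_risk=np.array(out_n, dtype=int),
        deaths=np.array(out_d, dtype=int), survival=np.array(out_s),
    )


def logrank_test(times1, events1, times2, events2) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic (1 df) and p-value.

    At each distinct event time the observed deaths in group 1 are compared
    with the hypergeometric expectation given the pooled risk sets.
    """
    t1, e1 = np.asarray(times1, float), np.asarray(events1, int)
    t2, e2 = np.asarray(times2, float), np.asarray(events2, int)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both groups must be non-empty")
    if e1.sum() + e2.sum() == 0:
        raise ValueError("no events in either group")
    event_times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = int((t1 >= t).sum())
        n2 = int((t2 >= t).sum())
        d1 = int(((t1 == t) & (e1 == 1)).sum())
        d2 = int(((t2 == t) & (e2 == 1)).sum())
        n = n1 + n2
        d = d1 + d2
        if n < 2 or n1 == 0 or n2 == 0:
            continue
        exp1 = d * n1 / n
        o_minus_e += d1 - exp1
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class CoxResult:
    """Outcome of a multivariate proportional-hazards fit.

    ``success`` is False for non-convergence or a rank-deficient design;
    the (empty) summary and the message say why.
    """

    success: bool
    summary: pd.DataFrame  # index covariate; columns coef, hazard_ratio, se, p
    message: str = ""

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hazard_ratio"])

    def p_value(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])


def cox_multivariate(
    records: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time",
    event_col: str = "event",
) -> CoxResult:
    """Multivariate Cox proportional-hazards fit (Efron tie handling).

    Refuses constant covariates and designs with fewer events than
    covariates; a rank-deficient (collinear) design or a failed fit is
    reported as an unsuccessful :class:`CoxResult`, never silently.
    """
    x = records[covariates].astype(float)
    for c in covariates:
        if x[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant")
    n_events = int(records[event_col].sum())
    if n_events < len(covariates):
        raise ValueError(
            f"only {n_events} events for {len(covariates)} covariates"
        )
    std = (x - x.mean()) / x.std(ddof=0)
    if np.linalg.matrix_rank(std.to_numpy()) < len(covariates):
        return CoxResult(
            success=False, summary=pd.DataFrame(),
            message="collinear covariates: design matrix is rank deficient",
        )
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = pd.concat(
        [records[[duration_col, event_col]], x], axis=1
    ).dropna()
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except (ConvergenceError, ValueError) as exc:
        return CoxResult(success=False, summary=pd.DataFrame(),
                         message=f"fit failure: {exc}")
    summ = pd.DataFrame({
        "coef": cph.params_,
        "hazard_ratio": np.exp(cph.params_),
        "se": cph.standard_errors_,
        "p": cph.summary["p"],
    })
    return CoxResult(success=True, summary=summ)
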