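"""Lymphocyte stability, 2x2 odds ratios and adjusted logistic association.

Lymphocyte stability (LS) compares the pre-treatment blood lymphocyte count
(the measurement closest to the first infusion, no more than 30 days before
it; day 0 qualifies) with the first count taken at least 21 days — and no
later than 49 days — after treatment start.  A patient is *stable* when the
count rose or fell by less than 20%; a fall of exactly 20% is unstable.

Association statistics follow the conventions of genotype-toxicity cohort
analyses: 2x2 odds ratios with Woolf (log-normal) confidence intervals and
a two-sided Fisher exact p computed by hypergeometric enumeration, and
covariate-adjusted logistic regression (maximum likelihood) with Wald
intervals for the adjusted odds ratio — a fixed-effect stand-in for
mediation-style "controlling for" analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PRE_WINDOW = (-30, 0)
POST_WINDOW = (21, 49)
STABLE_FALL_PCT = -20.0


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


@dataclass(frozen=True)
class Observation:
    day: int
    count: float


@dataclass(frozen=True)
class PairSelection:
    patient_id: str
    pre: Observation | None
    post: Observation | None
    reasons: tuple = ()

    @property
    def complete(self) -> bool:
        return self.pre is not None and self.post is not None


@dataclass(frozen=True)
class LSResult:
    patient_id: str
    pre_count: float
    post_count: float
    pre_day: int
    post_day: int
    delta: float
    pct_change: float
    stable: bool


@dataclass(frozen=True)
class AssociationResult:
    estimate: float
    ci_lo: float
    ci_hi: float
    p_value: float
    method: str
    n: int


def select_lymphocyte_pair(series: pd.DataFrame, patient_id: str = "") -> PairSelection:
    """Pick the pre/post-treatment counts from one patient's series.

    ``series`` needs ``day_offset`` and ``lymphocyte_count`` columns.  Pre
    is the observation in [-30, 0] with the largest day (closest to
    treatment); post is the first observation in [21, 49].  When several
    rows share the chosen day, the last-entered row wins.  Missing windows
    are reported as reason codes, never raised.
    """
    pid = patient_id or (str(series["patient_id"].iloc[0]) if "patient_id" in series and len(series) else "")
    reasons = []

    def _pick(lo: int, hi: int, which: str) -> Observation | None:
        win = series[(series["day_offset"] >= lo) & (series["day_offset"] <= hi)]
        if len(win) == 0:
            reasons.append(f"no_{which}")
            return None
        day = win["day_offset"].max() if which == "pre" else win["day_offset"].min()
        row = win[win["day_offset"] == day].iloc[-1]  # last-entered wins on ties
        return Observation(day=int(day), count=float(row["lymphocyte_count"]))

    pre = _pick(*PRE_WINDOW, "pre")
    post = _pick(*POST_WINDOW, "post")
    return PairSelection(patient_id=pid, pre=pre, post=post, reasons=tuple(reasons))


def lymphocyte_stability(pre: Observation, post: Observation, patient_id: str = "") -> LSResult:
    """Classify a patient's lymphocyte trajectory as stable or unstable.

    Stable means the count increased or fell by less than 20%; a fall of
    20% or more is unstable.
    """
    if pre.count <= 0:
        raise ValueError(f"pre-treatment count must be positive, got {pre.count}")
    delta = post.count - pre.count
    pct = 100.0 * delta / pre.count
    # strict ">" at the -20% boundary, robust to float round-off of the ratio
    stable = pct > STABLE_FALL_PCT + 1e-9
    return LSResult(
        patient_id=patient_id,
        pre_count=pre.count,
        post_count=post.count,
        pre_day=pre.day,
        post_day=post.day,
        delta=delta,
        pct_change=pct,
        stable=bool(stable),
    )


def ls_table(series: pd.DataFrame) -> pd.DataFrame:
    """Per-patient LS results for a long-format lymphocyte table.

    Patients missing either window appear with ``excluded_reason`` set and
    NaN metrics.
    """
    rows = []
    for pid, sub in series.groupby("patient_id", sort=True):
        sel = select_lymphocyte_pair(sub, patient_id=str(pid))
        if not sel.complete:
            rows.append({"patient_id": str(pid), "excluded_reason": ";".join(sel.reasons)})
            continue
        r = lymphocyte_stability(sel.pre, sel.post, patient_id=str(pid))
        rows.append(
            {
                "patient_id": r.patient_id,
                "pre_count": r.pre_count,
                "post_count": r.post_count,
                "pre_day": r.pre_day,
                "post_day": r.post_day,
                "delta": r.delta,
                "pct_change": r.pct_change,
                "stable": r.stable,
                "excluded_reason": "",
            }
        )
    return pd.DataFrame(rows)


def fisher_exact_p(table: np.ndarray) -> float:
    """Two-sided Fisher exact p by enumeration of the hypergeometric pmf.

    All tables with the observed margins are enumerated; those whose
    probability does not exceed the observed table's (within a relative
    tolerance of 1e-7) contribute to p.
    """
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    k = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(k, n, row1, col1)
    p_obs = stats.hypergeom.pmf(a, n, row1, col1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum().clip(0.0, 1.0))


def odds_ratio_2x2(table, zero_rule: str = "haldane") -> AssociationResult:
    """Odds ratio of a 2x2 table with Woolf 95% CI and Fisher exact p.

    ``zero_rule='haldane'`` adds 0.5 to every cell when any cell is zero
    before forming the estimate and interval; ``'none'`` raises instead.
    The Fisher p is always computed on the raw counts.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be a 2x2 array of non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("2x2 table has a zero margin")
    p = fisher_exact_p(t)
    w = t.copy()
    if (w == 0).any():
        if zero_rule == "haldane":
            w = w + 0.5
        elif zero_rule == "none":
            raise ValueError("zero cell with zero_rule='none'")
        else:
            raise ValueError(f"unknown zero_rule {zero_rule!r}")
    a, b, c, d = w.ravel()
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    return AssociationResult(
        estimate=float(np.exp(log_or)),
        ci_lo=float(np.exp(log_or - z * se)),
        ci_hi=float(np.exp(log_or + z * se)),
        p_value=p,
        method="fisher",
        n=int(t.sum()),
    )


def logistic_association(
    outcome,
    exposure,
    covariates: pd.DataFrame | None = None,
) -> AssociationResult:
    """Adjusted odds ratio for ``exposure`` from a logistic regression.

    Fits P(outcome) by maximum likelihood on an intercept, the exposure
    and any covariates, and returns the exponentiated exposure coefficient
    with its Wald 95% interval.  Perfect separation is detected and
    raised as :class:`SeparationError` rather than silently returned.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    if y.size < 20:
        raise ValueError(f"need n >= 20 subjects, got {y.size}")
    X = pd.DataFrame({"exposure": x})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        X = pd.concat([X, cov.astype(float)], axis=1)
    X = sm.add_constant(X)

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
        except (PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
            raise SeparationError(f"perfect separation or singular fit: {exc}") from exc
    if not fit.mle_retvals.get("converged", True) or abs(fit.params["exposure"]) > 15:
        raise SeparationError("logistic fit did not converge; exposure likely separates outcome")

    coef = float(fit.params["exposure"])
    se = float(fit.bse["exposure"])
    z = stats.norm.ppf(0.975)
    return AssociationResult(
        estimate=float(np.exp(coef)),
        ci_lo=float(np.exp(coef - z * se)),
        ci_hi=float(np.exp(coef + z * se)),
        p_value=float(fit.pvalues["exposure"]),
        method="glm_binomial",
        n=int(y.size),
    )
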