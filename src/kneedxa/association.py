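"""Association models validating the rKOA grades against clinical outcomes.

Binary outcomes (prolonged knee pain, hospital-diagnosed knee OA) are fitted
with logistic regression and reported as odds ratios; total knee replacement
is fitted with Cox proportional hazards (Efron tie handling) and reported as
hazard ratios. Every exposure level is contrasted against the grade-0
reference; confidence intervals are Wald intervals on the log scale. The
standard adjustment set is age, sex, height, weight and ethnicity, with
optional sex stratification and exposure-by-sex interaction terms, and a
Schoenfeld-residual check of the proportional-hazards assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats
from sklearn.metrics import cohen_kappa_score

DEFAULT_ADJUST = ("age", "sex", "height_cm", "weight_kg", "ethnicity")

_Z95 = stats.norm.ppf(0.975)


class ModelError(RuntimeError):
    """Raised when a model cannot be fitted on the supplied data."""


@dataclass(frozen=True)
class AssocResult:
    """One fitted exposure-level contrast against the grade-0 reference."""

    exposure: str
    level: str
    outcome: str
    measure: str  # "OR" or "HR"
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted: bool
    stratum: str = "all"  # all | female | male
    n: int = 0
    n_events: int = 0
    flag: Optional[str] = None
    interaction_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.flag is None and not (
            self.ci_low <= self.estimate <= self.ci_high and self.estimate > 0
        ):
            raise ValueError("confidence interval must bracket a positive estimate")


def _design(
    rows: pd.DataFrame,
    exposure: str,
    adjust: Sequence[str],
    *,
    with_sex_interaction: bool = False,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Build a design matrix with exposure dummies (reference = lowest level).

    Returns (X, exposure_columns, interaction_columns). Categorical
    covariates (sex, ethnicity) are dummy-coded against their most frequent
    level.
    """
    levels = sorted(rows[exposure].unique())
    if len(levels) < 2:
        raise ModelError(f"exposure {exposure!r} has a single level")
    X = pd.DataFrame(index=rows.index)
    exp_cols = []
    for lv in levels[1:]:
        col = f"{exposure}_{lv}"
        X[col] = (rows[exposure] == lv).astype(float)
        exp_cols.append(col)

    sex_col = None
    for cov in adjust:
        if cov not in rows.columns:
            raise ModelError(f"adjustment covariate {cov!r} missing from data")
        if rows[cov].dtype == object or str(rows[cov].dtype) == "category":
            ref = rows[cov].value_counts().idxmax()
            for lv in sorted(v for v in rows[cov].unique() if v != ref):
                X[f"{cov}_{lv}"] = (rows[cov] == lv).astype(float)
                if cov == "sex":
                    sex_col = f"{cov}_{lv}"
        else:
            X[cov] = rows[cov].astype(float)

    inter_cols = []
    if with_sex_interaction:
        if sex_col is None:
            if "sex" not in rows.columns or rows["sex"].nunique() < 2:
                raise ModelError("sex interaction requires both sexes present")
            ref = rows["sex"].value_counts().idxmax()
            other = sorted(v for v in rows["sex"].unique() if v != ref)[0]
            sex_col = f"sex_{other}"
            X[sex_col] = (rows["sex"] == other).astype(float)
        for col in exp_cols:
            icol = f"{col}:{sex_col}"
            X[icol] = X[col] * X[sex_col]
            inter_cols.append(icol)
    return X, exp_cols, inter_cols


def _wald_results(
    params: pd.Series,
    se: pd.Series,
    pvals: pd.Series,
    exp_cols: list[str],
    *,
    exposure: str,
    outcome: str,
    measure: str,
    adjusted: bool,
    stratum: str,
    n: int,
    n_events: int,
    flags: dict[str, str],
) -> list[AssocResult]:
    out = []
    for col in exp_cols:
        level = col[len(exposure) + 1 :]
        b, s = float(params[col]), float(se[col])
        with np.errstate(over="ignore"):  # flagged unstable fits may overflow
            out.append(
                AssocResult(
                    exposure=exposure,
                    level=str(level),
                    outcome=outcome,
                    measure=measure,
                    estimate=float(np.exp(b)),
                    ci_low=float(np.exp(b - _Z95 * s)),
                    ci_high=float(np.exp(b + _Z95 * s)),
                    p_value=float(pvals[col]),
                    adjusted=adjusted,
                    stratum=stratum,
                    n=n,
                    n_events=n_events,
                    flag=flags.get(col),
                )
            )
    return out


def fit_logistic(
    rows: pd.DataFrame,
    outcome: str,
    exposure: str,
    adjust: Sequence[str] = (),
    stratum: str = "all",
) -> list[AssocResult]:
    """Logistic regression of a binary outcome on exposure levels.

    Returns one odds ratio (Wald 95% CI) per non-reference exposure level.
    Quasi-separated levels are returned flagged rather than failing silently.
    """
    y = rows[outcome].astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ModelError(f"outcome {outcome!r} is not binary")
    X, exp_cols, _ = _design(rows, exposure, adjust)
    X = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        except Exception as exc:  # singular design and the like
            raise ModelError(f"logistic fit failed: {exc}") from exc
    flags = {
        c: "possible separation (unstable estimate)"
        for c in exp_cols
        if float(res.bse[c]) > 10 or not np.isfinite(res.bse[c])
    }
    return _wald_results(
        res.params, res.bse, res.pvalues, exp_cols,
        exposure=exposure, outcome=outcome, measure="OR", adjusted=bool(adjust),
        stratum=stratum, n=len(rows), n_events=int(y.sum()), flags=flags,
    )


def _fit_cox(X: pd.DataFrame, time: str, event: str) -> CoxPHFitter:
    """Fit a CoxPHFitter, damping the Newton step if the default diverges."""
    last: Exception | None = None
    for step in (None, 0.5, 0.1):
        cph = CoxPHFitter()
        opts = {"step_size": step} if step else None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cph.fit(X, duration_col=time, event_col=event, fit_options=opts)
                return cph
            except Exception as exc:
                last = exc
    raise ModelError(f"Cox fit failed: {last}") from last


def fit_coxph(
    rows: pd.DataFrame,
    time: str,
    event: str,
    exposure: str,
    adjust: Sequence[str] = (),
    stratum: str = "all",
    return_fitter: bool = False,
):
    """Cox proportional-hazards regression of a time-to-event outcome.

    Ties are handled by Efron's method. Exposure levels with zero events are
    dropped from the contrast and returned as flagged placeholder results.
    Set ``return_fitter=True`` to also receive the fitted lifelines model and
    its design frame (for residual diagnostics).
    """
    if (rows[time] <= 0).any():
        raise ModelError("event/censoring times must be positive")
    events_by_level = rows.groupby(exposure)[event].sum()
    dead_levels = [lv for lv, k in events_by_level.items() if k == 0]
    flagged = [
        AssocResult(
            exposure=exposure, level=str(lv), outcome=event, measure="HR",
            estimate=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            p_value=float("nan"), adjusted=bool(adjust), stratum=stratum,
            n=int((rows[exposure] == lv).sum()), n_events=0,
            flag="no events at this level; dropped from contrast",
        )
        for lv in dead_levels if lv != sorted(rows[exposure].unique())[0]
    ]
    keep = rows[~rows[exposure].isin([lv for lv in dead_levels if lv != sorted(rows[exposure].unique())[0]])]
    if keep[event].sum() < 1 or keep[exposure].nunique() < 2:
        raise ModelError("too few events to fit a Cox model")

    X, exp_cols, _ = _design(keep, exposure, adjust)
    X = X.assign(**{time: keep[time].values, event: keep[event].astype(int).values})
    cph = _fit_cox(X, time, event)
    flags = {
        c: "possible monotone likelihood (unstable estimate)"
        for c in exp_cols
        if float(cph.standard_errors_[c]) > 10
    }
    results = _wald_results(
        cph.params_, cph.standard_errors_, cph.summary["p"], exp_cols,
        exposure=exposure, outcome=event, measure="HR", adjusted=bool(adjust),
        stratum=stratum, n=len(keep), n_events=int(keep[event].sum()), flags=flags,
    ) + flagged
    if return_fitter:
        return results, cph, X
    return results


def schoenfeld_check(cph: CoxPHFitter, design: pd.DataFrame) -> dict[str, float]:
    """Schoenfeld-residual test of proportional hazards, per covariate.

    Returns a mapping covariate -> p-value for association of the scaled
    Schoenfeld residuals with (rank) event time; small p indicates a
    time-varying effect.
    """
    if cph.event_observed.sum() < 2:
        raise ModelError("proportional-hazards check needs at least two events")
    res = proportional_hazard_test(cph, design, time_transform="rank")
    p = res.summary["p"]
    return {str(ix): float(v) for ix, v in p.items()}


def sex_interaction(
    rows: pd.DataFrame,
    outcome: str,
    exposure: str,
    adjust: Sequence[str] = (),
    time: Optional[str] = None,
) -> dict[str, float]:
    """Wald p-values for exposure-by-sex product terms, one per level.

    Fits the pooled model with interaction terms: logistic when ``time`` is
    None, Cox otherwise (``outcome`` is then the event indicator).
    """
    if rows["sex"].nunique() < 2:
        raise ModelError("sex interaction requires both sexes in the data")
    adjust = tuple(adjust)
    if "sex" not in adjust:
        adjust = adjust + ("sex",)
    X, exp_cols, inter_cols = _design(rows, exposure, adjust, with_sex_interaction=True)
    if time is None:
        y = rows[outcome].astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, sm.add_constant(X, has_constant="add"),
                         family=sm.families.Binomial()).fit()
        pv = res.pvalues
    else:
        Xc = X.assign(**{time: rows[time].values, "_event": rows[outcome].astype(int).values})
        cph = _fit_cox(Xc, time, "_event")
        pv = cph.summary["p"]
    out = {}
    for col, icol in zip(exp_cols, inter_cols):
        out[col[len(exposure) + 1 :]] = float(pv[icol])
    return out


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa, the chance-corrected agreement between two raters."""
    a, b = list(labels_a), list(labels_b)
    if len(a) != len(b):
        raise ValueError(f"label sequences differ in length ({len(a)} vs {len(b)})")
    if len(a) == 0:
        raise ValueError("empty label sequences")
    if a == b:  # perfect agreement, incl. the degenerate single-category case
        return 1.0
    return float(cohen_kappa_score(a, b))
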