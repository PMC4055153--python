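"""Group contrasts and tinnitus-duration analyses.

The group comparison is a linear mixed model, outcome ~ group with a random
intercept per subject, fitted on two observations per subject (left/right
hemisphere ROI values). The group effect is reported as an F statistic with
denominator degrees of freedom n_subjects - 2 (a between-subject test; in a
balanced design it coincides with the one-way ANOVA on per-subject hemisphere
means). With 21 + 21 subjects this yields df = (1, 40).

The duration association is the hyperbolic model cv = b / duration + a —
linear in the transformed regressor 1/duration, fitted by ordinary least
squares; ``fix_b`` gives the literal reading with b fixed at 1. The median
split uses the sample median of duration with at-median subjects assigned to
the short-duration group, compared by Welch's unequal-variance t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .exceptions import ConvergenceError, InvalidArgumentError

__all__ = [
    "GroupTestResult",
    "DurationFitResult",
    "MedianSplitResult",
    "CorrelationResult",
    "mixed_anova",
    "fit_duration_model",
    "median_split_welch",
    "covariate_check",
]


@dataclass(frozen=True)
class GroupTestResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    outcome_kind: str
    band: str

    def __post_init__(self) -> None:
        if self.F < 0 or not 0 <= self.p <= 1 or self.df_num < 1 or self.df_den < 1:
            raise InvalidArgumentError("invalid test result fields")


@dataclass(frozen=True)
class DurationFitResult:
    a: float
    b: float
    t_a: float
    p_a: float
    residual_sd: float
    b_fixed: bool = False


@dataclass(frozen=True)
class MedianSplitResult:
    split_point: float
    t: float
    df: float
    p: float
    mean_short: float
    mean_long: float
    n_short: int
    n_long: int


@dataclass(frozen=True)
class CorrelationResult:
    covariate: str
    r: float
    p: float
    n: int


def mixed_anova(
    summaries: pd.DataFrame, outcome: str, band: str
) -> GroupTestResult:
    """Mixed-model group test on hemisphere-level ROI values.

    ``summaries`` needs columns subject_id, group, hemisphere, band plus the
    outcome column ('mean_power' or 'cv'); exactly two hemisphere rows per
    subject for the requested band.
    """
    if outcome not in ("mean_power", "cv"):
        raise InvalidArgumentError("outcome must be 'mean_power' or 'cv'")
    data = summaries[summaries["band"] == band].copy()
    if data.empty:
        raise InvalidArgumentError(f"no rows for band {band!r}")
    counts = data.groupby("subject_id")["hemisphere"].count()
    if not (counts == 2).all():
        raise InvalidArgumentError(
            "each subject needs exactly two hemisphere observations"
        )
    groups = data.groupby("subject_id")["group"].first()
    n1 = int((groups == "tinnitus").sum())
    n2 = int((groups == "control").sum())
    if n1 == 0 or n2 == 0:
        raise InvalidArgumentError("both groups must be nonempty")
    df_den = n1 + n2 - 2
    data = data.rename(columns={outcome: "value"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "value ~ C(group, Treatment('control'))", data, groups=data["subject_id"]
        )
        try:
            fit = model.fit(reml=True)
        except (np.linalg.LinAlgError, ValueError) as err:
            raise ConvergenceError(f"mixed model failed: {err}") from err
    name = "C(group, Treatment('control'))[T.tinnitus]"
    t = fit.params[name] / fit.bse[name]
    if not np.isfinite(t):
        raise ConvergenceError("singular mixed-model fit (non-finite group effect)")
    F = float(t**2)
    p = float(scipy.stats.f.sf(F, 1, df_den))
    return GroupTestResult(
        effect="group", F=F, df_num=1, df_den=df_den, p=p,
        outcome_kind=outcome, band=band,
    )


def fit_duration_model(
    cv: np.ndarray, durations: np.ndarray, fix_b: float | None = None
) -> DurationFitResult:
    """Least-squares fit of cv = b / duration + a on tinnitus subjects."""
    cv = np.asarray(cv, dtype=float)
    d = np.asarray(durations, dtype=float)
    if cv.shape != d.shape or cv.ndim != 1:
        raise InvalidArgumentError("cv and durations must be equal-length vectors")
    if len(cv) < 3:
        raise InvalidArgumentError("need at least 3 subjects")
    if np.any(d <= 0):
        raise InvalidArgumentError("durations must be positive")
    if np.ptp(d) == 0:
        raise InvalidArgumentError("degenerate design: all durations equal")
    inv = 1.0 / d
    if fix_b is not None:
        resid_target = cv - fix_b * inv
        a = float(resid_target.mean())
        resid = resid_target - a
        se = resid.std(ddof=1) / np.sqrt(len(cv))
        t_a = float(a / se) if se > 0 else np.inf
        p_a = float(2 * scipy.stats.t.sf(abs(t_a), len(cv) - 1))
        return DurationFitResult(
            a=a, b=float(fix_b), t_a=t_a, p_a=p_a,
            residual_sd=float(resid.std(ddof=1)), b_fixed=True,
        )
    X = sm.add_constant(inv)
    fit = sm.OLS(cv, X).fit()
    return DurationFitResult(
        a=float(fit.params[0]),
        b=float(fit.params[1]),
        t_a=float(fit.tvalues[0]),
        p_a=float(fit.pvalues[0]),
        residual_sd=float(np.sqrt(fit.mse_resid)),
        b_fixed=False,
    )


def median_split_welch(cv: np.ndarray, durations: np.ndarray) -> MedianSplitResult:
    """Welch t-test of CV between short- and long-duration halves.

    Split at the sample median; subjects exactly at the median fall in the
    short group. Positive t means higher variability in the short group.
    """
    cv = np.asarray(cv, dtype=float)
    d = np.asarray(durations, dtype=float)
    if cv.shape != d.shape or cv.ndim != 1:
        raise InvalidArgumentError("cv and durations must be equal-length vectors")
    if np.ptp(d) == 0:
        raise InvalidArgumentError("all durations identical: no split possible")
    split = float(np.median(d))
    short = cv[d <= split]
    long = cv[d > split]
    if len(short) == 0 or len(long) == 0:
        raise InvalidArgumentError("median split produced an empty group")
    res = scipy.stats.ttest_ind(short, long, equal_var=False)
    return MedianSplitResult(
        split_point=split,
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_short=float(short.mean()),
        mean_long=float(long.mean()),
        n_short=len(short),
        n_long=len(long),
    )


def covariate_check(cv: np.ndarray, covariate: np.ndarray, name: str) -> CorrelationResult:
    """Pearson correlation (two-sided) between CV and a covariate."""
    cv = np.asarray(cv, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if cv.shape != cov.shape or len(cv) < 3:
        raise InvalidArgumentError("need at least 3 paired values")
    if cv.std() == 0 or cov.std() == 0:
        raise InvalidArgumentError("zero variance: correlation undefined")
    r, p = scipy.stats.pearsonr(cv, cov)
    return CorrelationResult(covariate=name, r=float(r), p=float(p), n=len(cv))
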