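"""Statsmodels-style model/results interface for the cohort-level analysis.

:class:`AlphaVariabilityModel` is built from the subject x hemisphere x band
summary table (ROI-averaged mean band power and band CV joined with subject
metadata) and `.fit()` returns an :class:`AlphaVariabilityResults` carrying

* mixed-model group contrasts (random subject intercept, between-subject
  F-test) for mean power and CV in the lower and upper alpha bands,
* the hyperbolic tinnitus-duration fit cv = b / duration + a,
* the median-split Welch test on duration,
* covariate checks (distress, age),

plus a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .stats import (
    CorrelationResult,
    DurationFitResult,
    GroupTestResult,
    MedianSplitResult,
    covariate_check,
    fit_duration_model,
    median_split_welch,
    mixed_anova,
)

__all__ = ["AlphaVariabilityModel", "AlphaVariabilityResults"]

REQUIRED_COLUMNS = (
    "subject_id",
    "group",
    "hemisphere",
    "band",
    "mean_power",
    "cv",
    "age",
)


class AlphaVariabilityModel:
    """Cohort-level model of auditory alpha power and its trial-to-trial CV.

    Parameters
    ----------
    summary
        One row per subject x hemisphere x band with columns
        ``subject_id, group, hemisphere, band, mean_power, cv, age`` and,
        for tinnitus subjects, ``duration`` (years) and ``distress``.
    duration_band
        Band whose CV enters the duration analyses (default ``low_alpha``).
    """

    def __init__(self, summary: pd.DataFrame, duration_band: str = "low_alpha"):
        missing = [c for c in REQUIRED_COLUMNS if c not in summary.columns]
        if missing:
            raise InvalidArgumentError(f"summary table lacks columns {missing}")
        if summary.empty:
            raise InvalidArgumentError("summary table is empty")
        self.summary = summary.reset_index(drop=True).copy()
        self.duration_band = duration_band
        self.bands = tuple(pd.unique(self.summary["band"]))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "AlphaVariabilityModel":
        return cls(df, **kwargs)

    def _tinnitus_cv(self) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
        """Per-subject hemisphere-averaged CV and duration, tinnitus only."""
        tin = self.summary[
            (self.summary["group"] == "tinnitus")
            & (self.summary["band"] == self.duration_band)
        ]
        per_subject = (
            tin.groupby("subject_id")
            .agg(
                cv=("cv", "mean"),
                duration=("duration", "first"),
                distress=("distress", "first"),
                age=("age", "first"),
            )
            .sort_index()
        )
        return (
            per_subject["cv"].to_numpy(),
            per_subject["duration"].to_numpy(),
            per_subject,
        )

    def fit(self, fix_b: float | None = None) -> "AlphaVariabilityResults":
        group_tests: dict[tuple[str, str], GroupTestResult] = {}
        for band in self.bands:
            for outcome in ("mean_power", "cv"):
                group_tests[(band, outcome)] = mixed_anova(
                    self.summary, outcome=outcome, band=band
                )
        cv, dur, per_subject = self._tinnitus_cv()
        duration_fit = fit_duration_model(cv, dur, fix_b=fix_b)
        split = median_split_welch(cv, dur)
        covariates = {}
        for name in ("distress", "age"):
            vals = per_subject[name].to_numpy(dtype=float)
            if np.isnan(vals).any():
                continue
            covariates[name] = covariate_check(cv, vals, name)
        return AlphaVariabilityResults(
            model=self,
            group_tests=group_tests,
            duration_fit=duration_fit,
            median_split=split,
            covariates=covariates,
        )


class AlphaVariabilityResults:
    """Fitted estimates, their tests, and a text summary."""

    def __init__(self, model, group_tests, duration_fit, median_split, covariates):
        self.model = model
        self.group_tests = group_tests
        self.duration_fit = duration_fit
        self.median_split = median_split
        self.covariates = covariates

    def to_dict(self) -> dict:
        def clean(obj):
            """JSON-safe: non-finite floats (degenerate tiny-cohort tests,
            e.g. a singleton Welch group) become None."""
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, float) and not np.isfinite(obj):
                return None
            return obj

        return clean(
            {
                "group_tests": {
                    f"{band}:{outcome}": asdict(res)
                    for (band, outcome), res in self.group_tests.items()
                },
                "duration_fit": asdict(self.duration_fit),
                "median_split": asdict(self.median_split),
                "covariates": {k: asdict(v) for k, v in self.covariates.items()},
            }
        )

    def summary(self) -> str:
        lines = []
        lines.append("Auditory alpha power and trial-to-trial variability")
        lines.append("=" * 67)
        n_sub = self.model.summary["subject_id"].nunique()
        lines.append(f"Subjects: {n_sub}   unit: subject x hemisphere ROI value")
        lines.append("")
        lines.append("Group contrasts (mixed model, random subject intercept)")
        lines.append("-" * 67)
        lines.append(f"{'band':<12}{'outcome':<12}{'F':>9}{'df':>10}{'p':>12}")
        for (band, outcome), r in self.group_tests.items():
            lines.append(
                f"{band:<12}{outcome:<12}{r.F:>9.2f}"
                f"{f'({r.df_num},{r.df_den})':>10}{r.p:>12.4g}"
            )
        d = self.duration_fit
        lines.append("")
        lines.append("Tinnitus-duration association (cv = b/duration + a)")
        lines.append("-" * 67)
        btag = " (fixed)" if d.b_fixed else ""
        lines.append(
            f"a = {d.a:.3f} (t = {d.t_a:.2f}, p = {d.p_a:.3g})   "
            f"b = {d.b:.3f}{btag}   resid sd = {d.residual_sd:.3f}"
        )
        m = self.median_split
        lines.append(
            f"median split at {m.split_point:.2f} y: "
            f"short mean {m.mean_short:.3f} (n={m.n_short}), "
            f"long mean {m.mean_long:.3f} (n={m.n_long}), "
            f"Welch t = {m.t:.2f}, df = {m.df:.1f}, p = {m.p:.3g}"
        )
        for name, c in self.covariates.items():
            lines.append(f"cv ~ {name}: r = {c.r:.3f}, p = {c.p:.3g} (n={c.n})")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<AlphaVariabilityResults: {len(self.group_tests)} group tests>"
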