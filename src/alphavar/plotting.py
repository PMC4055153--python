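"""Optional figures (never part of any quantitative output)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_duration_fit", "plot_group_cv"]


def plot_duration_fit(report, path):
    """Tinnitus CV vs duration with the fitted b/duration + a curve."""
    df = report.summary_table
    tin = df[(df["group"] == "tinnitus") & (df["band"] == "low_alpha")]
    per = tin.groupby("subject_id").agg(cv=("cv", "mean"), duration=("duration", "first"))
    fit = report.results["duration_fit"]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(per["duration"], per["cv"], color="k", s=25)
    d = np.linspace(per["duration"].min(), per["duration"].max(), 200)
    ax.plot(d, fit["b"] / d + fit["a"], "r-")
    ax.set_xlabel("tinnitus duration (years)")
    ax.set_ylabel("low-alpha CV (temporal ROI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_group_cv(report, path, band: str = "low_alpha"):
    """Bar plot of group mean ROI CV with per-subject points."""
    df = report.summary_table
    sub = df[df["band"] == band].groupby(["subject_id", "group"], as_index=False)["cv"].mean()
    fig, ax = plt.subplots(figsize=(4, 4))
    for i, grp in enumerate(("control", "tinnitus")):
        vals = sub[sub["group"] == grp]["cv"]
        ax.bar(i, vals.mean(), width=0.6, alpha=0.6)
        ax.scatter(np.full(len(vals), i), vals, color="k", s=12, zorder=3)
    ax.set_xticks([0, 1], ["control", "tinnitus"])
    ax.set_ylabel(f"{band} CV (temporal ROI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
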