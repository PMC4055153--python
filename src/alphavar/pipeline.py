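"""End-to-end orchestration: simulate -> preprocess -> spectra -> CV -> ROI -> stats.

Subjects are processed one at a time (a full-scale cohort holds ~10 GB of raw
signal; only per-subject sensor tables are retained across the loop). The ROI
is defined once, from the cohort's low-alpha group-difference topography, and
frozen for every band and outcome. One master seed fans out to every
stochastic stage through hashing, so reports are reproducible end to end.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import IncompleteReportError, InvalidArgumentError
from .model import AlphaVariabilityModel
from .preprocess import STAGE_ORDER, preprocess_recording
from .recordings import Recording
from .roi import define_roi, difference_topography
from .seeding import derive_seed
from .simulate import CohortConfig, SubjectSpec, iter_cohort
from .spectral import HIGH_ALPHA, LOW_ALPHA, Band, band_average, compute_epoch_spectra, default_grid
from .variability import compute_cv, cv_of_band_power

__all__ = ["RunConfig", "RunReport", "run_pipeline", "write_report"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; a seed is mandatory (no silent
    nondeterminism — the cohort seed doubles as the master seed)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    line_freq: float = 50.0
    target_rate: float = 600.0
    ptp_factor: float = 6.0
    z_threshold: float = 25.0
    grid_start: float = 1.0
    grid_stop: float = 100.0
    grid_step: float = 0.5
    roi_k_per_side: int = 4
    fix_b: float | None = None
    sd_kind: str = "sample"
    cv_order: str = "per_bin"  # or 'band_first'

    def __post_init__(self) -> None:
        if self.cv_order not in ("per_bin", "band_first"):
            raise InvalidArgumentError("cv_order must be 'per_bin' or 'band_first'")
        if self.sd_kind not in ("sample", "population"):
            raise InvalidArgumentError("sd_kind must be 'sample' or 'population'")
        if self.target_rate > self.cohort.sampling_rate:
            raise InvalidArgumentError("target_rate must not exceed the cohort rate")

    @property
    def bands(self) -> tuple[Band, Band]:
        return (LOW_ALPHA, HIGH_ALPHA)

    def to_dict(self) -> dict:
        # JSON round-trip normalizes tuples to lists for stable comparison
        return json.loads(json.dumps(dataclasses.asdict(self)))


@dataclass
class RunReport:
    """Config echo, per-stage record counts, all statistical results."""

    config: dict
    stage_order: tuple[str, ...]
    subjects: list[dict]
    roi: dict
    results: dict
    summary_table: pd.DataFrame
    version: str = __version__
    started: str = ""
    finished: str = ""

    def to_json(self, include_timestamps: bool = True, indent: int = 2) -> str:
        payload = {
            "config": self.config,
            "stage_order": list(self.stage_order),
            "subjects": self.subjects,
            "roi": self.roi,
            "results": self.results,
            "summary_table": self.summary_table.to_dict(orient="list"),
            "version": self.version,
        }
        if include_timestamps:
            payload["started"] = self.started
            payload["finished"] = self.finished
        return json.dumps(payload, indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        d = json.loads(text)
        return cls(
            config=d["config"],
            stage_order=tuple(d["stage_order"]),
            subjects=d["subjects"],
            roi=d["roi"],
            results=d["results"],
            summary_table=pd.DataFrame(d["summary_table"]),
            version=d.get("version", ""),
            started=d.get("started", ""),
            finished=d.get("finished", ""),
        )


def _subject_tables(
    recording: Recording, spec: SubjectSpec, config: RunConfig
) -> tuple[dict, dict]:
    """Per-sensor band power (epoch-averaged) and band CV for one subject."""
    seed = derive_seed(config.cohort.seed, spec.subject_id, "select")
    pre = preprocess_recording(
        recording,
        line_freq=config.line_freq,
        target_rate=config.target_rate,
        epoch_length_s=config.cohort.epoch_length_s,
        n_select=config.cohort.epochs_analyzed,
        ptp_factor=config.ptp_factor,
        z_threshold=config.z_threshold,
        seed=seed,
    )
    grid = default_grid(config.grid_start, config.grid_stop, config.grid_step)
    spectra = compute_epoch_spectra(pre.epochs, grid)
    cvmap = compute_cv(spectra, sd_kind=config.sd_kind)
    per_band: dict[str, dict] = {}
    for band in config.bands:
        power = band_average(spectra, band).mean(axis=0)  # per sensor
        mask = grid.band_mask(band)
        cv_sensor = cvmap.cv[:, mask].mean(axis=1)
        per_band[band.name] = {
            "power": power,
            "cv_sensor": pd.Series(cv_sensor, index=list(spectra.sensor_ids)),
        }
    info = {
        "subject_id": spec.subject_id,
        **{k: v for k, v in pre.counts.items()},
        "stages": pre.stages,
        "spectra": spectra if config.cv_order == "band_first" else None,
    }
    return per_band, info


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis on a (simulated) cohort and report results."""
    started = datetime.datetime.now().isoformat(timespec="seconds")
    specs: list[SubjectSpec] = []
    per_subject: list[dict] = []
    subject_info: list[dict] = []
    layout = None
    stage_order: tuple[str, ...] | None = None
    for recording, spec in iter_cohort(config.cohort):
        layout = recording.layout
        tables, info = _subject_tables(recording, spec, config)
        if stage_order is None:
            stage_order = info["stages"]
        elif info["stages"] != stage_order:
            raise InvalidArgumentError(
                f"stage order changed for subject {spec.subject_id}"
            )
        specs.append(spec)
        per_subject.append(tables)
        subject_info.append(info)

    # ROI: frozen once from the low-alpha difference topography.
    low_power = pd.DataFrame(
        [t[LOW_ALPHA.name]["power"] for t in per_subject],
        index=[s.subject_id for s in specs],
    )
    labels = pd.Series([s.group for s in specs], index=low_power.index)
    diff_map = difference_topography(low_power, labels, LOW_ALPHA)
    roi = define_roi(diff_map, layout, config.roi_k_per_side, LOW_ALPHA)

    rows = []
    for spec, tables, info in zip(specs, per_subject, subject_info):
        for band in config.bands:
            t = tables[band.name]
            if config.cv_order == "band_first":
                cv_by_hemi = cv_of_band_power(
                    info["spectra"], band, roi, sd_kind=config.sd_kind
                )
            else:
                cv_by_hemi = None
            for hemi, members in (("left", roi.left), ("right", roi.right)):
                if cv_by_hemi is None:
                    cv_val = float(t["cv_sensor"][list(members)].mean())
                else:
                    cv_val = cv_by_hemi[hemi]
                rows.append(
                    {
                        "subject_id": spec.subject_id,
                        "group": spec.group,
                        "hemisphere": hemi,
                        "band": band.name,
                        "mean_power": float(t["power"][list(members)].mean()),
                        "cv": cv_val,
                        "age": spec.age,
                        "sex": spec.sex,
                        "duration": spec.duration if spec.duration is not None else np.nan,
                        "distress": spec.distress if spec.distress is not None else np.nan,
                    }
                )
    summary = pd.DataFrame(rows)

    model = AlphaVariabilityModel(summary)
    results = model.fit(fix_b=config.fix_b)

    subjects = [
        {k: v for k, v in info.items() if k not in ("stages", "spectra")}
        for info in subject_info
    ]
    finished = datetime.datetime.now().isoformat(timespec="seconds")
    assert stage_order == STAGE_ORDER
    return RunReport(
        config=config.to_dict(),
        stage_order=stage_order,
        subjects=subjects,
        roi={"left": list(roi.left), "right": list(roi.right),
             "k_per_side": roi.k_per_side, "source_band": roi.source_band},
        results=results.to_dict(),
        summary_table=summary,
        started=started,
        finished=finished,
    )


def write_report(report: RunReport, out_dir, plots: bool = False) -> list:
    """Write report.json + TSV tables (+ optional figures) under ``out_dir``."""
    from pathlib import Path

    if not report.results or not report.results.get("group_tests"):
        raise IncompleteReportError("report carries no statistical results")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    p = out / "report.json"
    p.write_text(report.to_json())
    written.append(p)
    p = out / "subject_summaries.tsv"
    report.summary_table.to_csv(p, sep="\t", index=False)
    written.append(p)
    tests = pd.DataFrame(
        [dict(key=k, **v) for k, v in report.results["group_tests"].items()]
    )
    p = out / "group_tests.tsv"
    tests.to_csv(p, sep="\t", index=False)
    written.append(p)
    if plots:
        from .plotting import plot_duration_fit, plot_group_cv  # lazy

        for name, fn in (("duration_fit.png", plot_duration_fit),
                         ("group_cv.png", plot_group_cv)):
            p = out / name
            fn(report, p)
            written.append(p)
    return written
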