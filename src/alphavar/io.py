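"""File formats: HDF5 containers for recordings/epochs/spectra/CV maps,
TSV for cohort metadata and band tables, YAML/JSON for configurations, and
an optional FIF export for interoperability with standard MEG tooling."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidArgumentError
from .preprocess import EpochSet
from .recordings import Recording, SensorLayout
from .simulate import CohortConfig, SubjectSpec
from .spectral import FrequencyGrid, PowerSpectra
from .variability import CVMap

__all__ = [
    "save_recording",
    "load_recording",
    "save_epochs",
    "load_epochs",
    "save_spectra",
    "load_spectra",
    "save_cvmap",
    "load_cvmap",
    "write_metadata_tsv",
    "read_metadata_tsv",
    "load_cohort_config",
    "dump_cohort_config",
    "export_fif",
]

_STR = h5py.string_dtype(encoding="utf-8")


def _write_layout(g: h5py.Group, layout: SensorLayout) -> None:
    g.create_dataset("ids", data=np.array(layout.sensor_ids, dtype=_STR))
    g.create_dataset("positions", data=layout.positions)
    g.create_dataset("tags", data=np.array(layout.region_tags, dtype=_STR))


def _read_layout(g: h5py.Group) -> SensorLayout:
    return SensorLayout(
        sensor_ids=tuple(s.decode() for s in g["ids"][()]),
        positions=g["positions"][()],
        region_tags=tuple(s.decode() for s in g["tags"][()]),
    )


def save_recording(recording: Recording, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate"] = recording.sampling_rate
        f.attrs["subject_id"] = recording.subject_id
        f.create_dataset("data", data=recording.data, compression="gzip", compression_opts=1)
        _write_layout(f.create_group("layout"), recording.layout)
        ann = f.create_group("annotations")
        ann.create_dataset(
            "onsets", data=np.array([a[0] for a in recording.annotations], dtype=float)
        )
        ann.create_dataset(
            "offsets", data=np.array([a[1] for a in recording.annotations], dtype=float)
        )
        ann.create_dataset(
            "kinds", data=np.array([a[2] for a in recording.annotations], dtype=_STR)
        )
    return path


def load_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        ann = list(
            zip(
                f["annotations/onsets"][()],
                f["annotations/offsets"][()],
                (k.decode() for k in f["annotations/kinds"][()]),
            )
        )
        return Recording(
            subject_id=str(f.attrs["subject_id"]),
            layout=_read_layout(f["layout"]),
            sampling_rate=float(f.attrs["sampling_rate"]),
            data=f["data"][()],
            annotations=ann,
        )


def save_epochs(epochs: EpochSet, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = epochs.subject_id
        f.attrs["sampling_rate"] = epochs.sampling_rate
        f.attrs["epoch_length_s"] = epochs.epoch_length_s
        f.create_dataset("epochs", data=epochs.epochs, compression="gzip", compression_opts=1)
        f.create_dataset("artifact_flags", data=epochs.artifact_flags)
        f.create_dataset("selected", data=epochs.selected)
        _write_layout(f.create_group("layout"), epochs.layout)
    return path


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            subject_id=str(f.attrs["subject_id"]),
            layout=_read_layout(f["layout"]),
            sampling_rate=float(f.attrs["sampling_rate"]),
            epochs=f["epochs"][()],
            epoch_length_s=float(f.attrs["epoch_length_s"]),
            artifact_flags=f["artifact_flags"][()],
            selected=f["selected"][()],
        )


def save_spectra(spectra: PowerSpectra, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = spectra.subject_id
        f.attrs["taper"] = spectra.taper
        f.create_dataset("power", data=spectra.power, compression="gzip", compression_opts=1)
        f.create_dataset("frequencies", data=spectra.grid.values)
        f.create_dataset("sensor_ids", data=np.array(spectra.sensor_ids, dtype=_STR))
    return path


def load_spectra(path) -> PowerSpectra:
    with h5py.File(path, "r") as f:
        return PowerSpectra(
            subject_id=str(f.attrs["subject_id"]),
            grid=FrequencyGrid(values=f["frequencies"][()]),
            power=f["power"][()],
            sensor_ids=tuple(s.decode() for s in f["sensor_ids"][()]),
            taper=str(f.attrs["taper"]),
        )


def save_cvmap(cvmap: CVMap, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = cvmap.subject_id
        f.attrs["n_epochs"] = cvmap.n_epochs
        f.attrs["sd_kind"] = cvmap.sd_kind
        f.create_dataset("cv", data=cvmap.cv, compression="gzip", compression_opts=1)
        f.create_dataset("frequencies", data=cvmap.grid.values)
        f.create_dataset("sensor_ids", data=np.array(cvmap.sensor_ids, dtype=_STR))
    return path


def load_cvmap(path) -> CVMap:
    with h5py.File(path, "r") as f:
        return CVMap(
            subject_id=str(f.attrs["subject_id"]),
            grid=FrequencyGrid(values=f["frequencies"][()]),
            cv=f["cv"][()],
            sensor_ids=tuple(s.decode() for s in f["sensor_ids"][()]),
            n_epochs=int(f.attrs["n_epochs"]),
            sd_kind=str(f.attrs["sd_kind"]),
        )


def write_metadata_tsv(specs: list[SubjectSpec], path) -> Path:
    path = Path(path)
    rows = [
        {
            "subject_id": s.subject_id,
            "group": s.group,
            "age": s.age,
            "sex": s.sex,
            "duration_years": s.duration if s.duration is not None else "",
            "distress": s.distress if s.distress is not None else "",
        }
        for s in specs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_metadata_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_cohort_config(path) -> CohortConfig:
    """CohortConfig from a YAML (or JSON — YAML superset) mapping."""
    with open(path) as f:
        data = yaml.safe_load(f)
    if not isinstance(data, dict):
        raise InvalidArgumentError("cohort config file must hold a mapping")
    if "duration_model" in data:
        data["duration_model"] = tuple(data["duration_model"])
    for key in ("alpha_peak_range", "duration_range", "upper_peak_range"):
        if key in data:
            data[key] = tuple(data[key])
    unknown = set(data) - set(CohortConfig.__dataclass_fields__)
    if unknown:
        raise InvalidArgumentError(f"unknown cohort config keys: {sorted(unknown)}")
    return CohortConfig(**data)


def dump_cohort_config(config: CohortConfig, path) -> Path:
    import dataclasses

    path = Path(path)
    d = dataclasses.asdict(config)
    for key in ("duration_model", "alpha_peak_range", "duration_range",
                "upper_peak_range"):
        d[key] = list(d[key])
    with open(path, "w") as f:
        yaml.safe_dump(d, f, sort_keys=True)
    return path


def export_fif(recording: Recording, path) -> Path:
    """Write the recording as a FIF raw file (requires mne)."""
    import mne  # optional dependency

    info = mne.create_info(
        ch_names=list(recording.layout.sensor_ids),
        sfreq=recording.sampling_rate,
        ch_types="mag",
    )
    raw = mne.io.RawArray(recording.data * 1e-15, info, verbose="error")
    for start, stop, kind in recording.annotations:
        raw.annotations.append(onset=start, duration=stop - start, description=kind)
    path = Path(path)
    raw.save(path, overwrite=True, verbose="error")
    return path
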