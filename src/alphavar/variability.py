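"""Trial-to-trial variability of spectral power: the coefficient of variation.

For every sensor and frequency bin the CV is the standard deviation of power
across the selected epochs divided by its mean,

    CV[s, f] = sd_epochs(P[:, s, f]) / mean_epochs(P[:, s, f]),

a dimensionless, scale-free measure of moment-to-moment variability. The
sample (n-1) standard deviation is used by default; the alternative
(population) convention is one switch away and recorded in the output.

CV is computed per (sensor, bin) first and then averaged over band bins and
ROI sensors — the finer, information-preserving order. The alternative
(CV of pre-averaged band power) is available via :func:`cv_of_band_power`
for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError, UndefinedCVError
from .roi import ROIDefinition
from .spectral import Band, FrequencyGrid, PowerSpectra, band_average

__all__ = ["CVMap", "compute_cv", "band_cv", "cv_of_band_power"]


@dataclass
class CVMap:
    """Coefficient of variation across epochs, per sensor and frequency bin."""

    subject_id: str
    grid: FrequencyGrid
    cv: np.ndarray  # sensor x frequency
    sensor_ids: tuple[str, ...]
    n_epochs: int
    sd_kind: str = "sample"

    def __post_init__(self) -> None:
        self.cv = np.asarray(self.cv, dtype=float)
        if self.cv.shape != (len(self.sensor_ids), self.grid.n_bins):
            raise InvalidArgumentError("cv must be sensor x frequency")
        if self.n_epochs < 2:
            raise InvalidArgumentError("CV requires at least 2 epochs")
        if np.any(self.cv < 0):
            raise InvalidArgumentError("cv must be nonnegative")
        if self.sd_kind not in ("sample", "population"):
            raise InvalidArgumentError("sd_kind must be 'sample' or 'population'")


def compute_cv(spectra: PowerSpectra, sd_kind: str = "sample") -> CVMap:
    """CV of power across epochs at every (sensor, frequency) cell."""
    if spectra.n_epochs < 2:
        raise InvalidArgumentError("CV requires at least 2 epochs")
    ddof = 1 if sd_kind == "sample" else 0
    mean = spectra.power.mean(axis=0)
    if np.any(mean <= 0):
        s, f = np.argwhere(mean <= 0)[0]
        raise UndefinedCVError(
            f"zero mean power at sensor {spectra.sensor_ids[s]}, "
            f"{spectra.grid.values[f]:g} Hz: CV undefined"
        )
    sd = spectra.power.std(axis=0, ddof=ddof)
    return CVMap(
        subject_id=spectra.subject_id,
        grid=spectra.grid,
        cv=sd / mean,
        sensor_ids=spectra.sensor_ids,
        n_epochs=spectra.n_epochs,
        sd_kind=sd_kind,
    )


def _roi_indices(sensor_ids: tuple[str, ...], members) -> np.ndarray:
    lookup = {sid: i for i, sid in enumerate(sensor_ids)}
    try:
        return np.array([lookup[s] for s in members], dtype=int)
    except KeyError as err:
        raise InvalidArgumentError(f"ROI sensor {err} not present in the map") from err


def band_cv(cvmap: CVMap, band: Band, roi: ROIDefinition) -> dict[str, float]:
    """Mean CV over the band's bins and each hemisphere's ROI sensors."""
    mask = cvmap.grid.band_mask(band)
    if not mask.any():
        raise InvalidArgumentError(f"band {band.name} does not overlap the grid")
    out = {}
    for hemi, members in (("left", roi.left), ("right", roi.right)):
        if not members:
            raise InvalidArgumentError(f"empty {hemi} ROI")
        idx = _roi_indices(cvmap.sensor_ids, members)
        out[hemi] = float(cvmap.cv[np.ix_(idx, np.where(mask)[0])].mean())
    return out


def cv_of_band_power(
    spectra: PowerSpectra, band: Band, roi: ROIDefinition, sd_kind: str = "sample"
) -> dict[str, float]:
    """Alternative aggregation order: CV of ROI/band pre-averaged epoch power."""
    table = band_average(spectra, band)
    ddof = 1 if sd_kind == "sample" else 0
    out = {}
    for hemi, members in (("left", roi.left), ("right", roi.right)):
        if not members:
            raise InvalidArgumentError(f"empty {hemi} ROI")
        series = table[list(members)].mean(axis=1).to_numpy()
        m = series.mean()
        if m <= 0:
            raise UndefinedCVError(f"zero mean band power in {hemi} ROI")
        out[hemi] = float(series.std(ddof=ddof) / m)
    return out
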