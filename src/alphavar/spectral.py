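"""Per-epoch power spectra on a fixed frequency grid.

Each selected 2 s epoch is multiplied by a Hann taper and Fourier transformed;
power is reported at the grid frequencies (default 1–100 Hz in 0.5 Hz steps,
199 bins — the native resolution of a 2 s epoch, so every grid frequency is an
exact DFT bin).

Power scaling convention (fixed so that oracle tests have closed forms): the
one-sided, taper-power-compensated density

    P[f] = 2 |X[f]|^2 / (fs * sum(w^2)),

i.e. for stationary noise with one-sided PSD S(f), E[P[f]] = S(f), and an
integer-cycle sinusoid of amplitude A contributes A^2 T / 3 at its bin
(T = epoch length). The CV statistic is invariant to this choice; mean-power
group contrasts are carried out on these unnormalized values. Normalization
(relative power) is presentation-only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import windows

from .exceptions import InvalidArgumentError, UndefinedCVError
from .preprocess import EpochSet

__all__ = [
    "FrequencyGrid",
    "PowerSpectra",
    "Band",
    "LOW_ALPHA",
    "HIGH_ALPHA",
    "default_grid",
    "compute_epoch_spectra",
    "normalize_spectrum",
    "band_average",
]


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing analysis frequencies in Hz."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0 or np.any(np.diff(v) <= 0):
            raise InvalidArgumentError("grid must be strictly increasing and non-empty")
        object.__setattr__(self, "values", v)

    @property
    def n_bins(self) -> int:
        return self.values.size

    def band_mask(self, band: "Band") -> np.ndarray:
        return (self.values >= band.lo) & (self.values < band.hi)


def default_grid(start: float = 1.0, stop: float = 100.0, step: float = 0.5) -> FrequencyGrid:
    """The analysis grid: 1–100 Hz in 0.5 Hz increments (199 bins)."""
    n = int(round((stop - start) / step)) + 1
    return FrequencyGrid(values=start + step * np.arange(n))


@dataclass(frozen=True)
class Band:
    """Half-open frequency band [lo, hi).

    The half-open convention assigns the shared 10 Hz edge to the upper alpha
    band exactly once (no double counting).
    """

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise InvalidArgumentError("band requires lo < hi")


LOW_ALPHA = Band("low_alpha", 8.0, 10.0)
HIGH_ALPHA = Band("high_alpha", 10.0, 12.0)


@dataclass
class PowerSpectra:
    """Per-epoch power: epoch x sensor x frequency, plus provenance."""

    subject_id: str
    grid: FrequencyGrid
    power: np.ndarray
    sensor_ids: tuple[str, ...]
    taper: str = "hann"

    def __post_init__(self) -> None:
        p = np.asarray(self.power, dtype=float)
        if p.ndim != 3:
            raise InvalidArgumentError("power must be epoch x sensor x frequency")
        if p.shape[2] != self.grid.n_bins:
            raise InvalidArgumentError("power last axis must match the grid")
        if p.shape[1] != len(self.sensor_ids):
            raise InvalidArgumentError("power sensor axis must match sensor_ids")
        if np.any(p < 0):
            raise InvalidArgumentError("power must be nonnegative")
        self.power = p

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]


def compute_epoch_spectra(epochs: EpochSet, grid: FrequencyGrid | None = None) -> PowerSpectra:
    """Hann-tapered power spectrum of every *selected* epoch.

    Grid frequencies must coincide with DFT bins of the epoch length and lie
    at or below the Nyquist frequency.
    """
    if grid is None:
        grid = default_grid()
    fs = epochs.sampling_rate
    if np.any(grid.values > fs / 2 + 1e-9):
        raise InvalidArgumentError("grid extends above the Nyquist frequency")
    data = epochs.epochs[epochs.selected]
    if data.shape[0] == 0:
        raise InvalidArgumentError("no selected epochs to transform")
    n = data.shape[2]
    bins = grid.values * n / fs
    bin_idx = np.round(bins).astype(int)
    if np.any(np.abs(bins - bin_idx) > 1e-6):
        raise InvalidArgumentError(
            "grid frequencies must be exact DFT bins of the epoch length"
        )
    w = windows.hann(n, sym=False)
    scale = 2.0 / (fs * np.sum(w**2))
    spec = np.fft.rfft(data * w, axis=2)
    power = scale * np.abs(spec[:, :, bin_idx]) ** 2
    return PowerSpectra(
        subject_id=epochs.subject_id,
        grid=grid,
        power=power,
        sensor_ids=epochs.layout.sensor_ids,
        taper="hann",
    )


def normalize_spectrum(spectra: PowerSpectra) -> PowerSpectra:
    """Relative power: each epoch x sensor spectrum divided by its grid total."""
    total = spectra.power.sum(axis=2, keepdims=True)
    if np.any(total <= 0):
        e, s = np.argwhere(total[:, :, 0] <= 0)[0]
        raise UndefinedCVError(
            f"zero total power at epoch {e}, sensor {spectra.sensor_ids[s]}: "
            "normalization undefined"
        )
    out = replace(spectra)
    out.power = spectra.power / total
    return out


def band_average(spectra: PowerSpectra, band: Band) -> pd.DataFrame:
    """Mean power over the band's grid bins ([lo, hi)), per epoch and sensor."""
    mask = spectra.grid.band_mask(band)
    if not mask.any():
        raise InvalidArgumentError(f"band {band.name} does not overlap the grid")
    values = spectra.power[:, :, mask].mean(axis=2)
    return pd.DataFrame(values, columns=list(spectra.sensor_ids))
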