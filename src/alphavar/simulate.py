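"""Synthetic resting-state MEG cohorts with controlled alpha power and CV.

Signal model (per subject)
--------------------------
Each hemisphere carries a narrowband alpha source: a pair of grid-aligned
sinusoids 0.5 Hz apart straddling the subject's alpha peak frequency, sharing
one slowly varying amplitude envelope. With 2 s epochs every component
completes an integer number of cycles, so a Hann-tapered spectrum confines
the source's energy to exactly the four 0.5 Hz bins of the low-alpha band —
band-level statistics then reflect the planted modulation rather than bin
alignment. The log-envelope follows an Ornstein-Uhlenbeck process (time
constant ~5 s), giving smooth between-epoch power fluctuation; left and
right envelopes share a common component plus an independent one. The source
projects to the sensors through Gaussian spatial gains centred on the ears,
so alpha is strongest over bilateral temporal sensors. On top: 1/f^chi
Gaussian background noise (known PSD), a 50 Hz line component, and occasional
blink-like low-frequency transients.

CV calibration
--------------
The planted quantity is the *measured* trial-to-trial CV of epoch alpha
power. For a lognormal envelope the population CV has the closed form
CV^2 = exp(s^2) - 1, but the sample CV of ~90 autocorrelated, heavy-tailed
epoch powers is substantially smaller than the population value. Additive band
noise dilutes the sample CV more than the population noise-to-signal ratio
suggests, because the sample mean in the denominator typically sits below
the population mean. The generator therefore inverts the expected sample CV
directly: one seeded Monte-Carlo table per cohort configuration maps
(log-envelope scale, cell noise-to-signal ratio) to the expected sample CV
of the measured band cells, with OU autocorrelation, epoch integration,
Hann-kernel leakage and random epoch selection included. No per-subject
iterative calibration is needed — the table is computed once and
interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.signal import lfilter

from .exceptions import InvalidArgumentError
from .recordings import EAR_LEFT, EAR_RIGHT, Recording, SensorLayout, make_layout
from .seeding import derive_rng, derive_seed

__all__ = [
    "SubjectSpec",
    "CohortConfig",
    "simulate_subject",
    "simulate_cohort",
    "iter_cohort",
    "sample_cohort_specs",
    "alpha_component_freqs",
    "noise_psd",
]

GAIN_WIDTH = 0.35  # spatial std of the ear-centred source gain (layout units)

_cached_layout = lru_cache(maxsize=8)(make_layout)


@dataclass(frozen=True)
class SubjectSpec:
    """Per-subject generative targets and metadata."""

    subject_id: str
    group: str  # 'tinnitus' | 'control'
    age: float
    sex: str  # 'f' | 'm'
    alpha_mean_amp: float
    alpha_cv_target: float
    alpha_peak_freq: float
    duration: float | None = None  # years, tinnitus only
    distress: float | None = None  # questionnaire points, tinnitus only
    # group-neutral upper-alpha source (0 disables it) and background level
    upper_alpha_amp: float = 0.0
    upper_alpha_cv: float = 0.0
    upper_alpha_peak: float = 11.0
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.group not in ("tinnitus", "control"):
            raise InvalidArgumentError("group must be 'tinnitus' or 'control'")
        if self.group == "tinnitus":
            if self.duration is None or self.duration <= 0:
                raise InvalidArgumentError("tinnitus subjects need duration > 0")
        elif self.duration is not None:
            raise InvalidArgumentError("controls must not carry a tinnitus duration")
        if self.alpha_cv_target < 0:
            raise InvalidArgumentError("alpha_cv_target must be nonnegative")
        if not 8.0 <= self.alpha_peak_freq <= 12.0:
            raise InvalidArgumentError("alpha_peak_freq must lie in [8, 12] Hz")
        if self.alpha_mean_amp < 0:
            raise InvalidArgumentError("alpha_mean_amp must be nonnegative")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults emulate the reference study design: 21 subjects per group,
    148 sensors, five minutes of rest recorded at 678.17 Hz (analysed at
    600 Hz downstream), 90 two-second epochs per subject, a planted tinnitus
    reduction of low-alpha mean power (power ratio 0.2) and of its
    trial-to-trial CV (control-minus-tinnitus offset 1.05), and the
    hyperbolic duration relation cv = b / duration + a with
    (a, b) = (2.38, 1.0). The planted group contrasts were sized by power
    analysis against the generator's own between-subject noise so that the
    standardized effects land near 1 at n = 21 + 21 (see docs/methods.md).
    """

    n_per_group: int = 21
    sampling_rate: float = 678.17
    duration_s: float = 300.0
    noise_exponent: float = 1.0  # spectral slope chi of the 1/f^chi background
    noise_psd_ref: float = 1.0  # one-sided background PSD at 10 Hz (units^2/Hz)
    line_amp: float = 5.0  # 50 Hz component amplitude (signal units)
    artifact_rate: float = 5.0  # expected blink-like epochs per recording
    group_power_ratio: float = 0.2  # tinnitus/control mean low-alpha power
    group_cv_delta: float = 1.05  # control-minus-tinnitus CV offset
    duration_model: tuple[float, float] = (2.38, 1.0)  # (a, b): cv = b/d + a
    seed: int = 0
    # geometry / analysis frame
    n_sensors: int = 148
    n_temporal_per_side: int = 10
    epoch_length_s: float = 2.0
    epochs_analyzed: int = 90  # epochs the downstream analysis will select
    # subject-level distributions
    alpha_amp: float = 90.0  # median alpha source amplitude (signal units)
    alpha_amp_logsd: float = 0.2
    alpha_peak_range: tuple[float, float] = (8.8, 9.2)
    # group-neutral upper-alpha source and background-level spread
    upper_alpha_relative: float = 0.5  # upper/lower amplitude ratio (median)
    upper_cv_mean: float = 1.3
    upper_cv_sd: float = 0.3
    upper_peak_range: tuple[float, float] = (10.8, 11.2)
    noise_logsd: float = 0.2  # between-subject spread of background level
    cv_jitter_sd: float = 0.15
    duration_median: float = 3.0  # years; the median-split point
    duration_logsd: float = 0.6
    duration_range: tuple[float, float] = (1.0, 25.0)
    line_freq: float = 50.0
    ou_tau: float = 5.0  # s, envelope time constant
    env_smooth_s: float = 0.25  # s, Gaussian smoothing of the (positive) envelope
    hemisphere_mix: float = 0.45  # weight of the hemisphere-specific envelope
    calibration_k: int = 4  # temporal sensors per side assumed in the noise correction

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise InvalidArgumentError("n_per_group must be at least 2")
        if self.sampling_rate <= 200:
            raise InvalidArgumentError(
                "sampling_rate must exceed 200 Hz (Nyquist above 100 Hz)"
            )
        if self.duration_s < self.epoch_length_s:
            raise InvalidArgumentError("duration_s too short to hold one epoch")
        if self.n_available_epochs < self.epochs_analyzed:
            raise InvalidArgumentError(
                "duration_s too short for the requested number of analysed epochs"
            )
        if not 0 < self.group_power_ratio <= 1:
            raise InvalidArgumentError("group_power_ratio must lie in (0, 1]")
        for name in ("noise_psd_ref", "line_amp", "artifact_rate", "alpha_amp"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be nonnegative")

    @property
    def n_available_epochs(self) -> int:
        return int(self.duration_s // self.epoch_length_s)


def noise_psd(f, config: CohortConfig):
    """One-sided background PSD: noise_psd_ref * (f/10)^-chi, flat below 1 Hz."""
    f = np.maximum(np.asarray(f, dtype=float), 1.0)
    return config.noise_psd_ref * (f / 10.0) ** (-config.noise_exponent)


def alpha_component_freqs(peak_freq: float) -> tuple[float, float]:
    """The two grid-aligned component frequencies straddling the alpha peak."""
    f1 = np.floor(2 * peak_freq - 0.5 + 1e-9) / 2.0
    return float(f1), float(f1 + 0.5)


def _source_gains(layout: SensorLayout) -> tuple[np.ndarray, np.ndarray]:
    """Spatial gain of each hemisphere's alpha source at every sensor.

    Temporal-tagged sensors of the source's own hemisphere get a strong,
    gently graded gain (1.0 down to 0.7 by distance rank from the ear) so
    every ROI candidate is signal-dominated in-band; remaining sensors see a
    Gaussian falloff from the ear, capped below the temporal floor.
    """
    pos = layout.positions
    out = []
    for side, ear in (("left", EAR_LEFT), ("right", EAR_RIGHT)):
        d2 = ((pos - ear) ** 2).sum(axis=1)
        g = np.minimum(np.exp(-d2 / (2 * GAIN_WIDTH**2)), 0.6)
        idx = layout.indices(layout.temporal_ids(side))
        rank = np.argsort(np.argsort(d2[idx]))
        denom = max(len(idx) - 1, 1)
        g[idx] = 1.0 - 0.3 * rank / denom
        out.append(g)
    return out[0], out[1]


def _cell_noise_ratios(
    amp: float,
    peak_freq: float,
    noise_scale: float,
    config: CohortConfig,
    layout: SensorLayout,
) -> np.ndarray:
    """Noise-to-signal power ratio rho at every expected ROI (sensor, bin) cell.

    Used to correct the CV calibration for the additive 1/f band power:
    measured cell CV ~= sqrt(CV_mod^2 + rho (2 + rho)) / (1 + rho), the
    rho(2+rho) term covering the chi-square fluctuation of the noise bin power
    and the signal-noise cross term. Evaluated at the top-k gain temporal
    sensors — the sensors the difference-topography ROI selects by
    construction.
    """
    if config.noise_psd_ref == 0 or amp == 0:
        return np.zeros(1)
    f1, f2 = alpha_component_freqs(peak_freq)
    gl, gr = _source_gains(layout)
    rhos = []
    for side, gains in (("left", gl), ("right", gr)):
        idx = layout.indices(layout.temporal_ids(side))
        top = np.sort(gains[idx])[::-1][: config.calibration_k]
        for g in top:
            a2 = (amp * g) ** 2 / 2.0  # per-component power amp^2/2
            p_full = a2 * config.epoch_length_s / 3.0
            cells = {
                f1 - 0.5: p_full / 4.0,
                f1: p_full * 1.25,
                f2: p_full * 1.25,
                f2 + 0.5: p_full / 4.0,
            }
            for f, p_sig in cells.items():
                rhos.append(noise_scale**2 * float(noise_psd(f, config)) / p_sig)
    return np.asarray(rhos)


def _ar1_paths(rng: np.random.Generator, n_paths: int, n: int, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1)/OU sample paths, shape (n_paths, n)."""
    e = rng.standard_normal((n_paths, n))
    e[:, 1:] *= np.sqrt(1.0 - phi**2)
    return lfilter([1.0], [1.0, -phi], e, axis=1)


def _smooth_envelope(env: np.ndarray, smooth_s: float, dt: float) -> np.ndarray:
    """Gaussian low-pass of the positive envelope along the last axis.

    Confines the modulation sidebands of the alpha components to the low-alpha
    band (without smoothing, a strongly modulated 9 Hz carrier splatters
    measurable sideband power past 10 Hz, where it would masquerade as an
    upper-alpha effect). Positivity is preserved. Short kernels use direct
    convolution; long ones the exact Gaussian transfer in the Fourier domain.
    """
    if smooth_s <= 0:
        return env
    # Exact Gaussian transfer in the Fourier domain — used identically for
    # the generated signal and the calibration Monte Carlo, so the envelope's
    # high-frequency content (which drives the sample CV at large sigma) is
    # attenuated consistently in both.
    n = env.shape[-1]
    f = np.fft.rfftfreq(n, d=dt)
    h = np.exp(-0.5 * (2 * np.pi * f * smooth_s) ** 2)
    return np.fft.irfft(np.fft.rfft(env, axis=-1) * h, n=n, axis=-1)


@lru_cache(maxsize=32)
def _sample_cv_curve(
    n_avail: int,
    n_sel: int,
    epoch_s: float,
    tau: float,
    env_smooth_s: float = 0.0,
    n_mc: int = 3000,
    sub: int = 16,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expected sample CV of measured epoch band power on a (sigma, rho) grid.

    Emulates the downstream measurement: for each epoch, the four band cells
    are the Hann-kernel transforms of the modulated component pair (offsets
    0, +-0.5 and +-1.0 Hz, random relative component phase) plus additive
    complex noise of relative power ``rho`` (the cell's noise-to-signal
    ratio, which also carries the signal-noise cross term); the per-cell
    sample CV is taken over a random selection of ``n_sel`` of ``n_avail``
    autocorrelated epochs. Noise is handled inside the Monte Carlo rather
    than analytically because, with heavy-tailed power, the *sample* mean in
    the CV denominator sits well below the population mean, so additive
    noise dilutes the sample CV substantially more than the population ratio
    suggests. Deterministic (fixed internal seed); one table per cohort
    configuration, cached. Returns (sigma grid, rho grid, CV[sigma, rho]).
    """
    rng = np.random.default_rng(987_654_321)
    dt = epoch_s / sub
    phi = float(np.exp(-dt / tau))
    x = _ar1_paths(rng, n_mc, n_avail * sub, phi)
    pick = np.argsort(rng.random((n_mc, n_avail)), axis=1)[:, :n_sel]
    # Hann-kernel weights at the cell offsets relative to each component.
    w = np.hanning(sub + 2)[1:-1]
    w = w / w.sum()
    tt = (np.arange(sub) + 0.5) / sub * epoch_s
    offsets = np.array([-1.0, -0.5, 0.0, 0.5, 1.0]) / epoch_s * 2.0  # Hz
    kern = (w[:, None] * np.exp(-2j * np.pi * offsets[None, :] * tt[:, None]))
    # cell c gets component 1 at offset index c and component 2 at c-1
    idx1 = np.array([1, 2, 3, 4])  # -0.5, 0, +0.5, +1.0 Hz vs component 1
    idx2 = np.array([0, 1, 2, 3])  # -1.0, -0.5, 0, +0.5 Hz vs component 2
    rel_phase = np.exp(1j * rng.uniform(0, 2 * np.pi, size=n_mc))
    noise = (
        rng.standard_normal((n_mc, n_sel, 4), dtype=np.float32)
        + 1j * rng.standard_normal((n_mc, n_sel, 4), dtype=np.float32)
    ) / np.sqrt(2.0)
    sigmas = np.linspace(0.0, 2.0, 41)
    rhos = np.array([0.0, 0.02, 0.05, 0.1, 0.2, 0.4])
    out = np.empty((sigmas.size, rhos.size))
    for i, s in enumerate(sigmas):
        amp = _smooth_envelope(np.exp(s * x), env_smooth_s, dt)
        k = (amp.reshape(n_mc * n_avail, sub) @ kern).reshape(n_mc, n_avail, -1)
        v = k[:, :, idx1] + rel_phase[:, None, None] * k[:, :, idx2]
        m_cell = np.mean(np.abs(v) ** 2, axis=(0, 1))  # population cell power
        v = np.take_along_axis(v, pick[:, :, None], axis=1)
        for j, r in enumerate(rhos):
            cells = np.abs(v + noise * np.sqrt(r * m_cell)) ** 2
            cv = cells.std(axis=1, ddof=1) / cells.mean(axis=1)
            out[i, j] = cv.mean()
    return sigmas, rhos, out


def _calibrate_sigma(target_cv: float, rhos: np.ndarray, config: CohortConfig) -> float:
    """Log-envelope scale whose expected measured sample CV equals the target.

    ``rhos`` holds the noise-to-signal ratio of every expected ROI cell; the
    predicted band CV at scale sigma is the cell average of the Monte-Carlo
    table interpolated at each cell's rho. Targets outside the achievable
    range clamp to the nearest achievable value (zero modulation below the
    additive-noise floor, the table ceiling above it) with a warning — under
    the default conditions clamping affects well under 1% of subjects.
    """
    if target_cv <= 0:
        return 0.0
    # Artifact epochs are excluded before selection, so the analysis draws
    # its epochs from a slightly smaller pool than the raw segmentation.
    n_avail = max(
        config.epochs_analyzed,
        config.n_available_epochs - int(round(config.artifact_rate)),
    )
    sigmas, rho_grid, table = _sample_cv_curve(
        n_avail,
        config.epochs_analyzed,
        config.epoch_length_s,
        config.ou_tau,
        config.env_smooth_s,
    )
    table = np.maximum.accumulate(table, axis=0)  # guard tiny MC wiggle in sigma
    cell_rho = np.clip(rhos, rho_grid[0], rho_grid[-1])

    def predicted(i_sigma: int) -> float:
        row = table[i_sigma]
        return float(np.mean(np.interp(cell_rho, rho_grid, row)))

    pred = np.array([predicted(i) for i in range(sigmas.size)])
    if target_cv <= pred[0]:
        return 0.0
    if target_cv > pred[-1]:
        warnings.warn(
            f"CV target {target_cv:.3g} exceeds the achievable sample-CV "
            f"ceiling {pred[-1]:.3g} at this band SNR; clamping",
            stacklevel=2,
        )
        return float(sigmas[-1])
    pred = np.maximum.accumulate(pred)
    return float(np.interp(target_cv, pred, sigmas))


def _synth_noise(
    rng: np.random.Generator, config: CohortConfig, n_sensors: int, n: int, fs: float
) -> np.ndarray:
    """Gaussian background with one-sided PSD noise_psd(f), sensors independent."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.sqrt(noise_psd(freqs, config) * fs * n / 2.0)
    scale[0] = 0.0
    out = np.empty((n_sensors, n))
    chunk = 32
    for lo in range(0, n_sensors, chunk):
        hi = min(lo + chunk, n_sensors)
        z = (
            rng.standard_normal((hi - lo, freqs.size), dtype=np.float32).astype(float)
            + 1j * rng.standard_normal((hi - lo, freqs.size), dtype=np.float32)
        ) / np.sqrt(2.0)
        if n % 2 == 0:
            z[:, -1] = z[:, -1].real * np.sqrt(2.0)
        out[lo:hi] = np.fft.irfft(z * scale, n=n)
    return out


def simulate_subject(spec: SubjectSpec, config: CohortConfig, seed: int) -> Recording:
    """One subject's continuous recording, fully reproducible from ``seed``."""
    fs = config.sampling_rate
    n = int(round(config.duration_s * fs))
    if n < int(round(config.epoch_length_s * fs)):
        raise InvalidArgumentError("duration_s too short to hold one epoch")
    layout = _cached_layout(config.n_sensors, config.n_temporal_per_side)
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs

    eta = config.hemisphere_mix
    phi = float(np.exp(-1.0 / (fs * config.ou_tau)))
    gl, gr = _source_gains(layout)
    data = np.zeros((layout.n_sensors, n))

    sources = [(spec.alpha_mean_amp, spec.alpha_cv_target, spec.alpha_peak_freq)]
    if spec.upper_alpha_amp > 0:
        sources.append(
            (spec.upper_alpha_amp, spec.upper_alpha_cv, spec.upper_alpha_peak)
        )
    # Component sinusoids are grid-aligned (multiples of 0.5 Hz), hence exactly
    # periodic over one 2 s epoch: when an epoch holds an integer number of
    # samples, build one epoch-long tile and repeat it.
    wlen = int(round(config.epoch_length_s * fs))
    reps = n // wlen + 1
    can_tile = abs(config.epoch_length_s * fs - wlen) < 1e-9
    for amp, cv_target, peak in sources:
        if amp <= 0:
            continue
        rhos = _cell_noise_ratios(amp, peak, spec.noise_scale, config, layout)
        sigma = _calibrate_sigma(cv_target, rhos, config)
        x = _ar1_paths(rng, 3, n, phi)  # common, left, right
        f1, f2 = alpha_component_freqs(peak)
        comp_amp = amp / np.sqrt(2.0)
        for gains, xh in ((gl, x[1]), (gr, x[2])):
            g = np.sqrt(1.0 - eta**2) * x[0] + eta * xh
            env = _smooth_envelope(
                np.exp(sigma * g - sigma**2), config.env_smooth_s, 1.0 / fs
            )
            ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
            if can_tile:
                tile = np.sin(2 * np.pi * f1 * t[:wlen] + ph1) + np.sin(
                    2 * np.pi * f2 * t[:wlen] + ph2
                )
                carrier = np.tile(tile, reps)[:n]
            else:
                carrier = np.sin(2 * np.pi * f1 * t + ph1) + np.sin(
                    2 * np.pi * f2 * t + ph2
                )
            wave = env * carrier
            data += gains[:, None] * (comp_amp * wave)[None, :]

    if config.noise_psd_ref > 0:
        data += spec.noise_scale * _synth_noise(rng, config, layout.n_sensors, n, fs)
    if config.line_amp > 0:
        line_phases = rng.uniform(0, 2 * np.pi, size=layout.n_sensors)
        # sin(wt + phi) expanded so only two length-n trig arrays are needed
        ls, lc = np.sin(2 * np.pi * config.line_freq * t), np.cos(
            2 * np.pi * config.line_freq * t
        )
        data += config.line_amp * (
            np.cos(line_phases)[:, None] * ls[None, :]
            + np.sin(line_phases)[:, None] * lc[None, :]
        )

    annotations: list[tuple[float, float, str]] = []
    n_art = rng.poisson(config.artifact_rate) if config.artifact_rate > 0 else 0
    n_avail = config.n_available_epochs
    if n_art > 0 and n_avail > 0:
        n_art = min(n_art, n_avail)
        # Blink amplitude is pinned to the *realized* background peak-to-peak
        # (per-epoch max over channels), so transients clear any plausible
        # flagging threshold even when the heavy-tailed envelope runs hot.
        wlen = int(round(config.epoch_length_s * fs))
        segs = data[:, : n_avail * wlen].reshape(data.shape[0], n_avail, wlen)
        ptp_max = float((segs.max(axis=2) - segs.min(axis=2)).max())
        amp_art = 8.0 * ptp_max  # >= 5x background peak-to-peak by construction
        width = 0.12
        for e in sorted(rng.choice(n_avail, size=n_art, replace=False)):
            tc = (e + 0.5) * config.epoch_length_s
            lo = max(0, int((tc - 4 * width) * fs))
            hi = min(n, int((tc + 4 * width) * fs))
            tt = t[lo:hi] - tc
            blink = amp_art * np.exp(-(tt**2) / (2 * width**2)) * np.sin(
                2 * np.pi * 2.0 * tt
            )
            data[:, lo:hi] += blink[None, :]
            annotations.append((tc - 2 * width, tc + 2 * width, "blink"))

    return Recording(
        subject_id=spec.subject_id,
        layout=layout,
        sampling_rate=fs,
        data=data,
        annotations=annotations,
    )


def _truncated_lognormal(
    rng: np.random.Generator, median: float, logsd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        v = float(np.exp(np.log(median) + logsd * rng.standard_normal()))
        if lo <= v <= hi:
            return v
    return float(np.clip(v, lo, hi))


def sample_cohort_specs(config: CohortConfig) -> list[SubjectSpec]:
    """Draw the per-subject generative targets for one cohort.

    Controls copy age/sex from their matched tinnitus subject; tinnitus CV
    targets follow cv = b/duration + a plus jitter, control targets sit at
    the tinnitus group mean plus ``group_cv_delta`` (same jitter scale).
    """
    rng = derive_rng(config.seed, "cohort-specs")
    a, b = config.duration_model

    def _shared_draws() -> dict:
        """Group-neutral subject features: upper-alpha source, background level."""
        return {
            "upper_alpha_amp": config.alpha_amp
            * config.upper_alpha_relative
            * float(np.exp(config.alpha_amp_logsd * rng.standard_normal())),
            "upper_alpha_cv": max(
                float(rng.normal(config.upper_cv_mean, config.upper_cv_sd)), 0.2
            ),
            "upper_alpha_peak": float(rng.uniform(*config.upper_peak_range)),
            "noise_scale": float(np.exp(config.noise_logsd * rng.standard_normal())),
        }

    tins: list[SubjectSpec] = []
    matched: list[tuple[float, str]] = []
    cv_targets: list[float] = []
    for i in range(config.n_per_group):
        duration = _truncated_lognormal(
            rng, config.duration_median, config.duration_logsd, *config.duration_range
        )
        age = float(rng.uniform(22, 69))
        sex = "f" if rng.random() < 6 / 21 else "m"
        distress = float(np.clip(np.exp(np.log(17.0) + 0.7 * rng.standard_normal()), 3, 59))
        amp = config.alpha_amp * float(np.exp(config.alpha_amp_logsd * rng.standard_normal()))
        amp *= float(np.sqrt(config.group_power_ratio))
        cv = a + b / duration + float(config.cv_jitter_sd * rng.standard_normal())
        cv = max(cv, 0.05)
        peak = float(rng.uniform(*config.alpha_peak_range))
        tins.append(
            SubjectSpec(
                subject_id=f"tin{i + 1:02d}",
                group="tinnitus",
                age=age,
                sex=sex,
                alpha_mean_amp=amp,
                alpha_cv_target=cv,
                alpha_peak_freq=peak,
                duration=duration,
                distress=distress,
                **_shared_draws(),
            )
        )
        matched.append((age, sex))
        cv_targets.append(cv)
    base_cv = float(np.mean(cv_targets)) + config.group_cv_delta
    cons: list[SubjectSpec] = []
    for i in range(config.n_per_group):
        age, sex = matched[i]
        amp = config.alpha_amp * float(np.exp(config.alpha_amp_logsd * rng.standard_normal()))
        cv = max(base_cv + float(config.cv_jitter_sd * rng.standard_normal()), 0.05)
        peak = float(rng.uniform(*config.alpha_peak_range))
        cons.append(
            SubjectSpec(
                subject_id=f"con{i + 1:02d}",
                group="control",
                age=age,
                sex=sex,
                alpha_mean_amp=amp,
                alpha_cv_target=cv,
                alpha_peak_freq=peak,
                **_shared_draws(),
            )
        )
    return tins + cons


def iter_cohort(config: CohortConfig):
    """Yield (Recording, SubjectSpec) one subject at a time (memory-friendly)."""
    for spec in sample_cohort_specs(config):
        seed = derive_seed(config.seed, spec.subject_id, "signal")
        yield simulate_subject(spec, config, seed), spec


def simulate_cohort(config: CohortConfig) -> list[tuple[Recording, SubjectSpec]]:
    """Materialize a full cohort.

    Note: a default-size cohort holds 42 recordings of 148 x ~200k samples;
    prefer :func:`iter_cohort` for anything close to full scale.
    """
    return list(iter_cohort(config))
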