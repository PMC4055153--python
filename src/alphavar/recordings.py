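"""Sensor layouts and continuous multichannel recordings.

The layout follows the flattened-cap convention: 2-D positions inside the unit
disk, the nose pointing to +y, left ear at negative x. Sensors nearest each
ear are tagged ``left_temporal`` / ``right_temporal``; the tag sets are exact
mirror images of each other about the midline (x = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError

__all__ = ["SensorLayout", "Recording", "make_layout", "EAR_LEFT", "EAR_RIGHT"]

#: Ear positions used both for tagging and for the synthetic source gains.
EAR_LEFT = np.array([-0.95, 0.0])
EAR_RIGHT = np.array([0.95, 0.0])

TEMPORAL_TAGS = ("left_temporal", "right_temporal")


@dataclass(frozen=True)
class SensorLayout:
    """Immutable sensor layout: ids, flattened 2-D positions, region tags."""

    sensor_ids: tuple[str, ...]
    positions: np.ndarray  # (n, 2)
    region_tags: tuple[str, ...]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        n = len(self.sensor_ids)
        if len(set(self.sensor_ids)) != n:
            raise InvalidArgumentError("sensor_ids must be unique")
        if pos.shape != (n, 2) or not np.all(np.isfinite(pos)):
            raise InvalidArgumentError("positions must be a finite (n, 2) array")
        if len(self.region_tags) != n:
            raise InvalidArgumentError("one region tag per sensor required")
        n_left = self.region_tags.count("left_temporal")
        n_right = self.region_tags.count("right_temporal")
        if n_left < 4 or n_right < 4:
            raise InvalidArgumentError("at least 4 sensors per temporal region")
        if n_left != n_right:
            raise InvalidArgumentError("temporal regions must be balanced")

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_ids)

    def temporal_ids(self, side: str) -> tuple[str, ...]:
        """Sensor ids tagged temporal on ``side`` ('left' or 'right')."""
        tag = f"{side}_temporal"
        if tag not in TEMPORAL_TAGS:
            raise InvalidArgumentError(f"side must be 'left' or 'right', got {side!r}")
        return tuple(
            sid for sid, t in zip(self.sensor_ids, self.region_tags) if t == tag
        )

    def index(self, sensor_id: str) -> int:
        return self.sensor_ids.index(sensor_id)

    def indices(self, sensor_ids) -> np.ndarray:
        lookup = {sid: i for i, sid in enumerate(self.sensor_ids)}
        return np.array([lookup[s] for s in sensor_ids], dtype=int)


@dataclass
class Recording:
    """One subject's continuous multichannel time series.

    ``data`` is sensors x samples in arbitrary signal units; ``annotations``
    holds (start_s, stop_s, kind) marks for injected artifacts.
    """

    subject_id: str
    layout: SensorLayout
    sampling_rate: float
    data: np.ndarray
    annotations: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.sampling_rate <= 0:
            raise InvalidArgumentError("sampling_rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != self.layout.n_sensors:
            raise InvalidArgumentError(
                "data must be (n_sensors, n_samples) matching the layout"
            )
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("data must be finite")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


def make_layout(n_sensors: int, n_temporal_per_side: int) -> SensorLayout:
    """Build a deterministic, mirror-symmetric flattened-cap layout.

    Sensors are placed on a symmetric lattice inside the unit disk (every
    off-midline sensor has an exact mirror partner). The ``n_temporal_per_side``
    sensors nearest each ear are tagged temporal; by symmetry the two tag sets
    mirror each other.
    """
    if n_temporal_per_side < 4:
        raise InvalidArgumentError("need at least 4 temporal sensors per side")
    if n_sensors < 2 * n_temporal_per_side:
        raise InvalidArgumentError(
            "n_sensors must be at least twice n_temporal_per_side"
        )

    n_half = n_sensors // 2
    odd = n_sensors % 2

    # Right-half lattice candidates: x = (i + 0.5) h > 0, y symmetric about 0.
    g = int(np.ceil(np.sqrt(2.0 * n_half))) + 2
    h = 2.0 / g
    xs = (np.arange(g) + 0.5) * h / 2.0 * 2.0  # (0.5h, 1.5h, ...)
    ys = (np.arange(2 * g + 1) - g) * h / 2.0 * 2.0
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    cand = np.column_stack([gx.ravel(), gy.ravel()])
    order = np.lexsort((cand[:, 1], cand[:, 0], np.hypot(cand[:, 0], cand[:, 1])))
    right = cand[order[:n_half]]
    left = right * np.array([-1.0, 1.0])
    mid = np.array([[0.0, 0.0]]) if odd else np.empty((0, 2))
    pos = np.vstack([left, right, mid])
    # Scale into the unit disk.
    pos = pos / (np.hypot(pos[:, 0], pos[:, 1]).max() + 1e-12)

    # Stable ordering: back-to-front rows, left-to-right within a row.
    order = np.lexsort((pos[:, 0], -pos[:, 1]))
    pos = pos[order]
    ids = tuple(f"MEG{i + 1:03d}" for i in range(n_sensors))

    tags = ["other"] * n_sensors
    for side, ear in (("left", EAR_LEFT), ("right", EAR_RIGHT)):
        sign = -1.0 if side == "left" else 1.0
        d = np.hypot(pos[:, 0] - ear[0], pos[:, 1] - ear[1])
        eligible = np.where(sign * pos[:, 0] > 0)[0]
        pick = eligible[np.lexsort((eligible, d[eligible]))[:n_temporal_per_side]]
        if len(pick) < n_temporal_per_side:
            raise InvalidArgumentError("layout too small for requested temporal tags")
        for i in pick:
            tags[i] = f"{side}_temporal"

    return SensorLayout(sensor_ids=ids, positions=pos, region_tags=tuple(tags))
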