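"""ROI definition from the low-alpha group-difference topography.

The ROI covers, per hemisphere, the temporal-tagged sensors with the
strongest alpha-power *reduction* in the tinnitus group (most negative
tinnitus-minus-control difference in the 8-10 Hz band). Once defined, the
same ROI is frozen and reused for every band and outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .recordings import SensorLayout
from .spectral import Band

__all__ = ["ROIDefinition", "difference_topography", "define_roi"]


@dataclass(frozen=True)
class ROIDefinition:
    """Per-hemisphere sensor-id sets, frozen after selection."""

    left: tuple[str, ...]
    right: tuple[str, ...]
    k_per_side: int
    source_band: str

    def __post_init__(self) -> None:
        if set(self.left) & set(self.right):
            raise InvalidArgumentError("left and right ROI must be disjoint")
        if len(self.left) != len(self.right) or len(self.left) != self.k_per_side:
            raise InvalidArgumentError("ROI sides must both contain k_per_side sensors")


def difference_topography(
    band_powers: pd.DataFrame, labels: pd.Series, band: Band
) -> pd.Series:
    """Per-sensor (tinnitus mean - control mean) of epoch-averaged band power.

    ``band_powers`` is a subjects x sensors table (one row per subject of
    epoch-averaged power in ``band``); ``labels`` the per-subject group.
    """
    labels = pd.Series(labels, index=band_powers.index)
    groups = set(labels)
    if not {"tinnitus", "control"} <= groups:
        raise InvalidArgumentError("both groups must be nonempty")
    tin = band_powers[labels == "tinnitus"]
    con = band_powers[labels == "control"]
    if tin.empty or con.empty:
        raise InvalidArgumentError("both groups must be nonempty")
    diff = tin.mean(axis=0) - con.mean(axis=0)
    diff.name = band.name
    return diff


def define_roi(
    diff_map: pd.Series, layout: SensorLayout, k_per_side: int, source_band: Band
) -> ROIDefinition:
    """Select, per side, the k temporal sensors with the most negative difference.

    Ties are broken by sensor-id order so the selection is deterministic.
    """
    sides = {}
    for side in ("left", "right"):
        candidates = list(layout.temporal_ids(side))
        if len(candidates) < k_per_side:
            raise InvalidArgumentError(
                f"{side} temporal region has fewer than {k_per_side} sensors"
            )
        missing = [s for s in candidates if s not in diff_map.index]
        if missing:
            raise InvalidArgumentError(f"difference map lacks sensors {missing}")
        order = sorted(candidates, key=lambda s: (diff_map[s], s))
        sides[side] = tuple(order[:k_per_side])
    return ROIDefinition(
        left=sides["left"],
        right=sides["right"],
        k_per_side=k_per_side,
        source_band=source_band.name,
    )
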