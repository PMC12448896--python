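"""Cumulative bregma-relative frequency maps and movement representations.

Positions (neurons or evoked-movement sites, pooled across animals) are
snapped to the nearest gridpoint of the 0.5-mm recording/stimulation grid
and counted. A movement representation is the set of gridpoints where a
movement class was evoked in at least 2 of the 5 animals (inclusive by
default; a strict > variant is available). All downstream statistics use
the raw counts and masks only — the interpolated field exists purely for
contour plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .synthgen import GridSpec

__all__ = [
    "FrequencyMap",
    "Representation",
    "build_frequency_map",
    "representation_mask",
    "interpolate_map",
    "nearest_gridpoint_index",
]


@dataclass
class FrequencyMap:
    """Per-gridpoint cumulative counts; shape (n_cols [ML], n_rows [AP])."""

    grid: GridSpec
    counts: np.ndarray
    label: str = ""

    def __post_init__(self):
        expected = (self.grid.n_cols, self.grid.n_rows)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != grid {expected}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class Representation:
    movement_class: str
    grid: GridSpec
    mask: np.ndarray

    @property
    def area(self) -> int:
        """Representation area in gridpoints (cell area is constant)."""
        return int(self.mask.sum())


class OffGridError(ValueError):
    pass


def nearest_gridpoint_index(
    position: tuple[float, float], grid: GridSpec
) -> tuple[int, int]:
    """(ML index, AP index) of the gridpoint nearest a bregma-relative point.

    Exact half-pitch ties round toward the smaller ML, then smaller AP
    index; positions more than half a pitch outside the grid are rejected.
    """
    ml, ap = position
    out = []
    for v, (lo, _), n in ((ml, grid.ml_range, grid.n_cols), (ap, grid.ap_range, grid.n_rows)):
        f = (v - lo) / grid.pitch
        idx = int(np.floor(f + 0.5 - 1e-9))  # ties toward the smaller index
        if idx < 0 or idx >= n or abs(v - (lo + idx * grid.pitch)) > grid.pitch / 2 + 1e-9:
            raise OffGridError(f"position {position} lies off-grid by > half pitch")
        out.append(idx)
    return out[0], out[1]


def build_frequency_map(
    positions: list[tuple[float, float]],
    grid: GridSpec,
    label: str = "",
) -> FrequencyMap:
    """Accumulate positions (pooled across animals) onto the grid."""
    counts = np.zeros((grid.n_cols, grid.n_rows), dtype=int)
    for pos in positions:
        i, j = nearest_gridpoint_index(pos, grid)
        counts[i, j] += 1
    return FrequencyMap(grid=grid, counts=counts, label=label)


def representation_mask(
    fmap: FrequencyMap, threshold: int = 2, strict: bool = False
) -> Representation:
    """Gridpoints where the cumulative count reaches the animal threshold."""
    mask = fmap.counts > threshold if strict else fmap.counts >= threshold
    if not mask.any():
        warnings.warn(
            f"representation {fmap.label!r} is empty at threshold {threshold}; "
            "it cannot be used downstream",
            stacklevel=2,
        )
    return Representation(movement_class=fmap.label, grid=fmap.grid, mask=mask)


def interpolate_map(
    fmap: FrequencyMap, sigma_pitch: float = 1.0, pad_pitch: int = 8
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-smoothed field for contour plotting (never for statistics).

    Smooths with sigma of one grid pitch on a zero-padded copy of the count
    grid so the total mass is conserved. Returns (field, ml_coords,
    ap_coords) on the padded grid.
    """
    pad = pad_pitch
    padded = np.pad(fmap.counts.astype(float), pad)
    field = gaussian_filter(padded, sigma=sigma_pitch, mode="constant", truncate=8.0)
    g = fmap.grid
    ml = g.ml_range[0] + g.pitch * (np.arange(padded.shape[0]) - pad)
    ap = g.ap_range[0] + g.pitch * (np.arange(padded.shape[1]) - pad)
    return field, ml, ap
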