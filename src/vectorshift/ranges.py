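"""Range-shift analysis of binary potential-range maps.

Overlaying the native and introduced binary potential ranges classifies
every cell as range expansion (introduced only), range stability (both),
range unfilling (native only) or absent. Areas are aggregated in km**2 with
latitude-weighted spherical cell areas, so high-latitude cells do not
inflate the indices. The potential range of the introduced population is
PRI = RE + RS and of the native population PRN = RS + RU; the range ratio
index RRI = PRI / PRN (> 1 when the introduced range is larger) and the
range similarity index RSI = 2 RS / (PRI + PRN) (> 0.5 when the two ranges
sit in similar positions). Dividing each population's range expansion by
its invasion duration gives comparable invasion rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GridSpec, cell_area_km2

__all__ = [
    "RangeDecomposition",
    "RangeShiftIndices",
    "decompose_ranges",
    "range_ratio_index",
    "range_similarity_index",
    "range_shift_indices",
    "invasion_rate_ratio",
    "CLASS_ABSENT",
    "CLASS_EXPANSION",
    "CLASS_STABILITY",
    "CLASS_UNFILLING",
]

CLASS_ABSENT = 0
CLASS_EXPANSION = 1
CLASS_STABILITY = 2
CLASS_UNFILLING = 3


@dataclass
class RangeDecomposition:
    """RE/RS/RU areas in km**2 plus the per-cell class raster."""

    RE: float
    RS: float
    RU: float
    classes: np.ndarray | None = None

    def __post_init__(self) -> None:
        if min(self.RE, self.RS, self.RU) < 0:
            raise ValueError("areas must be nonnegative")

    @property
    def PRI(self) -> float:
        """Potential range of the introduced population = RE + RS."""
        return self.RE + self.RS

    @property
    def PRN(self) -> float:
        """Potential range of the native population = RS + RU."""
        return self.RS + self.RU


@dataclass(frozen=True)
class RangeShiftIndices:
    RRI: float
    RSI: float


def decompose_ranges(
    native: np.ndarray, introduced: np.ndarray, grid: GridSpec
) -> RangeDecomposition:
    """Overlay two binary range maps into RE/RS/RU areas (km**2).

    Cell classes: introduced-only -> expansion, both -> stability,
    native-only -> unfilling, neither -> absent.
    """
    nat = np.asarray(native, dtype=bool)
    intro = np.asarray(introduced, dtype=bool)
    if nat.shape != intro.shape or nat.shape != grid.shape:
        raise ValueError("range maps and grid must share a shape")
    classes = np.full(grid.shape, CLASS_ABSENT, dtype=np.int8)
    classes[intro & ~nat] = CLASS_EXPANSION
    classes[intro & nat] = CLASS_STABILITY
    classes[nat & ~intro] = CLASS_UNFILLING
    area_row = cell_area_km2(grid, np.arange(grid.n_rows))
    area = np.broadcast_to(np.asarray(area_row)[:, None], grid.shape)
    re = float(area[classes == CLASS_EXPANSION].sum())
    rs = float(area[classes == CLASS_STABILITY].sum())
    ru = float(area[classes == CLASS_UNFILLING].sum())
    return RangeDecomposition(RE=re, RS=rs, RU=ru, classes=classes)


def range_ratio_index(d: RangeDecomposition) -> float:
    """RRI = PRI / PRN; > 1 when the introduced range is the larger one."""
    if d.PRN == 0:
        raise ValueError("native potential range is empty (PRN = 0)")
    return d.PRI / d.PRN


def range_similarity_index(d: RangeDecomposition) -> float:
    """RSI = 2 RS / (PRI + PRN) in [0, 1]; > 0.5 means similar positions."""
    denom = d.PRI + d.PRN
    if denom == 0:
        raise ValueError("both potential ranges are empty")
    return 2.0 * d.RS / denom


def range_shift_indices(d: RangeDecomposition) -> RangeShiftIndices:
    return RangeShiftIndices(RRI=range_ratio_index(d), RSI=range_similarity_index(d))


def invasion_rate_ratio(
    re_a: float, duration_a: float, re_b: float, duration_b: float
) -> float:
    """Ratio of range-expansion rates (area per year) of two invasions."""
    if duration_a <= 0 or duration_b <= 0:
        raise ValueError("invasion durations must be positive")
    return (re_a / duration_a) / (re_b / duration_b)
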