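"""The 19 bioclimatic variables from monthly climatologies.

Given 12 monthly minimum/maximum temperature grids (degrees C) and 12
monthly precipitation grids (mm), computes the standard WorldClim-style
bioclimatic summary variables bio01-bio19 per cell:

==== =======================================================
bio01 annual mean temperature (degC)
bio02 mean diurnal range, mean of monthly tmax - tmin (degC)
bio03 isothermality, 100 * bio02 / bio07 (%)
bio04 temperature seasonality, sd of monthly tmean x 100
bio05 max temperature of warmest month (degC)
bio06 min temperature of coldest month (degC)
bio07 temperature annual range, bio05 - bio06 (degC)
bio08 mean temperature of wettest quarter (degC)
bio09 mean temperature of driest quarter (degC)
bio10 mean temperature of warmest quarter (degC)
bio11 mean temperature of coldest quarter (degC)
bio12 annual precipitation (mm)
bio13 precipitation of wettest month (mm)
bio14 precipitation of driest month (mm)
bio15 precipitation seasonality, 100 * sd(prec) / (1 + mean(prec)) (%)
bio16 precipitation of wettest quarter (mm)
bio17 precipitation of driest quarter (mm)
bio18 precipitation of warmest quarter (mm)
bio19 precipitation of coldest quarter (mm)
==== =======================================================

Conventions (matching the widely used biovars/dismo implementation):
monthly mean temperature defaults to (tmin + tmax) / 2 unless an explicit
tmean is supplied; quarters are the 12 *cyclic* consecutive 3-month windows
(Dec-Jan-Feb allowed), ties broken by the earliest window index; standard
deviations are sample (n-1) for bio04 and bio15, and bio15 adds 1 mm to the
mean in the denominator so all-dry cells stay finite. Cells with zero
annual temperature range get NaN isothermality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import GridSpec, PredictorStack

__all__ = ["MonthlyClimate", "compute_bioclim", "BIOCLIM_NAMES"]

BIOCLIM_NAMES = [f"bio{i:02d}" for i in range(1, 20)]


@dataclass
class MonthlyClimate:
    """Aligned 12-month tmin/tmax/precipitation grids on one grid spec."""

    grid: GridSpec
    tmin: np.ndarray  # (12, rows, cols), degC
    tmax: np.ndarray  # (12, rows, cols), degC
    prec: np.ndarray  # (12, rows, cols), mm
    tmean: np.ndarray | None = None  # optional explicit monthly mean temperature

    def __post_init__(self) -> None:
        self.tmin = np.asarray(self.tmin, dtype=float)
        self.tmax = np.asarray(self.tmax, dtype=float)
        self.prec = np.asarray(self.prec, dtype=float)
        expected = (12, *self.grid.shape)
        for name, arr in (("tmin", self.tmin), ("tmax", self.tmax), ("prec", self.prec)):
            if arr.shape != expected:
                raise ValueError(f"{name} must have shape {expected}, got {arr.shape}")
        if np.any(self.tmax < self.tmin):
            raise ValueError("tmax < tmin in at least one cell-month")
        if np.any(self.prec < 0):
            raise ValueError("negative precipitation")
        if self.tmean is not None:
            self.tmean = np.asarray(self.tmean, dtype=float)
            if self.tmean.shape != expected:
                raise ValueError(f"tmean must have shape {expected}")

    def monthly_mean_temperature(self) -> np.ndarray:
        if self.tmean is not None:
            return self.tmean
        return (self.tmin + self.tmax) / 2.0


def _quarter_sums(monthly: np.ndarray) -> np.ndarray:
    """Sums over the 12 cyclic 3-month windows; window w = months w, w+1, w+2 mod 12."""
    ext = np.concatenate([monthly, monthly[:2]], axis=0)
    return np.stack([ext[w : w + 3].sum(axis=0) for w in range(12)], axis=0)


def compute_bioclim(clim: MonthlyClimate) -> PredictorStack:
    """Compute bio01-bio19 as a :class:`PredictorStack` (layer names bio01...bio19)."""
    tmin, tmax, prec = clim.tmin, clim.tmax, clim.prec
    tmean = clim.monthly_mean_temperature()

    out = PredictorStack(clim.grid)
    out["bio01"] = tmean.mean(axis=0)
    out["bio02"] = (tmax - tmin).mean(axis=0)
    out["bio04"] = tmean.std(axis=0, ddof=1) * 100.0
    out["bio05"] = tmax.max(axis=0)
    out["bio06"] = tmin.min(axis=0)
    bio7 = out["bio05"] - out["bio06"]
    out["bio07"] = bio7
    with np.errstate(divide="ignore", invalid="ignore"):
        bio3 = 100.0 * out["bio02"] / bio7
    bio3[bio7 == 0] = np.nan
    out["bio03"] = bio3
    out["bio12"] = prec.sum(axis=0)
    out["bio13"] = prec.max(axis=0)
    out["bio14"] = prec.min(axis=0)
    out["bio15"] = 100.0 * prec.std(axis=0, ddof=1) / (1.0 + prec.mean(axis=0))

    # cyclic quarters; argmin/argmax pick the earliest window on ties
    q_prec = _quarter_sums(prec)
    q_tsum = _quarter_sums(tmean)
    q_tmean = q_tsum / 3.0
    wettest = q_prec.argmax(axis=0)
    driest = q_prec.argmin(axis=0)
    warmest = q_tmean.argmax(axis=0)
    coldest = q_tmean.argmin(axis=0)

    def take(grids: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return np.take_along_axis(grids, idx[None, ...], axis=0)[0]

    out["bio08"] = take(q_tmean, wettest)
    out["bio09"] = take(q_tmean, driest)
    out["bio10"] = take(q_tmean, warmest)
    out["bio11"] = take(q_tmean, coldest)
    out["bio16"] = take(q_prec, wettest)
    out["bio17"] = take(q_prec, driest)
    out["bio18"] = take(q_prec, warmest)
    out["bio19"] = take(q_prec, coldest)

    ordered = PredictorStack(clim.grid, {n: out[n] for n in BIOCLIM_NAMES})
    return ordered
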