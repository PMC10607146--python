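"""Virtual landscapes and virtual species with known niche geometry.

Downstream stages (occurrence cleaning, bioclim, predictor selection,
ensemble SDMs, niche and range dynamics) are validated by *parameter
recovery* on simulated data: we build an environmental landscape, define a
species whose true habitat suitability is a Gaussian response to the
environment, sample presence records proportionally to suitability, run the
estimation pipeline, and compare estimates against the known truth.

The landscape generator produces smooth deterministic gradients plus
spatially autocorrelated noise (moving-average-smoothed Gaussian white
noise, a simple stand-in for a full Gaussian random field). A native and an
introduced population are given separate Gaussian niches; shifting the
introduced optimum away from the native one creates a controllable true
niche shift, and :func:`true_coue` provides the ground-truth
expansion/stability/unfilling decomposition that estimators must recover.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grids import GridSpec, PredictorStack
from .occurrences import OccurrenceSet

__all__ = [
    "LandscapeConfig",
    "VirtualNiche",
    "VirtualSpeciesConfig",
    "generate_landscape",
    "generate_monthly_climate",
    "suitability_surface",
    "sample_occurrences",
    "true_coue",
    "simulate_virtual_species",
]


@dataclass(frozen=True)
class LandscapeConfig:
    """Synthetic landscape: grid geometry plus gradient/noise structure.

    ``cell_size_deg`` defaults to 2.5 arc minutes (2.5/60 degrees), the
    working resolution of the predictor stacks this generator stands in for.
    """

    n_rows: int = 100
    n_cols: int = 100
    cell_size_deg: float = 2.5 / 60.0
    origin_lon: float = 0.0
    origin_lat: float = 50.0
    n_gradient_layers: int = 4
    noise_sd: float = 0.5
    autocorrelation_range: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("landscape needs at least a 2x2 grid")
        if self.cell_size_deg <= 0:
            raise ValueError("cell_size_deg must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.autocorrelation_range < 1:
            raise ValueError("autocorrelation_range must be >= 1")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            cell_size_deg=self.cell_size_deg,
            origin_lon=self.origin_lon,
            origin_lat=self.origin_lat,
        )


@dataclass(frozen=True)
class VirtualNiche:
    """Gaussian niche: optimum and width per environmental layer.

    True suitability at environment e is
    ``prevalence_scale * exp(-0.5 * sum(((e_k - mu_k) / sigma_k)**2))``.
    """

    mu: tuple[float, ...]
    sigma: tuple[float, ...]
    prevalence_scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", tuple(float(m) for m in self.mu))
        object.__setattr__(self, "sigma", tuple(float(s) for s in self.sigma))
        if len(self.mu) != len(self.sigma):
            raise ValueError("mu and sigma must have the same length")
        if any(s <= 0 for s in self.sigma):
            raise ValueError("all niche widths must be positive")
        if not 0 < self.prevalence_scale <= 1:
            raise ValueError("prevalence_scale must be in (0, 1]")

    def shifted(self, delta: float | tuple[float, ...]) -> "VirtualNiche":
        """A copy with the optimum displaced by ``delta`` (scalar or per-layer)."""
        if np.isscalar(delta):
            delta = (float(delta),) * len(self.mu)
        return VirtualNiche(
            mu=tuple(m + d for m, d in zip(self.mu, delta)),
            sigma=self.sigma,
            prevalence_scale=self.prevalence_scale,
        )


@dataclass(frozen=True)
class VirtualSpeciesConfig:
    """Paired native/introduced virtual populations."""

    native: VirtualNiche
    introduced: VirtualNiche
    n_native: int = 2000
    n_introduced: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_native < 1 or self.n_introduced < 1:
            raise ValueError("record counts must be >= 1")


def _smoothed_noise(rng: np.random.Generator, shape: tuple[int, int],
                    sd: float, rng_cells: int) -> np.ndarray:
    """Moving-average smoothing of white noise over a square window,
    rescaled so the marginal standard deviation stays ``sd``."""
    white = rng.normal(0.0, 1.0, size=shape)
    k = 2 * rng_cells + 1
    kernel = np.ones(k) / k
    # separable box filter with edge padding
    pad = rng_cells
    padded = np.pad(white, pad, mode="reflect")
    sm = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, padded)
    sm = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="valid"), 0, sm)
    s = sm.std()
    if s > 0:
        sm = sm / s
    return sd * sm


def generate_landscape(config: LandscapeConfig) -> PredictorStack:
    """Environmental layers: deterministic gradient + autocorrelated noise.

    Layer k is linear in the row/col indices with a direction that rotates
    across layers (west-east, north-south and two diagonals cycling), scaled
    to span [0, 10] before noise, so layers are not mutually redundant.
    Layer names are ``env00``, ``env01``, ...
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = np.meshgrid(
        np.arange(config.n_rows), np.arange(config.n_cols), indexing="ij"
    )
    directions = [
        cols / max(config.n_cols - 1, 1),
        rows / max(config.n_rows - 1, 1),
        (cols + rows) / max(config.n_cols + config.n_rows - 2, 1),
        (cols - rows - (1 - config.n_rows)) / max(config.n_cols + config.n_rows - 2, 1),
    ]
    stack = PredictorStack(config.grid)
    for k in range(config.n_gradient_layers):
        gradient = 10.0 * directions[k % len(directions)]
        layer = gradient.astype(float)
        if config.noise_sd > 0:
            layer = layer + _smoothed_noise(
                rng, config.grid.shape, config.noise_sd, config.autocorrelation_range
            )
        stack[f"env{k:02d}"] = layer
    return stack


def generate_monthly_climate(
    config: LandscapeConfig,
    seasonal_amplitude: float,
    annual_mean_field: np.ndarray,
    prec_pattern: np.ndarray,
    annual_prec_total: float | np.ndarray = 1200.0,
    diurnal_half_range: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Monthly (tmin, tmax, prec) series, each (12, rows, cols).

    Mean temperature follows a sinusoid around the per-cell annual mean,
    ``tmean_m = mean - A * cos(2*pi*m/12)`` for month index m = 0..11, so
    January (m=0) is exactly the coldest month ("northern" convention) and
    the per-cell annual range of monthly means is exactly 2A. tmax/tmin are
    tmean +/- a fixed diurnal half-range. Precipitation distributes an
    annual total over months proportionally to the 12 nonnegative weights.
    """
    prec_pattern = np.asarray(prec_pattern, dtype=float)
    if prec_pattern.shape != (12,):
        raise ValueError("prec_pattern must have 12 entries")
    if np.any(prec_pattern < 0):
        raise ValueError("precipitation weights must be nonnegative")
    if prec_pattern.sum() == 0:
        raise ValueError("precipitation weights must not all be zero")
    annual_mean_field = np.asarray(annual_mean_field, dtype=float)
    if annual_mean_field.shape != config.grid.shape:
        raise ValueError("annual_mean_field shape must match the landscape grid")

    months = np.arange(12)
    season = -np.cos(2.0 * np.pi * months / 12.0)  # trough at January
    tmean = annual_mean_field[None, :, :] + seasonal_amplitude * season[:, None, None]
    tmax = tmean + diurnal_half_range
    tmin = tmean - diurnal_half_range
    weights = prec_pattern / prec_pattern.sum()
    total = np.broadcast_to(np.asarray(annual_prec_total, dtype=float), config.grid.shape)
    prec = weights[:, None, None] * total[None, :, :]
    return tmin, tmax, prec


def suitability_surface(stack: PredictorStack, niche: VirtualNiche) -> np.ndarray:
    """True habitat suitability in [0, prevalence_scale] per cell."""
    if len(stack) != len(niche.mu):
        raise ValueError(
            f"stack has {len(stack)} layers but niche defines {len(niche.mu)} optima"
        )
    z2 = np.zeros(stack.grid.shape)
    for k, name in enumerate(stack.names):
        z2 += ((stack[name] - niche.mu[k]) / niche.sigma[k]) ** 2
    return niche.prevalence_scale * np.exp(-0.5 * z2)


def sample_occurrences(
    suitability: np.ndarray,
    grid: GridSpec,
    n: int,
    seed: int | None = None,
    population: str = "unassigned",
    uncertainty_km: float = 0.0,
) -> OccurrenceSet:
    """Draw n presence records with probability proportional to suitability.

    Cells are drawn multinomially (with replacement), then each record is
    jittered uniformly within its cell so deduplication and thinning have
    non-degenerate inputs.
    """
    s = np.asarray(suitability, dtype=float).ravel()
    if s.shape[0] != grid.n_rows * grid.n_cols:
        raise ValueError("suitability shape does not match grid")
    if np.any(s < 0):
        raise ValueError("suitability must be nonnegative")
    total = s.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample")
    rng = np.random.default_rng(seed)
    cells = rng.choice(s.shape[0], size=n, replace=True, p=s / total)
    row, col = np.unravel_index(cells, grid.shape)
    jitter_lon = rng.uniform(0.0, 1.0, size=n)
    jitter_lat = rng.uniform(0.0, 1.0, size=n)
    lon = grid.origin_lon + (col + jitter_lon) * grid.cell_size_deg
    lat = grid.origin_lat - (row + jitter_lat) * grid.cell_size_deg
    import pandas as pd

    return OccurrenceSet(
        pd.DataFrame(
            {
                "lon": lon,
                "lat": lat,
                "uncertainty_km": uncertainty_km,
                "source": "synthetic",
                "population": population,
            }
        )
    )


def true_coue(
    native: VirtualNiche,
    introduced: VirtualNiche,
    stack: PredictorStack,
    occupancy_cutoff: float = 0.05,
) -> tuple[float, float, float]:
    """Ground-truth (E, S, U) from the known suitability surfaces.

    Each population's true suitability is binarized at
    ``occupancy_cutoff x its maximum``; E is the fraction of introduced
    cells not native, S = 1 - E, and U the fraction of native cells not
    introduced. This is the oracle that estimated COUE indices are checked
    against in recovery tests.
    """
    if not 0 < occupancy_cutoff < 1:
        raise ValueError("occupancy_cutoff must be in (0, 1)")
    s_nat = suitability_surface(stack, native)
    s_int = suitability_surface(stack, introduced)
    occ_nat = s_nat >= occupancy_cutoff * s_nat.max()
    occ_int = s_int >= occupancy_cutoff * s_int.max()
    n_int = occ_int.sum()
    n_nat = occ_nat.sum()
    e = float((occ_int & ~occ_nat).sum() / n_int) if n_int else 0.0
    u = float((occ_nat & ~occ_int).sum() / n_nat) if n_nat else 0.0
    return e, 1.0 - e, u


def simulate_virtual_species(
    landscape: LandscapeConfig,
    species: VirtualSpeciesConfig,
    occupancy_cutoff: float = 0.05,
) -> dict:
    """Full simulation bundle for one virtual-species experiment.

    Returns a dict with the predictor stack, native/introduced occurrence
    sets, both true suitability surfaces and the true (E, S, U).
    """
    stack = generate_landscape(landscape)
    s_nat = suitability_surface(stack, species.native)
    s_int = suitability_surface(stack, species.introduced)
    rng = np.random.default_rng(species.seed)
    seed_nat, seed_int = rng.integers(0, 2**31 - 1, size=2)
    occ_nat = sample_occurrences(
        s_nat, stack.grid, species.n_native, seed=int(seed_nat), population="native"
    )
    occ_int = sample_occurrences(
        s_int, stack.grid, species.n_introduced, seed=int(seed_int), population="introduced"
    )
    e, s, u = true_coue(species.native, species.introduced, stack, occupancy_cutoff)
    return {
        "stack": stack,
        "native_occurrences": occ_nat,
        "introduced_occurrences": occ_int,
        "native_suitability": s_nat,
        "introduced_suitability": s_int,
        "true_E": e,
        "true_S": s,
        "true_U": u,
    }


def save_simulation(bundle: dict, out_dir: str | Path) -> None:
    """Write a simulation bundle: .asc predictors, CSV occurrences, JSON truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["stack"].save(out / "predictors")
    bundle["native_occurrences"].save(out / "occurrences_native.csv")
    bundle["introduced_occurrences"].save(out / "occurrences_introduced.csv")
    truth = {k: bundle[k] for k in ("true_E", "true_S", "true_U")}
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
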