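"""COUE niche dynamics in a 2-axis PCA environmental space.

The niche comparison between a native and an introduced population follows
the COUE scheme (Centroid shift, Overlap, Unfilling, Expansion):

1. :func:`pca_env` — PCA of the predictor values over the pooled background
   (all available environments), standardized, keeping the first two axes.
2. :func:`density_grid` — Gaussian kernel densities of each population's
   occurrence scores and of the background scores, evaluated on an R x R
   grid (default 100 x 100) spanning the pooled background; the normalized
   occupancy z is the occurrence density scaled by its maximum wherever the
   background has support.
3. :func:`coue_indices` — decomposes the introduced occupancy into
   expansion E (introduced density mass in cells the native niche does not
   occupy) and stability S = 1 - E, and the native occupancy into unfilling
   U (native mass outside the introduced niche).
4. Shift indices on top of the decomposition: with the introduced niche
   breadth normalized to IB = S + E = 1 and the native breadth NB = S + U,
   the breadth ratio is BR = IB / NB and the niche similarity index
   SI = 2S / (IB + NB). Niche conservatism is rejected only when SI < 0.5
   and BR > 1 simultaneously.

Overlap between two occupancy grids is Schoener's D, and the classic
permutation tests (niche equivalency and niche similarity) use D as their
statistic.

A Gaussian kernel never reaches exact zero, so "unoccupied" cells are
defined by a small relative occupancy floor (default 1e-6 of the maximum,
equivalent to truncating the kernel at about 5.3 bandwidths).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EnvSpaceGrid",
    "COUEDecomposition",
    "NicheShiftIndices",
    "pca_env",
    "density_grid",
    "schoener_D",
    "coue_indices",
    "breadth_ratio",
    "niche_similarity_index",
    "conservatism_verdict",
    "niche_shift_indices",
    "equivalency_test",
    "similarity_test",
    "niche_dynamics_report",
]

OCCUPANCY_FLOOR = 1e-6  # relative to max density; see module docstring


@dataclass
class PCAEnv:
    """2-axis environmental PCA fitted on pooled background values."""

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # (2, n_predictors)
    explained_variance_ratio: np.ndarray
    kept: np.ndarray  # boolean mask of non-constant predictors

    def transform(self, env: np.ndarray) -> np.ndarray:
        env = np.asarray(env, dtype=float)[:, self.kept]
        z = (env - self.mean) / self.scale
        return z @ self.components.T


def pca_env(background_env: np.ndarray) -> PCAEnv:
    """PCA of pooled background predictor values, standardized, top 2 axes.

    Constant predictors are dropped with a warning. Returns a projection
    applicable to occurrence environments and the explained-variance
    fractions of the two axes.
    """
    env = np.asarray(background_env, dtype=float)
    if env.ndim != 2 or env.shape[0] < 3 or env.shape[1] < 2:
        raise ValueError("need >= 3 background points and >= 2 predictors")
    sd = env.std(axis=0, ddof=0)
    kept = sd > 0
    if not kept.all():
        logger.warning("dropping %d constant predictors from PCA", int((~kept).sum()))
    env = env[:, kept]
    if env.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant predictors")
    mean = env.mean(axis=0)
    scale = env.std(axis=0, ddof=0)
    z = (env - mean) / scale
    cov = np.cov(z, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    comps = evecs[:, :2].T
    for i in range(2):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    evr = evals / evals.sum()
    return PCAEnv(
        mean=mean,
        scale=scale,
        components=comps,
        explained_variance_ratio=evr[:2],
        kept=kept,
    )


def _silverman_bandwidth(x: np.ndarray) -> float:
    """Normal-reference (Silverman) rule per axis."""
    n = x.shape[0]
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread == 0:
        spread = max(abs(x).max(), 1.0) * 1e-3
    return 0.9 * spread * n ** (-1 / 5)


def _kde_on_grid(points: np.ndarray, gx: np.ndarray, gy: np.ndarray,
                 bw: tuple[float, float]) -> np.ndarray:
    """Gaussian product-kernel density on the grid (len(gx) x len(gy))."""
    dx = (gx[:, None] - points[None, :, 0]) / bw[0]
    dy = (gy[:, None] - points[None, :, 1]) / bw[1]
    kx = np.exp(-0.5 * dx**2)
    ky = np.exp(-0.5 * dy**2)
    dens = kx @ ky.T  # (len(gx), len(gy)) sum over points of kx*ky
    dens /= 2 * np.pi * bw[0] * bw[1] * points.shape[0]
    return dens


@dataclass
class EnvSpaceGrid:
    """Occupancy and availability densities on an R x R environmental grid."""

    axis1: np.ndarray  # cell-center coordinates on PCA axis 1 (len R)
    axis2: np.ndarray
    occ_density: np.ndarray  # (R, R), sums to 1
    env_density: np.ndarray  # (R, R), sums to 1
    bandwidth: tuple[float, float]

    @property
    def occupancy(self) -> np.ndarray:
        """z: occurrence density / max, zeroed where the background is absent
        or below the relative occupancy floor."""
        z = self.occ_density / self.occ_density.max()
        z = np.where(self.env_density > 0, z, 0.0)
        z[z < OCCUPANCY_FLOOR] = 0.0
        return z


def density_grid(
    occ_scores: np.ndarray,
    background_scores: np.ndarray,
    R: int = 100,
    bandwidth: tuple[float, float] | None = None,
    extent: tuple[np.ndarray, np.ndarray] | None = None,
) -> EnvSpaceGrid:
    """Kernel-density occupancy grid over the pooled background extent.

    Both densities use a Gaussian product kernel with per-axis Silverman
    bandwidths from the occurrence scores (overridable) and are normalized
    to sum to 1 over the grid. Background cells whose availability density
    falls below the relative floor are treated as unavailable. ``extent``
    ((lo, hi) per axis) overrides the background bounding box so several
    grids can share one coordinate frame.
    """
    occ = np.asarray(occ_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if occ.ndim != 2 or occ.shape[1] != 2 or bg.ndim != 2 or bg.shape[1] != 2:
        raise ValueError("scores must be (n, 2) arrays")
    if occ.shape[0] < 5:
        raise ValueError("need at least 5 occurrence points for a density grid")
    if extent is not None:
        lo, hi = np.asarray(extent[0], float), np.asarray(extent[1], float)
    else:
        lo = bg.min(axis=0)
        hi = bg.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    gx = lo[0] + (np.arange(R) + 0.5) / R * span[0]
    gy = lo[1] + (np.arange(R) + 0.5) / R * span[1]
    if bandwidth is None:
        bandwidth = (_silverman_bandwidth(occ[:, 0]), _silverman_bandwidth(occ[:, 1]))
    occ_d = _kde_on_grid(occ, gx, gy, bandwidth)
    env_d = _kde_on_grid(bg, gx, gy, bandwidth)
    env_d[env_d < OCCUPANCY_FLOOR * env_d.max()] = 0.0
    occ_d /= occ_d.sum()
    env_d = env_d / env_d.sum()
    return EnvSpaceGrid(
        axis1=gx, axis2=gy, occ_density=occ_d, env_density=env_d, bandwidth=bandwidth
    )


def schoener_D(z1: np.ndarray, z2: np.ndarray) -> float:
    """Schoener's niche overlap D = 1 - 0.5 * sum|p1 - p2| in [0, 1].

    Each occupancy grid is renormalized to sum to 1; D = 1 for identical
    grids, 0 for disjoint supports, and is symmetric.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError("occupancy grids must share a shape")
    p1 = z1 / z1.sum()
    p2 = z2 / z2.sum()
    return float(1.0 - 0.5 * np.abs(p1 - p2).sum())


@dataclass(frozen=True)
class COUEDecomposition:
    """Niche expansion / stability / unfilling fractions.

    E and S are fractions of the *introduced* niche (E + S = 1 exactly);
    U is the fraction of the *native* niche found outside the introduced one.
    """

    E: float
    S: float
    U: float

    def __post_init__(self) -> None:
        for name, v in (("E", self.E), ("S", self.S), ("U", self.U)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(self.E + self.S - 1.0) > 1e-9:
            raise ValueError("E + S must equal 1")


def coue_indices(
    z_native: np.ndarray,
    z_introduced: np.ndarray,
    env_mask_native: np.ndarray | None = None,
    env_mask_introduced: np.ndarray | None = None,
    analog_only: bool = True,
) -> COUEDecomposition:
    """Expansion/stability/unfilling from two occupancy grids.

    E = introduced density mass in cells where the native occupancy is zero,
    as a fraction of total introduced mass; S = 1 - E; U = native mass in
    cells where the introduced occupancy is zero, as a fraction of total
    native mass. With ``analog_only`` the sums are restricted to analog
    environments: cells available in both backgrounds (when masks given).
    """
    z_nat = np.asarray(z_native, dtype=float)
    z_int = np.asarray(z_introduced, dtype=float)
    if z_nat.shape != z_int.shape:
        raise ValueError("occupancy grids must share a shape")
    if z_nat.sum() == 0 or z_int.sum() == 0:
        raise ValueError("empty occupancy grid")
    if analog_only and env_mask_native is not None and env_mask_introduced is not None:
        analog = np.asarray(env_mask_native, bool) & np.asarray(env_mask_introduced, bool)
        z_nat = np.where(analog, z_nat, 0.0)
        z_int = np.where(analog, z_int, 0.0)
        if z_nat.sum() == 0 or z_int.sum() == 0:
            raise ValueError("no analog environment shared by both backgrounds")
    e = float(z_int[z_nat == 0].sum() / z_int.sum())
    u = float(z_nat[z_int == 0].sum() / z_nat.sum())
    return COUEDecomposition(E=e, S=1.0 - e, U=u)


def breadth_ratio(d: COUEDecomposition) -> float:
    """Breadth ratio BR = IB / NB with the introduced breadth normalized.

    In introduced-niche units IB = S + E = 1 and NB = S + U, so
    BR = 1 / (S + U); BR > 1 means the introduced niche is the wider one.
    """
    nb = d.S + d.U
    if nb == 0:
        raise ValueError("native breadth S + U is zero")
    return (d.S + d.E) / nb


def niche_similarity_index(d: COUEDecomposition) -> float:
    """Niche similarity index SI = 2S / (IB + NB) = 2S / (1 + S + U).

    SI > 0.5 indicates the two populations hold similar niche positions.
    """
    return 2.0 * d.S / ((d.S + d.E) + (d.S + d.U))


def conservatism_verdict(br: float, si: float) -> Literal["conserved", "not_conserved"]:
    """Niche conservatism is rejected only when SI < 0.5 and BR > 1."""
    if not (np.isfinite(br) and np.isfinite(si)):
        raise ValueError("BR and SI must be finite")
    return "not_conserved" if (si < 0.5 and br > 1.0) else "conserved"


@dataclass(frozen=True)
class NicheShiftIndices:
    NB: float
    IB: float
    BR: float
    SI: float
    verdict: Literal["conserved", "not_conserved"]


def niche_shift_indices(d: COUEDecomposition) -> NicheShiftIndices:
    br = breadth_ratio(d)
    si = niche_similarity_index(d)
    return NicheShiftIndices(
        NB=d.S + d.U, IB=d.S + d.E, BR=br, SI=si, verdict=conservatism_verdict(br, si)
    )


def _D_between(occ1: np.ndarray, occ2: np.ndarray, bg: np.ndarray, R: int,
               bandwidth=None) -> float:
    g1 = density_grid(occ1, bg, R=R, bandwidth=bandwidth)
    g2 = density_grid(occ2, bg, R=R, bandwidth=bandwidth)
    return schoener_D(g1.occupancy, g2.occupancy)


def equivalency_test(
    occ_scores1: np.ndarray,
    occ_scores2: np.ndarray,
    background_scores: np.ndarray,
    n_perm: int = 99,
    R: int = 100,
    seed: int | None = None,
) -> tuple[float, float]:
    """Niche equivalency test: are the two niches interchangeable?

    Null distribution: pool the two occurrence sets, randomly re-split into
    groups of the original sizes, recompute D. One-sided
    p = (1 + #{D_null <= D_obs}) / (n_perm + 1) against the alternative
    that the observed niches are *less* equivalent than random splits.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    occ1 = np.asarray(occ_scores1, float)
    occ2 = np.asarray(occ_scores2, float)
    bg = np.asarray(background_scores, float)
    d_obs = _D_between(occ1, occ2, bg, R)
    pooled = np.vstack([occ1, occ2])
    n1 = occ1.shape[0]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        d_null = _D_between(pooled[perm[:n1]], pooled[perm[n1:]], bg, R)
        if d_null <= d_obs:
            count += 1
    return d_obs, (1 + count) / (n_perm + 1)


def similarity_test(
    occ_scores1: np.ndarray,
    occ_scores2: np.ndarray,
    background_scores2: np.ndarray,
    n_perm: int = 99,
    R: int = 100,
    seed: int | None = None,
) -> tuple[float, float]:
    """Niche similarity test: is niche 2 more similar to niche 1 than a
    niche placed at random within background 2?

    Null distribution: translate niche 2's occurrences so their centroid
    lands at a uniformly random point inside background 2's occupied
    envelope, recompute D against niche 1. One-sided
    p = (1 + #{D_null >= D_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    occ1 = np.asarray(occ_scores1, float)
    occ2 = np.asarray(occ_scores2, float)
    bg2 = np.asarray(background_scores2, float)
    lo, hi = bg2.min(axis=0), bg2.max(axis=0)
    if np.any(hi <= lo):
        raise ValueError("background envelope too small to shift within")
    d_obs = _D_between(occ1, occ2, bg2, R)
    centroid = occ2.mean(axis=0)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        target = rng.uniform(lo, hi)
        shifted = occ2 + (target - centroid)
        d_null = _D_between(occ1, shifted, bg2, R)
        if d_null >= d_obs:
            count += 1
    return d_obs, (1 + count) / (n_perm + 1)


def niche_dynamics_report(
    native_env: np.ndarray,
    introduced_env: np.ndarray,
    background_native_env: np.ndarray,
    background_introduced_env: np.ndarray,
    R: int = 100,
    n_perm: int = 0,
    seed: int | None = None,
    analog_only: bool = True,
) -> dict:
    """End-to-end COUE analysis from raw predictor values.

    Fits the environmental PCA on the pooled backgrounds, builds the two
    occupancy grids on a shared R x R grid, and returns E/S/U, Schoener's D,
    BR, SI, the conservatism verdict and (when ``n_perm > 0``) the
    equivalency and similarity test p-values.
    """
    bg_pool = np.vstack([background_native_env, background_introduced_env])
    pca = pca_env(bg_pool)
    sc_bg_nat = pca.transform(background_native_env)
    sc_bg_int = pca.transform(background_introduced_env)
    sc_bg = np.vstack([sc_bg_nat, sc_bg_int])
    sc_nat = pca.transform(native_env)
    sc_int = pca.transform(introduced_env)
    extent = (sc_bg.min(axis=0), sc_bg.max(axis=0))
    g_nat = density_grid(sc_nat, sc_bg, R=R, extent=extent)
    g_int = density_grid(sc_int, sc_bg, R=R, bandwidth=g_nat.bandwidth, extent=extent)
    # availability masks come from each population's own background density,
    # evaluated on the shared pooled-extent grid
    mask_nat = density_grid(sc_nat, sc_bg_nat, R=R, bandwidth=g_nat.bandwidth, extent=extent)
    mask_int = density_grid(sc_int, sc_bg_int, R=R, bandwidth=g_nat.bandwidth, extent=extent)
    d = coue_indices(
        g_nat.occupancy,
        g_int.occupancy,
        env_mask_native=mask_nat.env_density > 0,
        env_mask_introduced=mask_int.env_density > 0,
        analog_only=analog_only,
    )
    idx = niche_shift_indices(d)
    report = {
        "E": d.E,
        "S": d.S,
        "U": d.U,
        "D": schoener_D(g_nat.occupancy, g_int.occupancy),
        "NB": idx.NB,
        "IB": idx.IB,
        "BR": idx.BR,
        "SI": idx.SI,
        "verdict": idx.verdict,
        "pca_explained_variance": pca.explained_variance_ratio.tolist(),
    }
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        s1, s2 = rng.integers(0, 2**31 - 1, size=2)
        _, p_eq = equivalency_test(sc_nat, sc_int, sc_bg, n_perm=n_perm, R=R, seed=int(s1))
        _, p_sim = similarity_test(sc_nat, sc_int, sc_bg_int, n_perm=n_perm, R=R, seed=int(s2))
        report["equivalency_p"] = p_eq
        report["similarity_p"] = p_sim
    return report
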