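"""End-to-end convenience workflows tying the modules together.

These wrap the common experiment: clean two occurrence populations, run the
COUE niche analysis on predictor values extracted at their locations, fit
the TSS-weighted ensemble for each population, binarize at the max
sensitivity+specificity threshold and decompose the two binary ranges into
expansion/stability/unfilling with the shift indices.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .grids import GridSpec, PredictorStack
from .niche import niche_dynamics_report
from .occurrences import OccurrenceSet, deduplicate, filter_uncertainty, spatial_thin
from .ranges import RangeDecomposition, decompose_ranges, range_shift_indices
from .sdm import (
    EnsembleModel,
    build_ensemble,
    cross_validate,
    max_sens_spec_threshold,
    sample_pseudo_absences,
)

__all__ = ["clean_occurrences", "niche_analysis", "fit_population_sdm", "range_analysis"]


def clean_occurrences(
    occ: OccurrenceSet,
    max_uncertainty_km: float = 5.0,
    thin_radius_km: float = 5.0,
    seed: int | None = None,
) -> OccurrenceSet:
    """Deduplicate, uncertainty-filter then spatially thin, in that order."""
    occ = deduplicate(occ)
    occ = filter_uncertainty(occ, max_km=max_uncertainty_km)
    return spatial_thin(occ, radius_km=thin_radius_km, seed=seed)


def niche_analysis(
    native: OccurrenceSet,
    introduced: OccurrenceSet,
    predictors: PredictorStack,
    predictor_names: Sequence[str] | None = None,
    R: int = 100,
    n_perm: int = 0,
    seed: int | None = None,
) -> dict:
    """COUE niche dynamics between two occurrence populations.

    Predictor values are extracted at each record's cell; the background
    for each population is every grid cell (shared landscape). Returns the
    dict from :func:`vectorshift.niche.niche_dynamics_report`.
    """
    names = list(predictor_names) if predictor_names is not None else predictors.names
    env_nat = predictors.values_at(native.lon, native.lat, names)
    env_int = predictors.values_at(introduced.lon, introduced.lat, names)
    bg = predictors.as_matrix(names)
    return niche_dynamics_report(
        env_nat, env_int, bg, bg, R=R, n_perm=n_perm, seed=seed
    )


def fit_population_sdm(
    occ: OccurrenceSet,
    predictors: PredictorStack,
    predictor_names: Sequence[str] | None = None,
    domain: np.ndarray | None = None,
    algorithms: Sequence[str] = ("GLM", "RF", "CTA", "SRE"),
    replicates: int = 3,
    repeats: int = 5,
    seed: int | None = None,
) -> dict:
    """Pseudo-absences, cross-validated evaluations, ensemble and binary map.

    Returns a dict with the fitted :class:`EnsembleModel`, the evaluations,
    the continuous suitability raster, the max sens+spec threshold and the
    binary potential-range map.
    """
    names = list(predictor_names) if predictor_names is not None else predictors.names
    if domain is None:
        domain = np.ones(predictors.grid.shape, dtype=bool)
    rng = np.random.default_rng(seed)
    s_pa, s_cv, s_ens = (int(x) for x in rng.integers(0, 2**31 - 1, size=3))
    tables = sample_pseudo_absences(
        occ, domain, predictors.grid, predictors, names,
        replicates=replicates, seed=s_pa,
    )
    evals = cross_validate(tables, algorithms, repeats=repeats, seed=s_cv)
    ensemble = build_ensemble(evals, tables, algorithms, seed=s_ens)
    suitability = ensemble.predict_raster(predictors, names)
    scores = ensemble.predict(tables[0].X)
    threshold = max_sens_spec_threshold(scores, tables[0].y)
    return {
        "ensemble": ensemble,
        "evaluations": evals,
        "tables": tables,
        "suitability": suitability,
        "threshold": threshold,
        "binary_range": suitability >= threshold,
    }


def range_analysis(
    native_range: np.ndarray, introduced_range: np.ndarray, grid: GridSpec
) -> dict:
    """RE/RS/RU areas plus RRI and RSI for two binary potential ranges."""
    d = decompose_ranges(native_range, introduced_range, grid)
    idx = range_shift_indices(d)
    return {
        "RE_km2": d.RE,
        "RS_km2": d.RS,
        "RU_km2": d.RU,
        "PRI_km2": d.PRI,
        "PRN_km2": d.PRN,
        "RRI": idx.RRI,
        "RSI": idx.RSI,
        "decomposition": d,
    }
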