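"""Importance-guided pruning of collinear predictors.

Predictor importance is measured by permutation: importance(p) = 1 minus
the Pearson correlation between a fitted model's predictions on the
original data and its predictions after permuting column p, averaged over
shuffles (and over ensemble members when given several models). A predictor
the model ignores scores 0; one the model depends on entirely scores near 1.

Collinearity is then removed iteratively: while any off-diagonal |r|
exceeds the threshold (default 0.7), the pair with the largest |r| loses
its lower-importance member, ties going against the lexicographically
later name. The surviving predictor set has no pairwise |r| above the
threshold and is never empty.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["variable_importance", "prune_collinear"]


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def variable_importance(
    models,
    X: np.ndarray,
    predictor_names: Sequence[str],
    n_shuffles: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation importance of each predictor, in [0, 1].

    ``models`` is a fitted model or a list of them (each exposing
    ``predict(X) -> scores``). For each predictor the column is permuted
    ``n_shuffles`` times; the importance is the mean of
    ``1 - corr(pred_original, pred_permuted)`` capped at 1 (negative
    correlations floor at importance 1). Constant predictions yield
    importance 0 with a warning. Returns a tidy DataFrame with one row per
    predictor: per-model mean importances and the cross-model mean.
    """
    if not isinstance(models, (list, tuple)):
        models = [models]
    X = np.asarray(X, dtype=float)
    names = list(predictor_names)
    if X.shape[1] != len(names):
        raise ValueError("predictor_names length must match X columns")
    rng = np.random.default_rng(seed)
    rows = []
    for mi, model in enumerate(models):
        base = model.predict(X)
        if np.std(base) == 0:
            logger.warning("model %d has constant predictions; importances set to 0", mi)
            for name in names:
                rows.append({"model": mi, "predictor": name, "importance": 0.0})
            continue
        for j, name in enumerate(names):
            vals = []
            for _ in range(n_shuffles):
                Xp = X.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                perm = model.predict(Xp)
                r = _safe_corr(base, perm)
                if np.isnan(r):  # permutation left predictions constant
                    vals.append(1.0 if np.std(perm) == 0 and not np.allclose(perm, base)
                                else 0.0)
                else:
                    vals.append(min(1.0 - r, 1.0))
            imp = float(np.clip(np.mean(vals), 0.0, 1.0))
            rows.append({"model": mi, "predictor": name, "importance": imp})
    df = pd.DataFrame(rows)
    out = df.groupby("predictor", as_index=False)["importance"].mean()
    return out.set_index("predictor").loc[names].reset_index()


def prune_collinear(
    corr: pd.DataFrame,
    importance: Mapping[str, float] | pd.DataFrame,
    threshold: float = 0.7,
) -> list[str]:
    """Iteratively drop the lower-importance member of the most collinear pair.

    ``corr`` is a symmetric predictor correlation matrix with unit diagonal;
    ``importance`` maps each predictor to its importance. Repeats until no
    off-diagonal |r| exceeds ``threshold`` and returns the retained names in
    their original order.
    """
    if isinstance(importance, pd.DataFrame):
        importance = dict(zip(importance["predictor"], importance["importance"]))
    names = list(corr.columns)
    if list(corr.index) != names:
        raise ValueError("correlation matrix must have matching row/column names")
    missing = [n for n in names if n not in importance]
    if missing:
        raise ValueError(f"importance missing for predictors: {missing}")
    mat = corr.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    alive = list(names)
    while len(alive) > 1:
        sub = corr.loc[alive, alive].to_numpy(dtype=float)
        absr = np.abs(sub)
        np.fill_diagonal(absr, 0.0)
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[i, j] <= threshold:
            break
        a, b = alive[i], alive[j]
        ia, ib = importance[a], importance[b]
        if ia > ib:
            drop = b
        elif ib > ia:
            drop = a
        else:
            drop = max(a, b)  # tie: drop the lexicographically later name
        alive.remove(drop)
    return alive
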