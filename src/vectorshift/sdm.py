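"""Ensemble species distribution modelling.

Presence-only modelling with pseudo-absences: presences plus an equal
number of background cells drawn uniformly from the modelling domain
(or 1000 when there are fewer than that many presences), in several
independent pseudo-absence replicates. A registry of algorithms (GLM, CTA,
ANN, FDA, MARS, GBM, RF, MAXENT, SRE) is fitted per replicate; each is
evaluated by repeated stratified 70/30 cross-validation with AUC and TSS.
Algorithms whose mean AUC > 0.8 or mean TSS > 0.6 enter the ensemble with a
weight proportional to their mean TSS; the ensemble suitability is the
weighted mean of member predictions, binarized at the threshold maximizing
sensitivity + specificity. A null-model test (random presences, real test
set) guards against spuriously high scores.

All algorithms except SRE delegate to scikit-learn estimators behind a
uniform predict-in-[0,1] contract; SRE (surface range envelope) is the
classic quantile bounding box and is implemented natively. MARS and FDA
are represented by hinge-basis and polynomial-basis discriminants of the
same family; MAXENT is a penalized logistic regression on maxnet-style
features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .grids import GridSpec
from .occurrences import OccurrenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "ALGORITHMS",
    "TrainingTable",
    "ModelEvaluation",
    "EnsembleModel",
    "sample_pseudo_absences",
    "fit_algorithm",
    "evaluate",
    "auc_score",
    "tss_score",
    "cross_validate",
    "build_ensemble",
    "max_sens_spec_threshold",
    "null_model_test",
]


@dataclass
class TrainingTable:
    """Presence/pseudo-absence training rows for one replicate."""

    X: np.ndarray  # (n, p) predictor values
    y: np.ndarray  # 1 presence, 0 pseudo-absence
    predictor_names: list[str]
    replicate: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")


@dataclass(frozen=True)
class ModelEvaluation:
    algorithm: str
    auc: float
    tss: float
    tss_threshold: float
    replicate: int = 0
    repeat: int = 0


def pseudo_absence_count(n_presence: int) -> int:
    """Equal numbers when presences exceed 1000, else 1000 ('over 1000' strict)."""
    return n_presence if n_presence > 1000 else 1000


def sample_pseudo_absences(
    presences: OccurrenceSet,
    domain: np.ndarray,
    grid: GridSpec,
    predictors: "object",
    predictor_names: Sequence[str],
    replicates: int = 3,
    seed: int | None = None,
) -> list[TrainingTable]:
    """Build presence/pseudo-absence tables for each replicate.

    ``domain`` is a boolean land-mask raster; pseudo-absence cells are drawn
    uniformly over domain cells *excluding* presence cells, independently
    per replicate. Presence predictor values are taken at each record's
    cell; pseudo-absence values at the sampled cells' centers.
    """
    domain = np.asarray(domain, dtype=bool)
    if domain.shape != grid.shape:
        raise ValueError("domain mask shape must match the grid")
    names = list(predictor_names)
    n_pres = len(presences)
    n_pa = pseudo_absence_count(n_pres)
    pres_rows, pres_cols = grid.cell_index(presences.lon, presences.lat)
    pres_flat = np.unique(np.ravel_multi_index((pres_rows, pres_cols), grid.shape))
    free = np.flatnonzero(domain.ravel())
    free = np.setdiff1d(free, pres_flat, assume_unique=False)
    if free.size < n_pa:
        raise ValueError(
            f"domain has only {free.size} free cells, need {n_pa} pseudo-absences"
        )
    X_pres = predictors.values_at(presences.lon, presences.lat, names)
    rng = np.random.default_rng(seed)
    tables = []
    for r in range(replicates):
        cells = rng.choice(free, size=n_pa, replace=False)
        rr, cc = np.unravel_index(cells, grid.shape)
        X_pa = np.column_stack([predictors[n][rr, cc] for n in names])
        X = np.vstack([X_pres, X_pa])
        y = np.concatenate([np.ones(n_pres, int), np.zeros(n_pa, int)])
        tables.append(TrainingTable(X=X, y=y, predictor_names=names, replicate=r))
    return tables


# ---------------------------------------------------------------------------
# algorithm registry


class SREModel:
    """Surface range envelope: inside the per-predictor presence quantile
    envelope [q, 1-q] on every predictor -> score 1, else 0."""

    def __init__(self, q: float = 0.025):
        if not 0 <= q < 0.5:
            raise ValueError("q must be in [0, 0.5)")
        self.q = q

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SREModel":
        pres = X[y == 1]
        if pres.shape[0] == 0:
            raise ValueError("no presences to fit envelope")
        self.lo_ = np.quantile(pres, self.q, axis=0)
        self.hi_ = np.quantile(pres, 1.0 - self.q, axis=0)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        inside = np.all((X >= self.lo_) & (X <= self.hi_), axis=1)
        return inside.astype(float)


class _HingeFeatures:
    """MARS-style hinge basis max(0, x-k), max(0, k-x) at quantile knots."""

    def __init__(self, n_knots: int = 5):
        self.n_knots = n_knots

    def fit(self, X: np.ndarray, y=None) -> "_HingeFeatures":
        qs = np.linspace(0.1, 0.9, self.n_knots)
        self.knots_ = np.quantile(X, qs, axis=0)  # (n_knots, p)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        feats = [X]
        for k in range(self.knots_.shape[0]):
            feats.append(np.maximum(0.0, X - self.knots_[k]))
            feats.append(np.maximum(0.0, self.knots_[k] - X))
        return np.hstack(feats)

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def get_params(self, deep=True):
        return {"n_knots": self.n_knots}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self


class _SklearnWrapper:
    """Adapts a scikit-learn classifier to the predict-in-[0,1] contract."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_SklearnWrapper":
        self.estimator.fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(X)
        classes = getattr(self.estimator, "classes_", None)
        if classes is None:  # pipeline
            classes = self.estimator[-1].classes_
        col = int(np.flatnonzero(classes == 1)[0])
        return proba[:, col]


def _make_glm(seed):
    return _SklearnWrapper(
        make_pipeline(
            StandardScaler(),
            PolynomialFeatures(degree=2, include_bias=False),
            LogisticRegression(max_iter=2000),
        )
    )


def _make_cta(seed):
    return _SklearnWrapper(DecisionTreeClassifier(min_samples_leaf=5, random_state=seed))


def _make_ann(seed):
    return _SklearnWrapper(
        make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(16,), max_iter=500, random_state=seed),
        )
    )


def _make_fda(seed):
    return _SklearnWrapper(
        make_pipeline(
            StandardScaler(),
            PolynomialFeatures(degree=2, include_bias=False),
            LinearDiscriminantAnalysis(),
        )
    )


def _make_mars(seed):
    return _SklearnWrapper(
        make_pipeline(
            StandardScaler(),
            _HingeFeatures(n_knots=5),
            LogisticRegression(max_iter=2000),
        )
    )


def _make_gbm(seed):
    return _SklearnWrapper(
        GradientBoostingClassifier(n_estimators=100, max_depth=3, random_state=seed)
    )


def _make_rf(seed):
    return _SklearnWrapper(
        RandomForestClassifier(n_estimators=200, min_samples_leaf=2, random_state=seed)
    )


def _make_maxent(seed):
    # maxnet-style: linear + quadratic + product features, L2-penalized logistic
    return _SklearnWrapper(
        make_pipeline(
            StandardScaler(),
            PolynomialFeatures(degree=2, include_bias=False),
            LogisticRegression(C=0.5, max_iter=2000),
        )
    )


def _make_sre(seed):
    return SREModel(q=0.025)


ALGORITHMS: dict[str, Callable[[int | None], object]] = {
    "GLM": _make_glm,
    "CTA": _make_cta,
    "ANN": _make_ann,
    "FDA": _make_fda,
    "MARS": _make_mars,
    "GBM": _make_gbm,
    "RF": _make_rf,
    "MAXENT": _make_maxent,
    "SRE": _make_sre,
}


def fit_algorithm(name: str, train: TrainingTable, seed: int | None = None):
    """Fit one registry algorithm on a training table."""
    if name not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {name!r}; choose from {sorted(ALGORITHMS)}")
    if len(np.unique(train.y)) < 2:
        raise ValueError("training data must contain both classes")
    model = ALGORITHMS[name](seed)
    return model.fit(train.X, train.y)


# ---------------------------------------------------------------------------
# evaluation


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank statistic (ties counted 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for AUC")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def tss_score(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(TSS, threshold): max over observed-score thresholds of
    sensitivity + specificity - 1, predicting positive at score >= t.

    Ties in the maximum go to the smallest qualifying threshold.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for TSS")
    thresholds = np.unique(scores)
    # at threshold t: sens = P(score_pos >= t), spec = P(score_neg < t)
    sens = (scores[pos][None, :] >= thresholds[:, None]).mean(axis=1)
    spec = (scores[~pos][None, :] < thresholds[:, None]).mean(axis=1)
    tss = sens + spec - 1.0
    best = np.max(tss)
    t = float(thresholds[np.flatnonzero(tss == best)[0]])
    return float(best), t


def evaluate(model, X_test: np.ndarray, y_test: np.ndarray,
             algorithm: str = "", replicate: int = 0, repeat: int = 0) -> ModelEvaluation:
    """AUC/TSS evaluation of a fitted model on a held-out table."""
    if len(np.unique(y_test)) < 2:
        raise ValueError("test data must contain both classes")
    scores = model.predict(np.asarray(X_test, float))
    auc = auc_score(scores, y_test)
    tss, thr = tss_score(scores, y_test)
    return ModelEvaluation(
        algorithm=algorithm, auc=auc, tss=tss, tss_threshold=thr,
        replicate=replicate, repeat=repeat,
    )


def _stratified_split(y: np.ndarray, train_fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        k = int(round(train_fraction * idx.size))
        k = min(max(k, 1), idx.size - 1)
        train_idx.append(idx[:k])
        test_idx.append(idx[k:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def cross_validate(
    tables: Sequence[TrainingTable],
    algorithms: Sequence[str],
    train_fraction: float = 0.7,
    repeats: int = 5,
    seed: int | None = None,
) -> list[ModelEvaluation]:
    """Repeated stratified 70/30 cross-validation over PA replicates.

    Returns repeats x replicates x algorithms evaluations.
    """
    rng = np.random.default_rng(seed)
    evals: list[ModelEvaluation] = []
    for rep in range(repeats):
        for table in tables:
            tr, te = _stratified_split(table.y, train_fraction, rng)
            if len(np.unique(table.y[tr])) < 2 or len(np.unique(table.y[te])) < 2:
                raise ValueError("degenerate split: a side lost a class")
            sub = TrainingTable(table.X[tr], table.y[tr], table.predictor_names,
                                table.replicate)
            fit_seed = int(rng.integers(0, 2**31 - 1))
            for name in algorithms:
                model = fit_algorithm(name, sub, seed=fit_seed)
                evals.append(
                    evaluate(model, table.X[te], table.y[te], algorithm=name,
                             replicate=table.replicate, repeat=rep)
                )
    return evals


# ---------------------------------------------------------------------------
# ensemble


@dataclass
class EnsembleModel:
    """TSS-weighted ensemble of qualifying member models."""

    members: list[tuple[str, object]]          # (algorithm, fitted model)
    weights: np.ndarray                        # per member, sums to 1
    evaluations: pd.DataFrame                  # per-algorithm mean AUC/TSS
    included_algorithms: list[str]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        out = np.zeros(X.shape[0])
        for w, (_, model) in zip(self.weights, self.members):
            out += w * model.predict(X)
        return out

    def predict_raster(self, predictors, names: Sequence[str]) -> np.ndarray:
        X = predictors.as_matrix(list(names))
        return self.predict(X).reshape(predictors.grid.shape)


def summarize_evaluations(evals: Sequence[ModelEvaluation]) -> pd.DataFrame:
    df = pd.DataFrame([vars(e) for e in evals])
    return df.groupby("algorithm", as_index=False)[["auc", "tss"]].mean()


def build_ensemble(
    evals: Sequence[ModelEvaluation],
    tables: Sequence[TrainingTable],
    algorithms: Sequence[str],
    auc_min: float = 0.8,
    tss_min: float = 0.6,
    seed: int | None = None,
) -> EnsembleModel:
    """TSS-weighted ensemble of algorithms passing AUC > 0.8 OR TSS > 0.6.

    Evaluations are averaged per algorithm over all replicates and repeats
    before applying the inclusion rule; qualifying algorithms are refitted
    on each full pseudo-absence replicate table and each fitted member gets
    weight proportional to its algorithm's mean TSS (split evenly across
    replicates). Raises when no algorithm qualifies.
    """
    summary = summarize_evaluations(evals)
    summary = summary[summary["algorithm"].isin(algorithms)]
    qual = summary[(summary["auc"] > auc_min) | (summary["tss"] > tss_min)]
    if qual.empty:
        raise ValueError("no qualifying models: every algorithm failed AUC/TSS inclusion")
    tss_by_alg = dict(zip(qual["algorithm"], qual["tss"]))
    rng = np.random.default_rng(seed)
    members: list[tuple[str, object]] = []
    weights: list[float] = []
    n_rep = len(tables)
    for name, tss in tss_by_alg.items():
        for table in tables:
            model = fit_algorithm(name, table, seed=int(rng.integers(0, 2**31 - 1)))
            members.append((name, model))
            weights.append(max(tss, 0.0) / n_rep)
    w = np.asarray(weights, float)
    if w.sum() <= 0:
        raise ValueError("no qualifying models with positive TSS weight")
    w = w / w.sum()
    return EnsembleModel(
        members=members,
        weights=w,
        evaluations=summary,
        included_algorithms=sorted(tss_by_alg),
    )


def max_sens_spec_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Binarization threshold maximizing sensitivity + specificity.

    Returns the smallest observed score achieving the maximum (positive
    predicted at score >= threshold); degenerate all-equal scores return
    that score with a warning.
    """
    scores = np.asarray(scores, float)
    if np.unique(scores).size == 1:
        logger.warning("all scores identical; degenerate threshold")
        return float(scores[0])
    _, thr = tss_score(scores, labels)
    return thr


def null_model_test(
    real_auc: float,
    tables: Sequence[TrainingTable],
    domain_X: np.ndarray,
    algorithm: str = "GLM",
    n_null: int = 19,
    train_fraction: float = 0.7,
    seed: int | None = None,
) -> float:
    """Null-model reliability test for an SDM.

    Each null run replaces the training presences with uniformly random
    domain cells (count = 70% of the real presences), fits the algorithm
    against the real pseudo-absences, and evaluates on a held-out 30% of
    the *real* presences (plus held-out pseudo-absences). The p-value is
    the rank of the real AUC: p = (1 + #{null AUC >= real}) / (n_null + 1).
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng(seed)
    count = 0
    table = tables[0]
    pres_idx = np.flatnonzero(table.y == 1)
    abs_idx = np.flatnonzero(table.y == 0)
    n_train_pres = int(round(train_fraction * pres_idx.size))
    n_train_abs = int(round(train_fraction * abs_idx.size))
    for _ in range(n_null):
        te_pres = rng.permutation(pres_idx)[n_train_pres:]
        perm_abs = rng.permutation(abs_idx)
        tr_abs, te_abs = perm_abs[:n_train_abs], perm_abs[n_train_abs:]
        null_pres = domain_X[rng.choice(domain_X.shape[0], size=n_train_pres, replace=True)]
        X_tr = np.vstack([null_pres, table.X[tr_abs]])
        y_tr = np.concatenate([np.ones(n_train_pres, int), np.zeros(tr_abs.size, int)])
        model = fit_algorithm(
            algorithm,
            TrainingTable(X_tr, y_tr, table.predictor_names),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        te = np.concatenate([te_pres, te_abs])
        scores = model.predict(table.X[te])
        null_auc = auc_score(scores, table.y[te])
        if null_auc >= real_auc:
            count += 1
    return (1 + count) / (n_null + 1)
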