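"""EVMAP model: recursive feature elimination, XGBoost grid search, and the
repeated-cross-validation ensemble of out-of-fold probabilities.

The EVMAP score for a patient is the mean of their *held-out* class
probabilities over repeated stratified 5-fold cross-validation (100 repeats x
5 folds = 500 gradient-boosting models at full scale), reported on a 0-100
percent scale.  Feature selection (random-forest-ranked recursive
elimination) and hyperparameter grid search each use their own repeated CV.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from xgboost import XGBClassifier

from .errors import ConfigurationError, FoldError, InputError

#: XGBoost parameters pinned for scaled runs (no grid search).
PINNED_PARAMS = {"n_rounds": 100, "max_depth": 3, "eta": 0.1}


@dataclass
class CVScheme:
    """Repeated (optionally stratified) k-fold scheme."""

    n_folds: int = 5
    n_repeats: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")


def _repeat_seeds(scheme: CVScheme) -> list:
    children = np.random.SeedSequence(scheme.seed).spawn(scheme.n_repeats)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


def make_cv_folds(labels, scheme: CVScheme) -> np.ndarray:
    """Fold assignments, shape ``(n_repeats, n_patients)`` of fold indices.

    Stratified folds preserve the class ratio within one patient per fold;
    deterministic under the scheme seed.
    """
    y = np.asarray(labels).astype(int)
    if scheme.stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < scheme.n_folds:
            raise FoldError(
                f"smallest class has {counts.min()} patients < n_folds="
                f"{scheme.n_folds}; reduce n_folds or disable stratification")
    elif len(y) < scheme.n_folds:
        raise FoldError(f"{len(y)} patients < n_folds={scheme.n_folds}")
    out = np.empty((scheme.n_repeats, len(y)), dtype=int)
    for r, seed in enumerate(_repeat_seeds(scheme)):
        splitter = (StratifiedKFold(scheme.n_folds, shuffle=True, random_state=seed)
                    if scheme.stratified
                    else KFold(scheme.n_folds, shuffle=True, random_state=seed))
        for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
            out[r, test_idx] = fold
    return out


def _check_features(features) -> pd.DataFrame:
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(np.asarray(features, dtype=float))
        features.columns = [f"f{i}" for i in range(features.shape[1])]
    bad = [c for c in features.columns if not np.isfinite(features[c].to_numpy()).all()]
    if bad:
        raise InputError(f"non-finite feature values in columns: {', '.join(map(str, bad))}")
    return features


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise InputError("labels contain a single class; a binary outcome is required")
    return y


# ---------------------------------------------------------------------------
# Recursive feature elimination
# ---------------------------------------------------------------------------

@dataclass
class RFEResult:
    schedule: list            # feature-subset sizes, strictly decreasing
    auc_profile: list         # mean cross-validated AUC per subset size
    selected_features: list   # subset maximizing the AUC profile
    subsets: dict = field(default_factory=dict)  # size -> feature names

    def __post_init__(self) -> None:
        if len(self.schedule) != len(self.auc_profile):
            raise InputError("schedule and auc_profile length mismatch")
        if any(b >= a for a, b in zip(self.schedule, self.schedule[1:])):
            raise InputError("schedule must be strictly decreasing")


def rfe_schedule(n_features: int, removal_fraction: float) -> list:
    """Subset sizes visited: each step removes floor(fraction x current),
    always at least one feature, down to a single feature."""
    sizes = [n_features]
    while sizes[-1] > 1:
        drop = max(math.floor(removal_fraction * sizes[-1]), 1)
        sizes.append(sizes[-1] - drop)
    return sizes


def run_rfe(features, labels, removal_fraction: float, scheme: CVScheme,
            rf_params: dict | None = None) -> RFEResult:
    """Random-forest-ranked recursive feature elimination.

    At each subset size, a random forest is fit per (repeat, fold) training
    split; the held-out AUCs are averaged into the profile, impurity
    importances are averaged across fits, and the ``floor(removal_fraction x
    current)`` (at least one) lowest-importance features are dropped.  The
    selected subset maximizes the mean AUC (ties broken toward fewer
    features).
    """
    if not (0 < removal_fraction < 1):
        raise ConfigurationError("removal_fraction must be in (0, 1)")
    X = _check_features(features)
    y = _check_labels(labels)
    if X.shape[1] < 2:
        raise InputError("recursive elimination needs at least 2 features")
    rf_params = {"n_estimators": 100, **(rf_params or {})}
    folds = make_cv_folds(y, scheme)
    model_seeds = iter(range(10 ** 6))

    current = list(X.columns)
    schedule, aucs, subsets = [], [], {}
    while True:
        Xc = X[current].to_numpy()
        fold_aucs, importances = [], np.zeros(len(current))
        n_fits = 0
        for r in range(scheme.n_repeats):
            for fold in range(scheme.n_folds):
                test = folds[r] == fold
                clf = RandomForestClassifier(random_state=next(model_seeds),
                                             n_jobs=1, **rf_params)
                clf.fit(Xc[~test], y[~test])
                prob = clf.predict_proba(Xc[test])[:, 1]
                fold_aucs.append(roc_auc_score(y[test], prob))
                importances += clf.feature_importances_
                n_fits += 1
        importances /= n_fits
        schedule.append(len(current))
        aucs.append(float(np.mean(fold_aucs)))
        subsets[len(current)] = list(current)
        if len(current) == 1:
            break
        n_drop = max(math.floor(removal_fraction * len(current)), 1)
        order = np.argsort(importances)  # ascending: least important first
        keep = sorted(order[n_drop:])
        current = [current[i] for i in keep]

    best = max(aucs)
    # ties -> the later (smaller) subset: parsimony
    best_idx = max(i for i, a in enumerate(aucs) if a == best)
    return RFEResult(schedule=schedule, auc_profile=aucs,
                     selected_features=subsets[schedule[best_idx]], subsets=subsets)


# ---------------------------------------------------------------------------
# XGBoost grid search
# ---------------------------------------------------------------------------

@dataclass
class XGBGrid:
    """The hyperparameter grid: 4 boosting-round counts x 3 depths x 2
    learning rates = 24 combinations."""

    n_rounds: tuple = (100, 150, 200, 250)
    max_depth: tuple = (3, 4, 5)
    eta: tuple = (0.01, 0.1)

    def __post_init__(self) -> None:
        for name in ("n_rounds", "max_depth", "eta"):
            vals = getattr(self, name)
            if not vals:
                raise ConfigurationError(f"grid.{name} must be non-empty")
            if any(v <= 0 for v in vals):
                raise ConfigurationError(f"grid.{name} values must be positive")

    def combinations(self) -> list:
        # sorted order doubles as the deterministic tie-break:
        # fewer rounds, then smaller depth, then smaller eta
        return [{"n_rounds": n, "max_depth": d, "eta": e}
                for n in sorted(self.n_rounds)
                for d in sorted(self.max_depth)
                for e in sorted(self.eta)]


def _make_booster(params: dict, seed: int) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=int(params["n_rounds"]), max_depth=int(params["max_depth"]),
        learning_rate=float(params["eta"]), tree_method="hist", n_jobs=1,
        random_state=seed, eval_metric="logloss")


@dataclass
class GridSearchResult:
    best_params: dict
    results: pd.DataFrame  # one row per combination with its mean CV AUC


def grid_search_xgb(features, labels, grid: XGBGrid, scheme: CVScheme) -> GridSearchResult:
    """Mean cross-validated AUC for every grid combination; returns the best."""
    X = _check_features(features).to_numpy()
    y = _check_labels(labels)
    folds = make_cv_folds(y, scheme)
    rows = []
    best_params, best_auc = None, -np.inf
    for combo in grid.combinations():
        fold_aucs = []
        for r in range(scheme.n_repeats):
            for fold in range(scheme.n_folds):
                test = folds[r] == fold
                clf = _make_booster(combo, seed=r * scheme.n_folds + fold)
                clf.fit(X[~test], y[~test])
                fold_aucs.append(roc_auc_score(y[test], clf.predict_proba(X[test])[:, 1]))
        mean_auc = float(np.mean(fold_aucs))
        rows.append({**combo, "mean_auc": mean_auc})
        if mean_auc > best_auc:  # strict: earlier (smaller) combos win ties
            best_auc, best_params = mean_auc, combo
    return GridSearchResult(best_params=best_params, results=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Out-of-fold ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleResult:
    """Per-patient out-of-fold probabilities and the averaged EVMAP score."""

    heldout_probabilities: np.ndarray  # (n_patients, n_repeats), each column one repeat
    fold_assignments: np.ndarray       # (n_repeats, n_patients)
    params: dict
    feature_names: list
    patient_ids: list
    base_models: list = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return len(self.base_models)

    @property
    def evmap_score(self) -> np.ndarray:
        """Mean held-out probability of the positive class, percent scale."""
        return self.heldout_probabilities.mean(axis=1) * 100.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"evmap_score": self.evmap_score}, index=self.patient_ids)
        df.index.name = "patient_id"
        return df


def train_ensemble(features, labels, params: dict | None = None,
                   scheme: CVScheme | None = None, keep_models: bool = True) -> EnsembleResult:
    """Train the out-of-fold XGBoost ensemble.

    For every repeat and fold, a booster is fit on the 4 training folds (80%
    of the cohort) and scores the held-out fold; the held-out fold never
    influences model development.  With 5 folds x 100 repeats this yields 500
    base models and 100 held-out probabilities per patient.
    """
    params = dict(params or PINNED_PARAMS)
    scheme = scheme or CVScheme(n_folds=5, n_repeats=100)
    X = _check_features(features)
    y = _check_labels(labels)
    patient_ids = list(X.index) if isinstance(X.index, pd.Index) else list(range(len(y)))
    Xa = X.to_numpy()
    folds = make_cv_folds(y, scheme)
    heldout = np.full((len(y), scheme.n_repeats), np.nan)
    models = []
    seeds = np.random.SeedSequence(scheme.seed).spawn(scheme.n_repeats * scheme.n_folds)
    for r in range(scheme.n_repeats):
        for fold in range(scheme.n_folds):
            test = folds[r] == fold
            seed = int(seeds[r * scheme.n_folds + fold].generate_state(1)[0] % (2 ** 31))
            clf = _make_booster(params, seed=seed)
            clf.fit(Xa[~test], y[~test])
            heldout[test, r] = clf.predict_proba(Xa[test])[:, 1]
            if keep_models:
                models.append(clf)
    assert not np.isnan(heldout).any()
    return EnsembleResult(heldout_probabilities=heldout, fold_assignments=folds,
                          params=params, feature_names=list(X.columns),
                          patient_ids=patient_ids, base_models=models)
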