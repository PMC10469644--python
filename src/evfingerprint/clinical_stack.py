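"""Clinical risk stacking: median imputation, a pluggable logistic clinical
risk calculator, and the cross-validated logistic stack that combines the
EVMAP score with clinical inputs into the EV-Fingerprint score.

The clinical risk model plays the role of an external high-grade-cancer risk
calculator over six covariates (age, race, family history, prior negative
biopsy, PSA, DRE).  Its published coefficients are not distributed here: the
default :data:`DEFAULT_RISK_SPEC` is a documented synthetic stand-in whose
output occupies the same percent range; the real calculator drops in as a
YAML :class:`RiskModelSpec`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from .errors import ConfigurationError, InputError, SeparationError
from .evmap_learner import CVScheme, make_cv_folds

BINARY_COVARIATES = ("dre_abnormal", "race_black", "family_history",
                     "prior_negative_biopsy", "diabetes")

#: Covariate transforms available to risk-model specs.
TRANSFORMS = {
    "identity": lambda x: x,
    "log": np.log,
    "log10": np.log10,
    "log10p1": lambda x: np.log10(np.asarray(x, dtype=float) + 1.0),
}

#: Stacking variants: name -> design columns ("evmap" and "pcptrc" are the
#: percent-scale model scores; the rest are clinical covariates).
VARIANTS = {
    "evmap_psa_age": ["evmap", "psa", "age"],
    "evmap_psa_age_dre": ["evmap", "psa", "age", "dre_abnormal"],
    "ev_fingerprint": ["evmap", "pcptrc"],
}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def impute_median(records: pd.DataFrame, covariates, training_ids) -> pd.DataFrame:
    """Fill missing covariate values with medians of the *training* rows only.

    Binary covariates are imputed with the training median rounded half-up to
    {0, 1}; observed values are never touched.
    """
    training_ids = list(training_ids)
    if not training_ids:
        raise InputError("training_ids must be non-empty")
    out = records.copy()
    train = records.loc[training_ids]
    for cov in covariates:
        if cov not in records.columns:
            raise InputError(f"covariate {cov!r} not in records")
        observed = train[cov].dropna()
        if observed.empty:
            raise InputError(f"covariate {cov!r} has no observed training values")
        med = float(observed.median())
        if cov in BINARY_COVARIATES:
            med = float(_round_half_up(med))
        out[cov] = out[cov].fillna(med)
    return out


@dataclass
class RiskModelSpec:
    """Logistic clinical risk model: percent = 100 x logistic(b0 + sum bi xi).

    ``transforms`` maps a coefficient name to ``(source_column, transform)``;
    coefficients without an entry read the same-named raw column.
    """

    intercept: float
    coefficients: dict
    transforms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (src, tname) in self.transforms.items():
            if tname not in TRANSFORMS:
                raise ConfigurationError(f"unknown transform {tname!r} for {name!r}")

    @classmethod
    def from_yaml(cls, path) -> "RiskModelSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        transforms = {k: tuple(v) for k, v in (raw.get("transforms") or {}).items()}
        return cls(intercept=float(raw["intercept"]),
                   coefficients={k: float(v) for k, v in raw["coefficients"].items()},
                   transforms=transforms)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"intercept": self.intercept,
                            "coefficients": dict(self.coefficients),
                            "transforms": {k: list(v) for k, v in self.transforms.items()}},
                           fh, sort_keys=False)


#: Synthetic stand-in for an external six-covariate high-grade risk
#: calculator.  Coefficient signs and the output range (median ~9% in GG<=2,
#: ~15% in GG>=3 on the default synthetic cohort) are realistic; the values
#: are NOT the published calculator's.
DEFAULT_RISK_SPEC = RiskModelSpec(
    intercept=-7.1,
    coefficients={"age": 0.045, "psa_log": 2.1, "dre_abnormal": 0.85,
                  "family_history": 0.45, "race_black": 0.35,
                  "prior_negative_biopsy": -0.55},
    transforms={"psa_log": ("psa", "log10p1")},
)


def clinical_risk(records, spec: RiskModelSpec | None = None) -> np.ndarray:
    """Evaluate the risk model on (imputed) records; returns percent in (0, 100)."""
    spec = spec or DEFAULT_RISK_SPEC
    df = records.to_frame().T if isinstance(records, pd.Series) else records
    lp = np.full(len(df), float(spec.intercept))
    for name, coef in spec.coefficients.items():
        src, tname = spec.transforms.get(name, (name, "identity"))
        if src not in df.columns:
            raise ConfigurationError(f"risk model references unknown covariate {src!r}")
        values = df[src].to_numpy(dtype=float)
        if np.isnan(values).any():
            raise InputError(f"covariate {src!r} has missing values; impute first")
        lp = lp + coef * np.asarray(TRANSFORMS[tname](values), dtype=float)
    return 100.0 / (1.0 + np.exp(-lp))


def _fit_logit(X: np.ndarray, y: np.ndarray, ridge: bool):
    """Plain maximum-likelihood logistic fit; perfect separation raises unless
    the ridge fallback is enabled."""
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        if converged and np.all(np.isfinite(res.params)) and np.abs(res.params).max() < 1e4:
            return ("mle", res)
    except Exception:
        if not ridge:
            raise SeparationError(
                "logistic maximum likelihood failed (perfect separation?); "
                "pass ridge=True for a penalized fallback")
    if not ridge:
        raise SeparationError(
            "logistic maximum likelihood did not converge (perfect separation?); "
            "pass ridge=True for a penalized fallback")
    from sklearn.linear_model import LogisticRegression
    clf = LogisticRegression(C=10.0, max_iter=1000)
    clf.fit(X, y)
    return ("ridge", clf)


def _predict_logit(model, X: np.ndarray) -> np.ndarray:
    kind, fit = model
    if kind == "mle":
        return np.asarray(fit.predict(sm.add_constant(X, has_constant="add")))
    return fit.predict_proba(X)[:, 1]


def fit_logistic(X, y):
    """Convenience MLE logistic fit returning (intercept, coefficients)."""
    kind, res = _fit_logit(np.asarray(X, dtype=float), np.asarray(y, dtype=int), ridge=False)
    params = np.asarray(res.params)
    return float(params[0]), params[1:]


@dataclass
class StackResult:
    scores: pd.Series          # held-out stacked score per patient, percent
    variant: str
    fold_models: list          # one fitted logistic per fold
    fold_assignments: np.ndarray

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy()
        if np.any((vals < 0) | (vals > 100)):
            raise InputError("stacked scores must lie in [0, 100]")


def stack_logistic(evmap_scores, records: pd.DataFrame, variant: str = "ev_fingerprint",
                   scheme: CVScheme | None = None,
                   risk_spec: RiskModelSpec | None = None,
                   labels=None, ridge: bool = False) -> StackResult:
    """Cross-validated logistic stack of the EVMAP score with clinical inputs.

    ``evmap_scores`` must be *held-out* ensemble scores (percent), aligned
    with ``records``.  Per fold: clinical covariates are imputed with
    training-fold medians, the clinical risk model is evaluated, a plain
    logistic regression is fit on the training patients, and the held-out
    patients are scored.  ``labels`` defaults to grade group >= 3.
    """
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown variant {variant!r}; one of {sorted(VARIANTS)}")
    scheme = scheme or CVScheme(n_folds=5, n_repeats=1, seed=2024)
    if scheme.n_repeats != 1:
        raise ConfigurationError("the stack uses a single repeat of k-fold CV")
    evmap = np.asarray(evmap_scores, dtype=float)
    if len(evmap) != len(records):
        raise InputError("evmap_scores and records must be aligned")
    y = (np.asarray(labels).astype(int) if labels is not None
         else (records["grade_group"].to_numpy() >= 3).astype(int))

    columns = VARIANTS[variant]
    clinical_cols = [c for c in columns if c not in ("evmap", "pcptrc")]
    needed = set(clinical_cols)
    if "pcptrc" in columns:
        spec = risk_spec or DEFAULT_RISK_SPEC
        needed |= {spec.transforms.get(n, (n, None))[0] for n in spec.coefficients}
    needed = sorted(needed)

    folds = make_cv_folds(y, scheme)[0]
    scores = np.full(len(records), np.nan)
    fold_models = []
    ids = list(records.index)
    for fold in range(scheme.n_folds):
        test = folds == fold
        if len(np.unique(y[~test])) < 2:
            raise InputError(f"training fold {fold} contains a single outcome class")
        train_ids = [pid for pid, t in zip(ids, test) if not t]
        imputed = impute_median(records, needed, train_ids) if needed else records

        design = pd.DataFrame(index=records.index)
        for col in columns:
            if col == "evmap":
                design[col] = evmap / 100.0  # internal math on [0, 1]
            elif col == "pcptrc":
                design[col] = clinical_risk(imputed, risk_spec) / 100.0
            else:
                design[col] = imputed[col].to_numpy(dtype=float)
        X = design.to_numpy()
        model = _fit_logit(X[~test], y[~test], ridge=ridge)
        scores[test] = _predict_logit(model, X[test]) * 100.0
        fold_models.append(model)
    return StackResult(scores=pd.Series(scores, index=records.index, name=variant),
                       variant=variant, fold_models=fold_models, fold_assignments=folds)
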