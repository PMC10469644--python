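"""Diagnostic-performance statistics.

ROC analysis with DeLong comparison of correlated AUCs, BCa bootstrap
confidence intervals, the fixed-sensitivity cutoff rule (>= 95% sensitivity,
maximum specificity), confusion metrics with exact count identities, biopsy
avoidance tables, decision-curve analysis and two-group cohort summaries
(Mann-Whitney for interval covariates, Fisher's exact for binary ones).

Conventions: model scores are on a 0-100 percent scale; "positive"
(biopsy recommended) means score >= cutoff; displayed percentages round
half-up to integers while machine-readable outputs keep full precision.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import InputError


def round_half_up(x: float) -> int:
    return int(math.floor(float(x) + 0.5))


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise InputError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise InputError("both outcome classes must be present")
    return y


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def mannwhitney_auc(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U statistic, ties counted 1/2."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(s)  # midranks
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending score values
    sens: np.ndarray
    spec: np.ndarray
    auc: float


def roc_auc(scores, labels) -> RocCurve:
    """Full ROC curve; ``auc`` is the trapezoidal integral, which equals the
    normalized Mann-Whitney U with midrank tie handling."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return RocCurve(thresholds=thr, sens=tpr, spec=1.0 - fpr,
                    auc=float(np.trapezoid(tpr, fpr)))


# ---------------------------------------------------------------------------
# DeLong comparison of correlated AUCs
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, y: np.ndarray):
    """Structural components via midranks: V10 (per positive) and V01 (per
    negative)."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    pos_r, neg_r = stats.rankdata(pos), stats.rankdata(neg)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return v10, v01


def delong_variance(scores, labels):
    """(AUC, DeLong variance) for a single ROC curve."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    v10, v01 = _placements(s, y)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    return auc, float(var)


@dataclass
class DelongResult:
    auc_a: float
    auc_b: float
    z: float
    p: float


def delong_test(scores_a, scores_b, labels) -> DelongResult:
    """Two-sided DeLong test for paired (same-patient) ROC curves."""
    y = _check_binary(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) != len(b) or len(a) != len(y):
        raise InputError("paired scores and labels must have equal length")
    va10, va01 = _placements(a, y)
    vb10, vb01 = _placements(b, y)
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    if np.array_equal(a, b):
        return DelongResult(auc_a, auc_b, 0.0, 1.0)
    m, n = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        if np.isclose(auc_a, auc_b):
            return DelongResult(auc_a, auc_b, 0.0, 1.0)
        raise InputError("zero DeLong variance with unequal AUCs")
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return DelongResult(auc_a, auc_b, float(z), float(p))


# ---------------------------------------------------------------------------
# BCa bootstrap
# ---------------------------------------------------------------------------

def bca_ci(statistic_fn, data, n_resamples: int = 100_000, level: float = 0.95,
           seed=None, strata=None):
    """Bias-corrected and accelerated bootstrap interval.

    ``data`` is an array or a tuple of aligned arrays resampled *pairwise* by
    patient; ``statistic_fn`` receives the resampled array(s).  ``strata``
    (e.g. outcome labels) restricts resampling to within-stratum draws so
    class counts are preserved.  Acceleration comes from jackknife skewness;
    a degenerate bootstrap distribution yields a zero-width interval with a
    warning.
    """
    if n_resamples < 1:
        raise InputError("n_resamples must be >= 1")
    arrays = tuple(np.asarray(a) for a in (data if isinstance(data, tuple) else (data,)))
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise InputError("all data arrays must be aligned")
    single = not isinstance(data, tuple)

    def evaluate(idx):
        parts = tuple(a[idx] for a in arrays)
        return float(statistic_fn(parts[0]) if single else statistic_fn(*parts))

    rng = np.random.default_rng(seed)
    theta_hat = evaluate(np.arange(n))

    if strata is not None:
        strata = np.asarray(strata)
        groups = [np.flatnonzero(strata == g) for g in np.unique(strata)]
    else:
        groups = [np.arange(n)]

    boot = np.empty(n_resamples)
    for b in range(n_resamples):
        idx = np.concatenate([rng.choice(g, size=len(g), replace=True) for g in groups])
        boot[b] = evaluate(idx)
    boot = boot[np.isfinite(boot)]
    if boot.size == 0:
        raise InputError("statistic undefined on every bootstrap resample")
    if np.allclose(boot, boot[0]) and np.isclose(boot[0], theta_hat):
        warnings.warn("degenerate bootstrap distribution; zero-width interval",
                      stacklevel=2)
        return theta_hat, theta_hat

    prop = np.mean(boot < theta_hat) + 0.5 * np.mean(boot == theta_hat)
    prop = min(max(prop, 1.0 / (len(boot) + 1)), len(boot) / (len(boot) + 1.0))
    z0 = stats.norm.ppf(prop)

    jack = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        jack[i] = evaluate(np.flatnonzero(mask))
        mask[i] = True
    jack = jack[np.isfinite(jack)]
    d = jack.mean() - jack
    denom = 6.0 * (np.sum(d ** 2) ** 1.5)
    accel = float(np.sum(d ** 3) / denom) if denom > 0 else 0.0

    alpha = (1.0 - level) / 2.0
    lo_hi = []
    for z_alpha in (stats.norm.ppf(alpha), stats.norm.ppf(1.0 - alpha)):
        adj = z0 + (z0 + z_alpha) / (1.0 - accel * (z0 + z_alpha))
        lo_hi.append(float(np.quantile(boot, np.clip(stats.norm.cdf(adj), 0.0, 1.0))))
    return lo_hi[0], lo_hi[1]


# ---------------------------------------------------------------------------
# Cutoff selection and confusion metrics
# ---------------------------------------------------------------------------

def select_cutoff(scores, labels, min_sensitivity: float = 0.95) -> float:
    """Highest-specificity cutoff among observed score values whose
    sensitivity is at least ``min_sensitivity``; ties prefer higher
    sensitivity, then the higher cutoff.  A cutoff at the minimum score
    (all positive) always qualifies."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    candidates = np.unique(s)
    n_pos, n_neg = y.sum(), (1 - y).sum()
    best = None  # (specificity, sensitivity, cutoff), lexicographic max
    for c in candidates:
        pred = s >= c
        sens = (pred & (y == 1)).sum() / n_pos
        if sens + 1e-12 < min_sensitivity:
            continue
        spec = (~pred & (y == 0)).sum() / n_neg
        key = (spec, sens, float(c))
        if best is None or key > best:
            best = key
    return best[2]


@dataclass
class ConfusionSummary:
    """2x2 confusion counts at a fixed cutoff plus percent-scale metrics.

    Undefined ratios (empty denominator) are reported as NaN, never as 0.
    """

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    ci: dict = field(default_factory=dict)  # metric -> (lo, hi), percent

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int,
                    cutoff: float = float("nan")) -> "ConfusionSummary":
        return cls(cutoff=cutoff, tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))

    def rounded(self) -> dict:
        """Integer-rounded (half-up) metrics, as printed in report tables."""
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            v = getattr(self, name)
            out[name] = round_half_up(v) if np.isfinite(v) else None
        return out

    def to_dict(self) -> dict:
        return {"cutoff": self.cutoff, "tp": self.tp, "fp": self.fp,
                "tn": self.tn, "fn": self.fn,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "ppv": self.ppv, "npv": self.npv,
                "ci": {k: list(v) for k, v in self.ci.items()}}


def confusion_metrics(scores, labels, cutoff: float, ci: bool = False,
                      n_resamples: int = 2000, seed=None) -> ConfusionSummary:
    """Confusion summary at ``cutoff`` (positive = score >= cutoff), with
    optional BCa CIs from stratified patient resampling."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    pred = s >= cutoff
    summary = ConfusionSummary(
        cutoff=float(cutoff),
        tp=int((pred & (y == 1)).sum()), fp=int((pred & (y == 0)).sum()),
        tn=int((~pred & (y == 0)).sum()), fn=int((~pred & (y == 1)).sum()))
    if ci:
        rng_seed = np.random.SeedSequence(seed).spawn(4)
        for metric, child in zip(("sensitivity", "specificity", "ppv", "npv"), rng_seed):
            def stat(sc, yy, _m=metric):
                p = sc >= cutoff
                cs = ConfusionSummary(cutoff, int((p & (yy == 1)).sum()),
                                      int((p & (yy == 0)).sum()),
                                      int((~p & (yy == 0)).sum()),
                                      int((~p & (yy == 1)).sum()))
                return getattr(cs, _m)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                summary.ci[metric] = bca_ci(stat, (s, y), n_resamples=n_resamples,
                                            seed=child, strata=y)
    return summary


# ---------------------------------------------------------------------------
# Biopsy avoidance table
# ---------------------------------------------------------------------------

def avoidance_table(scores, grades, cutoffs) -> pd.DataFrame:
    """Biopsies performed/avoided at each cutoff, and cancers found/missed for
    each target class (grade group >= 1, 2, 3); percentages integer-rounded."""
    s = np.asarray(scores, dtype=float)
    g = np.asarray(grades).astype(int)
    n = len(s)
    rows = []
    for cutoff in cutoffs:
        pred = s >= cutoff
        performed = int(pred.sum())
        row = {"cutoff": float(cutoff),
               "performed": performed, "performed_pct": round_half_up(100 * performed / n),
               "avoided": n - performed,
               "avoided_pct": round_half_up(100 * (n - performed) / n)}
        for k in (1, 2, 3):
            in_class = g >= k
            n_class = int(in_class.sum())
            found = int((pred & in_class).sum())
            row[f"found_ge{k}"] = found
            row[f"found_ge{k}_pct"] = round_half_up(100 * found / n_class) if n_class else None
            row[f"missed_ge{k}"] = n_class - found
            row[f"missed_ge{k}_pct"] = (round_half_up(100 * (n_class - found) / n_class)
                                        if n_class else None)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Decision curve analysis
# ---------------------------------------------------------------------------

@dataclass
class DecisionCurve:
    thresholds: np.ndarray          # probability scale, (0, 1)
    net_benefit_model: np.ndarray
    net_benefit_treat_all: np.ndarray
    net_benefit_treat_none: np.ndarray
    biopsies_avoided_per_100: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "net_benefit_model": self.net_benefit_model,
            "net_benefit_treat_all": self.net_benefit_treat_all,
            "net_benefit_treat_none": self.net_benefit_treat_none,
            "biopsies_avoided_per_100": self.biopsies_avoided_per_100})


def decision_curve(scores, labels, thresholds) -> DecisionCurve:
    """Net benefit of "biopsy if score >= threshold" across threshold
    probabilities: NB(pt) = TP/n - (FP/n) pt/(1-pt), with treat-all and
    treat-none references and the biopsies-avoided-per-100 transform."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    pt = np.asarray(thresholds, dtype=float)
    if np.any(pt > 1.0):
        pt = pt / 100.0  # percent grid accepted
    pt = pt[(pt > 0.0) & (pt < 1.0)]
    n = len(y)
    prevalence = y.mean()
    nb_model = np.empty(len(pt))
    for i, t in enumerate(pt):
        pred = s >= t * 100.0  # scores are percent-scale
        tp = (pred & (y == 1)).sum() / n
        fp = (pred & (y == 0)).sum() / n
        nb_model[i] = tp - fp * t / (1.0 - t)
    odds = pt / (1.0 - pt)
    nb_all = prevalence - (1.0 - prevalence) * odds
    avoided = 100.0 * (nb_model - nb_all) * (1.0 - pt) / pt
    return DecisionCurve(thresholds=pt, net_benefit_model=nb_model,
                         net_benefit_treat_all=nb_all,
                         net_benefit_treat_none=np.zeros(len(pt)),
                         biopsies_avoided_per_100=avoided)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibration_curve(scores, labels, n_groups: int = 10) -> pd.DataFrame:
    """Quantile-grouped calibration: per group, mean predicted percent,
    observed event percent and group size.  Fewer distinct scores than groups
    merges bins with a warning."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    try:
        groups = pd.qcut(s, n_groups, labels=False, duplicates="drop")
    except ValueError:
        groups = np.zeros(len(s), dtype=int)
    if pd.isna(groups).all():  # constant scores: a single degenerate group
        groups = np.zeros(len(s), dtype=int)
    n_actual = int(pd.Series(groups).nunique())
    if n_actual < n_groups:
        warnings.warn(f"calibration: {n_actual} groups after merging ties "
                      f"(requested {n_groups})", stacklevel=2)
    df = pd.DataFrame({"score": s, "event": y, "group": groups})
    agg = df.groupby("group").agg(mean_predicted=("score", "mean"),
                                  observed_pct=("event", lambda e: 100.0 * e.mean()),
                                  n=("event", "size"))
    return agg.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cohort descriptive summary
# ---------------------------------------------------------------------------

def cohort_summary(records: pd.DataFrame, group_mask,
                   continuous=("age", "psa", "bmi"),
                   binary=("race_black", "prior_negative_biopsy", "family_history",
                           "diabetes", "dre_abnormal")) -> pd.DataFrame:
    """Two-group descriptive table: median (IQR) + Mann-Whitney p for interval
    covariates; count (%) + Fisher exact p for binary covariates."""
    mask = np.asarray(group_mask, dtype=bool)
    if mask.all() or not mask.any():
        raise InputError("grouping must split the cohort into two non-empty groups")
    g0, g1 = records.loc[~mask], records.loc[mask]
    rows = []
    for cov in continuous:
        a = g0[cov].dropna().to_numpy(dtype=float)
        b = g1[cov].dropna().to_numpy(dtype=float)
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue) \
            if len(a) and len(b) else float("nan")
        rows.append({"covariate": cov, "test": "mannwhitney",
                     "g0_median": float(np.median(a)), "g0_q1": float(np.quantile(a, 0.25)),
                     "g0_q3": float(np.quantile(a, 0.75)),
                     "g1_median": float(np.median(b)), "g1_q1": float(np.quantile(b, 0.25)),
                     "g1_q3": float(np.quantile(b, 0.75)), "p_value": p})
    for cov in binary:
        a = g0[cov].dropna().astype(int)
        b = g1[cov].dropna().astype(int)
        table = [[int((a == 1).sum()), int((a == 0).sum())],
                 [int((b == 1).sum()), int((b == 0).sum())]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        rows.append({"covariate": cov, "test": "fisher",
                     "g0_count": table[0][0],
                     "g0_pct": 100.0 * table[0][0] / max(len(a), 1),
                     "g1_count": table[1][0],
                     "g1_pct": 100.0 * table[1][0] / max(len(b), 1),
                     "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

def save_table(df: pd.DataFrame, path_base) -> None:
    """Write a report table as both CSV and JSON (records orientation)."""
    path_base = str(path_base)
    df.to_csv(path_base + ".csv", index=False)
    df.to_json(path_base + ".json", orient="records", indent=1)


def save_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=float)
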