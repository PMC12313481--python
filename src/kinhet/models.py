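"""LASSO-logistic Radscore models and their evaluation.

The modeling stage mirrors a standard radiomics signature workflow for a
binary outcome (e.g. Luminal vs rest, HER2-enriched vs rest, HER2
positive vs negative):

1. a stratified 7:3 train/test split of the cohort;
2. feature screening on the training rows only (zero-variance removal
   plus an optional two-sided Mann-Whitney filter at p < 0.05);
3. L1-penalized logistic regression with the penalty lambda chosen at
   the minimum mean binomial deviance over 10 cross-validation folds,
   refit on the full training set at that lambda;
4. the Radscore ``intercept + sum_j beta_j x_ij`` on standardized
   features, evaluated by ROC analysis (rank-statistic AUC with an
   asymptotic confidence interval, Youden-index operating point) and
   decision-curve analysis on the logistic-calibrated probabilities.

Screening, standardization and lambda selection see training rows only;
the fitted transform is stored on the model and applied unchanged to
test data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import InvalidParameterError, ModelError, ScreeningError

__all__ = [
    "SplitSpec",
    "split_cohort",
    "ScreenResult",
    "screen_features",
    "RadscoreModel",
    "fit_lasso_cv",
    "compute_radscore",
    "radscore_probability",
    "RocSummary",
    "evaluate_roc",
    "univariate_roc",
    "decision_curve",
    "run_subtype_task",
    "TaskResult",
]


# ------------------------------------------------------------- splitting


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split specification (default 7:3, stratified)."""

    train_fraction: float = 0.7
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise InvalidParameterError("train_fraction must be in (0, 1)")


def split_cohort(labels, spec: SplitSpec = SplitSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint train/test index split.

    The training size is ``round(n * train_fraction)`` (124 patients at
    0.7 give 87/37); stratification keeps class fractions within one
    patient of the cohort's.
    """
    y = np.asarray(labels, dtype=int)
    n = len(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ModelError("each class needs at least 2 patients to split")
    n_train = int(round(n * spec.train_fraction))
    idx = np.arange(n)
    train, test = train_test_split(
        idx,
        train_size=n_train,
        random_state=spec.seed,
        stratify=y if spec.stratified else None,
        shuffle=True,
    )
    return np.sort(train), np.sort(test)


# ------------------------------------------------------------- screening


@dataclass
class ScreenResult:
    """Screened feature table plus a record of every removal."""

    table: pd.DataFrame
    removed: dict[str, str] = field(default_factory=dict)

    @property
    def kept(self) -> list[str]:
        return list(self.table.columns)


def screen_features(
    train_table: pd.DataFrame,
    labels,
    rank_filter: bool = True,
    alpha: float = 0.05,
) -> ScreenResult:
    """Pre-selection screening on training rows only.

    Always removes zero-variance columns; when ``rank_filter`` is on,
    additionally removes columns whose two-sided Mann-Whitney U test
    between outcome groups has p >= ``alpha``.  Every removal is
    recorded with its reason.
    """
    y = np.asarray(labels, dtype=int)
    if len(y) != len(train_table):
        raise InvalidParameterError("labels length must match table rows")
    removed: dict[str, str] = {}
    x = train_table.to_numpy(dtype=np.float64)
    keep = []
    for j, name in enumerate(train_table.columns):
        col = x[:, j]
        if np.ptp(col) == 0:
            removed[name] = "zero variance"
            continue
        if rank_filter:
            p = stats.mannwhitneyu(col[y == 0], col[y == 1], alternative="two-sided")[1]
            if p >= alpha:
                removed[name] = f"rank test p={p:.3g} >= {alpha}"
                continue
        keep.append(name)
    if not keep:
        raise ScreeningError("screening removed every feature")
    return ScreenResult(train_table[keep], removed)


# ---------------------------------------------------------------- LASSO


@dataclass
class RadscoreModel:
    """A fitted LASSO-logistic Radscore.

    Coefficients are on standardized features (training mean/SD stored
    in ``feature_means``/``feature_sds``); ``selected`` lists the
    features with non-zero coefficients at the chosen lambda.
    """

    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    lambda_: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    cv_deviance: pd.DataFrame  # columns: lambda, mean_deviance
    screening: dict[str, str] = field(default_factory=dict)

    @property
    def selected(self) -> list[str]:
        return [n for n, b in zip(self.feature_names, self.coefficients) if b != 0]

    def to_dict(self) -> dict:
        return {
            "selected_features": self.selected,
            "coefficients": {
                n: float(b)
                for n, b in zip(self.feature_names, self.coefficients)
                if b != 0
            },
            "intercept": float(self.intercept),
            "lambda": float(self.lambda_),
            "n_screened_out": len(self.screening),
        }


def _deviance(y: np.ndarray, prob: np.ndarray) -> float:
    eps = 1e-12
    prob = np.clip(prob, eps, 1 - eps)
    return float(-2 * np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


def fit_lasso_cv(
    train_table: pd.DataFrame,
    labels,
    n_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 30,
    screening: dict[str, str] | None = None,
) -> RadscoreModel:
    """L1-logistic fit with lambda at minimum 10-fold CV binomial deviance.

    Features are standardized to zero mean / unit variance on the
    training set (the transform is stored for test-time application).
    The lambda grid spans from the smallest penalty that zeroes every
    coefficient down three decades; the model is refit on the full
    training set at the winning lambda.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ModelError("cannot fit a classifier on single-class labels")
    names = list(train_table.columns)
    # contiguous copy: the fit must depend on values only, not memory layout
    x = np.ascontiguousarray(train_table.to_numpy(dtype=np.float64))
    means, sds = x.mean(axis=0), x.std(axis=0)
    sds = np.where(sds == 0, 1.0, sds)
    xs = (x - means) / sds
    n = len(y)

    # lambda_max: smallest penalty with an all-zero solution
    lam_max = np.abs(xs.T @ (y - y.mean())).max() / n
    lambdas = np.geomspace(lam_max, lam_max * 1e-3, n_lambdas)

    n_folds_eff = min(n_folds, int(np.bincount(y).min()))
    if n_folds_eff < 2:
        raise ModelError("too few samples per class for cross-validation")
    cv = StratifiedKFold(n_splits=n_folds_eff, shuffle=True, random_state=seed)
    dev = np.zeros((n_folds_eff, len(lambdas)))
    for f, (tr, va) in enumerate(cv.split(xs, y)):
        for i, lam in enumerate(lambdas):
            clf = LogisticRegression(
                l1_ratio=1.0,
                C=1.0 / (len(tr) * lam),
                solver="liblinear",
                max_iter=1000,
                random_state=seed,
            )
            clf.fit(xs[tr], y[tr])
            dev[f, i] = _deviance(y[va], clf.predict_proba(xs[va])[:, 1])
    mean_dev = dev.mean(axis=0)
    best = int(np.argmin(mean_dev))
    lam = float(lambdas[best])

    final = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear", max_iter=1000,
        random_state=seed,
    )
    final.fit(xs, y)
    return RadscoreModel(
        feature_names=names,
        coefficients=final.coef_.ravel().copy(),
        intercept=float(final.intercept_[0]),
        lambda_=lam,
        feature_means=means,
        feature_sds=sds,
        cv_deviance=pd.DataFrame({"lambda": lambdas, "mean_deviance": mean_dev}),
        screening=screening or {},
    )


def compute_radscore(model: RadscoreModel, table: pd.DataFrame) -> np.ndarray:
    """Radscore = intercept + sum of coefficient-weighted (standardized) features."""
    missing = [n for n in model.feature_names if n not in table.columns]
    if missing:
        raise ModelError(f"table is missing model features: {missing[:5]}")
    x = table[model.feature_names].to_numpy(dtype=np.float64)
    xs = (x - model.feature_means) / model.feature_sds
    return model.intercept + xs @ model.coefficients


def radscore_probability(model: RadscoreModel, table: pd.DataFrame) -> np.ndarray:
    """Logistic-calibrated probability of the Radscore (its linear predictor)."""
    return 1.0 / (1.0 + np.exp(-compute_radscore(model, table)))


# ------------------------------------------------------------------ ROC


@dataclass
class RocSummary:
    """AUC with asymptotic CI and Youden-index operating metrics."""

    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    flipped: bool = False  # univariate orientation flag
    degenerate: bool = False  # constant scores

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci95": [self.ci_low, self.ci_high],
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
        }


def _rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic (ties count one half)."""
    pos, neg = scores[y == 1], scores[y == 0]
    ranks = stats.rankdata(scores)
    n1, n0 = len(pos), len(neg)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate_roc(scores, labels) -> RocSummary:
    """ROC summary of a score vector against binary labels.

    The AUC is the probability that a random positive outscores a random
    negative (ties one half); the 95% CI uses the Hanley-McNeil
    asymptotic variance.  The cutoff maximizes the Youden index
    ``sensitivity + specificity - 1`` (positives called at
    ``score >= cutoff``); sensitivity, specificity, PPV, NPV and
    accuracy are reported at that cutoff.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ModelError("ROC needs both classes present")
    degenerate = np.ptp(scores) == 0

    auc = _rank_auc(scores, y)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (
        n1 * n0
    )
    se = float(np.sqrt(max(var, 0.0)))
    ci_low, ci_high = max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se)

    best_cut, best_j = None, -np.inf
    for cut in np.unique(scores):
        pred = scores >= cut
        sens = (pred & (y == 1)).sum() / n1
        spec = (~pred & (y == 0)).sum() / n0
        j = sens + spec - 1
        if j > best_j:
            best_j, best_cut = j, float(cut)
    pred = scores >= best_cut
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    tn = int((~pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    return RocSummary(
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        cutoff=best_cut,
        sensitivity=tp / n1,
        specificity=tn / n0,
        ppv=tp / (tp + fp) if tp + fp else float("nan"),
        npv=tn / (tn + fn) if tn + fn else float("nan"),
        accuracy=(tp + tn) / len(y),
        degenerate=degenerate,
    )


def univariate_roc(values, labels) -> RocSummary:
    """ROC of a single kinetic parameter, auto-oriented so AUC >= 0.5.

    If the raw parameter discriminates in the negative direction its
    sign is flipped before evaluation and the summary is flagged.
    """
    values = np.asarray(values, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ModelError("ROC needs both classes present")
    flipped = _rank_auc(values, y) < 0.5
    summary = evaluate_roc(-values if flipped else values, y)
    summary.flipped = flipped
    return summary


# ------------------------------------------------------------------ DCA


def decision_curve(
    probabilities,
    labels,
    thresholds=None,
) -> pd.DataFrame:
    """Decision-curve analysis: net benefit across threshold probabilities.

    Net benefit at threshold p_t is ``TP/n - FP/n * p_t / (1 - p_t)``
    with positives called at ``probability >= p_t``.  The treat-all and
    treat-none reference strategies are included
    (treat-none is identically 0; treat-all equals
    ``prevalence - (1 - prevalence) * p_t / (1 - p_t)``).
    """
    prob = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if ((prob <= 0) | (prob >= 1)).any():
        raise InvalidParameterError("probabilities must lie strictly in (0, 1)")
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    pt = np.asarray(thresholds, dtype=np.float64)
    if ((pt <= 0) | (pt >= 1)).any():
        raise InvalidParameterError("threshold grid must lie strictly in (0, 1)")
    n = len(y)
    prevalence = y.mean()
    odds = pt / (1 - pt)
    tp = (prob[None, :] >= pt[:, None]) & (y == 1)[None, :]
    fp = (prob[None, :] >= pt[:, None]) & (y == 0)[None, :]
    nb = tp.sum(axis=1) / n - fp.sum(axis=1) / n * odds
    return pd.DataFrame(
        {
            "threshold": pt,
            "net_benefit": nb,
            "treat_all": prevalence - (1 - prevalence) * odds,
            "treat_none": np.zeros_like(pt),
        }
    )


# ------------------------------------------------------------- pipeline


@dataclass
class TaskResult:
    """End-to-end result of one binary subtype task."""

    model: RadscoreModel
    train_roc: RocSummary
    test_roc: RocSummary
    train_dca: pd.DataFrame
    test_dca: pd.DataFrame
    train_idx: np.ndarray
    test_idx: np.ndarray


def run_subtype_task(
    table: pd.DataFrame,
    labels,
    split: SplitSpec = SplitSpec(),
    rank_filter: bool = True,
    n_folds: int = 10,
    seed: int | None = None,
) -> TaskResult:
    """Split, screen, fit and evaluate one Radscore model end to end."""
    y = np.asarray(labels, dtype=int)
    seed = split.seed if seed is None else seed
    train_idx, test_idx = split_cohort(y, split)
    screened = screen_features(table.iloc[train_idx], y[train_idx], rank_filter)
    model = fit_lasso_cv(
        screened.table, y[train_idx], n_folds=n_folds, seed=seed,
        screening=screened.removed,
    )
    cols = screened.kept
    tr_scores = compute_radscore(model, table.iloc[train_idx][cols])
    te_scores = compute_radscore(model, table.iloc[test_idx][cols])
    tr_prob = 1 / (1 + np.exp(-tr_scores))
    te_prob = 1 / (1 + np.exp(-te_scores))
    return TaskResult(
        model=model,
        train_roc=evaluate_roc(tr_scores, y[train_idx]),
        test_roc=evaluate_roc(te_scores, y[test_idx]),
        train_dca=decision_curve(tr_prob, y[train_idx]),
        test_dca=decision_curve(te_prob, y[test_idx]),
        train_idx=train_idx,
        test_idx=test_idx,
    )
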