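"""Predictive modelling of major arrhythmic events.

Model families: unpenalized logistic regression (with a literal
linear-probability option), linear-kernel SVM, RBF-kernel SVM, and a small
feed-forward neural network.  The evaluation protocol is a stratified 80:20
train/test split with 3-fold cross-validation inside the training set;
metrics are AUC (train and test), accuracy, precision, sensitivity and
specificity at a 0.5 probability threshold.  Model search enumerates
variable subsets of a univariately pre-ranked candidate pool, ranks by mean
cross-validated AUC then accuracy, and reports the top models with their
coefficients (linear families) or mean-|Shapley| attributions (nonlinear
families).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, KFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .shapley import mean_abs_attribution, shap_attribution

__all__ = [
    "FAMILIES",
    "LINEAR_FAMILIES",
    "SplitPlan",
    "Split",
    "FittedModel",
    "ModelReport",
    "SearchResult",
    "make_split",
    "fit_model",
    "evaluate",
    "report_model",
    "search_models",
    "logistic_inference",
]

FAMILIES = ("logistic", "linear-probability", "linear-svm", "rbf-svm", "ann")
LINEAR_FAMILIES = ("logistic", "linear-probability", "linear-svm")

#: standardized-scale coefficient magnitude beyond which a logistic fit is
#: treated as (quasi-)separated and refitted with an L2 bound
SEPARATION_BOUND = 50.0


@dataclass(frozen=True)
class SplitPlan:
    train_fraction: float = 0.8
    n_folds: int = 3
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")


@dataclass
class Split:
    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]  # positional (fit, validate) pairs


def make_split(cohort: pd.DataFrame, plan: SplitPlan, outcome: str = "MAE") -> Split:
    """Stratified, reproducible train/test split with CV folds inside training."""
    if len(cohort) < 10:
        raise ValueError("need at least 10 patients to split")
    y = cohort[outcome].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    idx = np.arange(len(cohort))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=plan.train_fraction,
        stratify=y if plan.stratified else None,
        random_state=plan.seed,
    )
    cv = (StratifiedKFold if plan.stratified else KFold)(
        n_splits=plan.n_folds, shuffle=True, random_state=plan.seed
    )
    folds = [
        (train_idx[fit], train_idx[val])
        for fit, val in cv.split(train_idx, y[train_idx])
    ]
    return Split(train_idx=np.sort(train_idx), test_idx=np.sort(test_idx), folds=folds)


class FittedModel:
    """A fitted classifier with a uniform probability interface.

    ``coefficients`` (including ``"Intercept"``) are populated for the linear
    families on the original variable scale; nonlinear families attribute via
    Shapley values instead.
    """

    def __init__(self, family: str, variables: list[str], predictor, coefficients=None,
                 bse=None, separation_fallback: bool = False):
        self.family = family
        self.variables = variables
        self._predictor = predictor
        self.coefficients: dict[str, float] | None = coefficients
        self.bse: dict[str, float] | None = bse
        self.separation_fallback = separation_fallback

    def _matrix(self, data) -> np.ndarray:
        if isinstance(data, pd.DataFrame):
            return data[self.variables].to_numpy(dtype=float)
        return np.atleast_2d(np.asarray(data, dtype=float))

    def predict_proba(self, data) -> np.ndarray:
        """P(outcome = 1) for each row."""
        return self._predictor(self._matrix(data))

    def predict(self, data, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(data) >= threshold).astype(int)


def _unscale_coefficients(
    names: Sequence[str], coef_std: np.ndarray, intercept_std: float,
    mean: np.ndarray, scale: np.ndarray,
) -> dict[str, float]:
    coef = coef_std / scale
    intercept = intercept_std - float(np.sum(coef_std * mean / scale))
    out = {"Intercept": float(intercept)}
    out.update({n: float(c) for n, c in zip(names, coef)})
    return out


def _fit_logistic(X: np.ndarray, y: np.ndarray, variables: list[str], seed: int):
    """Unpenalized ML logistic fit with a bounded-coefficient fallback.

    Quasi-separated data produce runaway coefficients under maximum
    likelihood; when detected (non-convergence, numerical failure, or
    standardized coefficients beyond the bound) the model is refitted with an
    L2 penalty and flagged.
    """
    mean, scale = X.mean(axis=0), X.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    Xs = (X - mean) / scale
    Xc = sm.add_constant(Xs, has_constant="add")
    params = None
    bse = None
    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and np.all(
                np.abs(res.params[1:]) <= SEPARATION_BOUND
            ):
                params = np.asarray(res.params)
                bse = np.asarray(res.bse)
        except Exception:  # perfect separation, singular Hessian, overflow
            params = None
    if params is None:
        fallback = True
        warnings.warn(
            "logistic fit is (quasi-)separated or failed to converge; "
            "refitting with a bounded-coefficient (L2) fallback",
            stacklevel=3,
        )
        clf = LogisticRegression(C=1.0, max_iter=2000, random_state=seed)
        clf.fit(Xs, y)
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    coefficients = _unscale_coefficients(variables, params[1:], params[0], mean, scale)
    bse_dict = None
    if bse is not None:
        bse_dict = {"Intercept": float(bse[0])}
        bse_dict.update({n: float(b / s) for n, b, s in zip(variables, bse[1:], scale)})
    beta0 = coefficients["Intercept"]
    beta = np.array([coefficients[n] for n in variables])

    def predictor(M: np.ndarray) -> np.ndarray:
        return expit(beta0 + M @ beta)

    return predictor, coefficients, bse_dict, fallback


def fit_model(
    family: str,
    variables: Sequence[str],
    train: pd.DataFrame,
    outcome: str = "MAE",
    seed: int = 0,
    hidden_units: int = 16,
) -> FittedModel:
    """Fit one model family on the training rows; deterministic under seed."""
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}; expected one of {FAMILIES}")
    variables = list(variables)
    missing = [v for v in variables if v not in train.columns]
    if missing:
        raise ValueError(f"variable(s) not in data: {', '.join(missing)}")
    X = train[variables].to_numpy(dtype=float)
    y = train[outcome].to_numpy(dtype=int)
    if np.isnan(X).any():
        raise ValueError("training data contain missing values; impute first")

    if family == "logistic" or (family == "ann" and hidden_units == 0):
        predictor, coefficients, bse, fallback = _fit_logistic(X, y, variables, seed)
        return FittedModel(family, variables, predictor, coefficients, bse, fallback)

    if family == "linear-probability":
        reg = LinearRegression().fit(X, y)
        coefficients = {"Intercept": float(reg.intercept_)}
        coefficients.update({n: float(c) for n, c in zip(variables, reg.coef_)})

        def predictor(M: np.ndarray) -> np.ndarray:
            return np.clip(reg.predict(M), 0.0, 1.0)

        return FittedModel(family, variables, predictor, coefficients)

    if family in ("linear-svm", "rbf-svm"):
        kernel = "linear" if family == "linear-svm" else "rbf"
        pipe = Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(kernel=kernel, probability=True, random_state=seed)),
        ])
        pipe.fit(X, y)
        coefficients = None
        if family == "linear-svm":
            svc: SVC = pipe.named_steps["svc"]
            scaler: StandardScaler = pipe.named_steps["scale"]
            coefficients = _unscale_coefficients(
                variables, svc.coef_.ravel(), float(svc.intercept_[0]),
                scaler.mean_, scaler.scale_,
            )
        return FittedModel(family, variables, lambda M: pipe.predict_proba(M)[:, 1], coefficients)

    # family == "ann"
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("mlp", MLPClassifier(
            hidden_layer_sizes=(hidden_units,),
            random_state=seed,
            max_iter=2000,
            early_stopping=True,
            n_iter_no_change=25,
        )),
    ])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pipe.fit(X, y)
    return FittedModel(family, variables, lambda M: pipe.predict_proba(M)[:, 1])


def evaluate(
    model: FittedModel,
    data: pd.DataFrame,
    outcome: str = "MAE",
    threshold: float = 0.5,
) -> dict[str, float]:
    """Threshold metrics at probability 0.5 plus rank-statistic AUC.

    A single-class evaluation set makes AUC undefined (returned as NaN), as
    is precision when no positive predictions are made.
    """
    y = data[outcome].to_numpy(dtype=int)
    p = model.predict_proba(data)
    yhat = (p >= threshold).astype(int)
    tp = int(((yhat == 1) & (y == 1)).sum())
    tn = int(((yhat == 0) & (y == 0)).sum())
    fp = int(((yhat == 1) & (y == 0)).sum())
    fn = int(((yhat == 0) & (y == 1)).sum())
    auc = float(roc_auc_score(y, p)) if len(np.unique(y)) == 2 else float("nan")
    return {
        "auc": auc,
        "accuracy": (tp + tn) / len(y),
        "precision": tp / (tp + fp) if (tp + fp) else float("nan"),
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
    }


@dataclass
class ModelReport:
    """One fitted model with its variables, attributions and metrics."""

    family: str
    variables: list[str]
    metrics: dict[str, float]
    coefficients: dict[str, float] | None = None
    shap: dict[str, float] | None = None
    cv_auc: float | None = None
    cv_accuracy: float | None = None

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "variables": list(self.variables),
            "metrics": dict(self.metrics),
            "coefficients": self.coefficients,
            "shap": self.shap,
            "cv_auc": self.cv_auc,
            "cv_accuracy": self.cv_accuracy,
        }


def report_model(
    model: FittedModel,
    train: pd.DataFrame,
    test: pd.DataFrame,
    outcome: str = "MAE",
    shap_background: pd.DataFrame | None = None,
    shap_instances: pd.DataFrame | None = None,
    shap_samples: int = 100,
    seed: int = 0,
) -> ModelReport:
    """Evaluate on train/test and attach coefficients or Shapley importance."""
    m_train = evaluate(model, train, outcome)
    m_test = evaluate(model, test, outcome)
    metrics = {
        "auc_train": m_train["auc"],
        "auc_test": m_test["auc"],
        "accuracy": m_test["accuracy"],
        "precision": m_test["precision"],
        "sensitivity": m_test["sensitivity"],
        "specificity": m_test["specificity"],
    }
    shap_importance = None
    if model.coefficients is None:
        background = shap_background if shap_background is not None else train
        instances = shap_instances if shap_instances is not None else test
        attr = shap_attribution(
            model, background, instances, n_samples=shap_samples, seed=seed
        )
        shap_importance = {k: float(v) for k, v in mean_abs_attribution(attr).items()}
    return ModelReport(
        family=model.family,
        variables=list(model.variables),
        metrics=metrics,
        coefficients=model.coefficients,
        shap=shap_importance,
    )


@dataclass
class SearchResult:
    reports: list[ModelReport]
    frequency: pd.Series          # variable -> occurrences among top models
    pool: list[str]

    def frequency_table(self) -> pd.DataFrame:
        rows = []
        for var in self.frequency.index:
            rows.append(
                {"variable": var}
                | {
                    f"model_{i + 1}": ("X" if var in rep.variables else "")
                    for i, rep in enumerate(self.reports)
                }
                | {"frequency": int(self.frequency[var])}
            )
        return pd.DataFrame(rows)


def _univariate_auc(x: np.ndarray, y: np.ndarray) -> float:
    if len(np.unique(y)) < 2 or np.all(x == x[0]):
        return 0.5
    a = roc_auc_score(y, x)
    return float(max(a, 1.0 - a))


def search_models(
    cohort: pd.DataFrame,
    family: str,
    split: Split,
    outcome: str = "MAE",
    max_vars: int = 8,
    top_k: int = 6,
    pool_size: int = 20,
    candidates: Sequence[str] | None = None,
    seed: int = 0,
    shap_samples: int = 100,
    max_subsets: int = 200_000,
    hidden_units: int = 16,
) -> SearchResult:
    """Exhaustive subset search over a univariately pre-ranked candidate pool.

    Subsets of size 1..max_vars are scored by mean cross-validated AUC (then
    accuracy, then fewer variables) on the training folds; the top models are
    refitted on the full training set and reported with test metrics, a
    frequency-of-occurrence table across the selected models mirroring the
    published model tables, and Shapley importances for nonlinear families.
    """
    if candidates is None:
        candidates = [
            c for c in cohort.columns
            if c != outcome and pd.api.types.is_numeric_dtype(cohort[c])
        ]
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate variables to search")

    train = cohort.iloc[split.train_idx]
    test = cohort.iloc[split.test_idx]
    y_tr = train[outcome].to_numpy(dtype=int)
    ranking = sorted(
        candidates,
        key=lambda c: (-_univariate_auc(train[c].to_numpy(dtype=float), y_tr), c),
    )
    pool = ranking[: min(pool_size, len(ranking))]

    max_vars = min(max_vars, len(pool))
    n_subsets = sum(comb(len(pool), k) for k in range(1, max_vars + 1))
    if n_subsets > max_subsets:
        raise ValueError(
            f"{n_subsets} candidate subsets exceed max_subsets={max_subsets}; "
            "reduce pool_size or max_vars"
        )

    scored: list[tuple[float, float, int, tuple[str, ...]]] = []
    for k in range(1, max_vars + 1):
        for subset in combinations(pool, k):
            aucs, accs = [], []
            for fit_rows, val_rows in split.folds:
                model = fit_model(
                    family, subset, cohort.iloc[fit_rows], outcome,
                    seed=seed, hidden_units=hidden_units,
                )
                m = evaluate(model, cohort.iloc[val_rows], outcome)
                aucs.append(m["auc"])
                accs.append(m["accuracy"])
            scored.append((float(np.nanmean(aucs)), float(np.mean(accs)), len(subset), subset))
    scored.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))

    rng = np.random.default_rng(seed)
    bg_rows = rng.choice(len(train), size=min(50, len(train)), replace=False)
    inst_rows = rng.choice(len(test), size=min(25, len(test)), replace=False)
    reports = []
    for cv_auc, cv_acc, _, subset in scored[:top_k]:
        model = fit_model(family, subset, train, outcome, seed=seed, hidden_units=hidden_units)
        rep = report_model(
            model, train, test, outcome,
            shap_background=train.iloc[bg_rows],
            shap_instances=test.iloc[inst_rows],
            shap_samples=shap_samples,
            seed=seed,
        )
        rep.cv_auc, rep.cv_accuracy = cv_auc, cv_acc
        reports.append(rep)

    counts: dict[str, int] = {}
    for rep in reports:
        for v in rep.variables:
            counts[v] = counts.get(v, 0) + 1
    frequency = pd.Series(counts, dtype=int).sort_values(ascending=False)
    return SearchResult(reports=reports, frequency=frequency, pool=pool)


def logistic_inference(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    outcome: str = "MAE",
) -> tuple[pd.Series, pd.Series]:
    """Maximum-likelihood logistic fit on the raw variable scale.

    Returns (coefficients, standard errors), each indexed by ``Intercept``
    followed by the variable names — the interface used for generative
    coefficient-recovery experiments.
    """
    X = sm.add_constant(cohort[list(variables)].to_numpy(dtype=float), has_constant="add")
    y = cohort[outcome].to_numpy(dtype=int)
    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    index = ["Intercept", *variables]
    return (
        pd.Series(np.asarray(res.params), index=index),
        pd.Series(np.asarray(res.bse), index=index),
    )
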