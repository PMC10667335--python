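"""Classifier training and the repeated-split AUC evaluation protocol.

Two statistical classifier tracks are evaluated on any feature matrix:

* a logistic regression whose terms are chosen by bidirectional stepwise
  search minimizing the Akaike information criterion (AIC), and
* a Breiman random forest (1000 trees, 6 candidate variables per split,
  terminal nodes of at least 5) with mean-decrease-Gini importances.

The protocol splits the cohort into stratified 70% training / 30% testing
parts, runs 3-fold cross-validation inside the training part as a model
assessment loop, fits the final model on the full training part and scores
the untouched test part with the area under the ROC curve.  The split is
repeated 100 times with seeds derived from one master seed; the per-split
AUCs, their mean and the averaged importances form the result.

The evaluation core follows the estimator/results idiom:
``RepeatedSplitEvaluation(X, y).fit()`` returns an :class:`EvalResult`
with a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split

from .exceptions import PdVoiceError, ProtocolError

RF_N_TREES = 1000
RF_MTRY = 6
RF_MIN_NODE = 5


@dataclass(frozen=True)
class EvalProtocol:
    """Repeated-split evaluation settings (100 x stratified 70/30 + 3-fold CV)."""

    n_iterations: int = 100
    train_fraction: float = 0.70
    cv_folds: int = 3
    rng_seed: int = 0
    stratified: bool = True
    #: run the 3-fold CV model-assessment loop inside each training part;
    #: switching it off only skips the cv_auc diagnostic, never the test AUC
    inner_cv: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class EvalResult:
    """Per-iteration AUCs and diagnostics for one classifier/feature pairing."""

    auc_per_iteration: np.ndarray
    cv_auc_per_iteration: np.ndarray
    feature_importances: Optional[np.ndarray] = None
    selected_features: Optional[List[List[str]]] = None
    feature_names: Optional[List[str]] = None
    model_name: str = ""

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_per_iteration))

    @property
    def std_auc(self) -> float:
        return float(np.std(self.auc_per_iteration, ddof=1)) if len(self.auc_per_iteration) > 1 else 0.0

    def summary(self) -> pd.DataFrame:
        """One-row AUC summary plus (for RF) ranked Gini importances."""
        rows = [
            {
                "model": self.model_name,
                "iterations": len(self.auc_per_iteration),
                "mean_auc": round(self.mean_auc, 4),
                "sd_auc": round(self.std_auc, 4),
                "mean_cv_auc": round(float(np.mean(self.cv_auc_per_iteration)), 4),
            }
        ]
        return pd.DataFrame(rows)

    def importance_table(self) -> Optional[pd.DataFrame]:
        if self.feature_importances is None:
            return None
        names = self.feature_names or [f"x{i}" for i in range(len(self.feature_importances))]
        table = pd.DataFrame(
            {"feature": names, "mean_decrease_gini": self.feature_importances}
        )
        return table.sort_values("mean_decrease_gini", ascending=False).reset_index(drop=True)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve, Mann-Whitney formulation with half-credit ties.

    Equals the probability that a random positive scores above a random
    negative, counting ties as 1/2; identical to trapezoidal ROC integration.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ProtocolError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class LogisticAicModel:
    """Stepwise-AIC logistic scorer (statsmodels backend)."""

    selected: List[str]
    params: np.ndarray
    aic: float
    feature_names: List[str]
    regularized_fallback: bool = False
    _sk_model: object = field(default=None, repr=False)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._sk_model is not None:
            cols = [self.feature_names.index(s) for s in self.selected]
            return self._sk_model.predict_proba(X[:, cols])[:, 1]
        cols = [self.feature_names.index(s) for s in self.selected]
        design = np.column_stack([np.ones(X.shape[0])] + [X[:, c] for c in cols])
        return 1.0 / (1.0 + np.exp(-design @ self.params))


def _fit_logit(y: np.ndarray, design: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, design)
        return model.fit(disp=0, method="bfgs", maxiter=200)


def train_logistic_aic(
    features: np.ndarray,
    labels: Sequence[int],
    feature_names: Optional[Sequence[str]] = None,
    max_steps: int = 60,
) -> LogisticAicModel:
    """Bidirectional stepwise selection minimizing AIC over logistic fits.

    Starts from the intercept-only model; at every step the single addition
    or removal that lowers AIC most is applied, until no move improves it.
    If the chosen model shows signs of complete separation (exploding
    coefficients), a ridge-penalized logistic fit over the same terms is
    returned instead, with a warning.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2:
        raise ProtocolError("features must be a 2-D matrix")
    classes = np.unique(y)
    if classes.size != 2:
        raise ProtocolError("logistic training needs exactly two classes")
    if min((y == c).sum() for c in classes) < 2:
        raise ProtocolError("need >= 2 samples per class")
    if np.isnan(X).any():
        raise ProtocolError("missing values in feature matrix")
    names = list(feature_names) if feature_names is not None else [f"x{i}" for i in range(X.shape[1])]

    def fit_subset(subset: List[str]):
        cols = [names.index(s) for s in subset]
        design = np.column_stack([np.ones(X.shape[0])] + [X[:, c] for c in cols])
        return _fit_logit(y, design)

    selected: List[str] = []
    current = fit_subset(selected)
    current_aic = current.aic
    for _ in range(max_steps):
        best_move = None
        best_aic = current_aic
        for name in names:
            trial = selected + [name] if name not in selected else [s for s in selected if s != name]
            try:
                res = fit_subset(trial)
            except Exception:
                continue
            if np.isfinite(res.aic) and res.aic < best_aic - 1e-9:
                best_aic = res.aic
                best_move = (trial, res)
        if best_move is None:
            break
        selected, current = best_move
        current_aic = current.aic

    model = LogisticAicModel(
        selected=selected,
        params=np.asarray(current.params, dtype=float),
        aic=float(current_aic),
        feature_names=names,
    )
    if selected and np.max(np.abs(current.params)) > 50.0:
        warnings.warn(
            "apparent complete separation in logistic fit; "
            "falling back to a ridge-penalized fit over the selected terms",
            stacklevel=2,
        )
        cols = [names.index(s) for s in selected]
        ridge = LogisticRegression(C=1.0, max_iter=1000)
        ridge.fit(X[:, cols], y)
        model.regularized_fallback = True
        model._sk_model = ridge
    return model


def train_random_forest(
    features: np.ndarray,
    labels: Sequence[int],
    n_trees: int = RF_N_TREES,
    m_try: int = RF_MTRY,
    min_node: int = RF_MIN_NODE,
    rng_seed: int = 0,
) -> RandomForestClassifier:
    """Breiman random forest with the study's hyperparameters.

    ``m_try`` (variables sampled per split) is capped by the feature count;
    requesting more is a parameter error.  Mean-decrease-Gini importances
    are available as ``feature_importances_`` after fitting.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if m_try > X.shape[1]:
        raise ProtocolError(
            f"m_try={m_try} exceeds the {X.shape[1]} available features"
        )
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=m_try,
        min_samples_leaf=min_node,
        criterion="gini",
        random_state=rng_seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


class RepeatedSplitEvaluation:
    """Repeated stratified-split evaluation of one classifier track.

    Parameters
    ----------
    features : (n, p) array
    labels : (n,) array of {0, 1}
    model : {'rf', 'lr'} or callable
        A callable receives ``(X_train, y_train, seed)`` and must return a
        scorer with ``predict_proba(X) -> P(class 1)`` (1-D or sklearn-style
        2-D output accepted).
    protocol : EvalProtocol
    feature_names : optional sequence of column names
    """

    MAX_REDRAWS = 20

    def __init__(
        self,
        features: np.ndarray,
        labels: Sequence[int],
        model: "str | Callable" = "rf",
        protocol: Optional[EvalProtocol] = None,
        feature_names: Optional[Sequence[str]] = None,
        rf_kwargs: Optional[dict] = None,
    ) -> None:
        self.X = np.asarray(features, dtype=float)
        self.y = np.asarray(labels, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ProtocolError("features and labels are inconsistent")
        self.model = model
        self.protocol = protocol or EvalProtocol()
        self.feature_names = (
            list(feature_names) if feature_names is not None
            else [f"x{i}" for i in range(self.X.shape[1])]
        )
        self.rf_kwargs = rf_kwargs or {}

    def _fit_one(self, X_train, y_train, seed: int):
        if callable(self.model):
            return self.model(X_train, y_train, seed)
        if self.model == "rf":
            kwargs = dict(self.rf_kwargs)
            kwargs.setdefault("m_try", min(RF_MTRY, X_train.shape[1]))
            return train_random_forest(X_train, y_train, rng_seed=seed, **kwargs)
        if self.model == "lr":
            return train_logistic_aic(X_train, y_train, self.feature_names)
        raise ProtocolError(f"unknown model spec {self.model!r}")

    @staticmethod
    def _scores(fitted, X) -> np.ndarray:
        proba = fitted.predict_proba(X)
        proba = np.asarray(proba)
        return proba[:, 1] if proba.ndim == 2 else proba

    def _split(self, seed: int):
        strat = self.y if self.protocol.stratified else None
        for attempt in range(self.MAX_REDRAWS):
            idx_train, idx_test = train_test_split(
                np.arange(self.y.size),
                train_size=self.protocol.train_fraction,
                random_state=seed + 7919 * attempt,
                stratify=strat,
            )
            if (
                np.unique(self.y[idx_train]).size == 2
                and np.unique(self.y[idx_test]).size == 2
            ):
                return idx_train, idx_test
        raise ProtocolError("could not draw a split containing both classes")

    def fit(self) -> EvalResult:
        proto = self.protocol
        master = np.random.default_rng(proto.rng_seed)
        iter_seeds = master.integers(0, 2**31 - 1, size=proto.n_iterations)
        aucs = np.empty(proto.n_iterations)
        cv_aucs = np.empty(proto.n_iterations)
        importances = []
        selections: List[List[str]] = []
        for it, seed in enumerate(iter_seeds):
            seed = int(seed)
            idx_train, idx_test = self._split(seed)
            X_tr, y_tr = self.X[idx_train], self.y[idx_train]
            X_te, y_te = self.X[idx_test], self.y[idx_test]

            # inner 3-fold CV on the training part: model assessment only
            if proto.inner_cv:
                skf = StratifiedKFold(n_splits=proto.cv_folds, shuffle=True, random_state=seed)
                fold_aucs = []
                for tr, va in skf.split(X_tr, y_tr):
                    if np.unique(y_tr[va]).size < 2:
                        continue
                    fold_model = self._fit_one(X_tr[tr], y_tr[tr], seed + 1)
                    fold_aucs.append(auc(self._scores(fold_model, X_tr[va]), y_tr[va]))
                cv_aucs[it] = float(np.mean(fold_aucs)) if fold_aucs else np.nan
            else:
                cv_aucs[it] = np.nan

            fitted = self._fit_one(X_tr, y_tr, seed)
            aucs[it] = auc(self._scores(fitted, X_te), y_te)
            if hasattr(fitted, "feature_importances_"):
                importances.append(np.asarray(fitted.feature_importances_))
            if isinstance(fitted, LogisticAicModel):
                selections.append(list(fitted.selected))

        return EvalResult(
            auc_per_iteration=aucs,
            cv_auc_per_iteration=cv_aucs,
            feature_importances=np.mean(importances, axis=0) if importances else None,
            selected_features=selections or None,
            feature_names=self.feature_names,
            model_name=self.model if isinstance(self.model, str) else getattr(
                self.model, "__name__", "custom"
            ),
        )


def run_protocol(
    features: np.ndarray,
    labels: Sequence[int],
    model_spec: "str | Callable" = "rf",
    protocol: Optional[EvalProtocol] = None,
    feature_names: Optional[Sequence[str]] = None,
    **kwargs,
) -> EvalResult:
    """Functional wrapper around :class:`RepeatedSplitEvaluation`."""
    return RepeatedSplitEvaluation(
        features, labels, model_spec, protocol, feature_names, **kwargs
    ).fit()


def chi_square_independence(table: Sequence[Sequence[float]], correction: bool = False):
    """Pearson chi-square test of independence on a 2x2 count table.

    Continuity correction is off by default.  Returns (statistic, p_value).
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise PdVoiceError("expected a 2x2 table")
    if (arr < 0).any() or arr.sum() <= 0:
        raise PdVoiceError("counts must be non-negative with a positive total")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise PdVoiceError("zero marginal: independence test undefined")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=correction)
    return float(stat), float(p)


@dataclass(frozen=True)
class GroupTestResult:
    group_p: float
    age_p: float
    group_coef: float


def age_adjusted_group_test(
    values: Sequence[float], group: Sequence[str], age: Sequence[float]
) -> GroupTestResult:
    """Linear model ``feature ~ group + age``; Wald p for the group term.

    Used to check that a group difference (e.g. in mean F0) survives
    adjustment for the age imbalance between the groups.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    age = np.asarray(age, dtype=float)
    if values.size <= 3:
        raise PdVoiceError("need more than 3 observations")
    levels = np.unique(group)
    if levels.size != 2:
        raise PdVoiceError("need exactly two groups")
    indicator = (group == levels[1]).astype(float)
    design = np.column_stack([np.ones(values.size), indicator, age])
    if np.linalg.matrix_rank(design) < 3:
        raise PdVoiceError("collinear design: group and age are confounded")
    fit = sm.OLS(values, design).fit()
    return GroupTestResult(
        group_p=float(fit.pvalues[1]),
        age_p=float(fit.pvalues[2]),
        group_coef=float(fit.params[1]),
    )


def pairwise_correlations(
    features: np.ndarray, subset: Optional[Sequence[int]] = None
) -> np.ndarray:
    """Pearson correlation matrix over selected columns.

    Zero-variance columns produce NaN rows/columns and a warning instead of
    silently propagating.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 3:
        raise PdVoiceError("need >= 3 rows for correlations")
    if subset is not None:
        X = X[:, list(subset)]
    sds = X.std(axis=0)
    corr = np.full((X.shape[1], X.shape[1]), np.nan)
    ok = sds > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} zero-variance column(s): correlation undefined",
            stacklevel=2,
        )
    if ok.any():
        sub = np.corrcoef(X[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = sub
    return corr
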