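"""Propensity estimation by cross-validated stacking, trimming, matching.

For each adjacent-grade pair (A,B), (B,C), (C,D) the "treatment" is
receiving the worse grade.  The propensity score P(worse grade | covariates)
is estimated by a stacked ensemble of three logistic base learners — plain
logistic regression, ridge-penalized logistic regression, and a natural
cubic-spline additive logistic model — whose convex stacking weights
minimize the k-fold cross-validated negative log-likelihood over the
simplex (exhaustive grid at 0.01 resolution, so the single-learner vertices
are always feasible and the stacked CV risk can never exceed the best
learner's).  The same machinery with a squared-error loss provides the
initial outcome regression for TMLE.

Overlap is enforced by percentile restriction (drop scores strictly above
the 99th or strictly below the 1st percentile of the pooled pair), then
each treated neighborhood is matched to its nearest-score control with
replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression, Ridge
from sklearn.model_selection import KFold
from sklearn.preprocessing import SplineTransformer

logger = logging.getLogger(__name__)

__all__ = [
    "StackedModel",
    "PropensityModel",
    "PropensityResults",
    "fit_propensity",
    "trim_by_percentile",
    "match_nearest",
    "MatchSet",
    "standardized_mean_differences",
]

_PROB_EPS = 1e-12


def _simplex_grid(k: int, step: float = 0.01) -> np.ndarray:
    """All weight vectors on the k-simplex with coordinates in step multiples."""
    n = round(1.0 / step)
    if k == 1:
        return np.array([[1.0]])
    pts = []
    if k == 3:
        for i in range(n + 1):
            for j in range(n + 1 - i):
                pts.append((i, j, n - i - j))
    elif k == 2:
        pts = [(i, n - i) for i in range(n + 1)]
    else:  # pragma: no cover - roster is fixed at 3
        raise NotImplementedError(k)
    return np.asarray(pts, dtype=float) / n


class _SplineFeatures:
    """Natural-ish cubic spline basis expansion, one block per covariate."""

    def __init__(self, n_knots: int = 4):
        self.n_knots = n_knots
        self._tr: SplineTransformer | None = None

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        self._tr = SplineTransformer(
            n_knots=self.n_knots, degree=3, include_bias=False, extrapolation="linear"
        )
        return self._tr.fit_transform(X)

    def transform(self, X: np.ndarray) -> np.ndarray:
        assert self._tr is not None
        return self._tr.transform(X)


class _BaseLearner:
    """One base learner; `task` is 'binary' or 'continuous'."""

    def __init__(self, name: str, task: str):
        self.name = name
        self.task = task
        self.spline: _SplineFeatures | None = None
        self.model = None

    def _design(self, X: np.ndarray, fit: bool) -> np.ndarray:
        if self.name != "spline":
            return X
        if fit:
            self.spline = _SplineFeatures()
            return self.spline.fit_transform(X)
        return self.spline.transform(X)

    def fit(self, X: np.ndarray, y: np.ndarray, w: np.ndarray) -> "_BaseLearner":
        Z = self._design(X, fit=True)
        if self.task == "binary":
            if self.name == "glm":
                self.model = LogisticRegression(C=np.inf, max_iter=2000)
            elif self.name == "ridge":
                self.model = LogisticRegression(C=1.0, max_iter=2000)
            else:
                self.model = LogisticRegression(C=1.0, max_iter=2000)
            # degenerate single-class folds: fall back to the constant rate
            if len(np.unique(y)) < 2:
                self._const = float(np.average(y, weights=w))
                self.model = None
                return self
            self._const = None
            self.model.fit(Z, y, sample_weight=w)
        else:
            if self.name == "glm":
                self.model = LinearRegression()
            elif self.name == "ridge":
                self.model = Ridge(alpha=1.0)
            else:
                self.model = Ridge(alpha=1.0)
            self.model.fit(Z, y, sample_weight=w)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = self._design(X, fit=False)
        if self.task == "binary":
            if self.model is None:
                return np.full(len(Z), self._const)
            return self.model.predict_proba(Z)[:, 1]
        return self.model.predict(Z)


def _loss(task: str, y: np.ndarray, pred: np.ndarray, w: np.ndarray) -> float:
    if task == "binary":
        p = np.clip(pred, _PROB_EPS, 1 - _PROB_EPS)
        return float(-np.average(y * np.log(p) + (1 - y) * np.log1p(-p), weights=w))
    return float(np.average((y - pred) ** 2, weights=w))


@dataclass
class StackedModel:
    """A fitted convex stack of base learners.

    ``weights`` lie on the simplex; ``cv_risk`` maps each learner name and
    ``"stacked"`` to its cross-validated loss.  Prediction standardizes
    covariates with the training moments and clips probabilities away from
    {0, 1}.
    """

    task: str
    learners: list[_BaseLearner]
    weights: np.ndarray
    cv_risk: dict[str, float]
    mean_: np.ndarray
    scale_: np.ndarray
    kept_cols: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, self.kept_cols]
        return (X - self.mean_) / self.scale_

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = self._standardize(X)
        preds = np.column_stack([ln.predict(Z) for ln in self.learners])
        out = preds @ self.weights
        if self.task == "binary":
            out = np.clip(out, _PROB_EPS, 1 - _PROB_EPS)
        return out


_LEARNER_NAMES = ("glm", "ridge", "spline")


def fit_stacked(
    X: np.ndarray,
    y: np.ndarray,
    task: str = "binary",
    k_folds: int = 10,
    seed: int = 0,
    sample_weight: np.ndarray | None = None,
    feature_names: list[str] | None = None,
) -> StackedModel:
    """Fit the cross-validated stack (shared by propensity and TMLE Q-step)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] == len(y) and len(y) != 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    n = len(y)
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)

    sd = X.std(axis=0)
    kept = sd > 0
    if not kept.all():
        dropped = (
            [feature_names[i] for i in np.flatnonzero(~kept)]
            if feature_names
            else list(np.flatnonzero(~kept))
        )
        logger.warning("dropping zero-variance covariates: %s", dropped)
    Xk = X[:, kept]
    mean_, scale_ = Xk.mean(axis=0), np.where(sd[kept] > 0, sd[kept], 1.0)
    Z = (Xk - mean_) / scale_

    if Z.shape[1] == 0:
        # intercept-only model: constant prediction at the weighted mean
        const = float(np.average(y, weights=w))
        model = StackedModel(task, [], np.array([1.0]), {}, mean_, scale_, kept)
        model.predict = lambda Xn, c=const: np.full(np.atleast_2d(Xn).shape[0], c)  # type: ignore
        return model

    k_folds = min(k_folds, n)
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    oof = np.zeros((n, len(_LEARNER_NAMES)))
    for tr, te in kf.split(Z):
        for j, name in enumerate(_LEARNER_NAMES):
            ln = _BaseLearner(name, task).fit(Z[tr], y[tr], w[tr])
            oof[te, j] = ln.predict(Z[te])

    grid = _simplex_grid(len(_LEARNER_NAMES))
    if task == "binary":
        P = np.clip(oof, _PROB_EPS, 1 - _PROB_EPS)
        combo = np.clip(P @ grid.T, _PROB_EPS, 1 - _PROB_EPS)
        losses = -(w[:, None] * (y[:, None] * np.log(combo) + (1 - y)[:, None] * np.log1p(-combo))).sum(0) / w.sum()
    else:
        combo = oof @ grid.T
        losses = (w[:, None] * (y[:, None] - combo) ** 2).sum(0) / w.sum()
    best = int(np.argmin(losses))
    weights = grid[best]

    cv_risk = {name: _loss(task, y, oof[:, j], w) for j, name in enumerate(_LEARNER_NAMES)}
    cv_risk["stacked"] = float(losses[best])

    learners = [_BaseLearner(name, task).fit(Z, y, w) for name in _LEARNER_NAMES]
    return StackedModel(
        task, learners, weights, cv_risk, mean_, scale_, kept,
        feature_names or [],
    )


def crossfit_stacked(
    X: np.ndarray,
    y: np.ndarray,
    task: str = "binary",
    k_folds: int = 10,
    seed: int = 0,
    sample_weight: np.ndarray | None = None,
    counterfactual_designs: tuple[np.ndarray, ...] = (),
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Cross-fitted stacked predictions for the training rows.

    Every unit's prediction comes from learners trained on the other folds,
    with stacking weights chosen on the pooled out-of-fold loss — the
    standard guard against nuisance overfitting in double-robust
    estimation.  ``counterfactual_designs`` are row-aligned alternative
    design matrices (e.g. the same units with treatment set to 0 or 1);
    their predictions are likewise produced by each unit's held-out models.

    Returns ``(pred, cf_preds)``: out-of-fold stacked predictions for X and
    one aligned array per counterfactual design.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] == len(y) and len(y) != 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    n = len(y)
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)

    sd = X.std(axis=0)
    kept = sd > 0
    Xk = X[:, kept]
    if Xk.shape[1] == 0:
        const = float(np.average(y, weights=w))
        return np.full(n, const), [np.full(n, const) for _ in counterfactual_designs]
    mean_, scale_ = Xk.mean(axis=0), sd[kept]
    Z = (Xk - mean_) / scale_
    cf_Z = [
        (np.asarray(C, dtype=float)[:, kept] - mean_) / scale_
        for C in counterfactual_designs
    ]

    k_folds = min(k_folds, n)
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    oof = np.zeros((n, len(_LEARNER_NAMES)))
    cf_oof = [np.zeros((n, len(_LEARNER_NAMES))) for _ in cf_Z]
    for tr, te in kf.split(Z):
        for j, name in enumerate(_LEARNER_NAMES):
            ln = _BaseLearner(name, task).fit(Z[tr], y[tr], w[tr])
            oof[te, j] = ln.predict(Z[te])
            for ci, Cz in enumerate(cf_Z):
                cf_oof[ci][te, j] = ln.predict(Cz[te])

    grid = _simplex_grid(len(_LEARNER_NAMES))
    if task == "binary":
        P = np.clip(oof, _PROB_EPS, 1 - _PROB_EPS)
        combo = np.clip(P @ grid.T, _PROB_EPS, 1 - _PROB_EPS)
        losses = -(w[:, None] * (y[:, None] * np.log(combo)
                                 + (1 - y)[:, None] * np.log1p(-combo))).sum(0)
    else:
        losses = (w[:, None] * (y[:, None] - oof @ grid.T) ** 2).sum(0)
    weights = grid[int(np.argmin(losses))]

    pred = oof @ weights
    if task == "binary":
        pred = np.clip(pred, _PROB_EPS, 1 - _PROB_EPS)
    cf_preds = [c @ weights for c in cf_oof]
    if task == "binary":
        cf_preds = [np.clip(c, _PROB_EPS, 1 - _PROB_EPS) for c in cf_preds]
    return pred, cf_preds


class PropensityModel:
    """Model for P(worse grade | covariates) within one adjacent-grade pair.

    Parameters
    ----------
    X : DataFrame or array, covariates (rows align with ``a``)
    a : 0/1 treatment labels, 1 = worse grade
    sample_weight : optional per-unit weights
    """

    def __init__(self, X, a, sample_weight=None):
        if isinstance(X, pd.DataFrame):
            self.feature_names = list(X.columns)
            self.X = X.to_numpy(dtype=float)
        else:
            self.X = np.atleast_2d(np.asarray(X, dtype=float))
            if self.X.shape[0] == 1 and len(a) != 1:
                self.X = self.X.T
            self.feature_names = [f"x{i}" for i in range(self.X.shape[1])]
        self.a = np.asarray(a, dtype=int)
        self.sample_weight = sample_weight
        if set(np.unique(self.a)) - {0, 1}:
            raise ValueError("treatment labels must be 0/1")

    def fit(self, k_folds: int = 10, seed: int = 0) -> "PropensityResults":
        n1, n0 = int(self.a.sum()), int((1 - self.a).sum())
        if min(n0, n1) < 20:
            raise ValueError(
                f"need >= 20 neighborhoods per arm (have {n1} treated, {n0} control)"
            )
        model = fit_stacked(
            self.X, self.a, task="binary", k_folds=k_folds, seed=seed,
            sample_weight=self.sample_weight, feature_names=self.feature_names,
        )
        return PropensityResults(self, model)


@dataclass
class PropensityResults:
    """Fitted propensity scores plus the underlying stack."""

    model: PropensityModel
    stacked: StackedModel

    @property
    def scores(self) -> np.ndarray:
        return self.stacked.predict(self.model.X)

    @property
    def weights(self) -> np.ndarray:
        return self.stacked.weights

    @property
    def cv_risk(self) -> dict[str, float]:
        return self.stacked.cv_risk

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        return self.stacked.predict(X)

    def summary(self) -> str:
        lines = ["Stacked propensity model", "-" * 34]
        for j, name in enumerate(_LEARNER_NAMES):
            lines.append(
                f"{name:>8s}: weight {self.stacked.weights[j]:.2f}  "
                f"cv risk {self.stacked.cv_risk[name]:.5f}"
            )
        lines.append(f" stacked: cv risk {self.stacked.cv_risk['stacked']:.5f}")
        return "\n".join(lines)


def fit_propensity(profiles, labels, k_folds: int = 10, seed: int = 0) -> PropensityResults:
    """Functional wrapper: fit the stacked propensity model."""
    return PropensityModel(profiles, labels).fit(k_folds=k_folds, seed=seed)


def trim_by_percentile(
    scores: np.ndarray,
    lower_pct: float = 1.0,
    upper_pct: float = 99.0,
    mode: str = "pooled",
    a: np.ndarray | None = None,
) -> np.ndarray:
    """Overlap restriction: boolean inclusion mask on the score vector.

    Percentiles use the linear-interpolation quantile definition on the
    pooled pair scores (default) or within each arm (``mode="per_arm"``);
    a unit is excluded iff its score is strictly below the lower or strictly
    above the upper percentile, so identical scores are never trimmed.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 10:
        raise ValueError("fewer than 10 units: percentiles unstable")
    if mode == "pooled":
        lo = np.percentile(scores, lower_pct, method="linear")
        hi = np.percentile(scores, upper_pct, method="linear")
        return (scores >= lo) & (scores <= hi)
    if mode == "per_arm":
        if a is None:
            raise ValueError("per_arm trimming requires treatment labels")
        a = np.asarray(a, dtype=int)
        mask = np.ones(len(scores), dtype=bool)
        for arm in (0, 1):
            idx = a == arm
            lo = np.percentile(scores[idx], lower_pct, method="linear")
            hi = np.percentile(scores[idx], upper_pct, method="linear")
            mask[idx] = (scores[idx] >= lo) & (scores[idx] <= hi)
        return mask
    raise ValueError(f"unknown trimming mode {mode!r}")


@dataclass
class MatchSet:
    """Nearest-neighbor matches (with replacement) for one pair design."""

    pairs: list[tuple[str, str, float]]  # (treated_id, control_id, |gap|)
    included_ids: set[str]
    control_weights: dict[str, int]  # control reuse frequencies

    @property
    def treated_ids(self) -> list[str]:
        return [t for t, _, _ in self.pairs]


def match_nearest(
    scores: "pd.Series | dict[str, float]",
    treated_ids: list[str],
    control_ids: list[str],
) -> MatchSet:
    """Match each treated unit to the nearest-score control, with replacement.

    Ties on |score gap| break to the lexicographically smallest control id.
    Controls may be reused; their reuse counts are returned as frequency
    weights.
    """
    s = pd.Series(scores, dtype=float)
    if len(control_ids) == 0:
        raise ValueError("empty control arm: nothing to match against")
    if len(treated_ids) == 0:
        raise ValueError("empty treated arm: nothing to match")
    ctrl = sorted(control_ids)  # lexicographic order → argmin breaks ties low
    c_scores = s.loc[ctrl].to_numpy()
    pairs: list[tuple[str, str, float]] = []
    weights: dict[str, int] = {}
    for t in treated_ids:
        gaps = np.abs(c_scores - s.loc[t])
        j = int(np.argmin(gaps))
        pairs.append((t, ctrl[j], float(gaps[j])))
        weights[ctrl[j]] = weights.get(ctrl[j], 0) + 1
    included = set(treated_ids) | set(weights)
    return MatchSet(pairs=pairs, included_ids=included, control_weights=weights)


def standardized_mean_differences(
    X: pd.DataFrame, a: np.ndarray, weights: np.ndarray | None = None
) -> pd.Series:
    """Absolute standardized mean difference per covariate (balance check)."""
    a = np.asarray(a, dtype=bool)
    w = np.ones(len(a)) if weights is None else np.asarray(weights, dtype=float)
    out = {}
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        m1 = np.average(x[a], weights=w[a])
        m0 = np.average(x[~a], weights=w[~a])
        v1 = np.average((x[a] - m1) ** 2, weights=w[a])
        v0 = np.average((x[~a] - m0) ** 2, weights=w[~a])
        pooled = np.sqrt((v1 + v0) / 2)
        out[col] = abs(m1 - m0) / pooled if pooled > 0 else 0.0
    return pd.Series(out)
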