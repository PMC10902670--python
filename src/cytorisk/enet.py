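"""Elastic-net logistic regression for feature selection and the risk score.

The model minimizes the penalized average negative log-likelihood

    (1/n) sum_i [log(1 + e^{eta_i}) - y_i eta_i]
        + lam * (alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2),

with eta = b0 + X b, solved by cyclic coordinate descent on the iteratively
reweighted quadratic approximation (the glmnet algorithm).  The intercept is
never penalized; features are standardized to unit sample SD internally and
coefficients are reported on both scales.  lam is chosen by cross-validated
binomial deviance over a decreasing lambda path with warm starts
(leave-one-out by default, suited to cohorts of a few dozen patients).

The predicted risk score for a patient with selected-feature values V_k is
the logistic transform of the linear predictor:

    score = e^(a + sum_k b_k V_k) / (1 + e^(a + sum_k b_k V_k)).
"""

from __future__ import annotations

import json
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from .association import auroc, bootstrap_auroc_ci, group_compare

__all__ = [
    "ElasticNetLogit",
    "fit_elastic_net",
    "predicted_score",
    "evaluate_score",
]

_WEIGHT_FLOOR = 1e-5


def _soft_threshold(u: float, g: float) -> float:
    return np.sign(u) * max(abs(u) - g, 0.0)


def _objective(X, y, b0, b, lam, alpha) -> float:
    eta = b0 + X @ b
    # log(1+e^eta) - y*eta, computed stably
    nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
    pen = lam * (alpha * np.abs(b).sum() + 0.5 * (1 - alpha) * (b**2).sum())
    return float(nll + pen)


def _cd_fit(X, y, lam, alpha, b0, b, tol=1e-10, max_iter=500,
            inner_tol=1e-12):
    """One penalized logistic fit by IRLS + cyclic coordinate descent.

    Operates on standardized X; warm-started from (b0, b).  Returns
    (b0, b, objective trace over IRLS steps)."""
    n, p = X.shape
    b = b.copy()
    trace = [_objective(X, y, b0, b, lam, alpha)]
    for _ in range(max_iter):
        b0_old, b_old = b0, b.copy()
        eta = b0 + X @ b
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), _WEIGHT_FLOOR, None)
        z = eta + (y - mu) / w
        # coordinate descent on the weighted quadratic, in Gram form
        Xw = X * w[:, None]
        A = (Xw.T @ X) / n              # p x p weighted Gram
        cz = (Xw.T @ z) / n
        hw = Xw.sum(axis=0) / n         # intercept coupling
        sw = w.sum() / n
        wz = (w * z).sum() / n
        denom = np.diag(A) + lam * (1 - alpha)
        for _ in range(200):
            delta = 0.0
            for j in range(p):
                u = cz[j] - A[j] @ b + A[j, j] * b[j] - b0 * hw[j]
                new = _soft_threshold(u, lam * alpha) / denom[j]
                if new != b[j]:
                    delta = max(delta, abs(new - b[j]))
                    b[j] = new
            b0_new = (wz - hw @ b) / sw
            delta = max(delta, abs(b0_new - b0))
            b0 = b0_new
            if delta < inner_tol:
                break
        obj = _objective(X, y, b0, b, lam, alpha)
        # step-halving keeps the true penalized objective non-increasing
        # even where the quadratic approximation overshoots
        step = 1.0
        while obj > trace[-1] + 1e-14 and step > 1e-8:
            step *= 0.5
            b = b_old + step * (b - b_old)
            b0 = b0_old + step * (b0 - b0_old)
            obj = _objective(X, y, b0, b, lam, alpha)
        trace.append(obj)
        if trace[-2] - trace[-1] < tol * max(abs(trace[-2]), 1.0):
            break
    return b0, b, np.asarray(trace)


class ElasticNetLogit(BaseEstimator, ClassifierMixin):
    """Elastic-net penalized logistic regression (glmnet-style solver).

    Parameters
    ----------
    mixing : L1/L2 mixing weight alpha in [0, 1] (1 = lasso, 0 = ridge).
    lam : penalty strength; ``None`` selects it by cross-validated deviance.
    n_lambdas, lambda_min_ratio : geometry of the automatic lambda path.
    cv : ``"loo"`` (default) or an integer fold count.
    rule : ``"1se"`` (default) or ``"min"``; if the 1-SE lambda yields the
        null model, the deviance-minimizing lambda is used instead.
    random_state : seeds the fold assignment for integer ``cv``.

    Fitted attributes (original feature scale): ``intercept_``, ``coef_``;
    standardized scale: ``intercept_std_``, ``coef_std_``; plus ``lambda_``,
    ``lambda_path_``, ``cv_deviance_``, ``selected_features_``,
    ``objective_trace_``.
    """

    def __init__(self, mixing: float = 0.5, lam: float | None = None,
                 n_lambdas: int = 50, lambda_min_ratio: float = 1e-3,
                 cv="loo", rule: str = "1se", tol: float = 1e-10,
                 max_iter: int = 500, random_state: int = 0):
        self.mixing = mixing
        self.lam = lam
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.rule = rule
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- internals -----------------------------------------------------
    def _standardize(self, X):
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
        scale = np.where(scale > 0, scale, 1.0)
        return (X - mean) / scale, mean, scale

    def _lambda_path(self, Xs, y):
        alpha = max(self.mixing, 1e-3)
        lmax = np.max(np.abs(Xs.T @ (y - y.mean()))) / (len(y) * alpha)
        lmax = max(lmax, 1e-10)
        return np.geomspace(lmax, lmax * self.lambda_min_ratio, self.n_lambdas)

    def _path_fit(self, Xs, y, lambdas):
        # cross-validation path fits are warm-started and run at a looser
        # inner tolerance; only the final refit needs KKT-grade precision
        p = Xs.shape[1]
        b0 = float(np.log(y.mean() / (1 - y.mean())))
        b = np.zeros(p)
        coefs, icpts = [], []
        for lam in lambdas:
            b0, b, _ = _cd_fit(Xs, y, lam, self.mixing, b0, b,
                               tol=1e-7, max_iter=50, inner_tol=1e-7)
            coefs.append(b.copy())
            icpts.append(b0)
        return np.asarray(icpts), np.asarray(coefs)

    def _cv_deviance(self, Xs, y, lambdas):
        n = len(y)
        if self.cv == "loo":
            folds = [np.array([i]) for i in range(n)]
        else:
            rng = np.random.default_rng(self.random_state)
            perm = rng.permutation(n)
            folds = np.array_split(perm, int(self.cv))
        dev = np.zeros((len(folds), len(lambdas)))
        for f, test in enumerate(folds):
            train = np.setdiff1d(np.arange(n), test)
            if len(np.unique(y[train])) < 2:
                dev[f] = np.nan
                continue
            icpts, coefs = self._path_fit(Xs[train], y[train], lambdas)
            eta = icpts[None, :] + Xs[test] @ coefs.T
            # binomial deviance of held-out observations
            dev[f] = 2.0 * np.mean(
                np.logaddexp(0.0, eta) - y[test, None] * eta, axis=0
            )
        mean = np.nanmean(dev, axis=0)
        se = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(len(folds))
        return mean, se

    # -- sklearn API ---------------------------------------------------
    def fit(self, X, y):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else [
            f"x{j}" for j in range(np.shape(X)[1])
        ]
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[1] < 1:
            raise ValueError("need at least one candidate feature")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("labels must contain exactly two classes")
        y = (y == classes.max()).astype(float)
        self.classes_ = np.array([0, 1])
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError("mixing must lie in [0, 1]")

        Xs, mean, scale = self._standardize(X)
        if self.lam is None:
            lambdas = self._lambda_path(Xs, y)
            if len(lambdas) == 0:
                raise ValueError("empty lambda grid")
            mean_dev, se_dev = self._cv_deviance(Xs, y, lambdas)
            best = int(np.nanargmin(mean_dev))
            lam = lambdas[best]
            if self.rule == "1se":
                thresh = mean_dev[best] + se_dev[best]
                within = np.where(mean_dev <= thresh)[0]
                lam_1se = lambdas[within.min()]  # largest lambda within 1 SE
                # keep the sparser model unless it is the null model
                _, coefs_chk, _ = (None, None, None)
                b0c, bc, _ = _cd_fit(
                    Xs, y, lam_1se, self.mixing,
                    float(np.log(y.mean() / (1 - y.mean()))),
                    np.zeros(Xs.shape[1]), self.tol, self.max_iter,
                )
                lam = lam_1se if np.any(bc != 0) else lam
                del b0c, coefs_chk
            self.lambda_path_ = lambdas
            self.cv_deviance_ = mean_dev
            self.cv_deviance_se_ = se_dev
        else:
            lam = float(self.lam)
            self.lambda_path_ = np.array([lam])
            self.cv_deviance_ = None
            self.cv_deviance_se_ = None

        # final fit at the chosen lambda, warm-started along the path
        b0 = float(np.log(y.mean() / (1 - y.mean())))
        b = np.zeros(Xs.shape[1])
        if self.lam is None:
            for l in self.lambda_path_[self.lambda_path_ > lam]:
                b0, b, _ = _cd_fit(Xs, y, l, self.mixing, b0, b,
                                   tol=1e-7, max_iter=50, inner_tol=1e-7)
        b0, b, trace = _cd_fit(Xs, y, lam, self.mixing, b0, b,
                               self.tol, self.max_iter)

        self.lambda_ = float(lam)
        self.feature_names_in_ = np.asarray(names)
        self.intercept_std_ = b0
        self.coef_std_ = b
        self.scale_ = scale
        self.mean_ = mean
        self.coef_ = b / scale
        self.intercept_ = float(b0 - np.sum(self.coef_ * mean))
        self.selected_features_ = [n for n, c in zip(names, b) if c != 0.0]
        self.objective_trace_ = trace
        self.n_iter_ = len(trace) - 1
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)

    def predicted_scores(self, X) -> np.ndarray:
        """Risk score per patient: logistic transform of the linear predictor."""
        return expit(self.decision_function(X))

    def kkt_residual(self, X, y) -> float:
        """Maximum violation of the stationarity conditions at the solution.

        For active coordinates the penalized gradient must vanish; for
        inactive ones the score must not exceed lam * mixing.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        y = (y == np.unique(y).max()).astype(float)
        Xs = (X - self.mean_) / self.scale_
        eta = self.intercept_std_ + Xs @ self.coef_std_
        mu = expit(eta)
        g = Xs.T @ (mu - y) / len(y) + self.lambda_ * (1 - self.mixing) * self.coef_std_
        viol = np.where(
            self.coef_std_ != 0,
            np.abs(g + self.lambda_ * self.mixing * np.sign(self.coef_std_)),
            np.clip(np.abs(g) - self.lambda_ * self.mixing, 0.0, None),
        )
        viol_icpt = abs(np.mean(mu - y))
        return float(max(viol.max(initial=0.0), viol_icpt))

    # -- serialization -------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "features": list(self.feature_names_in_),
            "intercept": self.intercept_,
            "coefficients": dict(zip(self.feature_names_in_,
                                     map(float, self.coef_))),
            "intercept_standardized": self.intercept_std_,
            "coefficients_standardized": dict(
                zip(self.feature_names_in_, map(float, self.coef_std_))
            ),
            "lambda": self.lambda_,
            "mixing": self.mixing,
            "selected_features": self.selected_features_,
            "seed": self.random_state,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit_elastic_net(
    table: pd.DataFrame,
    labels,
    mixing: float = 0.5,
    lambda_grid=None,
    cv_folds="loo",
    seed: int = 0,
    rule: str = "1se",
) -> ElasticNetLogit:
    """Fit the variable-selection model on a candidate-feature table."""
    model = ElasticNetLogit(mixing=mixing, cv=cv_folds, rule=rule,
                            random_state=seed)
    if lambda_grid is not None:
        grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
        if len(grid) == 0:
            raise ValueError("empty lambda grid")
        model.n_lambdas = len(grid)
        model._lambda_path = lambda Xs, y: grid  # user-supplied path
    return model.fit(table, labels)


def predicted_score(model: ElasticNetLogit, features: Mapping[str, float]) -> float:
    """Printed-equation risk score for one patient.

    ``features`` maps feature name -> value; every model feature with a
    nonzero coefficient must be present.
    """
    eta = model.intercept_
    for name, beta in zip(model.feature_names_in_, model.coef_):
        if beta == 0.0:
            continue
        if name not in features:
            raise KeyError(f"missing feature value: {name!r}")
        eta += beta * float(features[name])
    return float(expit(eta))


def evaluate_score(
    scores, labels, reps: int = 1000, seed: int = 0
) -> dict[str, float | tuple[float, float]]:
    """Mann-Whitney p between outcome groups, AUROC, and its bootstrap CI."""
    u, p = group_compare(scores, labels)
    a = auroc(scores, labels)
    ci = bootstrap_auroc_ci(scores, labels, reps=reps, seed=seed)
    return {"mann_whitney_u": u, "mann_whitney_p": p, "auroc": a, "ci": ci}
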