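"""L1-penalized logistic regression with stability selection.

Smoothed gene scores are related to a binary phenotype by LASSO logistic
regression fitted along a decreasing grid of sparsity values lambda. The fit
is repeated on many class-stratified half-samples; a gene's selection
probability at a given lambda is the fraction of half-sample fits in which
its coefficient is nonzero, and genes whose probability exceeds a threshold
(default 0.80) anywhere on the grid are declared selected.

The penalized objective follows the glmnet parameterisation,

    (1/n) * sum_i l(y_i, yhat_i) + lambda * ||beta||_1,

with an unpenalized intercept. Individual fits delegate to scikit-learn's
liblinear solver; to keep full regularization paths affordable, each fit is
restricted to a feature subset chosen by the sequential strong rule of
Tibshirani et al. (2012), followed by a KKT check on the discarded features
(violators are added back and the fit repeated), so screening never changes
the solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LambdaPath",
    "StabilityResult",
    "StabilitySelector",
    "make_lambda_path",
    "lasso_path",
    "stability_select",
]


@dataclass(frozen=True)
class LambdaPath:
    """Strictly decreasing grid of positive sparsity values."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        v = self.values
        if v.ndim != 1 or v.size == 0:
            raise ValueError("lambda path must be a nonempty 1-D sequence")
        if np.any(v <= 0):
            raise ValueError("lambda values must be positive")
        if np.any(np.diff(v) >= 0):
            raise ValueError("lambda path must be strictly decreasing")

    @property
    def n_points(self) -> int:
        return self.values.size


def make_lambda_path(
    X, y, n_points: int = 50, min_ratio: float = 0.01
) -> LambdaPath:
    """Data-driven lambda grid from lambda_max down to min_ratio*lambda_max.

    lambda_max is the smallest lambda with an all-zero solution,
    max_j |x_j' (y - ybar)| / n on standardized columns; the grid is
    log-spaced.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xs = _standardize(X)
    n = X.shape[0]
    lam_max = np.abs(Xs.T @ (y - y.mean())).max() / n
    if lam_max <= 0:
        raise ValueError("all columns are constant; lambda path undefined")
    return LambdaPath(lam_max * np.logspace(0, np.log10(min_ratio), n_points))


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _check_two_classes(y: np.ndarray):
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(
            f"phenotype must contain exactly two classes, found {classes}"
        )


def lasso_path(
    X,
    y,
    path: LambdaPath,
    solver_tol: float = 1e-3,
    standardize: bool = True,
    max_active: int | None = None,
) -> list[np.ndarray]:
    """Nonzero-coefficient supports of the L1 logistic model along a path.

    Returns, for each lambda in decreasing order, the sorted array of column
    indices with nonzero coefficients. Deterministic given inputs.

    ``max_active`` caps the number of variables allowed to enter the path
    (the q of stability-selection error control): once a fit's support
    exceeds it, that and all smaller lambdas report the last support within
    the cap. Without a cap the near-unpenalized end of the path saturates
    and stability probabilities lose their false-selection control.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    _check_two_classes(y)
    if standardize:
        X = _standardize(X)
    n, m = X.shape
    lams = path.values
    # glmnet-scale lambda <-> sklearn C: C = 1 / (n * lambda)
    supports: list[np.ndarray] = []
    beta = np.zeros(m)
    b0 = _null_intercept(y)
    p = _sigmoid(np.full(n, b0))
    grad = np.abs(X.T @ (y - p)) / n
    prev_lam = lams[0]
    active = np.zeros(m, dtype=bool)
    for lam in lams:
        keep = (grad >= 2 * lam - prev_lam) | active
        while True:
            idx = np.flatnonzero(keep)
            if idx.size == 0:
                beta[:] = 0.0
                p = _sigmoid(np.full(n, b0))
            else:
                clf = LogisticRegression(
                    l1_ratio=1,
                    solver="liblinear",
                    C=1.0 / (n * lam),
                    tol=solver_tol,
                    max_iter=200,
                    intercept_scaling=10.0,
                    random_state=0,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf.fit(X[:, idx], y)
                beta[:] = 0.0
                beta[idx] = clf.coef_[0]
                b0 = clf.intercept_[0]
                p = _sigmoid(X[:, idx] @ clf.coef_[0] + b0)
            grad = np.abs(X.T @ (y - p)) / n
            violations = (~keep) & (grad > lam * (1 + 1e-4))
            if not violations.any():
                break
            keep |= violations
        active = beta != 0.0
        support = np.flatnonzero(active)
        if max_active is not None and support.size > max_active:
            frozen = supports[-1] if supports else np.empty(0, dtype=int)
            supports.extend([frozen] * (len(lams) - len(supports)))
            break
        supports.append(support)
        prev_lam = lam
    return supports


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _null_intercept(y):
    pbar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    return float(np.log(pbar / (1 - pbar)))


@dataclass
class StabilityResult:
    """Per-gene selection probabilities over the lambda grid."""

    genes: np.ndarray
    lambda_path: LambdaPath
    selection_probability: np.ndarray  # genes x lambdas
    n_resamples: int
    threshold: float
    seed: int | None
    complementary_pairs: bool = False
    max_probability: np.ndarray = field(init=False)
    selected: np.ndarray = field(init=False)

    def __post_init__(self):
        self.max_probability = self.selection_probability.max(axis=1)
        self.selected = self.genes[self.max_probability >= self.threshold]

    def monotone_path(self) -> np.ndarray:
        """Running maximum over decreasing lambda (plotting convention)."""
        return np.maximum.accumulate(self.selection_probability, axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.selection_probability,
            index=self.genes,
            columns=[f"lambda_{i}" for i in range(self.lambda_path.n_points)],
        )
        df.insert(0, "max_probability", self.max_probability)
        return df


class StabilitySelector(SelectorMixin, BaseEstimator):
    """Stability selection over an L1 logistic regularization path.

    Each of ``n_resamples`` resamples draws floor(S/2) subjects without
    replacement, stratified by class; :func:`lasso_path` is fitted per
    resample and a feature's selection probability at each lambda is the
    fraction of fits with a nonzero coefficient there. Features whose
    maximum probability over the grid reaches ``threshold`` are selected.

    Parameters
    ----------
    n_lambda, lambda_min_ratio : path construction (log-spaced grid from the
        data-driven lambda_max); ignored when an explicit ``lambda_path`` is
        given.
    n_resamples : int, default 100
        Number of half-sample draws.
    threshold : float, default 0.80
        Selection-probability cutoff.
    complementary_pairs : bool, default False
        Also fit each draw's complement, giving probability granularity
        1/(2*n_resamples).
    standardize : bool, default True
        Standardize columns within each resample before the penalized fit.
    max_active : int, None or 'auto', default 'auto'
        Per-fit cap q on the number of variables entering the path (the
        error-control device of stability selection): 'auto' uses
        ceil(sqrt((2*threshold - 1) * p)), the Meinshausen-Buhlmann bound at
        an expected false-selection count of one. None disables the cap, in
        which case the saturated low-lambda end of the path can make
        chance-correlated features look stable.
    random_state : int or None
        Seed for the resampling draws.

    Attributes
    ----------
    result_ : StabilityResult
    selection_probability_, max_probability_, support_ : convenience views.
    """

    def __init__(
        self,
        n_lambda: int = 50,
        lambda_min_ratio: float = 0.01,
        lambda_path: LambdaPath | None = None,
        n_resamples: int = 100,
        threshold: float = 0.80,
        complementary_pairs: bool = False,
        standardize: bool = True,
        solver_tol: float = 1e-3,
        max_active="auto",
        random_state: int | None = None,
    ):
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.lambda_path = lambda_path
        self.n_resamples = n_resamples
        self.threshold = threshold
        self.complementary_pairs = complementary_pairs
        self.standardize = standardize
        self.solver_tol = solver_tol
        self.max_active = max_active
        self.random_state = random_state

    def fit(self, X, y):
        feature_names = getattr(X, "columns", None)
        subject_ids = getattr(X, "index", None)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the number of subjects")
        if X.shape[0] < 20:
            raise ValueError("stability selection needs at least 20 subjects")
        _check_two_classes(y)
        if subject_ids is not None:
            # canonical order: results do not depend on input row order
            order = np.argsort(np.asarray(subject_ids, dtype=object).astype(str))
            X, y = X[order], y[order]
        path = self.lambda_path
        if path is None:
            path = make_lambda_path(
                X, y, n_points=self.n_lambda, min_ratio=self.lambda_min_ratio
            )
        n, m = X.shape
        if self.max_active == "auto":
            theta = max(2.0 * self.threshold - 1.0, 0.2)
            max_active = int(np.ceil(np.sqrt(theta * m)))
        else:
            max_active = self.max_active
        cls1 = np.flatnonzero(y == np.unique(y)[1])
        cls0 = np.flatnonzero(y == np.unique(y)[0])
        half = n // 2
        k1 = max(1, len(cls1) // 2)
        k0 = max(1, half - k1)
        if k1 > len(cls1) or k0 > len(cls0):
            raise ValueError("a class is too small for stratified half-sampling")
        rng = np.random.default_rng(self.random_state)
        counts = np.zeros((m, path.n_points), dtype=float)
        n_fits = 0
        for _ in range(self.n_resamples):
            pick1 = rng.choice(cls1, size=k1, replace=False)
            pick0 = rng.choice(cls0, size=k0, replace=False)
            halves = [np.concatenate([pick1, pick0])]
            if self.complementary_pairs:
                halves.append(
                    np.concatenate(
                        [np.setdiff1d(cls1, pick1), np.setdiff1d(cls0, pick0)]
                    )
                )
            for idx in halves:
                sup = lasso_path(
                    X[idx],
                    y[idx],
                    path,
                    solver_tol=self.solver_tol,
                    standardize=self.standardize,
                    max_active=max_active,
                )
                for j, s in enumerate(sup):
                    counts[s, j] += 1
                n_fits += 1
        probs = counts / n_fits
        genes = (
            np.asarray(feature_names, dtype=object)
            if feature_names is not None
            else np.arange(m).astype(object)
        )
        self.result_ = StabilityResult(
            genes=genes,
            lambda_path=path,
            selection_probability=probs,
            n_resamples=self.n_resamples,
            threshold=self.threshold,
            seed=self.random_state,
            complementary_pairs=self.complementary_pairs,
        )
        self.lambda_path_ = path
        self.selection_probability_ = probs
        self.max_probability_ = self.result_.max_probability
        self.n_features_in_ = m
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "result_")
        return self.max_probability_ >= self.threshold

    @property
    def selected_genes_(self) -> np.ndarray:
        check_is_fitted(self, "result_")
        return self.result_.selected


def stability_select(
    scores,
    phenotype,
    path: LambdaPath | None = None,
    n_resamples: int = 100,
    threshold: float = 0.80,
    seed: int | None = None,
    **kwargs,
) -> StabilityResult:
    """Functional wrapper around :class:`StabilitySelector`."""
    sel = StabilitySelector(
        lambda_path=path,
        n_resamples=n_resamples,
        threshold=threshold,
        random_state=seed,
        **kwargs,
    )
    sel.fit(scores, phenotype)
    return sel.result_
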