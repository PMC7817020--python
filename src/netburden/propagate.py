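"""Network propagation of rare-variant burden signals.

The subject x gene burden matrix G0 is smoothed over a gene-interaction
network by iterating

    G(t+1) = alpha * G(t) . (D . N) + (1 - alpha) * G0

where N is the symmetric similarity matrix, D holds the inverse node
strengths (so D.N is row-stochastic) and alpha in [0, 1] is the diffusion
length: alpha = 0 leaves the burden untouched, larger alpha lets signal
travel further. Iteration stops when the L2 (Frobenius) norm of the iterate
difference drops below ``tol``. For alpha < 1 the map is a contraction, so
the fixed point

    G* = (1 - alpha) * G0 . (I - alpha * D.N)^-1

exists and is unique; :func:`closed_form_propagate` computes it by a direct
linear solve and serves as an exact oracle for the iterative path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .burden import BurdenMatrix
from .network import GeneNetwork, NormalizedOperator, degree_normalize

__all__ = [
    "PropagationConfig",
    "SmoothedScores",
    "NetworkPropagator",
    "propagate",
    "closed_form_propagate",
    "quantile_normalize_rows",
]


@dataclass(frozen=True)
class PropagationConfig:
    """Settings for the diffusion iteration.

    alpha : diffusion length in [0, 1] (default 0.5).
    tol : convergence threshold on the Frobenius norm of the iterate
        difference (default 1e-6).
    quantile_normalize : map every subject's smoothed profile onto the common
        mean order-statistic distribution after convergence (default off).
    max_iters : safety cap; hitting it flags nonconvergence.
    """

    alpha: float = 0.5
    tol: float = 1e-6
    quantile_normalize: bool = False
    max_iters: int = 1000

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


@dataclass
class SmoothedScores:
    """Converged subject x gene scores plus iteration diagnostics."""

    subjects: np.ndarray
    genes: np.ndarray
    values: np.ndarray
    iterations_run: int
    final_delta: float
    converged: bool

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.subjects, columns=self.genes)


def _as_matrix(burden) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Return (dense array, subjects, genes) from BurdenMatrix/DataFrame/array."""
    if isinstance(burden, BurdenMatrix):
        return burden.values.toarray(), burden.subjects, burden.genes
    if hasattr(burden, "columns"):  # DataFrame
        return (
            burden.to_numpy(dtype=float),
            burden.index.to_numpy(dtype=object),
            burden.columns.to_numpy(dtype=object),
        )
    if sp.issparse(burden):
        return burden.toarray().astype(float), None, None
    return np.asarray(burden, dtype=float), None, None


def _check_alignment(genes, op: NormalizedOperator):
    if genes is not None and not np.array_equal(genes, op.genes):
        raise ValueError(
            "burden gene order does not match the operator's gene order"
        )


class NetworkPropagator(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer applying network propagation to burden rows.

    Parameters
    ----------
    network : GeneNetwork or NormalizedOperator
        The diffusion substrate; a GeneNetwork is degree-normalized at fit.
    alpha : float, default 0.5
        Diffusion length; 0 returns the input unchanged.
    tol : float, default 1e-6
        Frobenius-norm convergence threshold.
    max_iters : int, default 1000
        Iteration cap; exceeding it raises unless ``error_on_nonconvergence``
        is False, in which case ``converged_`` is set False.
    quantile_normalize : bool, default False
        Quantile-normalize subject rows after convergence.
    mode : {'auto', 'dense', 'sparse'}, default 'auto'
        Execution path; 'auto' picks sparse operator matmul when the operator
        density is below 25%. Both paths agree to 1e-10.

    Attributes
    ----------
    operator_ : NormalizedOperator
    n_iterations_, final_delta_, converged_ : diagnostics of the last
        transform.
    """

    def __init__(
        self,
        network=None,
        alpha: float = 0.5,
        tol: float = 1e-6,
        max_iters: int = 1000,
        quantile_normalize: bool = False,
        mode: str = "auto",
        error_on_nonconvergence: bool = True,
    ):
        self.network = network
        self.alpha = alpha
        self.tol = tol
        self.max_iters = max_iters
        self.quantile_normalize = quantile_normalize
        self.mode = mode
        self.error_on_nonconvergence = error_on_nonconvergence

    def _config(self) -> PropagationConfig:
        return PropagationConfig(
            alpha=self.alpha,
            tol=self.tol,
            quantile_normalize=self.quantile_normalize,
            max_iters=self.max_iters,
        )

    def fit(self, X=None, y=None):
        if isinstance(self.network, NormalizedOperator):
            self.operator_ = self.network
        elif isinstance(self.network, GeneNetwork):
            self.operator_ = degree_normalize(self.network)
        else:
            raise TypeError(
                "network must be a GeneNetwork or NormalizedOperator"
            )
        self._config()  # validates hyperparameters
        if X is not None:
            _, _, genes = _as_matrix(X)
            _check_alignment(genes, self.operator_)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "operator_")
        cfg = self._config()
        g0, _, genes = _as_matrix(X)
        _check_alignment(genes, self.operator_)
        if np.isnan(g0).any():
            raise ValueError("burden matrix contains NaN")
        if g0.shape[1] != len(self.operator_.genes):
            raise ValueError("burden gene dimension does not match operator")
        values, n_iter, delta, converged = _iterate(
            g0, self.operator_.matrix, cfg, self.mode
        )
        if not converged and self.error_on_nonconvergence:
            raise RuntimeError(
                f"propagation did not converge in {cfg.max_iters} iterations "
                f"(final delta {delta:.3g} >= tol {cfg.tol:g})"
            )
        if cfg.quantile_normalize:
            values = quantile_normalize_rows(values)
        self.n_iterations_ = n_iter
        self.final_delta_ = delta
        self.converged_ = converged
        return values


def _iterate(g0, w: sp.spmatrix, cfg: PropagationConfig, mode: str = "auto"):
    if cfg.alpha == 0.0:
        return g0.copy(), 1, 0.0, True
    if mode == "auto":
        density = w.nnz / max(1, w.shape[0] * w.shape[1])
        mode = "sparse" if density < 0.25 else "dense"
    op = w.tocsr() if mode == "sparse" else w.toarray()
    a = cfg.alpha
    g = g0
    for it in range(1, cfg.max_iters + 1):
        g_new = a * (g @ op) + (1.0 - a) * g0
        delta = float(np.linalg.norm(g_new - g))
        g = g_new
        if delta < cfg.tol:
            return np.asarray(g), it, delta, True
    return np.asarray(g), cfg.max_iters, delta, False


def propagate(
    burden, operator, config: PropagationConfig | None = None, mode: str = "auto"
) -> SmoothedScores:
    """Smooth a burden matrix over the network; iterative solver.

    ``burden`` may be a BurdenMatrix, a subjects x genes DataFrame or a bare
    array whose columns already follow the operator's gene order.
    """
    if config is None:
        config = PropagationConfig()
    if isinstance(operator, GeneNetwork):
        operator = degree_normalize(operator)
    prop = NetworkPropagator(
        network=operator,
        alpha=config.alpha,
        tol=config.tol,
        max_iters=config.max_iters,
        quantile_normalize=config.quantile_normalize,
        mode=mode,
        error_on_nonconvergence=False,
    )
    prop.fit()
    _, subjects, genes = _as_matrix(burden)
    values = prop.transform(burden)
    if subjects is None:
        subjects = np.arange(values.shape[0])
    return SmoothedScores(
        subjects=np.asarray(subjects, dtype=object),
        genes=operator.genes.copy() if genes is None else np.asarray(genes, dtype=object),
        values=values,
        iterations_run=prop.n_iterations_,
        final_delta=prop.final_delta_,
        converged=prop.converged_,
    )


def closed_form_propagate(burden, operator, alpha: float = 0.5) -> SmoothedScores:
    """Exact fixed point of the diffusion by a direct linear solve.

    Solves G* (I - alpha W) = (1 - alpha) G0, i.e. the stationary point of
    the iteration; requires alpha < 1 (the system is then nonsingular for a
    row-stochastic W). Intended for verification and small gene sets.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("closed-form solve requires 0 <= alpha < 1")
    if isinstance(operator, GeneNetwork):
        operator = degree_normalize(operator)
    g0, subjects, genes = _as_matrix(burden)
    _check_alignment(genes, operator)
    if alpha == 0.0:
        values = g0.copy()
    else:
        w = operator.matrix.toarray()
        m = w.shape[0]
        system = (np.eye(m) - alpha * w).T
        rhs = (1.0 - alpha) * g0.T
        values = np.linalg.solve(system, rhs).T
    if subjects is None:
        subjects = np.arange(g0.shape[0])
    return SmoothedScores(
        subjects=np.asarray(subjects, dtype=object),
        genes=operator.genes.copy(),
        values=values,
        iterations_run=0,
        final_delta=0.0,
        converged=True,
    )


def quantile_normalize_rows(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize the rows of a matrix.

    Every row is mapped onto the reference distribution formed by the mean of
    all rows' order statistics: within-row ranks are preserved and tied
    values share the mean of their target quantiles (linear interpolation on
    average ranks).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    n = values.shape[1]
    reference = np.sort(values, axis=1).mean(axis=0)
    ranks = np.apply_along_axis(rankdata, 1, values)  # average ranks for ties
    return np.interp(ranks, np.arange(1, n + 1), reference)
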