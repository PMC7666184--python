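"""Predictor reduction: CV screening, forward selection, PCA retention.

The environmental battery of a habitat-assessment protocol easily runs to
hundreds of partially redundant variables.  The reduction chain applied here
mirrors the standard workflow for variation partitioning:

1. **CV screening** — drop variables with a coefficient of variation below a
   lower bound (uninformative along the gradient) or above an upper bound
   (zero-inflated / sampling artefacts).
2. **Forward selection** — greedy inclusion of the variable giving the
   largest canonical-R² gain against the (transformed) community matrix,
   tested at each step by permutation of the partial residuals, with the
   double stopping rule (permutation alpha plus the global model's adjusted
   R² as a ceiling).
3. **PCA retention** — principal components of the selected variables
   (correlation-matrix PCA), keeping axes until the cumulative explained
   variance reaches a threshold; the retained scores are the predictors
   entering the ordination.

The same forward-selection machinery is reused to pick PCNM spatial filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .datamodel import EnvMatrix
from .ordination import TransformedResponse, _as_matrix, adjusted_r2

__all__ = [
    "ScreeningReport",
    "SelectionResult",
    "PCAAxes",
    "CVScreen",
    "ForwardSelector",
    "RetainedVariancePCA",
    "cv_screen",
    "forward_select",
    "pca_reduce",
]


# ---------------------------------------------------------------------------
# CV screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningReport:
    cv_values: dict[str, float]
    kept: list[str]
    dropped_low: list[str]
    dropped_high: list[str]

    def to_dataframe(self) -> pd.DataFrame:
        status = {v: "kept" for v in self.kept}
        status.update({v: "dropped_low" for v in self.dropped_low})
        status.update({v: "dropped_high" for v in self.dropped_high})
        return pd.DataFrame(
            {
                "variable": list(self.cv_values),
                "cv_percent": [self.cv_values[v] for v in self.cv_values],
                "status": [status[v] for v in self.cv_values],
            }
        )


def _cv_percent(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    out = np.full(values.shape[1], np.inf)
    ok = np.abs(mean) >= 1e-12
    out[ok] = 100.0 * sd[ok] / np.abs(mean[ok])
    return out


def cv_screen(env: EnvMatrix, cv_low: float = 40.0, cv_high: float = 80.0) -> ScreeningReport:
    """Screen variables on the coefficient of variation, CV = 100·sd/|mean|.

    Variables with CV strictly below ``cv_low`` or strictly above ``cv_high``
    are dropped (boundary values are kept); a variable whose mean is
    numerically zero gets CV = +inf and is dropped on the high side.
    """
    values = _as_matrix(env)
    labels = env.var_ids if isinstance(env, EnvMatrix) else [str(j) for j in range(values.shape[1])]
    cv = _cv_percent(values)
    kept, low, high = [], [], []
    for lab, c in zip(labels, cv):
        if c < cv_low:
            low.append(lab)
        elif c > cv_high:
            high.append(lab)
        else:
            kept.append(lab)
    return ScreeningReport(
        cv_values=dict(zip(labels, cv.tolist())),
        kept=kept,
        dropped_low=low,
        dropped_high=high,
    )


class CVScreen(SelectorMixin, BaseEstimator):
    """Coefficient-of-variation screening as a scikit-learn selector."""

    def __init__(self, cv_low: float = 40.0, cv_high: float = 80.0):
        self.cv_low = cv_low
        self.cv_high = cv_high

    def fit(self, X, y=None):
        values = _as_matrix(X)
        self.cv_values_ = _cv_percent(values)
        self.support_ = (self.cv_values_ >= self.cv_low) & (self.cv_values_ <= self.cv_high)
        self.n_features_in_ = values.shape[1]
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self)
        return self.support_


# ---------------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    order: list[str]
    pvalues: list[float]
    r2_path: list[float]          # cumulative unadjusted R², strictly increasing
    adj_r2_path: list[float]      # cumulative adjusted R² (may dip)
    stop_reason: str              # "alpha" | "global_adjr2" | "exhausted"
    candidates: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, len(self.order) + 1),
                "variable": self.order,
                "p_value": self.pvalues,
                "cum_r2": self.r2_path,
                "cum_adj_r2": self.adj_r2_path,
            }
        )


def _residualize(M: np.ndarray, Q: np.ndarray) -> np.ndarray:
    if Q.shape[1] == 0:
        return M
    return M - Q @ (Q.T @ M)


def _step_increments(Yr: np.ndarray, Cr: np.ndarray, ss_total: float) -> np.ndarray:
    """R² gain of each candidate column given current residualized state.

    ``Yr`` and ``Cr`` are the response and candidate columns after projecting
    out the already-selected block; candidate columns are unit-normalized, so
    the gain is just the squared projection of Y onto each column.
    """
    proj = Cr.T @ Yr  # (n_cand, n_resp)
    return np.sum(proj * proj, axis=1) / ss_total


def forward_select(
    Yt,
    candidates,
    alpha: float = 0.05,
    nperm: int = 999,
    seed: int = 0,
    labels: list[str] | None = None,
    adjr2_ceiling: bool = True,
) -> SelectionResult:
    """Greedy forward selection of predictors against a community matrix.

    At each step the candidate with the largest canonical-R² increment is
    proposed and tested by permuting the rows of the partial residuals of the
    response (given the already-selected block): the permutation statistic is
    the *best* increment over the remaining candidates, so the test accounts
    for the selection of the maximum and the first step is exactly calibrated
    under the null.  Selection stops when the permutation p-value exceeds
    ``alpha``, when the cumulative adjusted R² would exceed the global
    model's adjusted R² (double stopping), or when candidates run out.
    Deterministic given ``seed``.
    """
    if nperm < 19:
        raise ValueError("nperm must be >= 19")
    Y = _as_matrix(Yt)
    Y = Y - Y.mean(axis=0, keepdims=True)
    C = _as_matrix(candidates)
    if labels is None:
        if isinstance(candidates, pd.DataFrame):
            labels = [str(c) for c in candidates.columns]
        elif isinstance(candidates, EnvMatrix):
            labels = list(candidates.var_ids)
        else:
            labels = [f"v{j + 1}" for j in range(C.shape[1])]
    n = Y.shape[0]
    ss_total = float(np.sum(Y * Y))
    if ss_total == 0.0:
        raise ValueError("zero-variance response")
    if C.size == 0 or C.shape[1] == 0:
        return SelectionResult([], [], [], [], "exhausted", candidates=list(labels or []))

    # centre and unit-normalize candidates; zero-variance candidates are inert
    C = C - C.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(C, axis=0)
    live = norms > 1e-12 * max(1.0, norms.max())
    C = np.where(live, C / np.where(norms > 0, norms, 1.0), 0.0)

    rng = np.random.default_rng(seed)
    remaining = list(range(C.shape[1]))
    Q = np.empty((n, 0))  # orthonormal basis of the selected block

    # global ceiling: adjusted R² of the model with all candidates
    from .ordination import _ortho_basis, _r2_from_basis

    Qall = _ortho_basis(C)
    global_adj = None
    if adjr2_ceiling and n > Qall.shape[1] + 1:
        global_adj = adjusted_r2(_r2_from_basis(Y, Qall, ss_total), n, Qall.shape[1])

    order: list[int] = []
    pvalues: list[float] = []
    r2_path: list[float] = []
    adj_path: list[float] = []
    cum_r2 = 0.0
    stop_reason = "exhausted"

    while remaining:
        if n <= len(order) + 2:
            stop_reason = "exhausted"
            break
        Yr = _residualize(Y, Q)
        Cr = _residualize(C[:, remaining], Q)
        rnorm = np.linalg.norm(Cr, axis=0)
        ok = rnorm > 1e-10
        Cr = np.where(ok, Cr / np.where(rnorm > 0, rnorm, 1.0), 0.0)
        incs = _step_increments(Yr, Cr, ss_total)
        best_local = int(np.argmax(incs))
        observed = float(incs[best_local])
        if observed <= 0:
            stop_reason = "exhausted"
            break

        # permutation test of the max increment
        count = 1
        for _ in range(nperm):
            perm = rng.permutation(n)
            incs_p = _step_increments(Yr[perm], Cr, ss_total)
            if incs_p.max() >= observed:
                count += 1
        p = count / (nperm + 1)
        if p > alpha:
            stop_reason = "alpha"
            break

        j = remaining[best_local]
        new_r2 = cum_r2 + observed
        new_adj = adjusted_r2(new_r2, n, len(order) + 1)
        # ceiling binds from the second step on: the first-step test is the
        # calibrated max-statistic permutation, and a one-variable model
        # cannot overfit past a ceiling estimated with every candidate in it
        if global_adj is not None and order and new_adj > global_adj + 1e-12:
            stop_reason = "global_adjr2"
            break

        order.append(j)
        pvalues.append(p)
        cum_r2 = new_r2
        r2_path.append(cum_r2)
        adj_path.append(new_adj)
        # extend the orthonormal basis with the residualized winner
        qnew = Cr[:, best_local:best_local + 1]
        Q = np.hstack([Q, qnew])
        remaining.remove(j)

    return SelectionResult(
        order=[labels[j] for j in order],
        pvalues=pvalues,
        r2_path=r2_path,
        adj_r2_path=adj_path,
        stop_reason=stop_reason,
        candidates=list(labels),
    )


class ForwardSelector(SelectorMixin, BaseEstimator):
    """Forward selection as a scikit-learn feature selector.

    ``fit(X, y)`` selects columns of ``X`` (the candidate predictors)
    against the multivariate response ``y`` (the transformed community
    matrix); ``transform(X)`` keeps the selected columns.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        nperm: int = 999,
        seed: int = 0,
        adjr2_ceiling: bool = True,
    ):
        self.alpha = alpha
        self.nperm = nperm
        self.seed = seed
        self.adjr2_ceiling = adjr2_ceiling

    def fit(self, X, y):
        labels = [str(c) for c in X.columns] if isinstance(X, pd.DataFrame) else None
        Xv = _as_matrix(X)
        self.result_ = forward_select(
            y,
            Xv,
            alpha=self.alpha,
            nperm=self.nperm,
            seed=self.seed,
            labels=labels,
            adjr2_ceiling=self.adjr2_ceiling,
        )
        names = self.result_.candidates
        chosen = set(self.result_.order)
        self.support_ = np.array([lab in chosen for lab in names])
        self.n_features_in_ = Xv.shape[1]
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self)
        return self.support_


# ---------------------------------------------------------------------------
# PCA retention
# ---------------------------------------------------------------------------

@dataclass
class PCAAxes:
    scores: np.ndarray        # n_sites x k retained axis scores
    explained: np.ndarray     # k proportions, descending
    cumulative: np.ndarray    # k cumulative proportions
    k: int

    def to_dataframe(self, site_ids=None) -> pd.DataFrame:
        cols = [f"PC{j + 1}" for j in range(self.k)]
        return pd.DataFrame(self.scores, index=site_ids, columns=cols)


class RetainedVariancePCA(BaseEstimator):
    """Correlation-matrix PCA keeping axes up to a cumulative-variance cut.

    Variables are standardized (the battery mixes units), a full PCA is
    fitted, and the smallest k with cumulative explained variance >=
    ``threshold`` is retained.
    """

    def __init__(self, threshold: float = 0.90):
        self.threshold = threshold

    def fit(self, X, y=None):
        values = _as_matrix(X)
        if values.shape[1] < 1:
            raise ValueError("need at least one variable")
        if values.shape[0] < 2:
            raise ValueError("need at least two sites")
        sd = values.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance variable; screen the battery first")
        Z = (values - values.mean(axis=0)) / sd
        pca = PCA(n_components=min(Z.shape), svd_solver="full")
        scores = pca.fit_transform(Z)
        explained = pca.explained_variance_ratio_
        nonzero = explained > 1e-12
        explained = explained[nonzero]
        scores = scores[:, nonzero]
        cumulative = np.cumsum(explained)
        k = int(np.searchsorted(cumulative, self.threshold - 1e-12) + 1)
        k = min(k, len(explained))
        self.k_ = k
        self.explained_ = explained[:k]
        self.cumulative_ = cumulative[:k]
        self.scores_ = scores[:, :k]
        self.all_explained_ = explained
        self.n_features_in_ = values.shape[1]
        return self

    def transform(self, X=None) -> np.ndarray:
        check_is_fitted(self)
        return self.scores_

    def fit_transform(self, X, y=None, **kwargs) -> np.ndarray:
        return self.fit(X).transform()


def pca_reduce(env_selected, threshold: float = 0.90) -> PCAAxes:
    """PCA of the selected variables, retaining axes to >= ``threshold``."""
    est = RetainedVariancePCA(threshold=threshold).fit(env_selected)
    return PCAAxes(
        scores=est.scores_,
        explained=est.explained_,
        cumulative=est.cumulative_,
        k=est.k_,
    )
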