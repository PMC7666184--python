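"""Redundancy analysis R², adjusted R², and two-block variation partitioning.

Variation partitioning decomposes the variance of a (transformed) community
matrix Y explained by an environmental block X and a spatial block W into
four fractions:

    [a]  pure environment        = adjR²(Y ~ X ∪ W) − adjR²(Y ~ W)
    [b]  shared (spatially structured environment)
                                 = adjR²(Y ~ X) + adjR²(Y ~ W) − adjR²(Y ~ X ∪ W)
    [c]  pure space              = adjR²(Y ~ X ∪ W) − adjR²(Y ~ X)
    [d]  residual                = 1 − adjR²(Y ~ X ∪ W)

where each R² is the canonical (RDA) R² — the fraction of the total sum of
squares of the column-centred Y captured by its least-squares projection onto
the predictor column space — and adjR² is the Ezekiel adjustment
1 − (1 − R²)(n − 1)/(n − m − 1) with m the effective rank of the block.
Fractions [a] and [c] can come out slightly negative through the adjustment;
they are reported as-is (flagged), never clamped, so the four fractions
always sum to one exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datamodel import CommunityMatrix

__all__ = [
    "TransformedResponse",
    "VarpartResult",
    "HellingerTransformer",
    "VariationPartitioning",
    "transform_response",
    "hellinger",
    "rda_r2",
    "adjusted_r2",
    "varpart2",
]


# ---------------------------------------------------------------------------
# response transforms
# ---------------------------------------------------------------------------

@dataclass
class TransformedResponse:
    """Column-centred response matrix ready for RDA."""

    values: np.ndarray
    transform_used: str

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]


def hellinger(values: np.ndarray) -> np.ndarray:
    """Hellinger transform: sqrt of the per-site relative abundance.

    Rows with zero total are left all-zero (with a warning); they carry no
    compositional information.
    """
    values = np.asarray(values, dtype=float)
    totals = values.sum(axis=1)
    if np.any(totals == 0):
        warnings.warn("rows with zero total left as all-zero under hellinger")
    safe = np.where(totals > 0, totals, 1.0)
    return np.sqrt(values / safe[:, None])


class HellingerTransformer(TransformerMixin, BaseEstimator):
    """Community-matrix response transform as a scikit-learn transformer.

    Parameters
    ----------
    mode : {"hellinger", "presence_absence", "none"}
        ``hellinger`` replaces each cell by sqrt(abundance / site total),
        ``presence_absence`` binarizes, ``none`` leaves abundances untouched.
        All modes column-centre the result, as RDA requires.
    """

    def __init__(self, mode: str = "hellinger"):
        self.mode = mode

    def fit(self, X, y=None):
        if self.mode not in ("hellinger", "presence_absence", "none"):
            raise ValueError(f"unknown transform mode: {self.mode!r}")
        X = self._coerce(X)
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _coerce(X) -> np.ndarray:
        if isinstance(X, CommunityMatrix):
            X = X.values
        # fixed memory layout so column means are bitwise reproducible
        # whether the matrix arrives whole or as a species slice
        return np.ascontiguousarray(X, dtype=float)

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = self._coerce(X)
        if self.mode == "hellinger":
            out = hellinger(X)
        elif self.mode == "presence_absence":
            out = (X > 0).astype(float)
        else:
            out = X.copy()
        return out - out.mean(axis=0, keepdims=True)


def transform_response(Y: CommunityMatrix | np.ndarray, mode: str = "hellinger") -> TransformedResponse:
    """Apply the configured abundance transform and column-centre."""
    vals = HellingerTransformer(mode=mode).fit_transform(Y)
    return TransformedResponse(values=vals, transform_used=mode)


# ---------------------------------------------------------------------------
# R² machinery
# ---------------------------------------------------------------------------

def _as_matrix(block) -> np.ndarray:
    if block is None:
        return np.empty((0, 0))
    if isinstance(block, TransformedResponse):
        return block.values
    if hasattr(block, "to_numpy"):
        return np.asarray(block.to_numpy(), dtype=float)
    if hasattr(block, "values") and not isinstance(block, np.ndarray):
        return np.asarray(block.values, dtype=float)
    return np.asarray(block, dtype=float)


def _ortho_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of the centred, scaled block.

    Columns are mean-centred and scaled to unit variance (zero-variance
    columns drop out); the basis is cut at the numerical rank so duplicated
    or collinear predictors are handled by projection onto the column space.
    """
    if X.size == 0:
        return np.empty((X.shape[0] if X.ndim == 2 else 0, 0))
    X = X - X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    keep = sd > 0
    if not np.any(keep):
        return np.empty((X.shape[0], 0))
    X = X[:, keep] / sd[keep]
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = s[0] * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    return U[:, :rank]


def _r2_from_basis(Yc: np.ndarray, Q: np.ndarray, ss_total: float) -> float:
    if Q.shape[1] == 0:
        return 0.0
    proj = Q.T @ Yc
    return float(np.sum(proj * proj) / ss_total)


def rda_r2(Yt, X) -> float:
    """Canonical R² of an RDA of the centred response on predictor block X.

    Equals SS(fitted)/SS(total) where the fit is the least-squares projection
    of each response column onto the column space of the centred X.  An empty
    block yields 0.  Raises when the model is saturated (``n`` sites no
    larger than the block rank plus one).
    """
    Yc = _as_matrix(Yt)
    Yc = Yc - Yc.mean(axis=0, keepdims=True)
    ss_total = float(np.sum(Yc * Yc))
    if ss_total == 0.0:
        raise ValueError("zero-variance response: all sites identical after transform")
    Q = _ortho_basis(_as_matrix(X))
    if Yc.shape[0] <= Q.shape[1] + 1:
        raise ValueError(
            f"saturated model: {Yc.shape[0]} sites for predictor rank {Q.shape[1]}"
        )
    return _r2_from_basis(Yc, Q, ss_total)


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel-adjusted R²: 1 − (1 − R²)(n − 1)/(n − m − 1).

    ``m`` is the number of (effective) predictors; ``m = 0`` returns ``r2``
    unchanged (the null model needs no correction).
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if m == 0:
        return float(r2)
    if n <= m + 1:
        raise ValueError(f"adjusted R2 undefined for n={n}, m={m}")
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - m - 1))


# ---------------------------------------------------------------------------
# variation partitioning
# ---------------------------------------------------------------------------

@dataclass
class VarpartResult:
    """The four adjusted fractions plus the three unadjusted canonical R²."""

    r2_env: float
    r2_space: float
    r2_full: float
    frac_a: float  # pure environment (adjusted)
    frac_b: float  # shared environment/space (adjusted)
    frac_c: float  # pure space (adjusted)
    frac_d: float  # residual (adjusted)
    n_sites: int
    m_env: int
    m_space: int
    negative_fractions: tuple[str, ...] = ()

    @property
    def explained_total(self) -> float:
        """Adjusted R² of the full model, = [a] + [b] + [c] = 1 − [d]."""
        return self.frac_a + self.frac_b + self.frac_c

    def component(self, name: str) -> float:
        if name == "explained_total":
            return self.explained_total
        if name in ("frac_a", "frac_b", "frac_c", "frac_d"):
            return getattr(self, name)
        raise KeyError(f"unknown component: {name!r}")


class _Bases:
    """Pre-computed orthonormal bases for the three nested models.

    The cascade and the null model re-fit the same predictor blocks against
    hundreds of reduced community matrices; factoring the blocks once makes
    each re-fit a pair of matrix multiplications.
    """

    __slots__ = ("Qx", "Qw", "Qxw", "n", "mx", "mw", "mxw")

    def __init__(self, X: np.ndarray, W: np.ndarray):
        X = _as_matrix(X)
        W = _as_matrix(W)
        n = X.shape[0] if X.size else W.shape[0]
        if X.size and W.size and X.shape[0] != W.shape[0]:
            raise ValueError("predictor blocks disagree on the number of sites")
        self.Qx = _ortho_basis(X)
        self.Qw = _ortho_basis(W)
        if X.size and W.size:
            XW = np.hstack([X, W])
        elif X.size:
            XW = X
        else:
            XW = W
        self.Qxw = _ortho_basis(XW)
        self.n = n
        self.mx = self.Qx.shape[1]
        self.mw = self.Qw.shape[1]
        self.mxw = self.Qxw.shape[1]

    def varpart(self, Yc: np.ndarray) -> VarpartResult:
        ss_total = float(np.sum(Yc * Yc))
        if ss_total == 0.0:
            raise ValueError("zero-variance response: all sites identical after transform")
        n = Yc.shape[0]
        if n <= self.mxw + 1:
            raise ValueError(
                f"saturated combined model: {n} sites for combined rank {self.mxw}"
            )
        r2x = _r2_from_basis(Yc, self.Qx, ss_total)
        r2w = _r2_from_basis(Yc, self.Qw, ss_total)
        r2xw = _r2_from_basis(Yc, self.Qxw, ss_total)
        A = adjusted_r2(r2x, n, self.mx)
        C = adjusted_r2(r2w, n, self.mw)
        T = adjusted_r2(r2xw, n, self.mxw)
        frac_a = T - C
        frac_c = T - A
        frac_b = A + C - T
        frac_d = 1.0 - T
        negs = tuple(
            name
            for name, val in (("frac_a", frac_a), ("frac_b", frac_b), ("frac_c", frac_c))
            if val < 0
        )
        return VarpartResult(
            r2_env=r2x,
            r2_space=r2w,
            r2_full=r2xw,
            frac_a=frac_a,
            frac_b=frac_b,
            frac_c=frac_c,
            frac_d=frac_d,
            n_sites=n,
            m_env=self.mx,
            m_space=self.mw,
            negative_fractions=negs,
        )


def varpart2(Yt, X, W) -> VarpartResult:
    """Two-block variation partitioning of Yt on environment X and space W.

    Returns the four adjusted fractions and the raw canonical R² of the three
    nested models.  Effective rank of each block is used as ``m`` in the
    Ezekiel adjustment, so duplicated or collinear columns are harmless.
    """
    Yc = _as_matrix(Yt)
    Yc = Yc - Yc.mean(axis=0, keepdims=True)
    bases = _Bases(_as_matrix(X), _as_matrix(W))
    if Yc.shape[0] != bases.n and bases.mxw > 0:
        raise ValueError("response and predictor blocks disagree on the number of sites")
    return bases.varpart(Yc)


class VariationPartitioning(BaseEstimator):
    """Environment/space variation partitioning as an estimator.

    Parameters
    ----------
    transform : {"hellinger", "presence_absence", "none"}
        Abundance transform applied to the community matrix before RDA.

    Attributes
    ----------
    result_ : VarpartResult
        Fractions and R² of the fitted partition.
    fractions_ : dict
        ``{"a": ..., "b": ..., "c": ..., "d": ...}`` adjusted fractions.
    """

    def __init__(self, transform: str = "hellinger"):
        self.transform = transform

    def fit(self, Y, env, space):
        """Partition community ``Y`` between predictor blocks ``env`` and ``space``."""
        Yt = transform_response(Y, mode=self.transform)
        self.result_ = varpart2(Yt, env, space)
        self.fractions_ = {
            "a": self.result_.frac_a,
            "b": self.result_.frac_b,
            "c": self.result_.frac_c,
            "d": self.result_.frac_d,
        }
        return self

    def score(self, *args) -> float:
        """Adjusted R² of the full (environment + space) model."""
        check_is_fitted(self)
        return self.result_.explained_total
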