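"""Penalized additive regression with data-driven smoothness.

Univariate effects are cubic P-splines: a B-spline basis of dimension ``k``
(quantile-placed interior knots) with a second-difference penalty on the
coefficients and a sum-to-zero constraint absorbed by a null-space
reparameterisation.  Bivariate isotropic effects (e.g. a single interacting
lon/lat surface, or a CEC x pH interaction) are low-rank radial smooths:
Gaussian radial basis functions on k-means centers over the standardised
plane plus unpenalised linear terms, ridge-penalised on the radial
coefficients.  One smoothing parameter per term is chosen by minimising
generalised cross-validation, GCV = n * RSS / (n - tr(A))^2, via coordinate
descent on a log-spaced grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import null_space
from sklearn.cluster import KMeans


class SmoothFitError(RuntimeError):
    """Raised when a smooth basis cannot be built (e.g. too few unique values)."""


@dataclass(frozen=True)
class SplineTerm:
    """Univariate cubic P-spline of one covariate with basis dimension k."""
    name: str
    k: int = 9


@dataclass(frozen=True)
class SurfaceTerm:
    """Isotropic bivariate radial smooth of two covariates, basis dimension k."""
    names: tuple[str, str]
    k: int = 50


def _spline_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    xc = np.clip(x, knots[0], knots[-1])  # flat extrapolation beyond the data
    return BSpline.design_matrix(xc, knots, 3).toarray()


class _FittedSpline:
    def __init__(self, x: np.ndarray, k: int, name: str):
        if len(np.unique(x)) < 4:
            raise SmoothFitError(f"covariate '{name}' has too few unique values "
                                 "for a spline basis")
        n_interior = k - 4  # basis dim = n_interior + degree + 1
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(x, qs)
        else:
            interior = np.array([])
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            raise SmoothFitError(f"covariate '{name}' is constant")
        self.knots = np.concatenate([[lo] * 4, interior, [hi] * 4])
        B = _spline_design(x, self.knots)
        # sum-to-zero constraint: reparameterise into the null space of the
        # column-mean functional so the term is identifiable beside the intercept
        C = B.mean(axis=0, keepdims=True)
        self.Z = null_space(C)
        D = np.diff(np.eye(B.shape[1]), 2, axis=0)
        self.penalty = self.Z.T @ D.T @ D @ self.Z

    def design(self, x: np.ndarray) -> np.ndarray:
        return _spline_design(x, self.knots) @ self.Z


class _FittedSurface:
    def __init__(self, xy: np.ndarray, k: int, seed: int = 0):
        self.mean = xy.mean(axis=0)
        self.sd = xy.std(axis=0)
        self.sd[self.sd == 0] = 1.0
        u = (xy - self.mean) / self.sd
        m = max(k - 2, 3)  # radial functions; 2 columns are the linear plane
        uniq = np.unique(u, axis=0)
        m = min(m, len(uniq))
        if m < 3:
            raise SmoothFitError("too few unique points for a surface smooth")
        km = KMeans(n_clusters=m, random_state=seed, n_init=2).fit(uniq)
        self.centers = km.cluster_centers_
        d = np.sqrt(((self.centers[:, None, :] - self.centers[None, :, :]) ** 2).sum(-1))
        h = np.median(d[np.triu_indices(m, 1)])
        self.h = float(h) if h > 0 else 1.0
        ncol = 2 + m
        self.colmeans = np.zeros(ncol)
        self.colmeans = self._raw_design(xy).mean(axis=0)
        P = np.eye(ncol)
        P[0, 0] = P[1, 1] = 0.0  # linear plane unpenalised
        self.penalty = P

    def _raw_design(self, xy: np.ndarray) -> np.ndarray:
        u = (xy - self.mean) / self.sd
        d2 = ((u[:, None, :] - self.centers[None, :, :]) ** 2).sum(-1)
        phi = np.exp(-d2 / (2.0 * self.h ** 2))
        return np.column_stack([u, phi])

    def design(self, xy: np.ndarray) -> np.ndarray:
        return self._raw_design(xy) - self.colmeans


class PenalizedAdditiveModel:
    """Additive model y = b0 + sum_j f_j(x_j) + f_s(u, v) + e.

    Parameters
    ----------
    terms
        Sequence of :class:`SplineTerm` / :class:`SurfaceTerm`.
    lambda_grid
        Candidate smoothing parameters per term (log-spaced by default).
    """

    def __init__(self, terms, lambda_grid: np.ndarray | None = None):
        self.terms = list(terms)
        self.lambda_grid = (np.logspace(-4, 6, 11) if lambda_grid is None
                            else np.asarray(lambda_grid, dtype=float))
        self.diagnostics: dict = {}

    # -- design assembly ---------------------------------------------------
    def _build(self, X: pd.DataFrame, fit: bool) -> np.ndarray:
        blocks = [np.ones((len(X), 1))]
        if fit:
            self._fitted_terms = []
            for t in self.terms:
                if isinstance(t, SplineTerm):
                    ft = _FittedSpline(X[t.name].to_numpy(dtype=float), t.k, t.name)
                else:
                    ft = _FittedSurface(X[list(t.names)].to_numpy(dtype=float), t.k)
                self._fitted_terms.append(ft)
        for t, ft in zip(self.terms, self._fitted_terms):
            if isinstance(t, SplineTerm):
                blocks.append(ft.design(X[t.name].to_numpy(dtype=float)))
            else:
                blocks.append(ft.design(X[list(t.names)].to_numpy(dtype=float)))
        self._block_sizes = [b.shape[1] for b in blocks]
        return np.hstack(blocks)

    def _stack_penalty(self, lambdas: np.ndarray) -> np.ndarray:
        p = sum(self._block_sizes)
        S = np.zeros((p, p))
        offset = self._block_sizes[0]
        for lam, ft, sz in zip(lambdas, self._fitted_terms, self._block_sizes[1:]):
            S[offset:offset + sz, offset:offset + sz] = lam * ft.penalty
            offset += sz
        return S

    # -- fitting -----------------------------------------------------------
    def fit(self, X: pd.DataFrame, y) -> "PenalizedAdditiveModel":
        y = np.asarray(y, dtype=float)
        self.feature_names = list(X.columns)
        Xd = self._build(X, fit=True)
        n, p = Xd.shape
        XtX = Xd.T @ Xd + 1e-9 * np.eye(p)
        Xty = Xd.T @ y

        def gcv(lams: np.ndarray) -> float:
            S = self._stack_penalty(lams)
            try:
                M = np.linalg.solve(XtX + S, np.column_stack([Xty, XtX]))
            except np.linalg.LinAlgError:
                return np.inf
            beta, A = M[:, 0], M[:, 1:]
            rss = float(((y - Xd @ beta) ** 2).sum())
            edf = np.trace(A)
            denom = max(n - edf, 1e-6)
            return n * rss / denom ** 2

        nt = len(self.terms)
        lams = np.full(nt, 1.0)
        best = gcv(lams)
        for _ in range(2):  # coordinate-descent sweeps over the grid
            for j in range(nt):
                for cand in self.lambda_grid:
                    trial = lams.copy()
                    trial[j] = cand
                    val = gcv(trial)
                    if val < best:
                        best, lams = val, trial
        S = self._stack_penalty(lams)
        self.beta = np.linalg.solve(XtX + S, Xty)
        A = np.linalg.solve(XtX + S, XtX)
        self.diagnostics = {
            "gcv": best,
            "lambdas": dict(zip([getattr(t, "name", getattr(t, "names", "?"))
                                 for t in self.terms], lams)),
            "edf": float(np.trace(A)),
            "criterion": "GCV",
        }
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xd = self._build(X[self.feature_names], fit=False)
        return Xd @ self.beta

    def term_contributions(self, X: pd.DataFrame) -> dict:
        """Per-term additive contributions f_j(x) (intercept excluded)."""
        Xd = self._build(X[self.feature_names], fit=False)
        out = {}
        offset = self._block_sizes[0]
        for t, sz in zip(self.terms, self._block_sizes[1:]):
            name = getattr(t, "name", None) or "x".join(t.names)
            out[name] = Xd[:, offset:offset + sz] @ self.beta[offset:offset + sz]
            offset += sz
        return out
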