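"""Multi-criteria performance index via factor analysis.

Seven standardized indicators (rice equivalent yield, partial N and K2O
productivity, energy efficiency, benefit-cost ratio, partial GHG footprint,
hired-labor energy productivity) are reduced to a single latent score per
household x system observation: principal-component extraction from the
correlation matrix, varimax rotation (the identity when one factor is
retained), and regression (Thurstone) factor scores.  Sampling adequacy is
checked with the Kaiser-Meyer-Olkin measure.  Total energy production is
excluded because most efficiency indicators already carry it in their
numerator.

Fitting is per stratum: polder and non-polder households get separate
models, and standardization is within stratum.

Sign indeterminacy of the first factor is resolved by forcing the partial-N
-productivity loading positive, which makes the GHG-footprint loading come
out negative on efficiency-structured data: higher scores mean better
overall performance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .indicators import SEVEN_INDICATORS


def kmo(correlation: np.ndarray) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    Returns ``(overall, per_variable)`` with all values in [0, 1].  The
    anti-image (partial) correlations ``q_ij`` are obtained from the
    inverse correlation matrix; a singular matrix falls back to the
    pseudo-inverse with a warning.

    overall MSA = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j,
    and the per-variable analogue sums over each row.
    """
    R = np.asarray(correlation, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p) or p < 2:
        raise ValueError("correlation matrix must be square with p >= 2")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    try:
        inv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        warnings.warn("singular correlation matrix: using pseudo-inverse")
        inv = np.linalg.pinv(R)
    d = 1.0 / np.sqrt(np.diag(inv))
    partial = -inv * np.outer(d, d)
    np.fill_diagonal(partial, 0.0)
    r2 = R**2
    np.fill_diagonal(r2, 0.0)
    q2 = partial**2
    per_variable = r2.sum(axis=1) / (r2.sum(axis=1) + q2.sum(axis=1))
    overall = r2.sum() / (r2.sum() + q2.sum())
    return float(overall), per_variable


def pca_loadings(
    correlation: np.ndarray, n_factors: int
) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component loadings from a correlation matrix.

    Returns ``(loadings, eigenvalues)`` where column j of ``loadings`` is
    the j-th eigenvector scaled by the square root of its eigenvalue.
    """
    R = np.asarray(correlation, dtype=float)
    p = R.shape[0]
    if n_factors < 1 or n_factors > p:
        raise ValueError(f"n_factors={n_factors} outside [1, {p}]")
    eigenvalues, eigenvectors = np.linalg.eigh(R)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order][:n_factors]
    eigenvectors = eigenvectors[:, order][:, :n_factors]
    loadings = eigenvectors * np.sqrt(np.clip(eigenvalues, 0.0, None))
    return loadings, eigenvalues


def extract_pca(
    X: np.ndarray, n_factors: int
) -> tuple[np.ndarray, np.ndarray]:
    """PCA extraction on standardized data: ``(loadings, scores)``.

    ``X`` must already be standardized per variable (z-scores).  Scores are
    regression (Thurstone) scores on the standardized variables, which for
    principal components reduce to ``Z v / sqrt(eigenvalue)`` and have unit
    variance.
    """
    Z = np.asarray(X, dtype=float)
    R = np.corrcoef(Z, rowvar=False)
    if Z.shape[1] == 1:
        return np.ones((1, 1)), Z.copy()
    loadings, _ = pca_loadings(R, n_factors)
    scores = regression_scores(Z, R, loadings)
    return loadings, scores


def regression_scores(
    Z: np.ndarray, R: np.ndarray, loadings: np.ndarray
) -> np.ndarray:
    """Thurstone regression factor scores: ``Z R^{-1} L``."""
    try:
        weights = np.linalg.solve(R, loadings)
    except np.linalg.LinAlgError:
        warnings.warn("singular correlation matrix: using pseudo-inverse")
        weights = np.linalg.pinv(R) @ loadings
    return Z @ weights


def varimax_criterion(loadings: np.ndarray, kaiser: bool = True) -> float:
    """The raw varimax objective (sum of column variances of squared loadings)."""
    L = np.asarray(loadings, dtype=float)
    if kaiser:
        h = np.sqrt((L**2).sum(axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    p = L.shape[0]
    L2 = L**2
    return float(((L2**2).sum(axis=0) - (L2.sum(axis=0) ** 2) / p).sum() / p)


def varimax(
    loadings: np.ndarray,
    kaiser: bool = True,
    max_iter: int = 1000,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation with Kaiser row normalization.

    Returns ``(rotated_loadings, rotation_matrix)``; for a single factor
    the rotation is the identity.  Non-convergence returns the best iterate
    with a warning.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    h = np.sqrt((L**2).sum(axis=1))
    if kaiser:
        h_safe = np.where(h == 0, 1.0, h)
        L = L / h_safe[:, None]
    R = np.eye(k)
    d = 0.0
    converged = False
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        )
        R = u @ vt
        d_new = s.sum()
        if d_new < d * (1 + tol):
            converged = True
            break
        d = d_new
    if not converged:
        warnings.warn(f"varimax did not converge in {max_iter} iterations")
    rotated = L @ R
    if kaiser:
        rotated = rotated * h_safe[:, None]
    return rotated, R


@dataclass
class IndexModel:
    """Fitted multi-criteria performance index for one stratum."""

    stratum: str
    indicator_names: list[str]
    correlation_matrix: pd.DataFrame
    kmo_overall: float
    kmo_per_variable: pd.Series
    loadings: pd.DataFrame
    ss_loadings: np.ndarray
    proportion_variance: np.ndarray
    rmsr: float
    scores: pd.Series
    n_factors_retained: int
    n_observations: int


class SampleSizeError(ValueError):
    """Too few complete rows to fit the index."""


class PerformanceIndex(BaseEstimator, TransformerMixin):
    """First-factor multi-criteria performance index (sklearn-style).

    Fit on an indicator table (or bare matrix) for a single stratum; the
    transform returns one index score per row (NaN for rows with any
    masked indicator).

    Parameters
    ----------
    n_factors : int
        Factors retained; the index uses the first.  Varimax rotation is
        applied when ``n_factors >= 2`` (a no-op for 1).
    indicator_names : list of str
        Columns used when fitting from a DataFrame.
    min_rows : int
        Sample-adequacy guard: refuse to fit on fewer complete rows.
    anchor : str
        Variable whose first-factor loading is forced positive to resolve
        sign indeterminacy.
    score_method : {"regression", "bartlett"}
        Factor-score estimator.
    """

    def __init__(
        self,
        n_factors: int = 1,
        indicator_names: list[str] | None = None,
        min_rows: int = 30,
        anchor: str = "pnp",
        score_method: str = "regression",
    ):
        self.n_factors = n_factors
        self.indicator_names = indicator_names
        self.min_rows = min_rows
        self.anchor = anchor
        self.score_method = score_method

    def _matrix(self, X) -> tuple[pd.DataFrame, list[str]]:
        names = self.indicator_names or SEVEN_INDICATORS
        if isinstance(X, pd.DataFrame):
            missing = [c for c in names if c not in X.columns]
            if missing:
                raise ValueError(f"indicator columns missing: {missing}")
            return X[names].astype(float), names
        X = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])] \
            if self.indicator_names is None else names
        return pd.DataFrame(X, columns=names), names

    def fit(self, X, y=None) -> "PerformanceIndex":
        data, names = self._matrix(X)
        complete = data.dropna()
        if len(complete) < self.min_rows:
            raise SampleSizeError(
                f"{len(complete)} complete rows < min_rows={self.min_rows}"
            )
        if self.score_method not in ("regression", "bartlett"):
            raise ValueError(f"unknown score_method {self.score_method!r}")
        Z = complete.to_numpy()
        self.mean_ = Z.mean(axis=0)
        self.std_ = Z.std(axis=0, ddof=0)
        if np.any(self.std_ == 0):
            bad = [n for n, s in zip(names, self.std_) if s == 0]
            raise ValueError(f"constant indicator(s): {bad}")
        Zs = (Z - self.mean_) / self.std_
        R = np.corrcoef(Zs, rowvar=False)
        self.correlation_ = pd.DataFrame(R, index=names, columns=names)
        overall, per_var = kmo(R)
        self.kmo_ = overall
        self.kmo_per_variable_ = pd.Series(per_var, index=names)
        loadings, eigenvalues = pca_loadings(R, self.n_factors)
        if self.n_factors >= 2:
            loadings, _ = varimax(loadings)
        # Resolve sign indeterminacy per factor via the anchor variable
        # (fall back to the largest-magnitude loading).
        anchor_idx = names.index(self.anchor) if self.anchor in names else None
        for j in range(loadings.shape[1]):
            ref = (
                loadings[anchor_idx, j]
                if anchor_idx is not None
                else loadings[np.argmax(np.abs(loadings[:, j])), j]
            )
            if ref < 0:
                loadings[:, j] = -loadings[:, j]
        self.loadings_ = pd.DataFrame(
            loadings,
            index=names,
            columns=[f"factor{j + 1}" for j in range(loadings.shape[1])],
        )
        self.ss_loadings_ = (loadings**2).sum(axis=0)
        self.proportion_variance_ = self.ss_loadings_ / len(names)
        residual = R - loadings @ loadings.T
        off = ~np.eye(len(names), dtype=bool)
        self.rmsr_ = float(np.sqrt((residual[off] ** 2).mean()))
        self.n_features_in_ = len(names)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        return self

    def _score_matrix(self, Zs: np.ndarray) -> np.ndarray:
        L = self.loadings_.to_numpy()
        R = self.correlation_.to_numpy()
        if self.score_method == "regression":
            return regression_scores(Zs, R, L)
        # Bartlett weighted-least-squares scores.
        psi = np.clip(1.0 - (L**2).sum(axis=1), 1e-6, None)
        W = L / psi[:, None]
        return Zs @ W @ np.linalg.inv(L.T @ W)

    def transform(self, X) -> np.ndarray:
        data, _ = self._matrix(X)
        Zs = (data.to_numpy() - self.mean_) / self.std_
        scores = np.full((len(data), self.loadings_.shape[1]), np.nan)
        ok = ~np.isnan(Zs).any(axis=1)
        if ok.any():
            scores[ok] = self._score_matrix(Zs[ok])
        return scores

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def build_index(
    indicator_rows: pd.DataFrame,
    stratum: str,
    n_factors: int = 1,
    min_rows: int = 30,
) -> IndexModel:
    """Fit the performance index for one stratum of an indicator table.

    The returned scores are aligned to the input rows of that stratum
    (NaN where any of the seven indicators is masked).
    """
    sub = indicator_rows[indicator_rows["stratum"] == stratum]
    if sub.empty:
        raise SampleSizeError(f"no rows for stratum {stratum!r}")
    est = PerformanceIndex(n_factors=n_factors, min_rows=min_rows)
    est.fit(sub)
    scores = est.transform(sub)[:, 0]
    return IndexModel(
        stratum=stratum,
        indicator_names=list(est.feature_names_in_),
        correlation_matrix=est.correlation_,
        kmo_overall=est.kmo_,
        kmo_per_variable=est.kmo_per_variable_,
        loadings=est.loadings_,
        ss_loadings=est.ss_loadings_,
        proportion_variance=est.proportion_variance_,
        rmsr=est.rmsr_,
        scores=pd.Series(scores, index=sub.index, name="mcpi"),
        n_factors_retained=n_factors,
        n_observations=int(len(sub.dropna(subset=SEVEN_INDICATORS))),
    )
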