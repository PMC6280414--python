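"""Feature standardization and PCA with a cumulative-contribution cutoff.

The pipeline z-scores every feature (training mean, sample standard
deviation with ddof=1), forms the correlation matrix R = X~'X~/(n-1), and
keeps the smallest number M' of principal axes whose cumulative eigenvalue
contribution reaches a threshold (default 85%).  Test data is always
transformed with the training-set statistics and eigenvectors; nothing is
refit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DegenerateFeatureError, InsufficientDataError

_EPS = 1e-12


@dataclass
class PCAModel:
    """Fitted standardize+PCA front end.

    Attributes
    ----------
    mu, delta : ndarray, shape (M,)
        Per-feature training means and sample standard deviations (ddof=1).
    eigenvalues : ndarray, shape (M,)
        Eigenvalues of the correlation matrix, sorted descending, clipped
        at 0 for the contribution sums.
    eigenvectors : ndarray, shape (M, M)
        Orthonormal eigenvectors as columns, same order as eigenvalues.
        Sign convention: the largest-magnitude entry of each column is
        positive, for reproducibility across BLAS builds.
    threshold : float
        Cumulative contribution-rate cutoff in (0, 1].
    n_components : int
        M': smallest r with sum(lambda[:r])/sum(lambda) >= threshold.
    """

    mu: np.ndarray
    delta: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    threshold: float
    n_components: int

    @property
    def contributions(self) -> np.ndarray:
        """Per-component contribution rates lambda_k / sum(lambda)."""
        total = self.eigenvalues.sum()
        return self.eigenvalues / total


def standardize(X: np.ndarray, mu: np.ndarray | None = None,
                delta: np.ndarray | None = None) -> np.ndarray:
    """Z-score columns: (x - mu) / delta with sample std (ddof=1).

    When ``mu``/``delta`` are given (transforming test data with training
    statistics) they are used as-is; otherwise they are estimated from X.

    Raises
    ------
    InsufficientDataError
        Fewer than 2 rows (sample std undefined).
    DegenerateFeatureError
        A constant column, naming the offending column index.
    """
    X = np.asarray(X, dtype=float)
    if mu is None or delta is None:
        if X.shape[0] < 2:
            raise InsufficientDataError(
                f"standardization needs >= 2 samples, got {X.shape[0]}"
            )
        mu = X.mean(axis=0)
        delta = X.std(axis=0, ddof=1)
        dead = np.flatnonzero(delta < _EPS)
        if dead.size:
            raise DegenerateFeatureError(
                f"constant feature column(s) {dead.tolist()}: zero variance, "
                "cannot be standardized"
            )
    return (X - mu) / delta


def pca_fit(X_std: np.ndarray, threshold: float = 0.85) -> PCAModel:
    """Eigen-decompose the correlation matrix of standardized data.

    ``X_std`` must already be standardized (unit-diagonal covariance);
    eigenvalues then sum to M and the contribution rate of component k is
    lambda_k / M.

    M' is the smallest r whose cumulative contribution reaches
    ``threshold``.
    """
    X_std = np.asarray(X_std, dtype=float)
    n = X_std.shape[0]
    if n < 2:
        raise InsufficientDataError("PCA needs >= 2 samples")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    R = X_std.T @ X_std / (n - 1)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    if total < _EPS:
        raise DegenerateFeatureError("rank-0 input: all eigenvalues vanish")
    # deterministic sign: largest-|entry| of each eigenvector made positive
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])])
    flip[flip == 0] = 1.0
    evecs = evecs * flip
    cum = np.cumsum(evals) / total
    n_components = int(np.searchsorted(cum, threshold - _EPS) + 1)
    n_components = min(n_components, evals.size)
    # training statistics live on the model so test rows reuse them
    mu = X_std.mean(axis=0)  # ~0 by construction; stored for completeness
    delta = X_std.std(axis=0, ddof=1)
    return PCAModel(mu=mu, delta=delta, eigenvalues=evals, eigenvectors=evecs,
                    threshold=threshold, n_components=n_components)


def pca_transform(X_std: np.ndarray, model: PCAModel) -> np.ndarray:
    """Project standardized rows onto the first M' principal axes."""
    X_std = np.atleast_2d(np.asarray(X_std, dtype=float))
    if X_std.shape[1] != model.eigenvectors.shape[0]:
        raise ValueError(
            f"dimension mismatch: data has {X_std.shape[1]} features, "
            f"model expects {model.eigenvectors.shape[0]}"
        )
    return X_std @ model.eigenvectors[:, : model.n_components]


@dataclass
class Preprocessor:
    """Standardize + PCA fitted on training data, reusable on test data."""

    threshold: float = 0.85
    mu: np.ndarray | None = None
    delta: np.ndarray | None = None
    pca: PCAModel | None = None

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise InsufficientDataError("need >= 2 training samples")
        self.mu = X.mean(axis=0)
        self.delta = X.std(axis=0, ddof=1)
        dead = np.flatnonzero(self.delta < _EPS)
        if dead.size:
            raise DegenerateFeatureError(
                f"constant feature column(s) {dead.tolist()}"
            )
        X_std = (X - self.mu) / self.delta
        self.pca = pca_fit(X_std, self.threshold)
        return pca_transform(X_std, self.pca)

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.pca is None:
            raise RuntimeError("Preprocessor not fitted")
        X_std = (np.atleast_2d(np.asarray(X, dtype=float)) - self.mu) / self.delta
        return pca_transform(X_std, self.pca)

    @property
    def n_components(self) -> int:
        if self.pca is None:
            raise RuntimeError("Preprocessor not fitted")
        return self.pca.n_components


def write_components(Z: np.ndarray, path, sep: str = ",") -> None:
    """Write a principal-component matrix with PC1..PCM' header."""
    cols = [f"PC{i + 1}" for i in range(Z.shape[1])]
    pd.DataFrame(Z, columns=cols).to_csv(path, sep=sep, index=False)
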