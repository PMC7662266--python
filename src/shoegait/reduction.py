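"""Feature standardization and PCA with the 99% explained-variance rule.

Features are standardized to zero mean and unit variance using training
statistics only (zero-variance features get scale 1 with a warning), then
projected onto principal axes of the empirical covariance.  The number of
components is the smallest k whose cumulative explained-variance ratio
reaches a threshold, 0.99 by default.

Both models are fitted per training fold in cross-validation so held-out
participants never leak into the statistics; a fixed global component
count can be requested instead for component-sweep experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA


@dataclass
class StandardizationModel:
    """Per-feature training mean and standard deviation."""

    mean_: np.ndarray = field(default=None)  # type: ignore[assignment]
    scale_: np.ndarray = field(default=None)  # type: ignore[assignment]

    def fit(self, X: np.ndarray) -> "StandardizationModel":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training rows")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            warnings.warn(
                f"{int((sd == 0).sum())} zero-variance feature(s); scale set "
                "to 1", stacklevel=2,
            )
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_


def fit_standardizer(X: np.ndarray) -> StandardizationModel:
    return StandardizationModel().fit(X)


def apply_standardizer(model: StandardizationModel, X: np.ndarray) -> np.ndarray:
    return model.transform(X)


class PCAModel:
    """Principal axes of standardized features, deterministic sign.

    Thin wrapper around a full-rank SVD-based PCA; each axis is oriented
    so its largest-magnitude loading is positive, making scores
    reproducible across linear-algebra backends.
    """

    def __init__(self) -> None:
        self._pca: PCA | None = None

    def fit(self, X: np.ndarray) -> "PCAModel":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2 or X.shape[1] < 1:
            raise ValueError("need >= 2 rows and >= 1 feature")
        pca = PCA(svd_solver="full")
        pca.fit(X)
        comp = pca.components_
        flip = np.sign(comp[np.arange(comp.shape[0]),
                            np.argmax(np.abs(comp), axis=1)])
        pca.components_ = comp * flip[:, None]
        self._pca = pca
        return self

    @property
    def components_(self) -> np.ndarray:
        return self._pca.components_

    @property
    def mean_(self) -> np.ndarray:
        return self._pca.mean_

    @property
    def explained_variance_(self) -> np.ndarray:
        return self._pca.explained_variance_

    @property
    def explained_variance_ratio_(self) -> np.ndarray:
        return self._pca.explained_variance_ratio_

    @property
    def cumulative_explained_variance_(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio_)

    @property
    def k_max(self) -> int:
        return self.components_.shape[0]

    def n_components_for_variance(self, threshold: float = 0.99) -> int:
        """Smallest k whose cumulative explained-variance ratio >= threshold."""
        if not 0.0 < threshold <= 1.0:
            raise ValueError("threshold must lie in (0, 1]")
        cum = self.cumulative_explained_variance_
        idx = np.searchsorted(cum, threshold - 1e-12)
        return int(min(idx + 1, self.k_max))

    def transform(self, X: np.ndarray, k: int | None = None) -> np.ndarray:
        """Scores on the first k axes (all axes when k is None)."""
        k = self.k_max if k is None else k
        if k <= 0:
            raise ValueError("k must be positive")
        if k > self.k_max:
            raise ValueError(f"k={k} exceeds fitted rank {self.k_max}")
        Xc = np.asarray(X, dtype=float) - self.mean_
        return Xc @ self.components_[:k].T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        k = scores.shape[1]
        return scores @ self.components_[:k] + self.mean_


def fit_pca(X: np.ndarray) -> PCAModel:
    return PCAModel().fit(X)


def explained_variance_table(model: PCAModel):
    """(component, ratio, cumulative) rows for explained-variance curves."""
    import pandas as pd

    return pd.DataFrame({
        "component": np.arange(1, model.k_max + 1),
        "explained_variance_ratio": model.explained_variance_ratio_,
        "cumulative_explained_variance": model.cumulative_explained_variance_,
    })
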