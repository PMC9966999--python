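"""PCA chemical space and bounding-box applicability domain.

Descriptors are z-score standardized before the eigendecomposition (the six
drug-likeness descriptors carry incommensurate units: Da, A^2, counts), so
this is correlation-matrix PCA. Component signs are fixed so the
largest-magnitude loading in each component is positive, which makes the
loadings report deterministic; published loading tables are matched up to a
per-component sign flip.

The applicability domain (AD) is the axis-aligned bounding box of the
training-set scores over the leading components: a query molecule is
in-domain iff each of its used component scores lies inside the closed
training interval (optionally expanded by a fractional margin).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import ConfigurationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PCAModel:
    feature_names: tuple[str, ...]
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray  # (n_features, n_components); columns are components
    explained_variance_ratio: np.ndarray
    dropped_features: tuple[str, ...] = ()

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def cumulative_variance(self) -> np.ndarray:
        """Running cumulative explained variance, in percent."""
        return np.cumsum(self.explained_variance_ratio) * 100.0

    def loadings_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.loadings,
            index=list(self.feature_names),
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )
        df.loc["explained_variance_%"] = self.explained_variance_ratio * 100.0
        df.loc["cumulative_variance_%"] = self.cumulative_variance
        return df


def fit_pca(
    X: np.ndarray | pd.DataFrame,
    n_components: int | None = None,
    feature_names: Sequence[str] | None = None,
) -> PCAModel:
    """Fit correlation-matrix PCA on an (n, d) descriptor matrix.

    Constant (zero-variance) columns are dropped with a warning. Components
    are ordered by explained variance; signs fixed as documented above.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ConfigurationError("need an (n>=2, d) matrix")
    if np.isnan(X).any():
        raise ConfigurationError("missing values are not allowed")
    d = X.shape[1]
    names = tuple(feature_names) if feature_names else tuple(f"x{i}" for i in range(d))

    scales = X.std(axis=0, ddof=1)
    keep = scales > 0
    dropped = tuple(n for n, k in zip(names, keep) if not k)
    if dropped:
        log.warning("dropping constant descriptor columns: %s", dropped)
    Xk = X[:, keep]
    means = Xk.mean(axis=0)
    sk = scales[keep]
    Z = (Xk - means) / sk

    k = min(n_components or Xk.shape[1], Xk.shape[1])
    pca = PCA(n_components=k)
    pca.fit(Z)
    loadings = pca.components_.T.copy()  # (d, k)
    # deterministic sign: largest-|weight| entry of each component positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
    return PCAModel(
        feature_names=tuple(n for n, kp in zip(names, keep) if kp),
        means=means,
        scales=sk,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        dropped_features=dropped,
    )


def project(model: PCAModel, X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Project descriptor rows into the fitted component space."""
    if isinstance(X, pd.DataFrame):
        missing = [c for c in model.feature_names if c not in X.columns]
        if missing:
            raise ConfigurationError(f"descriptor-set mismatch; missing {missing}")
        X = X[list(model.feature_names)].to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.feature_names):
        raise ConfigurationError(
            f"expected {len(model.feature_names)} descriptors, got {X.shape[1]}"
        )
    return ((X - model.means) / model.scales) @ model.loadings


@dataclass(frozen=True)
class BoundingBox:
    lower: np.ndarray
    upper: np.ndarray
    margin: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper):
            raise ConfigurationError("bounding box requires lower <= upper")

    @property
    def n_components(self) -> int:
        return int(self.lower.size)


def bounding_box(
    training_scores: np.ndarray, n_components: int | None = None, margin: float = 0.0
) -> BoundingBox:
    """Axis-aligned box spanning the training scores on the leading components.

    ``margin`` expands each interval by ``margin * (upper - lower)`` on both
    sides (a degenerate zero-range component stays degenerate).
    """
    S = np.atleast_2d(np.asarray(training_scores, dtype=float))
    if S.shape[0] < 1:
        raise ConfigurationError("need at least one training score row")
    if n_components is not None:
        S = S[:, :n_components]
    lo = S.min(axis=0)
    hi = S.max(axis=0)
    span = hi - lo
    return BoundingBox(lower=lo - margin * span, upper=hi + margin * span, margin=margin)


def components_for_coverage(model: PCAModel, coverage: float = 0.9) -> int:
    """Smallest k whose cumulative explained variance reaches ``coverage``."""
    cum = np.cumsum(model.explained_variance_ratio)
    return int(np.searchsorted(cum, coverage - 1e-12) + 1)


def check_in_domain(box: BoundingBox, scores: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-row in-domain flags plus the coverage fraction.

    A row is in-domain iff every used component score lies inside the closed
    interval. Empty input yields an empty flag array and NaN coverage.
    """
    S = np.atleast_2d(np.asarray(scores, dtype=float))
    if S.size == 0:
        return np.zeros(0, dtype=bool), math.nan
    if S.shape[1] < box.n_components:
        raise ConfigurationError(
            f"scores have {S.shape[1]} components, box needs {box.n_components}"
        )
    S = S[:, : box.n_components]
    flags = np.all((S >= box.lower) & (S <= box.upper), axis=1)
    return flags, float(flags.mean())
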