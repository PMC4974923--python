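"""PCA feature selection with the 95% cumulative-variance criterion.

Features are z-scored (population σ) before PCA — the 114 features mix
unitless shape statistics with m/s² spectral amplitudes, so PCA on the
correlation matrix is the defensible reading, and it makes "factor
loading" well defined as the correlation between an original feature and
a component score.  The number of retained components is the smallest m
whose cumulative explained-variance share reaches the threshold (default
0.95).  The loading report lists, per retained component, the original
features with |loading| ≥ a cutoff (default 0.71, i.e. the component
captures ≥ ~50% of that feature's variance), tagged with their feature
family (temporal / frequency / temporal-frequency).

Component signs are fixed so each component's largest-magnitude loading
is positive; PCA signs are otherwise arbitrary and determinism requires
a rule.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import DegeneracyError, SchemaError

def feature_family(name: str) -> str:
    """Family of a canonical feature name; 'other' for foreign columns."""
    suffix = name.split("_", 1)[1] if "_" in name else name
    if suffix in ("skewness", "kurtosis", "std", "correlation"):
        return "temporal"
    if suffix in ("psd_mean", "psd_std"):
        return "frequency"
    if suffix.startswith("fft_"):
        return "temporal-frequency"
    return "other"


@dataclass(frozen=True)
class SelectionModel:
    """Fitted PCA state for the 114-dimensional feature space."""

    feature_names: tuple[str, ...]
    means: np.ndarray  # fit-time column means
    sigmas: np.ndarray  # fit-time population stds (0 kept as-is; see transform)
    components: np.ndarray  # (n_retained, n_features) orthonormal directions
    explained_variance_shares: np.ndarray  # all components, non-increasing
    n_retained: int
    load_matrix: np.ndarray  # (n_features, n_retained), entries in [-1, 1]
    threshold: float = 0.95

    @property
    def cumulative_share(self) -> float:
        return float(self.explained_variance_shares[: self.n_retained].sum())


def _standardize(X: np.ndarray, means: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    safe = np.where(sigmas == 0.0, 1.0, sigmas)
    Z = (X - means) / safe
    Z[:, sigmas == 0.0] = 0.0  # constant columns carry no information
    return Z


def fit_select(features: pd.DataFrame, threshold: float = 0.95) -> SelectionModel:
    """Fit PCA on z-scored features and pick the 95%-variance prefix.

    Parameters
    ----------
    features
        One row per segment, one named column per feature.
    threshold
        Cumulative explained-variance fraction to reach (default 0.95).
    """
    X = features.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise DegeneracyError(f"need >= 2 rows to fit, got {X.shape[0]}")
    means = X.mean(axis=0)
    sigmas = X.std(axis=0)
    if np.all(sigmas == 0.0):
        raise DegeneracyError("all feature columns are constant")
    Z = _standardize(X, means, sigmas)

    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(Z)
    shares = pca.explained_variance_ratio_
    cumulative = np.cumsum(shares)
    n_retained = int(np.searchsorted(cumulative, threshold) + 1)
    n_retained = min(n_retained, len(shares))

    components = pca.components_[:n_retained].copy()
    scores = scores[:, :n_retained].copy()

    # factor loadings = correlation(original standardized column, score)
    load = np.zeros((X.shape[1], n_retained))
    score_sd = scores.std(axis=0)
    col_sd = Z.std(axis=0)
    for k in range(n_retained):
        if score_sd[k] == 0.0:
            continue
        cov = (Z - Z.mean(axis=0)).T @ (scores[:, k] - scores[:, k].mean()) / Z.shape[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            lk = cov / (col_sd * score_sd[k])
        lk[col_sd == 0.0] = 0.0
        load[:, k] = np.clip(lk, -1.0, 1.0)

    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(n_retained):
        j = int(np.argmax(np.abs(load[:, k])))
        if load[j, k] < 0:
            load[:, k] *= -1.0
            components[k] *= -1.0

    return SelectionModel(
        feature_names=tuple(features.columns),
        means=means,
        sigmas=sigmas,
        components=components,
        explained_variance_shares=shares,
        n_retained=n_retained,
        load_matrix=load,
        threshold=threshold,
    )


def transform(model: SelectionModel, features: pd.DataFrame) -> np.ndarray:
    """Project new rows onto the retained components (center, scale, dot)."""
    got = set(features.columns)
    want = set(model.feature_names)
    if got != want:
        missing = sorted(want - got)
        extra = sorted(got - want)
        raise SchemaError(f"feature columns differ: missing={missing}, extra={extra}")
    X = features[list(model.feature_names)].to_numpy(dtype=float)
    Z = _standardize(X, model.means, model.sigmas)
    return Z @ model.components.T


def loading_report(
    model: SelectionModel, cutoff: float = 0.71
) -> dict[int, list[dict]]:
    """Per retained component, the original features with |loading| ≥ cutoff.

    Entries are sorted by |loading| descending and carry the feature
    family so the dominant feature kinds can be read off per component.
    """
    report: dict[int, list[dict]] = {}
    for k in range(model.n_retained):
        col = model.load_matrix[:, k]
        idx = np.flatnonzero(np.abs(col) >= cutoff)
        order = idx[np.argsort(-np.abs(col[idx]), kind="stable")]
        report[k] = [
            {
                "feature": model.feature_names[j],
                "loading": float(col[j]),
                "family": feature_family(model.feature_names[j]),
            }
            for j in order
        ]
    return report
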