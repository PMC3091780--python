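"""PCA-based discrimination diagnostics for spike-in panel experiments.

Two views of the same normalised expression matrix are used:

* **conditions mode** — observations are arrays (samples), variables are
  features; separation of the panels along PC1 indicates that the condition
  difference dominates technical run-to-run noise.
* **entities mode** — the matrix is transposed so observations are features;
  standards with different spike ratios form distinct clusters.

The matrix is mean-centred and (by default) scaled to unit variance per
variable; components come from an SVD with a fixed sign convention (each
component's largest-magnitude loading is positive) so results are exactly
reproducible.  Group separation is quantified as the mean silhouette width
over the first two components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .microarray import QCError

__all__ = ["PcaResult", "pca", "group_separation"]


@dataclass
class PcaResult:
    """Scores, loadings and the full explained-variance spectrum."""

    scores: pd.DataFrame  # observations x kept components
    loadings: pd.DataFrame  # variables x kept components
    variance_fraction: np.ndarray  # all possible components; sums to 1
    mode: str
    n_components: int

    def explained(self, k: int) -> float:
        """Variance fraction captured by component k (1-based)."""
        return float(self.variance_fraction[k - 1])


def pca(
    matrix: pd.DataFrame,
    mode: str = "conditions",
    n_components: int = 4,
    center: bool = True,
    scale: bool = True,
) -> PcaResult:
    """Principal component analysis of an observations x variables frame.

    The input is always oriented arrays x features.  In ``conditions`` mode
    it is analysed as given (observations = arrays); in ``entities`` mode it
    is transposed so observations are features and scaling applies across
    arrays.  Zero-variance variables are dropped with a warning when
    scaling; missing values are rejected.  Component signs are fixed by
    making each component's largest-magnitude loading positive.
    """
    if mode not in ("conditions", "entities"):
        raise QCError(f"unknown PCA mode {mode!r}")
    if mode == "entities":
        matrix = matrix.T
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise QCError("missing values in PCA input; impute or filter upstream")
    n_obs, n_var = X.shape
    if n_obs < 2 or n_var < 2:
        raise QCError("PCA needs >= 2 observations and >= 2 variables")
    cols = np.asarray(matrix.columns)
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} zero-variance variables")
            X, cols, sd = X[:, keep], cols[keep], sd[keep]
            if X.shape[1] < 2:
                raise QCError("fewer than 2 variables left after dropping zero variance")
        X = X / sd
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise QCError("matrix has no variance; PCA undefined")
    frac = var / total
    k = min(n_components, len(s))
    comps = vt[:k]
    # sign convention: largest-|loading| entry of each component positive
    for i in range(k):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    scores = X @ comps.T
    names = [f"PC{i+1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=names),
        loadings=pd.DataFrame(comps.T, index=cols, columns=names),
        variance_fraction=frac,
        mode=mode,
        n_components=k,
    )


def group_separation(scores: pd.DataFrame, labels: pd.Series | list) -> float:
    """Mean silhouette width of labelled groups on the first two components.

    Euclidean distances; singleton groups contribute silhouette 0 (flagged
    with a warning).  Values near 1 mean tight, well-separated groups; near
    0, no structure.
    """
    from sklearn.metrics import silhouette_score

    y = np.asarray(labels)
    if len(y) != len(scores):
        raise QCError("labels must align with score rows")
    if len(np.unique(y)) < 2:
        raise QCError("need >= 2 distinct groups")
    counts = pd.Series(y).value_counts()
    if (counts == 1).any():
        warnings.warn(f"singleton groups (silhouette 0): {list(counts[counts == 1].index)}")
    X = scores.iloc[:, : min(2, scores.shape[1])].to_numpy(dtype=float)
    return float(silhouette_score(X, y, metric="euclidean"))
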