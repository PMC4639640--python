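"""Minimal-redundancy-maximal-relevance feature ranking on binary indicators.

Mutual information is the plug-in estimate in nats.  The selection criterion
is the standard incremental form: at each step pick the unselected feature x
maximizing  I(x; c) - (1/|S|) * sum_{x_j in S} I(x; x_j),
ties broken by lower column index.  Pairwise MI terms are computed once per
newly selected feature and accumulated, so ranking k of F features costs
O(k * F) MI evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_K = 500


def empirical_mutual_information(x, y) -> float:
    """Plug-in mutual information (nats) between two discrete vectors.

    I = sum over observed cells of p(x,y) * ln[p(x,y) / (p(x) p(y))],
    with 0 * ln(0) taken as 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size == 0:
        raise ValueError("vectors must be non-empty")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= x.size
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log(joint[mask] / (px @ py)[mask])))


def _mi_binary_counts(n11, n1x, nx1, n):
    """Vectorized MI from 2x2 cell counts (arrays broadcast together)."""
    n11, n1x, nx1 = np.broadcast_arrays(
        np.asarray(n11, dtype=float),
        np.asarray(n1x, dtype=float),
        np.asarray(nx1, dtype=float),
    )
    cells = np.stack(
        [n11, n1x - n11, nx1 - n11, n - n1x - nx1 + n11]
    )  # (4, F): joint counts for (1,1),(1,0),(0,1),(0,0)
    px = np.stack([n1x, n1x, n - n1x, n - n1x])
    py = np.stack([nx1, n - nx1, nx1, n - nx1])
    with np.errstate(divide="ignore", invalid="ignore"):
        term = cells / n * np.log(cells * n / (px * py))
    term[cells == 0] = 0.0
    return term.sum(axis=0)


def _mi_vector_vs_columns(v: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """MI of binary vector v against every column of binary matrix cols."""
    v = v.astype(np.float64)
    n = v.size
    n11 = v @ cols
    return _mi_binary_counts(n11, v.sum(), cols.sum(axis=0), n)


@dataclass
class MRMRRanking:
    """Ordered feature column indices with the criterion value at selection."""

    order: list[int]
    phi_scores: list[float]
    k: int


def mrmr_rank(features, labels, k: int = DEFAULT_K) -> MRMRRanking:
    """Greedy incremental mRMR ranking of binary feature columns.

    features: (n_samples, n_features) binary matrix; labels: binary vector.
    Returns the top min(k, n_features) columns; the first maximizes relevance
    I(x; c) alone.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be (n_samples, n_features) matching labels")
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    if not set(np.unique(X)) <= {0.0, 1.0}:
        raise ValueError("features must be binary indicators")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels contain a single class")

    n_features = X.shape[1]
    k = min(k, n_features)
    relevance = _mi_vector_vs_columns(y, X)

    order: list[int] = []
    phi_scores: list[float] = []
    selected = np.zeros(n_features, dtype=bool)
    redundancy_sum = np.zeros(n_features)

    first = int(np.argmax(relevance))  # argmax takes the lowest index on ties
    order.append(first)
    phi_scores.append(float(relevance[first]))
    selected[first] = True

    for _ in range(1, k):
        redundancy_sum += _mi_vector_vs_columns(X[:, order[-1]], X)
        phi = relevance - redundancy_sum / len(order)
        phi[selected] = -np.inf
        pick = int(np.argmax(phi))
        order.append(pick)
        phi_scores.append(float(phi[pick]))
        selected[pick] = True

    return MRMRRanking(order=order, phi_scores=phi_scores, k=k)
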