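"""Correlation structure and 2-cluster split of the five behavioural metrics.

The working hypothesis is that the metrics organise along two axes —
accuracy (hit, bias, precision) and speed (rt, speed).  This module
quantifies that split: Pearson correlations over the concatenated trials,
Ward hierarchical clustering on the 1 - r distance, a cut at k = 2 and
silhouette scores on the same distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

from .synthetic import METRICS

#: metrics flipped before correlating so that higher = better performance
#: (precision is already oriented that way by construction)
DEFAULT_INVERT = ("rt", "bias")


@dataclass
class ClusterResult:
    correlation: pd.DataFrame          # 5x5 Pearson r
    linkage: np.ndarray                # scipy linkage matrix (Ward on 1 - r)
    assignment: dict                   # metric -> cluster id (1 or 2)
    silhouettes: dict                  # metric -> silhouette score
    mean_silhouette: float


def correlate_metrics(frame: pd.DataFrame,
                      invert: tuple = DEFAULT_INVERT) -> pd.DataFrame:
    """Pairwise Pearson correlations of the five metric columns.

    ``invert`` lists metrics whose sign is flipped first so that higher
    values mean better performance for every metric.
    """
    data = frame[list(METRICS)].copy()
    if len(data) < 3:
        raise ValueError("need at least 3 trials to correlate metrics")
    for m in invert:
        data[m] = -data[m]
    return data.corr(method="pearson")


def cluster_metrics(correlation: pd.DataFrame) -> ClusterResult:
    """Ward linkage on 1 - r, cut at two clusters, silhouette per metric."""
    r = correlation.loc[list(METRICS), list(METRICS)].to_numpy()
    if not np.allclose(r, r.T, atol=1e-12) or not np.allclose(np.diag(r), 1.0):
        raise ValueError("not a valid correlation matrix")
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0]):
        raise ValueError("degenerate distances: all metric pairs equidistant")
    Z = linkage(condensed, method="ward")
    labels = fcluster(Z, t=2, criterion="maxclust")
    sil = silhouette_samples(dist, labels, metric="precomputed")
    return ClusterResult(
        correlation=correlation,
        linkage=Z,
        assignment={m: int(c) for m, c in zip(METRICS, labels)},
        silhouettes={m: float(s) for m, s in zip(METRICS, sil)},
        mean_silhouette=float(sil.mean()),
    )


def cluster_report(result: ClusterResult) -> dict:
    """JSON-serialisable summary of a clustering result."""
    return {
        "correlation": result.correlation.round(6).to_dict(),
        "assignment": result.assignment,
        "silhouettes": {m: round(s, 6) for m, s in result.silhouettes.items()},
        "mean_silhouette": round(result.mean_silhouette, 6),
    }
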