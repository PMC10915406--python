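"""Post-hoc analyses: correlating dataset statistics with model performance,
and descriptor-space visualization with per-cluster clustering coefficients.

The correlation analysis asks which properties of a dataset (size,
similarity structure, activity order consistency, activity ratio) predict
how well the models generalize; each (statistic, metric) pair gets a Pearson
r, its square, a two-sided p-value and the overlay regression line. The
visualization side embeds descriptor vectors with t-SNE and scores how
distinctly each known family clusters using the silhouette coefficient
(computed in the original descriptor space, so values do not depend on the
embedding).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_samples

from .descriptors import DescriptorTable
from .exceptions import ConfigurationError, DomainError, UndefinedStatisticError


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with its two-sided p-value.

    The p-value comes from the exact t transform: t = r sqrt((n-2)/(1-r^2))
    referred to a t distribution with n-2 degrees of freedom. Both vectors
    must be non-constant with length >= 3.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise DomainError("pearson correlation needs equal lengths >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    r = float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    n = xa.size
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return r, min(p, 1.0)


@dataclass(frozen=True)
class CorrelationRecord:
    """One dataset-statistic vs performance-metric correlation."""

    statistic_name: str
    metric_name: str
    r: float
    r2: float
    p_value: float
    slope: float
    intercept: float
    n: int


def correlate_statistics_with_performance(
    stats_table: pd.DataFrame,
    performance_table: pd.DataFrame,
    statistics: Sequence[str] | None = None,
    metrics: Sequence[str] | None = None,
) -> tuple[list[CorrelationRecord], pd.DataFrame]:
    """Correlate per-dataset statistics against per-dataset metric means.

    Both tables are indexed by dataset name. Returns one record per
    requested (statistic, metric) pair -- including the least-squares
    overlay line -- plus the statistic-vs-statistic correlation matrix.
    Needs at least three datasets in common.
    """
    common = stats_table.index.intersection(performance_table.index)
    if len(common) < 3:
        raise DomainError("need at least three datasets to correlate")
    stats_table = stats_table.loc[common]
    performance_table = performance_table.loc[common]
    statistics = list(statistics or stats_table.columns)
    metrics = list(metrics or performance_table.columns)

    records = []
    for stat in statistics:
        xa = stats_table[stat].to_numpy(dtype=float)
        for met in metrics:
            ya = performance_table[met].to_numpy(dtype=float)
            r, p = pearson_correlation(xa, ya)
            slope, intercept = np.polyfit(xa, ya, 1)
            records.append(
                CorrelationRecord(
                    statistic_name=stat,
                    metric_name=met,
                    r=r,
                    r2=r * r,
                    p_value=p,
                    slope=float(slope),
                    intercept=float(intercept),
                    n=len(common),
                )
            )
    stat_corr = stats_table[statistics].corr(method="pearson")
    return records, stat_corr


# -- descriptor-space structure --------------------------------------------


def embed_2d(
    table: DescriptorTable | np.ndarray, perplexity: float = 30.0, seed: int = 0
) -> np.ndarray:
    """t-SNE embedding of descriptor vectors into the plane.

    Perplexity is auto-reduced to (n - 1) / 3 for small inputs; asking for a
    perplexity at or above n is a configuration error. Deterministic given
    the seed.
    """
    X = table.vectors if isinstance(table, DescriptorTable) else np.asarray(table, float)
    n = X.shape[0]
    if n < 5:
        raise ConfigurationError("t-SNE embedding needs at least 5 objects")
    if perplexity >= n:
        raise ConfigurationError(f"perplexity {perplexity} must be below n={n}")
    perplexity = min(perplexity, (n - 1) / 3)
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    )
    return tsne.fit_transform(X)


def per_cluster_silhouette(
    vectors: np.ndarray | DescriptorTable, labels: Sequence
) -> dict:
    """Mean silhouette coefficient of each cluster's members.

    Silhouette of a point is (b - a) / max(a, b) with a the mean distance to
    its own cluster and b the mean distance to the nearest other cluster
    (Euclidean); per-cluster values lie in [-1, 1], near 0 for random
    labellings and near 1 for well-separated clusters.
    """
    X = vectors.vectors if isinstance(vectors, DescriptorTable) else np.asarray(vectors, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise UndefinedStatisticError("silhouette needs at least two clusters")
    sil = silhouette_samples(X, labels, metric="euclidean")
    return {lab: float(np.mean(sil[labels == lab])) for lab in uniq}


def mean_cluster_coefficient(per_cluster: Mapping) -> float:
    """Unweighted mean of the per-cluster silhouette values."""
    return float(np.mean(list(per_cluster.values())))
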