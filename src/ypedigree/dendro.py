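"""Weighted dendrograms from pairwise Y-STR differences.

The distance between two men is the sum over markers of the conservative
mutation count, optionally multiplied by a per-marker weight defined as
-log10 of the locus mutation rate: rarely mutating loci weigh more, since
a difference there is unlikely to be recurrent and hence more informative
about the deep structure of the pedigree.  Samples are clustered by
complete-linkage agglomeration; the number of clusters is either user-set
or chosen automatically by maximising the mean silhouette coefficient on
the precomputed distance matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

__all__ = [
    "weight_vector",
    "distance_matrix",
    "choose_k_silhouette",
    "build_dendrogram",
    "plot_dendrogram",
    "DendrogramResult",
]


@dataclass
class DendrogramResult:
    """Complete-linkage clustering of one pedigree's haplotypes."""

    labels: list[str]  # sample labels, matrix order
    condensed: np.ndarray  # condensed distance vector
    linkage: np.ndarray  # scipy linkage matrix
    k: int  # chosen cluster count
    clusters: np.ndarray  # per-sample cluster id (1..k)
    silhouette_by_k: dict[int, float]  # candidate k -> mean silhouette

    def assignments(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.labels, "cluster": self.clusters})


def weight_vector(rates: dict[str, float], markers: list[str]) -> np.ndarray:
    """Per-marker weights -log10(mutation rate); requires 0 < rate < 1."""
    weights = []
    for marker in markers:
        if marker not in rates:
            raise KeyError(f"no mutation rate provided for marker {marker!r}")
        rate = rates[marker]
        if not 0 < rate < 1:
            raise ValueError(
                f"mutation rate for {marker!r} must lie in (0, 1), got {rate}"
            )
        weights.append(-np.log10(rate))
    return np.asarray(weights)


def distance_matrix(
    diffs: pd.DataFrame,
    markers: list[str],
    rates: dict[str, float] | None = None,
) -> tuple[list[str], np.ndarray]:
    """Condensed pairwise distance matrix from a difference table.

    d(a, b) = sum_m count_m(a, b) * w_m, with w_m = 1 unweighted or
    -log10(rate_m) when rates are given.  Returns (sample labels in matrix
    order, condensed vector as used by scipy).
    """
    missing = [m for m in markers if m not in diffs.columns]
    if missing:
        raise ValueError(f"difference table lacks marker column(s) {missing}")
    w = weight_vector(rates, markers) if rates is not None else np.ones(len(markers))

    labels = sorted(set(diffs["sample_a"]) | set(diffs["sample_b"]))
    index = {s: i for i, s in enumerate(labels)}
    n = len(labels)
    full = np.zeros((n, n))
    seen = np.zeros((n, n), dtype=bool)
    counts = diffs[markers].to_numpy(dtype=float)
    for row, d in zip(diffs.itertuples(index=False), counts @ w):
        i, j = index[row.sample_a], index[row.sample_b]
        full[i, j] = full[j, i] = d
        seen[i, j] = seen[j, i] = True
    np.fill_diagonal(seen, True)
    if not seen.all():
        i, j = np.argwhere(~seen)[0]
        raise ValueError(
            f"difference table lacks the pair ({labels[i]}, {labels[j]}); "
            "all pairs of the sample set are required"
        )
    return labels, squareform(full, checks=False)


def choose_k_silhouette(
    condensed: np.ndarray,
    linkage: np.ndarray | None = None,
    k_range: range | None = None,
) -> tuple[int, dict[int, float]]:
    """Cluster count maximising the mean silhouette on the distance matrix.

    Candidates default to 2..min(n-1, 10); ties pick the smallest k.  With
    fewer than three samples there is nothing to choose: returns k=1.
    """
    full = squareform(condensed)
    n = full.shape[0]
    if n < 3:
        logger.warning("silhouette selection needs >=3 samples; using k=1")
        return 1, {}
    if linkage is None:
        linkage = hierarchy.linkage(condensed, method="complete")
    if k_range is None:
        k_range = range(2, min(n - 1, 10) + 1)
    scores: dict[int, float] = {}
    for k in k_range:
        if not 2 <= k <= n - 1:
            continue
        clusters = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
        if len(np.unique(clusters)) < 2:
            continue
        scores[k] = float(silhouette_score(full, clusters, metric="precomputed"))
    if not scores:
        logger.warning("no valid cluster count in range; using smallest candidate")
        return min(k_range), {}
    best = max(scores.values())
    k = min(k for k, s in scores.items() if s == best)
    return k, scores


def build_dendrogram(
    diffs: pd.DataFrame,
    markers: list[str],
    rates: dict[str, float] | None = None,
    k: int | None = None,
) -> DendrogramResult:
    """Complete-linkage dendrogram of all samples in a difference table.

    ``k`` fixes the number of clusters; when omitted it is chosen by
    silhouette.  Weighted and unweighted trees share the same merges
    whenever all rates are equal (the weight is then a global scale).
    """
    labels, condensed = distance_matrix(diffs, markers, rates)
    linkage = hierarchy.linkage(condensed, method="complete")
    n = len(labels)
    scores: dict[int, float] = {}
    if k is None:
        k, scores = choose_k_silhouette(condensed, linkage)
    elif k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    if k <= 1 or n < 2:
        clusters = np.ones(n, dtype=int)
        k = 1
    else:
        clusters = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return DendrogramResult(
        labels=labels,
        condensed=condensed,
        linkage=linkage,
        k=k,
        clusters=clusters,
        silhouette_by_k=scores,
    )


def plot_dendrogram(
    result: DendrogramResult,
    path: str,
    title: str = "",
    weighted: bool = False,
) -> None:
    """Write the dendrogram image; leaf order is deterministic for a fixed
    input.  The y-axis is the complete-linkage merge distance: the total
    number of variations, or its -log10(rate)-weighted sum."""
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(result.labels)), 4.5))
    cluster_of = dict(zip(result.labels, result.clusters))
    palette = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    hierarchy.dendrogram(
        result.linkage,
        labels=result.labels,
        ax=ax,
        color_threshold=0,
        above_threshold_color="black",
    )
    for tick in ax.get_xmajorticklabels():
        tick.set_color(palette[(cluster_of[tick.get_text()] - 1) % len(palette)])
    ax.set_ylabel(
        "sum of variations x -log10(mutation rate)" if weighted else "number of variations"
    )
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
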