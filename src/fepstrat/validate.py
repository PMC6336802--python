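"""Cluster-solution validation: silhouettes, a PCA+k-means comparator, and
train/test assignment stability over repeated random drawings.

Silhouettes use Euclidean distance and are computed in the space a method
actually clusters in (the standardized selected items for the sparse
solution, the retained principal components for PCA+k-means): a method
that optimizes full-space within-cluster scatter would otherwise win the
comparison by construction regardless of how well it recovers structure.
:func:`silhouette_report` takes whatever matrix defines that space, and
records it in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .cluster import HierarchicalKSparse, StandardizedMatrix, _as_frame, standardize_items


@dataclass
class SilhouetteReport:
    """Per-sample silhouette values and their mean (the silhouette coefficient)."""

    per_sample: pd.Series
    mean_value: float
    metric: str = "euclidean"
    space: str = "full-standardized"

    def to_frame(self) -> pd.DataFrame:
        return self.per_sample.rename("silhouette").to_frame()


def silhouette_report(Z, labels, space: str = "full-standardized") -> SilhouetteReport:
    """Standard Euclidean silhouette; singleton clusters score 0 by convention.

    `Z` is the matrix defining the clustering space (a StandardizedMatrix,
    DataFrame or array); `space` labels it in the report.
    """
    if isinstance(Z, StandardizedMatrix):
        vals, index = Z.values, Z.index
    else:
        frame = _as_frame(Z)
        vals, index = frame.to_numpy(dtype=float), frame.index
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    per = silhouette_samples(vals, labels, metric="euclidean")
    series = pd.Series(per, index=index, name="silhouette")
    return SilhouetteReport(per_sample=series, mean_value=float(per.mean()), space=space)


def pca_kmeans(
    X,
    k: int = 2,
    q_rule: float | int = 0.8,
    n_starts: int = 20,
    seed: int | None = None,
    return_scores: bool = False,
):
    """PCA + k-means comparator.

    Items are z-scored, projected onto the leading principal components
    (the smallest number explaining at least `q_rule` of the variance, or a
    fixed count if `q_rule` is an int), then clustered by k-means with
    `n_starts` restarts.  With `return_scores=True` the retained component
    scores are returned alongside the labels (the method's working space,
    e.g. for silhouette computation).
    """
    frame = _as_frame(X)
    if frame.shape[0] <= k:
        raise ValueError(f"need more than k={k} patients, got {frame.shape[0]}")
    Z = standardize_items(frame).values
    pca = PCA(random_state=0)
    scores = pca.fit_transform(Z)
    if isinstance(q_rule, (int, np.integer)) and not isinstance(q_rule, bool):
        q = int(q_rule)
    else:
        cum = np.cumsum(pca.explained_variance_ratio_)
        q = int(np.searchsorted(cum, q_rule - 1e-12) + 1)
    q = max(1, min(q, scores.shape[1]))
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
    labels = km.fit_predict(scores[:, :q])
    if return_scores:
        return labels, scores[:, :q]
    return labels


def sparse_solution_silhouette(result, Z: StandardizedMatrix | None = None) -> SilhouetteReport:
    """Silhouette of a fitted sparse solution in its own working space
    (the standardized selected items)."""
    if Z is None:
        vals = None
    elif isinstance(Z, StandardizedMatrix):
        vals = Z.values
    else:
        vals = standardize_items(_as_frame(Z)).values
    if vals is None:
        raise ValueError("the standardized matrix the solution was fitted on is required")
    sub = vals[:, result.selected_idx]
    return silhouette_report(sub, result.labels, space="selected-items")


@dataclass
class StabilityReport:
    """Assignment stability of the two-level solution over random splits."""

    n_drawings: int
    split_fraction: float
    per_cluster_accuracy: dict[str, float]
    per_drawing: pd.DataFrame = field(repr=False, default=None)
    label_matching: str = "maximal-agreement bipartite matching on training patients"

    def summary(self) -> str:
        lines = [
            f"Cluster assignment stability ({self.n_drawings} drawings, "
            f"{self.split_fraction:.0%} training fraction)"
        ]
        for cl, acc in sorted(self.per_cluster_accuracy.items()):
            lines.append(f"  {cl}: {acc:.1%} correctly classified")
        return "\n".join(lines)


def _match_labels(pred: pd.Series, ref: pd.Series) -> dict[str, str]:
    """Map predicted label names onto reference names by maximal agreement."""
    pred_names = sorted(pred.unique())
    ref_names = sorted(ref.unique())
    agree = np.zeros((len(pred_names), len(ref_names)))
    for i, p in enumerate(pred_names):
        for j, r in enumerate(ref_names):
            agree[i, j] = ((pred == p) & (ref == r)).sum()
    ri, ci = linear_sum_assignment(-agree)
    return {pred_names[i]: ref_names[j] for i, j in zip(ri, ci)}


def crossvalidate_clustering(
    X,
    n_drawings: int = 50,
    split_fraction: float = 0.8,
    seed: int | None = None,
    reference=None,
    **hier_kwargs,
) -> StabilityReport:
    """Train/test stability of the two-level stratification.

    Per drawing: fit the hierarchical solution on a random training split,
    assign the held-out patients by nearest centroid, map the train-derived
    cluster names onto the full-data (reference) names by maximal-agreement
    matching computed on the training patients, and record the fraction of
    held-out patients whose mapped label agrees with the reference, per
    reference cluster.
    """
    frame = _as_frame(X)
    m = frame.shape[0]
    if n_drawings < 1:
        raise ValueError("n_drawings must be >= 1")
    n_train = int(round(split_fraction * m))
    if n_train < 4 or m - n_train < 2:
        raise ValueError("degenerate train/test split")
    ss = np.random.SeedSequence(seed)
    ref_seed = int(ss.generate_state(1)[0] % (2**31))
    if reference is None:
        reference = HierarchicalKSparse(frame, **hier_kwargs).fit(seed=ref_seed)
    ref_labels = reference.final_labels
    clusters = sorted(ref_labels.unique())
    rows = []
    for draw, child in enumerate(ss.spawn(n_drawings)):
        rng = np.random.default_rng(child)
        perm = rng.permutation(m)
        tr, te = perm[:n_train], perm[n_train:]
        fit = HierarchicalKSparse(frame.iloc[tr], **hier_kwargs).fit(
            seed=int(rng.integers(0, 2**31 - 1))
        )
        mapping = _match_labels(fit.final_labels, ref_labels.iloc[tr])
        pred_te = fit.assign_new(frame.iloc[te]).map(lambda c: mapping.get(c, c))
        ref_te = ref_labels.iloc[te]
        row = {"drawing": draw}
        for cl in clusters:
            mask = ref_te == cl
            row[cl] = float((pred_te[mask] == cl).mean()) if mask.any() else np.nan
        rows.append(row)
    per_drawing = pd.DataFrame(rows).set_index("drawing")
    acc = {cl: float(np.nanmean(per_drawing[cl])) for cl in clusters}
    return StabilityReport(
        n_drawings=n_drawings,
        split_fraction=split_fraction,
        per_cluster_accuracy=acc,
        per_drawing=per_drawing,
    )
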