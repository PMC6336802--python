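"""Sparse k-means clustering of symptom profiles with built-in item selection.

The estimator alternates between a label step and a weight step to minimize
the Frobenius reconstruction objective

    || Z - Y W^T ||_F^2

over a one-hot label matrix Y (m patients x k clusters) and a row-sparse
weight matrix W (d items x k) with at most s nonzero rows.  Given labels,
the unconstrained minimizer of each W column is the cluster mean of Z; the
s retained items are those whose cluster-mean rows explain the most sum of
squares (the exact objective decrease from un-zeroing a row), so the weight
step is an exact minimization over (W, S).  Given W, each patient moves to
the nearest weight column in the selected-item subspace, which is again
exact; the objective is therefore non-increasing and the iteration
terminates.  With s = d the procedure reduces to standard k-means on Z.

Two-level stratification applies the estimator with k = 2 to the whole
cohort and then once more inside each branch, re-standardizing and
re-selecting items per split, yielding the four subtypes C1A, C1B, C2A and
C2B.  Branch naming follows symptom severity: C1 is the branch with the
higher mean negative-subscale score, and the "A" subtype within each branch
has the higher mean PANSS total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panss import ItemScoreMatrix, NEGATIVE_ITEMS


class EmptyClusterError(RuntimeError):
    """Raised by the weight step when a cluster has no members."""


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


@dataclass
class Standardization:
    """Per-item center/scale used to z-score a score matrix (reusable on new data)."""

    center: np.ndarray
    scale: np.ndarray
    columns: list[str]
    constant: np.ndarray  # boolean, True where the training column was constant

    def transform(self, values: np.ndarray) -> np.ndarray:
        out = (values - self.center) / self.scale
        out[:, self.constant] = 0.0
        return out

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return z * self.scale + self.center


@dataclass
class StandardizedMatrix:
    values: np.ndarray
    columns: list[str]
    index: pd.Index
    standardization: Standardization


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, ItemScoreMatrix):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, dtype=float)
    return pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])


def standardize_items(X) -> StandardizedMatrix:
    """Z-score each item; constant items map to all-zero columns."""
    df = _as_frame(X)
    if df.shape[0] < 2:
        raise ValueError("need at least 2 patients to standardize")
    vals = df.to_numpy(dtype=float)
    center = vals.mean(axis=0)
    scale = vals.std(axis=0, ddof=0)
    constant = scale == 0.0
    scale = np.where(constant, 1.0, scale)
    std = Standardization(center=center, scale=scale, columns=list(df.columns), constant=constant)
    return StandardizedMatrix(
        values=std.transform(vals), columns=list(df.columns), index=df.index, standardization=std
    )


# ---------------------------------------------------------------------------
# Alternating minimization half-steps
# ---------------------------------------------------------------------------


def wstep(Z: np.ndarray, labels: np.ndarray, k: int, s: int) -> tuple[np.ndarray, np.ndarray]:
    """Weight half-step: cluster means on the s best items, zero elsewhere.

    Item ranking uses the per-item explained sum of squares
    Delta_i = sum_j n_j * mean_{ij}^2 (the exact decrease of the Frobenius
    objective from retaining row i); ties break toward the lower item index.

    Returns (W, selected) with W of shape (d, k) and `selected` the sorted
    indices of the s retained items.
    """
    m, d = Z.shape
    if not (1 <= s <= d):
        raise ValueError(f"s must be in [1, {d}], got {s}")
    counts = np.bincount(labels, minlength=k)
    if (counts == 0).any():
        raise EmptyClusterError(f"empty cluster(s): {np.flatnonzero(counts == 0).tolist()}")
    sums = np.zeros((k, d))
    np.add.at(sums, labels, Z)
    means = sums / counts[:, None]  # k x d
    delta = (counts[:, None] * means**2).sum(axis=0)  # per-item explained SS
    order = np.lexsort((np.arange(d), -delta))
    selected = np.sort(order[:s])
    W = np.zeros((d, k))
    W[selected, :] = means.T[selected, :]
    return W, selected


def ystep(Z: np.ndarray, W: np.ndarray, selected: np.ndarray) -> np.ndarray:
    """Label half-step: nearest weight column in the selected-item subspace.

    Ties go to the lowest cluster index (argmin convention).
    """
    if selected.size == 0:
        raise ValueError("no selected items")
    Ws = W[selected, :]
    if W.shape[1] > 1 and not np.any(W != 0.0):
        raise ValueError("all-zero weight matrix")
    Zs = Z[:, selected]
    d2 = ((Zs[:, :, None] - Ws[None, :, :]) ** 2).sum(axis=1)
    return d2.argmin(axis=1)


def reconstruction_objective(Z: np.ndarray, labels: np.ndarray, W: np.ndarray) -> float:
    """|| Z - Y W^T ||_F^2 for one-hot Y encoding `labels`."""
    resid = Z - W.T[labels, :]
    return float((resid**2).sum())


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------


@dataclass
class KSparseResults:
    """Fitted sparse-k-means solution.

    `labels` are 0-based cluster indices; `weights` is the d x k weight
    matrix with exactly `s` nonzero rows; `selected_items` the corresponding
    item names.  `objective_path` records the (non-increasing) objective of
    the winning restart.
    """

    labels: np.ndarray
    weights: np.ndarray
    selected_idx: np.ndarray
    selected_items: list[str]
    objective: float
    k: int
    s: int
    n_iter: int
    seed: int | None
    standardization: Standardization
    columns: list[str]
    index: pd.Index
    objective_path: list[float] = field(default_factory=list)

    @property
    def labels_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.index, name="cluster")

    def assign_new(self, X_new) -> np.ndarray:
        """Assign new patients: training standardization, nearest centroid on selected items."""
        df = _as_frame(X_new)
        if list(df.columns) != self.columns:
            raise ValueError(
                f"item-name mismatch: expected {self.columns}, got {list(df.columns)}"
            )
        Z = self.standardization.transform(df.to_numpy(dtype=float))
        return ystep(Z, self.weights, self.selected_idx)

    def summary(self) -> str:
        counts = np.bincount(self.labels, minlength=self.k)
        lines = [
            "Sparse k-means solution",
            f"  clusters (k):        {self.k}",
            f"  selected items (s):  {self.s}  -> {', '.join(self.selected_items)}",
            f"  objective:           {self.objective:.6f}",
            f"  iterations:          {self.n_iter}",
            f"  cluster sizes:       {counts.tolist()}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class KSparseCluster:
    """Sparse k-means model over a patients x items score matrix.

    Parameters
    ----------
    X
        ItemScoreMatrix, DataFrame or array (m x d).
    k
        Number of clusters.
    s
        Number of items to retain; None means all (classic k-means).
    """

    def __init__(self, X, k: int = 2, s: int | None = None):
        self._frame = _as_frame(X)
        self.Zm = standardize_items(self._frame)
        self.k = int(k)
        m, d = self.Zm.values.shape
        self.s = d if s is None else int(s)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if m < self.k:
            raise ValueError(f"need at least k={self.k} patients, got {m}")
        if not (1 <= self.s <= d):
            raise ValueError(f"s must be in [1, {d}]")

    # -- single restart ----------------------------------------------------
    def _init_labels(self, rng: np.random.Generator) -> np.ndarray:
        from sklearn.cluster import kmeans_plusplus

        Z = self.Zm.values
        if self.k == 1:
            return np.zeros(Z.shape[0], dtype=int)
        centers, _ = kmeans_plusplus(
            Z, self.k, random_state=int(rng.integers(0, 2**31 - 1))
        )
        d2 = ((Z[:, :, None] - centers.T[None, :, :]) ** 2).sum(axis=1)
        return d2.argmin(axis=1)

    def _repair_empty(
        self, Z: np.ndarray, labels: np.ndarray, W: np.ndarray
    ) -> np.ndarray:
        """Move the worst-reconstructed point into each empty cluster."""
        labels = labels.copy()
        counts = np.bincount(labels, minlength=self.k)
        while (counts == 0).any():
            empty = int(np.flatnonzero(counts == 0)[0])
            err = ((Z - W.T[labels, :]) ** 2).sum(axis=1)
            err[counts[labels] <= 1] = -np.inf  # do not empty another cluster
            donor = int(err.argmax())
            counts[labels[donor]] -= 1
            labels[donor] = empty
            counts[empty] += 1
            W[self._last_selected, empty] = Z[donor, self._last_selected]
        return labels

    def _run(self, rng: np.random.Generator, max_iter: int, tol: float):
        Z = self.Zm.values
        labels = self._init_labels(rng)
        # guard: the nearest-center init may leave clusters empty
        for j in range(self.k):
            if not (labels == j).any():
                labels[int(rng.integers(0, Z.shape[0]))] = j
        path: list[float] = []
        prev_obj = np.inf
        for it in range(1, max_iter + 1):
            W, selected = wstep(Z, labels, self.k, self.s)
            self._last_selected = selected
            try:
                new_labels = ystep(Z, W, selected)
            except ValueError:
                new_labels = labels  # all centroids coincide (degenerate data)
            if (np.bincount(new_labels, minlength=self.k) == 0).any():
                new_labels = self._repair_empty(Z, new_labels, W)
                W, selected = wstep(Z, new_labels, self.k, self.s)
            obj = reconstruction_objective(Z, new_labels, W)
            path.append(obj)
            if obj > prev_obj + 1e-9:
                raise AssertionError(
                    f"objective increased: {prev_obj} -> {obj}"
                )  # alternating exact minimization guarantees monotonicity
            converged = np.array_equal(new_labels, labels) or prev_obj - obj < tol
            labels = new_labels
            prev_obj = obj
            if converged:
                break
        W, selected = wstep(Z, labels, self.k, self.s)
        obj = reconstruction_objective(Z, labels, W)
        return labels, W, selected, obj, it, path

    def fit(
        self,
        n_starts: int = 20,
        max_iter: int = 100,
        tol: float = 1e-8,
        seed: int | None = None,
    ) -> KSparseResults:
        """Best of `n_starts` k-means++-seeded restarts by objective (ties: lowest start)."""
        ss = np.random.SeedSequence(seed)
        best = None
        for start, child in enumerate(ss.spawn(n_starts)):
            rng = np.random.default_rng(child)
            labels, W, selected, obj, n_iter, path = self._run(rng, max_iter, tol)
            if best is None or obj < best[3] - 1e-12:
                best = (labels, W, selected, obj, n_iter, path)
        labels, W, selected, obj, n_iter, path = best
        check = reconstruction_objective(self.Zm.values, labels, W)
        assert abs(check - obj) < 1e-8
        return KSparseResults(
            labels=labels,
            weights=W,
            selected_idx=selected,
            selected_items=[self.Zm.columns[j] for j in selected],
            objective=obj,
            k=self.k,
            s=self.s,
            n_iter=n_iter,
            seed=seed,
            standardization=self.Zm.standardization,
            columns=list(self.Zm.columns),
            index=self.Zm.index,
            objective_path=path,
        )


def fit_ksparse(
    X, k: int, s: int, n_starts: int = 20, max_iter: int = 100, tol: float = 1e-8,
    seed: int | None = None,
) -> KSparseResults:
    """Functional wrapper around :class:`KSparseCluster`."""
    return KSparseCluster(X, k=k, s=s).fit(n_starts=n_starts, max_iter=max_iter, tol=tol, seed=seed)


def choose_sparsity(
    X, k: int, s_grid, seed: int | None = None, n_starts: int = 20
) -> int:
    """Pick the sparsity level maximizing the mean silhouette.

    Silhouettes are computed in the full standardized item space (common
    yardstick across s); ties break toward the smallest s.
    """
    from sklearn.metrics import silhouette_samples

    s_grid = sorted(int(s) for s in s_grid)
    if not s_grid:
        raise ValueError("empty sparsity grid")
    model_frame = _as_frame(X)
    Z = standardize_items(model_frame).values
    ss = np.random.SeedSequence(seed)
    best_s, best_score = None, -np.inf
    for s, child in zip(s_grid, ss.spawn(len(s_grid))):
        res = KSparseCluster(model_frame, k=k, s=s).fit(
            n_starts=n_starts, seed=int(child.generate_state(1)[0] % (2**31))
        )
        if len(np.unique(res.labels)) < 2:
            score = -np.inf
        else:
            score = float(silhouette_samples(Z, res.labels).mean())
        if score > best_score + 1e-10:
            best_s, best_score = s, score
    return int(best_s)


# ---------------------------------------------------------------------------
# Two-level stratification
# ---------------------------------------------------------------------------


@dataclass
class HierarchicalResults:
    """Two-level stratification into C1A/C1B/C2A/C2B.

    `level1` is the whole-cohort k=2 solution, `level2` maps branch name
    ("C1"/"C2") to the within-branch k=2 solution (None if the branch was
    too small to split).  `final_labels` holds the subtype per patient.
    """

    level1: KSparseResults
    level2: dict[str, KSparseResults | None]
    branch_of_cluster: dict[int, str]  # level-1 cluster index -> "C1"/"C2"
    subtype_of: dict[tuple[str, int], str]  # (branch, level-2 cluster) -> subtype
    final_labels: pd.Series
    unsplit_branches: list[str] = field(default_factory=list)

    @property
    def per_split_s(self) -> dict[str, int | None]:
        out = {"level1": self.level1.s}
        for b, res in self.level2.items():
            out[b] = res.s if res is not None else None
        return out

    def assign_new(self, X_new) -> pd.Series:
        """Hierarchical nearest-centroid assignment of new patients."""
        df = _as_frame(X_new)
        l1 = self.level1.assign_new(df)
        out = np.empty(len(df), dtype=object)
        for cl, branch in self.branch_of_cluster.items():
            mask = l1 == cl
            if not mask.any():
                continue
            res2 = self.level2.get(branch)
            if res2 is None:
                out[mask] = branch
                continue
            sub = res2.assign_new(df.iloc[mask])
            names = np.array([self.subtype_of[(branch, int(c))] for c in sub], dtype=object)
            out[mask] = names
        return pd.Series(out, index=df.index, name="subtype")

    def summary(self) -> str:
        counts = self.final_labels.value_counts()
        lines = ["Two-level sparse clustering"]
        lines.append(
            f"  level 1: s={self.level1.s}, items {', '.join(self.level1.selected_items)}"
        )
        for b in ("C1", "C2"):
            res = self.level2.get(b)
            if res is None:
                lines.append(f"  {b}: unsplit")
            else:
                lines.append(f"  {b} split: s={res.s}, items {', '.join(res.selected_items)}")
        for st in ("C1A", "C1B", "C2A", "C2B"):
            if st in counts.index:
                lines.append(f"  {st}: n={int(counts[st])}")
        return "\n".join(lines)


class HierarchicalKSparse:
    """Two-level sparse clustering model (k=2 at each split).

    Sparsity per split can be pinned via `s_level1`/`s_within` or chosen
    per split by silhouette over `s_grid`.
    """

    def __init__(
        self,
        X,
        s_level1: int | None = None,
        s_within: dict[str, int] | int | None = None,
        s_grid=range(2, 16),
        n_starts: int = 20,
    ):
        self._frame = _as_frame(X)
        if self._frame.shape[0] < 4:
            raise ValueError("need at least 4 patients for two-level stratification")
        self.s_level1 = s_level1
        if isinstance(s_within, int) or s_within is None:
            self.s_within = {"C1": s_within, "C2": s_within}
        else:
            self.s_within = dict(s_within)
        self.s_grid = list(s_grid)
        self.n_starts = n_starts

    def _fit_split(self, frame: pd.DataFrame, s: int | None, seed: int) -> KSparseResults:
        d = frame.shape[1]
        if s is None:
            grid = [g for g in self.s_grid if 1 <= g <= d]
            s = choose_sparsity(frame, k=2, s_grid=grid, seed=seed, n_starts=self.n_starts)
        return KSparseCluster(frame, k=2, s=s).fit(n_starts=self.n_starts, seed=seed)

    def fit(self, seed: int | None = None) -> HierarchicalResults:
        frame = self._frame
        ss = np.random.SeedSequence(seed)
        seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)]
        level1 = self._fit_split(frame, self.s_level1, seeds[0])

        # branch naming: higher mean negative-subscale score -> C1
        neg_items = [c for c in frame.columns if c in NEGATIVE_ITEMS]
        score_cols = neg_items if neg_items else list(frame.columns)
        neg_mean = {
            j: frame.iloc[level1.labels == j][score_cols].to_numpy().mean()
            for j in range(2)
        }
        c1_cluster = max(neg_mean, key=lambda j: (neg_mean[j], -j))
        branch_of_cluster = {c1_cluster: "C1", 1 - c1_cluster: "C2"}

        level2: dict[str, KSparseResults | None] = {}
        subtype_of: dict[tuple[str, int], str] = {}
        final = pd.Series(index=frame.index, dtype=object, name="subtype")
        unsplit: list[str] = []
        for j, branch in branch_of_cluster.items():
            mask = level1.labels == j
            sub_frame = frame.iloc[mask]
            branch_seed = seeds[1] if branch == "C1" else seeds[2]
            if mask.sum() < 2:
                level2[branch] = None
                unsplit.append(branch)
                final.iloc[np.flatnonzero(mask)] = branch
                continue
            res2 = self._fit_split(sub_frame, self.s_within.get(branch), branch_seed)
            level2[branch] = res2
            # within-branch naming: higher mean total score -> "A"
            tot = {
                c: sub_frame.iloc[res2.labels == c].to_numpy().mean() for c in range(2)
            }
            a_cluster = max(tot, key=lambda c: (tot[c], -c))
            subtype_of[(branch, a_cluster)] = branch + "A"
            subtype_of[(branch, 1 - a_cluster)] = branch + "B"
            names = np.array([subtype_of[(branch, int(c))] for c in res2.labels], dtype=object)
            final.iloc[np.flatnonzero(mask)] = names
        return HierarchicalResults(
            level1=level1,
            level2=level2,
            branch_of_cluster=branch_of_cluster,
            subtype_of=subtype_of,
            final_labels=final,
            unsplit_branches=unsplit,
        )


def fit_hierarchical(
    X,
    s_level1: int | None = None,
    s_within: dict[str, int] | int | None = None,
    s_grid=range(2, 16),
    n_starts: int = 20,
    seed: int | None = None,
) -> HierarchicalResults:
    """Functional wrapper around :class:`HierarchicalKSparse`."""
    return HierarchicalKSparse(
        X, s_level1=s_level1, s_within=s_within, s_grid=s_grid, n_starts=n_starts
    ).fit(seed=seed)


def assign_new(solution: KSparseResults | HierarchicalResults, X_new):
    """Assign new patients to clusters of a fitted (possibly hierarchical) solution."""
    return solution.assign_new(X_new)
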