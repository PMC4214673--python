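"""Objective functions and exploratory analyses of population rate vectors.

Two scalar objectives quantify the two codes:

* Fisher's discriminant ratio (FDR) — odor-class separability, the trace
  ratio of between-class to within-class scatter,
  ``FDR = tr(S_B) / tr(S_W)`` with ``S_B = sum_i n_i (mu_i - mu)(mu_i - mu)^T``
  and ``S_W = sum_i sum_{x in class i} (x - mu_i)(x - mu_i)^T``.
* Pearson's correlation coefficient (PCC) against stimulus concentration,
  computed per odor and summarized as mean +/- sd across odors.

Exploratory structure is read out with mean-centred (unscaled) PCA and a
divisive bisecting-k-means hierarchical clustering whose dendrogram can be
exported as Newick text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "DegenerateDataError",
    "fisher_discriminant_ratio",
    "pearson_correlation",
    "concentration_correlation",
    "pca_scores",
    "hierarchical_kmeans",
    "DendrogramNode",
]


class DegenerateDataError(ValueError):
    """Raised when a metric is undefined on the given data (zero scatter,
    constant sequence, ...)."""


def fisher_discriminant_ratio(X: np.ndarray, labels,
                              class_weighted: bool = True) -> float:
    """Trace-ratio Fisher discriminant of labelled samples.

    X is (n_samples, n_features) — or 1-D for scalar samples. With
    ``class_weighted`` (default) the between-class scatter weights each
    class mean by its size n_i, the standard multiclass form. The ratio is
    invariant to translating all samples and to rescaling them by any
    s > 0.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("one label per sample required")
    classes, inv = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError("FDR requires at least two classes")
    mu = X.mean(axis=0)
    sb = 0.0
    sw = 0.0
    for i in range(classes.size):
        Xi = X[inv == i]
        if Xi.shape[0] < 2:
            raise ValueError("FDR requires at least two samples per class")
        mu_i = Xi.mean(axis=0)
        w = Xi.shape[0] if class_weighted else 1.0
        sb += w * float(((mu_i - mu) ** 2).sum())
        sw += float(((Xi - mu_i) ** 2).sum())
    if sw == 0.0:
        raise DegenerateDataError("within-class scatter is zero; FDR undefined")
    return sb / sw


def pearson_correlation(x, y) -> float:
    """Product-moment correlation of two equal-length sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 2:
        raise ValueError("need at least two samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant input; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class ConcentrationCorrelation:
    mean: float
    sd: float
    per_odor: dict
    excluded: list


def concentration_correlation(X: np.ndarray, odor_labels, concentrations,
                              method: str = "pooled") -> ConcentrationCorrelation:
    """Per-odor correlation between population response and concentration.

    Two readings of "correlation between the response pattern and the
    concentration" are supported:

    * ``pooled`` (default): within each odor, every (glomerulus,
      concentration) response is one Eq-sample; the per-glomerulus response
      magnitudes differ, so even a perfectly concentration-linear input
      correlates well below 1. This is the reading under which the raw
      input panel scores ~0.55 and a concentration-sharing tufted output
      scores higher.
    * ``mean``: each sample is first scalarized as its mean over
      glomeruli; a linear-in-concentration input then gives exactly 1.

    Odors whose response is constant (correlation undefined) are excluded
    and reported. Returns mean and sd of the per-odor coefficients.
    """
    X = np.asarray(X, dtype=float)
    odor_labels = np.asarray(odor_labels)
    conc = np.asarray(concentrations, dtype=float)
    if method not in ("pooled", "mean"):
        raise ValueError("method must be 'pooled' or 'mean'")
    per_odor: dict = {}
    excluded: list = []
    for odor in np.unique(odor_labels):
        sel = odor_labels == odor
        Xi, ci = X[sel], conc[sel]
        if np.unique(ci).size < 2:
            raise ValueError(f"odor {odor!r} needs >= 2 distinct concentrations")
        if method == "mean":
            xs, ys = Xi.mean(axis=1), ci
        else:
            xs, ys = Xi.ravel(), np.repeat(ci, Xi.shape[1])
        try:
            per_odor[odor] = pearson_correlation(xs, ys)
        except DegenerateDataError:
            excluded.append(odor)
    if not per_odor:
        raise DegenerateDataError("all odors degenerate; no correlations defined")
    vals = np.array(list(per_odor.values()))
    return ConcentrationCorrelation(mean=float(vals.mean()),
                                    sd=float(vals.std(ddof=0)),
                                    per_odor=per_odor, excluded=excluded)


def pca_scores(X: np.ndarray, n_components: int | None = None):
    """Mean-centred, unscaled PCA: (scores, explained-variance fractions)."""
    X = np.asarray(X, dtype=float)
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if n_components is None:
        n_components = max_comp
    if not (1 <= n_components <= max_comp):
        raise ValueError(f"n_components must be in [1, {max_comp}]")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_


@dataclass
class DendrogramNode:
    """Binary dendrogram node from divisive bisecting k-means.

    ``height`` is the mean Euclidean distance of the node's members to the
    node centroid (0 at leaves and for duplicated points). ``members``
    are sample indices; leaves carry the sample label.
    """

    members: list
    height: float
    label: str | None = None
    children: tuple = ()
    split_order: int | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf:
            return [self]
        return [lf for ch in self.children for lf in ch.leaves()]

    def cut(self, n_clusters: int) -> list[list]:
        """Member index sets after the first ``n_clusters - 1`` splits.

        Splits are replayed in construction order (largest within-cluster
        sum of squares first), so ``cut(2)`` is the top bisection.
        """
        clusters = [self]
        while len(clusters) < n_clusters:
            splittable = [c for c in clusters if not c.is_leaf]
            if not splittable:
                break
            nxt = min(splittable, key=lambda c: c.split_order)
            clusters.remove(nxt)
            clusters.extend(nxt.children)
        return [sorted(c.members) for c in clusters]

    def to_newick(self) -> str:
        def rec(node, parent_height):
            bl = max(parent_height - node.height, 0.0)
            if node.is_leaf:
                name = node.label if node.label is not None else str(node.members[0])
                return f"{_escape(name)}:{bl:.6g}"
            inner = ",".join(rec(ch, node.height) for ch in node.children)
            return f"({inner}):{bl:.6g}"
        return rec(self, self.height) + ";"


def _escape(name: str) -> str:
    for ch in " (),:;":
        name = name.replace(ch, "_")
    return name


def _mean_dist_to_centroid(X: np.ndarray) -> float:
    centroid = X.mean(axis=0)
    return float(np.linalg.norm(X - centroid, axis=1).mean())


def _best_bisection(X: np.ndarray, seed: int, n_restarts: int = 10):
    """2-means with seeded restarts; lowest inertia wins, ties to lowest
    restart index. Degenerate (all-identical) clusters split first-vs-rest."""
    if np.allclose(X, X[0]):
        lab = np.zeros(X.shape[0], dtype=int)
        lab[0] = 1
        return lab
    best = None
    for j in range(n_restarts):
        km = KMeans(n_clusters=2, n_init=1, random_state=seed + j)
        lab = km.fit_predict(X)
        if lab.min() == lab.max():  # collapsed split; force a separation
            continue
        if best is None or km.inertia_ < best[0] - 1e-12:
            best = (km.inertia_, lab)
    if best is None:
        lab = np.zeros(X.shape[0], dtype=int)
        lab[0] = 1
        return lab
    return best[1]


def hierarchical_kmeans(X: np.ndarray, labels=None, seed: int = 0) -> DendrogramNode:
    """Divisive hierarchical clustering by recursive bisecting k-means.

    Starting from all samples, the cluster with the largest within-cluster
    sum of squares is repeatedly split by 2-means (Euclidean, 10 seeded
    restarts) until every cluster is a singleton. Node heights measure the
    spread of members around their cluster centroid, so merges of
    duplicated points sit at height 0. Deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two samples")
    if labels is None:
        labels = [str(i) for i in range(X.shape[0])]
    labels = list(labels)

    def make_node(members: list) -> DendrogramNode:
        Xm = X[members]
        if len(members) == 1:
            return DendrogramNode(members=members, height=0.0,
                                  label=labels[members[0]])
        return DendrogramNode(members=members, height=_mean_dist_to_centroid(Xm))

    root = make_node(list(range(X.shape[0])))
    frontier = [root]
    order = 0
    while frontier:
        # split the cluster with largest within-cluster sum of squares
        def wss(node):
            Xm = X[node.members]
            return float(((Xm - Xm.mean(axis=0)) ** 2).sum())
        frontier.sort(key=lambda nd: (-wss(nd), min(nd.members)))
        node = frontier.pop(0)
        lab = _best_bisection(X[node.members], seed=seed + 1009 * order)
        left = [m for m, l in zip(node.members, lab) if l == lab[0]]
        right = [m for m in node.members if m not in left]
        ch_l, ch_r = make_node(left), make_node(right)
        node.children = (ch_l, ch_r)
        node.split_order = order
        order += 1
        frontier.extend(ch for ch in (ch_l, ch_r) if len(ch.members) > 1)
    return root
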