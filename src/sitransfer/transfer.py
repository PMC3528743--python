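"""Heterogeneous regression (HEGS): instance-based transfer learning for
target-specific siRNA efficacy modeling.

Given a scarce target-domain training set and one or more source domains
(siRNA data for other targets or platforms), HEGS enlarges the target
training set in two steps per source task:

1. *Distribution unification* -- k-means clustering of the pooled
   (target + source) samples; the source/target cluster-membership
   proportions define a discrete Kullback-Leibler divergence.  Source
   samples are accepted cluster by cluster, preferring clusters whose
   KL term is small; clusters containing no target samples have an
   infinite term and are never selected.

2. *Output-space unification* -- selected source samples are re-labeled
   with predictions of the ridge model fit on the target training set,
   then shrunk toward the centers of groups obtained by clustering those
   predictions.  The affine shrinkage preserves the relative ordering of
   outputs within each group ("similarity-preserving"), and re-labeled
   outputs are clipped to the target training output range.

The final ridge model is re-fit on the augmented pool.  With nothing
selected, the result is exactly the single-domain baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .records import DomainDataset
from .ridge import RidgeModel, Standardizer, fit_ridge, predict


@dataclass
class TransferConfig:
    """Free parameters of the HEGS transfer step.

    k_clusters
        Number of clusters for the pooled clustering, or "auto" for
        min(10, floor(n_pooled / 5)) (at least 2).
    kl_threshold
        Accept clusters whose KL term is <= this value; ``None`` uses the
        median of the finite per-cluster terms.
    use_centroid_weighting
        Multiply each cluster's KL term by (1 + distance between the
        within-cluster source and target centroids).
    n_output_groups, shrinkage
        Groups for the 1-D clustering of source outputs during
        re-labeling, and the shrinkage alpha in
        new = alpha * group_center + (1 - alpha) * prediction.
    max_augment_ratio
        Cap on total selected samples relative to the target training
        size (shared across source tasks).  The default is deliberately
        generous: the augmented ridge fit only averages out pseudo-label
        noise when the pool is overdetermined relative to the feature
        count; a small augmented pool is interpolated instead, which
        makes transfer harmful.
    sequential
        Re-fit the labeling model after each source task instead of
        labeling every task with the initial target-only model.
    """

    k_clusters: int | str = "auto"
    kl_threshold: Optional[float] = None
    use_centroid_weighting: bool = True
    n_output_groups: int = 10
    shrinkage: float = 0.5
    seed: int = 0
    max_augment_ratio: float = 10.0
    sequential: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.shrinkage <= 1.0):
            raise ValueError("shrinkage must be in [0, 1]")
        if self.kl_threshold is not None and self.kl_threshold < 0:
            raise ValueError("kl_threshold must be >= 0")
        if self.max_augment_ratio < 0:
            raise ValueError("max_augment_ratio must be >= 0")


@dataclass
class ClusterModel:
    """K-means result on the pooled [target; source] standardized data."""

    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    seed: int
    X_combined: np.ndarray = field(repr=False)
    n_target: int = 0


@dataclass
class ClusterTerm:
    cluster_id: int
    n_source: int
    n_target: int
    p_source: float
    p_target: float
    centroid_distance: Optional[float]
    term: float
    infinite: bool


@dataclass
class KLReport:
    """Per-cluster KL diagnostics for one source task."""

    per_cluster: list[ClusterTerm]
    total: float
    has_infinite: bool
    source_name: str = ""

    def to_dict(self) -> dict:
        return {
            "source_name": self.source_name,
            "total": self.total,
            "has_infinite": self.has_infinite,
            "per_cluster": [
                {
                    "cluster_id": t.cluster_id,
                    "n_source": t.n_source,
                    "n_target": t.n_target,
                    "p_source": t.p_source,
                    "p_target": t.p_target,
                    "centroid_distance": t.centroid_distance,
                    "term": None if t.infinite else t.term,
                    "infinite": t.infinite,
                }
                for t in self.per_cluster
            ],
        }


@dataclass
class SelectionResult:
    """Selected source-sample indices, their generated outputs, diagnostics."""

    selected_indices: np.ndarray
    generated_outputs: np.ndarray
    diagnostics: KLReport


def _auto_k(n_combined: int) -> int:
    return max(2, min(10, n_combined // 5))


def cluster_combined(
    X_target: np.ndarray, X_source: np.ndarray, k: int, seed: int
) -> ClusterModel:
    """K-means on the concatenated [target; source] samples."""
    X = np.vstack([X_target, X_source])
    if not (2 <= k <= X.shape[0]):
        raise ValueError(f"k={k} out of range for {X.shape[0]} samples")
    km = KMeans(n_clusters=k, random_state=seed, n_init=1).fit(X)
    return ClusterModel(
        k=k,
        assignments=km.labels_,
        centroids=km.cluster_centers_,
        seed=seed,
        X_combined=X,
        n_target=X_target.shape[0],
    )


def kl_divergence(
    cluster_model: ClusterModel,
    n_target: int,
    n_source: int,
    use_centroid_weighting: bool = True,
    source_name: str = "",
) -> KLReport:
    """Clustering-based KL divergence between source and target.

    For each cluster c, P_S(c) and P_T(c) are the fractions of source
    resp. target samples falling in c; the cluster term is
    P_S log(P_S / P_T), with 0 log 0 := 0 and an infinite term whenever
    P_S > 0 but P_T = 0 (a source-only region of feature space).  With
    centroid weighting, the finite term is multiplied by (1 + d) where d
    is the Euclidean distance between the within-cluster source and
    target centroids.  The total sums the finite terms and carries a
    flag for any infinite ones.
    """
    if n_target < 1 or n_source < 1:
        raise ValueError("need non-empty target and source")
    assign = cluster_model.assignments
    X = cluster_model.X_combined
    is_target = np.arange(len(assign)) < n_target
    terms: list[ClusterTerm] = []
    total = 0.0
    has_inf = False
    for c in range(cluster_model.k):
        in_c = assign == c
        n_t = int(np.sum(in_c & is_target))
        n_s = int(np.sum(in_c & ~is_target))
        p_t = n_t / n_target
        p_s = n_s / n_source
        dist: Optional[float] = None
        if n_t > 0 and n_s > 0:
            c_t = X[in_c & is_target].mean(axis=0)
            c_s = X[in_c & ~is_target].mean(axis=0)
            dist = float(np.linalg.norm(c_s - c_t))
        if p_s == 0.0:
            term, inf = 0.0, False
        elif p_t == 0.0:
            term, inf = np.inf, True
        else:
            term = p_s * np.log(p_s / p_t)
            if use_centroid_weighting and dist is not None:
                term *= 1.0 + dist
            inf = False
        if inf:
            has_inf = True
        else:
            total += term
        terms.append(
            ClusterTerm(c, n_s, n_t, p_s, p_t, dist, term, inf)
        )
    return KLReport(terms, total, has_inf, source_name)


def select_source_samples(
    source_task: DomainDataset,
    target_train: DomainDataset,
    config: TransferConfig,
    *,
    standardizer: Optional[Standardizer] = None,
    max_select: Optional[int] = None,
) -> tuple[np.ndarray, KLReport]:
    """Pick source samples from distribution-compatible clusters.

    Clusters with zero target membership are excluded (infinite KL
    term); the remaining clusters are taken in ascending order of their
    term while the term stays below the threshold and the augmentation
    cap is not exceeded.  Returns indices into ``source_task`` plus the
    KL diagnostics.  An empty selection is a valid result.
    """
    if target_train.n == 0:
        raise ValueError("target training set is empty")
    std = standardizer or Standardizer.fit(target_train.X)
    Xt = std.transform(target_train.X)
    Xs = std.transform(source_task.X)
    n_t, n_s = Xt.shape[0], Xs.shape[0]
    k = _auto_k(n_t + n_s) if config.k_clusters == "auto" else int(config.k_clusters)
    k = min(k, n_t + n_s)
    model = cluster_combined(Xt, Xs, k, config.seed)
    report = kl_divergence(
        model, n_t, n_s, config.use_centroid_weighting, source_task.name
    )
    finite = [t for t in report.per_cluster if not t.infinite and t.n_source > 0]
    if not finite:
        return np.array([], dtype=int), report
    if config.kl_threshold is not None:
        tau = config.kl_threshold
    else:
        tau = float(np.median([t.term for t in finite]))
    cap = (
        max_select
        if max_select is not None
        else int(np.floor(config.max_augment_ratio * n_t))
    )
    selected: list[int] = []
    source_assign = model.assignments[n_t:]
    for t in sorted(finite, key=lambda t: (t.term, t.cluster_id)):
        if t.term > tau or len(selected) >= cap:
            break
        members = np.flatnonzero(source_assign == t.cluster_id)
        room = cap - len(selected)
        selected.extend(members[:room].tolist())
    return np.array(sorted(selected), dtype=int), report


def generate_outputs(
    selected_X: np.ndarray,
    initial_model: RidgeModel,
    config: TransferConfig,
    target_y_range: tuple[float, float],
    source_outputs: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Similarity-preserving re-labeling of selected source samples.

    Initial outputs are predictions of the model fit on the target
    training set.  The samples are then grouped by 1-D k-means on their
    *original source outputs* (when available) -- the grouping that
    survives any monotone distortion of the source efficacy scale -- and
    each sample's output is shrunk toward its group's center of initial
    predictions (alpha = config.shrinkage), so samples that were similar
    in the original output space stay similar in the target output
    space.  Without source outputs the grouping falls back to the
    predictions themselves.  Results are clipped to the target training
    output range.  Within a group the ordering of outputs is preserved
    for alpha < 1 and collapses to the center at alpha = 1.
    """
    selected_X = np.asarray(selected_X, dtype=float)
    if selected_X.shape[0] == 0:
        return np.array([])
    y_hat = predict(initial_model, selected_X)
    grouping = y_hat if source_outputs is None else np.asarray(source_outputs, dtype=float)
    if grouping.shape != y_hat.shape:
        raise ValueError("source_outputs length must match selected_X rows")
    g = config.n_output_groups
    if g > len(y_hat):
        warnings.warn(
            f"reducing output groups from {g} to {len(y_hat)} "
            "(fewer selected samples than groups)",
            stacklevel=2,
        )
        g = len(y_hat)
    if g >= 2 and len(np.unique(grouping)) >= g:
        km = KMeans(n_clusters=g, random_state=config.seed, n_init=1).fit(
            grouping.reshape(-1, 1)
        )
        labels = km.labels_
        group_means = np.array([y_hat[labels == l].mean() for l in range(g)])
        centers = group_means[labels]
    else:
        centers = np.full_like(y_hat, y_hat.mean())
    alpha = config.shrinkage
    y_new = alpha * centers + (1.0 - alpha) * y_hat
    lo, hi = target_y_range
    return np.clip(y_new, lo, hi)


def hegs_fit(
    target_train: DomainDataset,
    source_tasks: Sequence[DomainDataset],
    config: TransferConfig | None = None,
    lam: float = 1.0,
) -> tuple[RidgeModel, list[SelectionResult]]:
    """Run the full HEGS loop and return the augmented-fit ridge model.

    Initializes with a ridge fit on the target training set; for each
    source task, selects distribution-compatible samples, re-labels
    them, and appends them to the training pool; re-fits on the
    augmented pool.  The per-task selection seed is derived from
    ``config.seed`` and the task position so tasks are decorrelated but
    the whole run is deterministic.  With zero selected samples the
    returned model equals the plain target-only fit exactly.
    """
    if config is None:
        config = TransferConfig()
    if target_train.n == 0:
        raise ValueError("target training set is empty")
    initial = fit_ridge(
        target_train.X, target_train.y, lam, feature_names=target_train.feature_names
    )
    y_range = (float(target_train.y.min()), float(target_train.y.max()))
    std = Standardizer.fit(target_train.X)

    pool_X = [target_train.X]
    pool_y = [target_train.y]
    results: list[SelectionResult] = []
    cap_total = int(np.floor(config.max_augment_ratio * target_train.n))
    n_selected_total = 0
    labeling_model = initial
    for i, task in enumerate(source_tasks):
        task_cfg = replace(config, seed=config.seed + i)
        idx, report = select_source_samples(
            task,
            target_train,
            task_cfg,
            standardizer=std,
            max_select=cap_total - n_selected_total,
        )
        if len(idx) > 0:
            y_new = generate_outputs(
                task.X[idx], labeling_model, task_cfg, y_range,
                source_outputs=task.y[idx],
            )
            pool_X.append(task.X[idx])
            pool_y.append(y_new)
            n_selected_total += len(idx)
            if config.sequential:
                labeling_model = fit_ridge(
                    np.vstack(pool_X), np.concatenate(pool_y), lam
                )
        results.append(SelectionResult(idx, y_new if len(idx) else np.array([]), report))

    if n_selected_total == 0:
        return initial, results
    final = fit_ridge(
        np.vstack(pool_X),
        np.concatenate(pool_y),
        lam,
        feature_names=target_train.feature_names,
    )
    return final, results
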