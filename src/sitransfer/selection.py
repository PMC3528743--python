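"""Correlation-based feature selection for siRNA design.

Two modes share one scoring path:

* *single-dataset* mode scores each feature against efficacy on the
  target data alone (Pearson r, its t-distributed significance, and an
  active-vs-inactive two-sample t-test), then keeps features with
  |r| >= 0.1 whose significance passes 0.05;
* *post-transfer* mode repeats the HEGS augmentation many times with
  fresh seeds, reruns the same selection on each augmented set, and
  ranks features by how often they are selected (frequency of
  occurrence), which is far more stable than a single pass on a scarce
  target set.

No multiple-testing correction is applied; raw p-values are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import ACTIVE_THRESHOLD, DomainDataset
from .transfer import TransferConfig, hegs_fit


@dataclass
class FeatureScore:
    """Association of one feature with siRNA efficacy."""

    feature_id: int
    name: str
    r: float
    p_r: float
    p_group: float  # NaN when the active/inactive split is degenerate
    frequency: Optional[int] = None


def _pearson_with_p(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson r per column and two-sided p from the t statistic.

    Constant columns get r = 0, p = 1.
    """
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    denom = sx * sy
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, Xc.T @ yc / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(denom > 0, p, 1.0)
    r = np.where(denom > 0, r, 0.0)
    return r, p


def score_features(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    active_threshold: float = ACTIVE_THRESHOLD,
) -> list[FeatureScore]:
    """Score every feature column against efficacy.

    ``p_r`` is the significance of the Pearson correlation; ``p_group``
    is a two-sample t-test of the feature values between active
    (y < active_threshold) and inactive siRNAs, NaN when either group is
    empty.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to score features")
    r, p_r = _pearson_with_p(X, y)
    active = y < active_threshold
    if active.any() and (~active).any():
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            # near-constant columns trigger harmless precision warnings
            warnings.simplefilter("ignore", RuntimeWarning)
            _, p_group = stats.ttest_ind(X[active], X[~active], axis=0)
        p_group = np.where(np.isfinite(p_group), p_group, np.nan)
    else:
        p_group = np.full(X.shape[1], np.nan)
    return [
        FeatureScore(j, feature_names[j], float(r[j]), float(p_r[j]), float(p_group[j]))
        for j in range(X.shape[1])
    ]


def select_features(
    scores: Sequence[FeatureScore],
    r_min: float = 0.1,
    alpha: float = 0.05,
    significance: str = "p_r",
) -> list[FeatureScore]:
    """Keep features with |r| >= r_min (inclusive) and significance < alpha.

    ``significance`` chooses the gating p-value: "p_r" (correlation
    significance, the default) or "p_group" (active/inactive t-test).
    Result is ranked by |r| descending.
    """
    if significance not in ("p_r", "p_group"):
        raise ValueError("significance must be 'p_r' or 'p_group'")
    kept = []
    for s in scores:
        p = s.p_r if significance == "p_r" else s.p_group
        if abs(s.r) >= r_min and np.isfinite(p) and p < alpha:
            kept.append(s)
    return sorted(kept, key=lambda s: (-abs(s.r), s.feature_id))


def hegs_frequency_ranking(
    target_train: DomainDataset,
    source_tasks: Sequence[DomainDataset],
    config: TransferConfig | None = None,
    repeats: int = 1000,
    top_m: int = 28,
    lam: float = 1.0,
    r_min: float = 0.1,
    alpha: float = 0.05,
    active_threshold: float = ACTIVE_THRESHOLD,
    significance: str = "p_r",
) -> pd.DataFrame:
    """Frequency ranking of features over repeated HEGS augmentations.

    Each repeat reruns the transfer with a fresh seed, scores and
    selects features on the augmented training set, and increments the
    count of every selected feature.  Returns the ``top_m`` features by
    frequency (ties broken by mean |r| across repeats, then feature id)
    as a tidy frame with columns rank, name, frequency, mean_r,
    mean_abs_r, sign.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if config is None:
        config = TransferConfig()
    names = target_train.feature_names
    if names is None:
        names = [f"f{j}" for j in range(target_train.X.shape[1])]
    n_feat = target_train.X.shape[1]
    counts = np.zeros(n_feat, dtype=int)
    r_sums = np.zeros(n_feat)
    r_abs_sums = np.zeros(n_feat)
    for rep in range(repeats):
        cfg = replace(config, seed=config.seed + 104729 * rep)
        _, selections = hegs_fit(target_train, source_tasks, cfg, lam)
        X_aug = [target_train.X]
        y_aug = [target_train.y]
        for task, sel in zip(source_tasks, selections):
            if len(sel.selected_indices):
                X_aug.append(task.X[sel.selected_indices])
                y_aug.append(sel.generated_outputs)
        X = np.vstack(X_aug)
        y = np.concatenate(y_aug)
        scores = score_features(X, y, names, active_threshold)
        for s in scores:
            r_sums[s.feature_id] += s.r
            r_abs_sums[s.feature_id] += abs(s.r)
        for s in select_features(scores, r_min, alpha, significance):
            counts[s.feature_id] += 1
    mean_r = r_sums / repeats
    mean_abs_r = r_abs_sums / repeats
    order = sorted(
        range(n_feat), key=lambda j: (-counts[j], -mean_abs_r[j], j)
    )[:top_m]
    frame = pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "name": [names[j] for j in order],
            "frequency": counts[order],
            "mean_r": mean_r[order],
            "mean_abs_r": mean_abs_r[order],
            "sign": ["+" if mean_r[j] >= 0 else "-" for j in order],
        }
    )
    return frame
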