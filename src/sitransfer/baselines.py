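"""Comparison strategies: single-domain baseline and the simply-combined
model (SCM).

The baseline is a plain ridge fit on the target training data.  SCM
pools all source domains with the target training data after per-domain
min-max normalization of the source outputs -- the naive integration
strategy that assumes the source output spaces map linearly onto the
target's, which heterogeneous efficacy scales break.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import DomainDataset
from .ridge import RidgeModel, fit_ridge


class DegenerateDomainError(ValueError):
    """A domain whose outputs are all identical cannot be min-max scaled."""


@dataclass(frozen=True)
class NormalizationSpec:
    method: str = "min-max"
    per_domain: bool = True
    target_range: tuple[float, float] = (0.0, 1.0)


def minmax_normalize(y: np.ndarray, target_range: tuple[float, float] = (0.0, 1.0)) -> np.ndarray:
    """(y - min) / (max - min), rescaled to ``target_range``."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 values to min-max normalize")
    lo, hi = float(y.min()), float(y.max())
    if hi == lo:
        raise DegenerateDomainError("constant output vector (max == min)")
    unit = (y - lo) / (hi - lo)
    a, b = target_range
    return a + unit * (b - a)


def fit_baseline(target_train: DomainDataset, lam: float = 1.0) -> RidgeModel:
    """Single-domain ridge model on the target training data only."""
    return fit_ridge(
        target_train.X, target_train.y, lam, feature_names=target_train.feature_names
    )


def fit_scm(
    target_train: DomainDataset,
    source_tasks: Sequence[DomainDataset],
    lam: float = 1.0,
    norm: NormalizationSpec = NormalizationSpec(),
) -> RidgeModel:
    """Simply-combined model: pool all domains after output normalization.

    Source outputs are min-max normalized per domain onto
    ``norm.target_range`` (the scale target efficacies live on); the
    target training outputs are used as-is.  A single ridge model is fit
    on the pooled set.  With no sources this is exactly the baseline.
    """
    if not source_tasks:
        return fit_baseline(target_train, lam)
    pool_X = [target_train.X]
    pool_y = [target_train.y]
    for task in source_tasks:
        y = task.y
        if norm.per_domain and norm.method == "min-max":
            y = minmax_normalize(y, norm.target_range)
        pool_X.append(task.X)
        pool_y.append(y)
    return fit_ridge(
        np.vstack(pool_X),
        np.concatenate(pool_y),
        lam,
        feature_names=target_train.feature_names,
    )
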