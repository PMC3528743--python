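"""Evaluation harness: RMSE, paired t-tests, training-fraction sweeps,
source-accumulation trajectories, and repeated k-fold cross-validation.

Every comparison uses a *paired* design: within one run all methods see
the identical target train/test split, so per-run RMSE differences are
directly comparable and paired t-tests across runs (or across domains)
are valid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .records import DomainDataset
from .ridge import RidgeModel, fit_ridge, predict

#: a method maps (target_train, source_tasks, seed) to a fitted model
MethodFn = Callable[[DomainDataset, Sequence[DomainDataset], int], RidgeModel]


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean square error."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if y_true.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


@dataclass(frozen=True)
class TTestResult:
    """Two-sided paired t-test; iterable as (t, p)."""

    t: float
    p: float
    zero_variance: bool = False

    def __iter__(self):
        return iter((self.t, self.p))


def paired_t_test(a: np.ndarray, b: np.ndarray) -> TTestResult:
    """Two-sided paired t-test on per-run (or per-domain) differences.

    Constant differences (zero variance) cannot be tested and are
    flagged instead of producing a spurious p-value.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = a - b
    if np.allclose(d, d[0]):
        return TTestResult(np.nan, np.nan, zero_variance=True)
    res = stats.ttest_rel(a, b)
    return TTestResult(float(res.statistic), float(res.pvalue))


@dataclass
class ExperimentResult:
    method: str
    domain: str
    train_fraction: float
    run_seeds: list[int]
    rmse_per_run: np.ndarray
    mean_rmse: float


def split_dataset(
    dataset: DomainDataset, train_fraction: float, seed: int
) -> tuple[DomainDataset, DomainDataset]:
    """Seeded uniform random train/test split (no stratification)."""
    n = dataset.n
    n_train = int(round(train_fraction * n))
    if not (1 <= n_train < n):
        raise ValueError(
            f"fraction {train_fraction} leaves an empty split for n={n}"
        )
    perm = np.random.default_rng(seed).permutation(n)
    return (
        dataset.subset(perm[:n_train], role="target"),
        dataset.subset(perm[n_train:], role="target"),
    )


def fraction_sweep(
    domain_sets: Sequence[DomainDataset],
    methods: Mapping[str, MethodFn],
    fractions: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9),
    n_runs: int = 10,
    seed: int = 0,
    target_names: Optional[Sequence[str]] = None,
) -> list[ExperimentResult]:
    """Rotate each domain through the target role and sweep training size.

    For every (target domain, fraction, run): split the target domain,
    fit each method on the identical split with the other domains as
    sources, and record held-out RMSE.  Averages over ``n_runs``.
    """
    results: list[ExperimentResult] = []
    for d_idx, target in enumerate(domain_sets):
        if target_names is not None and target.name not in target_names:
            continue
        sources = [d for i, d in enumerate(domain_sets) if i != d_idx]
        for frac in fractions:
            run_seeds = [seed + 10007 * d_idx + 101 * int(frac * 100) + r
                         for r in range(n_runs)]
            per_method: dict[str, list[float]] = {m: [] for m in methods}
            for run_seed in run_seeds:
                train, test = split_dataset(target, frac, run_seed)
                for mname, fn in methods.items():
                    model = fn(train, sources, run_seed)
                    per_method[mname].append(rmse(test.y, predict(model, test.X)))
            for mname in methods:
                arr = np.array(per_method[mname])
                results.append(
                    ExperimentResult(
                        method=mname,
                        domain=target.name,
                        train_fraction=frac,
                        run_seeds=run_seeds,
                        rmse_per_run=arr,
                        mean_rmse=float(arr.mean()),
                    )
                )
    return results


def results_to_frame(results: Sequence[ExperimentResult]) -> pd.DataFrame:
    """Tidy frame: one row per (method, domain, fraction, run)."""
    rows = []
    for r in results:
        for run, (s, v) in enumerate(zip(r.run_seeds, r.rmse_per_run)):
            rows.append(
                {
                    "method": r.method,
                    "domain": r.domain,
                    "fraction": r.train_fraction,
                    "run": run,
                    "seed": s,
                    "rmse": v,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AccumulationResult:
    """Mean RMSE after adding 0, 1, ..., n source tasks."""

    trajectory: np.ndarray  # length n_sources + 1; entry 0 is the baseline
    baseline_rmse: float
    homolog_rmse: Optional[float]


def accumulation_experiment(
    target: DomainDataset,
    source_pool: Sequence[DomainDataset],
    method: MethodFn,
    order_seed: int = 0,
    n_repeats: int = 10,
    train_fraction: float = 0.5,
    homolog: Optional[DomainDataset] = None,
) -> AccumulationResult:
    """Add source tasks one by one in random order and track held-out RMSE.

    Step j fits ``method`` with the first j sources of a per-repeat
    random ordering; step 0 is the no-transfer baseline.  Optionally
    reports a homolog-only reference (transfer from a single designated
    source).  Averages over ``n_repeats`` reshuffled orders and splits.
    """
    if len(source_pool) < 2:
        raise ValueError("need at least 2 source tasks")
    n_steps = len(source_pool) + 1
    traj = np.zeros(n_steps)
    homolog_vals = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(order_seed + rep)
        order = rng.permutation(len(source_pool))
        train, test = split_dataset(target, train_fraction, order_seed + 7919 * rep)
        for j in range(n_steps):
            sources = [source_pool[i] for i in order[:j]]
            model = method(train, sources, order_seed + rep)
            traj[j] += rmse(test.y, predict(model, test.X))
        if homolog is not None:
            model = method(train, [homolog], order_seed + rep)
            homolog_vals.append(rmse(test.y, predict(model, test.X)))
    traj /= n_repeats
    return AccumulationResult(
        trajectory=traj,
        baseline_rmse=float(traj[0]),
        homolog_rmse=float(np.mean(homolog_vals)) if homolog_vals else None,
    )


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    fit_fn: Callable[[np.ndarray, np.ndarray], RidgeModel] | None = None,
    k: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
) -> float:
    """Repeated k-fold cross-validated RMSE.

    Every sample appears in exactly one test fold per repeat; folds are
    reshuffled between repeats.  ``fit_fn`` defaults to a lambda-1 ridge
    fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < k:
        raise ValueError(f"n={X.shape[0]} < k={k}")
    if fit_fn is None:
        fit_fn = lambda Xa, ya: fit_ridge(Xa, ya, 1.0)  # noqa: E731
    vals = []
    for rep in range(n_repeats):
        kf = KFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for train_idx, test_idx in kf.split(X):
            model = fit_fn(X[train_idx], y[train_idx])
            vals.append(rmse(y[test_idx], predict(model, X[test_idx])))
    return float(np.mean(vals))
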