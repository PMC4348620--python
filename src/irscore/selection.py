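"""Two-stage feature selection over pattern-frequency features.

Stage 1 ranks features by an mRMR-style criterion — mutual information with
the class label minus mean mutual information with already-selected
features (both estimated after quantile binning, since pattern frequencies
live in [0, 1] with heavy mass at zero).  Stage 2 refines the subset with a
sequential floating add/remove search whose objective is inner-cross-
validated pairwise ranking accuracy; a step is accepted only if it strictly
improves the objective beyond a tolerance, so the objective trace is
non-decreasing and the search terminates.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)


def _as_codes(x: np.ndarray) -> np.ndarray:
    _, codes = np.unique(x, return_inverse=True)
    return codes


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI (nats) between two discrete variables via a bincount contingency
    table; equivalent to sklearn's mutual_info_score but with negligible
    call overhead for the many small evaluations the greedy search makes."""
    a, b = _as_codes(a), _as_codes(b)
    na, nb = a.max() + 1, b.max() + 1
    cont = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb).astype(float)
    n = cont.sum()
    pij = cont / n
    pi = pij.sum(axis=1, keepdims=True)
    pj = pij.sum(axis=0, keepdims=True)
    nz = pij > 0
    return float((pij[nz] * np.log(pij[nz] / (pi @ pj)[nz])).sum())


@dataclass
class SelectionConfig:
    k0: int = 30                 # stage-1 target subset size
    n_mi_bins: int = 10          # quantile bins for MI estimation
    tolerance: float = 1e-6      # minimum objective improvement to accept a step
    max_iterations: int = 20     # refinement sweeps cap
    inner_folds: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.k0 < 1:
            raise ValueError("k0 must be >= 1")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")


def _quantile_bin(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize a feature to quantile bins (ties collapse duplicate edges)."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, x, side="right")


def rank_relevance_redundancy(
    features: np.ndarray,
    labels: np.ndarray,
    config: SelectionConfig,
) -> list[int]:
    """Greedy mRMR ordering; returns up to k0 feature indices.

    The first feature maximizes relevance MI(feature; label); each subsequent
    feature maximizes relevance minus mean redundancy MI to the already
    selected set.  Deterministic: ties break toward the lower feature index.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    n, k = X.shape
    k_target = config.k0
    if k_target > k:
        warnings.warn(f"k0={k_target} exceeds available features ({k}); returning all")
        k_target = k

    binned = [ _quantile_bin(X[:, j], config.n_mi_bins) for j in range(k) ]
    relevance = np.array([mutual_information(y, bj) for bj in binned])

    selected: list[int] = []
    remaining = list(range(k))
    # cache pairwise MI lazily
    mi_cache: dict[tuple[int, int], float] = {}

    def red(a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        if key not in mi_cache:
            mi_cache[key] = mutual_information(binned[a], binned[b])
        return mi_cache[key]

    first = int(np.argmax(relevance))
    selected.append(first)
    remaining.remove(first)
    while len(selected) < k_target and remaining:
        best_j, best_score = None, -np.inf
        for j in remaining:
            score = relevance[j] - np.mean([red(j, s) for s in selected])
            if score > best_score + 1e-15:
                best_j, best_score = j, score
        selected.append(best_j)
        remaining.remove(best_j)
    return selected


def mrmr_criterion(j: int, selected: Sequence[int], features: np.ndarray,
                   labels: np.ndarray, n_bins: int = 10) -> float:
    """The greedy criterion for candidate j given a selected set (oracle hook)."""
    bj = _quantile_bin(features[:, j], n_bins)
    rel = mutual_information(labels, bj)
    if not selected:
        return rel
    reds = [mutual_information(bj, _quantile_bin(features[:, s], n_bins))
            for s in selected]
    return rel - float(np.mean(reds))


@dataclass
class RefinementResult:
    subset: list[int]
    objective_trace: list[float]


def refine_subset(
    initial: Sequence[int],
    features: np.ndarray,
    objective: Callable[[Sequence[int]], float],
    config: SelectionConfig,
) -> RefinementResult:
    """Sequential floating add/remove refinement of a feature subset.

    ``objective`` maps a subset of feature indices to a score (typically
    inner-CV pairwise ranking accuracy); it must be deterministic.  Each
    sweep tries the single best addition then the single best removal,
    accepting only strict improvements > tolerance.  The trace of accepted
    objective values is non-decreasing by construction.
    """
    if len(initial) == 0:
        raise ValueError("initial subset must be nonempty")
    subset = list(initial)
    k = features.shape[1]
    current = objective(subset)
    trace = [current]
    for _ in range(config.max_iterations):
        changed = False
        # best single addition
        candidates = [j for j in range(k) if j not in subset]
        if candidates:
            scores = [(objective(subset + [j]), j) for j in candidates]
            best_score, best_j = max(scores, key=lambda t: (t[0], -t[1]))
            if best_score > current + config.tolerance:
                subset.append(best_j)
                current = best_score
                trace.append(current)
                changed = True
        # best single removal (keep at least one feature)
        if len(subset) > 1:
            scores = [
                (objective([s for s in subset if s != j]), j) for j in subset
            ]
            best_score, best_j = max(scores, key=lambda t: (t[0], -t[1]))
            if best_score > current + config.tolerance:
                subset = [s for s in subset if s != best_j]
                current = best_score
                trace.append(current)
                changed = True
        if not changed:
            break
    return RefinementResult(subset, trace)


def selection_report(result: RefinementResult, config: SelectionConfig) -> str:
    return json.dumps({
        "selected_features": list(map(int, result.subset)),
        "objective_trace": result.objective_trace,
        "config": {
            "k0": config.k0, "n_mi_bins": config.n_mi_bins,
            "tolerance": config.tolerance,
            "max_iterations": config.max_iterations,
            "inner_folds": config.inner_folds, "seed": config.seed,
        },
    }, indent=1)
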