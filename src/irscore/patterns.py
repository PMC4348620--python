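"""Discretization, frequent-pattern mining and discriminative pattern features.

Per-pixel metric values are discretized into equal-width bins; a *pattern*
is a set of (metric, bin) items, and a pixel matches a pattern when all its
items hold.  Frequent patterns (support >= theta * n pixels) are mined per
outcome class with FP-growth, screened by a two-stage rank test on
per-subject match frequencies, and the per-sample frequencies of the top-m
survivors form the feature vector fed to the ranking model.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass
class DiscretizationScheme:
    """Equal-width binning per metric, fitted on training pixels only.

    ``edges[j]`` holds n_bins+1 strictly increasing edges spanning the
    training range of metric j; ``representatives[j]`` the bin midpoints.
    Bins are half-open [lo, hi) with the last bin closed; out-of-range test
    values clip to the extreme bins.
    """

    metric_names: list[str]
    edges: list[np.ndarray]
    representatives: list[np.ndarray]
    n_bins: int

    def bin_of(self, metric_index: int, value: float) -> int:
        e = self.edges[metric_index]
        width = (e[-1] - e[0]) / self.n_bins
        if width == 0:
            return 0
        b = int(np.floor((value - e[0]) / width))
        return min(max(b, 0), self.n_bins - 1)


def fit_discretizer(matrix, n_bins: int = 20) -> DiscretizationScheme:
    """Fit equal-width bin edges spanning [min, max] of each metric column."""
    values = matrix.values
    if values.shape[0] < 2:
        raise ValueError("need at least 2 pixels to fit a discretizer")
    edges, reps = [], []
    for j in range(values.shape[1]):
        lo, hi = float(values[:, j].min()), float(values[:, j].max())
        if lo == hi:
            warnings.warn(
                f"metric {matrix.metric_names[j]!r} is constant; degenerate single bin",
                stacklevel=2,
            )
            e = np.linspace(lo, lo + 1.0, n_bins + 1)  # arbitrary width, all values -> bin 0
        else:
            e = np.linspace(lo, hi, n_bins + 1)
        edges.append(e)
        reps.append((e[:-1] + e[1:]) / 2.0)
    return DiscretizationScheme(list(matrix.metric_names), edges, reps, n_bins)


def discretize(values: np.ndarray, scheme: DiscretizationScheme,
               metric_names: Sequence[str] | None = None) -> np.ndarray:
    """Map an n x k value array to integer bin indices in [0, n_bins-1]."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != len(scheme.metric_names):
        raise ValueError("column count does not match scheme")
    if metric_names is not None and list(metric_names) != scheme.metric_names:
        raise ValueError("metric names do not match scheme")
    out = np.empty(values.shape, dtype=np.int32)
    for j in range(values.shape[1]):
        e = scheme.edges[j]
        width = (e[-1] - e[0]) / scheme.n_bins
        if width == 0:
            out[:, j] = 0
            continue
        b = np.floor((values[:, j] - e[0]) / width).astype(np.int64)
        out[:, j] = np.clip(b, 0, scheme.n_bins - 1)
    return out


# ---------------------------------------------------------------------------
# patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pattern:
    """A set of (metric index, bin index) items with per-class support."""

    items: frozenset  # of (metric_index, bin_index)
    source_class: str | None = None  # "case" | "control" | None
    support_case: float | None = None
    support_control: float | None = None

    def __post_init__(self):
        if len(self.items) == 0:
            raise ValueError("pattern items must be nonempty")
        metrics = [m for m, _ in self.items]
        if len(set(metrics)) != len(metrics):
            raise ValueError("at most one item per metric index")
        for s in (self.support_case, self.support_control):
            if s is not None and not (0.0 <= s <= 1.0):
                raise ValueError("supports must lie in [0, 1]")

    @property
    def sorted_items(self) -> tuple:
        return tuple(sorted(self.items))

    def canonical_key(self) -> tuple:
        return (len(self.items), self.sorted_items)

    def __repr__(self):
        items = ",".join(f"(m{m},b{b})" for m, b in self.sorted_items)
        return f"Pattern[{items}]"


@dataclass
class MiningConfig:
    theta: float = 0.02          # minimum support fraction
    max_len: int | None = 4      # cap on pattern cardinality
    n_bins: int = 20

    def __post_init__(self):
        if not 0 < self.theta <= 1:
            raise ValueError("theta must lie in (0, 1]")


def _count_threshold(theta: float, n: int) -> int:
    # "no less than theta*|D|": minimal integer count c with c >= theta*n
    return max(1, int(math.ceil(theta * n - 1e-9)))


# --- FP-growth -------------------------------------------------------------

class _FPNode:
    __slots__ = ("item", "count", "parent", "children", "link")

    def __init__(self, item, parent):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children = {}
        self.link = None


def _build_fptree(transactions: Iterable[tuple], counts: Iterable[int],
                  item_order: dict) -> tuple[_FPNode, dict]:
    root = _FPNode(None, None)
    headers: dict = {}
    tails: dict = {}
    for txn, cnt in zip(transactions, counts):
        items = sorted((i for i in txn if i in item_order), key=lambda i: item_order[i])
        node = root
        for it in items:
            child = node.children.get(it)
            if child is None:
                child = _FPNode(it, node)
                node.children[it] = child
                if it in tails:
                    tails[it].link = child
                else:
                    headers[it] = child
                tails[it] = child
            child.count += cnt
            node = child
    return root, headers


def _fpgrowth(transactions: list[tuple], counts: list[int], min_count: int,
              max_len: int | None, suffix: tuple, out: dict) -> None:
    # item support in this (conditional) database
    support: dict = {}
    for txn, cnt in zip(transactions, counts):
        for it in txn:
            support[it] = support.get(it, 0) + cnt
    frequent = {it: c for it, c in support.items() if c >= min_count}
    if not frequent:
        return
    # deterministic order: support desc, item asc
    order = {it: r for r, it in enumerate(
        sorted(frequent, key=lambda it: (-frequent[it], it)))}
    _, headers = _build_fptree(transactions, counts, order)
    # process items least-frequent first
    for it in sorted(frequent, key=lambda it: (frequent[it], it)):
        new_suffix = suffix + (it,)
        out[frozenset(new_suffix)] = frequent[it]
        if max_len is not None and len(new_suffix) >= max_len:
            continue
        # conditional pattern base for `it`
        cond_txns, cond_counts = [], []
        node = headers.get(it)
        while node is not None:
            path = []
            p = node.parent
            while p is not None and p.item is not None:
                path.append(p.item)
                p = p.parent
            if path:
                cond_txns.append(tuple(reversed(path)))
                cond_counts.append(node.count)
            node = node.link
        if cond_txns:
            _fpgrowth(cond_txns, cond_counts, min_count, max_len, new_suffix, out)


def mine_frequent_patterns(discretized: np.ndarray, config: MiningConfig) -> list[Pattern]:
    """All patterns matched by at least ceil(theta * n) pixels, via FP-growth.

    Output is canonically ordered (by cardinality, then lexicographic items)
    with each pattern's support fraction recorded in ``support_case`` (the
    caller relabels per class).
    """
    disc = np.asarray(discretized)
    n, k = disc.shape
    if n < 1:
        raise ValueError("empty pixel matrix")
    min_count = _count_threshold(config.theta, n)
    # every pixel is a transaction of exactly k (metric, bin) items
    transactions = [tuple((j, int(disc[i, j])) for j in range(k)) for i in range(n)]
    found: dict = {}
    _fpgrowth(transactions, [1] * n, min_count, config.max_len, (), found)
    patterns = [
        Pattern(items=items, support_case=cnt / n)
        for items, cnt in found.items()
    ]
    patterns.sort(key=lambda p: p.canonical_key())
    return patterns


def pattern_support(pattern: Pattern, discretized: np.ndarray) -> float:
    """Fraction of pixels matching every item of the pattern."""
    disc = np.asarray(discretized)
    if disc.shape[0] == 0:
        raise ValueError("empty pixel matrix")
    mask = np.ones(disc.shape[0], dtype=bool)
    for m, b in pattern.items:
        mask &= disc[:, m] == b
    return float(mask.mean())


def enumerate_frequent_patterns(discretized: np.ndarray, config: MiningConfig) -> list[Pattern]:
    """Brute-force itemset enumeration; independent oracle for the miner.

    Enumerates every combination of metrics and every observed bin value per
    metric, counting support directly.  Exponential — only for tiny inputs.
    """
    disc = np.asarray(discretized)
    n, k = disc.shape
    min_count = _count_threshold(config.theta, n)
    max_len = config.max_len if config.max_len is not None else k
    out = []
    for r in range(1, min(k, max_len) + 1):
        for metrics in itertools.combinations(range(k), r):
            observed = [np.unique(disc[:, m]) for m in metrics]
            for bins in itertools.product(*observed):
                mask = np.ones(n, dtype=bool)
                for m, b in zip(metrics, bins):
                    mask &= disc[:, m] == b
                cnt = int(mask.sum())
                if cnt >= min_count:
                    items = frozenset(zip(metrics, (int(b) for b in bins)))
                    out.append(Pattern(items=items, support_case=cnt / n))
    out.sort(key=lambda p: p.canonical_key())
    return out


# ---------------------------------------------------------------------------
# per-subject frequencies
# ---------------------------------------------------------------------------

def pattern_match_matrix(patterns: Sequence[Pattern], discretized: np.ndarray) -> np.ndarray:
    """Boolean matrix (n_pixels x n_patterns) of pattern matches."""
    disc = np.asarray(discretized)
    n = disc.shape[0]
    out = np.empty((n, len(patterns)), dtype=bool)
    for j, p in enumerate(patterns):
        mask = np.ones(n, dtype=bool)
        for m, b in p.items:
            mask &= disc[:, m] == b
        out[:, j] = mask
    return out


def subject_pattern_frequencies(
    patterns: Sequence[Pattern],
    discretized: np.ndarray,
    subject_index: np.ndarray,
    n_subjects: int,
) -> np.ndarray:
    """Per-subject pooled match fractions (n_subjects x n_patterns).

    A subject's frequency is the fraction of *all* their eligible pixels
    (pooled over cores) that match the pattern, weighting by pixel evidence.
    """
    subject_index = np.asarray(subject_index)
    counts = np.bincount(subject_index, minlength=n_subjects).astype(float)
    if np.any(counts == 0):
        raise ValueError("every subject must contribute at least one pixel")
    match = pattern_match_matrix(patterns, discretized).astype(np.float32)
    order = np.argsort(subject_index, kind="stable")
    starts = np.searchsorted(subject_index[order], np.arange(n_subjects))
    sums = np.add.reduceat(match[order], starts, axis=0)
    return sums / counts[:, None]


# ---------------------------------------------------------------------------
# discriminative selection (two-stage rank test)
# ---------------------------------------------------------------------------

@dataclass
class DiscriminativeConfig:
    m: int = 100           # retained pattern count
    alpha1: float = 0.05   # stage-1 two-sided significance level

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0 < self.alpha1 < 1:
            raise ValueError("alpha1 must lie in (0, 1)")


def _mannwhitney_vectorized(x: np.ndarray, y: np.ndarray):
    """Row-wise Mann-Whitney U (x vs y) with tie-corrected normal approximation.

    x: (rows x n1), y: (rows x n2).  Returns (U, z) where z is the
    standardized statistic for 'x tends larger'.
    """
    n1, n2 = x.shape[1], y.shape[1]
    combined = np.concatenate([x, y], axis=1)
    ranks = rankdata(combined, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction per row: sum of (t^3 - t) over tie-group sizes t,
    # computed via vectorized run-length encoding of the sorted rows
    n = n1 + n2
    nrows = combined.shape[0]
    srt = np.sort(combined, axis=1)
    new_group = np.concatenate(
        [np.ones((nrows, 1), dtype=bool), srt[:, 1:] != srt[:, :-1]], axis=1
    )
    gid = np.cumsum(new_group, axis=1) - 1  # per-row tie-group ids, < n
    flat = (np.arange(nrows)[:, None] * n + gid).ravel()
    sizes = np.bincount(flat, minlength=nrows * n).reshape(nrows, n).astype(np.float64)
    tie_term = (sizes**3 - sizes).sum(axis=1)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, (u - mu) / sigma, 0.0)
    return u, z


@dataclass
class DiscriminativeResult:
    pattern: Pattern
    p_two_sided: float
    p_one_sided: float
    effect: float  # rank-biserial correlation toward the source class


def select_discriminative_patterns(
    patterns: Sequence[Pattern],
    freq_case: np.ndarray,     # (n_patterns x n_case_subjects)
    freq_control: np.ndarray,  # (n_patterns x n_control_subjects)
    config: DiscriminativeConfig,
) -> list[DiscriminativeResult]:
    """Two-stage screen of candidate patterns.

    Stage 1 keeps patterns whose per-subject frequency distributions differ
    between classes (two-sided rank-sum, p < alpha1).  Stage 2 keeps those
    whose frequencies are one-sidedly larger in the pattern's source class.
    Survivors are ranked by stage-2 p ascending, ties broken by |effect|
    descending then canonical pattern order; the top m are returned.
    """
    if freq_case.shape[1] < 2 or freq_control.shape[1] < 2:
        raise ValueError("need at least 2 subjects per class")
    if len(patterns) == 0:
        return []
    u, z = _mannwhitney_vectorized(freq_case, freq_control)
    n1, n2 = freq_case.shape[1], freq_control.shape[1]
    p_two = 2.0 * stats.norm.sf(np.abs(z))
    # one-sided in the direction of each pattern's source class
    direction = np.array([1.0 if p.source_class != "control" else -1.0 for p in patterns])
    p_one = stats.norm.sf(direction * z)
    effect = direction * (2.0 * u / (n1 * n2) - 1.0)  # rank-biserial toward source class

    survivors = []
    for i, p in enumerate(patterns):
        if p_two[i] >= config.alpha1:
            continue  # stage 1
        if p_one[i] > config.alpha1 / 2.0:
            continue  # stage 2: not one-sidedly larger in source class
        survivors.append(DiscriminativeResult(p, float(p_two[i]), float(p_one[i]),
                                              float(effect[i])))
    if not survivors:
        logger.warning("select_discriminative_patterns: no pattern survived the two stages")
        return []
    survivors.sort(key=lambda r: (r.p_one_sided, -abs(r.effect), r.pattern.canonical_key()))
    return survivors[: config.m]


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    sample_id: str
    values: np.ndarray  # per-pattern match fraction, in [0, 1]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("feature values must lie in [0, 1]")


def compute_pattern_features(
    discretized_sample: np.ndarray,
    patterns: Sequence[Pattern],
    sample_id: str = "",
) -> FeatureVector:
    """Fraction of the sample's pixels matching each retained pattern."""
    if len(patterns) == 0:
        raise ValueError("patterns must be nonempty")
    disc = np.asarray(discretized_sample)
    if disc.shape[0] == 0:
        raise ValueError("sample has no pixels")
    match = pattern_match_matrix(patterns, disc)
    return FeatureVector(sample_id, match.mean(axis=0))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def patterns_to_json(results: Sequence[DiscriminativeResult]) -> str:
    payload = []
    for r in results:
        payload.append({
            "items": [list(it) for it in r.pattern.sorted_items],
            "source_class": r.pattern.source_class,
            "support_case": r.pattern.support_case,
            "support_control": r.pattern.support_control,
            "p_two_sided": r.p_two_sided,
            "p_one_sided": r.p_one_sided,
            "effect": r.effect,
        })
    return json.dumps(payload, indent=1)
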