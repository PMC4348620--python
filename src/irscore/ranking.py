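"""Ranking-SVM training, rank-preference scores and the logistic IR Score.

The classifier is a linear Ranking-SVM fitted by the pairwise transform:
every ordered constraint "case core s should outrank control core t" becomes
a hinge-loss example on the difference vector s - t.  Patient-level
comparison aggregates core ranks into a preference score
``Preference(p1; p2) = sum over s in S1 of rank(s)^d`` computed on the
pooled ranks of S1 and S2, normalized by its attainable extremes to
``nPreference`` in [0, 1]; at d = 1 without ties this is exactly the
normalized Mann-Whitney U of patient 1's cores over patient 2's.

A clinical unknown is scored by a lookup: find the most clinically similar
recurrent and non-recurrent training patients, compute nPreference against
each, and map the two covariates to a predicted probability of recurrence
(the "IR Score") with a logistic regression model.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .tissue import ClinicalRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Ranking-SVM
# ---------------------------------------------------------------------------

@dataclass
class RankingModel:
    """Linear scoring function f(x) = w . z(x) over z-scored features."""

    weights: np.ndarray
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    C: float
    training_pairwise_accuracy: float

    def score(self, samples: np.ndarray) -> np.ndarray:
        X = (np.asarray(samples, dtype=float) - self.scaler_mean) / self.scaler_scale
        if X.shape[1] != len(self.weights):
            raise ValueError("feature dimension mismatch")
        return X @ self.weights


def _pairwise_differences(
    case_samples: np.ndarray,
    control_samples: np.ndarray,
    case_patients: np.ndarray,
    control_patients: np.ndarray,
    pairing: Sequence[tuple[str, str]] | None,
    max_constraints: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Difference vectors (case core - control core) for the ordered constraints.

    With an explicit case-control ``pairing`` only within-pair core
    combinations are used (nested design); otherwise all case x control core
    combinations, subsampled to ``max_constraints`` when larger.
    """
    diffs = []
    if pairing is not None:
        ctrl_of = dict(pairing)
        by_case = {p: np.flatnonzero(case_patients == p) for p in ctrl_of}
        by_ctrl = {c: np.flatnonzero(control_patients == c) for c in ctrl_of.values()}
        for case_pid, ctrl_pid in pairing:
            for i in by_case[case_pid]:
                for j in by_ctrl[ctrl_pid]:
                    diffs.append(case_samples[i] - control_samples[j])
        diffs = np.asarray(diffs)
    else:
        n1, n2 = len(case_samples), len(control_samples)
        total = n1 * n2
        if total > max_constraints:
            idx = rng.choice(total, size=max_constraints, replace=False)
        else:
            idx = np.arange(total)
        i, j = idx // n2, idx % n2
        diffs = case_samples[i] - control_samples[j]
    return np.asarray(diffs, dtype=float)


def train_ranking_svm(
    case_samples: np.ndarray,
    control_samples: np.ndarray,
    case_patients: np.ndarray | None = None,
    control_patients: np.ndarray | None = None,
    pairing: Sequence[tuple[str, str]] | None = None,
    C: float = 1.0,
    feature_names: Sequence[str] | None = None,
    max_constraints: int = 100_000,
    seed: int = 0,
) -> RankingModel:
    """Fit the linear Ranking-SVM so case cores outrank control cores.

    Features are z-scored on the pooled training cores; each ordered
    constraint contributes the two symmetric hinge examples (s - t, +1) and
    (t - s, -1), and the separating direction w is the scoring function.
    """
    case_samples = np.asarray(case_samples, dtype=float)
    control_samples = np.asarray(control_samples, dtype=float)
    if case_samples.ndim != 2 or control_samples.ndim != 2:
        raise ValueError("sample arrays must be 2-D (cores x features)")
    pooled = np.vstack([case_samples, control_samples])
    mean = pooled.mean(axis=0)
    scale = pooled.std(axis=0)
    if np.all(scale == 0):
        raise ValueError("degenerate model: all training features identical")
    scale = np.where(scale == 0, 1.0, scale)
    zc = (case_samples - mean) / scale
    zt = (control_samples - mean) / scale

    rng = np.random.default_rng(seed)
    if pairing is not None:
        if case_patients is None or control_patients is None:
            raise ValueError("pairing requires patient ids for the samples")
        diffs = _pairwise_differences(zc, zt, np.asarray(case_patients),
                                      np.asarray(control_patients), pairing,
                                      max_constraints, rng)
    else:
        diffs = _pairwise_differences(zc, zt, None, None, None, max_constraints, rng)
    if len(diffs) == 0:
        raise ValueError("no ranking constraints could be formed")

    X = np.vstack([diffs, -diffs])
    y = np.concatenate([np.ones(len(diffs)), -np.ones(len(diffs))])
    svm = LinearSVC(C=C, fit_intercept=False, loss="hinge", max_iter=20000, tol=1e-5,
                    random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svm.fit(X, y)
    w = svm.coef_.ravel().copy()
    train_acc = float(np.mean(diffs @ w > 0))
    names = list(feature_names) if feature_names is not None \
        else [f"f{i}" for i in range(pooled.shape[1])]
    return RankingModel(w, names, mean, scale, C, train_acc)


def rank_samples(model: RankingModel, samples: np.ndarray) -> np.ndarray:
    """Ranks 1..N: N for the highest (most recurrence-like) score, 1 lowest.

    Ties are broken by stable input order with a logged warning.
    """
    scores = model.score(np.asarray(samples, dtype=float))
    return _ranks_from_scores(scores)


def _ranks_from_scores(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(scores)) < len(scores):
        logger.warning("rank_samples: tied scores broken by stable input order")
    order = np.argsort(scores, kind="stable")
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


# ---------------------------------------------------------------------------
# preference scores
# ---------------------------------------------------------------------------

@dataclass
class PreferenceResult:
    n1: int
    n2: int
    d: float
    preference: float
    preference_min: float
    preference_max: float
    npreference: float


def preference_from_ranks(ranks_s1: np.ndarray, n2: int, d: float = 1.0) -> PreferenceResult:
    """Preference of patient 1 given their cores' pooled ranks among n1+n2."""
    ranks_s1 = np.asarray(ranks_s1, dtype=float)
    n1 = len(ranks_s1)
    if n1 == 0 or n2 == 0:
        raise ValueError("both core sets must be nonempty")
    if d < 1:
        raise ValueError("exponent d must be >= 1")
    pref = float(np.sum(ranks_s1**d))
    lo = float(np.sum(np.arange(1, n1 + 1, dtype=float) ** d))
    hi = float(np.sum(np.arange(n2 + 1, n1 + n2 + 1, dtype=float) ** d))
    npref = (pref - lo) / (hi - lo) if hi > lo else 0.5
    npref = float(np.clip(npref, 0.0, 1.0))  # midranks at d > 1 can graze the bounds
    return PreferenceResult(n1, n2, d, pref, lo, hi, npref)


def preference_score(
    model: RankingModel,
    s1_samples: np.ndarray,
    s2_samples: np.ndarray,
    d: float = 1.0,
) -> PreferenceResult:
    """Rank the pooled cores of both patients and score patient 1's tendency
    to outrank patient 2.

    Tied scores receive midranks so the comparison is symmetric in the two
    patients (fully tied sets give nPreference exactly 0.5); at d = 1 this
    makes nPreference the tie-corrected normalized Mann-Whitney U.
    """
    s1 = np.asarray(s1_samples, dtype=float)
    s2 = np.asarray(s2_samples, dtype=float)
    if len(s1) == 0 or len(s2) == 0:
        raise ValueError("both core sets must be nonempty")
    pooled = np.vstack([s1, s2])
    ranks = rankdata(model.score(pooled), method="average")
    return preference_from_ranks(ranks[: len(s1)], len(s2), d)


# ---------------------------------------------------------------------------
# clinical lookup matching
# ---------------------------------------------------------------------------

def _clinical_vector(r: ClinicalRecord) -> np.ndarray:
    return np.array([r.age, r.gleason_sum, r.stage_code], dtype=float)


def match_similar_patients(
    query: ClinicalRecord,
    training: Sequence[ClinicalRecord],
) -> tuple[ClinicalRecord, ClinicalRecord]:
    """Most clinically similar recurrent and non-recurrent training patients.

    Similarity is inverse Euclidean distance over z-score-standardized
    (age, Gleason sum, ordinal stage code); the scaler is fitted on the
    training records.  Equidistant candidates resolve to the lower patient id.
    """
    cases = [r for r in training if r.recurrence]
    controls = [r for r in training if not r.recurrence]
    if not cases or not controls:
        raise ValueError("training set must contain both classes")
    mat = np.array([_clinical_vector(r) for r in training])
    mean, scale = mat.mean(axis=0), mat.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)

    def nearest(pool: list[ClinicalRecord]) -> ClinicalRecord:
        qv = (_clinical_vector(query) - mean) / scale
        dists = [float(np.linalg.norm((_clinical_vector(r) - mean) / scale - qv))
                 for r in pool]
        best = min(dists)
        tied = [r for r, dd in zip(pool, dists) if abs(dd - best) <= 1e-12]
        if len(tied) > 1:
            logger.warning("match_similar_patients: %d equidistant candidates; "
                           "lowest patient id wins", len(tied))
        return min(tied, key=lambda r: r.patient_id)

    return nearest(cases), nearest(controls)


# ---------------------------------------------------------------------------
# IR Score
# ---------------------------------------------------------------------------

@dataclass
class IRScoreModel:
    """Logistic model P(recurrence) ~ nPref-vs-matched-case + nPref-vs-matched-control."""

    coef: np.ndarray
    intercept: float

    def predict(self, npref_vs_case: float, npref_vs_control: float) -> float:
        eta = self.intercept + self.coef[0] * npref_vs_case + self.coef[1] * npref_vs_control
        return float(1.0 / (1.0 + np.exp(-eta)))


def _query_covariates(
    query: ClinicalRecord,
    query_cores: np.ndarray,
    training: Sequence[ClinicalRecord],
    cores_by_patient: dict[str, np.ndarray],
    model: RankingModel,
    d: float = 1.0,
) -> tuple[float, float]:
    case_match, control_match = match_similar_patients(query, training)
    np_case = preference_score(model, query_cores,
                               cores_by_patient[case_match.patient_id], d).npreference
    np_ctrl = preference_score(model, query_cores,
                               cores_by_patient[control_match.patient_id], d).npreference
    return np_case, np_ctrl


def fit_ir_score_model(
    training: Sequence[ClinicalRecord],
    cores_by_patient: dict[str, np.ndarray],
    model: RankingModel,
    d: float = 1.0,
    ridge_c: float = 1e6,
) -> IRScoreModel:
    """Fit the logistic IR-Score model on leave-one-out covariates.

    Each training patient is treated as a held-out query against the rest:
    their nPreference versus the matched recurrent and matched non-recurrent
    patients form the two covariates; recurrence status is the response.
    Maximum likelihood with a weak ridge keeps coefficients finite under
    separation.
    """
    labels, covs = [], []
    for i, q in enumerate(training):
        rest = [r for j, r in enumerate(training) if j != i]
        covs.append(_query_covariates(q, cores_by_patient[q.patient_id], rest,
                                      cores_by_patient, model, d))
        labels.append(bool(q.recurrence))
    X = np.asarray(covs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2 or X.shape[0] < 4:
        raise ValueError("need at least 2 patients per class")
    if np.allclose(X.std(axis=0), 0):
        # degenerate covariates: intercept-only model at the class prevalence
        prev = y.mean()
        prev = min(max(prev, 1e-9), 1 - 1e-9)
        return IRScoreModel(np.zeros(2), float(np.log(prev / (1 - prev))))
    clf = LogisticRegression(C=ridge_c, solver="lbfgs", max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return IRScoreModel(clf.coef_.ravel().copy(), float(clf.intercept_[0]))


def predict_ir_score(
    query: ClinicalRecord,
    query_cores: np.ndarray,
    training: Sequence[ClinicalRecord],
    cores_by_patient: dict[str, np.ndarray],
    ranking_model: RankingModel,
    ir_model: IRScoreModel,
    d: float = 1.0,
) -> float:
    """Match -> preference -> logistic composition; deterministic."""
    np_case, np_ctrl = _query_covariates(query, query_cores, training,
                                         cores_by_patient, ranking_model, d)
    return ir_model.predict(np_case, np_ctrl)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def ranking_model_to_json(model: RankingModel, ir_model: IRScoreModel | None = None) -> str:
    payload = {
        "weights": model.weights.tolist(),
        "feature_names": model.feature_names,
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_scale": model.scaler_scale.tolist(),
        "C": model.C,
        "training_pairwise_accuracy": model.training_pairwise_accuracy,
    }
    if ir_model is not None:
        payload["ir_logistic"] = {
            "coef": ir_model.coef.tolist(),
            "intercept": ir_model.intercept,
        }
    return json.dumps(payload, indent=1)
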