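"""Evaluation designs and statistics for the recurrence classifier.

Two cross-validation designs: the nested design presents the classifier
with a matched case-control pair and asks it to pick the case (summarized
by accuracy and an exact one-sided binomial test against chance), and the
query design scores each patient once with a model never trained on them
(summarized by ROC/AUC).  AUCs are reported both empirically (tie-corrected
rank statistic, identical to the normalized Mann-Whitney U) and smoothed by
a binormal fit; bootstrap resampling gives confidence intervals and paired
AUC-difference tests.  Quartile odds ratios come from a logistic model with
Wald inference.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

import statsmodels.api as sm

from .pipeline import PipelineConfig, RecurrencePipeline, fit_pipeline_on_cohort
from .ranking import preference_from_ranks
from .synthetic import Cohort

logger = logging.getLogger(__name__)


@dataclass
class CVConfig:
    K: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("K must be >= 2")


# ---------------------------------------------------------------------------
# cross-validation drivers
# ---------------------------------------------------------------------------

def binomial_tail_p(successes: int, n: int, p: float = 0.5) -> float:
    """Exact one-sided binomial tail P(X >= successes | n, p)."""
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    return float(stats.binom.sf(successes - 1, n, p))


@dataclass
class NestedCVResult:
    n_pairs: int
    n_correct: int
    accuracy: float
    p_value: float
    fold_of_pair: dict[tuple[str, str], int]


def _forced_choice_pair(pipe: RecurrencePipeline, cores_case, cores_ctrl,
                        rng: np.random.Generator) -> tuple[bool, bool]:
    """Decide which pair member looks recurrent; returns (correct, used_tie_break).

    Core-score ties are separated by an infinitesimal seeded jitter before
    ranking; an exactly indifferent nPreference of 0.5 falls back to a
    seeded fair coin, so an uninformative comparison succeeds with
    probability exactly 1/2.
    """
    from scipy.stats import rankdata as _rankdata

    s1 = pipe.ranking_model.score(pipe.transform_cores(cores_case))
    s2 = pipe.ranking_model.score(pipe.transform_cores(cores_ctrl))
    pooled = np.concatenate([s1, s2])
    tie_broken = False
    if len(np.unique(pooled)) < len(pooled):
        gaps = np.diff(np.unique(pooled))
        eps = 0.25 * gaps.min() if len(gaps) else 1.0
        pooled = pooled + rng.uniform(0, eps, size=len(pooled))
        tie_broken = True
    ranks = _rankdata(pooled)
    npref = preference_from_ranks(ranks[: len(s1)], len(s2),
                                  pipe.config.d).npreference
    if npref == 0.5:
        return bool(rng.random() < 0.5), True
    return bool(npref > 0.5), tie_broken


def nested_cv_pair_accuracy(
    cohort: Cohort,
    pipeline_config: PipelineConfig | None = None,
    config: CVConfig | None = None,
) -> NestedCVResult:
    """K-fold CV over matched pairs; pairs are never split across folds.

    Per test pair the case is predicted as the member with the higher
    nPreference against its partner (> 0.5 wins).  The comparison is forced-
    choice: tied core scores are separated by a seeded infinitesimal jitter
    and an exactly indifferent pair (nPreference = 0.5, which a rank
    statistic over 2-4 cores per patient hits for a non-negligible fraction
    of uninformative pairs) is resolved by a seeded fair coin.  This
    randomized decision rule makes the null success probability exactly 1/2
    per pair — the calibration the binomial test assumes; any deterministic
    tie rule couples the outcome to the fitted model's score distribution
    and miscalibrates the test.  Ties are counted and logged.  Significance
    is the exact one-sided binomial tail P(X >= correct | n, 0.5).
    """
    cv = config or CVConfig()
    if len(cohort.pairs) < cv.K:
        raise ValueError("need at least K pairs")
    rng = np.random.default_rng(cv.seed)
    order = rng.permutation(len(cohort.pairs))
    folds = np.array_split(order, cv.K)
    cores_by_pid = {p.patient_id: [c.stromal_values() for c in cohort.cores_of(p.patient_id)]
                    for p in cohort.patients}

    correct, total, n_ties = 0, 0, 0
    fold_of_pair = {}
    for k, fold in enumerate(folds):
        train_pids = {p for i, pr in enumerate(cohort.pairs) if i not in set(fold)
                      for p in pr}
        pipe = fit_pipeline_on_cohort(cohort, pipeline_config,
                                      patient_subset=train_pids, use_pairing=True)
        for i in fold:
            case_pid, ctrl_pid = cohort.pairs[i]
            fold_of_pair[(case_pid, ctrl_pid)] = k
            pair_rng = np.random.default_rng([cv.seed, int(i)])
            outcome = _forced_choice_pair(pipe, cores_by_pid[case_pid],
                                          cores_by_pid[ctrl_pid], pair_rng)
            correct += outcome[0]
            n_ties += outcome[1]
            total += 1
    if n_ties:
        logger.info("nested CV: %d of %d pairs decided through randomized "
                    "tie-breaking", n_ties, total)
    p = binomial_tail_p(int(correct), total)
    return NestedCVResult(total, int(correct), correct / total, p, fold_of_pair)


def kfold_query_cv(
    cohort: Cohort,
    pipeline_config: PipelineConfig | None = None,
    config: CVConfig | None = None,
) -> pd.DataFrame:
    """Stratified K-fold over patients; each patient receives exactly one
    IR Score from a model never trained on them.

    Returns a DataFrame with columns patient_id, recurrence, ir_score, fold.
    """
    cv = config or CVConfig()
    labels = cohort.labels()
    pids = sorted(labels)
    cases = [p for p in pids if labels[p]]
    ctrls = [p for p in pids if not labels[p]]
    if min(len(cases), len(ctrls)) < cv.K and cv.K < len(pids):
        pass  # folds may still each contain both classes after interleaving
    rng = np.random.default_rng(cv.seed)
    fold_of = {}
    for group in (cases, ctrls):
        perm = rng.permutation(len(group))
        for slot, i in enumerate(perm):
            fold_of[group[i]] = slot % cv.K
    cores_by_pid = {p: [c.stromal_values() for c in cohort.cores_of(p)] for p in pids}

    rows = []
    for k in range(cv.K):
        test_pids = [p for p in pids if fold_of[p] == k]
        if not test_pids:
            continue
        train_pids = {p for p in pids if fold_of[p] != k}
        train_labels = {labels[p] for p in train_pids}
        if len(train_labels) < 2:
            raise ValueError(f"fold {k}: training split lacks a class")
        pipe = fit_pipeline_on_cohort(cohort, pipeline_config,
                                      patient_subset=train_pids,
                                      use_pairing=False, fit_ir=True)
        for pid in test_pids:
            score = pipe.score_query(cohort.record(pid), cores_by_pid[pid])
            rows.append({"patient_id": pid, "recurrence": labels[pid],
                         "ir_score": score, "fold": k})
    df = pd.DataFrame(rows).sort_values("patient_id").reset_index(drop=True)
    assert len(df) == len(pids), "every patient must be scored exactly once"
    return df


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    auc_empirical: float
    auc_smoothed: float | None
    points: np.ndarray            # (1-specificity, sensitivity) empirical points
    binormal_params: tuple[float, float, float, float] | None  # mu1, sd1, mu0, sd0

    @property
    def auc(self) -> float:
        return self.auc_smoothed if self.auc_smoothed is not None else self.auc_empirical


def empirical_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected rank AUC: the normalized Mann-Whitney U of cases over
    controls."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = labels.sum(), (~labels).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_auc_smoothed(scores: np.ndarray, labels: np.ndarray,
                     smooth: bool = True) -> RocResult:
    """Empirical ROC points and AUC, plus a binormal-smoothed AUC.

    The binormal fit models each class's scores as normal; the smoothed AUC
    is Phi(delta_mu / sqrt(sd1^2 + sd0^2)), compensating the downward bias of
    the empirical step-function AUC at small n.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    auc_emp = empirical_auc(scores, labels)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    pts = []
    n1, n0 = labels.sum(), (~labels).sum()
    for t in thresholds:
        pred = scores >= t
        sens = (pred & labels).sum() / n1
        fpr = (pred & ~labels).sum() / n0
        pts.append((fpr, sens))
    points = np.asarray(pts)
    auc_s, params = None, None
    if smooth:
        s1, s0 = scores[labels], scores[~labels]
        mu1, mu0 = s1.mean(), s0.mean()
        sd1 = s1.std(ddof=1) if len(s1) > 1 else 0.0
        sd0 = s0.std(ddof=1) if len(s0) > 1 else 0.0
        denom = np.sqrt(sd1**2 + sd0**2)
        if denom == 0:
            auc_s = 1.0 if mu1 > mu0 else (0.0 if mu1 < mu0 else 0.5)
        else:
            auc_s = float(stats.norm.cdf((mu1 - mu0) / denom))
        params = (float(mu1), float(sd1), float(mu0), float(sd0))
    return RocResult(auc_emp, auc_s, points, params)


def bootstrap_auc_ci(scores: np.ndarray, labels: np.ndarray, reps: int = 2000,
                     level: float = 0.95, seed: int = 0,
                     smooth: bool = False) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, resampling patients within class."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    idx1, idx0 = np.flatnonzero(labels), np.flatnonzero(~labels)
    rng = np.random.default_rng(seed)
    aucs = np.empty(reps)
    for r in range(reps):
        b1 = rng.choice(idx1, size=len(idx1), replace=True)
        b0 = rng.choice(idx0, size=len(idx0), replace=True)
        s = np.concatenate([scores[b1], scores[b0]])
        y = np.concatenate([np.ones(len(b1), bool), np.zeros(len(b0), bool)])
        if smooth:
            aucs[r] = roc_auc_smoothed(s, y).auc_smoothed
        else:
            aucs[r] = empirical_auc(s, y)
    alpha = 1 - level
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def bootstrap_auc_difference(scores_a: np.ndarray, scores_b: np.ndarray,
                             labels: np.ndarray, reps: int = 2000,
                             seed: int = 0) -> float:
    """Two-sided p for AUC_A - AUC_B via paired stratified bootstrap."""
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels, bool)
    if len(scores_a) != len(scores_b) or len(scores_a) != len(labels):
        raise ValueError("paired scores must have equal length")
    idx1, idx0 = np.flatnonzero(labels), np.flatnonzero(~labels)
    rng = np.random.default_rng(seed)
    diffs = np.empty(reps)
    for r in range(reps):
        b = np.concatenate([rng.choice(idx1, len(idx1), True),
                            rng.choice(idx0, len(idx0), True)])
        y = labels[b]
        diffs[r] = empirical_auc(scores_a[b], y) - empirical_auc(scores_b[b], y)
    p_low = np.mean(diffs <= 0)
    p_high = np.mean(diffs >= 0)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def ks_compare(scores_cases: np.ndarray, scores_controls: np.ndarray):
    """Two-sample two-sided Kolmogorov-Smirnov comparison of score
    distributions; returns (D, p)."""
    res = stats.ks_2samp(scores_cases, scores_controls, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# quartile odds ratios
# ---------------------------------------------------------------------------

@dataclass
class QuartileORResult:
    table: pd.DataFrame     # per-quartile OR, CI bounds, Wald p (Q1 = reference)
    trend_p: float
    quartile_of: np.ndarray


def assign_quartiles(scores: np.ndarray) -> np.ndarray:
    """Quartiles 1-4 by score order; stable ranking sends ties to the lower
    quartile; group sizes differ by at most one."""
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    order = np.argsort(scores, kind="stable")
    q = np.empty(n, dtype=int)
    for qi, chunk in enumerate(np.array_split(np.arange(n), 4), start=1):
        q[order[chunk]] = qi
    return q


def quartile_odds_ratios(scores: np.ndarray, labels: np.ndarray,
                         covariates: np.ndarray | None = None,
                         level: float = 0.95) -> QuartileORResult:
    """Logistic regression of recurrence on quartile indicators (lowest
    quartile = reference) plus optional covariates; Wald CIs and a trend test
    using the quartile index as an ordinal covariate."""
    scores = np.asarray(scores, float)
    y = np.asarray(labels, bool).astype(int)
    q = assign_quartiles(scores)
    for qi in range(1, 5):
        if (q == qi).sum() < 2:
            raise ValueError("each quartile needs at least 2 patients")
    dummies = np.column_stack([(q == qi).astype(float) for qi in (2, 3, 4)])
    X = dummies if covariates is None else np.column_stack([dummies, covariates])
    X = sm.add_constant(X, has_constant="add")
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # near-separation convergence noise
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params, bse = fit.params, fit.bse
        pvals = fit.pvalues
    except Exception:
        logger.warning("quartile_odds_ratios: ML fit failed; weak-ridge fallback")
        fit = sm.Logit(y, X).fit_regularized(alpha=1e-4, L1_wt=0.0, disp=0)
        params = np.asarray(fit.params)
        bse = np.full_like(params, np.nan)
        pvals = np.full_like(params, np.nan)
    zcrit = stats.norm.ppf(0.5 + level / 2)
    rows = [{"quartile": 1, "odds_ratio": 1.0, "ci_low": np.nan, "ci_high": np.nan,
             "wald_p": np.nan}]
    with np.errstate(over="ignore"):  # CI bounds may saturate near separation
        for i, qi in enumerate((2, 3, 4), start=1):
            beta, se = params[i], bse[i]
            rows.append({
                "quartile": qi,
                "odds_ratio": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - zcrit * se)),
                "ci_high": float(np.exp(beta + zcrit * se)),
                "wald_p": float(pvals[i]),
            })
    # trend: ordinal quartile index
    Xt = np.column_stack([q.astype(float)]) if covariates is None \
        else np.column_stack([q.astype(float), covariates])
    Xt = sm.add_constant(Xt, has_constant="add")
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            tfit = sm.Logit(y, Xt).fit(disp=0, maxiter=200)
        trend_p = float(tfit.pvalues[1])
    except Exception:
        trend_p = float("nan")
    return QuartileORResult(pd.DataFrame(rows), trend_p, q)
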