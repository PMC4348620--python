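"""End-to-end recurrence-prediction pipeline.

Composes the stages in the order the method runs: fit an equal-width
discretizer on training pixels, mine frequent patterns per outcome class,
screen them with the two-stage discriminative test, form per-core
pattern-frequency features, optionally select features (mRMR with floating
refinement), train the linear Ranking-SVM, and — for individual-query
scoring — fit the logistic IR-Score model on leave-one-out preference
covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .patterns import (
    DiscriminativeConfig,
    MiningConfig,
    Pattern,
    compute_pattern_features,
    discretize,
    fit_discretizer,
    mine_frequent_patterns,
    pattern_match_matrix,
    select_discriminative_patterns,
    subject_pattern_frequencies,
)
from .ranking import (
    IRScoreModel,
    RankingModel,
    fit_ir_score_model,
    predict_ir_score,
    preference_score,
    train_ranking_svm,
)
from .selection import SelectionConfig, rank_relevance_redundancy, refine_subset
from .synthetic import Cohort, CoreSample
from .tissue import ClinicalRecord, MetricMatrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    n_bins: int = 20
    theta: float = 0.02
    max_len: int | None = 4
    m: int = 100
    alpha1: float = 0.05
    selection: str = "mrmr_refine"   # "none" | "mrmr" | "mrmr_refine"
    k0: int = 30
    C: float = 1.0
    d: float = 1.0
    max_constraints: int = 100_000
    inner_folds: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.selection not in ("none", "mrmr", "mrmr_refine"):
            raise ValueError("selection must be 'none', 'mrmr' or 'mrmr_refine'")


@dataclass
class _TrainingCore:
    core_id: str
    patient_id: str
    values: np.ndarray  # stromal pixels x metrics


class RecurrencePipeline:
    """One fitted instance of the full method (train once, score queries)."""

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        self.scheme = None
        self.patterns: list[Pattern] = []
        self.retained: list[Pattern] = []
        self.discriminative = []
        self.selected_features: list[int] = []
        self.ranking_model: RankingModel | None = None
        self.ir_model: IRScoreModel | None = None
        self._training_records: list[ClinicalRecord] | None = None
        self._training_core_features: dict[str, np.ndarray] | None = None

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        cores: Sequence[CoreSample] | Sequence[tuple[str, str, np.ndarray]],
        labels: dict[str, bool],
        pairs: Sequence[tuple[str, str]] | None = None,
        records: Sequence[ClinicalRecord] | None = None,
        fit_ir: bool = False,
    ) -> "RecurrencePipeline":
        cfg = self.config
        tcores = [self._coerce_core(c) for c in cores]
        patient_ids = sorted({c.patient_id for c in tcores})
        pid_index = {p: i for i, p in enumerate(patient_ids)}

        pooled = np.vstack([c.values for c in tcores])
        subj_idx = np.concatenate([
            np.full(len(c.values), pid_index[c.patient_id]) for c in tcores
        ]).astype(np.int64)
        n_metrics = pooled.shape[1]
        matrix = MetricMatrix(np.arange(len(pooled)),
                              [f"m{j:02d}" for j in range(n_metrics)], pooled)
        self.scheme = fit_discretizer(matrix, cfg.n_bins)
        disc = discretize(pooled, self.scheme)

        case_mask = np.array([labels[patient_ids[i]] for i in subj_idx])
        mining = MiningConfig(theta=cfg.theta, max_len=cfg.max_len, n_bins=cfg.n_bins)
        self.patterns = self._mine_union(disc[case_mask], disc[~case_mask], mining)
        if not self.patterns:
            raise RuntimeError("no frequent patterns mined from training data")

        # per-subject pooled frequencies and the two-stage discriminative screen
        freqs = subject_pattern_frequencies(self.patterns, disc, subj_idx,
                                            len(patient_ids))
        case_cols = np.array([labels[p] for p in patient_ids])
        results = select_discriminative_patterns(
            self.patterns, freqs[case_cols].T, freqs[~case_cols].T,
            DiscriminativeConfig(m=cfg.m, alpha1=cfg.alpha1),
        )
        if not results:
            # a prediction must still be emitted (e.g. CV folds on null data):
            # relax stage 1 and keep direction-consistent patterns ranked by p
            logger.warning("no pattern passed the discriminative screen at "
                           "alpha1=%.3g; relaxing to direction-consistent top-m",
                           cfg.alpha1)
            results = select_discriminative_patterns(
                self.patterns, freqs[case_cols].T, freqs[~case_cols].T,
                DiscriminativeConfig(m=cfg.m, alpha1=1 - 1e-12),
            )
        self.discriminative = results
        self.retained = [r.pattern for r in results]
        if not self.retained:
            raise RuntimeError("no discriminative patterns survived the screen")

        # per-core pattern-frequency features
        core_idx = np.concatenate([
            np.full(len(c.values), i) for i, c in enumerate(tcores)
        ]).astype(np.int64)
        core_feats = subject_pattern_frequencies(self.retained, disc, core_idx,
                                                 len(tcores)).astype(float)
        core_labels = np.array([labels[c.patient_id] for c in tcores])

        self.selected_features = self._select_features(
            core_feats, core_labels, tcores, pairs)
        X = core_feats[:, self.selected_features]

        case_rows = core_labels
        self.ranking_model = train_ranking_svm(
            X[case_rows], X[~case_rows],
            case_patients=np.array([c.patient_id for c in tcores])[case_rows],
            control_patients=np.array([c.patient_id for c in tcores])[~case_rows],
            pairing=pairs,
            C=cfg.C,
            feature_names=[f"pattern_{j}" for j in self.selected_features],
            max_constraints=cfg.max_constraints,
            seed=cfg.seed,
        )

        self._training_core_features = {
            p: X[[i for i, c in enumerate(tcores) if c.patient_id == p]]
            for p in patient_ids
        }
        if fit_ir:
            if records is None:
                raise ValueError("fit_ir requires clinical records")
            self._training_records = list(records)
            self.ir_model = fit_ir_score_model(
                self._training_records, self._training_core_features,
                self.ranking_model, d=cfg.d)
        return self

    @staticmethod
    def _coerce_core(core) -> _TrainingCore:
        if isinstance(core, CoreSample):
            return _TrainingCore(core.core_id, core.patient_id, core.stromal_values())
        core_id, pid, values = core
        return _TrainingCore(core_id, pid, np.asarray(values, dtype=float))

    def _mine_union(self, disc_case: np.ndarray, disc_control: np.ndarray,
                    mining: MiningConfig) -> list[Pattern]:
        """Mine per class, record both supports, union on items.

        A pattern frequent in both classes is attributed to the class where
        its support is higher.
        """
        mined_case = mine_frequent_patterns(disc_case, mining)
        mined_ctrl = mine_frequent_patterns(disc_control, mining)
        by_items: dict[frozenset, dict] = {}
        for p in mined_case:
            by_items[p.items] = {"case": p.support_case, "control": None}
        for p in mined_ctrl:
            entry = by_items.setdefault(p.items, {"case": None, "control": None})
            entry["control"] = p.support_case
        out = []
        for items, sup in by_items.items():
            sc = sup["case"] if sup["case"] is not None else self._support(
                items, disc_case)
            st = sup["control"] if sup["control"] is not None else self._support(
                items, disc_control)
            source = "case" if sc >= st else "control"
            out.append(Pattern(items=items, source_class=source,
                               support_case=sc, support_control=st))
        out.sort(key=lambda p: p.canonical_key())
        return out

    @staticmethod
    def _support(items: frozenset, disc: np.ndarray) -> float:
        mask = np.ones(disc.shape[0], dtype=bool)
        for m, b in items:
            mask &= disc[:, m] == b
        return float(mask.mean())

    def _select_features(self, core_feats, core_labels, tcores, pairs) -> list[int]:
        cfg = self.config
        k = core_feats.shape[1]
        if cfg.selection == "none" or k <= 1:
            return list(range(k))
        sel_cfg = SelectionConfig(k0=min(cfg.k0, k), inner_folds=cfg.inner_folds,
                                  seed=cfg.seed)
        subset = rank_relevance_redundancy(core_feats, core_labels, sel_cfg)
        if cfg.selection == "mrmr":
            return sorted(subset)
        objective = self._make_ranking_objective(core_feats, core_labels,
                                                 tcores, pairs, sel_cfg)
        refined = refine_subset(subset, core_feats, objective, sel_cfg)
        return sorted(refined.subset)

    def _make_ranking_objective(self, core_feats, core_labels, tcores, pairs,
                                sel_cfg: SelectionConfig):
        """Inner-CV pairwise ranking accuracy of a candidate feature subset."""
        cfg = self.config
        patient_of = np.array([c.patient_id for c in tcores])
        pids = sorted(set(patient_of))
        rng = np.random.default_rng(sel_cfg.seed)
        if pairs is not None:
            units = list(pairs)
        else:
            # pair up cases and controls at random for a pair-CV surrogate
            cases = sorted({p for p in pids if core_labels[patient_of == p][0]})
            ctrls = sorted({p for p in pids if not core_labels[patient_of == p][0]})
            n = min(len(cases), len(ctrls))
            units = list(zip(rng.permutation(cases)[:n], rng.permutation(ctrls)[:n]))
        folds = np.array_split(rng.permutation(len(units)), sel_cfg.inner_folds)

        def objective(subset: Sequence[int]) -> float:
            subset = list(subset)
            correct, total = 0, 0
            for fold in folds:
                test_units = [units[i] for i in fold]
                train_units = [u for i, u in enumerate(units) if i not in set(fold)]
                train_pids = {p for u in train_units for p in u}
                rows_train = np.isin(patient_of, list(train_pids))
                Xtr = core_feats[np.ix_(rows_train, subset)]
                ytr = core_labels[rows_train]
                if ytr.all() or not ytr.any():
                    continue
                try:
                    model = train_ranking_svm(
                        Xtr[ytr], Xtr[~ytr], C=cfg.C,
                        max_constraints=min(cfg.max_constraints, 20_000),
                        seed=sel_cfg.seed)
                except ValueError:
                    continue
                for case_pid, ctrl_pid in test_units:
                    s1 = core_feats[np.ix_(patient_of == case_pid, subset)]
                    s2 = core_feats[np.ix_(patient_of == ctrl_pid, subset)]
                    if len(s1) == 0 or len(s2) == 0:
                        continue
                    npref = preference_score(model, s1, s2, cfg.d).npreference
                    correct += npref > 0.5
                    total += 1
            return correct / total if total else 0.0

        return objective

    # -- inference ----------------------------------------------------------

    def transform_cores(self, core_values: Sequence[np.ndarray]) -> np.ndarray:
        """Map raw per-core pixel matrices to selected pattern-frequency rows."""
        if self.scheme is None:
            raise RuntimeError("pipeline is not fitted")
        rows = []
        for vals in core_values:
            disc = discretize(np.asarray(vals, dtype=float), self.scheme)
            fv = compute_pattern_features(disc, self.retained)
            rows.append(fv.values[self.selected_features])
        return np.asarray(rows)

    def npreference(self, cores_p1: Sequence[np.ndarray],
                    cores_p2: Sequence[np.ndarray]) -> float:
        """nPreference of patient 1 over patient 2 from raw core pixels."""
        X1 = self.transform_cores(cores_p1)
        X2 = self.transform_cores(cores_p2)
        return preference_score(self.ranking_model, X1, X2, self.config.d).npreference

    def score_query(self, record: ClinicalRecord,
                    core_values: Sequence[np.ndarray]) -> float:
        """IR Score (predicted probability of recurrence) for an unseen patient."""
        if self.ir_model is None:
            raise RuntimeError("IR-Score model not fitted (fit with fit_ir=True)")
        X = self.transform_cores(core_values)
        return predict_ir_score(record, X, self._training_records,
                                self._training_core_features,
                                self.ranking_model, self.ir_model, d=self.config.d)


# ---------------------------------------------------------------------------
# convenience constructors
# ---------------------------------------------------------------------------

def fit_pipeline_on_cohort(cohort: Cohort, config: PipelineConfig | None = None,
                           patient_subset: set[str] | None = None,
                           use_pairing: bool = True,
                           fit_ir: bool = False) -> RecurrencePipeline:
    """Fit a pipeline on (a subset of) a cohort's patients."""
    labels = cohort.labels()
    cores = [c for c in cohort.cores
             if patient_subset is None or c.patient_id in patient_subset]
    pairs = None
    if use_pairing:
        pairs = [pr for pr in cohort.pairs
                 if patient_subset is None or
                 (pr[0] in patient_subset and pr[1] in patient_subset)]
    records = [r for r in cohort.patients
               if patient_subset is None or r.patient_id in patient_subset]
    pipe = RecurrencePipeline(config)
    pipe.fit(cores, labels, pairs=pairs, records=records, fit_ir=fit_ir)
    return pipe
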