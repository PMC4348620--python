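"""Matched case-control cohort simulator with planted pattern signal.

Emulates the structure of an outcomes tissue-microarray study: patients in
matched case-control pairs (matched exactly on Gleason sum, pathologic
stage and race, within +/-3 years of age), each with 2-4 cores, each core
carrying a few hundred stromal pixels with k spectral-metric values.

Pixels are i.i.d. within a core given class.  A *planted pattern* — a set
of (metric, bin) items enriched in one class — is injected by overwriting
the pattern's metrics with the bin's representative value plus small
sub-bin jitter in a Bernoulli-selected pixel subset, so its true per-class
match fraction is analytically known.  A null generator produces the same
structure with outcome labels carrying no information about any metric.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .tissue import (
    CellTypeMask,
    ClinicalRecord,
    MetricMatrix,
    STAGE_CODES,
    write_clinical_table,
    write_pixel_table,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPatternSpec:
    """A pattern to enrich: items (metric index, bin index), the target class
    and the per-class pixel enrichment fractions."""

    items: tuple[tuple[int, int], ...]
    target_class: str = "case"
    enrichment_target: float = 0.30
    enrichment_other: float = 0.05

    def __post_init__(self):
        if self.target_class not in ("case", "control"):
            raise ValueError("target_class must be 'case' or 'control'")
        for f in (self.enrichment_target, self.enrichment_other):
            if not 0 < f <= 1:
                raise ValueError("enrichment fractions must lie in (0, 1]")
        metrics = [m for m, _ in self.items]
        if len(metrics) == 0 or len(set(metrics)) != len(metrics):
            raise ValueError("pattern needs >= 1 item, one per metric")


@dataclass
class ClinicalModel:
    """Marginal clinical distributions of a mid-grade-dominant cohort."""

    age_mean: float = 62.0
    age_sd: float = 7.0
    age_delta_sd: float = 1.5       # control minus case age, clipped to +/-3
    race_white_prob: float = 0.85
    gleason_sum_probs: tuple[float, float, float] = (0.20, 0.70, 0.10)  # sums 6,7,8
    gleason_7_primary3_prob: float = 35 / 42
    stage_probs: tuple[float, float, float, float] = (0.117, 0.55, 0.317, 0.016)
    psa_logmean_case: float = 2.1034   # lognormal matching mean 10.6, SD 8.7
    psa_logsd_case: float = 0.7176
    psa_logmean_control: float = 1.9535  # mean 8.6, SD 6.0
    psa_logsd_control: float = 0.6298
    margin_prob_case: float = 0.35
    margin_prob_control: float = 0.25
    ece_prob_t3: float = 0.80
    ece_prob_t2: float = 0.10
    lni_prob: float = 0.03
    therapy_prob: float = 0.32
    months_mean: float = 38.6
    months_sd: float = 29.0


@dataclass
class CohortConfig:
    n_pairs: int = 60
    cores_per_patient: tuple[int, int] = (2, 4)
    pixels_per_core: tuple[int, int] = (200, 1500)
    n_metrics: int = 20
    n_bins: int = 20
    planted_patterns: tuple[PlantedPatternSpec, ...] = ()
    value_range: tuple[float, float] = (-4.0, 4.0)  # generator bin grid span
    jitter_fraction: float = 0.05   # planted sub-bin jitter, fraction of bin width
    epithelium_fraction_range: tuple[float, float] = (0.15, 0.35)
    clinical_model: ClinicalModel = field(default_factory=ClinicalModel)
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.pixels_per_core[0] < 1:
            raise ValueError("pixels_per_core must be >= 1")
        if not (2 <= self.cores_per_patient[0] <= self.cores_per_patient[1] <= 4):
            raise ValueError("cores_per_patient must be a range within [2, 4]")
        for spec in self.planted_patterns:
            for m, b in spec.items:
                if not 0 <= m < self.n_metrics:
                    raise ValueError(f"planted pattern metric {m} out of range")
                if not 0 <= b < self.n_bins:
                    raise ValueError(f"planted pattern bin {b} outside bin range")

    @property
    def generator_bin_edges(self) -> np.ndarray:
        return np.linspace(self.value_range[0], self.value_range[1], self.n_bins + 1)


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

@dataclass
class CoreSample:
    core_id: str
    patient_id: str
    matrix: MetricMatrix
    mask: CellTypeMask

    def stromal_values(self) -> np.ndarray:
        return self.matrix.values[self.mask.labels == "stroma"]


@dataclass
class Cohort:
    config: CohortConfig
    patients: list[ClinicalRecord]
    pairs: list[tuple[str, str]]  # (case id, control id)
    cores: list[CoreSample]

    @property
    def metric_names(self) -> list[str]:
        return self.cores[0].matrix.metric_names

    def record(self, patient_id: str) -> ClinicalRecord:
        return next(r for r in self.patients if r.patient_id == patient_id)

    def cores_of(self, patient_id: str) -> list[CoreSample]:
        return [c for c in self.cores if c.patient_id == patient_id]

    def labels(self) -> dict[str, bool]:
        return {r.patient_id: bool(r.recurrence) for r in self.patients}


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _draw_clinical_pair(cfg: CohortConfig, rng: np.random.Generator,
                        pair_idx: int, null: bool) -> tuple[ClinicalRecord, ClinicalRecord]:
    cm = cfg.clinical_model
    age_case = float(np.clip(rng.normal(cm.age_mean, cm.age_sd), 42, 80))
    delta = float(np.clip(rng.normal(0.0, cm.age_delta_sd), -3.0, 3.0))
    age_ctrl = float(np.clip(age_case + delta, 40, 83))
    if abs(age_ctrl - age_case) > 3:  # clip at the age bounds could break matching
        age_ctrl = age_case
    race = "white" if rng.random() < cm.race_white_prob else "african_american"
    gsum = int(rng.choice([6, 7, 8], p=np.asarray(cm.gleason_sum_probs) /
                          np.sum(cm.gleason_sum_probs)))
    if gsum == 6:
        gp, gs = 3, 3
    elif gsum == 8:
        gp, gs = 4, 4
    else:
        gp = 3 if rng.random() < cm.gleason_7_primary3_prob else 4
        gs = gsum - gp
    stage = str(rng.choice(list(STAGE_CODES), p=np.asarray(cm.stage_probs) /
                           np.sum(cm.stage_probs)))
    is_t3 = stage.startswith("T3")

    def one(pid: str, recurrence: bool, age: float) -> ClinicalRecord:
        if null or not recurrence:
            psa = float(rng.lognormal(cm.psa_logmean_control, cm.psa_logsd_control))
            margin_p = cm.margin_prob_control
        else:
            psa = float(rng.lognormal(cm.psa_logmean_case, cm.psa_logsd_case))
            margin_p = cm.margin_prob_case
        months = None
        if recurrence:
            months = float(np.clip(rng.normal(cm.months_mean, cm.months_sd), 1, 180))
        return ClinicalRecord(
            patient_id=pid,
            age=round(age, 1),
            race=race,
            gleason_primary=gp,
            gleason_secondary=gs,
            gleason_sum=gsum,
            stage=stage,
            psa=round(psa, 2),
            positive_margins=bool(rng.random() < margin_p),
            svi=bool(rng.random() < (0.9 if stage == "T3b" else 0.03)),
            ece=bool(rng.random() < (cm.ece_prob_t3 if is_t3 else cm.ece_prob_t2)),
            lni=bool(rng.random() < cm.lni_prob),
            therapy=bool(rng.random() < cm.therapy_prob),
            recurrence=recurrence,
            months_to_recurrence=months,
        )

    case = one(f"P{pair_idx:03d}R", True, age_case)
    ctrl = one(f"P{pair_idx:03d}N", False, age_ctrl)
    return case, ctrl


def _core_mask(n_pixels: int, epi_fraction: float) -> CellTypeMask:
    """Square-ish core layout with a central epithelial blob in a stromal field."""
    side = int(math.ceil(math.sqrt(n_pixels)))
    rows, cols = np.divmod(np.arange(n_pixels), side)
    center = (side - 1) / 2.0
    dist = np.maximum(np.abs(rows - center), np.abs(cols - center))
    n_epi = max(1, int(round(epi_fraction * n_pixels)))
    order = np.argsort(dist, kind="stable")
    labels = np.full(n_pixels, "stroma", dtype=object)
    labels[order[:n_epi]] = "epithelium"
    return CellTypeMask(rows, cols, labels)


def _plant(values: np.ndarray, stroma_rows: np.ndarray, spec: PlantedPatternSpec,
           enrichment: float, edges: np.ndarray, jitter_fraction: float,
           rng: np.random.Generator) -> None:
    """Overwrite the pattern's metrics in a Bernoulli subset of stromal pixels."""
    width = edges[1] - edges[0]
    chosen = stroma_rows[rng.random(len(stroma_rows)) < enrichment]
    if len(chosen) == 0:
        return
    for m, b in spec.items:
        rep = (edges[b] + edges[b + 1]) / 2.0
        jitter = rng.uniform(-jitter_fraction, jitter_fraction, size=len(chosen)) * width
        values[chosen, m] = rep + jitter


def generate_cohort(config: CohortConfig, *, _null: bool = False) -> Cohort:
    """Generate a matched case-control cohort with the configured planted signal.

    Identical config and seed give bitwise-identical cohorts.  Every emitted
    pair matches exactly on Gleason sum, stage and race and within +/-3 years
    of age; for a pattern planted at enrichment f in class c, the expected
    match fraction among class-c stromal pixels is f (plus a negligible
    chance-match term).
    """
    ss = np.random.SeedSequence(config.seed)
    clinical_rng, pixel_rng, plant_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    metric_names = [f"m{j:02d}" for j in range(config.n_metrics)]
    edges = config.generator_bin_edges

    patients: list[ClinicalRecord] = []
    pairs: list[tuple[str, str]] = []
    cores: list[CoreSample] = []
    for i in range(config.n_pairs):
        case, ctrl = _draw_clinical_pair(config, clinical_rng, i, _null)
        patients.extend([case, ctrl])
        pairs.append((case.patient_id, ctrl.patient_id))
        for rec in (case, ctrl):
            n_cores = int(clinical_rng.integers(config.cores_per_patient[0],
                                                config.cores_per_patient[1] + 1))
            for c in range(n_cores):
                n_px = int(pixel_rng.integers(config.pixels_per_core[0],
                                              config.pixels_per_core[1] + 1))
                epi_frac = float(pixel_rng.uniform(*config.epithelium_fraction_range))
                mask = _core_mask(n_px, epi_frac)
                values = pixel_rng.standard_normal((n_px, config.n_metrics))
                # epithelium has a mildly shifted chemistry; not analysed downstream
                values[mask.labels == "epithelium"] += 0.8
                if not _null:
                    stroma_rows = np.flatnonzero(mask.labels == "stroma")
                    is_case = bool(rec.recurrence)
                    for spec in config.planted_patterns:
                        target_is_me = (spec.target_class == "case") == is_case
                        f = spec.enrichment_target if target_is_me else spec.enrichment_other
                        _plant(values, stroma_rows, spec, f, edges,
                               config.jitter_fraction, plant_rng)
                matrix = MetricMatrix(np.arange(n_px), metric_names, values)
                cores.append(CoreSample(f"{rec.patient_id}_c{c}", rec.patient_id,
                                        matrix, mask))
    cohort = Cohort(config, patients, pairs, cores)
    validate_matching(cohort)
    return cohort


def generate_null_cohort(config: CohortConfig) -> Cohort:
    """Same cohort structure with labels independent of all metric values:
    no patterns are planted and both classes share every pixel and clinical
    distribution (except the recurrence label and follow-up time)."""
    return generate_cohort(config, _null=True)


def validate_matching(cohort: Cohort) -> None:
    """Check every pair satisfies the matching predicate; raise if not."""
    rec = {r.patient_id: r for r in cohort.patients}
    for case_id, ctrl_id in cohort.pairs:
        a, b = rec[case_id], rec[ctrl_id]
        if a.gleason_sum != b.gleason_sum or a.stage != b.stage or a.race != b.race:
            raise ValueError(f"pair ({case_id}, {ctrl_id}) violates exact matching")
        if abs(a.age - b.age) > 3.0 + 1e-9:
            raise ValueError(f"pair ({case_id}, {ctrl_id}) violates age matching")


# ---------------------------------------------------------------------------
# ground-truth helpers
# ---------------------------------------------------------------------------

def generator_discretize(values: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Discretize values on the generator's own canonical bin grid."""
    edges = config.generator_bin_edges
    width = edges[1] - edges[0]
    b = np.floor((np.asarray(values) - edges[0]) / width).astype(int)
    return np.clip(b, 0, config.n_bins - 1)


def empirical_match_fraction(cohort: Cohort, spec: PlantedPatternSpec,
                             klass: str) -> float:
    """Fraction of a class's stromal pixels matching the pattern, in
    generator-bin terms (the analytically known truth scale)."""
    want = klass == "case"
    blocks = [c.stromal_values() for c in cohort.cores
              if bool(cohort.record(c.patient_id).recurrence) == want]
    vals = np.vstack(blocks)
    disc = generator_discretize(vals, cohort.config)
    mask = np.ones(len(disc), dtype=bool)
    for m, b in spec.items:
        mask &= disc[:, m] == b
    return float(mask.mean())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write clinical CSV, pixel CSV and a JSON manifest (config + pairs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_clinical_table(out / "clinical.csv", cohort.patients)
    write_pixel_table(out / "pixels.csv",
                      [(c.core_id, c.matrix, c.mask) for c in cohort.cores])
    manifest = {
        "seed": cohort.config.seed,
        "pairs": cohort.pairs,
        "config": _config_to_dict(cohort.config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _config_to_dict(cfg: CohortConfig) -> dict:
    d = asdict(cfg)
    d["planted_patterns"] = [
        {"items": [list(it) for it in s.items], "target_class": s.target_class,
         "enrichment_target": s.enrichment_target,
         "enrichment_other": s.enrichment_other}
        for s in cfg.planted_patterns
    ]
    return d
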