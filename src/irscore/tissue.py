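"""Data model and I/O for FT-IR tissue imaging data.

Pixels of a tissue-microarray core carry an infrared absorption spectrum
each; spectra are summarized into scalar *spectral metrics* (peak
absorbance, peak ratio, band area, band center of gravity) which form the
per-pixel feature matrix consumed by the pattern-mining stages.  The module
also implements cell-type-aware eligibility filtering: cores need enough
malignant epithelium and a non-empty set of tumor-adjacent stromal pixels
to enter the analysis.
"""

from __future__ import annotations


import logging

from dataclasses import dataclass, asdict
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: wavenumber range (cm^-1) spectra are truncated to
SPECTRAL_RANGE = (720.0, 4000.0)

#: default pixel pitch of the imaging system, micrometres
DEFAULT_PIXEL_PITCH_UM = 6.25

#: pathologic stage -> ordinal code used for patient similarity
STAGE_CODES = {"T2a": 1, "T2b": 2, "T3a": 3, "T3b": 4}

MetricKind = Literal["peak_absorbance", "peak_ratio", "band_area", "center_of_gravity"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PixelSpectrum:
    """One pixel's absorption spectrum on a strictly monotone wavenumber grid."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self):
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.shape != ab.shape or wn.ndim != 1:
            raise ValueError("wavenumbers and absorbance must be equal-length 1-D")
        d = np.diff(wn)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber grid must be strictly monotone")
        if wn.min() < SPECTRAL_RANGE[0] - 1e-9 or wn.max() > SPECTRAL_RANGE[1] + 1e-9:
            raise ValueError(f"wavenumbers must lie within {SPECTRAL_RANGE} cm^-1")
        if not np.all(np.isfinite(ab)):
            raise ValueError("absorbance values must be finite")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)

    @property
    def ascending(self) -> "PixelSpectrum":
        if self.wavenumbers[0] <= self.wavenumbers[-1]:
            return self
        return PixelSpectrum(self.wavenumbers[::-1].copy(), self.absorbance[::-1].copy())


@dataclass(frozen=True)
class MetricDefinition:
    """A scalar summary of a spectrum.

    kind:
      * ``peak_absorbance`` — absorbance at the grid point nearest ``position``.
      * ``peak_ratio``      — A(position) / A(position2).
      * ``band_area``       — trapezoidal integral of A over [band_lo, band_hi].
      * ``center_of_gravity`` — sum(nu * A) / sum(A) over the band samples.

    If ``baseline_anchors`` (two wavenumbers) are given, a straight line
    through the spectrum at the anchors is subtracted before evaluation.
    """

    name: str
    kind: MetricKind
    position: float | None = None
    position2: float | None = None
    band_lo: float | None = None
    band_hi: float | None = None
    baseline_anchors: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind in ("peak_absorbance", "peak_ratio") and self.position is None:
            raise ValueError(f"{self.name}: {self.kind} needs a position")
        if self.kind == "peak_ratio" and self.position2 is None:
            raise ValueError(f"{self.name}: peak_ratio needs position2")
        if self.kind in ("band_area", "center_of_gravity"):
            if self.band_lo is None or self.band_hi is None:
                raise ValueError(f"{self.name}: {self.kind} needs band limits")
            if not self.band_lo < self.band_hi:
                raise ValueError(f"{self.name}: band_lo must be < band_hi")

    def positions_used(self) -> list[float]:
        out = []
        for p in (self.position, self.position2, self.band_lo, self.band_hi):
            if p is not None:
                out.append(float(p))
        if self.baseline_anchors is not None:
            out.extend(float(a) for a in self.baseline_anchors)
        return out


@dataclass
class MetricMatrix:
    """Per-pixel metric values for one core / cell type: n pixels x k metrics."""

    pixel_ids: np.ndarray
    metric_names: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.pixel_ids = np.asarray(self.pixel_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (pixels x metrics)")
        if self.values.shape[0] != len(self.pixel_ids):
            raise ValueError("pixel_ids length must match rows")
        if self.values.shape[1] != len(self.metric_names):
            raise ValueError("metric_names length must match columns")
        if len(set(self.metric_names)) != len(self.metric_names):
            raise ValueError("metric names must be unique")
        if self.values.shape[0] < 1:
            raise ValueError("matrix must contain at least one pixel")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("metric values must be finite")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_metrics(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.metric_names, index=self.pixel_ids)


@dataclass
class CellTypeMask:
    """Per-pixel grid coordinates and cell-type labels for one core."""

    rows: np.ndarray
    cols: np.ndarray
    labels: np.ndarray  # entries in {"epithelium", "stroma", "other"}
    pitch_um: float = DEFAULT_PIXEL_PITCH_UM

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        self.labels = np.asarray(self.labels, dtype=object)
        if not (len(self.rows) == len(self.cols) == len(self.labels)):
            raise ValueError("rows, cols, labels must have equal length")
        if self.pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        coords = set(zip(self.rows.tolist(), self.cols.tolist()))
        if len(coords) != len(self.rows):
            raise ValueError("pixel coordinates must be unique within a core")
        bad = set(self.labels) - {"epithelium", "stroma", "other"}
        if bad:
            raise ValueError(f"unknown cell-type labels: {bad}")

    def __len__(self) -> int:
        return len(self.rows)

    def epithelium_fraction(self) -> float:
        return float(np.mean(self.labels == "epithelium"))


@dataclass
class ClinicalRecord:
    """Per-patient clinical variables (matching, CAPRA-S, covariate models)."""

    patient_id: str
    age: float
    race: str
    gleason_primary: int | None
    gleason_secondary: int | None
    gleason_sum: int
    stage: str
    psa: float
    positive_margins: bool | None = None
    svi: bool | None = None
    ece: bool | None = None
    lni: bool | None = None
    therapy: bool = False
    recurrence: bool | None = None
    months_to_recurrence: float | None = None

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.psa < 0:
            raise ValueError("PSA must be non-negative")
        if self.stage not in STAGE_CODES:
            raise ValueError(f"unknown pathologic stage {self.stage!r}")
        if self.gleason_primary is not None and self.gleason_secondary is not None:
            if self.gleason_sum != self.gleason_primary + self.gleason_secondary:
                raise ValueError("Gleason sum must equal primary + secondary")

    @property
    def stage_code(self) -> int:
        return STAGE_CODES[self.stage]


# ---------------------------------------------------------------------------
# metric computation
# ---------------------------------------------------------------------------

#: ratio/center-of-gravity denominators below this are flagged invalid
DENOM_TOL = 1e-12


def _baseline(spec: PixelSpectrum, anchors: tuple[float, float]) -> np.ndarray:
    """Linear baseline through the spectrum values at two anchor wavenumbers."""
    wn = spec.wavenumbers
    a0, a1 = sorted(anchors)
    i0 = int(np.argmin(np.abs(wn - a0)))
    i1 = int(np.argmin(np.abs(wn - a1)))
    x0, x1 = wn[i0], wn[i1]
    y0, y1 = spec.absorbance[i0], spec.absorbance[i1]
    if x0 == x1:
        return np.full_like(wn, y0)
    slope = (y1 - y0) / (x1 - x0)
    return y0 + slope * (wn - x0)


def compute_metric(spectrum: PixelSpectrum, definition: MetricDefinition) -> float:
    """Evaluate one metric on one spectrum.

    Returns NaN when a ratio or center-of-gravity denominator is below
    tolerance (flagged-invalid); raises if a definition position falls
    outside the spectrum's wavenumber range.
    """
    spec = spectrum.ascending
    wn, ab = spec.wavenumbers, spec.absorbance
    for p in definition.positions_used():
        if p < wn[0] - 1e-9 or p > wn[-1] + 1e-9:
            raise ValueError(
                f"metric {definition.name}: position {p} outside spectral range "
                f"[{wn[0]}, {wn[-1]}]"
            )
    if definition.baseline_anchors is not None:
        ab = ab - _baseline(spec, definition.baseline_anchors)

    kind = definition.kind
    if kind == "peak_absorbance":
        return float(ab[np.argmin(np.abs(wn - definition.position))])
    if kind == "peak_ratio":
        num = ab[np.argmin(np.abs(wn - definition.position))]
        den = ab[np.argmin(np.abs(wn - definition.position2))]
        if abs(den) <= DENOM_TOL:
            return float("nan")
        return float(num / den)

    sel = (wn >= definition.band_lo - 1e-9) & (wn <= definition.band_hi + 1e-9)
    if sel.sum() < 2:
        raise ValueError(f"metric {definition.name}: band covers <2 grid points")
    if kind == "band_area":
        return float(np.trapezoid(ab[sel], wn[sel]))
    if kind == "center_of_gravity":
        total = ab[sel].sum()
        if abs(total) <= DENOM_TOL:
            return float("nan")
        return float((wn[sel] * ab[sel]).sum() / total)
    raise ValueError(f"unknown metric kind {kind!r}")


def apply_metrics(
    spectra: Sequence[PixelSpectrum],
    defs: Sequence[MetricDefinition],
    pixel_ids: Sequence | None = None,
    invalid_policy: Literal["drop", "impute_median"] = "drop",
) -> MetricMatrix:
    """Convert spectra into a pixel x metric matrix.

    Pixels yielding any flagged-invalid metric are dropped (default) or
    imputed with the column median; counts are logged either way.
    """
    if len(spectra) == 0 or len(defs) == 0:
        raise ValueError("need at least one spectrum and one metric definition")
    if pixel_ids is None:
        pixel_ids = np.arange(len(spectra))
    vals = np.array([[compute_metric(s, d) for d in defs] for s in spectra], dtype=float)
    bad = ~np.isfinite(vals)
    if bad.any():
        n_bad = int(bad.any(axis=1).sum())
        if invalid_policy == "drop":
            keep = ~bad.any(axis=1)
            logger.warning("apply_metrics: dropping %d pixel(s) with invalid metrics", n_bad)
            vals = vals[keep]
            pixel_ids = np.asarray(pixel_ids)[keep]
            if vals.shape[0] == 0:
                raise ValueError("all pixels dropped by invalid-metric policy")
        elif invalid_policy == "impute_median":
            logger.warning("apply_metrics: imputing %d pixel(s) with column medians", n_bad)
            for j in range(vals.shape[1]):
                col = vals[:, j]
                med = np.nanmedian(col)
                col[~np.isfinite(col)] = med
        else:
            raise ValueError(f"unknown invalid policy {invalid_policy!r}")
    return MetricMatrix(np.asarray(pixel_ids), [d.name for d in defs], vals)


# ---------------------------------------------------------------------------
# adjacency selection & eligibility filtering
# ---------------------------------------------------------------------------

def select_adjacent_stroma(
    mask: CellTypeMask,
    radius_um: float = 50.0,
    metric: Literal["chebyshev", "euclidean"] = "chebyshev",
) -> np.ndarray:
    """Indices of stromal pixels within ``radius_um`` of any epithelial pixel.

    Distance is Chebyshev on the pixel grid scaled by the pitch (equivalent to
    a morphological dilation of the epithelium; with a 6.25 um pitch and a
    50 um radius this is the 8-pixel square neighbourhood); Euclidean is
    available as an option.
    """
    if len(mask) == 0:
        raise ValueError("empty mask")
    epi = mask.labels == "epithelium"
    stroma = mask.labels == "stroma"
    if not epi.any():
        logger.warning("select_adjacent_stroma: no epithelium pixels in core")
        return np.array([], dtype=int)
    if not stroma.any():
        return np.array([], dtype=int)
    coords = np.column_stack([mask.rows, mask.cols]).astype(float) * mask.pitch_um
    p = np.inf if metric == "chebyshev" else 2
    tree = cKDTree(coords[epi])
    d, _ = tree.query(coords[stroma], k=1, p=p)
    sel = d <= radius_um + 1e-9
    return np.flatnonzero(stroma)[sel]


@dataclass
class CoreEligibility:
    core_id: str
    eligible: bool
    epithelium_fraction: float
    n_adjacent_stroma: int
    reason: str = ""


def filter_eligible(
    cores: dict[str, CellTypeMask],
    patients_of_cores: dict[str, str],
    min_epithelium_fraction: float = 0.10,
    min_cores: int = 2,
    radius_um: float = 50.0,
) -> tuple[set[str], set[str], list[CoreEligibility]]:
    """Apply the study eligibility rules.

    A core is eligible iff its malignant-epithelium fraction is >= 10 % of the
    core *and* it has at least one tumor-adjacent stromal pixel; a patient is
    eligible iff they retain at least ``min_cores`` eligible cores.

    Returns (eligible patient ids, eligible core ids, per-core audit trail).
    """
    audit: list[CoreEligibility] = []
    eligible_cores: set[str] = set()
    per_patient: dict[str, int] = {}
    for core_id, mask in cores.items():
        frac = mask.epithelium_fraction()
        n_adj = len(select_adjacent_stroma(mask, radius_um)) if frac > 0 else 0
        ok = frac >= min_epithelium_fraction and n_adj > 0
        reason = ""
        if frac < min_epithelium_fraction:
            reason = f"epithelium fraction {frac:.3f} < {min_epithelium_fraction}"
        elif n_adj == 0:
            reason = "no adjacent stromal pixels"
        audit.append(CoreEligibility(core_id, ok, frac, n_adj, reason))
        if ok:
            eligible_cores.add(core_id)
            pid = patients_of_cores[core_id]
            per_patient[pid] = per_patient.get(pid, 0) + 1
    eligible_patients = {p for p, n in per_patient.items() if n >= min_cores}
    eligible_cores = {c for c in eligible_cores if patients_of_cores[c] in eligible_patients}
    for rec in audit:
        if rec.eligible and rec.core_id not in eligible_cores:
            rec.eligible = False
            rec.reason = f"patient has < {min_cores} eligible cores"
    return eligible_patients, eligible_cores, audit


# ---------------------------------------------------------------------------
# default metric definitions
# ---------------------------------------------------------------------------

def default_metric_definitions() -> list[MetricDefinition]:
    """Illustrative spectral-metric panel.

    Covers the spectral regions repeatedly implicated in stromal prognosis:
    the C-O stretching mode of oligosaccharides at 1042 cm^-1, the
    990-1132 cm^-1 carbohydrate window, amide I/II bands and the
    3000-3600 cm^-1 N-H/O-H stretching region.  The full panel used on real
    data is configurable; this default is a documented subset.
    """
    defs = [
        MetricDefinition("abs_1042", "peak_absorbance", position=1042),
        MetricDefinition("abs_1080", "peak_absorbance", position=1080),
        MetricDefinition("abs_1238", "peak_absorbance", position=1238),
        MetricDefinition("abs_1545", "peak_absorbance", position=1545),
        MetricDefinition("abs_1655", "peak_absorbance", position=1655),
        MetricDefinition("abs_2920", "peak_absorbance", position=2920),
        MetricDefinition("abs_3290", "peak_absorbance", position=3290),
        MetricDefinition("ratio_1042_1655", "peak_ratio", position=1042, position2=1655),
        MetricDefinition("ratio_1080_1545", "peak_ratio", position=1080, position2=1545),
        MetricDefinition("ratio_1655_1545", "peak_ratio", position=1655, position2=1545),
        MetricDefinition("ratio_3290_1655", "peak_ratio", position=3290, position2=1655),
        MetricDefinition("area_990_1132", "band_area", band_lo=990, band_hi=1132),
        MetricDefinition("area_1180_1300", "band_area", band_lo=1180, band_hi=1300),
        MetricDefinition("area_1600_1700", "band_area", band_lo=1600, band_hi=1700),
        MetricDefinition("area_3000_3600", "band_area", band_lo=3000, band_hi=3600),
        MetricDefinition("cog_990_1132", "center_of_gravity", band_lo=990, band_hi=1132),
        MetricDefinition("cog_1600_1700", "center_of_gravity", band_lo=1600, band_hi=1700),
        MetricDefinition("cog_3000_3600", "center_of_gravity", band_lo=3000, band_hi=3600),
        MetricDefinition(
            "area_1022_1062_bc", "band_area", band_lo=1022, band_hi=1062,
            baseline_anchors=(1022, 1062),
        ),
        MetricDefinition(
            "abs_1042_bc", "peak_absorbance", position=1042,
            baseline_anchors=(990, 1132),
        ),
    ]
    return defs


# ---------------------------------------------------------------------------
# I/O: pixel tables, clinical tables, metric definitions
# ---------------------------------------------------------------------------

PIXEL_TABLE_FIXED_COLS = ["core_id", "x", "y", "cell_type"]


def write_pixel_table(
    path,
    cores: Iterable[tuple[str, MetricMatrix, CellTypeMask]],
) -> None:
    """Write cores as a single CSV: core_id,x,y,cell_type,metric_*."""
    frames = []
    for core_id, matrix, mask in cores:
        df = pd.DataFrame({
            "core_id": core_id,
            "x": mask.cols,
            "y": mask.rows,
            "cell_type": mask.labels,
        })
        for j, name in enumerate(matrix.metric_names):
            df[f"metric_{name}"] = matrix.values[:, j]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_pixel_table(path) -> list[tuple[str, MetricMatrix, CellTypeMask]]:
    df = pd.read_csv(path)
    metric_cols = [c for c in df.columns if c.startswith("metric_")]
    names = [c[len("metric_"):] for c in metric_cols]
    out = []
    for core_id, grp in df.groupby("core_id", sort=True):
        mask = CellTypeMask(grp["y"].to_numpy(), grp["x"].to_numpy(),
                            grp["cell_type"].to_numpy())
        mat = MetricMatrix(np.arange(len(grp)), names, grp[metric_cols].to_numpy())
        out.append((str(core_id), mat, mask))
    return out


_CLINICAL_COLS = [
    "patient_id", "age", "race", "gleason_primary", "gleason_secondary",
    "gleason_sum", "stage", "psa", "positive_margins", "svi", "ece", "lni",
    "therapy", "recurrence", "months_to_recurrence",
]


def write_clinical_table(path, records: Sequence[ClinicalRecord]) -> None:
    rows = [asdict(r) for r in records]
    pd.DataFrame(rows, columns=_CLINICAL_COLS).to_csv(path, index=False)


def _opt_bool(v):
    if pd.isna(v):
        return None
    return bool(v)


def read_clinical_table(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(ClinicalRecord(
            patient_id=str(r["patient_id"]),
            age=float(r["age"]),
            race=str(r["race"]),
            gleason_primary=None if pd.isna(r["gleason_primary"]) else int(r["gleason_primary"]),
            gleason_secondary=None if pd.isna(r["gleason_secondary"]) else int(r["gleason_secondary"]),
            gleason_sum=int(r["gleason_sum"]),
            stage=str(r["stage"]),
            psa=float(r["psa"]),
            positive_margins=_opt_bool(r["positive_margins"]),
            svi=_opt_bool(r["svi"]),
            ece=_opt_bool(r["ece"]),
            lni=_opt_bool(r["lni"]),
            therapy=bool(r["therapy"]),
            recurrence=_opt_bool(r["recurrence"]),
            months_to_recurrence=None if pd.isna(r["months_to_recurrence"])
            else float(r["months_to_recurrence"]),
        ))
    return out


def write_metric_definitions(path, defs: Sequence[MetricDefinition]) -> None:
    payload = []
    for d in defs:
        entry = {k: v for k, v in asdict(d).items() if v is not None}
        if d.baseline_anchors is not None:
            entry["baseline_anchors"] = list(d.baseline_anchors)
        payload.append(entry)
    text = yaml.safe_dump(payload, sort_keys=False)
    with open(path, "w") as fh:
        fh.write(text)


def read_metric_definitions(path) -> list[MetricDefinition]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    defs = []
    for entry in payload:
        if "baseline_anchors" in entry and entry["baseline_anchors"] is not None:
            entry["baseline_anchors"] = tuple(entry["baseline_anchors"])
        defs.append(MetricDefinition(**entry))
    return defs
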