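"""Reference clinical risk scores: CAPRA-S, a pluggable nomogram, and the
weighted combined score.

CAPRA-S is a post-surgical point score in 0-12 built from PSA, pathologic
Gleason pattern, surgical margin status, seminal vesicle invasion (SVI),
extracapsular extension (ECE) and lymph node invasion (LNI); totals 0-2,
3-5 and >=6 map to low-, intermediate- and high-risk groups.  The point
table ships as an editable config with the published assignments as the
default.  The Kattan nomogram's proprietary Cox coefficients are not
re-derived: a user-supplied table drives ``kattan_ppr`` and its absence is
an explicit error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import yaml

from .tissue import ClinicalRecord


# ---------------------------------------------------------------------------
# CAPRA-S
# ---------------------------------------------------------------------------

@dataclass
class CapraSPoints:
    """Per-variable point assignments.

    Defaults follow the published CAPRA-S table: PSA contributes up to 3
    points by cut-points (<=6: 0, <=10: 1, <=20: 2, >20: 3); pathologic
    Gleason up to 3 (no pattern >=4: 0, secondary pattern >=4: 1, primary
    pattern >=4: 3); positive margins and SVI 2 each; ECE and LNI 1 each.
    """

    psa_cutpoints: tuple[float, ...] = (6.0, 10.0, 20.0)
    psa_points: tuple[int, ...] = (0, 1, 2, 3)
    gleason_no_pattern4: int = 0
    gleason_secondary4: int = 1
    gleason_primary4: int = 3
    margin_points: int = 2
    svi_points: int = 2
    ece_points: int = 1
    lni_points: int = 1
    category_cutpoints: tuple[int, int] = (3, 6)  # low < 3 <= intermediate < 6 <= high

    @property
    def max_total(self) -> int:
        return (max(self.psa_points) + self.gleason_primary4 + self.margin_points
                + self.svi_points + self.ece_points + self.lni_points)


def _require(record: ClinicalRecord, attr: str):
    v = getattr(record, attr)
    if v is None:
        raise ValueError(f"CAPRA-S requires {attr!r} for patient {record.patient_id}")
    return v


def capra_s_score(record: ClinicalRecord, points: CapraSPoints | None = None) -> int:
    """Total CAPRA-S points (0-12 with the default table).

    Missing required variables raise; nothing is imputed silently.
    """
    pts = points or CapraSPoints()
    psa = _require(record, "psa")
    primary = _require(record, "gleason_primary")
    secondary = _require(record, "gleason_secondary")
    total = pts.psa_points[int(np.searchsorted(pts.psa_cutpoints, psa, side="left"))]
    if primary >= 4:
        total += pts.gleason_primary4
    elif secondary >= 4:
        total += pts.gleason_secondary4
    else:
        total += pts.gleason_no_pattern4
    if _require(record, "positive_margins"):
        total += pts.margin_points
    if _require(record, "svi"):
        total += pts.svi_points
    if _require(record, "ece"):
        total += pts.ece_points
    if _require(record, "lni"):
        total += pts.lni_points
    return int(total)


def capra_s_category(score: int, points: CapraSPoints | None = None) -> str:
    """Risk group for a CAPRA-S total: 0-2 low, 3-5 intermediate, >=6 high."""
    pts = points or CapraSPoints()
    if not 0 <= score <= pts.max_total:
        raise ValueError(f"score {score} outside [0, {pts.max_total}]")
    lo, hi = pts.category_cutpoints
    if score < lo:
        return "low"
    if score < hi:
        return "intermediate"
    return "high"


def capra_s_points_to_yaml(points: CapraSPoints) -> str:
    return yaml.safe_dump({
        "psa_cutpoints": list(points.psa_cutpoints),
        "psa_points": list(points.psa_points),
        "gleason_no_pattern4": points.gleason_no_pattern4,
        "gleason_secondary4": points.gleason_secondary4,
        "gleason_primary4": points.gleason_primary4,
        "margin_points": points.margin_points,
        "svi_points": points.svi_points,
        "ece_points": points.ece_points,
        "lni_points": points.lni_points,
        "category_cutpoints": list(points.category_cutpoints),
    }, sort_keys=False)


def capra_s_points_from_yaml(text: str) -> CapraSPoints:
    d = yaml.safe_load(text)
    d["psa_cutpoints"] = tuple(d["psa_cutpoints"])
    d["psa_points"] = tuple(d["psa_points"])
    d["category_cutpoints"] = tuple(d["category_cutpoints"])
    return CapraSPoints(**d)


# ---------------------------------------------------------------------------
# Kattan nomogram (pluggable)
# ---------------------------------------------------------------------------

@dataclass
class NomogramTable:
    """User-supplied nomogram: per-variable prognostic points and the mapping
    from total points to recurrence probability.

    ``point_functions`` maps a clinical attribute name to a callable
    attribute value -> points; ``probability_of_total`` maps the summed
    points to a survival probability (PPR = 1 - survival).
    """

    point_functions: dict[str, Callable[[float], float]]
    probability_of_total: Callable[[float], float]


def kattan_ppr(record: ClinicalRecord, table: NomogramTable | None) -> float:
    """Predicted probability of recurrence under a supplied nomogram table.

    The published nomogram's Cox coefficients are proprietary and are not
    bundled; calling without a table raises.
    """
    if table is None:
        raise NotImplementedError(
            "Kattan nomogram coefficients are not distributed with this package; "
            "supply a NomogramTable built from the published nomogram"
        )
    total = 0.0
    for attr, fn in table.point_functions.items():
        v = getattr(record, attr)
        if v is None:
            raise ValueError(f"nomogram requires {attr!r}")
        total += float(fn(v))
    surv = float(table.probability_of_total(total))
    if not 0.0 <= surv <= 1.0:
        raise ValueError("probability_of_total must return a probability")
    return 1.0 - surv


# ---------------------------------------------------------------------------
# combined score
# ---------------------------------------------------------------------------

def combined_score(ir: float, external: float, x: float) -> float:
    """Convex combination C = (1 - x) * IR + x * E with weight 0 < x <= 1.

    Both inputs are expected on a [0, 1] probability scale (CAPRA-S totals
    should be divided by 12 before combining; a nomogram PPR is used as-is).
    """
    if not 0 < x <= 1:
        raise ValueError("weight x must lie in (0, 1]")
    return (1.0 - x) * ir + x * external
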