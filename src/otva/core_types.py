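"""Domain model for outflow-tract ventricular arrhythmia (OTVA) localization.

Holds the vocabulary shared by every stage of the pipeline: the precordial
transition site and its half-point score, per-beat QRS measurements, the
patient record (measurements + chest-radiograph cardiac long-axis angle +
ablation-confirmed origin label), and the evaluation products (per-criterion
calls, confusion-matrix metrics, ROC results).

Conventions
-----------
* R- and S-wave amplitudes are stored as non-negative magnitudes in mV.
* The positive class throughout the package is RVOT.
* A missing measurement is ``None``; operations that need a missing field
  return a missing result (``None`` / ``INDETERMINATE``), never a silent zero.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence


class Origin(str, enum.Enum):
    """Anatomical origin of the arrhythmia (RVOT is the positive class)."""

    RVOT = "RVOT"
    LVOT = "LVOT"
    UNKNOWN = "UNKNOWN"


class Call(str, enum.Enum):
    """Predicted origin under one criterion; INDETERMINATE = missing input."""

    RVOT = "RVOT"
    LVOT = "LVOT"
    INDETERMINATE = "INDETERMINATE"


class Direction(str, enum.Enum):
    """Orientation of a threshold rule: which side of the cutoff calls RVOT."""

    GE_PREDICTS_RVOT = "GE_PREDICTS_RVOT"
    GE_PREDICTS_LVOT = "GE_PREDICTS_LVOT"


# --------------------------------------------------------------------------
# Precordial transition site
# --------------------------------------------------------------------------

_TZ_PAIR_RE = re.compile(r"^\s*[vV]\s*([1-6])\s*[-–—/]\s*[vV]?\s*([1-6])\s*$")
_TZ_SINGLE_RE = re.compile(r"^\s*[vV]\s*([1-6])\s*$")


@dataclass(frozen=True)
class TransitionSite:
    """Site of the precordial R-wave transition.

    ``lead_index`` is k for lead V_k (1..6); ``between_next`` marks a
    transition falling between V_k and V_{k+1}.
    """

    lead_index: int
    between_next: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.lead_index, int) or not 1 <= self.lead_index <= 6:
            raise ValueError(f"lead_index must be an integer in 1..6, got {self.lead_index!r}")
        if self.between_next and self.lead_index > 5:
            raise ValueError("between_next requires lead_index <= 5")

    @property
    def score(self) -> float:
        return tz_score(self)

    def __str__(self) -> str:
        return format_transition(self)


def tz_score(site: TransitionSite) -> float:
    """Transition-zone score in half-point increments: V1=1, V1-V2=1.5, ... V6=6."""
    return site.lead_index + (0.5 if site.between_next else 0.0)


def format_transition(site: TransitionSite) -> str:
    """Canonical text form, e.g. ``V2`` or ``V2-V3``."""
    if site.between_next:
        return f"V{site.lead_index}-V{site.lead_index + 1}"
    return f"V{site.lead_index}"


def parse_transition(text: str) -> TransitionSite:
    """Parse ``"V2"``, ``"V2-V3"`` (en-dash tolerated) or a half-integer numeral.

    Raises ``ValueError`` for non-adjacent lead pairs or leads outside V1..V6.
    """
    if not isinstance(text, str):
        raise ValueError(f"cannot parse transition site from {text!r}")
    s = text.strip()
    m = _TZ_PAIR_RE.match(s)
    if m:
        a, b = int(m.group(1)), int(m.group(2))
        if b != a + 1:
            raise ValueError(f"non-adjacent transition pair {text!r}")
        return TransitionSite(a, True)
    m = _TZ_SINGLE_RE.match(s)
    if m:
        return TransitionSite(int(m.group(1)), False)
    try:
        val = float(s)
    except ValueError:
        raise ValueError(f"cannot parse transition site from {text!r}") from None
    if not math.isfinite(val) or (2 * val) != int(2 * val):
        raise ValueError(f"transition score must be a half-integer, got {text!r}")
    lead = int(math.floor(val))
    between = (val - lead) == 0.5
    return TransitionSite(lead, between)


ALL_TRANSITION_SITES: tuple[TransitionSite, ...] = tuple(
    TransitionSite(k, b) for k in range(1, 7) for b in ((False, True) if k < 6 else (False,))
)


# --------------------------------------------------------------------------
# Measurements and patient record
# --------------------------------------------------------------------------

def _check_nonneg(name: str, value: Optional[float]) -> None:
    if value is not None and (not math.isfinite(value) or value < 0):
        raise ValueError(f"{name} must be a finite value >= 0, got {value!r}")


@dataclass
class BeatMeasurements:
    """Amplitude/duration measurements of one QRS complex (the arrhythmic beat).

    Amplitudes in mV (S-wave stored as positive magnitude), durations in ms.
    Any field may be ``None`` (missing).
    """

    v1r: Optional[float] = None
    v1s: Optional[float] = None
    v2r: Optional[float] = None
    v2s: Optional[float] = None
    v3r: Optional[float] = None
    v3s: Optional[float] = None
    lead1_r: Optional[float] = None
    r_dur_v1: Optional[float] = None
    r_dur_v2: Optional[float] = None
    r_defl_v3: Optional[float] = None
    qrs_dur: Optional[float] = None
    tz: Optional[TransitionSite] = None

    def __post_init__(self) -> None:
        for name in ("v1r", "v1s", "v2r", "v2s", "v3r", "v3s", "lead1_r",
                     "r_dur_v1", "r_dur_v2", "r_defl_v3"):
            _check_nonneg(name, getattr(self, name))
        if self.qrs_dur is not None and (not math.isfinite(self.qrs_dur) or self.qrs_dur <= 0):
            raise ValueError(f"qrs_dur must be > 0, got {self.qrs_dur!r}")
        if self.qrs_dur is not None:
            for name in ("r_dur_v1", "r_dur_v2", "r_defl_v3"):
                v = getattr(self, name)
                if v is not None and v > self.qrs_dur:
                    raise ValueError(f"{name}={v} exceeds qrs_dur={self.qrs_dur}")


@dataclass
class PatientRecord:
    """One patient: arrhythmic-beat measurements, sinus transition, long-axis
    angle (degrees, strictly inside (0, 90)), and the ablation-confirmed
    origin (UNKNOWN for prediction-only inputs)."""

    patient_id: str
    beat: BeatMeasurements = field(default_factory=BeatMeasurements)
    sinus_tz: Optional[TransitionSite] = None
    angle_deg: Optional[float] = None
    origin: Origin = Origin.UNKNOWN
    age_years: Optional[float] = None
    bmi: Optional[float] = None
    lvef_pct: Optional[float] = None
    pvc_burden_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.angle_deg is not None and not (0.0 < self.angle_deg < 90.0):
            raise ValueError(f"angle_deg must lie strictly inside (0, 90), got {self.angle_deg!r}")
        if not isinstance(self.origin, Origin):
            self.origin = Origin(self.origin)


# --------------------------------------------------------------------------
# Evaluation products
# --------------------------------------------------------------------------

@dataclass
class CriterionResult:
    """Index value and predicted origin for one patient under one criterion."""

    criterion_name: str
    value: Optional[float]
    predicted_origin: Call
    cutoff_used: Optional[float] = None
    direction: Optional[Direction] = None


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


@dataclass
class DiagnosticMetrics:
    """Confusion counts (positive class = RVOT) and derived proportions.

    Undefined ratios (zero denominator) are ``None``, never 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    n_indeterminate: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn", "n_indeterminate"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> Optional[float]:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return _ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> Optional[float]:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Optional[float]:
        return _ratio(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> Optional[float]:
        return _ratio(self.tp + self.tn, self.n)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "n_indeterminate": self.n_indeterminate,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "accuracy": self.accuracy,
        }


@dataclass
class ROCResult:
    """ROC curve with AUC, confidence interval, and Youden-optimal cutoff.

    ``thresholds`` are the sorted unique index values; ``tpr``/``fpr`` trace
    the curve from (0, 0) to (1, 1) with RVOT as the positive class.
    """

    thresholds: Sequence[float]
    tpr: Sequence[float]
    fpr: Sequence[float]
    auc: float
    auc_ci_low: Optional[float] = None
    auc_ci_high: Optional[float] = None
    optimal_cutoff: Optional[float] = None
    direction: Direction = Direction.GE_PREDICTS_RVOT
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"auc must lie in [0, 1], got {self.auc}")
        if self.auc_ci_low is not None and self.auc_ci_high is not None:
            if not (self.auc_ci_low <= self.auc_ci_high):
                raise ValueError("auc_ci_low must not exceed auc_ci_high")


CSV_COLUMNS = [
    "patient_id", "origin",
    "v1r_mv", "v1s_mv", "v2r_mv", "v2s_mv", "v3r_mv", "v3s_mv",
    "lead1_r_mv", "r_dur_v1_ms", "r_dur_v2_ms", "r_defl_v3_ms", "qrs_ms",
    "tz_pvc", "tz_sinus", "angle_deg",
    "age_years", "bmi", "lvef_pct", "pvc_burden_pct",
]
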