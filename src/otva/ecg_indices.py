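"""ECG localization indices for outflow-tract ventricular arrhythmias.

Implements the angle-corrected V2S index (V2S amplitude x cardiac long-axis
angle, in mV deg) together with the comparator algorithms it was evaluated
against: the transition-zone (TZ) index, V2S/V3R ratio, the combined linear
index Y = -1.15*TZ - 0.494*(V2S/V3R), the V1-V2 S-R difference, the V3
transition rule, lead-I R amplitude, the initial R-wave surface-area (ISA)
index, and the V1 R/S index — plus the angle-corrected variant of each
(base index multiplied by the long-axis angle in degrees).

Missing-value policy: a missing input yields ``None`` (and downstream an
INDETERMINATE call), never a silent zero. Ratio indices return a signed
infinity sentinel on division by zero so threshold classification still
resolves; a combined index that would consume an infinity is missing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Optional, Tuple

from .classification import CriterionRule, classify
from .core_types import (
    Call,
    CriterionResult,
    Direction,
    PatientRecord,
    tz_score,
)

__all__ = [
    "v2s_angle", "lead_wave_angle", "tz_index", "v2s_v3r",
    "combined_tz_v2sv3r", "v12_srd", "v3_transition_criterion",
    "lead1_r_criterion", "isa", "v1r_v1s_index", "angle_correct",
    "CriteriaConfig", "compute_all", "ANGLE_CORRECTABLE",
]

LEAD_WAVES = ("V1S", "V2S", "V3S", "V1R", "V2R", "V3R")

#: base criteria that gain an "_angle" variant by multiplication with the angle
ANGLE_CORRECTABLE = (
    "v2s_v3r", "tz_index", "combined", "v12_srd", "lead1_r", "isa", "v1r_v1s",
)


def _check_angle(angle: float) -> None:
    if not (0.0 < angle < 90.0):
        raise ValueError(f"cardiac long-axis angle must lie strictly inside (0, 90) degrees, got {angle!r}")


def v2s_angle(v2s: float, angle: float) -> float:
    """Angle-corrected V2S: S-wave amplitude in V2 (mV) times the cardiac
    long-axis angle (degrees), in mV deg. E.g. 1.3 mV x 45.1 deg = 58.63."""
    if v2s < 0:
        raise ValueError("v2s amplitude must be >= 0")
    _check_angle(angle)
    return v2s * angle


def lead_wave_angle(amplitude: float, angle: float, which: str) -> float:
    """Angle-corrected amplitude of one precordial wave (V1S..V3R), in mV deg."""
    if which.upper() not in LEAD_WAVES:
        raise ValueError(f"unknown lead wave {which!r}; expected one of {LEAD_WAVES}")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    _check_angle(angle)
    return amplitude * angle


def tz_index(pvc_tz_score: float, sinus_tz_score: float) -> float:
    """TZ index: transition-zone score of the arrhythmic beat minus that of
    the sinus beat (half-point increments, V1 = 1 .. V6 = 6)."""
    for s in (pvc_tz_score, sinus_tz_score):
        if not math.isfinite(s) or (2 * s) != int(2 * s) or not 1.0 <= s <= 6.0:
            raise ValueError(f"TZ score must be a half-integer in [1, 6], got {s!r}")
    return pvc_tz_score - sinus_tz_score


def v2s_v3r(v2s: float, v3r: float) -> Optional[float]:
    """S-wave amplitude in V2 divided by R-wave amplitude in V3.

    A pure ratio: +inf sentinel when v3r = 0 < v2s (classifies to the high
    side of any threshold), missing when both amplitudes are zero.
    """
    if v2s < 0 or v3r < 0:
        raise ValueError("amplitudes must be >= 0")
    if v3r == 0:
        return math.inf if v2s > 0 else None
    return v2s / v3r


def combined_tz_v2sv3r(tz: float, ratio: float) -> Optional[float]:
    """Combined linear index Y = -1.15*TZ - 0.494*(V2S/V3R).

    Y >= -0.76 predicts an LVOT origin. An infinite ratio makes Y missing."""
    if math.isinf(ratio):
        return None
    return -1.15 * tz - 0.494 * ratio


def v12_srd(v1s: float, v2s: float, v1r: float, v2r: float) -> float:
    """V1-V2 S-R difference: (V1S + V2S) - (V1R + V2R), in mV."""
    for a in (v1s, v2s, v1r, v2r):
        if a < 0:
            raise ValueError("amplitudes must be >= 0")
    return (v1s + v2s) - (v1r + v2r)


def v3_transition_criterion(
    r_defl_v3: float,
    v1r: float,
    v1s: float,
    amplitude_index_mode: Literal["bounded", "ratio"] = "bounded",
) -> Optional[bool]:
    """V3-transition rule: R-wave deflection interval in V3 > 80 ms AND a V1
    R-wave amplitude index > 0.3 predicts an LVOT origin (returns True).

    The amplitude index is v1r/(v1r+v1s) by default (bounded in [0, 1]); the
    ``"ratio"`` mode uses the raw v1r/v1s ratio instead. Returns ``None``
    when v1r = v1s = 0 (index undefined).
    """
    if r_defl_v3 < 0 or v1r < 0 or v1s < 0:
        raise ValueError("inputs must be >= 0")
    if v1r == 0 and v1s == 0:
        return None
    if amplitude_index_mode == "bounded":
        amp_index = v1r / (v1r + v1s)
    elif amplitude_index_mode == "ratio":
        amp_index = math.inf if v1s == 0 else v1r / v1s
    else:
        raise ValueError(f"unknown amplitude_index_mode {amplitude_index_mode!r}")
    return (r_defl_v3 > 80.0) and (amp_index > 0.3)


def lead1_r_criterion(lead1_r: float, cutoff: float = 0.1) -> bool:
    """Lead-I R-amplitude rule: R >= cutoff (default 0.1 mV) predicts LVOT."""
    if lead1_r < 0:
        raise ValueError("lead1_r must be >= 0")
    return lead1_r >= cutoff


def isa(
    r_dur_v1: float, v1r: float, r_dur_v2: float, v2r: float
) -> Tuple[float, float, float]:
    """Initial R-wave surface-area surrogate: R duration (ms) x R amplitude
    (mV) per lead; the index is the highest of V1 and V2.

    Returns ``(isa_v1, isa_v2, isa_max)``.
    """
    for x in (r_dur_v1, v1r, r_dur_v2, v2r):
        if x < 0:
            raise ValueError("inputs must be >= 0")
    isa_v1 = r_dur_v1 * v1r
    isa_v2 = r_dur_v2 * v2r
    return isa_v1, isa_v2, max(isa_v1, isa_v2)


def v1r_v1s_index(
    v1r: float, v1s: float, r_dur_v1: float, qrs_dur: float
) -> Tuple[Optional[float], float, Optional[bool]]:
    """V1 R/S index: amplitude ratio v1r/v1s, R-duration index r_dur/qrs, and
    the aortic-sinus-cusp pattern flag (duration index >= 50% AND amplitude
    ratio >= 30%, both inclusive).

    Returns ``(amp_ratio, dur_index, asc_pattern)``; the ratio is the +inf
    sentinel when v1s = 0 < v1r and missing when both amplitudes are zero.
    """
    if qrs_dur <= 0:
        raise ValueError("qrs_dur must be > 0")
    if v1r < 0 or v1s < 0 or r_dur_v1 < 0:
        raise ValueError("amplitudes and durations must be >= 0")
    if v1s == 0:
        amp_ratio: Optional[float] = math.inf if v1r > 0 else None
    else:
        amp_ratio = v1r / v1s
    dur_index = r_dur_v1 / qrs_dur
    if amp_ratio is None:
        return None, dur_index, None
    return amp_ratio, dur_index, (dur_index >= 0.5) and (amp_ratio >= 0.3)


def angle_correct(base_value: float, angle: float) -> Optional[float]:
    """Angle-correct any base index: base x angle (degrees).

    Infinite bases (ratio sentinels) yield a missing corrected value."""
    _check_angle(angle)
    if math.isinf(base_value):
        return None
    return base_value * angle


# --------------------------------------------------------------------------
# Criteria configuration
# --------------------------------------------------------------------------

_R = Direction.GE_PREDICTS_RVOT
_L = Direction.GE_PREDICTS_LVOT


def _published_rules() -> Dict[str, CriterionRule]:
    """Each rule with its published comparator; criteria published without a
    decision rule carry their ROC-derived cutoff (development-cohort Table)."""
    rules = [
        CriterionRule("v1s_angle", 31.77, _R),
        CriterionRule("v2s_angle", 58.28, _R),
        CriterionRule("v3s_angle", 18.14, _R),
        CriterionRule("v1r_angle", 9.15, _R),
        CriterionRule("v2r_angle", 91.20, _R),
        CriterionRule("v3r_angle", 136.30, _R),
        CriterionRule("tz_index", 0.0, _R),
        CriterionRule("v2s_v3r", 1.5, _R, strict=True),
        CriterionRule("combined", -0.76, _L),
        CriterionRule("v12_srd", 1.625, _R, strict=True),
        CriterionRule("v3_transition", 0.5, _L),
        CriterionRule("lead1_r", 0.1, _L),
        CriterionRule("isa", 15.0, _L),
        CriterionRule("isa_v1", 0.36, _R),
        CriterionRule("isa_v2", 42.0, _R),
        CriterionRule("v1r_v1s", 0.3, _L),
        # angle-corrected family (development-cohort ROC cutoffs)
        CriterionRule("v2s_v3r_angle", 48.36, _R),
        CriterionRule("tz_index_angle", -5.68, _R),
        CriterionRule("combined_angle", -508.28, _R),
        CriterionRule("v12_srd_angle", 52.71, _R),
        CriterionRule("lead1_r_angle", 0.98, _R),
        CriterionRule("isa_angle", 1.31, _R),
        CriterionRule("v1r_v1s_angle", 1565.0, _R),
    ]
    return {r.name: r for r in rules}


def _roc_table2_rules() -> Dict[str, CriterionRule]:
    """The ROC-derived cutoff family, oriented so the stated inequality
    predicts RVOT (matching the diagnostic-index table)."""
    rules = _published_rules()
    rules.update({r.name: r for r in [
        CriterionRule("tz_index", -0.25, _R),
        CriterionRule("v2s_v3r", 1.40, _R),
        CriterionRule("lead1_r", 2.67, _R),
        CriterionRule("isa", 250.0, _R),
        CriterionRule("v1r_v1s", 0.3, _L, strict=True),  # <= 0.3 predicts RVOT
    ]})
    return rules


_PRESETS = {"published": _published_rules, "roc_table2": _roc_table2_rules}


@dataclass
class CriteriaConfig:
    """Cutoffs, directions, and comparators for every localization criterion.

    Two named presets exist: ``"published"`` (each rule with the comparator it
    was published with) and ``"roc_table2"`` (the ROC-derived cutoff family).
    """

    rules: Dict[str, CriterionRule] = field(default_factory=_published_rules)
    preset_name: str = "published"
    v1_amplitude_index_mode: Literal["bounded", "ratio"] = "bounded"

    @classmethod
    def preset(cls, name: str = "published") -> "CriteriaConfig":
        try:
            factory = _PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
            ) from None
        return cls(rules=factory(), preset_name=name)

    def rule(self, name: str) -> CriterionRule:
        return self.rules[name]

    def enabled_criteria(self) -> List[str]:
        return [n for n, r in self.rules.items() if r.enabled]

    def with_overrides(self, **overrides: dict) -> "CriteriaConfig":
        """Return a copy with per-criterion fields replaced, e.g.
        ``cfg.with_overrides(v2s_angle={"cutoff": 60.0})``."""
        rules = dict(self.rules)
        for name, fields in overrides.items():
            rules[name] = replace(rules[name], **fields)
        return CriteriaConfig(rules=rules, preset_name=f"{self.preset_name}+overrides",
                              v1_amplitude_index_mode=self.v1_amplitude_index_mode)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            name: {
                "cutoff": r.cutoff,
                "direction": r.direction.value,
                "strict": r.strict,
                "enabled": r.enabled,
            }
            for name, r in sorted(self.rules.items())
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict, base_preset: str = "published") -> "CriteriaConfig":
        cfg = cls.preset(base_preset)
        rules = dict(cfg.rules)
        for name, spec in data.items():
            base = rules.get(name, CriterionRule(name, 0.0, _R))
            rules[name] = CriterionRule(
                name=name,
                cutoff=float(spec.get("cutoff", base.cutoff)),
                direction=Direction(spec.get("direction", base.direction.value)),
                strict=bool(spec.get("strict", base.strict)),
                enabled=bool(spec.get("enabled", base.enabled)),
            )
        return cls(rules=rules, preset_name=f"{base_preset}+file")


# --------------------------------------------------------------------------
# Per-record computation of every criterion
# --------------------------------------------------------------------------

def _all_values(record: PatientRecord, config: CriteriaConfig) -> Dict[str, Optional[float]]:
    b = record.beat
    angle = record.angle_deg
    vals: Dict[str, Optional[float]] = {}

    amp = {"V1S": b.v1s, "V2S": b.v2s, "V3S": b.v3s,
           "V1R": b.v1r, "V2R": b.v2r, "V3R": b.v3r}
    for wave, a in amp.items():
        key = f"{wave.lower()}_angle"  # v1s_angle etc.
        vals[key] = None if (a is None or angle is None) else lead_wave_angle(a, angle, wave)

    if b.tz is not None and record.sinus_tz is not None:
        vals["tz_index"] = tz_index(tz_score(b.tz), tz_score(record.sinus_tz))
    else:
        vals["tz_index"] = None

    if b.v2s is not None and b.v3r is not None:
        vals["v2s_v3r"] = v2s_v3r(b.v2s, b.v3r)
    else:
        vals["v2s_v3r"] = None

    tz_val, ratio = vals["tz_index"], vals["v2s_v3r"]
    if tz_val is None or ratio is None:
        vals["combined"] = None
    else:
        vals["combined"] = combined_tz_v2sv3r(tz_val, ratio)

    if None not in (b.v1s, b.v2s, b.v1r, b.v2r):
        vals["v12_srd"] = v12_srd(b.v1s, b.v2s, b.v1r, b.v2r)
    else:
        vals["v12_srd"] = None

    if None not in (b.r_defl_v3, b.v1r, b.v1s):
        flag = v3_transition_criterion(
            b.r_defl_v3, b.v1r, b.v1s, config.v1_amplitude_index_mode
        )
        vals["v3_transition"] = None if flag is None else float(flag)
    else:
        vals["v3_transition"] = None

    vals["lead1_r"] = b.lead1_r

    if None not in (b.r_dur_v1, b.v1r):
        vals["isa_v1"] = b.r_dur_v1 * b.v1r
    else:
        vals["isa_v1"] = None
    if None not in (b.r_dur_v2, b.v2r):
        vals["isa_v2"] = b.r_dur_v2 * b.v2r
    else:
        vals["isa_v2"] = None
    if vals["isa_v1"] is not None and vals["isa_v2"] is not None:
        vals["isa"] = max(vals["isa_v1"], vals["isa_v2"])
    else:
        vals["isa"] = None

    if b.v1r is not None and b.v1s is not None:
        if b.v1s == 0:
            vals["v1r_v1s"] = math.inf if b.v1r > 0 else None
        else:
            vals["v1r_v1s"] = b.v1r / b.v1s
    else:
        vals["v1r_v1s"] = None

    for base in ANGLE_CORRECTABLE:
        v = vals[base]
        if v is None or angle is None:
            vals[f"{base}_angle"] = None
        else:
            vals[f"{base}_angle"] = angle_correct(v, angle)

    return vals


def compute_all(record: PatientRecord, config: Optional[CriteriaConfig] = None) -> List[CriterionResult]:
    """Compute every enabled criterion for one patient.

    Missing inputs yield a ``None`` value and an INDETERMINATE call; a record
    with every field missing never raises.
    """
    if config is None:
        config = CriteriaConfig.preset("published")
    vals = _all_values(record, config)
    results: List[CriterionResult] = []
    for name in config.enabled_criteria():
        rule = config.rule(name)
        value = vals.get(name)
        results.append(CriterionResult(
            criterion_name=name,
            value=value,
            predicted_origin=classify(value, rule),
            cutoff_used=rule.cutoff,
            direction=rule.direction,
        ))
    return results
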