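import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from otva import (
    BeatMeasurements,
    Origin,
    PatientRecord,
    TransitionSite,
    worked_example_record,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def fig_record() -> PatientRecord:
    """The worked-example beat (V2S 1.3 mV, V3R 1.4 mV, angle 45.1 deg,
    arrhythmia transition V2, sinus transition V2-V3)."""
    return worked_example_record()


def make_record(pid: str = "p1", origin: Origin = Origin.UNKNOWN, **beat_kwargs) -> PatientRecord:
    angle = beat_kwargs.pop("angle_deg", 40.0)
    sinus = beat_kwargs.pop("sinus_tz", TransitionSite(3, False))
    return PatientRecord(
        patient_id=pid,
        beat=BeatMeasurements(**beat_kwargs),
        sinus_tz=sinus,
        angle_deg=angle,
        origin=origin,
    )


@pytest.fixture
def full_record() -> PatientRecord:
    """A record with every measurement present."""
    return make_record(
        v1r=0.2, v1s=1.1, v2r=0.4, v2s=1.8, v3r=0.6, v3s=0.9,
        lead1_r=0.3, r_dur_v1=30.0, r_dur_v2=40.0, r_defl_v3=60.0,
        qrs_dur=160.0, tz=TransitionSite(3, True),
        sinus_tz=TransitionSite(3, False), angle_deg=38.0,
    )


def pair_count_auc(values, labels) -> float:
    """Exhaustive pair-counting AUC oracle: (concordant + 0.5*tied) over all
    positive-negative pairs, positive class RVOT."""
    pos = [v for v, l in zip(values, labels) if str(getattr(l, "value", l)) == "RVOT"]
    neg = [v for v, l in zip(values, labels) if str(getattr(l, "value", l)) == "LVOT"]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
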