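"""The nine in-silico TdP biomarkers and feature-table assembly.

From the representative beat of a paced, drug-blocked myocyte we extract:

========== =====================================================
dvdt_max   maximal upstroke velocity, mV/ms
vm_resting pre-stimulus membrane potential, mV
apd90/50   action-potential duration to 90%/50% repolarisation, ms
ca_resting diastolic [Ca]i, mM
cad90/50   Ca-transient duration to 90%/50% decay, ms
qnet       net charge: integral over the beat of
           IKr + ICaL + INaL + Ito + IKs + IK1, uC/uF
qinward    mean of the drug/control integral ratios of the two
           inward currents INaL and ICaL (dimensionless)
========== =====================================================

Durations are measured from the instant of maximal upstroke slope
(dVm/dt for APD, dCai/dt for CaD) to the first linear-interpolated crossing
of the amplitude threshold relative to the pre-stimulus resting value.
Beats that never recross the threshold (repolarisation failure under heavy
block) yield the :data:`NO_REPOL` sentinel, which propagates through
concentration averaging and is dropped (with a count) at dataset assembly.

Per the study protocol each (drug, Hill-sample) is simulated at four
concentration multiples of Cmax and the nine biomarkers are averaged
across the four concentrations to give one feature row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

QNET_CHANNELS = ("IKr", "ICaL", "INaL", "Ito", "IKs", "IK1")
QINWARD_CHANNELS = ("INaL", "ICaL")

FEATURE_NAMES = [
    "dvdt_max", "vm_resting", "apd90", "apd50",
    "ca_resting", "cad90", "cad50", "qnet", "qinward",
]
RISK_LEVELS = ("high", "intermediate", "low")

FEATURE_CSV_COLUMNS = ["drug", "sample"] + FEATURE_NAMES + ["risk"]


class NoRepolarization:
    """Sentinel: the trace never recrossed the repolarisation threshold."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "NO_REPOL"


NO_REPOL = NoRepolarization()


def is_flagged(value) -> bool:
    return value is NO_REPOL


class DegenerateControlError(ValueError):
    """Control-beat integral of an inward current is zero."""


# ---------------------------------------------------------------------------
# Duration metrics
# ---------------------------------------------------------------------------

def _duration(time, signal, fraction, min_upstroke=None):
    """Time from max-slope onset to the interpolated crossing of
    rest + (1-fraction) * amplitude on the falling limb."""
    slope = np.gradient(signal, time)
    smax = slope.max()
    # earliest sample attaining the maximal slope (ties within float noise)
    i_up = int(np.nonzero(slope >= smax - abs(smax) * 1e-9)[0][0])
    if min_upstroke is not None and smax <= min_upstroke:
        return NO_REPOL
    rest = signal[0]
    i_peak = int(np.argmax(signal))
    peak = signal[i_peak]
    if peak <= rest:
        return NO_REPOL
    threshold = peak - fraction * (peak - rest)
    below = np.nonzero(signal[i_peak:] < threshold)[0]
    if len(below) == 0:
        return NO_REPOL
    j = i_peak + below[0]
    # linear interpolation between the bracketing samples
    t_cross = np.interp(threshold, [signal[j], signal[j - 1]], [time[j], time[j - 1]])
    return float(t_cross - time[i_up])


def apd(beat, fraction: float) -> float:
    """Action-potential duration at the given repolarisation fraction (ms)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    return _duration(beat.time, beat.vm, fraction, min_upstroke=10.0)


def cad(beat, fraction: float) -> float:
    """Ca-transient duration at the given decay fraction (ms)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    return _duration(beat.time, beat.cai, fraction)


def vm_resting(beat) -> float:
    """Pre-stimulus membrane potential (first sample of the beat), mV."""
    return float(beat.vm[0])


def ca_resting(beat) -> float:
    """Pre-stimulus diastolic [Ca]i (first sample of the beat), mM."""
    return float(beat.cai[0])


def dvdt_max(beat) -> float:
    """Global maximum of dVm/dt over the beat (finite differences), mV/ms."""
    return float(np.max(np.gradient(beat.vm, beat.time)))


# ---------------------------------------------------------------------------
# Charge metrics
# ---------------------------------------------------------------------------

def qnet(beat) -> float:
    """Trapezoidal integral of the six-current sum over the beat, uC/uF."""
    missing = [ch for ch in QNET_CHANNELS if ch not in beat.currents]
    if missing:
        raise KeyError(f"qnet requires currents {missing}")
    total = np.sum([beat.currents[ch] for ch in QNET_CHANNELS], axis=0)
    return float(np.trapezoid(total, beat.time))


def qinward(drug_beat, control_beat) -> float:
    """Mean drug/control integral ratio of INaL and ICaL (dimensionless)."""
    if abs(drug_beat.time[-1] - control_beat.time[-1]) > 1e-9:
        raise ValueError("drug and control beats must share the cycle length")
    ratios = []
    for ch in QINWARD_CHANNELS:
        denom = np.trapezoid(control_beat.currents[ch], control_beat.time)
        if denom == 0.0:
            raise DegenerateControlError(f"control integral of {ch} is zero")
        num = np.trapezoid(drug_beat.currents[ch], drug_beat.time)
        ratios.append(num / denom)
    return float(0.5 * sum(ratios))


# ---------------------------------------------------------------------------
# Feature rows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiomarkerVector:
    """The nine features for one (drug, sample, concentration); any component
    may carry the NO_REPOL sentinel."""

    dvdt_max: object
    vm_resting: object
    apd90: object
    apd50: object
    ca_resting: object
    cad90: object
    cad50: object
    qnet: object
    qinward: object

    def as_dict(self):
        return {k: getattr(self, k) for k in FEATURE_NAMES}

    @property
    def flagged(self) -> bool:
        return any(is_flagged(v) for v in self.as_dict().values())


def extract_biomarkers(beat, control_beat) -> BiomarkerVector:
    """All nine biomarkers for one beat against its zero-block control."""
    return BiomarkerVector(
        dvdt_max=dvdt_max(beat),
        vm_resting=vm_resting(beat),
        apd90=apd(beat, 0.9),
        apd50=apd(beat, 0.5),
        ca_resting=ca_resting(beat),
        cad90=cad(beat, 0.9),
        cad50=cad(beat, 0.5),
        qnet=qnet(beat),
        qinward=qinward(beat, control_beat),
    )


def average_over_concentrations(vectors) -> BiomarkerVector:
    """Elementwise mean of the per-concentration biomarker vectors.

    A NO_REPOL flag in any component of any vector flags the corresponding
    output component (flagged rows are excluded, and counted, downstream).
    """
    vectors = list(vectors)
    if not vectors:
        raise ValueError("no biomarker vectors to average")
    out = {}
    for name in FEATURE_NAMES:
        vals = [getattr(v, name) for v in vectors]
        out[name] = NO_REPOL if any(is_flagged(v) for v in vals) else float(np.mean(vals))
    return BiomarkerVector(**out)


def assemble_dataset(rows: pd.DataFrame, registry: pd.DataFrame):
    """Partition averaged feature rows into train/test per the drug registry.

    ``rows`` columns: drug, sample, the nine features.  ``registry`` columns:
    name, risk, split.  Flagged rows must already be excluded.  Returns
    (train, test) DataFrames in the feature-CSV dialect.
    """
    reg = registry.set_index("name")
    unknown = set(rows["drug"]) - set(reg.index)
    if unknown:
        raise KeyError(f"drugs absent from registry: {sorted(unknown)}")
    merged = rows.copy()
    merged["risk"] = merged["drug"].map(reg["risk"])
    merged["split"] = merged["drug"].map(reg["split"])
    if merged.duplicated(["drug", "sample"]).any():
        raise ValueError("duplicate (drug, sample) rows")
    train = merged[merged["split"] == "train"][FEATURE_CSV_COLUMNS].reset_index(drop=True)
    test = merged[merged["split"] == "test"][FEATURE_CSV_COLUMNS].reset_index(drop=True)
    return train, test


def validate_features(df: pd.DataFrame) -> pd.DataFrame:
    """Schema check for the feature-CSV dialect."""
    missing = set(FEATURE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    bad = set(df["risk"]) - set(RISK_LEVELS)
    if bad:
        raise ValueError(f"unknown risk labels: {sorted(bad)}")
    X = df[FEATURE_NAMES].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        rows = np.nonzero(~np.isfinite(X).all(axis=1))[0]
        raise ValueError(f"non-finite features at rows {rows.tolist()[:10]}")
    return df
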