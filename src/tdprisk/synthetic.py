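"""Synthetic data with known ground truth for every pipeline stage.

Three generators:

* :func:`gen_dose_response` — Hill-curve measurements with truncated
  Gaussian noise over log-spaced doses, for exercising the MCMC fitter
  against known (IC50, h).
* :func:`gen_trace_fixture` — piecewise-linear action-potential and
  calcium-transient beats plus closed-form current waveforms, so every
  biomarker has an exact arithmetic oracle.
* :func:`gen_feature_table` — drug-clustered, class-separated 9-feature
  tables emulating the statistical shape of the study dataset (drug-level
  means per risk class, per-sample scatter, disjoint train/test drugs).

Class-conditional directions in :func:`gen_feature_table` follow the
expected pharmacology: high-risk (strong IKr-block phenotype) drugs carry
prolonged APD/CaD, reduced qNet, and an altered qInward signature, so
explanation sanity checks have a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomarkers import FEATURE_NAMES, RISK_LEVELS, BiomarkerVector
from .drug_block import BLOCKABLE_CHANNELS, inhibition_factor
from .myocyte import BeatTrace


@dataclass(frozen=True)
class SyntheticDrugSpec:
    """Ground-truth pharmacology of one invented drug."""

    drug_id: str
    channel_params: dict          # channel -> (ic50 nM, h)
    cmax: float
    risk_label: str
    n_samples: int = 2000

    def __post_init__(self):
        for ch, (ic50, h) in self.channel_params.items():
            if ch not in BLOCKABLE_CHANNELS:
                raise KeyError(f"unknown channel {ch!r}")
            if ic50 <= 0 or h <= 0:
                raise ValueError("ic50 and h must be positive")
        if self.cmax <= 0:
            raise ValueError("cmax must be positive")
        if self.risk_label not in RISK_LEVELS:
            raise ValueError(f"unknown risk label {self.risk_label!r}")


def gen_dose_response(spec: SyntheticDrugSpec, n_doses: int = 8,
                      noise_sd: float = 0.02, seed: int = 0) -> pd.DataFrame:
    """Noisy Hill measurements at log-spaced doses spanning [IC50/30, 30*IC50].

    Gaussian noise truncated by clipping to [0, 1]; deterministic per seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for ch in BLOCKABLE_CHANNELS:
        if ch not in spec.channel_params:
            continue
        ic50, h = spec.channel_params[ch]
        doses = np.geomspace(ic50 / 30.0, ic50 * 30.0, n_doses)
        clean = inhibition_factor(ic50, h, doses)
        noisy = np.clip(clean + rng.normal(0.0, noise_sd, n_doses), 0.0, 1.0)
        for i, (d, b) in enumerate(zip(doses, noisy)):
            rows.append({"drug": spec.drug_id, "channel": ch, "conc": d,
                         "block": b, "replicate": f"r{i}"})
    return pd.DataFrame(rows, columns=["drug", "channel", "conc", "block", "replicate"])


# ---------------------------------------------------------------------------
# Closed-form beat fixtures
# ---------------------------------------------------------------------------

@dataclass
class CurrentSpec:
    """A current waveform with an exact integral over [0, bcl].

    kind 'constant' (value), 'sine' (amplitude, period; integral of full
    periods is 0), or 'pulse' (value on [t0, t1]).
    """

    kind: str
    params: dict

    def sample(self, t):
        p = self.params
        if self.kind == "constant":
            return np.full_like(t, float(p["value"]))
        if self.kind == "sine":
            return p["amplitude"] * np.sin(2 * np.pi * t / p["period"])
        if self.kind == "pulse":
            return np.where((t >= p["t0"]) & (t < p["t1"]), float(p["value"]), 0.0)
        raise ValueError(f"unknown current kind {self.kind!r}")

    def integral(self, bcl):
        p = self.params
        if self.kind == "constant":
            return p["value"] * bcl
        if self.kind == "sine":
            w = 2 * np.pi / p["period"]
            return p["amplitude"] / w * (1 - np.cos(w * bcl))
        if self.kind == "pulse":
            return p["value"] * (min(p["t1"], bcl) - min(p["t0"], bcl))
        raise ValueError(self.kind)


@dataclass
class TraceFixture:
    beat: BeatTrace
    truth: BiomarkerVector
    current_integrals: dict


def _two_segment_decay(t, t_peak, peak, rest, d50, d90):
    """Falling limb through the 50% point at t_peak+d50 and the 90% point at
    t_peak+d90 (linear segments), then flat at rest."""
    amp = peak - rest
    v50 = peak - 0.5 * amp
    v90 = peak - 0.9 * amp
    t50 = t_peak + d50
    t90 = t_peak + d90
    t_end = t90 + (d90 - d50) / 0.4 * 0.1   # reach rest continuing the 2nd slope
    out = np.full_like(t, rest, dtype=float)
    seg1 = (t >= t_peak) & (t < t50)
    out[seg1] = peak + (v50 - peak) * (t[seg1] - t_peak) / (t50 - t_peak)
    seg2 = (t >= t50) & (t < t_end)
    out[seg2] = v50 + (v90 - v50) * (t[seg2] - t50) / (t90 - t50)
    out = np.maximum(out, rest)
    before = t < t_peak
    out[before] = rest
    return out


def gen_trace_fixture(apd90: float = 270.0, apd50: float = 150.0,
                      cad90: float = 450.0, cad50: float = 250.0,
                      dvdt_max: float = 120.0, vm_rest: float = -85.0,
                      vm_peak: float = 35.0, ca_rest: float = 1e-4,
                      ca_peak: float = 1.1e-3, t_up: float = 10.0,
                      ca_up: float = 20.0, bcl: float = 2000.0,
                      dt: float = 0.1,
                      current_spec: dict | None = None) -> TraceFixture:
    """Piecewise-linear beat whose biomarkers equal the requested values.

    The AP rises from ``vm_rest`` at ``t_up`` with slope ``dvdt_max`` and
    decays through the 50%/90% repolarisation points at ``t_up + apd50`` and
    ``t_up + apd90`` exactly; analogously for the Ca transient.  Currents
    default to zero; pass :class:`CurrentSpec` objects per channel for
    closed-form charge-metric oracles.
    """
    if not 0 < apd50 < apd90 < bcl:
        raise ValueError("need 0 < apd50 < apd90 < bcl")
    if not 0 < cad50 < cad90 < bcl:
        raise ValueError("need 0 < cad50 < cad90 < bcl")
    t = np.arange(0.0, bcl + dt / 2, dt)
    rise = (vm_peak - vm_rest) / dvdt_max
    if not rise < apd50:
        raise ValueError("upstroke must complete before the 50% crossing")
    # durations are measured from the max-slope instant (within the rise), so
    # the decay crossings are placed at t_up + apd50 / t_up + apd90 exactly
    vm = _two_segment_decay(t, t_up + rise, vm_peak, vm_rest,
                            apd50 - rise, apd90 - rise)
    up = (t >= t_up) & (t < t_up + rise)
    vm[up] = vm_rest + dvdt_max * (t[up] - t_up)
    ca_rise = 1.0  # ms, effectively instant
    cai = _two_segment_decay(t, ca_up + ca_rise, ca_peak, ca_rest,
                             cad50 - ca_rise, cad90 - ca_rise)
    cup = (t >= ca_up) & (t < ca_up + ca_rise)
    cai[cup] = ca_rest + (ca_peak - ca_rest) * (t[cup] - ca_up) / ca_rise

    spec = dict(current_spec or {})
    currents = {}
    integrals = {}
    from .drug_block import ALL_CHANNELS

    for ch in ALL_CHANNELS:
        cs = spec.get(ch, CurrentSpec("constant", {"value": 0.0}))
        currents[ch] = cs.sample(t)
        integrals[ch] = float(cs.integral(bcl))
    beat = BeatTrace(time=t, vm=vm, cai=cai, currents=currents)
    from .biomarkers import QNET_CHANNELS

    truth = BiomarkerVector(
        dvdt_max=dvdt_max, vm_resting=vm_rest, apd90=apd90, apd50=apd50,
        ca_resting=ca_rest, cad90=cad90, cad50=cad50,
        qnet=float(sum(integrals[ch] for ch in QNET_CHANNELS)),
        qinward=np.nan,  # defined only against a control fixture
    )
    return TraceFixture(beat=beat, truth=truth, current_integrals=integrals)


# ---------------------------------------------------------------------------
# Class-structured feature tables
# ---------------------------------------------------------------------------

# per-feature class direction (units of the feature's population sd);
# high-risk drugs: prolonged repolarisation, reduced qNet, altered inward
# charge; low-risk drugs: the opposite.  'intermediate' sits at 0.
_CLASS_DIRECTION = {
    "dvdt_max":   0.1,
    "vm_resting": 0.1,
    "apd90":      1.0,
    "apd50":      1.0,
    "ca_resting": 0.2,
    "cad90":      0.8,
    "cad50":      0.8,
    "qnet":      -1.0,
    "qinward":   -1.2,
}
_BASELINE = {
    "dvdt_max": 50.0, "vm_resting": -88.0, "apd90": 250.0, "apd50": 200.0,
    "ca_resting": 1e-4, "cad90": 420.0, "cad50": 250.0, "qnet": 60.0,
    "qinward": 1.0,
}
_FEATURE_SD = {
    "dvdt_max": 5.0, "vm_resting": 1.0, "apd90": 30.0, "apd50": 25.0,
    "ca_resting": 1e-5, "cad90": 40.0, "cad50": 30.0, "qnet": 20.0,
    "qinward": 0.15,
}
_CLASS_SIGN = {"high": 1.0, "intermediate": 0.0, "low": -1.0}


def gen_feature_table(n_drugs_per_class: int = 3, n_samples: int = 2000,
                      effect_size: float = 2.0, drug_sd_frac: float = 0.5,
                      seed: int = 0, n_test_drugs_per_class: int | None = None):
    """Drug-clustered 9-feature tables with class-separated means.

    Drug-level means are drawn around their class mean (separation
    ``effect_size`` population sd between adjacent classes); samples scatter
    around their drug's mean.  ``effect_size = 0`` gives a label-free null.
    Returns ``(train, test)`` with disjoint drugs; test gets
    ``n_test_drugs_per_class`` drugs per class (default: same as train).
    """
    if n_drugs_per_class < 1:
        raise ValueError("need at least one drug per class")
    n_test = n_test_drugs_per_class or n_drugs_per_class
    rng = np.random.default_rng(seed)
    frames = {"train": [], "test": []}
    counter = 0
    for split, n_cls in (("train", n_drugs_per_class), ("test", n_test)):
        for risk in RISK_LEVELS:
            for _ in range(n_cls):
                counter += 1
                drug = f"syn{counter:03d}"
                rec = {"drug": drug, "sample": np.arange(n_samples), "risk": risk}
                for f in FEATURE_NAMES:
                    sd = _FEATURE_SD[f]
                    mu_cls = _BASELINE[f] + _CLASS_SIGN[risk] * effect_size * _CLASS_DIRECTION[f] * sd
                    mu_drug = rng.normal(mu_cls, drug_sd_frac * sd)
                    rec[f] = rng.normal(mu_drug, sd, n_samples)
                frames[split].append(pd.DataFrame(rec))
    cols = ["drug", "sample"] + FEATURE_NAMES + ["risk"]
    train = pd.concat(frames["train"], ignore_index=True)[cols]
    test = pd.concat(frames["test"], ignore_index=True)[cols]
    return train, test


def gen_registry(n_drugs_per_class: int = 3, seed: int = 0,
                 cmax_range=(1.0, 1000.0)) -> pd.DataFrame:
    """Synthetic drug registry (name, cmax, risk, split) covering all classes."""
    rng = np.random.default_rng(seed)
    rows = []
    counter = 0
    for split in ("train", "test"):
        for risk in RISK_LEVELS:
            for _ in range(n_drugs_per_class):
                counter += 1
                rows.append({"name": f"syn{counter:03d}",
                             "cmax": float(np.round(rng.uniform(*cmax_range), 2)),
                             "risk": risk, "split": split})
    return pd.DataFrame(rows)


def gen_drug_specs(registry: pd.DataFrame, seed: int = 0) -> list[SyntheticDrugSpec]:
    """Ground-truth Hill parameters consistent with a registry's risk labels.

    High-risk drugs get potent IKr block (IC50 near Cmax); low-risk drugs
    weak IKr but appreciable ICaL/INaL block; intermediate in between.
    """
    rng = np.random.default_rng(seed)
    potency = {"high": 1.0, "intermediate": 5.0, "low": 40.0}
    specs = []
    for _, row in registry.iterrows():
        scale = potency[row["risk"]]
        params = {
            "IKr": (row["cmax"] * scale * rng.uniform(0.8, 1.2), rng.uniform(0.8, 1.5)),
            "ICaL": (row["cmax"] * 8 * rng.uniform(0.8, 1.2) / np.sqrt(scale), rng.uniform(0.8, 1.5)),
            "INaL": (row["cmax"] * 20 * rng.uniform(0.8, 1.2), rng.uniform(0.8, 1.5)),
            "INa": (row["cmax"] * 30 * rng.uniform(0.8, 1.2), rng.uniform(0.8, 1.5)),
        }
        specs.append(SyntheticDrugSpec(
            drug_id=row["name"], channel_params=params, cmax=float(row["cmax"]),
            risk_label=row["risk"],
        ))
    return specs
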