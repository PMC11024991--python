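"""Paced ventricular-myocyte simulation: cell-model contract, compact surrogate, pacing driver.

The pipeline needs a paced human-ventricular cell whose seven sarcolemmal
currents (INa, INaL, ICaL, IKr, IKs, IK1, Ito) can be scaled by drug block
and whose action potential / calcium transient yield the nine risk
biomarkers.  Detailed community models (ToR-ORd class) plug in through
:class:`CellModel`; the package ships :func:`surrogate_model`, a compact
Hodgkin-Huxley-style cell with a single-pool calcium transient that
reproduces the qualitative electrophysiology the biomarkers rely on:

* resting Vm near -88 mV, APD90 ~250 ms at BCL 2000 ms,
* APD90 prolongs monotonically under IKr block,
* Ca-transient amplitude shrinks monotonically under ICaL block.

Voltages are mV, time ms, currents uA/uF, [Ca]i mM.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .drug_block import ALL_CHANNELS, ConductanceSet

VM, CAI = "vm", "cai"  # required state names


class SimulationError(RuntimeError):
    """Integrator failure or non-finite state; carries the beat index."""

    def __init__(self, msg, beat=None):
        super().__init__(msg)
        self.beat = beat


class ContractViolationError(ValueError):
    """A cell model does not satisfy the required interface."""


class ConfigurationError(ValueError):
    """Parameter overrides produce a non-excitable cell."""


@dataclass(frozen=True)
class PacingProtocol:
    """Periodic-stimulus protocol.

    bcl : basic cycle length, ms (default 2000).
    n_beats : number of paced cycles (default 1000; desk-scale runs use 50-100).
    stimulus_amplitude : uA/uF, negative = depolarising (default -80).
    stimulus_duration : ms (default 0.5).
    output_dt : output sampling step, ms (<= 1).
    """

    bcl: float = 2000.0
    n_beats: int = 1000
    stimulus_amplitude: float = -80.0
    stimulus_duration: float = 0.5
    output_dt: float = 0.25

    def __post_init__(self):
        if self.bcl <= 0 or self.n_beats < 1:
            raise ValueError("bcl must be positive and n_beats >= 1")
        if not self.stimulus_duration < self.bcl:
            raise ValueError("stimulus_duration must be < bcl")
        if not (0 < self.output_dt <= 1.0):
            raise ValueError("output_dt must be in (0, 1] ms")


@dataclass(frozen=True)
class CellModel:
    """Contract for a paced ventricular cell.

    ``derivative(t, y, params)`` and ``currents(t, y, params)`` must be pure
    functions; ``currents`` reports every channel in
    :data:`tdprisk.drug_block.ALL_CHANNELS` in uA/uF.  Conductances are
    addressable per channel through ``params['g'][channel]``.
    """

    name: str
    state_names: tuple
    initial_state: np.ndarray
    params: dict
    derivative: callable = field(repr=False)
    currents: callable = field(repr=False)

    def __post_init__(self):
        for req in (VM, CAI):
            if req not in self.state_names:
                raise ContractViolationError(f"state {req!r} missing from model states")
        missing = set(ALL_CHANNELS) - set(self.params.get("g", {}))
        if missing:
            raise ContractViolationError(
                f"model lacks conductance parameters for channels: {sorted(missing)}"
            )

    def with_conductances(self, conductances: ConductanceSet) -> "CellModel":
        g = dict(self.params["g"])
        for ch, v in conductances.g.items():
            if ch not in g:
                raise ContractViolationError(f"unknown channel {ch!r}")
            g[ch] = v
        return replace(self, params={**self.params, "g": g})

    def control_conductances(self) -> ConductanceSet:
        return ConductanceSet(dict(self.params["g"]))


@dataclass(frozen=True)
class BeatTrace:
    """One pacing cycle sampled on the output grid (time starts at 0)."""

    time: np.ndarray
    vm: np.ndarray
    cai: np.ndarray
    currents: dict  # channel -> np.ndarray, uA/uF

    def __post_init__(self):
        if self.time[0] != 0 or np.any(np.diff(self.time) <= 0):
            raise ValueError("time must start at 0 and be strictly increasing")
        n = len(self.time)
        arrays = [self.vm, self.cai, *self.currents.values()]
        if any(len(a) != n for a in arrays):
            raise ValueError("all trace arrays must share the time grid length")

    @property
    def bcl(self):
        return float(self.time[-1])


@dataclass
class PacedTrace:
    beats: list  # list[BeatTrace], length n_beats
    metadata: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.beats)


# ---------------------------------------------------------------------------
# Compact surrogate cell
# ---------------------------------------------------------------------------

_SURROGATE_DEFAULTS = dict(
    g=dict(INa=11.0, INaL=0.06, ICaL=0.25, IKr=0.7, IKs=0.02, IK1=0.5, Ito=0.08),
    ENa=60.0, EK=-88.0, ECa=60.0,
    kCa=6e-6, tauCa=200.0, Ca0=1e-4,
)

_SURROGATE_STATES = (VM, "m", "h", "mL", "hL", "d", "f", "xr", "xs", "r", "s", CAI)
_SURROGATE_Y0 = np.array([-86.0, 0.0, 1.0, 0.0, 0.5, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0, 1e-4])


def _surrogate_currents(t, y, p):
    V, m, h, mL, hL, d, f, xr, xs, r, s, Cai = y
    e = math.exp
    g = p["g"]
    rkr = 1 / (1 + e((V + 20) / 15))      # IKr inward-rectification factor
    k1 = 1 / (1 + e(0.1 * (V + 75)))      # instantaneous IK1 gate
    return dict(
        INa=g["INa"] * m**3 * h * (V - p["ENa"]),
        INaL=g["INaL"] * mL * hL * (V - p["ENa"]),
        ICaL=g["ICaL"] * d * f * (V - p["ECa"]),
        IKr=g["IKr"] * xr * rkr * (V - p["EK"]),
        IKs=g["IKs"] * xs * xs * (V - p["EK"]),
        IK1=g["IK1"] * k1 * (V - p["EK"]),
        Ito=g["Ito"] * r * s * (V - p["EK"]),
    )


def _surrogate_derivative(t, y, p):
    # hot path: inlined gates/currents (no dict construction per call)
    V, m, h, mL, hL, d, f, xr, xs, r, s, Cai = y
    e = math.exp
    g = p["g"]
    ENa, EK, ECa = p["ENa"], p["EK"], p["ECa"]
    INa = g["INa"] * m**3 * h * (V - ENa)
    INaL = g["INaL"] * mL * hL * (V - ENa)
    ICaL = g["ICaL"] * d * f * (V - ECa)
    IKr = g["IKr"] * xr * (1 / (1 + e((V + 20) / 15))) * (V - EK)
    IKs = g["IKs"] * xs * xs * (V - EK)
    IK1 = g["IK1"] * (1 / (1 + e(0.1 * (V + 75)))) * (V - EK)
    Ito = g["Ito"] * r * s * (V - EK)
    dy = np.empty(12)
    dy[0] = -(INa + INaL + ICaL + IKr + IKs + IK1 + Ito)
    dy[1] = (1 / (1 + e(-(V + 40) / 6)) - m) / 0.3
    dy[2] = (1 / (1 + e((V + 70) / 6)) - h) / (1 + 9 / (1 + e((V + 55) / 8)))
    dy[3] = (1 / (1 + e(-(V + 42) / 6)) - mL) / 2.0
    dy[4] = (1 / (1 + e((V + 90) / 6.1)) - hL) / 200.0
    dy[5] = (1 / (1 + e(-(V + 10) / 6)) - d) / 2.0
    dy[6] = (1 / (1 + e((V + 25) / 6)) - f) / 80.0
    dy[7] = (1 / (1 + e(-(V + 15) / 8)) - xr) / 400.0
    dy[8] = (1 / (1 + e(-(V - 5) / 12)) - xs) / 600.0
    dy[9] = (1 / (1 + e(-V / 11)) - r) / 4.0
    dy[10] = (1 / (1 + e((V + 45) / 5)) - s) / 30.0
    dy[11] = -p["kCa"] * ICaL - (Cai - p["Ca0"]) / p["tauCa"]
    return dy


def surrogate_model(overrides: dict | None = None) -> CellModel:
    """Build the shipped compact surrogate cell.

    ``overrides`` may replace any default parameter (nested ``g`` dict is
    merged).  Overrides that leave the cell non-excitable (no upstroke
    faster than 10 mV/ms under the default stimulus) raise
    :class:`ConfigurationError`.
    """
    params = {k: (dict(v) if isinstance(v, dict) else v) for k, v in _SURROGATE_DEFAULTS.items()}
    if overrides:
        for k, v in overrides.items():
            if k == "g":
                params["g"].update(v)
            elif k not in params:
                raise KeyError(f"unknown surrogate parameter {k!r}")
            else:
                params[k] = v
    model = CellModel(
        name="surrogate",
        state_names=_SURROGATE_STATES,
        initial_state=_SURROGATE_Y0.copy(),
        params=params,
        derivative=_surrogate_derivative,
        currents=_surrogate_currents,
    )
    if overrides:
        _check_excitable(model)
    return model


def _check_excitable(model):
    protocol = PacingProtocol(n_beats=1, bcl=500.0, output_dt=0.25)
    beat = simulate_paced(model, model.control_conductances(), protocol,
                          _validate=False).beats[0]
    # judge the intrinsic upstroke after the stimulus artefact has ended
    after = beat.time > protocol.stimulus_duration + 1.0
    dvdt = np.gradient(beat.vm, beat.time)[after]
    if np.max(dvdt) <= 10.0:
        raise ConfigurationError("parameter overrides produce a non-excitable cell")


# ---------------------------------------------------------------------------
# Pacing driver
# ---------------------------------------------------------------------------

def simulate_paced(
    model: CellModel,
    conductances: ConductanceSet | None = None,
    protocol: PacingProtocol = PacingProtocol(),
    metadata: dict | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    _validate: bool = True,
) -> PacedTrace:
    """Integrate the cell beat by beat under periodic stimulation.

    The final state of beat k seeds beat k+1.  The stimulus current is
    injected by the driver (protocol-level), so the model derivative stays a
    pure description of the membrane.  Deterministic for fixed inputs.
    """
    if conductances is not None:
        model = model.with_conductances(conductances)
    p = model.params
    amp, dur = protocol.stimulus_amplitude, protocol.stimulus_duration
    vm_idx = model.state_names.index(VM)
    cai_idx = model.state_names.index(CAI)

    def rhs(t, y):
        dy = model.derivative(t, y, p)
        if t < dur:
            dy[vm_idx] -= amp
        return dy

    n_out = int(round(protocol.bcl / protocol.output_dt))
    tgrid = np.linspace(0.0, protocol.bcl, n_out + 1)
    y = model.initial_state.copy()
    beats = []
    for b in range(protocol.n_beats):
        sol = solve_ivp(rhs, (0.0, protocol.bcl), y, method="LSODA",
                        rtol=rtol, atol=atol, t_eval=tgrid)
        if not sol.success:
            raise SimulationError(f"solver failed at beat {b}: {sol.message}", beat=b)
        if not np.all(np.isfinite(sol.y)):
            raise SimulationError(f"non-finite state at beat {b}", beat=b)
        y = sol.y[:, -1].copy()
        cur = _currents_on_grid(model, sol.t, sol.y)
        beats.append(BeatTrace(time=sol.t, vm=sol.y[vm_idx], cai=sol.y[cai_idx], currents=cur))
    return PacedTrace(beats=beats, metadata=dict(metadata or {}))


def _currents_on_grid(model, t, Y):
    if model.name == "surrogate":  # vectorised fast path
        V, m, h, mL, hL, d, f, xr, xs, r, s, _ = Y
        p = model.params
        g = p["g"]
        rkr = 1 / (1 + np.exp((V + 20) / 15))
        k1 = 1 / (1 + np.exp(0.1 * (V + 75)))
        return dict(
            INa=g["INa"] * m**3 * h * (V - p["ENa"]),
            INaL=g["INaL"] * mL * hL * (V - p["ENa"]),
            ICaL=g["ICaL"] * d * f * (V - p["ECa"]),
            IKr=g["IKr"] * xr * rkr * (V - p["EK"]),
            IKs=g["IKs"] * xs * xs * (V - p["EK"]),
            IK1=g["IK1"] * k1 * (V - p["EK"]),
            Ito=g["Ito"] * r * s * (V - p["EK"]),
        )
    out = {ch: np.empty(len(t)) for ch in ALL_CHANNELS}
    for j in range(len(t)):
        cur = model.currents(t[j], Y[:, j], model.params)
        for ch in ALL_CHANNELS:
            out[ch][j] = cur[ch]
    return out


def max_repol_dvdt(beat: BeatTrace, window_after_peak: float = 50.0) -> float:
    """Maximal dVm/dt in the repolarisation window (50 ms after the Vm peak
    to end of beat).  Positive values flag early-afterdepolarisation-like
    upward deflections."""
    dv = np.gradient(beat.vm, beat.time)
    t0 = beat.time[int(np.argmax(beat.vm))] + window_after_peak
    mask = beat.time >= t0
    if not mask.any():
        return -np.inf
    return float(np.max(dv[mask]))


def select_representative_beat(trace: PacedTrace, last_n: int = 250) -> BeatTrace:
    """Among the final ``last_n`` beats, return the one with the largest
    repolarisation-phase dVm/dt; ties go to the latest beat."""
    if last_n > len(trace):
        raise ValueError(f"last_n={last_n} exceeds the {len(trace)}-beat trace")
    tail = trace.beats[-last_n:]
    scores = [max_repol_dvdt(b) for b in tail]
    best = max(range(len(tail)), key=lambda i: (scores[i], i))
    return tail[best]


# ---------------------------------------------------------------------------
# Model exchange (export / load)
# ---------------------------------------------------------------------------

_SCHEMA_VERSION = 1
_EXPR_NAMES = {"exp": math.exp, "log": math.log, "sqrt": math.sqrt, "tanh": math.tanh,
               "pow": pow, "pi": math.pi}


def export_model(model: CellModel, path) -> None:
    """Write a model to the JSON exchange schema.

    The surrogate is exported by reference (kind ``surrogate`` + parameters);
    expression-based models round-trip their rate expressions.
    """
    if model.name == "surrogate":
        doc = {"schema_version": _SCHEMA_VERSION, "kind": "surrogate",
               "params": _jsonable(model.params)}
    else:
        doc = model.params.get("_exchange_doc")
        if doc is None:
            raise ContractViolationError("only surrogate or expression models can be exported")
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def _jsonable(p):
    return {k: (dict(v) if isinstance(v, dict) else v) for k, v in p.items()}


def load_external_model(path) -> CellModel:
    """Load a cell model from the JSON exchange schema.

    Supports ``kind: surrogate`` (parameter overrides of the shipped cell)
    and ``kind: expressions`` (state names, parameters, and per-state rate /
    per-channel current expressions over the state and parameter names).
    Missing channel reporters raise :class:`ContractViolationError`; malformed
    files raise a parse error carrying the line number.
    """
    with open(path) as fh:
        text = fh.read()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as err:
        raise ValueError(f"malformed model file {path}: line {err.lineno}: {err.msg}") from err
    kind = doc.get("kind")
    if kind == "surrogate":
        params = doc.get("params", {})
        base = {k: v for k, v in params.items() if k != "g"}
        model = surrogate_model()
        merged = {**model.params, **base}
        merged["g"] = {**model.params["g"], **params.get("g", {})}
        return replace(model, params=merged)
    if kind != "expressions":
        raise ValueError(f"unknown model kind {kind!r} in {path}")
    states = tuple(doc["states"])
    params = dict(doc.get("params", {}))
    g = dict(doc.get("g", {}))
    missing = set(ALL_CHANNELS) - set(doc.get("currents", {}))
    if missing:
        raise ContractViolationError(
            f"model file missing current reporters for channels: {sorted(missing)}"
        )
    d_expr = {s: compile(doc["derivatives"][s], f"<{s}>", "eval") for s in states}
    c_expr = {ch: compile(doc["currents"][ch], f"<{ch}>", "eval") for ch in ALL_CHANNELS}

    def _env(t, y, p):
        env = dict(_EXPR_NAMES)
        env.update(p)
        env.update(p.get("g", {}))
        env.update(zip(states, y))
        env["t"] = t
        return env

    def derivative(t, y, p):
        env = _env(t, y, p)
        return np.array([eval(d_expr[s], {"__builtins__": {}}, env) for s in states])

    def currents(t, y, p):
        env = _env(t, y, p)
        return {ch: eval(c_expr[ch], {"__builtins__": {}}, env) for ch in ALL_CHANNELS}

    params["g"] = g
    return CellModel(
        name=doc.get("name", "external"),
        state_names=states,
        initial_state=np.asarray(doc["initial_state"], dtype=float),
        params=params,
        derivative=derivative,
        currents=currents,
    )


def export_trace_csv(trace: PacedTrace, path) -> None:
    """Tidy per-sample CSV: beat,time_ms,vm_mv,cai_mm,INa,...,Ito."""
    import pandas as pd

    frames = []
    for b, beat in enumerate(trace.beats):
        rec = {"beat": b, "time_ms": beat.time, "vm_mv": beat.vm, "cai_mm": beat.cai}
        rec.update({ch: beat.currents[ch] for ch in ALL_CHANNELS})
        frames.append(pd.DataFrame(rec))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
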