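"""Pacing driver, surrogate electrophysiology, beat selection, model exchange."""

import numpy as np
import pytest

from tdprisk import myocyte as myo
from tdprisk.biomarkers import apd
from tdprisk.drug_block import ConductanceSet


def short_protocol(n_beats=5, dt=0.5):
    return myo.PacingProtocol(n_beats=n_beats, output_dt=dt)


class TestPacingDriver:
    def test_steady_state_convergence(self, surrogate_runs):
        trace, _ = surrogate_runs["control"]
        a = apd(trace.beats[-2], 0.9)
        b = apd(trace.beats[-1], 0.9)
        assert abs(a - b) < 1.0

    def test_no_stimulus_stays_at_rest(self):
        model = myo.surrogate_model()
        prot = myo.PacingProtocol(n_beats=3, stimulus_amplitude=0.0, output_dt=0.5)
        trace = myo.simulate_paced(model, None, prot)
        vm = np.concatenate([b.vm for b in trace.beats])
        assert np.ptp(vm) < 2.0

    def test_determinism_bitwise(self):
        model = myo.surrogate_model()
        t1 = myo.simulate_paced(model, None, short_protocol())
        t2 = myo.simulate_paced(model, None, short_protocol())
        for b1, b2 in zip(t1.beats, t2.beats):
            np.testing.assert_array_equal(b1.vm, b2.vm)
            np.testing.assert_array_equal(b1.cai, b2.cai)

    def test_state_carryover_split_run(self):
        # 4 beats straight equals 2+2 with explicit state handoff
        import dataclasses

        model = myo.surrogate_model()
        whole = myo.simulate_paced(model, None, short_protocol(4))
        model2 = dataclasses.replace(model, initial_state=_final_state(model, 2))
        second = myo.simulate_paced(model2, None, short_protocol(2))
        np.testing.assert_allclose(second.beats[-1].vm, whole.beats[-1].vm, atol=1e-6)

    def test_unit_conductance_scaling_is_identity(self):
        model = myo.surrogate_model()
        g0 = model.control_conductances()
        t1 = myo.simulate_paced(model, None, short_protocol(3))
        t2 = myo.simulate_paced(model, ConductanceSet({k: v * 1.0 for k, v in g0.g.items()}),
                                short_protocol(3))
        for b1, b2 in zip(t1.beats, t2.beats):
            np.testing.assert_array_equal(b1.vm, b2.vm)


def _final_state(model, n_beats):
    """Integrate n beats and return the raw final state vector."""
    from scipy.integrate import solve_ivp

    prot = short_protocol(n_beats)
    y = model.initial_state.copy()

    def rhs(t, y_):
        dy = model.derivative(t, y_, model.params)
        if t < prot.stimulus_duration:
            dy[0] -= prot.stimulus_amplitude
        return dy

    for _ in range(n_beats):
        sol = solve_ivp(rhs, (0, prot.bcl), y, method="LSODA", rtol=1e-6, atol=1e-8)
        y = sol.y[:, -1].copy()
    return y


class TestSurrogateElectrophysiology:
    def test_control_apd90_in_physiological_band(self, surrogate_runs):
        _, beat = surrogate_runs["control"]
        assert 150.0 <= apd(beat, 0.9) <= 350.0

    def test_resting_potential(self, surrogate_runs):
        _, beat = surrogate_runs["control"]
        assert -90.0 <= beat.vm[0] <= -80.0

    def test_apd_prolongs_under_ikr_block(self, surrogate_runs):
        apds = [apd(surrogate_runs[k][1], 0.9) for k in ("control", "ikr25", "ikr50")]
        assert apds[0] < apds[1] < apds[2]

    def test_ca_amplitude_shrinks_under_ical_block(self, surrogate_runs):
        amps = []
        for k in ("control", "ical25", "ical50"):
            beat = surrogate_runs[k][1]
            amps.append(beat.cai.max() - beat.cai[0])
        assert amps[0] > amps[1] > amps[2] > 0

    def test_full_ical_block_abolishes_transient(self):
        model = myo.surrogate_model()
        g = dict(model.control_conductances().g)
        ctrl = myo.simulate_paced(model, None, short_protocol(10))
        g["ICaL"] = 0.0
        blocked = myo.simulate_paced(model, ConductanceSet(g), short_protocol(10))
        amp_c = ctrl.beats[-1].cai.max() - ctrl.beats[-1].cai[0]
        amp_b = blocked.beats[-1].cai.max() - blocked.beats[-1].cai[0]
        assert amp_b < 0.2 * amp_c

    def test_refinement_stability(self):
        # halving the default output step leaves APD90 grid-converged
        model = myo.surrogate_model()
        beats = {}
        for dt in (0.25, 0.125):
            prot = myo.PacingProtocol(n_beats=5, output_dt=dt)
            trace = myo.simulate_paced(model, None, prot)
            beats[dt] = apd(trace.beats[-1], 0.9)
        assert abs(beats[0.25] - beats[0.125]) < 0.5

    def test_non_excitable_override_rejected(self):
        with pytest.raises(myo.ConfigurationError):
            myo.surrogate_model({"g": {"INa": 0.0, "ICaL": 0.0}})


class TestBeatSelection:
    def _identical_trace(self, n=6):
        from tdprisk.synthetic import gen_trace_fixture

        beat = gen_trace_fixture(dt=0.5).beat
        return myo.PacedTrace(beats=[beat] * n)

    def test_tiebreak_returns_final_beat(self):
        trace = self._identical_trace()
        sel = myo.select_representative_beat(trace, last_n=6)
        assert sel is trace.beats[-1]

    def test_ead_bump_beat_selected(self):
        trace = self._identical_trace()
        base = trace.beats[0]
        vm = base.vm.copy()
        t = base.time
        # inject a 2 mV/ms upward deflection deep in the repolarisation phase
        window = (t > 200.0) & (t < 215.0)
        vm[window] += 2.0 * (t[window] - 200.0)
        bumped = myo.BeatTrace(time=t, vm=vm, cai=base.cai, currents=base.currents)
        beats = list(trace.beats)
        beats[2] = bumped
        sel = myo.select_representative_beat(myo.PacedTrace(beats=beats), last_n=6)
        assert sel is bumped

    def test_last_n_one_returns_final(self):
        trace = self._identical_trace()
        assert myo.select_representative_beat(trace, last_n=1) is trace.beats[-1]

    def test_last_n_too_large_rejected(self):
        trace = self._identical_trace(3)
        with pytest.raises(ValueError):
            myo.select_representative_beat(trace, last_n=10)


class TestModelExchange:
    def test_surrogate_roundtrip_derivatives(self, tmp_path):
        model = myo.surrogate_model()
        path = tmp_path / "cell.json"
        myo.export_model(model, path)
        loaded = myo.load_external_model(path)
        rng = np.random.default_rng(0)
        for _ in range(100):
            y = model.initial_state + rng.normal(0, 0.1, 12)
            np.testing.assert_allclose(
                model.derivative(0.0, y, model.params),
                loaded.derivative(0.0, y, loaded.params), atol=1e-9)

    def test_missing_channel_reporter_rejected(self, tmp_path):
        doc = {"kind": "expressions", "states": ["vm", "cai"],
               "g": {ch: 1.0 for ch in
                     ("INa", "INaL", "ICaL", "IKr", "IKs", "IK1", "Ito")},
               "initial_state": [-85.0, 1e-4],
               "derivatives": {"vm": "-0.1*(vm+85)", "cai": "0.0"},
               "currents": {ch: "0.0" for ch in ("INa", "INaL", "ICaL", "IKr",
                                                  "IKs", "Ito")}}  # IK1 missing
        path = tmp_path / "bad.json"
        import json

        path.write_text(json.dumps(doc))
        with pytest.raises(myo.ContractViolationError, match="IK1"):
            myo.load_external_model(path)

    def test_malformed_file_reports_line(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text('{"kind": "expressions",\n  "states": [,]\n}')
        with pytest.raises(ValueError, match="line 2"):
            myo.load_external_model(path)

    def test_expression_model_simulates(self, tmp_path):
        import json

        doc = {"kind": "expressions", "states": ["vm", "cai"],
               "g": {ch: 0.0 for ch in
                     ("INa", "INaL", "ICaL", "IKr", "IKs", "IK1", "Ito")},
               "initial_state": [-85.0, 1e-4],
               "derivatives": {"vm": "-0.05*(vm+85)", "cai": "0.0"},
               "currents": {ch: "0.0" for ch in ("INa", "INaL", "ICaL", "IKr",
                                                  "IKs", "IK1", "Ito")}}
        path = tmp_path / "leak.json"
        path.write_text(json.dumps(doc))
        model = myo.load_external_model(path)
        prot = myo.PacingProtocol(n_beats=1, stimulus_amplitude=-10.0, output_dt=1.0)
        trace = myo.simulate_paced(model, None, prot)
        assert np.isfinite(trace.beats[0].vm).all()
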