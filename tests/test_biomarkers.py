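"""Biomarker extraction against closed-form fixtures and integration oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import simpson

from tdprisk import biomarkers as bm
from tdprisk.myocyte import BeatTrace
from tdprisk.registry import builtin_registry
from tdprisk.synthetic import CurrentSpec, gen_trace_fixture

DT = 0.1


@pytest.fixture(scope="module")
def triangle():
    """The canonical fixture: rest -85 mV, peak +35 at t=10, APD90 270 / APD50
    150; Ca rest 1e-4 mM, peak 1.1e-3 at t=20, CaD90 450 / CaD50 250."""
    return gen_trace_fixture(dt=DT)


class TestDurations:
    @pytest.mark.parametrize("metric,frac,expected", [
        (bm.apd, 0.9, 270.0), (bm.apd, 0.5, 150.0),
        (bm.cad, 0.9, 450.0), (bm.cad, 0.5, 250.0),
    ])
    def test_closed_form_geometry(self, triangle, metric, frac, expected):
        assert metric(triangle.beat, frac) == pytest.approx(expected, abs=DT + 1e-9)

    def test_apd_monotone_in_fraction(self, triangle):
        assert bm.apd(triangle.beat, 0.5) <= bm.apd(triangle.beat, 0.9)

    def test_grid_shift_robustness(self):
        a = gen_trace_fixture(t_up=10.0, ca_up=20.0, dt=DT)
        b = gen_trace_fixture(t_up=10.0 + DT / 2, ca_up=20.0 + DT / 2, dt=DT)
        for metric, frac in [(bm.apd, 0.9), (bm.apd, 0.5), (bm.cad, 0.9)]:
            assert abs(metric(a.beat, frac) - metric(b.beat, frac)) < DT

    def test_flat_trace_flagged(self):
        t = np.arange(0.0, 100.0, 1.0)
        beat = BeatTrace(time=t, vm=np.full_like(t, -85.0),
                         cai=np.full_like(t, 1e-4),
                         currents={ch: np.zeros_like(t) for ch in
                                   ("INa", "INaL", "ICaL", "IKr", "IKs", "IK1", "Ito")})
        assert bm.is_flagged(bm.apd(beat, 0.9))

    def test_no_repolarization_flagged(self):
        # AP that never recrosses the 90% threshold before the beat ends
        fx = gen_trace_fixture(apd90=1900.0, apd50=1000.0, bcl=2000.0, dt=1.0)
        vm = fx.beat.vm.copy()
        late = fx.beat.time > 50.0
        vm[late & (vm < 0.0)] = 0.0  # clamp repolarisation midway, keep rest
        beat = BeatTrace(time=fx.beat.time, vm=vm, cai=fx.beat.cai,
                         currents=fx.beat.currents)
        assert bm.is_flagged(bm.apd(beat, 0.9))

    def test_resting_values(self, triangle):
        assert bm.vm_resting(triangle.beat) == pytest.approx(-85.0)
        assert bm.ca_resting(triangle.beat) == pytest.approx(1e-4)

    def test_dvdt_max_of_ramp(self):
        t = np.arange(0.0, 100.0, 1.0)
        beat = BeatTrace(time=t, vm=t.copy(), cai=np.full_like(t, 1e-4),
                         currents={})
        assert bm.dvdt_max(beat) == pytest.approx(1.0)


class TestChargeMetrics:
    def _beat_with(self, spec):
        return gen_trace_fixture(current_spec=spec, dt=DT).beat

    def test_qnet_zero_currents(self):
        assert bm.qnet(self._beat_with({})) == 0.0

    def test_qnet_constant_current(self):
        beat = self._beat_with({"IKr": CurrentSpec("constant", {"value": 1.0})})
        assert bm.qnet(beat) == pytest.approx(2000.0, rel=1e-12)

    def test_qnet_full_sine_period_vanishes(self):
        beat = self._beat_with(
            {"IKs": CurrentSpec("sine", {"amplitude": 1.0, "period": 2000.0})})
        assert abs(bm.qnet(beat)) < 1e-6

    def test_qnet_missing_channel_rejected(self):
        fx = gen_trace_fixture(dt=1.0)
        currents = {k: v for k, v in fx.beat.currents.items() if k != "IK1"}
        beat = BeatTrace(time=fx.beat.time, vm=fx.beat.vm, cai=fx.beat.cai,
                         currents=currents)
        with pytest.raises(KeyError):
            bm.qnet(beat)

    def test_qinward_identity(self):
        beat = self._beat_with({
            "INaL": CurrentSpec("constant", {"value": -0.5}),
            "ICaL": CurrentSpec("pulse", {"value": -2.0, "t0": 10.0, "t1": 300.0}),
        })
        assert bm.qinward(beat, beat) == 1.0

    @pytest.mark.parametrize("s_nal,s_cal,expected", [
        (0.5, 0.5, 0.5),
        (0.2, 0.8, 0.5),
        (1.0, 0.0, 0.5),
    ])
    def test_qinward_scaling(self, s_nal, s_cal, expected):
        ctrl = self._beat_with({
            "INaL": CurrentSpec("constant", {"value": -0.4}),
            "ICaL": CurrentSpec("constant", {"value": -1.5}),
        })
        drug = self._beat_with({
            "INaL": CurrentSpec("constant", {"value": -0.4 * s_nal}),
            "ICaL": CurrentSpec("constant", {"value": -1.5 * s_cal}),
        })
        assert bm.qinward(drug, ctrl) == pytest.approx(expected, rel=1e-12)

    def test_qinward_degenerate_control(self):
        ctrl = self._beat_with({})
        with pytest.raises(bm.DegenerateControlError):
            bm.qinward(ctrl, ctrl)

    def test_integration_matches_fine_simpson_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            period = rng.uniform(200.0, 4000.0)
            amp = rng.uniform(0.1, 3.0)
            off = rng.uniform(-1.0, 1.0)
            beat = self._beat_with({
                "IKr": CurrentSpec("sine", {"amplitude": amp, "period": period}),
                "IK1": CurrentSpec("constant", {"value": off}),
            })
            t_fine = np.linspace(0.0, 2000.0, 200001)
            y = amp * np.sin(2 * np.pi * t_fine / period) + off
            oracle = simpson(y, x=t_fine)
            assert bm.qnet(beat) == pytest.approx(oracle, rel=1e-4, abs=1e-6)


class TestAveraging:
    def _vec(self, apd90=230.0, **kw):
        base = dict(dvdt_max=100.0, vm_resting=-85.0, apd90=apd90, apd50=150.0,
                    ca_resting=1e-4, cad90=450.0, cad50=250.0, qnet=60.0,
                    qinward=0.9)
        base.update(kw)
        return bm.BiomarkerVector(**base)

    def test_idempotent_mean(self):
        v = self._vec()
        avg = bm.average_over_concentrations([v] * 4)
        assert avg == v

    def test_arithmetic_mean(self):
        vecs = [self._vec(apd90=a) for a in (200.0, 220.0, 240.0, 260.0)]
        assert bm.average_over_concentrations(vecs).apd90 == pytest.approx(230.0)

    def test_flag_propagates(self):
        vecs = [self._vec() for _ in range(3)] + [self._vec(apd90=bm.NO_REPOL)]
        avg = bm.average_over_concentrations(vecs)
        assert bm.is_flagged(avg.apd90)
        assert avg.flagged


class TestDatasetAssembly:
    def _rows(self, registry, n_samples):
        recs = []
        rng = np.random.default_rng(0)
        for name in registry["name"]:
            for s in range(n_samples):
                recs.append({"drug": name, "sample": s,
                             **{f: float(rng.normal()) for f in bm.FEATURE_NAMES}})
        return pd.DataFrame(recs)

    def test_split_counts_and_conservation(self):
        reg = builtin_registry()
        rows = self._rows(reg, 5)
        train, test = bm.assemble_dataset(rows, reg)
        assert len(train) == 12 * 5 and len(test) == 16 * 5
        assert len(train) + len(test) == len(rows)
        keys = pd.concat([train, test])[["drug", "sample"]]
        assert not keys.duplicated().any()

    def test_labels_preserved(self):
        reg = builtin_registry().iloc[:6]
        rows = self._rows(reg, 10)
        train, _ = bm.assemble_dataset(rows, reg)
        assert set(train["risk"]) <= {"high", "intermediate", "low"}
        assert len(train) == 6 * 10

    def test_unknown_drug_rejected(self):
        reg = builtin_registry()
        rows = self._rows(reg, 1)
        rows.loc[0, "drug"] = "unobtainium"
        with pytest.raises(KeyError):
            bm.assemble_dataset(rows, reg)
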