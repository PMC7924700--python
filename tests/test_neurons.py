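"""Neuron models: gate kinetics, single-step oracles, firing behaviour,
the RK4 reference, and the constrained-object forms."""

import math

import numpy as np
import pytest

from tcob.engine import TimeGrid
from tcob.engine.errors import CobParameterError
from tcob.neurons import (ADEX_PRESETS, AdExParams, AdExState, HHParams,
                          HHState, IZH_PRESETS, IzhParams, IzhState,
                          SpikeTrain, adex_step, build_adex_store,
                          build_hh_store, build_izh_store, detect_spikes,
                          firing_onset, hh_rates, hh_steady_gates, hh_step,
                          integrate_reference, izh_step, simulate_adex,
                          simulate_hh, simulate_izh)


class TestHHRates:
    def test_values_at_rest_shift_zero(self):
        r = hh_rates(0.0)
        assert r.alpha_h == pytest.approx(0.07)
        assert r.beta_m == pytest.approx(4.0)
        assert r.beta_n == pytest.approx(0.125)

    @pytest.mark.parametrize("v, expected, which", [
        (25.0, 1.0, "alpha_m"),   # limit of x/(e^x - 1) as x -> 0, scaled
        (10.0, 0.1, "alpha_n"),
    ])
    def test_removable_singularities_return_limits(self, v, expected, which):
        assert getattr(hh_rates(v), which) == pytest.approx(expected)
        # numeric cross-check just off the singular point
        for eps in (-1e-6, 1e-6):
            assert getattr(hh_rates(v + eps), which) == pytest.approx(
                expected, rel=1e-5)

    def test_rates_are_total_and_positive_over_physiological_range(self):
        for v in np.linspace(-50.0, 150.0, 201):
            assert all(x > 0 for x in hh_rates(float(v)))


class TestHHStep:
    def test_rest_with_steady_gates_is_stable(self, hh_params):
        res = simulate_hh(hh_params, 0.0, dt=0.01, t_stop=100.0)
        assert np.abs(res["V"] - hh_params.Vrest).max() < 0.5

    def test_zero_conductance_zero_current_keeps_v(self):
        p = HHParams(gNaMax=0.0, gKMax=0.0, gL=0.0)
        s = hh_step(HHState(-70.0, 0.0, 0.0, 0.0, IExt=0.0), p, 0.01)
        assert s.V == -70.0

    def test_single_step_equals_hand_formula(self, hh_params):
        p = hh_params
        V, m, h, n, I, dt = -55.0, 0.1, 0.5, 0.4, 3.0, 0.01
        s = hh_step(HHState(V, m, h, n, I), p, dt)
        am, bm, an, bn, ah, bh = hh_rates(V - p.Vrest)
        i_ion = (p.gNaMax * m ** 3 * h * (V - p.ENa)
                 + p.gKMax * n ** 4 * (V - p.EK) + p.gL * (V - p.EL))
        assert s.V == pytest.approx(V + dt * (I - i_ion) / p.Cm, abs=1e-12)
        assert s.m == pytest.approx(m + dt * (am * (1 - m) - bm * m), abs=1e-12)
        assert s.h == pytest.approx(h + dt * (ah * (1 - h) - bh * h), abs=1e-12)
        assert s.n == pytest.approx(n + dt * (an * (1 - n) - bn * n), abs=1e-12)

    def test_gates_stay_in_unit_interval_under_strong_drive(self, hh_params):
        res = simulate_hh(hh_params, 50.0, dt=0.01, t_stop=50.0)
        for g in "mhn":
            assert res[g].min() >= 0.0 and res[g].max() <= 1.0

    def test_firing_rate_nondecreasing_in_current(self, hh_params):
        counts = [len(detect_spikes(
            simulate_hh(hh_params, float(i), dt=0.01, t_stop=200.0)["V"],
            dt=0.01)) for i in (7, 10, 15)]
        assert counts == sorted(counts)


class TestIzhStep:
    def test_hand_evaluated_subthreshold_update(self):
        s = izh_step(IzhState(-70.0, -14.0), IzhParams(a=0.02, b=0.2),
                     I=10.0, dt=1.0)
        # dV = 0.04*4900 - 350 + 140 + 14 + 10 = 10 -> V' = -60; du = 0
        assert s.V == pytest.approx(-60.0)
        assert s.u == pytest.approx(-14.0)

    def test_reset_path_applies_c_and_d(self):
        s = izh_step(IzhState(35.0, -10.0), IzhParams(c=-65.0, d=8.0),
                     I=0.0, dt=1.0)
        assert (s.V, s.u) == (-65.0, -2.0)

    def test_subthreshold_quiescence_at_zero_current(self):
        res = simulate_izh(IZH_PRESETS["regular_spiking"], 0.0, dt=0.1,
                           t_stop=1000.0)
        assert len(res["resets"]) == 0

    def test_vpeak_must_exceed_reset(self):
        with pytest.raises(CobParameterError):
            IzhParams(c=-50.0, Vpeak=-60.0)

    def test_regular_spiking_is_periodic(self):
        res = simulate_izh(IZH_PRESETS["regular_spiking"], 10.0, dt=0.1,
                           t_stop=1000.0)
        train = detect_spikes(resets=res["resets"], dt=0.1)
        isis = train.isis()[1:]  # drop the onset transient
        assert len(train) >= 5
        assert isis.std() / isis.mean() < 0.05

    def test_chattering_groups_spikes_bimodally(self):
        res = simulate_izh(IZH_PRESETS["chattering"], 10.0, dt=0.1,
                           t_stop=1000.0)
        isis = detect_spikes(resets=res["resets"], dt=0.1).isis()
        within = isis[isis < 10.0]
        between = isis[isis >= 10.0]
        assert len(within) > 0 and len(between) > 0
        assert between.mean() > 4 * within.mean()


class TestAdExStep:
    def test_rest_is_a_fixed_point_up_to_the_exponential_tail(self):
        p = ADEX_PRESETS["tonic"]
        s = adex_step(AdExState(p.EL, 0.0), p, Iin=0.0, dt=0.1)
        # at V = EL = Vt - 10*DeltaT the spike-initiation term is ~e^-10
        assert abs(s.V - p.EL) < 1e-3 * 0.1

    def test_reset_applies_vr_and_b(self):
        p = AdExParams(b=50.0, Vr=-58.0)
        s = adex_step(AdExState(5.0, 100.0), p, Iin=0.0, dt=0.1)
        assert (s.V, s.w) == (-58.0, 150.0)

    def test_single_euler_step_matches_independent_evaluation(self):
        p = ADEX_PRESETS["adapting"]
        V, w, I, dt = -60.0, 20.0, 150.0, 0.1
        s = adex_step(AdExState(V, w), p, I, dt)
        ex = math.exp((V - p.Vt) / p.DeltaT)
        dv = (-p.gL * (V - p.EL) + p.gL * p.DeltaT * ex - w + I) / p.C
        dw = (p.a * (V - p.EL) - w) / p.tau_w
        assert s.V == pytest.approx(V + dt * dv, abs=1e-12)
        assert s.w == pytest.approx(w + dt * dw, abs=1e-12)

    def test_adaptation_stretches_interspike_intervals(self):
        res = simulate_adex(ADEX_PRESETS["adapting"], 500.0, dt=0.1,
                            t_stop=500.0)
        isis = detect_spikes(resets=res["resets"], dt=0.1).isis()
        assert len(isis) >= 3
        assert all(b >= a - 1e-9 for a, b in zip(isis, isis[1:]))

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(CobParameterError):
            AdExParams(DeltaT=0.0)
        with pytest.raises(CobParameterError):
            AdExParams(tau_w=-1.0)


class TestDetectSpikes:
    def test_flat_trace_yields_empty_train(self):
        assert len(detect_spikes(np.full(1000, -70.0), dt=0.1)) == 0

    def test_two_upward_crossings_give_two_spikes(self):
        v = np.full(100, -70.0)
        v[20:25] = 10.0
        v[60:65] = 10.0
        train = detect_spikes(v, dt=0.5, threshold=-20.0)
        assert list(train.times) == [10.0, 30.0]

    def test_reset_events_map_to_times(self):
        train = detect_spikes(resets=[10, 25, 40], dt=0.1)
        assert list(train.times) == pytest.approx([1.0, 2.5, 4.0])

    def test_requires_exactly_one_input_form(self):
        with pytest.raises(CobParameterError):
            detect_spikes(np.zeros(3), resets=[1], dt=0.1)

    def test_spike_times_must_increase(self):
        with pytest.raises(CobParameterError):
            SpikeTrain([1.0, 1.0])


class TestReferenceIntegrator:
    def test_linear_relaxation_matches_closed_form(self):
        # subthreshold AdEx with w frozen is dV/dt = -(gL/C)(V - EL):
        # an exact exponential to compare RK4 against
        p = AdExParams(C=1.0, gL=1.0, EL=0.0, Vt=1e6, DeltaT=1.0,
                       tau_w=1e9, a=0.0, b=0.0, Vcut=1e7)
        res = integrate_reference("adex", p, 0.0, dt=0.01, t_stop=1.0, v0=1.0)
        assert res["V"][-1] == pytest.approx(math.exp(-1.0), abs=1e-8)

    def test_euler_discrepancy_shrinks_with_dt(self, hh_params):
        sup = []
        for dt in (0.04, 0.02, 0.01):
            e = simulate_hh(hh_params, 6.0, dt=dt, t_stop=50.0)
            r = integrate_reference("hh", hh_params, 6.0, dt=dt, t_stop=50.0)
            sup.append(np.abs(e["V"] - r["V"]).max())
        assert sup[0] > sup[1] > sup[2]

    def test_zero_stimulus_flat_trace_agrees_with_euler(self, hh_params):
        e = simulate_hh(hh_params, 0.0, dt=0.01, t_stop=50.0)
        r = integrate_reference("hh", hh_params, 0.0, dt=0.01, t_stop=50.0)
        assert np.abs(e["V"] - r["V"]).max() < 0.5

    def test_unknown_model_id_rejected(self):
        with pytest.raises(CobParameterError):
            integrate_reference("lif", None, 0.0, dt=0.1, t_stop=1.0)


class TestConstrainedObjectForms:
    def test_engine_hh_reproduces_fast_path(self, hh_params):
        dt, t_stop = 0.01, 20.0
        grid = TimeGrid(t_end=int(round(t_stop / dt)), dt=dt)
        store, inst = build_hh_store(hh_params, 10.0, grid)
        store.run()
        fast = simulate_hh(hh_params, 10.0, dt=dt, t_stop=t_stop)
        # tick k of the engine corresponds to fast-path sample k-1
        engine_v = inst.series_array("V")
        assert np.abs(engine_v - fast["V"][:-1]).max() < 1e-9
        assert store.residual_sweep() <= 1e-9

    def test_engine_izh_counts_spikes_like_fast_path(self):
        p = IZH_PRESETS["regular_spiking"]
        dt, t_stop = 0.1, 300.0
        grid = TimeGrid(t_end=int(round(t_stop / dt)), dt=dt)
        store, inst = build_izh_store(p, 10.0, grid)
        store.run()
        engine_spikes = int(inst.series_array("flag").sum())
        fast = simulate_izh(p, 10.0, dt=dt, t_stop=t_stop)
        assert engine_spikes == len(fast["resets"])
        assert store.residual_sweep() <= 1e-9
        # the display series clamps the upswing at Vpeak
        assert inst.series_array("Varray").max() <= p.Vpeak + 1e-12

    def test_engine_adex_matches_fast_path_voltage(self):
        p = ADEX_PRESETS["tonic"]
        dt, t_stop = 0.1, 200.0
        grid = TimeGrid(t_end=int(round(t_stop / dt)), dt=dt)
        store, inst = build_adex_store(p, 300.0, grid)
        store.run()
        fast = simulate_adex(p, 300.0, dt=dt, t_stop=t_stop)
        engine_flags = int(inst.series_array("flag").sum())
        assert engine_flags == len(fast["resets"])
        assert store.residual_sweep() <= 1e-9


class TestFiringOnset:
    def test_subthreshold_range_reports_no_onset(self, hh_params):
        onset, counts = firing_onset(hh_params, [1, 2], t_stop=100.0)
        assert onset is None
        assert all(c == 0 for c in counts.values())
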