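"""Composite neurons and the granular-layer microcircuit: aggregation,
wiring constraints, routing, causality and feed-forward inhibition."""

import numpy as np
import pytest

from tcob.engine import ConstraintStore, TimeGrid
from tcob.engine.errors import CobParameterError
from tcob.network import (ConnectivityConfig, SynapseSpec, build_microcircuit,
                          build_neuron, run_microcircuit)
from tcob.neurons import ADEX_PRESETS
from tcob.synapses import receptor_preset

BURST = [20.0, 30.0, 40.0, 50.0, 60.0]  # five-spike in-vivo-like input


def _grid(t_stop=100.0, dt=0.1):
    return TimeGrid(t_end=int(round(t_stop / dt)), dt=dt)


class TestCompositeNeuron:
    def test_silent_synapses_give_zero_input_current(self):
        store = ConstraintStore(_grid(50.0))
        specs = [SynapseSpec(receptor_preset("AMPA"), spike_times=[]),
                 SynapseSpec(receptor_preset("GABAA"), spike_times=[])]
        n = build_neuron(store, ADEX_PRESETS["granule"], specs, name="N")
        store.run()
        assert np.abs(n.cell.series_array("Iin")).max() == 0.0
        assert len(n.spike_train()) == 0

    def test_single_active_synapse_drives_the_sum(self):
        store = ConstraintStore(_grid(60.0))
        specs = [SynapseSpec(receptor_preset("AMPA"), spike_times=[20.0],
                             name="Am"),
                 SynapseSpec(receptor_preset("GABAA"), spike_times=[],
                             name="Ga")]
        n = build_neuron(store, ADEX_PRESETS["granule"], specs, name="N")
        store.run()
        iin = n.cell.series_array("Iin")
        i_ampa = store.instances["Am"].series_array("I")
        assert np.abs(iin - i_ampa).max() <= 1e-9

    def test_three_receptor_aggregation_constraint(self):
        # N.Iin = Am.I + Ga.I + Nm.I at every tick
        store = ConstraintStore(_grid(80.0))
        specs = [SynapseSpec(receptor_preset("AMPA"), spike_times=[20.0],
                             name="Am"),
                 SynapseSpec(receptor_preset("NMDA"), spike_times=[20.0],
                             name="Nm"),
                 SynapseSpec(receptor_preset("GABAA"), spike_times=[25.0],
                             name="Ga")]
        n = build_neuron(store, ADEX_PRESETS["granule"], specs, name="N")
        store.run()
        total = sum(store.instances[s].series_array("I")
                    for s in ("Am", "Nm", "Ga"))
        assert np.abs(n.cell.series_array("Iin") - total).max() <= 1e-9
        assert store.residual_sweep() <= 1e-9


class TestConnectivity:
    def test_default_wiring_four_excitatory_four_inhibitory(self):
        mc = build_microcircuit(grid=_grid(10.0))
        assert (mc.n_exc, mc.n_inh) == (4, 4)
        ampa = [s for s in mc.grc.synapses if "ampa" in s.path]
        gaba = [s for s in mc.grc.synapses if "gaba" in s.path]
        assert (len(ampa), len(gaba)) == (4, 4)

    def test_poisson_draws_reproduce_under_a_seed(self):
        cfg = ConnectivityConfig(mode="poisson", mean=4.0, seed=42)
        draws = {build_microcircuit(config=cfg, grid=_grid(5.0)).n_exc
                 for _ in range(3)}
        assert len(draws) == 1

    def test_poisson_mode_requires_seed(self):
        with pytest.raises(CobParameterError):
            ConnectivityConfig(mode="poisson", seed=None)

    def test_zero_afferent_fixed_config_rejected(self):
        cfg = ConnectivityConfig(n_excitatory=0, n_inhibitory=0)
        with pytest.raises(CobParameterError):
            build_microcircuit(config=cfg, grid=_grid(5.0))


@pytest.fixture(scope="module")
def wired():
    mc = build_microcircuit(grid=_grid(150.0))
    return mc, run_microcircuit(mc, BURST)


class TestMicrocircuitRun:
    def test_burst_input_elicits_granule_spiking(self, wired):
        _, res = wired
        assert len(res.spikes["GrC"]) >= 1

    def test_wiring_audit_goc_output_equals_grc_input(self, wired):
        mc, res = wired
        out = mc.goc.cell.series_array("SpikeTrain")
        routed = mc.grc.cell.series_array("GoCInput")
        assert np.array_equal(out, routed)

    def test_parallel_fibre_relays_granule_output(self, wired):
        mc, res = wired
        assert np.array_equal(mc.pf.series_array("Input"),
                              mc.grc.cell.series_array("Output"))
        assert np.array_equal(mc.pc.cell.series_array("GrCInput"),
                              mc.pf.series_array("Input"))

    def test_causality_of_the_response_chain(self, wired):
        _, res = wired
        grc, pc = res.spikes["GrC"], res.spikes["Pc"]
        assert grc.times[0] >= BURST[0]
        if len(pc):
            assert pc.times[0] >= grc.times[0]

    def test_constraint_residuals_after_run(self, wired):
        _, res = wired
        assert res.store.residual_sweep() <= 1e-9

    def test_zero_mossy_input_keeps_circuit_quiescent(self):
        mc = build_microcircuit(grid=_grid(80.0))
        res = run_microcircuit(mc, [])
        assert all(len(res.spikes[c]) == 0 for c in ("GrC", "GoC", "Pc"))

    def test_stimulus_beyond_horizon_rejected(self):
        mc = build_microcircuit(grid=_grid(50.0))
        with pytest.raises(CobParameterError, match="horizon"):
            run_microcircuit(mc, [60.0])


class TestFeedForwardInhibition:
    def test_silencing_golgi_never_decreases_granule_spikes(self):
        grid_kw = dict(t_stop=150.0)
        wired = run_microcircuit(build_microcircuit(grid=_grid(**grid_kw)),
                                 BURST)
        silenced = run_microcircuit(
            build_microcircuit(grid=_grid(**grid_kw), golgi_silenced=True),
            BURST)
        n_wired = len(wired.spikes["GrC"])
        n_silenced = len(silenced.spikes["GrC"])
        assert n_wired <= n_silenced

    def test_silenced_circuit_sees_zero_inhibitory_drive(self):
        mc = build_microcircuit(grid=_grid(60.0), golgi_silenced=True)
        run_microcircuit(mc, [20.0])
        assert np.abs(mc.grc.cell.series_array("GoCInput")).max() == 0.0
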