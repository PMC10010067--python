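"""Cable assembly, extracellular coupling, spike detection, classification."""

import numpy as np
import pytest

from rgcstim import cable, field, morphology
from rgcstim.field import PulseWaveform


def two_compartment_fiber(length=5.0, diameter=1.0):
    m = morphology.Morphology(
        x=np.array([0.0, length]), y=np.zeros(2), z=np.full(2, -15.0),
        length=np.full(2, length), d_prox=np.full(2, diameter),
        d_dist=np.full(2, diameter),
        region=np.array(["soma", "axon"], dtype=object),
        parent=np.array([-1, 0]), arc=np.array([length / 2, 1.5 * length]))
    return cable.assemble(m)


class TestAssemble:
    def test_axial_resistance_closed_form(self):
        sys_ = two_compartment_fiber(5.0, 1.0)
        # rho L / A for the full 5 um x 1 um cylinder (two half-compartments)
        r_ohm = 136.6 * 5e-4 / (np.pi * (0.5e-4) ** 2)
        assert 1e6 / sys_.g_axial[1] == pytest.approx(r_ohm, rel=1e-9)
        assert 1e6 / sys_.g_axial[1] == pytest.approx(8.70e6, rel=0.01)

    def test_soma_capacitance(self):
        m = morphology.build_rgc()
        sys_ = cable.assemble(m)
        soma = m.region_index("soma")
        total_pF = sys_.cap_nF[soma].sum() * 1e3
        assert total_pF == pytest.approx(1e-6 * np.pi * 20 * 20 * 1e-8 * 1e12, rel=1e-9)
        assert total_pF == pytest.approx(12.57, rel=0.001)

    def test_laplacian_symmetric_zero_rowsum(self, default_cell):
        lap = default_cell.axial_laplacian()
        dense = lap.toarray()
        assert np.allclose(dense, dense.T)
        assert np.allclose(dense.sum(axis=1), 0.0, atol=1e-9)
        off = dense - np.diag(np.diag(dense))
        assert np.all(off <= 1e-12)

    def test_passive_copy_strips_voltage_gated_channels(self, default_cell):
        p = default_cell.passive_copy()
        for ch in ("na", "k", "ca", "kca"):
            assert np.all(p.gbar[ch] == 0.0)
        np.testing.assert_array_equal(p.gbar["pas"], default_cell.gbar["pas"])


class TestSimulate:
    def test_uniform_extracellular_potential_produces_no_response(self, default_cell):
        """Pinning every compartment to the same applied potential is
        equivalent to no stimulation (only potential differences drive
        current)."""
        ve = np.full(len(default_cell), 1.0)
        res = cable.simulate(default_cell, ve, PulseWaveform(100.0),
                             cable.SolverConfig(duration=5.0))
        base = cable.simulate(default_cell, np.zeros(len(default_cell)),
                              PulseWaveform(0.0), cable.SolverConfig(duration=5.0))
        np.testing.assert_allclose(res.v, base.v, atol=1e-8)

    def test_quiescent_window_at_zero_amplitude(self, default_cell):
        res = cable.simulate(default_cell, np.zeros(len(default_cell)),
                             PulseWaveform(0.0))
        assert sum(len(s) for s in res.spikes) == 0
        assert np.all(res.v < 0.0)

    def test_conduction_down_the_axon(self, default_cell):
        src = field.DiscElectrode(center=(52.0, 0, 50))
        ve = src.unit_potentials(default_cell.morph.centers)
        res = cable.simulate(default_cell, ve, PulseWaveform(120.0))
        axon = default_cell.morph.region_index("axon")
        spiking = [i for i in axon if len(res.spike_times(i)) > 0]
        assert len(spiking) > 100
        arcs = default_cell.morph.arc[spiking]
        first = np.array([res.spike_times(i)[0] for i in spiking])
        distal = arcs > 1000.0
        # latency grows with distance along the axon (finite conduction speed)
        assert np.corrcoef(arcs[distal], first[distal])[0, 1] > 0.95

    def test_field_vector_length_checked(self, default_cell):
        with pytest.raises(ValueError, match="compartments"):
            cable.simulate(default_cell, np.zeros(3), PulseWaveform(1.0))

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            cable.SolverConfig(dt=0.0)


class TestDetectSpikes:
    def test_flat_trace_no_spikes(self):
        t = np.arange(0, 10, 0.01)
        assert len(cable.detect_spikes(t, np.full_like(t, -65.0))) == 0

    def test_single_crossing_interpolated(self):
        t = np.array([0.0, 1.0, 2.0])
        v = np.array([-10.0, -2.0, 6.0])
        times = cable.detect_spikes(t, v)
        assert len(times) == 1
        assert times[0] == pytest.approx(1.0 + 2.0 / 8.0)

    def test_refractory_merge(self):
        t = np.arange(0, 3, 0.01)
        v = np.full_like(t, -65.0)
        v[(t > 1.0) & (t < 1.05)] = 10.0
        v[(t > 1.2) & (t < 1.25)] = 10.0     # 0.2 ms later: merged
        v[(t > 2.5) & (t < 2.55)] = 10.0     # 1.5 ms later: separate
        assert len(cable.detect_spikes(t, v)) == 2


class TestClassification:
    def _fake_result(self, system, n_soma, n_socb, n_distal):
        lm = [system.landmark(k) for k in ("soma", "socb", "distal_axon")]
        t = np.arange(0, 10, 0.01)
        traces = []
        for n in (n_soma, n_socb, n_distal):
            v = np.full_like(t, -65.0)
            for k in range(n):
                v[(t > 2 + 2 * k) & (t < 2.2 + 2 * k)] = 20.0
            traces.append(v)
        v = np.column_stack(traces)
        idx = np.array(lm)
        spikes = [cable.detect_spikes(t, v[:, k]) for k in range(3)]
        return cable.SimulationResult(t, v, idx, spikes)

    @pytest.mark.parametrize("counts, label", [
        ((1, 1, 1), "bidirectional"),
        ((0, 1, 1), "soma_failure"),
        ((1, 2, 2), "echo_spike"),
        ((0, 2, 2), "echo_spike"),
        ((0, 0, 0), "no_spike"),
        ((0, 1, 0), "no_spike"),
    ])
    def test_labels(self, default_cell, counts, label):
        res = self._fake_result(default_cell, *counts)
        assert cable.classify_propagation(res, default_cell.morph, default_cell) == label

    def test_initiation_site_requires_spikes(self, default_cell):
        res = self._fake_result(default_cell, 0, 0, 0)
        with pytest.raises(ValueError):
            cable.initiation_site(res, default_cell.morph)

    def test_initiation_in_socb_for_soma_electrode(self, default_cell):
        """With the electrode over the proximal soma-SOCB stretch the spike
        starts in the sodium channel band, whose Na+ density is 3-5x that of
        its neighbors."""
        src = field.DiscElectrode(center=(0.0, 0, 50))
        ve = src.unit_potentials(default_cell.morph.centers)
        res = cable.simulate(default_cell, ve, PulseWaveform(150.0))
        region, arc = cable.initiation_site(res, default_cell.morph)
        assert region == "socb"
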