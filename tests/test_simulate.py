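"""Synthetic-data generator: layouts, spiking, traces, stacks, walks."""

import numpy as np
import pytest

from neuromotif import (
    SimulationConfig, StructuralLayout, ValidationError, get_motif,
    layout_neurons, render_stack, render_traces, simulate_spikes,
    simulate_trajectories,
)
from neuromotif.simulate import F0_UNITS


def _two_pop_layout(directed=True, distance=1000.0):
    adj = np.array([[0, 1], [0, 0]]) if directed else \
        np.array([[0, 1], [1, 0]])
    return StructuralLayout(
        ["A", "B"], np.array([[0.0, 0.0], [distance, 0.0]]), adj)


# ---------------------------------------------------------------------------
# config validation


def test_config_rejects_bad_probabilities_and_negatives():
    with pytest.raises(ValidationError):
        SimulationConfig(p_base=1.5)
    with pytest.raises(ValidationError):
        SimulationConfig(p_trans=-0.1)
    with pytest.raises(ValidationError):
        SimulationConfig(duration=0)
    with pytest.raises(ValidationError):
        SimulationConfig(noise_sd=-0.01)
    with pytest.raises(ValidationError):
        SimulationConfig(n_per_node=0)
    with pytest.raises(ValidationError):
        SimulationConfig(bleach_tau=0.0)
    assert SimulationConfig(noise_sd=0.0).noise_sd == 0.0


def test_n_frames_rounding():
    assert SimulationConfig(duration=600, frame_rate=2).n_frames == 1200


# ---------------------------------------------------------------------------
# neuron layout


def test_b5_default_layout_has_100_neurons_within_radius():
    cfg = SimulationConfig(seed=0)
    lay = get_motif("B5")
    neurons = layout_neurons(lay, cfg)
    assert len(neurons) == 100
    assert neurons["neuron_id"].is_unique
    for k, label in enumerate(lay.population_labels):
        sub = neurons[neurons["population"] == label]
        assert len(sub) == 25
        d = np.hypot(sub["x_um"] - lay.positions[k, 0],
                     sub["y_um"] - lay.positions[k, 1])
        assert (d <= cfg.node_radius).all()


def test_one_neuron_per_node_and_determinism():
    cfg = SimulationConfig(seed=7, n_per_node=1)
    lay = get_motif("A1")
    a = layout_neurons(lay, cfg)
    b = layout_neurons(lay, cfg)
    assert len(a) == 3
    assert a.equals(b)


def test_overlapping_node_discs_warn():
    lay = _two_pop_layout(distance=100.0)
    with pytest.warns(UserWarning, match="overlap"):
        layout_neurons(lay, SimulationConfig(seed=0))


# ---------------------------------------------------------------------------
# spiking model


def test_no_sources_empty_raster():
    cfg = SimulationConfig(seed=0, p_base=0.0, p_burst=0.0)
    lay = get_motif("A1")
    truth = simulate_spikes(lay, layout_neurons(lay, cfg), cfg)
    assert truth.raster.sum() == 0


def test_spontaneous_rate_matches_binomial_oracle():
    cfg = SimulationConfig(seed=3, p_burst=0.0, duration=500)
    lay = get_motif("A1")
    truth = simulate_spikes(lay, layout_neurons(lay, cfg), cfg)
    n = truth.raster.size
    assert n >= 7.5e4
    se = np.sqrt(0.01 * 0.99 / n)
    assert abs(truth.raster.mean() - 0.01) < 3 * se


def test_forced_burst_propagates_one_frame_later():
    cfg = SimulationConfig(seed=0, p_base=0.0, p_burst=0.0, p_in=1.0,
                           p_trans=1.0, burst_len=1)
    lay = _two_pop_layout(directed=True)
    neurons = layout_neurons(lay, cfg)
    truth = simulate_spikes(lay, neurons, cfg, forced_bursts=[("A", 10)])
    in_a = neurons["population"].to_numpy() == "A"
    assert truth.raster[in_a, 10].all()
    assert truth.raster[~in_a, 11].all()
    assert truth.raster[~in_a, 10].sum() == 0
    (event,) = truth.events
    assert event.population == "A" and event.start_frame == 10
    assert event.propagated_to == ["B"]


def test_directed_edge_does_not_propagate_backwards():
    cfg = SimulationConfig(seed=0, p_base=0.0, p_burst=0.0, p_in=1.0,
                           p_trans=1.0, burst_len=1)
    lay = _two_pop_layout(directed=True)
    neurons = layout_neurons(lay, cfg)
    truth = simulate_spikes(lay, neurons, cfg, forced_bursts=[("B", 10)])
    in_a = neurons["population"].to_numpy() == "A"
    assert truth.raster[in_a].sum() == 0


def test_propagation_targets_are_structural_successors():
    cfg = SimulationConfig(seed=5, duration=300)
    lay = get_motif("A4")  # directed chain 0 -> 1 -> 2 -> 3
    neurons = layout_neurons(lay, cfg)
    truth = simulate_spikes(lay, neurons, cfg)
    succ = {lab: [lay.population_labels[j]
                  for j in np.flatnonzero(lay.adjacency[k])]
            for k, lab in enumerate(lay.population_labels)}
    assert truth.events
    for ev in truth.events:
        assert set(ev.propagated_to) <= set(succ[ev.population])


def test_unknown_population_rejected():
    cfg = SimulationConfig(seed=0)
    lay = _two_pop_layout()
    neurons = layout_neurons(lay, cfg)
    neurons.loc[0, "population"] = "X"
    with pytest.raises(ValidationError):
        simulate_spikes(lay, neurons, cfg)


def test_same_seed_bit_identical_raster_and_traces():
    cfg = SimulationConfig(seed=11, duration=120)
    lay = get_motif("B1")
    neurons = layout_neurons(lay, cfg)
    t1 = simulate_spikes(lay, neurons, cfg)
    t2 = simulate_spikes(lay, neurons, cfg)
    assert np.array_equal(t1.raster, t2.raster)
    r1 = render_traces(t1, cfg)
    r2 = render_traces(t2, cfg)
    assert np.array_equal(r1.traces, r2.traces)


# ---------------------------------------------------------------------------
# calcium traces


def _single_spike_truth(lay, cfg, neuron=0, frame=20):
    neurons = layout_neurons(lay, cfg)
    truth = simulate_spikes(lay, neurons, cfg)
    truth.raster[:] = 0
    truth.raster[neuron, frame] = 1
    return truth


def test_empty_raster_noiseless_trace_is_constant_f0():
    cfg = SimulationConfig(seed=0, p_base=0.0, p_burst=0.0, noise_sd=0.0,
                           duration=60)
    lay = get_motif("A1")
    truth = simulate_spikes(lay, layout_neurons(lay, cfg), cfg)
    rec = render_traces(truth, cfg)
    assert np.allclose(rec.traces, F0_UNITS)


def test_single_spike_kernel_closed_forms():
    cfg = SimulationConfig(seed=0, p_base=0.0, p_burst=0.0, noise_sd=0.0,
                           duration=60, tau_ca=2.0, frame_rate=2.0, amp=0.3)
    lay = get_motif("A1")
    truth = _single_spike_truth(lay, cfg, neuron=0, frame=20)
    rec = render_traces(truth, cfg)
    trace = rec.traces[0]
    assert np.argmax(trace) == 20
    assert trace[20] == pytest.approx(F0_UNITS * (1 + cfg.amp))
    # 2 s after the spike (4 frames at 2 Hz) the transient decayed by e^-1
    assert trace[24] == pytest.approx(F0_UNITS * (1 + cfg.amp * np.e ** -1))


def test_bleaching_drift_applies_exponential_envelope():
    cfg = SimulationConfig(seed=0, p_base=0.0, p_burst=0.0, noise_sd=0.0,
                           duration=60, bleach_tau=30.0)
    lay = get_motif("A1")
    truth = simulate_spikes(lay, layout_neurons(lay, cfg), cfg)
    rec = render_traces(truth, cfg)
    t = np.arange(cfg.n_frames) / cfg.frame_rate
    assert np.allclose(rec.traces[0], F0_UNITS * np.exp(-t / 30.0))


# ---------------------------------------------------------------------------
# image stacks


def test_single_neuron_stack_pages_identical_and_mean_correct():
    import pandas as pd

    neurons = pd.DataFrame([{"neuron_id": 0, "population": "A",
                             "x_um": 0.0, "y_um": 0.0,
                             "soma_diameter_um": 10.0}])

    class Rec:
        traces = np.full((1, 5), 500.0)

    stack = render_stack(neurons, Rec(), pixel_size=1.0, background=100.0)
    assert (stack == stack[0]).all()
    disc = stack[0][stack[0] > 100]
    assert np.allclose(disc, 600.0)
    # disc pixel count close to the area pi (d / 2s)^2
    expected = np.pi * 5.0 ** 2
    assert abs(len(disc) - expected) / expected < 0.2


def test_zero_neurons_stack_is_background():
    import pandas as pd

    class Rec:
        traces = np.zeros((0, 4))

    stack = render_stack(pd.DataFrame(
        columns=["neuron_id", "population", "x_um", "y_um",
                 "soma_diameter_um"]), Rec(), background=100.0)
    assert (stack == 100).all()


def test_render_stack_rejects_bad_pixel_size():
    import pandas as pd

    class Rec:
        traces = np.zeros((0, 4))

    with pytest.raises(ValidationError):
        render_stack(pd.DataFrame(columns=["x_um", "y_um"]), Rec(),
                     pixel_size=0.0)


# ---------------------------------------------------------------------------
# trajectories


def test_zero_turn_sd_walks_are_straight():
    trajs = simulate_trajectories(3, field_on=False, turn_sd=0.0, seed=0,
                                  n_steps=10)
    for tr in trajs:
        assert np.allclose(tr.points[:, 1], 0.0)
        assert np.allclose(np.diff(tr.points[:, 0]), 5.0)


def test_field_on_keeps_walks_out_of_barrier():
    barrier = ((0.0, 20.0), (0.0, 1.0))   # forbidden: y > 20
    trajs = simulate_trajectories(50, field_on=True, barrier=barrier,
                                  seed=1, n_steps=200)
    for tr in trajs:
        assert (tr.points[:, 1] <= 20.0 + 1e-9).all()


def test_field_reduces_final_heading_deviation():
    def mean_final_dev(trajs):
        devs = []
        for tr in trajs:
            d = tr.points[-1] - tr.points[-2]
            devs.append(abs(np.degrees(np.arctan2(d[1], d[0]))))
        return np.mean(devs)

    on = simulate_trajectories(200, field_on=True, seed=0)
    off = simulate_trajectories(200, field_on=False, seed=0)
    assert mean_final_dev(on) < mean_final_dev(off)


def test_trajectories_deterministic_under_seed():
    a = simulate_trajectories(5, field_on=True, seed=9)
    b = simulate_trajectories(5, field_on=True, seed=9)
    for ta, tb in zip(a, b):
        assert np.array_equal(ta.points, tb.points)
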