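import numpy as np
import pytest

import lfpsim as L
from lfpsim import cable


def make_single_comp():
    m = L.make_stick(100.0, 2.0, 2)
    return L.compartmentalize(m, nseg_override={"dend": 1})


# ---------------------------------------------------------------------------
# axial conductances

def test_axial_conductance_reference_value():
    # uniform cylinder d=2 μm, Δs=100 μm, Ra=150 Ω·cm:
    # full-segment resistance ≈ 47.7 MΩ → edge conductance ≈ 0.0209 μS
    m = L.make_stick(200.0, 2.0, 2)
    cell = L.compartmentalize(
        m, L.CompartmentalizationParams(Ra=150.0), nseg_override={"dend": 2}
    )
    g = cable.axial_conductances(cell)
    assert g[1] == pytest.approx(0.02094, rel=1e-3)


def test_axial_conductance_scales_with_segment_length():
    p = L.CompartmentalizationParams(Ra=150.0)
    g2 = L.compartmentalize(L.make_stick(200.0, 2.0, 2), p, {"dend": 2}).g_axial[1]
    g4 = L.compartmentalize(L.make_stick(100.0, 2.0, 2), p, {"dend": 2}).g_axial[1]
    assert g4 == pytest.approx(2.0 * g2)


def test_axial_conductance_single_valued_per_edge(ball_and_stick_cell):
    # g is stored once per edge (on the child), so both endpoints see the
    # same value by construction; verify root has none
    g = cable.axial_conductances(ball_and_stick_cell)
    assert g[0] == 0.0
    assert np.all(g[1:] > 0)


# ---------------------------------------------------------------------------
# equilibrium and passivity

def test_equilibrium_no_stimuli_constant_v_zero_imem():
    cell = make_single_comp()
    res = L.simulate(cell, None, L.SimControl(tstop=10.0, dt=0.1, v_init=cell.e_pas))
    assert np.all(res.V == cell.e_pas)
    assert np.all(res.I_mem == 0.0)


def test_passive_relaxation_is_monotone(ball_and_stick_cell):
    res = L.simulate(
        ball_and_stick_cell, None,
        L.SimControl(tstop=100.0, dt=0.5, v_init=-50.0),
    )
    dev = np.max(np.abs(res.V - ball_and_stick_cell.e_pas), axis=0)
    assert np.all(np.diff(dev) <= 1e-12)


def test_single_compartment_cell_has_zero_potential_everywhere():
    cell = make_single_comp()
    stim = cable.Stimuli(cell)
    stim.add_synapse(L.SynapseSpec(target=0, weight=0.01, spike_times=(2.0,)))
    res = L.simulate(cell, stim, L.SimControl(tstop=20.0, dt=0.0625))
    # net transmembrane current of a one-compartment cell is identically zero
    np.testing.assert_allclose(res.I_mem, 0.0, atol=1e-12)
    phi = L.lfp_point_source(cell, res.I_mem, [100.0, 0.0, 0.0], 0.3)
    np.testing.assert_allclose(phi, 0.0, atol=1e-15)


# ---------------------------------------------------------------------------
# RC closed form and convergence

@pytest.mark.parametrize("method, order", [("backward_euler", 1), ("crank_nicolson", 2)])
def test_rc_step_response_converges_at_scheme_order(method, order):
    cell = make_single_comp()
    gL, C = cell.g_leak[0], cell.capacitance[0]
    I = 0.1

    def err(dt):
        stim = cable.Stimuli(cell)
        stim.add_clamp(L.CurrentClampSpec(target=0, amplitude=I, delay=0.0, duration=1e9))
        res = L.simulate(
            cell, stim, L.SimControl(tstop=20.0, dt=dt, v_init=cell.e_pas, method=method)
        )
        exact = cell.e_pas + (I / gL) * (1.0 - np.exp(-res.t * gL / C))
        return np.max(np.abs(res.V[0] - exact))

    e1, e2 = err(0.2), err(0.1)
    assert e2 < e1
    assert e1 / e2 == pytest.approx(2.0 ** order, rel=0.15)


# ---------------------------------------------------------------------------
# Kirchhoff conservation

@pytest.mark.parametrize("method", ["backward_euler", "crank_nicolson"])
def test_current_conservation_synapse_only(ball_and_stick_cell, method):
    cell = ball_and_stick_cell
    stim = cable.Stimuli(cell)
    stim.add_synapse(L.SynapseSpec(
        target=cell.n_compartments - 1, weight=0.01, spike_times=(5.0, 12.0)
    ))
    res = L.simulate(cell, stim, L.SimControl(tstop=40.0, dt=0.0625, method=method))
    assert np.max(np.abs(res.I_mem.sum(axis=0))) <= 1e-9 * cell.n_compartments


def test_current_clamp_creates_exact_monopole(ball_and_stick_cell):
    cell = ball_and_stick_cell
    amp = 0.5
    stim = cable.Stimuli(cell)
    stim.add_clamp(L.CurrentClampSpec(target=0, amplitude=amp, delay=5.0, duration=20.0))
    res = L.simulate(cell, stim, L.SimControl(tstop=40.0, dt=0.0625))
    total = res.I_mem.sum(axis=0)
    inj = res.I_inj.sum(axis=0)
    np.testing.assert_allclose(total, inj, atol=1e-9 * cell.n_compartments)
    during = (res.t > 5.0) & (res.t < 25.0)
    np.testing.assert_allclose(total[during], amp, atol=1e-9 * cell.n_compartments)


def test_zero_amplitude_clamp_is_noop(ball_and_stick_cell):
    cell = ball_and_stick_cell
    stim = cable.Stimuli(cell)
    stim.add_clamp(L.CurrentClampSpec(target=0, amplitude=0.0, delay=5.0, duration=20.0))
    ctl = L.SimControl(tstop=20.0, dt=0.0625, v_init=-60.0)
    res = L.simulate(cell, stim, ctl)
    ref = L.simulate(cell, None, ctl)
    np.testing.assert_array_equal(res.V, ref.V)


def test_steady_clamp_far_field_is_monopole(ball_and_stick_cell):
    # during a long steady pulse the far potential tends to I/(4πσr)
    cell = ball_and_stick_cell
    amp, sigma = 1.0, 0.3
    stim = cable.Stimuli(cell)
    stim.add_clamp(L.CurrentClampSpec(target=0, amplitude=amp, delay=0.0, duration=1e9))
    res = L.simulate(cell, stim, L.SimControl(tstop=400.0, dt=0.25))
    r = 100 * 520.0
    phi = L.lfp_line_source(cell, res.I_mem[:, -1:], [r, 0.0, 0.0], sigma)[0]
    assert phi == pytest.approx(amp / (4 * np.pi * sigma * r), rel=1e-3)


# ---------------------------------------------------------------------------
# synapses

def test_synapse_without_spikes_is_silent(ball_and_stick_cell):
    cell = ball_and_stick_cell
    stim = cable.Stimuli(cell)
    h = stim.add_synapse(L.SynapseSpec(target=3, weight=0.01))
    ctl = L.SimControl(tstop=20.0, dt=0.0625, rec_isyn=True, v_init=cell.e_pas)
    res = L.simulate(cell, stim, ctl)
    np.testing.assert_allclose(res.syn_currents[h], 0.0, atol=1e-15)
    np.testing.assert_allclose(res.I_mem, 0.0, atol=1e-12)


def test_synapse_current_vanishes_at_reversal():
    # a cell resting exactly at the synaptic reversal draws zero current
    m = L.make_stick(100.0, 2.0, 2)
    cell = L.compartmentalize(m, L.CompartmentalizationParams(e_pas=0.0), {"dend": 3})
    stim = cable.Stimuli(cell)
    h = stim.add_synapse(L.SynapseSpec(target=1, weight=0.01, e_rev=0.0, spike_times=(2.0,)))
    res = L.simulate(
        cell, stim,
        L.SimControl(tstop=20.0, dt=0.0625, v_init=0.0, rec_isyn=True),
    )
    np.testing.assert_allclose(res.syn_currents[h], 0.0, atol=1e-12)
    np.testing.assert_allclose(res.V, 0.0, atol=1e-12)


def test_apical_synapse_sink_source_sign_pattern(ball_and_stick_cell):
    # excitatory input at the distal stick: negative extracellular transient
    # near the synapse, positive near the soma (sink/source dipole pattern)
    cell = ball_and_stick_cell
    distal = cell.n_compartments - 1
    stim = cable.Stimuli(cell)
    stim.add_synapse(L.SynapseSpec(target=distal, weight=0.01, spike_times=(20.0,)))
    res = L.simulate(cell, stim, L.SimControl(tstop=60.0, dt=0.0625))
    sigma = 0.3
    near_syn = L.lfp_line_source(cell, res.I_mem, [30.0, 0.0, 510.0], sigma)
    near_soma = L.lfp_line_source(cell, res.I_mem, [30.0, 0.0, 0.0], sigma)
    assert near_syn.min() < 0 and abs(near_syn.min()) > abs(near_syn.max())
    assert near_soma.max() > 0 and abs(near_soma.max()) > abs(near_soma.min())


def test_invalid_stimulus_target_raises(ball_and_stick_cell):
    stim = cable.Stimuli(ball_and_stick_cell)
    with pytest.raises(IndexError):
        stim.add_synapse(L.SynapseSpec(target=9999, weight=0.01))
    with pytest.raises(IndexError):
        stim.add_clamp(L.CurrentClampSpec(target=-500, amplitude=1.0))


# ---------------------------------------------------------------------------
# externally imposed extracellular potentials

def _vext_grid(control):
    n = int(round((control.tstop - control.tstart) / control.dt))
    return control.tstart + control.dt * np.arange(n + 1)


def test_v_ext_zero_is_noop(ball_and_stick_cell):
    cell = ball_and_stick_cell
    ctl = L.SimControl(tstop=20.0, dt=0.0625, v_init=-60.0)
    t = _vext_grid(ctl)
    stim = cable.Stimuli(cell)
    cable.insert_v_ext(stim, np.zeros((cell.n_compartments, t.size)), t)
    res = L.simulate(cell, stim, ctl)
    ref = L.simulate(cell, None, ctl)
    np.testing.assert_array_equal(res.V, ref.V)


def test_uniform_v_ext_leaves_membrane_potential_unchanged(ball_and_stick_cell):
    cell = ball_and_stick_cell
    ctl = L.SimControl(tstop=20.0, dt=0.0625, v_init=-60.0)
    t = _vext_grid(ctl)
    v_ext = np.tile(5.0 * np.sin(t / 3.0), (cell.n_compartments, 1))
    stim = cable.Stimuli(cell)
    cable.insert_v_ext(stim, v_ext, t)
    res = L.simulate(cell, stim, ctl)
    ref = L.simulate(cell, None, ctl)
    np.testing.assert_allclose(res.V, ref.V, atol=1e-9)


def test_linear_gradient_polarizes_antisymmetrically():
    # steady uniform field along a straight uniform cable: depolarization at
    # one end mirrors hyperpolarization at the other about the midpoint
    m = L.make_stick(400.0, 2.0, 2)
    cell = L.compartmentalize(m, nseg_override={"dend": 8})
    ctl = L.SimControl(tstop=400.0, dt=0.5, v_init=cell.e_pas)
    t = _vext_grid(ctl)
    grad = (cell.mid[:, 2] - 200.0) * 0.01  # mV/μm along the cable
    stim = cable.Stimuli(cell)
    cable.insert_v_ext(stim, np.tile(grad[:, None], (1, t.size)), t)
    res = L.simulate(cell, stim, ctl)
    dv = res.V[:, -1] - cell.e_pas
    np.testing.assert_allclose(dv, -dv[::-1], atol=1e-6)
    assert np.max(np.abs(dv)) > 1e-3


def test_v_ext_shape_mismatch_raises(ball_and_stick_cell):
    stim = cable.Stimuli(ball_and_stick_cell)
    with pytest.raises(ValueError):
        cable.insert_v_ext(stim, np.zeros((3, 5)), np.arange(5.0))


# ---------------------------------------------------------------------------
# runtime sinks, warm-up, determinism

def test_runtime_sink_equals_posthoc(ball_and_stick_cell):
    cell = ball_and_stick_cell
    stim = cable.Stimuli(cell)
    stim.add_synapse(L.SynapseSpec(target=8, weight=0.01, spike_times=(5.0,)))
    el = L.ElectrodeArray(positions=[[100.0, 0.0, 0.0], [0.0, 80.0, 400.0]], sigma=0.3)
    C = L.compute_coefficient_matrix(cell, el)
    res = L.simulate(cell, stim, L.SimControl(tstop=40.0, dt=0.0625), runtime_sinks=[C])
    posthoc = L.apply_coefficients(C, res.I_mem)
    np.testing.assert_allclose(res.sink_potentials[0], posthoc, rtol=1e-12, atol=1e-16)


def test_warmup_discards_negative_time_samples(ball_and_stick_cell):
    cell = ball_and_stick_cell
    ctl = L.SimControl(tstart=-50.0, tstop=20.0, dt=0.0625, v_init=-50.0)
    res = L.simulate(cell, None, ctl)
    assert res.t[0] == 0.0
    assert res.t[-1] == pytest.approx(20.0)
    # after 50 ms of free relaxation the start-of-recording state is closer
    # to rest than the initial condition
    assert np.max(np.abs(res.V[:, 0] - cell.e_pas)) < 15.0


def test_incommensurate_tstart_raises():
    with pytest.raises(ValueError, match="commensurate"):
        L.SimControl(tstart=-0.03, tstop=10.0, dt=0.0625)


def test_simulation_is_bit_reproducible(ball_and_stick_cell):
    cell = ball_and_stick_cell
    def run():
        stim = cable.Stimuli(cell)
        stim.add_synapse(L.SynapseSpec(target=5, weight=0.01, spike_times=(3.0,)))
        return L.simulate(cell, stim, L.SimControl(tstop=30.0, dt=0.0625))
    a, b = run(), run()
    np.testing.assert_array_equal(a.V, b.V)
    np.testing.assert_array_equal(a.I_mem, b.I_mem)


def test_chain_and_tree_solvers_agree():
    # same cable solved via the banded chain path and the sparse tree path
    m = L.make_stick(300.0, 2.0, 2)
    cell = L.compartmentalize(m, nseg_override={"dend": 6})
    stim = cable.Stimuli(cell)
    stim.add_synapse(L.SynapseSpec(target=5, weight=0.01, spike_times=(2.0,)))
    ctl = L.SimControl(tstop=20.0, dt=0.0625)
    res_chain = L.simulate(cell, stim, ctl)

    shuffled = cable._TreeSolver(cell)
    shuffled.is_chain = False
    import scipy.sparse
    rows, cols, vals = [], [], []
    for n in range(cell.n_compartments):
        q = cell.parent[n]
        if q >= 0:
            rows += [n, q]; cols += [q, n]
            vals += [-cell.g_axial[n], -cell.g_axial[n]]
    shuffled._off = scipy.sparse.coo_matrix(
        (vals, (rows, cols)), shape=(cell.n_compartments,) * 2
    ).tocsc()
    shuffled._lu = None
    shuffled._lu_diag = None

    import unittest.mock
    with unittest.mock.patch.object(cable, "_TreeSolver", return_value=shuffled):
        stim2 = cable.Stimuli(cell)
        stim2.add_synapse(L.SynapseSpec(target=5, weight=0.01, spike_times=(2.0,)))
        res_tree = L.simulate(cell, stim2, ctl)
    np.testing.assert_allclose(res_tree.V, res_chain.V, rtol=1e-10, atol=1e-10)
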