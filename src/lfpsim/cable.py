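"""Passive multicompartment cable dynamics.

Each compartment n obeys Kirchhoff's current law:

    C_n dV_n/dt + g_L,n (V_n − e_pas) + Σ_syn g_s(t)(V_n − e_s)
        = Σ_adj g_ax (V_adj − V_n) + I_inj,n(t)

solved implicitly (backward Euler by default, Crank–Nicolson optionally) on
the tree defined by the cell's parent links.  The net transmembrane current
(outward positive, electrode injection excluded) is recovered from the
discrete identity

    I_mem,n = Σ_adj g_ax (V_adj − V_n) + I_inj,n

evaluated at the solved step, which makes Σ_n I_mem = Σ_n I_inj hold to
machine precision — the Kirchhoff sum rule: a neuron's net transmembrane
current is zero unless an electrode injects charge intracellularly, in which
case the imbalance is exactly the injected (monopole) current.

Units: ms, mV, nA, μS, nF.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from .morphology import CompartmentalizedCell

__all__ = [
    "MembraneMechanism",
    "SynapseSpec",
    "CurrentClampSpec",
    "SinusoidClampSpec",
    "SimControl",
    "SimulationResult",
    "Stimuli",
    "attach_exp_synapse",
    "attach_current_clamp",
    "attach_sinusoid_clamp",
    "insert_v_ext",
    "axial_conductances",
    "simulate",
]


class MembraneMechanism(ABC):
    """A linearizable point membrane mechanism on one compartment.

    The implicit solver uses the declared linearization: at time t the
    mechanism contributes an outward current g(t)·(V − e) with conductance
    ``conductance(t)`` (μS) and reversal ``reversal`` (mV).  A purely
    conductance-based mechanism therefore passes zero current at V = e.
    """

    target: int
    reversal: float

    @abstractmethod
    def conductance(self, t: float) -> float:  # μS
        ...


@dataclass(frozen=True)
class SynapseSpec:
    """Single-exponential conductance synapse.

    g(t) = weight · Σ_spikes exp(−(t − t_s)/τ) for t ≥ t_s; the synaptic
    current g(t)(V − e_rev) is a transmembrane current (part of I_mem).
    """

    target: int
    weight: float          # μS
    tau: float = 2.0       # ms
    e_rev: float = 0.0     # mV
    spike_times: tuple = ()

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass(frozen=True)
class CurrentClampSpec:
    """Intracellular electrode step current: ``amplitude`` nA for
    t ∈ [delay, delay + duration).  Not a transmembrane current."""

    target: int
    amplitude: float       # nA
    delay: float = 0.0     # ms
    duration: float = 0.0  # ms

    def __post_init__(self):
        if self.duration < 0:
            raise ValueError("duration must be >= 0")


@dataclass(frozen=True)
class SinusoidClampSpec:
    """Intracellular sinusoidal current amplitude·sin(2πf(t−delay) + phase)
    for t ∈ [delay, delay + duration)."""

    target: int
    amplitude: float       # nA
    frequency: float       # kHz-free: cycles per second (Hz)
    delay: float = 0.0
    duration: float = np.inf
    phase: float = 0.0

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")


@dataclass(frozen=True)
class SimControl:
    """Simulation window and solver controls.

    Recording always starts at t = 0; a negative ``tstart`` runs warm-up
    steps whose samples are discarded (start-up transient removal).
    """

    tstop: float
    tstart: float = 0.0
    dt: float = 0.0625
    v_init: float = -65.0
    method: str = "backward_euler"   # or "crank_nicolson"
    rec_imem: bool = True
    rec_v: bool = True
    rec_isyn: bool = False

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.tstart >= self.tstop:
            raise ValueError("tstart must be < tstop")
        if self.tstop <= 0:
            raise ValueError("tstop must be > 0 (recording covers [0, tstop])")
        if self.method not in ("backward_euler", "crank_nicolson"):
            raise ValueError(f"unknown method {self.method!r}")
        for name in ("tstart", "tstop"):
            v = getattr(self, name)
            if abs(round(v / self.dt) - v / self.dt) > 1e-9:
                raise ValueError(f"{name} is not commensurate with dt")


@dataclass
class SimulationResult:
    """Time axis (ms) plus per-compartment traces over t ∈ [0, tstop].

    V: (N, T) mV.  I_mem: (N, T) nA, outward positive, excluding electrode
    injection.  I_inj: (N, T) nA.  ``sink_potentials`` holds the runtime
    coefficient-matrix accumulations when requested.
    """

    t: np.ndarray
    V: np.ndarray | None
    I_mem: np.ndarray | None
    I_inj: np.ndarray
    syn_currents: dict[int, np.ndarray] = field(default_factory=dict)
    sink_potentials: list[np.ndarray] = field(default_factory=list)


class Stimuli:
    """Collection of stimuli and external-field insertions for one cell."""

    def __init__(self, cell: CompartmentalizedCell):
        self.cell = cell
        self.synapses: list[SynapseSpec] = []
        self.clamps: list[CurrentClampSpec | SinusoidClampSpec] = []
        self.mechanisms: list[MembraneMechanism] = []
        self.v_ext: np.ndarray | None = None
        self.v_ext_t: np.ndarray | None = None

    def _check_target(self, idx: int) -> None:
        if not 0 <= idx < self.cell.n_compartments:
            raise IndexError(f"compartment index {idx} out of range")

    def add_synapse(self, spec: SynapseSpec) -> int:
        self._check_target(spec.target)
        self.synapses.append(spec)
        return len(self.synapses) - 1

    def add_clamp(self, spec) -> int:
        self._check_target(spec.target)
        self.clamps.append(spec)
        return len(self.clamps) - 1

    def add_mechanism(self, mech: MembraneMechanism) -> int:
        self._check_target(mech.target)
        self.mechanisms.append(mech)
        return len(self.mechanisms) - 1

    def set_v_ext(self, v_ext: np.ndarray, t: np.ndarray) -> None:
        v_ext = np.asarray(v_ext, dtype=float)
        t = np.asarray(t, dtype=float)
        if v_ext.shape != (self.cell.n_compartments, t.size):
            raise ValueError(
                f"v_ext shape {v_ext.shape} does not match "
                f"(n_compartments, len(t)) = ({self.cell.n_compartments}, {t.size})"
            )
        self.v_ext = v_ext
        self.v_ext_t = t


def attach_exp_synapse(stim: Stimuli, spec: SynapseSpec) -> int:
    """Register a conductance-based exponential synapse; returns its handle."""
    return stim.add_synapse(spec)


def attach_current_clamp(stim: Stimuli, spec) -> int:
    """Register an intracellular current electrode; returns its handle."""
    return stim.add_clamp(spec)


def attach_sinusoid_clamp(stim: Stimuli, spec: SinusoidClampSpec) -> int:
    return stim.add_clamp(spec)


def insert_v_ext(stim: Stimuli, v_ext: np.ndarray, t: np.ndarray) -> Stimuli:
    """Impose an external extracellular potential per compartment.

    Axial currents are then driven by gradients of V + v_ext; membrane
    currents keep their form.  ``t`` must cover the solver grid (samples are
    linearly interpolated onto it)."""
    stim.set_v_ext(v_ext, t)
    return stim


def axial_conductances(cell: CompartmentalizedCell) -> np.ndarray:
    """Per-compartment conductance (μS) of the edge to the parent; 0 at root.

    g = 1/(R_half(n) + R_half(parent)) with R_half = (Ra·Δs/2)/(π d²/4)."""
    return cell.g_axial.copy()


def _clamp_current(spec, t: float) -> float:
    if isinstance(spec, CurrentClampSpec):
        if spec.delay <= t < spec.delay + spec.duration:
            return spec.amplitude
        return 0.0
    if spec.delay <= t < spec.delay + spec.duration:
        # frequency in Hz, t in ms
        return spec.amplitude * np.sin(
            2.0 * np.pi * spec.frequency * 1e-3 * (t - spec.delay) + spec.phase
        )
    return 0.0


def _syn_conductance_traces(synapses, t_grid: np.ndarray) -> np.ndarray:
    """(n_syn, T) conductance arrays on the solver grid."""
    g = np.zeros((len(synapses), t_grid.size))
    for k, s in enumerate(synapses):
        for ts in s.spike_times:
            m = t_grid >= ts
            g[k, m] += s.weight * np.exp(-(t_grid[m] - ts) / s.tau)
    return g


class _TreeSolver:
    """Solve (D + L) v = b for the symmetric tree-structured system.

    Chain topologies (parent[n] = n−1) use the banded Cholesky solver;
    general trees go through sparse LU.  The off-diagonal structure is fixed;
    only the diagonal varies in time (synaptic conductances), so the chain
    path rebuilds its 2×N band cheaply and the sparse path refactorizes only
    when the diagonal changed.
    """

    def __init__(self, cell: CompartmentalizedCell):
        N = cell.n_compartments
        self.N = N
        self.parent = cell.parent
        self.g_ax = cell.g_axial
        self.is_chain = bool(np.all(self.parent == np.arange(N) - 1))
        if not self.is_chain:
            rows, cols, vals = [], [], []
            for n in range(N):
                q = self.parent[n]
                if q >= 0:
                    rows += [n, q]
                    cols += [q, n]
                    vals += [-self.g_ax[n], -self.g_ax[n]]
            self._off = scipy.sparse.coo_matrix(
                (vals, (rows, cols)), shape=(N, N)
            ).tocsc()
            self._lu = None
            self._lu_diag = None

    def solve(self, diag: np.ndarray, b: np.ndarray) -> np.ndarray:
        if self.N == 1:
            return b / diag
        if self.is_chain:
            ab = np.zeros((2, self.N))
            ab[0, 1:] = -self.g_ax[1:]
            ab[1] = diag
            return scipy.linalg.solveh_banded(ab, b)
        if self._lu is None or not np.array_equal(diag, self._lu_diag):
            A = self._off + scipy.sparse.diags(diag, format="csc")
            self._lu = scipy.sparse.linalg.splu(A.tocsc())
            self._lu_diag = diag.copy()
        return self._lu.solve(b)


def _axial_inflow(cell: CompartmentalizedCell, v: np.ndarray) -> np.ndarray:
    """Net intracellular current flowing into each compartment (nA)."""
    inflow = np.zeros_like(v)
    has_parent = cell.parent >= 0
    idx = np.flatnonzero(has_parent)
    par = cell.parent[idx]
    flow = cell.g_axial[idx] * (v[par] - v[idx])  # parent → child
    inflow[idx] += flow
    np.add.at(inflow, par, -flow)
    return inflow


def simulate(
    cell: CompartmentalizedCell,
    stimuli: Stimuli | None,
    control: SimControl,
    runtime_sinks: list | None = None,
) -> SimulationResult:
    """Advance the passive cable system and record t ∈ [0, tstop].

    ``runtime_sinks`` is an optional list of coefficient matrices (or objects
    with a ``matrix`` attribute of shape (n_contacts, N)); each time step's
    contact potentials Φ = C·I_mem are accumulated on the fly, so storing
    the full I_mem array can be switched off (rec_imem=False) without losing
    the extracellular signal.
    """
    N = cell.n_compartments
    stimuli = stimuli if stimuli is not None else Stimuli(cell)
    if stimuli.cell is not cell:
        raise ValueError("stimuli were built for a different cell")
    dt = control.dt
    n_steps = int(round((control.tstop - control.tstart) / dt))
    t_grid = control.tstart + dt * np.arange(n_steps + 1)
    rec_mask = t_grid >= -1e-9
    t_rec = t_grid[rec_mask]
    T = t_rec.size
    rec_offset = int(np.flatnonzero(rec_mask)[0])

    sink_mats = []
    for s in runtime_sinks or []:
        M = getattr(s, "matrix", s)
        M = np.asarray(M, dtype=float)
        if M.shape[1] != N:
            raise ValueError("runtime sink matrix has wrong number of columns")
        sink_mats.append(M)

    g_syn = _syn_conductance_traces(stimuli.synapses, t_grid)
    syn_targets = np.array([s.target for s in stimuli.synapses], dtype=int)
    syn_erev = np.array([s.e_rev for s in stimuli.synapses])

    if stimuli.v_ext is not None:
        ve = np.empty((N, t_grid.size))
        for n in range(N):
            ve[n] = np.interp(t_grid, stimuli.v_ext_t, stimuli.v_ext[n])
    else:
        ve = None

    C_dt = cell.capacitance / dt
    gL = cell.g_leak
    ax_diag = _axial_diag(cell)
    solver = _TreeSolver(cell)
    cn = control.method == "crank_nicolson"

    V = np.full(N, float(control.v_init))
    out_V = np.empty((N, T)) if control.rec_v else None
    out_imem = np.empty((N, T)) if control.rec_imem else None
    out_iinj = np.zeros((N, T))
    out_isyn = (
        {h: np.empty(T) for h in range(len(stimuli.synapses))}
        if control.rec_isyn else {}
    )
    sink_out = [np.empty((M.shape[0], T)) for M in sink_mats]

    mech = stimuli.mechanisms

    def inj_vector(t: float) -> np.ndarray:
        i = np.zeros(N)
        for spec in stimuli.clamps:
            i[spec.target] += _clamp_current(spec, t)
        return i

    def record(k_rec: int, k_grid: int, i_inj: np.ndarray) -> None:
        vv = V if ve is None else V + ve[:, k_grid]
        imem = _axial_inflow(cell, vv) + i_inj
        if not np.all(np.isfinite(imem)):
            raise FloatingPointError(f"non-finite state at step {k_grid}")
        if out_V is not None:
            out_V[:, k_rec] = V
        if out_imem is not None:
            out_imem[:, k_rec] = imem
        out_iinj[:, k_rec] = i_inj
        for h in out_isyn:
            s = stimuli.synapses[h]
            out_isyn[h][k_rec] = g_syn[h, k_grid] * (V[s.target] - s.e_rev)
        for M, acc in zip(sink_mats, sink_out):
            acc[:, k_rec] = M @ imem

    # initial sample (t = tstart if tstart == 0, else discarded warm-up)
    i_inj0 = inj_vector(t_grid[0])
    if rec_mask[0]:
        record(0, 0, i_inj0)

    # Backward Euler solves   (C/dt + G(t₊)) V₊ = (C/dt) V + b(t₊)
    # Crank–Nicolson (×2)     (2C/dt + G(t₊)) V₊ = (2C/dt) V + f(V, t₀) + b(t₊)
    # with G(t) the conductance matrix (leak + synaptic + axial Laplacian),
    # b(t) the source vector and f(V, t) = −G(t)V + b(t) the full RHS.
    i_inj_prev = i_inj0
    for k in range(n_steps):
        t_new = t_grid[k + 1]
        i_inj_new = inj_vector(t_new)
        scale = 2.0 if cn else 1.0
        diag = scale * C_dt + gL + ax_diag
        rhs = scale * C_dt * V + gL * cell.e_pas + i_inj_new
        if syn_targets.size:
            gs_new = g_syn[:, k + 1]
            np.add.at(diag, syn_targets, gs_new)
            np.add.at(rhs, syn_targets, gs_new * syn_erev)
        for mm in mech:
            gm = mm.conductance(t_new)
            diag[mm.target] += gm
            rhs[mm.target] += gm * mm.reversal
        if ve is not None:
            rhs += _axial_inflow(cell, ve[:, k + 1])
        if cn:
            vv_old = V if ve is None else V + ve[:, k]
            f_old = (
                _axial_inflow(cell, vv_old)
                - gL * (V - cell.e_pas)
                + i_inj_prev
            )
            if syn_targets.size:
                gs_old = g_syn[:, k]
                np.subtract.at(
                    f_old, syn_targets, gs_old * (V[syn_targets] - syn_erev)
                )
            for mm in mech:
                gm = mm.conductance(t_grid[k])
                f_old[mm.target] -= gm * (V[mm.target] - mm.reversal)
            rhs += f_old
        V = solver.solve(diag, rhs)
        if not np.all(np.isfinite(V)):
            raise FloatingPointError(f"solver diverged at step {k + 1}")
        k_rec = k + 1 - rec_offset
        if 0 <= k_rec < T:
            record(k_rec, k + 1, i_inj_new)
        i_inj_prev = i_inj_new

    return SimulationResult(
        t=t_rec, V=out_V, I_mem=out_imem, I_inj=out_iinj,
        syn_currents=out_isyn, sink_potentials=sink_out,
    )


def _axial_diag(cell: CompartmentalizedCell) -> np.ndarray:
    d = np.zeros(cell.n_compartments)
    idx = np.flatnonzero(cell.parent >= 0)
    d[idx] += cell.g_axial[idx]
    np.add.at(d, cell.parent[idx], cell.g_axial[idx])
    return d
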