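"""Populations of independent cells with correlated synaptic input.

All cells share one pool of presynaptic Poisson spike trains; each cell
independently selects ``n_select`` trains uniformly without replacement and
receives each through its own synapse.  For independent Poisson trains the
expected pairwise correlation of two cells' summed inputs equals the
expected shared fraction n_select/n_trains — selecting 100 of 1000 trains
yields an input correlation of 0.1.  Contributions to the extracellular
potential add linearly, so the population signal is the exact sum of
per-cell signals, and serial and process-parallel execution are bit-identical
under the same master seed.

Seed hygiene: the pool uses one shared seed; per-cell randomness (train
selection, synapse placement) derives from
``SeedSequence(master_seed, spawn_key=(cell_index,))`` — a fixed, documented
algorithm — so changing one cell's seed changes only that cell's
contribution.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from . import cable, forward, morphology

__all__ = [
    "SpikeTrainPool",
    "PopulationConfig",
    "PopulationResult",
    "generate_poisson_pool",
    "select_inputs",
    "cell_seed_sequence",
    "binned_input_correlation",
    "input_correlation_experiment",
    "disc_positions",
    "run_population",
]


@dataclass(frozen=True)
class SpikeTrainPool:
    """Pool of independent homogeneous Poisson spike trains.

    rate in events/s, window in ms; each train's times are sorted and lie
    strictly within the window.  Identical constructor arguments give
    bit-identical pools.
    """

    n_trains: int
    rate: float
    window: tuple[float, float]
    seed: int
    trains: tuple = field(default_factory=tuple)


def generate_poisson_pool(
    n_trains: int, rate: float, window: tuple[float, float], seed: int
) -> SpikeTrainPool:
    """Draw ``n_trains`` independent homogeneous Poisson processes."""
    if n_trains < 1:
        raise ValueError("n_trains must be >= 1")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive duration")
    rng = np.random.default_rng(seed)
    duration_s = (t1 - t0) * 1e-3
    trains = []
    for _ in range(n_trains):
        n = rng.poisson(rate * duration_s)
        times = np.sort(rng.uniform(t0, t1, n))
        trains.append(times)
    return SpikeTrainPool(n_trains, rate, (t0, t1), seed, tuple(trains))


def cell_seed_sequence(master_seed: int, cell_index: int) -> np.random.SeedSequence:
    """Deterministic per-cell seed stream (fixed derivation algorithm)."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(cell_index,))


def select_inputs(pool: SpikeTrainPool, n_select: int, cell_seed) -> np.ndarray:
    """Uniform sample of train indices without replacement, per-cell seeded.

    ``cell_seed`` may be an int or a SeedSequence.
    """
    if n_select > pool.n_trains:
        raise ValueError(
            f"n_select={n_select} exceeds pool size {pool.n_trains}"
        )
    rng = np.random.default_rng(cell_seed)
    return np.sort(rng.choice(pool.n_trains, size=n_select, replace=False))


def binned_input_correlation(
    pool: SpikeTrainPool,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    bin_ms: float = 5.0,
) -> float:
    """Pearson correlation of two cells' summed inputs in ``bin_ms`` bins."""
    t0, t1 = pool.window
    edges = np.arange(t0, t1 + bin_ms, bin_ms)
    a = np.concatenate([pool.trains[i] for i in idx_a]) if len(idx_a) else np.array([])
    b = np.concatenate([pool.trains[i] for i in idx_b]) if len(idx_b) else np.array([])
    ca, _ = np.histogram(a, edges)
    cb, _ = np.histogram(b, edges)
    return float(np.corrcoef(ca, cb)[0, 1])


def input_correlation_experiment(
    n_trains: int = 1000,
    rate: float = 5.0,
    window: tuple[float, float] = (0.0, 100_000.0),
    n_select: int = 100,
    n_pairs: int = 20,
    bin_ms: float = 5.0,
    seed: int = 0,
) -> float:
    """Mean pairwise input correlation over ``n_pairs`` independent seed pairs.

    One shared pool; for each pair, two cells select ``n_select`` trains with
    fresh per-cell seeds.  The expectation is n_select/n_trains.
    """
    pool = generate_poisson_pool(n_trains, rate, window, seed)
    rs = []
    for p in range(n_pairs):
        ia = select_inputs(pool, n_select, cell_seed_sequence(seed, 2 * p + 1))
        ib = select_inputs(pool, n_select, cell_seed_sequence(seed, 2 * p + 2))
        rs.append(binned_input_correlation(pool, ia, ib, bin_ms))
    return float(np.mean(rs))


def disc_positions(
    n: int, radius: float, z: float, seed: int
) -> np.ndarray:
    """Uniform cell positions on a horizontal disc of ``radius`` μm at height
    z (a column-like population layout), seeded."""
    rng = np.random.default_rng(seed)
    r = radius * np.sqrt(rng.random(n))
    a = 2.0 * np.pi * rng.random(n)
    return np.column_stack([r * np.cos(a), r * np.sin(a), np.full(n, float(z))])


# ---------------------------------------------------------------------------

@dataclass
class PopulationConfig:
    """Specification of a population run.

    Each of ``n_cells`` cells is an identical passive morphology (an SWC
    path or a named built-in fixture) at its own position/rotation, receives
    ``n_select`` synapses each fed one train from the shared pool, and is
    simulated independently; extracellular contributions are summed.
    """

    n_cells: int
    morphology_fixture: str | None = "ball_and_stick"
    morphology_path: str | None = None
    fixture_params: dict = field(default_factory=dict)
    passive: morphology.CompartmentalizationParams = field(
        default_factory=morphology.CompartmentalizationParams
    )
    nseg_override: dict | None = None
    positions: np.ndarray | None = None
    rotations: np.ndarray | None = None
    n_select: int = 100
    synapse_weight: float = 0.002       # μS
    synapse_tau: float = 2.0            # ms
    synapse_e_rev: float = 0.0          # mV
    synapse_sections: tuple = ("dend", "apic")
    pool_n_trains: int = 1000
    pool_rate: float = 5.0              # events/s
    master_seed: int = 0
    control: cable.SimControl | None = None
    electrode: forward.ElectrodeArray | None = None
    n_workers: int = 1                  # 1 = serial

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not (1 <= self.n_select <= self.pool_n_trains):
            raise ValueError("need 1 <= n_select <= pool_n_trains")


@dataclass
class PopulationResult:
    """Per-cell and summed contact potentials plus selected train indices."""

    t: np.ndarray
    per_cell: list[np.ndarray]
    summed: np.ndarray
    selections: list[np.ndarray]


def _build_cell(config: PopulationConfig) -> morphology.CompartmentalizedCell:
    if config.morphology_path is not None:
        return morphology.load_cell(
            config.morphology_path, config.passive, config.nseg_override
        )
    fixtures = {
        "ball_and_stick": morphology.make_ball_and_stick,
        "stick": morphology.make_stick,
    }
    if config.morphology_fixture not in fixtures:
        raise ValueError(f"unknown fixture {config.morphology_fixture!r}")
    defaults = {
        "ball_and_stick": dict(
            soma_diameter=20.0, stick_length=500.0, stick_diameter=2.0, n_points=11
        ),
        "stick": dict(length=500.0, diameter=2.0, n_points=11),
    }[config.morphology_fixture]
    params = {**defaults, **config.fixture_params}
    m = fixtures[config.morphology_fixture](**params)
    return morphology.compartmentalize(m, config.passive, config.nseg_override)


def _simulate_one(args) -> tuple[int, np.ndarray, np.ndarray, np.ndarray]:
    config, pool, i = args
    try:
        return _simulate_one_inner(config, pool, i)
    except Exception as exc:
        raise RuntimeError(f"simulation of cell {i} failed: {exc}") from exc


def _simulate_one_inner(config, pool, i):
    ss = cell_seed_sequence(config.master_seed, i)
    selection = select_inputs(pool, config.n_select, ss)
    rng = np.random.default_rng(ss.spawn(1)[0])

    cell = _build_cell(config)
    if config.rotations is not None:
        cell = morphology.set_rotation(cell, *np.asarray(config.rotations)[i])
    if config.positions is not None:
        cell = morphology.set_position(cell, *np.asarray(config.positions)[i])

    # area-weighted synapse placement on the configured sections
    target_pool = np.concatenate([
        cell.section_indices(nm)
        for nm in cell.section_names
        if nm.split("[")[0] in config.synapse_sections
    ]) if config.synapse_sections else np.arange(cell.n_compartments)
    if target_pool.size == 0:
        target_pool = np.arange(cell.n_compartments)
    w = cell.area[target_pool]
    targets = rng.choice(target_pool, size=config.n_select, p=w / w.sum())

    stim = cable.Stimuli(cell)
    for syn_i, train_i in enumerate(selection):
        cable.attach_exp_synapse(stim, cable.SynapseSpec(
            target=int(targets[syn_i]),
            weight=config.synapse_weight,
            tau=config.synapse_tau,
            e_rev=config.synapse_e_rev,
            spike_times=tuple(pool.trains[train_i]),
        ))

    control = config.control or cable.SimControl(tstop=200.0)
    C = forward.compute_coefficient_matrix(cell, config.electrode)
    res = cable.simulate(cell, stim, control, runtime_sinks=[C])
    return i, res.t, res.sink_potentials[0], selection


def run_population(config: PopulationConfig) -> PopulationResult:
    """Simulate every cell independently and sum the contact potentials.

    Execution mode does not affect results: with the same master seed, the
    serial path and the process-pool path return bit-identical output.
    """
    if config.electrode is None:
        raise ValueError("population run requires an electrode specification")
    t0, t1 = (config.control or cable.SimControl(tstop=200.0)).tstart, \
             (config.control or cable.SimControl(tstop=200.0)).tstop
    pool = generate_poisson_pool(
        config.pool_n_trains, config.pool_rate, (min(t0, 0.0), t1),
        config.master_seed,
    )
    jobs = [(config, pool, i) for i in range(config.n_cells)]
    if config.n_workers > 1:
        with ProcessPoolExecutor(max_workers=config.n_workers) as ex:
            raw = list(ex.map(_simulate_one, jobs))
    else:
        raw = [_simulate_one(j) for j in jobs]

    raw.sort(key=lambda r: r[0])
    t = raw[0][1]
    per_cell = [r[2] for r in raw]
    selections = [r[3] for r in raw]
    summed = np.zeros_like(per_cell[0])
    for phi in per_cell:  # fixed cell-index order: summation is reproducible
        summed += phi
    return PopulationResult(t=t, per_cell=per_cell, summed=summed, selections=selections)
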