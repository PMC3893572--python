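"""Run configuration: YAML schema, validation and end-to-end execution.

A run is a pure function of its configuration file: morphology source,
passive parameters, stimuli, simulation control, electrode geometry, seeds
and output paths are all explicit, so two runs from the same file produce
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cable, forward, io, morphology, population

__all__ = ["ConfigError", "RunConfig", "load_config", "run_from_config"]

log = logging.getLogger("lfpsim")

SCHEMA_VERSION = 1
MODES = ("single", "population", "coeffs", "validate")


class ConfigError(ValueError):
    """A configuration file violated the schema; the message names the field."""


@dataclass
class RunConfig:
    """Validated run configuration (see the YAML examples in the README)."""

    mode: str
    raw: dict
    path: Path | None = None


def _need(d: dict, key: str, ctx: str):
    if key not in d:
        raise ConfigError(f"missing required field '{ctx}{key}'")
    return d[key]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    version = raw.get("version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported config 'version' {version}")
    mode = raw.get("mode", "single")
    if mode not in MODES:
        raise ConfigError(f"'mode' must be one of {MODES}, got {mode!r}")
    cfg = RunConfig(mode=mode, raw=raw, path=Path(path))
    _validate(cfg)
    return cfg


def _validate(cfg: RunConfig) -> None:
    raw = cfg.raw
    if cfg.mode in ("single", "coeffs", "population"):
        if "morphology" not in raw:
            raise ConfigError("missing required field 'morphology'")
        mo = raw["morphology"]
        if "path" not in mo and "fixture" not in mo:
            raise ConfigError("'morphology' needs either 'path' or 'fixture'")
    if cfg.mode in ("single", "population"):
        sim = raw.get("sim", {})
        try:
            _sim_control(sim)
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"invalid 'sim' block: {exc}") from None
    if cfg.mode in ("single", "coeffs", "population"):
        if "electrode" not in raw:
            raise ConfigError("missing required field 'electrode'")
        try:
            _electrode(raw["electrode"])
        except (ValueError, TypeError, KeyError) as exc:
            raise ConfigError(f"invalid 'electrode' block: {exc}") from None


def _passive(raw: dict) -> morphology.CompartmentalizationParams:
    p = raw.get("passive", {})
    try:
        return morphology.CompartmentalizationParams(
            d_lambda=p.get("d_lambda", 0.1),
            f=p.get("f", 100.0),
            Ra=p.get("Ra", 150.0),
            cm=p.get("cm", 1.0),
            g_pas=p.get("g_pas", 1.0 / 30000.0),
            e_pas=p.get("e_pas", -65.0),
        )
    except ValueError as exc:
        raise ConfigError(f"invalid 'passive' block: {exc}") from None


def _build_cell(raw: dict) -> morphology.CompartmentalizedCell:
    mo = raw["morphology"]
    params = _passive(raw)
    nseg = raw.get("nseg")
    if "path" in mo:
        cell = morphology.load_cell(mo["path"], params, nseg)
    else:
        fixture = mo["fixture"]
        fparams = mo.get("params", {})
        if fixture == "ball_and_stick":
            m = morphology.make_ball_and_stick(**fparams)
        elif fixture == "stick":
            m = morphology.make_stick(**fparams)
        else:
            raise ConfigError(f"unknown morphology fixture {fixture!r}")
        cell = morphology.compartmentalize(m, params, nseg)
    if "rotation" in raw:
        cell = morphology.set_rotation(cell, *raw["rotation"])
    if "position" in raw:
        cell = morphology.set_position(cell, *raw["position"])
    return cell


def _sim_control(sim: dict) -> cable.SimControl:
    return cable.SimControl(
        tstop=_need(sim, "tstop", "sim."),
        tstart=sim.get("tstart", 0.0),
        dt=sim.get("dt", 0.0625),
        v_init=sim.get("v_init", -65.0),
        method=sim.get("method", "backward_euler"),
        rec_v=sim.get("rec_v", True),
        rec_imem=sim.get("rec_imem", True),
        rec_isyn=sim.get("rec_isyn", False),
    )


def _electrode(el: dict) -> forward.ElectrodeArray:
    if "contacts" in el:
        positions = np.asarray(el["contacts"], dtype=float)
    elif "grid" in el:
        g = el["grid"]
        origin = np.asarray(_need(g, "origin", "electrode.grid."), dtype=float)
        shape = _need(g, "shape", "electrode.grid.")
        pitch = float(_need(g, "pitch", "electrode.grid."))
        plane = g.get("plane", "xz")
        axes = {"xz": (0, 2), "xy": (0, 1), "yz": (1, 2)}
        if plane not in axes:
            raise ConfigError(f"electrode.grid.plane must be one of {list(axes)}")
        a0, a1 = axes[plane]
        positions = []
        for i in range(int(shape[0])):
            for j in range(int(shape[1])):
                p = origin.copy()
                p[a0] += i * pitch
                p[a1] += j * pitch
                positions.append(p)
        positions = np.asarray(positions)
    else:
        raise ConfigError("'electrode' needs 'contacts' or 'grid'")
    return forward.ElectrodeArray(
        positions=positions,
        sigma=el.get("sigma", 0.3),
        method=el.get("method", "line_source"),
        radius=el.get("radius", 0.0),
        normal=el.get("normal"),
        n_average=el.get("n_average", 1),
        seed=el.get("seed", 0),
    )


def _stimuli(raw: dict, cell: morphology.CompartmentalizedCell) -> cable.Stimuli:
    stim = cable.Stimuli(cell)
    for k, s in enumerate(raw.get("stimuli", [])):
        kind = _need(s, "kind", f"stimuli[{k}].")
        if "target" in s:
            target = int(s["target"])
        elif "section" in s:
            target = cell.closest_idx(s["section"], s.get("relpos", 0.5))
        else:
            raise ConfigError(f"stimuli[{k}] needs 'target' or 'section'")
        if kind == "synapse":
            cable.attach_exp_synapse(stim, cable.SynapseSpec(
                target=target,
                weight=_need(s, "weight", f"stimuli[{k}]."),
                tau=s.get("tau", 2.0),
                e_rev=s.get("e_rev", 0.0),
                spike_times=tuple(s.get("spike_times", ())),
            ))
        elif kind == "current_clamp":
            cable.attach_current_clamp(stim, cable.CurrentClampSpec(
                target=target,
                amplitude=_need(s, "amplitude", f"stimuli[{k}]."),
                delay=s.get("delay", 0.0),
                duration=s.get("duration", 0.0),
            ))
        elif kind == "sinusoid_clamp":
            cable.attach_sinusoid_clamp(stim, cable.SinusoidClampSpec(
                target=target,
                amplitude=_need(s, "amplitude", f"stimuli[{k}]."),
                frequency=_need(s, "frequency", f"stimuli[{k}]."),
                delay=s.get("delay", 0.0),
                duration=s.get("duration", np.inf),
                phase=s.get("phase", 0.0),
            ))
        else:
            raise ConfigError(f"stimuli[{k}].kind {kind!r} is not recognized")
    return stim


def run_from_config(cfg: RunConfig | str | Path) -> dict:
    """Execute a validated configuration end-to-end; returns a summary dict
    with output paths and key problem sizes."""
    if not isinstance(cfg, RunConfig):
        cfg = load_config(cfg)
    raw = cfg.raw
    out = raw.get("output", {})
    out_path = out.get("path")
    fmt = out.get("format", "h5")

    if cfg.mode == "single":
        cell = _build_cell(raw)
        control = _sim_control(raw.get("sim", {}))
        electrode = _electrode(raw["electrode"])
        stim = _stimuli(raw, cell)
        log.info(
            "single run: N=%d, n_contacts=%d, dt=%g, method=%s, seed=%s",
            cell.n_compartments, electrode.n_contacts, control.dt,
            electrode.method, raw.get("seed", 0),
        )
        C = forward.compute_coefficient_matrix(cell, electrode)
        res = cable.simulate(cell, stim, control, runtime_sinks=[C])
        phi = res.sink_potentials[0]
        if out_path:
            io.write_result(
                out_path, res.t, phi,
                v=res.V if out.get("save_v") else None,
                imem=res.I_mem if out.get("save_imem") else None,
                format=fmt,
            )
        return {
            "mode": "single", "n_compartments": cell.n_compartments,
            "n_contacts": electrode.n_contacts, "n_samples": res.t.size,
            "output": out_path, "phi": phi, "t": res.t,
        }

    if cfg.mode == "coeffs":
        cell = _build_cell(raw)
        electrode = _electrode(raw["electrode"])
        C = forward.compute_coefficient_matrix(cell, electrode)
        log.info("coeffs: shape=%s method=%s", C.shape, C.method)
        if out_path:
            import h5py

            with h5py.File(out_path, "w") as f:
                f.create_dataset("C", data=C.matrix)
                f.attrs["method"] = C.method
                f.attrs["sigma"] = C.sigma
                f.attrs["cell_hash"] = C.cell_hash
        return {"mode": "coeffs", "shape": C.shape, "output": out_path, "C": C}

    if cfg.mode == "population":
        pop_raw = raw.get("population", {})
        control = _sim_control(raw.get("sim", {}))
        electrode = _electrode(raw["electrode"])
        pos = pop_raw.get("positions")
        if isinstance(pos, dict):
            pos = population.disc_positions(
                _need(pop_raw, "n_cells", "population."),
                pos.get("radius", 100.0), pos.get("z", 0.0),
                pos.get("seed", raw.get("seed", 0)),
            )
        elif pos is not None:
            pos = np.asarray(pos, dtype=float)
        mo = raw["morphology"]
        pcfg = population.PopulationConfig(
            n_cells=_need(pop_raw, "n_cells", "population."),
            morphology_fixture=mo.get("fixture"),
            morphology_path=mo.get("path"),
            fixture_params=mo.get("params", {}),
            passive=_passive(raw),
            nseg_override=raw.get("nseg"),
            positions=pos,
            rotations=np.asarray(pop_raw["rotations"], dtype=float)
            if "rotations" in pop_raw else None,
            n_select=pop_raw.get("n_select", 100),
            synapse_weight=pop_raw.get("synapse_weight", 0.002),
            synapse_tau=pop_raw.get("synapse_tau", 2.0),
            synapse_e_rev=pop_raw.get("synapse_e_rev", 0.0),
            pool_n_trains=pop_raw.get("pool_n_trains", 1000),
            pool_rate=pop_raw.get("pool_rate", 5.0),
            master_seed=raw.get("seed", 0),
            control=control,
            electrode=electrode,
            n_workers=pop_raw.get("n_workers", 1),
        )
        log.info(
            "population run: n_cells=%d, n_select=%d/%d, seed=%d, workers=%d",
            pcfg.n_cells, pcfg.n_select, pcfg.pool_n_trains,
            pcfg.master_seed, pcfg.n_workers,
        )
        res = population.run_population(pcfg)
        if out_path:
            io.write_result(out_path, res.t, res.summed, format=fmt)
        return {
            "mode": "population", "n_cells": pcfg.n_cells,
            "n_samples": res.t.size, "output": out_path, "result": res,
        }

    if cfg.mode == "validate":
        from . import benchmarks

        v = raw.get("validate", {})
        bench = benchmarks.stick_benchmark(
            sigma=v.get("sigma", 0.3),
            nseg=v.get("nseg", 501),
            dt=v.get("dt", 1.0 / 64.0),
            solver=v.get("method", "crank_nicolson"),
        )
        log.info("validate: matching digits = %.2f", bench.matching_digits)
        return {
            "mode": "validate",
            "matching_digits": bench.matching_digits,
            "rel_error_max": float(bench.rel_error.max()),
        }

    raise ConfigError(f"unhandled mode {cfg.mode!r}")
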