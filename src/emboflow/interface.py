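"""Experiment configuration and the canned case-matrix runner.

An ExperimentConfig describes one end-to-end study: which circle-of-Willis
variant to generate, how the outflow boundary is treated (pressure outlets or
the fixed-mass-flow "M1" mode), which particle cases of the 9-cell size x
density matrix to run under which release modes, and the seed.  run_experiment
executes generate -> calibrate -> solve -> release/track -> metrics for every
(case x release mode) cell and writes the network JSON, flow CSVs, trajectory
and summary CSVs, metric tables and a reproducibility manifest to the output
directory.  All outputs are byte-reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import hemodynamics as hd
from . import metrics as mt
from . import particle_dynamics as pd_mod
from . import vasculature as vs

__all__ = [
    "ExperimentConfig",
    "ConfigError",
    "load_config",
    "dump_config",
    "run_experiment",
]

log = logging.getLogger("emboflow")

CASE_LABELS = tuple(pd_mod.CASE_MATRIX)
_BOUNDARY_MODES = ("pressure", "m1")
_RELEASE_MODES = ("core", "near_wall")


class ConfigError(ValueError):
    """An experiment configuration violates the schema."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated, fully-defaulted description of one experiment."""

    variant: str = "complete"
    diameter_scale: float = 1.0
    boundary_mode: str = "pressure"
    release_modes: tuple[str, ...] = ("core", "near_wall")
    cases: tuple[str, ...] = CASE_LABELS
    release_window: int = 100
    particles_per_cell: int | None = None
    inlet_extension: float = 10.0
    calibration_targets: Mapping[str, float] = field(
        default_factory=lambda: {"ACA": 20.0, "MCA": 60.0, "POSTERIOR": 20.0}
    )
    calibration_tol: float = 1.0
    inlet_velocity: float = 0.2
    dt: float = 0.01
    total_time: float = 5.0
    gravity: tuple[float, float, float] = (0.0, 0.0, 0.0)
    drag_cap_mode: str = "standard_0.44"
    outdir: str = "emboflow_out"
    seed: int = 0
    write_trajectories: bool = True

    def validate(self) -> None:
        if self.variant not in vs.CoWVariantSpec.VARIANTS:
            raise ConfigError(
                f"variant: {self.variant!r} not in {vs.CoWVariantSpec.VARIANTS}"
            )
        if self.boundary_mode not in _BOUNDARY_MODES:
            raise ConfigError(f"boundary_mode: {self.boundary_mode!r} not in {_BOUNDARY_MODES}")
        for m in self.release_modes:
            if m not in _RELEASE_MODES:
                raise ConfigError(f"release_modes: {m!r} not in {_RELEASE_MODES}")
        for c in self.cases:
            if c not in CASE_LABELS:
                raise ConfigError(f"cases: {c!r} is not a valid case label (A1...C3)")
        if self.release_window < 1:
            raise ConfigError("release_window: must be >= 1")
        if self.particles_per_cell is not None and self.particles_per_cell < 1:
            raise ConfigError("particles_per_cell: must be >= 1 when given")
        if self.dt <= 0 or self.total_time < self.dt:
            raise ConfigError("dt must be positive and total_time >= dt")
        if not 0 <= self.seed < 2**31:
            raise ConfigError("seed: must be a non-negative 31-bit integer")

    def sim_config(self, seed: int) -> pd_mod.SimConfig:
        return pd_mod.SimConfig(
            dt=self.dt,
            total_time=self.total_time,
            gravity=tuple(self.gravity),
            drag_cap_mode=self.drag_cap_mode,
            seed=seed,
        )

    def normalized(self) -> dict:
        d = asdict(self)
        d["release_modes"] = list(self.release_modes)
        d["cases"] = list(self.cases)
        d["gravity"] = list(self.gravity)
        d["calibration_targets"] = {k: float(v) for k, v in self.calibration_targets.items()}
        return d


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: Mapping) -> ExperimentConfig:
    known = set(ExperimentConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    for key in ("release_modes", "cases", "gravity"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    try:
        cfg = ExperimentConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    cfg.validate()
    return cfg


def dump_config(cfg: ExperimentConfig, path=None) -> str:
    """Serialize a config to normalized YAML (round-trips via load_config)."""
    text = yaml.safe_dump(cfg.normalized(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def _config_hash(cfg: ExperimentConfig) -> str:
    payload = json.dumps(cfg.normalized(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def _cell_seed(base_seed: int, case: str, mode: str) -> int:
    """Stable per-cell seed below 2^31, derived from the base seed."""
    digest = hashlib.sha256(f"{base_seed}:{case}:{mode}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _m1_boundary(net, base_sol, cfg: ExperimentConfig) -> hd.BoundarySpec:
    """Fixed-flow outlet boundary enforcing the physiological territory split.

    Territory totals follow the calibration targets; within each territory the
    prescribed outlet flows keep the base solution's relative shares.  One
    left-MCA outlet is kept as the pressure reference.
    """
    per_outlet, _ = hd.outlet_fractions(net, base_sol)
    targets = dict(cfg.calibration_targets)
    groups = {
        "ACA": (vs.Territory.ACA,),
        "MCA": (vs.Territory.MCA_L, vs.Territory.MCA_R),
        "POSTERIOR": (vs.Territory.POSTERIOR,),
        "MCA_L": (vs.Territory.MCA_L,),
        "MCA_R": (vs.Territory.MCA_R,),
        "PCA": (vs.Territory.POSTERIOR,),
    }
    total_q = base_sol.total_inflow
    flows: dict[str, float] = {}
    for gname, pct in targets.items():
        members = groups[gname]
        outlets = [s for s in net.terminal_segments if s.territory in members]
        base = {s.id: per_outlet[s.id] for s in outlets}
        base_sum = sum(base.values())
        for sid, share in base.items():
            w = share / base_sum if base_sum > 0 else 1.0 / len(base)
            flows[sid] = (pct / 100.0) * total_q * w
    reference = next(s.id for s in net.terminal_segments if s.territory is vs.Territory.MCA_L)
    return hd.BoundarySpec.fixed_flow(
        net, flows, reference_outlet=reference, inlet_velocity=cfg.inlet_velocity
    )


def _release_protocol(cfg: ExperimentConfig, mode: str, net) -> pd_mod.ReleaseProtocol:
    proto = pd_mod.ReleaseProtocol(mode=mode, window=cfg.release_window, speed=cfg.inlet_velocity)
    if cfg.particles_per_cell is not None:
        per_step = len(proto.resolved_sites(net))
        window = max(1, int(np.ceil(cfg.particles_per_cell / per_step)))
        proto = replace(proto, window=window)
    return proto


def run_experiment(cfg: ExperimentConfig, outdir=None) -> dict:
    """Execute the full pipeline for a config; returns the manifest dict.

    Writes network.json, flow_segments.csv, outlet_fractions.csv, per-cell
    particle summary (and optional trajectory) CSVs, aggregated metric
    tables, and manifest.json into the output directory.
    """
    cfg.validate()
    out = Path(outdir if outdir is not None else cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "config": cfg.normalized(),
        "seed": cfg.seed,
        "network_schema_version": vs.SCHEMA_VERSION,
        "stages": {},
    }
    stage = "generate"
    try:
        t0 = time.perf_counter()
        spec = vs.CoWVariantSpec(cfg.variant, cfg.diameter_scale, cfg.seed)
        net = vs.generate_cow(spec)
        if cfg.inlet_extension > 0:
            net = vs.extend_inlets(net, cfg.inlet_extension)
        log.info("generate: %s (%d segments) in %.2fs", net.name, len(net.segments), time.perf_counter() - t0)
        manifest["stages"][stage] = "ok"

        stage = "calibrate"
        t0 = time.perf_counter()
        fluid = hd.FluidProperties()
        cal = vs.calibrate_terminals(
            net,
            fluid,
            target_fractions=cfg.calibration_targets,
            tol=cfg.calibration_tol,
        )
        net = cal.network
        log.info(
            "calibrate: %d iterations, achieved %s in %.2fs",
            cal.iterations,
            {k: round(v, 2) for k, v in cal.achieved.items()},
            time.perf_counter() - t0,
        )
        manifest["stages"][stage] = "ok"
        manifest["calibration_achieved"] = cal.achieved

        stage = "solve"
        t0 = time.perf_counter()
        bc = hd.BoundarySpec.default(net, cfg.inlet_velocity)
        sol = hd.solve_flow(net, fluid, bc)
        if cfg.boundary_mode == "m1":
            bc = _m1_boundary(net, sol, cfg)
            sol = hd.solve_flow(net, fluid, bc)
        vs.write_network(net, out / "network.json")
        hd.flow_to_frame(net, sol).to_csv(out / "flow_segments.csv", index=False)
        hd.fractions_to_frame(net, sol).to_csv(out / "outlet_fractions.csv", index=False)
        log.info("solve: boundary=%s in %.2fs", cfg.boundary_mode, time.perf_counter() - t0)
        manifest["stages"][stage] = "ok"

        stage = "track"
        records_by_cell: dict[tuple[str, str], list] = {}
        for case in cfg.cases:
            for mode in cfg.release_modes:
                t0 = time.perf_counter()
                cell_seed = _cell_seed(cfg.seed, case, mode)
                sim = cfg.sim_config(cell_seed)
                proto = _release_protocol(cfg, mode, net)
                records = pd_mod.run(
                    net, sol, pd_mod.case_spec(case), proto, sim, fluid, case=case
                )
                records_by_cell[(case, mode)] = records
                pd_mod.records_to_summary_frame(records).to_csv(
                    out / f"particles_{case}_{mode}.csv", index=False
                )
                if cfg.write_trajectories:
                    pd_mod.records_to_trajectory_frame(records).to_csv(
                        out / f"trajectories_{case}_{mode}.csv", index=False
                    )
                n_exit = sum(r.exited for r in records)
                log.info(
                    "track %s/%s: %d released, %d exited in %.2fs",
                    case, mode, len(records), n_exit, time.perf_counter() - t0,
                )
        manifest["stages"][stage] = "ok"

        stage = "metrics"
        t0 = time.perf_counter()
        tables = mt.case_report(records_by_cell, net)
        for name, frame in tables.items():
            frame.to_csv(out / f"metrics_{name}.csv", index=False)
        log.info("metrics: %d tables in %.2fs", len(tables), time.perf_counter() - t0)
        manifest["stages"][stage] = "ok"
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
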