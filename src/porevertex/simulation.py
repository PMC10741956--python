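"""Simulation driver: initialization, the per-step loop, scenario presets
and snapshot I/O.

A run starts from a single relaxed hexagonal cell at the channel
entrance and repeats, per explicit-Euler step: node forces -> threshold
overdamped motion with wall slip -> stochastic division trials (shear
modulated if the flow coupling is on) -> intercalation scan -> periodic
measurements.  A run ends when the tissue covers the configured fraction
of the pore area (the fill criterion) or at ``t_end``.

The four scenario presets share the reference parameter set and the
pore extent 0 <= x <= 120, h = 4.5:

========================  ========  ==============
name                      epsilon   shear coupling
========================  ========  ==============
``straight-uniform``      0.0       off
``wavy-uniform``          0.2       off
``straight-shear``        0.0       on
``wavy-shear``            0.2       on
========================  ========  ==============

The wavy presets use K = 1/6 and phase = -pi/2, so the channel starts at
a bottleneck: ``|y| <= 4.5 (1 + 0.2 sin(x/6 - pi/2))``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import sys
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import _kernels
from ._flat import compile_mesh
from .events import (
    EventParams,
    collapse_short_edges,
    divide_cell,
    find_intercalation_candidates,
    perform_t1,
    resonant_stress,
)
from .flowfield import FlowConfig, StressField, stress_at_points
from .geometry import ChannelGeometry, TissueMesh, regular_hexagon
from .measurements import (
    TimeSeriesRecord,
    ensemble_average,
    ensemble_stats,
    records_to_frame,
    stats_from_arrays,
)
from .mechanics import MechParams

__all__ = [
    "SimConfig",
    "Trajectory",
    "ScenarioResult",
    "SCENARIOS",
    "init_single_cell",
    "init_hex_patch",
    "run_simulation",
    "make_scenario_config",
    "run_scenario",
    "write_snapshot",
    "read_snapshot",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Complete run configuration (geometry, mechanics, events, flow, run)."""

    geom: ChannelGeometry = field(default_factory=ChannelGeometry)
    mech: MechParams = field(default_factory=MechParams)
    events: EventParams = field(default_factory=EventParams)
    flow: FlowConfig | None = None
    enable_shear_coupling: bool = False
    cell_diameter: float = 2.0
    t_end: float = 4000.0
    output_interval: float = 1.0
    stop_on_fill: bool = True
    fill_fraction: float = 0.98

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.flow is not None:
            d["flow"].pop("geom", None)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class Trajectory:
    """Result of one seeded run: time series, fill time and final mesh."""

    seed: int
    records: list[TimeSeriesRecord]
    fill_time: float | None
    mesh: TissueMesh
    config: SimConfig

    @property
    def frame(self):
        return records_to_frame(self.records)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_single_cell(geom: ChannelGeometry, a: float = 2.0, rng=None) -> TissueMesh:
    """One relaxed hexagon of diameter ``a`` seeded at the pore entrance.

    The centroid sits at ``(x_min + a, 0)`` on the channel axis.  The
    channel must be wide enough for the cell everywhere
    (``2 h (1 - eps) > a``).
    """
    if 2.0 * geom.h * (1.0 - geom.epsilon) <= a:
        raise ValueError("channel too narrow for the seed cell")
    mesh = TissueMesh()
    pts = regular_hexagon(a, center=(geom.x_min + a, 0.0))
    ids = [mesh.add_vertex(p) for p in pts]
    mesh.add_cell(ids)
    return mesh


def init_hex_patch(rows: int, cols: int, a: float = 2.0) -> TissueMesh:
    """Conformal honeycomb of ``rows x cols`` relaxed hexagons (test fixture).

    Every cell is a regular reference hexagon, so the patch carries zero
    elastic energy and all interior vertices are force-free.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    r = 0.5 * a
    mesh = TissueMesh()
    seen: dict[tuple[int, int], int] = {}

    def vertex_at(x, y):
        key = (round(x * 1e8), round(y * 1e8))
        if key not in seen:
            seen[key] = mesh.add_vertex((x, y))
        return seen[key]

    for col in range(cols):
        for row in range(rows):
            cx = 1.5 * r * col
            cy = math.sqrt(3.0) * r * row + (col % 2) * math.sqrt(3.0) * r / 2.0
            pts = regular_hexagon(a, center=(cx, cy))
            mesh.add_cell([vertex_at(x, y) for x, y in pts])
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# the main loop
# ---------------------------------------------------------------------------

def run_simulation(config: SimConfig, seed: int = 0,
                   progress: bool = False) -> Trajectory:
    """Run one seeded realization of the growth process.

    Fully reproducible: the same config and seed give bit-identical time
    series.  Raises ``RuntimeError`` on numerical blow-up (total energy
    exceeding 1e6 times its initial scale) or on a broken mesh invariant.
    """
    geom, mech, ev = config.geom, config.mech, config.events
    rng = np.random.default_rng(seed)
    mesh = init_single_cell(geom, config.cell_diameter)

    stress_field = None
    if config.enable_shear_coupling:
        flow = config.flow or FlowConfig(geom=geom, u0=1.0)
        if flow.geom is not geom:
            flow = replace(flow, geom=geom)
        stress_field = StressField(flow, tau_res=resonant_stress(ev.delta))

    tau_res = resonant_stress(ev.delta)
    fill_target = config.fill_fraction * geom.area()
    records = [ensemble_stats(mesh, mech, 0.0)]
    energy_scale = max(1.0, records[0].E1 * records[0].N)

    t = 0.0
    next_out = config.output_interval
    fill_time = None
    step = 0
    gate_area = ev.m * mech.A0
    t1_age: dict[tuple[int, int], float] = {}

    q_pow = ev.q ** (np.arange(64.0) - 6.0)  # q^(n-6) lookup by side count
    # the static stress field varies over the channel scale h, while a
    # centroid moves < 1e-2 per step: re-sample only every few steps
    tau_cache: tuple[int, int, np.ndarray] | None = None
    STRESS_REFRESH = 10

    while t < config.t_end - 1e-12:
        flat = compile_mesh(mesh)
        pos = mesh.positions
        dt_eff, L, A, cx, cy, el = _kernels.step_all(
            pos, mesh.wall_mask,
            flat.corner_cell, flat.corner_vert, flat.next_vert, flat.prev_vert,
            flat.edge_a, flat.edge_b, flat.n_cells,
            mech.mu, mech.eta, mech.L0, mech.A0,
            mech.k, mech.F0, mech.threshold_on_magnitude,
            mech.dt, 0.1, ev.l_merge,
            geom.h, geom.epsilon, geom.wavenumber, geom.phase,
            geom.x_min, geom.x_max, geom.closed_ends,
        )
        if dt_eff < 0.0:  # inverted sliver: repair and retry the step
            flipped = mesh.repair_orientation()
            log.warning("re-oriented %d inverted cell(s) at t=%.2f", flipped, t)
            if not flipped:
                raise RuntimeError(f"degenerate cell at t={t:.2f}")
            continue
        t += dt_eff
        step += 1

        # --- division trials (rate ev.trials_per_unit_time per cell) ---
        p = ev.P0 * (A > gate_area) * q_pow[np.minimum(flat.cell_len, 63)]
        if stress_field is not None:
            if (tau_cache is None or tau_cache[0] != mesh.topology_version
                    or step - tau_cache[1] >= STRESS_REFRESH):
                tau = stress_at_points(cx, cy, stress_field)
                tau_cache = (mesh.topology_version, step, tau)
            else:
                tau = tau_cache[2]
            p = p / ((1.0 - tau ** 2) ** 2 + ev.delta * tau ** 2)
        p = np.minimum(p * ev.trials_per_unit_time * dt_eff, 1.0)
        hits = np.nonzero(rng.random(flat.n_cells) < p)[0]
        edited = False
        for idx in hits:
            if divide_cell(mesh, int(flat.cell_ids[idx]), rng) is not None:
                edited = True

        # --- intercalation scan (cooldown-gated) ---
        short = (el < ev.l0) & (flat.edge_count == 2)
        if short.any():
            ready = [
                (int(a), int(b))
                for a, b in zip(flat.edge_a[short], flat.edge_b[short])
                if t - t1_age.get((int(a), int(b)), -np.inf) >= ev.t1_cooldown
            ]
            if ready and not edited:
                touched: set[int] = set()
                cands = set(find_intercalation_candidates(mesh, ev.l0))
                for key in ready:
                    t1_age[key] = t  # cooldown applies to failures too
                    if key not in cands:
                        continue
                    cids = mesh.edge_map().get(key)
                    if cids is None or touched.intersection(cids):
                        continue
                    if perform_t1(mesh, key, ev.extrusion_factor, geom):
                        touched.update(cids)
                        edited = True
            elif ready:
                # divisions already changed the topology this step; the
                # edges stay eligible and are revisited next step
                pass

        # degenerate edges that cannot intercalate are merged away
        if np.min(el, initial=np.inf) < ev.l_merge:
            if collapse_short_edges(mesh, ev.l_merge, geom):
                edited = True

        if edited:
            mesh.validate_fast()

        # --- measurements ---
        if t >= next_out - 1e-9:
            if int(next_out) % 10 == 0:
                mesh.validate()
            flat3 = compile_mesh(mesh)
            L3, A3, _, _, _ = _kernels.geometry_pass(
                mesh.positions, flat3.corner_cell, flat3.corner_vert,
                flat3.next_vert, flat3.n_cells,
            )
            rec = stats_from_arrays(next_out, L3, A3, flat3.cell_len, mech)
            records.append(rec)
            total_energy = rec.E1 * rec.N
            if total_energy > 1e6 * energy_scale:
                raise RuntimeError(
                    f"energy blow-up at t={t:.2f}: E={total_energy:.3e}"
                )
            tissue_area = rec.A1 * mech.A0 * rec.N
            if progress and int(next_out) % 100 == 0:
                print(
                    f"  t={next_out:7.1f}  N={rec.N:5d}  E1={rec.E1:8.3f} "
                    f" fill={tissue_area / fill_target * config.fill_fraction:6.3f}",
                    file=sys.stderr,
                )
            if config.stop_on_fill and tissue_area >= fill_target:
                fill_time = next_out
                break
            next_out += config.output_interval

    return Trajectory(seed=seed, records=records, fill_time=fill_time,
                      mesh=mesh, config=config)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

SCENARIOS = {
    "straight-uniform": {"epsilon": 0.0, "shear": False},
    "wavy-uniform": {"epsilon": 0.2, "shear": False},
    "straight-shear": {"epsilon": 0.0, "shear": True},
    "wavy-shear": {"epsilon": 0.2, "shear": True},
}


def make_scenario_config(name: str, **overrides) -> SimConfig:
    """Build the :class:`SimConfig` of a named scenario preset."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    spec = SCENARIOS[name]
    geom = ChannelGeometry(
        h=4.5, epsilon=spec["epsilon"], wavenumber=1.0 / 6.0,
        phase=-math.pi / 2.0, x_min=0.0, x_max=120.0, closed_ends=True,
    )
    cfg = SimConfig(
        geom=geom,
        mech=MechParams.from_cell_diameter(2.0),
        events=EventParams(),
        flow=FlowConfig(geom=geom, u0=1.0) if spec["shear"] else None,
        enable_shear_coupling=spec["shear"],
    )
    return cfg.with_(**overrides) if overrides else cfg


@dataclass
class ScenarioResult:
    name: str
    trajectories: list[Trajectory]

    @property
    def fill_times(self) -> list[float | None]:
        return [tr.fill_time for tr in self.trajectories]

    def mean_frame(self):
        return ensemble_average([tr.frame for tr in self.trajectories])


def run_scenario(name: str, seeds=(1, 2, 3, 4, 5), outdir=None,
                 progress: bool = False, **overrides) -> ScenarioResult:
    """Run a preset for every seed; optionally write CSV/JSON outputs."""
    config = make_scenario_config(name, **overrides)
    trajectories = []
    for seed in seeds:
        log.info("scenario %s seed %s", name, seed)
        trajectories.append(run_simulation(config, seed=seed, progress=progress))
    result = ScenarioResult(name, trajectories)
    if outdir is not None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for tr in trajectories:
            tr.frame.to_csv(out / f"{name}-seed{tr.seed}.csv", index=False)
            write_snapshot(tr.mesh, out / f"{name}-seed{tr.seed}-final.json",
                           config=config, t=tr.records[-1].t)
        mean, std = result.mean_frame()
        mean.to_csv(out / f"{name}-ensemble-mean.csv", index=False)
        std.to_csv(out / f"{name}-ensemble-std.csv", index=False)
    return result


# ---------------------------------------------------------------------------
# snapshots
# ---------------------------------------------------------------------------

def write_snapshot(mesh: TissueMesh, path, config: SimConfig | None = None,
                   t: float = 0.0) -> None:
    """Serialize the mesh (and config provenance) to JSON."""
    doc = {
        "format": "porevertex-snapshot-1",
        "time": t,
        "config_hash": config.config_hash() if config is not None else None,
        "config": config.to_dict() if config is not None else None,
        "vertices": [
            [float(x), float(y), int(m)]
            for (x, y), m in zip(mesh.positions, mesh.wall_mask)
        ],
        "cells": [mesh.cells[c].vertex_ids for c in sorted(mesh.cells)],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_snapshot(path, check_overlap: bool = False) -> tuple[TissueMesh, dict]:
    """Load a snapshot; validates mesh conformity before returning.

    Returns ``(mesh, metadata)`` where metadata holds the stored time,
    config dict and config hash.  Malformed documents raise ``ValueError``
    with context; a non-conformal mesh raises ``MeshConformityError``.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed snapshot {path}: {exc}") from exc
    if doc.get("format") != "porevertex-snapshot-1":
        raise ValueError(f"{path}: not a porevertex snapshot")
    mesh = TissueMesh()
    for entry in doc["vertices"]:
        x, y, m = entry
        mesh.add_vertex((x, y), int(m))
    for ring in doc["cells"]:
        mesh.add_cell(ring)
    mesh.validate(check_overlap=check_overlap)
    meta = {"time": doc.get("time"), "config": doc.get("config"),
            "config_hash": doc.get("config_hash")}
    return mesh, meta
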