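"""Config-driven simulation building and ready-made scenarios.

A simulation is described by a plain nested-dict configuration (YAML on
disk). :func:`build_scenario` expands a scenario name into a complete
configuration; :func:`build_simulation` turns any configuration into a
runnable :class:`~cellflow.engine.Simulation`.

Scenarios
---------
``poiseuille``
    Empty body-force-driven channel (4 x 24 x 4 nodes, walls two nodes thick
    on each y side, 20 fluid nodes across). Validates the fluid solver
    against the parabolic profile ``u(y) = g y (H - y) / (2 nu)``.
``stretch``
    One spherical cell in still fluid with equal and opposite forces pulled
    at the two x-extremal node caps -- the topology of the classic cell
    stretching experiment. With the forces released the cell recovers its
    relaxed diameter.
``bifurcation_demo``
    Miniature periodic Y-channel (60 x 30 x 16 nodes) split by a rhomboid
    divider into two daughter branches of slightly unequal width, with two
    oblate elastic cells advected through it. A desk-scale version of the
    microfluidic bifurcation geometry; fluid parameters follow the
    micrometre/microsecond scaling (kinematic viscosity 1.5, density 1).
"""

from __future__ import annotations

import copy

import numpy as np
import yaml

from .cells import (
    CellType,
    create_cell_type,
    instantiate_cell,
    seed_cells_random,
    suggest_coupling_gamma,
)
from .coupling import CouplingParams
from .elastic import ElasticCoefficients
from .engine import Simulation, SimulationConfig
from .errors import ConfigError
from .fluid import Cylinder, FluidLattice, Rhomboid, WallPlane
from .interactions import MembraneCollisionParams, SoftSphereParams
from .mesh import generate_icosphere

__all__ = [
    "SCENARIOS",
    "build_scenario",
    "build_simulation",
    "load_config",
    "save_config",
]

# Red-blood-cell-scale elastic coefficients (lattice units).
RBC_COEFFS = {"ks": 0.005, "kb": 0.02, "kal": 0.007, "kag": 0.7, "kv": 0.9}


def _poiseuille() -> dict:
    return {
        "name": "poiseuille",
        "box": [4, 24, 4],
        "fluid": {
            # tau = 1 keeps the bounce-back wall error minimal
            "viscosity": 1.0 / 6.0,
            "density": 1.0,
            "spacing": 1.0,
            "body_force": [1e-4, 0.0, 0.0],
        },
        "md": {"dt": 1.0, "substep_ratio": 1, "seed": 0},
        "boundaries": [
            {"kind": "wall", "normal": [0, 1, 0], "offset": 1.5},
            {"kind": "wall", "normal": [0, -1, 0], "offset": -21.5},
        ],
        "cell_types": {},
        "cells": [],
        "run": {"steps": 6000, "output_every": 1000},
    }


def _stretch() -> dict:
    return {
        "name": "stretch",
        "box": [16, 16, 16],
        "fluid": {"viscosity": 1.5, "density": 1.0, "spacing": 1.0,
                  "body_force": [0.0, 0.0, 0.0]},
        "md": {"dt": 0.1, "substep_ratio": 1, "seed": 0},
        "boundaries": [],
        "cell_types": {
            "sphere": {
                "icosphere": {"subdivisions": 2, "radius": 3.91},
                "resize": [1.0, 1.0, 1.0],
                "mass": 1.0,
                **RBC_COEFFS,
            }
        },
        "cells": [{"type": "sphere", "origin": [8.0, 8.0, 8.0],
                   "rotation": [0.0, 0.0, 0.0]}],
        # low gamma: the coupling only damps this no-flow relaxation
        # experiment, and the elastic steady state is reached sooner
        "coupling": {"gamma": 0.3},
        "external": {"kind": "polar_stretch", "cell": 0, "axis": 0,
                     "force": 0.005, "fraction": 0.1},
        "run": {"steps": 10000, "output_every": 500},
    }


def _bifurcation_demo() -> dict:
    return {
        "name": "bifurcation_demo",
        "box": [60, 30, 16],
        "fluid": {"viscosity": 1.5, "density": 1.0, "spacing": 1.0,
                  "body_force": [2e-4, 0.0, 0.0],
                  "initial_velocity": [0.005, 0.0, 0.0]},
        "md": {"dt": 0.1, "substep_ratio": 1, "seed": 0},
        "boundaries": [
            {"kind": "wall", "normal": [0, 1, 0], "offset": 1.5},
            {"kind": "wall", "normal": [0, -1, 0], "offset": -28.5},
            {"kind": "wall", "normal": [0, 0, 1], "offset": 1.5},
            {"kind": "wall", "normal": [0, 0, -1], "offset": -14.5},
            # divider splitting the channel into two daughter branches
            {"kind": "rhomboid", "corner": [22.0, 12.0, 0.0],
             "a": [20.0, 0.0, 0.0], "b": [0.0, 5.0, 0.0], "c": [0.0, 0.0, 16.0]},
        ],
        "cell_types": {
            "rbc": {
                "icosphere": {"subdivisions": 2, "radius": 3.91},
                "resize": [1.0, 1.0, 0.4],
                "mass": 1.0,
                **RBC_COEFFS,
            }
        },
        "cells": [
            {"type": "rbc", "origin": [10.0, 8.0, 8.0], "rotation": [0.0, 0.0, 0.0]},
            {"type": "rbc", "origin": [10.0, 21.0, 8.0], "rotation": [0.0, 0.0, 0.0]},
        ],
        "coupling": {"gamma": "auto"},
        "interactions": {
            "wall": {"a": 0.002, "n": 2.0, "d_cut": 1.0},
            "cell_cell": {"a": 0.01, "n": 2.0, "d_cut": 1.0},
        },
        "run": {"steps": 400, "output_every": 50},
    }


SCENARIOS = {
    "poiseuille": _poiseuille,
    "stretch": _stretch,
    "bifurcation_demo": _bifurcation_demo,
}


def build_scenario(name: str, **overrides) -> dict:
    """Expand a scenario name into a complete configuration dict."""
    if name not in SCENARIOS:
        raise ConfigError(
            f"unknown scenario '{name}'; available: {sorted(SCENARIOS)}"
        )
    cfg = SCENARIOS[name]()
    cfg.update(copy.deepcopy(overrides))
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# building


def _build_boundary(spec: dict):
    kind = spec.get("kind")
    if kind == "wall":
        return WallPlane(spec["normal"], spec["offset"])
    if kind == "rhomboid":
        return Rhomboid(spec["corner"], spec["a"], spec["b"], spec["c"])
    if kind == "cylinder":
        return Cylinder(spec["center"], spec["axis"], spec["radius"],
                        spec.get("half_length"))
    raise ConfigError(f"unknown boundary kind '{kind}'")


def _build_cell_type(spec: dict) -> CellType:
    coeffs = ElasticCoefficients(
        ks=spec.get("ks", 0.0), kb=spec.get("kb", 0.0), kal=spec.get("kal", 0.0),
        kag=spec.get("kag", 0.0), kv=spec.get("kv", 0.0),
    )
    resize = spec.get("resize", [1.0, 1.0, 1.0])
    mass = spec.get("mass", 1.0)
    if "icosphere" in spec:
        ic = spec["icosphere"]
        pos, faces = generate_icosphere(ic.get("subdivisions", 2),
                                        ic.get("radius", 1.0))
        return CellType.from_arrays(pos, faces, coeffs, resize, mass)
    if "nodes" in spec and "triangles" in spec:
        return create_cell_type(spec["nodes"], spec["triangles"], resize,
                                coeffs, mass, spec.get("index_base", 0))
    raise ConfigError("cell type needs either 'icosphere' or 'nodes'+'triangles'")


def _polar_caps(cell, axis: int, fraction: float):
    """Node index sets of the two axis-extremal caps (ceil(fraction*N) each)."""
    coord = cell.mesh.positions[:, axis]
    k = max(1, int(np.ceil(fraction * cell.n_nodes)))
    order = np.argsort(coord)
    return order[-k:], order[:k]


def apply_polar_stretch(cell, axis: int, total_force: float,
                        fraction: float = 0.1) -> None:
    """Attach equal-and-opposite external pulls at the two polar node caps."""
    hi, lo = _polar_caps(cell, axis, fraction)
    ext = np.zeros_like(cell.mesh.positions)
    ext[hi, axis] = total_force / len(hi)
    ext[lo, axis] = -total_force / len(lo)
    cell.external_forces = ext


def build_simulation(cfg: dict) -> Simulation:
    """Construct a runnable :class:`Simulation` from a configuration dict."""
    box = [float(b) for b in cfg["box"]]
    fluid_cfg = cfg.get("fluid", {})
    spacing = float(fluid_cfg.get("spacing", 1.0))
    md = cfg.get("md", {})
    dt_md = float(md.get("dt", 1.0))
    sub = int(md.get("substep_ratio", 1))
    shape = [int(round(b / spacing)) for b in box]
    lattice = FluidLattice(
        shape, spacing=spacing, dt=dt_md / sub,
        viscosity=float(fluid_cfg.get("viscosity", 1.0 / 6.0)),
        density=float(fluid_cfg.get("density", 1.0)),
    )
    lattice.body_force = np.asarray(
        fluid_cfg.get("body_force", [0.0, 0.0, 0.0]), dtype=float
    )
    if "initial_velocity" in fluid_cfg:
        lattice.set_equilibrium(fluid_cfg["initial_velocity"])
    boundaries = [_build_boundary(b) for b in cfg.get("boundaries", [])]
    for b in boundaries:
        lattice.add_boundary(b)

    types = {name: _build_cell_type(spec)
             for name, spec in cfg.get("cell_types", {}).items()}
    cells = []
    offset = 0
    for k, spec in enumerate(cfg.get("cells", [])):
        ct = types[spec["type"]]
        cells.append(instantiate_cell(
            ct, origin=spec.get("origin", (0, 0, 0)),
            rotation=spec.get("rotation", (0, 0, 0)),
            particle_id_offset=offset, label=spec.get("label", f"cell{k}"),
        ))
        offset += ct.template_mesh.n_points
    for spec in cfg.get("seed_cells", []):
        ct = types[spec["type"]]
        region = (spec.get("region_lo", (0, 0, 0)),
                  spec.get("region_hi", box))
        seeded = seed_cells_random(
            region, ct, int(spec["n"]), float(spec.get("min_gap", 0.0)),
            rng_seed=int(spec.get("rng_seed", md.get("seed", 0))),
            max_attempts=int(spec.get("max_attempts", 10000)),
        )
        for cell in seeded:
            cell.particle_id_offset = offset
            offset += ct.template_mesh.n_points
        cells.extend(seeded)

    coupling = None
    if "coupling" in cfg and cells:
        gamma = cfg["coupling"].get("gamma", "auto")
        if gamma == "auto":
            gamma = suggest_coupling_gamma(
                cells[0], lattice.viscosity * lattice.density, spacing
            )
        coupling = CouplingParams(float(gamma))

    inter = cfg.get("interactions", {})
    wall_params = (SoftSphereParams(**inter["wall"]) if "wall" in inter else None)
    cc_params = (MembraneCollisionParams(**inter["cell_cell"])
                 if "cell_cell" in inter else None)
    self_cfg = inter.get("self_cell")
    self_params = None
    self_depth = 2
    if self_cfg:
        self_depth = int(self_cfg.pop("exclusion_depth", 2))
        self_params = SoftSphereParams(**self_cfg)

    sim = Simulation(
        config=SimulationConfig(
            box=tuple(box), dt=dt_md, lbm_substep_ratio=sub,
            rng_seed=int(md.get("seed", 0)),
            output_every=int(cfg.get("run", {}).get("output_every", 100)),
        ),
        lattice=lattice, cells=cells, boundaries=boundaries,
        coupling=coupling, wall_params=wall_params, cell_cell_params=cc_params,
        self_params=self_params, self_exclusion_depth=self_depth,
    )

    ext = cfg.get("external")
    if ext:
        if ext.get("kind") != "polar_stretch":
            raise ConfigError(f"unknown external force kind '{ext.get('kind')}'")
        apply_polar_stretch(sim.cells[int(ext.get("cell", 0))],
                            int(ext.get("axis", 0)), float(ext["force"]),
                            float(ext.get("fraction", 0.1)))
    return sim
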