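"""YAML run configuration: parsing, validation, defaults, and run manifests.

A run is described by a small YAML document::

    grid:    {width_cm: 4.0, height_cm: 4.0, dx_cm: 0.05, dy_cm: 0.05}
    medium:
      n_m: 1.4
      background: {mu_a: 0.5, mu_s: 50.0, g: 0.8}
      regions:
        - {shape: annulus, cx_cm: 2.0, cy_cm: 2.0, inner_d_cm: 2.8,
           outer_d_cm: 3.0, mu_a: 0.02, mu_s: 1.0, g: 0.0}
    quadrature: {M: 16}
    solver:  {alpha: 0.5, rho: 1.1, tol: 1.0e-8, dt_s: 1.0e-13}
    source:  {kind: cw, side: bottom, offset_cm: 2.0,
              amplitude_mW_cm2_sr: 20.0}
    detectors:
      - {side: top, count: 18, aperture_deg: 45.0}

Unspecified solver/quadrature keys fall back to the validated defaults
(alpha 0.5, rho 1.1, tol 1e-8, dt 1e-13 s, M 16).  Unknown keys raise with
the offending name; property violations list every failing key.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .boundary import ConfigurationError, DetectorSpec, SIDES, uniform_detectors
from .medium import (GeometryError, InvalidPropertyError, MediumMap,
                     OpticalProperties, build_grid)
from .solver import SolverConfig, TransportProblem
from .sources import Source

#: settings stated by the validated study configuration; the manifest flags
#: any resolved value that differs from these.
REFERENCE_DEFAULTS = {"alpha": 0.5, "rho": 1.1, "tol": 1e-8, "dt": 1e-13,
                      "M": 16, "aperture_deg": 45.0,
                      "cw_amplitude": 0.020, "pulse_amplitude": 0.200,
                      "pulse_duration_s": 100e-15}

_TOP_KEYS = {"grid", "medium", "quadrature", "solver", "source", "sources",
             "detectors", "name"}
_GRID_KEYS = {"width_cm", "height_cm", "dx_cm", "dy_cm"}
_MEDIUM_KEYS = {"n_m", "n_0", "background", "regions"}
_PROP_KEYS = {"mu_a", "mu_s", "g"}
_REGION_KEYS = {"shape", "cx_cm", "cy_cm", "inner_d_cm", "outer_d_cm",
                "x0_cm", "y0_cm", "x1_cm", "y1_cm", "diameter_cm"} | _PROP_KEYS
_SOLVER_KEYS = {"alpha", "rho", "tol", "dt_s", "max_inner_iters",
                "max_time_steps"}
_SOURCE_KEYS = {"kind", "side", "offset_cm", "amplitude_mW_cm2_sr",
                "duration_fs"}
_DET_KEYS = {"side", "count", "positions_cm", "aperture_deg"}


class ConfigError(ValueError):
    """A configuration document failed validation."""


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}; "
                          f"allowed: {sorted(allowed)}")


def _props(block: dict, where: str) -> OpticalProperties:
    missing = {"mu_a", "mu_s"} - set(block)
    if missing:
        raise ConfigError(f"missing {sorted(missing)} in {where}")
    try:
        return OpticalProperties(mu_a=float(block["mu_a"]),
                                 mu_s=float(block["mu_s"]),
                                 g=float(block.get("g", 0.0)))
    except InvalidPropertyError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def build_medium(cfg: dict) -> MediumMap:
    """MediumMap from the grid and medium blocks of a config dict."""
    if "grid" not in cfg:
        raise ConfigError("missing required block 'grid'")
    if "medium" not in cfg:
        raise ConfigError("missing required block 'medium'")
    gblock = cfg["grid"]
    _check_keys(gblock, _GRID_KEYS, "grid")
    missing = _GRID_KEYS - set(gblock)
    if missing:
        raise ConfigError(f"missing {sorted(missing)} in grid")
    try:
        grid = build_grid(float(gblock["width_cm"]), float(gblock["height_cm"]),
                          float(gblock["dx_cm"]), float(gblock["dy_cm"]))
    except GeometryError as exc:
        raise ConfigError(f"grid: {exc}") from exc
    mblock = cfg["medium"]
    _check_keys(mblock, _MEDIUM_KEYS, "medium")
    if "background" not in mblock:
        raise ConfigError("missing 'background' in medium")
    medium = MediumMap.homogeneous(grid, _props(mblock["background"],
                                                "medium.background"),
                                   n_m=float(mblock.get("n_m", 1.0)),
                                   n_0=float(mblock.get("n_0", 1.0)))
    for k, region in enumerate(mblock.get("regions", []) or []):
        where = f"medium.regions[{k}]"
        _check_keys(region, _REGION_KEYS, where)
        props = _props(region, where)
        shape = region.get("shape")
        if shape == "annulus":
            medium.set_annulus(float(region["cx_cm"]), float(region["cy_cm"]),
                               float(region["inner_d_cm"]),
                               float(region["outer_d_cm"]), props)
        elif shape == "disk":
            medium.set_disk(float(region["cx_cm"]), float(region["cy_cm"]),
                            float(region["diameter_cm"]), props)
        elif shape == "rectangle":
            medium.set_rectangle(float(region["x0_cm"]), float(region["y0_cm"]),
                                 float(region["x1_cm"]), float(region["y1_cm"]),
                                 props)
        else:
            raise ConfigError(f"{where}: shape must be annulus|disk|rectangle, "
                              f"got {shape!r}")
    return medium


def build_sources(cfg: dict) -> list[Source]:
    blocks = cfg.get("sources")
    if blocks is None:
        blocks = [cfg["source"]] if "source" in cfg else []
    if not blocks:
        raise ConfigError("missing 'source' (or 'sources') block")
    out = []
    for k, b in enumerate(blocks):
        where = f"source[{k}]"
        _check_keys(b, _SOURCE_KEYS, where)
        kind = b.get("kind", "cw")
        amp_mw = float(b.get("amplitude_mW_cm2_sr",
                             20.0 if kind == "cw" else 200.0))
        try:
            if kind == "cw":
                out.append(Source(kind="cw", side=b.get("side", "bottom"),
                                  offset_cm=float(b["offset_cm"]),
                                  amplitude=amp_mw * 1e-3))
            elif kind == "pulse":
                dur = float(b.get("duration_fs", 100.0)) * 1e-15
                out.append(Source(kind="pulse", side=b.get("side", "bottom"),
                                  offset_cm=float(b["offset_cm"]),
                                  amplitude=amp_mw * 1e-3, duration_s=dur))
            else:
                raise ConfigError(f"{where}: kind must be cw|pulse, got {kind!r}")
        except (ConfigurationError, KeyError) as exc:
            raise ConfigError(f"{where}: {exc}") from exc
    return out


def build_detectors(cfg: dict, medium: MediumMap) -> list[DetectorSpec]:
    out: list[DetectorSpec] = []
    for k, b in enumerate(cfg.get("detectors", []) or []):
        where = f"detectors[{k}]"
        _check_keys(b, _DET_KEYS, where)
        side = b.get("side")
        if side not in SIDES:
            raise ConfigError(f"{where}: side must be one of {SIDES}, got {side!r}")
        ap = float(b.get("aperture_deg", 45.0))
        if "positions_cm" in b:
            for p in b["positions_cm"]:
                out.append(DetectorSpec(side=side, position_cm=float(p),
                                        aperture_deg=ap,
                                        name=f"{side}_{len(out)}"))
        else:
            out.extend(uniform_detectors(side, medium.grid,
                                         int(b.get("count", 18)), ap))
    return out


def build_solver_config(cfg: dict) -> SolverConfig:
    b = cfg.get("solver", {}) or {}
    _check_keys(b, _SOLVER_KEYS, "solver")
    kwargs = {}
    if "alpha" in b:
        kwargs["alpha"] = float(b["alpha"])
    if "rho" in b:
        kwargs["rho"] = float(b["rho"])
    if "tol" in b:
        kwargs["tol"] = float(b["tol"])
    if "dt_s" in b:
        kwargs["dt"] = float(b["dt_s"])
    if "max_inner_iters" in b:
        kwargs["max_inner_iters"] = int(b["max_inner_iters"])
    if "max_time_steps" in b:
        kwargs["max_time_steps"] = int(b["max_time_steps"])
    try:
        return SolverConfig(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"solver: {exc}") from exc


def build_problem(cfg: dict) -> TransportProblem:
    _check_keys(cfg, _TOP_KEYS, "top level")
    qb = cfg.get("quadrature", {}) or {}
    _check_keys(qb, {"M"}, "quadrature")
    medium = build_medium(cfg)
    return TransportProblem(medium=medium, ordinates=int(qb.get("M", 16)),
                            sources=build_sources(cfg),
                            detectors=build_detectors(cfg, medium),
                            config=build_solver_config(cfg))


def load_config(path) -> TransportProblem:
    """Parse and validate a YAML run description into a TransportProblem."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    return build_problem(cfg)


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Every resolved numeric setting of a run, serializable round-trip.

    ``deviations`` lists settings that differ from the reference defaults so
    a reader can see at a glance how a run departed from the validated
    configuration.
    """

    grid: dict
    n_m: float
    n_0: float
    M: int
    solver: dict
    sources: list
    detectors: list
    source_off_normal_deg: list
    seed: int | None = None
    mode: str = "steady"
    convergence: dict = field(default_factory=dict)
    deviations: list = field(default_factory=list)
    code_version: str = "0.1.0"

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "RunManifest":
        try:
            data = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path) as fh:
                data = json.load(fh)
        return cls(**data)


def make_manifest(problem: TransportProblem, mode: str = "steady",
                  seed: int | None = None,
                  convergence: dict | None = None) -> RunManifest:
    grid = problem.medium.grid
    cfg = problem.config
    solver = {"alpha": cfg.alpha, "rho": cfg.rho, "tol": cfg.tol,
              "dt_s": cfg.dt, "max_inner_iters": cfg.max_inner_iters,
              "max_time_steps": cfg.max_time_steps, "c_cm_s": cfg.c}
    deviations = []
    for key, mine in (("alpha", cfg.alpha), ("rho", cfg.rho), ("tol", cfg.tol),
                      ("dt", cfg.dt), ("M", problem.ordinates.M)):
        ref = REFERENCE_DEFAULTS[key]
        if not np.isclose(mine, ref):
            deviations.append(f"{key} = {mine} (reference {ref})")
    return RunManifest(
        grid={"nx": grid.nx, "ny": grid.ny, "dx_cm": grid.dx, "dy_cm": grid.dy},
        n_m=problem.medium.n_m, n_0=problem.medium.n_0,
        M=problem.ordinates.M, solver=solver,
        sources=[dataclasses.asdict(s) for s in problem.sources],
        detectors=[dataclasses.asdict(d) for d in problem.detectors],
        source_off_normal_deg=[inj.off_normal_deg for inj in problem.injections],
        seed=seed, mode=mode, convergence=convergence or {},
        deviations=deviations)
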