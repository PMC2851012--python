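"""Programmatic study media.

The geometries follow the two study cases — a 4 cm x 4 cm medium containing
a water-filled void-like ring (inner diameter 2.8 cm, outer 3.0 cm, source at
the middle of the bottom side) and a rectangular rat-liver-like medium probed
at several wavelengths — plus two homogeneous media used by the validation
suite (a pure absorber for the Beer-Lambert limit and a forward-scattering
medium for the Monte Carlo cross-check).

All OPTICAL PROPERTY VALUES here are synthetic fixture defaults of plausible
magnitude, NOT literature measurements: the study's property values exist
only in figures.  Override them via the config to model a real tissue.
"""

from __future__ import annotations

import copy
import io

import pandas as pd

from .config import ConfigError, build_problem
from .medium import MediumMap
from .solver import TransportProblem

#: synthetic wavelength-indexed property table for the rat-liver-like medium
#: (columns: wavelength nm, mu_a cm^-1, mu_s cm^-1, g, n_m). Fixture values.
RAT_LIVER_TABLE_CSV = """\
lambda_nm,mu_a,mu_s,g,n_m
488,10.0,120.0,0.90,1.40
632.8,3.2,100.0,0.91,1.40
800,0.9,80.0,0.93,1.40
1064,0.5,60.0,0.93,1.40
1320,1.8,50.0,0.92,1.40
2100,12.0,40.0,0.90,1.40
"""


def rat_liver_table() -> pd.DataFrame:
    return pd.read_csv(io.StringIO(RAT_LIVER_TABLE_CSV))


_FIXTURES: dict[str, dict] = {
    # Ring phantom: 4 x 4 cm, annulus 2.8/3.0 cm, CW source at mid-bottom,
    # 16 detectors on the far (top) side.  Background and ring properties
    # are synthetic fixtures (ring = water-like: nearly transparent).
    "ring_phantom": {
        "name": "ring_phantom",
        "grid": {"width_cm": 4.0, "height_cm": 4.0, "dx_cm": 0.05,
                 "dy_cm": 0.05},
        "medium": {
            "n_m": 1.4,
            "background": {"mu_a": 0.5, "mu_s": 50.0, "g": 0.8},
            "regions": [
                {"shape": "annulus", "cx_cm": 2.0, "cy_cm": 2.0,
                 "inner_d_cm": 2.8, "outer_d_cm": 3.0,
                 "mu_a": 0.02, "mu_s": 1.0, "g": 0.0},
            ],
        },
        "quadrature": {"M": 16},
        "source": {"kind": "cw", "side": "bottom", "offset_cm": 2.0,
                   "amplitude_mW_cm2_sr": 20.0},
        "detectors": [{"side": "top", "count": 16, "aperture_deg": 45.0}],
    },
    # Rat-liver-like rectangle; per-wavelength properties come from
    # rat_liver_table() via expand_wavelengths().  18 detectors on the top
    # and left sides.  Liver-like media are strongly forward-peaked and
    # optically thick per cell, where diamond interpolation oscillates, so
    # this fixture uses the stabilized upwind closure.
    "rat_liver_like": {
        "name": "rat_liver_like",
        "grid": {"width_cm": 2.0, "height_cm": 2.0, "dx_cm": 0.04,
                 "dy_cm": 0.04},
        "solver": {"alpha": 1.0},
        "medium": {
            "n_m": 1.4,
            "background": {"mu_a": 0.9, "mu_s": 80.0, "g": 0.93},
        },
        "quadrature": {"M": 16},
        "source": {"kind": "cw", "side": "bottom", "offset_cm": 1.0,
                   "amplitude_mW_cm2_sr": 20.0},
        "detectors": [{"side": "top", "count": 18, "aperture_deg": 45.0},
                      {"side": "left", "count": 18, "aperture_deg": 45.0}],
    },
    # Pure absorber: Beer-Lambert validation medium (no scattering, matched
    # refractive index so the collimated beam decays as exp(-mu_a s)).
    "homogeneous_absorber": {
        "name": "homogeneous_absorber",
        "grid": {"width_cm": 2.0, "height_cm": 2.0, "dx_cm": 0.02,
                 "dy_cm": 0.02},
        "medium": {"n_m": 1.0,
                   "background": {"mu_a": 1.0, "mu_s": 0.0, "g": 0.0}},
        "quadrature": {"M": 16},
        "source": {"kind": "cw", "side": "bottom", "offset_cm": 0.7,
                   "amplitude_mW_cm2_sr": 20.0},
        "detectors": [{"side": "top", "count": 16, "aperture_deg": 45.0}],
    },
    # Forward-scattering homogeneous medium (mu_s' = 5 cm^-1, g = 0.9) used
    # by the Monte Carlo cross-validation.
    "homogeneous_scatterer": {
        "name": "homogeneous_scatterer",
        "grid": {"width_cm": 1.0, "height_cm": 1.0, "dx_cm": 0.04,
                 "dy_cm": 0.04},
        "medium": {"n_m": 1.4,
                   "background": {"mu_a": 0.5, "mu_s": 50.0, "g": 0.9}},
        "quadrature": {"M": 32},
        "source": {"kind": "cw", "side": "bottom", "offset_cm": 0.5,
                   "amplitude_mW_cm2_sr": 20.0},
        "detectors": [{"side": "top", "count": 5, "aperture_deg": 45.0}],
    },
}


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def fixture_config(name: str) -> dict:
    """Deep copy of a named fixture's config dict."""
    try:
        return copy.deepcopy(_FIXTURES[name])
    except KeyError:
        raise ConfigError(
            f"unknown fixture {name!r}; available: {fixture_names()}") from None


def make_fixture(name: str) -> tuple[dict, MediumMap]:
    """Named fixture as (config dict, MediumMap)."""
    cfg = fixture_config(name)
    problem = build_problem(cfg)
    return cfg, problem.medium


def make_fixture_problem(name: str, **overrides) -> TransportProblem:
    """Named fixture as a ready TransportProblem.

    ``overrides`` are merged into the top-level config blocks, e.g.
    ``solver={"tol": 1e-10}``.
    """
    cfg = fixture_config(name)
    for key, block in overrides.items():
        if isinstance(block, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(block)
        else:
            cfg[key] = block
    return build_problem(cfg)


def expand_wavelengths(base: dict | str = "rat_liver_like",
                       table: pd.DataFrame | None = None) -> dict[float, dict]:
    """Fan a base config out into one config per wavelength-table row."""
    cfg = fixture_config(base) if isinstance(base, str) else copy.deepcopy(base)
    table = rat_liver_table() if table is None else table
    out = {}
    for _, row in table.iterrows():
        c = copy.deepcopy(cfg)
        c["medium"]["n_m"] = float(row["n_m"])
        c["medium"]["background"] = {"mu_a": float(row["mu_a"]),
                                     "mu_s": float(row["mu_s"]),
                                     "g": float(row["g"])}
        c["name"] = f"{cfg.get('name', 'sweep')}_{row['lambda_nm']:g}nm"
        out[float(row["lambda_nm"])] = c
    return out
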