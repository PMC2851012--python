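"""Fresnel/Snell optics at the index-mismatched outer boundary.

The medium (refractive index ``n_m``) is surrounded by air (``n_0`` = 1
unless overridden).  Radiance leaving through a side is partly transmitted
and partly reflected back; the reflected part closes the boundary condition

    I(r_b, Omega, t) = S(r_b, Omega, t) + R * I(r_b, Omega_ref, t),  n.Omega < 0

where Omega_ref is Omega mirrored across the side's normal and R the
direction-dependent Fresnel reflectivity (R = 1 beyond the critical angle).

Detector readout integrates the transmitted radiance over the ordinates whose
angle to the outward normal is within the detector aperture AP (default 45
degrees, read as the half-angle of the acceptance cone).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .medium import Grid2D, MediumMap
from .quadrature import OrdinateSet, QuadratureError

SIDES = ("bottom", "top", "left", "right")

#: outward unit normal of each side
NORMALS = {"bottom": (0.0, -1.0), "top": (0.0, 1.0),
           "left": (-1.0, 0.0), "right": (1.0, 0.0)}


class TotalInternalReflectionError(ValueError):
    """Incidence at or beyond the critical angle: no transmitted ray exists."""


class ConfigurationError(ValueError):
    """A detector or source specification is unusable."""


def critical_angle(n_m: float, n_0: float = 1.0) -> float:
    """Critical angle for total internal reflection, sin(phi_cr) = n_0/n_m.

    For n_m < n_0 there is no total internal reflection; pi/2 is returned.
    """
    if n_m <= 0 or n_0 <= 0:
        raise ValueError("refractive indices must be positive")
    if n_m < n_0:
        return np.pi / 2.0
    return float(np.arcsin(n_0 / n_m))


def snell_transmission_angle(phi_ref: float, n_m: float, n_0: float = 1.0) -> float:
    """Transmission angle from n_m sin(phi_ref) = n_0 sin(phi_tra)."""
    if not 0 <= phi_ref < np.pi / 2:
        raise ValueError(f"phi_ref must be in [0, pi/2), got {phi_ref}")
    s = n_m * np.sin(phi_ref) / n_0
    if s > 1.0:
        raise TotalInternalReflectionError(
            f"phi_ref={phi_ref:.4f} rad exceeds the critical angle "
            f"{critical_angle(n_m, n_0):.4f} rad; use R = 1")
    return float(np.arcsin(s))


def fresnel_reflectivity(phi_ref: float, n_m: float, n_0: float = 1.0) -> float:
    """Direction-dependent boundary reflectivity, in [0, 1].

    Below the critical angle, the mean of the two squared-ratio terms
    (n_m cos(phi_tra) -/+ n_0 cos(phi_ref)) / (n_m cos(phi_tra) +/- ...);
    at or beyond it, exactly 1.
    """
    if not 0 <= phi_ref <= np.pi / 2:
        raise ValueError(f"phi_ref must be in [0, pi/2], got {phi_ref}")
    if phi_ref >= critical_angle(n_m, n_0):
        return 1.0
    phi_tra = snell_transmission_angle(phi_ref, n_m, n_0)
    a = n_m * np.cos(phi_tra)
    b = n_0 * np.cos(phi_ref)
    r1 = ((a - b) / (a + b)) ** 2
    r2 = ((b - a) / (b + a)) ** 2
    return float(np.clip(0.5 * (r1 + r2), 0.0, 1.0))


@dataclass(frozen=True)
class FresnelTable:
    """Per-ordinate reflectivity for each boundary side.

    The incidence angle of ordinate m at a side is arccos(|Omega_m . n|),
    which depends only on the side's axis, so one table per axis suffices:
    ``R_x`` applies on left/right sides, ``R_y`` on bottom/top.
    """

    R_x: np.ndarray
    R_y: np.ndarray
    phi_cr: float
    n_m: float
    n_0: float

    def for_side(self, side: str) -> np.ndarray:
        if side in ("left", "right"):
            return self.R_x
        if side in ("bottom", "top"):
            return self.R_y
        raise ValueError(f"unknown side {side!r}")


def fresnel_table(ordinates: OrdinateSet, n_m: float, n_0: float = 1.0) -> FresnelTable:
    phi_x = np.arccos(np.abs(ordinates.xi))
    phi_y = np.arccos(np.abs(ordinates.eta))
    R_x = np.array([fresnel_reflectivity(p, n_m, n_0) for p in phi_x])
    R_y = np.array([fresnel_reflectivity(p, n_m, n_0) for p in phi_y])
    return FresnelTable(R_x=R_x, R_y=R_y, phi_cr=critical_angle(n_m, n_0),
                        n_m=n_m, n_0=n_0)


def reflect_ordinate(ordinates: OrdinateSet, m: int, side: str) -> int:
    """Ordinate with the side-normal component negated (specular mirror)."""
    if side in ("bottom", "top"):
        return int(ordinates.mirror_y[m])
    if side in ("left", "right"):
        return int(ordinates.mirror_x[m])
    raise ValueError(f"unknown side {side!r}")


def outgoing_mask(ordinates: OrdinateSet, side: str) -> np.ndarray:
    """Boolean mask of ordinates with Omega . n > 0 for the side."""
    nx, ny = NORMALS[side]
    return ordinates.xi * nx + ordinates.eta * ny > 0


def aperture_mask(ordinates: OrdinateSet, side: str, aperture_deg: float) -> np.ndarray:
    """Outgoing ordinates within the acceptance cone of half-angle AP."""
    nx, ny = NORMALS[side]
    cos_to_normal = ordinates.xi * nx + ordinates.eta * ny
    return cos_to_normal >= np.cos(np.radians(aperture_deg)) - 1e-12


def apply_boundary(outgoing: np.ndarray, side: str, ordinates: OrdinateSet,
                   fresnel: FresnelTable, source: np.ndarray | None = None
                   ) -> np.ndarray:
    """Boundary closure: incoming radiances from reflection plus source.

    ``outgoing``: (nfaces, M) face radiances at the side (only entries for
    outgoing ordinates are used).  ``source``: optional (nfaces, M) injected
    inward radiance.  Returns (nfaces, M) with inward ordinates filled and
    outgoing ordinates zero.
    """
    outgoing = np.asarray(outgoing, dtype=float)
    R = fresnel.for_side(side)
    incoming = np.zeros_like(outgoing)
    out = outgoing_mask(ordinates, side)
    for m in np.nonzero(~out)[0]:
        m_ref = reflect_ordinate(ordinates, m, side)
        incoming[:, m] = R[m_ref] * outgoing[:, m_ref]
    if source is not None:
        incoming[:, ~out] += np.asarray(source, dtype=float)[:, ~out]
    return incoming


def transmitted_fluence(face_radiance: np.ndarray, fresnel: FresnelTable,
                        ordinates: OrdinateSet, side: str) -> np.ndarray | float:
    """Transmitted fluence rate sum_{Omega.n>0} w_m (1 - R_m) I_m (W cm^-2)."""
    face_radiance = np.asarray(face_radiance, dtype=float)
    R = fresnel.for_side(side)
    mask = outgoing_mask(ordinates, side)
    wt = ordinates.w * (1.0 - R) * mask
    out = face_radiance @ wt
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class DetectorSpec:
    """A boundary detector: side, position along the side, aperture half-angle."""

    side: str
    position_cm: float
    aperture_deg: float = 45.0
    name: str | None = None

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ConfigurationError(f"unknown side {self.side!r}; use one of {SIDES}")
        if not 0 < self.aperture_deg <= 90:
            raise ConfigurationError(
                f"aperture must be in (0, 90] degrees, got {self.aperture_deg}")

    def side_extent(self, grid: Grid2D) -> float:
        return grid.width if self.side in ("bottom", "top") else grid.height

    def face_index(self, grid: Grid2D) -> int:
        """Nearest boundary cell face along the side (snap-to-cell)."""
        extent = self.side_extent(grid)
        if not 0 <= self.position_cm <= extent:
            raise ConfigurationError(
                f"detector position {self.position_cm} cm outside side of "
                f"length {extent} cm")
        d = grid.dx if self.side in ("bottom", "top") else grid.dy
        n = grid.nx if self.side in ("bottom", "top") else grid.ny
        return int(np.clip(int(self.position_cm / d), 0, n - 1))

    def distance_from(self, grid: Grid2D, x: float, y: float) -> float:
        """Straight-line distance from (x, y) to the detector point."""
        if self.side == "bottom":
            px, py = self.position_cm, 0.0
        elif self.side == "top":
            px, py = self.position_cm, grid.height
        elif self.side == "left":
            px, py = 0.0, self.position_cm
        else:
            px, py = grid.width, self.position_cm
        return float(np.hypot(px - x, py - y))


def uniform_detectors(side: str, grid: Grid2D, count: int,
                      aperture_deg: float = 45.0) -> list[DetectorSpec]:
    """``count`` detectors spread uniformly along a side (half-spacing insets)."""
    extent = grid.width if side in ("bottom", "top") else grid.height
    pos = (np.arange(count) + 0.5) * extent / count
    return [DetectorSpec(side=side, position_cm=float(p),
                         aperture_deg=aperture_deg, name=f"{side}_{k}")
            for k, p in enumerate(pos)]


def detected_fluence(face_radiance: np.ndarray, detector: DetectorSpec,
                     fresnel: FresnelTable, ordinates: OrdinateSet
                     ) -> np.ndarray | float:
    """Detected fluence rate: transmitted sum restricted to the aperture cone."""
    mask = aperture_mask(ordinates, detector.side, detector.aperture_deg)
    if not mask.any():
        raise ConfigurationError(
            f"aperture {detector.aperture_deg} deg on side {detector.side!r} "
            f"admits no ordinate of the M={ordinates.M} set")
    face_radiance = np.asarray(face_radiance, dtype=float)
    R = fresnel.for_side(detector.side)
    wt = ordinates.w * (1.0 - R) * mask
    out = face_radiance @ wt
    return float(out) if np.ndim(out) == 0 else out


def trapezoid_weights(n: int) -> np.ndarray:
    """Generalized trapezoidal-rule weights: 1/2 at endpoints, 1 inside."""
    if n < 2:
        raise ValueError(f"need at least 2 points, got {n}")
    w = np.ones(n)
    w[0] = w[-1] = 0.5
    return w


def normalize_profile(values: np.ndarray, weights: np.ndarray | None = None
                      ) -> np.ndarray:
    """Normalized detected fluence profile phi_d / ((1/D) sum_d w_d phi_d).

    The normalization is scale-invariant, so profiles from different source
    amplitudes (or wavelengths) become comparable in shape.
    """
    values = np.asarray(values, dtype=float)
    D = values.shape[-1]
    if D < 2:
        raise ValueError(f"need at least 2 detectors on the side, got {D}")
    if weights is None:
        weights = trapezoid_weights(D)
    weights = np.asarray(weights, dtype=float)
    denom = (values @ weights) / D
    if np.any(denom == 0):
        raise ZeroDivisionError("all-zero detector profile cannot be normalized")
    return values / np.expand_dims(denom, -1) if values.ndim > 1 else values / denom


__all__ = [
    "SIDES", "NORMALS", "critical_angle", "snell_transmission_angle",
    "fresnel_reflectivity", "FresnelTable", "fresnel_table",
    "reflect_ordinate", "outgoing_mask", "aperture_mask", "apply_boundary",
    "transmitted_fluence", "DetectorSpec", "uniform_detectors",
    "detected_fluence", "trapezoid_weights", "normalize_profile",
    "TotalInternalReflectionError", "ConfigurationError", "QuadratureError",
    "Grid2D", "MediumMap",
]
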