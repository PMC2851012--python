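"""Grid geometry, optical-property maps and phantom builders.

Media are uniform 2D rectangular grids of cells, each carrying an absorption
coefficient ``mu_a`` (cm^-1), a scattering coefficient ``mu_s`` (cm^-1) and a
Henyey-Greenstein anisotropy factor ``g``.  The refractive index ``n_m`` is a
single global value: the index mismatch acts only at the outer boundary.

Conventions: all lengths in cm, indices 0-based, cell (0, 0) at the lower-left
corner, x increasing rightward and y upward.  The source side ("bottom") is
y = 0.  Cell (i, j) has its center at ((i + 0.5) dx, (j + 0.5) dy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class InvalidPropertyError(ValueError):
    """An optical property is outside its admissible range."""


class GeometryError(ValueError):
    """A grid or region specification is geometrically inconsistent."""


class ResolutionError(ValueError):
    """The grid is too coarse to represent a requested feature."""


def reduced_scattering(mu_s: float, g: float) -> float:
    """Reduced scattering coefficient mu_s' = (1 - g) mu_s (cm^-1).

    ``g`` is the mean cosine of the single-scattering deflection angle; the
    reduced coefficient is the effective isotropic scattering rate.
    """
    mu_s = np.asarray(mu_s, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any(mu_s < 0):
        raise InvalidPropertyError(f"mu_s must be >= 0, got {mu_s}")
    if np.any(np.abs(g) >= 1):
        raise InvalidPropertyError(f"anisotropy g must satisfy |g| < 1, got {g}")
    out = (1.0 - g) * mu_s
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Grid2D:
    """Uniform rectangular grid of nx * ny cells, each dx * dy (cm)."""

    nx: int
    ny: int
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise GeometryError(f"need nx, ny >= 2, got {self.nx} x {self.ny}")
        if self.dx <= 0 or self.dy <= 0:
            raise GeometryError(f"need dx, dy > 0, got {self.dx}, {self.dy}")

    @property
    def width(self) -> float:
        return self.nx * self.dx

    @property
    def height(self) -> float:
        return self.ny * self.dy

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dy

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        return ((i + 0.5) * self.dx, (j + 0.5) * self.dy)


def build_grid(width_cm: float, height_cm: float, dx_cm: float, dy_cm: float,
               rtol: float = 1e-9) -> Grid2D:
    """Build a grid covering width x height; dimensions must be commensurate
    with the cell size (within rounding tolerance)."""
    nx = round(width_cm / dx_cm)
    ny = round(height_cm / dy_cm)
    if abs(nx * dx_cm - width_cm) > rtol * max(1.0, width_cm):
        raise GeometryError(f"width {width_cm} cm is not a multiple of dx={dx_cm} cm")
    if abs(ny * dy_cm - height_cm) > rtol * max(1.0, height_cm):
        raise GeometryError(f"height {height_cm} cm is not a multiple of dy={dy_cm} cm")
    return Grid2D(nx=nx, ny=ny, dx=dx_cm, dy=dy_cm)


@dataclass(frozen=True)
class OpticalProperties:
    """Per-region optical properties: mu_a, mu_s (cm^-1) and anisotropy g."""

    mu_a: float
    mu_s: float
    g: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise InvalidPropertyError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s < 0:
            raise InvalidPropertyError(f"mu_s must be >= 0, got {self.mu_s}")
        if not -1.0 < self.g < 1.0:
            raise InvalidPropertyError(f"g must satisfy |g| < 1, got {self.g}")

    @property
    def mu_s_reduced(self) -> float:
        return reduced_scattering(self.mu_s, self.g)

    @property
    def mu_t(self) -> float:
        return self.mu_a + self.mu_s


@dataclass
class MediumMap:
    """Per-cell optical properties on a grid, plus the global refractive index.

    ``mu_a``, ``mu_s``, ``g`` are (nx, ny) arrays indexed [i, j]; ``n_m`` is
    the medium refractive index and ``n_0`` the external one (air = 1).
    """

    grid: Grid2D
    mu_a: np.ndarray
    mu_s: np.ndarray
    g: np.ndarray
    n_m: float = 1.0
    n_0: float = 1.0

    def __post_init__(self) -> None:
        shape = (self.grid.nx, self.grid.ny)
        for name in ("mu_a", "mu_s", "g"):
            arr = np.ascontiguousarray(np.asarray(getattr(self, name), dtype=float))
            if arr.shape != shape:
                raise GeometryError(f"{name} has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr)
        if np.any(self.mu_a < 0) or np.any(self.mu_s < 0):
            raise InvalidPropertyError("mu_a and mu_s must be >= 0 everywhere")
        if np.any(np.abs(self.g) >= 1):
            raise InvalidPropertyError("|g| < 1 required everywhere")
        if self.n_m < 1.0:
            raise InvalidPropertyError(f"n_m must be >= 1, got {self.n_m}")

    @classmethod
    def homogeneous(cls, grid: Grid2D, props: OpticalProperties,
                    n_m: float = 1.0, n_0: float = 1.0) -> "MediumMap":
        shape = (grid.nx, grid.ny)
        return cls(grid=grid,
                   mu_a=np.full(shape, props.mu_a),
                   mu_s=np.full(shape, props.mu_s),
                   g=np.full(shape, props.g),
                   n_m=n_m, n_0=n_0)

    @property
    def mu_t(self) -> np.ndarray:
        return self.mu_a + self.mu_s

    @property
    def mu_s_reduced(self) -> np.ndarray:
        return (1.0 - self.g) * self.mu_s

    def _center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.grid.x_centers, self.grid.y_centers, indexing="ij")

    def _assign(self, mask: np.ndarray, props: OpticalProperties) -> None:
        self.mu_a[mask] = props.mu_a
        self.mu_s[mask] = props.mu_s
        self.g[mask] = props.g

    def set_rectangle(self, x0: float, y0: float, x1: float, y1: float,
                      props: OpticalProperties) -> int:
        """Assign props to cells whose centers lie in [x0, x1) x [y0, y1)."""
        xc, yc = self._center_mesh()
        mask = (xc >= x0) & (xc < x1) & (yc >= y0) & (yc < y1)
        self._assign(mask, props)
        return int(mask.sum())

    def set_disk(self, cx: float, cy: float, diameter: float,
                 props: OpticalProperties) -> int:
        """Assign props to cells whose centers lie inside the disk (r < d/2)."""
        xc, yc = self._center_mesh()
        mask = (xc - cx) ** 2 + (yc - cy) ** 2 < (diameter / 2.0) ** 2
        self._assign(mask, props)
        return int(mask.sum())

    def set_annulus(self, cx: float, cy: float, inner_d: float, outer_d: float,
                    props: OpticalProperties) -> int:
        """Assign props on the half-open annulus inner_d/2 <= r < outer_d/2."""
        if not 0 < inner_d < outer_d:
            raise ResolutionError(
                f"need 0 < inner_d < outer_d, got {inner_d}, {outer_d}")
        xc, yc = self._center_mesh()
        r2 = (xc - cx) ** 2 + (yc - cy) ** 2
        mask = (r2 >= (inner_d / 2.0) ** 2) & (r2 < (outer_d / 2.0) ** 2)
        self._assign(mask, props)
        return int(mask.sum())

    def unique_g(self) -> tuple[np.ndarray, np.ndarray]:
        """Distinct anisotropy values and the per-cell index into them.

        The solver builds one phase matrix per distinct g.
        """
        values, idx = np.unique(self.g, return_inverse=True)
        return values, idx.reshape(self.g.shape).astype(np.int64)

    def to_dataframe(self) -> pd.DataFrame:
        xc, yc = self._center_mesh()
        ii, jj = np.meshgrid(np.arange(self.grid.nx), np.arange(self.grid.ny),
                             indexing="ij")
        return pd.DataFrame({
            "i": ii.ravel(), "j": jj.ravel(),
            "x_cm": xc.ravel(), "y_cm": yc.ravel(),
            "mu_a_cm1": self.mu_a.ravel(), "mu_s_cm1": self.mu_s.ravel(),
            "g": self.g.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_hdf5(self, path_or_group) -> None:
        import h5py

        own = isinstance(path_or_group, (str, bytes)) or hasattr(path_or_group, "__fspath__")
        h = h5py.File(path_or_group, "w") if own else path_or_group
        try:
            h.attrs["nx"], h.attrs["ny"] = self.grid.nx, self.grid.ny
            h.attrs["dx_cm"], h.attrs["dy_cm"] = self.grid.dx, self.grid.dy
            h.attrs["n_m"], h.attrs["n_0"] = self.n_m, self.n_0
            for name in ("mu_a", "mu_s", "g"):
                h.create_dataset(name, data=getattr(self, name))
        finally:
            if own:
                h.close()

    @classmethod
    def from_hdf5(cls, path) -> "MediumMap":
        import h5py

        with h5py.File(path, "r") as h:
            grid = Grid2D(int(h.attrs["nx"]), int(h.attrs["ny"]),
                          float(h.attrs["dx_cm"]), float(h.attrs["dy_cm"]))
            return cls(grid=grid, mu_a=h["mu_a"][...], mu_s=h["mu_s"][...],
                       g=h["g"][...], n_m=float(h.attrs["n_m"]),
                       n_0=float(h.attrs["n_0"]))


def make_ring_phantom(grid: Grid2D, background: OpticalProperties,
                      ring: OpticalProperties, center_xy: tuple[float, float],
                      inner_d: float, outer_d: float,
                      n_m: float = 1.0, n_0: float = 1.0) -> MediumMap:
    """Homogeneous background with an annular (void-like ring) inclusion.

    Cells belong to the ring iff their center lies in the half-open annulus
    inner_d/2 <= r < outer_d/2.  Raises :class:`ResolutionError` if the grid
    is too coarse for any cell center to fall inside the annulus.
    """
    cx, cy = center_xy
    if not 0 < inner_d < outer_d:
        raise ResolutionError(f"need 0 < inner_d < outer_d, got {inner_d}, {outer_d}")
    if outer_d > min(grid.width, grid.height):
        raise GeometryError("ring does not fit inside the medium")
    medium = MediumMap.homogeneous(grid, background, n_m=n_m, n_0=n_0)
    n_cells = medium.set_annulus(cx, cy, inner_d, outer_d, ring)
    if n_cells == 0:
        raise ResolutionError(
            f"annulus {inner_d}/{outer_d} cm captured no cell centers at "
            f"dx={grid.dx} cm; refine the grid")
    return medium


@dataclass
class ResolutionReport:
    """Advisory check of the cell-size condition dx < 1/(mu_a + mu_s').

    Moving between neighboring cells should cover less than one transport
    mean free path; cells violating this are flagged.
    """

    ok: np.ndarray = field(repr=False)
    worst_ratio: float
    n_failed: int

    @property
    def passed(self) -> bool:
        return self.n_failed == 0


def check_resolution(medium: MediumMap) -> ResolutionReport:
    """Flag cells where dx >= 1/(mu_a + mu_s') (grid too coarse)."""
    h = max(medium.grid.dx, medium.grid.dy)
    mu_tr = medium.mu_a + medium.mu_s_reduced
    # ratio = dx * (mu_a + mu_s'); < 1 passes.  mu_tr = 0 gives ratio 0.
    ratio = h * mu_tr
    ok = ratio < 1.0
    return ResolutionReport(ok=ok, worst_ratio=float(ratio.max()),
                            n_failed=int((~ok).sum()))
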