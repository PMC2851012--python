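"""Control-volume discrete-ordinates (CVDOM) transport core.

The 2D time-dependent radiative transfer equation is integrated over each
rectangular cell and each discrete ordinate.  For ordinate m with direction
cosines (xi_m, eta_m) the cell update is the closed form

    I_P = [A f_up_x + B f_up_y + dx dy (S + mu_s sum_m' w_m' p_mm' I_m'
           + history)] / [dx dy ct + A + B + dx dy (mu_a + mu_s)]

with A = dy |xi_m| / alpha, B = dx |eta_m| / alpha, upstream face radiances
f_up, and downstream faces closed by the interpolation
f_down = (I_P - (1 - alpha) f_up) / alpha (alpha = 1/2: diamond, second
order; alpha = 1: step/upwind, positivity-preserving).

Time is advanced by an implicit three-level second-order scheme,
dI/dt ~ (3 I^{n+1} - 4 I^n + I^{n-1}) / (2 dt); the first step (which lacks
I^{n-1}) uses backward Euler.  Within a step, the scattering source is lagged
and iterated (source iteration) with successive over-relaxation, sweeping
the four sign quadrants in upwind order; each quadrant re-applies its
upstream boundary closure with the newest outgoing faces (Gauss-Seidel
coupling).  The steady driver solves the same equations with the
time-derivative terms dropped — the fixed point of the marching scheme,
since the 3 - 4 + 1 stencil cancels at stationarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import _kernels
from .boundary import (DetectorSpec, FresnelTable, detected_fluence,
                       fresnel_table, outgoing_mask)
from .medium import MediumMap
from .quadrature import OrdinateSet, PhaseMatrix, make_ordinates, phase_matrix
from .sources import InjectionPoint, Source, inject

SPEED_OF_LIGHT = 2.99792458e10  # cm / s

#: fixed quadrant processing order: (sign xi, sign eta)
QUADRANTS = ((1, 1), (-1, 1), (-1, -1), (1, -1))


class NonConvergenceError(RuntimeError):
    """Inner iteration or steady march failed to reach tolerance."""

    def __init__(self, msg: str, eps_history=None):
        super().__init__(msg)
        self.eps_history = list(eps_history or [])


class InstabilityError(RuntimeError):
    """A sweep produced a non-finite radiance."""


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings; defaults follow the validated study configuration."""

    alpha: float = 0.5          # interpolation parameter (0.5 diamond, 1 upwind)
    rho: float = 1.1            # SOR relaxation factor
    tol: float = 1e-8           # relative-change tolerance
    dt: float = 1e-13           # time step (s)
    max_inner_iters: int = 50_000
    max_time_steps: int = 500_000
    c: float = SPEED_OF_LIGHT   # vacuum speed of light (cm/s)
    eps_abs: float = 1e-300     # floor for relative-change denominators
    # (guards division by zero on dark cells while keeping the metric
    # scale-invariant in the source amplitude, so linearity is exact)

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not 1 <= self.rho < 2:
            raise ValueError(f"rho must be in [1, 2), got {self.rho}")
        if self.tol <= 0 or self.dt <= 0:
            raise ValueError("tol and dt must be positive")


@dataclass
class RadianceField:
    """Radiance on (nx, ny, M) at the three retained time levels."""

    I_prev2: np.ndarray
    I_prev: np.ndarray
    I_curr: np.ndarray
    n: int
    dt: float


def relative_change(new: np.ndarray, old: np.ndarray, eps_abs: float) -> float:
    """max |new - old| / max(|old|, eps_abs) over all cells and ordinates."""
    return float(np.max(np.abs(new - old) / np.maximum(np.abs(old), eps_abs)))


class TransportProblem:
    """A fully specified transport run: medium, ordinates, sources, detectors.

    Precomputes the Fresnel table, the renormalized phase matrix for every
    distinct anisotropy value in the medium, and the source injection points.
    """

    def __init__(self, medium: MediumMap, ordinates: OrdinateSet | int = 16,
                 sources: list[Source] | None = None,
                 detectors: list[DetectorSpec] | None = None,
                 config: SolverConfig | None = None):
        self.medium = medium
        self.ordinates = (ordinates if isinstance(ordinates, OrdinateSet)
                          else make_ordinates(ordinates))
        self.sources = list(sources or [])
        self.detectors = list(detectors or [])
        self.config = config or SolverConfig()
        self.fresnel: FresnelTable = fresnel_table(self.ordinates, medium.n_m,
                                                   medium.n_0)
        g_values, gidx = medium.unique_g()
        self.g_values = g_values
        self._gidx = gidx
        self.phase_matrices: list[PhaseMatrix] = [
            phase_matrix(self.ordinates, g) for g in g_values]
        # W_g[m, m'] = p_g[m, m'] w_m' so scat_m = (I @ W_g.T)_m
        self._Wg = [pm.p * self.ordinates.w[np.newaxis, :]
                    for pm in self.phase_matrices]
        self.injections: list[InjectionPoint] = [
            inject(s, self.ordinates, medium.grid) for s in self.sources]
        self._quadrants = [(sx, sy, self.ordinates.quadrant_ordinates(sx, sy))
                           for sx, sy in QUADRANTS]

    # -- derived geometry ------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.medium.grid.nx, self.medium.grid.ny, self.ordinates.M)

    def zero_field(self) -> np.ndarray:
        return np.zeros(self.shape)

    def zero_faces(self) -> dict[str, np.ndarray]:
        nx, ny, M = self.shape
        return {"bottom": np.zeros((nx, M)), "top": np.zeros((nx, M)),
                "left": np.zeros((ny, M)), "right": np.zeros((ny, M))}

    # -- physics pieces --------------------------------------------------
    def scattering_source(self, I: np.ndarray) -> np.ndarray:
        """mu_s(r) * sum_m' w_m' p_mm' I_m' for every cell and ordinate."""
        M = self.ordinates.M
        if len(self._Wg) == 1:
            scat = I @ self._Wg[0].T
        else:
            scat = np.empty_like(I)
            flat_in = I.reshape(-1, M)
            flat_out = scat.reshape(-1, M)
            gsel = self._gidx.reshape(-1)
            for gi, W in enumerate(self._Wg):
                rows = gsel == gi
                flat_out[rows] = flat_in[rows] @ W.T
        return scat * self.medium.mu_s[:, :, np.newaxis]

    def _boundary_inflow(self, side: str, axis: str, faces: dict[str, np.ndarray],
                         q_ords: np.ndarray, active: list[bool]) -> np.ndarray:
        """Incoming face radiances on one upstream side for a quadrant.

        Reflection closure R(m_ref) I_out(m_ref) plus any active source
        injected on this side whose ordinate belongs to the quadrant.
        """
        out = faces[side]
        incoming = np.zeros_like(out)
        mirror = (self.ordinates.mirror_x if axis == "x"
                  else self.ordinates.mirror_y)
        R = self.fresnel.for_side(side)
        for m in q_ords:
            m_ref = mirror[m]
            incoming[:, m] = R[m_ref] * out[:, m_ref]
        for inj, on in zip(self.injections, active):
            if on and inj.side == side and inj.ordinate in q_ords:
                incoming[inj.face_index, inj.ordinate] += inj.amplitude
        return incoming

    def iterate_once(self, I_k: np.ndarray, faces: dict[str, np.ndarray],
                     ct: float, hist: np.ndarray | None,
                     active: list[bool]) -> np.ndarray:
        """One source-iteration pass: scattering at iterate k, four sweeps.

        ``ct`` is the implicit time-derivative coefficient (n_m/(c dt) scaled
        by the stencil; 0 for the steady equations); ``hist`` the matching
        history term.  ``faces`` is updated in place with the newest outgoing
        boundary faces.  Returns the swept (un-relaxed) iterate k+1.
        """
        grid = self.medium.grid
        dx, dy = grid.dx, grid.dy
        area = dx * dy
        src = self.scattering_source(I_k)
        if hist is not None:
            src = src + hist
        vol = area * src
        ct_area = area * ct
        I_new = np.empty_like(I_k)
        mu_t = self.medium.mu_t
        xi, eta = self.ordinates.xi, self.ordinates.eta
        for sx, sy, q_ords in self._quadrants:
            up_x = "left" if sx > 0 else "right"
            up_y = "bottom" if sy > 0 else "top"
            in_x = self._boundary_inflow(up_x, "x", faces, q_ords, active)
            in_y = self._boundary_inflow(up_y, "y", faces, q_ords, active)
            out_x = np.zeros_like(faces["left"])
            out_y = np.zeros_like(faces["bottom"])
            _kernels.sweep_ordinates(I_new, vol, mu_t, xi, eta,
                                     np.ascontiguousarray(q_ords), sx, sy,
                                     self.config.alpha, dx, dy, ct_area,
                                     in_x, in_y, out_x, out_y)
            down_x = "right" if sx > 0 else "left"
            down_y = "top" if sy > 0 else "bottom"
            faces[down_x][:, q_ords] = out_x[:, q_ords]
            faces[down_y][:, q_ords] = out_y[:, q_ords]
        if not np.all(np.isfinite(I_new)):
            bad = np.argwhere(~np.isfinite(I_new))[0]
            raise InstabilityError(
                f"non-finite radiance at cell ({bad[0]}, {bad[1]}), "
                f"ordinate {bad[2]}")
        return I_new

    def converge(self, I: np.ndarray, faces: dict[str, np.ndarray], ct: float,
                 hist: np.ndarray | None, active: list[bool],
                 tol: float | None = None) -> tuple[np.ndarray, int, list[float]]:
        """SOR-accelerated source iteration until relative change <= tol."""
        cfg = self.config
        tol = cfg.tol if tol is None else tol
        history: list[float] = []
        for it in range(cfg.max_inner_iters):
            I_new = self.iterate_once(I, faces, ct, hist, active)
            I_upd = I + cfg.rho * (I_new - I)
            eps = relative_change(I_upd, I, cfg.eps_abs)
            history.append(eps)
            I = I_upd
            if eps <= tol:
                return I, it + 1, history
        raise NonConvergenceError(
            f"no convergence after {cfg.max_inner_iters} inner iterations "
            f"(last eps = {history[-1]:.3e})", history)


def fluence_matrix(I: np.ndarray, ordinates: OrdinateSet) -> np.ndarray:
    """Fluence rate Phi_ij = sum_m w_m I_ijm (W cm^-2)."""
    return np.asarray(I) @ ordinates.w


@dataclass
class EnergyBalance:
    """Discrete power budget (W per unit depth) of a steady solution."""

    injected: float
    absorbed: float
    transmitted: float
    residual_fraction: float


def _face_lengths(problem: TransportProblem, side: str) -> float:
    grid = problem.medium.grid
    return grid.dx if side in ("bottom", "top") else grid.dy


def energy_balance(problem: TransportProblem, I: np.ndarray,
                   faces: dict[str, np.ndarray],
                   active: list[bool] | None = None) -> EnergyBalance:
    """injected vs absorbed + net transmitted power, per unit depth."""
    ords = problem.ordinates
    grid = problem.medium.grid
    phi = fluence_matrix(I, ords)
    absorbed = float(np.sum(problem.medium.mu_a * phi) * grid.cell_area)
    injected = 0.0
    if active is None:
        active = [True] * len(problem.injections)
    for inj, on in zip(problem.injections, active):
        if not on:
            continue
        ncos = (abs(ords.eta[inj.ordinate]) if inj.side in ("bottom", "top")
                else abs(ords.xi[inj.ordinate]))
        injected += inj.amplitude * ords.w[inj.ordinate] * ncos \
            * _face_lengths(problem, inj.side)
    transmitted = 0.0
    from .boundary import NORMALS
    for side, out in faces.items():
        nx_, ny_ = NORMALS[side]
        ncos = np.abs(ords.xi * nx_ + ords.eta * ny_)
        mask = outgoing_mask(ords, side)
        R = problem.fresnel.for_side(side)
        wt = ords.w * ncos * (1.0 - R) * mask
        transmitted += float(np.sum(out @ wt)) * _face_lengths(problem, side)
    resid = abs(injected - absorbed - transmitted) / injected if injected else np.nan
    return EnergyBalance(injected=injected, absorbed=absorbed,
                         transmitted=transmitted, residual_fraction=resid)


@dataclass
class SteadyResult:
    """Converged steady-state field with detector readout helpers."""

    problem: TransportProblem
    I: np.ndarray = dc_field(repr=False)
    faces: dict = dc_field(repr=False)
    iterations: int
    eps_history: list = dc_field(repr=False)
    n_negative: int = 0
    min_radiance: float = 0.0

    @property
    def fluence(self) -> np.ndarray:
        return fluence_matrix(self.I, self.problem.ordinates)

    def detector_values(self, detectors=None):
        detectors = self.problem.detectors if detectors is None else detectors
        vals = np.array([
            detected_fluence(self.faces[d.side][d.face_index(self.problem.medium.grid)],
                             d, self.problem.fresnel, self.problem.ordinates)
            for d in detectors])
        return np.array([0.0]), vals[np.newaxis, :]

    def detector_profile(self, side: str) -> np.ndarray:
        dets = [d for d in self.problem.detectors if d.side == side]
        _, vals = self.detector_values(dets)
        return vals[0]

    def energy_balance(self) -> EnergyBalance:
        return energy_balance(self.problem, self.I, self.faces)


@dataclass
class TransientResult:
    """Time-marched solution: detector series plus optional fluence snapshots."""

    problem: TransportProblem
    times_s: np.ndarray
    detector_series: np.ndarray = dc_field(repr=False)  # (nt, ndet)
    snapshots: dict = dc_field(repr=False)              # time -> fluence matrix
    field: RadianceField = dc_field(repr=False)
    faces: dict = dc_field(repr=False)
    inner_iterations: list = dc_field(repr=False)
    step_changes: list = dc_field(default_factory=list, repr=False)
    n_negative: int = 0
    final_step_change: float = np.nan

    def detector_values(self, detectors=None):
        if detectors is not None and list(detectors) != list(self.problem.detectors):
            raise ValueError("transient series were recorded for the problem's "
                             "own detector list")
        return self.times_s, self.detector_series

    @property
    def fluence(self) -> np.ndarray:
        return fluence_matrix(self.field.I_curr, self.problem.ordinates)


def _negativity(I: np.ndarray) -> tuple[int, float]:
    neg = I < 0
    return int(neg.sum()), float(I.min()) if I.size else 0.0


def run_steady(problem: TransportProblem, dt: float | None = None,
               tol: float | None = None) -> SteadyResult:
    """Steady-state solution under CW sources.

    By default the time-derivative terms are dropped (the Delta t -> infinity
    limit of the marching scheme, whose fixed point this is) and the source
    iteration runs to tolerance.  Passing ``dt`` instead marches the
    transient scheme with that step until the inter-step relative change
    falls below tol, reproducing the time-marched route to equilibrium.
    """
    for s in problem.sources:
        if s.kind != "cw":
            raise ValueError("run_steady requires CW sources")
    active = [True] * len(problem.sources)
    if dt is not None:
        res = run_transient(problem, t_max=problem.config.max_time_steps * dt,
                            dt=dt, stop_at_steady=True, tol=tol)
        n_neg, mn = _negativity(res.field.I_curr)
        return SteadyResult(problem=problem, I=res.field.I_curr, faces=res.faces,
                            iterations=int(np.sum(res.inner_iterations)),
                            eps_history=[res.final_step_change],
                            n_negative=n_neg, min_radiance=mn)
    I = problem.zero_field()
    faces = problem.zero_faces()
    I, iters, history = problem.converge(I, faces, ct=0.0, hist=None,
                                         active=active, tol=tol)
    n_neg, mn = _negativity(I)
    return SteadyResult(problem=problem, I=I, faces=faces, iterations=iters,
                        eps_history=history, n_negative=n_neg, min_radiance=mn)


def run_transient(problem: TransportProblem, t_max: float,
                  dt: float | None = None,
                  snapshot_times: tuple[float, ...] = (),
                  stop_at_steady: bool = False,
                  tol: float | None = None,
                  stop_tol: float | None = None) -> TransientResult:
    """March the implicit three-level scheme from a dark initial field.

    Steps n = 1 .. t_max/dt; the first step uses the two-level backward-Euler
    startup (no I^{n-1} exists yet).  Detected fluence at every configured
    detector is recorded each step; fluence-rate matrices are stored at the
    steps nearest ``snapshot_times``.  With ``stop_at_steady`` the march ends
    once the inter-step relative change drops below tol (CW equilibration).
    """
    cfg = problem.config
    dt = cfg.dt if dt is None else dt
    stop_tol = (tol if tol is not None else cfg.tol) if stop_tol is None \
        else stop_tol
    if t_max < dt:
        n_steps = 0
    else:
        n_steps = int(round(t_max / dt))
    tc = problem.medium.n_m / (cfg.c * dt)
    detectors = problem.detectors
    det_idx = [d.face_index(problem.medium.grid) for d in detectors]

    I_prev2 = problem.zero_field()
    I_prev = problem.zero_field()
    faces = problem.zero_faces()
    times = []
    det_rows = []
    inner_counts = []
    step_changes = []
    snap_steps = {max(1, int(round(t / dt))): t for t in snapshot_times}
    snapshots = {}
    step_change = np.nan
    I_curr = I_prev
    n_done = 0
    for n in range(1, n_steps + 1):
        t_start = (n - 1) * dt
        active = [s.active(t_start, dt) for s in problem.sources]
        if n == 1:
            ct = tc                       # backward Euler startup
            hist = tc * I_prev
        else:
            ct = 1.5 * tc                 # three-level scheme
            hist = tc * (2.0 * I_prev - 0.5 * I_prev2)
        I_curr, iters, _ = problem.converge(I_prev.copy(), faces, ct=ct,
                                            hist=hist, active=active, tol=tol)
        inner_counts.append(iters)
        times.append(n * dt)
        det_rows.append([
            detected_fluence(faces[d.side][fi], d, problem.fresnel,
                             problem.ordinates)
            for d, fi in zip(detectors, det_idx)])
        if n in snap_steps:
            snapshots[snap_steps[n]] = fluence_matrix(I_curr, problem.ordinates)
        step_change = relative_change(I_curr, I_prev, cfg.eps_abs)
        step_changes.append(step_change)
        I_prev2, I_prev = I_prev, I_curr
        n_done = n
        if stop_at_steady and n >= 2 and step_change <= stop_tol:
            break
    if stop_at_steady and n_done == n_steps and n_steps > 0 \
            and step_change > stop_tol:
        raise NonConvergenceError(
            f"steady state not reached in {n_steps} steps "
            f"(last inter-step change {step_change:.3e})")
    n_neg, _mn = _negativity(I_curr)
    field = RadianceField(I_prev2=I_prev2, I_prev=I_prev, I_curr=I_curr,
                          n=n_done, dt=dt)
    ndet = len(detectors)
    return TransientResult(
        problem=problem,
        times_s=np.array(times),
        detector_series=(np.array(det_rows).reshape(len(times), ndet)
                         if times else np.zeros((0, ndet))),
        snapshots=snapshots, field=field, faces=faces,
        inner_iterations=inner_counts, step_changes=step_changes,
        n_negative=n_neg, final_step_change=step_change)


def sweep_quadrant(problem: TransportProblem, quadrant: tuple[int, int],
                   I_iterate: np.ndarray, faces: dict[str, np.ndarray],
                   ct: float = 0.0, hist: np.ndarray | None = None,
                   active: list[bool] | None = None) -> np.ndarray:
    """One quadrant's upwind sweep (exposed for testing and inspection).

    Applies the quadrant's upstream boundary closure from ``faces``, sweeps
    its ordinates with the scattering source evaluated at ``I_iterate``, and
    returns the full field array with that quadrant's ordinates updated
    (other ordinates copied unchanged).  ``faces`` receives the downstream
    outgoing face radiances.
    """
    sx, sy = quadrant
    q_ords = problem.ordinates.quadrant_ordinates(sx, sy)
    if active is None:
        active = [True] * len(problem.injections)
    grid = problem.medium.grid
    src = problem.scattering_source(I_iterate)
    if hist is not None:
        src = src + hist
    vol = grid.cell_area * src
    I_new = I_iterate.copy()
    up_x = "left" if sx > 0 else "right"
    up_y = "bottom" if sy > 0 else "top"
    in_x = problem._boundary_inflow(up_x, "x", faces, q_ords, active)
    in_y = problem._boundary_inflow(up_y, "y", faces, q_ords, active)
    out_x = np.zeros_like(faces["left"])
    out_y = np.zeros_like(faces["bottom"])
    _kernels.sweep_ordinates(I_new, vol, problem.medium.mu_t,
                             problem.ordinates.xi, problem.ordinates.eta,
                             np.ascontiguousarray(q_ords), sx, sy,
                             problem.config.alpha, grid.dx, grid.dy,
                             grid.cell_area * ct, in_x, in_y, out_x, out_y)
    if not np.all(np.isfinite(I_new[:, :, q_ords])):
        raise InstabilityError("non-finite radiance in quadrant sweep")
    faces["right" if sx > 0 else "left"][:, q_ords] = out_x[:, q_ords]
    faces["top" if sy > 0 else "bottom"][:, q_ords] = out_y[:, q_ords]
    return I_new
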