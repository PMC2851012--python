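"""Discrete ordinates on the unit circle and the Henyey-Greenstein phase matrix.

The transport equation is genuinely two-dimensional here: directions are unit
vectors in the (x, y) plane, Omega_m = (xi_m, eta_m), with a constant-weight
quadrature w_m = 2*pi/M summing to the full planar solid angle 2*pi.

A half-step angular offset keeps every ordinate strictly off the coordinate
axes, so each of the four sign quadrants (sign xi, sign eta) holds exactly
M/4 directions and mirror images across either axis exist exactly within the
set — both properties the sweep and the boundary reflection rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .medium import InvalidPropertyError

FOUR_PI = 4.0 * np.pi


class QuadratureError(ValueError):
    """The requested ordinate set cannot satisfy the sweep's requirements."""


@dataclass(frozen=True)
class OrdinateSet:
    """M planar directions with angles theta_m = (m + 1/2) 2 pi / M."""

    M: int
    theta: np.ndarray = field(repr=False)
    xi: np.ndarray = field(repr=False)
    eta: np.ndarray = field(repr=False)
    w: np.ndarray = field(repr=False)
    mirror_x: np.ndarray = field(repr=False)  # ordinate with xi negated
    mirror_y: np.ndarray = field(repr=False)  # ordinate with eta negated

    def quadrant_ordinates(self, sx: int, sy: int) -> np.ndarray:
        """Indices of ordinates with sign(xi) = sx and sign(eta) = sy."""
        return np.nonzero((np.sign(self.xi) == sx) & (np.sign(self.eta) == sy))[0]


def make_ordinates(M: int) -> OrdinateSet:
    """Constant-weight ordinate set of M directions (M divisible by 4)."""
    if M < 4 or M % 4 != 0:
        raise QuadratureError(f"M must be >= 4 and divisible by 4, got {M}")
    m = np.arange(M)
    theta = (m + 0.5) * 2.0 * np.pi / M
    xi = np.cos(theta)
    eta = np.sin(theta)
    w = np.full(M, 2.0 * np.pi / M)
    # theta -> pi - theta negates xi; theta -> 2 pi - theta negates eta.
    # With the half-step offset both maps permute the index set exactly.
    mirror_x = (M // 2 - 1 - m) % M
    mirror_y = (M - 1 - m) % M
    assert np.allclose(xi[mirror_x], -xi), "mirror_x must negate xi"
    assert np.allclose(eta[mirror_x], eta)
    assert np.allclose(eta[mirror_y], -eta), "mirror_y must negate eta"
    assert np.allclose(xi[mirror_y], xi)
    return OrdinateSet(M=M, theta=theta, xi=xi, eta=eta, w=w,
                       mirror_x=mirror_x, mirror_y=mirror_y)


def hg_phase(cos_theta, g: float):
    """Henyey-Greenstein phase function (sr^-1), normalized on the sphere.

    p(cos t) = (1 - g^2) / (4 pi (1 + g^2 - 2 g cos t)^(3/2)).
    """
    if not np.all(np.abs(g) < 1):
        raise InvalidPropertyError(f"|g| < 1 required, got {g}")
    cos_theta = np.asarray(cos_theta, dtype=float)
    if np.any(np.abs(cos_theta) > 1.0 + 1e-12):
        raise ValueError("cos_theta outside [-1, 1]")
    cos_theta = np.clip(cos_theta, -1.0, 1.0)
    out = (1.0 - g * g) / (FOUR_PI * (1.0 + g * g - 2.0 * g * cos_theta) ** 1.5)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PhaseMatrix:
    """Discretized HG kernel p[m, m'] with energy-conserving renormalization.

    p[m, m'] is the probability density (sr^-1) of scattering from ordinate m'
    into ordinate m.  Columns are rescaled so sum_m w_m p[m, m'] = 1 exactly:
    the discrete scattering event conserves energy, which the global energy
    balance of the solver requires.
    """

    p: np.ndarray = field(repr=False)
    g: float
    norm_factors: np.ndarray = field(repr=False)
    mean_cosine: float = np.nan  # effective anisotropy of the discrete kernel


def phase_matrix(ordinates: OrdinateSet, g: float,
                 method: str = "bin", n_fine: int = 1 << 16) -> PhaseMatrix:
    """Discretize the HG kernel onto the ordinate set, conserving energy.

    method="bin" (default): each entry carries the exact probability mass of
    the kernel over the angular bin of width 2 pi / M centered on the
    ordinate-pair deflection angle, p[m, m'] = q_{m-m'} / w.  This keeps the
    forward peak's mass even when it is narrower than the ordinate spacing
    (strongly forward-peaked g at moderate M), where point sampling badly
    misrepresents the kernel (its renormalization factor collapses well
    below 1, the under-resolution flag).

    method="point": the kernel evaluated at the ordinate-pair angles and
    column-rescaled, the textbook discretization.

    Either way columns are scaled so sum_m w_m p[m, m'] = 1 exactly.
    """
    if not abs(g) < 1:
        raise InvalidPropertyError(f"|g| < 1 required, got {g}")
    M = ordinates.M
    if method == "bin":
        # bin masses of the in-plane-renormalized kernel over width-2pi/M
        # bins centered on the discrete deflection angles (circulant)
        psi = (np.arange(n_fine) + 0.5) * 2.0 * np.pi / n_fine - np.pi
        pdf = hg_phase(np.cos(psi), g)
        pdf /= pdf.sum()
        bins = np.round(psi / (2.0 * np.pi / M)).astype(int) % M
        q = np.zeros(M)
        np.add.at(q, bins, pdf)
        k = (np.arange(M)[:, np.newaxis] - np.arange(M)[np.newaxis, :]) % M
        raw = q[k] / ordinates.w[0]
    elif method == "point":
        cosang = (np.outer(ordinates.xi, ordinates.xi)
                  + np.outer(ordinates.eta, ordinates.eta))
        raw = hg_phase(cosang, g)
    else:
        raise ValueError(f"method must be 'bin' or 'point', got {method!r}")
    col = ordinates.w @ raw  # sum_m w_m p[m, m'] per column m'
    norm = 1.0 / col
    p = raw * norm[np.newaxis, :]
    # mean deflection cosine of the discrete kernel (column 0; the uniform
    # ordinate set makes the kernel circulant, so any column gives the same)
    cos0 = ordinates.xi * ordinates.xi[0] + ordinates.eta * ordinates.eta[0]
    moment = float(np.sum(ordinates.w * p[:, 0] * cos0))
    return PhaseMatrix(p=p, g=g, norm_factors=norm, mean_cosine=moment)


def inplane_hg_mean_cosine(g: float, n: int = 200_001) -> float:
    """Mean deflection cosine of the HG kernel restricted to the circle.

    The exponent-3/2 kernel renormalized over the planar angle does not have
    mean cosine g (it is more forward-peaked); this quadrature value is what
    an in-plane sampler should reproduce.
    """
    psi = np.linspace(-np.pi, np.pi, n)
    p = hg_phase(np.cos(psi), g)
    return float(np.trapezoid(np.cos(psi) * p, psi) / np.trapezoid(p, psi))
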