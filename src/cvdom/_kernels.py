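"""Hot loops: the per-ordinate upwind sweep and the Monte Carlo random walk.

Both are written as plain nopython-compatible functions and jitted with numba
when it is importable; otherwise the pure-Python versions run unchanged
(correct but slow).  Everything above this module is NumPy-vectorized.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=False)
def sweep_ordinates(I_new, vol_src, mu_t, xi, eta, ords, sx, sy,
                    alpha, dx, dy, ct_area, in_x, in_y, out_x, out_y):
    """Upwind sweep of one sign quadrant's ordinates over the whole grid.

    Cell update (control-volume form, upstream FACE values fx, fy):

        I_P = (A fx + B fy + vol_src) / (ct_area + A + B + dx dy mu_t)

    with A = dy|xi|/alpha, B = dx|eta|/alpha, followed by the interpolation
    closure f_down = (I_P - (1-alpha) f_up)/alpha passed to the next cell.
    ``vol_src`` carries dx dy (history + scattering + any volume source);
    ``ct_area`` carries dx dy times the implicit time-derivative coefficient.

    in_x (ny, M) / in_y (nx, M): incoming boundary faces on the quadrant's
    upstream sides; out_x / out_y receive the exit faces on the downstream
    sides.  I_new is written in place for the swept ordinates.
    """
    nx, ny = mu_t.shape
    area = dx * dy
    if sy > 0:
        j0, j1, js = 0, ny, 1
    else:
        j0, j1, js = ny - 1, -1, -1
    if sx > 0:
        i0, i1, istep = 0, nx, 1
    else:
        i0, i1, istep = nx - 1, -1, -1
    fy = np.empty(nx)
    for k in range(ords.shape[0]):
        m = ords[k]
        A = dy * abs(xi[m]) / alpha
        B = dx * abs(eta[m]) / alpha
        for i in range(nx):
            fy[i] = in_y[i, m]
        for j in range(j0, j1, js):
            fx = in_x[j, m]
            for i in range(i0, i1, istep):
                denom = ct_area + A + B + area * mu_t[i, j]
                Ip = (A * fx + B * fy[i] + vol_src[i, j, m]) / denom
                I_new[i, j, m] = Ip
                fx = (Ip - (1.0 - alpha) * fx) / alpha
                fy[i] = (Ip - (1.0 - alpha) * fy[i]) / alpha
            out_x[j, m] = fx
        for i in range(nx):
            out_y[i, m] = fy[i]


@njit(cache=False)
def _fresnel_R(cos_inc, n_m, n_0):
    """Boundary reflectivity for incidence cosine |Omega.n| (R = 1 beyond TIR)."""
    if cos_inc < 1e-12:
        return 1.0
    sin_inc = np.sqrt(max(0.0, 1.0 - cos_inc * cos_inc))
    sin_tra = n_m * sin_inc / n_0
    if sin_tra >= 1.0:
        return 1.0
    cos_tra = np.sqrt(1.0 - sin_tra * sin_tra)
    a = n_m * cos_tra
    b = n_0 * cos_inc
    r = (a - b) / (a + b)
    return r * r


@njit(cache=False)
def mc_transport(n_photons, seed, x_start, y_start, ux0, uy0,
                 dx, dy, mu_a, mu_s, gidx, ang_tables,
                 n_m, n_0, ap_cos, max_segments,
                 fluence_tl, trans_sides, det_sides, det2_sides, cnt_sides):
    """Analog 2D photon random walk with Fresnel boundaries.

    Photons start at (x_start, y_start) with direction (ux0, uy0) and unit
    weight.  Free paths are sampled cell-locally from exp(-(mu_a+mu_s) s);
    collisions absorb with probability mu_a/mu_t, else deflect in-plane by an
    angle drawn from the tabulated inverse CDF ``ang_tables[gidx]``.  At the
    outer boundary the photon is specularly reflected with probability R
    (same Fresnel relation as the deterministic solver) or escapes.

    Tallies (all per launched photon, unnormalized):
      fluence_tl[i, j]      track length (cm) deposited per cell
      trans_sides[s, f]     1/|cos| per escape through face f of side s
      det_sides[s, f]       same, restricted to the aperture cone
      det2_sides[s, f]      squared aperture contributions (for SE)
      cnt_sides[s, f]       escape counts
    Side order: 0=bottom, 1=top, 2=left, 3=right.
    Returns (n_absorbed, n_escaped, n_capped).
    """
    np.random.seed(seed)
    nx, ny = mu_a.shape
    K = ang_tables.shape[1]
    n_abs = 0
    n_esc = 0
    n_cap = 0
    for _p in range(n_photons):
        x = x_start
        y = y_start
        ux = ux0
        uy = uy0
        i = int(x / dx)
        if i < 0:
            i = 0
        if i > nx - 1:
            i = nx - 1
        j = int(y / dy)
        if j < 0:
            j = 0
        if j > ny - 1:
            j = ny - 1
        tau = -np.log(np.random.random())
        seg = 0
        alive = True
        while alive:
            seg += 1
            if seg > max_segments:
                n_cap += 1
                break
            if ux > 1e-15:
                tx = ((i + 1) * dx - x) / ux
            elif ux < -1e-15:
                tx = (i * dx - x) / ux
            else:
                tx = 1e30
            if uy > 1e-15:
                ty = ((j + 1) * dy - y) / uy
            elif uy < -1e-15:
                ty = (j * dy - y) / uy
            else:
                ty = 1e30
            t_face = tx if tx < ty else ty
            if t_face < 0.0:
                t_face = 0.0
            mu = mu_a[i, j] + mu_s[i, j]
            if mu > 0.0 and tau < mu * t_face:
                s = tau / mu
                x += ux * s
                y += uy * s
                fluence_tl[i, j] += s
                if np.random.random() < mu_a[i, j] / mu:
                    n_abs += 1
                    alive = False
                else:
                    u = np.random.random() * (K - 1)
                    ki = int(u)
                    if ki >= K - 1:
                        ki = K - 2
                    frac = u - ki
                    g_i = gidx[i, j]
                    psi = (ang_tables[g_i, ki] * (1.0 - frac)
                           + ang_tables[g_i, ki + 1] * frac)
                    c = np.cos(psi)
                    sn = np.sin(psi)
                    ux_new = ux * c - uy * sn
                    uy = ux * sn + uy * c
                    ux = ux_new
                    tau = -np.log(np.random.random())
            else:
                fluence_tl[i, j] += t_face
                tau -= mu * t_face
                x += ux * t_face
                y += uy * t_face
                if tx <= ty:  # crossing a vertical face
                    if ux > 0.0:
                        if i == nx - 1:
                            cos_inc = ux
                            if np.random.random() < _fresnel_R(cos_inc, n_m, n_0):
                                ux = -ux
                                x = nx * dx
                            else:
                                n_esc += 1
                                w = 1.0 / cos_inc
                                trans_sides[3, j] += w
                                cnt_sides[3, j] += 1.0
                                if cos_inc >= ap_cos:
                                    det_sides[3, j] += w
                                    det2_sides[3, j] += w * w
                                alive = False
                        else:
                            i += 1
                            x = i * dx
                    else:
                        if i == 0:
                            cos_inc = -ux
                            if np.random.random() < _fresnel_R(cos_inc, n_m, n_0):
                                ux = -ux
                                x = 0.0
                            else:
                                n_esc += 1
                                w = 1.0 / cos_inc
                                trans_sides[2, j] += w
                                cnt_sides[2, j] += 1.0
                                if cos_inc >= ap_cos:
                                    det_sides[2, j] += w
                                    det2_sides[2, j] += w * w
                                alive = False
                        else:
                            x = i * dx
                            i -= 1
                else:  # crossing a horizontal face
                    if uy > 0.0:
                        if j == ny - 1:
                            cos_inc = uy
                            if np.random.random() < _fresnel_R(cos_inc, n_m, n_0):
                                uy = -uy
                                y = ny * dy
                            else:
                                n_esc += 1
                                w = 1.0 / cos_inc
                                trans_sides[1, i] += w
                                cnt_sides[1, i] += 1.0
                                if cos_inc >= ap_cos:
                                    det_sides[1, i] += w
                                    det2_sides[1, i] += w * w
                                alive = False
                        else:
                            j += 1
                            y = j * dy
                    else:
                        if j == 0:
                            cos_inc = -uy
                            if np.random.random() < _fresnel_R(cos_inc, n_m, n_0):
                                uy = -uy
                                y = 0.0
                            else:
                                n_esc += 1
                                w = 1.0 / cos_inc
                                trans_sides[0, i] += w
                                cnt_sides[0, i] += 1.0
                                if cos_inc >= ap_cos:
                                    det_sides[0, i] += w
                                    det2_sides[0, i] += w * w
                                alive = False
                        else:
                            y = j * dy
                            j -= 1
    return n_abs, n_esc, n_cap
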