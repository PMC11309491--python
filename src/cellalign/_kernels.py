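"""Compiled numerical kernels.

Everything here operates on plain float64 arrays so the hot loop (pairwise
ellipse boundary intersection + explicit Euler stepping) runs inside numba.
The public modules (:mod:`cellalign.geometry`, :mod:`cellalign.engine`, ...)
wrap these kernels in typed containers.

Conventions
-----------
* The box is ``[0, L)^2`` with periodic boundaries; pair displacements use the
  minimum-image convention mapping each component into ``(-L/2, L/2]``.
* An ellipse is ``X + cosθ·a·e(α) + sinθ·b·e⊥(α)`` with ``e⊥`` the left-turn
  of ``e`` (``(x, y) -> (-y, x)``); θ increasing traverses the boundary
  anticlockwise.
* Boundary crossings of a pair are found by substituting cell i's boundary
  parameterisation into cell j's implicit quadratic, which after the
  Weierstrass substitution ``t = tan(θ/2)`` is a real quartic.  The quartic is
  solved in closed form (resolvent cubic) and every root is polished by Newton
  iteration directly on the trigonometric residual ``f(θ)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# residual tolerance for an accepted boundary crossing; the public contract is
# |Q| < 1e-8 on both implicit quadratics, we polish well below that
_ROOT_TOL = 1e-10
# boundary-coordinate distance below which two roots merge (tangency)
_MERGE_TOL = 1e-8

TWO_PI = 2.0 * np.pi

# pair-contact flags
FLAG_OK = 0
FLAG_I_IN_J = 1
FLAG_J_IN_I = 2
FLAG_COINCIDENT = 3
FLAG_TANGENT = 4        # crossings remain after a tangency was discarded


@njit(cache=True)
def min_image_1d(x, L):
    """Map a displacement component into (-L/2, L/2]."""
    y = x - L * np.floor(x / L + 0.5)
    if y <= -0.5 * L:
        y += L
    return y


@njit(cache=True)
def _cbrt(x):
    if x >= 0.0:
        return x ** (1.0 / 3.0)
    return -((-x) ** (1.0 / 3.0))


@njit(cache=True)
def _cubic_roots(b2, b1, b0):
    """All three complex roots of z^3 + b2 z^2 + b1 z + b0 (real coeffs)."""
    shift = b2 / 3.0
    p = b1 - b2 * b2 / 3.0
    q = 2.0 * b2 ** 3 / 27.0 - b2 * b1 / 3.0 + b0
    disc = 0.25 * q * q + p ** 3 / 27.0
    if disc >= 0.0:
        sq = np.sqrt(disc)
        u = _cbrt(-0.5 * q + sq)
        v = _cbrt(-0.5 * q - sq)
        t1 = u + v
        re = -0.5 * t1
        im = 0.5 * np.sqrt(3.0) * (u - v)
        z1 = complex(t1 - shift, 0.0)
        z2 = complex(re - shift, im)
        z3 = complex(re - shift, -im)
        return z1, z2, z3
    # three real roots (trigonometric form)
    m = 2.0 * np.sqrt(-p / 3.0)
    arg = 3.0 * q / (p * m)
    if arg > 1.0:
        arg = 1.0
    elif arg < -1.0:
        arg = -1.0
    phi = np.arccos(arg) / 3.0
    z1 = complex(m * np.cos(phi) - shift, 0.0)
    z2 = complex(m * np.cos(phi - TWO_PI / 3.0) - shift, 0.0)
    z3 = complex(m * np.cos(phi + TWO_PI / 3.0) - shift, 0.0)
    return z1, z2, z3


@njit(cache=True)
def _quartic_roots(c4, c3, c2, c1, c0):
    """All four complex roots of c4 t^4 + ... + c0 (|c4| not tiny)."""
    a = c3 / c4
    b = c2 / c4
    c = c1 / c4
    d = c0 / c4
    # depressed quartic y^4 + p y^2 + q y + r, t = y - a/4
    p = b - 3.0 * a * a / 8.0
    q = c - 0.5 * a * b + a ** 3 / 8.0
    r = d - 0.25 * a * c + a * a * b / 16.0 - 3.0 * a ** 4 / 256.0
    shift = 0.25 * a
    # resolvent cubic m^3 + 2p m^2 + (p^2 - 4r) m - q^2 = 0; pick largest real root
    z1, z2, z3 = _cubic_roots(2.0 * p, p * p - 4.0 * r, -q * q)
    m = z1.real
    if abs(z2.imag) < 1e-9 and z2.real > m:
        m = z2.real
    if abs(z3.imag) < 1e-9 and z3.real > m:
        m = z3.real
    scale = 1.0 + abs(p) + abs(q) + abs(r)
    if m > 1e-14 * scale:
        s = np.sqrt(complex(m, 0.0))
        half = 0.5 * (p + m)
        qq = q / (2.0 * s)
        c1a = half - qq
        c2a = half + qq
        d1 = np.sqrt(s * s * 0.25 - c1a)
        d2 = np.sqrt(s * s * 0.25 - c2a)
        y1 = -0.5 * s + d1
        y2 = -0.5 * s - d1
        y3 = 0.5 * s + d2
        y4 = 0.5 * s - d2
    else:
        # biquadratic: y^2 = (-p ± sqrt(p^2 - 4r)) / 2
        disc = np.sqrt(complex(p * p - 4.0 * r, 0.0))
        w1 = np.sqrt(0.5 * (-p + disc))
        w2 = np.sqrt(0.5 * (-p - disc))
        y1 = w1
        y2 = -w1
        y3 = w2
        y4 = -w2
    return y1 - shift, y2 - shift, y3 - shift, y4 - shift


@njit(cache=True)
def _f_eval(theta, A, B, C, D, E, F):
    c = np.cos(theta)
    s = np.sin(theta)
    return A * c * c + B * c * s + C * s * s + D * c + E * s + F


@njit(cache=True)
def _fprime_eval(theta, A, B, C, D, E, F):
    c = np.cos(theta)
    s = np.sin(theta)
    return 2.0 * (C - A) * s * c + B * (c * c - s * s) - D * s + E * c


@njit(cache=True)
def _polish(theta, A, B, C, D, E, F):
    """Newton-polish a candidate crossing angle on f(θ)."""
    for _ in range(16):
        fv = _f_eval(theta, A, B, C, D, E, F)
        fp = _fprime_eval(theta, A, B, C, D, E, F)
        if abs(fp) < 1e-14:
            break
        step = fv / fp
        theta -= step
        if abs(step) < 1e-13:
            break
    return theta


@njit(cache=True)
def _trig_coeffs(wx, wy, ca, sa, ai, bi, cb, sb, aj, bj):
    """Coefficients of f(θ) = Q_j(x_i(θ)) = A cos²θ + B cosθ sinθ + C sin²θ
    + D cosθ + E sinθ + F, the residual of i's boundary point in j's implicit
    quadratic."""
    # j-frame unit axes
    ujx, ujy = cb, sb
    vjx, vjy = -sb, cb
    uix, uiy = ca, sa
    vix, viy = -sa, ca
    # p(θ) - X_j = (cosθ ai u_i + sinθ bi v_i) - w ; components in j's scaled frame
    Px = (-wx * ujx - wy * ujy) / aj
    Py = (-wx * vjx - wy * vjy) / bj
    Ux = ai * (uix * ujx + uiy * ujy) / aj
    Uy = ai * (uix * vjx + uiy * vjy) / bj
    Vx = bi * (vix * ujx + viy * ujy) / aj
    Vy = bi * (vix * vjx + viy * vjy) / bj
    A = Ux * Ux + Uy * Uy
    B = 2.0 * (Ux * Vx + Uy * Vy)
    C = Vx * Vx + Vy * Vy
    D = 2.0 * (Px * Ux + Py * Uy)
    E = 2.0 * (Px * Vx + Py * Vy)
    F = Px * Px + Py * Py - 1.0
    return A, B, C, D, E, F


@njit(cache=True)
def _pair_contact(wx, wy, ca, sa, ai, bi, cb, sb, aj, bj, thetas):
    """Boundary crossings of ellipse i (origin, orientation (ca,sa), axes
    ai>=bi) with ellipse j (centre (wx,wy), orientation (cb,sb), axes aj>=bj).

    Fills ``thetas[:n]`` with crossing angles on i's boundary, sorted
    ascending in [0, 2π); returns ``(n, flag)`` with n in {0, 2, 4}.
    """
    A, B, C, D, E, F = _trig_coeffs(wx, wy, ca, sa, ai, bi, cb, sb, aj, bj)

    # quartic in t = tan(θ/2)
    c4 = A - D + F
    c3 = 2.0 * (E - B)
    c2 = -2.0 * A + 4.0 * C + 2.0 * F
    c1 = 2.0 * (B + E)
    c0 = A + D + F
    cmax = max(abs(c4), abs(c3), abs(c2), abs(c1), abs(c0))
    if cmax < 1e-12:
        return 0, FLAG_COINCIDENT

    cand = np.empty(5)
    ncand = 0
    if abs(c4) > 1e-9 * cmax:
        z1, z2, z3, z4 = _quartic_roots(c4, c3, c2, c1, c0)
        cand[0] = 2.0 * np.arctan(z1.real)
        cand[1] = 2.0 * np.arctan(z2.real)
        cand[2] = 2.0 * np.arctan(z3.real)
        cand[3] = 2.0 * np.arctan(z4.real)
        ncand = 4
    else:
        # θ = π is (nearly) a crossing; remaining crossings from the cubic
        cand[0] = np.pi
        ncand = 1
        if abs(c3) > 1e-9 * cmax:
            z1, z2, z3 = _cubic_roots(c2 / c3, c1 / c3, c0 / c3)
            cand[1] = 2.0 * np.arctan(z1.real)
            cand[2] = 2.0 * np.arctan(z2.real)
            cand[3] = 2.0 * np.arctan(z3.real)
            ncand = 4
        elif abs(c2) > 1e-9 * cmax:
            disc = c1 * c1 - 4.0 * c2 * c0
            if disc >= 0.0:
                sq = np.sqrt(disc)
                cand[1] = 2.0 * np.arctan((-c1 + sq) / (2.0 * c2))
                cand[2] = 2.0 * np.arctan((-c1 - sq) / (2.0 * c2))
                ncand = 3
        elif abs(c1) > 1e-9 * cmax:
            cand[1] = 2.0 * np.arctan(-c0 / c1)
            ncand = 2

    # polish in θ, accept true roots, wrap to [0, 2π)
    acc = np.empty(5)
    nacc = 0
    for k in range(ncand):
        th = _polish(cand[k], A, B, C, D, E, F)
        if abs(_f_eval(th, A, B, C, D, E, F)) < _ROOT_TOL:
            th = th % TWO_PI
            acc[nacc] = th
            nacc += 1
    # sort (insertion, n<=5)
    for k in range(1, nacc):
        key = acc[k]
        m = k - 1
        while m >= 0 and acc[m] > key:
            acc[m + 1] = acc[m]
            m -= 1
        acc[m + 1] = key
    # merge near-duplicates (tangency), incl. cyclic wrap
    merged = False
    n = 0
    for k in range(nacc):
        if n > 0 and acc[k] - thetas[n - 1] < _MERGE_TOL:
            merged = True
            continue
        thetas[n] = acc[k]
        n += 1
    if n > 1 and (thetas[0] + TWO_PI) - thetas[n - 1] < _MERGE_TOL:
        n -= 1
        merged = True
    # odd counts reduce: drop the most tangential point (smallest |f'|)
    if n % 2 == 1:
        merged = True
        if n == 1:
            n = 0
        else:
            kmin = 0
            fmin = abs(_fprime_eval(thetas[0], A, B, C, D, E, F))
            for k in range(1, n):
                fp = abs(_fprime_eval(thetas[k], A, B, C, D, E, F))
                if fp < fmin:
                    fmin = fp
                    kmin = k
            for k in range(kmin, n - 1):
                thetas[k] = thetas[k + 1]
            n -= 1
    if n == 0:
        # containment tests: no crossings, one boundary wholly in/out
        if _f_eval(0.0, A, B, C, D, E, F) < 0.0:
            return 0, FLAG_I_IN_J
        di = (wx * ca + wy * sa) / ai
        dj = (-wx * sa + wy * ca) / bi
        if di * di + dj * dj < 1.0:
            return 0, FLAG_J_IN_I
        return 0, FLAG_OK
    if merged:
        return n, FLAG_TANGENT
    return n, FLAG_OK


@njit(cache=True)
def _order_pairs(thetas, n, A, B, C, D, E, F):
    """Rotate sorted crossing angles so consecutive pairs (0,1),(2,3) bound
    anticlockwise arcs of cell i lying inside cell j.  Entries may exceed 2π
    after rotation (the wrapped arc)."""
    mid = 0.5 * (thetas[0] + thetas[1])
    if _f_eval(mid, A, B, C, D, E, F) < 0.0:
        return
    first = thetas[0]
    for k in range(n - 1):
        thetas[k] = thetas[k + 1]
    thetas[n - 1] = first + TWO_PI


@njit(cache=True)
def _pair_contact_full(wx, wy, ca, sa, ai, bi, cb, sb, aj, bj, thetas):
    """Contact with i's angles ordered/paired (arc inside j). Returns (n, flag)."""
    n, flag = _pair_contact(wx, wy, ca, sa, ai, bi, cb, sb, aj, bj, thetas)
    if n >= 2:
        A, B, C, D, E, F = _trig_coeffs(wx, wy, ca, sa, ai, bi, cb, sb, aj, bj)
        _order_pairs(thetas, n, A, B, C, D, E, F)
    return n, flag


@njit(cache=True)
def _inside_ellipse(px, py, ca, sa, a, b):
    """Is the point (relative to the ellipse centre) strictly inside?"""
    du = (px * ca + py * sa) / a
    dv = (-px * sa + py * ca) / b
    return du * du + dv * dv < 1.0


@njit(cache=True)
def _sep_axis_disjoint(wx, wy, ca, sa, ai, bi, cb, sb, aj, bj):
    """Cheap sufficient test for disjointness: separating axis along the
    centre line (extent of an ellipse along unit d is
    sqrt(a²(e·d)² + b²(e⊥·d)²))."""
    d = np.sqrt(wx * wx + wy * wy)
    if d < 1e-12:
        return False
    dx = wx / d
    dy = wy / d
    pi_ = ca * dx + sa * dy
    qi = -sa * dx + ca * dy
    ext_i = np.sqrt(ai * ai * pi_ * pi_ + bi * bi * qi * qi)
    pj = cb * dx + sb * dy
    qj = -sb * dx + cb * dy
    ext_j = np.sqrt(aj * aj * pj * pj + bj * bj * qj * qj)
    return d > ext_i + ext_j


@njit(cache=True)
def compute_rhs(X, alpha, r, L, nu, gamma, rbar, kappa, mu, lam,
                shape_on, junctions_on, dX, dA, dR, counters):
    """Full model right-hand side at the given state.

    dX, dA, dR are output arrays (overwritten).  counters accumulates
    [containment events, coincidence jitters, lower r-clamps, upper r-clamps]
    (clamp slots are filled by the step loop).  May perturb X/alpha in place
    by 1e-6 when a coincident pair is met (deterministic jitter, logged).
    """
    N = X.shape[0]
    for i in range(N):
        dX[i, 0] = nu * np.cos(alpha[i])
        dX[i, 1] = nu * np.sin(alpha[i])
        dA[i] = 0.0
        if shape_on:
            ri = r[i]
            dR[i] = 16.0 * gamma * (1.0 + rbar * ri ** 3) / (1.0 + ri * ri) \
                * (1.0 - ri / rbar)
        else:
            dR[i] = 0.0

    thetas = np.empty(5)
    thj = np.empty(5)
    ptx = np.empty(4)
    pty = np.empty(4)

    for i in range(N):
        ai = np.sqrt(r[i])
        bi = 1.0 / ai
        ca = np.cos(alpha[i])
        sa = np.sin(alpha[i])
        for j in range(i + 1, N):
            aj = np.sqrt(r[j])
            bj = 1.0 / aj
            wx = min_image_1d(X[j, 0] - X[i, 0], L)
            wy = min_image_1d(X[j, 1] - X[i, 1], L)
            d2 = wx * wx + wy * wy
            rcut = ai + aj
            jcut = rcut + lam
            if d2 >= jcut * jcut and d2 >= rcut * rcut:
                continue
            cb = np.cos(alpha[j])
            sb = np.sin(alpha[j])

            # --- overlap avoidance ---
            if d2 < rcut * rcut and not _sep_axis_disjoint(
                    wx, wy, ca, sa, ai, bi, cb, sb, aj, bj):
                n, flag = _pair_contact_full(
                    wx, wy, ca, sa, ai, bi, cb, sb, aj, bj, thetas)
                if flag == FLAG_COINCIDENT:
                    # deterministic infinitesimal jitter, then retry once
                    X[j, 0] += 1e-6
                    alpha[j] = (alpha[j] + 1e-6) % TWO_PI
                    cb = np.cos(alpha[j])
                    sb = np.sin(alpha[j])
                    wx = min_image_1d(X[j, 0] - X[i, 0], L)
                    counters[1] += 1
                    n, flag = _pair_contact_full(
                        wx, wy, ca, sa, ai, bi, cb, sb, aj, bj, thetas)
                if flag == FLAG_I_IN_J or flag == FLAG_J_IN_I:
                    counters[0] += 1
                    d = np.sqrt(d2)
                    if d < 1e-12:
                        ex, ey = ca, sa
                    else:
                        ex, ey = wx / d, wy / d
                    if flag == FLAG_I_IN_J:
                        dX[i, 0] -= bj * ex
                        dX[i, 1] -= bj * ey
                    else:
                        dX[j, 0] += bi * ex
                        dX[j, 1] += bi * ey
                elif n >= 2:
                    pref_i = 2.0 * r[i] / (r[i] * r[i] + 1.0)
                    shp_i = 4.0 * r[i] * r[i] / (r[i] * r[i] + 1.0)
                    for m in range(n):
                        th = thetas[m]
                        ptx[m] = np.cos(th) * ai * ca - np.sin(th) * bi * sa
                        pty[m] = np.cos(th) * ai * sa + np.sin(th) * bi * ca
                    for k in range(0, n, 2):
                        y1x, y1y = ptx[k], pty[k]
                        y2x, y2y = ptx[k + 1], pty[k + 1]
                        chx = y1x - y2x
                        chy = y1y - y2y
                        # -(Y1 - Y2)^perp, perp = left turn (x,y)->(-y,x)
                        dX[i, 0] -= -chy
                        dX[i, 1] -= chx
                        dA[i] += pref_i * ((y2x * y2x + y2y * y2y)
                                           - (y1x * y1x + y1y * y1y))
                        if shape_on:
                            dR[i] += shp_i * (np.sin(2.0 * thetas[k])
                                              - np.sin(2.0 * thetas[k + 1]))
                    # same physical points, from cell j's perspective
                    for m in range(n):
                        qx = ptx[m] - wx
                        qy = pty[m] - wy
                        thj[m] = np.arctan2((-qx * sb + qy * cb) / bj,
                                            (qx * cb + qy * sb) / aj) % TWO_PI
                    for k in range(1, n):
                        key = thj[k]
                        m2 = k - 1
                        while m2 >= 0 and thj[m2] > key:
                            thj[m2 + 1] = thj[m2]
                            m2 -= 1
                        thj[m2 + 1] = key
                    # rotate so arcs of j between pairs lie inside i
                    mid = 0.5 * (thj[0] + thj[1])
                    mx = np.cos(mid) * aj * cb - np.sin(mid) * bj * sb + wx
                    my = np.cos(mid) * aj * sb + np.sin(mid) * bj * cb + wy
                    if not _inside_ellipse(mx, my, ca, sa, ai, bi):
                        first = thj[0]
                        for k in range(n - 1):
                            thj[k] = thj[k + 1]
                        thj[n - 1] = first + TWO_PI
                    pref_j = 2.0 * r[j] / (r[j] * r[j] + 1.0)
                    shp_j = 4.0 * r[j] * r[j] / (r[j] * r[j] + 1.0)
                    for k in range(0, n, 2):
                        t1 = thj[k]
                        t2 = thj[k + 1]
                        y1x = np.cos(t1) * aj * cb - np.sin(t1) * bj * sb
                        y1y = np.cos(t1) * aj * sb + np.sin(t1) * bj * cb
                        y2x = np.cos(t2) * aj * cb - np.sin(t2) * bj * sb
                        y2y = np.cos(t2) * aj * sb + np.sin(t2) * bj * cb
                        chx = y1x - y2x
                        chy = y1y - y2y
                        dX[j, 0] -= -chy
                        dX[j, 1] -= chx
                        dA[j] += pref_j * ((y2x * y2x + y2y * y2y)
                                           - (y1x * y1x + y1y * y1y))
                        if shape_on:
                            dR[j] += shp_j * (np.sin(2.0 * t1)
                                              - np.sin(2.0 * t2))

            # --- junctions + actin ---
            if junctions_on and lam > 0.0 and d2 < jcut * jcut:
                tq_i = 4.0 * kappa * r[i] ** 1.5 / (r[i] * r[i] + 1.0)
                tq_j = 4.0 * kappa * r[j] ** 1.5 / (r[j] * r[j] + 1.0)
                ac_i = mu * r[i] / (r[i] * r[i] + 1.0)
                ac_j = mu * r[j] / (r[j] * r[j] + 1.0)
                sdiff = np.sin(alpha[i] - alpha[j])
                for si in (-1.0, 1.0):
                    eix = si * ai * ca
                    eiy = si * ai * sa
                    for sj in (-1.0, 1.0):
                        sepx = (wx + sj * aj * cb) - eix
                        sepy = (wy + sj * aj * sb) - eiy
                        if sepx * sepx + sepy * sepy < lam * lam:
                            dX[i, 0] += kappa * sepx
                            dX[i, 1] += kappa * sepy
                            dX[j, 0] -= kappa * sepx
                            dX[j, 1] -= kappa * sepy
                            # torque: separation · (s · e_perp)
                            dA[i] += tq_i * (si * (-sepx * sa + sepy * ca))
                            dA[j] += tq_j * (sj * (sepx * sb - sepy * cb))
                            if si * sj < 0.0:   # fb: polar alignment
                                dA[i] += ac_i * (-sdiff)
                                dA[j] += ac_j * sdiff
                            else:               # ff/bb: anti-polar
                                dA[i] += ac_i * sdiff
                                dA[j] += ac_j * (-sdiff)
    return 0


@njit(cache=True)
def run_steps(X, alpha, r, n_steps, L, dt, nu, gamma, rbar, kappa, mu, lam,
              shape_on, junctions_on, counters):
    """Advance the population n_steps explicit-Euler steps in place.

    Returns 0, or 1 if any state component became non-finite."""
    N = X.shape[0]
    dX = np.empty((N, 2))
    dA = np.empty(N)
    dR = np.empty(N)
    for _ in range(n_steps):
        compute_rhs(X, alpha, r, L, nu, gamma, rbar, kappa, mu, lam,
                    shape_on, junctions_on, dX, dA, dR, counters)
        for i in range(N):
            X[i, 0] = (X[i, 0] + dt * dX[i, 0]) % L
            X[i, 1] = (X[i, 1] + dt * dX[i, 1]) % L
            alpha[i] = (alpha[i] + dt * dA[i]) % TWO_PI
            if shape_on:
                ri = r[i] + dt * dR[i]
                if ri < 1.0:
                    ri = 1.0
                    counters[2] += 1
                elif ri > 16.0:
                    ri = 16.0
                    counters[3] += 1
                r[i] = ri
            if not (np.isfinite(X[i, 0]) and np.isfinite(X[i, 1])
                    and np.isfinite(alpha[i]) and np.isfinite(r[i])):
                return 1
    return 0
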