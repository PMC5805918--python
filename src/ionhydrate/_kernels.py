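"""Jitted numerical kernels: rigid-body energy/gradient and L-BFGS quench.

Everything here is a plain-array implementation of what ``energy`` and
``optimize`` expose at the object level, compiled with numba when it is
available.  The pure-numpy path in ``energy`` remains the reference
implementation; both are cross-checked in the test suite.
"""
from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # no-op decorator fallback
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _rotmat(p):
    """Rodrigues rotation matrix for rotation vector p (3,)."""
    R = np.empty((3, 3))
    t2 = p[0] * p[0] + p[1] * p[1] + p[2] * p[2]
    if t2 < 1e-16:
        # second-order Taylor: I + [p]x + 0.5 [p]x^2
        R[0, 0] = 1.0 - 0.5 * (p[1] * p[1] + p[2] * p[2])
        R[1, 1] = 1.0 - 0.5 * (p[0] * p[0] + p[2] * p[2])
        R[2, 2] = 1.0 - 0.5 * (p[0] * p[0] + p[1] * p[1])
        R[0, 1] = -p[2] + 0.5 * p[0] * p[1]
        R[1, 0] = p[2] + 0.5 * p[0] * p[1]
        R[0, 2] = p[1] + 0.5 * p[0] * p[2]
        R[2, 0] = -p[1] + 0.5 * p[0] * p[2]
        R[1, 2] = -p[0] + 0.5 * p[1] * p[2]
        R[2, 1] = p[0] + 0.5 * p[1] * p[2]
        return R
    theta = np.sqrt(t2)
    kx, ky, kz = p[0] / theta, p[1] / theta, p[2] / theta
    c = np.cos(theta)
    s = np.sin(theta)
    C = 1.0 - c
    R[0, 0] = c + kx * kx * C
    R[0, 1] = kx * ky * C - kz * s
    R[0, 2] = kx * kz * C + ky * s
    R[1, 0] = ky * kx * C + kz * s
    R[1, 1] = c + ky * ky * C
    R[1, 2] = ky * kz * C - kx * s
    R[2, 0] = kz * kx * C - ky * s
    R[2, 1] = kz * ky * C + kx * s
    R[2, 2] = c + kz * kz * C
    return R


@njit(cache=True)
def _skew3(v):
    S = np.zeros((3, 3))
    S[0, 1] = -v[2]
    S[0, 2] = v[1]
    S[1, 0] = v[2]
    S[1, 2] = -v[0]
    S[2, 0] = -v[1]
    S[2, 1] = v[0]
    return S


@njit(cache=True)
def _drotmat(p, R):
    """dR/dp_k for k = 0..2, shape (3, 3, 3); closed form with R given."""
    out = np.empty((3, 3, 3))
    t2 = p[0] * p[0] + p[1] * p[1] + p[2] * p[2]
    if t2 < 1e-20:
        for k in range(3):
            e = np.zeros(3)
            e[k] = 1.0
            out[k] = _skew3(e)
        return out
    Px = _skew3(p)
    for k in range(3):
        # v = (I - R) e_k  (k-th column of I - R)
        v = np.empty(3)
        for i in range(3):
            v[i] = (1.0 if i == k else 0.0) - R[i, k]
        cr = np.empty(3)
        cr[0] = p[1] * v[2] - p[2] * v[1]
        cr[1] = p[2] * v[0] - p[0] * v[2]
        cr[2] = p[0] * v[1] - p[1] * v[0]
        A = (p[k] * Px + _skew3(cr)) / t2
        out[k] = A @ R
    return out


@njit(cache=True)
def eval_energy_gradient(x, body, eps, sig, q, molid, nmol, geometric, k_c):
    """Energy, packed gradient (6M,), and minimum inter-molecular distance.

    x is the packed (6M,) rigid-body coordinate vector.
    """
    n = body.shape[0]
    X = x.reshape(nmol, 6)
    Rs = np.empty((nmol, 3, 3))
    for m in range(nmol):
        Rs[m] = _rotmat(X[m, 3:])
    pos = np.empty((n, 3))
    for s in range(n):
        m = molid[s]
        for i in range(3):
            pos[s, i] = (
                Rs[m, i, 0] * body[s, 0]
                + Rs[m, i, 1] * body[s, 1]
                + Rs[m, i, 2] * body[s, 2]
                + X[m, i]
            )
    U = 0.0
    gs = np.zeros((n, 3))
    rmin = 1e30
    for i in range(n - 1):
        mi = molid[i]
        qi = q[i]
        epsi = eps[i]
        sigi = sig[i]
        for j in range(i + 1, n):
            if molid[j] == mi:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            r = np.sqrt(r2)
            if r < rmin:
                rmin = r
            e = 0.0
            dudr = 0.0
            qq = qi * q[j]
            if qq != 0.0:
                ec = k_c * qq / r
                e += ec
                dudr -= ec / r
            if epsi > 0.0 and eps[j] > 0.0 and sigi > 0.0 and sig[j] > 0.0:
                epsij = np.sqrt(epsi * eps[j])
                if geometric:
                    sigij = np.sqrt(sigi * sig[j])
                else:
                    sigij = 0.5 * (sigi + sig[j])
                s2 = sigij * sigij / r2
                sr6 = s2 * s2 * s2
                sr12 = sr6 * sr6
                e += 4.0 * epsij * (sr12 - sr6)
                dudr += 4.0 * epsij * (-12.0 * sr12 + 6.0 * sr6) / r
            U += e
            c = dudr / r
            gs[i, 0] += c * dx
            gs[i, 1] += c * dy
            gs[i, 2] += c * dz
            gs[j, 0] -= c * dx
            gs[j, 1] -= c * dy
            gs[j, 2] -= c * dz
    g = np.zeros(6 * nmol)
    for m in range(nmol):
        dR = _drotmat(X[m, 3:], Rs[m])
        base = 6 * m
        for s in range(n):
            if molid[s] != m:
                continue
            g[base] += gs[s, 0]
            g[base + 1] += gs[s, 1]
            g[base + 2] += gs[s, 2]
            for k in range(3):
                vx = (
                    dR[k, 0, 0] * body[s, 0]
                    + dR[k, 0, 1] * body[s, 1]
                    + dR[k, 0, 2] * body[s, 2]
                )
                vy = (
                    dR[k, 1, 0] * body[s, 0]
                    + dR[k, 1, 1] * body[s, 1]
                    + dR[k, 1, 2] * body[s, 2]
                )
                vz = (
                    dR[k, 2, 0] * body[s, 0]
                    + dR[k, 2, 1] * body[s, 1]
                    + dR[k, 2, 2] * body[s, 2]
                )
                g[base + 3 + k] += gs[s, 0] * vx + gs[s, 1] * vy + gs[s, 2] * vz
    return U, g, rmin


@njit(cache=True)
def lbfgs_quench(
    x0, body, eps, sig, q, molid, nmol, geometric, k_c, gtol, maxiter
):
    """L-BFGS minimization of the cluster energy, fully jitted.

    Returns (x, energy, gmax, converged_flag, n_evals).  Uses a two-loop
    recursion with memory 8 and Armijo backtracking; non-finite or
    collapsing trial energies are treated as +inf and backtracked.
    """
    mmem = 8
    ndof = x0.shape[0]
    x = x0.copy()
    f, g, rmin = eval_energy_gradient(x, body, eps, sig, q, molid, nmol, geometric, k_c)
    nev = 1
    if not np.isfinite(f) or rmin < 0.5:
        return x, f, 1e30, 0, nev
    S = np.zeros((mmem, ndof))
    Y = np.zeros((mmem, ndof))
    rho = np.zeros(mmem)
    nstored = 0
    head = 0  # next slot to write
    gamma = 1.0
    alpha_work = np.zeros(mmem)
    for it in range(maxiter):
        gmax = 0.0
        for i in range(ndof):
            a = abs(g[i])
            if a > gmax:
                gmax = a
        if gmax <= gtol:
            return x, f, gmax, 1, nev
        # two-loop recursion
        d = -g.copy()
        for c in range(nstored):
            idx = (head - 1 - c) % mmem
            alpha_work[idx] = rho[idx] * np.dot(S[idx], d)
            d -= alpha_work[idx] * Y[idx]
        d *= gamma
        for c in range(nstored - 1, -1, -1):
            idx = (head - 1 - c) % mmem
            beta = rho[idx] * np.dot(Y[idx], d)
            d += (alpha_work[idx] - beta) * S[idx]
        dg = np.dot(d, g)
        if dg >= 0.0:
            d = -g.copy()
            dg = -np.dot(g, g)
            gamma = 1.0
        # cap the step length to avoid wild rigid-body jumps
        dnorm = np.sqrt(np.dot(d, d))
        step = 1.0
        if dnorm * step > 0.5 * ndof**0.5:
            step = 0.5 * ndof**0.5 / dnorm
        # Armijo backtracking
        ok = 0
        fnew = f
        gnew = g
        for ls in range(30):
            xn = x + step * d
            fn, gn, rmn = eval_energy_gradient(
                xn, body, eps, sig, q, molid, nmol, geometric, k_c
            )
            nev += 1
            if np.isfinite(fn) and rmn > 0.5 and fn <= f + 1e-4 * step * dg:
                ok = 1
                fnew = fn
                gnew = gn
                break
            step *= 0.5
        if ok == 0:
            return x, f, gmax, 0, nev
        s_vec = step * d
        y_vec = gnew - g
        sy = np.dot(s_vec, y_vec)
        if sy > 1e-10:
            S[head] = s_vec
            Y[head] = y_vec
            rho[head] = 1.0 / sy
            gamma = sy / np.dot(y_vec, y_vec)
            head = (head + 1) % mmem
            if nstored < mmem:
                nstored += 1
        x = xn
        f = fnew
        g = gnew
    gmax = 0.0
    for i in range(ndof):
        a = abs(g[i])
        if a > gmax:
            gmax = a
    return x, f, gmax, 1 if gmax <= gtol else 0, nev
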