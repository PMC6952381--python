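"""Radial Schroedinger machinery for the self-consistent atomic solver.

Everything here works in Hartree atomic units.  Bound orbitals are found by
Numerov shooting on a logarithmic grid (substitution ``u = sqrt(r) y``,
``x = ln r``); continuum waves are integrated on a uniform grid and
energy-normalized against their outer WKB envelope.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _stability_stop(W, h):
    """Last index where the Numerov scheme is stable (h^2 W / 12 << 1).

    Beyond the outermost classical turning point W grows like r^2 on the log
    grid; integrating further adds no nodes and would break the recursion.
    """
    n = W.shape[0]
    cap = 3.0 / (h * h)
    stop = n - 1
    for i in range(n):
        if W[i] > cap:
            stop = i
            break
    return stop


@njit(cache=True)
def _nodes_for_energy(W0, two_r2, h, E):
    """Node count of the outward shot at energy E, fused (no W allocation)."""
    cap = 3.0 / (h * h)
    n = W0.shape[0]
    c = h * h / 12.0
    y0 = 0.0
    y1 = 1e-20
    nodes = 0
    w_prev = W0[0] - two_r2[0] * E
    w_cur = W0[1] - two_r2[1] * E
    for i in range(1, n - 1):
        w_next = W0[i + 1] - two_r2[i + 1] * E
        if w_cur > cap:
            break
        y2 = (2.0 * y1 * (1.0 + 5.0 * c * w_cur) - y0 * (1.0 - c * w_prev)) / (
            1.0 - c * w_next
        )
        if (y2 < 0.0 and y1 > 0.0) or (y2 > 0.0 and y1 < 0.0):
            nodes += 1
        if abs(y2) > 1e150:
            y2 *= 1e-150
            y1 *= 1e-150
        y0 = y1
        y1 = y2
        w_prev = w_cur
        w_cur = w_next
    return nodes


@njit(cache=True)
def _bisect_eigenvalue(W0, two_r2, h, target, e_lo, e_hi, tol, max_iter):
    """Bisection on the node count; returns (status, energy).

    status: 0 ok, 1 lower bound invalid, 2 upper bound invalid.
    """
    if _nodes_for_energy(W0, two_r2, h, e_lo) > target:
        return 1, 0.0
    if _nodes_for_energy(W0, two_r2, h, e_hi) <= target:
        return 2, 0.0
    lo = e_lo
    hi = e_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if _nodes_for_energy(W0, two_r2, h, mid) > target:
            hi = mid
        else:
            lo = mid
        span = hi - lo
        bound = abs(lo)
        if bound < 1.0:
            bound = 1.0
        if span < tol * bound:
            break
    return 0, 0.5 * (lo + hi)


@njit(cache=True)
def _numerov_nodes(W, h):
    """Shoot outward for y'' = W y; return node count.

    The solution is renormalized when it grows large, which preserves node
    count and divergence sign; integration stops where the scheme would
    lose stability deep in the forbidden region.
    """
    n = _stability_stop(W, h) + 1
    y0 = 0.0
    y1 = 1e-20
    nodes = 0
    c = h * h / 12.0
    for i in range(1, n - 1):
        y2 = (2.0 * y1 * (1.0 + 5.0 * c * W[i]) - y0 * (1.0 - c * W[i - 1])) / (
            1.0 - c * W[i + 1]
        )
        if (y2 < 0.0 and y1 > 0.0) or (y2 > 0.0 and y1 < 0.0):
            nodes += 1
        if abs(y2) > 1e150:
            y2 *= 1e-150
            y1 *= 1e-150
        y0 = y1
        y1 = y2
    return nodes


@njit(cache=True)
def _numerov_wave(W, h, l):
    """Outward+inward Numerov with matching at the outer turning point.

    Returns the (unnormalized) matched solution y on the full grid; beyond
    the Numerov stability range the tail is left at zero (it is exponentially
    negligible there).
    """
    n_full = W.shape[0]
    n = _stability_stop(W, h) + 1
    # outermost turning point
    m = n - 3
    while m > 1 and W[m] > 0.0:
        m -= 1
    if m < 2:
        m = 2
    c = h * h / 12.0

    y = np.zeros(n_full)
    # outward branch up to m+1
    y[0] = 1e-20
    y[1] = 1e-20 * np.exp((l + 0.5) * h)
    for i in range(1, m + 1):
        y[i + 1] = (2.0 * y[i] * (1.0 + 5.0 * c * W[i]) - y[i - 1] * (1.0 - c * W[i - 1])) / (
            1.0 - c * W[i + 1]
        )
        if abs(y[i + 1]) > 1e100:
            for j in range(i + 2):
                y[j] *= 1e-100
    y_match_out = y[m]

    # inward branch from the end down to m
    yi = np.zeros(n_full)
    yi[n - 1] = 1e-30
    w_end = W[n - 2]
    if w_end < 0.0:
        w_end = 0.0
    yi[n - 2] = yi[n - 1] * np.exp(np.sqrt(w_end) * h)
    for i in range(n - 2, m, -1):
        yi[i - 1] = (2.0 * yi[i] * (1.0 + 5.0 * c * W[i]) - yi[i + 1] * (1.0 - c * W[i + 1])) / (
            1.0 - c * W[i - 1]
        )
        if abs(yi[i - 1]) > 1e100:
            for j in range(n - 1, i - 2, -1):
                yi[j] *= 1e-100
    if yi[m] != 0.0 and y_match_out != 0.0:
        scale = y_match_out / yi[m]
        for i in range(m, n):
            y[i] = yi[i] * scale
    return y


@njit(cache=True)
def _continuum_numerov(r, V, E, l, Z_origin):
    """Outward Numerov for a continuum wave on a uniform grid starting at r[0].

    ``V`` is the potential on the same grid; near the origin the centrifugal
    plus Coulomb behavior fixes u ~ r^(l+1).
    """
    n = r.shape[0]
    dr = r[1] - r[0]
    c = dr * dr / 12.0
    u = np.zeros(n)
    u[0] = r[0] ** (l + 1)
    u[1] = r[1] ** (l + 1)
    W = np.empty(n)
    for i in range(n):
        W[i] = l * (l + 1) / (r[i] * r[i]) + 2.0 * (V[i] - E)
    for i in range(1, n - 1):
        u[i + 1] = (2.0 * u[i] * (1.0 + 5.0 * c * W[i]) - u[i - 1] * (1.0 - c * W[i - 1])) / (
            1.0 - c * W[i + 1]
        )
    return u


def bound_state(r, V, n_quantum, l, e_lo=None, e_hi=-1e-9, tol=1e-10, max_iter=200):
    """Bound eigenstate of the radial potential V(r) on a log grid.

    Parameters
    ----------
    r:
        Logarithmically spaced radial grid (a0).
    V:
        Potential on the grid (Hartree).
    n_quantum, l:
        Principal and orbital quantum numbers; the state has
        ``n_quantum - l - 1`` radial nodes.

    Returns
    -------
    (energy, u) with u = r R(r) normalized to unit ``int u^2 dr``.

    Raises
    ------
    RuntimeError if no eigenvalue is bracketed.
    """
    h = np.log(r[1] / r[0])
    target = n_quantum - l - 1
    W0 = (l + 0.5) ** 2 + 2.0 * r * r * V
    two_r2 = 2.0 * r * r

    if e_lo is None:
        # below the deepest reachable level
        zeff = max(1.0, -np.min(V * r))
        e_lo = -2.0 * zeff**2

    status, E = _bisect_eigenvalue(W0, two_r2, h, target, e_lo, e_hi, tol, max_iter)
    if status == 1:
        raise RuntimeError(f"lower energy bound {e_lo} already has too many nodes")
    if status == 2:
        raise RuntimeError("no bound state with the requested node count in bracket")
    y = _numerov_wave(W0 - two_r2 * E, h, l)
    u = y * np.sqrt(r)
    norm = np.trapezoid(u * u * r, dx=h)  # du integral: u^2 dr = u^2 r dx
    if norm <= 0 or not np.isfinite(norm):
        raise RuntimeError("degenerate bound-state normalization")
    u = u / np.sqrt(norm)
    # sign convention: positive near origin
    i0 = np.argmax(np.abs(u) > 0.1 * np.max(np.abs(u)))
    if u[i0] < 0:
        u = -u
    return E, u


def continuum_wave(r_lin, V_lin, E, l):
    """Energy-normalized continuum wave u_El on the uniform grid ``r_lin``.

    Normalization is per unit energy (Hartree): asymptotically
    ``u ~ sqrt(2/(pi k(r))) sin(...)``; the amplitude is fixed by the WKB
    envelope averaged over the outer 20% of the grid.
    """
    u = _continuum_numerov(r_lin, V_lin, E, l, 0.0)
    n = len(r_lin)
    i0 = int(0.8 * n)
    dr = r_lin[1] - r_lin[0]
    # local wavenumber including centrifugal term
    k_loc = np.sqrt(
        np.maximum(2.0 * (E - V_lin[i0:n]) - l * (l + 1) / r_lin[i0:n] ** 2, 1e-12)
    )
    du = np.gradient(u[i0:n], dr)
    env2 = u[i0:n] ** 2 + (du / k_loc) ** 2
    # envelope of an energy-normalized wave is 2/(pi k)
    scale2 = (2.0 / (np.pi * k_loc)) / env2
    scale = np.sqrt(np.median(scale2))
    return u * scale


def hartree_potential(r, rho4pir2, h):
    """V_H(r) from the radial density; ``rho4pir2 = 4 pi r^2 rho``.

    Uses dr = r dx on the log grid.
    """
    # Q(r): electrons enclosed
    integrand = rho4pir2 * r  # * dx
    Q = np.concatenate(([0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * h)))
    # outer part: int_r^inf rho4pir2 / r dr = int rho4pir2 dx
    t_all = np.concatenate(([0.0], np.cumsum(0.5 * (rho4pir2[1:] + rho4pir2[:-1]) * h)))
    T = t_all[-1] - t_all
    return Q / r + T
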