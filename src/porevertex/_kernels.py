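"""Numba-compiled inner loops of the vertex-dynamics step.

These kernels mirror the reference implementations in
:mod:`porevertex.mechanics` exactly (a test asserts agreement); they exist
so that runs to several hundred thousand steps stay cheap.
"""

from __future__ import annotations

import numpy as np
from numba import njit

WALL_TOP = 1
WALL_BOTTOM = 2
WALL_INLET = 4
WALL_OUTLET = 8


@njit(cache=False)
def step_all(pos, mask, corner_cell, corner_vert, next_vert, prev_vert,
             edge_a, edge_b, n_cells,
             mu, eta, L0, A0, k, F0, thr_on_mag, dt, courant_c, l_floor,
             h, eps, K, phase, x_min, x_max, closed_ends):
    """Fused per-step kernel: geometry, forces, Courant dt, motion.

    Returns ``(dt_eff, L, A, cx, cy, el)`` with per-cell perimeter, signed
    area and centroid (pre-move, i.e. the state the forces acted on) and
    post-move edge lengths.  If any cell area is non-positive the kernel
    makes no move and returns ``dt_eff = -1`` so the caller can repair
    the orientation first.
    """
    n_corner = corner_vert.shape[0]
    n_vert = pos.shape[0]
    L = np.zeros(n_cells)
    A = np.zeros(n_cells)
    cx = np.zeros(n_cells)
    cy = np.zeros(n_cells)
    lmin = 1e300
    for i in range(n_corner):
        c = corner_cell[i]
        v = corner_vert[i]
        w = next_vert[i]
        x0, y0 = pos[v, 0], pos[v, 1]
        x1, y1 = pos[w, 0], pos[w, 1]
        dx, dy = x1 - x0, y1 - y0
        el_ = (dx * dx + dy * dy) ** 0.5
        if el_ < lmin:
            lmin = el_
        L[c] += el_
        cross = x0 * y1 - x1 * y0
        A[c] += 0.5 * cross
        cx[c] += (x0 + x1) * cross
        cy[c] += (y0 + y1) * cross
    bad = False
    for c in range(n_cells):
        if A[c] <= 0.0:
            bad = True
        if abs(A[c]) > 1e-14:
            cx[c] /= 6.0 * A[c]
            cy[c] /= 6.0 * A[c]
    el = np.empty(edge_a.shape[0])
    if bad:
        for e in range(edge_a.shape[0]):
            el[e] = 1e300
        return -1.0, L, A, cx, cy, el

    F = np.zeros((n_vert, 2))
    for i in range(n_corner):
        c = corner_cell[i]
        v = corner_vert[i]
        vn = next_vert[i]
        vp = prev_vert[i]
        px, py = pos[v, 0], pos[v, 1]
        nx_, ny_ = pos[vn, 0], pos[vn, 1]
        qx, qy = pos[vp, 0], pos[vp, 1]
        gx = 0.0
        gy = 0.0
        dxn, dyn = px - nx_, py - ny_
        ln = (dxn * dxn + dyn * dyn) ** 0.5
        if ln > 1e-12:
            gx += dxn / ln
            gy += dyn / ln
        dxp, dyp = px - qx, py - qy
        lp = (dxp * dxp + dyp * dyp) ** 0.5
        if lp > 1e-12:
            gx += dxp / lp
            gy += dyp / lp
        coefL = mu * (L[c] - L0)
        coefA = eta * (A[c] - A0)
        F[v, 0] -= coefL * gx + coefA * 0.5 * (ny_ - qy)
        F[v, 1] -= coefL * gy + coefA * 0.5 * (qx - nx_)

    dt_eff = step_pass(pos, mask, F, k, F0, thr_on_mag, dt, courant_c,
                       max(lmin, l_floor),
                       h, eps, K, phase, x_min, x_max, closed_ends)
    for e in range(edge_a.shape[0]):
        dx = pos[edge_b[e], 0] - pos[edge_a[e], 0]
        dy = pos[edge_b[e], 1] - pos[edge_a[e], 1]
        el[e] = (dx * dx + dy * dy) ** 0.5
    return dt_eff, L, A, cx, cy, el


@njit(cache=False)
def geometry_pass(pos, corner_cell, corner_vert, next_vert, n_cells):
    """Per-cell perimeter, signed area, centroid and the global shortest edge."""
    L = np.zeros(n_cells)
    A = np.zeros(n_cells)
    cx = np.zeros(n_cells)
    cy = np.zeros(n_cells)
    lmin = 1e300
    for i in range(corner_vert.shape[0]):
        c = corner_cell[i]
        v = corner_vert[i]
        w = next_vert[i]
        x0, y0 = pos[v, 0], pos[v, 1]
        x1, y1 = pos[w, 0], pos[w, 1]
        dx, dy = x1 - x0, y1 - y0
        el = (dx * dx + dy * dy) ** 0.5
        if el < lmin:
            lmin = el
        L[c] += el
        cross = x0 * y1 - x1 * y0
        A[c] += 0.5 * cross
        cx[c] += (x0 + x1) * cross
        cy[c] += (y0 + y1) * cross
    for c in range(n_cells):
        if abs(A[c]) > 1e-14:
            cx[c] /= 6.0 * A[c]
            cy[c] /= 6.0 * A[c]
    return L, A, cx, cy, lmin


@njit(cache=False)
def force_pass(pos, corner_cell, corner_vert, next_vert, prev_vert,
               L, A, mu, eta, L0, A0, n_vertices):
    """Conservative node forces: minus the gradient of the tissue energy.

    Each corner adds the incident cell's perimeter-tension term
    ``-mu (L - L0) dL/dr`` and area-elasticity term ``-eta (A - A0) dA/dr``
    to its vertex.  Zero-length edges contribute nothing.
    """
    F = np.zeros((n_vertices, 2))
    for i in range(corner_vert.shape[0]):
        c = corner_cell[i]
        v = corner_vert[i]
        vn = next_vert[i]
        vp = prev_vert[i]
        px, py = pos[v, 0], pos[v, 1]
        nx_, ny_ = pos[vn, 0], pos[vn, 1]
        qx, qy = pos[vp, 0], pos[vp, 1]
        gx = 0.0
        gy = 0.0
        dxn, dyn = px - nx_, py - ny_
        ln = (dxn * dxn + dyn * dyn) ** 0.5
        if ln > 1e-12:
            gx += dxn / ln
            gy += dyn / ln
        dxp, dyp = px - qx, py - qy
        lp = (dxp * dxp + dyp * dyp) ** 0.5
        if lp > 1e-12:
            gx += dxp / lp
            gy += dyp / lp
        coefL = mu * (L[c] - L0)
        coefA = eta * (A[c] - A0)
        F[v, 0] -= coefL * gx + coefA * 0.5 * (ny_ - qy)
        F[v, 1] -= coefL * gy + coefA * 0.5 * (qx - nx_)
    return F


@njit(cache=False)
def step_pass(pos, mask, F, k, F0, thr_on_mag, dt, courant_c, lmin,
              h, eps, K, phase, x_min, x_max, closed_ends):
    """Threshold overdamped motion with wall slip, snap and attach/detach.

    Returns the time step actually taken (the Courant-limited ``dt``).
    Wall contact is unilateral: a wall vertex whose velocity points into
    the fluid is released; otherwise the normal velocity component is
    removed and the vertex re-snapped onto the wall curve after moving.
    """
    n = pos.shape[0]
    vmax = 0.0
    for i in range(n):
        f2 = F[i, 0] * F[i, 0] + F[i, 1] * F[i, 1]
        if thr_on_mag:
            moving = f2 ** 0.5 > F0
        else:
            moving = f2 > F0
        if moving:
            sp = k * f2 ** 0.5
            if sp > vmax:
                vmax = sp
    dt_eff = dt
    if vmax > 0.0 and courant_c * lmin / vmax < dt:
        dt_eff = courant_c * lmin / vmax

    for i in range(n):
        f2 = F[i, 0] * F[i, 0] + F[i, 1] * F[i, 1]
        if thr_on_mag:
            moving = f2 ** 0.5 > F0
        else:
            moving = f2 > F0
        if not moving:
            continue
        vx = k * F[i, 0]
        vy = k * F[i, 1]
        m = mask[i]
        x = pos[i, 0]
        y = pos[i, 1]
        if m & (WALL_TOP | WALL_BOTTOM):
            slope = h * eps * K * np.cos(K * x + phase)
            inv = 1.0 / (1.0 + slope * slope) ** 0.5
            if m & WALL_TOP:
                nx_, ny_ = slope * inv, -inv
            else:
                nx_, ny_ = slope * inv, inv
            vn = vx * nx_ + vy * ny_
            if vn > 0.0:
                m &= ~(WALL_TOP | WALL_BOTTOM)   # leaves the wall
            else:
                vx -= vn * nx_
                vy -= vn * ny_
        if m & WALL_INLET:
            if vx > 0.0:
                m &= ~WALL_INLET
            else:
                vx = 0.0
        if m & WALL_OUTLET:
            if vx < 0.0:
                m &= ~WALL_OUTLET
            else:
                vx = 0.0
        x += vx * dt_eff
        y += vy * dt_eff
        # axial confinement
        if x < x_min:
            x = x_min
            m |= WALL_INLET
        elif closed_ends and x > x_max:
            x = x_max
            m |= WALL_OUTLET
        # lateral walls: snap flagged vertices, attach crossing ones
        xw = min(max(x, x_min), x_max)
        w = h * (1.0 + eps * np.sin(K * xw + phase))
        if m & WALL_TOP:
            y = w
        elif m & WALL_BOTTOM:
            y = -w
        elif y > w:
            y = w
            m |= WALL_TOP
        elif y < -w:
            y = -w
            m |= WALL_BOTTOM
        pos[i, 0] = x
        pos[i, 1] = y
        mask[i] = m
    return dt_eff
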