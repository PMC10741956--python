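"""Closed-form laminar flow and shear stress in a straight or wavy channel.

The nutrient solution creeps through the pore at Reynolds numbers of
order 0.1, so the flow obeys the Stokes equations.  In a straight channel
this is plane Poiseuille flow,

    u_x(y) = (dp/dx) (h^2 - y^2) / (4 eta0),   tau = eta0 du_x/dy,

with the shear stress vanishing on the centreline and maximal in
magnitude at the walls.  For a wavy wall ``y = +/- h (1 + eps sin(Kx))``
the stream function is expanded to first order in the small amplitude
``eps``.  Mapping the channel onto the straight strip ``phi = y / w(x)``
(walls at ``phi = +/- 1``), the solution is

    psi(theta, phi) = psi0(phi) + eps sin(beta theta + phase) g(phi),
    psi0 = phi - phi^3 / 3,      beta = K h,
    g(phi) = f(phi) + phi - phi^3,
    f(phi) = [2 sinh(b) phi cosh(b phi) - 2 cosh(b) sinh(b phi)]
             / (cosh(b) sinh(b) - b),        b = beta,

where ``f`` is the odd biharmonic profile satisfying ``f(+/-1) = 0`` and
``f'(+/-1) = 2``, i.e. it cancels the slip the wall undulation would
otherwise induce, and the ``phi - phi^3`` term is the coordinate-map
image of the base flow.  Velocities follow from ``u_x = dpsi/dy``,
``u_y = -dpsi/dx`` by exact chain-rule differentiation, so no-slip holds
exactly on the mapped walls and the divergence vanishes identically.

The tangential (flow-aligned) shear stress is evaluated from the
velocity-gradient tensor projected on the local flow direction and is
reported normalized by the straight-channel wall stress
``tau0 = 2 eta0 u0 / h``.  For the biology coupling the field is rescaled
once so that its largest wall value equals ``stress_amplitude * tau_res``.

.. note:: **Sign of the wavy correction.**  Because ``f`` satisfies
   homogeneous wall conditions, ``-f`` is also an admissible profile —
   it is the solution for a channel whose undulation is inverted
   (``eps -> -eps``).  The two choices place the peak wall stress at
   opposite stations: ``field_source="consistent"`` (the solution of the
   stated first-order problem) peaks at the *bottleneck*, the classical
   lubrication result, whereas ``field_source="printed"`` (the default)
   flips the correction sign and peaks at the *expansion*.  The printed
   variant reproduces the stress maps and the expansion-side growth
   zones that the scenario results in this package are built on; the
   discrepancy is documented in docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import ChannelGeometry

__all__ = [
    "FlowConfig",
    "StressField",
    "poiseuille_velocity",
    "poiseuille_shear",
    "stream_function",
    "velocity_from_stream",
    "shear_field",
    "reynolds",
    "stress_for_cells",
]


@dataclass(frozen=True)
class FlowConfig:
    """Flow through the pore: geometry, viscosity and one driving scale.

    Exactly one of ``u0`` (centreline inlet velocity) and ``dpdx``
    (pressure gradient) is given; in the straight limit they are related
    by ``u0 = dpdx h^2 / (4 eta0)``.  ``stress_amplitude`` sets the peak
    wall stress in units of the resonant stress ``tau_res`` used by the
    division coupling.
    """

    geom: ChannelGeometry = field(default_factory=ChannelGeometry)
    eta0: float = 1.0
    u0: float | None = None
    dpdx: float | None = None
    tau_scale: float = 1.0
    stress_amplitude: float = 1.0
    field_source: str = "printed"

    def __post_init__(self):
        if not self.eta0 > 0:
            raise ValueError("eta0 must be positive")
        if (self.u0 is None) == (self.dpdx is None):
            raise ValueError("provide exactly one of u0 and dpdx")
        if self.field_source not in ("printed", "consistent"):
            raise ValueError("field_source must be 'printed' or 'consistent'")

    @property
    def correction_sign(self) -> float:
        """-1 for the printed wavy correction, +1 for the consistent one."""
        return -1.0 if self.field_source == "printed" else 1.0

    @property
    def u_center(self) -> float:
        if self.u0 is not None:
            return self.u0
        return self.dpdx * self.geom.h ** 2 / (4.0 * self.eta0)

    @property
    def tau0_wall(self) -> float:
        """Straight-channel wall shear stress ``2 eta0 u0 / h``."""
        return 2.0 * self.eta0 * self.u_center / self.geom.h


def reynolds(u0: float, h: float, nu: float) -> float:
    """Reynolds number ``u0 h / nu`` of the pore flow."""
    return u0 * h / nu


# ---------------------------------------------------------------------------
# straight channel
# ---------------------------------------------------------------------------

def poiseuille_velocity(y, cfg: FlowConfig):
    """Parabolic profile ``u0 (1 - (y/h)^2)``; zero on the walls."""
    h = cfg.geom.h
    y = np.asarray(y, dtype=float)
    if np.any(np.abs(y) > h + 1e-12):
        raise ValueError("|y| exceeds the channel half-width")
    out = cfg.u_center * (1.0 - (y / h) ** 2)
    return float(out) if out.ndim == 0 else out


def poiseuille_shear(y, cfg: FlowConfig):
    """Shear stress ``eta0 du_x/dy = -2 eta0 u0 y / h^2`` (odd in y).

    The sign convention follows the fluid-side gradient; the stress felt
    by the wall surface is its negative.
    """
    h = cfg.geom.h
    y = np.asarray(y, dtype=float)
    out = -2.0 * cfg.eta0 * cfg.u_center * y / h ** 2
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# wavy channel, first order in eps
# ---------------------------------------------------------------------------

def _profile(phi, beta: float):
    """Odd biharmonic correction profile f and its first two derivatives."""
    b = beta
    denom = math.cosh(b) * math.sinh(b) - b
    C = -2.0 * math.cosh(b) / denom
    D = 2.0 * math.sinh(b) / denom
    ch = np.cosh(b * phi)
    sh = np.sinh(b * phi)
    f = C * sh + D * phi * ch
    fp = C * b * ch + D * (ch + b * phi * sh)
    fpp = C * b * b * sh + D * (2.0 * b * sh + b * b * phi * ch)
    return f, fp, fpp


def stream_function(theta, phi, cfg: FlowConfig):
    """Dimensionless stream function ``psi0(phi) + eps psi1(theta, phi)``.

    ``theta = x/h`` and ``phi = y/w(x)`` are the mapped coordinates in
    which the walls are flat at ``phi = +/- 1``.  The flux carried between
    the walls is ``4/3`` independently of ``theta`` (to first order).
    """
    g = cfg.geom
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(np.abs(phi) > 1.0 + 1e-12):
        raise ValueError("|phi| exceeds 1 (outside the mapped channel)")
    beta = g.wavenumber * g.h
    psi0 = phi - phi ** 3 / 3.0
    if g.epsilon == 0.0:
        out = psi0
    else:
        f, _, _ = _profile(phi, beta)
        S = cfg.correction_sign * np.sin(beta * theta + g.phase)
        out = psi0 + g.epsilon * S * (f + phi - phi ** 3)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def _velocity_and_gradient(x, y, cfg: FlowConfig):
    """Velocity (ux, uy) and its spatial gradient, by exact chain rule."""
    g = cfg.geom
    u0 = cfg.u_center
    h = g.h
    K = g.wavenumber
    eps = g.epsilon
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    s = np.sin(K * x + g.phase)
    c = np.cos(K * x + g.phase)
    w = h * (1.0 + eps * s)
    wp = h * eps * K * c
    wpp = -h * eps * K * K * s
    phi = y / w
    beta = K * h

    # psi and partials in (theta, phi); S(theta) = sin(beta theta + phase)
    f, fp, fpp = _profile(phi, beta)
    gph = f + phi - phi ** 3
    gp = fp + 1.0 - 3.0 * phi ** 2
    gpp = fpp - 6.0 * phi
    sgn = cfg.correction_sign   # flips only the psi1 correction, not the wall
    S = sgn * s
    Sp = sgn * beta * c        # d/dtheta
    Spp = -sgn * beta * beta * s

    psi_phi = (1.0 - phi ** 2) + eps * S * gp
    psi_th = eps * Sp * gph
    psi_phiphi = -2.0 * phi + eps * S * gpp
    psi_thphi = eps * Sp * gp
    psi_thth = eps * Spp * gph

    phi_x = -phi * wp / w
    scale = u0 * h

    ux = scale * psi_phi / w
    uy = scale * (-psi_th / h + psi_phi * phi * wp / w)

    dpsiphi_dx = psi_thphi / h + psi_phiphi * phi_x
    dux_dx = scale * (dpsiphi_dx / w - psi_phi * wp / w ** 2)
    dux_dy = scale * psi_phiphi / w ** 2
    duy_dy = scale * (-psi_thphi / (h * w) + wp * (psi_phiphi * phi + psi_phi) / w ** 2)
    duy_dx = scale * (
        -(psi_thth / h + psi_thphi * phi_x) / h
        + (psi_thphi / h + psi_phiphi * phi_x) * phi * wp / w
        + psi_phi * (phi_x * wp / w + phi * (wpp * w - wp ** 2) / w ** 2)
    )
    return ux, uy, dux_dx, dux_dy, duy_dx, duy_dy


def velocity_from_stream(x, y, cfg: FlowConfig):
    """Fluid velocity ``(u_x, u_y)`` at interior points of the channel."""
    g = cfg.geom
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = g.h * (1.0 + g.epsilon * np.sin(g.wavenumber * x + g.phase))
    if np.any(np.abs(y) > w + 1e-9):
        raise ValueError("point outside the channel")
    ux, uy, *_ = _velocity_and_gradient(x, y, cfg)
    if np.ndim(ux) == 0:
        return np.array([float(ux), float(uy)])
    return np.stack([ux, uy], axis=-1)


def shear_field(x, y, cfg: FlowConfig):
    """Flow-aligned shear stress normalized by the straight wall stress.

    Evaluates ``tau = eta0 (n . grad)(u . t)`` with ``t`` the local flow
    direction and ``n`` orthogonal to it, reduced to velocity gradients:

        tau = (ux uy / U^2)(duy/dy - dux/dx)
            + (ux^2 / U^2) dux/dy - (uy^2 / U^2) duy/dx.

    Returned in units of ``tau0 = 2 eta0 u0 / h`` (signed); for a straight
    channel this is exactly ``-y/h``.  On a symmetry centreline where
    ``U = 0`` the limit is zero.
    """
    ux, uy, dxx, dxy, dyx, dyy = _velocity_and_gradient(x, y, cfg)
    U2 = ux * ux + uy * uy
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = (ux * uy * (dyy - dxx) + ux * ux * dxy - uy * uy * dyx) / U2
    tau = np.where(U2 > 0, tau, 0.0)
    tau = tau * cfg.eta0 / (cfg.tau0_wall if cfg.tau0_wall != 0 else 1.0)
    tau = np.asarray(tau)
    return float(tau) if tau.ndim == 0 else tau


# ---------------------------------------------------------------------------
# biology coupling
# ---------------------------------------------------------------------------

class StressField:
    """Static shear-stress field sampled by the growing tissue.

    The flow is one-way coupled: it is computed once for the empty
    channel and cells do not perturb it.  ``tau_res_units`` rescales the
    wall-normalized field so that the largest wall-adjacent stress equals
    ``stress_amplitude * tau_res`` — cells sitting in the peak-stress
    zones then divide at (or near) the resonant rate.
    """

    #: relative wall offset used for the wall-adjacent stress samples
    WALL_OFFSET = 1e-6

    def __init__(self, cfg: FlowConfig, tau_res: float = 1.0, n_samples: int = 2001):
        self.cfg = cfg
        self.tau_res = tau_res
        g = cfg.geom
        xs = np.linspace(g.x_min, g.x_max, n_samples)
        w = g.h * (1.0 + g.epsilon * np.sin(g.wavenumber * xs + g.phase))
        yw = (1.0 - self.WALL_OFFSET) * w
        self._xs = xs
        self._wall_tau = np.abs(shear_field(xs, yw, cfg))
        self.wall_max = float(self._wall_tau.max())

    def wall_stress_profile(self):
        """(x, |tau/tau0| just inside the top wall) along the channel."""
        return self._xs, self._wall_tau

    def tau_wall_units(self, x, y):
        return shear_field(x, y, self.cfg)

    def tau_res_units(self, x, y):
        """|tau| in units of tau_res, calibrated to the peak wall stress."""
        scale = self.cfg.stress_amplitude * self.tau_res / self.wall_max
        return np.abs(shear_field(x, y, self.cfg)) * scale

    def grid(self, nx: int = 200, ny: int = 60):
        """Sample tau/tau0 on a rectangular grid (NaN outside the channel)."""
        g = self.cfg.geom
        xs = np.linspace(g.x_min, g.x_max, nx)
        ymax = g.h * (1.0 + g.epsilon)
        ys = np.linspace(-ymax, ymax, ny)
        X, Y = np.meshgrid(xs, ys)
        w = g.h * (1.0 + g.epsilon * np.sin(g.wavenumber * X + g.phase))
        inside = np.abs(Y) <= w
        T = np.full(X.shape, np.nan)
        T[inside] = shear_field(X[inside], Y[inside], self.cfg)
        return xs, ys, T


def stress_for_cells(mesh, cfg: FlowConfig, tau_res: float,
                     field: StressField | None = None) -> np.ndarray:
    """Per-cell |shear stress| in units of ``tau_res``, sampled at centroids.

    Centroids that drifted outside the channel (numerically) are clamped
    to the nearest interior point.  With ``stress_amplitude = 0`` every
    cell sees zero stress (uniform growth).
    """
    if field is None:
        field = StressField(cfg, tau_res)
    cids = sorted(mesh.cells)
    cent = np.array([mesh.cell_centroid(c) for c in cids])
    return stress_at_points(cent[:, 0], cent[:, 1], field)


def stress_at_points(x, y, field: StressField) -> np.ndarray:
    """Clamped evaluation of ``tau_res``-normalized stress at points."""
    cfg = field.cfg
    g = cfg.geom
    if cfg.stress_amplitude == 0.0:
        return np.zeros(np.broadcast(np.asarray(x), np.asarray(y)).shape)
    x = np.clip(np.asarray(x, dtype=float), g.x_min, g.x_max)
    w = g.h * (1.0 + g.epsilon * np.sin(g.wavenumber * x + g.phase))
    y = np.clip(np.asarray(y, dtype=float), -0.999999 * w, 0.999999 * w)
    return field.tau_res_units(x, y)
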