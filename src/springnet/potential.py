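"""Compactly supported spring potential and its Fourier modes.

Every particle pair connected by a link interacts through a quadratic
spring of equilibrium length ``ell``, active only within the detection
radius ``R``.  In the scaled model (``kappa = 2``) the resulting effective
pair potential is

    V(x) = (|x| - ell)^2 - (R - ell)^2   for |x| <  R,
    V(x) = 0                            for |x| >= R,

continuous at ``|x| = R`` and radially symmetric.  Its Fourier modes on
the periodic box ``[-L, L)^dim`` control the linear stability of the
uniform state: in 1D they have an elementary closed form, in 2D they are
expressed through Bessel and Struve functions.

For a general spring constant the potential carries an overall factor
``kappa / 2`` (the spring energy is ``kappa/2 (r - ell)^2``); all closed
forms below include that factor, so the default ``kappa = 2`` reproduces
the expressions above.
"""

from __future__ import annotations

import numpy as np
from scipy import special

from .params import ModelParams

__all__ = [
    "potential_value",
    "potential_gradient",
    "fourier_mode_1d",
    "fourier_mode_2d",
    "fourier_mode",
    "struve_h",
    "link_density_closure",
    "PairPotential",
]


def potential_value(r, params: ModelParams):
    """Pair potential V as a function of the separation distance ``r >= 0``.

    Returns ``kappa/2 * ((r - ell)^2 - (R - ell)^2)`` for ``r < R`` and 0
    for ``r >= R``.  Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation distance must be non-negative")
    ell, R, half_k = params.ell, params.R, 0.5 * params.kappa
    inside = r < R
    val = np.where(inside, half_k * ((r - ell) ** 2 - (R - ell) ** 2), 0.0)
    return val.item() if val.ndim == 0 else val


def potential_gradient(dx, params: ModelParams):
    """Gradient of V with respect to the displacement vector ``dx``.

    ``dx`` is the (minimum-image) displacement: a scalar or length-1 array
    in 1D, a length-2 array in 2D, or an ``(..., dim)`` batch.  Returns
    ``kappa (|dx| - ell) dx/|dx|`` for ``0 < |dx| <= R`` (closed support)
    and the zero vector outside.

    At exactly zero separation the gradient direction is undefined when
    ``ell > 0``; the zero vector is returned by convention (coincident
    particles are a probability-zero event, and any fixed direction would
    break isotropy).
    """
    dx = np.atleast_1d(np.asarray(dx, dtype=float))
    scalar_in = dx.ndim == 1
    arr = dx if not scalar_in else dx[None, :]
    r = np.linalg.norm(arr, axis=-1)
    safe_r = np.where(r > 0, r, 1.0)
    mag = np.where((r > 0) & (r <= params.R), params.kappa * (r - params.ell) / safe_r, 0.0)
    grad = arr * mag[..., None]
    return grad[0] if scalar_in else grad


def _z(k_norm: float, params: ModelParams) -> float:
    return np.pi * params.R * k_norm / params.L


def fourier_mode_1d(k: int, params: ModelParams) -> float:
    """Fourier coefficient V-hat_k of the 1D potential on ``[-L, L)``.

    For ``k != 0`` the closed form is

        V-hat_k = (2 R^3 / L) (-sin z / z^3 + (1 - alpha) cos z / z^2
                               + alpha / z^2),    z = pi R |k| / L,

    scaled by ``kappa / 2``.  Even in k.  The mass mode ``k = 0`` is the
    mean of V over the box (the closed-form expression is singular there);
    it never enters the stability formulas but is exposed for completeness.
    """
    k = int(k)
    ell, R, L = params.ell, params.R, params.L
    half_k = 0.5 * params.kappa
    if k == 0:
        # (1/2L) * integral of V over [-R, R]
        integral = 2.0 * (((R - ell) ** 3 + ell**3) / 3.0 - R * (R - ell) ** 2)
        return half_k * integral / (2.0 * L)
    alpha = params.alpha
    z = _z(abs(k), params)
    return half_k * (2.0 * R**3 / L) * (
        -np.sin(z) / z**3 + (1.0 - alpha) * np.cos(z) / z**2 + alpha / z**2
    )


def struve_h(order: int, x: float):
    """Struve function H_order(x) for order 0 or 1.

    Thin wrapper around the library routine; the power series
    ``sum_m (-1)^m / (Gamma(m + 3/2) Gamma(m + order + 3/2)) (x/2)^(2m+order+1)``
    serves as the independent oracle in the test suite.
    """
    if order not in (0, 1):
        raise ValueError("struve_h supports orders 0 and 1 only")
    return special.struve(order, x)


def fourier_mode_2d(k1: int, k2: int, params: ModelParams) -> float:
    """Fourier coefficient V-hat_{k1,k2} of the radial potential on ``[-L, L)^2``.

    For ``(k1, k2) != (0, 0)``:

        V-hat = (pi / L^2) [ (pi R^3 ell / (2 z^2)) (J1(z) H0(z) - J0(z) H1(z))
                             - (R^4 / z^2) J2(z) ],
        z = (pi R / L) sqrt(k1^2 + k2^2),

    scaled by ``kappa / 2``; depends on ``k1^2 + k2^2`` only.  The (0, 0)
    mode is the mean of V over the box.
    """
    k1, k2 = int(k1), int(k2)
    ell, R, L = params.ell, params.R, params.L
    half_k = 0.5 * params.kappa
    if k1 == 0 and k2 == 0:
        # (1/4L^2) * 2*pi * int_0^R r [ (r-ell)^2 - (R-ell)^2 ] dr
        radial = (R**4 / 4.0 - 2.0 * ell * R**3 / 3.0 + ell**2 * R**2 / 2.0
                  - (R - ell) ** 2 * R**2 / 2.0)
        return half_k * 2.0 * np.pi * radial / (4.0 * L**2)
    z = _z(np.hypot(k1, k2), params)
    bessel_struve = (special.jv(1, z) * special.struve(0, z)
                     - special.jv(0, z) * special.struve(1, z))
    return half_k * (np.pi / L**2) * (
        np.pi * R**3 * ell / (2.0 * z**2) * bessel_struve
        - R**4 / z**2 * special.jv(2, z)
    )


def fourier_mode(mode, params: ModelParams) -> float:
    """Dispatch to the 1D or 2D Fourier coefficient based on the mode index.

    ``mode`` is an int (1D) or a pair ``(k1, k2)`` (2D).
    """
    if np.isscalar(mode):
        return fourier_mode_1d(int(mode), params)
    k1, k2 = mode
    return fourier_mode_2d(k1, k2, params)


def link_density_closure(f_x, f_y, separation, params: ModelParams, xi_ratio: float):
    """Local equilibrium of the link density in the fast-linking regime.

    When link creation/destruction is much faster than particle transport,
    the two-particle link density closes as

        g(x, y) = nu_f / (2 xi nu_d) * f(x) f(y) * chi_{|x-y| <= R},

    with ``xi`` the limiting link-to-particle ratio K/N.
    """
    if xi_ratio <= 0:
        raise ValueError("xi_ratio must be positive")
    f_x = np.asarray(f_x, dtype=float)
    f_y = np.asarray(f_y, dtype=float)
    if np.any(f_x < 0) or np.any(f_y < 0):
        raise ValueError("densities must be non-negative")
    sep = np.asarray(separation, dtype=float)
    pref = params.nu_f / (2.0 * xi_ratio * params.nu_d)
    out = np.where(sep <= params.R, pref * f_x * f_y, 0.0)
    return out.item() if out.ndim == 0 else out


class PairPotential:
    """Bundles the potential evaluation handles for a fixed parameter set."""

    def __init__(self, params: ModelParams):
        self.params = params

    def value(self, r):
        return potential_value(r, self.params)

    def spring_energy(self, r):
        """Bare spring energy ``kappa/2 (r - ell)^2`` (no support cutoff)."""
        r = np.asarray(r, dtype=float)
        return 0.5 * self.params.kappa * (r - self.params.ell) ** 2

    def gradient(self, dx):
        return potential_gradient(dx, self.params)

    def fourier_mode(self, mode):
        return fourier_mode(mode, self.params)
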