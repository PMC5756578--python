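"""Linear stability and weakly nonlinear analysis of the uniform state.

The uniform density (total mass 1) of the aggregation-diffusion equation
is linearly stable against the Fourier mode ``k`` iff ``D + V-hat_k >= 0``:
the perturbation mode grows at the rate

    lambda_k = -(pi^2 |k|^2 / L^2) (D + V-hat_k),

so the first mode crosses zero at the critical noise ``D_c = -V-hat_1``.
Because ``V-hat_1`` is affine in the spring length ``ell``, the instability
boundary ``D(ell)`` is a straight line with root ``ell_c = R alpha_c``.

Near the threshold the dynamics reduces to an amplitude equation for the
critical mode; the sign of its cubic coefficient - controlled by the
discriminant ``2 V-hat_2 - V-hat_1`` in 1D and by the ``V*`` combination of
modes (1,0), (2,0), (1,1) in 2D - decides whether the aggregated branch
bifurcates continuously (supercritical) or with a jump (subcritical).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .params import ModelParams
from .potential import fourier_mode, fourier_mode_1d, fourier_mode_2d

__all__ = [
    "SpectralReport",
    "BifurcationClassification",
    "AmplitudePrediction",
    "VStarResult",
    "growth_rate",
    "critical_noise",
    "critical_alpha",
    "critical_lengths_1d",
    "noise_for_growth",
    "bifurcation_type_1d",
    "vstar_discriminant",
    "supercritical_window_2d",
    "amplitude_prediction",
    "instability_slope_1d",
]


@dataclass(frozen=True)
class SpectralReport:
    """Growth-rate report for a single Fourier mode."""

    mode: object          # int k (1D) or tuple (k1, k2) (2D)
    vhat: float           # Fourier coefficient of the potential
    growth_rate: float    # lambda_k, per unit time
    z: float              # reduced wavenumber pi R |k| / L


@dataclass(frozen=True)
class BifurcationClassification:
    regime: str                 # 'stable' | 'supercritical' | 'subcritical' | 'degenerate'
    discriminant: float         # 1D: 2 V-hat_2 - V-hat_1
    critical_noise: float       # D_c at which lambda_1 crosses 0


@dataclass(frozen=True)
class VStarResult:
    vstar: float
    c: float
    d: float
    regime: str
    D_used: float


@dataclass(frozen=True)
class AmplitudePrediction:
    lam: float        # distance to threshold (growth rate of the first mode)
    A_sat: float      # saturated amplitude |A| of the critical mode
    rho_th: float     # predicted steady perturbation amplitude |rho|_th
    h2: float         # second-harmonic coefficient
    h_minus2: float


def _mode_norm_sq(mode) -> float:
    if np.isscalar(mode):
        return float(mode) ** 2
    k1, k2 = mode
    return float(k1) ** 2 + float(k2) ** 2


def growth_rate(mode, D: float, params: ModelParams) -> SpectralReport:
    """Linear growth rate of a Fourier perturbation of the uniform state."""
    n2 = _mode_norm_sq(mode)
    if n2 == 0:
        raise ValueError("the zero (mass) mode has no growth rate")
    if D < 0:
        raise ValueError("noise intensity D must be non-negative")
    vhat = fourier_mode(mode, params)
    lam = -(np.pi**2 * n2 / params.L**2) * (D + vhat)
    z = np.pi * params.R * np.sqrt(n2) / params.L
    return SpectralReport(mode=mode, vhat=vhat, growth_rate=lam, z=z)


def critical_noise(params: ModelParams) -> float:
    """Critical noise ``D_c`` below which the uniform state is unstable.

    ``D_c = -V-hat_1`` (1D) or ``-V-hat_{1,0}`` (2D).  When the first mode
    of the potential is non-negative (``alpha >= alpha_c``) no positive
    threshold exists - the uniform state is stable for every ``D`` - and 0
    is returned.
    """
    first = 1 if params.dim == 1 else (1, 0)
    vhat1 = fourier_mode(first, params)
    return max(0.0, -vhat1)


def critical_alpha(R: float = 0.75, L: float = 3.0, dim: int = 1) -> float:
    """Critical ratio ``alpha_c = ell_c / R`` at which V-hat_1 changes sign.

    1D closed form (from the vanishing of the first mode at z1 = pi R / L):

        alpha_c = (sin z1 / z1 - cos z1) / (1 - cos z1).

    In 2D the root of the Bessel-Struve expression
    ``(pi/2) alpha (J1 H0 - J0 H1)(z_{1,0}) = J2(z_{1,0})`` is found by
    bracketing bisection.
    """
    if dim == 1:
        z1 = np.pi * R / L
        return (np.sin(z1) / z1 - np.cos(z1)) / (1.0 - np.cos(z1))

    def first_mode(alpha: float) -> float:
        p = ModelParams(D=0.0, ell=alpha * R, R=R, L=L, dim=2)
        return fourier_mode_2d(1, 0, p)

    lo, hi = 1e-9, 1.0 - 1e-9
    flo, fhi = first_mode(lo), first_mode(hi)
    if flo * fhi > 0:
        raise RuntimeError(
            f"no sign change of V-hat_(1,0) in alpha on ({lo}, {hi}): "
            f"f({lo})={flo:.3e}, f({hi})={fhi:.3e}"
        )
    return brentq(first_mode, lo, hi, xtol=1e-12)


def instability_slope_1d(R: float = 0.75, L: float = 3.0, kappa: float = 2.0) -> float:
    """Slope of the linear instability boundary ``D(ell)``.

    ``-V-hat_1`` is affine in ``ell``; its (negative) derivative gives the
    boundary ``D(ell) = slope * (ell_c - ell)`` with
    ``slope = kappa R^2 (1 - cos z1) / (L z1^2)``.
    """
    z1 = np.pi * R / L
    return 0.5 * kappa * 2.0 * R**2 * (1.0 - np.cos(z1)) / (L * z1**2)


def critical_lengths_1d(R: float = 0.75, L: float = 3.0) -> Tuple[float, float, float]:
    """Critical spring lengths ``(ell_c, ell_star, D_star)`` in 1D.

    ``ell_c``: largest spring length with a positive instability threshold;
    ``ell_star``: root of the bifurcation-type discriminant
    ``2 V-hat_2 - V-hat_1`` (supercritical for ``ell`` in
    ``(ell_star, ell_c)``, subcritical below); ``D_star``: instability
    threshold at ``ell_star``.
    """
    ell_c = R * critical_alpha(R=R, L=L, dim=1)

    def discriminant(ell: float) -> float:
        p = ModelParams(D=0.0, ell=ell, R=R, L=L)
        return 2.0 * fourier_mode_1d(2, p) - fourier_mode_1d(1, p)

    lo, hi = 1e-9, R * (1 - 1e-9)
    if discriminant(lo) * discriminant(hi) > 0:
        raise RuntimeError("bifurcation-type discriminant does not change sign in (0, R)")
    ell_star = brentq(discriminant, lo, hi, xtol=1e-12)
    D_star = critical_noise(ModelParams(D=0.0, ell=ell_star, R=R, L=L))
    return ell_c, ell_star, D_star


def noise_for_growth(lam: float, mode, params: ModelParams) -> float:
    """Noise intensity D at which the given mode grows at rate ``lam``.

    Inverts the dispersion relation:
    ``D = -V-hat_mode - lam L^2 / (pi^2 |mode|^2)``.  A negative return
    value (requested growth not attainable at non-negative noise) is
    flagged with a warning.
    """
    n2 = _mode_norm_sq(mode)
    if n2 == 0:
        raise ValueError("the zero (mass) mode has no dispersion relation")
    D = -fourier_mode(mode, params) - lam * params.L**2 / (np.pi**2 * n2)
    if D < 0:
        warnings.warn(
            f"growth rate {lam} is outside the attainable range (requires D = {D:.3e} < 0)",
            RuntimeWarning,
        )
    return D


def bifurcation_type_1d(params: ModelParams, boundary_tol: float = 1e-12) -> BifurcationClassification:
    """Classify the 1D bifurcation of the uniform state.

    Supercritical iff ``2 V-hat_2 - V-hat_1 > 0`` and subcritical iff
    ``< 0`` (the criterion involves the potential only, not D).  When no
    positive instability threshold exists the state is stable for all D.
    """
    disc = 2.0 * fourier_mode_1d(2, params) - fourier_mode_1d(1, params)
    D_c = critical_noise(params)
    if D_c == 0.0:
        regime = "stable"
    elif abs(disc) <= boundary_tol:
        regime = "degenerate"
    elif disc > 0:
        regime = "supercritical"
    else:
        regime = "subcritical"
    return BifurcationClassification(regime=regime, discriminant=disc, critical_noise=D_c)


def vstar_discriminant(
    alpha: float,
    ratio_RL: float,
    D: Optional[float] = None,
    L: float = 3.0,
    hypothesis_tol: float = 1e-12,
) -> VStarResult:
    """2D bifurcation-type discriminant ``V*`` with its (c, d) pair.

    ``V* = V-hat_10 (2 V-hat_20 - V-hat_10) |D + V-hat_11|
           + 4 (D + V-hat_20) |V-hat_10 V-hat_11|``;
    subcritical iff ``V* > 0`` (equivalently ``c > d`` when the higher
    modes are stable).  By default D is evaluated at the bifurcation
    crossing, ``D = -V-hat_{1,0}``.
    """
    R = ratio_RL * L
    p = ModelParams(D=0.0, ell=alpha * R, R=R, L=L, dim=2)
    v10 = fourier_mode_2d(1, 0, p)
    v20 = fourier_mode_2d(2, 0, p)
    v11 = fourier_mode_2d(1, 1, p)
    if D is None:
        D = -v10
    den_c, den_d = D + v20, D + v11
    if abs(den_c) < hypothesis_tol or abs(den_d) < hypothesis_tol:
        raise ArithmeticError(
            "higher-mode denominator vanishes: the bifurcation-criterion "
            f"hypothesis is violated (D+V20={den_c:.3e}, D+V11={den_d:.3e})"
        )
    c = v10 * (2.0 * v20 - v10) / den_c
    d = -abs(4.0 * v10 * v11 / den_d)
    vstar = v10 * (2.0 * v20 - v10) * abs(den_d) + 4.0 * den_c * abs(v10 * v11)
    regime = "subcritical" if vstar > 0 else "supercritical"
    return VStarResult(vstar=vstar, c=c, d=d, regime=regime, D_used=D)


def supercritical_window_2d(
    ratio_RL: float,
    L: float = 3.0,
    n_scan: int = 2000,
    alpha_tol: float = 1e-8,
) -> Optional[Tuple[float, float]]:
    """Maximal alpha-interval in ``(0, alpha_c)`` with a supercritical 2D bifurcation.

    Scans ``V*(alpha)`` (evaluated at the threshold noise) on a uniform
    grid and refines every sign change by bisection; returns the widest
    interval where ``V* < 0``, or ``None`` when ``V* > 0`` throughout.
    """
    if not 0 < ratio_RL <= 1:
        raise ValueError("ratio_RL must lie in (0, 1]")
    a_c = critical_alpha(R=ratio_RL * L, L=L, dim=2)
    grid = np.linspace(a_c * 1e-4, a_c * (1 - 1e-6), n_scan)
    vals = np.array([vstar_discriminant(a, ratio_RL, L=L).vstar for a in grid])

    def f(a: float) -> float:
        return vstar_discriminant(a, ratio_RL, L=L).vstar

    crossings = []
    for i in np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0):
        crossings.append(brentq(f, grid[i], grid[i + 1], xtol=alpha_tol))

    # assemble sign intervals over (0, alpha_c)
    edges = [grid[0]] + crossings + [grid[-1]]
    best: Optional[Tuple[float, float]] = None
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0 and (best is None or hi - lo > best[1] - best[0]):
            best = (lo, hi)
    if best is None:
        return None
    # snap outer edges that are not true roots to the scan boundary 0 / alpha_c
    lo, hi = best
    if lo == grid[0] and vals[0] < 0:
        lo = 0.0
    if hi == grid[-1] and vals[-1] < 0:
        hi = a_c
    return (lo, hi)


def amplitude_prediction(lam: float, params: ModelParams) -> AmplitudePrediction:
    """Weakly nonlinear saturation amplitude near a 1D supercritical threshold.

    For a distance-to-threshold growth rate ``lam >= 0`` of the first mode
    (with the noise set accordingly and the second-mode rate ``lambda_2``
    evaluated at that same noise), the critical-mode amplitude saturates at

        |A| = (sqrt(lam) L / (2 sqrt(2) pi^2))
              * sqrt(-lambda_2 / (-V-hat_1 (2 V-hat_2 - V-hat_1)))

    and the steady perturbation amplitude is estimated by

        |rho|_th = 2 |A| + lam L / (pi^2 (2 V-hat_2 - V-hat_1)).

    The second-harmonic coefficients are
    ``h_{+-2} = -(4 pi^2 / L) V-hat_{+-1} / (2 lam - lambda_2)``.
    """
    if lam < 0:
        raise ValueError("amplitude prediction requires lam >= 0")
    v1 = fourier_mode_1d(1, params)
    v2 = fourier_mode_1d(2, params)
    disc = 2.0 * v2 - v1
    if disc <= 0:
        raise ValueError("amplitude saturation requires the supercritical regime (2 V2 - V1 > 0)")
    if lam == 0.0:
        return AmplitudePrediction(lam=0.0, A_sat=0.0, rho_th=0.0, h2=0.0, h_minus2=0.0)
    L = params.L
    D = noise_for_growth(lam, 1, params)
    lam2 = growth_rate(2, D, params).growth_rate
    if abs(2.0 * lam - lam2) < 1e-15:
        raise ArithmeticError("second-harmonic denominator 2*lam - lambda_2 vanishes")
    A = (np.sqrt(lam) * L / (2.0 * np.sqrt(2.0) * np.pi**2)) * np.sqrt(
        (-lam2) / (-v1 * disc)
    )
    rho_th = 2.0 * A + lam * L / (np.pi**2 * disc)
    h2 = -(4.0 * np.pi**2 / L) * v1 / (2.0 * lam - lam2)
    return AmplitudePrediction(lam=lam, A_sat=A, rho_th=rho_th, h2=h2, h_minus2=h2)
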