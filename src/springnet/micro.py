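"""Stochastic particle simulator: overdamped dynamics with transient spring links.

One-dimensional particles on the periodic interval [-L, L) follow
Euler-Maruyama dynamics

    X_i(t + dt) = X_i(t) - grad_i W dt + sqrt(2 D dt) N(0, 1),

where W sums the spring energies of the currently active links.  Links
between unlinked pairs closer than the detection radius R are created with
probability ``P_f = 1 - exp(-nu_f dt / ((N-1) eps^2))`` per step and
existing links destroyed with probability
``P_d = 1 - exp(-nu_d dt / eps^2)`` (at most one link per pair).  The
1/(N-1) factor sits in the creation rate only: the kinetic limit defines
``nu_f = lim nu_f^N (N-1)`` but ``nu_d = lim nu_d^N``, so per-pair
creation scales with the pair count while destruction does not.  This
makes the stationary per-pair link probability
``nu_f / (nu_f + nu_d (N-1))`` and keeps the link-to-particle ratio K/N
of order one.

In the instantaneous-relinking limit ``eps = 0`` no link state survives:
every pair within R interacts, with the mean-field drift

    drift_i = -(nu_f / nu_d) / (N - 1) * sum_{j != i, |d_ij| <= R} grad V(d_ij).

The 1/(N-1) normalisation matches both the stationary per-pair link
probability ``nu_f / (nu_f + nu_d (N-1))`` of the finite-eps process and
the mass-one density convention of the macroscopic equation, so that the
empirical density converges to the aggregation-diffusion solution as
N grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Set, Tuple

import numba
import numpy as np

from .params import ModelParams
from .macro1d import DensityField1D, order_parameter

__all__ = [
    "MicroConfig",
    "ParticleState",
    "LinkSet",
    "EnsembleResult",
    "sample_initial",
    "initialize_links",
    "update_links",
    "forces",
    "adaptive_dt",
    "step",
    "estimate_density",
    "recenter",
    "run",
    "run_single",
]

# Per-step cap on the link-event probability scale for eps > 0: dt is held
# below c_eps * eps^2 / max(nu_f, nu_d) so per-pair probabilities stay
# below 1 - exp(-c_eps).
C_EPS = 0.1


@dataclass(frozen=True)
class MicroConfig:
    """Numerical controls of the particle simulator (scaled units)."""

    N: int = 1000
    epsilon: float = 0.0        # 0 selects the instantaneous-relinking model
    dt_max: float = 0.01
    delta_step: float = 0.1     # cap on per-step deterministic displacement
    T_f: float = 20.0
    n_bins: int = 64
    n_replicates: int = 6
    xi_init: float = 0.1        # initial link-to-particle ratio K/N
    seed: int = 0

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("need at least two particles")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.T_f <= 0 or self.dt_max <= 0 or self.delta_step <= 0:
            raise ValueError("time controls must be positive")
        if self.n_bins < 2:
            raise ValueError("need at least two histogram bins")


@dataclass
class ParticleState:
    positions: np.ndarray
    time: float = 0.0

    @property
    def N(self) -> int:
        return self.positions.size


@dataclass
class LinkSet:
    """Unordered pairs (i < j) currently connected by a spring; one link per pair."""

    pairs: Set[Tuple[int, int]] = field(default_factory=set)

    @property
    def K(self) -> int:
        return len(self.pairs)

    def add(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError("a particle cannot link to itself")
        self.pairs.add((min(i, j), max(i, j)))


@dataclass
class EnsembleResult:
    """Ensemble output: per-replicate order parameters and mean densities."""

    bin_centers: np.ndarray
    mean_density: np.ndarray       # recentered ensemble mean at the final save time
    Q: np.ndarray                  # per replicate, at the final save time
    snapshot_times: np.ndarray
    snapshot_densities: np.ndarray             # (n_times, n_bins) ensemble mean
    seeds: np.ndarray


def _wrap(x: np.ndarray, L: float) -> np.ndarray:
    return (x + L) % (2.0 * L) - L


def _min_image(d, L: float):
    return d - 2.0 * L * np.rint(d / (2.0 * L))


def sample_initial(delta: float, config: MicroConfig, params: ModelParams,
                   rng: Optional[np.random.Generator] = None) -> ParticleState:
    """Draw N positions from ``f0 = 1/(2L) + delta cos(pi x / L)``.

    Inverse-CDF sampling on a fine grid; reproducible given the generator.
    """
    L = params.L
    if not 0 <= delta < 1.0 / (2.0 * L):
        raise ValueError("delta must satisfy 0 <= delta < 1/(2L)")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    grid = np.linspace(-L, L, 8193)
    cdf = (grid + L) / (2.0 * L) + delta * L / np.pi * (np.sin(np.pi * grid / L) + 0.0)
    cdf -= cdf[0]
    cdf /= cdf[-1]
    u = rng.random(config.N)
    positions = np.interp(u, cdf, grid)
    return ParticleState(positions=_wrap(positions, L), time=0.0)


def initialize_links(state: ParticleState, config: MicroConfig,
                     params: ModelParams,
                     rng: Optional[np.random.Generator] = None) -> LinkSet:
    """Draw ``K = round(xi_init N)`` links uniformly among pairs within R."""
    if config.epsilon <= 0:
        raise ValueError("the eps = 0 limit carries no link state")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x = state.positions
    d = np.abs(_min_image(x[:, None] - x[None, :], params.L))
    iu, ju = np.triu_indices(state.N, k=1)
    eligible = np.flatnonzero(d[iu, ju] <= params.R)
    K = int(round(config.xi_init * state.N))
    if K > eligible.size:
        K = eligible.size
    chosen = rng.choice(eligible, size=K, replace=False)
    links = LinkSet()
    for idx in chosen:
        links.add(int(iu[idx]), int(ju[idx]))
    return links


def _event_probabilities(dt: float, N: int, epsilon: float,
                         params: ModelParams) -> Tuple[float, float]:
    p_f = 1.0 - np.exp(-params.nu_f * dt / ((N - 1) * epsilon**2))
    p_d = 1.0 - np.exp(-params.nu_d * dt / epsilon**2)
    return p_f, p_d


def update_links(links: LinkSet, state: ParticleState, dt: float,
                 config: MicroConfig, params: ModelParams,
                 rng: np.random.Generator) -> LinkSet:
    """One linking/unlinking sweep over all pairs (finite eps only).

    Existing links break with probability ``P_d``; unlinked pairs within R
    gain a link with probability ``P_f``.  Events are independent within
    the step.
    """
    if config.epsilon <= 0:
        raise ValueError("link updates require epsilon > 0")
    p_f, p_d = _event_probabilities(dt, state.N, config.epsilon, params)
    x = state.positions
    d = np.abs(_min_image(x[:, None] - x[None, :], params.L))
    new = LinkSet()
    # destruction sweep
    for (i, j) in links.pairs:
        if rng.random() >= p_d:
            new.pairs.add((i, j))
    # creation sweep over unlinked close pairs
    iu, ju = np.triu_indices(state.N, k=1)
    close = d[iu, ju] <= params.R
    for i, j in zip(iu[close], ju[close]):
        pair = (int(i), int(j))
        if pair not in links.pairs and rng.random() < p_f:
            new.pairs.add(pair)
    return new


def forces(state: ParticleState, links: Optional[LinkSet],
           config: MicroConfig, params: ModelParams) -> np.ndarray:
    """Per-particle drift.

    Finite eps (``links`` given): minus the gradient of the summed spring
    energies of the active links.  eps = 0 (``links`` is None): mean-field
    sum over all neighbours within R with the 1/(N-1) normalisation.
    """
    x = state.positions
    N = state.N
    drift = np.zeros(N)
    kappa, ell, L, R = params.kappa, params.ell, params.L, params.R
    if links is not None:
        for (i, j) in links.pairs:
            d = _min_image(x[i] - x[j], L)
            r = abs(d)
            if r == 0:
                continue
            g = kappa * (r - ell) * d / r
            drift[i] -= g
            drift[j] += g
        return drift
    pref = params.nu_f / (params.nu_d * (N - 1))
    d = _min_image(x[:, None] - x[None, :], L)
    r = np.abs(d)
    np.fill_diagonal(r, np.inf)
    g = np.zeros_like(d)
    mask = r <= R
    g[mask] = kappa * (r[mask] - ell) * np.sign(d[mask])
    return -pref * g.sum(axis=1)


def adaptive_dt(drift: np.ndarray, config: MicroConfig, params: ModelParams) -> float:
    """Time step: caps from dt_max, the displacement bound, and link events."""
    dt = config.dt_max
    md = float(np.max(np.abs(drift))) if drift.size else 0.0
    if md > 0:
        dt = min(dt, config.delta_step / md)
    if config.epsilon > 0:
        dt = min(dt, C_EPS * config.epsilon**2 / max(params.nu_f, params.nu_d))
    return dt


def step(state: ParticleState, links: Optional[LinkSet], config: MicroConfig,
         params: ModelParams, rng: np.random.Generator,
         dt: Optional[float] = None) -> Tuple[ParticleState, Optional[LinkSet]]:
    """One Euler-Maruyama update followed by a link sweep (finite eps)."""
    drift = forces(state, links, config, params)
    if dt is None:
        dt = adaptive_dt(drift, config, params)
    noise = rng.standard_normal(state.N)
    newx = _wrap(state.positions + drift * dt + np.sqrt(2.0 * params.D * dt) * noise,
                 params.L)
    new_state = ParticleState(positions=newx, time=state.time + dt)
    if links is not None:
        links = update_links(links, new_state, dt, config, params, rng)
    return new_state, links


def estimate_density(state_or_positions, n_bins: int, L: float) -> DensityField1D:
    """Histogram density on ``n_bins`` equal boxes over [-L, L], unit mass.

    ``f_i = N_i / (N dx)`` so that the (periodic trapezoid = midpoint)
    integral of the returned density is exactly 1.
    """
    if n_bins < 2:
        raise ValueError("need at least two bins")
    x = state_or_positions.positions if isinstance(state_or_positions, ParticleState) \
        else np.asarray(state_or_positions)
    counts, edges = np.histogram(x, bins=n_bins, range=(-L, L))
    dx = 2.0 * L / n_bins
    return DensityField1D(values=counts / (x.size * dx), L=L)


def recenter(state_or_positions, L: float):
    """Shift positions so the circular mean sits at the origin.

    The circular mean is ``X_m = (L/pi) arg( (1/2) sum_j exp(i pi X_j / L) )``;
    all particles are shifted by ``-X_m`` with periodic wrapping (the
    two-branch unwrapping rule is equivalent to wrapping into [-L, L)).
    Degenerate (vanishing-resultant) configurations are returned unchanged.
    """
    st = isinstance(state_or_positions, ParticleState)
    x = state_or_positions.positions if st else np.asarray(state_or_positions, dtype=float)
    resultant = 0.5 * np.mean(np.exp(1j * np.pi * x / L)) * 2.0
    if abs(resultant) < 1e-12:
        import warnings
        warnings.warn("vanishing circular resultant: recentering skipped", RuntimeWarning)
        out = x.copy()
    else:
        x_m = L / np.pi * np.angle(0.5 * np.sum(np.exp(1j * np.pi * x / L)))
        out = _wrap(x - x_m, L)
    if st:
        return ParticleState(positions=out, time=state_or_positions.time)
    return out


@numba.njit(cache=True)
def _drive_meanfield(x, L, R, ell, kappa, pref, D, dt_max, delta_step,
                     save_times, saved, seed):  # pragma: no cover
    """Mean-field (eps = 0) run loop; positions stored at each save time.

    Neighbour pairs are found by sorting the positions each step and
    walking rightwards (with periodic wrap) until the separation exceeds
    R, so the force sweep costs O(N * neighbours) instead of O(N^2).
    """
    np.random.seed(seed)
    N = x.size
    twoL = 2.0 * L
    t = 0.0
    n_save = save_times.size
    k_save = 0
    t_final = save_times[n_save - 1]
    drift = np.empty(N)
    while t < t_final:
        for i in range(N):
            drift[i] = 0.0
        order = np.argsort(x)
        xs = x[order]
        for a in range(N):
            xa = xs[a]
            for boff in range(1, N):
                b = a + boff
                if b < N:
                    xb = xs[b]
                    bi = b
                else:
                    xb = xs[b - N] + twoL
                    bi = b - N
                sep = xb - xa
                if sep > R:
                    break
                if sep > 0.0:
                    # a sits left of b: force is +kappa (sep - ell) on a
                    g = pref * kappa * (sep - ell)
                    drift[order[a]] += g
                    drift[order[bi]] -= g
        md = 0.0
        for i in range(N):
            if abs(drift[i]) > md:
                md = abs(drift[i])
        dt = dt_max
        if md > 0.0 and delta_step / md < dt:
            dt = delta_step / md
        if t + dt > save_times[k_save]:
            dt = save_times[k_save] - t
        amp = np.sqrt(2.0 * D * dt)
        for i in range(N):
            xn = x[i] + drift[i] * dt + amp * np.random.standard_normal()
            xn = (xn + L) % twoL - L
            x[i] = xn
        t += dt
        if t >= save_times[k_save] - 1e-12:
            for i in range(N):
                saved[k_save, i] = x[i]
            k_save += 1
            if k_save >= n_save:
                break
    return t


def run_single(config: MicroConfig, params: ModelParams, delta: float,
               seed: int, save_times: Sequence[float]) -> np.ndarray:
    """One replicate; returns positions at each save time, shape (n_times, N).

    eps = 0 uses the JIT-compiled mean-field loop; finite eps runs the
    link-resolved dynamics through the step operation.
    """
    rng = np.random.default_rng(seed)
    state = sample_initial(delta, config, params, rng)
    save_times = np.asarray(save_times, dtype=float)
    if np.any(np.diff(save_times) <= 0) or save_times[0] <= 0:
        raise ValueError("save times must be positive and increasing")
    saved = np.empty((save_times.size, config.N))
    if config.epsilon == 0:
        pref = params.nu_f / (params.nu_d * (config.N - 1))
        _drive_meanfield(
            state.positions, params.L, params.R, params.ell, params.kappa,
            pref, params.D, config.dt_max, config.delta_step,
            save_times, saved, seed % 2**31,
        )
        return saved
    links = initialize_links(state, config, params, rng)
    k = 0
    while k < save_times.size:
        drift = forces(state, links, config, params)
        dt = min(adaptive_dt(drift, config, params), save_times[k] - state.time)
        state, links = step(state, links, config, params, rng, dt=dt)
        if state.time >= save_times[k] - 1e-12:
            saved[k] = state.positions
            k += 1
    return saved


def run(config: MicroConfig, params: ModelParams, delta: float = 0.01,
        save_times: Optional[Sequence[float]] = None) -> EnsembleResult:
    """Ensemble of replicates; recentered mean densities at each save time
    and per-replicate order parameters at the last one (default ``T_f``)."""
    if save_times is None:
        save_times = [config.T_f]
    save_times = sorted(save_times)
    ss = np.random.SeedSequence(config.seed)
    seeds = np.array([int(s.generate_state(1)[0] % 2**31)
                      for s in ss.spawn(config.n_replicates)])
    n_t = len(save_times)
    dens_acc = np.zeros((n_t, config.n_bins))
    Qs = np.empty(config.n_replicates)
    centers = None
    for r, seed in enumerate(seeds):
        traj = run_single(config, params, delta, int(seed), save_times)
        for k in range(n_t):
            fld = estimate_density(recenter(traj[k], params.L), config.n_bins, params.L)
            dens_acc[k] += fld.values
            if centers is None:
                centers = fld.centers
            if k == n_t - 1:
                Qs[r] = order_parameter(fld)
    dens_acc /= config.n_replicates
    return EnsembleResult(
        bin_centers=centers,
        mean_density=dens_acc[-1],
        Q=Qs,
        snapshot_times=np.asarray(save_times),
        snapshot_densities=dens_acc,
        seeds=seeds,
    )
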