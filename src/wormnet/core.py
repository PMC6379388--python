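"""Core model definitions and reference dynamics.

The model describes N point particles on a periodic square of side L.
Each particle i carries a position r_i, a heading theta_i and a rotation
rate omega_i.  Active particles self-propel at unit speed along their
heading; all particles experience a short-range linear repulsion (the
excluded volume of a worm body), a longer-range 1/r attraction (the
surface tension of the water film that glues colliding worms together)
and a nematic alignment torque from neighbours in the attraction shell.
The rotation rate is an Ornstein--Uhlenbeck process with mean ``omega0``,
stationary standard deviation ``sigma_omega`` and correlation time
``tau`` -- the "smooth turning with memory" seen in isolated dauer
larvae.

Equations of motion (dimensionless units: half a body length, and the
time to travel half a body length):

    dr_i/dt     = a_i e(theta_i) + sum_{r_ij < r_r} F_r(ij)
                                 + sum_{r_r < r_ij < 1} F_a(ij)
    dtheta_i/dt = a_i omega_i + (1/N_i) sum_{r_r < r_ij < 1}
                                        sin 2(theta_j - theta_i)
    domega_i/dt = -(omega_i - omega0)/tau + sqrt(2/tau) sigma_omega xi_i

with F_r(ij) = k_r (r_ij - r_r) e_ij  (repulsive for r_ij < r_r) and
F_a(ij) = (k_a / r_ij) e_ij, where e_ij points from i to j.  The
activity flag a_i in {0, 1} implements the optogenetics-style protocol:
an inactive particle neither self-propels nor applies its intrinsic
rotation rate, but it still exerts/receives forces and still aligns.

This module holds the parameter/state containers and a plain-NumPy
all-pairs reference implementation of the interactions and of a single
Euler--Maruyama step.  The reference path is the correctness oracle for
the fast cell-list engine in :mod:`wormnet.engine`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "ParticleState",
    "ActivitySchedule",
    "Trajectory",
    "minimum_image",
    "pair_repulsion",
    "pair_attraction",
    "alignment_rate",
    "all_pairs_interactions",
    "ou_increment",
    "step",
]

#: below this separation two particles are treated as coincident and
#: pushed apart along an arbitrary (index-derived) direction
COINCIDENCE_TOL = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """All constants of the particle model plus integration settings.

    Defaults are the wild-type operating point: rotation-rate statistics
    estimated from single-worm tracks converted to simulation units
    (omega0 = 0.0035, sigma_omega = 0.35, tau = 10), repulsion fixed at
    (k_r, r_r) = (10, 0.2), Euler time step 0.001.  ``k_a`` has no
    universal default in the model -- it is the humidity-like control
    parameter -- so it must be given.
    """

    k_a: float
    k_r: float = 10.0
    r_r: float = 0.2
    omega0: float = 0.0035
    sigma_omega: float = 0.35
    tau: float = 10.0
    dt: float = 0.001
    box_side: float = 64.0
    n_particles: int | None = None
    density: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.r_r < 1.0):
            raise ValueError(f"r_r must lie in (0, 1), got {self.r_r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.dt >= self.tau:
            raise ValueError("explicit scheme requires dt < tau")
        if self.sigma_omega < 0 or self.k_r < 0 or self.k_a < 0:
            raise ValueError("k_a, k_r and sigma_omega must be non-negative")
        if self.box_side <= 2.0:
            raise ValueError(
                "box_side must exceed 2 so the minimum image is unambiguous "
                "for the unit interaction radius"
            )
        if self.n_particles is None and self.density is None:
            raise ValueError("give either n_particles or density")
        if self.n_particles is not None and self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")

    @property
    def n(self) -> int:
        """Particle count; derived from density when not given directly."""
        if self.n_particles is not None:
            return int(self.n_particles)
        return int(round(self.density * self.box_side**2))

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class ParticleState:
    """Snapshot of all particles at one instant.

    Headings are stored unwrapped (on the real line) so that rotation
    statistics and the track estimator see a continuous theta(t);
    positions are always wrapped into [0, L).
    """

    t: float
    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    omega: np.ndarray
    active: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.x)
        for name in ("y", "theta", "omega", "active"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array length mismatch in field {name!r}")
        for name in ("x", "y", "theta", "omega"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in field {name!r}")

    @property
    def n(self) -> int:
        return len(self.x)

    def copy(self) -> "ParticleState":
        return ParticleState(
            self.t,
            self.x.copy(),
            self.y.copy(),
            self.theta.copy(),
            self.omega.copy(),
            self.active.copy(),
        )


@dataclass(frozen=True)
class ActivitySchedule:
    """Time windows during which a fraction of particles is inactive.

    ``intervals`` is a sequence of ``(t_start, t_end, inactive_fraction)``
    triples.  Particles to inactivate are drawn uniformly at random at
    the start of each interval and kept fixed for its duration; at
    ``t_end`` every particle is reactivated.
    """

    intervals: tuple = ()

    def __post_init__(self) -> None:
        ivals = tuple(tuple(iv) for iv in self.intervals)
        object.__setattr__(self, "intervals", ivals)
        prev_end = -np.inf
        for t0, t1, frac in ivals:
            if t1 <= t0:
                raise ValueError("interval end must exceed start")
            if t0 < prev_end:
                raise ValueError("schedule intervals must not overlap")
            if not (0.0 <= frac < 1.0):
                raise ValueError("inactive_fraction must lie in [0, 1)")
            prev_end = t1

    def boundaries(self) -> list[float]:
        out: list[float] = []
        for t0, t1, _ in self.intervals:
            out.extend((t0, t1))
        return out


@dataclass
class Trajectory:
    """Sequence of snapshots at a fixed output interval, with provenance."""

    params: ModelParams
    states: list = field(default_factory=list)
    delta_out: float = 1.0
    schedule: ActivitySchedule = field(default_factory=ActivitySchedule)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    def __len__(self) -> int:
        return len(self.states)


# ---------------------------------------------------------------------------
# reference (all-pairs) interaction terms


def minimum_image(pos_i, pos_j, box_side: float) -> np.ndarray:
    """Displacement r_j - r_i with each component folded into (-L/2, L/2]."""
    pos_i = np.asarray(pos_i, dtype=float)
    pos_j = np.asarray(pos_j, dtype=float)
    if not (np.all(np.isfinite(pos_i)) and np.all(np.isfinite(pos_j))):
        raise ValueError("non-finite position")
    d = pos_j - pos_i
    d -= box_side * np.round(d / box_side)
    # np.round maps +/-L/2 ties to the even multiple; force +L/2 convention
    d = np.where(d == -box_side / 2, box_side / 2, d)
    return d


def pair_repulsion(d: np.ndarray, k_r: float, r_r: float) -> np.ndarray:
    """Linear-spring excluded-volume force of j on i, F = k_r (r - r_r) e_ij.

    The coefficient is negative inside the repulsion radius, so the force
    points away from the neighbour.
    """
    r = float(np.hypot(*d))
    if r >= r_r:
        raise ValueError(f"pair_repulsion called outside repulsion shell (r={r})")
    if r < COINCIDENCE_TOL:
        raise ValueError("coincident particles: direction undefined at this level")
    return k_r * (r - r_r) * (np.asarray(d, dtype=float) / r)


def pair_attraction(d: np.ndarray, k_a: float, r_r: float = 0.2) -> np.ndarray:
    """Surface-tension-like attraction of j on i, F = (k_a / r) e_ij."""
    r = float(np.hypot(*d))
    if not (r_r < r < 1.0):
        raise ValueError(f"pair_attraction called outside attraction shell (r={r})")
    return (k_a / r**2) * np.asarray(d, dtype=float)


def alignment_rate(theta_i: float, neighbor_headings) -> float:
    """Mean nematic torque (1/N_i) sum sin 2(theta_j - theta_i); 0 if no neighbours."""
    nb = np.asarray(neighbor_headings, dtype=float)
    if nb.size == 0:
        return 0.0
    return float(np.mean(np.sin(2.0 * (nb - theta_i))))


def _coincident_direction(i: int, j: int) -> tuple[float, float]:
    """Arbitrary but deterministic unit vector used when r_ij ~ 0."""
    ang = 2.0 * np.pi * (((i * 2654435761 + j * 40503) % 8191) / 8191.0)
    return float(np.cos(ang)), float(np.sin(ang))


def all_pairs_interactions(
    x: np.ndarray,
    y: np.ndarray,
    theta: np.ndarray,
    params: ModelParams,
):
    """O(N^2) evaluation of force sums and alignment rates for every particle.

    Returns ``(fx, fy, align)`` where ``align`` is already normalised by the
    neighbour count.  This is the oracle the cell-list engine is tested
    against.
    """
    n = len(x)
    L = params.box_side
    fx = np.zeros(n)
    fy = np.zeros(n)
    al = np.zeros(n)
    cnt = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[j] - x[i]
            dy = y[j] - y[i]
            dx -= L * np.round(dx / L)
            dy -= L * np.round(dy / L)
            r2 = dx * dx + dy * dy
            if r2 >= 1.0:
                continue
            r = np.sqrt(r2)
            if r > params.r_r:
                coef = params.k_a / r2
                fx[i] += coef * dx
                fy[i] += coef * dy
                fx[j] -= coef * dx
                fy[j] -= coef * dy
                a = np.sin(2.0 * (theta[j] - theta[i]))
                al[i] += a
                al[j] -= a
                cnt[i] += 1
                cnt[j] += 1
            elif r >= COINCIDENCE_TOL:
                coef = params.k_r * (r - params.r_r) / r
                fx[i] += coef * dx
                fy[i] += coef * dy
                fx[j] -= coef * dx
                fy[j] -= coef * dy
            else:
                ux, uy = _coincident_direction(i, j)
                mag = params.k_r * params.r_r
                fx[i] -= mag * ux
                fy[i] -= mag * uy
                fx[j] += mag * ux
                fy[j] += mag * uy
    align = np.where(cnt > 0, al / np.maximum(cnt, 1), 0.0)
    return fx, fy, align


def ou_increment(
    omega: np.ndarray,
    params: ModelParams,
    gauss: np.ndarray,
) -> np.ndarray:
    """One Euler--Maruyama update of the rotation-rate OU process.

    omega' = omega - (omega - omega0) dt/tau + sigma_omega sqrt(2 dt/tau) xi

    With this discretisation the stationary law is N(omega0, sigma_omega^2)
    up to O(dt/tau) and the autocorrelation time is tau.
    """
    dt, tau = params.dt, params.tau
    return (
        omega
        - (omega - params.omega0) * (dt / tau)
        + params.sigma_omega * np.sqrt(2.0 * dt / tau) * np.asarray(gauss)
    )


def step(
    state: ParticleState,
    params: ModelParams,
    rng: np.random.Generator | None = None,
    noise: np.ndarray | None = None,
) -> ParticleState:
    """One explicit Euler step of the full model (all-pairs reference path).

    All right-hand sides are evaluated at the incoming state.  ``noise``
    may supply the N standard-normal draws explicitly (used by symmetry
    tests that need a shared noise stream); otherwise they come from
    ``rng``.
    """
    if noise is None:
        if rng is None:
            raise ValueError("provide rng or noise")
        noise = rng.standard_normal(state.n)
    noise = np.asarray(noise, dtype=float)
    dt = params.dt
    L = params.box_side
    a = state.active.astype(float)
    fx, fy, align = all_pairs_interactions(state.x, state.y, state.theta, params)
    vx = a * np.cos(state.theta) + fx
    vy = a * np.sin(state.theta) + fy
    x = np.mod(state.x + dt * vx, L)
    y = np.mod(state.y + dt * vy, L)
    theta = state.theta + dt * (a * state.omega + align)
    omega = ou_increment(state.omega, params, noise)
    new = ParticleState(state.t + dt, x, y, theta, omega, state.active.copy())
    return new
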