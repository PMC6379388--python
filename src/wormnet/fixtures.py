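"""Synthetic inputs with known ground truth.

Every generator here is deterministic under a fixed seed and returns its
ground-truth parameters alongside the data, so the estimators and the
image pipeline can be validated without any external recordings.  The
default parameters of the track generator reproduce the wild-type dauer
regime measured by single-worm tracking (v0 = 87 um/s, omega0 =
1.4e-3 rad/s, sigma_omega = 0.155 rad/s, tau = 27 s, 38 tracks of 60
points at 0.21669 s), so tests exercise the estimator in the data regime
it is meant for.
"""

from __future__ import annotations

import numpy as np

from .core import ActivitySchedule, ModelParams, ParticleState, Trajectory
from .engine import simulate
from .estimation import TrackSet

__all__ = [
    "make_ou_tracks",
    "make_lattice_image",
    "make_collision_pair",
    "make_lognormal_sizes",
    "make_uniform_gas",
]

#: wild-type dauer operating point (micrometres, seconds)
DAUER_TRACK_DEFAULTS = dict(
    v0=87.0,
    omega0=1.4e-3,
    sigma_omega=0.155,
    tau=27.0,
    dt=0.21669,
    n_tracks=38,
    n_points=60,
)


def make_ou_tracks(
    v0: float = 87.0,
    omega0: float = 1.4e-3,
    sigma_omega: float = 0.155,
    tau: float = 27.0,
    dt: float = 0.21669,
    n_tracks: int = 38,
    n_points: int = 60,
    seed: int = 0,
    substeps: int = 20,
) -> tuple[TrackSet, dict]:
    """Smooth-turning walker tracks with OU rotation-rate memory.

    Each track integrates  theta' = omega,  omega' = OU(omega0,
    sigma_omega, tau),  r' = v0 e(theta)  by Euler--Maruyama at a fine
    step dt/substeps and samples positions every dt.  Rotation rates
    start in the stationary law.  With ``sigma_omega = 0`` the exact
    closed form is used instead: a circle of radius v0/|omega0| (or a
    straight line when omega0 = 0).

    Returns ``(tracks, truth)`` where ``truth`` records the generating
    parameters.
    """
    if v0 <= 0 or tau <= 0 or dt <= 0 or sigma_omega < 0:
        raise ValueError("parameters out of range")
    rng = np.random.default_rng(seed)
    truth = dict(
        v0=v0, omega0=omega0, sigma_omega=sigma_omega, tau=tau,
        dt=dt, n_tracks=n_tracks, n_points=n_points, seed=seed,
    )
    t = np.arange(n_points) * dt
    pos = np.empty((n_tracks, n_points, 2))
    theta0 = rng.uniform(-np.pi, np.pi, n_tracks)
    if sigma_omega == 0.0:
        for i in range(n_tracks):
            th = theta0[i] + omega0 * t
            if omega0 == 0.0:
                pos[i, :, 0] = v0 * t * np.cos(theta0[i])
                pos[i, :, 1] = v0 * t * np.sin(theta0[i])
            else:
                R = v0 / omega0
                pos[i, :, 0] = R * (np.sin(th) - np.sin(theta0[i]))
                pos[i, :, 1] = -R * (np.cos(th) - np.cos(theta0[i]))
        return TrackSet(pos, dt), truth
    h = dt / substeps
    n_fine = (n_points - 1) * substeps
    for i in range(n_tracks):
        th = theta0[i]
        om = rng.normal(omega0, sigma_omega)
        xi = rng.standard_normal(n_fine)
        x = y = 0.0
        pos[i, 0] = (0.0, 0.0)
        amp = sigma_omega * np.sqrt(2.0 * h / tau)
        for k in range(n_fine):
            x += v0 * np.cos(th) * h
            y += v0 * np.sin(th) * h
            th += om * h
            om += -(om - omega0) * h / tau + amp * xi[k]
            if (k + 1) % substeps == 0:
                pos[i, (k + 1) // substeps] = (x, y)
    return TrackSet(pos, dt), truth


def make_lattice_image(
    n_cells: int | tuple = 3,
    cell_side_px: int = 10,
    line_width_px: int = 1,
    pad_px: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed rectangular grid of lines with known enclosed areas.

    Returns ``(mask, true_areas)``: a boolean image whose True pixels are
    the grid lines, and the exact pixel areas of the n_x * n_y enclosed
    cells (each ``cell_side_px**2``).  The oracle for compartment
    measurement.
    """
    if isinstance(n_cells, int):
        ny = nx = n_cells
    else:
        ny, nx = n_cells
    if min(ny, nx) < 1 or cell_side_px < 1 or line_width_px < 1 or pad_px < 0:
        raise ValueError("sizes must be positive (pad may be zero)")
    w, c = line_width_px, cell_side_px
    H = ny * (c + w) + w
    W = nx * (c + w) + w
    mask = np.zeros((H + 2 * pad_px, W + 2 * pad_px), dtype=bool)
    grid = np.zeros((H, W), dtype=bool)
    for k in range(ny + 1):
        r = k * (c + w)
        grid[r : r + w, :] = True
    for k in range(nx + 1):
        col = k * (c + w)
        grid[:, col : col + w] = True
    mask[pad_px : pad_px + H, pad_px : pad_px + W] = grid
    areas = np.full(ny * nx, float(c * c))
    return mask, areas


def make_collision_pair(
    incoming_angle: float,
    params: ModelParams | None = None,
    seed: int = 0,
    approach_distance: float = 3.0,
    impact_parameter: float = 0.1,
    duration: float = 30.0,
    delta_out: float = 0.2,
    noiseless: bool = False,
) -> Trajectory:
    """Two-particle collision at a prescribed incoming angle.

    The particles start ``approach_distance`` from the domain centre on
    converging straight-line courses whose headings differ by
    ``incoming_angle``; a small impact parameter offsets one course so
    the encounter is generic rather than perfectly head-on.
    ``noiseless=True`` zeroes sigma_omega and omega0 for deterministic
    reference collisions.
    """
    if not (0.0 < incoming_angle < np.pi):
        raise ValueError("incoming angle must lie in (0, pi)")
    if params is None:
        params = ModelParams(k_a=0.002, box_side=32.0, n_particles=2)
    params = params.with_(n_particles=2, density=None, seed=seed)
    if noiseless:
        params = params.with_(sigma_omega=0.0, omega0=0.0)
    L = params.box_side
    cx = cy = L / 2.0
    half = incoming_angle / 2.0
    # initial pair separation is 2 d sin(half): enlarge d at shallow
    # angles so the particles start outside the interaction radius
    approach_distance = max(approach_distance, 0.75 / np.sin(half))
    if approach_distance > 0.4 * L:
        raise ValueError("box too small for this incoming angle")
    headings = np.array([half, -half])
    x = np.array(
        [cx - approach_distance * np.cos(half),
         cx - approach_distance * np.cos(half)]
    )
    y = np.array(
        [cy - approach_distance * np.sin(half),
         cy + approach_distance * np.sin(half) + impact_parameter]
    )
    omega = np.full(2, params.omega0)
    state = ParticleState(
        0.0, x, y, headings.copy(), omega, np.ones(2)
    )
    return simulate(
        params, duration, delta_out=delta_out, state=state, seed=seed
    )


def make_lognormal_sizes(
    mu: float, sigma: float, n: int, seed: int = 0
) -> np.ndarray:
    """I.i.d. log-normal sample: ln(size) ~ N(mu, sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    return np.exp(rng.normal(mu, sigma, n))


def make_uniform_gas(
    n: int, box_side: float, seed: int = 0, k_a: float = 0.002
) -> tuple[ParticleState, ModelParams]:
    """Random uniform particle configuration for interaction/property tests."""
    params = ModelParams(
        k_a=k_a, box_side=box_side, n_particles=n, seed=seed
    )
    rng = np.random.default_rng(seed)
    state = ParticleState(
        0.0,
        rng.uniform(0, box_side, n),
        rng.uniform(0, box_side, n),
        rng.uniform(-np.pi, np.pi, n),
        rng.normal(params.omega0, params.sigma_omega, n),
        np.ones(n),
    )
    return state, params
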